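"""Genome model: parsing, coordinate arithmetic, spacers, validation, I/O."""

import pytest

from mitoarch.io import ParseError, parse_feature_table, read_fasta, read_genbank, write_feature_table, write_genbank
from mitoarch.model import (
    AnnotatedGenome,
    FeatureClass,
    GeneFeature,
    extract_feature_sequence,
    feature_length,
    feature_positions,
    intergenic_regions,
    spacer_summary,
    validate_annotation,
)

HEADER = "gene\tdirection\tposition\tsize\tanticodon\tstart_codon\tstop_codon\n"


class TestParseFeatureTable:
    def test_published_table_counts(self, cf_genome):
        g = cf_genome
        assert g.genome_length == 20456
        assert len(g.features_of_class(FeatureClass.PCG)) == 13
        assert len(g.features_of_class(FeatureClass.tRNA)) == 22
        assert len(g.features_of_class(FeatureClass.rRNA)) == 2
        assert len(g.features_of_class(FeatureClass.control_region)) == 1
        assert len(g.features_of_class(FeatureClass.repeat_region)) == 1
        # table-derived strand tallies (text says 17/5; the table itself gives 16/6)
        trnas = g.features_of_class(FeatureClass.tRNA)
        assert sum(1 for f in trnas if f.strand == "+") == 16
        assert sum(1 for f in trnas if f.strand == "-") == 6

    @pytest.mark.parametrize("dash", ["-", "–", "—"])
    def test_single_row_and_dash_dialects(self, dash):
        g = parse_feature_table(HEADER + f"trnM\tF\t1{dash}68\t68\t31{dash}33 CAT\t-\t-\n")
        (f,) = g.features
        assert f.klass is FeatureClass.tRNA
        assert (f.start, f.end) == (1, 68)
        assert feature_length(f, g.genome_length) == 68
        assert f.anticodon == "CAT"
        assert (f.anticodon_start, f.anticodon_end) == (31, 33)

    def test_thousands_separators_normalized(self):
        g = parse_feature_table(HEADER + "rrnL\tR\t1,334-2,500\t-\t-\t-\t-\n")
        assert g.features[0].start == 1334

    def test_empty_table_errors(self):
        with pytest.raises(ParseError, match="no features"):
            parse_feature_table("")

    def test_malformed_coordinate_names_line(self):
        with pytest.raises(ParseError, match="line 2"):
            parse_feature_table(HEADER + "trnM\tF\tone-68\t-\t-\t-\t-\n")

    def test_duplicate_gene_errors(self):
        text = HEADER + "trnM\tF\t1-68\t-\t-\t-\t-\ntrnM\tF\t70-140\t-\t-\t-\t-\n"
        with pytest.raises(ParseError, match="duplicate"):
            parse_feature_table(text)

    def test_leucine_serine_paralogs_are_distinct(self):
        text = HEADER + "trnL(UUR)\tF\t1-70\t-\t-\t-\t-\ntrnL(CUN)\tR\t80-150\t-\t-\t-\t-\n"
        g = parse_feature_table(text)
        assert len(g.features) == 2


class TestFeatureLength:
    def test_published_sizes(self, cf_genome):
        g = cf_genome
        assert feature_length(g.get("rrnL"), g.genome_length) == 1334
        assert feature_length(g.get("rrnS"), g.genome_length) == 763
        assert feature_length(g.get("A+T-rich region"), g.genome_length) == 1816
        assert feature_length(g.get("TRU"), g.genome_length) == 2856
        assert feature_length(g.get("nad2"), g.genome_length) == 1017

    def test_single_base(self):
        assert feature_length(GeneFeature("x", start=5, end=5), 100) == 1

    def test_wrap(self):
        f = GeneFeature("x", start=20450, end=10)
        # brute-force oracle: enumerate covered positions
        assert feature_length(f, 20456) == len(list(feature_positions(f, 20456))) == 17

    def test_wrap_on_linear_genome_errors(self):
        with pytest.raises(ValueError, match="wraps"):
            feature_length(GeneFeature("x", start=10, end=2), 20, circular=False)

    def test_wrap_matches_enumeration_randomized(self, rng):
        n = 997
        for _ in range(1000):
            a, b = int(rng.integers(1, n + 1)), int(rng.integers(1, n + 1))
            f = GeneFeature("x", start=a, end=b)
            assert feature_length(f, n) == len(list(feature_positions(f, n)))


class TestIntergenicRegions:
    def test_published_spacers(self, cf_genome):
        recs = {(r.upstream, r.downstream): r.length for r in intergenic_regions(cf_genome)}
        assert recs[("trnI", "trnW")] == 2888  # TRU excluded from the chain
        assert recs[("trnE", "trnF")] == 217
        assert recs[("nad2", "trnI")] == 131
        assert recs[("atp8", "atp6")] == -7
        assert recs[("trnM", "nad2")] == 0

    def test_published_summary(self, cf_genome):
        s = spacer_summary(cf_genome)
        assert s["n_positive"] == 24
        assert s["total_positive"] == 3783
        assert (s["min_positive"], s["max_positive"]) == (1, 2888)
        assert (s["longest_pair"].upstream, s["longest_pair"].downstream) == ("trnI", "trnW")

    def test_abutting_features_not_counted(self):
        g = AnnotatedGenome(
            200,
            features=[
                GeneFeature("a", FeatureClass.tRNA, "+", 1, 100),
                GeneFeature("b", FeatureClass.tRNA, "+", 101, 200),
            ],
        )
        recs = intergenic_regions(g)
        assert [r.length for r in recs] == [0, 0]
        assert spacer_summary(g)["n_positive"] == 0

    def test_chain_tiles_the_circle(self, cf_genome):
        chain = [f for f in cf_genome.features if f.klass is not FeatureClass.repeat_region]
        total = sum(feature_length(f, cf_genome.genome_length) for f in chain)
        total += sum(r.length for r in intergenic_regions(cf_genome))
        assert total == cf_genome.genome_length

    def test_coverage_conservation(self, cf_genome):
        """Features + positive spacers tile {1..20456} exactly (brute force)."""
        n = cf_genome.genome_length
        covered = set()
        for f in cf_genome.features:
            covered.update(feature_positions(f, n))
        chain = [f for f in cf_genome.features if f.klass is not FeatureClass.repeat_region]
        for up, down in zip(chain, chain[1:] + chain[:1]):
            up_end = up.end
            gap_start = up_end % n + 1
            down_start = down.start
            pos = gap_start
            while pos != down_start:
                covered.add(pos)
                pos = pos % n + 1
        assert covered == set(range(1, n + 1))

    def test_too_few_features_errors(self):
        g = AnnotatedGenome(100, features=[GeneFeature("a", FeatureClass.tRNA, "+", 1, 50)])
        with pytest.raises(ValueError):
            intergenic_regions(g)


class TestExtractSequence:
    def test_plus_minus_and_wrap(self):
        g = AnnotatedGenome(8, sequence="ATGCATGC")
        assert extract_feature_sequence(g, GeneFeature("a", start=1, end=3)) == "ATG"
        assert extract_feature_sequence(g, GeneFeature("a", strand="-", start=1, end=3)) == "CAT"
        # wrap: positions 7,8,1,2 -> "GC" + "AT"
        assert extract_feature_sequence(g, GeneFeature("a", start=7, end=2)) == "GCAT"
        assert (
            extract_feature_sequence(g, GeneFeature("a", strand="-", start=7, end=2)) == "ATGC"
        )

    def test_sequence_free_genome_errors(self, cf_genome):
        with pytest.raises(ValueError, match="sequence-free"):
            extract_feature_sequence(cf_genome, cf_genome.get("trnM"))


class TestValidation:
    def test_published_anticodon_typo_is_flagged_not_fatal(self, cf_genome):
        findings = validate_annotation(cf_genome)
        assert [(f.feature, f.rule) for f in findings] == [
            ("trnL(CUN)", "anticodon_outside_span")
        ]

    def test_clean_trna_has_no_finding(self):
        g = AnnotatedGenome(
            100,
            features=[
                GeneFeature("trnM", FeatureClass.tRNA, "+", 1, 68, "CAT", 31, 33),
                GeneFeature("x", FeatureClass.tRNA, "+", 69, 100),
            ],
        )
        assert validate_annotation(g) == []

    def test_anticodon_sequence_mismatch_is_error(self):
        seq = "A" * 100
        g = AnnotatedGenome(
            100,
            sequence=seq,
            features=[GeneFeature("trnM", FeatureClass.tRNA, "+", 1, 68, "CAT", 31, 33)],
        )
        (finding,) = [f for f in validate_annotation(g) if f.rule == "anticodon_sequence_mismatch"]
        assert finding.severity == "error"

    def test_incomplete_stop_is_warning_not_error(self):
        g = AnnotatedGenome(
            100,
            features=[
                GeneFeature("nad1", FeatureClass.PCG, "+", 1, 50, start_codon="ATG", stop_codon="TA"),
                GeneFeature("x", FeatureClass.tRNA, "+", 51, 100),
            ],
        )
        (finding,) = validate_annotation(g)
        assert (finding.rule, finding.severity) == ("incomplete_stop_codon", "warning")

    def test_unusual_codons_are_errors(self):
        g = AnnotatedGenome(
            100,
            features=[
                GeneFeature("nad1", FeatureClass.PCG, "+", 1, 50, start_codon="CCC", stop_codon="TGA"),
            ],
        )
        rules = {f.rule for f in validate_annotation(g)}
        assert rules == {"unusual_start_codon", "unusual_stop_codon"}


class TestRoundTrips:
    def test_feature_table_round_trip(self, cf_genome):
        text = write_feature_table(cf_genome)
        g2 = parse_feature_table(text, genome_length=cf_genome.genome_length)
        assert g2.features == cf_genome.features

    def test_genbank_round_trip(self, cf_genome, tmp_path):
        path = tmp_path / "cf.gb"
        write_genbank(cf_genome, path)
        g2 = read_genbank(path)
        assert g2.features == cf_genome.features
        assert g2.genome_length == cf_genome.genome_length
        assert g2.circular

    def test_genbank_complement_maps_to_minus_strand(self, tmp_path):
        gb = tmp_path / "t.gb"
        g = AnnotatedGenome(
            9600,
            sequence="ACGT" * 2400,
            features=[GeneFeature("trnE", FeatureClass.tRNA, "-", 9441, 9526)],
        )
        write_genbank(g, gb)
        assert "complement(9441..9526)" in gb.read_text()
        assert read_genbank(gb).features[0].strand == "-"

    def test_genbank_wrap_feature(self, tmp_path):
        gb = tmp_path / "w.gb"
        g = AnnotatedGenome(
            100,
            sequence="ACGT" * 25,
            features=[GeneFeature("x", FeatureClass.tRNA, "+", 95, 5)],
        )
        write_genbank(g, gb)
        f = read_genbank(gb).features[0]
        assert (f.start, f.end) == (95, 5)

    def test_fasta_length_mismatch_errors(self, tmp_path):
        fa = tmp_path / "x.fa"
        fa.write_text(">x\nACGTACGT\n")
        with pytest.raises(ValueError, match="genome_length"):
            read_fasta(fa, genome_length=100)


def test_rotated_genome_preserves_features(cf_genome):
    g = cf_genome.rotated(4284)  # cox1 start becomes position 1
    assert g.get("cox1").start == 1
    n = g.genome_length
    assert {feature_length(f, n) for f in g.features} == {
        feature_length(f, n) for f in cf_genome.features
    }
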