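"""Motif scanners: cloverleaves, stem-loops, poly-T runs, ORFs, identity."""

import numpy as np
import pytest

from mitoarch.model import reverse_complement
from mitoarch.motifs import (
    CloverleafParams,
    build_cloverleaf_sequence,
    find_cloverleaves,
    find_orfs,
    find_poly_t,
    find_stem_loops,
    isotype_from_anticodon,
    percent_identity,
    scan_region_for_trna_like,
    select_nonoverlapping,
)
from mitoarch.simulate import CloverleafPlant, SimulationConfig, TruSpec, generate_genome

from tests.conftest import random_dna


class TestCloverleaf:
    def _flanked(self, rng, motif, pad=30):
        return random_dna(rng, pad) + motif + random_dna(rng, pad), pad

    def test_planted_motif_detected_with_anticodon(self, rng):
        motif = build_cloverleaf_sequence(rng, "CAT")
        seq, pad = self._flanked(rng, motif)
        hits = [
            c
            for c in find_cloverleaves(seq)
            if c.strand == "+" and c.start == pad + 1 and c.end == pad + len(motif)
        ]
        assert hits
        assert hits[0].anticodon == "CAT"
        assert hits[0].inferred_isotype == "M"

    def test_dhu_less_variant_detected(self, rng):
        motif = build_cloverleaf_sequence(rng, "GCT", dhu_present=False)
        seq, pad = self._flanked(rng, motif)
        hits = [
            c
            for c in find_cloverleaves(seq)
            if c.anticodon == "GCT" and c.dhu is None and c.start == pad + 1
        ]
        assert hits
        assert 7 <= hits[0].dhu_loop <= 14

    def test_dhu_required_when_not_optional(self, rng):
        motif = build_cloverleaf_sequence(rng, "GCT", dhu_present=False)
        seq, pad = self._flanked(rng, motif)
        strict = CloverleafParams(dhu_optional=False)
        assert not [
            c for c in find_cloverleaves(seq, strict) if c.start == pad + 1 and c.dhu is None
        ]

    def test_strand_mirror(self, rng):
        motif = build_cloverleaf_sequence(rng, "TTC")
        seq, pad = self._flanked(rng, motif)
        plus = {(c.start, c.end) for c in find_cloverleaves(seq) if c.strand == "+"}
        n = len(seq)
        minus_mirrored = {
            (n - c.end + 1, n - c.start + 1)
            for c in find_cloverleaves(reverse_complement(seq))
            if c.strand == "-"
        }
        assert plus == minus_mirrored

    def test_planted_recovery_randomized(self, rng):
        """50 random constructions within the grammar are all detected."""
        recovered = 0
        anticodons = ["CAT", "GAT", "TGC", "GTA", "TTC", "GCT", "TAA", "TCA"]
        for i in range(50):
            anticodon = anticodons[i % len(anticodons)]
            motif = build_cloverleaf_sequence(rng, anticodon, dhu_present=bool(i % 3))
            seq, pad = self._flanked(rng, motif, pad=15)
            # the grammar is ambiguous (alternative foldings of the same
            # span exist), so recovery means: a candidate overlapping the
            # planted span reads out the planted anticodon
            hits = [
                c
                for c in find_cloverleaves(seq)
                if c.strand == "+"
                and c.anticodon == anticodon
                and c.start <= pad + len(motif)
                and c.end >= pad + 1
            ]
            recovered += bool(hits)
        assert recovered == 50

    def test_ranked_by_mismatches_then_pairs(self, rng):
        motif = build_cloverleaf_sequence(rng, "CAT")
        seq, _ = self._flanked(rng, motif)
        hits = find_cloverleaves(seq)
        ranks = [(c.total_mismatches, -c.paired_bases) for c in hits]
        assert ranks == sorted(ranks)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            find_cloverleaves("ACGT" * 5)


class TestTrnaLikeScan:
    def test_one_hit_per_repeat_copy(self):
        cfg = SimulationConfig(
            seed=9,
            tru=TruSpec(unit_length=135, full_copies=5, partial_length=21),
            cloverleaf=CloverleafPlant(anticodon="TGC"),
        )
        g = generate_genome(cfg).genome
        tru = g.get("TRU")
        hits = scan_region_for_trna_like(g, (tru.start, tru.end))
        planted = [h for h in hits if h["candidate"].anticodon == "TGC"]
        assert len(planted) == 5
        assert {h["best_reference"] for h in planted} == {"trnA"}

    def test_anticodon_pairs_to_matching_reference(self):
        cfg = SimulationConfig(
            seed=13,
            tru=TruSpec(unit_length=135, full_copies=3, partial_length=0),
            cloverleaf=CloverleafPlant(anticodon="GTA"),
        )
        g = generate_genome(cfg).genome
        tru = g.get("TRU")
        hits = [
            h
            for h in scan_region_for_trna_like(g, (tru.start, tru.end))
            if h["candidate"].anticodon == "GTA"
        ]
        assert hits and {h["best_reference"] for h in hits} == {"trnY"}
        assert all(0 < h["identity"] <= 1 for h in hits)

    def test_region_without_candidates_is_empty(self):
        from mitoarch.model import AnnotatedGenome

        # a homopolymer cannot base-pair, so no cloverleaf can fold
        g = AnnotatedGenome(200, sequence="A" * 200)
        assert scan_region_for_trna_like(g, (1, 150)) == []

    def test_select_nonoverlapping_keeps_best(self, rng):
        motif = build_cloverleaf_sequence(rng, "CAT")
        seq = random_dna(rng, 20) + motif + random_dna(rng, 20)
        kept = select_nonoverlapping(find_cloverleaves(seq))
        for a, b in zip(kept, kept[1:]):
            assert a.end < b.start


class TestStemLoops:
    def test_perfect_hairpin(self):
        hits = find_stem_loops("GGGGG" + "AAATT" + "CCCCC", min_stem=5, max_loop=20)
        assert (5, 5) in {(h.stem_length, h.loop_length) for h in hits}

    def test_conserved_flanks_annotated(self):
        seq = "TATA" + "GGGGG" + "AAATT" + "CCCCC" + "GAAAT"
        (hit,) = [
            h
            for h in find_stem_loops(seq, min_stem=5)
            if h.stem_length == 5 and h.loop_length == 5
        ]
        assert hit.flank_5prime_tata and hit.flank_3prime_gant and hit.gant_n == 3

    def test_matches_independent_enumeration(self, rng):
        """Candidate set equals a naive all-(i, stem, loop) oracle."""

        def pairs(a, b):
            return (a, b) in {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}

        seq = random_dna(rng, 120)
        min_stem, max_loop, max_mm = 4, 10, 1
        oracle = set()
        n = len(seq)
        for i in range(n):
            for stem in range(min_stem, n):
                for loop in range(3, max_loop + 1):
                    end = i + 2 * stem + loop
                    if end > n:
                        continue
                    mm = sum(
                        0 if pairs(seq[i + k], seq[end - 1 - k]) else 1 for k in range(stem)
                    )
                    if mm <= max_mm:
                        oracle.add((i + 1, stem, loop, mm))
        got = {
            (h.start, h.stem_length, h.loop_length, h.mismatches)
            for h in find_stem_loops(seq, min_stem=min_stem, max_loop=max_loop, max_mismatch=max_mm)
        }
        assert got == oracle

    def test_strand_mirror_watson_crick(self, rng):
        # inverted repeats mirror exactly under Watson-Crick pairing;
        # G-U wobble is strand-asymmetric by nature, so it is disabled here
        seq = random_dna(rng, 80)
        n = len(seq)
        fwd = {
            (h.start, h.end, h.stem_length, h.loop_length, h.mismatches)
            for h in find_stem_loops(seq, min_stem=4, max_mismatch=0, allow_gu=False)
        }
        rev = {
            (n - h.end + 1, n - h.start + 1, h.stem_length, h.loop_length, h.mismatches)
            for h in find_stem_loops(
                reverse_complement(seq), min_stem=4, max_mismatch=0, allow_gu=False
            )
        }
        assert fwd == rev


class TestPolyT:
    def test_pure_run(self):
        (run,) = find_poly_t("T" * 10, min_len=10, max_interruptions=0)
        assert (run.start, run.end, run.length, run.interruptions) == (1, 10, 10, 0)

    def test_single_interruption_counted_in_length(self):
        (run,) = find_poly_t("TTTTATTTTT", min_len=10, max_interruptions=1)
        assert run.length == 10 and run.interruptions == 1

    def test_short_run_rejected(self):
        assert find_poly_t("TTTTT", min_len=10, max_interruptions=1) == []

    def test_runs_start_and_end_with_t(self):
        runs = find_poly_t("AATTTTTTTTTTAA", min_len=10, max_interruptions=1)
        assert runs and all(r.length == 10 for r in runs)

    def test_min_len_validated(self):
        with pytest.raises(ValueError):
            find_poly_t("TTT", min_len=1)


class TestOrfs:
    def test_simple_orf(self):
        (orf,) = find_orfs("ATGAAATAA", strand_both=False)
        assert (orf.start_codon, orf.stop_codon, orf.aa_length) == ("ATG", "TAA", 2)

    def test_uorf_with_ttg_start_and_incomplete_stop(self, rng):
        """TTG + 42 sense codons + TA: 131 nt encoding 43 residues."""
        codons = []
        while len(codons) < 42:
            c = random_dna(rng, 3)
            if c not in {"TAA", "TAG"} and c != "TTG":
                codons.append(c)
        region = "TTG" + "".join(codons) + "TA"
        assert len(region) == 131
        hits = [o for o in find_orfs(region, strand_both=False) if o.stop_codon == "TA"]
        assert hits and hits[0].aa_length == 43
        assert hits[0].start_codon == "TTG"

    def test_incomplete_stop_requires_flag(self):
        region = "TTG" + "GCTGCA" + "TA"
        assert not find_orfs(region, strand_both=False, allow_incomplete_stop=False)

    def test_no_start_codon_no_orf(self):
        assert find_orfs("CCCCCCCCCTAA", strand_both=False) == []

    def test_minus_strand_mirrored_coordinates(self):
        seq = reverse_complement("ATGAAATAA")
        (orf,) = [o for o in find_orfs(seq, strand_both=True) if o.strand == "-"]
        assert (orf.start, orf.end) == (1, 9)
        assert (orf.start_codon, orf.stop_codon, orf.aa_length) == ("ATG", "TAA", 2)

    def test_tga_is_not_a_stop(self):
        # TGA codes tryptophan in the invertebrate mitochondrial code
        (orf,) = find_orfs("ATGTGATAA", strand_both=False)
        assert orf.aa_length == 2


class TestPercentIdentity:
    def test_identical_and_hand_count(self):
        assert percent_identity("A" * 70, "A" * 70) == 1.0
        assert percent_identity("AAAA", "AATA") == 0.75

    def test_symmetry(self, rng):
        for _ in range(20):
            a, b = random_dna(rng, 12), random_dna(rng, 15)
            assert percent_identity(a, b) == pytest.approx(percent_identity(b, a))

    def test_identity_one_iff_identical(self, rng):
        a = random_dna(rng, 30)
        b = a[:15] + ("A" if a[15] != "A" else "C") + a[16:]
        assert percent_identity(a, a) == 1.0
        assert percent_identity(a, b) < 1.0

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            percent_identity("", "ACGT")

    def test_against_exhaustive_alignment_oracle(self):
        """Identity equals that of an optimal alignment found by enumeration."""

        def oracle_identities(a, b):
            best = {}

            def rec(i, j, score, matches, length):
                if i == len(a) and j == len(b):
                    key = score
                    best.setdefault(key, set()).add((matches, length))
                    return
                if i < len(a) and j < len(b):
                    m = a[i] == b[j]
                    rec(i + 1, j + 1, score + (1 if m else 0), matches + m, length + 1)
                if i < len(a):
                    rec(i + 1, j, score - 1, matches, length + 1)
                if j < len(b):
                    rec(i, j + 1, score - 1, matches, length + 1)

            rec(0, 0, 0, 0, 0)
            top = max(best)
            return {m / l for m, l in best[top]}

        for a in ("ACGT", "TGCA", "AAAA", "ACCA"):
            for b in ("TGCA", "ACGT", "GGGG", "ACTA"):
                assert percent_identity(a, b) in oracle_identities(a, b)


def test_isotype_mapping_uses_mito_code():
    assert isotype_from_anticodon("CAT") == "M"
    assert isotype_from_anticodon("TGC") == "A"
    assert isotype_from_anticodon("GTA") == "Y"
    assert isotype_from_anticodon("TCA") == "W"  # TGA = Trp in the mito code
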