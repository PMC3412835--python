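"""Circular annotated-genome data model.

Coordinates are 1-based and inclusive at every interface, following the
GenBank convention and the feature tables printed in mitogenome papers.
On a circular genome a feature may wrap past the origin, in which case
``end`` is smaller than ``start`` (equivalently, the feature covers
``start..genome_length`` followed by ``1..end``).  At most one wrap is
permitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterator, Optional, Sequence

__all__ = [
    "FeatureClass",
    "GeneFeature",
    "AnnotatedGenome",
    "SpacerRecord",
    "ValidationFinding",
    "feature_length",
    "feature_positions",
    "extract_feature_sequence",
    "intergenic_regions",
    "spacer_summary",
    "validate_annotation",
    "reverse_complement",
    "PCG_NAMES",
]

#: Canonical protein-coding gene labels of the animal mitogenome.
PCG_NAMES = frozenset(
    {
        "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
        "cox1", "cox2", "cox3", "atp6", "atp8", "cytb",
    }
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Start codons observed for invertebrate mitochondrial PCGs.
VALID_START_CODONS = frozenset({"ATA", "ATT", "ATC", "ATG", "TTG", "GTG"})
#: Stop codons, including the incomplete T / TA completed by polyadenylation.
VALID_STOP_CODONS = frozenset({"TAA", "TAG", "T", "TA"})


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FeatureClass(str, Enum):
    PCG = "PCG"
    tRNA = "tRNA"
    rRNA = "rRNA"
    control_region = "control_region"
    repeat_region = "repeat_region"
    other = "other"


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene or region on a circular genome.

    ``strand`` is '+' for the major strand (the strand carrying the
    majority of genes, written 5'->3' in the genome sequence) and '-'
    for the minor strand.  ``anticodon`` carries the tRNA anticodon
    triplet as written on the coding strand, together with its 1-based
    inclusive position pair on the genome.
    """

    name: str
    klass: FeatureClass = FeatureClass.other
    strand: str = "+"
    start: int = 1
    end: int = 1
    anticodon: Optional[str] = None
    anticodon_start: Optional[int] = None
    anticodon_end: Optional[int] = None
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"feature {self.name!r}: start must be >= 1, got {self.start}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"feature {self.name!r}: strand must be '+' or '-'")
        if self.stop_codon is not None and len(self.stop_codon) not in (1, 2, 3):
            raise ValueError(f"feature {self.name!r}: stop codon length must be 1-3")

    @property
    def wraps(self) -> bool:
        return self.end < self.start


@dataclass
class AnnotatedGenome:
    """A circular genome with its ordered, strand-aware feature list."""

    genome_length: int
    circular: bool = True
    sequence: Optional[str] = None
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.genome_length:
                raise ValueError(
                    f"sequence length {len(self.sequence)} != genome_length {self.genome_length}"
                )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def features_of_class(self, klass: FeatureClass) -> list[GeneFeature]:
        return [f for f in self.features if f.klass is klass]

    def genes(self) -> list[GeneFeature]:
        """Gene features only: PCGs, tRNAs and rRNAs, in genome order."""
        return [
            f
            for f in self.features
            if f.klass in (FeatureClass.PCG, FeatureClass.tRNA, FeatureClass.rRNA)
        ]

    def rotated(self, new_origin: int) -> "AnnotatedGenome":
        """Return the same circular genome with position ``new_origin`` as base 1."""
        if not self.circular:
            raise ValueError("cannot rotate a linear genome")
        n = self.genome_length
        shift = new_origin - 1

        def mv(pos: Optional[int]) -> Optional[int]:
            if pos is None:
                return None
            return (pos - 1 - shift) % n + 1

        feats = [
            replace(
                f,
                start=mv(f.start),
                end=mv(f.end),
                anticodon_start=mv(f.anticodon_start),
                anticodon_end=mv(f.anticodon_end),
            )
            for f in self.features
        ]
        seq = None
        if self.sequence is not None:
            seq = self.sequence[shift:] + self.sequence[:shift]
        return AnnotatedGenome(n, circular=True, sequence=seq, features=feats)


@dataclass(frozen=True)
class SpacerRecord:
    """Signed gap between two consecutive features of the circular chain.

    Positive lengths are intergenic spacers, negative lengths are
    overlaps, zero means the features abut.
    """

    upstream: str
    downstream: str
    length: int


@dataclass(frozen=True)
class ValidationFinding:
    feature: str
    rule: str
    severity: str  # "error" | "warning"
    message: str


# ---------------------------------------------------------------------------
# coordinate arithmetic


def feature_length(f: GeneFeature, genome_length: int, circular: bool = True) -> int:
    """Length in bp of a feature, supporting a single circular wrap."""
    if f.end >= f.start:
        return f.end - f.start + 1
    if not circular:
        raise ValueError(f"feature {f.name!r} wraps but the genome is not circular")
    return (genome_length - f.start + 1) + f.end


def feature_positions(f: GeneFeature, genome_length: int) -> Iterator[int]:
    """All 1-based genome positions covered by the feature, 5'->3' on the major strand."""
    if f.end >= f.start:
        yield from range(f.start, f.end + 1)
    else:
        yield from range(f.start, genome_length + 1)
        yield from range(1, f.end + 1)


def extract_feature_sequence(g: AnnotatedGenome, f: GeneFeature) -> str:
    """Coding-strand (sense) sequence of a feature.

    Major-strand features return the genome subsequence as is; minor-strand
    features return its reverse complement.  Wrapping features are
    concatenated across the origin.
    """
    if g.sequence is None:
        raise ValueError("sequence-free genome")
    if f.end >= f.start:
        sub = g.sequence[f.start - 1 : f.end]
    else:
        if not g.circular:
            raise ValueError(f"feature {f.name!r} wraps but the genome is not circular")
        sub = g.sequence[f.start - 1 :] + g.sequence[: f.end]
    return reverse_complement(sub) if f.strand == "-" else sub


# ---------------------------------------------------------------------------
# spacer / overlap accounting


def _chain_features(g: AnnotatedGenome) -> list[GeneFeature]:
    """Features forming the circular adjacency chain.

    Repeat regions are excluded: a tandem repeat unit sits inside its host
    spacer and must not split that spacer in two.  The control region stays
    in the chain so that the gap between its flanking genes is not reported
    as an intergenic spacer; its flanks count as zero-length gaps instead
    and the region itself is reported separately.
    """
    return [f for f in g.features if f.klass is not FeatureClass.repeat_region]


def intergenic_regions(g: AnnotatedGenome) -> list[SpacerRecord]:
    """Signed spacer/overlap between each consecutive feature pair, circularly.

    One record per adjacent pair in the chain (including the wrap pair).
    ``length = start(downstream) - end(upstream) - 1`` under circular
    arithmetic.
    """
    chain = _chain_features(g)
    if len(chain) < 2:
        raise ValueError("need at least 2 chained features")
    n = g.genome_length
    records: list[SpacerRecord] = []
    total_len = 0
    for up, down in zip(chain, chain[1:] + chain[:1]):
        gap = down.start - _effective_end(up, n) - 1
        if up is chain[-1]:  # wrap pair
            gap = (down.start + n) - _effective_end(up, n) - 1
        records.append(SpacerRecord(up.name, down.name, gap))
        total_len += feature_length(up, n, g.circular)
    if g.circular and total_len + sum(r.length for r in records) != n:
        # chain must tile the circle; a violation means inconsistent coordinates
        raise ValueError("feature chain does not close the circle (overlap chain too long?)")
    if not g.circular:
        records.pop()  # no wrap pair on a linear genome
    return records


def _effective_end(f: GeneFeature, genome_length: int) -> int:
    return f.end if f.end >= f.start else f.end + genome_length


def spacer_summary(g: AnnotatedGenome) -> dict:
    """Positive-spacer summary over the gene chain.

    Records with a control-region flank are not intergenic (the region is
    accounted for separately) and are excluded from the positive counts.
    """
    cr_names = {f.name for f in g.features_of_class(FeatureClass.control_region)}
    records = intergenic_regions(g)
    gene_records = [r for r in records if r.upstream not in cr_names and r.downstream not in cr_names]
    positive = [r for r in gene_records if r.length > 0]
    return {
        "records": records,
        "n_positive": len(positive),
        "total_positive": sum(r.length for r in positive),
        "min_positive": min((r.length for r in positive), default=0),
        "max_positive": max((r.length for r in positive), default=0),
        "longest_pair": max(positive, key=lambda r: r.length) if positive else None,
    }


# ---------------------------------------------------------------------------
# validation


def validate_annotation(g: AnnotatedGenome) -> list[ValidationFinding]:
    """Non-fatal consistency checks over an annotated genome.

    Published feature tables do contain the occasional typo (e.g. an
    anticodon coordinate inconsistent with its tRNA span), so every check
    reports a finding instead of raising.
    """
    findings: list[ValidationFinding] = []
    n = g.genome_length
    for f in g.features:
        if f.anticodon_start is not None and f.anticodon_end is not None:
            span = set(feature_positions(f, n))
            anti = GeneFeature(f.name, start=f.anticodon_start, end=f.anticodon_end)
            if not set(feature_positions(anti, n)) <= span:
                findings.append(
                    ValidationFinding(
                        f.name,
                        "anticodon_outside_span",
                        "warning",
                        f"anticodon positions {f.anticodon_start}-{f.anticodon_end} "
                        f"outside feature span {f.start}-{f.end}",
                    )
                )
            elif g.sequence is not None and f.anticodon is not None:
                sub = g.sequence[f.anticodon_start - 1 : f.anticodon_end]
                if f.strand == "-":
                    sub = reverse_complement(sub)
                if sub.upper() != f.anticodon.upper():
                    findings.append(
                        ValidationFinding(
                            f.name,
                            "anticodon_sequence_mismatch",
                            "error",
                            f"declared anticodon {f.anticodon} but sequence reads {sub}",
                        )
                    )
        if f.anticodon is not None and f.klass is not FeatureClass.tRNA:
            findings.append(
                ValidationFinding(
                    f.name, "anticodon_on_non_trna", "warning",
                    f"{f.klass.value} feature carries an anticodon",
                )
            )
        if f.klass is FeatureClass.PCG:
            if f.start_codon and f.start_codon.upper() not in VALID_START_CODONS:
                findings.append(
                    ValidationFinding(
                        f.name, "unusual_start_codon", "error",
                        f"start codon {f.start_codon} not a mitochondrial initiation codon",
                    )
                )
            if f.stop_codon:
                sc = f.stop_codon.upper()
                if sc not in VALID_STOP_CODONS:
                    findings.append(
                        ValidationFinding(
                            f.name, "unusual_stop_codon", "error",
                            f"stop codon {f.stop_codon} not in TAA/TAG/TA/T",
                        )
                    )
                elif len(sc) < 3:
                    findings.append(
                        ValidationFinding(
                            f.name, "incomplete_stop_codon", "warning",
                            f"incomplete stop codon ({sc}), completed by polyadenylation",
                        )
                    )
        if feature_length(f, n, g.circular) > n:
            findings.append(
                ValidationFinding(
                    f.name, "feature_longer_than_genome", "error",
                    "feature covers more than one full revolution",
                )
            )
    return findings
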