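"""Nucleotide composition and strand-asymmetry (skew) statistics.

AT-skew = (A - T)/(A + T) and GC-skew = (G - C)/(G + C), computed from
the base counts of a sequence.  Most insect mitogenomes are A- and
C-skewed on the major strand; a reversed sign pattern (T- and G-skew) is
read as evidence that the replication origin in the control region has
been inverted.  Skews of the minor-strand gene set are computed on the
coding-strand (sense) sequences of those genes, not by re-reading the
major strand.

A zero denominator yields an explicit ``None`` ("undefined"), never a
NaN.  ``N`` bases are excluded from every count; lowercase is accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

from .model import AnnotatedGenome, FeatureClass, extract_feature_sequence

__all__ = [
    "CompositionProfile",
    "SkewPair",
    "base_composition",
    "at_gc_skew",
    "classify_skew",
    "codon_position_composition",
    "strand_partition_skew",
    "round_half_away",
]

_VALID = set("ACGTN")


@dataclass(frozen=True)
class CompositionProfile:
    a: int
    c: int
    g: int
    t: int

    @property
    def total(self) -> int:
        return self.a + self.c + self.g + self.t

    @property
    def fractions(self) -> Optional[dict]:
        n = self.total
        if n == 0:
            return None
        return {"A": self.a / n, "C": self.c / n, "G": self.g / n, "T": self.t / n}

    @property
    def at_content(self) -> Optional[float]:
        n = self.total
        return (self.a + self.t) / n if n else None

    def __add__(self, other: "CompositionProfile") -> "CompositionProfile":
        return CompositionProfile(
            self.a + other.a, self.c + other.c, self.g + other.g, self.t + other.t
        )


@dataclass(frozen=True)
class SkewPair:
    """AT and GC skew; a component is None when its denominator is zero."""

    at_skew: Optional[float]
    gc_skew: Optional[float]

    def rounded(self, ndigits: int = 3) -> "SkewPair":
        return SkewPair(
            round_half_away(self.at_skew, ndigits) if self.at_skew is not None else None,
            round_half_away(self.gc_skew, ndigits) if self.gc_skew is not None else None,
        )


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Round half away from zero (the convention used for printed skews)."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def base_composition(seq: str) -> CompositionProfile:
    """Exact base counts of a sequence; N is ignored."""
    s = seq.upper()
    bad = set(s) - _VALID
    if bad:
        pos = next(i for i, ch in enumerate(s) if ch in bad)
        raise ValueError(f"non-IUPAC character {s[pos]!r} at position {pos + 1}")
    return CompositionProfile(s.count("A"), s.count("C"), s.count("G"), s.count("T"))


def at_gc_skew(x: Union[str, CompositionProfile]) -> SkewPair:
    p = base_composition(x) if isinstance(x, str) else x
    at = (p.a - p.t) / (p.a + p.t) if (p.a + p.t) else None
    gc = (p.g - p.c) / (p.g + p.c) if (p.g + p.c) else None
    return SkewPair(at, gc)


def classify_skew(p: SkewPair) -> str:
    """Sign-pattern class of a skew pair.

    Classes follow the survey vocabulary: ``A_and_C`` (AT-skew > 0,
    GC-skew < 0), ``T_and_G``, ``T_and_C``, ``A_and_G``, the degenerate
    ``*_gc_zero`` labels when GC-skew is zero or undefined, and
    ``undefined`` when AT-skew is zero or undefined.
    """
    if p.at_skew is None or p.at_skew == 0:
        return "undefined"
    first = "A" if p.at_skew > 0 else "T"
    if p.gc_skew is None or p.gc_skew == 0:
        return f"{first}_only_gc_zero"
    second = "G" if p.gc_skew > 0 else "C"
    return f"{first}_and_{second}"


def codon_position_composition(g: AnnotatedGenome) -> dict[int, CompositionProfile]:
    """Per-codon-position composition over the concatenated in-frame PCGs.

    Codons are read on the coding strand, anchored at the annotated start;
    a trailing incomplete codon (1-2 nt left over by an incomplete stop)
    is excluded from the tallies.
    """
    pcgs = g.features_of_class(FeatureClass.PCG)
    if not pcgs:
        raise ValueError("no PCG features")
    parts = {1: [], 2: [], 3: []}
    for f in pcgs:
        seq = extract_feature_sequence(g, f)
        if not seq:
            raise ValueError(f"PCG {f.name!r} has length 0")
        usable = len(seq) - len(seq) % 3
        for offset in (0, 1, 2):
            parts[offset + 1].append(seq[offset:usable:3])
    return {
        pos: base_composition("".join(chunks)) for pos, chunks in parts.items()
    }


def strand_partition_skew(g: AnnotatedGenome) -> dict:
    """Skew report for the whole genome and the strand-partitioned PCG sets.

    ``whole_genome`` is computed on the major strand over all positions;
    each PCG partition is computed on the concatenated sense sequences of
    its member genes.  A partition with no genes is reported as undefined.
    """
    if g.sequence is None:
        raise ValueError("sequence-free genome")
    report: dict = {}
    whole = at_gc_skew(g.sequence)
    report["whole_genome"] = {
        "skew": whole,
        "skew_class": classify_skew(whole),
        "genes": None,
        "composition": base_composition(g.sequence),
    }
    pcgs = g.features_of_class(FeatureClass.PCG)
    partitions = {
        "all_PCGs": pcgs,
        "major_strand_PCGs": [f for f in pcgs if f.strand == "+"],
        "minor_strand_PCGs": [f for f in pcgs if f.strand == "-"],
    }
    for label, members in partitions.items():
        if not members:
            report[label] = {"skew": None, "skew_class": "undefined", "genes": []}
            continue
        comp = base_composition("".join(extract_feature_sequence(g, f) for f in members))
        pair = at_gc_skew(comp)
        report[label] = {
            "skew": pair,
            "skew_class": classify_skew(pair),
            "genes": [f.name for f in members],
            "composition": comp,
        }
    return report
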