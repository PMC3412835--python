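"""Combinatorial motif search in non-coding mitochondrial sequence.

Scans for tRNA-like cloverleaf candidates, inverted-repeat stem-loops
with the conserved ``TATA`` / ``G(A)nT`` flanking motifs of insect
control regions, poly-T stretches, and unidentified open reading frames
(UORFs) with alternative starts and incomplete stops.

The cloverleaf model is purely structural: arm lengths are constrained
to the canonical metazoan mitochondrial tRNA ranges (7-bp acceptor stem,
5-bp anticodon stem with a 7-nt loop, a DHU arm that may be reduced to a
bare loop as in trnS(AGN), a variable loop that may reach ~20 nt as in
some earwig tRNAs, and a TpsiC arm).  Base pairing is Watson-Crick plus
optional G-U wobble; no free-energy model is used — the contract is
combinatorial, not thermodynamic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import re

from Bio import Align
from Bio.Data import CodonTable

from .model import AnnotatedGenome, FeatureClass, GeneFeature, extract_feature_sequence, reverse_complement

__all__ = [
    "CloverleafParams",
    "CloverleafCandidate",
    "StemLoopCandidate",
    "OrfCandidate",
    "PolyTRun",
    "find_cloverleaves",
    "find_stem_loops",
    "find_poly_t",
    "find_orfs",
    "percent_identity",
    "scan_region_for_trna_like",
    "build_cloverleaf_sequence",
]

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


def _pairs(a: str, b: str, allow_gu: bool) -> bool:
    return (a, b) in _WC or (allow_gu and (a, b) in _GU)


# invertebrate mitochondrial genetic code, for anticodon -> isotype
_MITO_TABLE = CodonTable.unambiguous_dna_by_id[5]


def isotype_from_anticodon(anticodon: str) -> str:
    codon = reverse_complement(anticodon.upper())
    if codon in _MITO_TABLE.stop_codons:
        return "*"
    return _MITO_TABLE.forward_table.get(codon, "?")


# ---------------------------------------------------------------------------
# cloverleaf scan


@dataclass(frozen=True)
class CloverleafParams:
    allow_gu: bool = True
    max_stem_mismatch: int = 1
    dhu_optional: bool = True
    var_loop_max: int = 21
    acceptor_stem: int = 7
    anticodon_stem: int = 5
    anticodon_loop: int = 7
    dhu_stem_range: tuple[int, int] = (3, 4)
    dhu_loop_range: tuple[int, int] = (4, 12)
    dhu_absent_loop_range: tuple[int, int] = (7, 14)
    var_loop_min: int = 3
    t_stem_range: tuple[int, int] = (3, 5)
    t_loop_range: tuple[int, int] = (4, 9)


@dataclass(frozen=True)
class CloverleafCandidate:
    start: int  # 1-based inclusive, on the scanned (plus-strand) sequence
    end: int
    strand: str
    acceptor_stem: int
    dhu: Optional[tuple[int, int]]  # (stem, loop) or None when the DHU stem is absent
    dhu_loop: int
    anticodon_arm: tuple[int, int]
    anticodon: str
    variable_loop: int
    tpsic: tuple[int, int]
    mismatches: dict = field(hash=False, compare=False, default_factory=dict)
    total_mismatches: int = 0
    paired_bases: int = 0
    inferred_isotype: str = "?"


def _shapes(p: CloverleafParams) -> dict[int, list[tuple[int, int, int, int, int]]]:
    """Shape tuples (d, dl, v, t, tl) grouped by total motif length."""
    dhu_options = []
    for d in range(p.dhu_stem_range[0], p.dhu_stem_range[1] + 1):
        for dl in range(p.dhu_loop_range[0], p.dhu_loop_range[1] + 1):
            dhu_options.append((d, dl))
    if p.dhu_optional:
        for dl in range(p.dhu_absent_loop_range[0], p.dhu_absent_loop_range[1] + 1):
            dhu_options.append((0, dl))
    fixed = 2 * p.acceptor_stem + 2 * p.anticodon_stem + p.anticodon_loop
    by_length: dict[int, list] = {}
    for d, dl in dhu_options:
        for v in range(p.var_loop_min, p.var_loop_max + 1):
            for t in range(p.t_stem_range[0], p.t_stem_range[1] + 1):
                for tl in range(p.t_loop_range[0], p.t_loop_range[1] + 1):
                    length = fixed + 2 * d + dl + v + 2 * t + tl
                    by_length.setdefault(length, []).append((d, dl, v, t, tl))
    return by_length


def _stem_mismatches(s: str, i5: int, i3_end: int, stem: int, allow_gu: bool, budget: int) -> int:
    """Mismatches pairing s[i5:i5+stem] against s[i3_end-stem:i3_end] (antiparallel)."""
    mm = 0
    for k in range(stem):
        if not _pairs(s[i5 + k], s[i3_end - 1 - k], allow_gu):
            mm += 1
            if mm > budget:
                return mm
    return mm


def _scan_one_strand(s: str, p: CloverleafParams) -> list[dict]:
    n = len(s)
    by_length = _shapes(p)
    acc, ac_stem, ac_loop = p.acceptor_stem, p.anticodon_stem, p.anticodon_loop
    hits = []
    for start in range(n):
        for length, shapes in by_length.items():
            end = start + length
            if end > n:
                continue
            mm_acc = _stem_mismatches(s, start, end, acc, p.allow_gu, p.max_stem_mismatch)
            if mm_acc > p.max_stem_mismatch:
                continue
            for d, dl, v, t, tl in shapes:
                i = start + acc
                mm_dhu = 0
                if d:
                    mm_dhu = _stem_mismatches(s, i, i + 2 * d + dl, d, p.allow_gu, p.max_stem_mismatch)
                    if mm_dhu > p.max_stem_mismatch:
                        continue
                i += 2 * d + dl
                mm_ac = _stem_mismatches(s, i, i + 2 * ac_stem + ac_loop, ac_stem, p.allow_gu, p.max_stem_mismatch)
                if mm_ac > p.max_stem_mismatch:
                    continue
                loop_start = i + ac_stem
                anticodon = s[loop_start + 2 : loop_start + 5]
                i += 2 * ac_stem + ac_loop + v
                mm_t = _stem_mismatches(s, i, i + 2 * t + tl, t, p.allow_gu, p.max_stem_mismatch)
                if mm_t > p.max_stem_mismatch:
                    continue
                total = mm_acc + mm_dhu + mm_ac + mm_t
                paired = acc + d + ac_stem + t
                hits.append(
                    {
                        "start0": start,
                        "end0": end,
                        "d": d,
                        "dl": dl,
                        "v": v,
                        "t": t,
                        "tl": tl,
                        "anticodon": anticodon,
                        "mm": {"acceptor": mm_acc, "dhu": mm_dhu, "anticodon": mm_ac, "tpsic": mm_t},
                        "total": total,
                        "paired": paired,
                    }
                )
    return hits


def find_cloverleaves(seq: str, params: Optional[CloverleafParams] = None) -> list[CloverleafCandidate]:
    """Exhaustively scan both strands for cloverleaf-compatible foldings.

    Candidates are deduplicated by (start, end, strand), keeping the
    folding with the fewest total stem mismatches (most paired bases on
    ties), and returned sorted by position.
    """
    p = params or CloverleafParams()
    s = seq.upper()
    if len(s) < 50:
        raise ValueError("sequence too short for a cloverleaf scan (< 50 nt)")
    n = len(s)
    best: dict[tuple[int, int, str], tuple] = {}
    for strand, scanned in (("+", s), ("-", reverse_complement(s))):
        for h in _scan_one_strand(scanned, p):
            if strand == "+":
                start, end = h["start0"] + 1, h["end0"]
            else:
                start, end = n - h["end0"] + 1, n - h["start0"]
            key = (start, end, strand)
            rank = (h["total"], -h["paired"])
            if key not in best or rank < best[key][0]:
                best[key] = (rank, h)
    out = []
    for (start, end, strand), (_, h) in sorted(
        best.items(), key=lambda kv: (kv[1][0], kv[0])
    ):
        anticodon = h["anticodon"]
        out.append(
            CloverleafCandidate(
                start=start,
                end=end,
                strand=strand,
                acceptor_stem=p.acceptor_stem,
                dhu=(h["d"], h["dl"]) if h["d"] else None,
                dhu_loop=h["dl"],
                anticodon_arm=(p.anticodon_stem, p.anticodon_loop),
                anticodon=anticodon,
                variable_loop=h["v"],
                tpsic=(h["t"], h["tl"]),
                mismatches=h["mm"],
                total_mismatches=h["total"],
                paired_bases=h["paired"],
                inferred_isotype=isotype_from_anticodon(anticodon),
            )
        )
    return out


def build_cloverleaf_sequence(
    rng,
    anticodon: str,
    dhu_present: bool = True,
    allow_gu: bool = False,
    params: Optional[CloverleafParams] = None,
) -> str:
    """Construct a sequence satisfying the cloverleaf constraint grammar.

    Stems are sampled as perfect Watson-Crick pairs (plus G-U when
    ``allow_gu``), loops uniformly at random, so the result is guaranteed
    detectable by :func:`find_cloverleaves`.  Used by the synthetic-genome
    generator to plant tRNA-like sequences.
    """
    p = params or CloverleafParams()
    bases = "ACGT"
    pair_of = {"A": "T", "T": "A", "G": "C", "C": "G"}

    def rand_seq(k: int) -> str:
        return "".join(bases[rng.integers(4)] for _ in range(k))

    def stem(k: int) -> tuple[str, str]:
        five = rand_seq(k)
        three = "".join(pair_of[ch] for ch in reversed(five))
        return five, three

    acc5, acc3 = stem(p.acceptor_stem)
    if dhu_present:
        d = int(rng.integers(p.dhu_stem_range[0], p.dhu_stem_range[1] + 1))
        dl = int(rng.integers(p.dhu_loop_range[0], p.dhu_loop_range[1] + 1))
        dhu5, dhu3 = stem(d)
        dhu = dhu5 + rand_seq(dl) + dhu3
    else:
        dl = int(rng.integers(p.dhu_absent_loop_range[0], p.dhu_absent_loop_range[1] + 1))
        dhu = rand_seq(dl)
    ac5, ac3 = stem(p.anticodon_stem)
    loop = rand_seq(2) + anticodon.upper() + rand_seq(2)
    v = int(rng.integers(p.var_loop_min, p.var_loop_max + 1))
    t = int(rng.integers(p.t_stem_range[0], p.t_stem_range[1] + 1))
    tl = int(rng.integers(p.t_loop_range[0], p.t_loop_range[1] + 1))
    t5, t3 = stem(t)
    return acc5 + dhu + ac5 + loop + ac3 + rand_seq(v) + t5 + rand_seq(tl) + t3 + acc3


def select_nonoverlapping(candidates: Sequence[CloverleafCandidate]) -> list[CloverleafCandidate]:
    """Greedy one-candidate-per-locus selection in rank order.

    Candidates come ranked best-first from :func:`find_cloverleaves`
    (fewest mismatches, most paired bases); each kept candidate shadows
    every later candidate overlapping its span.
    """
    kept: list[CloverleafCandidate] = []
    for cand in candidates:
        if all(cand.end < k.start or k.end < cand.start for k in kept):
            kept.append(cand)
    return sorted(kept, key=lambda c: (c.start, c.end))


# ---------------------------------------------------------------------------
# stem-loops


@dataclass(frozen=True)
class StemLoopCandidate:
    start: int  # 1-based inclusive span of the full hairpin
    end: int
    stem_length: int
    loop_length: int
    mismatches: int
    flank_5prime_tata: bool = False
    flank_3prime_gant: bool = False
    gant_n: int = 0


_TATA_RE = re.compile("TATA")
_GANT_RE = re.compile("G(A{2,})T")


def find_stem_loops(
    seq: str,
    min_stem: int = 5,
    max_loop: int = 20,
    max_mismatch: int = 0,
    min_loop: int = 3,
    flank_window: int = 10,
    allow_gu: bool = True,
) -> list[StemLoopCandidate]:
    """All inverted repeats with stem >= min_stem and loop in [min_loop, max_loop].

    Every qualifying (start, stem, loop) triple is reported (the brute
    force enumeration), deduplicated by exact span and geometry.  Flank
    flags mark a ``TATA`` within ``flank_window`` nt upstream and a
    ``G(A)nT`` (n >= 2) starting within ``flank_window`` nt downstream.
    Note that G-U wobble pairs are strand-asymmetric: with ``allow_gu``
    the candidate set is not mirrored by reverse complementation.
    """
    s = seq.upper()
    n = len(s)
    if n < 2 * min_stem + min_loop:
        raise ValueError("sequence too short for a stem-loop scan")
    out = []
    for i in range(n):
        for stem in range(min_stem, (n - i - min_loop) // 2 + 1):
            for loop in range(min_loop, max_loop + 1):
                end = i + 2 * stem + loop
                if end > n:
                    break
                mm = _stem_mismatches(s, i, end, stem, allow_gu, max_mismatch)
                if mm > max_mismatch:
                    continue
                up = s[max(0, i - flank_window) : i]
                down = s[end : end + flank_window + 4]
                m = _GANT_RE.search(down[: flank_window + 4])
                gant = bool(m and m.start() <= flank_window)
                out.append(
                    StemLoopCandidate(
                        start=i + 1,
                        end=end,
                        stem_length=stem,
                        loop_length=loop,
                        mismatches=mm,
                        flank_5prime_tata=bool(_TATA_RE.search(up)),
                        flank_3prime_gant=gant,
                        gant_n=len(m.group(1)) if gant else 0,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# poly-T stretches


@dataclass(frozen=True)
class PolyTRun:
    start: int  # 1-based inclusive
    end: int
    length: int
    interruptions: int


def find_poly_t(seq: str, min_len: int = 10, max_interruptions: int = 1) -> list[PolyTRun]:
    """Maximal T-runs containing at most ``max_interruptions`` non-T bases.

    Runs begin and end with T; length counts interruptions.  Only runs not
    contained in a longer qualifying run are reported.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    s = seq.upper()
    n = len(s)
    raw = []
    for i in range(n):
        if s[i] != "T":
            continue
        interruptions = 0
        j = i
        last_t = i
        while j < n:
            if s[j] == "T":
                last_t = j
            else:
                if interruptions == max_interruptions:
                    break
                interruptions += 1
            j += 1
        used = sum(1 for k in range(i, last_t + 1) if s[k] != "T")
        if last_t - i + 1 >= min_len:
            raw.append((i, last_t, used))
    out = []
    for i, j, used in raw:
        if any(oi <= i and j <= oj and (oi, oj) != (i, j) for oi, oj, _ in raw):
            continue
        out.append(PolyTRun(start=i + 1, end=j + 1, length=j - i + 1, interruptions=used))
    # deduplicate identical spans
    return sorted(set(out), key=lambda r: r.start)


# ---------------------------------------------------------------------------
# ORFs


@dataclass(frozen=True)
class OrfCandidate:
    start: int  # 1-based inclusive, plus-strand coordinates of the scanned sequence
    end: int
    strand: str
    frame: int
    start_codon: str
    stop_codon: str  # may be incomplete: "TA" or "T"
    aa_length: int


DEFAULT_START_CODONS = frozenset({"ATG", "ATA", "ATT", "ATC", "TTG", "GTG"})
_STOPS = {"TAA", "TAG"}  # TGA codes tryptophan in the invertebrate mito code


def find_orfs(
    seq: str,
    strand_both: bool = True,
    starts: frozenset = DEFAULT_START_CODONS,
    allow_incomplete_stop: bool = True,
    min_aa: int = 1,
) -> list[OrfCandidate]:
    """ORFs per frame and strand, with optional incomplete terminal stops.

    An ORF runs from the first start codon after the previous stop to the
    next stop codon; the start codon counts as residue 1.  When the frame
    ends at the sequence boundary with a trailing ``T`` or ``TA`` and
    ``allow_incomplete_stop`` is set, the ORF qualifies with that
    incomplete stop (completed by polyadenylation in vivo).
    """
    if len(seq) < 6:
        raise ValueError("sequence too short for ORF scan")
    s = seq.upper()
    n = len(s)
    out = []
    strands = [("+", s)] + ([("-", reverse_complement(s))] if strand_both else [])
    for strand, scanned in strands:
        for frame in range(3):
            open_at: Optional[int] = None
            i = frame
            while i + 3 <= n:
                codon = scanned[i : i + 3]
                if open_at is None and codon in starts:
                    open_at = i
                elif open_at is not None and codon in _STOPS:
                    aa = (i - open_at) // 3
                    if aa >= min_aa:
                        out.append(_orf(open_at, i + 3, strand, frame, scanned, codon, aa, n))
                    open_at = None
                i += 3
            if open_at is not None and allow_incomplete_stop:
                tail = scanned[i:]
                if tail in {"T", "TA"}:
                    aa = (i - open_at) // 3
                    if aa >= min_aa:
                        out.append(_orf(open_at, n, strand, frame, scanned, tail, aa, n))
    return sorted(out, key=lambda o: (o.start, o.end, o.strand))


def _orf(lo: int, hi: int, strand: str, frame: int, scanned: str, stop: str, aa: int, n: int) -> OrfCandidate:
    if strand == "+":
        start, end = lo + 1, hi
    else:
        start, end = n - hi + 1, n - lo
    return OrfCandidate(
        start=start,
        end=end,
        strand=strand,
        frame=frame,
        start_codon=scanned[lo : lo + 3],
        stop_codon=stop,
        aa_length=aa,
    )


# ---------------------------------------------------------------------------
# similarity scoring


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def percent_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment length.

    Match +1, mismatch 0, linear gap -1; the first (high-road) optimal
    alignment is used, which is deterministic.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    aln = _aligner().align(a.upper(), b.upper())[0]
    counts = aln.counts()
    length = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / length


def scan_region_for_trna_like(
    g: AnnotatedGenome,
    region: tuple[int, int],
    reference_trnas: Optional[dict[str, str]] = None,
    params: Optional[CloverleafParams] = None,
    cluster: bool = True,
) -> list[dict]:
    """Cloverleaf candidates in a genome region, paired to reference tRNAs.

    References default to the genome's own annotated tRNA sequences.  Each
    candidate is paired to the reference sharing its inferred anticodon;
    when no reference anticodon matches, the highest-identity reference is
    used.  One hit is reported per candidate, so a repeat region with one
    planted motif per copy yields one hit per copy.
    """
    if g.sequence is None:
        raise ValueError("sequence-free genome")
    lo, hi = region
    sub = extract_feature_sequence(g, GeneFeature("region", start=lo, end=hi))
    if reference_trnas is None:
        reference_trnas = {
            f.name: extract_feature_sequence(g, f)
            for f in g.features_of_class(FeatureClass.tRNA)
        }
    anticodon_of = {
        f.name: f.anticodon
        for f in g.features_of_class(FeatureClass.tRNA)
        if f.anticodon
    }
    candidates = find_cloverleaves(sub, params)
    if cluster:
        candidates = select_nonoverlapping(candidates)
    hits = []
    for cand in candidates:
        by_anticodon = [
            name for name, anti in anticodon_of.items()
            if anti == cand.anticodon and name in reference_trnas
        ]
        if by_anticodon:
            ref = by_anticodon[0]
        elif reference_trnas:
            cand_seq = sub[cand.start - 1 : cand.end]
            if cand.strand == "-":
                cand_seq = reverse_complement(cand_seq)
            ref = max(
                reference_trnas,
                key=lambda name: (percent_identity(cand_seq, reference_trnas[name]), name),
            )
        else:
            ref = None
        identity = None
        if ref is not None:
            cand_seq = sub[cand.start - 1 : cand.end]
            if cand.strand == "-":
                cand_seq = reverse_complement(cand_seq)
            identity = percent_identity(cand_seq, reference_trnas[ref])
        hits.append(
            {
                "candidate": cand,
                "region_start": (lo - 1 + cand.start - 1) % g.genome_length + 1,
                "best_reference": ref,
                "identity": identity,
            }
        )
    return hits
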