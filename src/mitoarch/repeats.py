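"""Tandem repeat unit (TRU) detection.

A TRU is a run of near-identical copies of a unit of length ``l``: ``c``
full copies (``c >= 2``) plus an optional partial copy of the beginning
of the unit at the run boundary, so that the region span is
``c*l + p``.  Insect control regions and large intergenic spacers often
carry such runs; the unit lengths of interest here range from
microsatellite-scale up to several hundred bp.

The detector is a self-alignment period scan: for each candidate period
``l`` it marks the positions where the sequence equals itself at lag
``l`` and chains windows of per-copy identity >= ``min_identity`` into
maximal runs.  Identity between copies is counted on ungapped columns
(``matches / l``); indel-containing repeats are out of scope.  Ties
between overlapping candidates are fully ordered (longest span, then
smallest unit, then leftmost start) so output is deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .model import AnnotatedGenome, FeatureClass, GeneFeature, extract_feature_sequence, intergenic_regions

__all__ = [
    "TandemRepeatUnit",
    "qualifying_runs",
    "find_tandem_repeats",
    "characterize_tru",
    "brute_force_runs",
]

#: Defaults chosen to span published insect TRU units (135, 189, 202,
#: 297, 554 bp) while suppressing homopolymer noise.
DEFAULT_MIN_UNIT = 10
DEFAULT_MAX_UNIT = 600
DEFAULT_MIN_COPIES = 2
DEFAULT_MIN_IDENTITY = 0.85


@dataclass(frozen=True)
class TandemRepeatUnit:
    """One detected tandem repeat run (1-based inclusive coordinates)."""

    region_start: int
    region_end: int
    unit_length: int
    full_copies: int
    partial_length: int
    consensus: str
    mean_copy_identity: float

    @property
    def span(self) -> int:
        return self.region_end - self.region_start + 1


def _qualifies(matches: int, unit: int, min_identity: float) -> bool:
    return matches >= min_identity * unit - 1e-9


def qualifying_runs(
    seq: str,
    min_unit: int,
    max_unit: int,
    min_copies: int = DEFAULT_MIN_COPIES,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[tuple[int, int, int]]:
    """All maximal qualifying runs as ``(start, unit_length, copies)``.

    ``start`` is a 0-based offset.  A run of ``c`` copies at period ``l``
    qualifies when every adjacent copy pair matches at >= ``min_identity``
    and ``c >= min_copies``; it is maximal when no further copy can be
    chained on either side.  This is the contract the brute-force oracle
    enumerates; :func:`find_tandem_repeats` adds consensus building,
    partial-copy measurement and overlap resolution on top.
    """
    if min_unit > max_unit:
        raise ValueError("min_unit > max_unit")
    if min_unit < 1 or min_copies < 2:
        raise ValueError("need min_unit >= 1 and min_copies >= 2")
    s = seq.upper()
    n = len(s)
    if n < 2 * min_unit:
        raise ValueError("sequence shorter than two units")
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    runs: list[tuple[int, int, int]] = []
    for ell in range(min_unit, min(max_unit, n // 2) + 1):
        m = arr[:-ell] == arr[ell:]
        cs = np.concatenate(([0], np.cumsum(m)))
        n_win = n - 2 * ell + 1  # window a compares copy a with copy a+ell
        w = cs[ell : ell + n_win] - cs[:n_win]
        q = w >= min_identity * ell - 1e-9
        prev = np.zeros_like(q)
        if n_win > ell:
            prev[ell:] = q[:-ell]
        for start in np.flatnonzero(q & ~prev):
            a = int(start)
            windows = 1
            while a + ell < n_win and q[a + ell]:
                a += ell
                windows += 1
            copies = windows + 1
            if copies >= min_copies:
                runs.append((int(start), ell, copies))
    runs.sort()
    return runs


def brute_force_runs(
    seq: str,
    min_unit: int,
    max_unit: int,
    min_copies: int = DEFAULT_MIN_COPIES,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[tuple[int, int, int]]:
    """Independent enumeration of all maximal qualifying (start, unit, copies)."""
    s = seq.upper()
    n = len(s)

    def pair_ok(a: int, ell: int) -> bool:
        if a < 0 or a + 2 * ell > n:
            return False
        matches = sum(1 for i in range(ell) if s[a + i] == s[a + ell + i])
        return _qualifies(matches, ell, min_identity)

    out = []
    for ell in range(min_unit, min(max_unit, n // 2) + 1):
        for start in range(0, n - 2 * ell + 1):
            if not pair_ok(start, ell):
                continue
            if pair_ok(start - ell, ell):
                continue  # extendable left -> not maximal
            copies = 2
            a = start
            while pair_ok(a + ell, ell):
                a += ell
                copies += 1
            if copies >= min_copies:
                out.append((start, ell, copies))
    return sorted(out)


def _consensus(s: str, start: int, ell: int, copies: int) -> str:
    cols = []
    for j in range(ell):
        counter = Counter(s[start + i * ell + j] for i in range(copies))
        best = max(counter.items(), key=lambda kv: (kv[1], -ord(kv[0])))
        cols.append(best[0])
    return "".join(cols)


def _exact_run(a: str, b: str) -> int:
    k = 0
    for x, y in zip(a, b):
        if x != y:
            break
        k += 1
    return k


def _match_intervals(m: np.ndarray, min_identity: float) -> list[tuple[int, int]]:
    """Maximal high-density intervals of a boolean lag-match profile.

    Max-scoring-subarray trimming: matches score +1, mismatches score
    negatively so that the background match density (~0.25 for random
    nucleotide sequence) drifts downward while densities at or above the
    identity threshold climb.  One interval is reported per positive
    burst, with tight boundaries (the burst's score peak).
    """
    # a mismatch must not be repayable by 2-3 chance matches (background
    # density 0.25), yet runs at min_identity must keep a positive drift
    penalty = min(3.0, 0.8 * min_identity / (1 - min_identity))
    intervals = []
    cur_start = 0
    cur = 0.0
    peak = 0.0
    peak_idx = -1
    for i, hit in enumerate(m):
        cur += 1.0 if hit else -penalty
        if cur > peak:
            peak, peak_idx = cur, i
        if cur <= 0:
            if peak_idx >= cur_start:
                intervals.append((cur_start, peak_idx))
            cur_start, cur, peak, peak_idx = i + 1, 0.0, 0.0, i
    if peak_idx >= cur_start:
        intervals.append((cur_start, peak_idx))
    return intervals


def find_tandem_repeats(
    seq: str,
    min_unit: int = DEFAULT_MIN_UNIT,
    max_unit: int = DEFAULT_MAX_UNIT,
    min_copies: int = DEFAULT_MIN_COPIES,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[TandemRepeatUnit]:
    """Detect tandem repeat units, resolving overlaps deterministically.

    For each candidate period the lag-match profile is trimmed to its
    high-density bursts (see :func:`_match_intervals`); boundary copies
    falling below ``min_identity`` against the consensus are dropped.
    Candidates are ranked by (span desc, unit asc, start asc) and selected
    greedily without overlap.  The partial copy is measured at the run
    boundary as the longest exact match against the consensus prefix
    (trailing) or suffix (leading), capped below one unit.
    """
    if min_unit > max_unit:
        raise ValueError("min_unit > max_unit")
    s = seq.upper()
    n = len(s)
    if n < 2 * min_unit:
        raise ValueError("sequence shorter than two units")
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)

    def pair_ok(a: int, ell: int) -> bool:
        if a < 0 or a + 2 * ell > n:
            return False
        matches = int(np.count_nonzero(arr[a : a + ell] == arr[a + ell : a + 2 * ell]))
        return _qualifies(matches, ell, min_identity)

    candidates = []
    for ell in range(min_unit, min(max_unit, n // 2) + 1):
        m = arr[:-ell] == arr[ell:]
        for m_lo, m_hi in _match_intervals(m, min_identity):
            if (m_hi - m_lo + 1) + ell < min_copies * ell:
                continue
            # the burst anchors the phase; copies are chained by pairwise
            # identity so a stray boundary mutation cannot shave a copy
            lo = m_lo
            while pair_ok(lo - ell, ell):
                lo -= ell
            if not pair_ok(lo, ell):
                continue
            copies = 2
            a = lo
            while pair_ok(a + ell, ell):
                a += ell
                copies += 1
            if copies < min_copies:
                continue
            # drop boundary copies below the identity threshold
            while copies >= min_copies:
                cons = _consensus(s, lo, ell, copies)
                ident = [
                    sum(1 for j in range(ell) if s[lo + i * ell + j] == cons[j]) / ell
                    for i in range(copies)
                ]
                if not _qualifies(round(ident[0] * ell), ell, min_identity):
                    lo += ell
                    copies -= 1
                elif not _qualifies(round(ident[-1] * ell), ell, min_identity):
                    copies -= 1
                else:
                    break
            if copies < min_copies:
                continue
            tail_p = _exact_run(s[lo + copies * ell : lo + copies * ell + ell - 1], cons)
            head_p = _exact_run(s[max(0, lo - (ell - 1)) : lo][::-1], cons[::-1])
            if head_p + tail_p >= ell:
                tail_p = max(0, ell - 1 - head_p)
            span = head_p + copies * ell + tail_p
            region_lo = lo - head_p
            # primitive-period reduction: a single noisy copy can break the
            # chain at the true period while surviving at a multiple of it,
            # so re-describe the run at the smallest self-consistent period
            for d in range(min_unit, ell):
                if ell % d:
                    continue
                self_matches = sum(1 for j in range(ell - d) if cons[j] == cons[j + d])
                if _qualifies(round(self_matches * d / (ell - d)), d, min_identity):
                    ell = d
                    copies = span // d
                    cons = _consensus(s, region_lo, d, copies)
                    tail_p = span - copies * d
                    head_p = 0
                    lo = region_lo
                    ident = [
                        sum(1 for j in range(d) if s[lo + i * d + j] == cons[j]) / d
                        for i in range(copies)
                    ]
                    break
            candidates.append(
                (span, ell, region_lo, lo, copies, head_p + tail_p, cons, ident)
            )

    candidates.sort(key=lambda r: (-r[0], r[1], r[2]))
    selected: list[TandemRepeatUnit] = []
    taken: list[tuple[int, int]] = []
    for span, ell, region_lo, lo, copies, partial, cons, ident in candidates:
        region_hi = region_lo + span  # [region_lo, region_hi) 0-based
        if any(region_lo < t_hi and t_lo < region_hi for t_lo, t_hi in taken):
            continue
        selected.append(
            TandemRepeatUnit(
                region_start=region_lo + 1,
                region_end=region_hi,
                unit_length=ell,
                full_copies=copies,
                partial_length=partial,
                consensus=cons,
                mean_copy_identity=sum(ident) / len(ident),
            )
        )
        taken.append((region_lo, region_hi))
    selected.sort(key=lambda t: (t.region_start, t.unit_length))
    return selected


def characterize_tru(
    g: AnnotatedGenome,
    min_unit: int = DEFAULT_MIN_UNIT,
    max_unit: int = DEFAULT_MAX_UNIT,
    min_copies: int = DEFAULT_MIN_COPIES,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> dict[str, list[TandemRepeatUnit]]:
    """Run the detector on each non-coding region of an annotated genome.

    Non-coding regions are the positive intergenic spacers plus the
    control (A+T-rich) region.  Reported coordinates are genome positions
    on the major strand; the arithmetic identity span = c*l + p holds for
    every record.
    """
    if g.sequence is None:
        raise ValueError("sequence-free genome")
    n = g.genome_length
    regions: list[tuple[str, int, int]] = []  # (label, start_1based, end_1based; may wrap)
    cr_names = {f.name for f in g.features_of_class(FeatureClass.control_region)}
    for rec in intergenic_regions(g):
        if rec.length <= 0 or rec.upstream in cr_names or rec.downstream in cr_names:
            continue
        up = g.get(rec.upstream)
        up_end = up.end if up.end >= up.start else up.end + n
        lo = up_end % n + 1
        hi = (up_end + rec.length - 1) % n + 1
        regions.append((f"{rec.upstream}-{rec.downstream}", lo, hi))
    for f in g.features_of_class(FeatureClass.control_region):
        regions.append((f.name, f.start, f.end))

    report: dict[str, list[TandemRepeatUnit]] = {}
    for label, lo, hi in regions:
        length = (hi - lo) % n + 1
        if length < 2 * min_unit:
            report[label] = []
            continue
        region_feature = GeneFeature(label, start=lo, end=hi)
        sub = extract_feature_sequence(g, region_feature)
        trus = find_tandem_repeats(sub, min_unit, max_unit, min_copies, min_identity)
        shifted = [
            TandemRepeatUnit(
                region_start=(lo - 1 + t.region_start - 1) % n + 1,
                region_end=(lo - 1 + t.region_end - 1) % n + 1,
                unit_length=t.unit_length,
                full_copies=t.full_copies,
                partial_length=t.partial_length,
                consensus=t.consensus,
                mean_copy_identity=t.mean_copy_identity,
            )
            for t in trus
        ]
        report[label] = shifted
    return report
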