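"""Signed circular gene orders and rearrangement classification.

A mitochondrial gene order is a circular sequence of signed elements
(gene name, orientation).  Comparing an observed order to the ancestral
insect arrangement (identical to *Drosophila*) classifies every gene as

* ``in_place`` — part of the conserved backbone,
* ``translocated`` — moved without an orientation change,
* ``local_inversion`` — orientation flipped within the same
  inter-backbone interval,
* ``shuffle_with_remote_inversion`` — both moved and flipped.

The backbone is found exactly: the classifier searches for all
minimum-cardinality sets of "moved" genes whose removal makes the two
circular signed orders identical, and a gene counts as rearranged when it
appears in *any* such minimum set.  Flagging the union keeps the
classification symmetric for block swaps (where either member's removal
alone would reconcile the orders, so both genes genuinely moved relative
to each other); event grouping then reports such a swap as a single
event.  Position is defined by adjacency context relative to the
backbone, never by absolute index, since a circle has no canonical
origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

from .model import AnnotatedGenome, FeatureClass, PCG_NAMES

__all__ = [
    "GeneOrderElement",
    "GeneOrder",
    "RearrangementEvent",
    "RearrangementReport",
    "ancestral_insect_order",
    "order_from_genome",
    "compare_orders",
    "apply_dup_loss",
    "apply_inversion",
    "apply_translocation",
    "breakpoint_count",
]


@dataclass(frozen=True)
class GeneOrderElement:
    name: str
    orientation: str  # "+" | "-"

    def flipped(self) -> "GeneOrderElement":
        return GeneOrderElement(self.name, "-" if self.orientation == "+" else "+")


@dataclass(frozen=True)
class GeneOrder:
    """A circular, signed gene order; equality is rotation-invariant."""

    elements: tuple[GeneOrderElement, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.elements]
        if len(names) != len(set(names)):
            raise ValueError("duplicate gene names in order")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "GeneOrder":
        return cls(tuple(GeneOrderElement(n, o) for n, o in pairs))

    def names(self) -> set[str]:
        return {e.name for e in self.elements}

    def index(self, name: str) -> int:
        for i, e in enumerate(self.elements):
            if e.name == name:
                return i
        raise KeyError(name)

    def rotated_to(self, name: str) -> "GeneOrder":
        i = self.index(name)
        return GeneOrder(self.elements[i:] + self.elements[:i])

    def rotated(self, shift: int) -> "GeneOrder":
        shift %= len(self.elements)
        return GeneOrder(self.elements[shift:] + self.elements[:shift])

    def _canonical(self) -> tuple:
        anchor = min(e.name for e in self.elements)
        return self.rotated_to(anchor).elements

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneOrder):
            return NotImplemented
        return self.names() == other.names() and self._canonical() == other._canonical()

    def __hash__(self) -> int:
        return hash(self._canonical())

    def __len__(self) -> int:
        return len(self.elements)

    def to_tsv(self) -> str:
        return "\n".join(f"{e.name}\t{e.orientation}" for e in self.elements) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "GeneOrder":
        pairs = []
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            name, orient = line.split("\t")
            pairs.append((name.strip(), orient.strip()))
        return cls.from_pairs(pairs)


#: The arrangement shared by most insects, identical to Drosophila.
_ANCESTRAL = (
    ("trnI", "+"), ("trnQ", "-"), ("trnM", "+"), ("nad2", "+"), ("trnW", "+"),
    ("trnC", "-"), ("trnY", "-"), ("cox1", "+"), ("trnL(UUR)", "+"), ("cox2", "+"),
    ("trnK", "+"), ("trnD", "+"), ("atp8", "+"), ("atp6", "+"), ("cox3", "+"),
    ("trnG", "+"), ("nad3", "+"), ("trnA", "+"), ("trnR", "+"), ("trnN", "+"),
    ("trnS(AGN)", "+"), ("trnE", "+"), ("trnF", "-"), ("nad5", "-"), ("trnH", "-"),
    ("nad4", "-"), ("nad4L", "-"), ("trnT", "+"), ("trnP", "-"), ("nad6", "+"),
    ("cytb", "+"), ("trnS(UCN)", "+"), ("nad1", "-"), ("trnL(CUN)", "-"),
    ("rrnL", "-"), ("trnV", "-"), ("rrnS", "-"), ("CR", "+"),
)


def ancestral_insect_order() -> GeneOrder:
    """The ancestral insect mitochondrial gene order (37 genes + CR)."""
    return GeneOrder.from_pairs(_ANCESTRAL)


def order_from_genome(g: AnnotatedGenome) -> GeneOrder:
    """Gene order of an annotated genome, ascending start position.

    Control regions are kept (as ``CR``); repeat regions and other
    non-gene features are dropped.
    """
    pairs = []
    for f in g.features:
        if f.klass in (FeatureClass.PCG, FeatureClass.tRNA, FeatureClass.rRNA):
            pairs.append((f.name, f.strand))
        elif f.klass is FeatureClass.control_region:
            pairs.append(("CR", f.strand))
    return GeneOrder.from_pairs(pairs)


# ---------------------------------------------------------------------------
# comparison


@dataclass(frozen=True)
class RearrangementEvent:
    genes: tuple[str, ...]
    klass: str
    ancestral_neighbors: tuple[str, str]
    observed_neighbors: tuple[str, str]


@dataclass
class RearrangementReport:
    classes: dict  # gene -> class label
    events: list
    summary: dict = field(default_factory=dict)

    def genes_in_class(self, klass: str) -> set[str]:
        return {g for g, k in self.classes.items() if k == klass}


def _projection(order: GeneOrder, keep: set[str]) -> tuple:
    elems = [e for e in order.elements if e.name in keep]
    if not elems:
        return ()
    anchor = min(e.name for e in elems)
    i = next(i for i, e in enumerate(elems) if e.name == anchor)
    return tuple((e.name, e.orientation) for e in elems[i:] + elems[:i])


def _adjacencies(seq: Sequence[tuple[str, str]]) -> set:
    out = set()
    for (x, ox), (y, oy) in zip(seq, seq[1:] + seq[:1]):
        a = ((x, ox), (y, oy))
        b = ((y, _flip(oy)), (x, _flip(ox)))
        out.add(min(a, b))
    return out


def _flip(o: str) -> str:
    return "-" if o == "+" else "+"


def compare_orders(
    observed: GeneOrder,
    ancestral: GeneOrder,
    never_flag: frozenset = frozenset({"CR"}),
    max_candidates: int = 16,
) -> RearrangementReport:
    """Classify every gene of ``observed`` against ``ancestral``.

    Raises on gene-set mismatch.  See module docstring for the backbone
    rule.  ``never_flag`` lists order elements that always stay in the
    backbone (the control region is an anchor, not a rearrangeable gene).
    """
    if observed.names() != ancestral.names():
        diff = observed.names() ^ ancestral.names()
        raise ValueError(f"gene sets differ: {sorted(diff)}")
    names = observed.names()
    obs_orient = {e.name: e.orientation for e in observed.elements}
    anc_orient = {e.name: e.orientation for e in ancestral.elements}
    forced = {n for n in names if obs_orient[n] != anc_orient[n] and n not in never_flag}

    def consistent(flags: set[str]) -> bool:
        keep = names - flags
        return _projection(observed, keep) == _projection(ancestral, keep)

    # conserved segments: maximal observed runs whose signed adjacencies all
    # exist in the ancestral order.  A rearrangement moves whole segments, so
    # candidate flag sets are unions of segments — a handful per genome.
    anc_adj = _adjacencies(tuple((e.name, e.orientation) for e in ancestral.elements))
    elems = observed.elements
    n_el = len(elems)
    conserved_after = [
        min(
            ((elems[i].name, elems[i].orientation), (elems[(i + 1) % n_el].name, elems[(i + 1) % n_el].orientation)),
            (
                (elems[(i + 1) % n_el].name, _flip(elems[(i + 1) % n_el].orientation)),
                (elems[i].name, _flip(elems[i].orientation)),
            ),
        )
        in anc_adj
        for i in range(n_el)
    ]
    if all(conserved_after) and not forced:
        solutions: list[frozenset] = [frozenset()]
    else:
        breaks = [i for i in range(n_el) if not conserved_after[i]] or [n_el - 1]
        segments: list[tuple[str, ...]] = []
        for b_idx, b in enumerate(breaks):
            start = (b + 1) % n_el
            end = breaks[(b_idx + 1) % len(breaks)]
            seg = []
            i = start
            while True:
                seg.append(elems[i].name)
                if i == end:
                    break
                i = (i + 1) % n_el
            segments.append(tuple(seg))
        mandatory = [s for s in segments if any(g in forced for g in s)]
        optional = [
            s
            for s in segments
            if s not in mandatory and not any(g in never_flag for g in s)
        ]
        if len(optional) > max_candidates:
            raise ValueError(
                f"orders too divergent for exact backbone search ({len(optional)} segments)"
            )
        scored: list[tuple[int, frozenset]] = []
        best_size = len(names) + 1
        for k in range(len(optional) + 1):
            for chosen in combinations(optional, k):
                flags = set(forced)
                for s in chosen:
                    flags.update(s)
                if len(flags) > best_size:
                    continue
                if consistent(flags):
                    scored.append((len(flags), frozenset(flags)))
                    best_size = min(best_size, len(flags))
        if not scored:
            raise ValueError("no consistent backbone found")
        solutions = [flags for size, flags in scored if size == best_size]
    flagged = frozenset().union(*solutions) if solutions else frozenset()
    backbone = names - flagged

    def interval(order: GeneOrder, gene: str) -> tuple[str, str]:
        elems = order.elements
        n = len(elems)
        i = order.index(gene)
        left = next(
            elems[(i - d) % n].name for d in range(1, n) if elems[(i - d) % n].name in backbone
        )
        right = next(
            elems[(i + d) % n].name for d in range(1, n) if elems[(i + d) % n].name in backbone
        )
        return (left, right)

    classes = {g: "in_place" for g in backbone}
    for g in sorted(flagged):
        if obs_orient[g] == anc_orient[g]:
            classes[g] = "translocated"
        elif interval(observed, g) == interval(ancestral, g):
            classes[g] = "local_inversion"
        else:
            classes[g] = "shuffle_with_remote_inversion"

    # group flagged genes contiguous in the observed order with equal class
    events: list[RearrangementEvent] = []
    elems = observed.elements
    n = len(elems)
    visited: set[str] = set()
    for i, e in enumerate(elems):
        if e.name not in flagged or e.name in visited:
            continue
        # walk left to the run start
        j = i
        while elems[(j - 1) % n].name in flagged and classes[elems[(j - 1) % n].name] == classes[e.name]:
            j = (j - 1) % n
            if j == i:
                break
        run = []
        k = j
        while elems[k].name in flagged and classes[elems[k].name] == classes[e.name] and elems[k].name not in visited:
            run.append(elems[k].name)
            visited.add(elems[k].name)
            k = (k + 1) % n
        anc_iv = interval(ancestral, run[0])
        obs_iv = interval(observed, run[0])
        events.append(
            RearrangementEvent(
                genes=tuple(run),
                klass=classes[run[0]],
                ancestral_neighbors=anc_iv,
                observed_neighbors=obs_iv,
            )
        )

    summary = {
        k: sorted(g for g, c in classes.items() if c == k)
        for k in ("in_place", "translocated", "local_inversion", "shuffle_with_remote_inversion")
    }
    report = RearrangementReport(classes=classes, events=events)
    report.summary = {
        "counts": {k: len(v) for k, v in summary.items()},
        "members": summary,
        "n_events": len(events),
    }
    return report


# ---------------------------------------------------------------------------
# scripted rearrangement operators


def _segment_bounds(order: GeneOrder, segment: Sequence[str]) -> int:
    """Index of segment start; raises unless the names form a contiguous run."""
    n = len(order.elements)
    i = order.index(segment[0])
    for off, name in enumerate(segment):
        if order.elements[(i + off) % n].name != name:
            raise ValueError(f"segment {list(segment)} not contiguous in order")
    return i


def apply_inversion(order: GeneOrder, segment: Sequence[str]) -> GeneOrder:
    """Reverse a contiguous segment and flip its orientations."""
    i = _segment_bounds(order, segment)
    n = len(order.elements)
    rot = order.rotated(i)  # segment now at front
    seg = [e.flipped() for e in reversed(rot.elements[: len(segment)])]
    return GeneOrder(tuple(seg) + rot.elements[len(segment) :]).rotated(-i % n)


def apply_translocation(order: GeneOrder, segment: Sequence[str], insert_after: str) -> GeneOrder:
    """Move a contiguous segment intact so it follows ``insert_after``."""
    if insert_after in segment:
        raise ValueError("insertion point inside the moved segment")
    i = _segment_bounds(order, segment)
    rot = order.rotated(i)
    seg = rot.elements[: len(segment)]
    rest = list(rot.elements[len(segment) :])
    j = next(k for k, e in enumerate(rest) if e.name == insert_after)
    new = rest[: j + 1] + list(seg) + rest[j + 1 :]
    return GeneOrder(tuple(new))


def apply_dup_loss(
    order: GeneOrder,
    block: Sequence[str],
    deletions: tuple[Iterable[str], Iterable[str]],
) -> GeneOrder:
    """Tandem-duplicate a block, then delete the listed copies.

    ``deletions`` gives the genes removed from copy 1 and copy 2; together
    they must cover each block gene exactly once so that each survives in
    exactly one copy.  Orientations are carried through unchanged.
    """
    del1, del2 = set(deletions[0]), set(deletions[1])
    if del1 | del2 != set(block) or del1 & del2:
        raise ValueError("deletion pattern must keep exactly one copy of each block gene")
    i = _segment_bounds(order, block)
    n = len(order.elements)
    rot = order.rotated(i)
    blk = rot.elements[: len(block)]
    survivors = [e for e in blk if e.name not in del1] + [e for e in blk if e.name not in del2]
    return GeneOrder(tuple(survivors) + rot.elements[len(block) :]).rotated(-i % n)


def breakpoint_count(a: GeneOrder, b: GeneOrder) -> int:
    """Number of signed circular adjacencies of ``a`` absent from ``b``."""
    if a.names() != b.names():
        raise ValueError("gene sets differ")
    adj_a = _adjacencies(tuple((e.name, e.orientation) for e in a.elements))
    adj_b = _adjacencies(tuple((e.name, e.orientation) for e in b.elements))
    return len(adj_a - adj_b)
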