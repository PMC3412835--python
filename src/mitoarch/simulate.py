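"""Synthetic circular mitogenomes and gene orders with planted structure.

The generator emulates the architecture of a large earwig-like insect
mitogenome: 37 genes with realistic published lengths, a long tandem
repeat unit (TRU) planted inside a designated intergenic spacer
(default: 21 copies of a 135-bp unit plus a 21-bp leading-partial copy),
tRNA-like cloverleaf motifs embedded in repeat copies, an AT-rich
control region, and per-strand background base probabilities that plant
a chosen skew sign pattern (default mirrors the reversed T/G skew of the
earwig major strand).

Everything stochastic flows from one seeded generator, so a config plus
seed reproduces the genome byte for byte.  Planted repeat boundaries are
guarded (the flanking base never continues the repeat pattern) so the
planted (unit, copies, partial) triple is the unambiguous ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .datasets import challia_fletcheri_genome
from .model import AnnotatedGenome, FeatureClass, GeneFeature, feature_length, reverse_complement
from .motifs import build_cloverleaf_sequence
from .rearrange import (
    GeneOrder,
    RearrangementReport,
    ancestral_insect_order,
    apply_dup_loss,
    apply_inversion,
    apply_translocation,
)

__all__ = [
    "TruSpec",
    "CloverleafPlant",
    "SimulationConfig",
    "GenomeSimulation",
    "generate_genome",
    "generate_order",
    "random_event_script",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class TruSpec:
    """A planted tandem repeat: c full copies of an l-mer plus a partial."""

    unit_length: int = 135
    full_copies: int = 21
    partial_length: int = 21
    divergence: float = 0.0
    copy_divergences: Optional[tuple[float, ...]] = None
    host_gene: str = "trnI"  # planted in the spacer downstream of this gene

    def __post_init__(self) -> None:
        if not (0 <= self.partial_length < self.unit_length):
            raise ValueError("partial_length must lie in [0, unit_length)")
        if self.full_copies < 2:
            raise ValueError("need at least 2 full copies")
        if self.copy_divergences is not None and len(self.copy_divergences) != self.full_copies:
            raise ValueError("copy_divergences must list one rate per full copy")


@dataclass(frozen=True)
class CloverleafPlant:
    """Plant one cloverleaf per TRU copy (anticodon on the plus strand)."""

    anticodon: str = "TGC"  # trnA-like
    per_tru_copy: bool = True


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    base_probs: tuple[float, float, float, float] = (0.282, 0.139, 0.176, 0.403)  # A, C, G, T
    cr_probs: tuple[float, float, float, float] = (0.45, 0.05, 0.05, 0.45)
    tru: Optional[TruSpec] = TruSpec()
    cloverleaf: Optional[CloverleafPlant] = None
    gene_order: Optional[GeneOrder] = None  # default: ancestral insect order
    spacer_length: int = 5
    cr_length: int = 1816
    event_script: tuple = ()

    def __post_init__(self) -> None:
        for probs in (self.base_probs, self.cr_probs):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("base probabilities must sum to 1")


@dataclass
class GenomeSimulation:
    genome: AnnotatedGenome
    truth: dict


def _template_features() -> dict[str, GeneFeature]:
    """Published gene metadata (lengths, codons, anticodon offsets)."""
    ref = challia_fletcheri_genome()
    return {f.name: f for f in ref.features}


def _random_bases(rng: np.random.Generator, k: int, probs: Sequence[float]) -> str:
    return rng.choice(_BASES, size=k, p=list(probs)).tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(3)]
    return "".join(chars)


def _build_tru(rng: np.random.Generator, spec: TruSpec, cloverleaf: Optional[CloverleafPlant], probs) -> tuple[str, str]:
    """Return (tru_sequence, unit) with divergence applied per copy."""
    unit = _random_bases(rng, spec.unit_length, probs)
    if cloverleaf is not None and cloverleaf.per_tru_copy:
        motif = build_cloverleaf_sequence(rng, cloverleaf.anticodon)
        if len(motif) + 2 > spec.unit_length:
            raise ValueError("unit too short to host the planted cloverleaf")
        offset = 1 + int(rng.integers(spec.unit_length - len(motif) - 1))
        unit = unit[:offset] + motif + unit[offset + len(motif):]
    rates = spec.copy_divergences or (spec.divergence,) * spec.full_copies
    copies = [_mutate(rng, unit, r) for r in rates]
    return "".join(copies) + unit[: spec.partial_length], unit


def generate_genome(cfg: SimulationConfig) -> GenomeSimulation:
    """Build a synthetic annotated circular genome from a config.

    Genes follow ``cfg.gene_order`` (ancestral by default) with published
    lengths, valid start/stop codons and planted anticodon triplets;
    spacers and the control region are sampled from the per-strand base
    probabilities; the TRU (and optional cloverleaf plants) go into the
    spacer downstream of ``tru.host_gene``.  Deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    templates = _template_features()
    order = cfg.gene_order or ancestral_insect_order()

    parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 0  # 0-based running offset

    def emit(segment: str) -> int:
        nonlocal pos
        parts.append(segment)
        start = pos
        pos += len(segment)
        return start

    guard_after: list[tuple[int, str]] = []  # (offset, banned_base)

    for elem in order.elements:
        if elem.name == "CR":
            cr_seq = _random_bases(rng, cfg.cr_length, cfg.cr_probs)
            start = emit(cr_seq)
            features.append(
                GeneFeature("A+T-rich region", FeatureClass.control_region, "+", start + 1, start + cfg.cr_length)
            )
            continue
        tpl = templates.get(elem.name)
        if tpl is None:
            raise ValueError(f"no template metadata for gene {elem.name!r}")
        length = feature_length(tpl, 10**9, circular=False)
        # background drawn on the major strand: the planted bias is a
        # property of the strand, not of the gene reading direction
        major_bg = _random_bases(rng, length, cfg.base_probs)
        sense = major_bg if elem.orientation == "+" else reverse_complement(major_bg)
        anticodon = anticodon_off = None
        if tpl.anticodon and tpl.anticodon_start and tpl.anticodon_end:
            off = (tpl.anticodon_start - tpl.start) if tpl.strand == "+" else (tpl.end - tpl.anticodon_end)
            if 0 <= off <= length - 3:
                sense = sense[:off] + tpl.anticodon + sense[off + 3:]
                anticodon, anticodon_off = tpl.anticodon, off
        start_codon = stop_codon = None
        if tpl.klass is FeatureClass.PCG:
            start_codon = tpl.start_codon or "ATG"
            stop_codon = tpl.stop_codon or "TAA"
            sense = start_codon + sense[len(start_codon):-len(stop_codon)] + stop_codon
        major = sense if elem.orientation == "+" else reverse_complement(sense)
        start = emit(major)
        anti_start = anti_end = None
        if anticodon is not None:
            if elem.orientation == "+":
                anti_start = start + anticodon_off + 1
            else:
                anti_start = start + length - anticodon_off - 3 + 1
            anti_end = anti_start + 2
        features.append(
            GeneFeature(
                elem.name,
                tpl.klass,
                elem.orientation,
                start + 1,
                start + length,
                anticodon=anticodon,
                anticodon_start=anti_start,
                anticodon_end=anti_end,
                start_codon=start_codon,
                stop_codon=stop_codon,
            )
        )
        # intergenic spacer, possibly hosting the TRU
        spacer = _random_bases(rng, cfg.spacer_length, cfg.base_probs)
        if cfg.tru is not None and elem.name == cfg.tru.host_gene:
            tru_seq, unit = _build_tru(rng, cfg.tru, cfg.cloverleaf, cfg.base_probs)
            pad = _random_bases(rng, cfg.spacer_length, cfg.base_probs)
            tru_start = emit(spacer) + len(spacer)
            emit(tru_seq)
            emit(pad)
            features.append(
                GeneFeature("TRU", FeatureClass.repeat_region, "+", tru_start + 1, tru_start + len(tru_seq))
            )
            guard_after.append((tru_start - 1, unit[-1]))  # base before run must break the pattern
            if cfg.tru.partial_length < cfg.tru.unit_length:
                guard_after.append((tru_start + len(tru_seq), unit[cfg.tru.partial_length]))
        else:
            emit(spacer)

    sequence = "".join(parts)
    seq_list = list(sequence)
    for offset, banned in guard_after:
        if 0 <= offset < len(seq_list) and seq_list[offset] == banned:
            choices = [b for b in "ACGT" if b != banned]
            seq_list[offset] = choices[rng.integers(3)]
    sequence = "".join(seq_list)

    genome = AnnotatedGenome(len(sequence), circular=True, sequence=sequence, features=features)
    truth = {
        "seed": cfg.seed,
        "tru": None
        if cfg.tru is None
        else {
            "unit_length": cfg.tru.unit_length,
            "full_copies": cfg.tru.full_copies,
            "partial_length": cfg.tru.partial_length,
            "host_gene": cfg.tru.host_gene,
        },
        "base_probs": dict(zip("ACGT", cfg.base_probs)),
        "expected_at_skew_sign": float(np.sign(cfg.base_probs[0] - cfg.base_probs[3])),
        "expected_gc_skew_sign": float(np.sign(cfg.base_probs[2] - cfg.base_probs[1])),
    }
    return GenomeSimulation(genome=genome, truth=truth)


def planted_repeat_sequence(
    rng: np.random.Generator,
    unit_length: int,
    full_copies: int,
    partial_length: int,
    flank: int = 500,
    divergence: float = 0.0,
    copy_divergences: Optional[Sequence[float]] = None,
    probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> tuple[str, int]:
    """Random flanks around a planted tandem repeat, boundaries guarded.

    Returns ``(sequence, region_start_0based)``.  The flanking bases
    adjacent to the run are resampled so they never continue the repeat
    pattern, making the planted (unit, copies, partial) triple the
    unambiguous ground truth.
    """
    unit = _random_bases(rng, unit_length, probs)
    rates = list(copy_divergences) if copy_divergences is not None else [divergence] * full_copies
    body = "".join(_mutate(rng, unit, r) for r in rates) + unit[:partial_length]
    left = _random_bases(rng, flank, probs)
    right = _random_bases(rng, flank, probs)
    if flank:
        if left[-1] == unit[-1]:
            left = left[:-1] + [b for b in "ACGT" if b != unit[-1]][rng.integers(3)]
        nxt = unit[partial_length] if partial_length < unit_length else unit[0]
        if right[0] == nxt:
            right = [b for b in "ACGT" if b != nxt][rng.integers(3)] + right[1:]
    return left + body + right, flank


# ---------------------------------------------------------------------------
# gene-order scripts


def _touched_genes(order: GeneOrder, event: dict) -> set[str]:
    """Genes whose adjacency context an event may alter (segment + flanks)."""
    seg = list(event.get("segment") or event.get("block"))
    n = len(order.elements)
    i = order.index(seg[0])
    touched = set(seg)
    touched.add(order.elements[(i - 1) % n].name)
    touched.add(order.elements[(i + len(seg)) % n].name)
    if event["type"] in ("translocate", "shuffle"):
        j = order.index(event["insert_after"])
        touched.add(event["insert_after"])
        touched.add(order.elements[(j + 1) % n].name)
    return touched


def _local_dup_loss_truth(block_old: list[str], block_new: list[str]) -> set[str]:
    """Union of minimal gene subsets whose removal reconciles two block orders.

    Independent small-instance enumeration (blocks are a handful of genes)
    used to derive scripted ground truth for duplication/random-loss events.
    """
    genes = list(block_old)
    if block_old == block_new:
        return set()
    solutions = []
    for k in range(1, len(genes) + 1):
        for sub in combinations(genes, k):
            drop = set(sub)
            if [g for g in block_old if g not in drop] == [g for g in block_new if g not in drop]:
                solutions.append(drop)
        if solutions:
            break
    return set().union(*solutions)


def generate_order(
    script: Sequence[dict],
    base: Optional[GeneOrder] = None,
) -> tuple[GeneOrder, dict]:
    """Apply a rearrangement script to the ancestral order with ground truth.

    Events must be non-interacting (disjoint touched-gene neighborhoods);
    overlap raises ``ValueError('ambiguous ground truth')``.  Translocations
    must jump further than their own block size, otherwise the minimal
    explanation is not unique and the ground truth would be ambiguous.
    Returns ``(order, truth)`` where truth maps each affected gene to its
    expected rearrangement class.
    """
    order = base or ancestral_insect_order()
    start_order = order
    seen: set[str] = set()
    truth: dict[str, str] = {}
    for event in script:
        touched = _touched_genes(start_order, event)
        if touched & seen:
            raise ValueError("ambiguous ground truth: interacting events")
        seen |= touched
        etype = event["type"]
        if etype == "invert":
            seg = list(event["segment"])
            order = apply_inversion(order, seg)
            for g in seg:
                truth[g] = "local_inversion"
        elif etype == "shuffle":
            seg = list(event["segment"])
            i = start_order.index(seg[0])
            left_flank = start_order.elements[(i - 1) % len(start_order.elements)].name
            if event["insert_after"] == left_flank:
                raise ValueError(
                    "ambiguous ground truth: in-place reinsertion is a local inversion, not a shuffle"
                )
            order = apply_inversion(order, seg)
            order = apply_translocation(order, list(reversed(seg)), event["insert_after"])
            for g in seg:
                truth[g] = "shuffle_with_remote_inversion"
        elif etype == "translocate":
            seg = list(event["segment"])
            i = start_order.index(seg[0])
            j = start_order.index(event["insert_after"])
            n = len(start_order.elements)
            hop = (j - (i + len(seg) - 1)) % n
            hop_back = (i - 1 - j) % n
            jumped = min(hop, hop_back)
            if jumped <= len(seg):
                raise ValueError(
                    "ambiguous ground truth: translocation must jump over more genes than it moves"
                )
            order = apply_translocation(order, seg, event["insert_after"])
            for g in seg:
                truth[g] = "translocated"
        elif etype == "dup_loss":
            block = list(event["block"])
            order = apply_dup_loss(order, block, (event["delete_copy1"], event["delete_copy2"]))
            survivors1 = [g for g in block if g not in set(event["delete_copy1"])]
            survivors2 = [g for g in block if g not in set(event["delete_copy2"])]
            for g in _local_dup_loss_truth(block, survivors1 + survivors2):
                truth[g] = "translocated"
        else:
            raise ValueError(f"unknown event type {etype!r}")
    return order, truth


def random_event_script(
    rng: np.random.Generator,
    n_events: int,
    base: Optional[GeneOrder] = None,
    max_block: int = 3,
    max_tries: int = 500,
) -> list[dict]:
    """Sample a non-interacting random script over the ancestral order.

    Rejection-samples candidate events until ``n_events`` pass the
    interaction and ambiguity checks of :func:`generate_order`.
    """
    order = base or ancestral_insect_order()
    names = [e.name for e in order.elements if e.name != "CR"]
    n = len(order.elements)
    script: list[dict] = []
    for _ in range(max_tries):
        if len(script) == n_events:
            break
        etype = ["invert", "translocate", "shuffle", "dup_loss"][rng.integers(4)]
        i = int(rng.integers(len(names)))
        size = int(rng.integers(1, max_block + 1))
        idx = order.index(names[i])
        seg = [order.elements[(idx + k) % n].name for k in range(size)]
        if "CR" in seg:
            continue
        event: dict = {"type": etype}
        if etype == "invert":
            event["segment"] = seg
        elif etype in ("translocate", "shuffle"):
            others = [g for g in names if g not in seg]
            event["segment"] = seg
            event["insert_after"] = others[rng.integers(len(others))]
        else:
            if size < 2:
                continue
            event["block"] = seg
            keep_from_copy1 = int(rng.integers(1, size))  # rotation split point
            event["delete_copy1"] = seg[:keep_from_copy1]
            event["delete_copy2"] = seg[keep_from_copy1:]
        try:
            generate_order(script + [event])
        except ValueError:
            continue
        script.append(event)
    if len(script) < n_events:
        raise RuntimeError("could not sample a non-interacting script")
    return script
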