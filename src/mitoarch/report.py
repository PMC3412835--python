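"""One-genome comparative report assembling all analysis stages."""

from __future__ import annotations

import dataclasses
import json
from typing import Optional

from . import __version__
from .model import AnnotatedGenome, FeatureClass, feature_length, spacer_summary, validate_annotation
from .rearrange import GeneOrder, ancestral_insect_order, breakpoint_count, compare_orders, order_from_genome
from .repeats import characterize_tru
from .skew import codon_position_composition, strand_partition_skew

__all__ = ["run_report", "report_to_text"]


def _plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _plain(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "value") and obj.__class__.__name__ == "FeatureClass":
        return obj.value
    return obj


def run_report(
    g: AnnotatedGenome,
    ancestral: Optional[GeneOrder] = None,
    inputs: Optional[dict] = None,
) -> dict:
    """Compute every applicable section; sequence-level sections are marked
    skipped on a sequence-free genome rather than erroring."""
    ancestral = ancestral or ancestral_insect_order()
    n = g.genome_length
    report: dict = {
        "provenance": {
            "tool": "mitoarch",
            "version": __version__,
            "inputs": inputs or {},
        }
    }

    counts = {k.value: len(g.features_of_class(k)) for k in FeatureClass}
    summary = spacer_summary(g)
    report["architecture"] = {
        "genome_length": n,
        "feature_counts": counts,
        "feature_lengths": {f.name: feature_length(f, n, g.circular) for f in g.features},
        "spacers": _plain(summary["records"]),
        "n_positive_spacers": summary["n_positive"],
        "total_positive_spacer_bp": summary["total_positive"],
        "longest_spacer": _plain(summary["longest_pair"]),
    }
    report["validation"] = _plain(validate_annotation(g))

    if g.sequence is None:
        report["skew"] = {"skipped": "no sequence"}
        report["tru"] = {"skipped": "no sequence"}
    else:
        skews = strand_partition_skew(g)
        skew_section = {}
        for label, entry in skews.items():
            pair = entry["skew"]
            skew_section[label] = {
                "at_skew": pair.rounded().at_skew if pair else None,
                "gc_skew": pair.rounded().gc_skew if pair else None,
                "skew_class": entry["skew_class"],
                "genes": entry["genes"],
            }
        if g.features_of_class(FeatureClass.PCG):
            cpc = codon_position_composition(g)
            skew_section["codon_position_at_content"] = {
                str(pos): round(profile.at_content, 3) for pos, profile in cpc.items()
            }
        report["skew"] = skew_section
        report["tru"] = {
            region: _plain(trus) for region, trus in characterize_tru(g).items()
        }

    observed = order_from_genome(g)
    if observed.names() == ancestral.names():
        cmp = compare_orders(observed, ancestral)
        report["rearrangement"] = {
            "classes": cmp.classes,
            "summary": cmp.summary,
            "events": _plain(cmp.events),
            "breakpoints": breakpoint_count(observed, ancestral),
        }
    else:
        missing = sorted(ancestral.names() - observed.names())
        extra = sorted(observed.names() - ancestral.names())
        report["rearrangement"] = {
            "skipped": f"gene set differs from ancestral (missing {missing}, extra {extra})"
        }
    return report


def report_to_text(report: dict) -> str:
    """Human-readable rendering; every number it prints is in the JSON."""
    lines = []
    arch = report["architecture"]
    lines.append(f"Genome: {arch['genome_length']} bp, features: {arch['feature_counts']}")
    lines.append(
        f"Positive intergenic spacers: {arch['n_positive_spacers']} "
        f"({arch['total_positive_spacer_bp']} bp total)"
    )
    if arch["longest_spacer"]:
        ls = arch["longest_spacer"]
        lines.append(f"Longest spacer: {ls['length']} bp ({ls['upstream']}-{ls['downstream']})")
    skew = report["skew"]
    if "skipped" in skew:
        lines.append(f"Skew: skipped ({skew['skipped']})")
    else:
        for label in ("whole_genome", "all_PCGs", "major_strand_PCGs", "minor_strand_PCGs"):
            e = skew[label]
            lines.append(
                f"Skew[{label}]: AT {e['at_skew']} GC {e['gc_skew']} class {e['skew_class']}"
            )
    tru = report["tru"]
    if "skipped" in tru:
        lines.append(f"TRU: skipped ({tru['skipped']})")
    else:
        for region, hits in tru.items():
            for t in hits:
                lines.append(
                    f"TRU[{region}]: unit {t['unit_length']} x {t['full_copies']} + "
                    f"{t['partial_length']} partial"
                )
    rearr = report["rearrangement"]
    if "skipped" in rearr:
        lines.append(f"Rearrangement: skipped ({rearr['skipped']})")
    else:
        lines.append(f"Rearrangement counts: {rearr['summary']['counts']}")
        lines.append(f"Breakpoints vs ancestral: {rearr['breakpoints']}")
    findings = report["validation"]
    lines.append(f"Validation findings: {len(findings)}")
    for f in findings:
        lines.append(f"  [{f['severity']}] {f['feature']}: {f['message']}")
    return "\n".join(lines) + "\n"


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
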