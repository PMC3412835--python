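"""Readers and writers: feature-table TSV, GenBank flat files, FASTA.

The feature-table parser accepts two dialects:

* the *canonical* dialect with explicit columns
  ``gene  class  direction  start  end  anticodon  anticodon_start
  anticodon_end  start_codon  stop_codon``;
* the *published-table* dialect used by mitogenome papers, with a
  combined coordinate column (``1-68``), a direction column (F/R), and a
  combined anticodon column (``31-33 CAT``).

Unicode dashes (– —) and thousands separators are normalized at parse
time.  Coordinates are 1-based inclusive in both dialects.
"""

from __future__ import annotations

import re
from typing import Optional, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .model import AnnotatedGenome, FeatureClass, GeneFeature, PCG_NAMES

__all__ = [
    "ParseError",
    "parse_feature_table",
    "write_feature_table",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
]


class ParseError(ValueError):
    pass


_DASH_RE = re.compile(r"[‒–—―]")
_COORD_RE = re.compile(r"^(\d+)-(\d+)$")
_ANTICODON_RE = re.compile(r"^(?:(\d+)-(\d+)\s+)?([ACGTUacgtu]{3})$")

_COORD_COLUMNS = ("position", "nucleotide_number", "coordinates")


def _normalize_cell(text: str) -> str:
    text = _DASH_RE.sub("-", text).strip()
    # thousands separators inside numbers: 18,641 -> 18641
    text = re.sub(r"(?<=\d),(?=\d{3})", "", text)
    return text


def _norm_header(name: str) -> str:
    return re.sub(r"\s+", "_", _normalize_cell(name).lower())


def infer_feature_class(name: str) -> FeatureClass:
    low = name.lower()
    if name in PCG_NAMES:
        return FeatureClass.PCG
    if low.startswith("trn"):
        return FeatureClass.tRNA
    if low.startswith("rrn"):
        return FeatureClass.rRNA
    if low in {"cr", "control region", "control_region"} or "a+t-rich" in low:
        return FeatureClass.control_region
    if low in {"tru"} or "repeat" in low:
        return FeatureClass.repeat_region
    return FeatureClass.other


def _none_if_dash(value: str) -> Optional[str]:
    value = value.strip()
    return None if value in {"", "-", "--"} else value


def parse_feature_table(
    text: Union[str, TextIO],
    genome_length: Optional[int] = None,
    circular: bool = True,
) -> AnnotatedGenome:
    """Parse a feature-table TSV into an :class:`AnnotatedGenome`.

    ``genome_length`` is inferred as the maximum feature end when not
    given.  Duplicate gene names (the two leucine/serine tRNAs are
    distinct names because of their codon-family suffix) raise an error.
    """
    if hasattr(text, "read"):
        text = text.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError("no features: empty table")
    header = [_norm_header(c) for c in lines[0].split("\t")]
    col = {name: i for i, name in enumerate(header)}
    coord_col = next((c for c in _COORD_COLUMNS if c in col), None)
    if coord_col is None and not ("start" in col and "end" in col):
        raise ParseError("no coordinate columns found (need start/end or a position column)")

    features: list[GeneFeature] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        cells = [_normalize_cell(c) for c in line.split("\t")]

        def get(name: str) -> str:
            i = col.get(name)
            return cells[i] if i is not None and i < len(cells) else ""

        name = get("gene") or get("name") or get("feature")
        name = name.strip("*_ ")
        if not name:
            raise ParseError(f"line {lineno}: missing gene name")
        if name in seen:
            raise ParseError(f"line {lineno}: duplicate gene name {name!r}")
        seen.add(name)

        if coord_col is not None and get(coord_col):
            m = _COORD_RE.match(get(coord_col))
            if not m:
                raise ParseError(
                    f"line {lineno}: malformed coordinate {get(coord_col)!r} (expected start-end)"
                )
            start, end = int(m.group(1)), int(m.group(2))
        else:
            try:
                start, end = int(get("start")), int(get("end"))
            except ValueError:
                raise ParseError(f"line {lineno}: malformed start/end coordinates") from None

        direction = get("direction").upper()
        strand = {"F": "+", "R": "-", "+": "+", "-": "-", "": "+"}.get(direction)
        if strand is None:
            raise ParseError(f"line {lineno}: unknown direction {direction!r}")

        klass_cell = _none_if_dash(get("class"))
        klass = FeatureClass(klass_cell) if klass_cell else infer_feature_class(name)

        anticodon = anticodon_start = anticodon_end = None
        anti_cell = _none_if_dash(get("anticodon"))
        if anti_cell:
            m = _ANTICODON_RE.match(anti_cell)
            if not m:
                raise ParseError(f"line {lineno}: malformed anticodon {anti_cell!r}")
            anticodon = m.group(3).upper().replace("U", "T")
            if m.group(1):
                anticodon_start, anticodon_end = int(m.group(1)), int(m.group(2))
        if _none_if_dash(get("anticodon_start")) and _none_if_dash(get("anticodon_end")):
            anticodon_start = int(get("anticodon_start"))
            anticodon_end = int(get("anticodon_end"))

        features.append(
            GeneFeature(
                name=name,
                klass=klass,
                strand=strand,
                start=start,
                end=end,
                anticodon=anticodon,
                anticodon_start=anticodon_start,
                anticodon_end=anticodon_end,
                start_codon=_none_if_dash(get("start_codon")),
                stop_codon=_none_if_dash(get("stop_codon")),
            )
        )
    if not features:
        raise ParseError("no features")
    if genome_length is None:
        genome_length = max(max(f.start, f.end) for f in features)
    return AnnotatedGenome(genome_length, circular=circular, features=features)


_CANONICAL_COLUMNS = (
    "gene", "class", "direction", "start", "end",
    "anticodon", "anticodon_start", "anticodon_end", "start_codon", "stop_codon",
)


def write_feature_table(g: AnnotatedGenome) -> str:
    """Serialize to the canonical TSV dialect (lossless round trip)."""
    rows = ["\t".join(_CANONICAL_COLUMNS)]
    for f in g.features:
        rows.append(
            "\t".join(
                [
                    f.name,
                    f.klass.value,
                    "F" if f.strand == "+" else "R",
                    str(f.start),
                    str(f.end),
                    f.anticodon or "-",
                    str(f.anticodon_start) if f.anticodon_start is not None else "-",
                    str(f.anticodon_end) if f.anticodon_end is not None else "-",
                    f.start_codon or "-",
                    f.stop_codon or "-",
                ]
            )
        )
    return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# GenBank

_CLASS_TO_GBK = {
    FeatureClass.PCG: "CDS",
    FeatureClass.tRNA: "tRNA",
    FeatureClass.rRNA: "rRNA",
    FeatureClass.control_region: "D-loop",
    FeatureClass.repeat_region: "repeat_region",
    FeatureClass.other: "misc_feature",
}
_GBK_TO_CLASS = {v: k for k, v in _CLASS_TO_GBK.items()}


def _feature_location(f: GeneFeature, n: int) -> SimpleLocation:
    strand = 1 if f.strand == "+" else -1
    if f.end >= f.start:
        return SimpleLocation(f.start - 1, f.end, strand)
    # circular wrap -> join(start..n, 1..end)
    return CompoundLocation(
        [SimpleLocation(f.start - 1, n, strand), SimpleLocation(0, f.end, strand)]
    )


def write_genbank(g: AnnotatedGenome, path) -> None:
    seq = Seq(g.sequence if g.sequence is not None else "N" * g.genome_length)
    record = SeqRecord(seq, id="mitogenome", name="mitogenome", description="")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if g.circular else "linear"
    for f in g.features:
        quals = {"gene": [f.name]}
        if f.anticodon:
            anti = f.anticodon
            if f.anticodon_start is not None:
                anti = f"{f.anticodon_start}-{f.anticodon_end} {anti}"
            quals["anticodon"] = [anti]
        if f.start_codon:
            quals["start_codon"] = [f.start_codon]
        if f.stop_codon:
            quals["stop_codon"] = [f.stop_codon]
        record.features.append(
            SeqFeature(_feature_location(f, g.genome_length), type=_CLASS_TO_GBK[f.klass], qualifiers=quals)
        )
    with open(path, "w") as fh:
        SeqIO.write(record, fh, "genbank")


def read_genbank(path) -> AnnotatedGenome:
    record = SeqIO.read(path, "genbank")
    n = len(record.seq)
    seq = str(record.seq)
    circular = record.annotations.get("topology", "circular") == "circular"
    features: list[GeneFeature] = []
    for sf in record.features:
        if sf.type == "source":
            continue
        klass = _GBK_TO_CLASS.get(sf.type)
        if klass is None:
            klass = FeatureClass.other  # unknown key retained, see module docs
        name = (
            sf.qualifiers.get("gene", [None])[0]
            or sf.qualifiers.get("product", [None])[0]
            or sf.type
        )
        strand = "-" if sf.location.strand == -1 else "+"
        parts = sf.location.parts
        if len(parts) == 2 and int(parts[0].end) == n and int(parts[1].start) == 0:
            start, end = int(parts[0].start) + 1, int(parts[1].end)
        else:
            start, end = int(sf.location.start) + 1, int(sf.location.end)
        anticodon = anticodon_start = anticodon_end = None
        anti = sf.qualifiers.get("anticodon", [None])[0]
        if anti:
            m = _ANTICODON_RE.match(_normalize_cell(anti))
            if m:
                anticodon = m.group(3).upper().replace("U", "T")
                if m.group(1):
                    anticodon_start, anticodon_end = int(m.group(1)), int(m.group(2))
        features.append(
            GeneFeature(
                name=name,
                klass=klass,
                strand=strand,
                start=start,
                end=end,
                anticodon=anticodon,
                anticodon_start=anticodon_start,
                anticodon_end=anticodon_end,
                start_codon=sf.qualifiers.get("start_codon", [None])[0],
                stop_codon=sf.qualifiers.get("stop_codon", [None])[0],
            )
        )
    has_real_seq = set(seq.upper()) - {"N"} != set()
    return AnnotatedGenome(
        n, circular=circular, sequence=seq if has_real_seq else None, features=features
    )


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(g: AnnotatedGenome, path, name: str = "mitogenome") -> None:
    if g.sequence is None:
        raise ValueError("sequence-free genome")
    with open(path, "w") as fh:
        SeqIO.write(SeqRecord(Seq(g.sequence), id=name, description=""), fh, "fasta")


def read_fasta(path, genome_length: Optional[int] = None, circular: bool = True) -> AnnotatedGenome:
    record = SeqIO.read(path, "fasta")
    seq = str(record.seq).upper()
    if genome_length is not None and genome_length != len(seq):
        raise ValueError(f"FASTA length {len(seq)} != declared genome_length {genome_length}")
    return AnnotatedGenome(len(seq), circular=circular, sequence=seq)
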