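"""Bundled published annotations.

The package ships the published feature table of the *Challia fletcheri*
mitochondrial genome (GenBank JN651407), the first earwig mitogenome and,
at 20,456 bp, the largest insect mitogenome on record.  The table is kept
exactly as printed — including one anticodon-coordinate typo in
*trnL*(CUN), which :func:`mitoarch.model.validate_annotation` flags — so
that the parser and validator are exercised on real published data.

The sequence itself is not bundled; sequence-level analyses require the
GenBank record to be supplied by the user.
"""

from __future__ import annotations

from importlib import resources

from .io import parse_feature_table
from .model import AnnotatedGenome

__all__ = ["challia_fletcheri_genome"]


def challia_fletcheri_genome() -> AnnotatedGenome:
    """The annotated *C. fletcheri* mitogenome (coordinates only, no sequence)."""
    text = (
        resources.files("mitoarch.data")
        .joinpath("challia_fletcheri_jn651407.tsv")
        .read_text()
    )
    return parse_feature_table(text)
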