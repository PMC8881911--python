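"""Packaged reference tables and primer constants.

The package ships two small TSV tables describing the insect mock
communities used throughout: the pool design (individuals per taxon per
pool, eight pools of ~100 insects from 16 species) and the per-taxon trait
table (primer mismatch, amplicon GC fraction, body volume, exoskeleton
hardness) for each of the two COI primer pairs.
"""

from __future__ import annotations

from importlib import resources

from .composition import MockDesign
from .io import read_design, read_traits
from .traits import TraitTable

__all__ = [
    "PRIMER_SEQUENCES",
    "PRIMER_PAIRS",
    "AMPLICON_COORDS",
    "QUICKEXTRACT_POOLS",
    "DNEASY_POOLS",
    "load_mock_design",
    "load_trait_table",
]

#: degenerate COI mini-barcode primers (IUPAC nucleotide codes)
PRIMER_SEQUENCES = {
    "fwhF2": "GGDACWGGWTGAACWGTWTAYCCHCC",
    "fwhR2n": "GTRATWGCHCCDGCTARWACWGG",
    "HexCOIR4": "TATDGTRATDGCHCCNGC",
}

#: primer pairs used for amplification, forward-reverse
PRIMER_PAIRS = ("fwhF2-fwhR2n", "fwhF2-HexCOIR4")

#: amplicon coordinates (start, end) within the conventional COI barcode,
#: excluding primers; length is end - start
AMPLICON_COORDS = {
    "fwhF2-fwhR2n": (346, 551),
    "fwhF2-HexCOIR4": (346, 560),
}

#: pools non-destructively extracted with each kit
QUICKEXTRACT_POOLS = (1, 2, 3, 4)
DNEASY_POOLS = (5, 6, 7, 8)


def _data_path(name: str):
    return resources.files("mockbias.data").joinpath(name)


def load_mock_design() -> MockDesign:
    """The packaged eight-pool mock-community design table."""
    with resources.as_file(_data_path("mock_design.tsv")) as path:
        return read_design(path)


def load_trait_table() -> TraitTable:
    """The packaged per-taxon trait table for both primer pairs."""
    with resources.as_file(_data_path("trait_table.tsv")) as path:
        return read_traits(path)
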