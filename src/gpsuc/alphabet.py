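"""Canonical amino-acid alphabet and window geometry constants.

Every encoder, profile parser and model in the package indexes amino acids
in the single canonical order defined here; external orderings (e.g. the
PSI-BLAST PSSM column order) are remapped on ingest.
"""

from __future__ import annotations

#: Canonical 20-letter alphabet, alphabetical by one-letter code.
CANONICAL = "ACDEFGHIKLMNPQRSTVWY"

#: Index of each canonical residue.
AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL)}

#: Unknown residue symbol (treated like a gap by all encoders).
UNKNOWN = "X"

#: Terminal padding symbol used in sequence windows.
GAP = "-"

#: Residue letters legal in an ingested protein sequence.
SEQUENCE_LETTERS = frozenset(CANONICAL) | {UNKNOWN}

#: Flank length on each side of the central lysine.
FLANK = 20

#: Total window length (centre + two flanks).
WINDOW = 2 * FLANK + 1

#: Native column order of PSI-BLAST ASCII PSSM files.
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Fixed fusion-channel order used by the score-fusion model.
CHANNEL_ORDER = ("AAC", "AAindex", "BE", "PSSM", "pCKSAAP")


def window_offsets() -> range:
    """Offsets of window positions relative to the centre: -20 .. +20."""
    return range(-FLANK, FLANK + 1)


def offset_label(offset: int) -> str:
    """Human-readable window-position label: ``pos-7``, ``pos0``, ``pos+3``."""
    return f"pos{offset:+d}" if offset else "pos0"
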