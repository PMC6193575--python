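"""Sequence and site-annotation I/O, window extraction, training-set assembly.

Succinylation predictors operate on fixed 41-residue fragments centred on a
candidate lysine (+/-20 flank); fragments that overhang a protein terminus
are padded with ``-``. This module reads FASTA sequences and tab-separated
site annotations, extracts such windows, and assembles labelled training
sets at the 1:2 positive:negative ratio used for model fitting.

All public coordinates are 1-based and inclusive, matching UniProt site
annotation practice.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .alphabet import FLANK, GAP, SEQUENCE_LETTERS, WINDOW

__all__ = [
    "ProteinRecord",
    "SiteLabel",
    "SequenceWindow",
    "read_fasta",
    "read_sites",
    "enumerate_lysines",
    "extract_window",
    "sample_training_set",
]

POSITIVE = "positive"
NEGATIVE = "negative"

_LABEL_TOKENS = {
    "positive": POSITIVE,
    "1": POSITIVE,
    "+1": POSITIVE,
    "negative": NEGATIVE,
    "-1": NEGATIVE,
}


class ParseError(ValueError):
    """Raised when an input file violates its expected format."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence over the 20 canonical letters plus ``X``."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.id!r}")
        bad = set(self.sequence) - SEQUENCE_LETTERS
        if bad:
            raise ValueError(
                f"illegal residue characters {sorted(bad)} in protein {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteLabel:
    """A labelled candidate site: 1-based lysine position in a protein."""

    protein_id: str
    position: int
    label: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(
                f"positions are 1-based; got {self.position} for {self.protein_id!r}"
            )
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class SequenceWindow:
    """41-symbol fragment centred on a lysine, with provenance.

    ``symbols`` contains amino-acid letters, ``X`` and the terminal padding
    symbol ``-``; padding only ever occurs as a contiguous prefix and/or
    suffix. Position 21 (1-based; index 20) is the site lysine itself.
    """

    symbols: str
    protein_id: str
    site_position: int
    label: str | None = None

    def __post_init__(self) -> None:
        if len(self.symbols) != WINDOW:
            raise ValueError(
                f"window must have {WINDOW} symbols, got {len(self.symbols)}"
            )
        if self.symbols[FLANK] != "K":
            raise ValueError("window centre must be the lysine 'K'")
        core = self.symbols.strip(GAP)
        if GAP in core:
            raise ValueError("padding '-' must be confined to the window ends")

    @property
    def centre(self) -> str:
        return self.symbols[FLANK]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased on ingest. Duplicate record ids and residue
    characters outside the canonical alphabet (plus ``X``; a trailing stop
    ``*`` is stripped) are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().rstrip("*")
        bad = set(seq) - SEQUENCE_LETTERS
        if bad:
            raise ParseError(
                f"illegal residue characters {sorted(bad)} in record {rec.id!r}"
            )
        if not seq:
            raise ParseError(f"empty sequence for record {rec.id!r}")
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise ParseError(f"no FASTA records found in {path}")
    return records


def read_sites(
    path: str | Path,
    proteins: Iterable[ProteinRecord] | None = None,
) -> list[SiteLabel]:
    """Read a sites TSV (``protein_id<TAB>position<TAB>label``, with header).

    Label tokens ``positive``/``1``/``+1`` and ``negative``/``-1`` are
    accepted. When ``proteins`` is given, each site is validated against the
    sequence: the position must be in range and the residue must be ``K``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    by_id = {p.id: p for p in proteins} if proteins is not None else None
    sites: list[SiteLabel] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"empty sites file {path}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 tab-separated fields")
            pid, pos_s, label_s = parts
            try:
                position = int(pos_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer position {pos_s!r}")
            token = label_s.strip().lower()
            if token not in _LABEL_TOKENS:
                raise ParseError(f"{path}:{lineno}: unknown label token {label_s!r}")
            if position < 1:
                raise ParseError(f"{path}:{lineno}: positions are 1-based, got {position}")
            if by_id is not None:
                if pid not in by_id:
                    raise ParseError(f"{path}:{lineno}: unknown protein id {pid!r}")
                seq = by_id[pid].sequence
                if position > len(seq):
                    raise ParseError(
                        f"{path}:{lineno}: position {position} beyond length {len(seq)}"
                    )
                if seq[position - 1] != "K":
                    raise ParseError(
                        f"{path}:{lineno}: residue at position {position} is "
                        f"{seq[position - 1]!r}, not 'K'"
                    )
            sites.append(SiteLabel(pid, position, _LABEL_TOKENS[token]))
    return sites


def write_sites(sites: Iterable[SiteLabel], path: str | Path) -> None:
    """Write sites to the TSV dialect read by :func:`read_sites`."""
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tlabel\n")
        for s in sites:
            fh.write(f"{s.protein_id}\t{s.position}\t{s.label}\n")


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as unwrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def enumerate_lysines(record: ProteinRecord) -> list[int]:
    """All 1-based positions of ``K`` in the sequence, ascending."""
    return [i + 1 for i, aa in enumerate(record.sequence) if aa == "K"]


def extract_window(record: ProteinRecord, position: int, label: str | None = None) -> SequenceWindow:
    """Extract the ±20 window around a lysine, padding overhangs with ``-``."""
    seq = record.sequence
    if not 1 <= position <= len(seq):
        raise ValueError(
            f"position {position} out of range 1..{len(seq)} for {record.id!r}"
        )
    if seq[position - 1] != "K":
        raise ValueError(
            f"residue at {record.id!r}:{position} is {seq[position - 1]!r}, not 'K'"
        )
    i = position - 1
    lo, hi = i - FLANK, i + FLANK + 1
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(seq))
    core = seq[max(lo, 0) : min(hi, len(seq))]
    return SequenceWindow(
        symbols=GAP * left_pad + core + GAP * right_pad,
        protein_id=record.id,
        site_position=position,
        label=label,
    )


def windows_for_sites(
    proteins: Sequence[ProteinRecord], sites: Iterable[SiteLabel]
) -> list[SequenceWindow]:
    """Extract one labelled window per site."""
    by_id = {p.id: p for p in proteins}
    return [extract_window(by_id[s.protein_id], s.position, s.label) for s in sites]


def sample_training_set(
    positives: Sequence[SequenceWindow],
    negatives: Sequence[SequenceWindow],
    seed: int,
) -> list[SequenceWindow]:
    """Assemble a training set at the 1:2 positive:negative ratio.

    All positives are retained; negatives are sampled without replacement
    down to twice the positive count. If fewer negatives are available, all
    are used and a warning is emitted. Deterministic given ``seed``.
    """
    n_wanted = 2 * len(positives)
    rng = random.Random(seed)
    if len(negatives) < n_wanted:
        warnings.warn(
            f"only {len(negatives)} negatives available for {len(positives)} "
            f"positives; 1:2 ratio not reachable, using all negatives",
            stacklevel=2,
        )
        chosen = list(negatives)
    else:
        chosen = rng.sample(list(negatives), n_wanted)
    return list(positives) + chosen
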