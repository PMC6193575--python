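"""Position-specific scoring matrices: parsing, windowing, pseudo-profiles.

Evolutionary features come from PSI-BLAST profiles (log-odds PSSMs). Only
the output format is handled here — running the search itself is an
external preprocessing step (the reference settings are an e-value cutoff
of 1e-4 and 3 iterations against a non-redundant protein database). For
fully self-contained runs a deterministic pseudo-profile built from the
BLOSUM62 substitution table stands in for a real search profile.

Profiles are L×20 matrices with columns in the package's canonical
alphabet order; the PSI-BLAST native column order is remapped at parse
time. Profile windows mirror sequence windows: 41 rows, with rows at
padded (``-``) or unknown (``X``) positions set to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from .alphabet import CANONICAL, FLANK, PSIBLAST_ORDER, WINDOW
from .seqio import ProteinRecord

__all__ = [
    "PssmProfile",
    "ProfileWindow",
    "read_psiblast_pssm",
    "write_pssm",
    "pseudo_profile",
    "profile_window",
    "load_profile_dir",
    "profiles_for",
]

# column permutation: canonical index -> position in PSI-BLAST native order
_PSIBLAST_TO_CANONICAL = [PSIBLAST_ORDER.index(aa) for aa in CANONICAL]


@dataclass(frozen=True)
class PssmProfile:
    """L×20 log-odds profile aligned to a protein sequence.

    Rows are 1-based sequence positions; columns follow the canonical
    alphabet order ``ACDEFGHIKLMNPQRSTVWY``.
    """

    protein_id: str
    scores: np.ndarray
    source: str = "psiblast"

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 2 or scores.shape[1] != len(CANONICAL):
            raise ValueError(f"profile must be L x 20, got {scores.shape}")
        if not np.isfinite(scores).all():
            raise ValueError("profile contains non-finite values")
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class ProfileWindow:
    """41×20 profile slice aligned to a sequence window."""

    rows: np.ndarray
    protein_id: str
    site_position: int

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=float)
        if rows.shape != (WINDOW, len(CANONICAL)):
            raise ValueError(f"profile window must be {WINDOW} x 20, got {rows.shape}")
        object.__setattr__(self, "rows", rows)


class PssmParseError(ValueError):
    """Raised when a PSI-BLAST ASCII PSSM file cannot be parsed."""


def read_psiblast_pssm(
    path: str | Path,
    protein_id: str | None = None,
    sequence: str | None = None,
) -> PssmProfile:
    """Parse an ASCII PSSM as written by PSI-BLAST ``-out_ascii_pssm``.

    Only the first 20 columns (log-odds scores) are read; the weighted
    percentage and information-content columns are ignored. Columns are
    remapped from the file's native order to the canonical alphabet. When
    ``sequence`` is given, the residue letter of each row is cross-checked
    against it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[list[float]] = []
    letters: list[str] = []
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not header_seen:
                # the column-header line lists the 20 residue letters twice
                if len(fields) >= 20 and all(len(f) == 1 and f.isalpha() for f in fields[:20]):
                    if "".join(fields[:20]) != PSIBLAST_ORDER:
                        raise PssmParseError(
                            f"{path}:{lineno}: unexpected PSSM column order"
                        )
                    header_seen = True
                continue
            if len(fields) < 22 or not fields[0].isdigit():
                break  # trailer (Lambda/K statistics) or blank line
            idx = int(fields[0])
            if idx != len(rows) + 1:
                raise PssmParseError(
                    f"{path}:{lineno}: row index {idx}, expected {len(rows) + 1}"
                )
            try:
                values = [float(v) for v in fields[2:22]]
            except ValueError:
                raise PssmParseError(f"{path}:{lineno}: non-numeric PSSM cell")
            letters.append(fields[1].upper())
            rows.append(values)
    if not header_seen or not rows:
        raise PssmParseError(f"{path}: truncated or unrecognised PSSM file")
    if sequence is not None:
        if len(sequence) != len(rows):
            raise PssmParseError(
                f"{path}: {len(rows)} PSSM rows but sequence length {len(sequence)}"
            )
        for i, (a, b) in enumerate(zip(letters, sequence.upper()), start=1):
            if b != "X" and a != b:
                raise PssmParseError(
                    f"{path}: row {i} residue {a!r} disagrees with sequence {b!r}"
                )
    scores = np.asarray(rows, dtype=float)[:, _PSIBLAST_TO_CANONICAL]
    return PssmProfile(
        protein_id=protein_id or path.stem, scores=scores, source="psiblast"
    )


def write_pssm(profile: PssmProfile, path: str | Path, sequence: str | None = None) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect read back by
    :func:`read_psiblast_pssm` (native column order, dummy trailer columns)."""
    canonical_to_native = [CANONICAL.index(aa) for aa in PSIBLAST_ORDER]
    native = profile.scores[:, canonical_to_native]
    letters = sequence.upper() if sequence else "K" * len(profile)
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write("            " + "  ".join(PSIBLAST_ORDER) + "  " + "  ".join(PSIBLAST_ORDER) + "\n")
        for i, row in enumerate(native, start=1):
            cells = " ".join(f"{v:7.2f}" for v in row)
            dummies = " ".join("0" for _ in range(20))
            fh.write(f"{i:5d} {letters[i - 1]} {cells} {dummies} 0.00 0.00\n")
        fh.write("\n                      K         Lambda\n")


_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_BLOSUM_ROWS = {
    aa: np.array([float(_BLOSUM62[aa, b]) for b in CANONICAL]) for aa in CANONICAL
}


def pseudo_profile(record: ProteinRecord) -> PssmProfile:
    """Deterministic substitution-table profile for a protein.

    Row *r*, column *a* holds the BLOSUM62 score between ``sequence[r]``
    and amino acid *a*; rows at ``X`` positions are all zero. This mimics
    the single-sequence profile PSI-BLAST emits when a query finds no
    homologs, and lets the whole pipeline run without an external search.
    """
    zero = np.zeros(len(CANONICAL))
    scores = np.stack(
        [_BLOSUM_ROWS.get(aa, zero) for aa in record.sequence]
    )
    return PssmProfile(protein_id=record.id, scores=scores, source="pseudo")


def profile_window(profile: PssmProfile, position: int) -> ProfileWindow:
    """Slice the ±20 profile window around a 1-based position.

    Rows that fall outside the protein are zero-filled, mirroring the
    ``-`` padding of the companion sequence window.
    """
    length = len(profile)
    if not 1 <= position <= length:
        raise ValueError(f"position {position} out of range 1..{length}")
    out = np.zeros((WINDOW, len(CANONICAL)))
    i = position - 1
    lo, hi = i - FLANK, i + FLANK + 1
    src_lo, src_hi = max(lo, 0), min(hi, length)
    out[src_lo - lo : src_hi - lo] = profile.scores[src_lo:src_hi]
    return ProfileWindow(rows=out, protein_id=profile.protein_id, site_position=position)


def load_profile_dir(
    directory: str | Path,
    proteins: list[ProteinRecord],
    missing: str = "pseudo",
) -> dict[str, PssmProfile]:
    """Load one ``<dir>/<protein_id>.pssm`` per protein.

    ``missing``: ``pseudo`` substitutes a pseudo-profile for proteins with
    no file; ``error`` raises instead.
    """
    directory = Path(directory)
    out: dict[str, PssmProfile] = {}
    for rec in proteins:
        path = directory / f"{rec.id}.pssm"
        if path.exists():
            out[rec.id] = read_psiblast_pssm(path, rec.id, rec.sequence)
        elif missing == "pseudo":
            out[rec.id] = pseudo_profile(rec)
        else:
            raise FileNotFoundError(path)
    return out


def profiles_for(proteins: list[ProteinRecord]) -> dict[str, PssmProfile]:
    """Pseudo-profiles for every protein, keyed by id."""
    return {rec.id: pseudo_profile(rec) for rec in proteins}
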