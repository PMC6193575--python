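"""Window feature encoders: AAC, BE, AAindex, PSSM and pCKSAAP.

Each candidate site is described by five fixed-width feature blocks
computed from its 41-residue sequence window and the aligned 41×20
profile window:

``AAC``
    amino-acid composition of the window, centre excluded (20 features);
``BE``
    one-hot binary encoding of each window position (41×20 = 820);
``AAindex``
    per-position physicochemical property values from a set of amino-acid
    index scales (41×12 = 492 with the default 12-scale table);
``PSSM``
    the flattened profile window (41×20 = 820);
``pCKSAAP``
    profile-based composition of k-spaced amino-acid pairs. For spacing
    k and ordered residue pair (a, b),

        S_ab(k) = sum_r max(min(P[r, a], P[r + k + 1, b]), 0) / (L - k - 1)

    over window rows r = 1..L-k-1 (L = 41); with k in {0,1,2,3,4} this
    gives 5 × 400 = 2000 non-negative features.

Padding (``-``) and unknown (``X``) positions contribute zeros everywhere,
and the AAC denominator counts only observed flank residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX, CANONICAL, FLANK, GAP, UNKNOWN, WINDOW, offset_label, window_offsets
from .profiles import ProfileWindow
from .seqio import SequenceWindow

__all__ = [
    "AAIndexTable",
    "FeatureBlock",
    "FeatureMatrix",
    "default_aaindex_table",
    "encode_aac",
    "encode_binary",
    "encode_aaindex",
    "encode_pssm",
    "encode_pcksaap",
    "encode_all",
    "build_feature_matrix",
]

DEFAULT_K_VALUES = (0, 1, 2, 3, 4)

ENCODING_NAMES = ("AAC", "AAindex", "BE", "PSSM", "pCKSAAP")


class AAIndexTable:
    """A set of amino-acid property scales keyed by accession.

    Each scale maps the 20 canonical residues to a real value; ``NA``
    entries of the source database are replaced by 0 on ingest.
    """

    def __init__(self, values: Mapping[str, Mapping[str, float]]):
        self.index_ids: list[str] = list(values)
        if not self.index_ids:
            raise ValueError("AAIndexTable needs at least one index")
        self._matrix = np.zeros((len(self.index_ids), len(CANONICAL)))
        for i, acc in enumerate(self.index_ids):
            scale = values[acc]
            missing = [aa for aa in CANONICAL if aa not in scale]
            if missing:
                warnings.warn(
                    f"index {acc}: residues {missing} missing, treated as 0",
                    stacklevel=2,
                )
            for j, aa in enumerate(CANONICAL):
                v = scale.get(aa, 0.0)
                self._matrix[i, j] = 0.0 if v is None or not np.isfinite(v) else v

    def __len__(self) -> int:
        return len(self.index_ids)

    def value(self, accession: str, residue: str) -> float:
        """Property value of a residue under one scale (gap/X give 0)."""
        i = self.index_ids.index(accession)
        j = AA_INDEX.get(residue)
        return 0.0 if j is None else float(self._matrix[i, j])

    def column(self, residue: str) -> np.ndarray:
        """All index values for one residue (zeros for gap/X)."""
        j = AA_INDEX.get(residue)
        if j is None:
            return np.zeros(len(self.index_ids))
        return self._matrix[:, j].copy()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AAIndexTable":
        df = pd.read_csv(path, sep="\t", comment="#").set_index("accession")
        return cls({acc: df.loc[acc].to_dict() for acc in df.index})


_DEFAULT_TABLE: AAIndexTable | None = None


def default_aaindex_table() -> AAIndexTable:
    """The packaged 12-scale table (accessions named in the method)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        with resources.as_file(
            resources.files("gpsuc.data").joinpath("aaindex12.tsv")
        ) as path:
            _DEFAULT_TABLE = AAIndexTable.from_tsv(path)
    return _DEFAULT_TABLE


@dataclass(frozen=True)
class FeatureBlock:
    """One encoding's named feature vector for a single window."""

    encoding_name: str
    feature_names: tuple[str, ...]
    vector: np.ndarray

    def __post_init__(self) -> None:
        vec = np.asarray(self.vector, dtype=float)
        if vec.shape != (len(self.feature_names),):
            raise ValueError("feature names and values misaligned")
        object.__setattr__(self, "vector", vec)

    @property
    def width(self) -> int:
        return len(self.feature_names)


def _observed(symbol: str) -> bool:
    return symbol != GAP and symbol != UNKNOWN


def encode_aac(window: SequenceWindow) -> FeatureBlock:
    """Amino-acid composition of the window, centre excluded.

    Frequencies are over observed flank residues only (gaps and ``X`` do
    not enter the denominator); a window with all-gap flanks yields the
    zero vector.
    """
    counts = np.zeros(len(CANONICAL))
    total = 0
    for i, aa in enumerate(window.symbols):
        if i == FLANK or not _observed(aa):
            continue
        counts[AA_INDEX[aa]] += 1
        total += 1
    vec = counts / total if total else counts
    names = tuple(f"AAC:{aa}" for aa in CANONICAL)
    return FeatureBlock("AAC", names, vec)


_BE_NAMES = tuple(
    f"BE:{offset_label(off)}:{aa}" for off in window_offsets() for aa in CANONICAL
)


def encode_binary(window: SequenceWindow) -> FeatureBlock:
    """One-hot encoding: 20 indicators per window position (820 total)."""
    vec = np.zeros(WINDOW * len(CANONICAL))
    for i, aa in enumerate(window.symbols):
        j = AA_INDEX.get(aa)
        if j is not None:
            vec[i * len(CANONICAL) + j] = 1.0
    return FeatureBlock("BE", _BE_NAMES, vec)


def decode_binary(block: FeatureBlock) -> str:
    """Invert :func:`encode_binary`; all-zero position blocks become ``-``."""
    symbols = []
    mat = block.vector.reshape(WINDOW, len(CANONICAL))
    for row in mat:
        hits = np.nonzero(row)[0]
        symbols.append(CANONICAL[hits[0]] if hits.size else GAP)
    return "".join(symbols)


def encode_aaindex(window: SequenceWindow, table: AAIndexTable | None = None) -> FeatureBlock:
    """Per-position property values, position-major layout (41×n_indices)."""
    table = table or default_aaindex_table()
    parts = [table.column(aa) for aa in window.symbols]
    names = tuple(
        f"AAindex:{offset_label(off)}:{acc}"
        for off in window_offsets()
        for acc in table.index_ids
    )
    return FeatureBlock("AAindex", names, np.concatenate(parts))


_PSSM_NAMES = tuple(
    f"PSSM:{offset_label(off)}:{aa}" for off in window_offsets() for aa in CANONICAL
)


def encode_pssm(pwin: ProfileWindow) -> FeatureBlock:
    """Row-major flattening of the 41×20 profile window (820 features)."""
    return FeatureBlock("PSSM", _PSSM_NAMES, pwin.rows.reshape(-1))


def _pcksaap_names(k_values: Sequence[int]) -> tuple[str, ...]:
    return tuple(
        f"pCKSAAP:k{k}:{a}{b}" for k in k_values for a in CANONICAL for b in CANONICAL
    )


def encode_pcksaap(
    pwin: ProfileWindow, k_values: Sequence[int] = DEFAULT_K_VALUES
) -> FeatureBlock:
    """Profile-based k-spaced pair composition over the profile window.

    For each spacing k and ordered pair (a, b), the positive part of the
    elementwise minimum of the two profile scores is summed over all row
    pairs (r, r+k+1) and divided by the number of such pairs, L-k-1.
    Features are ordered k-major, then pair-lexicographic in the canonical
    alphabet. All values are non-negative by construction.
    """
    L = WINDOW
    P = pwin.rows
    parts = []
    for k in k_values:
        if k >= L - 1:
            raise ValueError(f"spacing k={k} too large for window length {L}")
        A = P[: L - k - 1, :]  # rows r
        B = P[k + 1 :, :]  # rows r + k + 1
        pair = np.maximum(np.minimum(A[:, :, None], B[:, None, :]), 0.0)
        parts.append(pair.sum(axis=0).reshape(-1) / (L - k - 1))
    return FeatureBlock("pCKSAAP", _pcksaap_names(k_values), np.concatenate(parts))


def encode_all(
    window: SequenceWindow,
    pwin: ProfileWindow,
    table: AAIndexTable | None = None,
    k_values: Sequence[int] = DEFAULT_K_VALUES,
) -> list[FeatureBlock]:
    """All five feature blocks for an aligned window/profile pair."""
    if (window.protein_id, window.site_position) != (pwin.protein_id, pwin.site_position):
        raise ValueError(
            "sequence window and profile window refer to different sites"
        )
    return [
        encode_aac(window),
        encode_aaindex(window, table),
        encode_binary(window),
        encode_pssm(pwin),
        encode_pcksaap(pwin, k_values),
    ]


@dataclass
class FeatureMatrix:
    """Named feature vectors per window, partitioned into encoding blocks.

    ``frame`` holds one row per window (index = (protein_id, position))
    and one column per feature; ``blocks`` maps each encoding name to its
    ordered column list. ``labels`` is +1/-1 aligned to the rows, or None
    for unlabelled prediction sets.
    """

    frame: pd.DataFrame
    blocks: dict[str, list[str]]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        cols = [c for names in self.blocks.values() for c in names]
        if list(self.frame.columns) != cols:
            raise ValueError("frame columns disagree with block layout")
        if len(set(cols)) != len(cols):
            raise ValueError("duplicate feature names")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != len(self.frame):
                raise ValueError("labels misaligned with rows")

    @property
    def n_samples(self) -> int:
        return len(self.frame)

    def block_values(self, encoding: str) -> np.ndarray:
        return self.frame[self.blocks[encoding]].to_numpy()

    def subset_rows(self, indices: np.ndarray) -> "FeatureMatrix":
        labels = None if self.labels is None else self.labels[indices]
        return FeatureMatrix(self.frame.iloc[indices], dict(self.blocks), labels)

    def to_tsv(self, path: str | Path) -> None:
        """Export with provenance columns first, then named features."""
        out = self.frame.copy()
        out.insert(0, "protein_id", [i[0] for i in self.frame.index])
        out.insert(1, "position", [i[1] for i in self.frame.index])
        if self.labels is not None:
            out.insert(2, "label", self.labels)
        out.to_csv(path, sep="\t", index=False)


def build_feature_matrix(
    windows: Sequence[SequenceWindow],
    profile_windows: Sequence[ProfileWindow],
    table: AAIndexTable | None = None,
    k_values: Sequence[int] = DEFAULT_K_VALUES,
) -> FeatureMatrix:
    """Encode aligned windows into a :class:`FeatureMatrix`.

    Labels are taken from the windows when every window carries one
    (+1 for positive, -1 for negative).
    """
    if len(windows) != len(profile_windows):
        raise ValueError("windows and profile windows differ in length")
    table = table or default_aaindex_table()
    rows = []
    names: list[str] | None = None
    blocks: dict[str, list[str]] = {}
    for win, pwin in zip(windows, profile_windows):
        fb = encode_all(win, pwin, table, k_values)
        if names is None:
            names = [n for b in fb for n in b.feature_names]
            blocks = {b.encoding_name: list(b.feature_names) for b in fb}
        rows.append(np.concatenate([b.vector for b in fb]))
    index = pd.MultiIndex.from_tuples(
        [(w.protein_id, w.site_position) for w in windows],
        names=["protein_id", "position"],
    )
    frame = pd.DataFrame(np.asarray(rows), index=index, columns=names)
    labels = None
    if windows and all(w.label is not None for w in windows):
        labels = np.array([1 if w.label == "positive" else -1 for w in windows])
    return FeatureMatrix(frame, blocks, labels)
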