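"""Wilcoxon rank-sum feature screening and per-encoding top-N selection.

Each feature column is scored by a two-sample Wilcoxon rank-sum (Mann-
Whitney) test between positive and negative windows. W is the sum of the
mid-ranks of the positive group in the pooled sample. The permutation
p-value is computed exactly when the number of rank assignments
C(r+s, r) is small, and by a tie-corrected, continuity-corrected normal
approximation otherwise; the reported two-sided p is
min(1, 2*min(P_upper, P_lower)).

Features are then ordered from most to least discriminative (ascending p,
ties broken by original column position) and the high-dimensional
pCKSAAP and AAindex blocks are cut to a per-encoding top-N, while AAC,
BE and PSSM are retained in full.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .encoders import FeatureMatrix

__all__ = [
    "WRResult",
    "SelectionPlan",
    "wilcoxon_rank_sum",
    "rank_features",
    "build_selection_plan",
    "apply_selection",
    "GENERIC_TOP_N",
    "SPECIES_TOP_N",
]

#: Default exact-mode gate: full-enumeration p when C(r+s, r) is below this.
EXACT_LIMIT = 200_000

#: Generic-model per-encoding retention (the other encodings stay full width).
GENERIC_TOP_N: dict[str, int] = {"pCKSAAP": 390, "AAindex": 250}

#: Species-specific retention presets: encoding -> top-N.
SPECIES_TOP_N: dict[str, dict[str, int]] = {
    "h_sapiens": {"AAindex": 260, "pCKSAAP": 440},
    "h_capsulatum": {"AAindex": 200, "pCKSAAP": 340},
    "m_musculus": {"AAindex": 150, "pCKSAAP": 390},
    "e_coli": {"AAindex": 200, "pCKSAAP": 350},
    "m_tuberculosis": {"AAindex": 240, "pCKSAAP": 350},
    "s_cerevisiae": {"AAindex": 220, "pCKSAAP": 450},
    "t_gondii": {"AAindex": 150, "pCKSAAP": 290},
    "s_lycopersicum": {"AAindex": 250, "pCKSAAP": 450},
    "t_aestivum": {"AAindex": 120, "pCKSAAP": 400},
}


@dataclass(frozen=True)
class WRResult:
    """Wilcoxon rank-sum outcome for a single feature."""

    feature_name: str
    W: float
    r: int
    s: int
    p_value: float
    method: str  # "exact" | "normal"


def _rank_sum_distribution(doubled_ranks: np.ndarray, r: int) -> np.ndarray:
    """Count r-subsets of the doubled mid-ranks by subset sum.

    Mid-ranks are half-integers, so doubling makes them exact integers and
    the full enumeration over C(r+s, r) rank assignments collapses to a
    subset-sum polynomial product. Returns counts indexed by doubled sum.
    """
    total = int(doubled_ranks.sum())
    # counts[j, s] = number of size-j subsets with doubled-rank sum s
    counts = np.zeros((r + 1, total + 1), dtype=float)
    counts[0, 0] = 1.0
    for value in doubled_ranks:
        v = int(value)
        # reverse-order update so an item is used at most once per subset
        for j in range(r, 0, -1):
            counts[j, v:] += counts[j - 1, : total + 1 - v]
    return counts[r]


def wilcoxon_rank_sum(
    pos_values: Sequence[float],
    neg_values: Sequence[float],
    method: str = "auto",
    feature_name: str = "",
) -> WRResult:
    """Two-sample Wilcoxon rank-sum test with mid-ranks for ties.

    ``method``: ``auto`` picks exact when C(r+s, r) <= 200,000 and the
    normal approximation otherwise; ``exact``/``normal`` force a mode.
    The exact mode is a full enumeration over all rank assignments
    (computed by dynamic programming over the rank-sum distribution).
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    r, s = len(pos), len(neg)
    if r == 0 or s == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([pos, neg])
    ranks = stats.rankdata(pooled)
    W = float(ranks[:r].sum())
    n = r + s
    if method == "auto":
        method = "exact" if math.comb(n, r) <= EXACT_LIMIT else "normal"
    if method == "exact":
        doubled = np.rint(2 * ranks).astype(int)
        dist = _rank_sum_distribution(doubled, r)
        total = math.comb(n, r)
        w2 = int(round(2 * W))
        p_upper = dist[w2:].sum() / total
        p_lower = dist[: w2 + 1].sum() / total
    elif method == "normal":
        mean = r * (n + 1) / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts**3) - tie_counts).sum())
        var = r * s / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:  # constant column
            return WRResult(feature_name, W, r, s, 1.0, "normal")
        sd = math.sqrt(var)
        p_upper = float(stats.norm.sf((W - 0.5 - mean) / sd))
        p_lower = float(stats.norm.cdf((W + 0.5 - mean) / sd))
    else:
        raise ValueError(f"unknown method {method!r}")
    p = min(1.0, 2.0 * min(p_upper, p_lower))
    return WRResult(feature_name, W, r, s, p, method)


def _normal_p_matrix(X: np.ndarray, pos_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised tie-corrected normal-approximation p per column."""
    n, p = X.shape
    r = int(pos_mask.sum())
    s = n - r
    ranks = stats.rankdata(X, axis=0)
    W = ranks[pos_mask].sum(axis=0)
    mean = r * (n + 1) / 2.0
    tie_terms = np.empty(p)
    for j in range(p):  # per-column tie runs
        counts = np.unique(X[:, j], return_counts=True)[1]
        tie_terms[j] = float(((counts**3) - counts).sum())
    var = r * s / 12.0 * ((n + 1) - tie_terms / (n * (n - 1)))
    pvals = np.ones(p)
    ok = var > 0
    sd = np.sqrt(var[ok])
    p_upper = stats.norm.sf((W[ok] - 0.5 - mean) / sd)
    p_lower = stats.norm.cdf((W[ok] + 0.5 - mean) / sd)
    pvals[ok] = np.minimum(1.0, 2.0 * np.minimum(p_upper, p_lower))
    return W, pvals


def rank_features(
    matrix: FeatureMatrix,
    labels: np.ndarray | None = None,
    method: str = "auto",
) -> list[WRResult]:
    """Score every feature column and order by ascending p-value.

    Ties in p are broken by original column index, so the ranking is
    deterministic and invariant to row order. Constant columns get p = 1
    and sort last.
    """
    labels = matrix.labels if labels is None else np.asarray(labels)
    if labels is None:
        raise ValueError("labels required for feature ranking")
    pos_mask = labels == 1
    r, s = int(pos_mask.sum()), int((~pos_mask).sum())
    if r == 0 or s == 0:
        raise ValueError("both classes must be present")
    X = matrix.frame.to_numpy()
    names = list(matrix.frame.columns)
    if method == "auto":
        method = "exact" if math.comb(r + s, r) <= EXACT_LIMIT else "normal"
    if method == "normal":
        W, pvals = _normal_p_matrix(X, pos_mask)
        results = [
            WRResult(names[j], float(W[j]), r, s, float(pvals[j]), "normal")
            for j in range(len(names))
        ]
    else:
        results = [
            wilcoxon_rank_sum(X[pos_mask, j], X[~pos_mask, j], method, names[j])
            for j in range(len(names))
        ]
    order = sorted(range(len(results)), key=lambda j: (results[j].p_value, j))
    return [results[j] for j in order]


@dataclass
class SelectionPlan:
    """Per-encoding ordered retained-feature lists.

    ``retained`` maps encoding name to the ordered feature names kept
    (most discriminative first); ``top_n`` records the requested cut.
    """

    retained: dict[str, list[str]]
    top_n: dict[str, int]
    p_values: dict[str, list[float]] = field(default_factory=dict)

    @property
    def all_columns(self) -> list[str]:
        return [c for names in self.retained.values() for c in names]

    def to_json(self, path: str | Path) -> None:
        payload = {
            enc: {
                "top_n": self.top_n[enc],
                "features": self.retained[enc],
                "p_values": self.p_values.get(enc, []),
            }
            for enc in self.retained
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionPlan":
        payload = json.loads(Path(path).read_text())
        return cls(
            retained={enc: d["features"] for enc, d in payload.items()},
            top_n={enc: d["top_n"] for enc, d in payload.items()},
            p_values={enc: d.get("p_values", []) for enc, d in payload.items()},
        )


def build_selection_plan(
    rankings: Sequence[WRResult],
    top_n_by_encoding: Mapping[str, int] | None = None,
    block_layout: Mapping[str, Sequence[str]] | None = None,
) -> SelectionPlan:
    """Cut a ranked feature list to per-encoding top-N sets.

    ``rankings`` is the ascending-p output of :func:`rank_features` over
    all encodings; features are grouped by the encoding prefix of their
    name. Encodings without an entry in ``top_n_by_encoding`` (default:
    the generic preset, pCKSAAP 390 / AAindex 250) are retained in full.
    """
    top_n_by_encoding = dict(GENERIC_TOP_N if top_n_by_encoding is None else top_n_by_encoding)
    by_enc: dict[str, list[WRResult]] = {}
    for res in rankings:
        enc = res.feature_name.split(":", 1)[0]
        by_enc.setdefault(enc, []).append(res)
    if block_layout is not None:
        for enc in block_layout:
            by_enc.setdefault(enc, [])
    retained: dict[str, list[str]] = {}
    top_n: dict[str, int] = {}
    p_values: dict[str, list[float]] = {}
    for enc, results in by_enc.items():
        n = top_n_by_encoding.get(enc, len(results))
        if n > len(results):
            raise ValueError(
                f"top_n={n} exceeds {len(results)} available {enc} features"
            )
        keep = results[:n]
        retained[enc] = [r.feature_name for r in keep]
        p_values[enc] = [r.p_value for r in keep]
        top_n[enc] = n
    return SelectionPlan(retained, top_n, p_values)


def apply_selection(matrix: FeatureMatrix, plan: SelectionPlan) -> FeatureMatrix:
    """Restrict and reorder a feature matrix per a selection plan."""
    missing = [c for c in plan.all_columns if c not in matrix.frame.columns]
    if missing:
        raise KeyError(f"plan columns absent from matrix: {missing[:5]}")
    blocks = {enc: list(names) for enc, names in plan.retained.items()}
    frame = matrix.frame[[c for names in blocks.values() for c in names]]
    return FeatureMatrix(frame, blocks, matrix.labels)
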