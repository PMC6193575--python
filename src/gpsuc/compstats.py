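"""Compositional-bias statistics around candidate succinylation sites.

Positional summaries over aligned 41-residue windows:

* AAF — per-position amino-acid occurrence frequencies (gaps excluded
  from the denominator), compared between succinylated and background
  lysine windows;
* MPV — per-position mean of the profile (PSSM) score of the observed
  residue, a proxy for local evolutionary conservation;
* MPP — per-position mean of a physicochemical property value of the
  observed residue (default scale: NAKH920108);
* enrichment/depletion — signed AAF differences (positive = enriched
  around succinylated sites), the quantity rendered by two-sample
  sequence logos;
* significance — per-position Kruskal-Wallis (equivalently Wilcoxon
  rank-sum for two groups) on numeric positional values, or per
  (position, residue) chi-square tests of occurrence counts restricted
  to the central positions, both Bonferroni-corrected.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .alphabet import AA_INDEX, CANONICAL, FLANK, window_offsets
from .encoders import AAIndexTable, default_aaindex_table
from .featselect import wilcoxon_rank_sum
from .profiles import ProfileWindow
from .seqio import SequenceWindow

__all__ = [
    "positional_aaf",
    "mean_profile_value",
    "mean_property_value",
    "positional_test",
    "enrichment_depletion",
    "positional_property_values",
    "positional_profile_values",
]

#: Default property scale for MPP summaries.
DEFAULT_MPP_INDEX = "NAKH920108"

#: Default position range for the chi-square occurrence test.
CHI_SQUARE_RANGE = (-5, 5)

_OFFSETS = list(window_offsets())


def positional_aaf(windows: Sequence[SequenceWindow]) -> pd.DataFrame:
    """Per-position amino-acid frequencies over observed residues.

    Rows are window offsets (-20..+20), columns the 20 canonical
    residues. At each position, frequencies are counts divided by the
    number of non-gap, non-X observations there (so they sum to 1
    whenever at least one residue is observed).
    """
    if not windows:
        raise ValueError("at least one window required")
    counts = np.zeros((len(_OFFSETS), len(CANONICAL)))
    for w in windows:
        for i, aa in enumerate(w.symbols):
            j = AA_INDEX.get(aa)
            if j is not None:
                counts[i, j] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(totals > 0, counts / totals, 0.0)
    return pd.DataFrame(freq, index=_OFFSETS, columns=list(CANONICAL))


def positional_profile_values(
    profile_windows: Sequence[ProfileWindow],
    windows: Sequence[SequenceWindow],
) -> np.ndarray:
    """Per-window, per-position profile score of the observed residue.

    Gap/X positions are NaN so means and tests can skip them.
    """
    out = np.full((len(windows), len(_OFFSETS)), np.nan)
    for n, (pw, w) in enumerate(zip(profile_windows, windows)):
        for i, aa in enumerate(w.symbols):
            j = AA_INDEX.get(aa)
            if j is not None:
                out[n, i] = pw.rows[i, j]
    return out


def mean_profile_value(
    profile_windows: Sequence[ProfileWindow],
    windows: Sequence[SequenceWindow],
) -> pd.Series:
    """MPV: per-position mean profile score of the observed residue."""
    values = positional_profile_values(profile_windows, windows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        means = np.nanmean(values, axis=0)
    return pd.Series(means, index=_OFFSETS, name="MPV")


def positional_property_values(
    windows: Sequence[SequenceWindow],
    index_id: str = DEFAULT_MPP_INDEX,
    table: AAIndexTable | None = None,
) -> np.ndarray:
    """Per-window, per-position property value of the observed residue."""
    table = table or default_aaindex_table()
    if index_id not in table.index_ids:
        raise KeyError(f"unknown property scale {index_id!r}")
    lookup = {aa: table.value(index_id, aa) for aa in CANONICAL}
    out = np.full((len(windows), len(_OFFSETS)), np.nan)
    for n, w in enumerate(windows):
        for i, aa in enumerate(w.symbols):
            if aa in lookup:
                out[n, i] = lookup[aa]
    return out


def mean_property_value(
    windows: Sequence[SequenceWindow],
    index_id: str = DEFAULT_MPP_INDEX,
    table: AAIndexTable | None = None,
) -> pd.Series:
    """MPP: per-position mean property value of the observed residue.

    Positions observed in no window (all-gap columns) are NaN.
    """
    values = positional_property_values(windows, index_id, table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        means = np.nanmean(values, axis=0)
    return pd.Series(means, index=_OFFSETS, name=f"MPP:{index_id}")


def _kruskal_positional(pos_values: np.ndarray, neg_values: np.ndarray) -> pd.DataFrame:
    rows = []
    for i, off in enumerate(_OFFSETS):
        a = pos_values[:, i]
        b = neg_values[:, i]
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        if a.size == 0 or b.size == 0:
            rows.append((off, np.nan))
            continue
        if np.ptp(np.concatenate([a, b])) == 0:
            rows.append((off, 1.0))
            continue
        rows.append((off, wilcoxon_rank_sum(a, b).p_value))
    return pd.DataFrame(rows, columns=["position", "p"]).set_index("position")


def _chi_square_positional(
    windows_pos: Sequence[SequenceWindow],
    windows_neg: Sequence[SequenceWindow],
    position_range: tuple[int, int],
) -> pd.DataFrame:
    lo, hi = position_range
    rows = []
    for off in range(lo, hi + 1):
        if off == 0:
            continue  # the centre is K by construction in both groups
        i = off + FLANK
        pos_syms = [w.symbols[i] for w in windows_pos]
        neg_syms = [w.symbols[i] for w in windows_neg]
        for aa in CANONICAL:
            a1 = sum(s == aa for s in pos_syms)
            a0 = sum(s in AA_INDEX and s != aa for s in pos_syms)
            b1 = sum(s == aa for s in neg_syms)
            b0 = sum(s in AA_INDEX and s != aa for s in neg_syms)
            table = np.array([[a1, a0], [b1, b0]])
            if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
                # degenerate margin: residue absent (or universal) in both
                # groups at this position; pool into "no test" with p = 1
                warnings.warn(
                    f"degenerate counts for residue {aa} at offset {off:+d}; "
                    "cell pooled, p set to 1",
                    stacklevel=3,
                )
                p = 1.0
            else:
                p = float(stats.chi2_contingency(table, correction=True)[1])
            rows.append((off, aa, p))
    return pd.DataFrame(rows, columns=["position", "residue", "p"]).set_index(
        ["position", "residue"]
    )


def positional_test(
    pos_inputs,
    neg_inputs,
    test: str = "kruskal_wallis",
    correction: str = "bonferroni",
    position_range: tuple[int, int] = CHI_SQUARE_RANGE,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-position significance of group differences, multiplicity-corrected.

    ``kruskal_wallis`` expects two (n_windows × 41) numeric arrays (e.g.
    from :func:`positional_property_values` or
    :func:`positional_profile_values`; with two groups the test reduces
    to the Wilcoxon rank-sum test). ``chi_square`` expects two window
    collections and tests each (position, residue) occurrence count over
    ``position_range``. The Bonferroni family size m is the number of
    tests actually performed and is recorded in the output attrs.
    """
    if test == "kruskal_wallis":
        raw = _kruskal_positional(np.asarray(pos_inputs, float), np.asarray(neg_inputs, float))
    elif test == "chi_square":
        raw = _chi_square_positional(pos_inputs, neg_inputs, position_range)
    else:
        raise ValueError(f"unknown test {test!r}")
    if correction != "bonferroni":
        raise ValueError(f"unknown correction {correction!r}")
    m = int(raw["p"].notna().sum())
    raw["p_adjusted"] = np.minimum(1.0, raw["p"] * m)
    raw["significant"] = raw["p_adjusted"] < alpha
    raw.attrs["n_tests"] = m
    raw.attrs["test"] = test
    return raw


def enrichment_depletion(
    windows_pos: Sequence[SequenceWindow],
    windows_neg: Sequence[SequenceWindow],
) -> pd.DataFrame:
    """Signed per-position frequency differences (positive = enriched
    around succinylated sites); the table behind a two-sample logo."""
    return positional_aaf(windows_pos) - positional_aaf(windows_neg)
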