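"""Per-encoding random-forest scorers with logistic-regression fusion.

The predictor is a two-stage ensemble. Each of the five feature
encodings feeds its own random forest whose score S_n for a window is
the fraction of trees voting the succinylated class. The five channel
scores are then combined by a logistic regression,

    log(P / (1 - P)) = sum_n beta_n * S_n + alpha,

fitted by maximum likelihood on out-of-fold channel scores so the fusion
never sees resubstitution optimism. The constant term alpha is clamped
to zero by default; published per-species coefficient sets are available
as presets for users bringing their own channel scores. A site is called
succinylated when P reaches the model's cutoff.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from scipy import optimize
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from . import __version__
from .alphabet import CANONICAL, CHANNEL_ORDER, WINDOW
from .encoders import AAIndexTable, FeatureMatrix, build_feature_matrix
from .featselect import (
    GENERIC_TOP_N,
    SelectionPlan,
    apply_selection,
    build_selection_plan,
    rank_features,
)
from .profiles import PssmProfile, profile_window
from .seqio import SequenceWindow

__all__ = [
    "ChannelModel",
    "FusionModel",
    "GpsucModel",
    "FUSION_PRESETS",
    "train_channel",
    "out_of_fold_scores",
    "fit_fusion",
    "choose_cutoff",
    "train_gpsuc",
    "predict",
    "save_model",
    "load_model",
]

#: Published per-species fusion coefficients, channel order
#: (AAC, AAindex, BE, PSSM, pCKSAAP); constant terms are zero.
FUSION_PRESETS: dict[str, tuple[float, ...]] = {
    "h_sapiens": (0.142, 1.566, 0.665, 0.342, 0.667),
    "h_capsulatum": (0.102, 0.466, 0.462, 0.242, 1.367),
    "e_coli": (0.121, 0.473, 0.763, 0.230, 1.214),
    "m_tuberculosis": (0.127, 0.358, 0.404, 0.109, 1.066),
    "s_cerevisiae": (0.320, 0.391, 0.553, 0.182, 1.122),
    "t_gondii": (0.117, 0.331, 0.734, 0.139, 1.014),
    "s_lycopersicum": (0.113, 0.417, 0.818, 0.103, 1.172),
    "t_aestivum": (0.112, 0.462, 0.723, 0.164, 1.299),
}

DEFAULT_N_TREES = 500
TREE_GRID = (100, 300, 500, 1000)


@dataclass
class ChannelModel:
    """A trained per-encoding tree-ensemble scorer."""

    encoding_name: str
    forest: RandomForestClassifier
    n_trees: int
    seed: int
    feature_names: list[str]

    def score(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting the positive class, in [0, 1]."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        pos_col = list(self.forest.classes_).index(1)
        return self.forest.predict_proba(X)[:, pos_col]


def train_channel(
    X: np.ndarray,
    labels: np.ndarray,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    encoding_name: str = "",
    feature_names: Sequence[str] | None = None,
) -> ChannelModel:
    """Fit one random-forest channel on a reduced feature block."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("channel training needs both classes")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(np.asarray(X, dtype=float), labels)
    return ChannelModel(
        encoding_name=encoding_name,
        forest=forest,
        n_trees=n_trees,
        seed=seed,
        feature_names=list(feature_names or []),
    )


def _channel_seed(seed: int, fold: int, channel_idx: int) -> int:
    return (seed * 1009 + fold * 101 + channel_idx) % (2**31 - 1)


def _fit_fold_channels(
    train_matrix: FeatureMatrix,
    train_labels: np.ndarray,
    top_n: Mapping[str, int] | None,
    n_trees: int,
    seed: int,
    fold: int,
) -> tuple[SelectionPlan, dict[str, ChannelModel]]:
    """Selection plan + channels fitted on one training split only."""
    ranking = rank_features(train_matrix, train_labels)
    plan = build_selection_plan(ranking, top_n, train_matrix.blocks)
    reduced = apply_selection(train_matrix, plan)
    channels = {}
    for ci, enc in enumerate(CHANNEL_ORDER):
        channels[enc] = train_channel(
            reduced.block_values(enc),
            train_labels,
            n_trees=n_trees,
            seed=_channel_seed(seed, fold, ci),
            encoding_name=enc,
            feature_names=plan.retained[enc],
        )
    return plan, channels


def _score_channels(
    matrix: FeatureMatrix, plan: SelectionPlan, channels: Mapping[str, ChannelModel]
) -> np.ndarray:
    reduced = apply_selection(matrix, plan)
    return np.column_stack(
        [channels[enc].score(reduced.block_values(enc)) for enc in CHANNEL_ORDER]
    )


def out_of_fold_scores(
    matrix: FeatureMatrix,
    labels: np.ndarray | None = None,
    folds: int = 10,
    seed: int = 0,
    top_n: Mapping[str, int] | None = None,
    n_trees: int = DEFAULT_N_TREES,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified out-of-fold channel scores for every sample.

    Feature selection and channel training are redone inside each
    training fold, so no sample is scored by a model (or selection plan)
    that saw its label. Returns ``(scores, fold_assignment)`` with one
    column per channel in the fixed channel order.
    """
    labels = matrix.labels if labels is None else np.asarray(labels)
    splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.full((matrix.n_samples, len(CHANNEL_ORDER)), np.nan)
    assignment = np.full(matrix.n_samples, -1)
    for fold, (train_idx, test_idx) in enumerate(splitter.split(scores, labels)):
        plan, channels = _fit_fold_channels(
            matrix.subset_rows(train_idx), labels[train_idx], top_n, n_trees, seed, fold
        )
        scores[test_idx] = _score_channels(matrix.subset_rows(test_idx), plan, channels)
        assignment[test_idx] = fold
    return scores, assignment


@dataclass
class FusionModel:
    """Logistic-regression combination of the five channel scores."""

    beta: np.ndarray
    alpha: float = 0.0
    cutoff: float = 0.5
    channel_order: tuple[str, ...] = CHANNEL_ORDER
    beta_se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(self.channel_order),):
            raise ValueError("one coefficient per channel required")
        if not np.isfinite(self.beta).all() or not np.isfinite(self.alpha):
            raise ValueError("fusion coefficients must be finite")
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError("cutoff must lie in (0, 1)")

    def predict_proba(self, channel_scores: np.ndarray) -> np.ndarray:
        S = np.asarray(channel_scores, dtype=float)
        if S.ndim == 1:
            S = S[None, :]
        logit = S @ self.beta + self.alpha
        return 1.0 / (1.0 + np.exp(-logit))

    @classmethod
    def from_preset(cls, species: str, cutoff: float = 0.5) -> "FusionModel":
        if species not in FUSION_PRESETS:
            raise KeyError(
                f"no preset {species!r}; available: {sorted(FUSION_PRESETS)}"
            )
        return cls(beta=np.array(FUSION_PRESETS[species]), alpha=0.0, cutoff=cutoff)


def _logit_negloglik(params: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Negative log-likelihood and gradient of a logistic regression."""
    eta = X @ params
    # log(1 + e^eta) computed stably
    ll = y @ eta - np.logaddexp(0.0, eta).sum()
    p = 1.0 / (1.0 + np.exp(-eta))
    grad = X.T @ (y - p)
    return -ll, -grad


def fit_fusion(
    oof_scores: np.ndarray,
    labels: np.ndarray,
    fix_alpha_zero: bool = True,
    nonnegative: bool = True,
) -> FusionModel:
    """Maximum-likelihood logistic fit of the fusion coefficients.

    ``fix_alpha_zero`` (default) clamps the constant term to zero.
    ``nonnegative`` (default) constrains every channel coefficient to be
    >= 0: each channel score is a probability of the positive class, so
    a channel can only add evidence for — never against — modification.
    The published coefficient sets are all positive, and the constraint
    stabilises the fit when channel scores are strongly correlated
    (unconstrained ML is then quasi-separated and its mixed-sign
    solutions invert outside the training score distribution).

    Standard errors come from the observed information at the optimum
    and are reported when the solution is interior (no active bound).
    Should the constrained fit still diverge (clean separation along a
    non-negative direction), a ridge-penalised fit is used with a
    warning.
    """
    S = np.asarray(oof_scores, dtype=float)
    y = (np.asarray(labels) == 1).astype(float)
    if S.ndim != 2 or S.shape[1] != len(CHANNEL_ORDER):
        raise ValueError(f"expected {len(CHANNEL_ORDER)} score columns")
    k = S.shape[1]
    X = S if fix_alpha_zero else np.column_stack([S, np.ones(len(S))])
    bounds = [(0.0, None)] * k if nonnegative else [(None, None)] * k
    if not fix_alpha_zero:
        bounds.append((None, None))
    res = optimize.minimize(
        _logit_negloglik,
        x0=np.full(X.shape[1], 0.1),
        args=(X, y),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500},
    )
    params = res.x
    eta = X @ params
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
        bse_all = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        bse_all = np.full(X.shape[1], np.inf)
    interior = not nonnegative or np.all(params[:k] > 1e-8)
    if (
        res.success
        and np.isfinite(params).all()
        and np.abs(params).max() <= 30.0
        and (not interior or np.max(bse_all) <= 50.0)
    ):
        beta = params[:k]
        alpha = 0.0 if fix_alpha_zero else float(params[-1])
        bse = bse_all[:k] if interior and np.isfinite(bse_all).all() else None
        return FusionModel(beta=beta, alpha=alpha, beta_se=bse)
    warnings.warn(
        "maximum-likelihood fusion fit diverged (separation); "
        "falling back to a ridge-penalised fit",
        stacklevel=2,
    )
    clf = LogisticRegression(
        C=1.0, fit_intercept=not fix_alpha_zero, solver="lbfgs", max_iter=1000
    )
    clf.fit(S, y.astype(int))
    beta = np.clip(clf.coef_[0], 0.0, None) if nonnegative else clf.coef_[0]
    alpha = 0.0 if fix_alpha_zero else float(clf.intercept_[0])
    return FusionModel(beta=beta, alpha=alpha)


def choose_cutoff(
    fused_scores: np.ndarray,
    labels: np.ndarray,
    mode: str = "specificity",
    target: float = 0.90,
    value: float = 0.5,
) -> float:
    """Pick the decision threshold on the fused probability.

    ``specificity`` mode returns the smallest cutoff whose specificity on
    the supplied scores reaches ``target`` (candidates are midpoints
    between adjacent distinct scores, so a clean separation yields the
    gap midpoint); ``fixed`` mode returns ``value`` unchanged.
    """
    if mode == "fixed":
        return float(value)
    if mode != "specificity":
        raise ValueError(f"unknown cutoff mode {mode!r}")
    scores = np.asarray(fused_scores, dtype=float)
    labels = np.asarray(labels)
    neg = scores[labels != 1]
    if neg.size == 0:
        raise ValueError("specificity cutoff needs negative samples")
    uniq = np.unique(scores)
    candidates = np.concatenate(
        [(uniq[:-1] + uniq[1:]) / 2.0, [min(uniq[-1] + 0.5 * (1 - uniq[-1]), 1 - 1e-9)]]
    )
    for c in candidates:  # ascending
        sp = float((neg < c).mean())
        if sp >= target:
            return float(c)
    raise ValueError(f"specificity target {target} unreachable")


@dataclass
class GpsucModel:
    """A complete trained predictor: plan, five channels, fusion, manifest."""

    plan: SelectionPlan
    channels: dict[str, ChannelModel]
    fusion: FusionModel
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(CHANNEL_ORDER) - set(self.channels)
        if missing:
            raise ValueError(f"missing channels: {sorted(missing)}")

    def channel_scores(self, matrix: FeatureMatrix) -> np.ndarray:
        return _score_channels(matrix, self.plan, self.channels)

    def predict_matrix(self, matrix: FeatureMatrix) -> np.ndarray:
        return self.fusion.predict_proba(self.channel_scores(matrix))


def train_gpsuc(
    matrix: FeatureMatrix,
    labels: np.ndarray | None = None,
    top_n: Mapping[str, int] | None = None,
    n_trees: int = DEFAULT_N_TREES,
    folds: int = 10,
    seed: int = 0,
    fix_alpha_zero: bool = True,
    cutoff_mode: str = "specificity",
    cutoff_target: float = 0.90,
    cutoff_value: float = 0.5,
) -> GpsucModel:
    """Train the full predictor on an encoded, labelled feature matrix.

    The fusion regression is fitted on stratified out-of-fold channel
    scores; the final selection plan and channels are then refitted on
    all rows. The decision cutoff is chosen on the out-of-fold fused
    scores, by default as the smallest value reaching 90% specificity:
    with the constant term clamped to zero and non-negative
    coefficients, fused probabilities never drop below 0.5, so a fixed
    0.5 threshold would call every site positive.
    """
    labels = matrix.labels if labels is None else np.asarray(labels)
    if labels is None:
        raise ValueError("labels are required for training")
    oof, _ = out_of_fold_scores(matrix, labels, folds=folds, seed=seed, top_n=top_n, n_trees=n_trees)
    fusion = fit_fusion(oof, labels, fix_alpha_zero=fix_alpha_zero)
    fused = fusion.predict_proba(oof)
    fusion.cutoff = choose_cutoff(
        fused, labels, mode=cutoff_mode, target=cutoff_target, value=cutoff_value
    )
    plan, channels = _fit_fold_channels(matrix, labels, top_n, n_trees, seed, fold=folds)
    manifest = {
        "package_version": __version__,
        "alphabet": CANONICAL,
        "window": WINDOW,
        "seed": seed,
        "n_trees": n_trees,
        "folds": folds,
        "top_n": dict(GENERIC_TOP_N if top_n is None else top_n),
        "fix_alpha_zero": fix_alpha_zero,
        "channel_order": list(CHANNEL_ORDER),
    }
    return GpsucModel(plan=plan, channels=channels, fusion=fusion, manifest=manifest)


def predict(
    model: GpsucModel,
    windows: Sequence[SequenceWindow],
    profiles: Mapping[str, PssmProfile],
    table: AAIndexTable | None = None,
):
    """Score candidate sites and call those reaching the cutoff.

    Returns a pandas DataFrame with protein_id, position, residue,
    probability and boolean call, one row per window.
    """
    import pandas as pd

    pwins = [
        profile_window(profiles[w.protein_id], w.site_position) for w in windows
    ]
    matrix = build_feature_matrix(windows, pwins, table)
    prob = model.predict_matrix(matrix)
    return pd.DataFrame(
        {
            "protein_id": [w.protein_id for w in windows],
            "position": [w.site_position for w in windows],
            "residue": [w.centre for w in windows],
            "probability": prob,
            "call": prob >= model.fusion.cutoff,
        }
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def save_model(model: GpsucModel, path: str | Path) -> None:
    """Persist a model as a self-describing directory archive."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    model.plan.to_json(path / "plan.json")
    fusion_payload = {
        "beta": model.fusion.beta.tolist(),
        "alpha": model.fusion.alpha,
        "cutoff": model.fusion.cutoff,
        "channel_order": list(model.fusion.channel_order),
    }
    (path / "fusion.json").write_text(json.dumps(fusion_payload, indent=1))
    for enc, channel in model.channels.items():
        joblib.dump(channel, path / f"channel_{enc}.joblib")
    manifest = dict(model.manifest)
    manifest["package_version"] = __version__
    manifest["files"] = {
        f.name: _sha256(f)
        for f in sorted(path.iterdir())
        if f.name != "manifest.json"
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_model(path: str | Path) -> GpsucModel:
    """Load a model archive, validating file hashes and version."""
    path = Path(path)
    manifest_file = path / "manifest.json"
    if not manifest_file.exists():
        raise FileNotFoundError(f"not a model archive (no manifest): {path}")
    manifest = json.loads(manifest_file.read_text())
    if manifest.get("package_version") != __version__:
        raise ValueError(
            f"model archive written by version {manifest.get('package_version')!r}, "
            f"this is {__version__}"
        )
    for name, digest in manifest.get("files", {}).items():
        f = path / name
        if not f.exists():
            raise FileNotFoundError(f"model archive is missing {name}")
        if _sha256(f) != digest:
            raise ValueError(f"model archive file {name} fails hash validation")
    plan = SelectionPlan.from_json(path / "plan.json")
    fusion_payload = json.loads((path / "fusion.json").read_text())
    fusion = FusionModel(
        beta=np.array(fusion_payload["beta"]),
        alpha=fusion_payload["alpha"],
        cutoff=fusion_payload["cutoff"],
        channel_order=tuple(fusion_payload["channel_order"]),
    )
    channels = {}
    for enc in CHANNEL_ORDER:
        f = path / f"channel_{enc}.joblib"
        if not f.exists():
            raise FileNotFoundError(f"model archive is missing channel {enc!r}")
        channels[enc] = joblib.load(f)
    return GpsucModel(plan=plan, channels=channels, fusion=fusion, manifest=manifest)
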