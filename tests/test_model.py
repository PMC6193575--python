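import math

import numpy as np
import pytest

from gpsuc import evaluate as ev
from gpsuc import model as mdl
from gpsuc import synthetic as syn
from gpsuc.alphabet import CHANNEL_ORDER


@pytest.fixture
def separable_block(rng):
    """A small feature block where class means are far apart."""
    n = 60
    labels = np.array([1] * (n // 3) + [-1] * (2 * n // 3))
    X = rng.normal(size=(n, 10))
    X[labels == 1, :3] += 6.0
    return X, labels


class TestTrainChannel:
    def test_separable_resubstitution_auc(self, separable_block):
        X, labels = separable_block
        ch = mdl.train_channel(X, labels, n_trees=100, seed=0)
        auc = ev.roc_auc(ch.score(X), labels).auc
        assert auc >= 0.99

    def test_shuffled_labels_near_chance(self, rng, separable_block):
        from sklearn.model_selection import StratifiedKFold

        X, labels = separable_block
        shuffled = rng.permutation(labels)
        scores = np.zeros(len(labels))
        for tr, te in StratifiedKFold(5, shuffle=True, random_state=0).split(X, shuffled):
            ch = mdl.train_channel(X[tr], shuffled[tr], n_trees=100, seed=0)
            scores[te] = ch.score(X[te])
        auc = ev.roc_auc(scores, shuffled).auc
        assert abs(auc - 0.5) <= 0.08

    def test_deterministic_given_seed(self, separable_block):
        X, labels = separable_block
        a = mdl.train_channel(X, labels, n_trees=40, seed=9).score(X)
        b = mdl.train_channel(X, labels, n_trees=40, seed=9).score(X)
        np.testing.assert_array_equal(a, b)

    def test_scores_bounded(self, separable_block):
        X, labels = separable_block
        s = mdl.train_channel(X, labels, n_trees=40, seed=0).score(X)
        assert (s >= 0).all() and (s <= 1).all()

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            mdl.train_channel(rng.normal(size=(10, 3)), np.ones(10, dtype=int))


class TestOutOfFoldScores:
    def test_every_sample_scored_once(self, small_matrix):
        scores, assignment = mdl.out_of_fold_scores(
            small_matrix, folds=3, seed=0, n_trees=25,
            top_n={"pCKSAAP": 50, "AAindex": 30},
        )
        assert scores.shape == (small_matrix.n_samples, 5)
        assert not np.isnan(scores).any()
        assert (assignment >= 0).all()

    def test_stratified_folds(self, small_matrix):
        _, assignment = mdl.out_of_fold_scores(
            small_matrix, folds=3, seed=0, n_trees=10,
            top_n={"pCKSAAP": 20, "AAindex": 20},
        )
        labels = small_matrix.labels
        global_frac = (labels == 1).mean()
        for fold in range(3):
            mask = assignment == fold
            frac = (labels[mask] == 1).mean()
            # within one sample of the global positive fraction
            assert abs(frac - global_frac) <= 1.5 / mask.sum()


class TestFusion:
    def test_zero_coefficients_give_half(self):
        fm = mdl.FusionModel(beta=np.zeros(5), alpha=0.0)
        assert fm.predict_proba(np.ones(5))[0] == pytest.approx(0.5)
        assert fm.predict_proba(np.zeros(5))[0] == pytest.approx(0.5)

    def test_h_sapiens_preset_arithmetic(self):
        fm = mdl.FusionModel.from_preset("h_sapiens")
        np.testing.assert_allclose(fm.beta, [0.142, 1.566, 0.665, 0.342, 0.667])
        assert fm.alpha == 0.0
        logit = sum(fm.beta)
        assert logit == pytest.approx(3.382)
        assert fm.predict_proba(np.ones(5))[0] == pytest.approx(1 / (1 + math.exp(-3.382)))

    def test_eight_presets_available(self):
        assert len(mdl.FUSION_PRESETS) == 8
        with pytest.raises(KeyError):
            mdl.FusionModel.from_preset("zebrafish")

    def test_planted_beta_recovery_within_2_se(self):
        beta = np.array(mdl.FUSION_PRESETS["h_sapiens"])
        S, labels = syn.generate_channel_scores(beta, alpha=0.0, n=2000, seed=0)
        fit = mdl.fit_fusion(S, labels, fix_alpha_zero=True, nonnegative=False)
        assert fit.beta_se is not None
        assert np.all(np.abs(fit.beta - beta) <= 2.0 * fit.beta_se)

    def test_monotone_in_each_channel_with_positive_beta(self, rng):
        fm = mdl.FusionModel.from_preset("e_coli")
        base = rng.uniform(size=5)
        p0 = fm.predict_proba(base)[0]
        for i in range(5):
            bumped = base.copy()
            bumped[i] = min(1.0, bumped[i] + 0.2)
            assert fm.predict_proba(bumped)[0] >= p0

    def test_perfect_separation_falls_back_with_warning(self):
        S = np.zeros((40, 5))
        labels = np.array([1] * 20 + [-1] * 20)
        S[:20, 0] = 1.0  # channel 0 perfectly separates
        with pytest.warns(UserWarning, match="ridge"):
            fit = mdl.fit_fusion(S, labels)
        assert np.isfinite(fit.beta).all()

    def test_probability_strictly_inside_unit_interval(self, rng):
        fm = mdl.FusionModel.from_preset("t_aestivum")
        p = fm.predict_proba(rng.uniform(size=(100, 5)))
        assert ((p > 0) & (p < 1)).all()


class TestChooseCutoff:
    def test_fixed_mode(self):
        assert mdl.choose_cutoff([0.1], [1], mode="fixed", value=0.5) == 0.5

    def test_separated_scores_midpoint(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([-1, -1, 1, 1])
        c = mdl.choose_cutoff(scores, labels, target=0.9)
        assert c == pytest.approx(0.5)  # midpoint of the separating gap

    def test_cutoff_achieves_specificity(self, rng):
        scores = rng.uniform(size=300)
        labels = rng.choice([1, -1], size=300)
        c = mdl.choose_cutoff(scores, labels, target=0.90)
        counts = ev.confusion_at_cutoff(scores, labels, c)
        rep = ev.metrics(counts, c)
        assert rep.Sp >= 0.90


@pytest.fixture(scope="module")
def separable_matrix():
    """A feature matrix where every encoding block carries clean signal."""
    import pandas as pd
    from gpsuc.encoders import FeatureMatrix

    rng = np.random.default_rng(21)
    n = 150
    labels = np.array([1] * 50 + [-1] * 100)
    frames, blocks = [], {}
    for enc in CHANNEL_ORDER:
        X = rng.normal(size=(n, 12))
        X[labels == 1, :3] += 2.5
        cols = [f"{enc}:f{i}" for i in range(12)]
        blocks[enc] = cols
        frames.append(pd.DataFrame(X, columns=cols))
    frame = pd.concat(frames, axis=1)
    frame.index = pd.MultiIndex.from_tuples(
        [("P", i + 1) for i in range(n)], names=["protein_id", "position"]
    )
    return FeatureMatrix(frame, blocks, labels)


class TestEndToEndModel:
    @pytest.fixture(scope="class")
    def trained(self, separable_matrix):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            return mdl.train_gpsuc(
                separable_matrix, n_trees=40, folds=3, seed=1, top_n={},
            )

    def test_training_windows_mostly_correct(self, trained, separable_matrix):
        prob = trained.predict_matrix(separable_matrix)
        calls = np.where(prob >= trained.fusion.cutoff, 1, -1)
        assert (calls == separable_matrix.labels).mean() >= 0.95

    def test_probabilities_bounded(self, trained, separable_matrix):
        prob = trained.predict_matrix(separable_matrix)
        assert ((prob > 0) & (prob < 1)).all()

    def test_same_seed_identical_models(self, separable_matrix):
        import warnings

        kw = dict(n_trees=15, folds=3, seed=5, top_n={})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            a = mdl.train_gpsuc(separable_matrix, **kw)
            b = mdl.train_gpsuc(separable_matrix, **kw)
        np.testing.assert_array_equal(a.fusion.beta, b.fusion.beta)
        assert a.plan.retained == b.plan.retained
        np.testing.assert_array_equal(
            a.predict_matrix(separable_matrix), b.predict_matrix(separable_matrix)
        )

    def test_save_load_roundtrip(self, trained, separable_matrix, tmp_path):
        before = trained.predict_matrix(separable_matrix)
        mdl.save_model(trained, tmp_path / "model")
        again = mdl.load_model(tmp_path / "model")
        np.testing.assert_array_equal(again.predict_matrix(separable_matrix), before)
        assert again.fusion.cutoff == trained.fusion.cutoff

    def test_missing_channel_rejected(self, trained, tmp_path):
        mdl.save_model(trained, tmp_path / "model")
        (tmp_path / "model" / "channel_PSSM.joblib").unlink()
        with pytest.raises(FileNotFoundError, match="PSSM"):
            mdl.load_model(tmp_path / "model")

    def test_corrupted_archive_rejected(self, trained, tmp_path):
        mdl.save_model(trained, tmp_path / "model")
        plan = tmp_path / "model" / "plan.json"
        plan.write_text(plan.read_text() + " ")
        with pytest.raises(ValueError, match="hash"):
            mdl.load_model(tmp_path / "model")

    def test_foreign_version_rejected(self, trained, tmp_path):
        import json

        mdl.save_model(trained, tmp_path / "model")
        manifest = tmp_path / "model" / "manifest.json"
        payload = json.loads(manifest.read_text())
        payload["package_version"] = "99.0.0"
        manifest.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="version"):
            mdl.load_model(tmp_path / "model")

    def test_predict_table(self, small_matrix, small_dataset):
        import warnings

        records, sites, profiles = small_dataset
        from gpsuc.seqio import windows_for_sites

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            sequence_model = mdl.train_gpsuc(
                small_matrix, n_trees=20, folds=3, seed=2,
                top_n={"pCKSAAP": 40, "AAindex": 30},
            )
        windows = windows_for_sites(records, sites[:30])
        table = mdl.predict(sequence_model, windows, profiles)
        assert list(table.columns) == ["protein_id", "position", "residue", "probability", "call"]
        assert (table["residue"] == "K").all()
        assert len(table) == len(windows)
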