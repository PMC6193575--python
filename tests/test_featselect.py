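import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gpsuc import featselect as fs
from gpsuc.encoders import FeatureMatrix


def brute_force_p(pos, neg):
    """Literal enumeration over all C(r+s, r) rank assignments."""
    from scipy.stats import rankdata

    pooled = np.concatenate([pos, neg])
    ranks = rankdata(pooled)
    r = len(pos)
    w_obs = ranks[:r].sum()
    sums = [sum(c) for c in itertools.combinations(ranks, r)]
    total = len(sums)
    pu = sum(s >= w_obs - 1e-9 for s in sums) / total
    pl = sum(s <= w_obs + 1e-9 for s in sums) / total
    return min(1.0, 2 * min(pu, pl))


def make_matrix(X, labels, encoding="pCKSAAP"):
    cols = [f"{encoding}:f{i}" for i in range(X.shape[1])]
    frame = pd.DataFrame(X, columns=cols,
                         index=pd.MultiIndex.from_tuples(
                             [("P", i + 1) for i in range(X.shape[0])],
                             names=["protein_id", "position"]))
    return FeatureMatrix(frame, {encoding: cols}, np.asarray(labels))


class TestWilcoxonRankSum:
    def test_symmetric_ties(self):
        res = fs.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.W == 10.5
        assert res.p_value == 1.0

    def test_separated_groups_exact(self):
        res = fs.wilcoxon_rank_sum([4, 5, 6], [1, 2, 3])
        assert res.W == 15
        assert res.method == "exact"
        assert res.p_value == pytest.approx(0.1)

    def test_exact_equals_brute_force_all_small_sizes(self, rng):
        """DP-based exact mode == literal enumeration for every r+s <= 10."""
        for r in range(1, 10):
            for s in range(1, 11 - r):
                vals = rng.integers(0, 4, size=r + s).astype(float)  # heavy ties
                res = fs.wilcoxon_rank_sum(vals[:r], vals[r:], method="exact")
                assert res.p_value == pytest.approx(brute_force_p(vals[:r], vals[r:]), abs=1e-12)

    def test_exact_vs_normal_at_30_30(self, rng):
        diffs = []
        for _ in range(20):
            pos = rng.normal(size=30)
            neg = rng.normal(size=30)
            pe = fs.wilcoxon_rank_sum(pos, neg, method="exact").p_value
            pn = fs.wilcoxon_rank_sum(pos, neg, method="normal").p_value
            diffs.append(abs(pe - pn))
        assert max(diffs) < 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fs.wilcoxon_rank_sum([], [1.0])

    def test_w_bounds(self, rng):
        pos = rng.normal(size=6)
        neg = rng.normal(size=9)
        res = fs.wilcoxon_rank_sum(pos, neg)
        assert 6 * 7 / 2 <= res.W <= sum(range(10, 16))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        # grid-valued data so the transform below is strictly monotone in
        # floating point (distinct inputs stay distinct, ties stay ties)
        data=st.lists(
            st.integers(-100_000, 100_000).map(lambda i: i / 1000.0),
            min_size=6, max_size=12,
        ),
        r=st.integers(2, 4),
    )
    def test_monotone_transform_invariance(self, data, r):
        """p-values depend only on ranks, so any strictly increasing
        transform of the pooled values leaves them unchanged."""
        vals = np.array(data)
        transformed = np.exp(vals / 50.0) + 3.0
        a = fs.wilcoxon_rank_sum(vals[:r], vals[r:])
        b = fs.wilcoxon_rank_sum(transformed[:r], transformed[r:])
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
        assert a.method == b.method


class TestRankFeatures:
    def test_separable_column_ranks_first(self, rng):
        X = rng.normal(size=(40, 6))
        labels = np.array([1] * 20 + [-1] * 20)
        X[:, 3] = labels * 10.0  # perfectly separating column
        ranked = fs.rank_features(make_matrix(X, labels))
        assert ranked[0].feature_name == "pCKSAAP:f3"

    def test_permutation_invariance(self, rng):
        X = rng.normal(size=(30, 5))
        labels = np.array([1] * 10 + [-1] * 20)
        m = make_matrix(X, labels)
        perm = rng.permutation(30)
        mp = make_matrix(X[perm], labels[perm])
        a = [(r.feature_name, r.p_value) for r in fs.rank_features(m)]
        b = [(r.feature_name, r.p_value) for r in fs.rank_features(mp)]
        assert a == b

    def test_constant_matrix_all_p_one(self):
        X = np.ones((12, 4))
        labels = np.array([1] * 6 + [-1] * 6)
        ranked = fs.rank_features(make_matrix(X, labels))
        assert all(r.p_value == 1.0 for r in ranked)
        assert [r.feature_name for r in ranked] == [f"pCKSAAP:f{i}" for i in range(4)]

    def test_normal_and_exact_paths_agree(self, rng):
        X = rng.normal(size=(16, 8))
        labels = np.array([1] * 8 + [-1] * 8)
        m = make_matrix(X, labels)
        pe = {r.feature_name: r.p_value for r in fs.rank_features(m, method="exact")}
        pn = {r.feature_name: r.p_value for r in fs.rank_features(m, method="normal")}
        for name in pe:
            assert pe[name] == pytest.approx(pn[name], abs=0.05)


class TestSelectionPlan:
    def _ranked(self, widths):
        results = []
        p = 0.0
        for enc, width in widths.items():
            for i in range(width):
                p += 1e-4
                results.append(fs.WRResult(f"{enc}:f{i}", 10.0, 5, 10, p, "normal"))
        return sorted(results, key=lambda r: r.p_value)

    def test_generic_defaults(self):
        ranked = self._ranked({"pCKSAAP": 2000, "AAindex": 492, "AAC": 20, "BE": 820, "PSSM": 820})
        plan = fs.build_selection_plan(ranked)
        assert plan.top_n["pCKSAAP"] == 390
        assert plan.top_n["AAindex"] == 250
        assert len(plan.retained["pCKSAAP"]) == 390
        assert len(plan.retained["AAC"]) == 20
        assert len(plan.retained["BE"]) == 820
        assert len(plan.retained["PSSM"]) == 820

    def test_full_width_identity(self):
        ranked = self._ranked({"pCKSAAP": 10})
        plan = fs.build_selection_plan(ranked, {"pCKSAAP": 10})
        assert len(plan.retained["pCKSAAP"]) == 10

    def test_excess_top_n_rejected(self):
        ranked = self._ranked({"pCKSAAP": 10})
        with pytest.raises(ValueError, match="exceeds"):
            fs.build_selection_plan(ranked, {"pCKSAAP": 11})

    def test_species_presets_cover_nine(self):
        assert len(fs.SPECIES_TOP_N) == 9
        assert fs.SPECIES_TOP_N["h_sapiens"] == {"AAindex": 260, "pCKSAAP": 440}

    def test_json_roundtrip(self, tmp_path):
        ranked = self._ranked({"pCKSAAP": 20, "AAC": 5})
        plan = fs.build_selection_plan(ranked, {"pCKSAAP": 7})
        path = tmp_path / "plan.json"
        plan.to_json(path)
        again = fs.SelectionPlan.from_json(path)
        assert again.retained == plan.retained
        assert again.top_n == plan.top_n


class TestApplySelection:
    def test_reduction_and_idempotence(self, rng):
        X = rng.normal(size=(24, 10))
        labels = np.array([1] * 12 + [-1] * 12)
        m = make_matrix(X, labels)
        ranked = fs.rank_features(m)
        plan = fs.build_selection_plan(ranked, {"pCKSAAP": 4})
        reduced = fs.apply_selection(m, plan)
        assert len(reduced.frame.columns) == 4
        twice = fs.apply_selection(reduced, plan)
        pd.testing.assert_frame_equal(twice.frame, reduced.frame)
        # surviving values unchanged
        for col in reduced.frame.columns:
            np.testing.assert_array_equal(reduced.frame[col], m.frame[col])

    def test_missing_column_named(self, rng):
        X = rng.normal(size=(10, 3))
        labels = np.array([1] * 5 + [-1] * 5)
        m = make_matrix(X, labels)
        plan = fs.SelectionPlan({"pCKSAAP": ["pCKSAAP:missing"]}, {"pCKSAAP": 1})
        with pytest.raises(KeyError, match="missing"):
            fs.apply_selection(m, plan)

    def test_no_test_label_leakage(self, rng):
        """Plans depend only on training rows: flipping held-out labels
        cannot change the plan."""
        X = rng.normal(size=(40, 8))
        labels = np.array([1] * 20 + [-1] * 20)
        train_idx = np.arange(30)
        m = make_matrix(X, labels)
        train = m.subset_rows(train_idx)
        plan_a = fs.build_selection_plan(fs.rank_features(train), {"pCKSAAP": 3})
        flipped = labels.copy()
        flipped[30:] *= -1
        m2 = make_matrix(X, flipped)
        plan_b = fs.build_selection_plan(fs.rank_features(m2.subset_rows(train_idx)), {"pCKSAAP": 3})
        assert plan_a.retained == plan_b.retained
        assert plan_a.p_values == plan_b.p_values

    def test_plans_reproducible(self, rng):
        X = rng.normal(size=(30, 6))
        labels = np.array([1] * 10 + [-1] * 20)
        m = make_matrix(X, labels)
        plans = [
            fs.build_selection_plan(fs.rank_features(m), {"pCKSAAP": 4}) for _ in range(2)
        ]
        assert plans[0].retained == plans[1].retained
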