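import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asnet import feature_selection as fs
from asnet.data_io import FeatureMatrix
from asnet.feature_selection import SelectionError

from .oracles import chi2_brute, nca_objective_direct, relieff_brute


def _fm(values, labels, source="m"):
    values = np.asarray(values, float)
    return FeatureMatrix(
        values=values,
        sample_ids=[f"s{i}" for i in range(values.shape[0])],
        labels=np.asarray(labels),
        source=source,
    )


class TestChi2:
    def test_constant_feature_scores_zero(self):
        X = np.column_stack([np.full(10, 3.7), np.arange(10.0)])
        y = np.array([1] * 5 + [2] * 5)
        r = fs.chi2_scores(X, y)
        assert r.scores[0] == 0.0

    def test_perfectly_aligned_binary_feature_equals_n(self):
        # 2x2 table with perfect dependence: chi-square statistic equals n
        X = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1], float)[:, None]
        y = np.array([1] * 5 + [2] * 5)
        r = fs.chi2_scores(X, y)
        assert r.scores[0] == pytest.approx(10.0, abs=1e-12)

    def test_matches_contingency_oracle_on_binned_data(self, rng):
        X = rng.standard_normal((40, 3))
        y = rng.integers(1, 3, 40)
        y[0], y[1] = 1, 2  # both classes present
        r = fs.chi2_scores(X, y, n_bins=5)
        for j in range(3):
            col = X[:, j]
            lo, hi = col.min(), col.max()
            bins = np.minimum(((col - lo) / (hi - lo) * 5).astype(int), 4)
            assert r.scores[j] == pytest.approx(chi2_brute(bins, y), abs=1e-10)

    def test_permutation_invariance(self, rng):
        X = rng.standard_normal((30, 4))
        y = np.array([1, 2] * 15)
        perm = rng.permutation(30)
        a = fs.chi2_scores(X, y).scores
        b = fs.chi2_scores(X[perm], y[perm]).scores
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(SelectionError, match="single class"):
            fs.chi2_scores(np.ones((5, 2)), np.ones(5, dtype=int))


class TestReliefF:
    def test_constant_feature_weight_exactly_zero(self):
        X = np.column_stack([np.full(8, 2.0), np.arange(8.0)])
        y = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        r = fs.relieff_scores(X, y, k_hits=2)
        assert r.scores[0] == 0.0

    def test_four_point_instance_matches_enumeration(self):
        # informative feature separates classes; noise feature does not
        X = np.array([[0.0, 0.3], [0.0, 0.9], [1.0, 0.1], [1.0, 0.7]])
        y = np.array([1, 1, 2, 2])
        got = fs.relieff_scores(X, y, k_hits=1).scores
        want = relieff_brute(X, y, k_hits=1)
        np.testing.assert_allclose(got, want, atol=1e-12)
        assert got[0] > got[1]

    def test_duplicated_samples_match_enumeration(self, rng):
        # duplicating every sample changes the weights (each duplicate becomes
        # its own zero-distance hit), but implementation and exhaustive
        # enumeration must agree exactly on the duplicated instance
        X = rng.standard_normal((10, 3))
        y = np.array([1] * 5 + [2] * 5)
        X2 = np.vstack([X, X])
        y2 = np.concatenate([y, y])
        b = fs.relieff_scores(X2, y2, k_hits=2).scores
        np.testing.assert_allclose(b, relieff_brute(X2, y2, k_hits=2), atol=1e-12)

    def test_small_class_rejected(self):
        X = np.arange(10.0).reshape(5, 2)
        y = np.array([1, 1, 1, 1, 2])
        with pytest.raises(SelectionError, match="class 2"):
            fs.relieff_scores(X, y, k_hits=2)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 13))
        d = int(rng.integers(1, 5))
        X = rng.standard_normal((n, d))
        y = np.concatenate([np.ones(n // 2, int), np.full(n - n // 2, 2, int)])
        got = fs.relieff_scores(X, y, k_hits=2).scores
        want = relieff_brute(X, y, k_hits=2)
        np.testing.assert_allclose(got, want, atol=1e-10)


class TestNCA:
    def test_objective_at_init_matches_direct_evaluation(self):
        # small printed instance, evaluated against an independent per-pair sum
        Xs = np.array([[0.0, 1.0], [0.2, 0.8], [1.0, 0.1], [0.9, 0.0]])
        y = np.array([1, 1, 2, 2])
        w = np.ones(2)
        lam = 0.25
        got = fs.nca_objective(Xs, y, w, lam)
        want = nca_objective_direct(Xs, y, w, lam)
        assert got == pytest.approx(want, abs=1e-12)

    def test_optimization_increases_objective(self, rng):
        X = np.vstack(
            [rng.normal(0, 1, (15, 3)), rng.normal(3, 1, (15, 3))]
        )
        y = np.array([1] * 15 + [2] * 15)
        mu, sd = X.mean(0), X.std(0)
        Xs = (X - mu) / sd
        r = fs.nca_weights(X, y, max_iter=50)
        w_final = np.sqrt(r.scores)
        lam = 1.0 / 30
        assert fs.nca_objective(Xs, y, w_final, lam) > fs.nca_objective(
            Xs, y, np.ones(3), lam
        )

    def test_noise_feature_down_weighted(self, rng):
        # separable 2-feature instance plus one pure-noise column
        n = 30
        X = np.vstack(
            [rng.normal([0, 0], 0.3, (n, 2)), rng.normal([3, 3], 0.3, (n, 2))]
        )
        X = np.column_stack([X, rng.standard_normal(2 * n)])
        y = np.array([1] * n + [2] * n)
        r = fs.nca_weights(X, y, lam=1.0, max_iter=200)
        assert r.scores[2] < 0.1 * r.scores[:2].max()

    def test_weights_vanish_as_lambda_grows(self, rng):
        X = rng.standard_normal((20, 3))
        y = np.array([1, 2] * 10)
        norms = [
            fs.nca_weights(X, y, lam=lam, max_iter=60).scores.sum()
            for lam in (0.1, 10.0, 1000.0)
        ]
        assert norms[0] > norms[1] > norms[2]
        assert norms[2] < 1e-3

    def test_deterministic(self, rng):
        X = rng.standard_normal((15, 4))
        y = np.array([1, 2, 1, 2, 1] * 3)
        a = fs.nca_weights(X, y).scores
        b = fs.nca_weights(X, y).scores
        np.testing.assert_array_equal(a, b)


class TestScaleInvariance:
    """Affine rescaling of a single feature never changes selector scores."""

    @pytest.mark.parametrize("selector", ["chi2", "relieff", "nca"])
    def test_affine_rescaling_single_column(self, selector, rng):
        X = rng.standard_normal((24, 4))
        y = np.array([1, 2] * 12)
        kwargs = {"max_iter": 30} if selector == "nca" else {}
        if selector == "relieff":
            kwargs = {"k_hits": 3}
        a = fs.score_features(X, y, selector=selector, **kwargs).scores
        X2 = X.copy()
        X2[:, 1] = 5.0 * X2[:, 1] - 7.0
        b = fs.score_features(X2, y, selector=selector, **kwargs).scores
        np.testing.assert_allclose(a, b, atol=1e-7)


class TestSelectTopK:
    def test_retains_272_of_1000(self, rng):
        fm = _fm(rng.standard_normal((20, 1000)), [1, 2] * 10)
        ranking = fs.chi2_scores(fm)
        sel, reduced = fs.select_top_k(ranking, fm)
        assert sel.k == 272
        assert reduced.d == 272
        assert len(set(sel.indices.tolist())) == 272

    def test_clamps_when_d_below_k(self, rng):
        fm = _fm(rng.standard_normal((20, 100)), [1, 2] * 10)
        sel, reduced = fs.select_top_k(fs.chi2_scores(fm), fm, k=272)
        assert sel.k == 100 and reduced.d == 100

    def test_all_equal_scores_keep_first_columns(self, rng):
        fm = _fm(rng.standard_normal((10, 50)), [1, 2] * 5)
        ranking = fs.FeatureRanking("chi2", np.zeros(50))
        sel, _ = fs.select_top_k(ranking, fm, k=20)
        assert sel.indices.tolist() == list(range(20))

    def test_columns_ordered_by_descending_score(self, rng):
        fm = _fm(rng.standard_normal((10, 30)), [1, 2] * 5)
        scores = rng.permutation(30).astype(float)
        sel, reduced = fs.select_top_k(fs.FeatureRanking("chi2", scores), fm, k=10)
        assert (np.diff(scores[sel.indices]) <= 0).all()
        np.testing.assert_array_equal(reduced.values, fm.values[:, sel.indices])

    def test_nonpositive_k_rejected(self, rng):
        fm = _fm(rng.standard_normal((10, 5)), [1, 2] * 5)
        with pytest.raises(SelectionError, match="positive"):
            fs.select_top_k(fs.chi2_scores(fm), fm, k=0)


def test_eighteen_selected_sets_from_six_matrices(rng):
    """3 selectors x 6 matrices -> exactly 18 selected feature sets."""
    sets = []
    for m in range(6):
        fm = _fm(rng.standard_normal((20, 300)), [1, 2] * 10, source=f"m{m}")
        for selector in fs.SELECTORS:
            kwargs = {"k_hits": 3} if selector == "relieff" else (
                {"max_iter": 5} if selector == "nca" else {}
            )
            ranking = fs.score_features(fm, selector=selector, **kwargs)
            sel, _ = fs.select_top_k(ranking, fm)
            sets.append(sel)
    assert len(sets) == 18
    assert len({s.name for s in sets}) == 18
    assert all(s.k == 272 for s in sets)
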