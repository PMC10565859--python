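"""swLDA selection, cross-validation, chance level and model comparison."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from earload.classify import (
    assign_folds,
    chance_level,
    compare_models,
    crossvalidate,
    swlda_predict,
    swlda_train,
)


def _partial_pvals(X, y, subset):
    """Independent least-squares oracle: partial-F p of each feature in the
    regression of y on X[:, subset] (all centered)."""
    Xc = X - X.mean(axis=0)
    yv = np.where(y == np.unique(y)[1], 1.0, -1.0)
    yc = yv - yv.mean()
    G = Xc[:, list(subset)]
    n, k = G.shape
    gram_inv = np.linalg.pinv(G.T @ G)
    w = gram_inv @ G.T @ yc
    resid = yc - G @ w
    df = n - k - 1
    sigma2 = resid @ resid / df
    F = w**2 / (sigma2 * np.diag(gram_inv))
    return sps.f.sf(F, 1, df)


def _entry_pval(X, y, subset, j):
    """Partial-F p for adding feature j to subset, via two full fits."""
    Xc = X - X.mean(axis=0)
    yv = np.where(y == np.unique(y)[1], 1.0, -1.0)
    yc = yv - yv.mean()

    def sse(cols):
        if not cols:
            return float(yc @ yc)
        G = Xc[:, list(cols)]
        w, *_ = np.linalg.lstsq(G, yc, rcond=None)
        r = yc - G @ w
        return float(r @ r)

    s0, s1 = sse(list(subset)), sse(list(subset) + [j])
    df2 = len(y) - (len(subset) + 1) - 1
    if s1 <= 0:
        return 0.0
    F = (s0 - s1) / (s1 / df2)
    return float(sps.f.sf(F, 1, df2))


def stable_subsets(X, y, p_in=0.1, p_out=0.15):
    """All subsets at which stepwise selection would terminate: no excluded
    feature enters at p < p_in and no included feature exits at p > p_out."""
    p = X.shape[1]
    out = []
    for r in range(p + 1):
        for subset in itertools.combinations(range(p), r):
            if subset and np.any(_partial_pvals(X, y, subset) > p_out):
                continue
            entries = [_entry_pval(X, y, subset, j) for j in range(p) if j not in subset]
            if entries and min(entries) < p_in:
                continue
            out.append(set(subset))
    return out


class TestSwldaTrain:
    def test_separable_feature_found(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((200, 10))
        y = (X[:, 3] > 0).astype(int)
        model = swlda_train(X, y)
        assert 3 in model.selected
        pred, _ = swlda_predict(model, X)
        assert np.mean(pred == y) > 0.97

    def test_matches_exhaustive_stable_subset(self):
        """On a 5-feature toy with one informative pair, the greedy
        selection lands on a stepwise-stable subset found by brute force
        over all 32 subsets under the same partial-F criterion."""
        rng = np.random.default_rng(1)
        n = 120
        latent = rng.standard_normal(n)
        X = rng.standard_normal((n, 5))
        X[:, 1] = latent + 0.1 * rng.standard_normal(n)
        X[:, 4] = latent + 0.1 * rng.standard_normal(n)  # correlated twin
        y = (latent + 0.5 * rng.standard_normal(n) > 0).astype(int)
        model = swlda_train(X, y)
        stables = stable_subsets(X, y)
        assert set(model.selected) in stables
        # the selected set must include exactly one of the informative twins
        assert len({1, 4} & set(model.selected)) >= 1

    def test_retained_features_respect_p_out(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((150, 20))
        y = (X[:, 0] + X[:, 5] + rng.standard_normal(150) > 0).astype(int)
        model = swlda_train(X, y)
        if model.selected:
            pv = _partial_pvals(X, y, model.selected)
            assert np.all(pv <= 0.15 + 1e-9)

    def test_trace_replays_to_final_set(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 8))
        y = (X[:, 2] - X[:, 6] + 0.5 * rng.standard_normal(100) > 0).astype(int)
        model = swlda_train(X, y)
        replay: list = []
        for _, action, j, _ in model.selection_trace:
            if action == "add":
                replay.append(j)
            else:
                replay.remove(j)
        assert replay == model.selected

    def test_null_data_selects_sparingly(self):
        """On pure noise the retained fraction stays near p_in."""
        rng = np.random.default_rng(4)
        fracs = []
        for _ in range(10):
            X = rng.standard_normal((100, 30))
            y = rng.integers(0, 2, 100)
            fracs.append(len(swlda_train(X, y).selected) / 30)
        assert 0.0 <= np.mean(fracs) < 0.3

    def test_empty_selection_majority_fallback(self):
        X = np.zeros((40, 3))  # constant features can never enter
        y = np.array([0] * 25 + [1] * 15)
        model = swlda_train(X, y)
        assert model.is_empty
        pred, scores = swlda_predict(model, X)
        assert np.all(pred == 0)
        assert np.all(scores == 0)

    def test_preconditions(self):
        X = np.random.default_rng(5).standard_normal((30, 4))
        with pytest.raises(ValueError):
            swlda_train(X, np.zeros(30))  # one class
        with pytest.raises(ValueError):
            swlda_train(X, np.arange(30) % 2, p_in=0.2, p_out=0.1)


class TestPredict:
    def test_hand_computed_score(self):
        from earload.classify import SWLDAModel

        model = SWLDAModel(
            selected=[0, 2], weights=np.array([2.0, -1.0]), threshold=0.5,
            feature_means=np.array([1.0, 1.0]), classes=np.array(["low", "high"]),
            p_in=0.1, p_out=0.15,
        )
        X = np.array([[2.0, 99.0, 3.0]])  # score = 2*(2-1) - 1*(3-1) = 0
        labels, scores = swlda_predict(model, X)
        assert scores[0] == pytest.approx(0.0)
        assert labels[0] == "low"  # below threshold 0.5


class TestFolds:
    def test_round_robin_sizes(self):
        part = assign_folds(20, 10)
        sizes = np.bincount(part)[1:]
        assert list(sizes) == [2] * 10
        part23 = assign_folds(23, 10)
        assert sorted(np.bincount(part23)[1:], reverse=True) == [3, 3, 3] + [2] * 7

    def test_partition_frozen_across_models(self):
        assert np.array_equal(assign_folds(501), assign_folds(501))
        assert assign_folds(501).tobytes() == assign_folds(501).tobytes()

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            assign_folds(5, 10)


class TestCrossValidate:
    def test_label_equals_feature_is_perfect(self):
        y = np.arange(100) % 2
        X = np.column_stack([y.astype(float), np.random.default_rng(6).standard_normal(100)])
        cv = crossvalidate(X, y)
        assert cv.mean_accuracy == 100.0

    def test_strong_gaussian_features_above_ninety(self):
        rng = np.random.default_rng(7)
        n = 400
        y = np.arange(n) % 2
        X = rng.standard_normal((n, 40))
        X[:, 5] += 3.0 * y
        X[:, 17] -= 2.5 * y
        cv = crossvalidate(X, y)
        assert cv.mean_accuracy >= 90.0

    def test_null_features_below_chance_threshold(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((768, 50))
        y = rng.integers(0, 2, 768)
        cv = crossvalidate(X, y)
        assert cv.chance_threshold == chance_level(768, 2, 0.001)
        assert cv.mean_accuracy < cv.chance_threshold

    def test_fold_missing_class_flagged(self):
        y = np.array([0] * 18 + [1] * 2)
        X = np.random.default_rng(9).standard_normal((20, 3))
        part = np.array([1] * 2 + [2] * 16 + [3] * 2)  # fold 3 holds all of class 1
        cv = crossvalidate(X, y, part)
        assert len(cv.fold_accuracies) + len(cv.excluded_folds) == 3


class TestChanceLevel:
    def test_paper_operating_point(self):
        assert chance_level(500, 2, 0.001) == 57.0

    def test_small_sample_binomial_oracle(self):
        # binomial tail: P(X >= 15 | n=20, p=.5) = 0.0207 <= 0.05,
        # so the binoinv threshold is 14/20 = 70%
        assert sps.binom.sf(14, 20, 0.5) == pytest.approx(0.0207, abs=1e-4)
        assert chance_level(20, 2, 0.05) == 70.0

    def test_monotonicity(self):
        levels = [chance_level(n, 2, 0.001) for n in (50, 100, 500, 2000)]
        assert all(a >= b for a, b in zip(levels, levels[1:]))
        by_alpha = [chance_level(500, 2, a) for a in (0.05, 0.01, 0.001)]
        assert by_alpha[0] <= by_alpha[1] <= by_alpha[2]

    def test_large_n_loose_alpha_approaches_half(self):
        assert chance_level(100_000, 2, 0.4999) == pytest.approx(50.0, abs=0.1)


class TestCompareModels:
    def test_zero_variance_guard(self):
        with pytest.raises(ValueError):
            compare_models([70.0, 71.0, 72.0], [70.0, 71.0, 72.0])

    def test_constant_shift_strongly_significant(self):
        rng = np.random.default_rng(10)
        a = 70 + rng.standard_normal(140)
        res = compare_models(a, a + 10.0 + 0.1 * rng.standard_normal(140))
        assert res.p < 0.001 and res.significant

    def test_hand_computed_t(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([1.5, 2.1, 3.4, 4.2, 5.8])
        d = b - a
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        res = compare_models(a, b)
        assert res.t == pytest.approx(-t_hand)  # ttest_rel(a, b) tests a - b
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t_hand), 4))
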