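"""Wilks' lambda, stepwise entry, and pooled-covariance LDA."""

import math

import numpy as np
import pytest
from scipy import linalg, stats
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.pipeline import Pipeline

from fibertex.discriminant import (
    PooledCovarianceLDA,
    WilksLambdaSelector,
    canonical_variables,
    confidence_ellipse,
    forward_select,
    partial_F,
    wilks_lambda,
)


class TestWilksLambda:
    def test_perfect_separation_is_zero(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]])
        y = np.array(["a", "a", "b", "b"])
        assert wilks_lambda(X, y) == 0.0

    def test_no_separation_is_one(self):
        X = np.array([[0.0], [1.0], [0.0], [1.0]])
        y = np.array(["a", "a", "b", "b"])
        assert wilks_lambda(X, y) == pytest.approx(1.0)

    def test_hand_computed_scatter_ratio(self):
        # A: {0, 1}, B: {2, 3} -> SSW = 1, SST = 5, lambda = 0.2
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array(["A", "A", "B", "B"])
        assert wilks_lambda(X, y) == pytest.approx(0.2, abs=1e-12)

    def test_singular_scatter_raises(self):
        X = np.column_stack([np.arange(8.0), np.arange(8.0)])  # collinear pair
        y = np.array(["a"] * 4 + ["b"] * 4)
        with pytest.raises(ValueError, match="singular"):
            wilks_lambda(X, y)

    def test_monotone_under_feature_addition(self, rng):
        X = rng.normal(0, 1, (40, 6))
        y = rng.choice(["a", "b", "c"], 40)
        for _ in range(20):
            k = rng.integers(1, 5)
            subset = list(rng.choice(6, size=k, replace=False))
            extra = int(rng.choice([j for j in range(6) if j not in subset]))
            lam = wilks_lambda(X, y, subset)
            lam_more = wilks_lambda(X, y, subset + [extra])
            assert lam_more <= lam + 1e-10


class TestPartialF:
    def test_formula_on_hand_example(self):
        # entering the hand-example feature into an empty 2-group model of n=4
        F, p = partial_F(1.0, 0.2, n=4, g=2, p_in_model=0)
        assert F == pytest.approx(8.0, abs=1e-12)

    def test_no_improvement_gives_zero(self):
        F, p = partial_F(0.5, 0.5, n=20, g=3, p_in_model=2)
        assert F == 0.0
        assert p == pytest.approx(1.0)

    def test_zero_lambda_convention(self):
        F, p = partial_F(0.5, 0.0, n=20, g=2, p_in_model=0)
        assert math.isinf(F)
        assert p == 0.0

    def test_p_value_matches_closed_form_f12(self):
        # F(1, 2): closed-form survival via the t(2) distribution, T^2 = F
        for Fval in (0.5, 1.0, 8.0, 30.0):
            _, p = partial_F(1.0, 1.0 / (1.0 + Fval / 2.0), n=4, g=2, p_in_model=0)
            t = math.sqrt(Fval)
            p_ref = 2 * (0.5 - 0.5 * t / math.sqrt(2.0) / math.sqrt(1 + t * t / 2.0))
            assert p == pytest.approx(p_ref, abs=1e-6)


class TestForwardSelect:
    def test_informative_feature_enters_first(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = np.repeat(["a", "b", "c"], 20)
            X = rng.normal(0, 1, (60, 6))
            shift = {"a": 0.0, "b": 5.0, "c": 10.0}
            X[:, 3] += [shift[c] for c in y]
            res = forward_select(X, y, feature_names=list("uvwxyz"))
            hits += res.entered[0] == "x"
        assert hits >= 9

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha_enter"):
            forward_select(np.zeros((10, 2)), np.repeat(["a", "b"], 5), alpha_enter=0.0)

    def test_identical_groups_select_nothing(self):
        X = np.tile(np.arange(10.0)[:, None], (2, 1))
        y = np.repeat(["a", "b"], 10)
        with pytest.warns(UserWarning, match="no features"):
            res = forward_select(X, y)
        assert res.entered == []

    def test_alpha_one_enters_all_nondegenerate(self, rng):
        X = rng.normal(0, 1, (30, 5))
        y = rng.choice(["a", "b"], 30)
        res = forward_select(X, y, alpha_enter=1.0)
        assert len(res.entered) == 5

    def test_lambda_non_increasing_and_p_below_alpha(self, rng):
        y = np.repeat(["a", "b", "c"], 20)
        X = rng.normal(0, 1, (60, 8))
        X[:, 0] += np.repeat([0.0, 1.5, 3.0], 20)
        res = forward_select(X, y, alpha_enter=0.35)
        lams = [s.wilks_lambda for s in res.steps]
        assert all(a >= b - 1e-12 for a, b in zip(lams, lams[1:]))
        assert all(s.p_value <= 0.35 for s in res.steps)


class TestSelectorEstimator:
    def test_sklearn_api_and_pipeline(self, rng):
        import pandas as pd

        y = np.repeat(["a", "b"], 30)
        X = pd.DataFrame(
            {"noise1": rng.normal(0, 1, 60),
             "signal": rng.normal(0, 1, 60) + (y == "b") * 4.0,
             "noise2": rng.normal(0, 1, 60)}
        )
        sel = WilksLambdaSelector(alpha_enter=0.05)
        clone(sel)  # get_params/set_params round trip
        sel.fit(X, y)
        assert sel.result_.entered[0] == "signal"
        assert sel.transform(X).shape[1] == sel.support_.sum()

        pipe = Pipeline([("sel", WilksLambdaSelector(alpha_enter=0.05)),
                         ("lda", PooledCovarianceLDA())])
        pipe.fit(X.to_numpy(), y)
        assert set(pipe.predict(X.to_numpy())) <= {"a", "b"}


class TestPooledCovarianceLDA:
    def test_two_gaussian_bayes_error(self):
        rng = np.random.default_rng(0)
        n = 2000
        Xtr = np.concatenate([rng.normal(-2, 1, n), rng.normal(2, 1, n)])[:, None]
        ytr = np.repeat(["neg", "pos"], n)
        Xte = np.concatenate([rng.normal(-2, 1, n), rng.normal(2, 1, n)])[:, None]
        yte = np.repeat(["neg", "pos"], n)
        lda = PooledCovarianceLDA().fit(Xtr, ytr)
        err = np.mean(lda.predict(Xte) != yte)
        bayes = stats.norm.cdf(-2.0)
        assert abs(err - bayes) < 0.02
        # decision boundary near zero
        xs = np.linspace(-1, 1, 2001)[:, None]
        flip = xs[np.argmax(lda.predict(xs) == "pos")]
        assert abs(flip[0]) < 0.1

    def test_uninformative_features_give_prior_posteriors(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (500, 3))
        y = np.array(["a"] * 300 + ["b"] * 200)
        lda = PooledCovarianceLDA().fit(X, y)
        post = lda.predict_proba(X)
        assert np.mean(np.abs(post - lda.priors_)) < 0.05

    def test_n_weighted_priors_track_class_sizes(self, rng):
        X = rng.normal(0, 1, (30, 2))
        y = np.array(["a"] * 10 + ["b"] * 20)
        lda = PooledCovarianceLDA().fit(X, y)
        assert np.allclose(lda.priors_, [1 / 3, 2 / 3])
        X2 = np.vstack([X, X[y == "a"]])
        y2 = np.concatenate([y, ["a"] * 10])
        lda2 = PooledCovarianceLDA().fit(X2, y2)
        assert np.allclose(lda2.priors_, [0.5, 0.5])

    def test_singleton_class_rejected(self, rng):
        X = rng.normal(0, 1, (5, 2))
        y = np.array(["a", "a", "a", "a", "lone"])
        with pytest.raises(ValueError, match="lone"):
            PooledCovarianceLDA().fit(X, y)

    def test_prediction_invariant_to_feature_rescaling(self, rng):
        X = rng.normal(0, 1, (80, 4))
        y = rng.choice(["a", "b", "c"], 80)
        X[:, 1] += (y == "b") * 2.0
        lda1 = PooledCovarianceLDA().fit(X, y)
        X2 = X.copy()
        X2[:, 1] = X2[:, 1] * 1e4 - 37.0
        lda2 = PooledCovarianceLDA().fit(X2, y)
        assert np.max(np.abs(lda1.predict_proba(X) - lda2.predict_proba(X2))) < 1e-8

    def test_matches_sklearn_reference(self, rng):
        X = rng.normal(0, 1, (150, 5))
        y = rng.choice(["a", "b", "c"], 150)
        X[:, 0] += (y == "a") * 1.5
        X[:, 2] -= (y == "c") * 2.0
        ours = PooledCovarianceLDA(standardize=False).fit(X, y)
        ref = LinearDiscriminantAnalysis(solver="svd").fit(X, y)
        assert np.mean(ours.predict(X) == ref.predict(X)) > 0.99
        assert np.allclose(ours.predict_proba(X), ref.predict_proba(X), atol=1e-6)


class TestCanonicalVariables:
    def _three_class_data(self, rng, collinear=False):
        n = 60
        means = {"a": [0, 0], "b": [4, 0], "c": [8, 0] if collinear else [2, 5]}
        X = np.vstack([rng.normal(means[c], 1.0, (n, 2)) for c in "abc"])
        y = np.repeat(list("abc"), n)
        return X, y

    def test_collinear_means_dominated_by_first_axis(self, rng):
        X, y = self._three_class_data(rng, collinear=True)
        lda = PooledCovarianceLDA().fit(X, y)
        ev = lda.canonical_eigenvalues_
        assert ev[0] > 100 * max(ev[1], 1e-12) or len(ev) == 1

    def test_projected_between_scatter_is_diagonal(self, rng):
        X, y = self._three_class_data(rng)
        lda = PooledCovarianceLDA().fit(X, y)
        proj = lda.transform(X)
        means = np.vstack([proj[y == c].mean(axis=0) for c in "abc"])
        counts = np.array([(y == c).sum() for c in "abc"])
        grand = proj.mean(axis=0)
        B = (means - grand).T @ ((means - grand) * counts[:, None])
        off = abs(B[0, 1]) / math.sqrt(abs(B[0, 0] * B[1, 1]))
        assert off < 1e-8

    def test_matches_generalized_eigensolver_oracle(self, rng):
        X, y = self._three_class_data(rng)
        lda = PooledCovarianceLDA(standardize=False).fit(X, y)
        # brute-force W^-1 B eigenproblem
        grand = X.mean(axis=0)
        W = np.zeros((2, 2))
        B = np.zeros((2, 2))
        for c in "abc":
            Xc = X[y == c]
            d = Xc - Xc.mean(axis=0)
            W += d.T @ d
            m = (Xc.mean(axis=0) - grand)[:, None]
            B += len(Xc) * (m @ m.T)
        evals, evecs = linalg.eigh(B, W)
        order = np.argsort(evals)[::-1]
        for k in range(2):
            a = lda.scalings_[:, k] / np.linalg.norm(lda.scalings_[:, k])
            b = evecs[:, order[k]] / np.linalg.norm(evecs[:, order[k]])
            assert min(np.linalg.norm(a - b), np.linalg.norm(a + b)) < 1e-8

    def test_two_class_pads_second_axis(self, rng):
        X = rng.normal(0, 1, (40, 3))
        y = np.repeat(["a", "b"], 20)
        X[:, 0] += (y == "b") * 3.0
        lda = PooledCovarianceLDA().fit(X, y)
        with pytest.warns(UserWarning, match="zero-filled"):
            proj, _ = canonical_variables(lda, X, y)
        assert proj.shape == (40, 2)
        assert np.all(proj[:, 1] == 0.0)

    def test_confidence_ellipse_covers_points(self, rng):
        pts = rng.multivariate_normal([1.0, -2.0], [[2.0, 0.7], [0.7, 1.0]], 4000)
        ell = confidence_ellipse(pts, level=0.95)
        # fraction inside the ellipse should be ~0.95
        d = pts - ell["center"]
        c, s = math.cos(ell["angle_rad"]), math.sin(ell["angle_rad"])
        u = d @ np.array([[c, -s], [s, c]])
        inside = (u[:, 0] / ell["semi_axes"][0]) ** 2 + (u[:, 1] / ell["semi_axes"][1]) ** 2 <= 1
        assert abs(inside.mean() - 0.95) < 0.02
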