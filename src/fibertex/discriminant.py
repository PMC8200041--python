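"""Wilks'-lambda forward feature selection and pooled-covariance LDA.

Selection follows classical stepwise discriminant analysis semantics
(forward-only entry, significance level to enter alpha = 0.35): at each step
the candidate feature with the largest partial F — derived from the ratio of
Wilks' lambda before and after entry — joins the model, until no candidate
reaches the entry level.  Wilks' lambda is det(W)/det(W + B), the ratio of
within-group to total scatter of the current feature subset; the partial F
for adding one feature to a p-feature model with g groups and n observations
is

    F = ((n - g - p) / (g - 1)) * (Lambda_p / Lambda_{p+1} - 1)

on (g - 1, n - g - p) degrees of freedom.

The classifier is linear discriminant analysis with a pooled within-class
covariance applied through its singular value decomposition (small singular
values truncated, i.e. numerically stabilized) and priors proportional to
class sizes (N-weighted).  Canonical variables — eigenvectors of W^{-1}B —
provide the 2D scatter used to visualize class separation.

Both stages are scikit-learn estimators (`WilksLambdaSelector`,
`PooledCovarianceLDA`) and compose in sklearn pipelines; the module-level
functions are thin wrappers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "SelectionStep",
    "SelectionResult",
    "wilks_lambda",
    "partial_F",
    "forward_select",
    "WilksLambdaSelector",
    "PooledCovarianceLDA",
    "fit_lda",
    "canonical_variables",
    "confidence_ellipse",
]


class DegeneracyError(ValueError):
    """Raised when the scatter of a feature subset is singular."""


def _scatter_matrices(X: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Within-group scatter W and total scatter T of X given labels y."""
    grand = X.mean(axis=0)
    Xc = X - grand
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for g in np.unique(y):
        Xg = X[y == g]
        d = Xg - Xg.mean(axis=0)
        W += d.T @ d
    return W, T


def wilks_lambda(
    X: np.ndarray, y: np.ndarray, subset: Optional[Sequence[int]] = None
) -> float:
    """Wilks' lambda det(W)/det(T) of a feature subset; in [0, 1].

    0 means perfect group separation (no within-group scatter), 1 means the
    group means coincide.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if subset is not None:
        if len(subset) == 0:
            raise ValueError("subset must be nonempty")
        X = X[:, list(subset)]
    n, p = X.shape
    g = len(np.unique(y))
    if n <= g + p - 1:
        raise ValueError(f"need n > g + p - 1 observations (n={n}, g={g}, p={p})")
    W, T = _scatter_matrices(X, y)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_t <= 0 or not np.isfinite(logdet_t):
        raise DegeneracyError(
            f"singular total scatter for feature subset {list(subset) if subset is not None else 'all'}"
        )
    sign_w, logdet_w = np.linalg.slogdet(W)
    if sign_w <= 0:
        return 0.0
    lam = math.exp(logdet_w - logdet_t)
    return float(min(lam, 1.0))


def partial_F(
    lambda_current: float, lambda_candidate: float, n: int, g: int, p_in_model: int
) -> Tuple[float, float]:
    """Partial F statistic and p-value for entering one feature.

    ``lambda_current`` is Wilks' lambda of the p-feature model (1.0 for the
    empty model) and ``lambda_candidate`` that of the model with the
    candidate added.  Degrees of freedom are (g - 1, n - g - p).
    """
    df2 = n - g - p_in_model
    if df2 <= 0:
        raise ValueError(f"non-positive denominator df (n={n}, g={g}, p={p_in_model})")
    if not (0.0 <= lambda_candidate <= lambda_current + 1e-12):
        raise ValueError("lambda_candidate must lie in (0, lambda_current]")
    if lambda_candidate == 0.0:
        return math.inf, 0.0
    F = (df2 / (g - 1)) * (lambda_current / lambda_candidate - 1.0)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, g - 1, df2))
    return float(F), p


@dataclass(frozen=True)
class SelectionStep:
    feature: str
    wilks_lambda: float
    partial_F: float
    p_value: float
    df: Tuple[int, int]


@dataclass
class SelectionResult:
    entered: List[str] = field(default_factory=list)
    steps: List[SelectionStep] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"step": i + 1, "feature": s.feature, "wilks_lambda": s.wilks_lambda,
                 "partial_F": s.partial_F, "p_value": s.p_value,
                 "df1": s.df[0], "df2": s.df[1]}
                for i, s in enumerate(self.steps)
            ]
        )


def forward_select(
    X: np.ndarray,
    y: np.ndarray,
    alpha_enter: float = 0.35,
    max_features: Optional[int] = None,
    feature_names: Optional[Sequence[str]] = None,
) -> SelectionResult:
    """Forward-only stepwise entry by largest partial F, gated at alpha_enter.

    Ties in F break lexicographically by feature name for reproducibility.
    Degenerate candidates (singular total scatter) are skipped with a
    warning.  An empty selection (no feature reaches the entry level) is
    returned with a warning, not an error.
    """
    if not (0.0 < alpha_enter <= 1.0):
        raise ValueError("alpha_enter must lie in (0, 1]")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, n_feat = X.shape
    g = len(np.unique(y))
    if g < 2:
        raise ValueError("need at least 2 groups")
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(n_feat)]
    feature_names = list(feature_names)
    if max_features is None:
        max_features = n_feat

    result = SelectionResult()
    entered_idx: List[int] = []
    lam_current = 1.0
    while len(entered_idx) < max_features:
        p_in = len(entered_idx)
        if n - g - p_in <= 0:
            break
        best: Optional[Tuple[float, str, int, float, float]] = None
        for j in range(n_feat):
            if j in entered_idx:
                continue
            try:
                lam_j = wilks_lambda(X, y, entered_idx + [j])
            except DegeneracyError:
                warnings.warn(f"feature {feature_names[j]!r} skipped: singular scatter",
                              stacklevel=2)
                continue
            lam_j = min(lam_j, lam_current)  # entry cannot increase lambda
            F, p = partial_F(lam_current, lam_j, n, g, p_in)
            key = (-F, feature_names[j])
            if best is None or key < (-best[0], best[1]):
                best = (F, feature_names[j], j, lam_j, p)
        if best is None:
            break
        F, name, j, lam_j, p = best
        if p > alpha_enter:
            break
        entered_idx.append(j)
        result.entered.append(name)
        result.steps.append(
            SelectionStep(feature=name, wilks_lambda=lam_j, partial_F=F, p_value=p,
                          df=(g - 1, n - g - len(entered_idx) + 1))
        )
        lam_current = lam_j
    if not result.entered:
        warnings.warn("forward selection entered no features", stacklevel=2)
    return result


class WilksLambdaSelector(SelectorMixin, BaseEstimator):
    """Forward stepwise feature selector by Wilks' lambda partial F.

    Parameters
    ----------
    alpha_enter : significance level to enter (classical default 0.35).
    max_features : optional cap on the number of entered features.
    """

    def __init__(self, alpha_enter: float = 0.35, max_features: Optional[int] = None):
        self.alpha_enter = alpha_enter
        self.max_features = max_features

    def fit(self, X, y):
        names = list(X.columns) if hasattr(X, "columns") else None
        X, y = check_X_y(X, y, dtype=float)
        self.n_features_in_ = X.shape[1]
        if names is None:
            names = [f"x{j}" for j in range(X.shape[1])]
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.result_ = forward_select(
            X, y, alpha_enter=self.alpha_enter, max_features=self.max_features,
            feature_names=names,
        )
        mask = np.zeros(X.shape[1], dtype=bool)
        name_to_idx = {nm: j for j, nm in enumerate(names)}
        for nm in self.result_.entered:
            mask[name_to_idx[nm]] = True
        self.support_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


class PooledCovarianceLDA(ClassifierMixin, BaseEstimator):
    """LDA with SVD-factorized pooled covariance and N-weighted priors.

    The pooled within-class covariance is inverted through its singular
    value decomposition with small singular values truncated
    (``sv_rtol`` x largest), i.e. pseudo-inverse behavior on near-singular
    problems.  Priors default to class proportions.  Features are z-scored
    internally (``standardize=True``) because the inputs span disparate
    scales; this leaves predictions invariant to affine rescaling of any
    feature.

    Discriminant score of class k at x:
    ``delta_k = x' S^-1 mu_k - mu_k' S^-1 mu_k / 2 + ln pi_k``;
    posteriors are the softmax of the scores.
    """

    def __init__(self, priors: Optional[Sequence[float]] = None,
                 sv_rtol: float = 1e-8, standardize: bool = True):
        self.priors = priors
        self.sv_rtol = sv_rtol
        self.standardize = standardize

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        counts = np.bincount(y_idx)
        for k, c in zip(self.classes_, counts):
            if c < 2:
                raise ValueError(f"class {k!r} has fewer than 2 observations")
        n, p = X.shape
        g = len(self.classes_)
        self.n_features_in_ = p

        if self.standardize:
            self.mean_ = X.mean(axis=0)
            scale = X.std(axis=0, ddof=0)
            self.scale_ = np.where(scale > 0, scale, 1.0)
        else:
            self.mean_ = np.zeros(p)
            self.scale_ = np.ones(p)
        Z = (X - self.mean_) / self.scale_

        if self.priors is None:
            self.priors_ = counts / n
        else:
            self.priors_ = np.asarray(self.priors, dtype=float)
            if len(self.priors_) != g or abs(self.priors_.sum() - 1.0) > 1e-9:
                raise ValueError("priors must match class count and sum to 1")

        self.means_ = np.vstack([Z[y_idx == k].mean(axis=0) for k in range(g)])
        W = np.zeros((p, p))
        for k in range(g):
            d = Z[y_idx == k] - self.means_[k]
            W += d.T @ d
        self.covariance_ = W / (n - g)

        # SVD factorization with singular-value truncation
        U, s, Vt = np.linalg.svd(self.covariance_, hermitian=True)
        keep = s > self.sv_rtol * s[0] if s[0] > 0 else np.zeros_like(s, dtype=bool)
        self.singular_values_ = s
        self.rank_ = int(keep.sum())
        s_inv = np.where(keep, 1.0 / np.where(s > 0, s, 1.0), 0.0)
        self._cov_inv = (Vt.T * s_inv) @ U.T

        self.coef_ = self.means_ @ self._cov_inv  # (g, p)
        self.intercept_ = (
            -0.5 * np.einsum("kp,kp->k", self.means_ @ self._cov_inv, self.means_)
            + np.log(self.priors_)
        )
        self._fit_canonical(W, Z, y_idx, counts)
        return self

    def _fit_canonical(self, W, Z, y_idx, counts):
        """Canonical axes: eigenvectors of W^-1 B via simultaneous whitening."""
        g = len(self.classes_)
        grand = Z.mean(axis=0)
        B = np.zeros_like(W)
        for k in range(g):
            d = (self.means_[k] - grand)[:, None]
            B += counts[k] * (d @ d.T)
        Uw, sw, _ = np.linalg.svd(W, hermitian=True)
        keep = sw > self.sv_rtol * sw[0] if sw[0] > 0 else np.zeros_like(sw, dtype=bool)
        half = Uw[:, keep] / np.sqrt(sw[keep])
        C = half.T @ B @ half
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        n_axes = min(g - 1, int(np.sum(evals[order] > 1e-12 * max(evals.max(), 1.0))))
        n_axes = max(n_axes, 1)
        axes = half @ evecs[:, order[:n_axes]]
        self.scalings_ = axes  # standardized space -> canonical space
        self.canonical_eigenvalues_ = evals[order[:n_axes]]
        self._grand_mean_std = grand

    # ------------------------------------------------------------------
    def _standardized(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        return (X - self.mean_) / self.scale_

    def decision_function(self, X) -> np.ndarray:
        Z = self._standardized(X)
        return Z @ self.coef_.T + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        d = self.decision_function(X)
        d -= d.max(axis=1, keepdims=True)
        e = np.exp(d)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def transform(self, X) -> np.ndarray:
        """Project onto the canonical axes, centered on the grand mean."""
        Z = self._standardized(X)
        return (Z - self._grand_mean_std) @ self.scalings_


def fit_lda(X, y, priors: Optional[Sequence[float]] = None) -> PooledCovarianceLDA:
    """Fit a pooled-covariance LDA with N-weighted (or given) priors."""
    return PooledCovarianceLDA(priors=priors).fit(X, y)


def confidence_ellipse(points: np.ndarray, level: float = 0.95) -> dict:
    """95% (by default) confidence ellipse of a 2D point cloud.

    Returns center, semi-axes and orientation from the sample mean and
    covariance at the chi-square(2 df) quantile of ``level``.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) < 3:
        raise ValueError("need an (n >= 3, 2) point array")
    center = points.mean(axis=0)
    cov = np.cov(points.T)
    evals, evecs = np.linalg.eigh(cov)
    q = stats.chi2.ppf(level, df=2)
    order = np.argsort(evals)[::-1]
    semi = np.sqrt(np.clip(evals[order], 0.0, None) * q)
    angle = math.atan2(evecs[1, order[0]], evecs[0, order[0]])
    return {"center": center, "semi_axes": semi, "angle_rad": angle}


def canonical_variables(
    model: PooledCovarianceLDA, X, y=None, pad_2d: bool = True
) -> Tuple[np.ndarray, dict]:
    """Canonical projections of X and per-class 95% confidence ellipses.

    With two classes there is a single canonical axis; the second coordinate
    is zero-filled (with a notice) so scatter plots stay two-dimensional.
    """
    proj = model.transform(X)
    if proj.shape[1] == 1 and pad_2d:
        warnings.warn("single canonical axis (two classes): second coordinate zero-filled",
                      stacklevel=2)
        proj = np.column_stack([proj[:, 0], np.zeros(len(proj))])
    ellipses = {}
    if y is not None and proj.shape[1] >= 2:
        y = np.asarray(y)
        for cls in np.unique(y):
            pts = proj[y == cls][:, :2]
            if len(pts) >= 3 and np.linalg.matrix_rank(np.cov(pts.T)) > 0:
                try:
                    ellipses[cls] = confidence_ellipse(pts)
                except ValueError:
                    pass
    return proj, ellipses
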