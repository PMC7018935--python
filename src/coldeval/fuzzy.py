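"""Fuzzy subordinate-function scoring and the comprehensive D value.

Each retained comprehensive index CI(i) is rescaled across varieties with the
subordinate (membership) function

    μ(x_i) = (x_i − x_min) / (x_max − x_min),

weighted by its normalized contribution rate

    w_i = p_i / Σ_retained p_j,

and combined into the comprehensive evaluation value

    D = Σ_i μ(x_i) · w_i  ∈ [0, 1],

where a larger D means a more stress-tolerant variety. D is then thresholded
into tolerance classes (very strong > 0.8, strong 0.5–0.8, moderate 0.2–0.5,
weak < 0.2; boundaries go to the higher class) and varieties are ranked by
descending D with competition ranking for ties.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import IndexMatrix
from .pca import CorrelationPCA, _as_frame

TOLERANCE_CLASSES = ("weak", "moderate", "strong", "very_strong")
DEFAULT_CLASS_BOUNDARIES = (0.2, 0.5, 0.8)


class MinMaxMembership(TransformerMixin, BaseEstimator):
    """Column-wise min–max subordinate-function scaling into [0, 1].

    Fitted attributes ``data_min_`` / ``data_max_`` record the per-component
    extremes of the CI scores used; on the training data each column attains
    an exact 0 (the minimum variety) and an exact 1 (the maximum variety).
    A constant column is rejected: it cannot discriminate varieties.
    """

    def fit(self, X, y=None):
        df = _as_frame(X)
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        self.n_features_in_ = df.shape[1]
        self.data_min_ = df.min().to_numpy()
        self.data_max_ = df.max().to_numpy()
        dead = [str(c) for c, lo, hi in zip(df.columns, self.data_min_, self.data_max_) if not hi > lo]
        if dead:
            raise ValueError(f"degenerate (constant) comprehensive index column(s): {dead}")
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "data_min_")
        df = _as_frame(X)
        mu = (df.to_numpy() - self.data_min_) / (self.data_max_ - self.data_min_)
        return pd.DataFrame(mu, index=df.index, columns=df.columns)


def membership(ci_scores) -> pd.DataFrame:
    """Subordinate-function values μ for a variety × component CI matrix."""
    return MinMaxMembership().fit_transform(ci_scores)


def weights(contribution_rates) -> np.ndarray:
    """Normalize retained-component contribution rates: w_i = p_i / Σp_j.

    The sum runs over the retained components only, so the weights sum to 1.
    """
    p = np.asarray(contribution_rates, dtype=float)
    if p.size == 0 or np.any(p <= 0) or not np.isfinite(p).all():
        raise ValueError("contribution rates must be positive and finite")
    return p / p.sum()


def d_score(mu, w) -> pd.Series:
    """Comprehensive evaluation value D = Σ μ(x_i)·w_i per variety."""
    mu_df = _as_frame(mu)
    w = np.asarray(w, dtype=float)
    if mu_df.shape[1] != w.size:
        raise ValueError(
            f"membership has {mu_df.shape[1]} components but {w.size} weights given"
        )
    return pd.Series(mu_df.to_numpy() @ w, index=mu_df.index, name="D")


def classify(d, boundaries=DEFAULT_CLASS_BOUNDARIES):
    """Map D value(s) to tolerance classes via the 0.2 / 0.5 / 0.8 thresholds.

    Boundary values are assigned to the higher class (D ≥ 0.8 → very_strong).
    """
    b = tuple(boundaries)
    if len(b) != 3 or not (0.0 < b[0] < b[1] < b[2] < 1.0):
        raise ValueError(f"class boundaries must be strictly increasing in (0,1): {b}")
    arr = np.asarray(d, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("D values must lie in [0, 1]")
    idx = np.searchsorted(b, arr, side="right")  # boundary -> higher class
    if arr.ndim == 0:
        return TOLERANCE_CLASSES[int(idx)]
    out = np.asarray(TOLERANCE_CLASSES, dtype=object)[idx]
    if isinstance(d, pd.Series):
        return pd.Series(out, index=d.index, name="tolerance_class")
    return out


def rank(d) -> pd.Series:
    """Competition ranking by descending D (ties share the smaller rank)."""
    arr = np.asarray(d, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty result set")
    r = rankdata(-arr, method="min").astype(int)
    index = d.index if isinstance(d, pd.Series) else pd.RangeIndex(arr.size)
    return pd.Series(r, index=index, name="rank")


class ColdToleranceEvaluator(BaseEstimator):
    """Full comprehensive-evaluation chain: PCA → μ → weights → D → class/rank.

    Fit on a variety × index matrix (an :class:`IndexMatrix` carries polarity
    metadata used to orient the components); with
    ``precomputed_ci=True`` the input is taken to be CI scores directly and
    ``contribution_rates`` must be supplied — the mode used to rerun a
    published worked example from its printed CI columns.

    Parameters
    ----------
    cumulative_threshold : float, default=85.0
        Percent cumulative contribution rate for component retention.
    class_boundaries : tuple of 3 floats, default=(0.2, 0.5, 0.8)
        D thresholds separating weak/moderate/strong/very_strong.
    precomputed_ci : bool, default=False
        Treat the fit input as CI scores and skip standardization + PCA.
    contribution_rates : sequence or None
        Retained-component contribution rates (percent); required and used
        only with ``precomputed_ci=True``.
    coefficient_convention : str, default="score"
        Passed through to :class:`~coldeval.pca.CorrelationPCA`.

    Attributes
    ----------
    pca_ : fitted CorrelationPCA (None when ``precomputed_ci``).
    ci_scores_, membership_ : variety × retained-component DataFrames.
    contribution_rates_, weights_ : per retained component.
    d_, classes_, ranks_ : per-variety Series.
    results_ : tidy per-variety DataFrame (CI scores, μ, D, class, rank).
    """

    def __init__(
        self,
        cumulative_threshold: float = 85.0,
        class_boundaries=DEFAULT_CLASS_BOUNDARIES,
        precomputed_ci: bool = False,
        contribution_rates=None,
        coefficient_convention: str = "score",
    ):
        self.cumulative_threshold = cumulative_threshold
        self.class_boundaries = class_boundaries
        self.precomputed_ci = precomputed_ci
        self.contribution_rates = contribution_rates
        self.coefficient_convention = coefficient_convention

    def fit(self, X, y=None):
        if self.precomputed_ci:
            if self.contribution_rates is None:
                raise ValueError("precomputed_ci=True requires contribution_rates")
            self.pca_ = None
            self.ci_scores_ = _as_frame(X).copy()
            rates = np.asarray(self.contribution_rates, dtype=float)
            if rates.size != self.ci_scores_.shape[1]:
                raise ValueError("one contribution rate per CI column is required")
        else:
            self.pca_ = CorrelationPCA(
                cumulative_threshold=self.cumulative_threshold,
                coefficient_convention=self.coefficient_convention,
            ).fit(X)
            self.ci_scores_ = self.pca_.ci_scores_
            rates = self.pca_.contribution_rates_[: self.pca_.n_retained_]
        self.contribution_rates_ = rates
        self.scaler_ = MinMaxMembership().fit(self.ci_scores_)
        self.membership_ = self.scaler_.transform(self.ci_scores_)
        self.weights_ = weights(rates)
        self.d_ = d_score(self.membership_, self.weights_)
        self.classes_ = classify(self.d_, self.class_boundaries)
        self.ranks_ = rank(self.d_)
        mu = self.membership_.copy()
        mu.columns = [c.replace("CI", "mu") if "CI" in str(c) else f"mu[{c}]" for c in mu.columns]
        self.results_ = pd.concat(
            [self.ci_scores_, mu, self.d_, self.classes_, self.ranks_], axis=1
        )
        self.results_.index.name = "variety"
        return self

    def fit_predict(self, X, y=None) -> pd.Series:
        """Fit and return the per-variety comprehensive score D."""
        return self.fit(X).d_

    def transform(self, X) -> pd.Series:
        """Score new varieties with the fitted PCA/membership parameters.

        Out-of-range CI values are clipped to [0, 1] after scaling so D stays
        a valid comprehensive score.
        """
        check_is_fitted(self, "d_")
        ci = _as_frame(X) if self.precomputed_ci else self.pca_.transform(X)
        mu = self.scaler_.transform(ci).clip(0.0, 1.0)
        return d_score(mu, self.weights_)
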