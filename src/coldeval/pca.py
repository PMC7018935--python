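"""Comprehensive indices by PCA on the correlation matrix.

Heterogeneous evaluation indices (ordinal damage degrees, ratios, enzyme
concentrations) are first standardized to zero mean and unit sample variance,
then eigendecomposed via their correlation matrix. Each retained principal
component defines a comprehensive index CI(x); its contribution rate
p_i = 100·λ_i/Σλ measures the share of total variance it explains, and the
cumulative-contribution rule decides how many components to keep.

Coefficients are reported as component *score* coefficients
(eigenvector entry / √λ), so CI scores are standardized (zero-mean,
unit-variance) linear combinations of the standardized indices; raw
eigenvectors and loadings (eigenvector·√λ) are available as alternates.
Downstream min–max membership is invariant to positive rescaling of CI, so
the comprehensive score D does not depend on this convention.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import IndexMatrix

#: Eigenvalue gap below which paired components are flagged as unstable.
DEGENERACY_TOL = 1e-10


class DegenerateColumnError(ValueError):
    """A constant (zero-variance) index column cannot be standardized."""


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, IndexMatrix):
        return X.data
    if isinstance(X, pd.DataFrame):
        return X
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D variety × index matrix")
    return pd.DataFrame(arr, columns=[f"x{j + 1}" for j in range(arr.shape[1])])


def standardize(matrix) -> pd.DataFrame:
    """Z-score every index column (sample sd, n−1 denominator).

    Raises :class:`DegenerateColumnError` naming any zero-variance index.
    """
    df = _as_frame(matrix)
    if not np.isfinite(df.to_numpy()).all():
        raise ValueError("non-finite values in index matrix")
    sd = df.std(ddof=1)
    dead = sd.index[~(sd > 0)].tolist()
    if dead:
        raise DegenerateColumnError(f"zero-variance index column(s): {dead}")
    return (df - df.mean()) / sd


def retain_components(contribution_rates, cumulative_threshold: float = 85.0) -> int:
    """Smallest k whose leading components reach the cumulative-rate threshold.

    ``contribution_rates`` are percentages in component order; the default
    85% threshold reproduces the usual two- or three-component retention.
    """
    rates = np.asarray(contribution_rates, dtype=float)
    if not 0.0 < cumulative_threshold <= 100.0:
        raise ValueError("cumulative_threshold must lie in (0, 100]")
    cum = np.cumsum(rates)
    hits = np.nonzero(cum >= cumulative_threshold - 1e-9)[0]
    return int(hits[0] + 1) if hits.size else len(rates)


class CorrelationPCA(TransformerMixin, BaseEstimator):
    """Correlation-matrix PCA with contribution-rate component retention.

    Parameters
    ----------
    cumulative_threshold : float, default=85.0
        Keep the smallest number of leading components whose cumulative
        contribution rate (percent of total variance) reaches this value.
    n_components : int or None
        Overrides the threshold rule with a fixed component count.
    coefficient_convention : {"score", "eigenvector", "loading"}
        How ``coefficients_`` are scaled. ``"score"`` (default) divides each
        eigenvector by √λ so transformed CI scores have unit sample variance.
    polarity_signs : array-like of ±1 or None
        Per-index orientation hints (−1 for lower-is-better indices). Each
        retained component is sign-flipped, if needed, so that it correlates
        non-negatively with the polarity-adjusted row mean of the
        standardized matrix — "bigger CI ⇒ more tolerant" where possible.
        Inferred automatically when fitting an :class:`IndexMatrix`.

    Attributes
    ----------
    eigenvalues_ : ndarray, descending, summing to the number of indices.
    contribution_rates_ : ndarray of percentages summing to 100.
    cumulative_rates_ : running sums of ``contribution_rates_``.
    n_retained_ : number of retained components k.
    coefficients_ : DataFrame (index × retained component) in the chosen
        convention; ``eigenvectors_`` and ``loadings_`` hold the alternates
        for all components.
    ci_scores_ : DataFrame (variety × retained component) of CI scores for
        the training data.
    unstable_components_ : boolean mask of components involved in a
        near-degenerate eigenvalue pair (coefficients arbitrary within the
        shared eigenspace).
    """

    def __init__(
        self,
        cumulative_threshold: float = 85.0,
        n_components: int | None = None,
        coefficient_convention: str = "score",
        polarity_signs=None,
    ):
        self.cumulative_threshold = cumulative_threshold
        self.n_components = n_components
        self.coefficient_convention = coefficient_convention
        self.polarity_signs = polarity_signs

    def fit(self, X, y=None):
        df = _as_frame(X)
        n, p = df.shape
        if n < 2 or p < 2:
            raise ValueError("need at least 2 varieties and 2 indices")
        if n <= p:
            warnings.warn(
                f"only {n} varieties for {p} indices; correlation matrix is "
                "rank-deficient and trailing components are uninformative",
                stacklevel=2,
            )
        if self.coefficient_convention not in ("score", "eigenvector", "loading"):
            raise ValueError(f"unknown coefficient convention {self.coefficient_convention!r}")
        z = standardize(df)
        zv = z.to_numpy()
        corr = zv.T @ zv / (n - 1)
        if not np.isfinite(corr).all():
            raise ValueError("correlation matrix contains non-finite entries")
        lam, vec = linalg.eigh(corr)
        order = np.argsort(lam)[::-1]
        lam = np.clip(lam[order], 0.0, None)
        vec = vec[:, order]

        rates = 100.0 * lam / lam.sum()
        if self.n_components is not None:
            k = int(self.n_components)
            if not 1 <= k <= p:
                raise ValueError(f"n_components={k} outside [1, {p}]")
        else:
            k = retain_components(rates, self.cumulative_threshold)

        # Orient signs: each component should track overall tolerance upward.
        signs = self._orientation_target_signs(X, p)
        target = zv @ signs
        for j in range(p):
            score_j = zv @ vec[:, j]
            c = float(score_j @ target)
            if c < 0 or (c == 0 and vec[np.argmax(np.abs(vec[:, j])), j] < 0):
                vec[:, j] = -vec[:, j]

        gaps = np.abs(np.diff(lam))
        unstable = np.zeros(p, dtype=bool)
        close = gaps < DEGENERACY_TOL
        unstable[:-1] |= close
        unstable[1:] |= close

        with np.errstate(divide="ignore", invalid="ignore"):
            inv_sqrt = np.where(lam > 0, 1.0 / np.sqrt(np.where(lam > 0, lam, 1.0)), 0.0)
        comp_names = [f"CI({i + 1})" for i in range(p)]
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        self.n_features_in_ = p
        self.mean_ = df.mean().to_numpy()
        self.scale_ = df.std(ddof=1).to_numpy()
        self.eigenvalues_ = lam
        self.eigenvectors_ = pd.DataFrame(vec, index=df.columns, columns=comp_names)
        self.loadings_ = pd.DataFrame(vec * np.sqrt(lam), index=df.columns, columns=comp_names)
        self._score_coefficients = pd.DataFrame(
            vec * inv_sqrt, index=df.columns, columns=comp_names
        )
        self.contribution_rates_ = rates
        self.cumulative_rates_ = np.cumsum(rates)
        self.n_retained_ = k
        self.unstable_components_ = unstable
        conv = {
            "score": self._score_coefficients,
            "eigenvector": self.eigenvectors_,
            "loading": self.loadings_,
        }[self.coefficient_convention]
        self.coefficients_ = conv.iloc[:, :k].copy()
        self.ci_scores_ = pd.DataFrame(
            z.to_numpy() @ self.coefficients_.to_numpy(),
            index=df.index,
            columns=comp_names[:k],
        )
        return self

    def _orientation_target_signs(self, X, p: int) -> np.ndarray:
        if self.polarity_signs is not None:
            signs = np.asarray(self.polarity_signs, dtype=float)
        elif isinstance(X, IndexMatrix):
            signs = X.polarity_signs()
        else:
            signs = np.ones(p)
        if signs.shape != (p,):
            raise ValueError(f"polarity_signs must have one entry per index ({p})")
        return signs / p

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "coefficients_")
        df = _as_frame(X)
        if list(df.columns) != list(self.feature_names_in_):
            raise ValueError("index columns do not match the fitted matrix")
        z = (df.to_numpy() - self.mean_) / self.scale_
        return pd.DataFrame(
            z @ self.coefficients_.to_numpy(),
            index=df.index,
            columns=self.coefficients_.columns,
        )

    def report_table(self, precision: int = 3) -> pd.DataFrame:
        """Publication-style block: coefficients per index, CR% and cumulative."""
        check_is_fitted(self, "coefficients_")
        tab = self.coefficients_.T.copy()
        tab["CR(%)"] = self.contribution_rates_[: self.n_retained_]
        tab["cumulative(%)"] = self.cumulative_rates_[: self.n_retained_]
        return tab.round(precision)


def fit_pca(z, cumulative_threshold: float = 85.0, **kwargs) -> CorrelationPCA:
    """Fit :class:`CorrelationPCA` on a (standardized or raw) index matrix."""
    return CorrelationPCA(cumulative_threshold=cumulative_threshold, **kwargs).fit(z)
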