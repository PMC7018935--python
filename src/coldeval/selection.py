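"""Indicator screening: which original indices track the comprehensive score.

Two complementary tools: per-index Pearson correlation with D (two-sided
t-test, df = n − 2), and p-value-based stepwise ordinary-least-squares
regression of D on the raw indices, yielding a reduced predictive equation
of the form D = b₀ + b₄·x₄ + b₁·x₁ that names the few indicators worth
measuring in future screens.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .pca import _as_frame


class CollinearityError(ValueError):
    """Perfect collinearity among candidate predictors."""


def correlate_with_d(matrix, d, alpha: float = 0.05) -> pd.DataFrame:
    """Pearson r of every index with the comprehensive score D.

    Returns a DataFrame indexed by index name with columns ``r``, ``p_value``
    and ``significant`` (p < alpha, two-sided t-test with n − 2 df).
    Raises for indices (or a D vector) without variance, where the
    correlation is undefined.
    """
    df = _as_frame(matrix)
    y = np.asarray(d, dtype=float)
    if df.shape[0] < 3:
        raise ValueError("need at least 3 varieties for a correlation test")
    if df.shape[0] != y.size:
        raise ValueError("variety sets of matrix and D are not aligned")
    if np.std(y) == 0:
        raise ValueError("D scores are constant; correlation undefined")
    rows = {}
    for col in df.columns:
        x = df[col].to_numpy()
        if np.std(x) == 0:
            raise ValueError(f"index {col!r} is constant; correlation undefined")
        r, p = stats.pearsonr(x, y)
        rows[col] = {"r": r, "p_value": p, "significant": bool(p < alpha)}
    return pd.DataFrame.from_dict(rows, orient="index")


class StepwiseSelector(RegressorMixin, BaseEstimator):
    """P-value stepwise OLS: forward entry with backward pruning.

    At each step the candidate with the smallest entry p-value below
    ``alpha_enter`` joins the model; any included predictor whose p-value
    rises above ``alpha_stay`` is dropped; iteration stops at a fixpoint and
    the final model is refit by plain OLS. Entry ties are broken by column
    order, so the procedure is deterministic. Predictors enter raw (not
    standardized) so coefficients are on the measured scale; standardized
    betas are reported alongside.

    Parameters
    ----------
    alpha_enter, alpha_stay : float, default=0.05
        Significance thresholds to add / keep a predictor.
    direction : {"bidirectional", "forward", "backward"}
        ``forward`` skips the pruning pass; ``backward`` starts from the
        full model and only drops.

    Attributes
    ----------
    selected_ : list of chosen column names, in final model order.
    selection_order_ : list of (step, action, name, p_value) tuples.
    intercept_, coef_ : OLS parameters of the final model.
    pvalues_ : Series of per-coefficient p-values (incl. intercept).
    std_coef_ : standardized betas of the selected predictors.
    r_squared_ : coefficient of determination of the final model.
    """

    def __init__(
        self,
        alpha_enter: float = 0.05,
        alpha_stay: float = 0.05,
        direction: str = "bidirectional",
    ):
        self.alpha_enter = alpha_enter
        self.alpha_stay = alpha_stay
        self.direction = direction

    # -- internal helpers ---------------------------------------------------
    @staticmethod
    def _ols(y: np.ndarray, X: pd.DataFrame):
        design = sm.add_constant(X, has_constant="add")
        if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
            raise CollinearityError(
                f"perfect collinearity among predictors {list(X.columns)}"
            )
        return sm.OLS(y, design).fit()

    def fit(self, X, y):
        if self.direction not in ("bidirectional", "forward", "backward"):
            raise ValueError(f"unknown direction {self.direction!r}")
        df = _as_frame(X)
        y = np.asarray(y, dtype=float)
        if df.shape[0] != y.size:
            raise ValueError("X and y have different numbers of varieties")
        included: list[str] = list(df.columns) if self.direction == "backward" else []
        log: list[tuple[int, str, str, float]] = []
        step = 0
        while True:
            changed = False
            step += 1
            if self.direction != "backward":
                candidates = [c for c in df.columns if c not in included]
                best_name, best_p = None, self.alpha_enter
                for name in candidates:
                    try:
                        fit = self._ols(y, df[included + [name]])
                    except CollinearityError:
                        continue
                    p = fit.pvalues[name]
                    if p < best_p:  # strict: column order breaks ties
                        best_name, best_p = name, p
                if best_name is not None:
                    included.append(best_name)
                    log.append((step, "add", best_name, float(best_p)))
                    changed = True
            if self.direction != "forward" and included:
                fit = self._ols(y, df[included])
                pvals = fit.pvalues.drop("const")
                worst = pvals.idxmax()
                if pvals[worst] > self.alpha_stay:
                    included.remove(worst)
                    log.append((step, "drop", worst, float(pvals[worst])))
                    changed = True
            if not changed:
                break

        self.selected_ = included
        self.selection_order_ = log
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        self.n_features_in_ = df.shape[1]
        final = self._ols(y, df[included]) if included else self._ols(y, df[[]])
        self.model_ = final
        self.intercept_ = float(final.params["const"])
        self.coef_ = final.params.drop("const")
        self.pvalues_ = final.pvalues
        self.r_squared_ = float(final.rsquared) if included else 0.0
        sy = np.std(y, ddof=1)
        self.std_coef_ = pd.Series(
            {c: self.coef_[c] * df[c].std(ddof=1) / sy for c in included},
            dtype=float,
        )
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        df = _as_frame(X)
        out = np.full(df.shape[0], self.intercept_)
        for name, b in self.coef_.items():
            out = out + b * df[name].to_numpy()
        return out

    def equation(self, precision: int = 4) -> str:
        """Human-readable regression equation, e.g. ``D = 0.585 + 1.1061·MDA``."""
        check_is_fitted(self, "model_")
        terms = [f"{self.intercept_:.{precision}g}"]
        terms += [f"{b:+.{precision}g}·{name}" for name, b in self.coef_.items()]
        return "D = " + " ".join(terms)


def stepwise_select(
    matrix,
    d,
    alpha_enter: float = 0.05,
    alpha_stay: float = 0.05,
    direction: str = "bidirectional",
) -> StepwiseSelector:
    """Fit a :class:`StepwiseSelector` of D on the index matrix."""
    return StepwiseSelector(alpha_enter, alpha_stay, direction).fit(matrix, d)
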