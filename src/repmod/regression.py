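"""OLS engine for the difference-score and per-condition models.

The interaction test in a two-instance repeated-measures design reduces to
an ordinary regression of the difference score on the moderators: with
per-condition models

    Y_i1 = b01 + b11 W_i + e_i1
    Y_i2 = b02 + b12 W_i + e_i2

the regression of Y_D = Y_i1 - Y_i2 on W has slope b11 - b12, so a t test on
that slope is the test of moderation.  This module builds the design matrix
(additive: one column per moderator; multiplicative: all cross-products),
fits by OLS, and exposes the coefficient covariance matrix that the probing
module needs for conditional-effect standard errors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .data import (
    ADDITIVE,
    MULTIPLICATIVE,
    ModelSpec,
    WideDataset,
    center_moderators,
    expand_categoricals,
    make_difference,
)
from .exceptions import SampleSizeError, SingularDesignError

__all__ = [
    "DesignMatrix",
    "FitResult",
    "ConditionFits",
    "build_design",
    "ols_fit",
    "fit_difference_model",
    "fit_per_condition",
    "prepare",
]

# Condition-number threshold on the column-scaled design above which the
# design is declared rank deficient.
_COND_LIMIT = 1e12


@dataclass(frozen=True)
class DesignMatrix:
    """Intercept-plus-moderator-terms design.

    ``terms`` records the composition of each column as a tuple of indices
    into ``w_names`` (the intercept is the empty tuple); evaluating the
    products of moderator values over these tuples reproduces a design row,
    which is exactly how probing builds its contrast vectors.
    """

    X: np.ndarray
    labels: list[str]
    terms: list[tuple[int, ...]]
    w_names: list[str]

    @property
    def q(self) -> int:
        return self.X.shape[1] - 1

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class FitResult:
    """OLS fit: coefficients, their covariance, and model-level summaries.

    ``Sigma`` uses the unbiased residual variance (denominator n - q - 1),
    so conditional-effect t ratios are referred to t(n - q - 1).  ``r2`` is
    NaN (with ``r2_defined`` False) when the response is constant.
    """

    b: np.ndarray
    Sigma: np.ndarray
    df: int
    r2: float
    F: float
    F_pvalue: float
    sigma2_hat: float
    labels: list[str]
    design: DesignMatrix
    nobs: int
    r2_defined: bool = True

    def coef_table(self, alpha: float = 0.05) -> pd.DataFrame:
        """Per-coefficient estimate, SE, t, two-sided p and (1-alpha) CI."""
        se = np.sqrt(np.diag(self.Sigma))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, self.b / np.where(se > 0, se, 1.0),
                         np.where(self.b == 0, 0.0, np.inf * np.sign(self.b)))
        p = 2.0 * st.t.sf(np.abs(t), self.df)
        tc = st.t.ppf(1.0 - alpha / 2.0, self.df)
        return pd.DataFrame(
            {
                "estimate": self.b,
                "se": se,
                "t": t,
                "p": p,
                "ci_low": self.b - tc * se,
                "ci_high": self.b + tc * se,
            },
            index=self.labels,
        )


@dataclass(frozen=True)
class ConditionFits:
    """The two per-condition fits (same design, outcomes y1 and y2)."""

    fit1: FitResult
    fit2: FitResult


def build_design(d: WideDataset, spec: ModelSpec) -> DesignMatrix:
    """Build the intercept + moderator-term design for ``d``.

    Additive: columns [1, W1, ..., Wm].  Multiplicative: one column for the
    product over every nonempty subset of moderators, ordered by subset size
    then input order, so m=2 gives [1, W1, W2, W1*W2].
    """
    if d.categorical:
        raise SingularDesignError(
            "categorical moderators must be contrast-coded before building a "
            f"design (still categorical: {sorted(d.categorical)})"
        )
    names = d.w_names
    m = len(names)
    W = d.moderators.to_numpy(dtype=float)
    if spec.model_type == ADDITIVE:
        terms = [()] + [(i,) for i in range(m)]
    else:
        terms = [()] + [
            combo
            for size in range(1, m + 1)
            for combo in itertools.combinations(range(m), size)
        ]
    n = d.n
    cols = []
    labels = []
    for term in terms:
        if not term:
            cols.append(np.ones(n))
            labels.append("constant")
        else:
            cols.append(np.prod(W[:, list(term)], axis=1))
            labels.append("*".join(names[i] for i in term))
    X = np.column_stack(cols)
    q = X.shape[1] - 1
    if n < q + 2:
        raise SampleSizeError(f"n={n} too small for q={q} predictors (need n >= q+2)")
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        bad = [labels[i] for i in np.flatnonzero(norms == 0)]
        raise SingularDesignError(f"design column(s) identically zero: {bad}")
    if np.linalg.cond(X / norms) > _COND_LIMIT:
        raise SingularDesignError(
            f"design is rank deficient (collinear columns among {labels})"
        )
    return DesignMatrix(X=X, labels=labels, terms=terms, w_names=names)


def ols_fit(y, design: DesignMatrix) -> FitResult:
    """Fit ``y`` on the design by ordinary least squares.

    The coefficient covariance is sigma2_hat * (X'X)^{-1} with
    sigma2_hat = SSE / (n - q - 1).  R^2 and the overall F statistic come
    from the SSR/SSE decomposition; both are NaN when undefined (constant
    response, or intercept-only design for F).
    """
    y = np.asarray(y, dtype=float)
    if len(y) != design.n:
        raise ValueError("response length does not match design")
    res = sm.OLS(y, design.X).fit()
    n, q = design.n, design.q
    df = n - q - 1
    if df < 1:
        raise SampleSizeError(f"no residual degrees of freedom (n={n}, q={q})")
    sse = float(res.ssr)
    sigma2 = sse / df
    Sigma = sigma2 * np.linalg.inv(design.X.T @ design.X)
    sst = float(np.sum((y - y.mean()) ** 2))
    scale = max(float(np.sum(y**2)), 1.0)
    if sst > 1e-12 * scale:
        r2 = 1.0 - sse / sst
        r2_defined = True
    else:
        r2, r2_defined = float("nan"), False
    ssm = max(sst - sse, 0.0)
    if q >= 1 and r2_defined:
        if sigma2 > 0:
            F = (ssm / q) / sigma2
            F_p = float(st.f.sf(F, q, df))
        else:  # perfect fit
            F, F_p = float("inf"), 0.0
    else:
        F, F_p = float("nan"), float("nan")
    return FitResult(
        b=np.asarray(res.params, dtype=float),
        Sigma=Sigma,
        df=df,
        r2=r2,
        F=F,
        F_pvalue=F_p,
        sigma2_hat=sigma2,
        labels=list(design.labels),
        design=design,
        nobs=n,
        r2_defined=r2_defined,
    )


def prepare(d: WideDataset, spec: ModelSpec) -> tuple[WideDataset, DesignMatrix]:
    """Center, contrast-code, validate, and build the design once."""
    centered = center_moderators(d, spec)
    expanded = expand_categoricals(centered)
    expanded.validate(q=None)
    design = build_design(expanded, spec)
    return expanded, design


def fit_difference_model(d: WideDataset, spec: ModelSpec) -> FitResult:
    """Regress the difference score on the moderator design.

    Coefficients are per-condition coefficient differences (first-listed
    instance minus second-listed); the t test on a moderator term is the
    test of its interaction with condition.
    """
    _, design = prepare(d, spec)
    return ols_fit(make_difference(d), design)


def fit_per_condition(d: WideDataset, spec: ModelSpec) -> ConditionFits:
    """Fit each instance's outcome on the same design.

    The moderator coefficients of these fits are the simple-slope estimates
    of the moderator's effect on the outcome within each condition.
    """
    _, design = prepare(d, spec)
    return ConditionFits(fit1=ols_fit(d.y1, design), fit2=ols_fit(d.y2, design))
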