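"""Probing interactions: pick-a-point conditional effects and Johnson-Neyman.

A conditional effect of condition at moderator values (w1, ..., wm) is the
linear combination theta = l'b of the difference-model coefficients, where
the contrast vector l evaluates each design term at the chosen values (for a
multiplicative two-moderator model, l = (1, w1, w2, w1*w2)).  Its sampling
variance is l' Sigma l, and theta/se is t-distributed with n - q - 1 df.

The Johnson-Neyman procedure inverts this: for a single continuous
moderator it solves |theta(W)| / se(W) = t* for W, giving the boundaries of
significance.  Squaring and rearranging yields the quadratic

    (b1^2 - t*^2 var(b1)) W^2 + 2 (b1 b0 - t*^2 cov(b0, b1)) W
        + (b0^2 - t*^2 var(b0)) = 0

whose real roots inside the observed moderator range are reported; roots
outside the data (or imaginary ones) are retained with flags but never
interpreted as regions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats as st

from .exceptions import JNNotApplicableError, ProbeError, RepmodError
from .regression import DesignMatrix, FitResult

__all__ = [
    "ConditionalEffect",
    "JNResult",
    "critical_t",
    "build_contrast",
    "conditional_effect",
    "default_probe_points",
    "pick_a_point_table",
    "jn_points",
]


def critical_t(alpha: float, df: int) -> float:
    """Two-sided critical value of Student's t at level ``alpha``."""
    if df < 1:
        raise RepmodError("df must be >= 1")
    return float(st.t.ppf(1.0 - alpha / 2.0, df))


@dataclass(frozen=True)
class ConditionalEffect:
    """A probed effect l'b with its inferential statistics."""

    estimate: float
    se: float
    t: float
    p: float
    ci: tuple[float, float]
    at: tuple[float, ...] | None
    df: int
    alpha: float

    @property
    def significant(self) -> bool:
        return bool(self.p < self.alpha)


@dataclass(frozen=True)
class JNResult:
    """Johnson-Neyman boundaries of significance for one moderator.

    ``roots`` are the real solutions inside the observed moderator range
    (sorted ascending) with ``pct_above`` the percentage of observed values
    strictly above each; ``all_roots`` keeps every real solution with an
    in-range flag.  ``region_table`` probes a 21-point even grid over the
    observed range with the in-range roots spliced in.
    """

    roots: tuple[float, ...]
    pct_above: tuple[float, ...]
    all_roots: tuple[tuple[float, bool], ...]
    region_table: tuple[ConditionalEffect, ...]
    alpha: float
    t_crit: float
    w_range: tuple[float, float]
    n: int


def build_contrast(at: Sequence[float], design: DesignMatrix) -> np.ndarray:
    """Contrast vector for the effect of condition at moderator values ``at``.

    Values are on the analysis (centered, coded) scale; each design term is
    evaluated at the tuple, so the intercept weight is always 1.
    """
    if len(at) != len(design.w_names):
        raise ProbeError(
            f"expected {len(design.w_names)} moderator values, got {len(at)}"
        )
    vals = np.asarray(at, dtype=float)
    return np.array([float(np.prod(vals[list(term)])) for term in design.terms])


def conditional_effect(
    fit: FitResult,
    l: np.ndarray,
    alpha: float = 0.05,
    at: Sequence[float] | None = None,
    alternative: str = "two-sided",
) -> ConditionalEffect:
    """Estimate l'b with SE sqrt(l' Sigma l) and t(df) inference.

    ``alternative`` may be 'two-sided' (default), 'greater' or 'less' for a
    directional p value; the confidence interval is always two-sided.
    """
    l = np.asarray(l, dtype=float)
    if l.shape != fit.b.shape:
        raise ProbeError(f"contrast length {l.shape} != coefficients {fit.b.shape}")
    if not np.all(np.isfinite(fit.Sigma)):
        raise ProbeError("coefficient covariance matrix has non-finite entries")
    est = float(l @ fit.b)
    var = float(l @ fit.Sigma @ l)
    se = math.sqrt(max(var, 0.0))
    if se > 0:
        t = est / se
    else:
        t = 0.0 if est == 0 else math.inf * (1 if est > 0 else -1)
    if alternative == "two-sided":
        p = float(2.0 * st.t.sf(abs(t), fit.df))
    elif alternative == "greater":
        p = float(st.t.sf(t, fit.df))
    elif alternative == "less":
        p = float(st.t.cdf(t, fit.df))
    else:
        raise ProbeError(f"unknown alternative {alternative!r}")
    tc = critical_t(alpha, fit.df)
    return ConditionalEffect(
        estimate=est,
        se=se,
        t=t,
        p=p,
        ci=(est - tc * se, est + tc * se),
        at=tuple(float(v) for v in at) if at is not None else None,
        df=fit.df,
        alpha=alpha,
    )


def default_probe_points(
    w, mode: str = "meansd", custom: Sequence[float] | None = None
) -> list[float]:
    """Default moderator values at which to probe.

    ``meansd``: mean and mean +/- one SD (sample SD, ddof=1).
    ``percentile``: 16th, 50th and 84th percentiles (linear interpolation
    between order statistics), guaranteed inside the observed range.
    ``custom``: the supplied values, passed through.
    """
    if mode == "custom":
        if custom is None:
            raise ProbeError("custom probe mode requires a list of values")
        return [float(v) for v in custom]
    w = np.asarray(w, dtype=float)
    if mode == "meansd":
        m, s = float(np.mean(w)), float(np.std(w, ddof=1))
        return [m - s, m, m + s]
    if mode == "percentile":
        return [float(v) for v in np.percentile(w, [16, 50, 84], method="linear")]
    raise ProbeError(f"unknown probe mode {mode!r}")


def pick_a_point_table(
    fit: FitResult,
    design: DesignMatrix,
    points: Sequence[Sequence[float]],
    alpha: float = 0.05,
) -> list[ConditionalEffect]:
    """Conditional effects at the Cartesian product of per-moderator values.

    ``points`` holds one list of values per moderator (analysis scale);
    rows are ordered with the last moderator varying fastest.
    """
    if len(points) != len(design.w_names):
        raise ProbeError(
            f"need one value list per moderator ({len(design.w_names)}), "
            f"got {len(points)}"
        )
    out = []
    for at in itertools.product(*points):
        l = build_contrast(at, design)
        out.append(conditional_effect(fit, l, alpha=alpha, at=at))
    return out


def jn_points(fit: FitResult, w, alpha: float = 0.05, grid_size: int = 21) -> JNResult:
    """Johnson-Neyman boundaries of significance for a simple moderation model.

    ``w`` are the observed moderator values on the analysis scale.  Requires
    a single continuous moderator (at least 3 distinct values); solutions of
    the JN quadratic are filtered to the observed range, and a near-zero
    quadratic coefficient degrades gracefully to the linear solution.
    """
    design = fit.design
    if design.q != 1 or len(design.w_names) != 1:
        raise JNNotApplicableError(
            "the Johnson-Neyman procedure is implemented for a single-moderator "
            f"model; this design has {design.q} predictor(s)"
        )
    w = np.asarray(w, dtype=float)
    if len(np.unique(w)) < 3:
        raise JNNotApplicableError(
            "the Johnson-Neyman procedure is limited to continuous moderators; "
            "this moderator has fewer than 3 distinct values"
        )
    b0, b1 = fit.b
    v0, v1 = fit.Sigma[0, 0], fit.Sigma[1, 1]
    c01 = fit.Sigma[0, 1]
    tc = critical_t(alpha, fit.df)
    t2 = tc * tc

    a = b1 * b1 - t2 * v1
    bq = 2.0 * (b1 * b0 - t2 * c01)
    cq = b0 * b0 - t2 * v0

    scale = max(abs(b1 * b1), abs(t2 * v1), abs(bq), abs(cq))
    real_roots: list[float] = []
    if scale == 0.0:
        pass  # all coefficients zero: no boundary
    elif abs(a) < 1e-12 * scale:
        if abs(bq) > 1e-12 * scale:
            real_roots = [-cq / bq]
    else:
        disc = bq * bq - 4.0 * a * cq
        if disc >= 0.0:
            sq = math.sqrt(disc)
            real_roots = sorted([(-bq - sq) / (2 * a), (-bq + sq) / (2 * a)])

    lo, hi = float(np.min(w)), float(np.max(w))
    all_roots = tuple((float(r), bool(lo <= r <= hi)) for r in real_roots)
    roots = tuple(r for r, ok in all_roots if ok)
    pct_above = tuple(float(100.0 * np.mean(w > r)) for r in roots)

    grid = np.unique(np.concatenate([np.linspace(lo, hi, grid_size), roots]))
    table = tuple(
        conditional_effect(fit, build_contrast((g,), design), alpha=alpha, at=(g,))
        for g in grid
    )
    return JNResult(
        roots=roots,
        pct_above=pct_above,
        all_roots=all_roots,
        region_table=table,
        alpha=alpha,
        t_crit=tc,
        w_range=(lo, hi),
        n=len(w),
    )
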