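"""Synthetic two-instance data with known per-condition coefficients.

The generator draws moderators, then builds each instance's outcome from
its own coefficient vector plus errors that are bivariate normal within
participant: mean zero, SDs sigma1/sigma2, correlation rho between the two
instances, independent across participants.  Because the difference-model
coefficients are the per-condition differences, a dataset generated here
has known truth for every quantity the analysis estimates, including the
difference-score residual variance sigma1^2 + sigma2^2 - 2 rho sigma1 sigma2.

Defaults emulate a small clinical pre/post study: n=40 participants on a
6-point outcome scale, one standard-normal moderator whose slope is weak
pre-treatment (0.03) and strong post-treatment (0.43), unit error SDs and
within-person error correlation 0.5.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ADDITIVE, MULTIPLICATIVE, ModelSpec, WideDataset
from .exceptions import RepmodError
from .probing import build_contrast, conditional_effect
from .regression import build_design, fit_difference_model

__all__ = ["GenParams", "SimSummary", "generate", "simulate_test", "write_csv"]


@dataclass(frozen=True)
class GenParams:
    """Generating parameters for a two-instance dataset.

    ``b_cond1``/``b_cond2`` are coefficient vectors over [1, W1..Wm] (length
    m+1, additive structure) or over the full product design (length 2^m,
    multiplicative).  ``moderator_dists`` gives one sampling spec per
    moderator: ("normal", mu, sd), ("bernoulli", p) coded 0/1, or
    ("uniform", a, b).
    """

    n: int = 40
    b_cond1: tuple[float, ...] = (3.5, 0.03)
    b_cond2: tuple[float, ...] = (3.3, 0.43)
    sigma1: float = 1.0
    sigma2: float = 1.0
    rho: float = 0.5
    moderator_dists: tuple[tuple, ...] = (("normal", 0.0, 1.0),)
    seed: int | np.random.SeedSequence | None = 0

    def __post_init__(self):
        if len(self.b_cond1) != len(self.b_cond2):
            raise RepmodError("coefficient vectors must have equal length")
        if not (-1.0 <= self.rho <= 1.0):
            raise RepmodError("rho must be in [-1, 1]")
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise RepmodError("error SDs must be nonnegative")
        m = len(self.moderator_dists)
        if len(self.b_cond1) not in (m + 1, 2**m):
            raise RepmodError(
                f"coefficient length {len(self.b_cond1)} matches neither the "
                f"additive (m+1={m + 1}) nor multiplicative (2^m={2 ** m}) design"
            )

    @property
    def model_type(self) -> str:
        m = len(self.moderator_dists)
        # m+1 == 2^m for m=1; the two designs coincide there.
        return ADDITIVE if len(self.b_cond1) == m + 1 else MULTIPLICATIVE

    @property
    def true_difference(self) -> np.ndarray:
        """Difference-model coefficients implied by first - second order."""
        return np.asarray(self.b_cond1) - np.asarray(self.b_cond2)


@dataclass(frozen=True)
class SimSummary:
    """Operating characteristics over replicated generate-and-fit runs."""

    rejection_rate: float
    coef_mean: np.ndarray
    coef_sd: np.ndarray
    coverage: float | None
    reps: int
    alpha: float
    labels: list[str]
    resid_var_mean: float = float("nan")


def _draw_moderator(rng: np.random.Generator, dist: tuple, n: int) -> np.ndarray:
    kind = dist[0]
    if kind == "normal":
        _, mu, sd = dist
        return rng.normal(mu, sd, size=n)
    if kind == "bernoulli":
        _, p = dist
        return rng.binomial(1, p, size=n).astype(float)
    if kind == "uniform":
        _, a, b = dist
        return rng.uniform(a, b, size=n)
    raise RepmodError(f"unknown moderator distribution {kind!r}")


def generate(params: GenParams) -> WideDataset:
    """Draw one dataset; reproducible for a fixed seed."""
    rng = np.random.default_rng(params.seed)
    n = params.n
    cols = {
        f"w{k + 1}": _draw_moderator(rng, dist, n)
        for k, dist in enumerate(params.moderator_dists)
    }
    mods = pd.DataFrame(cols)
    d0 = WideDataset(y1=np.zeros(n), y2=np.zeros(n), moderators=mods)
    design = build_design(d0, ModelSpec(model_type=params.model_type, center=False))
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    e1 = params.sigma1 * z1
    e2 = params.sigma2 * (params.rho * z1 + np.sqrt(1.0 - params.rho**2) * z2)
    y1 = design.X @ np.asarray(params.b_cond1, dtype=float) + e1
    y2 = design.X @ np.asarray(params.b_cond2, dtype=float) + e2
    return WideDataset(y1=y1, y2=y2, moderators=mods)


def write_csv(d: WideDataset, path) -> None:
    """Write a dataset in the CSV dialect ``read_wide_csv`` reads."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(d.y_names) + d.w_names)
        W = d.moderators.to_numpy()
        for i in range(d.n):
            writer.writerow([d.y1[i], d.y2[i], *W[i]])


def simulate_test(
    params: GenParams,
    reps: int,
    alpha: float = 0.05,
    probe_at: Sequence[float] | None = None,
) -> SimSummary:
    """Replicate generate -> difference-model fit and summarise the test.

    The interaction test is the t test on the last (highest-order) design
    coefficient: the moderator slope in a simple model, the three-way
    interaction in a multiplicative two-moderator model.  When ``probe_at``
    is given, also tracks coverage of the (1 - alpha) CI for the conditional
    effect of condition at those moderator values against its true value.

    Per-replicate seeds are spawned deterministically from ``params.seed``,
    so any single replicate can be reproduced in isolation.
    """
    if reps < 1:
        raise RepmodError("reps must be >= 1")
    ss = (
        params.seed
        if isinstance(params.seed, np.random.SeedSequence)
        else np.random.SeedSequence(params.seed)
    )
    children = ss.spawn(reps)
    spec = ModelSpec(model_type=params.model_type, center=False, alpha=alpha)
    truth = params.true_difference

    rejections = 0
    covered = 0
    coefs = np.empty((reps, len(truth)))
    resid_vars = np.empty(reps)
    labels: list[str] = []
    for r, child in enumerate(children):
        d = generate(replace(params, seed=child))
        fit = fit_difference_model(d, spec)
        labels = fit.labels
        tab = fit.coef_table(alpha)
        if tab["p"].iloc[-1] < alpha:
            rejections += 1
        coefs[r] = fit.b
        resid_vars[r] = fit.sigma2_hat
        if probe_at is not None:
            l = build_contrast(probe_at, fit.design)
            ce = conditional_effect(fit, l, alpha=alpha, at=probe_at)
            true_theta = float(l @ truth)
            if ce.ci[0] <= true_theta <= ce.ci[1]:
                covered += 1
    return SimSummary(
        rejection_rate=rejections / reps,
        coef_mean=coefs.mean(axis=0),
        coef_sd=coefs.std(axis=0, ddof=1) if reps > 1 else np.zeros(len(truth)),
        coverage=(covered / reps) if probe_at is not None else None,
        reps=reps,
        alpha=alpha,
        labels=labels,
        resid_var_mean=float(resid_vars.mean()),
    )
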