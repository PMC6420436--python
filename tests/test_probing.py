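"""Pick-a-point conditional effects and the Johnson-Neyman procedure."""

import numpy as np
import pandas as pd
import pytest
import scipy.integrate
import scipy.optimize
import scipy.special

from repmod import (
    DesignMatrix,
    FitResult,
    JNNotApplicableError,
    ModelSpec,
    ProbeError,
    WideDataset,
    build_contrast,
    build_design,
    conditional_effect,
    critical_t,
    default_probe_points,
    fit_difference_model,
    jn_points,
    pick_a_point_table,
)

from conftest import random_dataset


def _design(m, multiplicative=True, names=None):
    """Design skeleton (terms/labels only) for contrast construction."""
    import itertools

    names = names or [f"w{i + 1}" for i in range(m)]
    if multiplicative:
        terms = [()] + [
            c for s in range(1, m + 1) for c in itertools.combinations(range(m), s)
        ]
    else:
        terms = [()] + [(i,) for i in range(m)]
    labels = ["constant"] + ["*".join(names[i] for i in t) for t in terms[1:]]
    return DesignMatrix(
        X=np.ones((0, len(terms))), labels=labels, terms=terms, w_names=names
    )


def _fit_from_table(b, Sigma, df, design):
    """FitResult assembled from a printed coefficient table."""
    b = np.asarray(b, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    return FitResult(
        b=b, Sigma=Sigma, df=df, r2=np.nan, F=np.nan, F_pvalue=np.nan,
        sigma2_hat=np.nan, labels=list(design.labels), design=design,
        nobs=df + len(b), r2_defined=False,
    )


def simple_fit(b0, b1, se0, se1, cov=0.0, df=38):
    """Simple moderation model fit from summary statistics."""
    return _fit_from_table(
        [b0, b1], [[se0**2, cov], [cov, se1**2]], df, _design(1, names=["w"])
    )


class TestCriticalT:
    def test_reference_value_df38(self):
        assert critical_t(0.05, 38) == pytest.approx(2.02, abs=0.005)

    def test_normal_limit(self):
        assert critical_t(0.05, 10**6) == pytest.approx(1.96, abs=0.005)

    def test_against_numeric_integration_oracle(self):
        # independent t quantile: invert the integrated density
        alpha, df = 0.01, 5

        def t_pdf(x):
            c = scipy.special.gamma((df + 1) / 2) / (
                np.sqrt(df * np.pi) * scipy.special.gamma(df / 2)
            )
            return c * (1 + x * x / df) ** (-(df + 1) / 2)

        def upper_tail(q):
            val, _ = scipy.integrate.quad(t_pdf, q, np.inf)
            return val - alpha / 2

        q_ref = scipy.optimize.brentq(upper_tail, 0.1, 50.0, xtol=1e-10)
        assert critical_t(alpha, df) == pytest.approx(q_ref, abs=1e-8)


class TestBuildContrast:
    def test_multiplicative_two_moderators(self):
        l = build_contrast((2.0, 3.0), _design(2, multiplicative=True))
        assert np.allclose(l, [1.0, 2.0, 3.0, 6.0])

    def test_additive_low_inflammation_act(self):
        l = build_contrast((-1.01, 0.0), _design(2, multiplicative=False))
        assert np.allclose(l, [1.0, -1.01, 0.0])

    def test_all_zero_values_select_intercept(self):
        l = build_contrast((0.0, 0.0, 0.0), _design(3, multiplicative=True))
        assert l[0] == 1.0
        assert np.allclose(l[1:], 0.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ProbeError):
            build_contrast((1.0,), _design(2))


class TestConditionalEffect:
    def test_worked_simple_model_numbers(self):
        """theta(0.85) from b=(0.20, -0.40), SEs 0.19, cov 0, df 38."""
        fit = simple_fit(0.20, -0.40, 0.19, 0.19)
        l = build_contrast((0.85,), fit.design)
        ce = conditional_effect(fit, l, at=(0.85,))
        assert ce.estimate == pytest.approx(-0.14, abs=1e-12)
        assert ce.se**2 == pytest.approx(0.062, abs=5e-4)
        assert ce.t == pytest.approx(-0.56, abs=5e-3)
        assert ce.p == pytest.approx(0.58, abs=5e-3)

    def test_additive_worked_numbers(self):
        fit = _fit_from_table(
            [0.43, -0.38, -0.50], np.eye(3) * 0.04, 37,
            _design(2, multiplicative=False),
        )
        l = build_contrast((-1.01, 0.0), fit.design)
        ce = conditional_effect(fit, l, at=(-1.01, 0.0))
        assert round(ce.estimate, 2) == pytest.approx(0.81)

    def test_zero_moderators_return_intercept_row(self):
        fit = simple_fit(0.7, -1.3, 0.21, 0.33, cov=0.01)
        ce = conditional_effect(fit, build_contrast((0.0,), fit.design))
        assert ce.estimate == pytest.approx(0.7)
        assert ce.se == pytest.approx(0.21)

    def test_directional_p_values(self):
        fit = simple_fit(0.20, -0.40, 0.19, 0.19)
        l = build_contrast((0.85,), fit.design)
        two = conditional_effect(fit, l)
        less = conditional_effect(fit, l, alternative="less")
        greater = conditional_effect(fit, l, alternative="greater")
        assert less.p == pytest.approx(two.p / 2)
        assert less.p + greater.p == pytest.approx(1.0)


class TestDefaultProbePoints:
    def test_meansd(self, rng):
        w = rng.normal(2.0, 3.0, size=200)
        pts = default_probe_points(w, "meansd")
        m, s = w.mean(), w.std(ddof=1)
        assert pts == pytest.approx([m - s, m, m + s])

    def test_percentiles_inside_range(self, rng):
        w = rng.normal(size=50)
        pts = default_probe_points(w, "percentile")
        assert pts == pytest.approx(
            list(np.percentile(w, [16, 50, 84], method="linear"))
        )
        assert w.min() <= pts[0] <= pts[1] <= pts[2] <= w.max()

    def test_custom_passthrough(self):
        assert default_probe_points(None, "custom", custom=[0.85]) == [0.85]


class TestPickAPoint:
    def test_row_counts(self, rng):
        d, _ = random_dataset(rng, n=30, m=2, multiplicative=True)
        spec = ModelSpec(model_type="multiplicative", center=False)
        fit = fit_difference_model(d, spec)
        one = pick_a_point_table(fit, fit.design, [[-1.0, 0.0, 1.0], [0.0]])
        assert len(one) == 3
        six = pick_a_point_table(fit, fit.design, [[-1.0, 0.0, 1.0], [0.0, 1.0]])
        assert len(six) == 6
        # last moderator varies fastest
        assert six[0].at == (-1.0, 0.0)
        assert six[1].at == (-1.0, 1.0)

    def test_estimates_equal_recentered_intercepts(self, rng):
        """Recentering oracle: shifting the moderators so the probe point is
        the origin and refitting must reproduce theta as the intercept."""
        for _ in range(10):
            m = int(rng.integers(1, 3))
            d, _ = random_dataset(rng, n=30, m=m, multiplicative=True)
            spec = ModelSpec(model_type="multiplicative", center=False)
            fit = fit_difference_model(d, spec)
            at = tuple(rng.normal(size=m))
            ce = pick_a_point_table(fit, fit.design, [[v] for v in at])[0]
            shifted = WideDataset(
                y1=d.y1, y2=d.y2, moderators=d.moderators - np.asarray(at)
            )
            refit = fit_difference_model(shifted, spec)
            assert abs(ce.estimate - refit.b[0]) < 1e-10
            assert abs(ce.se - np.sqrt(refit.Sigma[0, 0])) < 1e-10


def _grid_scan_roots(fit, w, alpha=0.05, npts=100_001):
    """Brute-force oracle: locate sign changes of |t(W)| - t_crit."""
    tc = critical_t(alpha, fit.df)
    grid = np.linspace(w.min(), w.max(), npts)
    theta = fit.b[0] + fit.b[1] * grid
    var = (
        fit.Sigma[0, 0]
        + grid**2 * fit.Sigma[1, 1]
        + 2 * grid * fit.Sigma[0, 1]
    )
    f = np.abs(theta / np.sqrt(var)) - tc
    idx = np.flatnonzero(np.sign(f[:-1]) != np.sign(f[1:]))
    return grid[idx], (grid[1] - grid[0])


class TestJohnsonNeyman:
    def test_roots_back_substitute_to_critical_t(self, rng):
        found = 0
        for _ in range(20):
            d, _ = random_dataset(rng, n=40, m=1)
            fit = fit_difference_model(d, ModelSpec())
            w = np.asarray(
                d.moderators["w1"] - d.moderators["w1"].mean()
            )
            jn = jn_points(fit, w)
            for r in jn.roots:
                found += 1
                l = build_contrast((r,), fit.design)
                ce = conditional_effect(fit, l)
                assert abs(abs(ce.t) - jn.t_crit) < 1e-6
        assert found >= 5  # the fixtures do produce in-range boundaries

    def test_roots_match_grid_scan_oracle(self, rng):
        for _ in range(10):
            d, _ = random_dataset(rng, n=40, m=1)
            fit = fit_difference_model(d, ModelSpec(center=False))
            w = d.moderators["w1"].to_numpy()
            jn = jn_points(fit, w)
            brackets, h = _grid_scan_roots(fit, w)
            assert len(jn.roots) == len(brackets)
            for r, g in zip(jn.roots, brackets):
                assert abs(r - g) <= 2 * h

    def test_flat_significant_ratio_all_significant(self):
        # b1 = 0 with a strongly significant intercept: the t ratio decays
        # only as var(theta) grows in W^2, so the boundaries fall far outside
        # the observed range and the whole range is significant
        fit = simple_fit(2.0, 0.0, 0.1, 0.1)
        w = np.linspace(-2, 2, 30)
        jn = jn_points(fit, w)
        assert jn.roots == ()
        assert all(e.significant for e in jn.region_table)

    def test_out_of_range_roots_flagged_not_reported(self, rng):
        # slope barely nonzero -> boundaries far outside the observed range
        fit = simple_fit(0.20, -0.40, 0.19, 0.19)
        w = np.linspace(-1.73, 2.14, 40)
        jn = jn_points(fit, w)
        in_range = [r for r, ok in jn.all_roots if ok]
        assert sorted(in_range) == sorted(jn.roots)
        for r in jn.roots:
            assert jn.w_range[0] <= r <= jn.w_range[1]

    def test_pct_above_strict_inequality(self):
        fit = simple_fit(0.5, -1.0, 0.05, 0.05)
        w = np.array([-1.0, 0.0, 0.25, 0.5, 1.0])
        jn = jn_points(fit, w)
        for r, pct in zip(jn.roots, jn.pct_above):
            assert pct == pytest.approx(100.0 * np.mean(w > r))
            assert 0.0 <= pct <= 100.0

    def test_region_significance_constant_between_roots(self, rng):
        for _ in range(5):
            d, _ = random_dataset(rng, n=40, m=1)
            fit = fit_difference_model(d, ModelSpec())
            w = np.asarray(d.moderators["w1"] - d.moderators["w1"].mean())
            jn = jn_points(fit, w)
            roots = set(jn.roots)
            status = None
            for e in jn.region_table:
                if e.at[0] in roots:
                    status = None  # boundary: status may change here
                    continue
                if status is None:
                    status = e.significant
                else:
                    assert e.significant == status

    def test_dichotomous_moderator_refused(self):
        fit = simple_fit(0.5, -1.0, 0.1, 0.1)
        with pytest.raises(JNNotApplicableError, match="continuous"):
            jn_points(fit, np.array([0.0, 1.0, 0.0, 1.0]))

    def test_multi_moderator_model_refused(self, rng):
        d, _ = random_dataset(rng, n=30, m=2, multiplicative=True)
        fit = fit_difference_model(d, ModelSpec(center=False))
        with pytest.raises(JNNotApplicableError):
            jn_points(fit, d.moderators["w1"].to_numpy())


class TestSymmetry:
    def test_interaction_t_equals_slope_difference_t(self, rng):
        """The m=1 interaction t statistic equals the t for equality of the
        per-condition slopes: b1 = b11 - b12 with the difference-model SE."""
        from repmod import fit_per_condition

        d, _ = random_dataset(rng, n=35, m=1)
        spec = ModelSpec()
        fit = fit_difference_model(d, spec)
        cond = fit_per_condition(d, spec)
        slope_diff = cond.fit1.b[1] - cond.fit2.b[1]
        t_diff = slope_diff / np.sqrt(fit.Sigma[1, 1])
        assert fit.coef_table()["t"].iloc[1] == pytest.approx(t_diff, rel=1e-10)
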