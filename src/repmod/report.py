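"""Plain-text report rendering and tidy exports.

The report follows the familiar macro-output layout for this analysis:
model information first (variables, subtraction order, sample size,
centering notes), then the overall-model summary and coefficient table for
the difference-score regression, then conditional effects of condition at
probed moderator values, the per-condition moderator effects, and finally
the Johnson-Neyman section.  Numbers are printed at a fixed precision and
identical inputs render byte-identical text; the renderer never recomputes
a statistic, it only formats module-level results.
"""

from __future__ import annotations

import csv
import json
from typing import Sequence

import numpy as np

from .analysis import AnalysisResult
from .probing import ConditionalEffect, JNResult

__all__ = ["render_report", "result_to_dict", "write_json", "export_jn_plot"]

_RULE = "*" * 70


def _fmt(x: float, dp: int) -> str:
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        if isinstance(x, float) and np.isinf(x):
            return "inf" if x > 0 else "-inf"
        return "nan"
    return f"{x:.{dp}f}"


def _table(headers: Sequence[str], rows: Sequence[Sequence], dp: int) -> list[str]:
    cells = [[h for h in headers]]
    for row in rows:
        cells.append([c if isinstance(c, str) else _fmt(c, dp) for c in row])
    widths = [max(len(r[j]) for r in cells) for j in range(len(headers))]
    return ["  ".join(r[j].rjust(widths[j]) for j in range(len(headers))) for r in cells]


def _coef_section(fit, alpha: float, dp: int) -> list[str]:
    tab = fit.coef_table(alpha)
    rows = [
        [lab, r.estimate, r.se, r.t, r.p, r.ci_low, r.ci_high]
        for lab, r in tab.iterrows()
    ]
    return _table(["", "coeff", "SE", "t", "p", "LLCI", "ULCI"], rows, dp)


def _effect_rows(effects: Sequence[ConditionalEffect], w_names, result, dp):
    headers = []
    for name in w_names:
        headers.append(name)
        if result and float(result.analysis_data.centered_means.get(name, 0.0)) != 0.0:
            headers.append(f"{name}(raw)")
    headers += ["effect", "SE", "t", "p", "LLCI", "ULCI"]
    rows = []
    for e in effects:
        row = []
        for j, name in enumerate(w_names):
            row.append(e.at[j])
            if result and float(result.analysis_data.centered_means.get(name, 0.0)) != 0.0:
                row.append(result.original_scale(name, e.at[j]))
        row += [e.estimate, e.se, e.t, e.p, e.ci[0], e.ci[1]]
        rows.append(row)
    return headers, rows


def render_report(result: AnalysisResult, dp: int = 4) -> str:
    """Render the full analysis as deterministic plain text."""
    d, spec, fit = result.dataset, result.spec, result.fit
    model_no = 2 if spec.model_type == "additive" else 3
    lines = [_RULE, "repmod: moderation in a two-instance repeated measures design", _RULE]
    lines += [
        f"Model = {model_no} ({spec.model_type})",
        f"Y = {d.y_names[0]}, {d.y_names[1]}"
        f"   (difference = {d.y_names[0]} - {d.y_names[1]})",
        "W = " + ", ".join(d.w_names),
        "",
        f"Sample size: {d.n}   (rows dropped listwise: {d.n_dropped})",
    ]
    means = result.analysis_data.centered_means
    for name, mu in means.items():
        lines.append(
            f"Note: {name} mean-centered for analysis (sample mean = {_fmt(mu, dp)};"
            " zero is the sample average)"
        )
    lines += ["", _RULE, f"Outcome: {d.y_names[0]} - {d.y_names[1]} (difference score)", ""]
    lines += ["Overall model:"]
    lines += _table(
        ["R-sq", "F", "df1", "df2", "p"],
        [[fit.r2, fit.F, float(fit.design.q), float(fit.df), fit.F_pvalue]],
        dp,
    )
    lines += ["", "Coefficients:"]
    lines += _coef_section(fit, spec.alpha, dp)

    lines += ["", _RULE, "Conditional effect of condition ('X') on Y at values of the moderator(s):", ""]
    headers, rows = _effect_rows(result.condition_effects, result.design.w_names, result, dp)
    lines += _table(headers, rows, dp)

    lines += ["", _RULE, "Conditional effect of moderator(s) on Y in each condition:", ""]
    for label, cfit in (
        (f"Condition 1 ({d.y_names[0]}):", result.condition_fits.fit1),
        (f"Condition 2 ({d.y_names[1]}):", result.condition_fits.fit2),
    ):
        lines.append(label)
        lines += _coef_section(cfit, spec.alpha, dp)
        lines.append("")

    lines += [_RULE, "Johnson-Neyman procedure:", ""]
    if result.jn is not None:
        jn = result.jn
        lines.append(
            f"Critical t ({_fmt(jn.alpha, 2)}, df={fit.df}) = {_fmt(jn.t_crit, dp)};"
            f" moderator range observed: {_fmt(jn.w_range[0], dp)} to {_fmt(jn.w_range[1], dp)}"
        )
        if jn.roots:
            lines.append("Boundaries of significance within the observed range:")
            lines += _table(
                ["value", "% above"],
                [[r, p] for r, p in zip(jn.roots, jn.pct_above)],
                dp,
            )
        else:
            lines.append(
                "No boundaries of significance fall inside the observed range."
            )
        outside = [r for r, ok in jn.all_roots if not ok]
        if outside:
            lines.append(
                "Solutions outside the observed range (not interpreted): "
                + ", ".join(_fmt(r, dp) for r in outside)
            )
        lines += ["", "Conditional effect of condition across the moderator range:"]
        headers, rows = _effect_rows(jn.region_table, result.design.w_names, result, dp)
        lines += _table(headers + ["sig"], [r + [("yes" if e.significant else "no")]
                                            for r, e in zip(rows, jn.region_table)], dp)
    elif result.jn_message is not None:
        lines.append(f"Johnson-Neyman procedure not run: {result.jn_message}")
    else:
        lines.append("Johnson-Neyman procedure not requested.")
    lines += [_RULE, ""]
    return "\n".join(lines)


def _effect_dict(e: ConditionalEffect) -> dict:
    return {
        "at": list(e.at) if e.at is not None else None,
        "estimate": e.estimate,
        "se": e.se,
        "t": e.t,
        "p": e.p,
        "ci": list(e.ci),
    }


def result_to_dict(result: AnalysisResult) -> dict:
    """Machine-readable mirror of the report (JSON sidecar)."""
    fit = result.fit

    def fit_dict(f):
        return {
            "labels": list(f.labels),
            "b": f.b.tolist(),
            "se": np.sqrt(np.diag(f.Sigma)).tolist(),
            "Sigma": f.Sigma.tolist(),
            "df": f.df,
            "r2": None if not f.r2_defined else f.r2,
            "F": None if not np.isfinite(f.F) else f.F,
            "F_pvalue": None if not np.isfinite(f.F_pvalue) else f.F_pvalue,
            "sigma2_hat": f.sigma2_hat,
        }

    out = {
        "model_type": result.spec.model_type,
        "alpha": result.spec.alpha,
        "n": result.dataset.n,
        "n_dropped": result.dataset.n_dropped,
        "y_names": list(result.dataset.y_names),
        "w_names": list(result.design.w_names),
        "centered_means": dict(result.analysis_data.centered_means),
        "difference_model": fit_dict(fit),
        "condition_1": fit_dict(result.condition_fits.fit1),
        "condition_2": fit_dict(result.condition_fits.fit2),
        "condition_effects": [_effect_dict(e) for e in result.condition_effects],
    }
    if result.jn is not None:
        jn = result.jn
        out["jn"] = {
            "t_crit": jn.t_crit,
            "roots": list(jn.roots),
            "pct_above": list(jn.pct_above),
            "all_roots": [[r, ok] for r, ok in jn.all_roots],
            "w_range": list(jn.w_range),
            "region_table": [_effect_dict(e) for e in jn.region_table],
        }
    elif result.jn_message is not None:
        out["jn_message"] = result.jn_message
    return out


def write_json(result: AnalysisResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(result_to_dict(result), fh, indent=2)


def export_jn_plot(jn: JNResult, path) -> None:
    """Write the tidy region table (one row per probed point) as CSV.

    Columns W, estimate, ci_low, ci_high, significant support rendering the
    classic plot of the conditional effect with its confidence band; the
    significance flag flips exactly at the spliced boundary points.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["W", "estimate", "ci_low", "ci_high", "significant"])
        for e in jn.region_table:
            writer.writerow(
                [e.at[0], e.estimate, e.ci[0], e.ci[1], int(e.significant)]
            )
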