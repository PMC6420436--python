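"""High-level orchestration: run a full moderation analysis in one call.

``moderation_analysis`` composes the pipeline the report and CLI expose:
difference-model fit, per-condition fits, pick-a-point probing of the
condition effect at default or user-supplied moderator values, and (on
request, simple models only) the Johnson-Neyman procedure.

Probe values supplied by the user are interpreted on the original variable
scale and translated onto the analysis (mean-centered) scale internally;
the report prints both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ModelSpec, WideDataset, make_difference
from .exceptions import JNNotApplicableError
from .probing import (
    ConditionalEffect,
    JNResult,
    default_probe_points,
    jn_points,
    pick_a_point_table,
)
from .regression import ConditionFits, DesignMatrix, FitResult, ols_fit, prepare

__all__ = ["AnalysisResult", "moderation_analysis"]


@dataclass(frozen=True)
class AnalysisResult:
    """Everything a report needs, computed once."""

    dataset: WideDataset        # as read (raw scale)
    analysis_data: WideDataset  # centered + contrast-coded
    spec: ModelSpec
    design: DesignMatrix
    fit: FitResult
    condition_fits: ConditionFits
    probe_points: dict[str, list[float]]  # analysis scale, per design column
    condition_effects: list[ConditionalEffect]
    jn: JNResult | None
    jn_message: str | None

    def original_scale(self, name: str, value: float) -> float:
        """Translate an analysis-scale moderator value back to raw scale."""
        return value + float(self.analysis_data.centered_means.get(name, 0.0))


def _probe_values_for(result_data: WideDataset, spec: ModelSpec, name: str) -> list[float]:
    col = result_data.moderators[name]
    mean_shift = float(result_data.centered_means.get(name, 0.0))
    if spec.probe_values and name in spec.probe_values:
        # user values are on the original scale; move to the analysis scale
        return [float(v) - mean_shift for v in spec.probe_values[name]]
    vals = col.to_numpy(dtype=float)
    if len(np.unique(vals)) <= 2:
        # dichotomous / indicator column: probe at its observed codes
        return [float(v) for v in sorted(np.unique(vals))]
    mode = spec.probe_mode if spec.probe_mode != "custom" else "meansd"
    return default_probe_points(vals, mode=mode)


def moderation_analysis(d: WideDataset, spec: ModelSpec) -> AnalysisResult:
    """Fit, probe and (optionally) run Johnson-Neyman on a wide dataset."""
    analysis_data, design = prepare(d, spec)
    y_d = make_difference(d)
    fit = ols_fit(y_d, design)
    cond = ConditionFits(
        fit1=ols_fit(d.y1, design), fit2=ols_fit(d.y2, design)
    )

    points = {
        name: _probe_values_for(analysis_data, spec, name)
        for name in design.w_names
    }
    effects = pick_a_point_table(
        fit, design, [points[name] for name in design.w_names], alpha=spec.alpha
    )

    jn = None
    jn_message = None
    if spec.jn:
        try:
            wcol = analysis_data.moderators[design.w_names[0]].to_numpy(dtype=float)
            jn = jn_points(fit, wcol, alpha=spec.alpha)
        except JNNotApplicableError as exc:
            jn_message = str(exc)

    return AnalysisResult(
        dataset=d,
        analysis_data=analysis_data,
        spec=spec,
        design=design,
        fit=fit,
        condition_fits=cond,
        probe_points=points,
        condition_effects=effects,
        jn=jn,
        jn_message=jn_message,
    )
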