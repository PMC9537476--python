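"""Incremental cost-effectiveness analysis.

ICERs are always computed from *unrounded* incremental means; dominance
labels replace the ratio whenever the cost and effect deltas disagree in
sign (a ratio of mixed signs has no decision-analytic meaning).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import ArmResult, expected_outcomes
from .parameters import CANCERS, ParameterSet, set_param

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"

#: Effect deltas smaller than this (in QALY or months) give an "undefined"
#: ratio rather than a numerically explosive one.
EFFECT_EPSILON = 1e-9


@dataclass
class IncrementalResult:
    """Deltas (strategy A minus strategy B) and the resulting ICERs."""

    delta_cost: float
    delta_qaly: float
    delta_pain_months: float
    icer_qaly: float | str
    icer_pain: float | str

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "delta_pain_months": self.delta_pain_months,
            "icer_qaly": self.icer_qaly,
            "icer_pain": self.icer_pain,
        }


def _ratio(delta_cost: float, delta_effect: float, epsilon: float) -> float | str:
    if abs(delta_effect) < epsilon:
        return UNDEFINED
    if delta_effect > 0 and delta_cost <= 0:
        return DOMINANT
    if delta_effect < 0 and delta_cost >= 0:
        return DOMINATED
    return delta_cost / delta_effect


def incremental_analysis(
    arm_a: ArmResult, arm_b: ArmResult, epsilon: float = EFFECT_EPSILON
) -> IncrementalResult:
    """Incremental analysis of strategy A against strategy B.

    When both deltas are strictly positive (the usual north-east quadrant),
    the ICER is ``delta_cost / delta_effect``.  A cheaper-and-at-least-as-
    effective A is ``dominant``; a costlier-and-less-effective A is
    ``dominated``; effect deltas below ``epsilon`` give ``undefined``.
    """
    dc = arm_a.mean_cost - arm_b.mean_cost
    dq = arm_a.mean_qaly - arm_b.mean_qaly
    dp = arm_a.mean_pain_months - arm_b.mean_pain_months
    return IncrementalResult(
        delta_cost=dc,
        delta_qaly=dq,
        delta_pain_months=dp,
        icer_qaly=_ratio(dc, dq, epsilon),
        icer_pain=_ratio(dc, dp, epsilon),
    )


def nmb(arm: ArmResult, wtp: float) -> float:
    """Net monetary benefit ``wtp * QALYs - cost`` (EUR)."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * arm.mean_qaly - arm.mean_cost


def run_strategies(
    params: ParameterSet, engine=expected_outcomes
) -> tuple[ArmResult, ArmResult]:
    """Evaluate both strategies with the given engine callable."""
    return engine("A", params), engine("B", params)


def subgroup_run(
    cancer: str, params: ParameterSet, engine=expected_outcomes
) -> IncrementalResult:
    """Incremental analysis for a single-primary-cancer cohort.

    Sets the cancer mix to the pure subgroup (the subgroup keeps its own
    mortality schedule; all other inputs unchanged) and reruns both arms.
    """
    if cancer not in CANCERS:
        raise ValueError(f"unknown cancer {cancer!r}; expected one of {CANCERS}")
    mix = tuple(1.0 if c == cancer else 0.0 for c in CANCERS)
    sub = set_param(params, "cancer_mix", mix)
    arm_a, arm_b = run_strategies(sub, engine)
    return incremental_analysis(arm_a, arm_b)


def table_report(params: ParameterSet, engine=expected_outcomes) -> pd.DataFrame:
    """Base-case plus per-cancer subgroup report (cost, QALY, pain response,
    increments and ICERs), one row per strategy and cohort."""
    rows = []

    def add(cohort: str, ps: ParameterSet) -> None:
        arm_a, arm_b = run_strategies(ps, engine)
        inc = incremental_analysis(arm_a, arm_b)
        rows.append(
            {
                "cohort": cohort,
                "strategy": "B",
                "cost": arm_b.mean_cost,
                "qaly": arm_b.mean_qaly,
                "pain_months": arm_b.mean_pain_months,
                "delta_cost": None,
                "delta_qaly": None,
                "delta_pain_months": None,
                "icer_qaly": None,
                "icer_pain": None,
            }
        )
        rows.append(
            {
                "cohort": cohort,
                "strategy": "A",
                "cost": arm_a.mean_cost,
                "qaly": arm_a.mean_qaly,
                "pain_months": arm_a.mean_pain_months,
                **inc.to_dict(),
            }
        )

    add("base_case", params)
    for cancer in CANCERS:
        mix = tuple(1.0 if c == cancer else 0.0 for c in CANCERS)
        add(cancer, set_param(params, "cancer_mix", mix))
    return pd.DataFrame(rows)
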