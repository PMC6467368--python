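"""One-way (tornado) sensitivity analysis and scan-price threshold analysis.

One-way analyses are evaluated deterministically at point estimates: a
probability is shifted on its point value (clamped to [0, 1]) or a unit cost
shifted in pounds, identically in both strategy arms, and the change in the
incremental (universal minus selective) per-patient cost is reported.  The
deterministic evaluation makes the tornado ordering free of Monte Carlo
noise, and the headline cost perturbation (+£10 on the scan price) is exactly
``10 * (1 - prevalence * detection)`` because each arm's screening cost is
linear in the scan price.

The threshold solver exploits that same exact linearity: incremental cost as
a function of the scan price c has slope ``s = 1 - prevalence * detection``,
so the price at which the ICER equals a willingness-to-pay ``w`` is
``c* = c0 + (w * dQALY - dCost(c0)) / s``.  With ``w = 0`` this is the price
below which universal screening is cost saving.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np
import pandas as pd

from .parameters import (
    PROBABILITY_FIELDS,
    ModelParameters,
    ParameterDraw,
    point_draw,
)
from .tree import evaluate_strategy

__all__ = [
    "COST_IDS",
    "SensitivityResult",
    "one_way",
    "tornado",
    "tornado_table",
    "scan_price_threshold",
]

#: Perturbable unit costs (field names of CostSchedule).
COST_IDS = (
    "scan",
    "ecv",
    "cephalic_vaginal",
    "elcs",
    "emcs",
    "vaginal_breech",
    "neonatal_death",
)


@dataclass(frozen=True)
class SensitivityResult:
    """Effect of one parameter perturbation on the incremental cost."""

    param_id: str
    delta: float
    baseline_inc_cost: float
    perturbed_inc_cost: float

    @property
    def change(self) -> float:
        return self.perturbed_inc_cost - self.baseline_inc_cost


def _incremental_cost(draw: ParameterDraw, econ) -> float:
    uni = evaluate_strategy("universal", draw, econ)
    sel = evaluate_strategy("selective", draw, econ)
    return float(uni.cost_total - sel.cost_total)


def _incremental_qaly(draw: ParameterDraw, econ) -> float:
    uni = evaluate_strategy("universal", draw, econ)
    sel = evaluate_strategy("selective", draw, econ)
    return float(uni.expected_qaly - sel.expected_qaly)


def one_way(params: ModelParameters, param_id: str, delta: float) -> SensitivityResult:
    """Shift one probability (by ``delta``, clamped to [0, 1]) or one unit
    cost (by ``delta`` pounds, floored at 0) and report the change in the
    incremental per-patient cost, evaluated at point estimates."""
    base = point_draw(params)
    baseline = _incremental_cost(base, params.econ)
    if param_id in PROBABILITY_FIELDS:
        shifted = float(np.clip(getattr(base, param_id) + delta, 0.0, 1.0))
        perturbed_draw = replace(base, **{param_id: shifted})
    elif param_id in COST_IDS:
        shifted = max(0.0, getattr(params.costs, param_id) + delta)
        perturbed_draw = replace(base, costs=replace(params.costs, **{param_id: shifted}))
    else:
        raise KeyError(f"unknown parameter id: {param_id!r}")
    perturbed = _incremental_cost(perturbed_draw, params.econ)
    return SensitivityResult(param_id, delta, baseline, perturbed)


def _default_spec(prob_delta: float, cost_delta: float) -> list[tuple[str, float]]:
    spec: list[tuple[str, float]] = []
    for p in PROBABILITY_FIELDS:
        spec += [(p, prob_delta), (p, -prob_delta)]
    for c in COST_IDS:
        spec += [(c, cost_delta), (c, -cost_delta)]
    return spec


def tornado(
    params: ModelParameters,
    spec: list[tuple[str, float]] | None = None,
    prob_delta: float = 0.01,
    cost_delta: float = 10.0,
) -> pd.DataFrame:
    """One row per (parameter, delta) perturbation, sorted by descending
    absolute effect.  The default spec shifts every probability by +/- 1
    percentage point and every unit cost by +/- £10."""
    if spec is None:
        spec = _default_spec(prob_delta, cost_delta)
    if not spec:
        raise ValueError("tornado requires a non-empty perturbation spec")
    rows = []
    for param_id, delta in spec:
        r = one_way(params, param_id, delta)
        rows.append(
            {
                "param_id": r.param_id,
                "delta": r.delta,
                "baseline_inc_cost": r.baseline_inc_cost,
                "perturbed_inc_cost": r.perturbed_inc_cost,
                "change": r.change,
            }
        )
    df = pd.DataFrame(rows)
    return df.reindex(df["change"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )


def tornado_table(
    params: ModelParameters, prob_delta: float = 0.01, cost_delta: float = 10.0
) -> pd.DataFrame:
    """Wide tornado table: one row per parameter with the effects of the
    downward and upward perturbations, sorted by bar length."""
    long = tornado(params, prob_delta=prob_delta, cost_delta=cost_delta)
    baseline = float(long["baseline_inc_cost"].iloc[0])
    long = long.assign(
        direction=np.where(long["delta"] > 0, "change_up", "change_down")
    )
    wide = long.pivot_table(
        index="param_id", columns="direction", values="change", aggfunc="first"
    )
    wide["baseline_inc_cost"] = baseline
    span = wide[["change_down", "change_up"]].abs().max(axis=1)
    return wide.loc[span.sort_values(ascending=False).index].reset_index()


def scan_price_threshold(
    params: ModelParameters,
    wtp: float,
    inc_cost: float | None = None,
    inc_qaly: float | None = None,
) -> float:
    """Scan price at which the ICER equals the willingness-to-pay ``wtp``.

    By default the incremental cost and QALYs are evaluated deterministically
    at point estimates; pass PSA means to solve around a simulated base case
    instead.  ``wtp = 0`` returns the cost-saving threshold.  Raises if the
    incremental QALY is not positive while ``wtp > 0``.
    """
    base = point_draw(params)
    if inc_cost is None:
        inc_cost = _incremental_cost(base, params.econ)
    if inc_qaly is None:
        inc_qaly = _incremental_qaly(base, params.econ)
    if wtp > 0 and inc_qaly <= 0:
        raise ValueError("threshold undefined: incremental QALY is not positive")
    slope = 1.0 - base.p_breech * base.p_detect
    return float(params.costs.scan + (wtp * inc_qaly - inc_cost) / slope)
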