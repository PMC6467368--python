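"""Synthetic individual-level cohort generator and microsimulation oracle.

Emulates the data structure of the source cohort: one record per nulliparous
woman with her breech status at the 36-week scan, prior clinical suspicion,
diagnosis under the chosen screening strategy, ECV attempt/success, reversion
and spontaneous-version events, final presentation, mode of delivery and
neonatal death.  Records are drawn by traversing exactly the same chance
nodes as the expected-value decision tree, which makes the simulator useful
twice over:

* **parameter recovery** -- tallying a universal-strategy cohort back into
  (events, non-events) and MOD counts reproduces the input parameters within
  binomial sampling error;
* **microsimulation oracle** -- empirical per-patient means over a large
  cohort must agree with the analytic tree evaluation, providing an
  independent brute-force check of the tree's path enumeration.

Cohorts are plain pandas DataFrames (one row per woman, documented columns)
and round-trip through CSV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import (
    ENDPOINT_CLASSES,
    MOD_CATEGORIES,
    CostSchedule,
    EconSettings,
    EventCount,
    ModCounts,
    ModelParameters,
    ParameterDraw,
    point_draw,
    validate,
)
from .tree import STRATEGIES, StrategyResult

__all__ = [
    "COHORT_COLUMNS",
    "PATHWAYS",
    "TalliedCounts",
    "simulate_cohort",
    "tally_parameters",
    "microsim_outcomes",
]

#: Pathway labels -> (MOD parameter field, presentation context at delivery).
PATHWAYS = {
    "no_breech": ("mod_no_breech", "cephalic"),
    "undetected_breech": ("mod_breech_undetected", "breech"),
    "reverted_after_ecv": ("mod_breech_undetected", "breech"),
    "cephalic_after_ecv": ("mod_ceph_after_ecv", "cephalic"),
    "spontaneous_version": ("mod_ceph_spontaneous", "cephalic"),
    "breech_failed_ecv": ("mod_breech_failed_ecv", "breech"),
    "breech_no_ecv": ("mod_breech_no_ecv", "breech"),
}

#: Column dictionary of a cohort DataFrame.
COHORT_COLUMNS = {
    "breech_at_36wk": "foetus breech at the 36-week scan",
    "clinically_suspected": "breech suspected before the scan (breech only)",
    "diagnosed": "breech diagnosed under the strategy (universal: all breech)",
    "scanned": "received a presentation scan charged to the strategy",
    "ecv_attempted": "ECV attempted (diagnosed breech only)",
    "ecv_successful": "ECV turned the foetus cephalic",
    "reverted_to_breech": "reverted to breech after successful ECV",
    "spontaneous_cephalic_version": "turned cephalic without ECV success",
    "pathway": "terminal pathway label (key of PATHWAYS)",
    "presentation_at_delivery": "cephalic | breech",
    "mode_of_delivery": "vaginal | elcs | emcs",
    "mod_category": "sampled MOD category (MOD_CATEGORIES)",
    "delivery_class": "endpoint class (ENDPOINT_CLASSES)",
    "neonatal_death": "neonatal death sampled from the mortality schedule",
}


@dataclass(frozen=True)
class TalliedCounts:
    """Input-table-shaped counts recovered from a simulated cohort."""

    p_breech: EventCount
    p_detect: EventCount
    p_ecv_attempt: EventCount
    p_ecv_success: EventCount
    p_src_no_ecv: EventCount
    p_srb_after_ecv: EventCount
    p_src_failed_ecv: EventCount
    mod_no_breech: ModCounts
    mod_ceph_after_ecv: ModCounts
    mod_ceph_spontaneous: ModCounts
    mod_breech_no_ecv: ModCounts
    mod_breech_failed_ecv: ModCounts
    mod_breech_undetected: ModCounts


def simulate_cohort(
    n: int,
    params: ModelParameters,
    strategy: str = "universal",
    seed: int | None = None,
    draw: ParameterDraw | None = None,
) -> pd.DataFrame:
    """Simulate ``n`` individual women under one screening strategy.

    Each woman traverses the same chance nodes as the decision tree: breech
    status, clinical suspicion, (strategy-dependent) diagnosis, ECV attempt /
    success / reversion, spontaneous version, then a mode of delivery from
    her pathway's MOD distribution and a neonatal-death draw from the
    mortality schedule.  By default the traversal probabilities are the point
    estimates of ``params``; pass an explicit ``draw`` to microsimulate an
    arbitrary parameter realisation.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy: {strategy!r}")
    bad = validate(params)
    if bad:
        raise ValueError("invalid parameters: " + "; ".join(bad))
    d = point_draw(params) if draw is None else draw
    rng = np.random.default_rng(seed)

    breech = rng.random(n) < d.p_breech
    suspected = breech & (rng.random(n) < d.p_detect)
    diagnosed = breech if strategy == "universal" else suspected
    ecv_attempted = diagnosed & (rng.random(n) < d.p_ecv_attempt)
    ecv_successful = ecv_attempted & (rng.random(n) < d.p_ecv_success)
    reverted = ecv_successful & (rng.random(n) < d.p_srb_after_ecv)
    u_spont = rng.random(n)
    spont_after_failed = ecv_attempted & ~ecv_successful & (u_spont < d.p_src_failed_ecv)
    spont_no_ecv = diagnosed & ~ecv_attempted & (u_spont < d.p_src_no_ecv)
    spontaneous = spont_after_failed | spont_no_ecv

    pathway = np.full(n, "no_breech", dtype=object)
    pathway[breech & ~diagnosed] = "undetected_breech"
    pathway[reverted] = "reverted_after_ecv"
    pathway[ecv_successful & ~reverted] = "cephalic_after_ecv"
    pathway[spontaneous] = "spontaneous_version"
    pathway[ecv_attempted & ~ecv_successful & ~spontaneous] = "breech_failed_ecv"
    pathway[diagnosed & ~ecv_attempted & ~spontaneous] = "breech_no_ecv"

    # per-woman MOD probabilities by pathway, then one categorical draw each
    probs = np.empty((n, 4))
    context = np.empty(n, dtype=object)
    for label, (field, ctx) in PATHWAYS.items():
        mask = pathway == label
        if mask.any():
            probs[mask] = np.asarray(getattr(d, field), dtype=float)
            context[mask] = ctx
    cum = probs.cumsum(axis=1)
    cat = (rng.random(n)[:, None] > cum).sum(axis=1)
    mod_category = np.array(MOD_CATEGORIES, dtype=object)[cat]

    presentation = np.where(
        mod_category == "vaginal_breech",
        "breech",
        np.where(mod_category == "cephalic_vaginal", "cephalic", context),
    )
    mode = np.array(["vaginal", "elcs", "emcs", "vaginal"], dtype=object)[cat]
    delivery_class = np.where(
        presentation == "cephalic",
        np.array(["cephalic_vaginal", "cephalic_elcs", "cephalic_emcs", ""], dtype=object)[cat],
        np.array(["", "breech_elcs", "breech_emcs", "vaginal_breech"], dtype=object)[cat],
    )

    risk_by_class = dict(zip(ENDPOINT_CLASSES, d.mortality.endpoint_risks()))
    risk = np.vectorize(risk_by_class.__getitem__)(delivery_class).astype(float)
    death = rng.random(n) < risk

    scanned = np.ones(n, dtype=bool) if strategy == "universal" else diagnosed

    return pd.DataFrame(
        {
            "breech_at_36wk": breech,
            "clinically_suspected": suspected,
            "diagnosed": diagnosed,
            "scanned": scanned,
            "ecv_attempted": ecv_attempted,
            "ecv_successful": ecv_successful,
            "reverted_to_breech": reverted,
            "spontaneous_cephalic_version": spontaneous,
            "pathway": pathway,
            "presentation_at_delivery": presentation,
            "mode_of_delivery": mode,
            "mod_category": mod_category,
            "delivery_class": delivery_class,
            "neonatal_death": death,
        }
    )


def _mod_counts(cohort: pd.DataFrame, mask, context: str) -> ModCounts:
    sub = cohort.loc[mask, "mod_category"]
    counts = tuple(int((sub == c).sum()) for c in MOD_CATEGORIES)
    return ModCounts(counts, context)


def tally_parameters(cohort: pd.DataFrame) -> TalliedCounts:
    """Tally a universal-strategy cohort back into input-table counts.

    Requires a cohort in which every breech is diagnosed (universal
    screening), so that ECV uptake, success, reversion and spontaneous
    version are observed for all breech women.
    """
    if len(cohort) == 0:
        raise ValueError("cannot tally an empty cohort")
    breech = cohort["breech_at_36wk"]
    diagnosed = cohort["diagnosed"]
    attempted = cohort["ecv_attempted"]
    success = cohort["ecv_successful"]
    reverted = cohort["reverted_to_breech"]
    spont = cohort["spontaneous_cephalic_version"]

    def ec(events_mask, denom_mask) -> EventCount:
        return EventCount(int(events_mask.sum()), int((denom_mask & ~events_mask).sum()))

    return TalliedCounts(
        p_breech=ec(breech, pd.Series(True, index=cohort.index)),
        p_detect=ec(breech & cohort["clinically_suspected"], breech),
        p_ecv_attempt=ec(attempted, diagnosed),
        p_ecv_success=ec(success, attempted),
        p_srb_after_ecv=ec(reverted, success),
        p_src_failed_ecv=ec(attempted & ~success & spont, attempted & ~success),
        p_src_no_ecv=ec(diagnosed & ~attempted & spont, diagnosed & ~attempted),
        mod_no_breech=_mod_counts(cohort, ~breech, "cephalic"),
        mod_ceph_after_ecv=_mod_counts(cohort, cohort["pathway"] == "cephalic_after_ecv", "cephalic"),
        mod_ceph_spontaneous=_mod_counts(cohort, cohort["pathway"] == "spontaneous_version", "cephalic"),
        mod_breech_no_ecv=_mod_counts(cohort, cohort["pathway"] == "breech_no_ecv", "breech"),
        mod_breech_failed_ecv=_mod_counts(cohort, cohort["pathway"] == "breech_failed_ecv", "breech"),
        mod_breech_undetected=_mod_counts(
            cohort,
            cohort["pathway"].isin(["undetected_breech", "reverted_after_ecv"]),
            "breech",
        ),
    )


def microsim_outcomes(
    cohort: pd.DataFrame, costs: CostSchedule, econ: EconSettings
) -> StrategyResult:
    """Empirical per-patient means over an individual-level cohort.

    The brute-force counterpart of the analytic tree evaluation: endpoint
    class frequencies, mean cost components (scan, ECV, delivery, neonatal
    death), death rate and mean QALYs, all computed from individual records.
    """
    if len(cohort) == 0:
        raise ValueError("cannot summarise an empty cohort")
    n = len(cohort)
    endpoint = np.array(
        [float((cohort["delivery_class"] == cls).sum()) / n for cls in ENDPOINT_CLASSES]
    )
    unit_costs = dict(zip(ENDPOINT_CLASSES, costs.endpoint_unit_costs()))
    delivery_cost = cohort["delivery_class"].map(unit_costs).astype(float)
    scan_rate = float(cohort["scanned"].mean())
    ecv_rate = float(cohort["ecv_attempted"].mean())
    p_mortality = float(cohort["neonatal_death"].mean())
    cost_screening = scan_rate * costs.scan
    cost_ecv = ecv_rate * costs.ecv
    cost_delivery = float(delivery_cost.mean())
    cost_mortality = p_mortality * costs.neonatal_death
    return StrategyResult(
        strategy="microsim",
        endpoint=endpoint,
        scan_rate=scan_rate,
        ecv_rate=ecv_rate,
        cost_screening=cost_screening,
        cost_ecv=cost_ecv,
        cost_delivery=cost_delivery,
        cost_mortality=cost_mortality,
        cost_total=cost_screening + cost_ecv + cost_delivery + cost_mortality,
        p_mortality=p_mortality,
        expected_qaly=(1 - p_mortality) * econ.qaly_per_surviving_birth,
    )
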