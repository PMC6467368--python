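"""Decision-tree evaluation for one parameter realisation.

The tree compares two screening strategies for breech presentation at the
36-week antenatal visit:

* **universal** -- every woman receives a presentation scan (assumed 100%
  sensitive and specific), so every breech is diagnosed and managed;
* **selective** -- no routine scan; breech is diagnosed only when clinically
  suspected (abdominal palpation, confirmed by a single ultrasound), so a
  fraction of breech presentations stays undetected until labour.

Diagnosed breech enters the management sub-tree: ECV is attempted with
probability ``p_ecv_attempt``; a successful ECV can spontaneously revert to
breech; a failed ECV or no attempt can still be followed by spontaneous
cephalic version.  Each terminal pathway carries its own mode-of-delivery
distribution, and each of the six endpoint classes (presentation at delivery
x mode) carries a unit delivery cost and a neonatal mortality risk.

All functions accept scalar draws or batched draws (arrays), so the same code
evaluates the deterministic point case and a full PSA batch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    ENDPOINT_CLASSES,
    CostSchedule,
    EconSettings,
    MortalitySchedule,
    ParameterDraw,
)

__all__ = [
    "StrategyResult",
    "STRATEGIES",
    "mod_to_endpoint",
    "resolve_breech_pathway",
    "evaluate_strategy",
    "expected_delivery_cost",
    "expected_mortality",
    "expected_qaly",
    "discounted_lifetime_qaly",
]

STRATEGIES = ("universal", "selective")


@dataclass(frozen=True)
class StrategyResult:
    """Per-patient expectations for one strategy under one parameter draw.

    ``endpoint`` is the probability vector over :data:`ENDPOINT_CLASSES`
    (shape ``(..., 6)``); every other field is the matching scalar or array.
    ``cost_total`` is exactly the sum of the four cost components, and
    ``expected_qaly`` is ``(1 - p_mortality) * qaly_per_surviving_birth``.
    """

    strategy: str
    endpoint: np.ndarray
    scan_rate: np.ndarray
    ecv_rate: np.ndarray
    cost_screening: np.ndarray
    cost_ecv: np.ndarray
    cost_delivery: np.ndarray
    cost_mortality: np.ndarray
    cost_total: np.ndarray
    p_mortality: np.ndarray
    expected_qaly: np.ndarray


def mod_to_endpoint(vec, context: str) -> np.ndarray:
    """Map a MOD probability vector onto the six endpoint classes.

    Cephalic vaginal and vaginal breech have fixed destinations; the ELCS and
    EMCS categories land in cephalic or breech classes depending on the
    presentation context of the distribution.
    """
    vec = np.asarray(vec, dtype=float)
    out = np.zeros(vec.shape[:-1] + (6,))
    out[..., 0] = vec[..., 0]  # cephalic vaginal
    out[..., 3] = vec[..., 3]  # vaginal breech
    if context == "cephalic":
        out[..., 1] = vec[..., 1]
        out[..., 2] = vec[..., 2]
    elif context == "breech":
        out[..., 4] = vec[..., 1]
        out[..., 5] = vec[..., 2]
    else:
        raise ValueError(f"unknown MOD context: {context!r}")
    return out


def resolve_breech_pathway(draw: ParameterDraw) -> np.ndarray:
    """Endpoint distribution for a woman with diagnosed breech at 36 weeks.

    Exact path enumeration of the management sub-tree::

        ECV attempted? -- yes -> success? -- yes -> reversion?  -- yes -> reverted MOD (breech)
                       |                 |                      -- no  -> post-ECV MOD (cephalic)
                       |                 -- no  -> spont. version? -- yes -> spontaneous MOD (cephalic)
                       |                                           -- no  -> failed-ECV MOD (breech)
                       -- no  -> spont. version? -- yes -> spontaneous MOD (cephalic)
                                                 -- no  -> no-ECV MOD (breech)
    """
    pA = np.asarray(draw.p_ecv_attempt, dtype=float)
    pS = np.asarray(draw.p_ecv_success, dtype=float)
    pR = np.asarray(draw.p_srb_after_ecv, dtype=float)
    pF = np.asarray(draw.p_src_failed_ecv, dtype=float)
    pN = np.asarray(draw.p_src_no_ecv, dtype=float)

    paths = [
        (pA * pS * pR, draw.mod_breech_undetected, "breech"),          # reverted after ECV
        (pA * pS * (1 - pR), draw.mod_ceph_after_ecv, "cephalic"),     # cephalic after ECV
        (pA * (1 - pS) * pF, draw.mod_ceph_spontaneous, "cephalic"),   # spont. version after failed ECV
        (pA * (1 - pS) * (1 - pF), draw.mod_breech_failed_ecv, "breech"),
        ((1 - pA) * pN, draw.mod_ceph_spontaneous, "cephalic"),        # spont. version, no ECV
        ((1 - pA) * (1 - pN), draw.mod_breech_no_ecv, "breech"),
    ]
    endpoint = sum(
        np.asarray(w, dtype=float)[..., np.newaxis] * mod_to_endpoint(mod, ctx)
        for w, mod, ctx in paths
    )
    return endpoint


def expected_delivery_cost(endpoint, costs: CostSchedule) -> np.ndarray:
    """Endpoint-probability-weighted delivery unit costs."""
    return np.asarray(endpoint, dtype=float) @ costs.endpoint_unit_costs()


def expected_mortality(endpoint, mortality: MortalitySchedule) -> np.ndarray:
    """Endpoint-probability-weighted neonatal mortality risk."""
    return np.asarray(endpoint, dtype=float) @ mortality.endpoint_risks()


def expected_qaly(p_mortality, econ: EconSettings) -> np.ndarray:
    """Survivors receive the constant discounted lifetime QALY value;
    neonatal deaths receive zero."""
    return (1 - np.asarray(p_mortality, dtype=float)) * econ.qaly_per_surviving_birth


def evaluate_strategy(
    strategy: str, draw: ParameterDraw, econ: EconSettings
) -> StrategyResult:
    """Evaluate one screening strategy for one (or a batch of) draws.

    Universal screening scans every woman and manages every breech; selective
    screening charges exactly one confirmatory scan per clinically detected
    breech, and undetected breech carries the undiagnosed-breech MOD
    distribution.  Both arms share the same non-breech MOD realisation, so
    the non-breech contribution cancels exactly in incremental quantities.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy: {strategy!r}")

    pB = np.asarray(draw.p_breech, dtype=float)
    pD = np.asarray(draw.p_detect, dtype=float)

    managed_c = resolve_breech_pathway(draw)
    no_breech = mod_to_endpoint(draw.mod_no_breech, "cephalic")
    undetected = mod_to_endpoint(draw.mod_breech_undetected, "breech")

    if strategy == "universal":
        scan_rate = np.ones_like(pB)
        w_managed = pB
        w_undetected = np.zeros_like(pB)
    else:
        scan_rate = pB * pD
        w_managed = pB * pD
        w_undetected = pB * (1 - pD)

    endpoint = (
        w_managed[..., np.newaxis] * managed_c
        + w_undetected[..., np.newaxis] * undetected
        + (1 - pB)[..., np.newaxis] * no_breech
    )

    ecv_rate = w_managed * np.asarray(draw.p_ecv_attempt, dtype=float)
    cost_screening = scan_rate * draw.costs.scan
    cost_ecv = ecv_rate * draw.costs.ecv
    cost_delivery = expected_delivery_cost(endpoint, draw.costs)
    p_mortality = expected_mortality(endpoint, draw.mortality)
    cost_mortality = p_mortality * draw.costs.neonatal_death

    return StrategyResult(
        strategy=strategy,
        endpoint=endpoint,
        scan_rate=scan_rate,
        ecv_rate=ecv_rate,
        cost_screening=cost_screening,
        cost_ecv=cost_ecv,
        cost_delivery=cost_delivery,
        cost_mortality=cost_mortality,
        cost_total=cost_screening + cost_ecv + cost_delivery + cost_mortality,
        p_mortality=p_mortality,
        expected_qaly=expected_qaly(p_mortality, econ),
    )


def discounted_lifetime_qaly(utility_by_age, survival_by_age, rate: float) -> float:
    """Net present value of lifetime QALYs at birth.

    ``sum_t utility_t * survival_t / (1 + rate)^t`` over equal-length yearly
    sequences of utilities (in [0, 1]) and survival probabilities.  This is
    the generic discounting operation behind the lifetime-QALY constant; the
    model itself takes that constant as an input.
    """
    utility = np.asarray(utility_by_age, dtype=float)
    survival = np.asarray(survival_by_age, dtype=float)
    if utility.shape != survival.shape:
        raise ValueError("utility and survival sequences must have equal length")
    t = np.arange(utility.size)
    return float(np.sum(utility * survival / (1 + rate) ** t))
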