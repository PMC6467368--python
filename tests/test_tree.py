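"""Decision-tree evaluation: path enumeration, costs, mortality, QALYs."""

import dataclasses

import numpy as np
import pytest

from breechcea import (
    CostSchedule,
    MortalitySchedule,
    default_parameters,
    discounted_lifetime_qaly,
    evaluate_strategy,
    expected_delivery_cost,
    expected_mortality,
    expected_qaly,
    point_draw,
    resolve_breech_pathway,
    sample_draw,
)
from breechcea.tree import mod_to_endpoint

COSTS = CostSchedule()
MORTALITY = MortalitySchedule()


def _enumerate_paths(draw):
    """Independent brute-force enumeration of the breech management sub-tree,
    written as literal branch arithmetic rather than the tree's vectorised
    form."""
    pA, pS = draw.p_ecv_attempt, draw.p_ecv_success
    pR, pF, pN = draw.p_srb_after_ecv, draw.p_src_failed_ecv, draw.p_src_no_ecv
    endpoint = np.zeros(6)
    branches = {
        "ecv-success-reverted": (pA * pS * pR, draw.mod_breech_undetected, "breech"),
        "ecv-success-cephalic": (pA * pS * (1 - pR), draw.mod_ceph_after_ecv, "cephalic"),
        "ecv-failed-spont": (pA * (1 - pS) * pF, draw.mod_ceph_spontaneous, "cephalic"),
        "ecv-failed-breech": (pA * (1 - pS) * (1 - pF), draw.mod_breech_failed_ecv, "breech"),
        "no-ecv-spont": ((1 - pA) * pN, draw.mod_ceph_spontaneous, "cephalic"),
        "no-ecv-breech": ((1 - pA) * (1 - pN), draw.mod_breech_no_ecv, "breech"),
    }
    for weight, mod, ctx in branches.values():
        cv, elcs, emcs, vb = np.asarray(mod, dtype=float)
        endpoint[0] += weight * cv
        endpoint[3] += weight * vb
        if ctx == "cephalic":
            endpoint[1] += weight * elcs
            endpoint[2] += weight * emcs
        else:
            endpoint[4] += weight * elcs
            endpoint[5] += weight * emcs
    return endpoint


def test_breech_pathway_matches_independent_enumeration(params):
    rng = np.random.default_rng(11)
    for _ in range(20):
        draw = sample_draw(params, rng)
        np.testing.assert_allclose(
            resolve_breech_pathway(draw), _enumerate_paths(draw), atol=1e-12
        )


def test_breech_pathway_degenerate_single_paths(params):
    base = point_draw(params)
    no_ecv_no_spont = dataclasses.replace(base, p_ecv_attempt=0.0, p_src_no_ecv=0.0)
    np.testing.assert_allclose(
        resolve_breech_pathway(no_ecv_no_spont),
        mod_to_endpoint(base.mod_breech_no_ecv, "breech"),
        atol=1e-12,
    )
    always_cephalic = dataclasses.replace(
        base, p_ecv_attempt=1.0, p_ecv_success=1.0, p_srb_after_ecv=0.0
    )
    np.testing.assert_allclose(
        resolve_breech_pathway(always_cephalic),
        mod_to_endpoint(base.mod_ceph_after_ecv, "cephalic"),
        atol=1e-12,
    )


def test_breech_mass_at_point_estimates(params):
    endpoint = resolve_breech_pathway(point_draw(params))
    assert endpoint.sum() == pytest.approx(1.0, abs=1e-10)
    assert endpoint[3:].sum() == pytest.approx(0.810, abs=1e-3)


def test_screening_and_ecv_costs_at_point_estimates(point_results):
    uni, sel = point_results["universal"], point_results["selective"]
    assert uni.cost_screening == pytest.approx(20.70, abs=1e-9)
    assert sel.cost_screening == pytest.approx(0.43, abs=0.005)
    assert uni.cost_ecv == pytest.approx(6.52, abs=0.02)
    assert sel.cost_ecv == pytest.approx(2.94, abs=0.02)


# published simulated endpoint distributions, in ENDPOINT_CLASSES order
UNIVERSAL_ENDPOINT = np.array([0.6850, 0.0442, 0.2321, 0.0007, 0.0273, 0.0107])
SELECTIVE_ENDPOINT = np.array([0.6826, 0.0441, 0.2305, 0.0110, 0.0123, 0.0194])


def test_expected_delivery_cost():
    assert expected_delivery_cost(UNIVERSAL_ENDPOINT, COSTS) == pytest.approx(2927.8, abs=0.1)
    all_cephalic = np.array([1.0, 0, 0, 0, 0, 0])
    assert expected_delivery_cost(all_cephalic, COSTS) == pytest.approx(2297.3)
    uniform = np.full(6, 1 / 6)
    assert expected_delivery_cost(uniform, COSTS) == pytest.approx(
        COSTS.endpoint_unit_costs().mean()
    )


def test_expected_mortality():
    assert expected_mortality(UNIVERSAL_ENDPOINT, MORTALITY) == pytest.approx(0.000982, abs=5e-7)
    assert expected_mortality(SELECTIVE_ENDPOINT, MORTALITY) == pytest.approx(0.000995, abs=5e-7)
    all_vb = np.array([0, 0, 0, 1.0, 0, 0])
    assert expected_mortality(all_vb, MORTALITY) == pytest.approx(0.002)


def test_expected_qaly(params):
    econ = params.econ
    assert expected_qaly(0.0, econ) == pytest.approx(24.3)
    assert expected_qaly(1.0, econ) == pytest.approx(0.0)
    assert expected_qaly(0.000982, econ) == pytest.approx(24.27615, abs=0.0005)


def test_discounted_lifetime_qaly():
    assert discounted_lifetime_qaly([1.0], [1.0], 0.0) == pytest.approx(1.0)
    horizon = 100
    expected = (1 - 1.035**-horizon) / (1 - 1 / 1.035)
    got = discounted_lifetime_qaly(np.ones(horizon), np.ones(horizon), 0.035)
    assert got == pytest.approx(expected, rel=1e-12)
    assert discounted_lifetime_qaly(np.zeros(10), np.ones(10), 0.035) == 0.0
    with pytest.raises(ValueError):
        discounted_lifetime_qaly([1.0, 1.0], [1.0], 0.035)


def test_endpoint_distributions_and_accounting_identities(params):
    rng = np.random.default_rng(12)
    draw = sample_draw(params, rng, size=200)
    for strategy in ("universal", "selective"):
        res = evaluate_strategy(strategy, draw, params.econ)
        np.testing.assert_allclose(res.endpoint.sum(axis=-1), 1.0, atol=1e-10)
        np.testing.assert_allclose(
            res.cost_total,
            res.cost_screening + res.cost_ecv + res.cost_delivery + res.cost_mortality,
            atol=1e-9,
        )
        np.testing.assert_allclose(
            res.expected_qaly,
            (1 - res.p_mortality) * params.econ.qaly_per_surviving_birth,
            atol=1e-12,
        )


def test_universal_screening_lowers_mortality_at_point_estimates(point_results):
    assert point_results["universal"].p_mortality < point_results["selective"].p_mortality


def test_non_breech_contribution_cancels_in_incrementals(params):
    """Both arms share the non-breech MOD realisation, so replacing it must
    leave every incremental endpoint probability unchanged."""
    base = point_draw(params)
    shifted = dataclasses.replace(base, mod_no_breech=np.array([0.5, 0.3, 0.2, 0.0]))
    for draw_variant in (base, shifted):
        uni = evaluate_strategy("universal", draw_variant, params.econ)
        sel = evaluate_strategy("selective", draw_variant, params.econ)
        inc = uni.endpoint - sel.endpoint
        if draw_variant is base:
            inc_base = inc
    np.testing.assert_allclose(inc, inc_base, atol=1e-12)


def test_incremental_cost_linear_in_scan_price(params):
    """Incremental cost is exactly linear in the scan unit price with slope
    1 - prevalence x detection."""
    base = point_draw(params)
    slope_expected = 1 - base.p_breech * base.p_detect

    def inc_cost(scan_price):
        costs = dataclasses.replace(params.costs, scan=scan_price)
        draw = dataclasses.replace(base, costs=costs)
        uni = evaluate_strategy("universal", draw, params.econ)
        sel = evaluate_strategy("selective", draw, params.econ)
        return float(uni.cost_total - sel.cost_total)

    slope = (inc_cost(30.7) - inc_cost(20.7)) / 10.0
    assert slope == pytest.approx(slope_expected, abs=1e-9)
    slope2 = (inc_cost(120.7) - inc_cost(20.7)) / 100.0
    assert slope2 == pytest.approx(slope_expected, abs=1e-9)


def test_unknown_strategy_rejected(params):
    with pytest.raises(ValueError):
        evaluate_strategy("both", point_draw(params), params.econ)
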