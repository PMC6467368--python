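"""Synthetic cohorts: pathway consistency, parameter recovery, and the
microsimulation oracle for the analytic tree."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from breechcea import (
    EventCount,
    ParameterDraw,
    default_parameters,
    evaluate_strategy,
    microsim_outcomes,
    point_draw,
    simulate_cohort,
    tally_parameters,
)
from breechcea.parameters import ENDPOINT_CLASSES, MOD_FIELDS, PROBABILITY_FIELDS


def test_no_breech_when_prevalence_zero(params):
    p0 = dataclasses.replace(params, p_breech=EventCount(0, 3700))
    cohort = simulate_cohort(2_000, p0, seed=0)
    assert not cohort["breech_at_36wk"].any()
    assert (cohort["pathway"] == "no_breech").all()


def test_breech_count_within_binomial_error(params):
    n, p = 3_879, params.p_breech.point
    cohort = simulate_cohort(n, params, seed=1)
    se = np.sqrt(n * p * (1 - p))
    assert abs(cohort["breech_at_36wk"].sum() - n * p) < 4 * se


def test_record_flags_are_internally_consistent(params):
    cohort = simulate_cohort(20_000, params, strategy="selective", seed=2)
    assert (cohort.loc[cohort["ecv_attempted"], "diagnosed"]).all()
    assert (cohort.loc[cohort["ecv_successful"], "ecv_attempted"]).all()
    assert (cohort.loc[cohort["reverted_to_breech"], "ecv_successful"]).all()
    assert (cohort["scanned"] == cohort["diagnosed"]).all()  # selective arm
    breech_classes = {"vaginal_breech", "breech_elcs", "breech_emcs"}
    is_breech_class = cohort["delivery_class"].isin(breech_classes)
    assert (is_breech_class == (cohort["presentation_at_delivery"] == "breech")).all()
    # undetected breech exists under selective screening and stays unmanaged
    undetected = cohort["breech_at_36wk"] & ~cohort["diagnosed"]
    assert undetected.any()
    assert not cohort.loc[undetected, "ecv_attempted"].any()


@pytest.mark.parametrize("seed", range(20))
def test_parameter_recovery_within_exact_binomial_bounds(params, seed):
    """Tallying a cohort of the source study's size recovers every input
    probability within its central 99.9% binomial interval."""
    cohort = simulate_cohort(3_879, params, strategy="universal", seed=seed)
    tallied = tally_parameters(cohort)
    for field in PROBABILITY_FIELDS:
        truth = getattr(params, field).point
        got = getattr(tallied, field)
        denom = got.events + got.non_events
        if denom == 0:
            continue
        lo, hi = stats.binom.ppf([0.0005, 0.9995], denom, truth)
        assert lo <= got.events <= hi, f"{field}: {got.events}/{denom} vs p={truth:.3f}"


def test_recovered_mod_counts_partition_their_groups(params):
    cohort = simulate_cohort(50_000, params, strategy="universal", seed=3)
    tallied = tally_parameters(cohort)
    total_mod = sum(sum(getattr(tallied, f).counts) for f in MOD_FIELDS)
    assert total_mod == len(cohort)
    assert sum(tallied.mod_no_breech.counts) == (~cohort["breech_at_36wk"]).sum()


def test_tally_single_woman_pathway():
    params = default_parameters()
    certain = dataclasses.replace(
        params,
        p_breech=EventCount(1, 0),
        p_ecv_attempt=EventCount(1, 0),
        p_ecv_success=EventCount(1, 0),
        p_srb_after_ecv=EventCount(0, 1),
    )
    cohort = simulate_cohort(1, certain, strategy="universal", seed=0)
    assert cohort["pathway"].iloc[0] == "cephalic_after_ecv"
    tallied = tally_parameters(cohort)
    assert (tallied.p_ecv_attempt.events, tallied.p_ecv_attempt.non_events) == (1, 0)
    assert (tallied.p_ecv_success.events, tallied.p_ecv_success.non_events) == (1, 0)
    assert sum(tallied.mod_ceph_after_ecv.counts) == 1
    # re-tallying is idempotent
    assert tally_parameters(cohort) == tallied


def test_tally_empty_cohort_rejected(params):
    with pytest.raises(ValueError):
        tally_parameters(simulate_cohort(1, params, seed=0).iloc[0:0])


def _microsim_cost_se(cohort, costs):
    unit = dict(zip(ENDPOINT_CLASSES, costs.endpoint_unit_costs()))
    per_record = (
        cohort["scanned"] * costs.scan
        + cohort["ecv_attempted"] * costs.ecv
        + cohort["delivery_class"].map(unit)
        + cohort["neonatal_death"] * costs.neonatal_death
    )
    return per_record.std() / np.sqrt(len(cohort))


@pytest.mark.parametrize("strategy", ["universal", "selective"])
def test_microsim_oracle_matches_tree_at_defaults(params, strategy):
    """A 10^6-woman microsimulation reproduces the analytic per-patient
    endpoint distribution and total cost within Monte Carlo error."""
    n = 1_000_000
    cohort = simulate_cohort(n, params, strategy=strategy, seed=42)
    sim = microsim_outcomes(cohort, params.costs, params.econ)
    tree = evaluate_strategy(strategy, point_draw(params), params.econ)
    for j in range(6):
        p = tree.endpoint[j]
        se = max(np.sqrt(p * (1 - p) / n), 1e-7)
        assert abs(sim.endpoint[j] - p) < 4 * se
    assert abs(sim.cost_total - float(tree.cost_total)) < 4 * _microsim_cost_se(
        cohort, params.costs
    )
    assert abs(sim.p_mortality - float(tree.p_mortality)) < 4 * np.sqrt(
        float(tree.p_mortality) / n
    )


@settings(max_examples=15, deadline=None, derandomize=True)
@given(
    probs=st.lists(st.floats(0.05, 0.95), min_size=7, max_size=7),
    mod_seed=st.integers(0, 2**31 - 1),
)
def test_microsim_oracle_on_arbitrary_draws(probs, mod_seed):
    """Tree expectations and microsimulated frequencies agree for arbitrary
    valid parameter realisations, not only the default inputs."""
    params = default_parameters()
    rng = np.random.default_rng(mod_seed)
    kwargs = dict(zip(PROBABILITY_FIELDS, probs))
    for field in MOD_FIELDS:
        kwargs[field] = getattr(params, field).sample(rng)
    draw = ParameterDraw(costs=params.costs, mortality=params.mortality, **kwargs)
    n = 40_000
    cohort = simulate_cohort(n, params, strategy="universal", seed=mod_seed, draw=draw)
    sim = microsim_outcomes(cohort, params.costs, params.econ)
    tree = evaluate_strategy("universal", draw, params.econ)
    for j in range(6):
        p = float(tree.endpoint[j])
        se = max(np.sqrt(p * (1 - p) / n), 1e-6)
        assert abs(sim.endpoint[j] - p) < 5 * se


def test_microsim_single_record_costs(params):
    cohort = pd.DataFrame(
        {
            "scanned": [True],
            "ecv_attempted": [False],
            "delivery_class": ["breech_elcs"],
            "neonatal_death": [False],
        }
    )
    sim = microsim_outcomes(cohort, params.costs, params.econ)
    assert sim.cost_delivery == pytest.approx(3438.1)
    assert sim.cost_mortality == 0.0
    assert sim.expected_qaly == pytest.approx(24.3)


def test_cohort_csv_round_trip(params, tmp_path):
    cohort = simulate_cohort(500, params, seed=6)
    path = tmp_path / "cohort.csv"
    cohort.to_csv(path, index=False)
    back = pd.read_csv(path)
    pd.testing.assert_frame_equal(back, cohort, check_dtype=False)
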