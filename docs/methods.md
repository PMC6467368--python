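# Methods

## The decision problem

The model compares two screening policies applied to an unselected cohort of
nulliparous women at ~36 weeks of gestational age (wkGA):

* **universal ultrasound** — every woman receives a presentation scan,
  assumed 100% sensitive and specific, so every breech presentation is
  diagnosed and enters the management pathway;
* **selective ultrasound** (current practice) — no routine scan; breech is
  diagnosed only when clinically suspected by abdominal palpation, confirmed
  by a single ultrasound. Undiagnosed breech reaches labour unmanaged.

The time horizon runs from the scan to infant lifetime; costs are NHS
perspective at the 2017 price level; the only long-term health outcome is
neonatal mortality, converted to QALYs.

## Tree structure

Diagnosed breech enters a management sub-tree traversed by exact path
enumeration (`breechcea.tree.resolve_breech_pathway`):

| path | probability | MOD distribution (context) |
|---|---|---|
| ECV attempted, successful, reverts to breech | p_A·p_S·p_R | undetected/reverted breech (breech) |
| ECV attempted, successful, stays cephalic | p_A·p_S·(1−p_R) | post-ECV cephalic (cephalic) |
| ECV attempted, failed, spontaneous version | p_A·(1−p_S)·p_F | spontaneous-version cephalic (cephalic) |
| ECV attempted, failed, stays breech | p_A·(1−p_S)·(1−p_F) | failed-ECV breech (breech) |
| no ECV, spontaneous version | (1−p_A)·p_N | spontaneous-version cephalic (cephalic) |
| no ECV, stays breech | (1−p_A)·(1−p_N) | no-ECV breech (breech) |

Spontaneous cephalic version is allowed a lower probability after a failed
ECV (p_F, literature-sourced) than without an attempt (p_N); reversion to
breech (p_R) is only possible after a successful ECV. Women with reverted
breech share one MOD distribution with undetected breech: the source counts
for reversion were too sparse to estimate a separate distribution. The MOD
vector of each terminal pathway maps onto six endpoint classes — cephalic
vaginal / cephalic ELCS / cephalic EMCS / vaginal breech / breech ELCS /
breech EMCS — with the ELCS/EMCS categories routed by the pathway's
presentation context.

Scan charging: the universal arm charges exactly one scan per woman; the
selective arm charges one confirmatory scan per clinically detected breech
(rate p_breech·p_detect). The pre-ECV confirmation scan is considered part
of the ECV episode cost. ECV is charged at rate
p_breech·(p_detect if selective else 1)·p_A.

## Parameters

Probabilities are stored as raw (events, non-events) counts from a
prospective cohort of 3,879 nulliparous women (prevalence 179/3,879;
detection without routine ultrasound 79/175; ECV attempted 84/177; ECV
success 12/84; spontaneous version 21/93 without ECV and 3/130 after failed
ECV; reversion 1/12), used directly — with no prior increment — as beta
shape parameters in the PSA, so the point estimate equals the distribution
mean and PSA means converge to the deterministic evaluation. MOD counts are
Dirichlet concentrations; a zero count is a *structural* zero (the category
is excluded from sampling entirely) because the input table prints 0 for
modes that are impossible in a given pathway.

Unit costs (GBP 2017): scan 20.70, ECV 297.40, cephalic vaginal delivery
2,297.30, ELCS 3,438.10, EMCS 4,553.40, vaginal breech 3,999.70. Costs are
fixed in the PSA: the source provides no distributional inputs for them and
its simulated cost components are consistent with fixed unit costs. The
neonatal-death unit cost is not part of the published input table; the
default £1,620 is recovered as the published per-patient mortality-cost
expectation divided by the published mortality probability (1.59/0.000982)
and is configurable.

Mortality risks: 0.10% for cephalic delivery in any mode (vaginal and ELCS
assumed identical, EMCS assumed equal to ELCS), 0.05% for breech cesarean,
0.20% for vaginal breech. Each surviving birth is credited 24.3 QALYs, the
net present value of average lifetime QALYs at a 3.5% annual discount rate;
`discounted_lifetime_qaly` exposes the generic discounting operation, but
the constant itself is an input, not re-derived. Population scaling uses
585,489 deliveries per year (England, 2016–17, ≥36 wkGA).

## PSA and estimators

100,000 iterations by default; a single seeded `numpy` PCG64 stream draws
the seven probabilities and six MOD vectors in a fixed documented order, so
runs are bit-reproducible. Both arms are evaluated on the same draw, making
the non-breech contribution cancel exactly in incremental quantities.
Credibility intervals are equal-tailed empirical 2.5/97.5 percentiles with
linear interpolation. Two ICER estimators are reported: the ratio of mean
incremental cost to mean incremental QALYs, and the mean of per-iteration
ratios (the published headline figure is most consistent with the latter;
the two differ by ~5–9% because the QALY denominator has ~30% coefficient of
variation and is negatively correlated with the cost numerator). Iterations
with non-positive incremental QALYs (or, for scans-per-death-averted,
non-positive mortality reduction) are excluded from ratio-based summaries
only and their count logged; at the default inputs none occur in 10⁵
iterations.

## One-way sensitivity and thresholds

One-way analyses shift a probability's *point value* (clamped to [0,1]) or a
unit cost, identically in both arms, and re-evaluate deterministically; this
removes Monte Carlo noise from tornado ordering and makes the scan-cost
result exact: Δ(incremental cost) = Δc_scan·(1 − p_breech·p_detect) =
9.79 for +£10. The scan-price threshold uses the same exact linearity,
c* = c₀ + (λ·ΔQALY − ΔCost)/(1 − p_breech·p_detect); a bisection fallback in
the test suite confirms the closed form, and setting the scan price to c*
and re-evaluating returns an ICER equal to λ within 0.1%.

## Synthetic cohorts and the microsimulation oracle

`breechcea.cohortsim.simulate_cohort` draws individual women through exactly
the same chance nodes as the tree (breech status, suspicion, diagnosis under
the strategy, ECV attempt/success/reversion, spontaneous version, MOD,
neonatal death), emulating the *structure* of the source study's records.
It deliberately does not emulate gestational-age timing, birthweight or
other covariates, missing-data patterns (the source's handful of missing
ECV/suspicion values; estimation here is complete-case), or the richer
ECV taxonomy (declined / accepted-but-not-performed are collapsed into
attempted vs not, as in the model's inputs). Passing recovery tests
therefore show that the estimation pipeline is consistent with the model's
own data-generating process — not that the model captures every feature of
real cohorts.

The same simulator doubles as a brute-force oracle: empirical endpoint
frequencies, cost components and death rates over 10⁶ simulated women must
match the analytic tree within binomial Monte Carlo error, for the default
inputs and for arbitrary random parameter draws (property-based test).

## Numerical choices and problem sizes

* Endpoint distributions must sum to 1 within 1e-10; MOD draws within 1e-12;
  cost accounting is exact to 1e-9.
* Degenerate inputs: Beta sampling with a zero count returns the degenerate
  0/1; a Dirichlet with one positive category returns that category with
  probability exactly 1; probability shifts in sensitivity analyses clamp to
  [0,1] and costs floor at 0.
* Default sizes: 100,000 PSA iterations (≈1 s vectorised); oracle checks use
  10⁶ women in the analysis driver and 3–4×10⁵ in the faster test variants;
  parameter-recovery tests use the source cohort size of 3,879 over 20 seeds
  with exact central 99.9% binomial bounds.

## Known inconsistencies and limitations

* The published *simulated* endpoint levels are not exactly reproducible
  from the published *input* counts: the cephalic ELCS/EMCS split and the
  universal-arm vaginal-breech mass differ at the third–fourth decimal.
  This package implements the input table faithfully and treats incremental
  quantities — where the shared non-breech term cancels — as the meaningful
  comparison surface. Residual consequences: the mean incremental cost
  evaluates to ≈£6.4 against a published £7.29 (well inside the published
  CrI 2.41–11.61), the universal-arm mortality to 0.000981 vs 0.000982, and
  the scan-price thresholds to ≈£20.9/£24.2/£14.1 against published
  £19.80/£23.10/£12.90.
* The published one-way ECV-success results (−£0.12 per +1 pp, −£0.91 per
  +10 pp) are mutually inconsistent with any model in which the incremental
  cost is linear in that probability — as it is here, exactly; this model
  gives −£0.081 and −£0.81.
* Morbidity, long-term cesarean sequelae, parous women, and two-way or
  value-of-information analyses are out of scope; mortality is the only
  health outcome, so results are conservative where mode of delivery also
  affects morbidity.
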