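# breechcea

A decision-analytic cost-effectiveness model of **universal versus selective
late-pregnancy ultrasound screening for breech presentation** in nulliparous
women, from the perspective of the English NHS.

Around 4–5% of first pregnancies are breech at 36 weeks of gestational age.
Under current practice ("selective ultrasound") presentation is assessed by
abdominal palpation, which misses roughly half of breech presentations; those
women reach labour with an undiagnosed breech and face higher rates of
emergency cesarean section, vaginal breech delivery and neonatal death. A
universal presentation scan at ~36 wkGA would detect essentially all of them,
allowing external cephalic version (ECV) to be offered and an elective
cesarean to be scheduled when ECV is declined or fails.

The package is aimed at health-economic modellers and perinatal researchers
who want to re-run, probe or extend that comparison: all model inputs are
typed and editable, every analysis step is a plain function, and a synthetic
individual-level cohort generator provides a brute-force microsimulation
oracle for the analytic tree.

## Model

A decision tree maps each woman to one of six endpoints — presentation at
delivery (cephalic/breech) × mode of delivery (vaginal, elective cesarean
ELCS, emergency cesarean EMCS) — via chance nodes for breech status,
clinical detection, ECV attempt/success, reversion to breech and spontaneous
cephalic version. For strategy *s* with endpoint distribution *eₛ*:

- cost/patient: `Cₛ = scanRateₛ·c_scan + ecvRateₛ·c_ecv + eₛ·c_delivery + πₛ·c_death`
- mortality/patient: `πₛ = eₛ·m`, with risks m = 0.10% (cephalic, any mode),
  0.05% (breech cesarean), 0.20% (vaginal breech)
- QALYs/patient: `(1 − πₛ) × 24.3`, where 24.3 is the discounted (3.5%/yr)
  net present value of average lifetime QALYs at birth.

Uncertainty is propagated by probabilistic sensitivity analysis (PSA):
event probabilities are Beta(events, non-events) with the raw study counts
as shape parameters, mode-of-delivery distributions are Dirichlet with the
raw counts as concentrations (zero counts are structural zeros), and unit
costs are fixed. Both strategies are evaluated on the same draw each
iteration, so incremental quantities (Δcost, ΔQALY, Δmortality, the ICER
ΔC/ΔQ) cancel all shared terms. One-way sensitivity analyses perturb point
estimates deterministically, and the scan-price threshold
`c* = c₀ + (λ·ΔQ − ΔC)/(1 − p_breech·p_detect)` exploits the exact linearity
of the incremental cost in the scan price (λ = willingness-to-pay).

## Worked example

```python
from breechcea import default_parameters, point_draw, evaluate_strategy
from breechcea.psa import run_psa, summarize

params = default_parameters()                 # the published model inputs
uni = evaluate_strategy("universal", point_draw(params), params.econ)
print(f"universal arm: screening £{float(uni.cost_screening):.2f}, "
      f"mortality {float(uni.p_mortality):.6f} per delivery")

samples = run_psa(params, 100_000, seed=1)    # PSA, both arms per draw
s = summarize(samples, params.econ)
inc = s["per_patient"]["incremental"]["cost"]
print(f"incremental cost £{inc['mean']:.2f} "
      f"(95% CrI {inc['cri'][0]:.2f} to {inc['cri'][1]:.2f}) per patient")
print(f"ICER (mean of ratios) £{s['icer']['mean_of_ratios']:,.0f} per QALY")
print(f"deaths averted per year: {s['population']['deaths_averted_per_year']['mean']:.2f}")
```

prints

```
universal arm: screening £20.70, mortality 0.000981 per delivery
incremental cost £6.44 (95% CrI 1.57 to 10.73) per patient
ICER (mean of ratios) £20,576 per QALY
deaths averted per year: 7.94
```

i.e. scanning every woman costs £20.70 of screening per patient but lowers
neonatal mortality; across 585,489 English deliveries a year the strategy
buys ~193 QALYs for ~£3.8M, an ICER of roughly £20–21k per QALY — borderline
against the usual £20,000–£30,000 willingness-to-pay range, and dominated by
the price of the scan itself (see `analysis/03_sensitivity.py`).

## Analysis scripts

The numbered drivers under `analysis/` narrate the full study and write
their tables to `results/`:

1. `01_point_estimates.py` — deterministic evaluation of both arms;
2. `02_psa.py` — the 100,000-iteration PSA with credibility intervals,
   ICER estimators and population-scaled annual counts;
3. `03_sensitivity.py` — tornado table (±1 pp probabilities, ±£10 costs)
   and scan-price thresholds at WTP £20,000 / £30,000 / £0;
4. `04_cohort_validation.py` — parameter recovery from a synthetic
   3,879-woman cohort and the 10⁶-woman microsimulation oracle check.

A `breechcea` command-line tool wraps the same functions
(`breechcea run|sa|threshold|simulate`, see `breechcea --help`); parameter
files round-trip through YAML/JSON keyed by the tree's chance-node codes.

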