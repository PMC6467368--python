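"""Probabilistic sensitivity analysis of universal vs selective screening.

Runs the 100,000-iteration PSA (seed 1), prints the incremental cost, QALY
and mortality summaries with 95% credibility intervals, both ICER estimators,
and the population-scaled annual counts for the English birth cohort.

Writes results/psa_summary.json.
"""

import json
from pathlib import Path

from breechcea import default_parameters
from breechcea.psa import run_psa, summarize

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1
ITERATIONS = 100_000


def main() -> None:
    params = default_parameters()
    samples = run_psa(params, ITERATIONS, seed=SEED)
    summary = summarize(samples, params.econ)
    summary["seed"] = SEED

    OUT.mkdir(exist_ok=True)
    (OUT / "psa_summary.json").write_text(json.dumps(summary, indent=2))

    pp = summary["per_patient"]
    pop = summary["population"]

    def fmt(mc, nd=2):
        return f"{mc['mean']:.{nd}f} (95% CrI {mc['cri'][0]:.{nd}f} to {mc['cri'][1]:.{nd}f})"

    print(f"PSA: {ITERATIONS} iterations, seed {SEED}\n")
    print(f"incremental cost / patient   £{fmt(pp['incremental']['cost'])}")
    print(f"incremental QALYs / patient   {fmt(pp['incremental']['qaly'], 6)}")
    print(f"ICER ratio-of-means          £{summary['icer']['ratio_of_means']:,.0f} per QALY")
    print(f"ICER mean-of-ratios          £{summary['icer']['mean_of_ratios']:,.0f} per QALY "
          f"(CrI {summary['icer']['ratio_cri'][0]:,.0f} to {summary['icer']['ratio_cri'][1]:,.0f}; "
          f"{summary['icer']['n_excluded']} excluded)")
    print(f"scans per extra detection     {fmt(summary['scans_per_detection'], 1)}")
    print(f"scans per death averted       {fmt(summary['scans_per_death_averted'], 0)}")
    print(f"\nAnnually across {pop['size']:,} deliveries:")
    print(f"  extra cost                 £{fmt(pop['incremental_cost'], 0)}")
    print(f"  extra detections            {fmt(pop['detections_per_year'], 0)}")
    print(f"  neonatal deaths averted     {fmt(pop['deaths_averted_per_year'], 2)}")
    print(f"  QALYs gained                {fmt(pop['qalys_gained_per_year'], 1)}")
    print(f"  vaginal breech avoided      {pop['vb_avoided_per_year']:,.0f}")
    print(f"  EMCS avoided                {pop['emcs_avoided_per_year']:,.0f}")
    print(f"  ELCS added                  {pop['elcs_added_per_year']:,.0f}")


if __name__ == "__main__":
    main()
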