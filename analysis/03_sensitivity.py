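"""One-way (tornado) sensitivity analysis and scan-price thresholds.

Perturbs every probability by +/-1 percentage point and every unit cost by
+/-£10 around the deterministic base case, ranks parameters by their effect
on the incremental cost, and solves for the scan prices at which universal
screening reaches each willingness-to-pay threshold (and becomes cost
saving at WTP = 0).

Writes results/tornado.csv and results/thresholds.json.
"""

import json
from pathlib import Path

from breechcea import default_parameters, scan_price_threshold, tornado_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    params = default_parameters()

    table = tornado_table(params)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "tornado.csv", index=False, float_format="%.6f")

    print("One-way sensitivity of the incremental cost (top 5):\n")
    print(table.head(5).to_string(index=False, float_format=lambda v: f"{v:.3f}"))

    thresholds = {
        wtp: scan_price_threshold(params, wtp) for wtp in (20_000.0, 30_000.0, 0.0)
    }
    (OUT / "thresholds.json").write_text(
        json.dumps({f"{k:g}": v for k, v in thresholds.items()}, indent=2)
    )
    print("\nScan-price thresholds (deterministic base case):")
    for wtp, price in thresholds.items():
        label = "cost saving" if wtp == 0 else f"WTP £{wtp:,.0f}/QALY"
        print(f"  {label}: scan must cost < £{price:.2f}")


if __name__ == "__main__":
    main()
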