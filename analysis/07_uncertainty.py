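"""Probabilistic sensitivity analysis of the base-case tax.

Re-samples mean BMI, relative risks, the energy-to-weight constant, SSB
intake and elasticities once per iteration and re-runs the full pipeline
(100 iterations here; the model default is 2000). Writes the 95%
uncertainty intervals to results/psa_summary.json.
"""

import json
from pathlib import Path

from ssbtax.config import MonteCarloConfig, SyntheticConfig, TaxScenario
from ssbtax.synthetic import generate_inputs
from ssbtax.uncertainty import run_psa

ROOT = Path(__file__).resolve().parents[1]
SEED = 1
ITERATIONS = 100


def main() -> None:
    bundle = generate_inputs(SyntheticConfig(seed=SEED))
    mc = MonteCarloConfig(iterations=ITERATIONS, seed=SEED)
    res = run_psa(mc, TaxScenario(), bundle)
    out = ROOT / "results" / "psa_summary.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(res.uncertainty, indent=2))

    print(f"PSA over {ITERATIONS} iterations (mean and 95% UI, discounted):")
    for k in ("dalys_averted", "qalys_gained", "cost_offset",
              "tax_revenue", "net_revenue"):
        u = res.uncertainty[k]
        print(f"  {k:20s} {u['mean']:>14,.1f}  ({u['lo']:,.1f}, {u['hi']:,.1f})")
    print(f"  ICER (ratio of means): "
          f"{res.uncertainty['icer_ratio_of_means']:,.0f} CAD/QALY")
    print(f"  ICER (mean of ratios): "
          f"{res.uncertainty['icer_mean_of_ratios']:,.0f} CAD/QALY")
    print(f"  failed iterations: {res.uncertainty['n_failures']}")
    print(f"Wrote {out}")


if __name__ == "__main__":
    main()
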