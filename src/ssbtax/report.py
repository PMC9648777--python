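"""Human-readable summaries of completed runs.

Mirrors the usual presentation for this model family: energy/BMI changes
by age and sex, lifetime outcomes by sex, the sensitivity table, and the
tax-ladder comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SEXES
from .pipeline import OUTCOME_KEYS, ScenarioResult


def energy_table(result: ScenarioResult) -> pd.DataFrame:
    """Population-average energy and BMI changes by sex."""
    rows = []
    for sex in SEXES:
        rows.append({
            "sex": sex,
            "delta_tei_kcal_per_day": result.extras["delta_tei_kcal_by_sex"][sex],
            "delta_bmi": result.extras["delta_bmi_by_sex"][sex],
            "cases_prevented_overweight_obesity":
                result.extras["cases_prevented_by_sex"][sex],
        })
    return pd.DataFrame(rows)


def outcomes_table(result: ScenarioResult) -> pd.DataFrame:
    """Lifetime discounted outcomes by sex and combined."""
    rate = result.scenario.discount_rate
    n = next(iter(result.streams.values())).size
    disc = (1.0 + rate) ** -np.arange(n)
    rows = []
    for s, sex in enumerate(SEXES):
        row = {"group": sex}
        for k in OUTCOME_KEYS:
            row[k] = float(result.streams_by_sex[k][s] @ disc)
        rows.append(row)
    rows.append({"group": "total", **{k: result.discounted[k] for k in OUTCOME_KEYS}})
    return pd.DataFrame(rows)


def render_report(result: ScenarioResult,
                  sensitivity: pd.DataFrame | None = None,
                  ladder: pd.DataFrame | None = None) -> str:
    """Assemble the full plain-text report."""
    parts = []
    sc = result.scenario
    parts.append(
        f"SSB tax scenario: CAD${sc.tax_per_oz:.3f}/oz on a "
        f"CAD${sc.baseline_price_per_oz:.2f}/oz base, "
        f"{sc.pass_through:.0%} pass-through, {sc.discount_rate:.1%} discount rate")
    parts.append(
        f"Price change: {result.extras['price_change_pct']:+.1f}%   "
        f"SSB demand change: {result.extras['ssb_demand_change_pct']:+.2f}%")
    parts.append("\nEnergy and BMI changes (population means):")
    parts.append(energy_table(result).to_string(index=False, float_format="%.3f"))
    parts.append("\nLifetime discounted outcomes:")
    parts.append(outcomes_table(result).to_string(index=False, float_format="%.1f"))
    icer = result.extras["icer"]
    if icer is not None:
        note = " (dominant: cost-saving and health-improving)" \
            if result.extras["icer_dominant"] else ""
        parts.append(f"\nICER: {icer:,.0f} CAD/QALY{note}")
    if result.uncertainty:
        parts.append("\n95% uncertainty intervals (discounted totals):")
        for k in OUTCOME_KEYS:
            u = result.uncertainty[k]
            parts.append(f"  {k}: {u['mean']:,.1f} ({u['lo']:,.1f}, {u['hi']:,.1f})")
    if sensitivity is not None:
        parts.append("\nSensitivity analyses (% change vs base):")
        parts.append(sensitivity.to_string(index=False, float_format="%.1f"))
    if ladder is not None:
        parts.append("\nTax ladder:")
        parts.append(ladder.to_string(index=False, float_format="%.1f"))
    return "\n".join(parts) + "\n"
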