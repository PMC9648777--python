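"""Tax design -> price change -> demand response -> energy-intake change.

The demand stage is linear in percentage terms: a 15% SSB price rise under
an own-price elasticity of -1.15 reduces SSB demand by 17.25%, and cross
price elasticities move substitute categories, partially offsetting the
energy reduction. Elasticities are identical across age/sex strata, so
absolute stratum differences come from baseline consumption alone. The
consumption change happens once and is held for the rest of the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import TaxScenario
from .errors import InputValidationError
from .synthetic import ElasticityMatrix


@dataclass
class DemandShift:
    """Stratum-level consumption and energy changes implied by a tax."""

    pct_price_change: np.ndarray  # % by category
    pct_demand_change: np.ndarray  # % by category
    strata: pd.DataFrame  # per age x sex: delta_ssb_kcal, delta_tei_kcal, ...


def price_change(scenario: TaxScenario) -> float:
    """Percent change in the SSB price: 100 * tax * pass_through / price."""
    if scenario.baseline_price_per_oz <= 0:
        raise InputValidationError("baseline_price_per_oz must be > 0")
    return 100.0 * scenario.tax_per_oz * scenario.pass_through / scenario.baseline_price_per_oz


def price_change_vector(scenario: TaxScenario, n_categories: int) -> np.ndarray:
    """Category price-change vector for a flat SSB-only tax (SSB first)."""
    v = np.zeros(n_categories)
    v[0] = price_change(scenario)
    return v


def demand_response(price_changes: np.ndarray, elasticities: ElasticityMatrix) -> np.ndarray:
    """% demand change per category: elasticity matrix times price changes."""
    price_changes = np.asarray(price_changes, dtype=float)
    if price_changes.shape != (len(elasticities.categories),):
        raise InputValidationError(
            f"price-change vector length {price_changes.shape} does not match "
            f"{len(elasticities.categories)} categories")
    return elasticities.values @ price_changes


def energy_change(demand_pct: np.ndarray, baseline: pd.DataFrame,
                  elasticities: ElasticityMatrix) -> DemandShift:
    """Map category demand changes onto per-stratum energy-intake changes.

    ``baseline`` must carry single-year strata with columns ``age``, ``sex``,
    ``ssb_kcal_mean``, ``tei_kcal_mean``, ``ssb_volume_mean``. Per stratum:
    delta-SSB-kcal is the SSB demand change applied to baseline SSB energy
    (floored so post-tax consumption cannot go negative), and delta-TEI adds
    each substitute category's demand change applied to its share of
    non-SSB energy.
    """
    required = {"age", "sex", "ssb_kcal_mean", "tei_kcal_mean", "ssb_volume_mean"}
    missing = required - set(baseline.columns)
    if missing:
        raise InputValidationError(f"baseline strata missing columns: {sorted(missing)}")
    demand_pct = np.asarray(demand_pct, dtype=float)
    # Demand below -100% would mean negative consumption; clamp at zero.
    eff = np.maximum(demand_pct, -100.0)

    ssb_kcal = baseline["ssb_kcal_mean"].to_numpy(float)
    tei = baseline["tei_kcal_mean"].to_numpy(float)
    vol = baseline["ssb_volume_mean"].to_numpy(float)
    other_kcal = np.maximum(tei - ssb_kcal, 0.0)

    d_ssb = eff[0] / 100.0 * ssb_kcal
    d_other = other_kcal[:, None] * elasticities.kcal_share[None, 1:] \
        * (eff[None, 1:] / 100.0)
    d_tei = d_ssb + d_other.sum(axis=1)

    strata = baseline[["age", "sex"]].copy()
    strata["delta_ssb_kcal"] = d_ssb
    strata["delta_tei_kcal"] = d_tei
    strata["delta_ssb_volume"] = eff[0] / 100.0 * vol
    strata["post_ssb_volume"] = np.maximum(vol + strata["delta_ssb_volume"], 0.0)
    strata["post_ssb_kcal"] = np.maximum(ssb_kcal + d_ssb, 0.0)
    return DemandShift(pct_price_change=None, pct_demand_change=eff, strata=strata)


def tax_to_demand_shift(scenario: TaxScenario, baseline: pd.DataFrame,
                        elasticities: ElasticityMatrix) -> DemandShift:
    """Full chain: tax design to stratum energy changes."""
    pv = price_change_vector(scenario, len(elasticities.categories))
    dv = demand_response(pv, elasticities)
    shift = energy_change(dv, baseline, elasticities)
    shift.pct_price_change = pv
    return shift
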