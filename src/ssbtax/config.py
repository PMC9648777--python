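"""Configuration objects for synthetic-data generation and scenario runs.

All user-facing knobs live here as pydantic models so that invalid
configurations fail loudly before any computation starts.
"""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel, Field, model_validator

SEXES = ("female", "male")

#: Ages included in the cost-effectiveness life table (adults only).
AGE_MIN = 20
AGE_MAX = 100


class SyntheticConfig(BaseModel):
    """Controls the synthetic, Canada-like input bundle.

    The defaults describe the modelled study conditions: the 2015 adult
    population (single-year ages 20-100, both sexes), 29 chronic diseases
    (27 mediated by BMI plus type-2 diabetes and ischaemic heart disease,
    which also carry a direct SSB-consumption pathway), and a six-category
    food demand system whose first category is SSBs.
    """

    seed: int = 0
    n_ages: int = Field(default=AGE_MAX - AGE_MIN + 1, ge=2)
    n_diseases: int = Field(default=29, ge=1)
    n_food_categories: int = Field(default=6, ge=2)
    base_year: int = 2015
    bmi_family: Literal["lognormal", "normal"] = "lognormal"
    #: Population scale factor; 1/1000 keeps a full run in seconds while
    #: preserving per-capita quantities exactly.
    scale: float = Field(default=1e-3, gt=0)
    #: Set every BMI secular-trend slope to zero (static-BMI inputs).
    zero_trend: bool = False

    model_config = {"frozen": True}


class TaxScenario(BaseModel):
    """A flat volumetric SSB tax design.

    ``tax_per_oz`` levels of 0.01, 0.015 and 0.02 CAD/oz on a 0.10 CAD/oz
    baseline price raise SSB prices by 10%, 15% and 20% at full
    pass-through; 0.015 is the base case.
    """

    tax_per_oz: float = Field(default=0.015, ge=0)
    pass_through: float = Field(default=1.0, ge=0, le=2)
    baseline_price_per_oz: float = Field(default=0.10, gt=0)
    discount_rate: float = Field(default=0.015, ge=0)

    model_config = {"frozen": True}


class RunOptions(BaseModel):
    """Model-structure toggles that are not part of the tax design."""

    bmi_trend: bool = True
    direct_ssb_pathway: bool = True
    qx_convention: Literal["exp", "half_cycle"] = "exp"
    #: kcal/day of sustained intake change per kg of steady-state weight
    #: change (Swinburn energy-balance constant).
    rho: float = Field(default=22.5, gt=0)
    elasticity_set: Literal["nz", "us"] = "nz"
    tmrel_bmi: float = 22.5
    serving_oz: float = 8.0
    admin_share: float = Field(default=0.02, ge=0, le=1)
    #: Gauss-Legendre node count for potential-impact-fraction integrals.
    pif_nodes: int = Field(default=96, ge=8)
    #: Integration bounds as percentiles of the comparator distribution.
    pif_bounds_pct: tuple[float, float] = (0.001, 0.999)

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check_bounds(self):
        lo, hi = self.pif_bounds_pct
        if not (0 <= lo < hi <= 1):
            raise ValueError("pif_bounds_pct must satisfy 0 <= lo < hi <= 1")
        return self


class MonteCarloConfig(BaseModel):
    """Probabilistic sensitivity analysis settings (2000 draws by default)."""

    iterations: int = Field(default=2000, ge=2)
    seed: int = 0
    interval_level: float = Field(default=0.95, gt=0, lt=1)
    #: Standard deviations of the sampled parameter families; zero switches
    #: a family off (degenerate sampling).
    sd_bmi_mean: float = Field(default=0.15, ge=0)
    sd_log_rr: float = Field(default=0.05, ge=0)
    sd_rho: float = Field(default=1.5, ge=0)
    sd_ssb_factor: float = Field(default=0.03, ge=0)
    sd_elasticity_factor: float = Field(default=0.05, ge=0)
    max_failure_fraction: float = 0.01

    model_config = {"frozen": True}


SENSITIVITY_SCENARIOS = (
    "static_bmi",
    "passthrough_80",
    "passthrough_120",
    "discount_3pct",
    "alt_elasticities",
)
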