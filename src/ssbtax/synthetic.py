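"""Synthetic, Canada-like model inputs with known ground truth.

Every table the pipeline consumes is fabricated here so the whole model is
testable without any external download: demography and all-cause mortality,
per-disease transition hazards, BMI distributions with a secular trend,
SSB/energy consumption by 10-year band, a food-category price-elasticity
matrix (a New-Zealand-style default whose SSB own-price elasticity is -1.15
and a US-style alternative at -1.04), and obesity-related utility weights.

Grouped rates are produced at age-band resolution and brought to single-year
ages with a shape-preserving monotone piecewise-cubic interpolation at band
midpoints, replacing the epidemiological smoothing software commonly used
for this step.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .config import AGE_MAX, AGE_MIN, SEXES, SyntheticConfig
from .errors import InputValidationError

# The two diseases that also carry a direct (non-BMI-mediated) SSB pathway.
DIRECT_PATHWAY_DISEASES = ("type2_diabetes", "ischaemic_heart_disease")

_BMI_DISEASES = (
    "ischaemic_stroke",
    "hemorrhagic_stroke",
    "hypertensive_heart_disease",
    "atrial_fibrillation",
    "breast_cancer",
    "colorectal_cancer",
    "uterine_cancer",
    "ovarian_cancer",
    "kidney_cancer",
    "pancreatic_cancer",
    "oesophageal_cancer",
    "gastric_cardia_cancer",
    "liver_cancer",
    "gallbladder_cancer",
    "thyroid_cancer",
    "multiple_myeloma",
    "leukaemia",
    "non_hodgkin_lymphoma",
    "gallbladder_biliary_disease",
    "osteoarthritis_knee",
    "osteoarthritis_hip",
    "chronic_kidney_disease",
    "low_back_pain",
    "gout",
    "asthma",
    "cataract",
    "alzheimers_dementia",
)

FOOD_CATEGORIES = (
    "ssb",
    "diet_beverages",
    "milk",
    "fruit_juice",
    "snacks",
    "other_food",
)

#: kcal per fluid oz of a typical sugar-sweetened beverage.
SSB_KCAL_PER_OZ = 10.0


@dataclass
class ElasticityMatrix:
    """Own- and cross-price elasticities for the food demand system.

    ``values[i, j]`` is the % change in demand for category ``i`` per 1%
    rise in the price of category ``j``. The first category is always SSB.
    ``kcal_share`` allocates non-SSB energy intake across categories so
    demand changes map onto total-energy-intake changes.
    """

    categories: tuple
    values: np.ndarray
    energy_density: np.ndarray  # kcal per consumption unit
    kcal_share: np.ndarray  # share of non-SSB energy, first entry unused

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.energy_density = np.asarray(self.energy_density, dtype=float)
        self.kcal_share = np.asarray(self.kcal_share, dtype=float)
        n = len(self.categories)
        problems = []
        if self.values.shape != (n, n):
            problems.append(f"elasticity matrix shape {self.values.shape} != ({n}, {n})")
        elif not np.all(np.isfinite(self.values)):
            problems.append("elasticity matrix contains non-finite entries")
        elif self.values[0, 0] >= 0:
            problems.append("SSB own-price elasticity must be negative")
        if np.any(self.energy_density < 0):
            problems.append("energy densities must be >= 0")
        if problems:
            raise InputValidationError(problems)


@dataclass
class InputBundle:
    """Everything one scenario run consumes, plus the ground-truth manifest."""

    population: pd.DataFrame  # age, sex, population, all_cause_mortality, pyld_rate
    consumption: pd.DataFrame  # 10-year bands: SSB kcal/volume and TEI, mean & se
    bmi: pd.DataFrame  # age, sex, bmi_mean, bmi_sd, trend_slope, height_m
    diseases: pd.DataFrame  # per-disease scalars (RRs, weight, cost, flags)
    hazards: pd.DataFrame  # disease, sex, age, incidence, remission, case_fatality
    elasticities: dict  # name -> ElasticityMatrix
    qaly_weights: pd.DataFrame  # age bands: utilities by BMI category
    manifest: dict = field(default_factory=dict)

    def checksum(self) -> str:
        """MD5 over the canonical CSV serialisation of every table."""
        h = hashlib.md5()
        for df in (self.population, self.consumption, self.bmi, self.diseases,
                   self.hazards, self.qaly_weights):
            h.update(df.to_csv(index=False, float_format="%.12g").encode())
        for name in sorted(self.elasticities):
            e = self.elasticities[name]
            h.update(name.encode())
            h.update(np.ascontiguousarray(e.values).tobytes())
            h.update(np.ascontiguousarray(e.kcal_share).tobytes())
        return h.hexdigest()

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name in ("population", "consumption", "bmi", "diseases", "hazards",
                     "qaly_weights"):
            getattr(self, name).to_csv(d / f"{name}.csv", index=False)
        for name, e in self.elasticities.items():
            pd.DataFrame(e.values, index=e.categories, columns=e.categories).to_csv(
                d / f"elasticity_{name}.csv")
            pd.DataFrame({"category": e.categories,
                          "energy_density": e.energy_density,
                          "kcal_share": e.kcal_share}).to_csv(
                d / f"categories_{name}.csv", index=False)
        (d / "manifest.json").write_text(json.dumps(self.manifest, indent=2, sort_keys=True))

    @classmethod
    def load(cls, directory) -> "InputBundle":
        d = Path(directory)
        tables = {name: pd.read_csv(d / f"{name}.csv")
                  for name in ("population", "consumption", "bmi", "diseases",
                               "hazards", "qaly_weights")}
        manifest = json.loads((d / "manifest.json").read_text())
        elasticities = {}
        for f in sorted(d.glob("elasticity_*.csv")):
            name = f.stem.replace("elasticity_", "")
            mat = pd.read_csv(f, index_col=0)
            cat = pd.read_csv(d / f"categories_{name}.csv")
            elasticities[name] = ElasticityMatrix(
                categories=tuple(mat.index),
                values=mat.to_numpy(),
                energy_density=cat["energy_density"].to_numpy(),
                kcal_share=cat["kcal_share"].to_numpy(),
            )
        return cls(**tables, elasticities=elasticities, manifest=manifest)


def interpolate_to_single_year(grouped: pd.DataFrame, value_cols,
                               age_lo_col: str = "age_lo",
                               age_hi_col: str = "age_hi") -> pd.DataFrame:
    """Interpolate band-level rates to single-year ages 20-100.

    Fits a monotone shape-preserving piecewise cubic (PCHIP) through the
    band midpoints and evaluates it at every single-year age; outside the
    first/last midpoint the end values are held constant, so the output can
    never leave the range spanned by the input bands. Bands must tile
    [20, 100] contiguously (``age_hi`` inclusive).
    """
    if isinstance(value_cols, str):
        value_cols = [value_cols]
    g = grouped.sort_values(age_lo_col).reset_index(drop=True)
    lo = g[age_lo_col].to_numpy(float)
    hi = g[age_hi_col].to_numpy(float)
    problems = []
    if lo[0] != AGE_MIN or hi[-1] != AGE_MAX:
        problems.append(f"bands must cover [{AGE_MIN}, {AGE_MAX}], got [{lo[0]}, {hi[-1]}]")
    if np.any(lo[1:] != hi[:-1] + 1):
        problems.append("bands must be contiguous (gap or overlap detected)")
    if np.any(hi < lo):
        problems.append("band with age_hi < age_lo")
    for col in value_cols:
        if np.any(g[col].to_numpy(float) < 0):
            problems.append(f"negative rate in column {col!r}")
    if problems:
        raise InputValidationError(problems)

    mid = (lo + hi) / 2.0
    ages = np.arange(AGE_MIN, AGE_MAX + 1, dtype=float)
    out = {"age": ages.astype(int)}
    for col in value_cols:
        v = g[col].to_numpy(float)
        if len(mid) == 1:
            y = np.full_like(ages, v[0])
        else:
            y = PchipInterpolator(mid, v)(np.clip(ages, mid[0], mid[-1]))
        out[col] = np.maximum(y, 0.0)
    return pd.DataFrame(out)


def _gompertz_mortality(ages: np.ndarray, m0: float, beta: float) -> np.ndarray:
    return np.minimum(m0 * np.exp(beta * (ages - AGE_MIN)), 1.4)


def generate_inputs(config: SyntheticConfig) -> InputBundle:
    """Fabricate the full input bundle; bit-identical under a fixed seed."""
    if config.n_ages != AGE_MAX - AGE_MIN + 1:
        raise InputValidationError(
            f"n_ages must be {AGE_MAX - AGE_MIN + 1} (single-year ages "
            f"{AGE_MIN}-{AGE_MAX}); got {config.n_ages}")
    rng = np.random.default_rng(config.seed)
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    n_ages = ages.size

    # --- demography: ~28M adults at scale 1, Gompertz mortality -------------
    pop_rows = []
    for sex in SEXES:
        # Plateau through midlife then roughly linear attrition.
        shape = np.where(ages < 65, 1.0, np.maximum(0.02, 1.0 - 0.028 * (ages - 65)))
        share = shape / shape.sum()
        total = 14.2e6 if sex == "female" else 13.8e6
        m0, beta = (4.2e-4, 0.088) if sex == "female" else (6.0e-4, 0.086)
        mort = _gompertz_mortality(ages, m0, beta)
        pyld = 0.05 + 0.20 * ((ages - AGE_MIN) / (AGE_MAX - AGE_MIN)) ** 2 \
            + (0.01 if sex == "female" else 0.0)
        pop_rows.append(pd.DataFrame({
            "age": ages, "sex": sex,
            "population": np.round(total * share * config.scale, 6),
            "all_cause_mortality": mort,
            "pyld_rate": pyld,
        }))
    population = pd.concat(pop_rows, ignore_index=True)

    # --- consumption by 10-year band ----------------------------------------
    band_lo = np.arange(20, 100, 10)
    band_hi = np.append(band_lo[1:] - 1, AGE_MAX)
    cons_rows = []
    for sex in SEXES:
        male = sex == "male"
        base_ssb = 190.0 if male else 120.0
        base_tei = 2550.0 if male else 1950.0
        decline = np.linspace(1.0, 0.45, band_lo.size)
        ssb = base_ssb * decline * rng.uniform(0.9, 1.1, band_lo.size)
        tei = base_tei * np.linspace(1.0, 0.78, band_lo.size) \
            * rng.uniform(0.97, 1.03, band_lo.size)
        cons_rows.append(pd.DataFrame({
            "age_lo": band_lo, "age_hi": band_hi, "sex": sex,
            "ssb_kcal_mean": np.round(ssb, 3),
            "ssb_kcal_se": np.round(0.04 * ssb + 0.5, 3),
            "tei_kcal_mean": np.round(tei, 3),
            "tei_kcal_se": np.round(0.015 * tei, 3),
            "ssb_volume_mean": np.round(ssb / SSB_KCAL_PER_OZ, 4),
            "ssb_volume_sd": np.round(0.85 * ssb / SSB_KCAL_PER_OZ, 4),
        }))
    consumption = pd.concat(cons_rows, ignore_index=True)

    # --- BMI distributions and secular trend --------------------------------
    bmi_rows = []
    for sex in SEXES:
        male = sex == "male"
        mean = (26.6 if male else 25.9) + 2.2 * np.sin(np.pi * (ages - AGE_MIN) / 110)
        sd = np.full(n_ages, 4.1 if male else 4.6)
        slope = np.zeros(n_ages) if config.zero_trend else \
            np.clip(rng.normal(0.025, 0.004, n_ages), 0.0, None)
        height = (1.765 if male else 1.625) - 0.0008 * (ages - AGE_MIN)
        bmi_rows.append(pd.DataFrame({
            "age": ages, "sex": sex,
            "bmi_mean": np.round(mean, 4), "bmi_sd": np.round(sd, 4),
            "trend_slope": np.round(slope, 5),
            "height_m": np.round(height, 4),
        }))
    bmi = pd.concat(bmi_rows, ignore_index=True)

    # --- diseases ------------------------------------------------------------
    names = (DIRECT_PATHWAY_DISEASES + _BMI_DISEASES)[: config.n_diseases]
    nd = len(names)
    direct = np.array([n in DIRECT_PATHWAY_DISEASES for n in names])
    rr5 = np.round(rng.uniform(1.10, 1.75, nd), 4)
    rr_serv = np.where(direct, np.round(rng.uniform(1.04, 1.12, nd), 4), 1.0)
    dw = np.round(rng.uniform(0.02, 0.09, nd), 4)
    cost = np.round(rng.uniform(600.0, 7500.0, nd), 2)
    cf_frac = rng.uniform(0.3, 1.0, nd)
    cf_frac = 0.35 * cf_frac / cf_frac.sum()
    diseases = pd.DataFrame({
        "name": names,
        "bmi_mediated": True,
        "direct_ssb": direct,
        "rr_per_5bmi": rr5,
        "rr_direct_per_serving": rr_serv,
        "disability_weight": dw,
        "annual_cost_per_case": cost,
        "case_fatality_share": np.round(cf_frac, 6),
    })

    # --- hazards at 5-year bands, interpolated to single-year ----------------
    h_lo = np.arange(20, 100, 5)
    h_hi = np.append(h_lo[1:] - 1, AGE_MAX)
    h_mid = (h_lo + h_hi) / 2.0
    hz_rows = []
    for k, name in enumerate(names):
        # Scale keeps the summed disease pYLD inside the all-disease envelope
        # at every age (the proportional decomposition must stay feasible).
        inc0 = rng.uniform(5e-5, 4.5e-4)
        g = rng.uniform(0.020, 0.045)
        for sex in SEXES:
            sex_mult = rng.uniform(0.75, 1.3)
            mort = population.loc[population["sex"] == sex, "all_cause_mortality"].to_numpy()
            band = pd.DataFrame({
                "age_lo": h_lo, "age_hi": h_hi,
                "incidence": np.minimum(inc0 * sex_mult * np.exp(g * (h_mid - AGE_MIN)), 0.02),
                "remission": 0.0,
                "case_fatality": cf_frac[k] * np.interp(h_mid, ages, mort),
            })
            single = interpolate_to_single_year(
                band, ["incidence", "remission", "case_fatality"])
            single.insert(0, "disease", name)
            single.insert(1, "sex", sex)
            hz_rows.append(single)
    hazards = pd.concat(hz_rows, ignore_index=True)

    # --- elasticity matrices --------------------------------------------------
    cats = FOOD_CATEGORIES[: config.n_food_categories]
    n_cat = len(cats)
    own = -np.abs(rng.uniform(0.4, 0.9, n_cat))
    own[0] = -1.15  # SSB own-price elasticity (NZ-style default)
    # Small positive cross terms: substitutes claw back only a few percent
    # of the SSB energy drop once applied to the (large) non-SSB kcal base.
    cross_ssb = np.zeros(n_cat)
    cross_ssb[1:] = rng.uniform(0.002, 0.015, n_cat - 1)
    values = np.zeros((n_cat, n_cat))
    np.fill_diagonal(values, own)
    values[:, 0] = np.where(np.arange(n_cat) == 0, own[0], cross_ssb)
    energy_density = np.array([SSB_KCAL_PER_OZ, 0.0, 18.0, 14.0, 130.0, 200.0][:n_cat])
    share = np.array([0.0, 0.0, 0.06, 0.04, 0.16, 0.74][:n_cat])
    share[1:] = share[1:] / share[1:].sum()
    nz = ElasticityMatrix(tuple(cats), values, energy_density, share)

    us_values = values.copy()
    us_values[0, 0] = -1.04  # US-style alternative: weaker own-price response
    # The US system lacks one of the food groups: drop its substitution term.
    if n_cat > 3:
        us_values[3, 0] = 0.0
    us = ElasticityMatrix(tuple(cats), us_values, energy_density.copy(), share.copy())

    # --- obesity-related utility weights -------------------------------------
    q_rows = []
    for sex in SEXES:
        u_n = np.round(np.linspace(0.92, 0.78, band_lo.size)
                       - (0.005 if sex == "male" else 0.0), 4)
        q_rows.append(pd.DataFrame({
            "age_lo": band_lo, "age_hi": band_hi, "sex": sex,
            "utility_normal": u_n,
            "utility_overweight": np.round(u_n - 0.015, 4),
            "utility_obese": np.round(u_n - 0.05, 4),
        }))
    qaly_weights = pd.concat(q_rows, ignore_index=True)

    manifest = {
        "seed": config.seed,
        "base_year": config.base_year,
        "scale": config.scale,
        "n_diseases": nd,
        "n_food_categories": n_cat,
        "bmi_family": config.bmi_family,
        "ssb_own_price_elasticity": float(nz.values[0, 0]),
        "ssb_own_price_elasticity_us": float(us.values[0, 0]),
        "ssb_kcal_per_oz": SSB_KCAL_PER_OZ,
        "rho_kcal_per_kg": 22.5,
        "tmrel_bmi": 22.5,
        "admin_share": 0.02,
        "direct_pathway_diseases": [n for n in names if n in DIRECT_PATHWAY_DISEASES],
    }
    bundle = InputBundle(population=population, consumption=consumption, bmi=bmi,
                         diseases=diseases, hazards=hazards,
                         elasticities={"nz": nz, "us": us},
                         qaly_weights=qaly_weights, manifest=manifest)
    bundle.manifest["checksum"] = bundle.checksum()
    _assert_ranges(bundle)
    return bundle


def _assert_ranges(bundle: InputBundle) -> None:
    """Cheap post-generation range checks; violations are generator bugs."""
    p = bundle.population
    problems = []
    if (p["population"] < 0).any():
        problems.append("negative population count")
    if not p["all_cause_mortality"].between(0, 1.5).all():
        problems.append("all-cause mortality outside [0, 1.5]")
    if not (p["pyld_rate"] < 1).all() or (p["pyld_rate"] < 0).any():
        problems.append("pyld_rate outside [0, 1)")
    c = bundle.consumption
    if (c["ssb_kcal_mean"] > c["tei_kcal_mean"]).any():
        problems.append("SSB kcal exceeds total energy intake")
    if (c[["ssb_kcal_se", "tei_kcal_se"]] <= 0).to_numpy().any():
        problems.append("non-positive consumption standard error")
    b = bundle.bmi
    if not b["bmi_mean"].between(15, 45).all():
        problems.append("bmi_mean outside [15, 45]")
    if not b["height_m"].between(1.2, 2.1).all():
        problems.append("height outside [1.2, 2.1] m")
    h = bundle.hazards
    if (h[["incidence", "remission", "case_fatality"]] < 0).to_numpy().any():
        problems.append("negative hazard")
    d = bundle.diseases
    if (d["rr_per_5bmi"] < 1).any():
        problems.append("rr_per_5bmi below 1")
    if ((d["rr_direct_per_serving"] > 1) != d["direct_ssb"]).any():
        problems.append("direct-pathway RR flags inconsistent")
    q = bundle.qaly_weights
    if not ((q["utility_normal"] >= q["utility_overweight"]).all()
            and (q["utility_overweight"] >= q["utility_obese"]).all()):
        problems.append("utility ordering violated")
    if problems:
        raise InputValidationError(problems)
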