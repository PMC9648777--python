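"""Schema-first validation of an input bundle before any computation.

Collects *all* violations rather than stopping at the first, so a report
can name every offending cell. The residual-mortality feasibility
pre-check uses the conservative bound sum_d case_fatality_d(a) <=
all-cause(a) (prevalence can approach 1 in a worst case); the pipeline
additionally enforces exact residual nonnegativity at run time.
"""

from __future__ import annotations

import numpy as np

from .config import AGE_MAX, AGE_MIN, SEXES
from .errors import InputValidationError
from .synthetic import InputBundle


def validate_bundle(bundle: InputBundle) -> list[str]:
    """Return a list of violations (empty = pristine)."""
    v: list[str] = []
    ages = np.arange(AGE_MIN, AGE_MAX + 1)

    p = bundle.population
    for sex in SEXES:
        sub = p[p["sex"] == sex]
        if not np.array_equal(np.sort(sub["age"].to_numpy()), ages):
            v.append(f"population: incomplete age coverage for sex={sex}")
    if (p["population"] < 0).any():
        v.append("population: negative head count")
    bad = p[~p["all_cause_mortality"].between(0, 1.5)]
    for _, row in bad.iterrows():
        v.append(f"population: all-cause mortality out of [0,1.5] at "
                 f"age={int(row['age'])} sex={row['sex']}")
    if ((p["pyld_rate"] < 0) | (p["pyld_rate"] >= 1)).any():
        v.append("population: pyld_rate outside [0, 1)")

    c = bundle.consumption
    if (c["ssb_kcal_mean"] > c["tei_kcal_mean"]).any():
        v.append("consumption: SSB energy exceeds total energy intake")
    if (c[["ssb_kcal_se", "tei_kcal_se"]] <= 0).to_numpy().any():
        v.append("consumption: standard errors must be > 0")

    b = bundle.bmi
    if not b["bmi_mean"].between(15, 45).all():
        v.append("bmi: mean outside [15, 45] kg/m^2")
    if (b["bmi_sd"] <= 0).any():
        v.append("bmi: sd must be > 0")
    if not b["height_m"].between(1.2, 2.1).all():
        v.append("bmi: height outside [1.2, 2.1] m")

    d = bundle.diseases
    if (d["rr_per_5bmi"] < 1).any():
        v.append("diseases: rr_per_5bmi < 1")
    mismatch = (d["rr_direct_per_serving"] > 1) != d["direct_ssb"]
    for name in d.loc[mismatch, "name"]:
        v.append(f"diseases: direct-pathway RR flag inconsistent for {name}")
    if (d["disability_weight"] < 0).any() or (d["disability_weight"] >= 1).any():
        v.append("diseases: disability weight outside [0, 1)")
    if (d["annual_cost_per_case"] < 0).any():
        v.append("diseases: negative annual cost per case")

    h = bundle.hazards
    neg = h[(h[["incidence", "remission", "case_fatality"]] < 0).any(axis=1)]
    for _, row in neg.iterrows():
        v.append(f"hazards: negative hazard for {row['disease']} "
                 f"sex={row['sex']} age={int(row['age'])}")

    # Residual-mortality feasibility (conservative: prevalence <= 1).
    mort = p.set_index(["sex", "age"])["all_cause_mortality"]
    cf_sum = h.groupby(["sex", "age"])["case_fatality"].sum()
    for (sex, age), total_cf in cf_sum.items():
        if total_cf > mort.loc[(sex, age)]:
            v.append(f"hazards: summed case fatality exceeds all-cause "
                     f"mortality at sex={sex} age={int(age)}")

    for name, e in bundle.elasticities.items():
        if e.values[0, 0] >= 0:
            v.append(f"elasticities[{name}]: SSB own-price elasticity must be negative")
        if not np.all(np.isfinite(e.values)):
            v.append(f"elasticities[{name}]: non-finite entries")

    q = bundle.qaly_weights
    if not ((q["utility_normal"] >= q["utility_overweight"])
            & (q["utility_overweight"] >= q["utility_obese"])).all():
        v.append("qaly_weights: utility ordering normal >= overweight >= obese violated")
    for col in ("utility_normal", "utility_overweight", "utility_obese"):
        if not q[col].between(0, 1).all():
            v.append(f"qaly_weights: {col} outside [0, 1]")

    return v


def validate_or_raise(bundle: InputBundle) -> None:
    violations = validate_bundle(bundle)
    if violations:
        raise InputValidationError(violations)
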