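"""End-to-end scenario execution over the synthetic input bundle.

A run follows one closed cohort per age x sex stratum (adults 20-100 in the
base year) through annual cycles to age 100, in two arms: a comparator
("business as usual") and the taxed arm. The tax changes SSB prices once;
elasticities turn that into consumption and energy changes; the energy
change shifts each stratum's BMI distribution; potential impact fractions
scale disease incidence; each disease's four-state process supplies
mortality and disability streams to the proportional multi-state life
table; and the economics layer discounts cost offsets, revenue and QALYs.

Everything is vectorised over (disease, cohort) arrays, so a full 29-disease
run over 81 cohorts x 2 sexes completes in a few seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import demand as demand_mod
from . import econ as econ_mod
from .bmi import category_prevalence_arrays, cases_prevented, energy_to_bmi
from .config import AGE_MAX, AGE_MIN, SEXES, RunOptions, TaxScenario
from .epi import DiseaseState, combine_pifs, pif_grid, step_disease
from .errors import ResidualRateError
from .mslt import mortality_to_q
from .synthetic import InputBundle, interpolate_to_single_year

OUTCOME_KEYS = ("dalys_averted", "qalys_gained", "cost_offset",
                "tax_revenue", "intervention_cost", "net_revenue")


@dataclass
class ParameterDraw:
    """One joint draw of the probabilistically sampled parameter families.

    The defaults are the degenerate (zero-variance) draw; the uncertainty
    module perturbs them once per iteration, shared across all strata.
    """

    bmi_mean_shift: float = 0.0
    rr_factor: float = 1.0
    rho: float | None = None  # None -> use RunOptions.rho
    ssb_factor: float = 1.0
    elasticity_factor: float = 1.0


@dataclass
class ScenarioResult:
    """Per-year outcome streams and their (un)discounted totals."""

    scenario: TaxScenario
    streams: dict  # name -> (n_years,) array, calendar years from base year
    streams_by_sex: dict  # name -> (2, n_years) array, SEXES order
    totals: dict  # name -> undiscounted total
    discounted: dict  # name -> discounted total
    extras: dict = field(default_factory=dict)
    uncertainty: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = [{"outcome": k, "total": self.totals[k],
                 "discounted": self.discounted[k]} for k in OUTCOME_KEYS]
        return pd.DataFrame(rows)


def _single_year_consumption(bundle: InputBundle, ssb_factor: float) -> dict:
    cols = ["ssb_kcal_mean", "tei_kcal_mean", "ssb_volume_mean", "ssb_volume_sd"]
    out = {}
    for sex in SEXES:
        bands = bundle.consumption[bundle.consumption["sex"] == sex]
        single = interpolate_to_single_year(bands, cols)
        for c in ("ssb_kcal_mean", "ssb_volume_mean", "ssb_volume_sd"):
            single[c] = single[c] * ssb_factor
        out[sex] = single
    return out


def _utility_by_age(bundle: InputBundle) -> dict:
    """Step-function utilities per sex and single-year age (3, n_ages)."""
    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    out = {}
    for sex in SEXES:
        q = bundle.qaly_weights[bundle.qaly_weights["sex"] == sex]
        u = np.zeros((3, ages.size))
        for _, row in q.iterrows():
            mask = (ages >= row["age_lo"]) & (ages <= row["age_hi"])
            u[0, mask] = row["utility_normal"]
            u[1, mask] = row["utility_overweight"]
            u[2, mask] = row["utility_obese"]
        out[sex] = u
    return out


def run_scenario(bundle: InputBundle, scenario: TaxScenario,
                 options: RunOptions | None = None,
                 draw: ParameterDraw | None = None) -> ScenarioResult:
    """Run the comparator and intervention arms and collect all outcomes."""
    options = options or RunOptions()
    draw = draw or ParameterDraw()
    rho = draw.rho if draw.rho is not None else options.rho
    family = bundle.manifest.get("bmi_family", "lognormal")
    base_year = int(bundle.manifest.get("base_year", 2015))

    ages = np.arange(AGE_MIN, AGE_MAX + 1)
    n_ages = ages.size
    n_years = n_ages  # a 20-year-old reaches 100 in the last cycle

    # ---- stratum arrays (cohorts = sex x entry age, flattened) -------------
    pop = bundle.population.set_index(["sex", "age"]).sort_index()
    sex_idx = np.repeat(np.arange(2), n_ages)  # 0 female, 1 male
    a0_idx = np.tile(np.arange(n_ages), 2)
    n_coh = sex_idx.size
    pop0 = np.concatenate([pop.loc[s]["population"].to_numpy() for s in SEXES])
    all_cause = np.stack([pop.loc[s]["all_cause_mortality"].to_numpy() for s in SEXES])
    pyld = np.stack([pop.loc[s]["pyld_rate"].to_numpy() for s in SEXES])

    cons = _single_year_consumption(bundle, draw.ssb_factor)
    cons_coh = pd.concat(
        [cons[s].assign(sex=s) for s in SEXES], ignore_index=True)
    bmi = bundle.bmi.set_index(["sex", "age"]).sort_index()
    bmi_mean = np.concatenate([bmi.loc[s]["bmi_mean"].to_numpy() for s in SEXES]) \
        + draw.bmi_mean_shift
    bmi_sd = np.concatenate([bmi.loc[s]["bmi_sd"].to_numpy() for s in SEXES])
    slope = np.concatenate([bmi.loc[s]["trend_slope"].to_numpy() for s in SEXES])
    height = np.concatenate([bmi.loc[s]["height_m"].to_numpy() for s in SEXES])
    if not options.bmi_trend:
        slope = np.zeros_like(slope)

    # ---- demand and energy stage -------------------------------------------
    elast = bundle.elasticities[options.elasticity_set]
    if draw.elasticity_factor != 1.0:
        from .synthetic import ElasticityMatrix
        elast = ElasticityMatrix(elast.categories,
                                 elast.values * draw.elasticity_factor,
                                 elast.energy_density, elast.kcal_share)
    shift = demand_mod.tax_to_demand_shift(scenario, cons_coh, elast)
    delta_tei = shift.strata["delta_tei_kcal"].to_numpy()
    post_vol = shift.strata["post_ssb_volume"].to_numpy()
    vol_mean = cons_coh["ssb_volume_mean"].to_numpy()
    vol_sd = cons_coh["ssb_volume_sd"].to_numpy()
    ssb_pct = float(shift.pct_demand_change[0])

    delta_bmi = energy_to_bmi(delta_tei, height, rho)

    # ---- disease parameter arrays ------------------------------------------
    dis = bundle.diseases
    nd = len(dis)
    rr5 = np.maximum(1.0, dis["rr_per_5bmi"].to_numpy() * draw.rr_factor)
    rr5 = np.where(dis["bmi_mediated"].to_numpy(bool), rr5, 1.0)
    rr_serv = np.maximum(1.0, dis["rr_direct_per_serving"].to_numpy() * draw.rr_factor)
    rr_serv = np.where(dis["direct_ssb"].to_numpy(bool), rr_serv, 1.0)
    dw = dis["disability_weight"].to_numpy()
    cost = dis["annual_cost_per_case"].to_numpy()

    hz = bundle.hazards.set_index(["disease", "sex", "age"]).sort_index()
    inc = np.empty((nd, 2, n_ages))
    rem = np.empty((nd, 2, n_ages))
    cf = np.empty((nd, 2, n_ages))
    for k, name in enumerate(dis["name"]):
        for s, sex in enumerate(SEXES):
            block = hz.loc[(name, sex)]
            inc[k, s] = block["incidence"].to_numpy()
            rem[k, s] = block["remission"].to_numpy()
            cf[k, s] = block["case_fatality"].to_numpy()

    # ---- direct SSB pathway PIF (time-invariant: one-time sustained shift) -
    if options.direct_ssb_pathway and np.any(rr_serv > 1.0):
        kappa = np.where(vol_mean > 0, post_vol / np.maximum(vol_mean, 1e-300), 1.0)
        pif_dir = pif_grid(rr_serv,
                           vol_mean / options.serving_oz,
                           np.maximum(vol_sd, 1e-9) / options.serving_oz,
                           kappa * vol_mean / options.serving_oz,
                           np.maximum(kappa * vol_sd, 1e-9) / options.serving_oz,
                           tmrel=0.0, unit=1.0, family=family,
                           nodes=options.pif_nodes,
                           bounds_pct=options.pif_bounds_pct)
    else:
        pif_dir = np.zeros((nd, n_coh))

    # ---- annual cycles ------------------------------------------------------
    state_c = DiseaseState.healthy((nd, n_coh))
    state_i = DiseaseState.healthy((nd, n_coh))
    m_dis_sum = {arm: np.zeros((n_coh, n_years)) for arm in ("comp", "int")}
    w_dis_sum = {arm: np.zeros((n_coh, n_years)) for arm in ("comp", "int")}
    wcost = {arm: np.zeros((n_coh, n_years)) for arm in ("comp", "int")}
    new_cases = {arm: np.zeros((nd, n_coh, n_years)) for arm in ("comp", "int")}
    dis_deaths = {arm: np.zeros((nd, n_coh, n_years)) for arm in ("comp", "int")}

    t_term = (n_ages - 1) - a0_idx  # cycle index at which each cohort turns 100
    age_cur_all = np.minimum(a0_idx[None, :] + np.arange(n_years)[:, None],
                             n_ages - 1)  # (T, coh)

    bmi_shifted = delta_bmi != 0.0
    pif_static = None
    for t in range(n_years):
        age_cur = age_cur_all[t]
        mu_c = bmi_mean + slope * t
        mu_i = mu_c + delta_bmi
        if np.any(bmi_shifted):
            if np.any(slope != 0.0) or pif_static is None:
                pif_bmi = pif_grid(rr5, mu_c, bmi_sd, mu_i, bmi_sd,
                                   tmrel=options.tmrel_bmi, unit=5.0,
                                   family=family, nodes=options.pif_nodes,
                                   bounds_pct=options.pif_bounds_pct)
                pif_static = pif_bmi
            else:
                pif_bmi = pif_static
        else:
            pif_bmi = np.zeros((nd, n_coh))

        factor = 1.0 - combine_pifs(pif_bmi, pif_dir)
        i_c = inc[:, sex_idx, age_cur]
        i_i = i_c * factor
        r_t = rem[:, sex_idx, age_cur]
        f_t = cf[:, sex_idx, age_cur]
        m_t = all_cause[sex_idx, age_cur][None, :]

        for arm, state, i_arm in (("comp", state_c, i_c), ("int", state_i, i_i)):
            alive0 = state.S + state.C
            p0 = np.where(alive0 > 0, state.C / np.maximum(alive0, 1e-300), 0.0)
            d0 = state.D_dis.copy()
            new_state = step_disease(state, (i_arm, r_t, f_t, m_t))
            alive1 = new_state.S + new_state.C
            p1 = np.where(alive1 > 0, new_state.C / np.maximum(alive1, 1e-300), 0.0)
            py = (alive0 + alive1) / 2.0
            d_deaths = new_state.D_dis - d0
            m_dis = np.where(py > 0, d_deaths / np.maximum(py, 1e-300), 0.0)
            p_mid = (p0 + p1) / 2.0
            m_dis_sum[arm][:, t] = m_dis.sum(axis=0)
            w_dis_sum[arm][:, t] = (p_mid * dw[:, None]).sum(axis=0)
            wcost[arm][:, t] = (p_mid * cost[:, None]).sum(axis=0)
            # incident inflow per original cohort member (approximate):
            new_cases[arm][:, :, t] = i_arm * (new_state.S + state.S) / 2.0
            dis_deaths[arm][:, :, t] = d_deaths
            if arm == "comp":
                state_c = new_state
            else:
                state_i = new_state

    # ---- proportional life tables ------------------------------------------
    t_grid = np.arange(n_years)[None, :]
    active = t_grid <= t_term[:, None]  # (coh, T)

    all_cause_grid = all_cause[sex_idx[:, None], age_cur_all.T]  # (coh, T)
    pyld_grid = pyld[sex_idx[:, None], age_cur_all.T]
    m_minus = all_cause_grid - m_dis_sum["comp"]
    w_minus = pyld_grid - w_dis_sum["comp"]
    for name, grid in (("mortality", m_minus), ("pYLD", w_minus)):
        if np.any((grid < -1e-12) & active):
            masked = np.where(active, grid, 0.0)
            c, t = np.unravel_index(np.argmin(masked), grid.shape)
            raise ResidualRateError(
                f"negative residual {name} for sex={SEXES[sex_idx[c]]} "
                f"entry-age={AGE_MIN + a0_idx[c]} cycle={t}")
    m_minus = np.maximum(m_minus, 0.0)
    w_minus = np.maximum(w_minus, 0.0)

    def life_table(arm: str):
        m = m_minus + m_dis_sum[arm]
        q = mortality_to_q(m, options.qx_convention)
        l = np.empty((n_coh, n_years))
        l[:, 0] = pop0
        for t in range(1, n_years):
            l[:, t] = l[:, t - 1] * (1.0 - q[:, t - 1])
        l_next = np.concatenate([l[:, 1:], (l[:, -1] * (1 - q[:, -1]))[:, None]], axis=1)
        L = (l + l_next) / 2.0
        # open-ended exponential tail in each cohort's terminal (age-100) cycle
        at_term = t_grid == t_term[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            tail = l / np.maximum(m, 1e-300)
        L = np.where(at_term & (m > 0), tail, L)
        L = np.where(active, L, 0.0)
        w = np.clip(w_minus + w_dis_sum[arm], 0.0, 1.0)
        Lw = L * (1.0 - w)
        return l, L, Lw

    l_c, L_c, Lw_c = life_table("comp")
    l_i, L_i, Lw_i = life_table("int")

    # ---- BMI category prevalences and QALYs --------------------------------
    mu_c_grid = bmi_mean[:, None] + slope[:, None] * t_grid
    mu_i_grid = mu_c_grid + delta_bmi[:, None]
    sd_grid = np.broadcast_to(bmi_sd[:, None], mu_c_grid.shape)
    prev_c = category_prevalence_arrays(mu_c_grid, sd_grid, family)
    prev_i = category_prevalence_arrays(mu_i_grid, sd_grid, family)
    util = _utility_by_age(bundle)
    u_grid = np.stack([util[SEXES[sex_idx[c]]][:, age_cur_all[:, c]]
                       for c in range(n_coh)], axis=1)  # (3, coh, T)
    qaly_c = L_c * sum(prev_c[k] * u_grid[k] for k in range(3))
    qaly_i = L_i * sum(prev_i[k] * u_grid[k] for k in range(3))

    # ---- streams -------------------------------------------------------------
    daly_coh = Lw_i - Lw_c
    qaly_coh = qaly_i - qaly_c
    cost_coh = wcost["comp"] * L_c - wcost["int"] * L_i
    rev_coh, admin_coh, net_coh = econ_mod.revenue_and_admin(
        L_i, post_vol[:, None], scenario.tax_per_oz, options.admin_share)

    def by_sex(grid):
        return np.stack([grid[sex_idx == s].sum(axis=0) for s in range(2)])

    streams_by_sex = {
        "dalys_averted": by_sex(daly_coh),
        "qalys_gained": by_sex(qaly_coh),
        "cost_offset": by_sex(cost_coh),
        "tax_revenue": by_sex(rev_coh),
        "intervention_cost": by_sex(admin_coh),
        "net_revenue": by_sex(net_coh),
    }
    streams = {k: v.sum(axis=0) for k, v in streams_by_sex.items()}
    totals = {k: float(v.sum()) for k, v in streams.items()}
    rate = scenario.discount_rate
    discounted = {k: econ_mod.discount(v, rate) for k, v in streams.items()}

    icer_res = econ_mod.icer(discounted["cost_offset"], discounted["qalys_gained"])

    # year-one overweight/obesity cases prevented, and 25-year disease counts
    prev0_c = tuple(p[:, 0] for p in prev_c)
    prev0_i = tuple(p[:, 0] for p in prev_i)
    cases_oo = cases_prevented(prev0_c, prev0_i, pop0)
    horizon25 = min(25, n_years)
    cases_by_dis = ((new_cases["comp"] - new_cases["int"])[:, :, :horizon25]
                    * pop0[None, :, None]).sum(axis=(1, 2))
    deaths_by_dis = ((dis_deaths["comp"] - dis_deaths["int"])[:, :, :horizon25]
                     * pop0[None, :, None]).sum(axis=(1, 2))

    pw = pop0 / pop0.sum()
    extras = {
        "base_year": base_year,
        "price_change_pct": demand_mod.price_change(scenario),
        "ssb_demand_change_pct": ssb_pct,
        "delta_tei_kcal_by_sex": {
            SEXES[s]: float(np.average(delta_tei[sex_idx == s],
                                       weights=pop0[sex_idx == s]))
            for s in range(2)},
        "delta_bmi_by_sex": {
            SEXES[s]: float(np.average(delta_bmi[sex_idx == s],
                                       weights=pop0[sex_idx == s]))
            for s in range(2)},
        "mean_delta_tei_kcal": float(np.average(delta_tei, weights=pw)),
        "cases_prevented_overweight_obesity": cases_oo,
        "cases_prevented_by_sex": {
            SEXES[s]: cases_prevented(tuple(p[sex_idx == s] for p in prev0_c),
                                      tuple(p[sex_idx == s] for p in prev0_i),
                                      pop0[sex_idx == s])
            for s in range(2)},
        "disease_cases_prevented_25y": dict(zip(dis["name"], cases_by_dis)),
        "disease_deaths_prevented_25y": dict(zip(dis["name"], deaths_by_dis)),
        "total_disease_cases_prevented_25y": float(cases_by_dis.sum()),
        "total_disease_deaths_prevented_25y": float(deaths_by_dis.sum()),
        "icer": icer_res.icer,
        "icer_dominant": icer_res.dominant,
        "population_total": float(pop0.sum()),
        "life_years_comparator": float(L_c.sum()),
        "life_years_intervention": float(L_i.sum()),
    }
    return ScenarioResult(scenario=scenario, streams=streams,
                          streams_by_sex=streams_by_sex, totals=totals,
                          discounted=discounted, extras=extras)
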