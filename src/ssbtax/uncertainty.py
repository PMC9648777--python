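"""Probabilistic uncertainty and univariate sensitivity scenarios.

The probabilistic analysis re-runs the full deterministic pipeline with
jointly re-sampled inputs (mean BMI, relative risks, the energy-to-weight
constant, SSB intake, and price elasticities), 2000 iterations by default,
and reports the iteration mean with an empirical 2.5/97.5-percentile 95%
uncertainty interval. Each parameter family is drawn once per iteration
and shared across strata, preserving the correlation structure of a
systematic parameter error.

The univariate sensitivity scenarios mirror common practice for this kind
of tax model: a static-BMI world, 80%/120% pass-through, a 3% discount
rate, and an alternative (US-style) elasticity set.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import SENSITIVITY_SCENARIOS, MonteCarloConfig, RunOptions, TaxScenario
from .errors import InputValidationError, PipelineError
from .pipeline import OUTCOME_KEYS, ParameterDraw, ScenarioResult, run_scenario
from .synthetic import InputBundle

logger = logging.getLogger(__name__)


def sample_draw(rng: np.random.Generator, mc: MonteCarloConfig,
                base_rho: float = 22.5) -> ParameterDraw:
    """One joint draw of the sampled parameter families.

    Normal families are truncated at physically meaningful bounds; relative
    risks get a shared lognormal factor.
    """
    rho = float(np.clip(rng.normal(base_rho, mc.sd_rho), 5.0, None)) \
        if mc.sd_rho > 0 else base_rho
    return ParameterDraw(
        bmi_mean_shift=float(rng.normal(0.0, mc.sd_bmi_mean)) if mc.sd_bmi_mean > 0 else 0.0,
        rr_factor=float(np.exp(rng.normal(0.0, mc.sd_log_rr))) if mc.sd_log_rr > 0 else 1.0,
        rho=rho,
        ssb_factor=float(np.clip(rng.normal(1.0, mc.sd_ssb_factor), 0.0, None))
        if mc.sd_ssb_factor > 0 else 1.0,
        elasticity_factor=float(np.clip(rng.normal(1.0, mc.sd_elasticity_factor), 0.0, None))
        if mc.sd_elasticity_factor > 0 else 1.0,
    )


def run_psa(mc: MonteCarloConfig, scenario: TaxScenario, bundle: InputBundle,
            options: RunOptions | None = None) -> ScenarioResult:
    """Monte Carlo over sampled inputs; deterministic under a fixed seed.

    Returns the zero-variance structure of a :class:`ScenarioResult` whose
    ``uncertainty`` dict holds, per discounted outcome, the iteration mean,
    the 95% UI, and the Monte-Carlo standard error of the mean. Iteration
    failures are logged and excluded; more than ``max_failure_fraction``
    aborts the analysis.
    """
    options = options or RunOptions()
    rng = np.random.default_rng(mc.seed)
    base_rho = options.rho
    samples: dict[str, list] = {k: [] for k in OUTCOME_KEYS}
    samples["icer"] = []
    failures = 0
    for it in range(mc.iterations):
        draw = sample_draw(rng, mc, base_rho)
        try:
            res = run_scenario(bundle, scenario, options, draw)
        except Exception as exc:  # noqa: BLE001 - iteration-level guard
            failures += 1
            logger.warning("PSA iteration %d failed: %s", it, exc)
            if failures > mc.max_failure_fraction * mc.iterations:
                raise PipelineError(
                    f"PSA aborted: {failures} failed iterations "
                    f"(> {mc.max_failure_fraction:.0%} of {mc.iterations})") from exc
            continue
        for k in OUTCOME_KEYS:
            samples[k].append(res.discounted[k])
        samples["icer"].append(res.extras["icer"])

    alpha = (1.0 - mc.interval_level) / 2.0
    point = run_scenario(bundle, scenario, options)  # zero-variance reference
    ui = {}
    for k, vals in samples.items():
        arr = np.asarray(vals, dtype=float)
        ui[k] = {
            "mean": float(arr.mean()),
            "lo": float(np.percentile(arr, 100 * alpha)),
            "hi": float(np.percentile(arr, 100 * (1 - alpha))),
            "mc_se": float(arr.std(ddof=1) / np.sqrt(arr.size)),
            "n_iterations": int(arr.size),
        }
    ui["n_failures"] = failures
    # Both ICER estimators (the ratio of mean costs to mean QALYs, and the
    # mean of per-iteration ratios) are reported; they differ in general.
    qal = np.asarray(samples["qalys_gained"], dtype=float)
    off = np.asarray(samples["cost_offset"], dtype=float)
    if np.all(qal != 0):
        ui["icer_ratio_of_means"] = float(-off.mean() / qal.mean())
        ui["icer_mean_of_ratios"] = float(np.mean(-off / qal))
    point.uncertainty = ui
    return point


def _scenario_patch(name: str, base: TaxScenario, options: RunOptions):
    if name == "identity":  # patch nothing: must reproduce the base exactly
        return base, options
    if name == "static_bmi":
        return base, options.model_copy(update={"bmi_trend": False})
    if name == "passthrough_80":
        return base.model_copy(update={"pass_through": 0.8}), options
    if name == "passthrough_120":
        return base.model_copy(update={"pass_through": 1.2}), options
    if name == "discount_3pct":
        return base.model_copy(update={"discount_rate": 0.03}), options
    if name == "alt_elasticities":
        return base, options.model_copy(update={"elasticity_set": "us"})
    raise InputValidationError(f"unknown sensitivity scenario {name!r}")


def run_sensitivity(bundle: InputBundle, base: TaxScenario,
                    options: RunOptions | None = None,
                    scenarios=SENSITIVITY_SCENARIOS) -> pd.DataFrame:
    """Deterministic univariate sensitivity table: absolute and % vs base."""
    options = options or RunOptions()
    base_res = run_scenario(bundle, base, options)
    cols = ("dalys_averted", "qalys_gained", "cost_offset", "net_revenue")
    rows = [{"scenario": "base", **{c: base_res.discounted[c] for c in cols}}]
    for name in scenarios:
        sc, op = _scenario_patch(name, base, options)
        res = run_scenario(bundle, sc, op)
        row = {"scenario": name}
        for c in cols:
            row[c] = res.discounted[c]
            denom = base_res.discounted[c]
            row[f"{c}_pct_change"] = 100.0 * (res.discounted[c] - denom) / denom \
                if denom != 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def run_tax_ladder(bundle: InputBundle, taxes=(0.01, 0.015, 0.02),
                   options: RunOptions | None = None,
                   base: TaxScenario | None = None) -> pd.DataFrame:
    """Outcomes across tax levels; monotone in the tax for every outcome."""
    options = options or RunOptions()
    base = base or TaxScenario()
    rows = []
    for tax in taxes:
        res = run_scenario(bundle, base.model_copy(update={"tax_per_oz": tax}), options)
        rows.append({
            "tax_per_oz": tax,
            "price_change_pct": res.extras["price_change_pct"],
            **{k: res.discounted[k] for k in OUTCOME_KEYS},
        })
    return pd.DataFrame(rows)
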