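"""Energy-intake changes -> BMI shifts, secular trend, and category counts.

A sustained change of ``rho`` kcal/day moves steady-state body weight by
1 kg (Swinburn energy-balance rule, default rho = 22.5 kcal/day/kg, about
94 kJ); dividing by height squared turns that into a BMI change. The
intervention shifts each stratum's BMI distribution location only (the
standard deviation is untouched) and the secular trend shifts comparator
and intervention arms identically, so the arm difference is always exactly
the tax-attributable BMI change.

BMI categories use the conventions: normal <= 25 < overweight <= 30 < obese.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import InputValidationError

OVERWEIGHT_CUT = 25.0
OBESE_CUT = 30.0


def lognormal_params(mean, sd):
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


@dataclass(frozen=True)
class ExposureDistribution:
    """A continuous risk-factor distribution for one stratum."""

    mean: float
    sd: float
    family: str = "lognormal"  # or "normal"

    def __post_init__(self):
        if self.sd <= 0:
            raise InputValidationError("exposure sd must be > 0")
        if self.family not in ("lognormal", "normal"):
            raise InputValidationError(f"unknown family {self.family!r}")

    def _frozen(self):
        if self.family == "normal":
            return stats.norm(loc=self.mean, scale=self.sd)
        mu, sigma = lognormal_params(self.mean, self.sd)
        return stats.lognorm(s=sigma, scale=np.exp(mu))

    def pdf(self, x):
        return self._frozen().pdf(x)

    def cdf(self, x):
        return self._frozen().cdf(x)

    def ppf(self, q):
        return self._frozen().ppf(q)

    def shift(self, delta: float) -> "ExposureDistribution":
        """Location shift of the mean; spread unchanged."""
        return replace(self, mean=self.mean + delta)


def energy_to_bmi(delta_tei, height_m, rho: float = 22.5):
    """BMI change from a sustained daily energy-intake change.

    delta-weight(kg) = delta_tei / rho; delta-BMI = delta-weight / height^2.
    Vectorised over strata.
    """
    if rho <= 0:
        raise InputValidationError("rho must be > 0")
    height_m = np.asarray(height_m, dtype=float)
    if np.any(height_m <= 0):
        raise InputValidationError("height must be > 0")
    return np.asarray(delta_tei, dtype=float) / rho / height_m**2


def apply_trend(dist: ExposureDistribution, years_elapsed: float,
                slope: float = 0.0) -> ExposureDistribution:
    """Shift the distribution mean by the secular trend slope x elapsed years."""
    return dist.shift(slope * years_elapsed)


def category_prevalence(dist: ExposureDistribution):
    """(p_normal, p_overweight, p_obese) under the stratum distribution."""
    c1 = dist.cdf(OVERWEIGHT_CUT)
    c2 = dist.cdf(OBESE_CUT)
    return c1, c2 - c1, 1.0 - c2


def category_prevalence_arrays(means, sds, family: str = "lognormal"):
    """Vectorised category probabilities for arrays of stratum parameters."""
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if family == "normal":
        c1 = stats.norm.cdf(OVERWEIGHT_CUT, loc=means, scale=sds)
        c2 = stats.norm.cdf(OBESE_CUT, loc=means, scale=sds)
    else:
        mu, sigma = lognormal_params(means, sds)
        c1 = stats.norm.cdf((np.log(OVERWEIGHT_CUT) - mu) / sigma)
        c2 = stats.norm.cdf((np.log(OBESE_CUT) - mu) / sigma)
    return c1, c2 - c1, 1.0 - c2


def cases_prevented(pre, post, population):
    """Overweight+obese cases prevented, floored at zero per stratum.

    ``pre``/``post`` are (p_normal, p_overweight, p_obese) triples (scalars
    or arrays); ``population`` the stratum head counts.
    """
    pre_excess = np.asarray(pre[1]) + np.asarray(pre[2])
    post_excess = np.asarray(post[1]) + np.asarray(post[2])
    drop = np.maximum(pre_excess - post_excess, 0.0)
    return float(np.sum(np.asarray(population, dtype=float) * drop))
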