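"""Payer-perspective economics: discounting, revenue, and the ICER.

Health-care cost offsets are prevalent-case-years times annual per-case
cost, comparator minus intervention. Tax revenue is post-tax SSB volume
times the tax rate over the alive population; intervention (administration)
cost is a fixed share of revenue (2%). The ICER divides incremental
health-care cost by incremental QALYs; revenue and administration costs are
excluded under the public-health-care-payer perspective, so a positive
cost offset with positive QALY gain yields a negative (dominant) ICER.
Discounting is annual at 1.5% with t = 0 in the first model year
(2015 reference, undiscounted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputValidationError


def discount_factors(n: int, rate: float) -> np.ndarray:
    if rate < 0:
        raise InputValidationError("discount rate must be >= 0")
    return (1.0 + rate) ** -np.arange(n, dtype=float)


def discount(stream, rate: float) -> float:
    """Discounted total of an annual stream; first element is year 0."""
    stream = np.asarray(stream, dtype=float)
    return float(stream @ discount_factors(stream.size, rate))


def revenue_and_admin(alive_person_years, post_tax_oz_per_day, tax_per_oz: float,
                      admin_share: float = 0.02):
    """Annual tax revenue, intervention (admin) cost and net revenue streams.

    ``alive_person_years`` and ``post_tax_oz_per_day`` are per-year arrays
    (already aggregated over strata, or broadcastable); revenue(year) =
    person-years x oz/day x 365.25 x tax.
    """
    vol = np.asarray(post_tax_oz_per_day, dtype=float)
    if np.any(vol < 0):
        raise InputValidationError("post-tax consumption must be >= 0")
    py = np.asarray(alive_person_years, dtype=float)
    revenue = py * vol * 365.25 * tax_per_oz
    admin = admin_share * revenue
    return revenue, admin, revenue - admin


@dataclass
class ICERResult:
    delta_cost: float  # incremental health-care cost (intervention - comparator)
    delta_effect: float  # incremental QALYs
    icer: float | None
    dominant: bool
    undefined: bool = False


def icer(cost_offset: float, qalys: float) -> ICERResult:
    """ICER from a (positive = saving) cost offset and QALY gain.

    The offset enters as negative incremental cost; a zero QALY difference
    is flagged as undefined rather than divided.
    """
    delta_cost = -float(cost_offset)
    delta_effect = float(qalys)
    if delta_effect == 0.0:
        return ICERResult(delta_cost, delta_effect, None, False, undefined=True)
    value = delta_cost / delta_effect
    dominant = delta_cost < 0 and delta_effect > 0
    return ICERResult(delta_cost, delta_effect, value, dominant)
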