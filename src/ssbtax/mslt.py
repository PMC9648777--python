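"""The proportional multi-state life table.

Each modelled disease contributes its own mortality and disability on top
of residual ("minus") rates that exclude the modelled diseases, so that in
the comparator arm the decomposition closes exactly back to the all-cause
inputs: m(a) = m_minus(a) + sum_d m_dis(a). Survivorship follows
q = 1 - exp(-m) (constant hazard within the year; an m/(1+m/2) alternative
is available), life years are trapezoidal, and the open terminal age gets
an exponential tail L = l/m. Health-adjusted life years Lw = L(1-w) with
w = w_minus + sum_d prevalence_d x disability-weight_d. DALYs averted are
the arm difference in Lw; QALYs weight life years by BMI-category
utilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputValidationError, ResidualRateError


def mortality_to_q(m: np.ndarray, convention: str = "exp") -> np.ndarray:
    """Annual death probability from a mortality rate."""
    m = np.asarray(m, dtype=float)
    if convention == "exp":
        return -np.expm1(-m)
    if convention == "half_cycle":
        return m / (1.0 + 0.5 * m)
    raise InputValidationError(f"unknown qx convention {convention!r}")


def survivorship(l0, m, convention: str = "exp"):
    """(l, L): survivors at each age and life years lived in each interval.

    ``m`` has one entry per remaining year; ``l`` has the same length with
    l[0] = l0. The last interval is open-ended: L[-1] = l[-1]/m[-1].
    Vectorised over leading axes of ``m`` (cohorts run along the last axis
    of time via a python loop of length n_years).
    """
    m = np.asarray(m, dtype=float)
    q = mortality_to_q(m, convention)
    n = m.shape[-1]
    l = np.empty_like(m)
    l[..., 0] = l0
    for t in range(1, n):
        l[..., t] = l[..., t - 1] * (1.0 - q[..., t - 1])
    l_next = l[..., -1] * (1.0 - q[..., -1])
    L = np.empty_like(m)
    L[..., :-1] = (l[..., :-1] + l[..., 1:]) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        tail = np.where(m[..., -1] > 0, l[..., -1] / np.maximum(m[..., -1], 1e-300),
                        (l[..., -1] + l_next) / 2.0)
    L[..., -1] = tail
    return l, L


def build_life_table(ages, l0, m_minus, m_dis_total, w_minus, w_dis_total,
                     convention: str = "exp", label: str = "") -> pd.DataFrame:
    """Assemble one cohort's life table from residual and modelled rates.

    Raises :class:`ResidualRateError` naming the offending age if residual
    mortality or residual pYLD is negative anywhere.
    """
    ages = np.asarray(ages)
    m_minus = np.asarray(m_minus, dtype=float)
    w_minus = np.asarray(w_minus, dtype=float)
    if np.any(m_minus < 0):
        a = ages[np.argmax(m_minus < 0)]
        raise ResidualRateError(
            f"negative residual mortality at age {a}{' (' + label + ')' if label else ''}")
    if np.any(w_minus < 0):
        a = ages[np.argmax(w_minus < 0)]
        raise ResidualRateError(
            f"negative residual pYLD at age {a}{' (' + label + ')' if label else ''}")
    m = m_minus + np.asarray(m_dis_total, dtype=float)
    w = np.clip(w_minus + np.asarray(w_dis_total, dtype=float), 0.0, 1.0)
    l, L = survivorship(l0, m, convention)
    Lw = L * (1.0 - w)
    e = np.where(l > 0, np.cumsum(L[::-1])[::-1] / np.maximum(l, 1e-300), 0.0)
    dale = np.where(l > 0, np.cumsum(Lw[::-1])[::-1] / np.maximum(l, 1e-300), 0.0)
    return pd.DataFrame({
        "x": ages, "m": m, "q": mortality_to_q(m, convention), "l": l,
        "L": L, "w": w, "Lw": Lw, "e": e, "dale": dale,
        "m_minus": m_minus, "w_minus": w_minus,
    })


def dalys_averted(comparator: pd.DataFrame, intervention: pd.DataFrame) -> np.ndarray:
    """Per-year DALYs averted: the arm difference in health-adjusted life years."""
    if len(comparator) != len(intervention) or \
            not np.array_equal(comparator["x"].to_numpy(), intervention["x"].to_numpy()):
        raise InputValidationError("life-table arms cover different strata/ages")
    return intervention["Lw"].to_numpy() - comparator["Lw"].to_numpy()


def qaly_stream(L, prevalences, utilities) -> np.ndarray:
    """Per-year QALYs for one arm.

    ``prevalences`` is a (p_normal, p_overweight, p_obese) triple and
    ``utilities`` the matching utility triple; every element broadcasts
    against ``L`` (person-years alive).
    """
    L = np.asarray(L, dtype=float)
    total = np.zeros_like(L)
    for p, u in zip(prevalences, utilities):
        total = total + np.asarray(p, dtype=float) * np.asarray(u, dtype=float)
    return L * total


def qalys_gained(L_comp, prev_comp, L_int, prev_int, utilities) -> np.ndarray:
    """Arm difference in QALYs, capturing both utility and survival effects."""
    return qaly_stream(L_int, prev_int, utilities) - qaly_stream(L_comp, prev_comp, utilities)
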