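import numpy as np
import pytest
from scipy.linalg import expm

from ssbtax.bmi import ExposureDistribution
from ssbtax.epi import (DiseaseState, RiskFunction, adjust_incidence,
                        combine_pifs, compute_pif, pif_grid, run_disease,
                        step_disease, transition_matrix)
from ssbtax.errors import InputValidationError


class TestRiskFunction:
    def test_flat_below_tmrel(self):
        rf = RiskFunction(rr_per_unit=1.5, tmrel=22.5, unit=5.0)
        assert rf.rr(20.0) == 1.0
        assert rf.rr(27.5) == pytest.approx(1.5)
        assert rf.rr(32.5) == pytest.approx(2.25)

    def test_nondecreasing(self):
        rf = RiskFunction(rr_per_unit=1.3)
        x = np.linspace(15, 45, 200)
        assert np.all(np.diff(rf.rr(x)) >= 0)

    def test_rr_below_one_rejected(self):
        with pytest.raises(InputValidationError):
            RiskFunction(rr_per_unit=0.9)


class _TwoSpikes:
    """Mixture of two narrow normals; stand-in for a discrete two-bin exposure."""

    def __init__(self, locs, weights, eps=0.3):
        self.locs, self.weights, self.eps = locs, weights, eps

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        out = 0.0
        for loc, w in zip(self.locs, self.weights):
            out = out + w * np.exp(-0.5 * ((x - loc) / self.eps) ** 2) \
                / (self.eps * np.sqrt(2 * np.pi))
        return out

    def ppf(self, q):  # only used for default bounds, not in this test
        raise NotImplementedError


class TestPIF:
    def test_identical_distributions_zero(self):
        rf = RiskFunction(rr_per_unit=1.5)
        p = ExposureDistribution(mean=27.0, sd=4.0)
        assert compute_pif(rf, p, p).pif == 0.0

    def test_flat_rr_zero_for_any_shift(self):
        rf = RiskFunction(rr_per_unit=1.0)
        p = ExposureDistribution(mean=27.0, sd=4.0)
        assert compute_pif(rf, p, p.shift(-1.0)).pif == pytest.approx(0.0, abs=1e-12)

    def test_two_bin_discrete_analogue(self):
        """Half the population at RR 1, half at RR 2 -> all at RR 1: PIF = 1/3."""
        # RR doubles per 5 units above tmrel 22.5, so x=27.5 has RR 2.
        rf = RiskFunction(rr_per_unit=2.0, tmrel=22.5, unit=5.0)
        p = _TwoSpikes([20.0, 27.5], [0.5, 0.5])
        p_star = _TwoSpikes([20.0, 20.0], [0.5, 0.5])
        res = compute_pif(rf, p, p_star, bounds=(15.0, 35.0))
        assert res.pif == pytest.approx(1.0 / 3.0, abs=1e-3)

    def test_grid_matches_adaptive_quadrature(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            rr = float(rng.uniform(1.05, 1.9))
            mean = float(rng.uniform(24, 31))
            sd = float(rng.uniform(3, 6))
            shift = float(rng.uniform(-1.5, 0))
            rf = RiskFunction(rr_per_unit=rr)
            p = ExposureDistribution(mean=mean, sd=sd)
            ref = compute_pif(rf, p, p.shift(shift)).pif
            got = pif_grid(np.array([rr]), [mean], [sd], [mean + shift], [sd])[0, 0]
            assert got == pytest.approx(ref, abs=1e-5)

    def test_downward_shift_gives_nonnegative_pif(self):
        rng = np.random.default_rng(11)
        rrs = rng.uniform(1.0, 2.0, 30)
        means = rng.uniform(23, 33, 30)
        sds = rng.uniform(2.5, 6.0, 30)
        shifts = -rng.uniform(0, 2.0, 30)
        pifs = np.array([
            pif_grid(np.array([rr]), [m], [s], [m + d], [s])[0, 0]
            for rr, m, s, d in zip(rrs, means, sds, shifts)])
        assert np.all(pifs >= -1e-12)
        assert np.all(pifs <= 1.0)


class TestAdjustIncidence:
    def test_examples(self):
        assert adjust_incidence(0.01, 0.0) == pytest.approx(0.01)
        assert adjust_incidence(0.010, 0.2) == pytest.approx(0.008)

    def test_multiplicative_combination(self):
        combined = combine_pifs(0.1, 0.1)
        assert combined == pytest.approx(1 - 0.81)
        assert adjust_incidence(1.0, combined) == pytest.approx(0.81)

    def test_pif_above_one_rejected(self):
        with pytest.raises(InputValidationError):
            adjust_incidence(0.01, 1.5)

    def test_negative_incidence_rejected(self):
        with pytest.raises(InputValidationError):
            adjust_incidence(-0.01, 0.1)


class TestStepDisease:
    def test_zero_hazards_identity(self):
        st = step_disease(DiseaseState.healthy(), (0.0, 0.0, 0.0, 0.0))
        assert float(st.S) == 1.0 and float(st.C) == 0.0
        assert float(st.total()) == pytest.approx(1.0, abs=1e-15)

    def test_no_inflow_keeps_disease_empty(self):
        st = DiseaseState.healthy()
        for _ in range(5):
            st = step_disease(st, (0.0, 0.0, 0.3, 0.1))
        assert float(st.C) == 0.0 and float(st.D_dis) == 0.0

    def test_closed_form_incidence_only(self):
        st = step_disease(DiseaseState.healthy(), (0.1, 0.0, 0.0, 0.0))
        assert float(st.C) == pytest.approx(1 - np.exp(-0.1), abs=1e-12)

    def test_negative_hazard_rejected(self):
        with pytest.raises(InputValidationError):
            step_disease(DiseaseState.healthy(), (-0.1, 0.0, 0.0, 0.0))

    def test_matches_scipy_matrix_exponential(self):
        rng = np.random.default_rng(19)
        worst = 0.0
        for _ in range(100):
            i, r, f, m = rng.uniform(0, 0.6, 4)
            Q = np.array([
                [-(i + m), i, 0.0, m],
                [r, -(r + f + m), f, m],
                [0, 0, 0, 0], [0, 0, 0, 0]])
            P = expm(Q)
            T = transition_matrix(i, r, f, m)
            worst = max(worst, float(np.abs(P - T).max()))
        assert worst < 1e-12

    def test_mass_conserved_on_random_states(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            i, r, f, m = rng.uniform(0, 0.8, 4)
            S0, C0, D0 = rng.dirichlet([2, 1, 1])
            st = DiseaseState(S=np.array(S0), C=np.array(C0),
                              D_dis=np.array(D0), D_other=np.array(0.0))
            out = step_disease(st, (i, r, f, m))
            assert float(out.total()) == pytest.approx(1.0, abs=1e-10)
            for v in (out.S, out.C, out.D_dis, out.D_other):
                assert float(v) >= -1e-12

    def test_degenerate_repeated_eigenvalue(self):
        # r = 0 and i = f makes the alive subsystem defective
        st = step_disease(DiseaseState.healthy(), (0.2, 0.0, 0.2, 0.05))
        assert float(st.total()) == pytest.approx(1.0, abs=1e-12)
        euler = _euler_reference(0.2, 0.0, 0.2, 0.05)
        np.testing.assert_allclose(
            [float(st.S), float(st.C), float(st.D_dis), float(st.D_other)],
            euler, atol=1e-5)


def _euler_reference(i, r, f, m, n=4096):
    dt = 1.0 / n
    S, C, Dd, Do = 1.0, 0.0, 0.0, 0.0
    for _ in range(n):
        dS = -(i + m) * S + r * C
        dC = i * S - (r + f + m) * C
        dDd = f * C
        dDo = m * (S + C)
        S, C, Dd, Do = S + dt * dS, C + dt * dC, Dd + dt * dDd, Do + dt * dDo
    return [S, C, Dd, Do]


class TestRunDisease:
    def test_zero_incidence_everywhere(self):
        n = 30
        out = run_disease(np.zeros(n), np.zeros(n), np.full(n, 0.1),
                          np.full(n, 0.02), disability_weight=0.1,
                          cost_per_case=1000.0, alive_population=np.ones(n))
        assert np.all(out["prevalence"] == 0)
        assert np.all(out["m_dis"] == 0)
        assert np.all(out["cost"] == 0)

    def test_prevalence_matches_step_composition(self):
        """Constant hazards for 10 years equal 10 composed annual steps."""
        i, f = 0.02, 0.05
        out = run_disease(np.full(10, i), np.zeros(10), np.full(10, f), np.zeros(10))
        st = DiseaseState.healthy()
        for _ in range(10):
            st = step_disease(st, (i, 0.0, f, 0.0))
        alive = float(st.S + st.C)
        assert out["prevalence_end"][-1] == pytest.approx(float(st.C) / alive, abs=1e-12)

    def test_lower_incidence_gives_lower_prevalence(self):
        n = 40
        rng = np.random.default_rng(5)
        inc = rng.uniform(0.001, 0.01, n)
        base = run_disease(inc, np.zeros(n), np.full(n, 0.03), np.full(n, 0.01))
        cut = run_disease(0.7 * inc, np.zeros(n), np.full(n, 0.03), np.full(n, 0.01))
        assert np.all(cut["prevalence"][1:] < base["prevalence"][1:])

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputValidationError):
            run_disease(np.zeros(5), np.zeros(4), np.zeros(5), np.zeros(5))
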