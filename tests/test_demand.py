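import numpy as np
import pandas as pd
import pydantic
import pytest

from ssbtax.config import TaxScenario
from ssbtax.demand import (demand_response, energy_change, price_change,
                           price_change_vector, tax_to_demand_shift)
from ssbtax.errors import InputValidationError
from ssbtax.synthetic import ElasticityMatrix


def _matrix(values, n=None, shares=None):
    values = np.asarray(values, dtype=float)
    n = n or values.shape[0]
    cats = tuple(f"c{i}" for i in range(n))
    cats = ("ssb",) + cats[1:]
    shares = shares if shares is not None else np.r_[0.0, np.full(n - 1, 1.0 / (n - 1))]
    return ElasticityMatrix(cats, values, np.ones(n), np.asarray(shares, float))


class TestPriceChange:
    @pytest.mark.parametrize("tax,pt,price,expected", [
        (0.015, 1.0, 0.10, 15.0),
        (0.01, 1.0, 0.10, 10.0),
        (0.02, 1.0, 0.10, 20.0),
        (0.5, 0.0, 0.10, 0.0),
        (0.015, 0.8, 0.10, 12.0),
    ])
    def test_examples(self, tax, pt, price, expected):
        sc = TaxScenario(tax_per_oz=tax, pass_through=pt, baseline_price_per_oz=price)
        assert price_change(sc) == pytest.approx(expected)

    def test_nonpositive_baseline_price_rejected(self):
        with pytest.raises(pydantic.ValidationError):
            TaxScenario(baseline_price_per_oz=0.0)

    def test_doubling_tax_doubles_price_change(self):
        a = price_change(TaxScenario(tax_per_oz=0.01))
        b = price_change(TaxScenario(tax_per_oz=0.02))
        assert b == pytest.approx(2 * a)


class TestDemandResponse:
    def test_headline_17pct_consumption_fall(self):
        e = _matrix([[-1.15, 0.0], [0.0, -0.5]])
        d = demand_response(np.array([15.0, 0.0]), e)
        assert d[0] == pytest.approx(-17.25)
        assert round(d[0]) == -17

    def test_null_elasticity(self):
        e = _matrix([[-1.15, 0.0], [0.0, -0.5]])
        e.values[:] = 0.0  # zero out after construction-time validation
        d = demand_response(np.array([10.0, 5.0]), e)
        assert np.all(d == 0)

    def test_hand_matrix_vector_product(self):
        e = _matrix([[-1.0, 0.5], [0.2, -0.8]])
        d = demand_response(np.array([10.0, 0.0]), e)
        np.testing.assert_allclose(d, [-10.0, 2.0])

    def test_category_mismatch_rejected(self):
        e = _matrix([[-1.0, 0.5], [0.2, -0.8]])
        with pytest.raises(InputValidationError, match="categories"):
            demand_response(np.array([10.0, 0.0, 0.0]), e)

    def test_homogeneous_degree_one(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 0.5, (3, 3))
        vals[0, 0] = -1.15
        e = _matrix(vals)
        p = rng.uniform(0, 20, 3)
        np.testing.assert_allclose(demand_response(3.0 * p, e),
                                   3.0 * demand_response(p, e), rtol=1e-12)


def _baseline(ssb=120.0, tei=2000.0):
    return pd.DataFrame({
        "age": [30], "sex": ["female"],
        "ssb_kcal_mean": [ssb], "tei_kcal_mean": [tei],
        "ssb_volume_mean": [ssb / 10.0],
    })


class TestEnergyChange:
    def test_zero_demand_changes(self):
        e = _matrix([[-1.15, 0.0], [0.0, -0.5]])
        shift = energy_change(np.zeros(2), _baseline(), e)
        assert (shift.strata["delta_tei_kcal"] == 0).all()
        assert (shift.strata["delta_ssb_kcal"] == 0).all()

    def test_no_substitution_means_tei_equals_ssb(self):
        e = _matrix([[-1.15, 0.0], [0.0, -0.5]])
        shift = energy_change(np.array([-17.25, 0.0]), _baseline(), e)
        s = shift.strata
        np.testing.assert_array_equal(s["delta_tei_kcal"], s["delta_ssb_kcal"])

    def test_hand_arithmetic_with_substitute(self):
        # SSB 120 kcal at -17.25% -> -20.7; substitute +2% on 200 kcal -> +4.0
        e = _matrix([[-1.15, 0.0], [0.1333, -0.5]],
                    shares=np.array([0.0, 1.0]))
        base = _baseline(ssb=120.0, tei=320.0)  # non-SSB kcal = 200
        shift = energy_change(np.array([-17.25, 2.0]), base, e)
        assert shift.strata["delta_ssb_kcal"][0] == pytest.approx(-20.7)
        assert shift.strata["delta_tei_kcal"][0] == pytest.approx(-20.7 + 4.0)

    def test_missing_stratum_columns_rejected(self):
        e = _matrix([[-1.15, 0.0], [0.0, -0.5]])
        with pytest.raises(InputValidationError, match="missing"):
            energy_change(np.zeros(2), _baseline().drop(columns=["tei_kcal_mean"]), e)

    def test_demand_clamped_at_minus_100pct(self):
        e = _matrix([[-1.15, 0.0], [0.0, -0.5]])
        shift = energy_change(np.array([-250.0, 0.0]), _baseline(), e)
        assert shift.strata["post_ssb_kcal"][0] == 0.0
        assert shift.strata["post_ssb_volume"][0] == 0.0


class TestFullChain:
    def test_substitution_only_dampens(self, bundle):
        """With nonnegative cross terms, |dTEI| <= |dSSB| in every stratum."""
        from ssbtax.synthetic import interpolate_to_single_year
        cols = ["ssb_kcal_mean", "tei_kcal_mean", "ssb_volume_mean", "ssb_volume_sd"]
        parts = []
        for sex in ("female", "male"):
            sub = bundle.consumption[bundle.consumption["sex"] == sex]
            parts.append(interpolate_to_single_year(sub, cols).assign(sex=sex))
        base = pd.concat(parts, ignore_index=True)
        e = bundle.elasticities["nz"]
        assert np.all(e.values[1:, 0] >= 0)
        shift = tax_to_demand_shift(TaxScenario(), base, e)
        s = shift.strata
        assert (s["delta_tei_kcal"].abs() <= s["delta_ssb_kcal"].abs() + 1e-12).all()
        assert (s["delta_tei_kcal"] < 0).all()

    def test_doubling_tax_doubles_demand_change(self, bundle):
        from ssbtax.demand import price_change_vector
        e = bundle.elasticities["nz"]
        d1 = demand_response(price_change_vector(TaxScenario(tax_per_oz=0.01), 6), e)
        d2 = demand_response(price_change_vector(TaxScenario(tax_per_oz=0.02), 6), e)
        np.testing.assert_allclose(d2, 2 * d1, rtol=1e-12)
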