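import numpy as np
import pandas as pd
import pydantic
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssbtax.config import SyntheticConfig
from ssbtax.errors import InputValidationError
from ssbtax.synthetic import (InputBundle, generate_inputs,
                              interpolate_to_single_year)
from ssbtax.validate import validate_bundle


class TestGeneration:
    def test_fixed_seed_is_bit_identical(self):
        a = generate_inputs(SyntheticConfig(seed=42))
        b = generate_inputs(SyntheticConfig(seed=42))
        assert a.checksum() == b.checksum()
        pd.testing.assert_frame_equal(a.hazards, b.hazards)

    def test_different_seeds_differ(self):
        a = generate_inputs(SyntheticConfig(seed=1))
        b = generate_inputs(SyntheticConfig(seed=2))
        assert a.checksum() != b.checksum()

    def test_manifest_echoes_own_price_elasticity(self):
        b = generate_inputs(SyntheticConfig(seed=0, n_diseases=1))
        assert b.manifest["ssb_own_price_elasticity"] == -1.15
        assert b.elasticities["nz"].values[0, 0] == -1.15
        assert b.elasticities["us"].values[0, 0] == -1.04

    def test_zero_trend_config_gives_constant_bmi(self):
        b = generate_inputs(SyntheticConfig(seed=0, zero_trend=True))
        assert (b.bmi["trend_slope"] == 0).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(pydantic.ValidationError):
            SyntheticConfig(n_food_categories=1)
        with pytest.raises(pydantic.ValidationError):
            SyntheticConfig(n_diseases=0)

    def test_generated_bundle_is_pristine(self, bundle):
        assert validate_bundle(bundle) == []

    def test_mortality_rises_beyond_age_60(self, bundle):
        for sex in ("female", "male"):
            m = bundle.population.query("sex == @sex and age >= 60") \
                .sort_values("age")["all_cause_mortality"].to_numpy()
            assert np.all(np.diff(m) >= 0)

    def test_direct_pathway_flags(self, bundle):
        d = bundle.diseases
        direct = set(d.loc[d["direct_ssb"], "name"])
        assert direct == {"type2_diabetes", "ischaemic_heart_disease"}
        assert (d.loc[~d["direct_ssb"], "rr_direct_per_serving"] == 1.0).all()

    def test_save_load_roundtrip(self, bundle, tmp_path):
        bundle.save(tmp_path / "inputs")
        loaded = InputBundle.load(tmp_path / "inputs")
        assert loaded.manifest["checksum"] == bundle.manifest["checksum"]
        np.testing.assert_allclose(loaded.elasticities["nz"].values,
                                   bundle.elasticities["nz"].values)
        pd.testing.assert_frame_equal(
            loaded.population, bundle.population, check_dtype=False)


def _bands(values, edges=None):
    if edges is None:
        lo = np.arange(20, 100, 10)
        hi = np.append(lo[1:] - 1, 100)
    else:
        lo, hi = edges
    return pd.DataFrame({"age_lo": lo, "age_hi": hi, "rate": values})


class TestInterpolation:
    def test_constant_rate_preserved(self):
        out = interpolate_to_single_year(_bands(np.full(8, 0.01)), "rate")
        np.testing.assert_allclose(out["rate"], 0.01)
        assert list(out["age"]) == list(range(20, 101))

    def test_two_bands_no_overshoot(self):
        bands = _bands([0.01, 0.03], edges=([20, 60], [59, 100]))
        out = interpolate_to_single_year(bands, "rate")
        assert out["rate"].between(0.01, 0.03).all()

    def test_linear_band_rates_reproduce_the_line(self):
        lo = np.arange(20, 100, 10)
        hi = np.append(lo[1:] - 1, 100)
        mid = (lo + hi) / 2
        line = 0.002 + 0.0004 * (mid - 20)
        out = interpolate_to_single_year(_bands(line), "rate")
        ages = out["age"].to_numpy(float)
        span = (ages >= mid[0]) & (ages <= mid[-1])
        expect = 0.002 + 0.0004 * (ages[span] - 20)
        np.testing.assert_allclose(out.loc[span, "rate"], expect, atol=1e-9)

    def test_band_means_reproduced(self):
        """Interior band means within 2%; end bands within 5% (their tails
        are held constant so rates never leave the input range)."""
        rng = np.random.default_rng(5)
        values = 0.005 * np.exp(0.25 * np.arange(8)) * rng.uniform(0.95, 1.05, 8)
        bands = _bands(values)
        out = interpolate_to_single_year(bands, "rate").set_index("age")["rate"]
        for k, row in bands.iterrows():
            got = out.loc[row["age_lo"]:row["age_hi"]].mean()
            tol = 0.02 if 0 < k < len(bands) - 1 else 0.05
            assert abs(got - row["rate"]) / row["rate"] < tol

    def test_gap_and_overlap_rejected(self):
        bad = pd.DataFrame({"age_lo": [20, 61], "age_hi": [59, 100], "rate": [1, 2]})
        with pytest.raises(InputValidationError, match="contiguous"):
            interpolate_to_single_year(bad, "rate")
        with pytest.raises(InputValidationError, match="cover"):
            interpolate_to_single_year(
                pd.DataFrame({"age_lo": [30], "age_hi": [100], "rate": [1]}), "rate")

    def test_negative_rates_rejected(self):
        with pytest.raises(InputValidationError, match="negative"):
            interpolate_to_single_year(_bands([0.01] * 7 + [-0.01]), "rate")

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=0.5), min_size=8, max_size=8))
    def test_shape_preservation_on_random_bands(self, values):
        out = interpolate_to_single_year(_bands(np.array(values)), "rate")
        r = out["rate"].to_numpy()
        assert np.all(r >= 0)
        assert r.min() >= min(values) - 1e-12
        assert r.max() <= max(values) + 1e-12
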