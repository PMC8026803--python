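"""Ground-truth dataset generation: truncation, shape, determinism."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import foragesim as fs
from foragesim.synthetic_data import InvalidParameterError


class TestTruncatedNormal:
    def test_all_draws_within_bounds(self):
        draws = fs.sample_truncated_normal(mean=0, sd=2, bound=2, n=1000, seed=0)
        assert draws.size == 1000
        assert np.all(draws >= -2) and np.all(draws <= 2)

    def test_degenerate_sd_limit_collapses_to_mean(self):
        draws = fs.sample_truncated_normal(mean=5, sd=1e-12, bound=1, n=100, seed=0)
        assert np.allclose(draws, 5.0)

    def test_moments_match_inverse_cdf_oracle(self):
        # scipy's truncnorm provides the closed-form moments of the target law
        mean, sd, bound, n = 5.0, 0.5, 1.0, 100_000
        draws = fs.sample_truncated_normal(mean, sd, bound, n, seed=42)
        dist = stats.truncnorm(-bound / sd, bound / sd, loc=mean, scale=sd)
        se = dist.std() / np.sqrt(n)
        assert abs(draws.mean() - dist.mean()) < 3 * se
        assert draws.min() >= 4.0 and draws.max() <= 6.0

    @pytest.mark.parametrize(
        "kwargs",
        [dict(sd=0), dict(sd=-1), dict(bound=0), dict(bound=-2), dict(n=0)],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        args = dict(mean=0, sd=1, bound=1, n=10, seed=0) | kwargs
        with pytest.raises(InvalidParameterError):
            fs.sample_truncated_normal(**args)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_draws_respect_bounds_for_any_seed(self, seed):
        draws = fs.sample_truncated_normal(mean=3, sd=0.5, bound=1, n=50, seed=seed)
        assert np.all(np.abs(draws - 3) <= 1)


class TestGradientModel:
    def test_given_curve_constant_at_plateau(self, given_model):
        m = np.linspace(given_model.b_true, 6, 50)
        assert np.allclose(given_model.mean_strength_of_moisture(m), given_model.a_true)

    def test_given_curve_nondecreasing(self, given_model):
        m = np.linspace(0, 6, 500)
        s = given_model.mean_strength_of_moisture(m)
        assert np.all(np.diff(s) >= -1e-12)

    def test_alternative_dips_then_levels(self, alt_model):
        plateau = alt_model.a_true - alt_model.dip_depth
        past = alt_model.b_true + alt_model.dip_width
        m = np.linspace(past, 6, 20)
        assert np.allclose(alt_model.mean_strength_of_moisture(m), plateau)
        at_b = alt_model.mean_strength_of_moisture(alt_model.b_true)
        assert at_b == pytest.approx(alt_model.a_true)

    def test_zero_dip_reduces_alternative_to_given(self, given_model):
        alt0 = fs.build_gradient_model("alternative", dip_depth=0.0)
        m = np.linspace(0, 6, 200)
        assert np.allclose(
            alt0.mean_strength_of_moisture(m),
            given_model.mean_strength_of_moisture(m),
        )

    def test_zero_slope_flattens_rise_at_crest_value(self):
        model = fs.build_gradient_model("given", k_true=0.0)
        m = np.linspace(0, 2.9, 30)
        assert np.allclose(model.mean_strength_of_moisture(m), 0.0)

    def test_linear_rise_variant_is_exactly_kx(self):
        model = fs.build_gradient_model("given", rise_power=1.0)
        m = np.linspace(0, 2.9, 30)
        assert np.allclose(model.mean_strength_of_moisture(m), model.k_true * m)

    def test_moisture_map_monotone_dry_crest_to_wet_interdune(self, given_model, grid):
        m = given_model.moisture_of_location(grid, np.arange(1, 23))
        assert m[0] == pytest.approx(given_model.moisture_min)
        assert m[-1] == pytest.approx(given_model.moisture_max)
        assert np.all(np.diff(m) > 0)

    @pytest.mark.parametrize(
        "params",
        [
            dict(a_true=-1),
            dict(b_true=10),
            dict(rise_power=0),
            dict(dip_width=0),
        ],
    )
    def test_invalid_model_parameters_rejected(self, params):
        with pytest.raises(InvalidParameterError):
            fs.build_gradient_model("given", **params)

    def test_dip_deeper_than_plateau_rejected(self):
        with pytest.raises(InvalidParameterError):
            fs.build_gradient_model("alternative", dip_depth=11.0)


class TestGenerateDataset:
    def test_default_dataset_has_220_records(self, given_dataset):
        assert given_dataset.n_records == 220
        counts = given_dataset.records.groupby("location_index").size()
        assert (counts == 10).all() and len(counts) == 22

    def test_truncation_bounds_hold_for_every_record(self, given_model, noise, grid):
        for seed in (0, 7, 99):
            ds = fs.generate_dataset(given_model, noise, grid, seed=seed)
            for loc, sub in ds.records.groupby("location_index"):
                mean_m = float(given_model.moisture_of_location(grid, int(loc)))
                assert np.all(np.abs(sub["moisture"] - mean_m) <= noise.moisture_bound + 1e-9)
                centers = given_model.mean_strength_of_moisture(sub["moisture"].to_numpy())
                assert np.all(
                    np.abs(sub["strength"].to_numpy() - centers)
                    <= noise.strength_bound + 1e-9
                )

    def test_same_seed_identical_different_seed_differs(self, given_model):
        a = fs.generate_dataset(given_model, seed=7)
        b = fs.generate_dataset(given_model, seed=7)
        c = fs.generate_dataset(given_model, seed=8)
        assert a.records.equals(b.records)
        assert not a.records.equals(c.records)

    def test_zero_noise_limit_reproduces_mean_curve(self, given_model, grid):
        tiny = fs.NoiseModel(
            strength_sd=1e-12, strength_bound=1e-9,
            moisture_sd=1e-12, moisture_bound=1e-9,
        )
        ds = fs.generate_dataset(given_model, tiny, grid, seed=0)
        mean_m = given_model.moisture_of_location(
            grid, ds.records["location_index"].to_numpy()
        )
        assert np.allclose(ds.records["moisture"].to_numpy(), mean_m, atol=1e-6)
        expected = given_model.mean_strength_of_moisture(
            ds.records["moisture"].to_numpy()
        )
        assert np.allclose(ds.records["strength"].to_numpy(), expected, atol=1e-6)

    def test_per_location_means_follow_curve_shape(self, given_model, noise, grid):
        # per-location strength means are nondecreasing up to saturation
        # within the replicate-noise tolerance 2*sd/sqrt(10)
        tol = 2 * noise.strength_sd / np.sqrt(10)
        ds = fs.generate_dataset(given_model, noise, grid, seed=3)
        means = ds.records.groupby("location_index")["strength"].mean()
        mean_m = given_model.moisture_of_location(grid, means.index.to_numpy())
        pre = means.to_numpy()[mean_m < given_model.b_true]
        assert np.all(np.diff(pre) >= -tol)

    def test_alternative_plateau_sits_below_given_by_dip(self, alt_model, noise, grid):
        tol = 2 * noise.strength_sd / np.sqrt(10)
        ds = fs.generate_dataset(alt_model, noise, grid, seed=3)
        means = ds.records.groupby("location_index")["strength"].mean()
        mean_m = alt_model.moisture_of_location(grid, means.index.to_numpy())
        # locations fully past the dip (allowing for moisture-noise smoothing)
        past = mean_m > alt_model.b_true + alt_model.dip_width + noise.moisture_bound
        plateau = alt_model.a_true - alt_model.dip_depth
        assert np.all(np.abs(means.to_numpy()[past] - plateau) <= tol)

    def test_zero_dip_alternative_dataset_identical_to_given(self, given_model):
        alt0 = fs.build_gradient_model("alternative", dip_depth=0.0)
        a = fs.generate_dataset(given_model, seed=5)
        b = fs.generate_dataset(alt0, seed=5)
        assert np.allclose(a.records["strength"], b.records["strength"])
        assert np.allclose(a.records["moisture"], b.records["moisture"])

    def test_csv_round_trip_preserves_values(self, given_dataset):
        buf = io.StringIO()
        given_dataset.to_csv(buf)
        buf.seek(0)
        back = fs.GroundTruthDataset.from_csv(buf)
        assert back.hypothesis_id == given_dataset.hypothesis_id
        assert np.allclose(
            back.records["moisture"], given_dataset.records["moisture"], rtol=1e-11
        )
        assert np.allclose(
            back.records["strength"], given_dataset.records["strength"], rtol=1e-11
        )

    def test_uncoupled_mode_centers_on_location_mean_curve(self, given_model, noise, grid):
        ds = fs.generate_dataset(
            given_model, noise, grid, seed=2, couple_strength_to_noisy_moisture=False
        )
        for loc, sub in ds.records.groupby("location_index"):
            mean_m = float(given_model.moisture_of_location(grid, int(loc)))
            center = float(given_model.mean_strength_of_moisture(mean_m))
            assert np.all(
                np.abs(sub["strength"] - center) <= noise.strength_bound + 1e-9
            )
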