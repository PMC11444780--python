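import math

import numpy as np
import pandas as pd
import pytest

import splitcost as sc
from splitcost.errors import ConfigError, DataError, ParameterError
from splitcost.simgen import MASS_COL, TIMING_COL


class TestTimingDistribution:
    def test_quantiles_match_calibration(self, default_config):
        """Large-n draws hit the calibrated 10th/50th/90th percentiles
        (days 55/60/65) within a day."""
        t = sc.sample_timing(default_config.with_(n=100_000))
        q10, q50, q90 = np.quantile(t, [0.1, 0.5, 0.9])
        assert abs(q10 - 55) < 1.0
        assert abs(q50 - 60) < 1.0
        assert abs(q90 - 65) < 1.0

    def test_quartiles_and_tail(self, default_config):
        t = sc.sample_timing(default_config.with_(n=100_000))
        q25, q75 = np.quantile(t, [0.25, 0.75])
        assert abs(q25 - 57) < 1.0
        assert abs(q75 - 63) < 1.0
        assert t.max() > 72  # right-skewed tail of late breeders

    def test_n_zero_gives_empty(self, default_config):
        assert len(sc.sample_timing(default_config.with_(n=0))) == 0

    def test_same_seed_identical(self, default_config):
        a = sc.sample_timing(default_config)
        b = sc.sample_timing(default_config)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("field", ["timing_shape", "timing_scale", "mass_shape"])
    def test_nonpositive_parameters_rejected(self, field):
        with pytest.raises(ParameterError):
            sc.SimulationConfig(**{field: -1.0})


class TestExpectedMass:
    def test_anchor_day55_is_43kg(self, default_config):
        assert sc.expected_mass(55, default_config) == pytest.approx(43.0, abs=1e-9)

    def test_ten_day_delay_gives_37kg(self, default_config):
        assert sc.expected_mass(65, default_config) == pytest.approx(36.97, abs=0.01)

    def test_unit_multiplier_is_constant(self, default_config):
        cfg = default_config.with_(daily_multiplier=1.0)
        days = np.array([0.0, 55.0, 200.0])
        np.testing.assert_allclose(
            sc.expected_mass(days, cfg), math.exp(cfg.intercept_log)
        )

    def test_rejects_nonlinear_config(self, default_config):
        cfg = default_config.with_(nonlinear_curve=sc.default_nonlinear_curve)
        with pytest.raises(ConfigError):
            sc.expected_mass(55, cfg)


class TestGenerateDataset:
    def test_mean_mass_ratio_near_one(self, default_config):
        """Law of large numbers: mass / E[mass|t] averages to 1."""
        cfg = default_config.with_(n=50_000)
        data = sc.generate_dataset(cfg)
        ratio = data[MASS_COL] / sc.expected_mass(data[TIMING_COL].to_numpy(), cfg)
        assert 0.99 < ratio.mean() < 1.01

    def test_huge_shape_collapses_to_mean(self, default_config):
        cfg = default_config.with_(n=200, mass_shape=1e8)
        data = sc.generate_dataset(cfg)
        mu = sc.expected_mass(data[TIMING_COL].to_numpy(), cfg)
        np.testing.assert_allclose(data[MASS_COL], mu, atol=1e-3 * mu.mean())

    def test_deterministic_under_seed(self, default_config):
        a = sc.generate_dataset(default_config)
        b = sc.generate_dataset(default_config)
        pd.testing.assert_frame_equal(a, b)

    def test_mass_positive(self, default_data):
        assert (default_data[MASS_COL] > 0).all()

    def test_slope_recovery_on_log_scale(self, default_config):
        """OLS of log(mass) on day at n=100k recovers ln(0.985) to 5e-4."""
        data = sc.generate_dataset(default_config.with_(n=100_000))
        slope = np.polyfit(data[TIMING_COL], np.log(data[MASS_COL]), 1)[0]
        assert abs(slope - math.log(0.985)) < 5e-4

    def test_cv_constant_across_timing_deciles(self, default_config):
        """Fixed Gamma shape: CV of mass given timing does not drift with t."""
        cfg = default_config.with_(n=100_000)
        data = sc.generate_dataset(cfg)
        resid = data[MASS_COL] / sc.expected_mass(data[TIMING_COL].to_numpy(), cfg)
        decile = pd.qcut(data[TIMING_COL], 10, labels=False)
        cvs = resid.groupby(decile).std()
        expected_cv = 1.0 / math.sqrt(cfg.mass_shape)
        assert np.allclose(cvs, expected_cv, rtol=0.08)


class TestSubsample:
    def test_full_size_is_permutation(self, default_data):
        rng = np.random.default_rng(1)
        sub = sc.subsample_preserving_range(default_data, len(default_data), rng)
        a = sorted(map(tuple, sub.to_numpy().tolist()))
        b = sorted(map(tuple, default_data.to_numpy().tolist()))
        assert a == b

    def test_m2_keeps_extremes_only(self, default_data):
        rng = np.random.default_rng(1)
        sub = sc.subsample_preserving_range(default_data, 2, rng)
        assert set(sub[TIMING_COL]) == {
            default_data[TIMING_COL].min(),
            default_data[TIMING_COL].max(),
        }

    def test_range_preserved(self, default_data):
        rng = np.random.default_rng(2)
        sub = sc.subsample_preserving_range(default_data, 20, rng)
        assert len(sub) == 20
        assert sub[TIMING_COL].min() == default_data[TIMING_COL].min()
        assert sub[TIMING_COL].max() == default_data[TIMING_COL].max()

    @pytest.mark.parametrize("m", [1, 0, 121])
    def test_out_of_range_m_rejected(self, default_data, m):
        with pytest.raises(ParameterError):
            sc.subsample_preserving_range(default_data, m, np.random.default_rng(0))


class TestNonlinearGenerator:
    def test_requires_curve(self, default_config):
        with pytest.raises(ConfigError):
            sc.generate_nonlinear_dataset(default_config)

    def test_constant_curve_reduces_to_flat_linear(self, default_config):
        c = math.log(40.0)
        cfg = default_config.with_(nonlinear_curve=lambda t: np.full_like(t, c))
        flat = default_config.with_(daily_multiplier=1.0, intercept_log=c)
        a = sc.generate_nonlinear_dataset(cfg)
        b = sc.generate_dataset(flat)
        pd.testing.assert_frame_equal(a, b)

    def test_binned_means_track_curve(self, default_config):
        cfg = default_config.with_(n=60_000, nonlinear_curve=sc.default_nonlinear_curve)
        data = sc.generate_nonlinear_dataset(cfg)
        bins = pd.cut(data[TIMING_COL], np.arange(52, 72, 2))
        observed = data.groupby(bins, observed=True)[MASS_COL].mean()
        centers = np.array([iv.mid for iv in observed.index])
        expected = np.exp(sc.default_nonlinear_curve(centers))
        np.testing.assert_allclose(observed, expected, rtol=0.02)

    def test_deterministic(self, default_config):
        cfg = default_config.with_(nonlinear_curve=sc.default_nonlinear_curve)
        pd.testing.assert_frame_equal(
            sc.generate_nonlinear_dataset(cfg), sc.generate_nonlinear_dataset(cfg)
        )


class TestIO:
    def test_csv_round_trip(self, default_data, tmp_path):
        path = tmp_path / "data.csv"
        sc.write_dataset(default_data, path)
        assert path.read_text().splitlines()[0] == "timing_day,mass_kg"
        back = sc.read_dataset(path)
        pd.testing.assert_frame_equal(back, default_data)

    def test_read_rejects_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("timing_day,weight\n55,43\n")
        with pytest.raises(DataError):
            sc.read_dataset(path)

    def test_config_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("n: 7\nseed: 3\nmass_shape: 50\nnonlinear_curve: quadratic\n")
        cfg = sc.SimulationConfig.from_file(path)
        assert (cfg.n, cfg.seed, cfg.mass_shape) == (7, 3, 50)
        assert cfg.nonlinear_curve is sc.default_nonlinear_curve
        assert cfg.to_dict()["nonlinear_curve"] == "quadratic"

    def test_config_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("n: 7\nbogus_key: 1\n")
        with pytest.raises(ConfigError, match="bogus_key"):
            sc.SimulationConfig.from_file(path)
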