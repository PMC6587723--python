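"""Synthetic BOLD generator: components, masks, determinism, ground truth."""

import numpy as np
import pytest

from alffpipe import regression as reg
from alffpipe.simulate import (
    SimulationConfig,
    generate_band_limited_signal,
    generate_bias_field,
    generate_drift,
    generate_group,
    generate_subject,
    make_tissue_masks,
)
from alffpipe.spectral import Band, compute_spectrum, falff


class TestConfigValidation:
    def test_band_must_lie_below_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            SimulationConfig(tr_seconds=2.0, lff_band=(0.01, 0.3))

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="thermal_noise_sd"):
            SimulationConfig(thermal_noise_sd=-1.0)

    def test_short_run_rejected(self):
        with pytest.raises(ValueError, match="n_timepoints"):
            SimulationConfig(n_timepoints=8)

    def test_bias_range_must_be_positive(self):
        with pytest.raises(ValueError, match="bias"):
            SimulationConfig(bias_field_range=(0.0, 1.0))


class TestDrift:
    def test_constant_and_linear_cases(self):
        np.testing.assert_allclose(generate_drift(100, (5, 0, 0)), 5.0)
        linear = generate_drift(100, (0, 1, 0))
        assert linear[0] == pytest.approx(-1.0)
        assert linear[-1] == pytest.approx(1.0)
        assert np.all(np.diff(linear) > 0)

    def test_matches_pointwise_polynomial_oracle(self):
        n, coeffs = 128, (1.0, 2.0, 3.0)
        drift = generate_drift(n, coeffs)
        for i in [0, 1, 17, 63, 127]:
            t = -1.0 + 2.0 * i / (n - 1)
            expected = coeffs[0] + coeffs[1] * t + coeffs[2] * t * t
            assert drift[i] == pytest.approx(expected, rel=1e-12)

    def test_nonfinite_coefficients_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            generate_drift(64, (1.0, np.inf, 0.0))


class TestBandLimitedSignal:
    def test_spectrum_confined_to_band(self, rng):
        x = generate_band_limited_signal(200, 2.0, (0.01, 0.1), 1.0, rng)
        spec = compute_spectrum(x, 2.0)
        outside = spec.frequencies > 0.1
        assert spec.magnitudes[outside].max() < 1e-9 * spec.magnitudes.max()
        assert abs(x.mean()) < 1e-9

    def test_zero_amplitude_gives_zero_series(self, rng):
        x = generate_band_limited_signal(200, 2.0, (0.01, 0.1), 0.0, rng)
        np.testing.assert_array_equal(x, 0.0)

    def test_sample_sd_matches_request(self, rng):
        x = generate_band_limited_signal(256, 2.0, (0.01, 0.1), 2.5, rng)
        assert x.std() == pytest.approx(2.5, rel=1e-9)

    def test_narrow_band_concentration_gives_unit_falff(self, rng):
        x = generate_band_limited_signal(256, 2.0, (0.04, 0.06), 2.0, rng)
        spec = compute_spectrum(x, 2.0)
        assert falff(spec, Band(0.01, 0.1)) == pytest.approx(1.0, abs=1e-9)

    def test_empty_band_raises_named_error(self, rng):
        with pytest.raises(ValueError, match="bin spacing"):
            generate_band_limited_signal(16, 2.0, (0.011, 0.014), 1.0, rng)


class TestBiasField:
    def test_degenerate_range_gives_identity(self, rng):
        field = generate_bias_field((8, 8, 8), (1.0, 1.0), rng)
        np.testing.assert_array_equal(field, 1.0)

    def test_values_within_range_and_smooth(self, rng):
        field = generate_bias_field((16, 16, 16), (0.5, 2.0), rng)
        assert field.min() >= 0.5 and field.max() <= 2.0
        # smoothness: neighbour differences well below the full range
        assert np.abs(np.diff(field, axis=0)).max() < 0.5 * (2.0 - 0.5)

    def test_seed_determinism(self):
        a = generate_bias_field((8, 8, 8), (0.5, 2.0), np.random.default_rng(5))
        b = generate_bias_field((8, 8, 8), (0.5, 2.0), np.random.default_rng(5))
        c = generate_bias_field((8, 8, 8), (0.5, 2.0), np.random.default_rng(6))
        np.testing.assert_array_equal(a, b)
        assert not np.allclose(a, c)

    def test_nonpositive_minimum_rejected(self, rng):
        with pytest.raises(ValueError, match="positive"):
            generate_bias_field((8, 8, 8), (-0.1, 1.0), rng)


class TestTissueMasks:
    def test_disjoint_and_nonempty(self):
        masks = make_tissue_masks((18, 16, 10))
        for t, m in masks.items():
            assert m.any(), t
        assert not np.any(masks["gm"] & masks["wm"])
        assert not np.any(masks["gm"] & masks["csf"])
        assert not np.any(masks["wm"] & masks["csf"])

    def test_grey_matter_takes_largest_share(self):
        masks = make_tissue_masks((18, 16, 10))
        assert masks["gm"].sum() > masks["wm"].sum()
        assert masks["gm"].sum() > masks["csf"].sum()

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            make_tissue_masks((8, 8, 8))


class TestGenerateSubject:
    def test_all_noise_off_gives_constant_wm_voxels(self):
        config = SimulationConfig(
            n_subjects=2,
            thermal_noise_sd=0.0,
            motion_coupling=0.0,
            physio_coupling={"gm": 0.0, "wm": 0.0, "csf": 0.0},
            drift_coeff_sd=0.0,
            slow_drift_sd=0.0,
            bias_field_range=(1.0, 1.0),
        )
        import alffpipe.simulate as sim

        old = sim.TISSUE_NOISE_SD
        sim.TISSUE_NOISE_SD = 0.0
        try:
            ds = generate_subject(config, 0, 0)
        finally:
            sim.TISSUE_NOISE_SD = old
        wm_tcs = ds.bold[ds.masks["wm"]]
        assert np.max(np.abs(wm_tcs - wm_tcs[:, :1])) < 1e-9

    def test_no_gm_signal_when_amplitude_zero(self):
        config = SimulationConfig(n_subjects=2, gm_lff_sd=0.0)
        ds = generate_subject(config, 0, 0)
        assert np.all(ds.ground_truth.amplitude_map == 0.0)

    def test_variance_decomposition_against_ground_truth(self):
        """Regressing the true components out of a WM voxel leaves thermal noise."""
        config = SimulationConfig(n_subjects=2, n_timepoints=256, rng_seed=42)
        ds = generate_subject(config, 0, 0)
        truth = ds.ground_truth
        n = config.n_timepoints
        # motion_signal is omitted: it is a linear combination of the
        # realignment parameters, which are already in the design
        X = np.column_stack(
            [
                np.ones(n),
                truth.drift,
                truth.slow_drift,
                truth.physio,
                ds.realignment_params,
            ]
        )
        # the shared broadband WM fluctuation is part of the nuisance too:
        # approximate it by the WM spatial mean (noise averages out)
        wm = ds.masks["wm"]
        X = np.column_stack([X, ds.bold[wm].mean(axis=0)])
        ix = np.argwhere(wm)[7]
        y = ds.bold[tuple(ix)]
        resid = reg.regress_out(y, X)
        gain = ds.bias_field[tuple(ix)]
        expected = (gain * config.thermal_noise_sd) ** 2
        assert resid.var() == pytest.approx(expected, rel=0.15)

    def test_masks_and_rp_invariants(self, small_dataset):
        ds = small_dataset
        assert ds.realignment_params.shape == (ds.n_timepoints, 6)
        assert np.all(np.isfinite(ds.bold))
        assert np.all(ds.bias_field > 0)


class TestGenerateGroup:
    def test_group_layout_and_counts(self):
        config = SimulationConfig(n_subjects=3, n_sessions=2, rng_seed=7)
        group = generate_group(config)
        assert len(group) == 3
        assert all(len(sessions) == 2 for sessions in group.values())

    def test_bit_identical_under_fixed_seed(self):
        config = SimulationConfig(n_subjects=2, n_sessions=2, rng_seed=9)
        g1 = generate_group(config)
        g2 = generate_group(config)
        np.testing.assert_array_equal(g1[1][1].bold, g2[1][1].bold)
        g3 = generate_group(SimulationConfig(n_subjects=2, n_sessions=2, rng_seed=10))
        assert not np.allclose(g1[1][1].bold, g3[1][1].bold)

    def test_subject_characteristics_stable_across_sessions(self, small_group):
        for sessions in small_group.values():
            ds0, ds1 = sessions[0], sessions[1]
            np.testing.assert_array_equal(
                ds0.ground_truth.amplitude_map, ds1.ground_truth.amplitude_map
            )
            np.testing.assert_array_equal(ds0.bias_field, ds1.bias_field)
            np.testing.assert_array_equal(
                ds0.ground_truth.subject_drift_coeffs,
                ds1.ground_truth.subject_drift_coeffs,
            )
            assert not np.allclose(ds0.bold, ds1.bold)

    def test_fitted_drift_spread_matches_configuration(self):
        """Across-subject variance of fitted linear trends reflects drift_coeff_sd.

        Other slow components (motion walks, scanner wander, shared tissue
        noise) also project onto the linear basis, so they are switched off
        to isolate the drift moment.
        """
        import alffpipe.simulate as sim

        old = sim.TISSUE_NOISE_SD
        sim.TISSUE_NOISE_SD = 0.0
        try:
            config = SimulationConfig(
                n_subjects=20, rng_seed=5, motion_coupling=0.0, slow_drift_sd=0.0
            )
            group = generate_group(config)
        finally:
            sim.TISSUE_NOISE_SD = old
        fitted = []
        poly = reg.polynomial_block(config.n_timepoints).columns
        for sessions in group.values():
            ds = sessions[0]
            wm_mean = ds.bold[ds.masks["wm"]].mean(axis=0) / ds.bias_field[
                ds.masks["wm"]
            ].mean()
            beta = np.linalg.lstsq(poly, wm_mean, rcond=None)[0]
            fitted.append(beta[1])
        session_var = (config.drift_coeff_sd**2) * (1.0 + 0.1**2)
        assert np.var(fitted, ddof=1) == pytest.approx(session_var, rel=0.3)
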