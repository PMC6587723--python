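"""Nuisance regressors, orthogonalisation, removal, surrogates, CCA trends."""

import numpy as np
import pytest

from alffpipe import regression as reg
from alffpipe.spectral import Band, alff, compute_spectrum


def normal_equations_residual(y, X):
    """Literal normal-equations solve, the independent oracle."""
    beta = np.linalg.inv(X.T @ X) @ X.T @ y
    return y - X @ beta


class TestPolynomialBlock:
    def test_shape_and_rank(self):
        block = reg.polynomial_block(10)
        assert block.columns.shape == (10, 3)
        assert np.linalg.matrix_rank(block.columns) == 3

    def test_exactly_spans_quadratics(self):
        n = 50
        t = reg.normalised_time_axis(n)
        y = 4 + 3 * t + 2 * t**2
        resid = reg.regress_out(y, reg.build_design([reg.polynomial_block(n)]))
        assert np.max(np.abs(resid)) < 1e-9

    def test_small_alff_change_for_in_band_sinusoid(self):
        # even-symmetric tone: nearly orthogonal to the odd linear trend,
        # so detrending leakage into the band stays small (an odd tone
        # projects onto the linear trend and distorts the band far more)
        n, tr = 256, 2.0
        band = Band(0.01, 0.1)
        t = np.arange(n)
        x = np.cos(2 * np.pi * 16 * t / n)  # 0.03125 Hz, well inside the band
        resid = reg.regress_out(x, reg.build_design([reg.polynomial_block(n)]))
        a0 = alff(compute_spectrum(x, tr), band)
        a1 = alff(compute_spectrum(resid, tr), band)
        assert abs(a1 - a0) / a0 < 0.05


class TestTissueExtraction:
    def test_degenerate_threshold_includes_everything(self, rng):
        bold = rng.normal(size=(4, 4, 4, 16))
        prob = rng.uniform(size=(4, 4, 4))
        ext = reg.extract_tissue_timecourses(bold, prob, threshold=0.0, erosion_voxels=0)
        assert ext.timecourses.shape == (16, 64)

    def test_erosion_keeps_only_centre_of_cube(self, rng):
        bold = rng.normal(size=(5, 5, 5, 8))
        prob = np.zeros((5, 5, 5))
        prob[1:4, 1:4, 1:4] = 1.0
        ext = reg.extract_tissue_timecourses(bold, prob, threshold=0.5, erosion_voxels=1)
        assert ext.mask.sum() == 1
        assert ext.mask[2, 2, 2]
        np.testing.assert_array_equal(ext.timecourses[:, 0], bold[2, 2, 2])

    def test_empty_mask_reports_parameters(self, rng):
        bold = rng.normal(size=(4, 4, 4, 8))
        with pytest.raises(ValueError, match="threshold=0.99"):
            reg.extract_tissue_timecourses(
                bold, np.full((4, 4, 4), 0.5), threshold=0.99
            )


class TestPcaBlock:
    def test_rank_one_recovery(self, rng):
        n, v = 100, 40
        shared = np.sin(np.linspace(0, 6 * np.pi, n))
        tcs = np.outer(shared, rng.uniform(0.5, 2.0, v)) + rng.normal(0, 0.01, (n, v))
        block = reg.pca_block(tcs, name="wm")
        pc1 = block.columns[:, 1]
        assert abs(np.corrcoef(pc1, shared)[0, 1]) > 0.99

    def test_components_orthogonal_and_variance_ordered(self, rng):
        tcs = rng.normal(size=(60, 30))
        block = reg.pca_block(tcs, name="csf")
        pcs = block.columns[:, 1:]
        gram = pcs.T @ pcs
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-9
        variances = np.diag(gram)
        assert np.all(np.diff(variances) <= 1e-9)

    def test_too_few_voxels_rejected(self, rng):
        with pytest.raises(ValueError, match="at least"):
            reg.pca_block(rng.normal(size=(60, 4)), name="wm")


class TestRpBlock:
    def test_pass_through(self, rng):
        rp = rng.normal(size=(100, 6))
        block = reg.rp_block(rp)
        np.testing.assert_array_equal(block.columns, rp)

    def test_wrong_column_count_rejected(self, rng):
        with pytest.raises(ValueError, match="6 columns"):
            reg.rp_block(rng.normal(size=(100, 5)))


class TestOrthogonalise:
    def test_gram_schmidt_oracle(self, rng):
        n = 80
        poly = reg.polynomial_block(n)
        t = reg.normalised_time_axis(n)
        sinusoid = np.sin(2 * np.pi * 8 * np.arange(n) / n)
        column = 2.0 * t + sinusoid
        block = reg.RegressorBlock("rp", np.tile(column[:, None], (1, 6)))
        out = reg.orthogonalise([block], poly)[0]
        # explicit Gram-Schmidt against the polynomial basis
        expected = column.copy()
        basis = []
        for p in poly.columns.T:
            q = p.copy()
            for b in basis:
                q = q - (q @ b) * b
            q /= np.linalg.norm(q)
            basis.append(q)
        for b in basis:
            expected = expected - (expected @ b) * b
        np.testing.assert_allclose(out.columns[:, 0], expected, atol=1e-9)
        for p in poly.columns.T:
            assert abs(out.columns[:, 0] @ p) < 1e-9

    def test_already_orthogonal_column_unchanged(self):
        n = 64
        poly = reg.polynomial_block(n)
        x = np.sin(2 * np.pi * 7 * np.arange(n) / n)
        x -= poly.columns @ np.linalg.lstsq(poly.columns, x, rcond=None)[0]
        block = reg.RegressorBlock("wm", np.column_stack([x] * 6))
        out = reg.orthogonalise([block], poly)[0]
        np.testing.assert_allclose(out.columns[:, 0], x, atol=1e-9)

    def test_polynomial_column_dropped_with_warning(self):
        n = 32
        poly = reg.polynomial_block(n)
        t = reg.normalised_time_axis(n)
        good = np.sin(2 * np.pi * 5 * np.arange(n) / n)
        block = reg.RegressorBlock("csf", np.column_stack([t**2, good]))
        with pytest.warns(UserWarning, match="polynomial trend span"):
            out = reg.orthogonalise([block], poly)[0]
        assert out.columns.shape[1] == 1

    def test_detr_and_exploratory_blocks_pass_through(self, rng):
        n = 64
        poly = reg.polynomial_block(n)
        expl = reg.RegressorBlock("expl", rng.normal(size=(n, 4)))
        out = reg.orthogonalise([poly, expl], poly)
        np.testing.assert_array_equal(out[0].columns, poly.columns)
        np.testing.assert_array_equal(out[1].columns, expl.columns)


class TestRegressOut:
    def test_matches_normal_equations(self, rng):
        y = rng.normal(size=50)
        X = rng.normal(size=(50, 4))
        resid = reg.regress_out(y, X)
        np.testing.assert_allclose(resid, normal_equations_residual(y, X), atol=1e-9)

    def test_exact_span_and_fixed_point(self, rng):
        X = rng.normal(size=(40, 3))
        y_in = X @ rng.normal(size=3)
        assert np.max(np.abs(reg.regress_out(y_in, X))) < 1e-9
        y_orth = rng.normal(size=40)
        y_orth -= X @ np.linalg.lstsq(X, y_orth, rcond=None)[0]
        np.testing.assert_allclose(reg.regress_out(y_orth, X), y_orth, atol=1e-9)

    def test_idempotent_and_linear_projection(self, rng):
        X = rng.normal(size=(60, 5))
        y1, y2 = rng.normal(size=60), rng.normal(size=60)
        r1 = reg.regress_out(y1, X)
        np.testing.assert_allclose(reg.regress_out(r1, X), r1, atol=1e-9)
        combo = reg.regress_out(2.0 * y1 - 3.0 * y2, X)
        np.testing.assert_allclose(
            combo, 2.0 * reg.regress_out(y1, X) - 3.0 * reg.regress_out(y2, X),
            atol=1e-9,
        )

    def test_residuals_orthogonal_to_design(self, rng):
        X = rng.normal(size=(80, 6))
        Y = rng.normal(size=(80, 10))
        resid = reg.regress_out(Y, X)
        assert np.max(np.abs(X.T @ resid)) < 1e-8 * np.abs(Y).max() * 80

    def test_rank_deficient_design_names_columns(self, rng):
        X = rng.normal(size=(30, 3))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])
        design = reg.DesignMatrix(X, ["a", "b", "c", "dup"])
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            reg.regress_out(rng.normal(size=30), design)


class TestFourierDomainRegression:
    def test_constant_design_zeroes_dc_only(self, rng):
        n = 32
        U = reg.unitary_dft_matrix(n)
        y = rng.normal(size=n)
        Y = U @ y
        Xf = U @ np.ones((n, 1))
        resid = reg.regress_fourier(Y, Xf)
        assert abs(resid[0]) < 1e-9
        np.testing.assert_allclose(resid[1:], Y[1:], atol=1e-9)

    def test_cross_domain_equivalence(self, rng):
        n, p = 32, 3
        U = reg.unitary_dft_matrix(n)
        y = rng.normal(size=n)
        X = rng.normal(size=(n, p))
        resid_time = reg.regress_out(y, X)
        resid_fourier = reg.regress_fourier(U @ y, U @ X)
        back = U.conj().T @ resid_fourier
        assert np.max(np.abs(back.imag)) < 1e-9
        np.testing.assert_allclose(back.real, resid_time, atol=1e-9)

    def test_linear_trend_mixes_frequencies(self):
        n = 64
        U = reg.unitary_dft_matrix(n)
        t = reg.normalised_time_axis(n)
        y = np.sin(2 * np.pi * 4 * np.arange(n) / n) + 0.5 * t
        Y = U @ y
        resid = reg.regress_fourier(Y, U @ np.column_stack([np.ones(n), t]))
        changed = np.abs(np.abs(resid) - np.abs(Y)) > 1e-9
        assert changed.sum() > 2  # cross-frequency mixing beyond the trend bins


class TestPhaseRandomise:
    def _blocks(self, rng, n=64):
        return [
            reg.RegressorBlock("wm", rng.normal(size=(n, 3))),
            reg.RegressorBlock("rp", rng.normal(size=(n, 6))),
        ]

    def test_shapes_and_repetition_count(self, rng):
        sets = reg.phase_randomise(self._blocks(rng), rng, n_repetitions=25)
        assert len(sets) == 25
        assert all(s[0].columns.shape == (64, 3) for s in sets)

    def test_amplitude_spectra_preserved(self, rng):
        blocks = self._blocks(rng)
        surr = reg.phase_randomise(blocks, rng, n_repetitions=3)
        for rep in surr:
            for orig, s in zip(blocks, rep):
                np.testing.assert_allclose(
                    np.abs(np.fft.rfft(s.columns, axis=0)),
                    np.abs(np.fft.rfft(orig.columns, axis=0)),
                    atol=1e-9,
                )

    def test_correlation_matrix_preserved(self, rng):
        cols = rng.normal(size=(128, 4))
        cols[:, 1] += 0.5 * cols[:, 0]  # induce correlation structure
        blocks = [reg.RegressorBlock("wm", cols)]
        surr = reg.phase_randomise(blocks, rng, n_repetitions=5)
        orig_corr = np.corrcoef(cols.T)
        for rep in surr:
            np.testing.assert_allclose(
                np.corrcoef(rep[0].columns.T), orig_corr, atol=1e-6
            )

    def test_surrogates_are_real_and_differ_from_original(self, rng):
        blocks = self._blocks(rng)
        rep = reg.phase_randomise(blocks, rng, n_repetitions=1)[0]
        assert np.isrealobj(rep[0].columns)
        assert not np.allclose(rep[0].columns, blocks[0].columns)


class TestExploratoryTrends:
    def test_recovers_shared_slow_drift(self):
        rng = np.random.default_rng(3)
        n, v = 200, 100
        t = reg.normalised_time_axis(n)
        drift = 1.0 + 0.8 * t + 0.6 * t**2
        gains = rng.uniform(0.5, 1.5, v)
        tcs = np.outer(drift, gains) + rng.normal(0, 0.5, (n, v))
        block = reg.exploratory_trends(tcs, n_trends=4)
        assert block.columns.shape == (n, 4)
        r = abs(np.corrcoef(block.columns[:, 0], drift)[0, 1])
        assert r > 0.9

    def test_white_noise_gives_low_autocorrelation(self):
        rng = np.random.default_rng(4)
        tcs = rng.normal(size=(400, 120))
        block = reg.exploratory_trends(tcs, n_trends=4)
        top = block.columns[:, 0]
        ac = abs(np.corrcoef(top[:-1], top[1:])[0, 1])
        assert ac < 0.5

    def test_trends_ranked_by_lag_one_autocorrelation(self, rng):
        tcs = rng.normal(size=(200, 80))
        tcs[:, :40] += np.cumsum(rng.normal(size=200))[:, None] * 0.2
        block = reg.exploratory_trends(tcs, n_trends=4)
        acs = [
            abs(np.corrcoef(block.columns[:-1, j], block.columns[1:, j])[0, 1])
            for j in range(4)
        ]
        assert acs == sorted(acs, reverse=True)

    def test_insufficient_dimensionality_rejected(self, rng):
        with pytest.raises(ValueError, match="n_trends"):
            reg.exploratory_trends(rng.normal(size=(40, 30)), n_trends=4)
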