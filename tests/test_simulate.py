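import numpy as np
import pytest

from fimsquant.simulate import (
    CalibrationDesign,
    MatrixParams,
    NoiseParams,
    generate_blank_spectrum,
    generate_blanks,
    generate_calibration_spectra,
    generate_fingerprint,
    generate_spiked_samples,
)
from fimsquant.spectra import MATRIX_FREE, MATRIX_MATCHED

SIX = (2.0, 20.0, 50.0, 100.0, 200.0, 400.0)


class TestFingerprint:
    @pytest.mark.parametrize("analyte, n", [("C", 9), ("G", 7)])
    def test_channel_count_and_bounds(self, analyte, n):
        fp = generate_fingerprint(analyte, n, seed=1)
        assert fp.n_principal == n
        assert np.all((fp.mz >= 100.0) & (fp.mz <= 700.0))
        assert len(np.unique(fp.mz)) == n
        assert all(c.response_slope > 0 for c in fp.principal_channels)

    def test_deterministic_for_fixed_seed(self):
        a = generate_fingerprint("C", 9, seed=1)
        b = generate_fingerprint("C", 9, seed=1)
        assert a == b
        assert a != generate_fingerprint("C", 9, seed=2)

    def test_disjoint_across_analytes_via_exclusion(self):
        a = generate_fingerprint("C", 9, seed=1)
        b = generate_fingerprint("G", 7, seed=1, exclude_mz=tuple(a.mz))
        assert not set(a.mz) & set(b.mz)

    def test_impossible_design_raises(self, small_grid):
        with pytest.raises(ValueError, match="impossible design"):
            generate_fingerprint("C", 50, seed=1, grid=small_grid)


class TestCalibrationSpectra:
    def test_inventory_is_design_product(self, two_channel_fingerprint):
        design = CalibrationDesign(levels=SIX, n_replicates=5, n_sets=3)
        spectra = generate_calibration_spectra(
            design, [two_channel_fingerprint], NoiseParams(background_channel_count=10),
            MatrixParams.identity(SIX), seed=0,
        )
        assert len(spectra) == design.n_spectra == 180

    def test_single_cell_design(self, two_channel_fingerprint):
        design = CalibrationDesign(levels=(50.0,), n_replicates=1, n_sets=1,
                                   matrix_conditions=(MATRIX_FREE,))
        spectra = generate_calibration_spectra(
            design, [two_channel_fingerprint], NoiseParams(),
            MatrixParams.identity((50.0,)), seed=0,
        )
        assert len(spectra) == 1

    def test_noise_free_intensity_is_exactly_affine(self, two_channel_fingerprint):
        design = CalibrationDesign(levels=SIX, n_replicates=2, n_sets=1,
                                   matrix_conditions=(MATRIX_FREE,))
        noise0 = NoiseParams(replicate_cv=0.0, baseline_mean=0.0, baseline_sd=0.0,
                             background_channel_count=0)
        spectra = generate_calibration_spectra(
            design, [two_channel_fingerprint], noise0, MatrixParams.identity(SIX), seed=0,
        )
        grid = spectra[0].channel_mz
        for s in spectra:
            for ch in two_channel_fingerprint.principal_channels:
                idx = np.searchsorted(grid, ch.mz)
                expected = ch.response_intercept + ch.response_slope * s.concentration
                assert s.intensity[idx] == pytest.approx(expected, rel=1e-12)

    def test_matrix_factor_scales_matched_condition_only(self, two_channel_fingerprint):
        design = CalibrationDesign(levels=(50.0, 100.0, 200.0, 400.0, 20.0, 2.0),
                                   n_replicates=1, n_sets=1)
        noise0 = NoiseParams(replicate_cv=0.0, baseline_mean=0.0, baseline_sd=0.0,
                             background_channel_count=0)
        factors = {2.0: 1.0, 20.0: 1.0, 50.0: 0.95, 100.0: 1.0, 200.0: 1.0, 400.0: 1.0}
        spectra = generate_calibration_spectra(
            design, [two_channel_fingerprint], noise0, MatrixParams(factors), seed=0,
        )
        grid = spectra[0].channel_mz
        idx = np.searchsorted(grid, two_channel_fingerprint.mz)
        free = {s.concentration: s.intensity[idx] for s in spectra
                if s.matrix_condition == MATRIX_FREE}
        matched = {s.concentration: s.intensity[idx] for s in spectra
                   if s.matrix_condition == MATRIX_MATCHED}
        np.testing.assert_allclose(matched[50.0], 0.95 * free[50.0])
        np.testing.assert_allclose(matched[100.0], free[100.0])

    def test_unknown_matrix_level_error_names_level(self, two_channel_fingerprint):
        design = CalibrationDesign(levels=SIX, n_replicates=1, n_sets=1)
        with pytest.raises(ValueError, match="400"):
            generate_calibration_spectra(
                design, [two_channel_fingerprint], NoiseParams(),
                MatrixParams({l: 1.0 for l in SIX[:-1]}), seed=0,
            )

    def test_metadata_complete_and_deterministic(self, two_channel_fingerprint):
        design = CalibrationDesign(levels=SIX, n_replicates=2, n_sets=2)
        kwargs = dict(
            design=design, fingerprints=[two_channel_fingerprint],
            noise=NoiseParams(background_channel_count=10),
            matrix=MatrixParams.identity(SIX), seed=5,
        )
        a = generate_calibration_spectra(**kwargs)
        b = generate_calibration_spectra(**kwargs)
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1.intensity, s2.intensity)
            assert s1.spectrum_id == s2.spectrum_id
            assert s1.concentration in SIX
            assert s1.matrix_condition in (MATRIX_FREE, MATRIX_MATCHED)
            assert s1.set_id is not None and s1.replicate_id is not None

    def test_background_correlation_centered_at_zero(self, two_channel_fingerprint):
        """Background channels have no mean association with concentration."""
        design = CalibrationDesign(levels=SIX, n_replicates=5, n_sets=1,
                                   matrix_conditions=(MATRIX_FREE,))
        rs = []
        for seed in range(8):
            spectra = generate_calibration_spectra(
                design, [two_channel_fingerprint],
                NoiseParams(background_channel_count=50),
                MatrixParams.identity(SIX), seed=seed,
            )
            conc = np.array([s.concentration for s in spectra])
            raw = np.vstack([s.intensity for s in spectra])
            bg_cols = np.flatnonzero(raw.std(axis=0) > 0)
            grid = spectra[0].channel_mz
            pc = np.searchsorted(grid, two_channel_fingerprint.mz)
            bg_cols = np.setdiff1d(bg_cols, pc)
            rs.extend(np.corrcoef(raw[:, j], conc)[0, 1] for j in bg_cols)
        rs = np.asarray(rs)
        assert abs(rs.mean()) < 3 * rs.std() / np.sqrt(len(rs)) + 0.05
        assert np.all(np.abs(rs) < 0.9)


class TestBlanks:
    def test_zero_noise_blank_is_all_zero(self):
        blank = generate_blank_spectrum(
            NoiseParams(baseline_mean=0.0, baseline_sd=0.0), seed=1
        )
        assert blank.concentration == 0.0
        assert np.all(blank.intensity == 0.0)

    def test_deterministic(self):
        a = generate_blank_spectrum(NoiseParams(), seed=9)
        b = generate_blank_spectrum(NoiseParams(), seed=9)
        assert np.array_equal(a.intensity, b.intensity)

    def test_mean_principal_intensity_matches_baseline(self, fingerprint_c):
        """Monte-Carlo: over many blanks the principal channels carry only
        baseline — their mean is baseline_mean within 3 standard errors."""
        noise = NoiseParams(baseline_mean=50.0, baseline_sd=5.0)
        blanks = generate_blanks(1000, noise, seed=3)
        grid = blanks[0].channel_mz
        idx = np.searchsorted(grid, fingerprint_c.mz)
        values = np.array([b.intensity[idx] for b in blanks]).ravel()
        se = noise.baseline_sd / np.sqrt(len(values))
        assert abs(values.mean() - noise.baseline_mean) < 3 * se


class TestSpikedSamples:
    def test_design_product(self, two_channel_fingerprint):
        spectra = generate_spiked_samples(
            [83, 166, 333], n_sets=6, n_replicates=5,
            fingerprints=[two_channel_fingerprint], noise=NoiseParams(),
            matrix=MatrixParams.identity(SIX), seed=0,
        )
        assert len(spectra) == 90
        assert all(s.day == 1 for s in spectra)

    def test_two_day_design_doubles_inventory(self, two_channel_fingerprint):
        spectra = generate_spiked_samples(
            None, n_sets=6, n_replicates=5,
            fingerprints=[two_channel_fingerprint], noise=NoiseParams(),
            matrix=MatrixParams.identity(SIX), seed=0,
            solution_concentrations=[50.0, 100.0, 200.0], n_days=2,
        )
        assert len(spectra) == 180
        assert {s.day for s in spectra} == {1, 2}

    def test_zero_level_spike_is_blank_equivalent(self, two_channel_fingerprint):
        spectra = generate_spiked_samples(
            [0.0], n_sets=1, n_replicates=3,
            fingerprints=[two_channel_fingerprint],
            noise=NoiseParams(baseline_mean=50.0, baseline_sd=5.0,
                              background_channel_count=0),
            matrix=MatrixParams.identity(SIX), seed=0,
        )
        grid = spectra[0].channel_mz
        idx = np.searchsorted(grid, two_channel_fingerprint.mz)
        for s in spectra:
            assert s.concentration == 0.0
            assert np.all(s.intensity[idx] < 80.0)  # baseline only, no analyte signal

    def test_negative_level_rejected(self, two_channel_fingerprint):
        with pytest.raises(ValueError, match="non-negative"):
            generate_spiked_samples(
                [-1.0], 1, 1, [two_channel_fingerprint], NoiseParams(),
                MatrixParams.identity(SIX), seed=0,
            )

    def test_reproducible_for_fixed_seed(self, two_channel_fingerprint):
        kwargs = dict(n_sets=2, n_replicates=2, fingerprints=[two_channel_fingerprint],
                      noise=NoiseParams(), matrix=MatrixParams.identity(SIX), seed=4)
        a = generate_spiked_samples([83.0], **kwargs)
        b = generate_spiked_samples([83.0], **kwargs)
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1.intensity, s2.intensity)

    def test_mg_kg_levels_convert_through_inverse_formula(self, two_channel_fingerprint):
        noise0 = NoiseParams(replicate_cv=0.0, baseline_mean=0.0, baseline_sd=0.0,
                             background_channel_count=0)
        spectra = generate_spiked_samples(
            None, 1, 1, [two_channel_fingerprint], noise0,
            MatrixParams.identity(SIX), seed=0,
            solution_concentrations=[50.0],
        )
        # 50 μg/mL at 25/3 mL on 5 g tags as 83 mg/kg
        assert "83mgkg" in spectra[0].spectrum_id


class TestNoiseParamsValidation:
    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            NoiseParams(replicate_cv=-0.1)

    def test_nonpositive_matrix_factor_rejected(self):
        with pytest.raises(ValueError, match="must be > 0"):
            MatrixParams({50.0: 0.0})
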