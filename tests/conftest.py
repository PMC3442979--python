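import numpy as np
import pytest

from fimsquant.simulate import (
    CalibrationDesign,
    FingerprintSpec,
    MatrixParams,
    NoiseParams,
    PrincipalChannel,
    generate_calibration_spectra,
    generate_fingerprint,
)
from fimsquant.spectra import MATRIX_FREE, SpectrumSet, normalize_channels

SIX_LEVELS = (2.0, 20.0, 50.0, 100.0, 200.0, 400.0)


@pytest.fixture
def small_grid():
    """A 13-channel grid that keeps hand-constructed spectra readable."""
    return np.round(np.arange(100.0, 101.3, 0.1), 1)


@pytest.fixture
def fingerprint_c():
    return generate_fingerprint("C", 9, seed=1)


@pytest.fixture
def two_channel_fingerprint():
    return FingerprintSpec(
        analyte_id="A",
        principal_channels=(
            PrincipalChannel(150.0, 10_000.0, 1_000.0),
            PrincipalChannel(250.0, 8_000.0, 500.0),
        ),
    )


def single_analyte_matrix(fingerprint, cv=0.02, seed=0, n_sets=3, n_replicates=5,
                          background=200, baseline_mean=50.0, baseline_sd=5.0):
    """Matrix-free single-analyte calibration series, normalized."""
    design = CalibrationDesign(
        levels=SIX_LEVELS, n_replicates=n_replicates, n_sets=n_sets,
        matrix_conditions=(MATRIX_FREE,),
    )
    noise = NoiseParams(replicate_cv=cv, background_channel_count=background,
                        baseline_mean=baseline_mean, baseline_sd=baseline_sd)
    spectra = generate_calibration_spectra(
        design, [fingerprint], noise, MatrixParams.identity(SIX_LEVELS), seed=seed
    )
    return normalize_channels(SpectrumSet(spectra, design=design))


@pytest.fixture
def calibration_matrix(two_channel_fingerprint):
    """30-point noisy calibration (1 set × 6 levels × 5 reps, 2 features)."""
    return single_analyte_matrix(two_channel_fingerprint, cv=0.02, seed=7, n_sets=1,
                                 background=20)
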