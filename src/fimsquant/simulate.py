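"""Synthetic flow-injection MS spectra with known ground truth.

The generator emulates a mixed two-analyte calibration study: each analyte
owns a small, disjoint set of *principal* m/z channels whose intensity is an
affine function of concentration (intercept + slope·c), on top of a
background of concentration-independent channels and a small additive
baseline.  Replicate scatter is multiplicative with a configurable
coefficient of variation; matrix-matched acquisitions scale the analyte
signal by a per-level enhancement/suppression factor.  Everything is a pure
function of its parameters and a seed.

Default condition set (configurable): 6 calibration levels at 2, 20, 50,
100, 200 and 400 μg mL⁻¹, 5 repeat analyses, 3 independent sets, matrix-free
and matrix-matched — a 180-spectrum inventory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import (
    MATRIX_FREE,
    MATRIX_MATCHED,
    Spectrum,
    default_grid,
)

DEFAULT_LEVELS = (2.0, 20.0, 50.0, 100.0, 200.0, 400.0)

# fixed stream offsets so each generator draws from an independent substream
# of the same root seed
_STREAM_FINGERPRINT = 11
_STREAM_CALIBRATION = 23
_STREAM_BLANK = 37
_STREAM_SPIKE = 41
_STREAM_BACKGROUND = 53


def _rng(stream: int, seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(stream), int(seed)]))


@dataclass(frozen=True)
class PrincipalChannel:
    mz: float                 # Da
    response_slope: float     # counts per μg mL⁻¹, > 0
    response_intercept: float  # counts at zero concentration


@dataclass(frozen=True)
class FingerprintSpec:
    """An analyte's ground-truth fingerprint: its principal channels."""

    analyte_id: str
    principal_channels: tuple[PrincipalChannel, ...]

    def __post_init__(self):
        mzs = [c.mz for c in self.principal_channels]
        if len(set(mzs)) != len(mzs):
            raise ValueError("principal m/z values must be unique within an analyte")
        for c in self.principal_channels:
            if not (100.0 <= c.mz <= 700.0):
                raise ValueError(f"principal m/z {c.mz} outside the [100, 700] grid")
            if c.response_slope <= 0:
                raise ValueError("response_slope must be > 0")

    @property
    def n_principal(self) -> int:
        return len(self.principal_channels)

    @property
    def mz(self) -> np.ndarray:
        return np.array([c.mz for c in self.principal_channels])


@dataclass(frozen=True)
class NoiseParams:
    """Stochastic structure of one acquisition.

    replicate_cv: CV of the multiplicative replicate noise (0.02 matches a
    best-case 2% intra-day RSD); baseline_mean/sd: additive detector baseline
    in counts; background_channel_count: number of concentration-independent
    matrix/chemical background channels.
    """

    replicate_cv: float = 0.02
    baseline_mean: float = 50.0
    baseline_sd: float = 5.0
    background_channel_count: int = 200

    def __post_init__(self):
        if self.replicate_cv < 0 or self.baseline_sd < 0:
            raise ValueError("replicate_cv and baseline_sd must be ≥ 0")
        if self.baseline_mean < 0 or self.background_channel_count < 0:
            raise ValueError("baseline_mean and background_channel_count must be ≥ 0")


@dataclass(frozen=True)
class MatrixParams:
    """Per-level multiplicative matrix enhancement/suppression factors.

    A factor of 0.95 is a 5% suppression, 1.03 a 3% enhancement, 1.0 no
    effect; matrix-free acquisitions always use 1.0.
    """

    effect_by_level: dict[float, float] = field(default_factory=dict)

    def __post_init__(self):
        for level, f in self.effect_by_level.items():
            if f <= 0:
                raise ValueError(f"matrix factor at level {level} must be > 0, got {f}")

    def factor(self, level: float) -> float:
        key = float(level)
        if key not in self.effect_by_level:
            raise ValueError(
                f"no matrix factor defined for concentration level {level}; "
                f"known levels: {sorted(self.effect_by_level)}"
            )
        return self.effect_by_level[key]

    def factor_nearest(self, level: float) -> float:
        """Factor of the nearest defined level (used for off-grid spikes)."""
        if not self.effect_by_level:
            return 1.0
        keys = np.array(sorted(self.effect_by_level))
        return self.effect_by_level[float(keys[np.argmin(np.abs(keys - level))])]

    @classmethod
    def identity(cls, levels=DEFAULT_LEVELS) -> "MatrixParams":
        return cls({float(l): 1.0 for l in levels})

    @classmethod
    def random_uniform(cls, levels=DEFAULT_LEVELS, low: float = 0.95, high: float = 1.03,
                       seed: int = 0) -> "MatrixParams":
        """Per-level factors drawn uniformly from [low, high] (default range
        matches a −5%..+3% enhancement/suppression envelope)."""
        rng = _rng(_STREAM_BACKGROUND + 1, seed)
        return cls({float(l): float(rng.uniform(low, high)) for l in levels})


@dataclass(frozen=True)
class CalibrationDesign:
    """Level × replicate × set × matrix-condition calibration inventory."""

    levels: tuple[float, ...] = DEFAULT_LEVELS
    n_replicates: int = 5
    n_sets: int = 3
    matrix_conditions: tuple[str, ...] = (MATRIX_FREE, MATRIX_MATCHED)

    def __post_init__(self):
        if not self.levels or any(l <= 0 for l in self.levels):
            raise ValueError("design levels must be positive")
        if self.n_replicates < 1 or self.n_sets < 1 or not self.matrix_conditions:
            raise ValueError("design counts must be ≥ 1")

    @property
    def n_spectra(self) -> int:
        return (
            len(self.matrix_conditions) * self.n_sets * len(self.levels) * self.n_replicates
        )


def generate_fingerprint(
    analyte_id: str,
    n_principal: int,
    seed: int,
    grid: np.ndarray | None = None,
    exclude_mz: tuple[float, ...] = (),
    slope_range: tuple[float, float] = (5_000.0, 20_000.0),
    intercept_range: tuple[float, float] = (500.0, 2_000.0),
) -> FingerprintSpec:
    """Draw a ground-truth fingerprint: n_principal channels on the grid,
    each with a positive response slope. ``exclude_mz`` keeps channel sets
    disjoint across analytes in one study."""
    if n_principal < 1:
        raise ValueError("n_principal must be ≥ 1")
    if grid is None:
        grid = default_grid()
    available = np.setdiff1d(grid, np.asarray(exclude_mz, dtype=float))
    if n_principal > len(available):
        raise ValueError(
            f"impossible design: {n_principal} principal channels requested but only "
            f"{len(available)} grid channels available"
        )
    # salt the stream with the analyte label so "C" and "G" differ at equal seed
    entropy = [_STREAM_FINGERPRINT, int(seed)] + [ord(ch) for ch in analyte_id]
    rng = np.random.default_rng(np.random.SeedSequence(entropy))
    mzs = np.sort(rng.choice(available, size=n_principal, replace=False))
    slopes = rng.uniform(*slope_range, size=n_principal)
    intercepts = rng.uniform(*intercept_range, size=n_principal)
    return FingerprintSpec(
        analyte_id=analyte_id,
        principal_channels=tuple(
            PrincipalChannel(float(m), float(s), float(b))
            for m, s, b in zip(mzs, slopes, intercepts)
        ),
    )


def draw_background_channels(
    count: int,
    seed: int,
    grid: np.ndarray | None = None,
    exclude_mz: tuple[float, ...] = (),
) -> np.ndarray:
    """Pick the m/z positions of the concentration-independent background
    channels (shared across every acquisition of a study)."""
    if grid is None:
        grid = default_grid()
    available = np.setdiff1d(grid, np.asarray(exclude_mz, dtype=float))
    if count > len(available):
        raise ValueError("more background channels requested than grid channels available")
    rng = _rng(_STREAM_BACKGROUND, seed)
    return np.sort(rng.choice(available, size=count, replace=False))


def _baseline(rng: np.random.Generator, noise: NoiseParams, n: int) -> np.ndarray:
    if noise.baseline_mean == 0 and noise.baseline_sd == 0:
        return np.zeros(n)
    return np.clip(rng.normal(noise.baseline_mean, noise.baseline_sd, size=n), 0.0, None)


def _replicate_factor(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    return np.clip(rng.normal(1.0, cv, size=n), 0.0, None)


class _StudyBackground:
    """Per-channel lognormal base intensities with per-spectrum scatter."""

    def __init__(self, mzs: np.ndarray, seed: int, median_log: float = np.log(2e4),
                 sigma_across: float = 1.0, sigma_within: float = 0.3):
        self.mzs = mzs
        rng = _rng(_STREAM_BACKGROUND + 2, seed)
        self.base = rng.lognormal(median_log, sigma_across, size=len(mzs))
        self.sigma_within = sigma_within

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        return self.base * rng.lognormal(0.0, self.sigma_within, size=len(self.base))


def generate_calibration_spectra(
    design: CalibrationDesign,
    fingerprints: list[FingerprintSpec],
    noise: NoiseParams,
    matrix: MatrixParams,
    seed: int,
    grid: np.ndarray | None = None,
    background_mz: np.ndarray | None = None,
) -> list[Spectrum]:
    """Generate the full calibration inventory for the given design.

    Expected principal-channel intensity is
    ``(intercept + slope · level) · matrix_factor`` (factor 1.0 when
    matrix-free), multiplied by replicate noise of the stated CV, plus the
    additive baseline. Spectrum count is exactly the design product.
    """
    if not fingerprints:
        raise ValueError("at least one fingerprint is required")
    if grid is None:
        grid = default_grid()
    principal_mz = np.concatenate([fp.mz for fp in fingerprints])
    if len(np.unique(principal_mz)) != len(principal_mz):
        raise ValueError("principal m/z values must be disjoint across analytes")
    # validate matrix factors up front so the error names the offending level
    if MATRIX_MATCHED in design.matrix_conditions:
        for level in design.levels:
            matrix.factor(level)
    if background_mz is None:
        background_mz = draw_background_channels(
            noise.background_channel_count, seed, grid, exclude_mz=tuple(principal_mz)
        )
    background = _StudyBackground(background_mz, seed)
    bg_idx = np.searchsorted(grid, background_mz)
    pc_idx = np.searchsorted(grid, principal_mz)
    slopes = np.concatenate([[c.response_slope for c in fp.principal_channels] for fp in fingerprints])
    intercepts = np.concatenate([[c.response_intercept for c in fp.principal_channels] for fp in fingerprints])
    mix = "+".join(fp.analyte_id for fp in fingerprints)

    rng = _rng(_STREAM_CALIBRATION, seed)
    spectra: list[Spectrum] = []
    for condition in design.matrix_conditions:
        for set_id in range(1, design.n_sets + 1):
            for level in design.levels:
                factor = matrix.factor(level) if condition == MATRIX_MATCHED else 1.0
                expected = (intercepts + slopes * level) * factor
                for rep in range(1, design.n_replicates + 1):
                    intensity = _baseline(rng, noise, len(grid))
                    intensity[bg_idx] += background.draw(rng)
                    intensity[pc_idx] += expected * _replicate_factor(
                        rng, noise.replicate_cv, len(expected)
                    )
                    spectra.append(
                        Spectrum(
                            channel_mz=grid,
                            intensity=intensity,
                            analyte_mix=mix,
                            concentration=float(level),
                            matrix_condition=condition,
                            set_id=set_id,
                            replicate_id=rep,
                            spectrum_id=f"{mix}|{condition}|set{set_id}|L{level:g}|r{rep}",
                        )
                    )
    assert len(spectra) == design.n_spectra
    return spectra


def generate_blank_spectrum(noise: NoiseParams, seed: int,
                            grid: np.ndarray | None = None) -> Spectrum:
    """A solvent blank: baseline noise only, no analyte, no matrix.

    The absence of signal at the principal channels is what marks a good
    solvent blank; their expected intensity here is exactly the baseline mean.
    """
    if grid is None:
        grid = default_grid()
    rng = _rng(_STREAM_BLANK, seed)
    return Spectrum(
        channel_mz=grid,
        intensity=_baseline(rng, noise, len(grid)),
        analyte_mix="blank",
        concentration=0.0,
        matrix_condition=MATRIX_FREE,
        spectrum_id=f"blank|{seed}",
    )


def generate_blanks(n: int, noise: NoiseParams, seed: int,
                    grid: np.ndarray | None = None) -> list[Spectrum]:
    """n independent solvent blanks derived from one root seed."""
    children = np.random.SeedSequence([_STREAM_BLANK, int(seed)]).generate_state(n)
    return [generate_blank_spectrum(noise, int(s) % (2**31), grid) for s in children]


def generate_spiked_samples(
    spike_levels: list[float] | None,
    n_sets: int,
    n_replicates: int,
    fingerprints: list[FingerprintSpec],
    noise: NoiseParams,
    matrix: MatrixParams,
    seed: int,
    solution_concentrations: list[float] | None = None,
    extraction_volume_ml: float = 25.0 / 3.0,
    matrix_weight_g: float = 5.0,
    n_days: int = 1,
    grid: np.ndarray | None = None,
    background_mz: np.ndarray | None = None,
) -> list[Spectrum]:
    """Matrix-matched spiked blanks with known ground truth for recovery work.

    ``spike_levels`` are in mg kg⁻¹ and are converted to solution
    concentrations by inverting the spiking-level formula
    (level = conc × volume / weight); alternatively pass
    ``solution_concentrations`` (μg mL⁻¹) directly. Each spectrum is tagged
    with its true solution concentration and day label.
    """
    if (spike_levels is None) == (solution_concentrations is None):
        raise ValueError("pass exactly one of spike_levels / solution_concentrations")
    if spike_levels is not None:
        if any(l < 0 for l in spike_levels):
            raise ValueError("spike levels must be non-negative")
        solution_concentrations = [
            l * matrix_weight_g / extraction_volume_ml for l in spike_levels
        ]
    else:
        if any(c < 0 for c in solution_concentrations):
            raise ValueError("spike concentrations must be non-negative")
    if grid is None:
        grid = default_grid()
    principal_mz = np.concatenate([fp.mz for fp in fingerprints])
    if background_mz is None:
        background_mz = draw_background_channels(
            noise.background_channel_count, seed, grid, exclude_mz=tuple(principal_mz)
        )
    background = _StudyBackground(background_mz, seed)
    bg_idx = np.searchsorted(grid, background_mz)
    pc_idx = np.searchsorted(grid, principal_mz)
    slopes = np.concatenate([[c.response_slope for c in fp.principal_channels] for fp in fingerprints])
    intercepts = np.concatenate([[c.response_intercept for c in fp.principal_channels] for fp in fingerprints])
    mix = "+".join(fp.analyte_id for fp in fingerprints)

    rng = _rng(_STREAM_SPIKE, seed)
    spectra: list[Spectrum] = []
    for day in range(1, n_days + 1):
        for set_id in range(1, n_sets + 1):
            for conc in solution_concentrations:
                factor = matrix.factor_nearest(conc)
                expected = np.where(conc > 0, (intercepts + slopes * conc) * factor, 0.0)
                for rep in range(1, n_replicates + 1):
                    intensity = _baseline(rng, noise, len(grid))
                    intensity[bg_idx] += background.draw(rng)
                    intensity[pc_idx] += expected * _replicate_factor(
                        rng, noise.replicate_cv, len(expected)
                    )
                    level_tag = int(conc * extraction_volume_ml / matrix_weight_g + 1e-9)
                    spectra.append(
                        Spectrum(
                            channel_mz=grid,
                            intensity=intensity,
                            analyte_mix=mix,
                            concentration=float(conc),
                            matrix_condition=MATRIX_MATCHED,
                            set_id=set_id,
                            replicate_id=rep,
                            day=day,
                            spectrum_id=(
                                f"spike|{mix}|d{day}|set{set_id}|{level_tag}mgkg|r{rep}"
                            ),
                        )
                    )
    assert len(spectra) == n_days * n_sets * len(solution_concentrations) * n_replicates
    return spectra
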