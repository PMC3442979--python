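"""End-to-end study orchestration: generate → select → train → validate.

A single :class:`StudyConfig` (YAML-serializable) drives the whole study;
every random draw descends from one root seed through fixed named
substreams, so a rerun with the same config is bit-identical and each stage
is independently reproducible.

Study layout (the emulated design):

* single-analyte matrix-free series per analyte → channel attribution
  (mixed calibrants cannot attribute channels: both analytes co-vary),
* mixed-analyte series under both matrix conditions → calibration, one
  model per analyte × matrix condition,
* matrix effect per level from predicted concentrations (matrix-free model
  predicting both conditions),
* LOD/LOQ against solvent blanks, noise-injection robustness check,
* a 2-day spiked-blank recovery study against the matrix-matched models.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ann import FitReport, KFoldSelection, NeuralCalibration
from .features import PrincipalFeatureSet, score_channels, select_principal
from .simulate import (
    CalibrationDesign,
    DEFAULT_LEVELS,
    FingerprintSpec,
    MatrixParams,
    NoiseParams,
    draw_background_channels,
    generate_blanks,
    generate_calibration_spectra,
    generate_spiked_samples,
    generate_fingerprint,
)
from .spectra import (
    MATRIX_FREE,
    MATRIX_MATCHED,
    IntensityMatrix,
    SpectrumSet,
    default_grid,
    normalize_channels,
    write_spectra_csv,
)
from .validation import (
    DetectionLimits,
    MatrixEffectEntry,
    RecoveryEntry,
    blank_labels,
    detection_limits,
    matrix_effect,
    recovery,
    spiking_level,
)

log = logging.getLogger("fimsquant")

# named substream tags hashed into per-stage seeds
_STAGES = ("fingerprints", "matrix", "background", "single_series", "mixed_series",
           "fits", "blanks", "spikes")


def _stage_seed(root: int, stage: str) -> int:
    digest = hashlib.sha256(f"{root}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class StudyConfig:
    """Everything needed to rerun a study from scratch."""

    levels: tuple[float, ...] = DEFAULT_LEVELS
    n_replicates: int = 5
    n_sets: int = 3
    matrix_conditions: tuple[str, ...] = (MATRIX_FREE, MATRIX_MATCHED)
    analytes: dict = field(default_factory=lambda: {"C": 9, "G": 7})
    replicate_cv: float = 0.02
    baseline_mean: float = 50.0
    baseline_sd: float = 5.0
    background_channels: int = 200
    matrix_factor_range: tuple[float, float] = (0.95, 1.03)
    matrix_factors: dict | None = None  # explicit level → factor map overrides the range
    threshold: float = 0.995
    k: int = 5
    n_restarts: int = 20
    seed: int = 42
    n_blanks: int = 18
    spike_concentrations: tuple[float, ...] = (50.0, 100.0, 200.0)
    spike_volume_ml: float = 25.0 / 3.0  # 3:5 sample-to-solvent ratio on 5 g
    spike_weight_g: float = 5.0
    n_spike_sets: int = 6
    n_spike_replicates: int = 5
    n_spike_days: int = 2
    outdir: str | None = None

    def design(self) -> CalibrationDesign:
        return CalibrationDesign(
            levels=tuple(float(l) for l in self.levels),
            n_replicates=self.n_replicates,
            n_sets=self.n_sets,
            matrix_conditions=tuple(self.matrix_conditions),
        )

    def noise(self) -> NoiseParams:
        return NoiseParams(
            replicate_cv=self.replicate_cv,
            baseline_mean=self.baseline_mean,
            baseline_sd=self.baseline_sd,
            background_channel_count=self.background_channels,
        )

    def matrix(self) -> MatrixParams:
        if self.matrix_factors is not None:
            return MatrixParams({float(k): float(v) for k, v in self.matrix_factors.items()})
        return MatrixParams.random_uniform(
            self.levels, *self.matrix_factor_range, seed=_stage_seed(self.seed, "matrix")
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["levels"] = list(d["levels"])
        d["matrix_conditions"] = list(d["matrix_conditions"])
        d["matrix_factor_range"] = list(d["matrix_factor_range"])
        d["spike_concentrations"] = list(d["spike_concentrations"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        doc = yaml.safe_load(Path(path).read_text())
        for key in ("levels", "matrix_conditions", "spike_concentrations",
                    "matrix_factor_range"):
            if key in doc and isinstance(doc[key], list):
                doc[key] = tuple(doc[key])
        return cls(**doc)


@dataclass
class ModelEntry:
    """One fitted calibration: (analyte, matrix condition) pair."""

    analyte: str
    condition: str
    selection: KFoldSelection

    @property
    def training_report(self) -> FitReport:
        return self.selection.training_report

    @property
    def validation_report(self) -> FitReport:
        return self.selection.validation_report

    @property
    def pooled_report(self) -> FitReport:
        return self.selection.pooled_report


@dataclass
class StudyReport:
    """Full study outcome; every number is recomputable from config + seed."""

    config: StudyConfig
    features: dict                     # analyte → PrincipalFeatureSet
    models: dict                       # (analyte, condition) → ModelEntry
    matrix_effects: list               # MatrixEffectEntry rows (+ analyte tag)
    limits: dict                       # analyte → DetectionLimits
    noise_injection: dict              # analyte → (clean, contaminated) FitReports
    recovery_table: list = field(default_factory=list)  # (analyte, RecoveryEntry)
    fingerprints: dict = field(default_factory=dict)    # ground truth, for closure checks
    _runtime: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "provenance": {
                "config": self.config.to_dict(),
                "config_hash": self.config.config_hash(),
                "seed": self.config.seed,
                "version": __version__,
            },
            "features": {
                a: fs.to_json() for a, fs in self.features.items()
            },
            "models": {
                f"{a}|{c}": {
                    "parameters": m.selection.results.model.to_json(),
                    "training": dataclasses.asdict(m.training_report),
                    "validation": dataclasses.asdict(m.validation_report),
                    "pooled": dataclasses.asdict(m.pooled_report),
                    "fold": m.selection.fold_index,
                }
                for (a, c), m in self.models.items()
            },
            "matrix_effects": [
                {"analyte": a, **dataclasses.asdict(e)} for a, e in self.matrix_effects
            ],
            "detection_limits": {
                a: dataclasses.asdict(d) for a, d in self.limits.items()
            },
            "noise_injection": {
                a: {"clean": dataclasses.asdict(cl), "contaminated": dataclasses.asdict(co)}
                for a, (cl, co) in self.noise_injection.items()
            },
            "recovery": [
                {"analyte": a, **dataclasses.asdict(e)} for a, e in self.recovery_table
            ],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def report_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()

    def matrix_effect_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"analyte": a, **dataclasses.asdict(e)} for a, e in self.matrix_effects]
        )

    def recovery_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"analyte": a, **dataclasses.asdict(e)} for a, e in self.recovery_table]
        )


class StageError(RuntimeError):
    """An orchestration stage failed; names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _run_stage(stage: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 — rewrap with stage context
        raise StageError(stage, exc) from exc


def run_calibration_study(config: StudyConfig, write_spectra: bool = False) -> StudyReport:
    """Execute the full calibration workflow for every analyte and condition."""
    grid = default_grid()
    noise = config.noise()
    matrix = config.matrix()
    design = config.design()

    # ground-truth fingerprints, disjoint across analytes
    fingerprints: dict[str, FingerprintSpec] = {}
    used: tuple[float, ...] = ()
    for analyte, n_principal in config.analytes.items():
        fp = _run_stage(
            "fingerprints", generate_fingerprint, analyte, n_principal,
            _stage_seed(config.seed, "fingerprints"), grid, used,
        )
        fingerprints[analyte] = fp
        used = used + tuple(fp.mz)
    background_mz = draw_background_channels(
        noise.background_channel_count, _stage_seed(config.seed, "background"),
        grid, exclude_mz=used,
    )
    log.info("fingerprints: %s", {a: fp.n_principal for a, fp in fingerprints.items()})

    # single-analyte matrix-free series → channel attribution
    features: dict[str, PrincipalFeatureSet] = {}
    single_design = CalibrationDesign(
        levels=design.levels, n_replicates=design.n_replicates,
        n_sets=design.n_sets, matrix_conditions=(MATRIX_FREE,),
    )
    for analyte, fp in fingerprints.items():
        spectra = _run_stage(
            "single_series", generate_calibration_spectra,
            single_design, [fp], noise, matrix,
            _stage_seed(config.seed, f"single_series:{analyte}"),
            grid, background_mz,
        )
        norm = normalize_channels(SpectrumSet(spectra, design=single_design))
        scores = _run_stage("feature_selection", score_channels, norm)
        features[analyte] = _run_stage(
            "feature_selection", select_principal, scores, config.threshold,
            analyte, f"single-analyte matrix-free series, {design.n_sets} sets",
        )
        log.info("analyte %s: %d principal channels selected", analyte, len(features[analyte]))

    # mixed-calibrant series for calibration (both conditions)
    mixed = _run_stage(
        "mixed_series", generate_calibration_spectra,
        design, list(fingerprints.values()), noise, matrix,
        _stage_seed(config.seed, "mixed_series"), grid, background_mz,
    )
    mixed_set = SpectrumSet(mixed, design=design)
    norm_mixed = normalize_channels(mixed_set)
    condition = np.array([s.matrix_condition for s in mixed_set])
    log.info("mixed series: %d spectra", len(mixed_set))

    models: dict[tuple[str, str], ModelEntry] = {}
    for analyte, fs in features.items():
        for cond in design.matrix_conditions:
            rows = condition == cond
            X = norm_mixed.feature_values(fs.mz)[rows]
            y = norm_mixed.row_concentration[rows]
            cal = NeuralCalibration(X, y, feature_mz=fs.mz)
            sel = _run_stage(
                "train", cal.fit_kfold, config.k,
                _stage_seed(config.seed, f"fits:{analyte}:{cond}"),
                config.n_restarts,
            )
            models[(analyte, cond)] = ModelEntry(analyte, cond, sel)
            log.info(
                "model %s|%s: fold %d, validation RMSE%% %.3f, r² %.5f",
                analyte, cond, sel.fold_index,
                sel.validation_report.rmse_percent, sel.validation_report.r_squared,
            )

    # matrix effect per level: matrix-free model predicts both conditions
    effects: list[tuple[str, MatrixEffectEntry]] = []
    if MATRIX_MATCHED in design.matrix_conditions:
        for analyte, fs in features.items():
            free_model = models[(analyte, MATRIX_FREE)].selection
            Xall = norm_mixed.feature_values(fs.mz)
            pred = free_model.predict(Xall)
            for level in design.levels:
                at_level = norm_mixed.row_concentration == level
                c_ps = float(pred[at_level & (condition == MATRIX_FREE)].mean())
                c_pm = float(pred[at_level & (condition == MATRIX_MATCHED)].mean())
                effects.append(
                    (
                        analyte,
                        MatrixEffectEntry(
                            level=float(level),
                            level_mg_kg=spiking_level(level, 100.0, 60.0),
                            effect=matrix_effect(c_pm, c_ps),
                            c_pm=c_pm,
                            c_ps=c_ps,
                        ),
                    )
                )

    # solvent blanks → detection limits and noise injection
    blanks = _run_stage(
        "blanks", generate_blanks, config.n_blanks, noise,
        _stage_seed(config.seed, "blanks"), grid,
    )
    limits: dict[str, DetectionLimits] = {}
    noise_inj: dict[str, tuple[FitReport, FitReport]] = {}
    for analyte, fs in features.items():
        cond_rows = [s for s in mixed_set if s.matrix_condition == MATRIX_MATCHED] \
            if MATRIX_MATCHED in design.matrix_conditions else list(mixed_set)
        limits[analyte] = _run_stage(
            "detection_limits", detection_limits,
            SpectrumSet(cond_rows), blanks, fs,
            config.spike_volume_ml, config.spike_weight_g,
        )
        entry = models.get((analyte, MATRIX_MATCHED)) or models[(analyte, MATRIX_FREE)]
        clean = entry.validation_report
        rows = condition == entry.condition
        Xb = norm_mixed.transform(blanks, fs.mz)
        X2 = np.vstack([norm_mixed.feature_values(fs.mz)[rows], Xb])
        y2 = np.concatenate([
            norm_mixed.row_concentration[rows],
            blank_labels(len(blanks), design.levels),
        ])
        contaminated = _run_stage(
            "noise_injection",
            lambda: NeuralCalibration(X2, y2, feature_mz=fs.mz)
            .fit_kfold(config.k, _stage_seed(config.seed, f"fits:{analyte}:{entry.condition}"),
                       config.n_restarts)
            .validation_report,
        )
        noise_inj[analyte] = (clean, contaminated)
        log.info(
            "noise injection %s: RMSE%% %.3f → %.3f, r² %.5f → %.5f",
            analyte, clean.rmse_percent, contaminated.rmse_percent,
            clean.r_squared, contaminated.r_squared,
        )

    report = StudyReport(
        config=config,
        features=features,
        models=models,
        matrix_effects=effects,
        limits=limits,
        noise_injection=noise_inj,
        fingerprints=fingerprints,
        _runtime={
            "norm_mixed": norm_mixed,
            "mixed_set": mixed_set,
            "matrix": matrix,
            "noise": noise,
            "background_mz": background_mz,
            "grid": grid,
        },
    )
    if config.outdir:
        _write_outputs(report, write_spectra=write_spectra)
    return report


def run_recovery_study(config: StudyConfig,
                       calibration: StudyReport | None = None) -> StudyReport:
    """2-day spiked-blank recovery study against the matrix-matched models.

    Trains the calibration in-run unless an existing :class:`StudyReport`
    is supplied. Emits one recovery row per analyte × spike level with
    intra-/inter-day RSDs.
    """
    report = calibration or run_calibration_study(config)
    rt = report._runtime
    if MATRIX_MATCHED not in config.matrix_conditions:
        raise ValueError("recovery study requires matrix-matched models")
    spiked = _run_stage(
        "spikes", generate_spiked_samples,
        None, config.n_spike_sets, config.n_spike_replicates,
        list(report.fingerprints.values()), rt["noise"], rt["matrix"],
        _stage_seed(config.seed, "spikes"),
        list(config.spike_concentrations),
        config.spike_volume_ml, config.spike_weight_g, config.n_spike_days,
        rt["grid"], rt["background_mz"],
    )
    norm = rt["norm_mixed"]
    rows = []
    for analyte, fs in report.features.items():
        entry = report.models[(analyte, MATRIX_MATCHED)]
        X = norm.transform(spiked, fs.mz)
        pred = entry.selection.predict(X)
        conc = np.array([s.concentration for s in spiked])
        days = np.array([s.day for s in spiked])
        for level in config.spike_concentrations:
            at = conc == level
            rows.append(
                (
                    analyte,
                    recovery(
                        pred[at], float(level), days[at],
                        config.spike_volume_ml, config.spike_weight_g,
                    ),
                )
            )
    report.recovery_table = rows
    if config.outdir:
        _write_outputs(report)
    return report


def _write_outputs(report: StudyReport, write_spectra: bool = False) -> None:
    outdir = Path(report.config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.config.to_yaml(outdir / "config.yaml")
    report.to_json(outdir / "study_report.json")
    for analyte, fs in report.features.items():
        fs.to_json(outdir / f"features_{analyte}.json")
    for (analyte, cond), entry in report.models.items():
        entry.selection.results.save(outdir / f"model_{analyte}_{cond}.json")
    report.matrix_effect_frame().to_csv(outdir / "matrix_effect.csv", index=False)
    if report.recovery_table:
        report.recovery_frame().to_csv(outdir / "recovery.csv", index=False)
    if write_spectra and "mixed_set" in report._runtime:
        write_spectra_csv(report._runtime["mixed_set"], outdir / "calibration_spectra.csv")
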