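"""Spectrum containers and I/O for flow-injection MS fingerprints.

A flow-injection acquisition has no chromatographic dimension: the analytical
signal is the full-scan mass spectrum, optionally summed over the injection
window (default 0–1.0 min).  All spectra in a study live on one fixed m/z
channel grid (0.1 Da spacing over m/z 100–700), so no peak picking or
alignment is ever needed downstream.

The on-disk format is a pair of plain CSV files: a long-format intensity
table (spectrum_id, mz, intensity) and a metadata table keyed by
spectrum_id.  Intensities round-trip bit-exactly on their text
representation.  Time-resolved mzML input is supported by binning scan
arrays onto the fixed grid (nearest channel, ties toward the lower channel)
and summing scans over the injection window.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MZ_MIN = 100.0
MZ_MAX = 700.0
MZ_STEP = 0.1

#: metadata columns that must be present in the metadata CSV
REQUIRED_META_COLUMNS = (
    "spectrum_id",
    "analyte_mix",
    "concentration",
    "matrix_condition",
    "set_id",
    "replicate_id",
)
OPTIONAL_META_COLUMNS = ("day", "rt_min")

MATRIX_FREE = "matrix_free"
MATRIX_MATCHED = "matrix_matched"


def default_grid() -> np.ndarray:
    """The fixed acquisition grid: 6001 channels, 0.1 Da apart, m/z 100–700."""
    n = int(round((MZ_MAX - MZ_MIN) / MZ_STEP)) + 1
    return np.round(MZ_MIN + MZ_STEP * np.arange(n), 1)


@dataclass
class Spectrum:
    """One acquisition: intensities on an m/z channel grid plus design metadata.

    ``concentration`` is the nominal mixed-calibrant concentration in
    μg mL⁻¹, or ``None`` for blanks and unknowns. ``matrix_condition`` is
    ``"matrix_free"`` or ``"matrix_matched"``.
    """

    channel_mz: np.ndarray
    intensity: np.ndarray
    analyte_mix: str = ""
    concentration: float | None = None
    matrix_condition: str = MATRIX_FREE
    set_id: str | int | None = None
    replicate_id: str | int | None = None
    day: str | int | None = None
    rt_min: float | None = None
    spectrum_id: str | None = None

    def __post_init__(self) -> None:
        self.channel_mz = np.asarray(self.channel_mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.channel_mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("channel_mz and intensity must be 1-D arrays")
        if len(self.channel_mz) != len(self.intensity):
            raise ValueError(
                f"length mismatch: {len(self.channel_mz)} m/z channels vs "
                f"{len(self.intensity)} intensities"
            )
        if np.any(np.diff(self.channel_mz) <= 0):
            raise ValueError("channel_mz must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def meta_dict(self) -> dict:
        return {
            "spectrum_id": self.spectrum_id,
            "analyte_mix": self.analyte_mix,
            "concentration": self.concentration,
            "matrix_condition": self.matrix_condition,
            "set_id": self.set_id,
            "replicate_id": self.replicate_id,
            "day": self.day,
            "rt_min": self.rt_min,
        }


@dataclass
class SpectrumSet:
    """A collection of spectra sharing one channel grid."""

    spectra: list[Spectrum]
    design: object | None = None

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError("SpectrumSet requires at least one spectrum")
        grid = self.spectra[0].channel_mz
        for s in self.spectra[1:]:
            if len(s.channel_mz) != len(grid) or not np.array_equal(s.channel_mz, grid):
                raise ValueError("all spectra in a SpectrumSet must share one channel grid")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def channel_mz(self) -> np.ndarray:
        return self.spectra[0].channel_mz

    def intensity_array(self) -> np.ndarray:
        """(n_spectra, n_channels) raw intensity matrix, row order preserved."""
        return np.vstack([s.intensity for s in self.spectra])

    def concentrations(self) -> np.ndarray:
        """Nominal concentrations per spectrum (NaN where unknown/blank)."""
        return np.array(
            [np.nan if s.concentration is None else float(s.concentration) for s in self.spectra]
        )

    def subset(self, predicate) -> "SpectrumSet":
        kept = [s for s in self.spectra if predicate(s)]
        if not kept:
            raise ValueError("subset predicate matched no spectra")
        return SpectrumSet(kept, design=self.design)


@dataclass
class IntensityMatrix:
    """Per-channel max-normalized intensities for feature selection/training.

    Each column is divided by its maximum over the set, mapping it to [0, 1]
    (identically-zero columns pass through as zeros).  The per-column scale
    is kept so that later spectra — blanks, spiked unknowns — can be
    projected onto the same normalized space.
    """

    values: np.ndarray          # (n_spectra, n_channels), in [0, 1]
    column_mz: np.ndarray       # (n_channels,)
    row_concentration: np.ndarray  # (n_spectra,), NaN for blanks/unknowns
    column_scale: np.ndarray    # the per-column maxima used as divisors
    row_meta: list[dict] = field(default_factory=list)

    def column_index(self, mz_values: Sequence[float]) -> np.ndarray:
        idx = np.searchsorted(self.column_mz, np.asarray(mz_values, dtype=float))
        idx = np.clip(idx, 0, len(self.column_mz) - 1)
        if not np.allclose(self.column_mz[idx], mz_values, atol=MZ_STEP / 4):
            missing = [m for m, i in zip(mz_values, idx) if abs(self.column_mz[i] - m) > MZ_STEP / 4]
            raise KeyError(f"m/z channels not on the grid: {missing}")
        return idx

    def feature_values(self, mz_values: Sequence[float]) -> np.ndarray:
        """Normalized intensity submatrix restricted to the given channels."""
        return self.values[:, self.column_index(mz_values)]

    def transform(self, spectra: Iterable[Spectrum], mz_values: Sequence[float]) -> np.ndarray:
        """Project new spectra onto the normalized feature space of this matrix."""
        idx = self.column_index(mz_values)
        scale = np.where(self.column_scale[idx] > 0, self.column_scale[idx], 1.0)
        rows = [np.asarray(s.intensity)[idx] / scale for s in spectra]
        return np.vstack(rows)


def normalize_channels(sset: SpectrumSet) -> IntensityMatrix:
    """Max-normalize each channel across the set.

    Scale-invariance of Pearson correlation means this leaves the
    intensity–concentration correlation (the feature-selection statistic)
    exactly unchanged while mapping every channel into [0, 1].
    """
    raw = sset.intensity_array()
    scale = raw.max(axis=0)
    divisor = np.where(scale > 0, scale, 1.0)
    return IntensityMatrix(
        values=raw / divisor,
        column_mz=sset.channel_mz.copy(),
        row_concentration=sset.concentrations(),
        column_scale=scale,
        row_meta=[s.meta_dict() for s in sset.spectra],
    )


def normalize_spectra_tic(sset: SpectrumSet) -> IntensityMatrix:
    """Alternative normalization: per-spectrum total-ion-current scaling.

    Provided as a config option; not the default because it changes each
    channel's correlation with concentration.
    """
    raw = sset.intensity_array()
    tic = raw.sum(axis=1, keepdims=True)
    tic = np.where(tic > 0, tic, 1.0)
    values = raw / tic
    colmax = values.max(axis=0)
    return IntensityMatrix(
        values=values,
        column_mz=sset.channel_mz.copy(),
        row_concentration=sset.concentrations(),
        column_scale=np.where(colmax > 0, colmax, 1.0),
        row_meta=[s.meta_dict() for s in sset.spectra],
    )


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _meta_path(path: Path) -> Path:
    if path.suffix == ".csv":
        return path.with_name(path.stem + "_meta.csv")
    return path.with_name(path.name + "_meta.csv")


def write_spectra_csv(sset: SpectrumSet, path: str | Path) -> Path:
    """Write the long-format intensity table and its metadata sidecar.

    Returns the intensity-table path; the metadata table lands next to it
    with an ``_meta.csv`` suffix.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ids = []
    for i, s in enumerate(sset.spectra):
        if s.spectrum_id is None:
            s.spectrum_id = f"spec{i:04d}"
        ids.append(s.spectrum_id)
    n_chan = len(sset.channel_mz)
    long = pd.DataFrame(
        {
            "spectrum_id": np.repeat(ids, n_chan),
            "mz": np.tile(sset.channel_mz, len(ids)),
            "intensity": sset.intensity_array().ravel(),
        }
    )
    long.to_csv(path, index=False)
    meta = pd.DataFrame([s.meta_dict() for s in sset.spectra])
    meta.to_csv(_meta_path(path), index=False)
    return path


def read_spectra_csv(path: str | Path) -> SpectrumSet:
    """Read a SpectrumSet written by :func:`write_spectra_csv`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        # round_trip parsing keeps the intensity text representation bit-exact
        long = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty spectra file: {path}") from None
    if long.empty:
        raise ValueError(f"no spectra rows in {path}")
    for col in ("spectrum_id", "mz", "intensity"):
        if col not in long.columns:
            raise ValueError(f"missing required column '{col}' in {path}")
    meta_path = _meta_path(path)
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata table not found: {meta_path}")
    meta = pd.read_csv(meta_path)
    for col in REQUIRED_META_COLUMNS:
        if col not in meta.columns:
            raise ValueError(f"missing required metadata column '{col}' in {meta_path}")
    meta = meta.set_index("spectrum_id", drop=False)

    spectra: list[Spectrum] = []
    for sid, block in long.groupby("spectrum_id", sort=False):
        mz = block["mz"].to_numpy(dtype=float)
        if np.any(np.diff(mz) <= 0):
            raise ValueError(f"non-monotone m/z values for spectrum '{sid}'")
        if sid not in meta.index:
            raise ValueError(f"spectrum '{sid}' has no metadata row")
        m = meta.loc[sid]
        conc = m["concentration"]
        conc = None if pd.isna(conc) else float(conc)

        def _opt(col):
            if col not in meta.columns:
                return None
            v = m[col]
            return None if pd.isna(v) else v

        spectra.append(
            Spectrum(
                channel_mz=mz,
                intensity=block["intensity"].to_numpy(dtype=float),
                analyte_mix=str(m["analyte_mix"]),
                concentration=conc,
                matrix_condition=str(m["matrix_condition"]),
                set_id=_opt("set_id"),
                replicate_id=_opt("replicate_id"),
                day=_opt("day"),
                rt_min=_opt("rt_min"),
                spectrum_id=str(sid),
            )
        )
    return SpectrumSet(spectra)


# ---------------------------------------------------------------------------
# Scan summation and mzML ingestion
# ---------------------------------------------------------------------------

def sum_scans(scans: Sequence[Spectrum], t_start: float = 0.0, t_end: float = 1.0) -> Spectrum:
    """Channel-wise sum of all scans with t_start ≤ rt < t_end (minutes).

    This collapses a time-resolved flow-injection acquisition into the single
    fingerprint spectrum used for all downstream analysis.
    """
    if not scans:
        raise ValueError("no scans supplied")
    grid = scans[0].channel_mz
    in_window = []
    for s in scans:
        if s.rt_min is None:
            raise ValueError("scan without a retention-time stamp cannot be windowed")
        if not np.array_equal(s.channel_mz, grid):
            raise ValueError("scans must share one channel grid")
        if t_start <= s.rt_min < t_end:
            in_window.append(s)
    if not in_window:
        raise ValueError(
            f"empty acquisition: no scans in window [{t_start}, {t_end}) min"
        )
    total = np.sum([s.intensity for s in in_window], axis=0)
    first = in_window[0]
    return replace(first, intensity=total, rt_min=None,
                   spectrum_id=None if first.spectrum_id is None else first.spectrum_id + "_sum")


def bin_to_grid(mz: np.ndarray, intensity: np.ndarray, grid: np.ndarray | None = None) -> np.ndarray:
    """Accumulate an (m/z, intensity) array pair onto the fixed channel grid.

    Nearest-channel binning; an m/z exactly halfway between two channels goes
    to the lower channel. Points outside the grid span are dropped.
    """
    if grid is None:
        grid = default_grid()
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    pos = (mz - grid[0]) / MZ_STEP
    idx = np.ceil(pos - 0.5).astype(int)  # ties (pos = k + 0.5) resolve to k
    ok = (idx >= 0) & (idx < len(grid))
    out = np.zeros(len(grid))
    np.add.at(out, idx[ok], intensity[ok])
    return out


def _decode_binary(binary_text: str, params: dict) -> np.ndarray:
    import base64 as _b64
    import zlib as _zlib

    raw = _b64.b64decode(binary_text)
    if "zlib compression" in params:
        raw = _zlib.decompress(raw)
    dtype = "<f4" if "32-bit float" in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path, grid: np.ndarray | None = None) -> list[Spectrum]:
    """Read MS1 scans from an mzML file onto the fixed channel grid.

    A deliberately small reader covering plain full-scan mzML: uncompressed
    or zlib-compressed 32/64-bit float m/z and intensity arrays, with scan
    start times converted to minutes. Metadata fields other than the
    retention time are left for the caller to fill in.
    """
    import xml.etree.ElementTree as ET

    if grid is None:
        grid = default_grid()
    ns = {"mz": "http://psi.hupo.org/ms/mzml"}

    def _findall(el, tag):
        found = el.findall(f"mz:{tag}", ns)
        return found if found else el.findall(tag)

    def _cvparams(el):
        return {p.get("name"): p for p in _findall(el, "cvParam")}

    tree = ET.parse(str(path))
    scans: list[Spectrum] = []
    for spec in tree.iter():
        if not spec.tag.endswith("spectrum") or spec.tag.endswith("chromatogram"):
            continue
        params = _cvparams(spec)
        if "ms level" in params and params["ms level"].get("value") not in (None, "", "1"):
            continue
        rt_min = None
        for scan_list in _findall(spec, "scanList"):
            for scan in _findall(scan_list, "scan"):
                p = _cvparams(scan).get("scan start time")
                if p is not None:
                    rt_min = float(p.get("value"))
                    if p.get("unitName", "minute").startswith("second"):
                        rt_min /= 60.0
        arrays = {}
        for bdal in _findall(spec, "binaryDataArrayList"):
            for bda in _findall(bdal, "binaryDataArray"):
                p = _cvparams(bda)
                binary = _findall(bda, "binary")
                if not binary or binary[0].text is None:
                    continue
                values = _decode_binary(binary[0].text.strip(), p)
                if "m/z array" in p:
                    arrays["mz"] = values
                elif "intensity array" in p:
                    arrays["intensity"] = values
        if "mz" not in arrays or "intensity" not in arrays:
            continue
        scans.append(
            Spectrum(
                channel_mz=grid,
                intensity=bin_to_grid(arrays["mz"], arrays["intensity"], grid),
                rt_min=rt_min,
                spectrum_id=spec.get("id"),
            )
        )
    return scans
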