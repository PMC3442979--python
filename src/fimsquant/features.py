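"""Principal m/z selection by the correlation-threshold rule.

A channel is *principal* to an analyte when the Pearson correlation of its
normalized intensity with concentration, over all replicate-level points of
a single-analyte calibration series, reaches the threshold (default
r ≥ 0.995, signed).  Mixed-calibrant series cannot attribute a channel to an
analyte — both analytes co-vary — so attribution always runs on
single-analyte series; the resulting feature subsets then drive calibration
on the mixed series.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .spectra import IntensityMatrix

DEFAULT_THRESHOLD = 0.995


@dataclass(frozen=True)
class ChannelScore:
    """Pearson correlation of one channel's normalized intensity with concentration."""

    mz: float
    r: float
    n_points: int
    degenerate: bool = False  # zero intensity variance → r fixed at 0

    def __post_init__(self):
        if not self.degenerate and abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be ≤ 1")


@dataclass(frozen=True)
class PrincipalFeatureSet:
    """The channels selected for one analyte, with their scores."""

    analyte_id: str
    channels: tuple[ChannelScore, ...]
    threshold: float = DEFAULT_THRESHOLD
    source: str = ""  # which series produced this selection

    @property
    def mz(self) -> np.ndarray:
        return np.array([c.mz for c in self.channels])

    def __len__(self) -> int:
        return len(self.channels)

    def to_json(self, path: str | Path | None = None) -> dict:
        doc = {
            "analyte_id": self.analyte_id,
            "threshold": self.threshold,
            "source": self.source,
            "channels": [
                {"mz": c.mz, "r": c.r, "n_points": c.n_points} for c in self.channels
            ],
        }
        if path is not None:
            Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))
        return doc

    @classmethod
    def from_json(cls, doc: dict | str | Path) -> "PrincipalFeatureSet":
        if not isinstance(doc, dict):
            doc = json.loads(Path(doc).read_text())
        return cls(
            analyte_id=doc["analyte_id"],
            channels=tuple(
                ChannelScore(c["mz"], c["r"], c["n_points"]) for c in doc["channels"]
            ),
            threshold=doc["threshold"],
            source=doc.get("source", ""),
        )


def score_channels(matrix: IntensityMatrix) -> list[ChannelScore]:
    """Pearson r of every channel's normalized intensity vs concentration.

    Computed on replicate-level points (every spectrum is a point).
    Channels with zero intensity variance get r = 0 and a degenerate flag.
    Rows without a concentration label (blanks/unknowns) are excluded.
    """
    conc = np.asarray(matrix.row_concentration, dtype=float)
    keep = ~np.isnan(conc)
    conc = conc[keep]
    values = matrix.values[keep]
    if len(np.unique(conc)) < 3:
        raise ValueError(
            "channel scoring requires ≥ 3 distinct concentration values "
            f"(got {len(np.unique(conc))}): correlation is unstable"
        )
    n = len(conc)
    yc = conc - conc.mean()
    xc = values - values.mean(axis=0)
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    degenerate = sx == 0
    denom = np.where(degenerate, 1.0, sx * sy)
    r = (xc * yc[:, None]).sum(axis=0) / denom
    r = np.where(degenerate, 0.0, np.clip(r, -1.0, 1.0))
    # exact affine channels must score exactly ±1 despite rounding
    r = np.where(np.abs(r) > 1.0 - 1e-12, np.sign(r), r)
    return [
        ChannelScore(float(mz), float(ri), n, bool(d))
        for mz, ri, d in zip(matrix.column_mz, r, degenerate)
    ]


def select_principal(
    scores: list[ChannelScore],
    threshold: float = DEFAULT_THRESHOLD,
    analyte_id: str = "",
    source: str = "",
) -> PrincipalFeatureSet:
    """Keep exactly the channels with signed r ≥ threshold, sorted by m/z.

    The threshold is inclusive and applies to signed r: principal channels
    are expected to respond positively to concentration.
    """
    if not scores:
        raise ValueError("no channel scores supplied")
    selected = tuple(
        sorted((s for s in scores if s.r >= threshold), key=lambda s: s.mz)
    )
    if not selected:
        raise ValueError(
            f"no channel reached r ≥ {threshold}; calibration is impossible with "
            "zero features — review the threshold or the calibration data"
        )
    return PrincipalFeatureSet(
        analyte_id=analyte_id, channels=selected, threshold=threshold, source=source
    )
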