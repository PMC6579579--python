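"""Flow-cytometry cross-calibration of absolute protein abundance.

Any Halo-tagged cell line can be quantified from the ratio of its
background-subtracted mean fluorescence to that of a standard line whose
absolute abundance is known:

    n_X = (I_X - I_bg_X) / (I_std - I_bg_std) * n_std

Backgrounds are the line-matched unlabeled samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, InvalidParameterError

__all__ = [
    "FCMSample",
    "FCMCalibration",
    "sample_mean_intensity",
    "scale_to_standard",
    "abundance_from_intensities",
    "dynamic_range_flags",
    "density_gate",
    "samples_from_csv",
    "LOW_ABUNDANCE_LIMIT",
    "HIGH_ABUNDANCE_LIMIT",
]

#: Below this many molecules/cell the ratio method loses robustness.
LOW_ABUNDANCE_LIMIT = 10_000
#: Above this it may saturate the detector.
HIGH_ABUNDANCE_LIMIT = 10_000_000

#: Convention: the standard line's mean is rescaled to this value.
STANDARD_SCALE_AU = 10_000.0


@dataclass(frozen=True)
class FCMSample:
    """Per-cell fluorescence events for one cell line, labeled or not."""

    cell_line: str
    labeled: bool
    event_intensities: np.ndarray
    channel: str = "TMR"

    def __post_init__(self) -> None:
        arr = np.asarray(self.event_intensities, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise InvalidParameterError(
                f"sample {self.cell_line!r}: non-finite event intensities"
            )
        object.__setattr__(self, "event_intensities", arr)

    @property
    def n_events(self) -> int:
        return int(self.event_intensities.size)


@dataclass(frozen=True)
class FCMCalibration:
    """Anchor of the cross-calibration: the standard line's abundance."""

    standard_line: str
    standard_abundance: float  # molecules/cell
    standard_scale: float = STANDARD_SCALE_AU

    def __post_init__(self) -> None:
        if self.standard_abundance <= 0:
            raise InvalidParameterError("standard abundance must be > 0")


def sample_mean_intensity(sample: FCMSample) -> float:
    """Arithmetic mean of the sample's event intensities."""
    if sample.n_events == 0:
        raise InvalidParameterError(f"sample {sample.cell_line!r} has no events")
    return float(np.mean(sample.event_intensities))


def scale_to_standard(
    samples: Sequence[FCMSample], standard_line: str
) -> dict[tuple[str, bool], float]:
    """Rescale all sample means so the labeled standard maps to 10,000 AU.

    Returns ``{(cell_line, labeled): scaled_mean}``. The abundance ratio is
    invariant under this common rescaling; it only standardizes reported
    intermediate intensities.
    """
    std = [s for s in samples if s.cell_line == standard_line and s.labeled]
    if not std:
        raise CalibrationError(f"labeled standard {standard_line!r} not found")
    std_mean = sample_mean_intensity(std[0])
    if std_mean <= 0:
        raise CalibrationError("standard mean intensity must be > 0")
    factor = STANDARD_SCALE_AU / std_mean
    return {
        (s.cell_line, s.labeled): sample_mean_intensity(s) * factor for s in samples
    }


def abundance_from_intensities(
    i_x: float,
    i_bg_x: float,
    i_std: float,
    i_bg_std: float,
    calib: FCMCalibration,
) -> tuple[float, list[str]]:
    """Absolute abundance of protein X from four mean intensities.

    Returns ``(molecules_per_cell, flags)``. A negative background-subtracted
    numerator clamps to zero and is flagged ``"negative-signal-clamped"``.
    """
    denom = i_std - i_bg_std
    if denom <= 0:
        raise CalibrationError(
            f"standard signal (I_std - I_bg_std) = {denom:g} is not positive"
        )
    flags: list[str] = []
    num = i_x - i_bg_x
    if num < 0:
        flags.append("negative-signal-clamped")
        num = 0.0
    n_x = num / denom * calib.standard_abundance
    flags.extend(dynamic_range_flags(n_x))
    return n_x, flags


def dynamic_range_flags(n_x: float) -> list[str]:
    """Warn outside the validated dynamic range of the ratio method."""
    if n_x < 0:
        raise InvalidParameterError("abundance must be >= 0")
    flags = []
    if n_x < LOW_ABUNDANCE_LIMIT:
        flags.append("low-abundance")
    if n_x > HIGH_ABUNDANCE_LIMIT:
        flags.append("high-abundance")
    return flags


def density_gate(
    x: np.ndarray, y: np.ndarray, keep_fraction: float = 0.90
) -> np.ndarray:
    """Boolean mask keeping events inside the highest-density scatter region.

    A stand-in for forward/side-scatter gating on pre-gated or synthetic
    data: kernel-density-ranks the 2D events and keeps the top
    ``keep_fraction``.
    """
    from scipy.stats import gaussian_kde

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidParameterError("x and y must be equal-length 1-D arrays")
    if not 0 < keep_fraction <= 1:
        raise InvalidParameterError("keep_fraction must be in (0, 1]")
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.ones_like(x, dtype=bool)
    dens = gaussian_kde(np.vstack([x, y]))(np.vstack([x, y]))
    cutoff = np.quantile(dens, 1 - keep_fraction)
    return dens >= cutoff


def samples_from_csv(path) -> list[FCMSample]:
    """Read event tables from CSV (cell_line, intensity_au, labeled)."""
    df = pd.read_csv(path)
    missing = {"cell_line", "intensity_au", "labeled"} - set(df.columns)
    if missing:
        raise InvalidParameterError(f"event CSV missing columns: {sorted(missing)}")
    out = []
    for (line, labeled), grp in df.groupby(["cell_line", "labeled"], sort=True):
        out.append(
            FCMSample(
                cell_line=str(line),
                labeled=bool(labeled),
                event_intensities=grp["intensity_au"].to_numpy(dtype=float),
            )
        )
    return out
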