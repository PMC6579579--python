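"""Intensity-to-concentration calibration for FCS-calibrated imaging."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ..errors import CalibrationError, InvalidParameterError

__all__ = ["CalibrationFactor", "calibration_factor"]


@dataclass(frozen=True)
class CalibrationFactor:
    """Conversion factor k (nM per AU) with the imaging background."""

    k_nm_per_au: float
    background_ib: float
    n_calibration_points: int
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        if self.k_nm_per_au <= 0:
            raise CalibrationError("k_nM must be > 0")
        if self.background_ib < 0:
            raise CalibrationError("background must be >= 0")


def calibration_factor(
    points: Sequence[tuple[float, float]], background_ib: float = 0.0
) -> CalibrationFactor:
    """Fit k_nM from (image intensity AU, FCS concentration nM) pairs.

    Least-squares line through the origin of concentration vs
    background-subtracted intensity. A single point is solved exactly.
    """
    if background_ib < 0:
        raise InvalidParameterError("background must be >= 0")
    if not points:
        raise InvalidParameterError("need >= 1 calibration point")
    intens = np.array([p[0] for p in points], dtype=float) - background_ib
    conc = np.array([p[1] for p in points], dtype=float)
    if np.all(intens <= 0):
        raise CalibrationError("all intensities are at or below background")
    if len(points) == 1:
        k = float(conc[0] / intens[0])
        resid = 0.0
    else:
        k = float(np.dot(intens, conc) / np.dot(intens, intens))
        resid = float(np.sqrt(np.mean((conc - k * intens) ** 2)))
    if k <= 0:
        raise CalibrationError(f"fitted k_nM {k} is not positive")
    return CalibrationFactor(
        k_nm_per_au=k,
        background_ib=background_ib,
        n_calibration_points=len(points),
        residual_rms=resid,
    )
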