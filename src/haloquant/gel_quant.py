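"""Absolute protein abundance from in-gel fluorescence.

A titration of purified, dye-labeled protein standard run alongside cell
lysates of known cell number yields a fluorescence-per-molecule calibration;
lysate band intensities are then converted to molecules per cell. Also
provides labeling-efficiency estimation from a dye titration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    DegenerateStandardError,
    FitFailureError,
    InsufficientStandardError,
    InvalidLaneError,
    InvalidParameterError,
)

__all__ = [
    "GelLane",
    "StandardCurve",
    "AbundanceEstimate",
    "TitrationPoint",
    "fit_standard_curve",
    "molecules_per_cell",
    "labeling_efficiency",
    "aggregate_replicates",
    "lanes_from_csv",
    "lanes_to_frame",
]


@dataclass(frozen=True)
class GelLane:
    """One gel lane: either a protein standard or a cell lysate band.

    Exactly one of ``amount`` (standard lanes, molecules) or ``n_cells``
    (lysate lanes) must be set, matching ``kind``.
    """

    lane_id: str
    kind: Literal["standard", "lysate"]
    band_intensity: float
    amount: float | None = None
    n_cells: float | None = None
    replicate_id: str | None = None
    cell_line: str | None = None

    def __post_init__(self) -> None:
        if self.band_intensity < 0 or not math.isfinite(self.band_intensity):
            raise InvalidLaneError(
                f"lane {self.lane_id!r}: band_intensity must be finite and >= 0"
            )
        if self.kind == "standard":
            if self.amount is None or self.n_cells is not None:
                raise InvalidLaneError(
                    f"lane {self.lane_id!r}: standard lanes carry 'amount' only"
                )
            if self.amount <= 0:
                raise InvalidLaneError(
                    f"lane {self.lane_id!r}: standard amount must be > 0"
                )
        elif self.kind == "lysate":
            if self.n_cells is None or self.amount is not None:
                raise InvalidLaneError(
                    f"lane {self.lane_id!r}: lysate lanes carry 'n_cells' only"
                )
        else:
            raise InvalidLaneError(f"lane {self.lane_id!r}: unknown kind {self.kind!r}")


@dataclass(frozen=True)
class StandardCurve:
    """Fitted fluorescence-per-molecule calibration line.

    The regression is through the origin by default (see
    :func:`fit_standard_curve`); ``intercept`` is zero in that case.
    """

    fluorescence_per_molecule: float
    n_points: int
    residual_rms: float
    intercept: float = 0.0
    max_standard_intensity: float = field(default=math.inf)

    def __post_init__(self) -> None:
        if self.fluorescence_per_molecule <= 0:
            raise DegenerateStandardError(
                "fluorescence_per_molecule must be > 0, got "
                f"{self.fluorescence_per_molecule}"
            )


@dataclass(frozen=True)
class AbundanceEstimate:
    """Replicate-level abundance summary for one cell line and method."""

    cell_line: str
    method: Literal["gel", "fcm", "fcs"]
    replicate_values: tuple[float, ...]
    mean: float
    std: float
    std_defined: bool = True


@dataclass(frozen=True)
class TitrationPoint:
    """Background-corrected fluorescence at one dye concentration."""

    dye_concentration: float  # nM
    background_corrected_intensity: float  # AU

    def __post_init__(self) -> None:
        if self.dye_concentration < 0:
            raise InvalidParameterError("dye concentration must be >= 0")


def fit_standard_curve(
    standard_lanes: Sequence[GelLane],
    *,
    fit_intercept: bool = False,
    weights: Literal["none", "relative"] = "none",
) -> StandardCurve:
    """Least-squares line of band intensity vs. standard amount.

    By default the line is forced through the origin; slope is the
    fluorescence per molecule (AU/molecule). Requires >= 2 standard
    lanes with distinct positive amounts. ``weights="relative"`` weights
    each lane by 1/amount^2, appropriate when band noise scales with band
    intensity (constant CV) as is typical for wide titrations.
    """
    lanes = [ln for ln in standard_lanes if ln.kind == "standard"]
    if len(lanes) < 2:
        raise InsufficientStandardError(
            f"need >= 2 standard lanes, got {len(lanes)}"
        )
    x = np.array([ln.amount for ln in lanes], dtype=float)
    y = np.array([ln.band_intensity for ln in lanes], dtype=float)
    if np.allclose(x, x[0]):
        raise InsufficientStandardError("standard amounts are all equal")

    w = 1.0 / x**2 if weights == "relative" else np.ones_like(x)
    if fit_intercept:
        A = np.column_stack([x, np.ones_like(x)]) * np.sqrt(w)[:, None]
        coef, *_ = np.linalg.lstsq(A, y * np.sqrt(w), rcond=None)
        slope, intercept = float(coef[0]), float(coef[1])
    else:
        slope = float(np.dot(w * x, y) / np.dot(w * x, x))
        intercept = 0.0
    if slope <= 0:
        raise DegenerateStandardError(f"fitted slope {slope} is not positive")
    resid = y - (slope * x + intercept)
    return StandardCurve(
        fluorescence_per_molecule=slope,
        n_points=len(lanes),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        intercept=intercept,
        max_standard_intensity=float(y.max()),
    )


def molecules_per_cell(lysate_lane: GelLane, curve: StandardCurve) -> float:
    """Convert a lysate band to molecules per cell.

    intensity / (fluorescence_per_molecule * n_cells). Lanes brighter than
    the standard range raise an extrapolation warning but still compute.
    """
    if lysate_lane.kind != "lysate":
        raise InvalidLaneError(f"lane {lysate_lane.lane_id!r} is not a lysate lane")
    if not lysate_lane.n_cells or lysate_lane.n_cells <= 0:
        raise InvalidLaneError(
            f"lane {lysate_lane.lane_id!r}: n_cells must be > 0"
        )
    if lysate_lane.band_intensity > curve.max_standard_intensity:
        warnings.warn(
            f"lane {lysate_lane.lane_id!r}: intensity "
            f"{lysate_lane.band_intensity:g} exceeds standard range "
            f"(max {curve.max_standard_intensity:g}); extrapolating",
            UserWarning,
            stacklevel=2,
        )
    return lysate_lane.band_intensity / (
        curve.fluorescence_per_molecule * lysate_lane.n_cells
    )


def labeling_efficiency(
    titration: Sequence[TitrationPoint], at_concentration: float
) -> float:
    """Labeling efficiency at a dye concentration from a saturation fit.

    Fits I(c) = Imax * c / (K + c) by nonlinear least squares and returns
    I(at_concentration) / Imax, a fraction in [0, 1].
    """
    if len(titration) < 3:
        raise InvalidParameterError("need >= 3 titration points")
    if at_concentration < 0:
        raise InvalidParameterError("query concentration must be >= 0")
    c = np.array([p.dye_concentration for p in titration], dtype=float)
    y = np.array([p.background_corrected_intensity for p in titration], dtype=float)

    def model(cc, imax, k):
        return imax * cc / (k + cc)

    ymax = float(y.max())
    if ymax <= 0:
        raise FitFailureError("all titration intensities are non-positive")
    # K=0 (instant saturation) is a valid limit the optimizer must reach.
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model,
                c,
                y,
                p0=[ymax, max(float(np.median(c[c > 0])) if (c > 0).any() else 1.0, 1e-9)],
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                maxfev=10000,
            )
    except (RuntimeError, ValueError) as exc:
        raise FitFailureError(
            "saturation fit did not converge",
            diagnostics={"concentrations": c.tolist(), "intensities": y.tolist()},
        ) from exc
    imax, k = popt
    if imax <= 0:
        raise FitFailureError("fitted Imax is non-positive", {"imax": imax, "K": k})
    if math.isinf(at_concentration):
        return 1.0
    eff = at_concentration / (k + at_concentration) if (k + at_concentration) > 0 else 1.0
    return float(min(max(eff, 0.0), 1.0))


def aggregate_replicates(
    values: Iterable[float],
    cell_line: str,
    method: Literal["gel", "fcm", "fcs"],
) -> AbundanceEstimate:
    """Mean and sample (n-1) standard deviation over biological replicates.

    A single replicate yields std 0.0 with ``std_defined=False``.
    """
    vals = tuple(float(v) for v in values)
    if not vals:
        raise InvalidParameterError("need >= 1 replicate value")
    mean = float(np.mean(vals))
    if len(vals) == 1:
        return AbundanceEstimate(cell_line, method, vals, mean, 0.0, std_defined=False)
    std = float(np.std(vals, ddof=1))
    return AbundanceEstimate(cell_line, method, vals, mean, std)


# ---------------------------------------------------------------- CSV I/O

_LANE_COLUMNS = [
    "lane_id",
    "kind",
    "intensity_au",
    "amount_molecules",
    "n_cells",
    "replicate",
    "cell_line",
]


def lanes_from_csv(path) -> list[GelLane]:
    """Read gel lanes from a CSV with the documented lane columns."""
    df = pd.read_csv(path)
    missing = {"lane_id", "kind", "intensity_au"} - set(df.columns)
    if missing:
        raise InvalidParameterError(f"lane CSV missing columns: {sorted(missing)}")
    lanes = []
    for row in df.itertuples(index=False):
        amount = getattr(row, "amount_molecules", None)
        n_cells = getattr(row, "n_cells", None)
        lanes.append(
            GelLane(
                lane_id=str(row.lane_id),
                kind=str(row.kind),
                band_intensity=float(row.intensity_au),
                amount=None if amount is None or pd.isna(amount) else float(amount),
                n_cells=None if n_cells is None or pd.isna(n_cells) else float(n_cells),
                replicate_id=str(getattr(row, "replicate", ""))
                if hasattr(row, "replicate")
                else None,
                cell_line=str(getattr(row, "cell_line", ""))
                if hasattr(row, "cell_line")
                else None,
            )
        )
    return lanes


def lanes_to_frame(lanes: Sequence[GelLane]) -> pd.DataFrame:
    """Serialize lanes to a DataFrame with the canonical column order."""
    return pd.DataFrame(
        [
            {
                "lane_id": ln.lane_id,
                "kind": ln.kind,
                "intensity_au": ln.band_intensity,
                "amount_molecules": ln.amount,
                "n_cells": ln.n_cells,
                "replicate": ln.replicate_id,
                "cell_line": ln.cell_line,
            }
            for ln in lanes
        ],
        columns=_LANE_COLUMNS,
    )
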