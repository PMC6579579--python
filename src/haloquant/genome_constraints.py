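"""Cell-cycle classification and 3D-genome model constraint calculations.

Combines absolute protein abundances with single-molecule bound/engaged
fractions and genome-level counts into per-site occupancy and per-Mb
extruding-complex density, plus the cross-method averaging used for the
final abundance estimates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "CellCycleFractions",
    "OccupancyInputs",
    "ExtrusionInputs",
    "ConstraintResults",
    "classify_cell_cycle",
    "mean_genome_copies",
    "fractional_occupancy",
    "extrusion_density",
    "combine_estimates",
    "round_half_up",
]


@dataclass(frozen=True)
class CellCycleFractions:
    """Fractions of interphase cells in G1, S and G2 (sum to 1)."""

    f_g1: float
    f_s: float
    f_g2: float

    def __post_init__(self) -> None:
        for f in (self.f_g1, self.f_s, self.f_g2):
            if not 0 <= f <= 1:
                raise InvalidParameterError(f"fraction {f} outside [0, 1]")
        if abs(self.f_g1 + self.f_s + self.f_g2 - 1.0) > 1e-9:
            raise InvalidParameterError("cell-cycle fractions must sum to 1")


@dataclass(frozen=True)
class OccupancyInputs:
    """Inputs for per-binding-site fractional occupancy."""

    f_bound: float  # fraction of protein bound to specific sites
    n_protein: float  # molecules/cell
    n_sites_haploid: float  # sites per haploid genome
    genome_copies: float  # copies/cell

    def __post_init__(self) -> None:
        if not 0 <= self.f_bound <= 1:
            raise InvalidParameterError("f_bound must be in [0, 1]")
        if self.n_protein <= 0 or self.n_sites_haploid <= 0 or self.genome_copies <= 0:
            raise InvalidParameterError("counts must be > 0")


@dataclass(frozen=True)
class ExtrusionInputs:
    """Inputs for extruding-complex density per Mb."""

    f_engaged: float  # fraction topologically engaged
    n_cohesin: float  # molecules/cell
    genome_size_mb: float  # haploid genome, Mb
    genome_copies: float
    stoichiometry: int = 1  # rings per extruding unit, 1 or 2

    def __post_init__(self) -> None:
        if not 0 <= self.f_engaged <= 1:
            raise InvalidParameterError("f_engaged must be in [0, 1]")
        if self.genome_size_mb <= 0:
            raise InvalidParameterError("genome size must be > 0")
        if self.n_cohesin <= 0 or self.genome_copies <= 0:
            raise InvalidParameterError("counts must be > 0")
        if self.stoichiometry not in (1, 2):
            raise InvalidParameterError("stoichiometry must be 1 or 2")


@dataclass(frozen=True)
class ConstraintResults:
    """Density/spacing (or occupancy) results with validity flags."""

    density_molecules_per_mb: float
    density_units_per_mb: float
    spacing_kb: float  # NaN when density is 0 (flagged)
    flags: tuple[str, ...] = ()


def classify_cell_cycle(
    events: pd.DataFrame,
    negative_control: pd.DataFrame,
    *,
    edu_quantile: float = 0.995,
) -> CellCycleFractions:
    """Classify DAPI/EdU bivariate events into G1 / S / G2 fractions.

    EdU-positive events (above the ``edu_quantile`` quantile of the
    negative control) are S-phase. EdU-negative events are split into G1
    and G2 by a two-component Gaussian mixture on DAPI, G1 being the
    lower-mean component; on mixture failure a midpoint threshold between
    the DAPI extremes is used and a warning emitted.
    """
    for name, df in (("events", events), ("negative_control", negative_control)):
        if df.empty:
            raise InvalidParameterError(f"{name} table is empty")
        if not {"dapi_au", "edu_au"} <= set(df.columns):
            raise InvalidParameterError(f"{name} needs dapi_au and edu_au columns")

    threshold = float(negative_control["edu_au"].quantile(edu_quantile))
    edu = events["edu_au"].to_numpy(dtype=float)
    dapi = events["dapi_au"].to_numpy(dtype=float)
    n = len(events)
    s_mask = edu > threshold
    n_s = int(s_mask.sum())
    neg_dapi = dapi[~s_mask]

    if neg_dapi.size == 0:
        return CellCycleFractions(0.0, 1.0, 0.0)

    n_g1, n_g2 = _split_g1_g2(neg_dapi, dapi[s_mask], n_s / n)
    return CellCycleFractions(n_g1 / n, n_s / n, n_g2 / n)


def _split_g1_g2(
    neg_dapi: np.ndarray, s_dapi: np.ndarray, s_fraction: float
) -> tuple[int, int]:
    """Count G1 (lower DAPI mode) and G2 events among EdU-negative cells.

    When the EdU-negative DAPI histogram has no resolvable 2C/4C bimodality
    (component means closer than 1.4x, well under the expected doubling),
    all events are assigned to one phase: G1 unless a sizable S population
    places its DAPI span below the cluster.
    """
    if np.ptp(neg_dapi) == 0:
        return neg_dapi.size, 0
    try:
        from sklearn.mixture import GaussianMixture

        gm = GaussianMixture(
            n_components=2, n_init=3, random_state=0, covariance_type="full"
        )
        labels = gm.fit_predict(neg_dapi.reshape(-1, 1))
        if not gm.converged_:
            raise RuntimeError("GMM did not converge")
        means = gm.means_.ravel()
        lo, hi = float(means.min()), float(means.max())
        if hi / max(lo, 1e-12) < 1.4:
            return _assign_unimodal(neg_dapi, s_dapi, s_fraction)
        g1_label = int(np.argmin(means))
        n_g1 = int((labels == g1_label).sum())
    except Exception:
        warnings.warn(
            "Gaussian mixture failed; falling back to DAPI midpoint threshold",
            UserWarning,
            stacklevel=2,
        )
        mid = 0.5 * (neg_dapi.min() + neg_dapi.max())
        n_g1 = int((neg_dapi <= mid).sum())
    return n_g1, neg_dapi.size - n_g1


def _assign_unimodal(
    neg_dapi: np.ndarray, s_dapi: np.ndarray, s_fraction: float
) -> tuple[int, int]:
    """All EdU-negative events form one DAPI cluster: call it G1 or G2."""
    if s_fraction >= 0.05 and s_dapi.size:
        # S spans 2C..4C; a cluster above its midpoint is the 4C (G2) peak
        mid = 0.5 * (np.quantile(s_dapi, 0.05) + np.quantile(s_dapi, 0.95))
        if float(np.mean(neg_dapi)) > mid:
            return 0, neg_dapi.size
        return neg_dapi.size, 0
    warnings.warn(
        "EdU-negative DAPI is unimodal and no S population is available to "
        "anchor ploidy; assigning all events to G1",
        UserWarning,
        stacklevel=3,
    )
    return neg_dapi.size, 0


def mean_genome_copies(
    fractions: CellCycleFractions,
    copies_g1: float = 2.0,
    copies_s: float = 3.0,
    copies_g2: float = 4.0,
) -> float:
    """Expected genome copies per cell over the cell-cycle distribution.

    Mid-S is assigned 3 copies by default; rounding to an integer is left
    to the caller.
    """
    return (
        copies_g1 * fractions.f_g1
        + copies_s * fractions.f_s
        + copies_g2 * fractions.f_g2
    )


def fractional_occupancy(inputs: OccupancyInputs) -> tuple[float, list[str]]:
    """Average per-site occupancy: bound molecules / total binding sites.

    f = f_bound * n_protein / (genome_copies * n_sites_haploid).  Values
    above 1 are returned as-is with an ``"over-occupancy"`` flag.
    """
    f = inputs.f_bound * inputs.n_protein / (
        inputs.genome_copies * inputs.n_sites_haploid
    )
    flags = ["over-occupancy"] if f > 1 else []
    return f, flags


def extrusion_density(inputs: ExtrusionInputs) -> ConstraintResults:
    """Density of extruding cohesin per Mb and implied spacing.

    density_molecules = f_engaged * n_cohesin / (copies * genome_Mb);
    units = molecules / stoichiometry; spacing_kb = 1000 / units.
    """
    density_mol = inputs.f_engaged * inputs.n_cohesin / (
        inputs.genome_copies * inputs.genome_size_mb
    )
    density_units = density_mol / inputs.stoichiometry
    if density_units > 0:
        spacing = 1000.0 / density_units
        flags: tuple[str, ...] = ()
    else:
        spacing = math.nan
        flags = ("zero-density-spacing-undefined",)
    return ConstraintResults(
        density_molecules_per_mb=density_mol,
        density_units_per_mb=density_units,
        spacing_kb=spacing,
        flags=flags,
    )


def round_half_up(x: float, nearest: float = 100.0) -> float:
    """Round to the nearest multiple of ``nearest``, halves away from zero
    for positive input (109,750 -> 109,800)."""
    return math.floor(x / nearest + 0.5) * nearest


def combine_estimates(values: Iterable[float], nearest: float = 100.0) -> float:
    """Cross-method final average: arithmetic mean, rounded to the nearest
    hundred with halves rounded up."""
    vals = [float(v) for v in values]
    if not vals:
        raise InvalidParameterError("need >= 1 method estimate")
    return round_half_up(float(np.mean(vals)), nearest)
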