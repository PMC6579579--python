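"""Per-compartment concentrations and molecule numbers.

For each compartment the average concentration and total molecule count are

    Ca = (It/Vp - Ib) * k_nM                      [nM]
    Nt = Ca * V_um3 * 0.602214086                 [molecules]

where It is the summed intensity, Vp the voxel count, Ib the per-voxel
background intensity and V_um3 the compartment volume. The count identity
Nt(nucleus) + Nt(cytoplasm) = Nt(cell) holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..constants import NA_NM_UM3
from ..errors import InvalidParameterError
from .calibration import CalibrationFactor
from .segment import SegmentationResult

__all__ = ["CompartmentQuant", "compartment_quant", "nuclear_fraction"]

COMPARTMENTS = ("nucleus", "cytoplasm", "cell")


@dataclass(frozen=True)
class CompartmentQuant:
    """Concentration (nM) and molecule count per compartment."""

    ca_nm: dict[str, float]
    nt: dict[str, float]
    flags: tuple[str, ...] = ()

    @property
    def nuclear_fraction(self) -> float:
        return nuclear_fraction(self)


def compartment_quant(
    seg: SegmentationResult,
    calib: CalibrationFactor,
    *,
    literal_volume_form: bool = False,
) -> CompartmentQuant:
    """Apply the calibration to segmentation statistics.

    Negative background-subtracted concentrations clamp to zero with a
    flag. ``literal_volume_form`` switches the count formula to the
    legacy literal expression Nt = (It - Vp*Ib)*k*V_um3*NA (which omits
    the 1/Vp normalization and is not additive); the default is the
    dimensionally consistent Nt = Ca*V_um3*NA.
    """
    ca: dict[str, float] = {}
    nt: dict[str, float] = {}
    flags: list[str] = []
    for comp in COMPARTMENTS:
        st = seg.stats[comp]
        if st["vp"] == 0:
            raise InvalidParameterError(f"compartment {comp!r} is empty")
        c = (st["it"] / st["vp"] - calib.background_ib) * calib.k_nm_per_au
        if c < 0:
            flags.append(f"negative-concentration-clamped:{comp}")
            c = 0.0
        ca[comp] = c
        if literal_volume_form:
            nt[comp] = (
                (st["it"] - st["vp"] * calib.background_ib)
                * calib.k_nm_per_au
                * st["v_um3"]
                * NA_NM_UM3
            )
        else:
            nt[comp] = c * st["v_um3"] * NA_NM_UM3
    return CompartmentQuant(ca_nm=ca, nt=nt, flags=tuple(flags))


def nuclear_fraction(quant: CompartmentQuant) -> float:
    """Fraction of the cell's molecules inside the nucleus."""
    total = quant.nt["cell"]
    if total <= 0:
        raise InvalidParameterError("cell molecule count must be > 0")
    return min(max(quant.nt["nucleus"] / total, 0.0), 1.0)
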