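"""Multi-channel 3D image stacks with voxel-size metadata (TIFF I/O)."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import tifffile

from ..errors import InvalidParameterError

__all__ = ["ImageStack", "read_stack_tiff", "write_stack_tiff"]

#: Canonical channel order.
CHANNELS = ("dna", "boundary", "protein")


@dataclass(frozen=True)
class ImageStack:
    """Three aligned voxel channels (DNA, cell boundary, protein).

    ``voxel_size_um`` is (z, y, x) in micrometers; anisotropy allowed.
    """

    dna: np.ndarray
    boundary: np.ndarray
    protein: np.ndarray
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        shapes = {self.dna.shape, self.boundary.shape, self.protein.shape}
        if len(shapes) != 1 or self.dna.ndim != 3:
            raise InvalidParameterError("channels must be 3-D arrays of equal shape")
        if len(self.voxel_size_um) != 3 or any(v <= 0 for v in self.voxel_size_um):
            raise InvalidParameterError("voxel sizes must be three positive values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dna.shape

    @property
    def voxel_volume_um3(self) -> float:
        vz, vy, vx = self.voxel_size_um
        return vz * vy * vx


def write_stack_tiff(stack: ImageStack, path) -> None:
    """Write channels as a CZYX TIFF with voxel size in the image description."""
    data = np.stack([stack.dna, stack.boundary, stack.protein]).astype(np.float32)
    meta = {"axes": "CZYX", "channels": list(CHANNELS),
            "voxel_size_um_zyx": list(stack.voxel_size_um)}
    tifffile.imwrite(path, data, description=json.dumps(meta))


def read_stack_tiff(path, voxel_size_um=None) -> ImageStack:
    """Read a CZYX TIFF written by :func:`write_stack_tiff`.

    ``voxel_size_um`` overrides (or supplies, for foreign files) the
    metadata voxel size.
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    if data.ndim != 4 or data.shape[0] != 3:
        raise InvalidParameterError(
            f"expected 3-channel CZYX stack, got shape {data.shape}"
        )
    if voxel_size_um is None:
        try:
            voxel_size_um = tuple(json.loads(desc)["voxel_size_um_zyx"])
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise InvalidParameterError(
                "no voxel size in TIFF metadata; pass voxel_size_um"
            ) from exc
    return ImageStack(
        dna=data[0].astype(float),
        boundary=data[1].astype(float),
        protein=data[2].astype(float),
        voxel_size_um=tuple(float(v) for v in voxel_size_um),
    )
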