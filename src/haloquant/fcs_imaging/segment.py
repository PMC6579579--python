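"""3D nucleus/cell segmentation of confocal stacks.

Pipeline: optional central crop -> z interpolation to isotropic voxels ->
3D Gaussian filter -> nucleus detection on the DNA channel by per-plane
plus whole-stack Otsu thresholding, with iterative re-thresholding after
clipping the bright histogram tail when the detected masses are implausible
-> morphological cleanup -> marker-based watershed on the boundary channel
seeded with the nuclear masses -> target nucleus/cell selection by volume
and centrality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import ball, closing
from skimage.segmentation import watershed

from ..errors import InvalidParameterError, SegmentationFailureError
from .stack import ImageStack

__all__ = ["SegmentationParams", "SegmentationResult", "segment_stack",
           "compartment_stats"]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the segmentation pipeline (defaults for interphase cells)."""

    crop_xy_um: float | None = None  # side of central xy crop; None = full frame
    gaussian_sigma_um: float = 0.5
    nuclear_volume_range_um3: tuple[float, float] = (150.0, 4000.0)
    max_nucleus_count: int = 50
    max_rethreshold_iter: int = 5
    clip_percentile: float = 99.0
    min_object_volume_um3: float = 20.0
    border_tolerance_fraction: float = 0.02
    volume_tie_tolerance: float = 0.10  # relative; ties broken by centrality


@dataclass(frozen=True)
class SegmentationResult:
    """Masks on the isotropic grid plus per-compartment raw statistics.

    ``stats`` maps compartment ("nucleus" | "cytoplasm" | "cell") to a dict
    with keys ``vp`` (voxel count), ``v_um3`` (volume) and ``it`` (summed
    protein-channel intensity).
    """

    nuclear_mask: np.ndarray
    cell_mask: np.ndarray
    voxel_volume_um3: float
    stats: dict[str, dict[str, float]]
    n_nuclei_detected: int
    threshold_iterations: int
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if np.any(self.nuclear_mask & ~self.cell_mask):
            raise InvalidParameterError("nuclear mask must lie within cell mask")


def compartment_stats(
    nuclear_mask: np.ndarray,
    cell_mask: np.ndarray,
    protein: np.ndarray,
    voxel_volume_um3: float,
) -> dict[str, dict[str, float]]:
    """Voxel counts, µm^3 volumes and summed intensities per compartment."""
    cyto_mask = cell_mask & ~nuclear_mask
    out = {}
    for name, mask in (
        ("nucleus", nuclear_mask),
        ("cytoplasm", cyto_mask),
        ("cell", cell_mask),
    ):
        vp = int(mask.sum())
        out[name] = {
            "vp": vp,
            "v_um3": vp * voxel_volume_um3,
            "it": float(protein[mask].sum()),
        }
    return out


def _isotropize(stack: ImageStack) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Linearly interpolate all channels to cubic voxels (xy pitch)."""
    vz, vy, vx = stack.voxel_size_um
    target = min(vy, vx)
    factors = (vz / target, vy / target, vx / target)
    if np.allclose(factors, 1.0):
        return stack.dna.astype(float), stack.boundary.astype(float), \
            stack.protein.astype(float), target
    chans = [
        ndi.zoom(np.asarray(c, dtype=float), factors, order=1, mode="nearest")
        for c in (stack.dna, stack.boundary, stack.protein)
    ]
    return chans[0], chans[1], chans[2], target


def _central_crop(stack: ImageStack, crop_um: float) -> ImageStack:
    _, vy, vx = stack.voxel_size_um
    nz, ny, nx = stack.shape
    hy = min(int(round(crop_um / vy / 2)), ny // 2)
    hx = min(int(round(crop_um / vx / 2)), nx // 2)
    sy = slice(ny // 2 - hy, ny // 2 + hy)
    sx = slice(nx // 2 - hx, nx // 2 + hx)
    return ImageStack(
        dna=stack.dna[:, sy, sx],
        boundary=stack.boundary[:, sy, sx],
        protein=stack.protein[:, sy, sx],
        voxel_size_um=stack.voxel_size_um,
    )


def _dual_otsu_mask(dna: np.ndarray) -> np.ndarray:
    """Per-plane Otsu combined with whole-stack Otsu (voxel must pass both)."""
    global_thr = threshold_otsu(dna)
    mask = np.zeros(dna.shape, dtype=bool)
    for z in range(dna.shape[0]):
        plane = dna[z]
        plane_thr = threshold_otsu(plane) if np.ptp(plane) > 0 else global_thr
        mask[z] = (plane > global_thr) & (plane > plane_thr)
    return mask


def segment_stack(
    stack: ImageStack, params: SegmentationParams | None = None
) -> SegmentationResult:
    """Segment the target nucleus and cell and collect compartment stats.

    Raises :class:`SegmentationFailureError` when no nuclear mass within the
    plausibility range is found after the bounded re-thresholding loop;
    warns (``watershed-leakage`` flag) when the cell mask touches the frame
    border beyond tolerance.
    """
    p = params or SegmentationParams()
    if p.crop_xy_um is not None:
        stack = _central_crop(stack, p.crop_xy_um)

    dna, boundary, protein, pitch = _isotropize(stack)
    voxel_vol = pitch**3
    sigma_vox = p.gaussian_sigma_um / pitch
    dna_f = gaussian(dna, sigma=sigma_vox, preserve_range=True)
    boundary_f = gaussian(boundary, sigma=sigma_vox, preserve_range=True)

    vmin, vmax = p.nuclear_volume_range_um3
    min_vox = max(int(round(p.min_object_volume_um3 / voxel_vol)), 1)

    work = dna_f.copy()
    labels = None
    accepted: list = []
    iterations = 0
    diagnostics: dict = {}
    for iterations in range(p.max_rethreshold_iter + 1):
        mask = _dual_otsu_mask(work)
        mask = closing(mask, ball(1))
        labels = cc_label(mask, connectivity=3)  # 26-neighbor
        labels = _drop_small(labels, min_vox)
        props = regionprops(labels)
        accepted = [
            r for r in props if vmin <= r.area * voxel_vol <= vmax
        ]
        diagnostics = {
            "iteration": iterations,
            "n_components": len(props),
            "volumes_um3": sorted(r.area * voxel_vol for r in props),
        }
        if 1 <= len(accepted) <= p.max_nucleus_count:
            break
        # suppress the bright tail and re-threshold
        work = np.minimum(work, np.percentile(work, p.clip_percentile))
    else:
        pass
    if not accepted:
        raise SegmentationFailureError(
            "no nuclear mass within the plausibility range "
            f"{p.nuclear_volume_range_um3} after {iterations + 1} attempts",
            diagnostics=diagnostics,
        )

    target = _select_target(accepted, dna.shape, p.volume_tie_tolerance)
    nuclear_mask = labels == target.label

    # cell region: marker-based watershed on the boundary channel
    markers = np.zeros(labels.shape, dtype=np.int32)
    for r in accepted:
        markers[labels == r.label] = r.label
    bg_label = labels.max() + 1
    bg_thr = threshold_otsu(boundary_f) if np.ptp(boundary_f) > 0 else np.inf
    background = (boundary_f <= bg_thr) & (labels == 0)
    markers[background] = bg_label
    regions = watershed(-boundary_f, markers)
    cell_mask = (regions == target.label) & (boundary_f > bg_thr)
    cell_mask |= nuclear_mask  # nucleus is part of the cell by definition

    flags = []
    border = np.zeros(cell_mask.shape, dtype=bool)
    border[0], border[-1] = True, True
    border[:, 0], border[:, -1] = True, True
    border[:, :, 0], border[:, :, -1] = True, True
    leak = (cell_mask & border).sum() / max(cell_mask.sum(), 1)
    if leak > p.border_tolerance_fraction:
        flags.append("watershed-leakage")
        warnings.warn(
            f"cell mask touches frame border ({leak:.1%} of its voxels)",
            UserWarning,
            stacklevel=2,
        )

    stats = compartment_stats(nuclear_mask, cell_mask, protein, voxel_vol)
    return SegmentationResult(
        nuclear_mask=nuclear_mask,
        cell_mask=cell_mask,
        voxel_volume_um3=voxel_vol,
        stats=stats,
        n_nuclei_detected=len(accepted),
        threshold_iterations=iterations,
        flags=tuple(flags),
    )


def _drop_small(labels: np.ndarray, min_vox: int) -> np.ndarray:
    """Zero out connected components below the minimum voxel count."""
    counts = np.bincount(labels.ravel())
    small = np.nonzero(counts < min_vox)[0]
    if small.size:
        labels = np.where(np.isin(labels, small), 0, labels)
    return labels


def _select_target(accepted, shape, tie_tolerance):
    """Largest in-range nucleus; near-ties resolved by distance to center."""
    center = np.array(shape, dtype=float) / 2.0
    vol_max = max(r.area for r in accepted)
    candidates = [r for r in accepted if r.area >= (1 - tie_tolerance) * vol_max]
    return min(
        candidates,
        key=lambda r: float(np.linalg.norm(np.array(r.centroid) - center)),
    )
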