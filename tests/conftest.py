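import warnings

import numpy as np
import pytest

from haloquant import synthetic
from haloquant.fcs_imaging import (
    CalibrationFactor,
    SegmentationParams,
    compartment_quant,
    segment_stack,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_phantom(
    seed=0,
    conc_nuc_nm=144.3,
    conc_cyt_nm=10.0,
    noise=False,
    voxel_size_um=(0.25, 0.25, 0.25),
    shape=(64, 112, 112),
):
    """Standard single-cell phantom used across segmentation tests."""
    center = tuple(n * v / 2 for n, v in zip(shape, voxel_size_um))
    return synthetic.gen_image_stack(
        nucleus=synthetic.Ellipsoid(center, (4.0, 6.0, 6.0)),
        cell=synthetic.Ellipsoid(center, (5.5, 10.5, 10.5)),
        conc_nuc_nm=conc_nuc_nm,
        conc_cyt_nm=conc_cyt_nm,
        k_nm_per_au=2.0,
        background_au=1.0,
        voxel_size_um=voxel_size_um,
        shape=shape,
        seed=seed,
        poisson_scale=20.0 if noise else 0.0,
        read_noise_sd=2.0 if noise else 0.0,
    )


def segment_quiet(stack, params=None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return segment_stack(stack, params)


def dice(a, b):
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


@pytest.fixture(scope="session")
def noiseless_phantom_segmentation():
    """Segment the canonical noiseless phantom once per session."""
    stack, truth = make_phantom(seed=0)
    seg = segment_quiet(stack)
    return stack, truth, seg


@pytest.fixture
def unit_calibration():
    return CalibrationFactor(k_nm_per_au=2.0, background_ib=1.0, n_calibration_points=1)
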