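import numpy as np
import pytest

from conftest import dice, make_phantom, segment_quiet

from haloquant import synthetic
from haloquant.constants import NA_NM_UM3
from haloquant.errors import (
    GeometryError,
    InvalidParameterError,
    SegmentationFailureError,
)
from haloquant.fcs_imaging import (
    CalibrationFactor,
    SegmentationParams,
    compartment_quant,
    nuclear_fraction,
    segment_stack,
)
from haloquant.fcs_imaging.quantify import CompartmentQuant
from haloquant.fcs_imaging.segment import compartment_stats


class TestPhantomGeneration:
    def test_uniform_background_only(self):
        stack, _ = synthetic.gen_image_stack(
            nucleus=synthetic.Ellipsoid((4, 4, 4), (2, 2, 2)),
            cell=synthetic.Ellipsoid((4, 4, 4), (3, 3, 3)),
            conc_nuc_nm=0.0, conc_cyt_nm=0.0, k_nm_per_au=1.0,
            background_au=7.0, voxel_size_um=(0.5, 0.5, 0.5),
            shape=(16, 16, 16),
        )
        np.testing.assert_allclose(stack.protein, 7.0)

    def test_sphere_volume(self):
        # radius 5 um at isotropic 0.5 um voxels -> within 2% of 4/3*pi*125
        sphere = synthetic.Ellipsoid((8, 8, 8), (5, 5, 5))
        mask = sphere.mask((32, 32, 32), (0.5, 0.5, 0.5))
        vox_vol = mask.sum() * 0.125
        assert vox_vol == pytest.approx(4 / 3 * np.pi * 125, rel=0.02)

    def test_ground_truth_count_arithmetic(self):
        _, truth = make_phantom(conc_nuc_nm=144.3)
        v = truth["volumes_um3"]["nucleus"]
        assert truth["counts"]["nucleus"] == pytest.approx(
            144.3 * v * NA_NM_UM3, rel=1e-12
        )

    def test_nucleus_outside_cell_errors(self):
        with pytest.raises(GeometryError):
            synthetic.gen_image_stack(
                nucleus=synthetic.Ellipsoid((4, 4, 4), (3, 3, 3)),
                cell=synthetic.Ellipsoid((4, 4, 4), (2, 2, 2)),
                conc_nuc_nm=1.0, conc_cyt_nm=1.0, k_nm_per_au=1.0,
                background_au=0.0, voxel_size_um=(0.5, 0.5, 0.5),
                shape=(16, 16, 16),
            )


class TestSegmentation:
    def test_noiseless_dice(self, noiseless_phantom_segmentation):
        _, truth, seg = noiseless_phantom_segmentation
        # phantom is already isotropic, so masks share the truth grid
        assert dice(seg.nuclear_mask, truth["nuclear_mask"]) >= 0.98

    def test_centered_nucleus_selected(self):
        # two equal nuclei; the centered one must win
        shape = (48, 96, 120)
        vox = (0.25, 0.25, 0.25)
        center = tuple(n * v / 2 for n, v in zip(shape, vox))
        off_center = (center[0], center[1], center[2] + 8.5)
        nuc = synthetic.Ellipsoid(center, (3.0, 3.75, 3.75))
        other = synthetic.Ellipsoid(off_center, (3.0, 3.75, 3.75))
        cell = synthetic.Ellipsoid(center, (5.0, 11.0, 13.0))
        base_mask = nuc.mask(shape, vox) | other.mask(shape, vox)
        stack, _ = synthetic.gen_image_stack(
            nucleus=nuc, cell=cell, conc_nuc_nm=100.0, conc_cyt_nm=10.0,
            k_nm_per_au=1.0, background_au=1.0, voxel_size_um=vox, shape=shape,
        )
        # paint the second nucleus into the DNA channel
        dna = np.where(base_mask, 1000.0, 0.0)
        from haloquant.fcs_imaging import ImageStack

        stack2 = ImageStack(
            dna=dna, boundary=stack.boundary, protein=stack.protein,
            voxel_size_um=vox,
        )
        seg = segment_quiet(stack2)
        assert seg.n_nuclei_detected == 2
        assert dice(seg.nuclear_mask, nuc.mask(shape, vox)) >= 0.95

    def test_failure_when_out_of_range(self):
        stack, _ = make_phantom(seed=0)
        params = SegmentationParams(nuclear_volume_range_um3=(4500.0, 5000.0))
        with pytest.raises(SegmentationFailureError) as err:
            segment_quiet(stack, params)
        assert "plausibility" in str(err.value)
        assert err.value.diagnostics  # carries what was seen

    def test_anisotropic_voxels_handled(self):
        stack, truth = make_phantom(
            voxel_size_um=(0.6, 0.2, 0.2), shape=(27, 128, 128)
        )
        seg = segment_quiet(stack)
        v_true = truth["volumes_um3"]["nucleus"]
        assert seg.stats["nucleus"]["v_um3"] == pytest.approx(v_true, rel=0.05)


class TestCompartmentQuant:
    def test_pure_background(self, noiseless_phantom_segmentation, unit_calibration):
        _, _, seg = noiseless_phantom_segmentation
        # background-only stats: every compartment at exactly Ib
        stats = {
            c: {"vp": 100, "v_um3": 10.0, "it": 100 * unit_calibration.background_ib}
            for c in ("nucleus", "cytoplasm", "cell")
        }
        seg2 = _seg_with_stats(seg, stats)
        q = compartment_quant(seg2, unit_calibration)
        assert all(v == 0.0 for v in q.ca_nm.values())
        assert all(v == 0.0 for v in q.nt.values())

    def test_direct_arithmetic(self, noiseless_phantom_segmentation):
        _, _, seg = noiseless_phantom_segmentation
        calib = CalibrationFactor(k_nm_per_au=2.0, background_ib=3.0,
                                  n_calibration_points=2)
        stats = {
            c: {"vp": 1000, "v_um3": 100.0, "it": 1000 * 8.0}  # mean-bg = 5
            for c in ("nucleus", "cytoplasm", "cell")
        }
        q = compartment_quant(_seg_with_stats(seg, stats), calib)
        assert q.ca_nm["nucleus"] == pytest.approx(10.0)
        assert q.nt["nucleus"] == pytest.approx(10.0 * 100.0 * NA_NM_UM3)

    def test_full_round_trip_concentration(
        self, noiseless_phantom_segmentation, unit_calibration
    ):
        _, truth, seg = noiseless_phantom_segmentation
        q = compartment_quant(seg, unit_calibration)
        assert q.ca_nm["nucleus"] == pytest.approx(truth["conc_nuc_nm"], rel=0.02)

    def test_additivity(self, noiseless_phantom_segmentation, unit_calibration):
        _, _, seg = noiseless_phantom_segmentation
        q = compartment_quant(seg, unit_calibration)
        total = q.nt["nucleus"] + q.nt["cytoplasm"]
        assert total == pytest.approx(q.nt["cell"], rel=1e-6)

    def test_resampling_invariance(self):
        # same geometry at two voxel sizes -> Nt within discretization tolerance
        counts = []
        for vox, shape in [((0.25, 0.25, 0.25), (64, 112, 112)),
                           ((0.35, 0.35, 0.35), (46, 80, 80))]:
            stack, truth = make_phantom(voxel_size_um=vox, shape=shape)
            seg = segment_quiet(stack)
            calib = CalibrationFactor(2.0, 1.0, 1)
            q = compartment_quant(seg, calib)
            counts.append(q.nt["cell"])
        assert counts[1] == pytest.approx(counts[0], rel=0.02)

    def test_literal_volume_form_differs(
        self, noiseless_phantom_segmentation, unit_calibration
    ):
        _, _, seg = noiseless_phantom_segmentation
        q_std = compartment_quant(seg, unit_calibration)
        q_lit = compartment_quant(seg, unit_calibration, literal_volume_form=True)
        # literal published expression omits the 1/Vp normalization
        ratio = q_lit.nt["cell"] / q_std.nt["cell"]
        assert ratio == pytest.approx(seg.stats["cell"]["vp"], rel=1e-9)


class TestNuclearFraction:
    def test_all_nuclear(self):
        q = CompartmentQuant(
            ca_nm={"nucleus": 10, "cytoplasm": 0, "cell": 5},
            nt={"nucleus": 100.0, "cytoplasm": 0.0, "cell": 100.0},
        )
        assert nuclear_fraction(q) == 1.0

    def test_zero_nuclear(self):
        q = CompartmentQuant(
            ca_nm={"nucleus": 0, "cytoplasm": 5, "cell": 3},
            nt={"nucleus": 0.0, "cytoplasm": 50.0, "cell": 50.0},
        )
        assert nuclear_fraction(q) == 0.0

    def test_analytic_ratio(self):
        # conc nuc:cyt = 20:1 with volume 1:2 -> 20/22
        nuc_n = 20.0 * 1.0
        cyt_n = 1.0 * 2.0
        q = CompartmentQuant(
            ca_nm={"nucleus": 20, "cytoplasm": 1, "cell": 0},
            nt={"nucleus": nuc_n, "cytoplasm": cyt_n, "cell": nuc_n + cyt_n},
        )
        assert nuclear_fraction(q) == pytest.approx(20 / 22)

    def test_synthetic_nuclear_localization(
        self, noiseless_phantom_segmentation, unit_calibration
    ):
        _, truth, seg = noiseless_phantom_segmentation
        q = compartment_quant(seg, unit_calibration)
        expected = truth["counts"]["nucleus"] / truth["counts"]["cell"]
        assert nuclear_fraction(q) == pytest.approx(expected, abs=0.02)

    def test_zero_cell_errors(self):
        q = CompartmentQuant(
            ca_nm={"nucleus": 0, "cytoplasm": 0, "cell": 0},
            nt={"nucleus": 0.0, "cytoplasm": 0.0, "cell": 0.0},
        )
        with pytest.raises(InvalidParameterError):
            nuclear_fraction(q)


def test_compartment_stats_truth_masks():
    stack, truth = make_phantom()
    stats = compartment_stats(
        truth["nuclear_mask"], truth["cell_mask"], stack.protein,
        stack.voxel_volume_um3,
    )
    assert stats["nucleus"]["v_um3"] == pytest.approx(
        truth["volumes_um3"]["nucleus"], rel=1e-12
    )
    # exact concentration recovery on the true masks
    calib = CalibrationFactor(2.0, 1.0, 1)
    ca = (stats["nucleus"]["it"] / stats["nucleus"]["vp"] - 1.0) * 2.0
    assert ca == pytest.approx(truth["conc_nuc_nm"], rel=1e-9)


def _seg_with_stats(seg, stats):
    from dataclasses import replace

    return replace(seg, stats=stats)


def test_stack_tiff_round_trip(tmp_path):
    from haloquant.fcs_imaging import read_stack_tiff, write_stack_tiff

    stack, _ = make_phantom(shape=(8, 16, 16), voxel_size_um=(0.5, 0.25, 0.25))
    path = tmp_path / "stack.tif"
    write_stack_tiff(stack, path)
    back = read_stack_tiff(path)
    assert back.voxel_size_um == stack.voxel_size_um
    np.testing.assert_allclose(back.protein, stack.protein, rtol=1e-6)
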