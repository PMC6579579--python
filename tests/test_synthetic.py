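import numpy as np
import pytest

from haloquant import synthetic
from haloquant.errors import InvalidParameterError
from haloquant.gel_quant import lanes_to_frame


class TestDeterminism:
    def test_gel_lanes_bytewise(self):
        a = synthetic.gen_gel_lanes(1e5, 2.0, [10, 20], [100], 0.1, seed=42)[0]
        b = synthetic.gen_gel_lanes(1e5, 2.0, [10, 20], [100], 0.1, seed=42)[0]
        assert lanes_to_frame(a).to_csv() == lanes_to_frame(b).to_csv()

    def test_fcm_events_bytewise(self):
        a = synthetic.gen_fcm_events([(1e4, 0.5)], (2.0, 0.3), 1000, seed=9)[0]
        b = synthetic.gen_fcm_events([(1e4, 0.5)], (2.0, 0.3), 1000, seed=9)[0]
        for sa, sb in zip(a, b):
            assert sa.event_intensities.tobytes() == sb.event_intensities.tobytes()

    def test_fcs_curve_bytewise(self):
        lags = np.geomspace(1e-6, 1.0, 64)
        a = synthetic.gen_fcs_curve(5, 0.7, 1e-4, 1e-2, 5, 0, lags, 0.01, seed=3)[0]
        b = synthetic.gen_fcs_curve(5, 0.7, 1e-4, 1e-2, 5, 0, lags, 0.01, seed=3)[0]
        assert a.g.tobytes() == b.g.tobytes()

    def test_image_stack_bytewise(self):
        kwargs = dict(
            nucleus=synthetic.Ellipsoid((4, 4, 4), (2, 2, 2)),
            cell=synthetic.Ellipsoid((4, 4, 4), (3, 3, 3)),
            conc_nuc_nm=100.0, conc_cyt_nm=5.0, k_nm_per_au=1.0,
            background_au=1.0, voxel_size_um=(0.5, 0.5, 0.5),
            shape=(16, 16, 16), seed=11, poisson_scale=10.0,
        )
        a = synthetic.gen_image_stack(**kwargs)[0]
        b = synthetic.gen_image_stack(**kwargs)[0]
        assert a.protein.tobytes() == b.protein.tobytes()

    def test_cell_cycle_bytewise(self):
        a = synthetic.gen_cell_cycle((0.2, 0.5, 0.3), n_events=500, seed=5)[0]
        b = synthetic.gen_cell_cycle((0.2, 0.5, 0.3), n_events=500, seed=5)[0]
        assert a.to_csv() == b.to_csv()

    def test_different_seeds_differ(self):
        a = synthetic.gen_fcm_events([(1e4, 0.5)], (2.0, 0.3), 100, seed=1)[0]
        b = synthetic.gen_fcm_events([(1e4, 0.5)], (2.0, 0.3), 100, seed=2)[0]
        assert not np.array_equal(a[0].event_intensities, b[0].event_intensities)


class TestGelGenerator:
    def test_noiseless_standard_linearity(self):
        lanes, _ = synthetic.gen_gel_lanes(100, 2.0, [10], [1], noise_cv=0.0)
        std = next(ln for ln in lanes if ln.kind == "standard")
        assert std.band_intensity == pytest.approx(20.0)

    def test_noiseless_lysate(self):
        lanes, _ = synthetic.gen_gel_lanes(100, 2.0, [10], [1000], noise_cv=0.0)
        lys = next(ln for ln in lanes if ln.kind == "lysate")
        assert lys.band_intensity == pytest.approx(200_000.0)

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            synthetic.gen_gel_lanes(0.0, 2.0, [10], [100])
        with pytest.raises(InvalidParameterError):
            synthetic.gen_gel_lanes(100, -1.0, [10], [100])
        with pytest.raises(InvalidParameterError):
            synthetic.gen_gel_lanes(100, 2.0, [10], [100], noise_cv=-0.1)

    def test_monte_carlo_sampling_distribution(self):
        # downstream estimate lands within 3 sd of truth (sd from MC reps)
        from haloquant import gel_quant

        truth_abundance = 1e5

        def estimate(seed):
            import warnings

            lanes, _ = synthetic.gen_gel_lanes(
                truth_abundance, 2.0, [10, 20, 40, 80], [1000] * 5,
                noise_cv=0.1, seed=seed,
            )
            curve = gel_quant.fit_standard_curve(
                [ln for ln in lanes if ln.kind == "standard"]
            )
            with warnings.catch_warnings():
                # lysate lanes intentionally sit above this tiny titration
                warnings.simplefilter("ignore", UserWarning)
                vals = [
                    gel_quant.molecules_per_cell(ln, curve)
                    for ln in lanes
                    if ln.kind == "lysate"
                ]
            return float(np.mean(vals))

        reps = np.array([estimate(s) for s in range(2000)])
        sd = reps.std(ddof=1)
        assert abs(estimate(99_999) - truth_abundance) <= 3 * sd
        # and the estimator is unbiased within MC error
        assert reps.mean() == pytest.approx(truth_abundance, rel=0.01)


class TestFCMGenerator:
    def test_noiseless_mean(self):
        samples, _ = synthetic.gen_fcm_events(
            [(1000.0, 2.0)], (-np.inf, 0.0), 100, signal_sigma=0.0
        )
        labeled = next(s for s in samples if s.labeled)
        assert labeled.event_intensities.mean() == pytest.approx(2000.0)

    def test_empty_lines_error(self):
        with pytest.raises(InvalidParameterError):
            synthetic.gen_fcm_events([], (2.0, 0.3), 100)

    def test_mean_parameterization_unbiased(self):
        # lognormal is parameterized by its arithmetic mean
        samples, _ = synthetic.gen_fcm_events(
            [(1e4, 0.1)], (-np.inf, 0.0), 200_000, seed=0, signal_sigma=0.4
        )
        labeled = next(s for s in samples if s.labeled)
        assert labeled.event_intensities.mean() == pytest.approx(1e3, rel=0.01)


class TestFCSGenerator:
    def test_zero_lag_limit(self):
        lags = np.array([1e-9, 1e-8, 1e-7])
        curve, _ = synthetic.gen_fcs_curve(4.0, 0.5, 1e-4, 1e-2, 5.0, 0.02, lags)
        assert curve.g[0] == pytest.approx(0.02 + 0.25, rel=1e-4)

    def test_long_lag_limit(self):
        lags = np.array([1e3, 1e4])
        curve, _ = synthetic.gen_fcs_curve(4.0, 0.5, 1e-4, 1e-2, 5.0, 0.02, lags)
        assert curve.g[-1] == pytest.approx(0.02, abs=1e-5)

    def test_invalid_kappa(self):
        with pytest.raises(InvalidParameterError):
            synthetic.gen_fcs_curve(
                4.0, 0.5, 1e-4, 1e-2, 0.0, 0.0, np.array([1e-4, 1e-3])
            )

    def test_trace_correlator_smoke(self):
        rng = np.random.default_rng(0)
        trace = rng.poisson(100, 10_000).astype(float)
        curve = synthetic.autocorrelate_trace(trace, dt_s=1e-4, max_lag_s=1e-2)
        # uncorrelated shot noise: G ~ 0 at all lags
        assert np.abs(curve.g).max() < 0.01


class TestCoIPGenerator:
    def test_loading_validation(self):
        with pytest.raises(InvalidParameterError):
            synthetic.gen_coip(0.1, 0.3, loading=(0.0, 0.1, 0.9))
        with pytest.raises(InvalidParameterError):
            synthetic.gen_coip(1.5, 0.3)

    def test_truth_records_efficiencies(self):
        _, truth = synthetic.gen_coip(0.3, 0.4)
        assert truth["pct_ip"] == pytest.approx(0.4)
        assert truth["pct_coip"] == pytest.approx(0.4 * 0.3 / 3)


class TestCellCycleGenerator:
    def test_fraction_validation(self):
        with pytest.raises(InvalidParameterError):
            synthetic.gen_cell_cycle((0.5, 0.2, 0.2))
        with pytest.raises(InvalidParameterError):
            synthetic.gen_cell_cycle((0.2, 0.5, 0.3), n_events=-1)

    def test_pure_g1_events(self):
        events, control, _ = synthetic.gen_cell_cycle(
            (1.0, 0.0, 0.0), n_events=5000, seed=0
        )
        thr = control["edu_au"].quantile(0.995)
        assert (events["edu_au"] > thr).mean() < 0.02
        assert events["dapi_au"].mean() == pytest.approx(100.0, rel=0.02)

    def test_s_events_edu_shifted(self):
        events, control, _ = synthetic.gen_cell_cycle(
            (0.0, 1.0, 0.0), n_events=2000, seed=0
        )
        thr = control["edu_au"].quantile(0.995)
        assert (events["edu_au"] > thr).mean() > 0.99
        assert events["dapi_au"].between(80, 230).all()
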