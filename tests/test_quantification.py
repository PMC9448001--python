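import numpy as np
import pytest

import fissionlapse as fl
from fissionlapse.quantification import (
    cell_trace,
    masked_region_traces,
    minimal_half_signal_hull,
    normalize_and_average,
)


def gaussian_blob(size=41, sigma=5.0, center=None):
    if center is None:
        center = ((size - 1) / 2.0, (size - 1) / 2.0)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    return np.exp(-((yy - center[0]) ** 2 + (xx - center[1]) ** 2)
                  / (2.0 * sigma ** 2))


class TestMinimalHalfSignalHull:
    def test_single_dominant_pixel(self):
        img = np.zeros((5, 5))
        img[2, 2] = 60.0
        img[0, 0] = 40.0
        res = minimal_half_signal_hull(img, fraction=0.5)
        assert res.area == 1.0
        assert res.contained_signal == 60.0
        assert res.concentration == 60.0

    def test_gaussian_blob_matches_analytic_half_mass_disk(self):
        sigma = 5.0
        res = minimal_half_signal_hull(gaussian_blob(sigma=sigma), fraction=0.5)
        analytic = np.pi * (sigma * np.sqrt(2 * np.log(2))) ** 2  # ~108.9 px^2
        assert res.area == pytest.approx(analytic, rel=0.10)
        assert res.contained_fraction >= 0.5

    def test_uniform_square_deterministic_tiebreak(self):
        img = np.zeros((12, 12))
        img[1:11, 1:11] = 1.0
        res = minimal_half_signal_hull(img, fraction=0.5)
        # exactly 50 of 100 equal pixels selected, in raster order
        assert res.contained_fraction == pytest.approx(0.5)
        assert res.vertices[:, 0].max() <= 5  # first five rows only

    def test_contained_fraction_bound_on_random_images(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            img = rng.random((16, 16))
            res = minimal_half_signal_hull(img, fraction=0.5)
            assert res.contained_fraction >= 0.5

    def test_area_monotone_in_fraction(self):
        img = gaussian_blob(sigma=4.0)
        areas = [minimal_half_signal_hull(img, fraction=f).area
                 for f in (0.2, 0.4, 0.6, 0.8)]
        assert all(a <= b for a, b in zip(areas, areas[1:]))

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError, match="total signal"):
            minimal_half_signal_hull(np.zeros((8, 8)))

    def test_translation_invariance(self):
        a = minimal_half_signal_hull(gaussian_blob(center=(15, 15)))
        b = minimal_half_signal_hull(gaussian_blob(center=(25, 22)))
        assert a.area == pytest.approx(b.area, rel=0.02)
        assert a.concentration == pytest.approx(b.concentration, rel=0.02)


class TestCellTrace:
    def test_noiseless_trace_matches_ground_truth(self, noiseless_cyclin_run):
        run = noiseless_cyclin_run
        footprint = np.asarray(run["movie"].channel("reference")[0]) > 0
        tr = cell_trace(run["unmixed"], footprint)
        np.testing.assert_allclose(tr.total_signal, run["truth"].true_trace,
                                   rtol=0.01)

    def test_homogeneity(self, noiseless_cyclin_run):
        run = noiseless_cyclin_run
        movie = run["unmixed"]
        footprint = np.asarray(run["movie"].channel("reference")[0]) > 0
        doubled = fl.Movie(data=movie.data * 2.0,
                           channel_names=list(movie.channel_names),
                           frame_interval=movie.frame_interval)
        t1 = cell_trace(movie, footprint)
        t2 = cell_trace(doubled, footprint)
        np.testing.assert_allclose(t2.total_signal, 2 * t1.total_signal,
                                   rtol=1e-9)
        np.testing.assert_allclose(t2.concentration, 2 * t1.concentration,
                                   rtol=1e-9)
        ok = ~np.isnan(t1.hull_area)
        np.testing.assert_allclose(t2.hull_area[ok], t1.hull_area[ok])

    def test_zero_reporter_frame_zero_concentration(self):
        data = np.zeros((2, 2, 16, 16))
        data[:, 1] = 10.0  # reference only
        movie = fl.Movie(data=data, channel_names=["reporter", "reference"])
        region = np.zeros((16, 16), dtype=bool)
        region[4:12, 4:12] = True
        tr = cell_trace(movie, region)
        np.testing.assert_allclose(tr.total_signal, 0.0, atol=1e-9)
        np.testing.assert_allclose(tr.concentration, 0.0)

    def test_empty_region_rejected(self):
        movie = fl.Movie(data=np.ones((1, 1, 8, 8)), channel_names=["reporter"])
        with pytest.raises(ValueError, match="empty cell region"):
            cell_trace(movie, np.zeros((8, 8), dtype=bool))


class TestMaskedRegionTraces:
    def test_zero_movie_gives_zero_traces(self):
        data = np.zeros((3, 1, 16, 16))
        movie = fl.Movie(data=data, channel_names=["reporter"])
        cell = np.zeros((16, 16), dtype=bool)
        cell[4:12, 4:12] = True
        peak = np.zeros_like(cell)
        peak[7:9, 7:9] = True
        ms = fl.MaskSet(peak_mask=peak, cell_mask=cell,
                        cytoplasm_mask=cell & ~peak, background_level=0.0)
        tr = masked_region_traces(movie, [ms] * 3)
        np.testing.assert_allclose(tr.region_signals["peak"], 0.0)
        np.testing.assert_allclose(tr.region_signals["cytoplasm"], 0.0)

    def test_wildtype_cytoplasm_minimum_in_spindle_window(self, wildtype_eb1_run):
        run = wildtype_eb1_run
        tr = masked_region_traces(run["unmixed"], run["static_masks"])
        cyto = tr.region_signals["cytoplasm"]
        sp = run["truth"].event_frame(0, "SP")
        spb = run["truth"].event_frame(0, "SPB")
        assert sp <= int(np.argmin(cyto)) <= spb

    def test_apc_cytoplasm_stays_suppressed_after_sp(self):
        scene, k = fl.make_preset_config("apc_mutant", reporter="eb1")
        movie, truth = fl.simulate_movie(scene, k, seed=5, frame_interval=1.0)
        unmixed, _ = fl.unmix_movie(movie)
        g = np.asarray(unmixed.channel("reporter"))
        r = np.asarray(movie.channel("reference"))
        from fissionlapse.segmentation import build_static_mask_set
        static = build_static_mask_set(g, r)
        tr = masked_region_traces(unmixed, [static] * movie.n_frames)
        cyto = tr.region_signals["cytoplasm"]
        sp = truth.event_frame(0, "SP")
        pre = cyto[:truth.event_frame(0, "PS")].mean()
        post = cyto[sp + 1:]
        assert np.all(post < 0.5 * pre)


class TestNormalizeAndAverage:
    @staticmethod
    def _trace(cell_id, y, dt=3.0):
        t = np.arange(len(y)) * dt
        return fl.CellTrace(cell_id, t, np.asarray(y, float),
                            np.full(len(y), np.nan), np.zeros(len(y)))

    def test_identical_traces_zero_sem(self):
        y = [1, 2, 5, 3, 1]
        grid, mean, sem, n = normalize_and_average(
            [self._trace(i, y) for i in range(4)])
        np.testing.assert_allclose(mean, np.asarray(y) / 5.0)
        np.testing.assert_allclose(sem, 0.0, atol=1e-12)
        assert np.all(n == 4)

    def test_single_trace_passthrough(self):
        grid, mean, sem, n = normalize_and_average([self._trace(1, [2, 4, 8])])
        np.testing.assert_allclose(mean, [0.25, 0.5, 1.0])
        np.testing.assert_allclose(sem, 0.0)

    def test_all_zero_trace_rejected(self):
        with pytest.raises(ValueError, match="non-positive maximum"):
            normalize_and_average([self._trace(1, [0, 0, 0])])

    def test_jittered_peaks_attenuate_averaged_peak(self):
        # asynchrony across cells lowers the averaged peak below the
        # individual normalized peaks (always exactly 1)
        rng = np.random.default_rng(12)
        k = fl.KineticParams()
        t = np.arange(0, 40, 3.0)
        traces = []
        for i in range(12):
            shift = rng.uniform(-4, 4)
            y = fl.simulate_trace(
                fl.KineticParams(onset_time=k.onset_time + shift), t)
            traces.append(self._trace(i, y))
        _, mean, _, _ = normalize_and_average(traces)
        assert mean.max() < 0.97

    def test_anchor_alignment(self):
        y = [1, 1, 10, 1, 1]
        traces = [self._trace(0, [1] + y[:-1]), self._trace(1, y)]
        grid, mean, sem, n = normalize_and_average(traces,
                                                   anchor_times=[9.0, 6.0])
        peak_idx = int(np.argmax(mean))
        assert grid[peak_idx] == pytest.approx(0.0)
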