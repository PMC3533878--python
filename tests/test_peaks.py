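"""Peak detection, deconvolution, filtering and integration."""

import math

import numpy as np
import pytest

from gcmskit.binning import IntensityMatrix, build_intensity_matrix_i, get_ic_at_mass
from gcmskit.core import IonChromatogram, MassSpectrum, RawRun, ScanRecord
from gcmskit.peaks import (
    PRESETS,
    DetectionParams,
    Peak,
    deconvolute,
    detect_peaks,
    filter_num_ions,
    filter_rel_intensity,
    find_ion_maxima,
    integrate_ion,
    make_uid,
    quantify_peak,
    read_peaks_json,
    write_peaks_csv,
    write_peaks_json,
)
from gcmskit.simulate import (
    benchmark_detection,
    mix_like_design,
    overlap_design,
    simulate_run,
)


def trace(values, dt=1.0):
    values = np.asarray(values, dtype=float)
    return IonChromatogram(values, dt * np.arange(values.size))


def matrix_from_columns(columns: dict[float, np.ndarray], dt=1.0) -> IntensityMatrix:
    """Build a small intensity matrix directly from per-ion traces."""
    masses = sorted(columns)
    centers = np.arange(masses[0], masses[-1] + 1.0)
    n = len(next(iter(columns.values())))
    values = np.zeros((n, centers.size))
    for m, col in columns.items():
        values[:, int(m - masses[0])] = col
    return IntensityMatrix(values, dt * np.arange(n), centers, 1.0, 0.3, 0.7)


def gaussian(n, center, sigma, height):
    t = np.arange(n, dtype=float)
    return height * np.exp(-((t - center) ** 2) / (2 * sigma**2))


class TestFindIonMaxima:
    def test_single_peak(self):
        assert find_ion_maxima(trace([0, 1, 5, 1, 0]), 3) == [2]

    def test_flat_trace_has_no_maxima(self):
        assert find_ion_maxima(trace([4.0] * 9), 3) == []
        assert find_ion_maxima(trace(np.zeros(9)), 5) == []

    def test_plateau_reports_leftmost_point(self):
        assert find_ion_maxima(trace([0, 5, 5, 0]), 3) == [1]

    def test_two_gaussians_found_at_true_centers(self):
        x = gaussian(200, 60, 4, 100) + gaussian(200, 90, 4, 80)
        assert find_ion_maxima(trace(x), 5) == [60, 90]

    def test_window_controls_suppression(self):
        # two bumps 3 apart: both are maxima at window 3, only one at window 9
        x = np.array([0, 0, 5, 1, 0, 4, 0, 0, 0], dtype=float)
        assert find_ion_maxima(trace(x), 3) == [2, 5]
        assert find_ion_maxima(trace(x), 9) == [2]

    def test_bad_window(self):
        with pytest.raises(ValueError):
            find_ion_maxima(trace(np.ones(5)), 4)
        with pytest.raises(ValueError):
            find_ion_maxima(trace(np.ones(5)), 7)


class TestDeconvolute:
    def test_apexes_within_scans_merge(self):
        cols = {
            100.0: gaussian(60, 30, 3, 1000),
            120.0: gaussian(60, 31, 3, 500),
        }
        im = matrix_from_columns(cols)
        peaks = deconvolute(im, DetectionParams(window=5, scans=2))
        assert len(peaks) == 1
        assert set(peaks[0].member_ions()) == {100.0, 120.0}

    def test_apexes_beyond_scans_split(self):
        cols = {
            100.0: gaussian(80, 30, 3, 1000),
            120.0: gaussian(80, 34, 3, 500),
        }
        im = matrix_from_columns(cols)
        peaks = deconvolute(im, DetectionParams(window=5, scans=2))
        assert len(peaks) == 2

    def test_apex_rt_maximizes_summed_member_intensity(self):
        cols = {
            100.0: gaussian(60, 30, 3, 100),
            120.0: gaussian(60, 32, 3, 5000),
        }
        im = matrix_from_columns(cols, dt=0.5)
        (peak,) = deconvolute(im, DetectionParams(window=5, scans=2))
        assert peak.rt == pytest.approx(32 * 0.5)

    def test_fixture_components_recovered_at_true_apexes(self, mix_run_truth):
        run, truth = mix_run_truth
        im = build_intensity_matrix_i(run)
        peaks = detect_peaks(im, PRESETS["mix"], noise_floor=100)
        assert len(peaks) == len(truth)
        for peak, true in zip(peaks, truth):
            assert abs(peak.rt - true.rt) <= 2 * 0.375

    def test_sorted_by_rt(self, mix_run_truth):
        run, _ = mix_run_truth
        im = build_intensity_matrix_i(run)
        peaks = deconvolute(im, PRESETS["mix"], noise_floor=100)
        rts = [p.rt for p in peaks]
        assert rts == sorted(rts)


class TestPeakFilters:
    def make_peak(self, intensities: dict[float, float], rt=100.0) -> Peak:
        masses = sorted(intensities)
        spec = MassSpectrum(masses, [intensities[m] for m in masses])
        return Peak(uid=make_uid(spec, rt), rt=rt, spectrum=spec)

    def test_num_ions_threshold(self):
        peak = self.make_peak({60.0: 2500.0, 73.0: 2100.0, 90.0: 900.0})
        assert filter_num_ions([peak], ions=3, threshold=2000.0) == []
        assert filter_num_ions([peak], ions=2, threshold=2000.0) == [peak]

    def test_rel_intensity_cutoff(self):
        peak = self.make_peak({50.0: 10000.0, 60.0: 150.0, 70.0: 250.0})
        out = filter_rel_intensity(peak, 2.0)  # 2% of 10000 = 200
        assert set(out.member_ions()) == {50.0, 70.0}

    def test_r_zero_is_identity_and_base_survives(self):
        peak = self.make_peak({50.0: 10.0, 60.0: 10000.0})
        assert set(filter_rel_intensity(peak, 0.0).member_ions()) == {50.0, 60.0}
        out = filter_rel_intensity(peak, 99.0)
        assert set(out.member_ions()) == {60.0}

    def test_filters_are_order_independent(self):
        peaks = [
            self.make_peak({50.0: 10000.0, 60.0: 150.0, 70.0: 3000.0, 80.0: 2500.0}),
            self.make_peak({55.0: 5000.0, 65.0: 90.0, 75.0: 60.0}),
        ]
        a = filter_num_ions(
            [filter_rel_intensity(p, 2.0) for p in peaks], ions=2, threshold=2000.0
        )
        b = [
            filter_rel_intensity(p, 2.0)
            for p in filter_num_ions(peaks, ions=2, threshold=2000.0)
        ]
        assert [p.uid for p in a] == [p.uid for p in b]
        assert [set(p.member_ions()) for p in a] == [set(p.member_ions()) for p in b]

    def test_monotonicity_in_threshold_and_ions(self, mix_run_truth):
        run, _ = mix_run_truth
        im = build_intensity_matrix_i(run)
        candidates = deconvolute(im, PRESETS["mix"], noise_floor=100)
        counts = [
            len(filter_num_ions(candidates, ions, threshold))
            for ions, threshold in [(1, 0.0), (3, 2000.0), (3, 20000.0), (5, 20000.0)]
        ]
        assert counts == sorted(counts, reverse=True)


class TestIntegrateIon:
    def test_hand_walked_triangle_default_stop(self):
        ic = trace([0, 10, 100, 10, 0], dt=0.5)
        left, right, area = integrate_ion(ic, 2)
        assert (left, right) == (1, 3)  # zero candidates fail the 0.5% rule
        assert area == pytest.approx(120 * 0.5)

    def test_hand_walked_triangle_zero_stop_reaches_ends(self):
        ic = trace([0, 10, 100, 10, 0], dt=0.5)
        left, right, area = integrate_ion(ic, 2, stop_fraction=0.0)
        assert (left, right) == (0, 4)
        assert area == pytest.approx(120 * 0.5)

    def test_stops_at_rising_edge_of_neighbour(self):
        x = np.concatenate([gaussian(60, 25, 3, 100), gaussian(60, 40, 3, 80)[:0]])
        x = gaussian(100, 40, 4, 100) + gaussian(100, 55, 4, 120)
        ic = trace(x)
        apexes = find_ion_maxima(ic, 5)
        assert apexes == [40, 55]
        left, right, _ = integrate_ion(ic, 40, stop_fraction=0.0)
        valley = 40 + int(np.argmin(x[40:55]))
        assert right <= valley  # never climbs the neighbour's rising edge
        assert left <= 40 <= right

    def test_apex_must_be_local_maximum(self):
        ic = trace([0, 10, 100, 10, 0])
        with pytest.raises(ValueError):
            integrate_ion(ic, 1)

    @staticmethod
    def gaussian_area_error(pts_per_sigma: int) -> float:
        sigma_s, height = 3.0, 1000.0
        analytic = height * sigma_s * math.sqrt(2 * math.pi)
        dt = sigma_s / pts_per_sigma
        n = int(60 * sigma_s / dt) | 1
        t = dt * np.arange(n)
        x = height * np.exp(-((t - t[n // 2]) ** 2) / (2 * sigma_s**2))
        _, _, area = integrate_ion(IonChromatogram(x, t), n // 2)
        return abs(area - analytic) / analytic

    def test_area_accurate_at_instrument_sampling(self):
        # quadrupole GC-MS sampling: a handful of points per sigma
        for pts_per_sigma in (4, 6, 8, 10):
            assert self.gaussian_area_error(pts_per_sigma) <= 0.02

    def test_stop_rule_truncates_more_at_finer_sampling(self):
        # the candidate-vs-accumulated-sum stop moves inward (in sigma
        # units) as the sum grows with sampling density; characterize it
        errors = [self.gaussian_area_error(p) for p in (8, 20, 80)]
        assert errors == sorted(errors)


class TestQuantifyAndUid:
    def test_uid_format_matches_field_convention(self):
        spec = MassSpectrum([61.0, 149.0], [823.0, 1000.0])
        assert make_uid(spec, 499.8) == "149-61-82.3-499.8"

    def test_uid_single_ion_fallback_and_tie_rule(self):
        assert make_uid(MassSpectrum([77.0], [10.0]), 12.34) == "77-12.3"
        spec = MassSpectrum([60.0, 80.0], [500.0, 500.0])
        assert make_uid(spec, 1.0).startswith("60-80-100.0")

    def test_all_ions_vs_single_ion_modes(self):
        cols = {
            100.0: gaussian(80, 40, 4, 1000),
            120.0: gaussian(80, 40, 4, 400),
        }
        im = matrix_from_columns(cols, dt=0.5)
        (peak,) = deconvolute(im, DetectionParams(window=5, scans=2))
        all_ions = quantify_peak(peak, im, "all-ions")
        single = quantify_peak(peak, im, 100.0)
        assert all_ions.area == pytest.approx(sum(all_ions.ion_areas.values()))
        assert single.area == pytest.approx(all_ions.ion_areas[100.0])
        assert all_ions.area > single.area > 0
        with pytest.raises(ValueError):
            quantify_peak(peak, im, 999.0)

    def test_one_ion_peak_modes_agree(self):
        im = matrix_from_columns({100.0: gaussian(60, 30, 3, 500)})
        (peak,) = deconvolute(im, DetectionParams(window=5, scans=2))
        assert (
            quantify_peak(peak, im, "all-ions").area
            == quantify_peak(peak, im, 100.0).area
        )

    def test_bounds_bracket_apex_within_matrix(self, mix_run_truth):
        run, _ = mix_run_truth
        im = build_intensity_matrix_i(run)
        for peak in detect_peaks(im, PRESETS["mix"], noise_floor=100):
            for left, apex, right in peak.ion_bounds.values():
                assert 0 <= left <= apex <= right < im.n_scans

    def test_fixture_area_close_to_analytic(self, mix_run_truth):
        run, truth = mix_run_truth
        im = build_intensity_matrix_i(run)
        peaks = detect_peaks(im, PRESETS["mix"], noise_floor=100)
        for peak, true in zip(peaks, truth):
            assert peak.area == pytest.approx(true.area, rel=0.05)


class TestDetectionGroundTruth:
    def test_overlapping_triplet_resolves_into_three_peaks(self):
        run, truth = simulate_run(overlap_design(1), 0)
        im = build_intensity_matrix_i(run)
        peaks = detect_peaks(im, PRESETS["mix"], noise_floor=100)
        assert len(peaks) == 3
        precision, recall = benchmark_detection(peaks, truth, rt_tol=0.75)
        assert precision == 1.0 and recall == 1.0


class TestPeakListIO:
    def test_json_round_trip(self, mix_run_truth, tmp_path):
        run, _ = mix_run_truth
        im = build_intensity_matrix_i(run)
        peaks = detect_peaks(im, PRESETS["mix"], noise_floor=100)
        write_peaks_json(peaks, tmp_path / "p.json")
        again = read_peaks_json(tmp_path / "p.json")
        assert [p.uid for p in again] == [p.uid for p in peaks]
        assert [p.area for p in again] == [p.area for p in peaks]
        assert [p.ion_bounds for p in again] == [dict(p.ion_bounds) for p in peaks]

    def test_csv_export(self, tmp_path):
        spec = MassSpectrum([61.0, 149.0], [823.0, 1000.0])
        peak = Peak(uid=make_uid(spec, 499.8), rt=499.8, spectrum=spec, area=5.0)
        write_peaks_csv([peak], tmp_path / "p.csv")
        lines = (tmp_path / "p.csv").read_text().splitlines()
        assert lines[0] == "uid,rt_s,area,spectrum"
        assert lines[1].startswith("149-61-82.3-499.8,499.8,5.0,61:823")
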