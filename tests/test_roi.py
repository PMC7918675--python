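"""ROI time courses, peak statistics, and profile-line half-max bands."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidmsot import (
    AcquisitionSchedule,
    ROIMask,
    TimeCourse,
    extract_timecourse,
    mean_roi_intensity,
    normalize_timecourse,
    peak_time,
    profile_band,
    relative_increase,
    simulate_study,
)
from lipidmsot.kinetics import KineticParams, lipid_timecourse
from lipidmsot.roi import MaskError, line_coordinates
from lipidmsot.spectra import GridError

from conftest import MEAN_KINETICS


def tc(values, times=None):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(len(values)) * 30.0
    return TimeCourse(times=np.asarray(times, dtype=float), values=values)


class TestMeanRoiIntensity:
    def test_constant_image(self):
        mask = np.zeros((3, 3), bool)
        mask[1, :] = True
        assert mean_roi_intensity(np.full((3, 3), 7.0), mask) == 7.0

    def test_hand_summed_top_row(self):
        image = np.array([[1.0, 2.0], [3.0, 4.0]])
        mask = np.array([[True, True], [False, False]])
        assert mean_roi_intensity(image, mask) == pytest.approx(1.5)

    def test_empty_mask_and_shape_mismatch(self):
        with pytest.raises(MaskError, match="no member"):
            mean_roi_intensity(np.ones((2, 2)), np.zeros((2, 2), bool))
        with pytest.raises(MaskError, match="shape"):
            mean_roi_intensity(np.ones((2, 2)), np.ones((3, 3), bool))


class TestExtractTimecourse:
    def test_lengths_follow_schedule(self, small_study):
        course = extract_timecourse(small_study, small_study.ground_truth_masks["vein"])
        assert course.values.size == 13
        assert np.array_equal(course.times, np.arange(0, 361, 30))

    def test_off_grid_wavelength(self, small_study):
        with pytest.raises(GridError):
            extract_timecourse(small_study, small_study.ground_truth_masks["vein"], 935)

    def test_static_compartment_noise_free_is_constant(self, small_geometry):
        schedule = AcquisitionSchedule(wavelengths=np.array([930.0]))
        study = simulate_study(
            small_geometry, {"fat": KineticParams(amplitude=0.0)},
            schedule=schedule, noise_frac=0.0, seed=2,
        )
        course = extract_timecourse(study, study.ground_truth_masks["fat"])
        assert np.ptp(course.values) == 0.0

    def test_noise_free_psf_free_reproduces_injected_multiplier_exactly(
        self, small_geometry
    ):
        """Compartment-mean 930-nm signal is proportional to m(t) to ~1e-9."""
        schedule = AcquisitionSchedule(wavelengths=np.array([930.0]))
        study = simulate_study(
            small_geometry, MEAN_KINETICS, schedule=schedule,
            noise_frac=0.0, psf_fwhm=0.0, seed=3, dtype=np.float64,
        )
        for name, params in MEAN_KINETICS.items():
            course = extract_timecourse(study, study.ground_truth_masks[name])
            expected = lipid_timecourse(params, course.times)
            ratio = course.values / course.values[0]
            assert np.max(np.abs(ratio / expected - 1)) < 1e-9


class TestNormalizeAndStatistics:
    def test_normalization_divides_by_the_maximum(self):
        course = normalize_timecourse(tc([2, 4, 8, 4]))
        assert np.allclose(course.normalized_values, [0.25, 0.5, 1.0, 0.5])
        assert np.array_equal(course.values, [2, 4, 8, 4])  # raw kept
        assert normalize_timecourse(tc([5, 5, 5])).normalized_values.max() == 1.0

    def test_normalization_idempotent_and_argmax_preserving(self):
        course = normalize_timecourse(tc([1, 3, 2]))
        renorm = normalize_timecourse(
            TimeCourse(times=course.times, values=course.normalized_values)
        )
        assert np.allclose(renorm.normalized_values, course.normalized_values)
        assert peak_time(course) == peak_time(tc([1, 3, 2]))

    def test_non_positive_maximum_rejected(self):
        with pytest.raises(ValueError, match="maximum"):
            normalize_timecourse(tc([0.0, -1.0, 0.0]))

    def test_relative_increase_examples(self):
        # a subject whose venous signal peaks 32.1% above fasting baseline
        assert relative_increase(tc([1.0, 1.1, 1.321, 1.2])) == pytest.approx(32.1)
        assert relative_increase(tc([5, 5, 5])) == 0.0
        assert relative_increase(tc([2.0, 3.0, 2.5])) == pytest.approx(50.0)
        assert relative_increase(tc([3.0, 2.0, 1.0])) == 0.0  # max at baseline

    def test_relative_increase_requires_positive_baseline(self):
        with pytest.raises(ValueError, match="baseline"):
            relative_increase(tc([0.0, 1.0]))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        values=st.lists(st.floats(0.5, 100), min_size=2, max_size=13),
        scale=st.floats(0.01, 1000),
    )
    def test_relative_increase_is_scale_free(self, values, scale):
        a = relative_increase(tc(values))
        b = relative_increase(tc(np.asarray(values) * scale))
        assert a == pytest.approx(b, rel=1e-9)

    def test_peak_time_examples_and_tie_rule(self):
        # the maximum landing on the 240-min sample
        times = np.arange(0, 391, 30.0)
        values = lipid_timecourse(KineticParams(amplitude=0.321, peak_time=240), times)
        assert peak_time(TimeCourse(times=times, values=values)) == 240.0
        assert peak_time(tc(np.arange(13.0), np.arange(0, 361, 30.0))) == 360.0
        assert peak_time(tc([1, 5, 5, 2])) == 30.0  # earliest tied point


def brute_force_band(intensities, frac):
    """Oracle: maximal runs of above-threshold samples; pick the argmax's run."""
    peak = int(np.argmax(intensities))
    above = intensities >= frac * intensities[peak]
    runs, start = [], None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(above) - 1))
    return next((a, b) for a, b in runs if a <= peak <= b)


class TestProfileBand:
    def test_triangular_profile(self):
        frame = np.array([[0, 1, 2, 3, 4, 3, 2, 1, 0]], dtype=float)
        line = [(0, c) for c in range(9)]
        band = profile_band(frame, line)
        assert band.band == (2, 6)
        assert band.width_px == 5

    def test_constant_and_single_spike_profiles(self):
        const = profile_band(np.ones((1, 7)), [(0, c) for c in range(7)])
        assert const.band == (0, 6)
        spike = profile_band(
            np.array([[0, 0, 9, 0, 0]], dtype=float), [(0, c) for c in range(5)]
        )
        assert spike.band == (2, 2)

    def test_band_width_in_mm(self):
        frame = np.array([[0, 1, 2, 3, 4, 3, 2, 1, 0]], dtype=float)
        band = profile_band(frame, [(0, c) for c in range(9)], pixel_pitch=0.1)
        assert band.width_mm == pytest.approx(0.5)

    def test_line_out_of_bounds(self):
        with pytest.raises(IndexError, match="bounds"):
            profile_band(np.ones((4, 4)), [(0, 2), (1, 3), (2, 4)])

    def test_line_coordinates_endpoints(self):
        coords = line_coordinates((0, 0), (3, 3))
        assert tuple(coords[0]) == (0, 0) and tuple(coords[-1]) == (3, 3)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        values=st.lists(st.floats(0.0, 10.0), min_size=3, max_size=40),
        frac=st.floats(0.05, 0.95),
    )
    def test_matches_brute_force_run_scan(self, values, frac):
        intensities = np.asarray(values)
        if intensities.max() <= 0:
            intensities[0] = 1.0
        frame = intensities[None, :]
        line = [(0, c) for c in range(intensities.size)]
        band = profile_band(frame, line, threshold_frac=frac)
        assert band.band == brute_force_band(intensities, frac)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(values=st.lists(st.floats(0.1, 10.0), min_size=3, max_size=30))
    def test_width_non_increasing_in_threshold(self, values):
        intensities = np.asarray(values)
        frame = intensities[None, :]
        line = [(0, c) for c in range(intensities.size)]
        widths = [
            profile_band(frame, line, threshold_frac=f).width_px
            for f in (0.2, 0.4, 0.6, 0.8)
        ]
        assert all(a >= b for a, b in zip(widths, widths[1:]))
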