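"""DoG filtering, robust background statistics, and the two focus criteria."""

import math

import numpy as np
import pytest

from focistat.foci_detection import (
    DetectionParams,
    NucleusStats,
    background_stats,
    count_summary,
    detect_foci,
    dog_filter,
)
from focistat.segmentation import LabelMap, segment_nuclei
from focistat.synthetic_data import FieldSpec, generate_field
from oracles import detect_foci_literal, gaussian_blur_reflect, median_and_mad


class TestDogFilter:
    def test_constant_image_maps_to_zero(self):
        out = dog_filter(np.full((32, 32), 123.0))
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 500, (32, 32))
        np.testing.assert_allclose(dog_filter(3.0 * img), 3.0 * dog_filter(img), rtol=1e-10)

    def test_matches_brute_force_convolutions(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 1000, (16, 16))
        params = DetectionParams(dog_sigma_small=1.5, dog_sigma_large=4.0)
        expected = gaussian_blur_reflect(img, 1.5) - gaussian_blur_reflect(img, 4.0)
        np.testing.assert_allclose(dog_filter(img, params), expected, atol=1e-8)

    def test_sigma_ordering_enforced(self):
        with pytest.raises(ValueError):
            DetectionParams(dog_sigma_small=6, dog_sigma_large=2)


class TestBackgroundStats:
    def _labels(self, shape, boxes):
        lab = np.zeros(shape, dtype=int)
        for i, (y0, y1, x0, x1) in enumerate(boxes, start=1):
            lab[y0:y1, x0:x1] = i
        return LabelMap(lab)

    def test_constant_nucleus_has_zero_spread(self):
        img = np.full((20, 20), 5.0)
        labels = self._labels((20, 20), [(2, 8, 2, 8)])
        stats, gsd = background_stats(img, labels)
        assert stats[0].bg_sd == 0.0
        assert gsd == 0.0

    def test_global_sd_is_median_of_per_nucleus_sds(self):
        rng = np.random.default_rng(2)
        img = np.zeros((30, 90))
        labels = self._labels((30, 90), [(5, 25, 5, 25), (5, 25, 35, 55), (5, 25, 65, 85)])
        # three nuclei with very different spreads
        img[5:25, 5:25] = rng.normal(0, 1, (20, 20))
        img[5:25, 35:55] = rng.normal(0, 5, (20, 20))
        img[5:25, 65:85] = rng.normal(0, 100, (20, 20))
        stats, gsd = background_stats(img, labels)
        sds = sorted(s.bg_sd for s in stats)
        assert gsd == pytest.approx(sds[1])

    def test_matches_sort_based_median_and_mad(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(-50, 50, (40, 60))
        boxes = [(1, 12, 1, 12), (14, 30, 5, 20), (2, 10, 30, 55), (20, 38, 30, 45), (32, 39, 48, 58)]
        labels = self._labels((40, 60), boxes)
        stats, _ = background_stats(img, labels)
        for s, (y0, y1, x0, x1) in zip(stats, boxes):
            med, sd = median_and_mad(img[y0:y1, x0:x1].ravel())
            assert s.bg_center == pytest.approx(med, abs=1e-12)
            assert s.bg_sd == pytest.approx(sd, abs=1e-12)

    def test_empty_label_map_rejected(self):
        with pytest.raises(ValueError):
            background_stats(np.zeros((5, 5)), LabelMap(np.zeros((5, 5), dtype=int)))


def _run_detection(marker, labels, params):
    filtered = dog_filter(marker, params)
    stats, gsd = background_stats(filtered, labels)
    return detect_foci(filtered, labels, stats, gsd, params, keep_pixels=True)


class TestDetectFoci:
    def test_no_planted_foci_counts_zero(self, detection_params):
        spec = FieldSpec(n_nuclei=3, width=300, height=300, foci_per_nucleus=0)
        _, marker, truth = generate_field(spec, 1)
        res = _run_detection(marker, LabelMap(truth.label_map), detection_params)
        assert all(c == 0 for c in res.counts.values())

    def test_area_criterion_is_strict(self):
        # a flat square bump of exactly 16 px is rejected, 17+ kept
        def field_with_area(n_px):
            img = np.zeros((40, 40))
            lab = np.zeros((40, 40), dtype=int)
            lab[5:35, 5:35] = 1
            ys, xs = np.unravel_index(np.arange(n_px), (5, 5))
            img[15 + ys, 15 + xs] = 500.0
            return img, LabelMap(lab)

        params = DetectionParams(abs_min=50.0, min_focus_area=16)
        for n_px, expected in [(15, 0), (16, 0), (17, 1)]:
            img, lab = field_with_area(n_px)
            # feed the image directly as the 'filtered' signal
            stats, gsd = background_stats(img, lab)
            res = detect_foci(img, lab, stats, gsd, params)
            assert sum(res.counts.values()) == expected, n_px

    def test_three_separated_foci_found(self, detection_params):
        spec = FieldSpec(n_nuclei=1, width=200, height=200, foci_per_nucleus=3)
        _, marker, truth = generate_field(spec, 2)
        res = _run_detection(marker, LabelMap(truth.label_map), detection_params)
        assert res.counts[1] == 3

    def test_missing_stats_named_in_error(self):
        lab = np.zeros((20, 20), dtype=int)
        lab[2:10, 2:10] = 1
        lab[12:18, 12:18] = 2
        stats = [NucleusStats(1, 0.0, 1.0, 64)]
        with pytest.raises(ValueError, match="2"):
            detect_foci(np.zeros((20, 20)), LabelMap(lab), stats, 1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_equivalent_to_literal_criteria(self, seed, detection_params):
        """Vectorised detection = pixel-by-pixel transcription of the criteria."""
        spec = FieldSpec(
            width=64, height=64, n_nuclei=1, nucleus_radius_range=(12.0, 16.0),
            foci_per_nucleus=2,
        )
        _, marker, truth = generate_field(spec, seed)
        lab = LabelMap(truth.label_map)
        filtered = dog_filter(marker, detection_params)
        stats, gsd = background_stats(filtered, lab)
        res = detect_foci(filtered, lab, stats, gsd, detection_params, keep_pixels=True)
        oracle_foci, oracle_gsd = detect_foci_literal(
            filtered, lab.labels, detection_params.fold_k, detection_params.abs_min,
            detection_params.min_focus_area,
        )
        assert gsd == pytest.approx(oracle_gsd, abs=1e-12)
        got = {(f.nucleus_id, frozenset(f.pixels)) for f in res.foci}
        want = set(oracle_foci)
        assert got == want

    def test_monotone_in_thresholds(self, detection_params):
        spec = FieldSpec(n_nuclei=2, width=300, height=300, foci_per_nucleus=5)
        _, marker, truth = generate_field(spec, 3)
        lab = LabelMap(truth.label_map)
        filtered = dog_filter(marker, detection_params)
        stats, gsd = background_stats(filtered, lab)

        def total(params):
            return sum(detect_foci(filtered, lab, stats, gsd, params).counts.values())

        base = total(detection_params)
        assert total(DetectionParams(abs_min=200.0)) <= base
        assert total(DetectionParams(abs_min=80.0, fold_k=20.0)) <= base
        assert total(DetectionParams(abs_min=80.0, min_focus_area=60)) <= base

    def test_per_nucleus_sd_flag_changes_reference(self):
        rng = np.random.default_rng(4)
        img = rng.normal(0, 1, (40, 40))
        img[10:14, 10:14] = 50.0
        lab = np.zeros((40, 40), dtype=int)
        lab[2:38, 2:38] = 1
        lm = LabelMap(lab)
        stats, gsd = background_stats(img, lm)
        p_global = DetectionParams(abs_min=-1e9, min_focus_area=1)
        p_local = DetectionParams(abs_min=-1e9, min_focus_area=1, use_per_nucleus_sd=True)
        r1 = detect_foci(img, lm, stats, gsd, p_global)
        r2 = detect_foci(img, lm, stats, gsd, p_local)
        # with a single nucleus the global median SD equals the local SD
        assert r1.counts == r2.counts


class TestCountSummary:
    def _result(self, counts):
        from focistat.foci_detection import FociResult

        return FociResult(foci=(), counts={i: c for i, c in enumerate(counts, 1)}, global_sd=1.0)

    def test_constant_counts(self):
        s = count_summary([self._result([3, 3, 3])], ["a"])[0]
        assert s.mean == 3.0 and s.sd == 0.0

    def test_single_nucleus_ci_flagged_undefined(self):
        s = count_summary([self._result([4])], ["a"])[0]
        assert not s.ci_defined
        assert math.isnan(s.ci_low)

    def test_hand_computed_mean_and_sd(self):
        s = count_summary([self._result([0, 1, 2, 3, 4])], ["a"])[0]
        assert s.mean == 2.0
        assert s.sd == pytest.approx(math.sqrt(2.5))

    def test_pools_across_fields_of_same_condition(self):
        s = count_summary([self._result([1, 2]), self._result([3, 4])], ["a", "a"])[0]
        assert s.n_nuclei == 4 and s.mean == 2.5
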