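"""Generator determinism, bookkeeping, and distributional calibration."""

import math

import numpy as np
import pytest

from focistat.break_model import CutKinetics, GuideTarget, RepairModel
from focistat.synthetic_data import (
    FieldSpec,
    Fixed,
    IndelMixSpec,
    PlacementError,
    TrackCohortSpec,
    Uniform,
    generate_field,
    sample_focus_counts,
    sample_indel_spectrum,
    simulate_break_events,
    simulate_focus_movie,
    simulate_tracks,
)


class TestGenerateField:
    def test_empty_field_is_noise_only(self):
        spec = FieldSpec(n_nuclei=0, width=64, height=64)
        dapi, marker, truth = generate_field(spec, 0)
        assert truth.n_nuclei == 0
        assert truth.focus_records == ()
        # background 100 with Poisson+read noise: nothing near nuclear level
        assert dapi.mean() < 150 and marker.mean() < 150

    def test_same_seed_bit_identical(self, small_field_spec):
        d1, m1, t1 = generate_field(small_field_spec, 42)
        d2, m2, t2 = generate_field(small_field_spec, 42)
        assert np.array_equal(d1, d2)
        assert np.array_equal(m1, m2)
        assert np.array_equal(t1.label_map, t2.label_map)
        assert t1.focus_records == t2.focus_records

    def test_different_seed_differs(self, small_field_spec):
        d1, _, _ = generate_field(small_field_spec, 1)
        d2, _, _ = generate_field(small_field_spec, 2)
        assert not np.array_equal(d1, d2)

    def test_focus_bookkeeping_matches_request(self):
        spec = FieldSpec(n_nuclei=3, width=300, height=300, foci_per_nucleus=[3, 0, 5])
        _, _, truth = generate_field(spec, 3)
        assert len(truth.focus_records) == 8
        assert truth.focus_count(1) == 3
        assert truth.focus_count(2) == 0
        assert truth.focus_count(3) == 5

    def test_focus_centroids_inside_their_nucleus(self):
        spec = FieldSpec(n_nuclei=4, foci_per_nucleus=4, overlap_fraction=0.5)
        _, _, truth = generate_field(spec, 5)
        for rec in truth.focus_records:
            assert truth.label_map[int(round(rec.y)), int(round(rec.x))] == rec.nucleus_id

    def test_nucleus_masks_disjoint_even_when_touching(self):
        spec = FieldSpec(n_nuclei=4, overlap_fraction=1.0)
        _, _, truth = generate_field(spec, 6)
        # label map encoding is disjoint by construction; all nuclei present
        assert truth.n_nuclei == 4
        for nid in range(1, 5):
            assert truth.nucleus_mask(nid).sum() > 200

    def test_overcrowded_field_raises_placement_error(self):
        spec = FieldSpec(width=100, height=100, n_nuclei=12)
        with pytest.raises(PlacementError):
            generate_field(spec, 0)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            FieldSpec(width=0)
        with pytest.raises(ValueError):
            FieldSpec(overlap_fraction=1.5)
        with pytest.raises(ValueError):
            FieldSpec(n_nuclei=2, foci_per_nucleus=[1, -2])


class TestBreakEvents:
    def test_zero_sites_zero_events(self):
        cells = simulate_break_events(
            GuideTarget("tracr", 0), CutKinetics(), None, 50, {"G1": 1.0}, 24, 0.5, 0
        )
        assert all(len(c.events) == 0 for c in cells)

    def test_zero_cut_probability_zero_events(self):
        cells = simulate_break_events(
            GuideTarget("HS4", 4), CutKinetics(p_max=0.0), None, 50, {"G1": 1.0}, 24, 0.5, 0
        )
        assert all(len(c.events) == 0 for c in cells)

    def test_mean_cuts_match_analytic_expectation(self):
        # 2 sites x 2 alleles x p_max=1 with duration >> lag+tau -> 4 cuts/cell
        n = 10_000
        cells = simulate_break_events(
            GuideTarget("HS2", 2), CutKinetics(p_max=1.0), None, n, {"G1": 1.0}, 200, 0.5, 1
        )
        counts = np.array([len(c.events) for c in cells])
        se = counts.std(ddof=1) / math.sqrt(n)
        assert abs(counts.mean() - 4.0) <= 3 * max(se, 1e-4)

    def test_each_allele_cut_at_most_once_and_after_lag(self):
        cells = simulate_break_events(
            GuideTarget("HS4", 4), CutKinetics(), RepairModel(), 200, {"G1": 0.5, "G2": 0.5}, 24, 0.5, 2
        )
        for cell in cells:
            keys = [(e.site, e.allele) for e in cell.events]
            assert len(keys) == len(set(keys))
            n_alleles = 2 if cell.phase == "G1" else 4
            for e in cell.events:
                assert e.cut_time > CutKinetics().t_lag
                assert e.repair_time > e.cut_time
                assert 0 <= e.allele < n_alleles

    def test_nonpositive_step_rejected(self):
        with pytest.raises(ValueError):
            simulate_break_events(
                GuideTarget("HS1", 1), CutKinetics(), None, 1, {"G1": 1.0}, 24, 0.0, 0
            )


class TestFocusMovie:
    def test_deterministic_and_counts(self):
        rep = RepairModel()
        m1 = simulate_focus_movie(50, rep, "cas9", seed=3)
        m2 = simulate_focus_movie(50, rep, "cas9", seed=3)
        assert np.array_equal(m1.lifetimes, m2.lifetimes)
        assert len(m1.frames) == len(m2.frames) == 48
        assert all(len(a) == len(b) for a, b in zip(m1.frames, m2.frames))

    def test_visible_frame_count_follows_lifetime(self):
        rep = RepairModel()
        mv = simulate_focus_movie(200, rep, "ir", seed=4)
        # focus i appears in exactly the frames whose time falls in [birth, birth+life)
        n_visible = np.zeros(200, dtype=int)
        for t_idx, dets in enumerate(mv.frames):
            for f in dets:
                n_visible[f.nucleus_id] += 1
        t = mv.frame_interval
        for i in range(200):
            expected = sum(
                1
                for fi in range(len(mv.frames))
                if mv.births[i] <= fi * t < mv.births[i] + mv.lifetimes[i]
            )
            assert n_visible[i] == expected


class TestTracks:
    def test_null_damage_equals_baseline(self):
        base = Uniform(10.0, 14.0)
        spec = TrackCohortSpec(
            n_cells=2000,
            phase_at_damage={"G2": 1.0},
            baseline_entry_time=base,
            g2_delay=Fixed(0.0),
            g1_arrest_fraction=0.0,
        )
        tracks = simulate_tracks(spec, 5)
        times = np.array([t.entry_time for t in tracks])
        assert times.min() >= 10.0 and times.max() <= 14.0
        assert times.mean() == pytest.approx(12.0, abs=3 * (4 / math.sqrt(12)) / math.sqrt(2000))

    def test_full_arrest_censors_all_g1(self):
        spec = TrackCohortSpec(
            n_cells=500,
            phase_at_damage={"G1_early": 0.5, "G1_late": 0.5},
            g1_arrest_fraction=1.0,
        )
        tracks = simulate_tracks(spec, 6)
        assert all(t.censored and t.entry_time is None for t in tracks)

    def test_fixed_delay_shifts_mean_entry(self):
        n = 10_000
        base = Uniform(10.0, 14.0)
        damaged = simulate_tracks(
            TrackCohortSpec(
                n_cells=n, phase_at_damage={"G2": 1.0}, baseline_entry_time=base,
                g2_delay=Fixed(5.0), horizon=48.0,
            ),
            7,
        )
        control = simulate_tracks(
            TrackCohortSpec(
                n_cells=n, phase_at_damage={"G2": 1.0}, baseline_entry_time=base,
                damage=False, horizon=48.0,
            ),
            8,
        )
        md = np.mean([t.entry_time for t in damaged])
        mc = np.mean([t.entry_time for t in control])
        se = (4 / math.sqrt(12)) * math.sqrt(2 / n)
        assert abs((md - mc) - 5.0) <= 3 * se

    def test_micronucleation_frequency_matches_configured_probability(self):
        spec = TrackCohortSpec(
            n_cells=10_000, phase_at_damage={"G2": 1.0}, checkpoint_intact=False
        )
        tracks = simulate_tracks(spec, 9)
        divided = [t for t in tracks if t.divided]
        freq = np.mean([t.micronucleated for t in divided])
        p = spec.micronucleation_prob_abrogated
        se = math.sqrt(p * (1 - p) / len(divided))
        assert abs(freq - p) <= 3 * se

    def test_abrogated_checkpoint_shortens_delay(self):
        base = Fixed(12.0)
        intact = simulate_tracks(
            TrackCohortSpec(n_cells=500, phase_at_damage={"G2": 1.0},
                            baseline_entry_time=base, g2_delay=Fixed(5.0)),
            10,
        )
        abrogated = simulate_tracks(
            TrackCohortSpec(n_cells=500, phase_at_damage={"G2": 1.0},
                            baseline_entry_time=base, g2_delay=Fixed(5.0),
                            checkpoint_intact=False),
            11,
        )
        mi = np.mean([t.entry_time for t in intact])
        ma = np.mean([t.entry_time for t in abrogated])
        assert mi == pytest.approx(17.0)
        assert ma == pytest.approx(12.5)  # delay scaled by the override factor


class TestIndelSampling:
    def test_degenerate_mix_is_pure(self):
        sp = sample_indel_spectrum(IndelMixSpec({+1: 1.0}, 1000), 0)
        assert sp.frequencies[+1] == 1.0

    def test_frequencies_sum_to_one(self):
        sp = sample_indel_spectrum(IndelMixSpec(n_reads=9973), 1)
        assert sum(sp.frequencies.values()) == pytest.approx(1.0, abs=1e-12)

    def test_class_frequency_within_binomial_se(self):
        n = 100_000
        sp = sample_indel_spectrum(IndelMixSpec({-5: 0.3, +1: 0.7}, n), 2)
        se = math.sqrt(0.3 * 0.7 / n)
        assert abs(sp.frequencies[-5] - 0.3) <= 3 * se

    def test_empty_mix_rejected(self):
        with pytest.raises(ValueError):
            IndelMixSpec({}, 100)


class TestFocusCounts:
    def test_mean_matches_break_model(self):
        g = GuideTarget("HS1", 1)
        counts = sample_focus_counts(g, CutKinetics(), 8.0, 20_000, seed=3)
        # 1 site x 2 alleles x 0.5 + Poisson background 3
        arr = np.array(counts)
        se = arr.std(ddof=1) / math.sqrt(arr.size)
        assert abs(arr.mean() - 4.0) <= 3 * se
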