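"""Generator determinism and distributional correctness."""

import numpy as np
import pytest

from kifquant import synthgen as sg
from kifquant.bleachsteps import truncated_pmf


class TestDeterminism:
    def test_generators_are_pure_functions_of_seed(self):
        h1 = sg.sim_bleach_counts(0.12, 0.8, 500, seed=9)
        h2 = sg.sim_bleach_counts(0.12, 0.8, 500, seed=9)
        assert h1.counts == h2.counts
        t1 = sg.sim_bleach_trace(3, seed=9)
        t2 = sg.sim_bleach_trace(3, seed=9)
        assert np.array_equal(t1.intensities, t2.intensities)
        a1, _ = sg.sim_motility(10.0, 2.0, seed=9)
        a2, _ = sg.sim_motility(10.0, 2.0, seed=9)
        assert len(a1) == len(a2)
        for x, y in zip(a1, a2):
            assert np.array_equal(x.x_um, y.x_um)
        k1 = sg.render_kymograph(a1, 10.0, 120.0, seed=9)
        k2 = sg.render_kymograph(a2, 10.0, 120.0, seed=9)
        assert np.array_equal(k1.pixels, k2.pixels)
        s1, _ = sg.sim_binding_series(1.0, noise_cv=0.05, seed=9)
        s2, _ = sg.sim_binding_series(1.0, noise_cv=0.05, seed=9)
        assert np.array_equal(s1.signal, s2.signal)


class TestBleachGenerators:
    def test_pure_dimer_all_two_steps(self):
        hist = sg.sim_bleach_counts(0.0, 1.0, 10, seed=0)
        assert hist.counts == {2: 10}

    def test_pure_tetramer_all_four_steps(self):
        hist = sg.sim_bleach_counts(1.0, 1.0, 10, seed=0)
        assert hist.counts == {4: 10}

    def test_frequencies_match_truncated_pmf(self):
        n = 100_000
        hist = sg.sim_bleach_counts(0.12, 0.8, n, seed=2)
        for k in range(1, 5):
            p = truncated_pmf(k, 0.12, 0.8)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(hist.counts.get(k, 0) / n - p) < 3 * se

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            sg.sim_bleach_counts(-0.1, 0.8, 10, seed=0)
        with pytest.raises(ValueError):
            sg.sim_bleach_counts(0.1, 0.0, 10, seed=0)
        with pytest.raises(ValueError):
            sg.sim_bleach_trace(2, n_frames=0)

    def test_noiseless_trace_level_changes(self):
        tr = sg.sim_bleach_trace(3, unit_intensity=100, noise_sd=0, seed=5)
        drops = np.flatnonzero(np.diff(tr.intensities) < 0)
        in_window = np.sum(tr.step_times < tr.frame_interval * tr.intensities.size)
        assert drops.size == in_window
        assert tr.intensities[0] == pytest.approx(300.0)

    def test_zero_steps_flat_baseline(self):
        tr = sg.sim_bleach_trace(0, noise_sd=0, seed=5)
        assert np.all(tr.intensities == 0)


class TestMotilityGenerator:
    def test_zero_rate_no_tracks(self):
        tracks, events = sg.sim_motility(
            10.0, 2.0, sg.MotilityGroundTruth(0.0, 0.45, 0.1, 5.0, 0.3), seed=1
        )
        assert tracks == [] and events == []

    def test_all_static_zero_slope(self):
        tracks, _ = sg.sim_motility(
            10.0, 2.0, sg.MotilityGroundTruth(0.5, 0.45, 0.1, 5.0, 1.0), seed=1
        )
        assert tracks
        for tr in tracks:
            assert np.ptp(tr.x_um) == 0.0

    def test_poisson_mean_event_count(self):
        """rate 0.5 /(µm·min) on 10 µm for 2 min -> mean 10 events."""
        truth = sg.MotilityGroundTruth(0.5, 0.45, 0.1, 5.0, 0.3)
        counts = [len(sg.sim_motility(10.0, 2.0, truth, seed=s)[1]) for s in range(500)]
        se = np.sqrt(10.0 / 500)
        assert abs(np.mean(counts) - 10.0) < 3 * se

    def test_run_truncation_at_plus_end(self):
        truth = sg.MotilityGroundTruth(1.0, 0.45, 0.0, 100.0, 0.0)
        tracks, events = sg.sim_motility(10.0, 3.0, truth, seed=2)
        for tr, ev in zip(tracks, events):
            assert tr.x_um.max() <= 10.0 + 1e-9
            if ev["runlength_true_um"] > 10.0 - ev["x_land_um"]:
                assert ev["censored"]

    def test_accumulate_mode_pauses_at_end(self):
        truth = sg.MotilityGroundTruth(1.0, 0.45, 0.0, 1000.0, 0.0)
        tracks, _ = sg.sim_motility(5.0, 3.0, truth, seed=3,
                                    end_behavior="accumulate")
        at_end = [tr for tr in tracks if np.isclose(tr.x_um[-1], 5.0)]
        assert at_end
        # some dwell at the end: final samples constant at mt end
        tr = max(at_end, key=lambda t: t.t_s.size)
        tail = tr.x_um[-5:]
        assert np.allclose(tail, 5.0)


class TestKymographRendering:
    def test_empty_tracks_zero_image(self):
        img = sg.render_kymograph([], 10.0, 60.0, noise_sd=0.0)
        assert not np.any(img.pixels)

    def test_static_track_bright_column(self):
        from kifquant.motility import Track

        tr = Track(0, np.arange(0.0, 60.0, 0.1), np.full(600, 5.0), is_static=True)
        img = sg.render_kymograph([tr], 10.0, 60.0, noise_sd=0.0)
        col = int(round(5.0 / 0.105))
        profile = img.pixels[:, col]
        assert np.all(profile[1:-1] > 0)
        colsums = img.pixels.sum(axis=0)
        assert np.argmax(colsums) == pytest.approx(col, abs=1)


class TestElutionGenerator:
    def test_sec_centre_on_printed_line(self):
        # log10(Rs) = 0.69 -> Ve - V0 = 20 ml on slope -0.014, intercept 0.97
        profiles, centres = sg.sim_elution(
            sg.SEC_LINE, sg.SEC_STANDARDS, 10**0.69, seed=0
        )
        assert centres["sample"] == pytest.approx(20.0, abs=1e-9)

    def test_gradient_centre_gives_printed_s(self):
        profiles, centres = sg.sim_elution(
            sg.GRADIENT_LINE, sg.GRADIENT_STANDARDS, 7.4, seed=0
        )
        assert centres["sample"] == pytest.approx(2.0, abs=1e-9)

    def test_zero_noise_peak_recovery(self):
        from kifquant.hydro import locate_peak

        profiles, centres = sg.sim_elution(
            sg.GRADIENT_LINE, sg.GRADIENT_STANDARDS, 11.0, seed=0
        )
        for name, prof in profiles.items():
            est, _ = locate_peak(prof)
            assert abs(est - centres[name]) < 0.05 * prof.fraction_ml


class TestCellGenerators:
    def test_cell_image_truth_ratio(self):
        _, truth = sg.sim_cell_image(100.0, 20.0, 10.0)
        assert truth["ratio_per_channel"][0] == pytest.approx(9.0)

    def test_podosome_zero_objects(self):
        from kifquant.cellimage import count_podosomes

        img, truth = sg.sim_podosome_image(0, seed=0)
        assert truth["n_coincident"] == 0
        det = count_podosomes(img.channels[0], img.channels[1], threshold=50.0)
        assert det.count == 0

    def test_podosome_discs_never_overlap(self):
        _, truth = sg.sim_podosome_image(12, radius_px=3, seed=5)
        centres = np.array(truth["centres"])
        for i in range(len(centres)):
            for j in range(i + 1, len(centres)):
                assert np.linalg.norm(centres[i] - centres[j]) >= 6.0

    def test_coincident_subset_size(self):
        _, truth = sg.sim_podosome_image(10, coloc_fraction=0.6, seed=6)
        assert truth["n_coincident"] == 6
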