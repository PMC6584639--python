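"""Kymograph tracing and motility statistics."""

import numpy as np
import pytest

from kifquant import synthgen as sg
from kifquant.motility import (
    KymographImage,
    MTObservation,
    Run,
    Track,
    classify_runs,
    classify_vesicle_tracks,
    landing_rate,
    summarize,
    trace_kymograph,
    vesicle_flux,
)


def _single_track(speed_um_s, t0=10.0, x0=1.0, dur=20.0, static=False):
    ts = np.arange(t0, t0 + dur, 0.1)
    xs = x0 + (0.0 if static else speed_um_s) * (ts - t0)
    return Track(track_id=0, t_s=ts, x_um=xs, is_static=static)


class TestTraceKymograph:
    def test_empty_image(self):
        img = KymographImage(np.zeros((100, 50)), 105.0, 0.1)
        assert trace_kymograph(img) == []

    def test_noiseless_single_run_slope(self):
        tr = _single_track(0.45)
        img = sg.render_kymograph([tr], 15.0, 60.0, noise_sd=0.0, seed=0)
        runs = trace_kymograph(img)
        assert len(runs) == 1
        assert runs[0].speed_um_s == pytest.approx(0.45, rel=0.02)

    def test_noiseless_static_motor(self):
        tr = _single_track(0.0, static=True)
        img = sg.render_kymograph([tr], 15.0, 60.0, noise_sd=0.0, seed=0)
        runs = trace_kymograph(img)
        assert len(runs) == 1
        assert runs[0].speed_um_s < 0.025

    def test_round_trip_traced_slope_within_5pct(self):
        tracks, _ = sg.sim_motility(
            15.0, 1.0,
            sg.MotilityGroundTruth(0.05, 0.45, 0.0, 100.0, 0.0),
            seed=1,
        )
        assert tracks
        img = sg.render_kymograph(tracks, 15.0, 60.0, noise_sd=20.0, seed=1)
        runs = [r for r in trace_kymograph(img) if r.speed_um_s > 0.025]
        assert runs
        assert np.mean([r.speed_um_s for r in runs]) == pytest.approx(0.45, rel=0.05)

    def test_event_recovery_and_spurious_rate(self):
        """At SNR 5 the tracer recovers >=90% of true events with <=5%
        spurious detections (pooled over 100 simulated microtubules)."""
        n_true = n_traced = 0
        for s in range(100):
            tracks, events = sg.sim_motility(
                15.0, 3.0, sg.WILD_TYPE_MOTILITY, seed=7000 + s
            )
            img = sg.render_kymograph(tracks, 15.0, 180.0, noise_sd=20.0,
                                      seed=90_000 + s)
            runs = trace_kymograph(img)
            n_true += len(events)
            n_traced += len(runs)
        assert n_traced >= 0.90 * n_true
        assert n_traced <= 1.05 * n_true


class TestClassifyRuns:
    def test_threshold_is_strict(self):
        running = Run(0, 10, 0, 0.26e-3 * 10 * 100)  # 26 nm/s
        static = Run(0, 10, 0, 0.25e-3 * 10 * 100)  # exactly 25 nm/s
        part = classify_runs([running, static])
        assert part["running"] == [running]
        assert part["static"] == [static]

    def test_empty(self):
        part = classify_runs([])
        assert part == {"running": [], "static": []}

    def test_partition_exhaustive_disjoint(self):
        rng = np.random.default_rng(0)
        runs = [Run(0, 10, 0, float(rng.uniform(0, 1))) for _ in range(50)]
        part = classify_runs(runs)
        assert len(part["running"]) + len(part["static"]) == 50
        assert not (set(map(id, part["running"])) & set(map(id, part["static"])))


class TestRates:
    def test_landing_rate_arithmetic(self):
        obs = MTObservation(10.0, 2.0, [Run(0, 1, 0, 0.5)] * 10)
        assert landing_rate(obs) == pytest.approx(0.5)
        assert landing_rate(MTObservation(10.0, 2.0, [])) == 0.0

    def test_window_splitting_invariance(self):
        runs = [Run(i, i + 1, 0, 0.5) for i in range(8)]
        whole = summarize([MTObservation(10.0, 4.0, runs)])
        split = summarize(
            [MTObservation(10.0, 2.0, runs[:5]), MTObservation(10.0, 2.0, runs[5:])]
        )
        assert whole.landing_rate == pytest.approx(split.landing_rate)

    def test_poisson_rate_unbiased(self):
        """Landing-rate estimate over 500 microtubules falls within 3 SE of
        the generative rate."""
        rate, L, dur, n_mt = 0.5, 10.0, 2.0, 500
        counts = [
            len(sg.sim_motility(L, dur, sg.MotilityGroundTruth(rate, 0.45, 0.1, 5, 0.3),
                                seed=s)[1])
            for s in range(n_mt)
        ]
        est = np.sum(counts) / (n_mt * L * dur)
        se = np.sqrt(rate / (n_mt * L * dur))
        assert abs(est - rate) <= 3 * se


class TestSummarize:
    def test_single_run(self):
        obs = MTObservation(10.0, 2.0, [Run(0, 10, 0, 4.5)])
        s = summarize([obs])
        assert s.mean_speed_um_s == pytest.approx(0.45)
        assert s.mean_run_length_um == pytest.approx(4.5)
        assert s.run_length_corrected_um == pytest.approx(4.5)

    def test_mean_of_two_runs(self):
        obs = MTObservation(10.0, 2.0, [Run(0, 10, 0, 4.0), Run(0, 10, 0, 5.0)])
        assert summarize([obs]).mean_speed_um_s == pytest.approx(0.45)

    def test_censoring_correction(self):
        runs = [Run(0, 10, 0, 4.0), Run(0, 10, 0, 6.0, censored=True)]
        s = summarize([MTObservation(10.0, 2.0, runs)])
        assert s.mean_run_length_um == pytest.approx(5.0)
        # (4 + 6) / 1 uncensored
        assert s.run_length_corrected_um == pytest.approx(10.0)

    def test_running_frequency_bounded_by_landing_rate(self, wild_type_roundtrip):
        summary, _ = wild_type_roundtrip
        assert summary.running_frequency <= summary.landing_rate


class TestVesicles:
    def test_stationary_below_threshold(self):
        tr = Track(0, np.array([0.0, 10.0]), np.array([0.0, 1.4]))
        res = classify_vesicle_tracks([tr])
        assert res["labels"] == ["stationary"]

    def test_plus_end_moving(self):
        tr = Track(0, np.array([0.0, 10.0]), np.array([0.0, 2.0]))
        assert classify_vesicle_tracks([tr])["labels"] == ["plus_end"]

    def test_repeated_point_is_stationary(self):
        tr = Track(0, np.arange(5.0), np.full(5, 3.3))
        assert classify_vesicle_tracks([tr])["labels"] == ["stationary"]

    def test_oscillation_counts_path_not_net(self):
        # net zero but 2 µm total path -> not stationary by the total rule
        tr = Track(0, np.arange(3.0), np.array([0.0, 1.0, 0.0]))
        assert classify_vesicle_tracks([tr])["labels"][0] != "stationary"

    def test_flux_single_crossing(self):
        tr = Track(0, np.array([0.0, 160.0]), np.array([0.0, 10.0]))
        res = vesicle_flux([tr], location_um=5.0, duration_min=160 / 60)
        assert res["anterograde_per_min"] == pytest.approx(0.375)
        assert res["retrograde_n"] == 0

    def test_flux_oscillating_track(self):
        xs = np.array([0.0, 10.0, 0.0, 10.0, 0.0])
        tr = Track(0, np.arange(5.0), xs)
        res = vesicle_flux([tr], location_um=5.0, duration_min=1.0)
        assert res["anterograde_n"] == 2
        assert res["retrograde_n"] == 2

    def test_flux_ratio_recovery(self):
        """A 2:1 anterograde:retrograde mixture of simulated tracks is
        recovered within 15% over 200 seeds."""
        rng = np.random.default_rng(42)
        a = r = 0
        for _ in range(200):
            n_a, n_r = rng.poisson(4), rng.poisson(2)
            tracks = []
            for i in range(n_a):
                tracks.append(Track(i, np.array([0.0, 60.0]), np.array([0.0, 10.0])))
            for i in range(n_r):
                tracks.append(Track(i, np.array([0.0, 60.0]), np.array([10.0, 0.0])))
            res = vesicle_flux(tracks, 5.0, 1.0)
            a += res["anterograde_n"]
            r += res["retrograde_n"]
        assert a / r == pytest.approx(2.0, rel=0.15)


class TestGenerativeRoundTrip:
    def test_wild_type_speed_recovery(self, wild_type_roundtrip):
        summary, _ = wild_type_roundtrip
        assert summary.mean_speed_um_s == pytest.approx(0.45, rel=0.10)

    def test_units_rescaling_consistency(self):
        tr = _single_track(0.45)
        img1 = sg.render_kymograph([tr], 15.0, 60.0, pixel_nm=105.0, frame_s=0.1,
                                   noise_sd=0.0)
        img2 = sg.render_kymograph([tr], 15.0, 60.0, pixel_nm=210.0, frame_s=0.2,
                                   noise_sd=0.0)
        s1 = trace_kymograph(img1)[0].speed_um_s
        s2 = trace_kymograph(img2)[0].speed_um_s
        assert s1 == pytest.approx(s2, rel=0.05)
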