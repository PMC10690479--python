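"""Spot detection, linking, MSD oracles and closed forms, live
colocalization, and run classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cargoquant as cq
from cargoquant.core import TrackSet, add_gaussian_spot


def make_track(positions_nm, dt=0.057, track_id=0, frames=None, **extra):
    pos = np.asarray(positions_nm, dtype=float)
    frames = np.arange(len(pos)) if frames is None else np.asarray(frames)
    df = pd.DataFrame({"track_id": track_id, "frame": frames,
                       "t_s": frames * dt, "x": pos[:, 0], "y": pos[:, 1]})
    for k, v in extra.items():
        df[k] = v
    return df


class TestDetectSpots:
    def test_noise_free_spot_recovered_precisely(self):
        img = np.full((40, 40), 50.0)
        x0, y0, amp, sig = 19.37, 22.61, 100.0, 1.5
        yy, xx = np.mgrid[0:40, 0:40]
        img += amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2)
                            / (2 * sig ** 2))
        # tiny noise so the robust scale (and hence the gate) is nonzero
        img += np.random.default_rng(0).normal(0, 0.05, img.shape)
        spots = cq.detect_spots(img, pfa=1e-4)
        assert len(spots) == 1
        s = spots[0]
        assert abs(s.x - x0) < 0.05 and abs(s.y - y0) < 0.05
        assert abs(s.sigma - sig) / sig < 0.05
        assert s.integrated_intensity == pytest.approx(
            2 * np.pi * amp * sig ** 2, rel=0.1)

    def test_two_distant_spots_detected_separately(self, rng):
        img = np.full((64, 64), 100.0)
        add_gaussian_spot(img, 20.0, 32.0, 4000.0, 1.3)
        add_gaussian_spot(img, 40.0, 32.0, 4000.0, 1.3)
        noisy = rng.poisson(img).astype(float)
        assert len(cq.detect_spots(noisy, pfa=1e-4)) == 2

    def test_false_alarm_rate_matches_pixelwise_pfa(self, rng):
        # on pure noise the number of candidates passing the PFA gate
        # calibrates against the per-pixel false-alarm probability times
        # the pixel count; the Gaussian-fit stage can only reject further
        pfa, shape, n_frames = 1e-4, (128, 128), 60
        diag = {}
        n_spots = sum(
            len(cq.detect_spots(rng.normal(100, 5, shape), pfa=pfa,
                                diagnostics=diag))
            for _ in range(n_frames))
        expected = pfa * shape[0] * shape[1] * n_frames
        se = np.sqrt(expected)  # Poisson-like error on the total count
        assert abs(diag["n_candidates"] - expected) < 4 * se + 2
        assert n_spots <= diag["n_candidates"]


class TestLinkTracks:
    def test_drifting_spot_forms_single_full_track(self):
        rows = [(f, f * 0.057, 10.0 + f, 20.0) for f in range(15)]
        spots = pd.DataFrame(rows, columns=["frame", "t_s", "x", "y"])
        ts = cq.link_tracks(spots, max_disp=3.0)
        assert ts.n_tracks == 1
        assert len(ts.df) == 15

    def test_two_stationary_spots_never_merge(self):
        rows = []
        for f in range(10):
            rows += [(f, f * 0.057, 10.0, 10.0), (f, f * 0.057, 60.0, 10.0)]
        spots = pd.DataFrame(rows, columns=["frame", "t_s", "x", "y"])
        ts = cq.link_tracks(spots, max_disp=5.0)
        assert ts.n_tracks == 2
        for _, sub in ts.tracks():
            assert sub["x"].nunique() == 1

    def test_gap_closing_with_memory(self):
        frames = [0, 1, 3, 4]  # frame 2 missing
        rows = [(f, f * 0.057, 10.0, 10.0) for f in frames]
        spots = pd.DataFrame(rows, columns=["frame", "t_s", "x", "y"])
        assert cq.link_tracks(spots, 3.0, memory=0).n_tracks == 2
        assert cq.link_tracks(spots, 3.0, memory=1).n_tracks == 1

    def test_diffusive_ground_truth_links_recovered(self):
        # noiseless positions from a diffusive simulation, scrambled into
        # per-frame detections: >= 90% of consecutive-frame links recovered
        ms = cq.MotionSpec(regime="diffusive", n_particles=12, n_frames=30,
                           D_nm2_per_s=2e4, box_nm=(110.0 * 200,) * 2,
                           seed=13)
        truth = cq.simulate_trajectories(ms)
        det = truth.df.copy()
        det["x"] /= 110.0
        det["y"] /= 110.0
        linked = cq.link_tracks(det[["frame", "t_s", "x", "y"]],
                                max_disp=5.0)
        # map each linked position back to its truth particle
        truth_px = det.set_index(["frame"])
        n_good = 0
        n_links = 0
        for _, sub in linked.tracks():
            ids = []
            for row in sub.itertuples():
                cand = det[det["frame"] == row.frame]
                d = np.hypot(cand["x"] - row.x, cand["y"] - row.y)
                ids.append(cand.loc[d.idxmin(), "track_id"])
            ids = np.asarray(ids)
            n_links += len(ids) - 1
            n_good += int((ids[1:] == ids[:-1]).sum())
        assert n_links > 0
        assert n_good / n_links >= 0.90


class TestFilterTracks:
    def _tracks(self, lengths):
        dfs = [make_track(np.zeros((n, 2)), track_id=i)
               for i, n in enumerate(lengths)]
        if not dfs:
            dfs = [pd.DataFrame(columns=["track_id", "frame", "t_s",
                                         "x", "y"])]
        return TrackSet(pd.concat(dfs, ignore_index=True), "px", 110.0)

    def test_nine_point_track_removed_ten_point_kept(self):
        ts = self._tracks([9, 10, 25])
        out = cq.filter_tracks(ts, min_points=10)
        assert set(out.track_ids()) == {1, 2}

    def test_empty_input_passes_through(self):
        ts = self._tracks([])
        assert len(cq.filter_tracks(ts).df) == 0

    def test_roi_excludes_outside_tracks(self):
        a = make_track(np.full((12, 2), 5.0), track_id=0)
        b = make_track(np.full((12, 2), 50.0), track_id=1)
        ts = TrackSet(pd.concat([a, b], ignore_index=True), "px", 110.0)
        roi = np.array([[0, 0], [20, 0], [20, 20], [0, 20]])
        out = cq.filter_tracks(ts, min_points=10, roi=roi)
        assert set(out.track_ids()) == {0}


def brute_force_msd(positions_nm, dt):
    """Exhaustive ordered-pair enumeration oracle."""
    pos = np.asarray(positions_nm, dtype=float)
    n = len(pos)
    out = {}
    for k in range(1, n):
        sq = [np.sum((pos[i + k] - pos[i]) ** 2) for i in range(n - k)]
        out[k * dt] = (float(np.mean(sq)), len(sq))
    return out


class TestMSD:
    def test_stationary_track_msd_zero(self):
        tr = make_track(np.full((12, 2), 500.0))
        c = cq.msd_per_track(tr, position_unit="nm", frame_interval_s=0.057)
        assert np.all(c.msd_nm2 == 0.0)

    def test_ballistic_closed_form(self):
        v, dt = 400.0, 0.05
        pos = np.column_stack([v * dt * np.arange(20), np.zeros(20)])
        c = cq.msd_per_track(make_track(pos, dt=dt), position_unit="nm",
                             frame_interval_s=dt)
        np.testing.assert_allclose(c.msd_nm2, v ** 2 * c.delays_s ** 2,
                                   rtol=1e-10)

    @given(st.integers(min_value=2, max_value=20), st.integers(0, 2 ** 31))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_enumeration(self, n_points, seed):
        gen = np.random.default_rng(seed)
        pos = gen.uniform(0, 5000, (n_points, 2))
        dt = 0.057
        c = cq.msd_per_track(make_track(pos, dt=dt), position_unit="nm",
                             frame_interval_s=dt)
        oracle = brute_force_msd(pos, dt)
        assert len(c.delays_s) == len(oracle)
        for d, m, w in zip(c.delays_s, c.msd_nm2, c.weight):
            om, ow = oracle[min(oracle, key=lambda k: abs(k - d))]
            assert m == pytest.approx(om, rel=1e-12)
            assert w == ow

    def test_pair_count_non_increasing_in_delay(self):
        pos = np.random.default_rng(5).uniform(0, 100, (15, 2))
        c = cq.msd_per_track(make_track(pos), position_unit="nm",
                             frame_interval_s=0.057)
        assert np.all(np.diff(c.weight) <= 0)


class TestWeightedMeanMSD:
    def test_single_curve_identity(self):
        pos = np.random.default_rng(3).uniform(0, 100, (10, 2))
        c = cq.msd_per_track(make_track(pos), position_unit="nm",
                             frame_interval_s=0.057)
        m = cq.weighted_mean_msd([c])
        np.testing.assert_allclose(m.msd_nm2, c.msd_nm2)

    def test_hand_weighted_average(self):
        a = cq.MSDCurve(np.array([0.1]), np.array([0.0]), np.array([1]))
        b = cq.MSDCurve(np.array([0.1]), np.array([4.0]), np.array([3]))
        m = cq.weighted_mean_msd([a, b])
        assert m.msd_nm2[0] == pytest.approx(3.0)
        assert m.weight[0] == 4

    def test_identical_curves_unchanged(self):
        c = cq.MSDCurve(np.array([0.1, 0.2]), np.array([5.0, 9.0]),
                        np.array([9, 8]))
        m = cq.weighted_mean_msd([c] * 4)
        np.testing.assert_allclose(m.msd_nm2, c.msd_nm2)

    def test_diffusive_ensemble_recovers_4d_slope(self):
        D = 1.0e4
        ms = cq.MotionSpec(regime="diffusive", n_particles=200, n_frames=60,
                           D_nm2_per_s=D, box_nm=(1e7, 1e7), seed=21)
        tr = cq.simulate_trajectories(ms)
        wm = cq.weighted_mean_msd(cq.msd_all_tracks(tr, 0.25))
        D_est = cq.fit_diffusion_coefficient(wm, 10)
        assert abs(D_est - D) / D < 0.10


class TestTrackMeanIntensity:
    def test_constant_amplitude_track(self):
        tr = make_track(np.zeros((5, 2)), amplitude=2.0, sigma=1.0)
        expected = 2 * np.pi * 2.0
        assert cq.track_mean_intensity(tr) == pytest.approx(expected)

    def test_amplitudes_one_and_three_sigma_one_gives_4pi(self):
        tr = make_track(np.zeros((2, 2)), amplitude=[1.0, 3.0],
                        sigma=[1.0, 1.0])
        assert cq.track_mean_intensity(tr) == pytest.approx(4 * np.pi)

    def test_rendered_spot_intensity_recovered(self, rng):
        photons = 4000.0
        img = np.full((48, 48), 100.0)
        add_gaussian_spot(img, 24.2, 23.8, photons, 1.3)
        noisy = rng.poisson(img).astype(float)
        spots = cq.detect_spots(noisy, pfa=1e-6)
        assert len(spots) == 1
        assert abs(spots[0].integrated_intensity - photons) / photons < 0.1


class TestColocalizeLive:
    def _trackset(self, dfs):
        return TrackSet(pd.concat(dfs, ignore_index=True), "nm", None)

    def _separated_tracks(self, rng, n=4, n_frames=20, spacing=8000.0):
        # anchors on a coarse grid so only intentional coincidences can
        # fall within the 300 nm colocalization radius
        dfs = []
        for i in range(n):
            anchor = np.array([(i % 2) * spacing, (i // 2) * spacing])
            jitter = rng.normal(0, 50.0, (n_frames, 2))
            dfs.append(make_track(anchor + jitter, track_id=i))
        return dfs

    def test_copied_channel_gives_100_percent(self, rng):
        dfs = self._separated_tracks(rng, 5)
        t1 = self._trackset(dfs)
        pct, _ = cq.colocalize_live(t1, t1, dist_nm=300.0)
        assert pct == 100.0

    def test_displaced_channel_gives_0_percent(self, rng):
        dfs = self._separated_tracks(rng)
        t1 = self._trackset(dfs)
        shifted = [d.assign(x=d["x"] + 500.0) for d in dfs]
        pct, _ = cq.colocalize_live(t1, self._trackset(shifted), 300.0)
        assert pct == 0.0

    def test_half_coinciding_tracks_give_50_percent(self, rng):
        dfs = self._separated_tracks(rng, 4)
        t1 = self._trackset(dfs)
        # ch2 = copies of half the ch1 tracks, rest far away
        far = [d.assign(x=d["x"] + 100000.0, track_id=d["track_id"] + 10)
               for d in dfs[2:]]
        t2 = self._trackset(dfs[:2] + far)
        pct, per_frame = cq.colocalize_live(t1, t2, 300.0)
        assert pct == pytest.approx(50.0)
        assert (per_frame["n_present"] == 4).all()

    def test_no_ch1_tracks_reports_missing(self):
        empty = TrackSet(pd.DataFrame(columns=["track_id", "frame", "t_s",
                                               "x", "y"]), "nm", None)
        t2 = self._trackset([make_track(np.zeros((5, 2)))])
        pct, _ = cq.colocalize_live(empty, t2)
        assert np.isnan(pct)

    def test_averaging_window_limits_frames(self, rng):
        dfs = [make_track(rng.uniform(0, 1000, (80, 2)), track_id=0)]
        t1 = self._trackset(dfs)
        _, per_frame = cq.colocalize_live(t1, t1, n_frames=50)
        assert len(per_frame) == 50


class TestClassifyRuns:
    def test_immobile_track_fully_stationary(self):
        tr = make_track(np.full((30, 2), 100.0))
        ts = TrackSet(tr, "nm", None)
        seg = cq.classify_runs_movie(ts)
        assert seg.percent_stationary == pytest.approx(100.0)
        assert seg.percent_apical == 0.0

    def test_pure_apical_run_stats(self):
        # 500 nm/s toward -y for 10 s: one apical run, 5 um, 100% apical
        dt = 0.1
        n = 101
        pos = np.column_stack([np.zeros(n),
                               -500.0 * dt * np.arange(n)])
        ts = TrackSet(make_track(pos, dt=dt), "nm", None)
        seg = cq.classify_runs_movie(ts, axis=(0, -1), v_min=100,
                                     min_run_length=500, smooth_window=3)
        assert seg.percent_apical == pytest.approx(100.0)
        assert len(seg.segments) == 1
        assert seg.apical_run_length_um == pytest.approx(5.0)
        assert seg.apical_velocity_nm_s == pytest.approx(500.0)

    def test_percentages_sum_to_100(self):
        ms = cq.MotionSpec(regime="run_and_pause", n_particles=10,
                           n_frames=200, seed=3)
        tr = cq.simulate_trajectories(ms)
        seg = cq.classify_runs_movie(tr)
        total = (seg.percent_apical + seg.percent_basal
                 + seg.percent_stationary)
        assert total == pytest.approx(100.0)

    def test_min_run_threshold_never_increases_percent_apical(self):
        ms = cq.MotionSpec(regime="run_and_pause", n_particles=15,
                           n_frames=200, seed=7)
        tr = cq.simulate_trajectories(ms)
        loose = cq.classify_runs_movie(tr, min_run_length=1e-6)
        strict = cq.classify_runs_movie(tr, min_run_length=2000.0)
        assert strict.percent_apical <= loose.percent_apical + 1e-9

    def test_ground_truth_percent_apical_recovered(self):
        ms = cq.MotionSpec(regime="run_and_pause", n_particles=60,
                           n_frames=400, v_nm_per_s=500.0,
                           dwell_mean_s=(6.0, 2.0, 2.0),
                           box_nm=(5e4, 5e4), seed=5)
        tr = cq.simulate_trajectories(ms)
        truth_ap = 100.0 * np.mean([
            (sub["state"].iloc[:-1] == "apical").mean()
            for _, sub in tr.tracks()])
        seg = cq.classify_runs_movie(tr)
        assert abs(seg.percent_apical - truth_ap) < 5.0
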