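"""Spot detection, trajectory linking, MSD analysis, live colocalization
and run-based motility classification.

The analysis chain mirrors a high-speed single-particle imaging workflow:
particles are detected per frame without a user-set intensity threshold by
2D Gaussian fitting gated at a probability of false alarm, linked frame to
frame by optimal assignment, filtered (tracks shorter than 10 timepoints
are discarded since short tracks make MSD analysis inaccurate), and
summarised as a weighted mean MSD across tracks.  Object-based live
colocalization declares a channel-1 track co-localised at a timepoint when
a channel-2 track member lies within 300 nm, and averages the per-timepoint
percentage over the first 50 timepoints of the movie.  For bidirectional
transport, each trajectory is segmented into apical runs, basal runs and
stationary periods along a declared axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import least_squares, linear_sum_assignment
from scipy.spatial import cKDTree

from .core import ImageScene, TrackSet, pfa_z, robust_sigma

__all__ = [
    "Spot",
    "MSDCurve",
    "detect_spots",
    "detect_spots_movie",
    "link_tracks",
    "filter_tracks",
    "msd_per_track",
    "weighted_mean_msd",
    "colocalize_live",
    "track_mean_intensity",
    "classify_runs",
    "classify_runs_movie",
]

TWO_PI = 2.0 * np.pi


@dataclass
class Spot:
    """A sub-pixel detection from a symmetric 2D Gaussian fit.

    ``integrated_intensity`` is the area under the fitted Gaussian,
    2*pi*amplitude*sigma^2.
    """

    frame: int
    x: float
    y: float
    amplitude: float
    sigma: float
    offset: float
    channel: int = 0

    @property
    def integrated_intensity(self) -> float:
        return TWO_PI * self.amplitude * self.sigma ** 2


@dataclass
class MSDCurve:
    """MSD per delay time with the number of contributing pairs.

    For a single track the pair count (``weight``) is non-increasing in
    the delay; for the weighted mean across tracks it is the summed count.
    """

    delays_s: np.ndarray
    msd_nm2: np.ndarray
    weight: np.ndarray
    kind: str = "per_track"  # or "weighted_mean"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"delay_s": self.delays_s,
                             "msd_nm2": self.msd_nm2,
                             "weight": self.weight})


def _gauss_residuals(p, xx, yy, data):
    a, x0, y0, s, b = p
    model = a * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * s * s)) + b
    return (model - data).ravel()


def detect_spots(frame: np.ndarray, pfa: float = 1e-4, fit_window: int = 7,
                 channel: int = 0, frame_index: int = 0,
                 diagnostics: dict | None = None) -> list[Spot]:
    """Detect diffraction-limited spots by PFA-gated 2D Gaussian fitting.

    Candidate local maxima are accepted when their raw peak value exceeds
    the robust background threshold median + z(1-pfa)*sigma_bg — i.e. a
    background-only pixel passes with probability ``pfa``, so no user
    intensity threshold is needed.  Accepted candidates are refined by a
    least-squares symmetric Gaussian fit (amplitude, x, y, sigma, offset);
    non-convergent fits are dropped and counted in ``diagnostics``.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_spots expects a single 2D frame")
    if fit_window < 5:
        raise ValueError("fit_window must be >= 5 px")
    bg = float(np.median(img))
    sigma_bg = robust_sigma(img)
    if sigma_bg == 0.0:
        return []
    thr = bg + pfa_z(pfa) * sigma_bg

    # local maxima of the raw frame above the PFA threshold
    maxf = ndimage.maximum_filter(img, size=3, mode="nearest")
    cand = np.argwhere((img == maxf) & (img > thr))

    half = fit_window // 2
    h, w = img.shape
    spots: list[Spot] = []
    n_failed = 0
    for r, c in cand:
        r0, r1 = max(r - half, 0), min(r + half + 1, h)
        c0, c1 = max(c - half, 0), min(c + half + 1, w)
        patch = img[r0:r1, c0:c1]
        yy, xx = np.mgrid[r0:r1, c0:c1]
        a0 = float(img[r, c] - bg)
        p0 = [max(a0, 1e-6), float(c), float(r), 1.3, bg]
        try:
            res = least_squares(
                _gauss_residuals, p0, args=(xx, yy, patch),
                bounds=([0, c0 - 1, r0 - 1, 0.3, -np.inf],
                        [np.inf, c1, r1, half + 2.0, np.inf]),
                max_nfev=200)
        except Exception:
            n_failed += 1
            continue
        if not res.success:
            n_failed += 1
            continue
        a, x0, y0, s, b = res.x
        if a <= 0 or not (c0 - 1 <= x0 <= c1 and r0 - 1 <= y0 <= r1):
            n_failed += 1
            continue
        spots.append(Spot(frame_index, float(x0), float(y0), float(a),
                          float(s), float(b), channel))

    # merge fits that converged onto the same spot (keep the brighter)
    spots.sort(key=lambda s: -s.amplitude)
    kept: list[Spot] = []
    for s in spots:
        if all(np.hypot(s.x - k.x, s.y - k.y) > 1.0 for k in kept):
            kept.append(s)
    if diagnostics is not None:
        diagnostics["n_candidates"] = diagnostics.get("n_candidates", 0) \
            + len(cand)
        diagnostics["n_failed_fits"] = diagnostics.get("n_failed_fits", 0) \
            + n_failed
    return kept


def detect_spots_movie(scene: ImageScene, channel: int = 0,
                       pfa: float = 1e-4, fit_window: int = 7,
                       diagnostics: dict | None = None) -> pd.DataFrame:
    """Run ``detect_spots`` on every frame of one channel of a movie.

    Returns a long table (frame, t_s, x, y, sigma, amplitude,
    integrated_intensity, channel) with positions in pixels.
    """
    rows = []
    for t in range(scene.n_frames):
        for s in detect_spots(scene.frame(t, channel), pfa, fit_window,
                              channel, t, diagnostics):
            rows.append((t, t * scene.frame_interval_s, s.x, s.y, s.sigma,
                         s.amplitude, s.integrated_intensity, channel))
    return pd.DataFrame(rows, columns=["frame", "t_s", "x", "y", "sigma",
                                       "amplitude", "integrated_intensity",
                                       "channel"])


def link_tracks(spots: pd.DataFrame, max_disp: float = 5.0,
                memory: int = 0, pixel_size_nm: float | None = None,
                frame_interval_s: float = 0.057) -> TrackSet:
    """Link per-frame spots into trajectories by optimal assignment.

    For each consecutive frame pair the globally minimal total squared
    displacement matching is computed (Hungarian algorithm) with links
    longer than ``max_disp`` pixels forbidden; with ``memory`` > 0, a track
    that misses a detection stays eligible for re-linking for that many
    frames (gap closing).  Unlinked spots start new tracks.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    cols = ["frame", "t_s", "x", "y"]
    extra = [c for c in ("sigma", "amplitude", "integrated_intensity",
                         "channel") if c in spots.columns]
    if not len(spots):
        return TrackSet(pd.DataFrame(columns=["track_id"] + cols + extra),
                        "px", pixel_size_nm, frame_interval_s)

    spots = spots.sort_values(["frame"]).reset_index(drop=True)
    track_of_row = np.full(len(spots), -1, dtype=int)
    next_track = 0
    # active tracks: track_id -> (last_frame, x, y)
    active: dict[int, tuple[int, float, float]] = {}
    gate2 = max_disp * max_disp

    for f, idx in spots.groupby("frame").groups.items():
        idx = np.asarray(idx)
        xy = spots.loc[idx, ["x", "y"]].to_numpy(float)
        elig = [(tid, lx, ly) for tid, (lf, lx, ly) in active.items()
                if f - lf <= memory + 1]
        if elig:
            txy = np.array([[lx, ly] for _, lx, ly in elig])
            d2 = ((txy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
            n_t, n_s = d2.shape
            # augmented square cost: real links top-left, "no link" dummies
            # at the gate cost on the diagonals, dummy-dummy free
            big = 1e12
            cost = np.zeros((n_t + n_s, n_s + n_t))
            cost[:n_t, :n_s] = np.where(d2 <= gate2, d2, big)
            cost[:n_t, n_s:] = np.where(np.eye(n_t, dtype=bool), gate2, big)
            cost[n_t:, :n_s] = np.where(np.eye(n_s, dtype=bool), gate2, big)
            ri, ci = linear_sum_assignment(cost)
            matched_spots = set()
            for r, c in zip(ri, ci):
                if r < n_t and c < n_s and d2[r, c] <= gate2:
                    tid = elig[r][0]
                    row = idx[c]
                    track_of_row[row] = tid
                    active[tid] = (f, xy[c, 0], xy[c, 1])
                    matched_spots.add(c)
        else:
            matched_spots = set()
        for c, row in enumerate(idx):
            if c not in matched_spots:
                track_of_row[row] = next_track
                active[next_track] = (f, xy[c, 0], xy[c, 1])
                next_track += 1
        # retire tracks that fell out of the memory window
        active = {tid: v for tid, v in active.items()
                  if f - v[0] <= memory}

    out = spots.copy()
    out.insert(0, "track_id", track_of_row)
    return TrackSet(out[["track_id"] + cols + extra], "px", pixel_size_nm,
                    frame_interval_s)


def filter_tracks(tracks: TrackSet, min_points: int = 10,
                  roi: np.ndarray | None = None) -> TrackSet:
    """Discard short tracks and tracks whose mean position leaves the ROI.

    Tracks with fewer than ``min_points`` timepoints are removed (short
    tracks make MSD estimates inaccurate); if ``roi`` is given as an (N, 2)
    polygon of (x, y) vertices, tracks whose mean position falls outside it
    are removed as well.
    """
    if min_points < 1:
        raise ValueError("min_points must be >= 1")
    df = tracks.df
    if not len(df):
        return tracks
    sizes = df.groupby("track_id").size()
    keep = set(sizes[sizes >= min_points].index)
    if roi is not None:
        from matplotlib.path import Path
        poly = Path(np.asarray(roi, dtype=float))
        means = df.groupby("track_id")[["x", "y"]].mean()
        inside = means.index[poly.contains_points(means.to_numpy())]
        keep &= set(inside)
    out = df[df["track_id"].isin(keep)].reset_index(drop=True)
    return TrackSet(out, tracks.position_unit, tracks.pixel_size_nm,
                    tracks.frame_interval_s, dict(tracks.meta))


def msd_per_track(track: pd.DataFrame, pixel_size_nm: float | None = None,
                  frame_interval_s: float | None = None,
                  max_delay_fraction: float = 1.0,
                  position_unit: str = "px") -> MSDCurve:
    """MSD of one track over all ordered pairs at each delay.

    msd(k*dt) = mean over pairs (i, i+k) of ||p_{i+k} - p_i||^2 in nm^2,
    with the pair count as weight.  Delays are limited to
    ``max_delay_fraction`` of the track duration.  The track must be
    regularly sampled in ``frame``; missing frames simply contribute no
    pairs at the affected delays.
    """
    sub = track.sort_values("frame")
    frames = sub["frame"].to_numpy(int)
    if len(frames) < 2:
        raise ValueError("MSD needs at least 2 points")
    xy = sub[["x", "y"]].to_numpy(float)
    if position_unit == "px":
        if pixel_size_nm is None:
            raise ValueError("pixel_size_nm required for px positions")
        xy = xy * pixel_size_nm
    dt = frame_interval_s
    if dt is None:
        ts = sub["t_s"].to_numpy(float)
        dts = np.diff(np.unique(frames))
        dt = float(np.median(np.diff(ts) / np.diff(frames)))
    span = frames.max() - frames.min()
    kmax = max(int(np.floor(span * max_delay_fraction)), 1)

    pos_by_frame = {f: xy[i] for i, f in enumerate(frames)}
    delays, msds, weights = [], [], []
    for k in range(1, kmax + 1):
        pairs = [(pos_by_frame[f], pos_by_frame[f + k])
                 for f in frames if f + k in pos_by_frame]
        if not pairs:
            continue
        a = np.array([p for p, _ in pairs])
        b = np.array([q for _, q in pairs])
        sq = ((b - a) ** 2).sum(axis=1)
        delays.append(k * dt)
        msds.append(float(sq.mean()))
        weights.append(len(pairs))
    return MSDCurve(np.asarray(delays), np.asarray(msds),
                    np.asarray(weights), "per_track")


def msd_all_tracks(tracks: TrackSet,
                   max_delay_fraction: float = 1.0) -> list[MSDCurve]:
    """Per-track MSD curves for every track with >= 2 points."""
    curves = []
    for _, sub in tracks.tracks():
        if len(sub) < 2:
            continue
        curves.append(msd_per_track(
            sub, tracks.pixel_size_nm, tracks.frame_interval_s,
            max_delay_fraction, tracks.position_unit))
    return curves


def weighted_mean_msd(curves: list[MSDCurve]) -> MSDCurve:
    """Mean MSD across tracks, weighted by each track's pair count.

    Per delay, the average of the per-track MSD values weighted by the
    number of displacement pairs each track contributes; delays covered by
    no track are omitted.
    """
    if not curves:
        raise ValueError("need at least one MSD curve")
    acc: dict[float, tuple[float, float]] = {}
    for c in curves:
        for d, m, w in zip(c.delays_s, c.msd_nm2, c.weight):
            s, ws = acc.get(round(float(d), 9), (0.0, 0.0))
            acc[round(float(d), 9)] = (s + m * w, ws + w)
    delays = np.array(sorted(acc))
    msd = np.array([acc[d][0] / acc[d][1] for d in delays])
    weight = np.array([acc[d][1] for d in delays])
    return MSDCurve(delays, msd, weight, "weighted_mean")


def fit_diffusion_coefficient(curve: MSDCurve, n_delays: int = 10) -> float:
    """Slope-based 2D diffusion estimate D = slope/4 from the first delays."""
    n = min(n_delays, len(curve.delays_s))
    if n < 2:
        raise ValueError("need >= 2 delays to fit a slope")
    x, y = curve.delays_s[:n], curve.msd_nm2[:n]
    slope = float(np.polyfit(x, y, 1)[0])
    return slope / 4.0


def track_mean_intensity(track: pd.DataFrame) -> float:
    """Mean integrated spot intensity (2*pi*A*sigma^2) over a track."""
    if "integrated_intensity" in track.columns:
        vals = track["integrated_intensity"].to_numpy(float)
    elif {"amplitude", "sigma"} <= set(track.columns):
        vals = TWO_PI * track["amplitude"].to_numpy(float) \
            * track["sigma"].to_numpy(float) ** 2
    else:
        raise ValueError("track carries no intensity information")
    if not len(vals):
        raise ValueError("empty track")
    return float(vals.mean())


def colocalize_live(tracks_ch1: TrackSet, tracks_ch2: TrackSet,
                    dist_nm: float = 300.0, n_frames: int = 50):
    """Object-based live colocalization percentage for a movie.

    At each timepoint, a channel-1 track counts as co-localised when a
    spot belonging to a channel-2 track lies within ``dist_nm``; the
    percentage of co-localised channel-1 tracks among those present is
    averaged over the first ``n_frames`` timepoints (all available if
    fewer).  Returns ``(percent, per_frame)`` where ``per_frame`` is a
    DataFrame (frame, n_present, n_coloc, percent); the movie value is NaN
    when no channel-1 track is present in the window.
    """
    if dist_nm <= 0:
        raise ValueError("dist_nm must be positive")
    t1 = tracks_ch1.in_nm().df
    t2 = tracks_ch2.in_nm().df
    if not len(t1):
        return float("nan"), pd.DataFrame(columns=["frame", "n_present",
                                                   "n_coloc", "percent"])
    frames = np.sort(t1["frame"].unique())[:n_frames]
    by2 = {f: sub[["x", "y"]].to_numpy(float)
           for f, sub in t2.groupby("frame")} if len(t2) else {}
    rows = []
    for f in frames:
        sub1 = t1[t1["frame"] == f]
        n_present = sub1["track_id"].nunique()
        pts2 = by2.get(f)
        if pts2 is None or not len(pts2):
            n_coloc = 0
        else:
            tree = cKDTree(pts2)
            d, _ = tree.query(sub1[["x", "y"]].to_numpy(float))
            coloc_rows = sub1.loc[np.asarray(d) < dist_nm, "track_id"]
            n_coloc = coloc_rows.nunique()
        rows.append((int(f), int(n_present), int(n_coloc),
                     100.0 * n_coloc / n_present if n_present else np.nan))
    per_frame = pd.DataFrame(rows, columns=["frame", "n_present", "n_coloc",
                                            "percent"])
    percent = float(per_frame["percent"].mean())
    return percent, per_frame


def _moving_average(v: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(v) < window:
        return v
    kernel = np.ones(window) / window
    pad = window // 2
    vp = np.pad(v, pad, mode="edge")
    out = np.convolve(vp, kernel, mode="valid")
    return out[:len(v)]


@dataclass
class RunSegmentation:
    """Per-track run segments and per-movie motility aggregates.

    ``segments`` rows: track_id, segment class (apical/basal/stationary),
    duration_s, length_nm (net axial displacement), mean_velocity_nm_s.
    Aggregate percentages are fractions of total trajectory time; run
    velocities and lengths average over included (above-threshold) runs.
    """

    segments: pd.DataFrame
    percent_apical: float
    percent_basal: float
    percent_stationary: float
    apical_velocity_nm_s: float
    basal_velocity_nm_s: float
    apical_run_length_um: float
    basal_run_length_um: float
    mean_instantaneous_velocity_nm_s: float
    params: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


def classify_runs(track: pd.DataFrame, axis: tuple[float, float] = (0.0, -1.0),
                  v_min: float = 100.0, min_run_length: float = 500.0,
                  smooth_window: int = 3,
                  position_unit: str = "nm",
                  pixel_size_nm: float | None = None) -> pd.DataFrame:
    """Segment one trajectory into apical/basal runs and stationary time.

    The per-step velocity projected on ``axis`` (apical positive) is
    smoothed over ``smooth_window`` frames and classified: >= ``v_min``
    apical, <= -``v_min`` basal, else stationary.  Contiguous same-class
    steps merge into segments; directed segments whose net axial length is
    below ``min_run_length`` (nm) are reclassified as stationary, so the
    inclusion threshold can only reduce the time attributed to runs.
    Returns the per-track segment table.
    """
    if v_min <= 0 or min_run_length <= 0:
        raise ValueError("v_min and min_run_length must be positive")
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.hypot(*ax)
    sub = track.sort_values("frame")
    xy = sub[["x", "y"]].to_numpy(float)
    if position_unit == "px":
        if pixel_size_nm is None:
            raise ValueError("pixel_size_nm required for px positions")
        xy = xy * pixel_size_nm
    t = sub["t_s"].to_numpy(float)
    if len(xy) < 2:
        raise ValueError("track too short to classify")
    s = xy @ ax
    dt = np.diff(t)
    v = np.diff(s) / dt
    if len(v) >= smooth_window > 1:
        v_s = _moving_average(v, smooth_window)
    else:
        v_s = v  # too short to smooth; flagged by caller aggregates
    cls = np.where(v_s >= v_min, 1, np.where(v_s <= -v_min, -1, 0))

    tid = sub["track_id"].iloc[0] if "track_id" in sub.columns else 0
    segs = []
    start = 0
    for i in range(1, len(cls) + 1):
        if i == len(cls) or cls[i] != cls[start]:
            dur = float(t[i] - t[start])
            length = float(abs(s[i] - s[start]))
            klass = {1: "apical", -1: "basal", 0: "stationary"}[int(cls[start])]
            if klass != "stationary" and length < min_run_length:
                klass = "stationary"
            segs.append((tid, klass, dur, length,
                         length / dur if dur > 0 else 0.0,
                         float(np.mean(np.abs(v[start:i])))))
            start = i
    return pd.DataFrame(segs, columns=["track_id", "klass", "duration_s",
                                       "length_nm", "mean_velocity_nm_s",
                                       "mean_abs_step_velocity_nm_s"])


def classify_runs_movie(tracks: TrackSet,
                        axis: tuple[float, float] = (0.0, -1.0),
                        v_min: float = 100.0, min_run_length: float = 500.0,
                        smooth_window: int = 3) -> RunSegmentation:
    """Run classification aggregated over all tracks of a movie.

    Percentages are of total trajectory time across tracks (they sum to
    100 up to rounding); apical/basal velocity and run length average over
    included runs.  The mean instantaneous velocity averages the absolute
    smoothed axial step speed over moving segments.
    """
    all_segs = []
    flags = []
    for tid, sub in tracks.tracks():
        if len(sub) < 2:
            continue
        if len(sub) - 1 < smooth_window:
            flags.append(f"track {tid}: shorter than smooth_window, "
                         "classified without smoothing")
        all_segs.append(classify_runs(
            sub, axis, v_min, min_run_length, smooth_window,
            tracks.position_unit, tracks.pixel_size_nm))
    if not all_segs:
        raise ValueError("no classifiable tracks")
    segs = pd.concat(all_segs, ignore_index=True)
    total = segs["duration_s"].sum()
    by = segs.groupby("klass")["duration_s"].sum()
    pct = {k: 100.0 * by.get(k, 0.0) / total
           for k in ("apical", "basal", "stationary")}
    ap = segs[segs["klass"] == "apical"]
    ba = segs[segs["klass"] == "basal"]
    moving = segs[segs["klass"] != "stationary"]
    return RunSegmentation(
        segments=segs,
        percent_apical=pct["apical"],
        percent_basal=pct["basal"],
        percent_stationary=pct["stationary"],
        apical_velocity_nm_s=float(ap["mean_velocity_nm_s"].mean())
        if len(ap) else np.nan,
        basal_velocity_nm_s=float(ba["mean_velocity_nm_s"].mean())
        if len(ba) else np.nan,
        apical_run_length_um=float(ap["length_nm"].mean() / 1000.0)
        if len(ap) else np.nan,
        basal_run_length_um=float(ba["length_nm"].mean() / 1000.0)
        if len(ba) else np.nan,
        mean_instantaneous_velocity_nm_s=float(
            moving["mean_abs_step_velocity_nm_s"].mean())
        if len(moving) else np.nan,
        params={"axis": tuple(axis), "v_min": v_min,
                "min_run_length": min_run_length,
                "smooth_window": smooth_window},
        flags=flags)
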