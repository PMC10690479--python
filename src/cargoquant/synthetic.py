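"""Synthetic microscopy and proteomics data with known ground truth.

Every generator is a pure function of its spec (including the seed), and
ground truth is returned alongside each artifact so that downstream
estimators — segmentation, spot detection, tracking, MSD, run
classification, enrichment — can be scored without any external data.

The generators emulate the three experimental input classes of the study:
fixed-cell immunofluorescence images of AP1-positive puncta around nuclei,
two-channel time-lapse movies of moving cargo particles, and label-free
pull-down intensity matrices with missing-not-at-random dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ImageScene, TrackSet, add_gaussian_spot

__all__ = [
    "SceneSpec",
    "MotionSpec",
    "ProteomicsSimSpec",
    "render_fixed_cell_scene",
    "render_bead_movie",
    "simulate_trajectories",
    "render_movie_from_trajectories",
    "simulate_proteomics_matrix",
]


@dataclass
class SceneSpec:
    """Parameters of a synthetic fixed-cell scene or movie rendering.

    ``puncta_intensity`` is the (mean, sd) of the integrated photon count
    per punctum; ``puncta_sigma_px`` the PSF standard deviation;
    ``dispersion_px`` the sd of puncta placement around the nucleus
    centroid; ``noise_model`` is ``"poisson"`` or ``"gaussian"`` (with
    ``gaussian_sd`` photons), or ``"none"`` for a noise-free render.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size_nm: float = 110.0
    frame_interval_s: float = 0.057
    n_cells: int = 5
    nucleus_radius_px: float = 12.0
    puncta_per_cell: int = 20
    puncta_intensity: tuple[float, float] = (2000.0, 200.0)
    puncta_sigma_px: float = 1.3
    dispersion_px: float = 20.0
    background_level: float = 100.0
    noise_model: str = "poisson"
    gaussian_sd: float = 0.0
    n_channels: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.puncta_per_cell < 0:
            raise ValueError("counts must be >= 0")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.puncta_sigma_px <= 0:
            raise ValueError("puncta_sigma_px must be positive")
        if self.noise_model not in ("poisson", "gaussian", "none"):
            raise ValueError("noise_model must be poisson|gaussian|none")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")


@dataclass
class MotionSpec:
    """Parameters of simulated 2D particle motion (positions in nm).

    Regimes: ``stationary``; ``diffusive`` (per-axis step variance
    2 D dt); ``directed`` (displacement v dt along ``direction``);
    ``run_and_pause`` — a three-state machine (apical run, basal run,
    stationary pause) with exponential dwell times ``dwell_mean_s`` and
    run speed ``v_nm_per_s`` along +/- ``direction`` (apical = the given
    direction, default -y, i.e. toward the image top).
    """

    regime: str = "diffusive"
    n_particles: int = 10
    n_frames: int = 100
    frame_interval_s: float = 0.057
    D_nm2_per_s: float = 1.0e4
    v_nm_per_s: float = 500.0
    direction: tuple[float, float] = (0.0, -1.0)
    dwell_mean_s: tuple[float, float, float] = (3.0, 1.0, 2.0)  # apical, basal, pause
    pause_D_nm2_per_s: float = 0.0
    box_nm: tuple[float, float] = (14080.0, 14080.0)  # 128 px at 110 nm/px
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in ("stationary", "diffusive", "directed",
                               "run_and_pause"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.D_nm2_per_s < 0 or self.pause_D_nm2_per_s < 0:
            raise ValueError("diffusion coefficients must be >= 0")
        if self.v_nm_per_s < 0:
            raise ValueError("speed must be >= 0")
        if any(d <= 0 for d in self.dwell_mean_s):
            raise ValueError("dwell means must be positive")
        n = float(np.hypot(*self.direction))
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("direction must have unit norm")


@dataclass
class ProteomicsSimSpec:
    """Parameters of a simulated label-free pull-down intensity matrix.

    Intensities are log-normal: log2 values are drawn from
    Normal(base_log2_mean, base_log2_sd) per protein with replicate noise
    ``rep_log2_sd``; ``n_spiked`` proteins have their group-2 (bait) log2
    mean raised by ``spike_log2_effect``.  Dropout is missing-not-at-random:
    the missing probability decreases with log2 intensity via a logistic
    curve centred ``dropout_center_sds`` below the base mean.
    """

    n_proteins: int = 1000
    n_per_group: int = 3
    base_log2_mean: float = 25.0
    base_log2_sd: float = 2.0
    rep_log2_sd: float = 0.5
    n_spiked: int = 0
    spike_log2_effect: float = 5.0
    dropout_max: float = 0.0        # dropout probability at very low intensity
    dropout_center_sds: float = 1.5
    dropout_slope: float = 1.0      # logistic steepness in log2 units
    peptides_lambda: float = 6.0    # Poisson mean of per-protein peptide count
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spiked > self.n_proteins:
            raise ValueError("n_spiked must be <= n_proteins")
        if self.n_per_group < 2:
            raise ValueError("need >= 2 replicates per group")
        if not 0.0 <= self.dropout_max <= 1.0:
            raise ValueError("dropout_max must be a probability")


def _apply_noise(clean: np.ndarray, spec: SceneSpec,
                 rng: np.random.Generator) -> np.ndarray:
    if spec.noise_model == "poisson":
        return rng.poisson(np.clip(clean, 0, None)).astype(float)
    if spec.noise_model == "gaussian":
        return clean + rng.normal(0.0, spec.gaussian_sd, clean.shape)
    return clean.copy()


def _place_nuclei(spec: SceneSpec, rng: np.random.Generator,
                  max_tries: int = 2000) -> np.ndarray:
    """Rejection-sample non-overlapping nucleus centers away from borders."""
    h, w = spec.image_shape
    margin = spec.nucleus_radius_px + 2
    min_sep = 2.0 * spec.nucleus_radius_px + 4.0
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < spec.n_cells:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {spec.n_cells} non-overlapping nuclei of "
                f"radius {spec.nucleus_radius_px} px in a {h}x{w} image "
                f"(min separation {min_sep:.1f} px) after {max_tries} tries")
        tries += 1
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, h - margin)
        if all(np.hypot(x - cx, y - cy) >= min_sep for cx, cy in centers):
            centers.append((x, y))
    return np.asarray(centers).reshape(-1, 2)


def render_fixed_cell_scene(spec: SceneSpec):
    """Render a fixed-cell scene: disk nuclei in channel 0, puncta beyond.

    Returns ``(scene, ground_truth)`` where ``ground_truth`` is a dict with
    ``"nuclei"`` (cell_id, x_px, y_px, radius_px) and ``"puncta"``
    (cell_id, channel, x_px, y_px, intensity) DataFrames holding exact
    subpixel positions and integrated intensities.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    clean = np.full((1, spec.n_channels, h, w), float(spec.background_level))

    centers = _place_nuclei(spec, rng)
    yy, xx = np.mgrid[0:h, 0:w]
    nuc_level = 4.0 * spec.background_level if spec.background_level > 0 else 200.0
    for cx, cy in centers:
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= spec.nucleus_radius_px ** 2
        clean[0, 0][disk] += nuc_level

    mean_i, sd_i = spec.puncta_intensity
    records = []
    for cid, (cx, cy) in enumerate(centers, start=1):
        for ch in range(1, spec.n_channels):
            for _ in range(spec.puncta_per_cell):
                for _try in range(200):
                    px = cx + rng.normal(0.0, spec.dispersion_px)
                    py = cy + rng.normal(0.0, spec.dispersion_px)
                    if 3 <= px < w - 3 and 3 <= py < h - 3:
                        break
                inten = max(rng.normal(mean_i, sd_i), mean_i * 0.1)
                add_gaussian_spot(clean[0, ch], px, py, inten,
                                  spec.puncta_sigma_px)
                records.append((cid, ch, px, py, inten))

    noisy = _apply_noise(clean, spec, rng)
    scene = ImageScene(noisy, spec.pixel_size_nm, spec.frame_interval_s)
    truth = {
        "nuclei": pd.DataFrame(
            {"cell_id": np.arange(1, len(centers) + 1),
             "x_px": centers[:, 0] if len(centers) else [],
             "y_px": centers[:, 1] if len(centers) else [],
             "radius_px": spec.nucleus_radius_px}),
        "puncta": pd.DataFrame(
            records, columns=["cell_id", "channel", "x_px", "y_px",
                              "intensity"]),
    }
    return scene, truth


def render_bead_movie(n_beads: int, n_frames: int, spec: SceneSpec):
    """Render an immobile two-channel bead movie (T x 2 x Y x X).

    The same subpixel bead positions are rendered in both channels of every
    frame — the control used to validate object-based live colocalization,
    which must report 100% on this input.

    Returns ``(scene, ground_truth)`` with ground truth rows
    (track_id, frame, channel, x_px, y_px, intensity).
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    margin = 6.0
    pos = np.column_stack([rng.uniform(margin, w - margin, n_beads),
                           rng.uniform(margin, h - margin, n_beads)])
    # enforce separation so beads stay individually resolvable
    for _ in range(200):
        d = np.hypot(pos[:, None, 0] - pos[None, :, 0],
                     pos[:, None, 1] - pos[None, :, 1])
        np.fill_diagonal(d, np.inf)
        close = np.argwhere(d < 12.0)
        if not len(close):
            break
        i = close[0, 0]
        pos[i] = [rng.uniform(margin, w - margin),
                  rng.uniform(margin, h - margin)]

    mean_i, _ = spec.puncta_intensity
    clean = np.full((1, 1, h, w), float(spec.background_level))
    frame0 = clean[0, 0]
    for x, y in pos:
        add_gaussian_spot(frame0, x, y, mean_i, spec.puncta_sigma_px)
    clean_movie = np.broadcast_to(frame0, (n_frames, 2, h, w)).copy()
    noisy = _apply_noise(clean_movie, spec, rng)

    rows = [(b, t, ch, pos[b, 0], pos[b, 1], mean_i)
            for t in range(n_frames) for ch in (0, 1)
            for b in range(n_beads)]
    truth = pd.DataFrame(rows, columns=["track_id", "frame", "channel",
                                        "x_px", "y_px", "intensity"])
    scene = ImageScene(noisy, spec.pixel_size_nm, spec.frame_interval_s)
    return scene, truth


_STATES = ("apical", "basal", "stationary")


def _simulate_run_and_pause(spec: MotionSpec, rng: np.random.Generator):
    """Per-particle 3-state trajectory; returns positions and state labels."""
    dt = spec.frame_interval_s
    ax = np.asarray(spec.direction, dtype=float)
    n, T = spec.n_particles, spec.n_frames
    pos = np.empty((n, T, 2))
    states = np.empty((n, T), dtype=object)
    for i in range(n):
        p = rng.uniform([0, 0], spec.box_nm)
        # stationary distribution of a 3-state cycle-free chain with uniform
        # switching: dwell-proportional occupancy
        dw = np.asarray(spec.dwell_mean_s)
        state = rng.choice(3, p=dw / dw.sum())
        remaining = rng.exponential(dw[state])
        for t in range(T):
            pos[i, t] = p
            states[i, t] = _STATES[state]
            if state == 0:
                step = spec.v_nm_per_s * dt * ax
            elif state == 1:
                step = -spec.v_nm_per_s * dt * ax
            else:
                step = rng.normal(0.0, np.sqrt(2 * spec.pause_D_nm2_per_s * dt),
                                  2) if spec.pause_D_nm2_per_s > 0 else np.zeros(2)
            prop = p + step
            hit_wall = np.any(prop < 0) or np.any(prop > spec.box_nm)
            if hit_wall and state != 2:
                # a run that reaches the cortex ends in a pause there
                # instead of bouncing in place under an unchanged label
                p = np.clip(prop, 0, spec.box_nm)
                state = 2
                remaining = rng.exponential(dw[2])
                continue
            p = _reflect(prop, spec.box_nm)
            remaining -= dt
            if remaining <= 0:
                others = [s for s in range(3) if s != state]
                state = others[rng.integers(2)]
                remaining = rng.exponential(dw[state])
    return pos, states


def _reflect(p: np.ndarray, box: tuple[float, float]) -> np.ndarray:
    out = p.copy()
    for k in range(2):
        L = box[k]
        v = out[k] % (2 * L)
        out[k] = v if v <= L else 2 * L - v
    return out


def simulate_trajectories(spec: MotionSpec) -> TrackSet:
    """Simulate ground-truth 2D trajectories in nm under the given regime.

    Diffusive steps have per-axis variance 2 D dt; directed motion advances
    v dt along the direction vector each frame; run-and-pause switches
    between apical/basal runs and pauses with exponential dwell times.
    Trajectories reflect off the box boundary so they remain renderable.
    """
    rng = np.random.default_rng(spec.seed)
    dt = spec.frame_interval_s
    n, T = spec.n_particles, spec.n_frames
    start = rng.uniform([0, 0], spec.box_nm, size=(n, 2))
    states = None

    if spec.regime == "stationary":
        pos = np.repeat(start[:, None, :], T, axis=1)
    elif spec.regime == "directed":
        ax = np.asarray(spec.direction)
        disp = spec.v_nm_per_s * dt * ax
        steps = np.broadcast_to(disp, (n, T - 1, 2)) if T > 1 else np.zeros((n, 0, 2))
        pos = _integrate(start, steps, spec.box_nm)
    elif spec.regime == "diffusive":
        sd = np.sqrt(2 * spec.D_nm2_per_s * dt)
        steps = rng.normal(0.0, sd, size=(n, T - 1, 2))
        pos = _integrate(start, steps, spec.box_nm)
    else:
        pos, states = _simulate_run_and_pause(spec, rng)

    rows = {
        "track_id": np.repeat(np.arange(n), T),
        "frame": np.tile(np.arange(T), n),
        "t_s": np.tile(np.arange(T) * dt, n),
        "x": pos[:, :, 0].ravel(),
        "y": pos[:, :, 1].ravel(),
    }
    df = pd.DataFrame(rows)
    if states is not None:
        df["state"] = states.ravel()
    return TrackSet(df, position_unit="nm", pixel_size_nm=None,
                    frame_interval_s=dt, meta={"regime": spec.regime})


def _integrate(start, steps, box):
    n = start.shape[0]
    T = steps.shape[1] + 1
    pos = np.empty((n, T, 2))
    pos[:, 0] = start
    for t in range(1, T):
        for i in range(n):
            pos[i, t] = _reflect(pos[i, t - 1] + steps[i, t - 1], box)
    return pos


def render_movie_from_trajectories(tracks: TrackSet,
                                   spec: SceneSpec) -> ImageScene:
    """Render each particle as an integrated-Gaussian spot per frame.

    Track positions (nm) are converted to pixels with ``spec.pixel_size_nm``;
    photon noise is applied per ``spec.noise_model``.  An empty TrackSet
    yields a pure background movie.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    if len(tracks.df):
        tr = tracks.in_nm() if tracks.position_unit == "px" else tracks
        n_frames = int(tr.df["frame"].max()) + 1
    else:
        tr = tracks
        n_frames = 1
    mean_i, sd_i = spec.puncta_intensity
    clean = np.full((n_frames, 1, h, w), float(spec.background_level))
    if len(tr.df):
        inten = {tid: max(rng.normal(mean_i, sd_i), mean_i * 0.1)
                 for tid in tr.track_ids()}
        for row in tr.df.itertuples():
            x_px = row.x / spec.pixel_size_nm
            y_px = row.y / spec.pixel_size_nm
            add_gaussian_spot(clean[int(row.frame), 0], x_px, y_px,
                              inten[row.track_id], spec.puncta_sigma_px)
    noisy = _apply_noise(clean, spec, rng)
    return ImageScene(noisy, spec.pixel_size_nm, spec.frame_interval_s)


def simulate_proteomics_matrix(spec: ProteomicsSimSpec):
    """Simulate a proteins x samples intensity matrix with known spike-ins.

    Returns ``(frame, spiked_ids)``: a DataFrame with columns
    ``ctrl_1..ctrl_n``, ``bait_1..bait_n`` (linear intensities, NaN where
    dropped out) plus a ``peptides`` column, and the index labels of the
    truly enriched proteins (group-2/bait log2 mean raised by
    ``spike_log2_effect``).
    """
    rng = np.random.default_rng(spec.seed)
    n, k = spec.n_proteins, spec.n_per_group
    base = rng.normal(spec.base_log2_mean, spec.base_log2_sd, n)
    log2 = np.empty((n, 2 * k))
    log2[:, :k] = base[:, None] + rng.normal(0, spec.rep_log2_sd, (n, k))
    spike = np.zeros(n)
    spiked_idx = rng.choice(n, spec.n_spiked, replace=False) \
        if spec.n_spiked else np.empty(0, dtype=int)
    spike[spiked_idx] = spec.spike_log2_effect
    log2[:, k:] = (base + spike)[:, None] + rng.normal(0, spec.rep_log2_sd,
                                                       (n, k))
    intens = np.power(2.0, log2)

    if spec.dropout_max > 0:
        center = spec.base_log2_mean - spec.dropout_center_sds * spec.base_log2_sd
        p_miss = spec.dropout_max / (
            1.0 + np.exp((log2 - center) / spec.dropout_slope))
        intens[rng.uniform(size=log2.shape) < p_miss] = np.nan

    cols = [f"ctrl_{j+1}" for j in range(k)] + [f"bait_{j+1}" for j in range(k)]
    index = [f"P{i:05d}" for i in range(n)]
    frame = pd.DataFrame(intens, columns=cols, index=index)
    frame["peptides"] = 1 + rng.poisson(spec.peptides_lambda, n)
    spiked_ids = [index[i] for i in sorted(spiked_idx)]
    return frame, spiked_ids
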