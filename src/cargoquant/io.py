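"""File I/O, configuration handling, and reproducible pipeline runs.

Images and movies travel as multi-page TIFF with axis order T x C x Y x X;
tables as CSV/TSV with header rows; label masks as 16-bit TIFF; configs as
YAML.  Every pipeline run writes a machine-readable provenance record
(parameters, seed, package version, config hash) next to its outputs, and
re-running with the same config reproduces the outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .core import ImageScene

__all__ = [
    "read_image_stack",
    "write_image_stack",
    "write_label_mask",
    "load_config",
    "config_hash",
    "run_pipeline",
]


def read_image_stack(path, pixel_size_nm: float = 110.0,
                     frame_interval_s: float = 0.057) -> ImageScene:
    """Read a TIFF as an ImageScene with normalized T x C x Y x X axes.

    2D images become 1 x 1 x H x W; 3D stacks are interpreted via the TIFF
    axes metadata when present, otherwise the leading axis is taken as
    time.  Physical metadata comes from the arguments (config), since
    plain TIFFs rarely carry it reliably.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tf:
        arr = tf.asarray()
        axes = tf.series[0].axes if tf.series else ""
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        if axes[:1] == "C":
            arr = arr[None, :, :, :]
        else:  # leading axis = time
            arr = arr[:, None, :, :]
    elif arr.ndim == 4:
        if axes and axes not in ("TCYX", "QQYX", ""):
            if axes == "CTYX":
                arr = np.swapaxes(arr, 0, 1)
            elif set(axes) == set("TCYX"):
                src = [axes.index(a) for a in "TCYX"]
                arr = np.transpose(arr, src)
            else:
                raise ValueError(
                    f"ambiguous 4D TIFF axes {axes!r} in {path.name}: "
                    "expected a permutation of TCYX")
    else:
        raise ValueError(f"unsupported TIFF dimensionality {arr.ndim} "
                         f"in {path.name}")
    return ImageScene(arr.astype(float), pixel_size_nm, frame_interval_s)


def write_image_stack(path, scene: ImageScene) -> None:
    """Write an ImageScene as a TCYX multi-page float32 TIFF."""
    tifffile.imwrite(str(path), scene.data.astype(np.float32),
                     metadata={"axes": "TCYX"})


def write_label_mask(path, labels: np.ndarray) -> None:
    """Write an integer label image as 16-bit TIFF."""
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable hash of a config mapping (order-independent)."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_csv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _check_keys(cfg: dict, allowed: set[str], context: str) -> None:
    unknown = set(cfg) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {context}: "
                         f"{sorted(unknown)}")


_COMMON_KEYS = {"pipeline", "outdir", "seed", "pixel_size_nm",
                "frame_interval_s"}


def run_pipeline(cfg: dict, outdir=None) -> dict:
    """Execute a configured pipeline and write outputs plus provenance.

    ``cfg["pipeline"]`` selects one of: ``fixed-scene`` (simulate or load a
    scene, segment nuclei and cells, detect puncta, write per-cell
    statistics and colocalization), ``bead-coloc`` (simulate a two-channel
    bead movie, detect/link/filter, report the live colocalization
    percentage), ``motility`` (simulate run-and-pause trajectories, render
    and re-track or classify directly, report MSD and run statistics), or
    ``enrichment`` (simulate or load an intensity matrix, run the screen).
    Returns a dict of result tables/values; every output directory gets a
    ``provenance.json`` with the config, its hash, and the package version.
    """
    from . import enrichment, puncta_stats, segmentation, synthetic, tracking

    name = cfg.get("pipeline")
    if name not in ("fixed-scene", "bead-coloc", "motility", "enrichment"):
        raise ValueError(f"unknown pipeline {name!r}")
    outdir = Path(outdir or cfg.get("outdir", "."))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    results: dict = {}

    try:
        if name == "fixed-scene":
            _check_keys(cfg, _COMMON_KEYS | {"scene", "segment", "puncta"},
                        name)
            scene_kw = dict(cfg.get("scene", {}))
            _check_keys(scene_kw, {f.name for f in dataclasses.fields(
                synthetic.SceneSpec)}, "scene")
            scene_kw.setdefault("seed", seed)
            spec = synthetic.SceneSpec(**scene_kw)
            scene, truth = synthetic.render_fixed_cell_scene(spec)
            seg_kw = dict(cfg.get("segment", {}))
            _check_keys(seg_kw, {"median_radius", "rolling_ball_radius",
                                 "pfa", "use_watershed", "smooth_sigma",
                                 "quantile"}, "segment")
            fg_kw = {k: seg_kw.pop(k) for k in ("smooth_sigma", "quantile")
                     if k in seg_kw}
            nuclei = segmentation.segment_nuclei(scene.frame(0, 0), **seg_kw)
            nuclei = segmentation.discard_border_regions(nuclei)
            fg = segmentation.foreground_mask(scene, **fg_kw)
            part = segmentation.assign_cells_by_edt(nuclei, fg)
            p_kw = dict(cfg.get("puncta", {}))
            _check_keys(p_kw, {"log_sigma", "threshold", "min_area",
                               "threshold_mode", "k_mad"}, "puncta")
            p_kw.setdefault("threshold_mode", "mad")
            sets = {}
            for ch in range(1, scene.n_channels):
                sets[ch] = segmentation.detect_puncta_log(
                    scene.frame(0, ch), partition=part, channel=ch, **p_kw)
                _write_csv(outdir / f"puncta_ch{ch}.csv", sets[ch].table)
                summary = puncta_stats.puncta_summary(sets[ch])
                _write_csv(outdir / f"puncta_summary_ch{ch}.csv", summary)
                results[f"puncta_ch{ch}"] = summary
            if len(sets) >= 2:
                chans = sorted(sets)
                coloc = puncta_stats.colocalize_fixed(sets[chans[0]],
                                                      sets[chans[1]])
                _write_csv(outdir / "coloc_fixed.csv", coloc)
                results["coloc_fixed"] = coloc
            write_label_mask(outdir / "nuclei.tif", nuclei.labels)
            _write_csv(outdir / "ground_truth_puncta.csv", truth["puncta"])

        elif name == "bead-coloc":
            _check_keys(cfg, _COMMON_KEYS | {"scene", "n_beads", "n_frames",
                                             "track"}, name)
            scene_kw = dict(cfg.get("scene", {}))
            scene_kw.setdefault("seed", seed)
            spec = synthetic.SceneSpec(**scene_kw)
            movie, _ = synthetic.render_bead_movie(
                int(cfg.get("n_beads", 10)), int(cfg.get("n_frames", 60)),
                spec)
            t_kw = dict(cfg.get("track", {}))
            _check_keys(t_kw, {"pfa", "fit_window", "max_disp", "memory",
                               "min_points", "dist_nm", "n_avg_frames"},
                        "track")
            tracks = {}
            for ch in (0, 1):
                spots = tracking.detect_spots_movie(
                    movie, channel=ch, pfa=t_kw.get("pfa", 1e-4),
                    fit_window=t_kw.get("fit_window", 7))
                linked = tracking.link_tracks(
                    spots, max_disp=t_kw.get("max_disp", 5.0),
                    memory=t_kw.get("memory", 0),
                    pixel_size_nm=spec.pixel_size_nm,
                    frame_interval_s=spec.frame_interval_s)
                tracks[ch] = tracking.filter_tracks(
                    linked, min_points=t_kw.get("min_points", 10))
            pct, per_frame = tracking.colocalize_live(
                tracks[0], tracks[1], dist_nm=t_kw.get("dist_nm", 300.0),
                n_frames=t_kw.get("n_avg_frames", 50))
            _write_csv(outdir / "coloc_live_per_frame.csv", per_frame)
            results["percent_colocalized"] = pct

        elif name == "motility":
            _check_keys(cfg, _COMMON_KEYS | {"motion", "runs", "msd"}, name)
            m_kw = dict(cfg.get("motion", {}))
            m_kw.setdefault("seed", seed)
            mspec = synthetic.MotionSpec(**m_kw)
            tracks = synthetic.simulate_trajectories(mspec)
            curves = tracking.msd_all_tracks(
                tracks, **dict(cfg.get("msd", {})))
            mean_curve = tracking.weighted_mean_msd(curves)
            _write_csv(outdir / "msd_weighted_mean.csv",
                       mean_curve.as_frame())
            results["msd"] = mean_curve
            if mspec.regime == "run_and_pause":
                seg = tracking.classify_runs_movie(
                    tracks, **dict(cfg.get("runs", {})))
                _write_csv(outdir / "run_segments.csv", seg.segments)
                results["runs"] = seg

        else:  # enrichment
            _check_keys(cfg, _COMMON_KEYS | {"matrix", "sim", "groups",
                                             "params"}, name)
            if "matrix" in cfg:
                m = pd.read_csv(cfg["matrix"], sep="\t", index_col=0)
                groups = cfg["groups"]
            else:
                sim_kw = dict(cfg.get("sim", {}))
                sim_kw.setdefault("seed", seed)
                spec = synthetic.ProteomicsSimSpec(**sim_kw)
                m, _ = synthetic.simulate_proteomics_matrix(spec)
                k = spec.n_per_group
                groups = {"bait": [f"bait_{i+1}" for i in range(k)],
                          "ctrl": [f"ctrl_{i+1}" for i in range(k)]}
            params = dict(cfg.get("params", {}))
            params.setdefault("seed", seed)
            table = enrichment.run_enrichment(m, groups, **params)
            table.reset_index(names="protein").to_csv(
                outdir / "enrichment.tsv", sep="\t", index=False,
                float_format="%.10g")
            _write_csv(outdir / "volcano.csv",
                       enrichment.volcano_table(table))
            results["enrichment"] = table
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    prov = {"pipeline": name, "config": cfg, "config_hash": config_hash(cfg),
            "seed": seed, "version": __version__}
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=2, sort_keys=True, default=str)
    return results
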