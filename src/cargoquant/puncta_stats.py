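"""Per-cell and per-region statistics of segmented puncta.

Covers the four quantification read-outs used on fixed samples: the
intensity-weighted spread of a signal away from its centroid, per-cell
puncta counts and mean intensities, object-based overlap colocalization
between two channels, and punctum counts inside rectangular zones of fixed
physical area (the syncytial-embryo read-out).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import CellPartition, PunctaSet

__all__ = [
    "SpreadResult",
    "Zone",
    "spread_statistic",
    "spread_per_cell",
    "puncta_summary",
    "colocalize_fixed",
    "quantify_zones",
]


@dataclass
class SpreadResult:
    """Intensity-weighted dispersion of a signal about its own centroid.

    ``spread`` = sum_i w_i * ||p_i - centroid||^2 (a.u. * px^2);
    ``normalized_spread`` = spread / sum_i w_i (px^2).  Zero iff all
    intensity sits at a single point.
    """

    cell_id: int
    spread: float
    normalized_spread: float
    total_intensity: float
    centroid_x_px: float
    centroid_y_px: float


@dataclass
class Zone:
    """A named rectangle in physical coordinates (um), half-open."""

    name: str
    x0_um: float
    y0_um: float
    width_um: float
    height_um: float

    @property
    def area_um2(self) -> float:
        return self.width_um * self.height_um


def spread_statistic(weights: np.ndarray, mask: np.ndarray,
                     cell_id: int = 0) -> SpreadResult:
    """Spread of the signal inside a mask about its intensity centroid.

    The centroid is the intensity-weighted mean pixel position within the
    mask; the spread is the intensity-weighted sum of squared deviations
    from it.  Doubling all weights doubles ``spread`` and leaves
    ``normalized_spread`` unchanged; translating mask and weights together
    changes neither.
    """
    w_img = np.asarray(weights, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if w_img.shape != m.shape:
        raise ValueError("weights and mask shapes differ")
    if not m.any():
        raise ValueError("empty signal: mask contains no pixels")
    ys, xs = np.nonzero(m)
    w = w_img[ys, xs]
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = float(w.sum())
    if total <= 0:
        raise ValueError("empty signal: zero total intensity in mask")
    cx = float((xs * w).sum() / total)
    cy = float((ys * w).sum() / total)
    sq = (xs - cx) ** 2 + (ys - cy) ** 2
    spread = float((w * sq).sum())
    return SpreadResult(cell_id, spread, spread / total, total, cx, cy)


def spread_per_cell(weights: np.ndarray,
                    partition: CellPartition) -> pd.DataFrame:
    """Spread statistic per cell of a partition (rows: one per cell id)."""
    rows = []
    for cid in np.unique(partition.cell_of_pixel):
        if cid == 0:
            continue
        mask = partition.cell_of_pixel == cid
        if not np.asarray(weights)[mask].sum() > 0:
            continue
        r = spread_statistic(weights, mask, cell_id=int(cid))
        rows.append((r.cell_id, r.spread, r.normalized_spread,
                     r.total_intensity, r.centroid_x_px, r.centroid_y_px))
    return pd.DataFrame(rows, columns=["cell_id", "spread",
                                       "normalized_spread",
                                       "total_intensity", "centroid_x_px",
                                       "centroid_y_px"])


def puncta_summary(puncta: PunctaSet, by: str = "cell") -> pd.DataFrame:
    """Count and mean total intensity of puncta per cell or per image.

    Empty groups report count 0 and a missing mean intensity.
    """
    if by not in ("cell", "image"):
        raise ValueError("by must be 'cell' or 'image'")
    t = puncta.table
    if by == "image":
        n = len(t)
        mean_i = float(t["total_intensity"].mean()) if n else np.nan
        return pd.DataFrame({"group": ["image"], "n_puncta": [n],
                             "mean_total_intensity": [mean_i]})
    if not len(t):
        return pd.DataFrame(columns=["cell_id", "n_puncta",
                                     "mean_total_intensity"])
    g = t.groupby("cell_id")["total_intensity"]
    out = pd.DataFrame({"cell_id": list(g.groups),
                        "n_puncta": g.size().values,
                        "mean_total_intensity": g.mean().values})
    return out.sort_values("cell_id").reset_index(drop=True)


def colocalize_fixed(puncta_ch1: PunctaSet,
                     puncta_ch2: PunctaSet) -> pd.DataFrame:
    """Object-based overlap colocalization, per cell.

    A channel-1 punctum counts as overlapping when its pixel set intersects
    any channel-2 punctum's pixel set; the result is reported as a
    percentage of the channel-1 puncta in each cell.  The measure is
    asymmetric by design: swapping the channels changes both the
    denominator and the set of overlapping objects.  Cells with no
    channel-1 puncta report a missing percentage, not 0.
    """
    if puncta_ch1.label_image.shape != puncta_ch2.label_image.shape:
        raise ValueError("puncta sets come from images of different shape")
    t1 = puncta_ch1.table
    ch2_occupied = puncta_ch2.label_image > 0
    overlap_flags = {}
    for row in t1.itertuples():
        sel = puncta_ch1.label_image == row.punctum_id
        overlap_flags[row.punctum_id] = bool(ch2_occupied[sel].any())

    cells = sorted(set(t1["cell_id"])) if len(t1) else []
    rows = []
    n2_by_cell = puncta_ch2.table.groupby("cell_id").size() \
        if len(puncta_ch2.table) else pd.Series(dtype=int)
    for cid in cells:
        sub = t1[t1["cell_id"] == cid]
        n1 = len(sub)
        n_ov = int(sum(overlap_flags[p] for p in sub["punctum_id"]))
        pct = 100.0 * n_ov / n1 if n1 else np.nan
        rows.append((cid, n1, int(n2_by_cell.get(cid, 0)), n_ov, pct))
    return pd.DataFrame(rows, columns=["cell_id", "n_puncta_ch1",
                                       "n_puncta_ch2", "n_overlapping",
                                       "percent"])


def quantify_zones(puncta: PunctaSet, zones: list[Zone],
                   pixel_size_nm: float,
                   expected_area_um2: float = 300.0) -> pd.DataFrame:
    """Punctum count and mean intensity inside fixed-area rectangles.

    Each rectangle must measure ``expected_area_um2`` (300 um^2 by
    default) to within one pixel's area; a punctum belongs to the zone
    whose half-open rectangle [x0, x0+w) x [y0, y0+h) contains its
    centroid, so boundary puncta are counted exactly once.
    """
    px_um = pixel_size_nm / 1000.0
    tol = px_um * px_um  # one pixel of area
    for z in zones:
        if abs(z.area_um2 - expected_area_um2) > tol:
            raise ValueError(
                f"zone {z.name!r} has area {z.area_um2:.3f} um^2, expected "
                f"{expected_area_um2} um^2 (tolerance {tol:.4f})")
    t = puncta.table
    rows = []
    for z in zones:
        if len(t):
            x_um = t["centroid_x_px"] * px_um
            y_um = t["centroid_y_px"] * px_um
            inside = ((x_um >= z.x0_um) & (x_um < z.x0_um + z.width_um)
                      & (y_um >= z.y0_um) & (y_um < z.y0_um + z.height_um))
            n = int(inside.sum())
            mean_i = float(t.loc[inside, "total_intensity"].mean()) \
                if n else np.nan
        else:
            n, mean_i = 0, np.nan
        rows.append((z.name, z.area_um2, n, mean_i))
    return pd.DataFrame(rows, columns=["zone", "region_area_um2", "n_puncta",
                                       "mean_total_intensity"])
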