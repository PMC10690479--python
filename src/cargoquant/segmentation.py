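"""Classical segmentation chains for fixed-cell images.

Nucleus segmentation follows the filter chain median -> rolling ball ->
PFA-controlled threshold -> watershed -> connected components; cells are
then defined by assigning every foreground pixel to its nearest nucleus via
the Euclidean distance transform, and puncta are segmented per channel with
a Laplacian-of-Gaussian filter (or a raw intensity threshold for the
particle-count path) followed by a minimum-area filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import median as median_filter
from skimage.morphology import disk
from skimage.restoration import rolling_ball
from skimage.segmentation import watershed

from .core import ImageScene, pfa_z, robust_sigma

__all__ = [
    "LabeledMask",
    "CellPartition",
    "PunctaSet",
    "segment_nuclei",
    "discard_border_regions",
    "foreground_mask",
    "assign_cells_by_edt",
    "detect_puncta_log",
    "segment_by_intensity_threshold",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity throughout


@dataclass
class LabeledMask:
    """Integer label image: 0 = background, k >= 1 = object k."""

    labels: np.ndarray
    source_channel: int = 0
    parameters: dict = field(default_factory=dict)

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def relabeled(self) -> "LabeledMask":
        """Return a copy with labels remapped to the contiguous set 1..K."""
        old = np.unique(self.labels)
        old = old[old > 0]
        out = np.zeros_like(self.labels)
        for new, lab in enumerate(old, start=1):
            out[self.labels == lab] = new
        return LabeledMask(out, self.source_channel, dict(self.parameters))


@dataclass
class CellPartition:
    """Per-pixel cell assignment derived from nuclei and a foreground mask.

    ``cell_of_pixel`` is 0 exactly where ``foreground_mask`` is 0;
    elsewhere it holds the label of the nearest nucleus.
    """

    nucleus_mask: LabeledMask
    cell_of_pixel: np.ndarray
    foreground_mask: np.ndarray


@dataclass
class PunctaSet:
    """Detected puncta: a per-punctum table plus the label image.

    ``table`` columns: punctum_id, channel, cell_id, area_px,
    total_intensity, centroid_x_px, centroid_y_px.  ``label_image`` maps
    each pixel to its punctum_id (0 = background) so that object-based
    overlap colocalization can operate on pixel sets.
    """

    table: pd.DataFrame
    label_image: np.ndarray
    channel: int = 0

    COLUMNS = ("punctum_id", "channel", "cell_id", "area_px",
               "total_intensity", "centroid_x_px", "centroid_y_px")

    def __len__(self) -> int:
        return len(self.table)

    @staticmethod
    def empty(shape: tuple[int, int], channel: int = 0) -> "PunctaSet":
        return PunctaSet(pd.DataFrame(columns=list(PunctaSet.COLUMNS)),
                         np.zeros(shape, dtype=np.int32), channel)


def _components_from_mask(mask: np.ndarray, image: np.ndarray,
                          min_area: int, channel: int,
                          partition: CellPartition | None) -> PunctaSet:
    """Label an object mask, drop small objects, and build the table."""
    labels, _ = ndimage.label(mask, structure=_STRUCT8)
    ids = np.arange(1, labels.max() + 1)
    if not len(ids):
        return PunctaSet.empty(mask.shape, channel)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, ids)
    keep = ids[areas >= min_area]
    out_labels = np.zeros_like(labels, dtype=np.int32)
    rows = []
    for new_id, lab in enumerate(keep, start=1):
        sel = labels == lab
        out_labels[sel] = new_id
        ys, xs = np.nonzero(sel)
        w = image[ys, xs].astype(float)
        total = float(w.sum())
        if total > 0:
            cx = float((xs * w).sum() / total)
            cy = float((ys * w).sum() / total)
        else:  # flat zero-intensity object: geometric centroid
            cx, cy = float(xs.mean()), float(ys.mean())
        cell_id = 0
        if partition is not None:
            r, c = int(round(cy)), int(round(cx))
            r = min(max(r, 0), partition.cell_of_pixel.shape[0] - 1)
            c = min(max(c, 0), partition.cell_of_pixel.shape[1] - 1)
            cell_id = int(partition.cell_of_pixel[r, c])
        rows.append((new_id, channel, cell_id, int(sel.sum()), total, cx, cy))
    table = pd.DataFrame(rows, columns=list(PunctaSet.COLUMNS))
    return PunctaSet(table, out_labels, channel)


def segment_nuclei(image: np.ndarray, median_radius: int = 2,
                   rolling_ball_radius: int = 50, pfa: float = 1e-3,
                   use_watershed: bool = True,
                   min_area: int = 25) -> LabeledMask:
    """Segment nuclei with the classical chain.

    A median filter suppresses shot noise, a rolling ball removes the
    smooth background, and the threshold is set so that a background pixel
    exceeds it with probability ``pfa`` under a robust Gaussian noise model
    (median + z(1-pfa) * 1.4826*MAD of the filtered image).  Touching
    objects are optionally split by a distance-transform watershed, and the
    8-connected components are labeled contiguously.  Components smaller
    than ``min_area`` pixels (isolated noise excursions above the
    threshold) are discarded.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_nuclei expects a single 2D channel")
    if median_radius < 1 or rolling_ball_radius < 1:
        raise ValueError("filter radii must be >= 1")
    if float(img.std()) == 0.0:
        raise ValueError("degenerate background: image has zero variance, "
                         "PFA threshold undefined")

    filt = median_filter(img, disk(median_radius))
    filt = filt - rolling_ball(filt, radius=rolling_ball_radius)

    sigma = robust_sigma(filt)
    if sigma == 0.0:
        raise ValueError("degenerate background: zero robust scale after "
                         "filtering, PFA threshold undefined")
    thr = float(np.median(filt)) + pfa_z(pfa) * sigma
    binary = filt > thr

    if use_watershed and binary.any():
        dist = ndimage.distance_transform_edt(binary)
        smooth = ndimage.gaussian_filter(dist, 2.0)
        peaks = (smooth == ndimage.maximum_filter(smooth, size=7)) & binary \
            & (dist > 2)
        markers, _ = ndimage.label(peaks, structure=_STRUCT8)
        if markers.max() > 0:
            labels = watershed(-dist, markers, mask=binary)
        else:
            labels, _ = ndimage.label(binary, structure=_STRUCT8)
    else:
        labels, _ = ndimage.label(binary, structure=_STRUCT8)

    labels = np.asarray(labels)
    if labels.max():
        ids = np.arange(1, labels.max() + 1)
        areas = ndimage.sum_labels(np.ones_like(labels), labels, ids)
        labels[np.isin(labels, ids[areas < min_area])] = 0

    params = {"median_radius": median_radius,
              "rolling_ball_radius": rolling_ball_radius, "pfa": pfa,
              "watershed": use_watershed, "min_area": min_area,
              "threshold": thr}
    return LabeledMask(labels, 0, params).relabeled()


def discard_border_regions(mask: LabeledMask) -> LabeledMask:
    """Remove labels touching the image border; relabel contiguously.

    Incomplete cells cut by the field of view would bias per-cell
    statistics, so any object whose pixel set intersects row/column 0 or
    H-1/W-1 is dropped.
    """
    labels = mask.labels
    border = np.concatenate([labels[0], labels[-1],
                             labels[:, 0], labels[:, -1]])
    bad = np.unique(border[border > 0])
    out = labels.copy()
    out[np.isin(out, bad)] = 0
    return LabeledMask(out, mask.source_channel,
                       dict(mask.parameters)).relabeled()


def foreground_mask(scene: ImageScene | np.ndarray, smooth_sigma: float = 2.0,
                    quantile: float = 0.5) -> np.ndarray:
    """Binary cell-foreground mask from the smoothed max projection.

    The maximum projection over channels is Gaussian-smoothed and
    thresholded at the given quantile of its own intensity distribution,
    which makes the mask invariant to adding a constant to the image.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must be in (0, 1)")
    if isinstance(scene, ImageScene):
        stack = scene.data[0]
    else:
        arr = np.asarray(scene, dtype=float)
        stack = arr[None] if arr.ndim == 2 else arr
    proj = stack.max(axis=0).astype(float)
    smooth = ndimage.gaussian_filter(proj, smooth_sigma)
    # >= so the mask tends to all-ones in the quantile -> 0 limit
    return smooth >= np.quantile(smooth, quantile)


def assign_cells_by_edt(nuclei: LabeledMask,
                        foreground: np.ndarray) -> CellPartition:
    """Assign each foreground pixel to the nearest nucleus.

    Distances are Euclidean to each nucleus's pixel set (the signed-EDT
    construction: pixels inside a nucleus have distance <= 0 to it and are
    assigned that nucleus).  Ties are broken toward the lowest nucleus
    label, so the output is deterministic.
    """
    labels = nuclei.labels
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if not len(ids):
        raise ValueError("no cells: nucleus mask is empty")
    fg = np.asarray(foreground, dtype=bool)
    if fg.shape != labels.shape:
        raise ValueError("foreground and nucleus mask shapes differ")

    dists = np.stack([ndimage.distance_transform_edt(labels != lab)
                      for lab in ids])
    nearest = ids[np.argmin(dists, axis=0)]  # argmin -> first = lowest label
    cell_of_pixel = np.where(fg, nearest, 0).astype(np.int32)
    return CellPartition(nuclei, cell_of_pixel, fg)


def detect_puncta_log(image: np.ndarray, log_sigma: float = 2.0,
                      threshold: float | None = None, min_area: int = 5,
                      partition: CellPartition | None = None,
                      threshold_mode: str = "absolute",
                      k_mad: float = 5.0, channel: int = 0) -> PunctaSet:
    """Segment puncta as connected components of the -LoG response.

    The negative Laplacian-of-Gaussian (scale-normalised by sigma^2)
    responds positively to bright blobs of radius ~ sigma*sqrt(2) and
    rejects constant offsets.  ``threshold_mode`` selects an absolute
    threshold on the response or a noise-scaled one (``k_mad`` robust
    standard deviations of the response).  Components smaller than
    ``min_area`` pixels are removed; each punctum is tagged with the cell
    id of its centroid pixel (0 outside the foreground).
    """
    img = np.asarray(image, dtype=float)
    if log_sigma <= 0:
        raise ValueError("log_sigma must be positive")
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    response = -ndimage.gaussian_laplace(img, log_sigma) * log_sigma ** 2
    if threshold_mode == "absolute":
        if threshold is None:
            raise ValueError("absolute mode requires a threshold")
        thr = float(threshold)
    elif threshold_mode == "mad":
        thr = float(np.median(response)) + k_mad * robust_sigma(response)
    else:
        raise ValueError("threshold_mode must be 'absolute' or 'mad'")
    return _components_from_mask(response > thr, img, min_area, channel,
                                 partition)


def segment_by_intensity_threshold(image: np.ndarray, threshold: float,
                                   min_area: int = 5,
                                   partition: CellPartition | None = None,
                                   channel: int = 0) -> PunctaSet:
    """Segment particles by thresholding raw intensity.

    The particle-count path: the unadjusted channel is thresholded and
    labeled, then particles smaller than ``min_area`` pixels (five by
    default) are removed.
    """
    img = np.asarray(image, dtype=float)
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    return _components_from_mask(img > threshold, img, min_area, channel,
                                 partition)
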