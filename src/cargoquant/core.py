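"""Shared containers and numerical helpers.

Coordinate convention (used everywhere in the package): ``x`` is the column
index, ``y`` the row index, origin at the top-left pixel, and subpixel
positions are real numbers measured at pixel centers.  Physical conversions
go through ``pixel_size_nm`` (nm per pixel) and ``frame_interval_s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf, erfinv

__all__ = [
    "ImageScene",
    "TrackSet",
    "add_gaussian_spot",
    "robust_sigma",
    "pfa_z",
]

_SQRT2 = np.sqrt(2.0)


@dataclass
class ImageScene:
    """A multi-channel image or movie with physical metadata.

    ``data`` always has axis order T x C x Y x X; a single 2D image is
    stored with singleton time and channel axes.
    """

    data: np.ndarray
    pixel_size_nm: float = 110.0
    frame_interval_s: float = 0.057

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim == 2:
            arr = arr[None, None]
        elif arr.ndim == 3:  # interpreted as C x Y x X single frame
            arr = arr[None]
        elif arr.ndim != 4:
            raise ValueError(f"expected 2-4 dims, got {arr.ndim}")
        self.data = arr
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def frame(self, t: int, channel: int = 0) -> np.ndarray:
        return self.data[t, channel]


@dataclass
class TrackSet:
    """Linked trajectories stored as a long-format table.

    ``df`` columns: ``track_id``, ``frame``, ``t_s``, ``x``, ``y`` plus any
    of ``sigma``, ``amplitude``, ``integrated_intensity``, ``channel``,
    ``state``.  ``position_unit`` is ``"px"`` or ``"nm"``.
    """

    df: pd.DataFrame
    position_unit: str = "px"
    pixel_size_nm: float | None = None
    frame_interval_s: float = 0.057
    meta: dict = field(default_factory=dict)

    REQUIRED = ("track_id", "frame", "t_s", "x", "y")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"TrackSet missing columns {missing}")
        if self.position_unit not in ("px", "nm"):
            raise ValueError("position_unit must be 'px' or 'nm'")

    @property
    def n_tracks(self) -> int:
        return self.df["track_id"].nunique()

    def track_ids(self) -> np.ndarray:
        return np.sort(self.df["track_id"].unique())

    def track(self, track_id) -> pd.DataFrame:
        sub = self.df[self.df["track_id"] == track_id]
        return sub.sort_values("frame").reset_index(drop=True)

    def tracks(self):
        for tid, sub in self.df.groupby("track_id", sort=True):
            yield tid, sub.sort_values("frame").reset_index(drop=True)

    def in_nm(self) -> "TrackSet":
        """Return a copy with positions in nm."""
        if self.position_unit == "nm":
            return self
        if self.pixel_size_nm is None:
            raise ValueError("pixel_size_nm required to convert px -> nm")
        df = self.df.copy()
        df["x"] = df["x"] * self.pixel_size_nm
        df["y"] = df["y"] * self.pixel_size_nm
        return TrackSet(df, "nm", self.pixel_size_nm, self.frame_interval_s,
                        dict(self.meta))


def add_gaussian_spot(image: np.ndarray, x: float, y: float,
                      intensity: float, sigma: float) -> None:
    """Add an integrated 2D Gaussian of total photon count ``intensity``.

    The Gaussian is integrated over each pixel area (pixel ``i`` spans
    ``[i-0.5, i+0.5]``), so the sum over an unclipped spot equals
    ``intensity`` exactly — the readout downstream is the integral under
    the fitted Gaussian, and rendering must conserve it.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    h, w = image.shape
    r = int(np.ceil(5.0 * sigma)) + 1
    x0, x1 = int(np.floor(x)) - r, int(np.floor(x)) + r + 1
    y0, y1 = int(np.floor(y)) - r, int(np.floor(y)) + r + 1
    x0, x1 = max(x0, 0), min(x1, w)
    y0, y1 = max(y0, 0), min(y1, h)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1)
    ys = np.arange(y0, y1)
    fx = 0.5 * (erf((xs + 0.5 - x) / (_SQRT2 * sigma))
                - erf((xs - 0.5 - x) / (_SQRT2 * sigma)))
    fy = 0.5 * (erf((ys + 0.5 - y) / (_SQRT2 * sigma))
                - erf((ys - 0.5 - y) / (_SQRT2 * sigma)))
    image[y0:y1, x0:x1] += intensity * np.outer(fy, fx)


def robust_sigma(values: np.ndarray) -> float:
    """Robust Gaussian scale estimate: 1.4826 * MAD about the median."""
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    return float(1.4826 * np.median(np.abs(v - np.median(v))))


def pfa_z(pfa: float) -> float:
    """Upper-tail standard-normal quantile z such that P(Z > z) = pfa."""
    if not 0.0 < pfa < 0.5:
        raise ValueError("pfa must be in (0, 0.5)")
    return float(_SQRT2 * erfinv(1.0 - 2.0 * pfa))
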