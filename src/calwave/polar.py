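"""Directionality analysis in polar coordinates about the stimulus point.

The movie is resampled into (radius, angle) with the laser stimulus as the
origin, so a wave propagating outward in all directions becomes left-to-right
motion along the radial axis.  The transformed image is tiled with square
regions of interest (70 um side, out to 400 um), each ROI's mean dF/F trace
is scanned for its half-maximum crossing (the *event* time), and the events
are grouped into radial *distance blocks*.  Within a block, events earlier
than the block median form the leading front and later ones the lagging
front; the spread of per-angle mean delays quantifies anisotropy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import DffStack, StimulusSpec

__all__ = [
    "PolarImageStack",
    "PolarROI",
    "PolarROIGrid",
    "FrontSummary",
    "polar_transform",
    "grid_rois",
    "detect_event",
    "detect_roi_events",
    "build_raster",
    "front_summary",
]


@dataclass
class PolarImageStack:
    """T x R x Theta resampling of a movie about the stimulus origin."""

    data: np.ndarray               # T x R x Theta, NaN where outside the frame
    radial_step_um: float
    angular_samples: int
    origin_px: tuple[float, float]
    frame_interval: float
    valid: np.ndarray              # R x Theta, True where the sample is inside

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class PolarROI:
    roi_id: int
    block: int                     # radial block index (0 = innermost)
    angle_index: int
    radius_um: float               # radial centre of the ROI
    block_um: float                # inner radius of the block (label, as in rasters)
    angle_deg: float
    trace: np.ndarray


@dataclass
class PolarROIGrid:
    rois: list[PolarROI]
    side_um: float
    limit_um: float
    r_offset_um: float
    n_blocks: int
    n_angles: int

    def __iter__(self):
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)


@dataclass
class FrontSummary:
    """Per-block event statistics, leading/lagging split and anisotropy."""

    per_block: pd.DataFrame        # block, n_events, t_min, t_median, t_max
    leading: dict[int, list[int]]  # block -> roi_ids with event <= block median
    lagging: dict[int, list[int]]  # block -> roi_ids with event > block median
    anisotropy_index: float        # CV of per-angle mean event delay
    per_angle_speed: pd.DataFrame  # angle_index, angle_deg, speed_um_s, n_blocks


def polar_transform(
    data: np.ndarray,
    origin_px: tuple[float, float],
    radial_step_um: float = 1.0,
    angular_samples: int | None = None,
    r_max_um: float = 400.0,
    pixel_size: float = 1.0,
    frame_interval: float = 1.0 / 1.2,
    order: int = 1,
) -> PolarImageStack:
    """Resample a frame or movie into polar coordinates about ``origin_px``.

    ``out[t, r, j] = data[t]`` sampled at ``origin + r_um * (cos θ_j, sin θ_j)``
    with θ_j = j * 2π / angular_samples, bilinear by default (``order=0`` for
    the nearest-neighbour check grid).  Samples outside the frame are NaN and
    flagged invalid.  The default angular count makes the arc length at the
    analysis limit match the radial step.
    """
    arr = np.asarray(data, dtype=float)
    single = arr.ndim == 2
    if single:
        arr = arr[None]
    T, H, W = arr.shape
    ox, oy = origin_px
    if not (0 <= ox < W and 0 <= oy < H):
        raise ValueError("origin must lie inside the image")
    if radial_step_um <= 0:
        raise ValueError("radial_step must be positive")
    if angular_samples is None:
        angular_samples = max(4, int(round(2 * math.pi * r_max_um / radial_step_um)))
    R = int(math.floor(r_max_um / radial_step_um)) + 1
    r_um = np.arange(R) * radial_step_um
    theta = np.arange(angular_samples) * (2 * math.pi / angular_samples)
    r_px = r_um / pixel_size
    X = ox + r_px[:, None] * np.cos(theta)[None, :]
    Y = oy + r_px[:, None] * np.sin(theta)[None, :]
    valid = (X >= 0) & (X <= W - 1) & (Y >= 0) & (Y <= H - 1)
    coords = np.stack([Y.ravel(), X.ravel()])
    out = np.empty((T, R, angular_samples))
    for t in range(T):
        s = ndimage.map_coordinates(arr[t], coords, order=order,
                                    mode="constant", cval=np.nan)
        out[t] = s.reshape(R, angular_samples)
    out[:, ~valid] = np.nan
    return PolarImageStack(out, radial_step_um, angular_samples,
                           (float(ox), float(oy)), frame_interval, valid)


def grid_rois(
    polar: PolarImageStack,
    side_um: float = 70.0,
    limit_um: float = 400.0,
    r_offset_um: float = 0.0,
    min_valid_fraction: float = 0.5,
) -> PolarROIGrid:
    """Tile the polar image with square ROIs and average their traces.

    ROIs are ``side x side`` squares of the transformed pixel grid (so the
    physical arc length they span grows with radius).  Radial blocks start at
    ``r_offset_um`` (use the stimulus-spot radius to skip directly irradiated
    pixels) out to ``limit_um``; ROIs with fewer than ``min_valid_fraction``
    valid pixels are dropped.
    """
    if side_um > limit_um:
        raise ValueError("ROI side must not exceed the radial limit")
    step = polar.radial_step_um
    side_px = int(round(side_um / step))
    if side_px < 1 or side_px > polar.data.shape[1]:
        raise ValueError("ROI side out of range for the transformed image")
    R = polar.data.shape[1]
    n_blocks = int((limit_um - r_offset_um) // side_um)
    n_angles = polar.angular_samples // side_px
    if n_blocks < 1 or n_angles < 1:
        raise ValueError("grid does not fit the transformed image")
    r0_px = int(round(r_offset_um / step))
    rois: list[PolarROI] = []
    rid = 0
    for b in range(n_blocks):
        lo = r0_px + b * side_px
        hi = min(lo + side_px, R)
        for a in range(n_angles):
            ja, jb = a * side_px, (a + 1) * side_px
            block_valid = polar.valid[lo:hi, ja:jb]
            frac = block_valid.mean() if block_valid.size else 0.0
            if frac < min_valid_fraction:
                continue
            patch = polar.data[:, lo:hi, ja:jb]
            trace = np.nanmean(patch.reshape(polar.n_frames, -1), axis=1)
            mid_angle = math.degrees((ja + jb) / 2 * 2 * math.pi
                                     / polar.angular_samples)
            rois.append(PolarROI(
                roi_id=rid, block=b, angle_index=a,
                radius_um=(lo + hi) / 2 * step,
                block_um=lo * step,
                angle_deg=mid_angle % 360.0,
                trace=trace))
            rid += 1
    return PolarROIGrid(rois, side_um, limit_um, r_offset_um, n_blocks, n_angles)


def detect_event(
    trace: np.ndarray,
    baseline_frames: int,
    min_amplitude: float = 0.05,
    frame_interval: float = 1.0,
) -> float | None:
    """Half-maximum event time of a fluorescence trace, or None.

    The baseline is the mean of the first ``baseline_frames`` samples and the
    peak the post-baseline maximum.  If the excursion reaches
    ``min_amplitude`` the event is the first post-baseline frame at or above
    baseline + half the excursion; otherwise no event.  The returned time is
    ``frame_index * frame_interval``.
    """
    trace = np.asarray(trace, dtype=float)
    if not 1 <= baseline_frames < trace.size:
        raise ValueError("baseline window must leave post-stimulus frames")
    finite = np.isfinite(trace)
    if not finite[:baseline_frames].any() or not finite[baseline_frames:].any():
        return None
    f0 = float(np.nanmean(trace[:baseline_frames]))
    peak = float(np.nanmax(trace[baseline_frames:]))
    if peak - f0 < min_amplitude:
        return None
    half = f0 + (peak - f0) / 2.0
    post = trace[baseline_frames:]
    above = np.flatnonzero(post >= half)
    idx = baseline_frames + int(above[0])
    return idx * frame_interval


def detect_roi_events(
    grid: PolarROIGrid,
    baseline_frames: int,
    min_amplitude: float = 0.05,
    frame_interval: float = 1.0 / 1.2,
) -> pd.DataFrame:
    """Scan every polar ROI for its half-maximum event.

    Returns the event table: one row per ROI with an event, with columns
    roi_id, block, block_um, angle_index, angle_deg, radius_um, event_s.
    """
    rows = []
    for roi in grid:
        t = detect_event(roi.trace, baseline_frames, min_amplitude, frame_interval)
        if t is not None:
            rows.append(dict(roi_id=roi.roi_id, block=roi.block,
                             block_um=roi.block_um, angle_index=roi.angle_index,
                             angle_deg=roi.angle_deg, radius_um=roi.radius_um,
                             event_s=t))
    return pd.DataFrame(rows, columns=["roi_id", "block", "block_um",
                                       "angle_index", "angle_deg",
                                       "radius_um", "event_s"])


def build_raster(events: pd.DataFrame, grid: PolarROIGrid,
                 n_frames: int, frame_interval: float = 1.0 / 1.2
                 ) -> tuple[np.ndarray, list[int]]:
    """Binary event raster: one row per grid ROI (block-major, angle-minor).

    Rows follow the grid layout; an ROI with an event gets a single mark at
    its event frame.  Returns (matrix, roi_id row order).
    """
    order = sorted(grid.rois, key=lambda r: (r.block, r.angle_index))
    raster = np.zeros((len(order), n_frames), dtype=np.uint8)
    if events.empty:
        warnings.warn("no events: empty raster", stacklevel=2)
        return raster, [r.roi_id for r in order]
    times = dict(zip(events["roi_id"], events["event_s"]))
    for i, roi in enumerate(order):
        if roi.roi_id in times:
            f = int(round(times[roi.roi_id] / frame_interval))
            if 0 <= f < n_frames:
                raster[i, f] = 1
    return raster, [r.roi_id for r in order]


def front_summary(events: pd.DataFrame, stim_time_s: float = 0.0) -> FrontSummary:
    """Leading/lagging fronts per distance block and wave anisotropy.

    Within each block, events at or before the block's median time are the
    leading front, later ones the lagging front.  The anisotropy index is the
    coefficient of variation of per-angle mean event delay (relative to the
    stimulus) across angular tracks — 0 for a perfectly isotropic wave.  The
    per-angle apparent speed is the least-squares slope of ROI radius versus
    event time across that angle's blocks.
    """
    if events.empty:
        empty = pd.DataFrame(columns=["block", "n_events", "t_min",
                                      "t_median", "t_max"])
        speeds = pd.DataFrame(columns=["angle_index", "angle_deg",
                                       "speed_um_s", "n_blocks"])
        return FrontSummary(empty, {}, {}, 0.0, speeds)

    blocks, leading, lagging = [], {}, {}
    for b, g in events.groupby("block"):
        med = float(g["event_s"].median())
        blocks.append(dict(block=int(b), n_events=len(g),
                           t_min=float(g["event_s"].min()), t_median=med,
                           t_max=float(g["event_s"].max())))
        leading[int(b)] = g.loc[g["event_s"] <= med, "roi_id"].tolist()
        lagging[int(b)] = g.loc[g["event_s"] > med, "roi_id"].tolist()

    delays = events.assign(delay=events["event_s"] - stim_time_s)
    per_angle = delays.groupby("angle_index")["delay"].mean()
    if len(per_angle) >= 2 and per_angle.mean() > 0:
        aniso = float(per_angle.std(ddof=0) / per_angle.mean())
    else:
        aniso = 0.0

    rows = []
    for a, g in events.groupby("angle_index"):
        if len(g) >= 2 and g["event_s"].nunique() > 1:
            slope = np.polyfit(g["event_s"], g["radius_um"], 1)[0]
            rows.append(dict(angle_index=int(a),
                             angle_deg=float(g["angle_deg"].iloc[0]),
                             speed_um_s=float(slope), n_blocks=len(g)))
    speeds = pd.DataFrame(rows, columns=["angle_index", "angle_deg",
                                         "speed_um_s", "n_blocks"])
    return FrontSummary(pd.DataFrame(blocks), leading, lagging, aniso, speeds)
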