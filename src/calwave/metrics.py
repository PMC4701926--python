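"""Per-recording wave statistics.

A recording's calcium wave is summarized by four headline numbers: the
density of recruited (active) cells normalized to the dye-loaded area
(cells/mm^2), the maximum propagation distance D (um), the propagation speed
(half the maximum distance divided by the time to reach the half-propagation
site, um/s), and the mean peak dF/F amplitude of active cells near the
half-propagation distance.

Cells are detected on the baseline image (band-pass + local maxima +
watershed-grown regions), their dF/F traces extracted, and a cell counts as
*active* when its post-stimulus dF/F exceeds the 5 % wave-border criterion.
Cells under the stimulus spot are flagged separately: they are directly
irradiated, not recruited by the wave, and are excluded from the distance
and density statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.segmentation import watershed

from .preprocess import DffStack, StimulusSpec

__all__ = [
    "CellROI",
    "WaveMetrics",
    "detect_cells",
    "attach_traces",
    "classify_active",
    "active_density",
    "threshold_onset",
    "extent_timeseries",
    "speed_and_half_metrics",
    "amplitude_at_half_distance",
    "compute_wave_metrics",
]


@dataclass
class CellROI:
    """One detected soma: pixels, geometry and (once attached) its trace."""

    id: int
    centroid_um: tuple[float, float]          # (x, y)
    pixels: tuple[np.ndarray, np.ndarray]     # (rows, cols) index arrays
    equiv_radius_um: float
    distance_to_stimulus_um: float = np.nan
    trace: np.ndarray | None = None           # dF/F over time
    onset_s: float | None = None
    in_stimulus_spot: bool = False

    @property
    def peak_dff(self) -> float:
        if self.trace is None:
            raise ValueError("trace not attached")
        return float(np.max(self.trace))


@dataclass
class WaveMetrics:
    """Headline statistics of one evoked wave."""

    active_cell_count: int
    active_density_per_mm2: float
    max_extent_um: float                      # D
    t_half_s: float                           # time to reach D/2, from stimulus
    speed_um_s: float                         # (D/2) / t_half
    amplitude_at_half_distance: float         # mean peak dF/F in the annulus
    loaded_area_mm2: float

    def as_row(self) -> dict:
        return {
            "n_active": self.active_cell_count,
            "density_per_mm2": self.active_density_per_mm2,
            "distance_um": self.max_extent_um,
            "t_half_s": self.t_half_s,
            "speed_um_s": self.speed_um_s,
            "amp_half_dff": self.amplitude_at_half_distance,
            "loaded_area_mm2": self.loaded_area_mm2,
        }


def detect_cells(
    baseline_image: np.ndarray,
    mask: np.ndarray,
    min_radius_um: float = 2.5,
    max_radius_um: float = 10.0,
    pixel_size: float = 1.0,
) -> list[CellROI]:
    """Detect somata on the baseline image, restricted to the dye mask.

    Band-pass (difference of Gaussians) enhancement, local maxima as seeds,
    and watershed-grown regions over a foreground threshold.  Regions whose
    equivalent radius falls outside [min_radius_um, max_radius_um] are
    discarded.  Fully deterministic.
    """
    if not np.any(mask):
        raise ValueError("dye mask is empty")
    img = np.asarray(baseline_image, dtype=float)
    r_px = 0.5 * (min_radius_um + max_radius_um) / pixel_size
    band = gaussian(img, sigma=max(r_px / 4.0, 0.5), preserve_range=True) \
        - gaussian(img, sigma=2.0 * r_px, preserve_range=True)
    band[~mask] = 0.0
    vals = band[mask]
    if vals.size == 0 or not np.any(vals > 0):
        warnings.warn("no cells found", stacklevel=2)
        return []
    # Foreground: Otsu split of the band-pass response (somata vs neuropil).
    if np.ptp(vals) == 0:
        warnings.warn("no cells found", stacklevel=2)
        return []
    thr = max(threshold_otsu(vals), 0.0)
    fg = band > thr
    min_dist = max(1, int(round(2.0 * min_radius_um / pixel_size)))
    seeds = peak_local_max(band, min_distance=min_dist, threshold_abs=thr,
                           labels=fg, exclude_border=False)
    if len(seeds) == 0:
        warnings.warn("no cells found", stacklevel=2)
        return []
    markers = np.zeros(img.shape, dtype=int)
    markers[tuple(seeds.T)] = np.arange(1, len(seeds) + 1)
    labels = watershed(-band, markers=markers, mask=fg)
    rois: list[CellROI] = []
    rid = 0
    for lab in range(1, len(seeds) + 1):
        rows, cols = np.nonzero(labels == lab)
        if rows.size == 0:
            continue
        r_equiv = np.sqrt(rows.size / np.pi) * pixel_size
        if not min_radius_um <= r_equiv <= max_radius_um:
            continue
        w = img[rows, cols]
        w = w / w.sum() if w.sum() > 0 else np.full(rows.size, 1.0 / rows.size)
        cx = float((cols * w).sum()) * pixel_size
        cy = float((rows * w).sum()) * pixel_size
        rois.append(CellROI(id=rid, centroid_um=(cx, cy), pixels=(rows, cols),
                            equiv_radius_um=float(r_equiv)))
        rid += 1
    if not rois:
        warnings.warn("no cells found", stacklevel=2)
    return rois


def attach_traces(rois: list[CellROI], dff: DffStack,
                  stim: StimulusSpec | None = None) -> list[CellROI]:
    """Fill each ROI's mean dF/F trace and its stimulus geometry in place."""
    stim = stim or dff.stimulus
    valid = ~dff.mask_invalid
    for roi in rois:
        rows, cols = roi.pixels
        ok = valid[rows, cols]
        if not ok.any():
            roi.trace = np.zeros(dff.data.shape[0])
        else:
            roi.trace = dff.data[:, rows[ok], cols[ok]].mean(axis=1)
        if stim is not None:
            sx = stim.center[0] * dff.pixel_size
            sy = stim.center[1] * dff.pixel_size
            d = float(np.hypot(roi.centroid_um[0] - sx, roi.centroid_um[1] - sy))
            roi.distance_to_stimulus_um = d
            roi.in_stimulus_spot = d <= stim.diameter / 2.0 + roi.equiv_radius_um
    return rois


def classify_active(rois: list[CellROI], threshold: float = 0.05,
                    stimulation_frame: int = 5) -> list[CellROI]:
    """Active cells by the wave-border rule: post-stimulus dF/F >= 5 %.

    A peak exactly at the threshold counts as active.  Cells overlapping the
    stimulus spot are flagged (``in_stimulus_spot``) by :func:`attach_traces`
    and are returned too — callers exclude them from wave statistics.
    """
    out = []
    for roi in rois:
        if roi.trace is None:
            raise ValueError("traces must be attached before classification")
        post = roi.trace[stimulation_frame:]
        if post.size and float(post.max()) >= threshold:
            out.append(roi)
    return out


def threshold_onset(trace: np.ndarray, threshold: float = 0.05,
                    stimulation_frame: int = 5,
                    frame_interval: float = 1.0 / 1.2) -> float | None:
    """Recruitment time of a cell: first post-stimulus frame with dF/F at or
    above the wave-border threshold, or None if never reached.

    This is the cell-level onset convention: a cell joins the wave when it
    crosses the same 5 % criterion that defines its being active, which keeps
    onset latency far below one frame for fast-rising transients (the
    half-maximum rule is reserved for polar-ROI event rasters).
    """
    trace = np.asarray(trace, dtype=float)
    post = trace[stimulation_frame:]
    above = np.flatnonzero(post >= threshold)
    if above.size == 0:
        return None
    return (stimulation_frame + int(above[0])) * frame_interval


def active_density(active_count: int, loaded_area_mm2: float) -> float:
    """Active cells normalized to the visible dye-loaded area (cells/mm^2)."""
    if loaded_area_mm2 <= 0:
        raise ValueError("loaded area must be positive")
    return active_count / loaded_area_mm2


def extent_timeseries(active_rois: list[CellROI], frame_times: np.ndarray,
                      stim: StimulusSpec) -> np.ndarray:
    """Wavefront radius r(t): farthest activated cell at or before each frame.

    Only wave-recruited cells count (stimulus-spot cells are excluded); cells
    without a detected onset are ignored.  r is non-decreasing by
    construction; the final value is the propagation distance D.
    """
    r = np.zeros(len(frame_times))
    cells = [c for c in active_rois
             if not c.in_stimulus_spot and c.onset_s is not None]
    if not cells:
        return r
    onsets = np.array([c.onset_s for c in cells])
    dists = np.array([c.distance_to_stimulus_um for c in cells])
    for i, t in enumerate(frame_times):
        reached = onsets <= t + 1e-12
        r[i] = dists[reached].max() if reached.any() else 0.0
    return np.maximum.accumulate(r)


def speed_and_half_metrics(r: np.ndarray, frame_times: np.ndarray,
                           stim_time_s: float) -> tuple[float, float, float]:
    """(D, t_half, speed) from the wavefront radius time series.

    D is the final radius; t_half the first frame time (relative to the
    stimulus) at which r(t) >= D/2; speed = (D/2) / t_half.  A failed wave
    (D = 0) yields NaN t_half and speed.
    """
    r = np.asarray(r, dtype=float)
    D = float(r[-1]) if r.size else 0.0
    if D <= 0:
        return 0.0, float("nan"), float("nan")
    idx = int(np.argmax(r >= D / 2.0))
    t_half = float(frame_times[idx] - stim_time_s)
    if t_half <= 0:
        return D, float("nan"), float("nan")
    return D, t_half, (D / 2.0) / t_half


def amplitude_at_half_distance(active_rois: list[CellROI], D_um: float,
                               annulus_width_um: float = 40.0) -> float:
    """Mean peak post-stimulus dF/F of active cells near the D/2 site.

    Cells whose centroid distance lies within ``D/2 ± width/2`` are averaged;
    if the annulus is empty it is widened once (2x) before reporting NaN.
    """
    if D_um <= 0:
        return float("nan")
    cells = [c for c in active_rois if not c.in_stimulus_spot]
    for w in (annulus_width_um, 2.0 * annulus_width_um):
        lo, hi = D_um / 2.0 - w / 2.0, D_um / 2.0 + w / 2.0
        peaks = [c.peak_dff for c in cells
                 if lo <= c.distance_to_stimulus_um <= hi]
        if peaks:
            return float(np.mean(peaks))
    return float("nan")


def compute_wave_metrics(
    active_rois: list[CellROI],
    frame_times: np.ndarray,
    stim: StimulusSpec,
    loaded_area_mm2: float,
    frame_interval: float,
    annulus_width_um: float = 40.0,
) -> WaveMetrics:
    """Assemble the per-recording summary from classified, onset-tagged cells."""
    wave_cells = [c for c in active_rois if not c.in_stimulus_spot]
    r = extent_timeseries(active_rois, frame_times, stim)
    stim_time = stim.stimulation_frame * frame_interval
    D, t_half, speed = speed_and_half_metrics(r, frame_times, stim_time)
    amp = amplitude_at_half_distance(active_rois, D, annulus_width_um)
    return WaveMetrics(
        active_cell_count=len(wave_cells),
        active_density_per_mm2=active_density(len(wave_cells), loaded_area_mm2),
        max_extent_um=D,
        t_half_s=t_half,
        speed_um_s=speed,
        amplitude_at_half_distance=amp,
        loaded_area_mm2=loaded_area_mm2,
    )
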