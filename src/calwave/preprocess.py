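"""Stack stabilization, temporal denoising and dF/F conversion.

The preprocessing chain mirrors how short evoked-wave recordings are treated
before quantification: rigid (translation-only) stabilization against a
reference frame, a per-pixel temporal Kalman filter, and conversion to
relative fluorescence change dF/F against the mean of the pre-stimulus
baseline frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage


@dataclass
class StimulusSpec:
    """Photostimulation geometry: the origin of all radial analysis.

    center is in pixels (x, y); diameter in micrometres; stimulation_frame
    is the index of the first irradiated frame.
    """

    center: tuple[float, float]
    diameter: float = 25.0
    stimulation_frame: int = 5

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("stimulus diameter must be positive")
        if self.stimulation_frame < 0:
            raise ValueError("stimulation_frame must be nonnegative")


@dataclass
class ImageStack:
    """A calibrated T x H x W fluorescence movie."""

    data: np.ndarray
    frame_interval: float = 1.0 / 1.2   # s
    pixel_size: float = 1.0             # um / pixel
    stimulus: StimulusSpec | None = None
    shifts: np.ndarray | None = None    # (T, 2) applied (dx, dy), set by register_stack

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("stack data must be T x H x W with T >= 1")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ValueError("intensities must be finite and nonnegative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def with_data(self, data: np.ndarray, **kw) -> "ImageStack":
        return replace(self, data=data, **kw)


@dataclass
class DffStack:
    """Relative fluorescence change (F - F0) / F0 against a baseline image."""

    data: np.ndarray                 # T x H x W dF/F
    baseline_image: np.ndarray       # H x W mean of baseline frames
    baseline_frames_used: int
    mask_invalid: np.ndarray         # H x W True where F0 <= 0 (dF/F undefined)
    frame_interval: float = 1.0 / 1.2
    pixel_size: float = 1.0
    stimulus: StimulusSpec | None = None

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.data.shape[0]) * self.frame_interval


def estimate_shift(reference: np.ndarray, target: np.ndarray) -> tuple[float, float]:
    """Translation (dx, dy) that moves ``reference`` onto ``target``.

    Maximizes the FFT cross-correlation of the mean-subtracted,
    Hann-windowed images (windowing suppresses the non-periodic boundary
    energy that otherwise biases the peak) and refines the integer peak to
    subpixel precision by separable quadratic interpolation.  Ties are
    broken toward zero shift; a constant image makes the shift
    unidentifiable and returns (0, 0) with a warning.
    """
    ref = np.asarray(reference, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if ref.shape != tgt.shape:
        raise ValueError("images must have the same shape")
    r = ref - ref.mean()
    t = tgt - tgt.mean()
    if not r.any() or not t.any():
        warnings.warn("constant image: shift is unidentifiable, returning (0, 0)",
                      stacklevel=2)
        return (0.0, 0.0)
    H, W = ref.shape
    window = np.outer(np.hanning(H), np.hanning(W))
    r = r * window
    t = t * window
    cc = np.real(np.fft.ifft2(np.fft.fft2(t) * np.conj(np.fft.fft2(r))))
    # Prefer the smallest displacement among equal maxima (tie toward zero).
    peak = cc.max()
    ties = np.argwhere(np.isclose(cc, peak, rtol=0, atol=1e-9 * max(abs(peak), 1.0)))
    wrap = lambda idx, n: idx - n * (idx > n // 2)
    disp = np.array([(wrap(i, H), wrap(j, W)) for i, j in ties], dtype=float)
    best = ties[np.argmin((disp ** 2).sum(axis=1))]
    iy, ix = int(best[0]), int(best[1])

    def _quad(cm: float, c0: float, cp: float) -> float:
        # Parabolic refinement on log-correlation when possible: the peak of
        # the correlation of band-limited images is near-Gaussian, so the
        # log-parabola is far less biased toward the grid.
        if cm > 0 and c0 > 0 and cp > 0 and c0 >= cm and c0 >= cp:
            cm, c0, cp = np.log(cm), np.log(c0), np.log(cp)
        denom = cm - 2.0 * c0 + cp
        if denom >= 0:  # no concave peak; stay on the grid
            return 0.0
        return float(np.clip(0.5 * (cm - cp) / denom, -0.5, 0.5))

    dy = wrap(iy, H) + _quad(cc[(iy - 1) % H, ix], cc[iy, ix], cc[(iy + 1) % H, ix])
    dx = wrap(ix, W) + _quad(cc[iy, (ix - 1) % W], cc[iy, ix], cc[iy, (ix + 1) % W])
    if abs(dx) < 1e-9:
        dx = 0.0
    if abs(dy) < 1e-9:
        dy = 0.0
    return (float(dx), float(dy))


def register_stack(stack: ImageStack, reference_frame: int = 0,
                   min_shift: float = 0.1) -> ImageStack:
    """Cancel per-frame rigid translation against a reference frame.

    Each frame is shifted by the negated estimated displacement using
    bilinear interpolation; pixels pulled in from outside the frame are
    filled with the frame median.  Estimated shifts below ``min_shift``
    pixels are treated as zero: resampling a static frame for a noise-driven
    subpixel estimate would blur it relative to unresampled frames and
    imprint edge artifacts on dF/F.  The applied shifts are stored on the
    returned stack (``shifts[t]`` = estimated (dx, dy) of frame t).
    """
    T = stack.n_frames
    if not 0 <= reference_frame < T:
        raise ValueError("reference_frame out of range")
    if T == 1:
        return stack.with_data(stack.data.copy(), shifts=np.zeros((1, 2)))
    # Estimate on intensity-clamped copies (99.5th pct of the reference):
    # the saturating irradiation artifact and large calcium transients
    # otherwise dominate the correlation and derail the estimate.
    ref = stack.data[reference_frame]
    ceiling = float(np.percentile(ref, 99.5))
    ref_c = np.minimum(ref, ceiling)
    out = np.empty_like(stack.data)
    shifts = np.zeros((T, 2))
    for t in range(T):
        if t == reference_frame:
            out[t] = stack.data[t]
            continue
        dx, dy = estimate_shift(ref_c, np.minimum(stack.data[t], ceiling))
        if np.hypot(dx, dy) < min_shift:
            dx = dy = 0.0
        shifts[t] = (dx, dy)
        if dx == 0.0 and dy == 0.0:
            out[t] = stack.data[t]
        else:
            out[t] = ndimage.shift(stack.data[t], (-dy, -dx), order=1,
                                   mode="constant", cval=float(np.median(stack.data[t])))
    out = np.clip(out, 0.0, None)
    return stack.with_data(out, shifts=shifts)


def kalman_filter(stack: ImageStack, gain: float = 0.8,
                  initial_variance: float = 0.05) -> ImageStack:
    """Per-pixel recursive temporal filter (stack-Kalman denoising).

    Each pixel runs a scalar predict/correct recursion with the previous
    estimate as prediction: ``estimate_t = prediction + K_t * (obs -
    prediction)``.  The raw gain ``P/(P + R)`` shrinks as the error variance
    P contracts; the observation weight is floored at ``1 - gain`` so the
    filter keeps responding to transients (``gain`` is the maximum fraction
    of the previous estimate retained, the stack-filter plugin convention).
    ``gain = 1`` disables the filter (output equals input).  The first frame
    passes through unchanged.
    """
    if not 0.0 < gain <= 1.0:
        raise ValueError("gain must be in (0, 1]")
    if initial_variance <= 0:
        raise ValueError("initial_variance must be positive")
    if gain == 1.0:
        return stack.with_data(stack.data.copy())
    data = stack.data
    out = np.empty_like(data)
    out[0] = data[0]
    P = initial_variance
    R = initial_variance
    estimate = data[0].astype(float)
    for t in range(1, data.shape[0]):
        K = max(P / (P + R), 1.0 - gain)
        estimate = estimate + K * (data[t] - estimate)
        P = P * (1.0 - K)
        out[t] = estimate
    return stack.with_data(out)


def compute_dff(stack: ImageStack, baseline_frames: int = 5) -> DffStack:
    """Convert to dF/F against the per-pixel mean of the first baseline frames.

    Pixels whose baseline mean F0 is not positive are masked (dF/F set to 0
    there and flagged) rather than producing infinities; downstream steps
    exclude them.
    """
    if not 1 <= baseline_frames < stack.n_frames:
        raise ValueError("baseline_frames must be >= 1 and < frame count")
    f0 = stack.data[:baseline_frames].mean(axis=0)
    invalid = f0 <= 0
    if invalid.all():
        raise ValueError("all-zero baseline: 100% of pixels masked, dF/F undefined")
    safe_f0 = np.where(invalid, 1.0, f0)
    dff = (stack.data - f0) / safe_f0
    dff[:, invalid] = 0.0
    return DffStack(
        data=dff, baseline_image=f0, baseline_frames_used=baseline_frames,
        mask_invalid=invalid, frame_interval=stack.frame_interval,
        pixel_size=stack.pixel_size, stimulus=stack.stimulus)


def loaded_area_mask(baseline_image: np.ndarray, threshold_factor: float = 2.0,
                     pixel_size: float = 1.0) -> tuple[np.ndarray, float]:
    """Mask of the visibly dye-loaded area and its size in mm^2.

    The background level is estimated robustly as the median of the lowest
    decile of baseline pixels; the mask keeps pixels at or above
    ``threshold_factor`` times that level.  Cell densities are normalized to
    this area.
    """
    if threshold_factor <= 0:
        raise ValueError("threshold_factor must be positive")
    img = np.asarray(baseline_image, dtype=float)
    lowest = np.quantile(img, 0.10)
    background = float(np.median(img[img <= lowest])) if np.any(img <= lowest) else float(lowest)
    mask = img >= threshold_factor * background
    if not mask.any():
        raise ValueError("no pixels above the dye-loading threshold: area undefined")
    area_mm2 = float(mask.sum()) * pixel_size ** 2 / 1e6
    return mask, area_mm2
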