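"""Synthetic evoked calcium-wave movies with known ground truth.

The generator emulates a two-photon recording of dye-loaded cortical-plate
somata responding to a point photostimulus: a field of fluorescent disks over
a dim background, a radially propagating activation front with per-cell onset
latency ``distance / velocity`` (plus optional jitter and angular
anisotropy), a fast-rise / slow-decay fluorescence transient, shot-like
noise, slow rigid drift, and a short pre-stimulus baseline.  Every stack
comes with its :class:`GroundTruth` (true velocity, per-cell onset map,
recruited-cell set), so downstream estimators can be validated by recovery.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import stats

from .preprocess import ImageStack, StimulusSpec

__all__ = [
    "CellField",
    "WaveParams",
    "AcquisitionParams",
    "GroundTruth",
    "ConditionPreset",
    "generate_cell_field",
    "assign_onsets",
    "render_stack",
    "simulate_recording",
    "condition_preset",
    "transient_kernel",
    "truncated_normal",
    "write_recording",
]

SATURATION_16BIT = 65535.0


@dataclass
class CellField:
    """A field of fluorescent somata (positions and sizes in micrometres)."""

    positions: np.ndarray          # (n, 2) array of (x, y) in um
    radii: np.ndarray              # (n,) um
    baseline_intensity: np.ndarray  # (n,) arbitrary fluorescence units
    background_intensity: float = 100.0
    field_size: tuple[float, float] = (512.0, 512.0)  # (width, height) um

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.size == 0:
            self.positions = self.positions.reshape(0, 2)
        self.radii = np.asarray(self.radii, dtype=float)
        self.baseline_intensity = np.asarray(self.baseline_intensity, dtype=float)
        if np.any(self.radii <= 0):
            raise ValueError("cell radii must be positive")
        w, h = self.field_size
        if self.n_cells and (
            self.positions[:, 0].min() < 0 or self.positions[:, 0].max() > w
            or self.positions[:, 1].min() < 0 or self.positions[:, 1].max() > h
        ):
            raise ValueError("cell positions must lie inside the field of view")

    @property
    def n_cells(self) -> int:
        return len(self.positions)


@dataclass
class WaveParams:
    """Phenomenological wave model: speed, reach, recruitment and transient.

    ``velocity`` may be a scalar (isotropic, um/s) or a callable ``v(theta)``
    of the propagation angle in radians for anisotropic waves.
    """

    velocity: float | Callable[[np.ndarray], np.ndarray] = 119.0
    max_extent: float = 273.0          # um
    onset_jitter_sd: float = 0.0       # s
    amplitude: float = 0.8             # peak dF/F of the transient
    rise_time: float = 0.5             # s to kernel peak
    decay_time: float = 2.0            # s, exponential decay
    recruitment_probability: float = 1.0

    def __post_init__(self) -> None:
        if not callable(self.velocity) and self.velocity <= 0:
            raise ValueError("velocity must be positive")
        if self.max_extent <= 0:
            raise ValueError("max_extent must be positive")
        if not 0.0 <= self.recruitment_probability <= 1.0:
            raise ValueError("recruitment_probability must be in [0, 1]")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")

    def velocity_at(self, theta: np.ndarray) -> np.ndarray:
        if callable(self.velocity):
            v = np.asarray(self.velocity(np.asarray(theta, dtype=float)), dtype=float)
        else:
            v = np.full_like(np.asarray(theta, dtype=float), float(self.velocity))
        if np.any(v <= 0):
            raise ValueError("velocity must be positive for every angle")
        return v


@dataclass
class AcquisitionParams:
    """Microscope acquisition settings (defaults mirror a 1.2 fps, 512x512
    two-photon recording with a five-frame pre-stimulus baseline)."""

    frame_interval: float = 1.0 / 1.2  # s
    frame_count: int = 45
    height: int = 512
    width: int = 512
    pixel_size: float = 1.0            # um / pixel
    baseline_frames: int = 5
    gaussian_noise_sd: float | None = None  # absolute units; None -> 5% of background
    poisson_noise: bool = False
    poisson_scale: float = 1.0         # photons per intensity unit when poisson_noise
    drift_per_frame: tuple[float, float] = (0.0, 0.0)  # (dx, dy) pixels / frame
    # Unloaded-tissue margin rendered at the left edge: dye loading never
    # covers the whole field, and the dye-area mask needs genuinely dark
    # pixels to estimate the background from.
    dark_margin_px: int = 28
    dark_level: float = 5.0
    psf_sigma_um: float = 1.0  # optical blur; 0 disables

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not 0 <= self.baseline_frames < self.frame_count:
            raise ValueError("baseline_frames must be < frame_count")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    onset_times: np.ndarray        # (n,) s from recording start; NaN = not recruited
    true_velocity: float | Callable[[np.ndarray], np.ndarray]
    active_cell_ids: np.ndarray    # indices into the CellField
    stimulus: StimulusSpec
    stimulus_time: float           # s
    loaded_area_mm2: float

    def is_active(self) -> np.ndarray:
        return np.isfinite(self.onset_times)


def generate_cell_field(
    field_size: tuple[float, float] = (512.0, 512.0),
    density: float = 1200.0,
    rng_seed: int | np.random.Generator = 0,
    *,
    radius_um: float = 5.0,
    radius_jitter: float = 0.0,
    baseline_mean: float = 600.0,
    baseline_cv: float = 0.15,
    background_intensity: float = 100.0,
    min_separation: float | None = None,
) -> CellField:
    """Scatter somata uniformly over the field.

    Parameters
    ----------
    field_size
        (width, height) of the field of view in micrometres.
    density
        Expected soma density in cells/mm^2; the realized count is Poisson.
    min_separation
        Optional centre-to-centre minimum distance (um); enforced by greedy
        thinning, which lowers the realized density.
    """
    if density < 0:
        raise ValueError("density must be nonnegative")
    w, h = field_size
    if w <= 0 or h <= 0:
        raise ValueError("field_size must be positive")
    rng = np.random.default_rng(rng_seed)
    area_mm2 = (w * h) / 1e6
    n = rng.poisson(density * area_mm2)
    pos = np.column_stack([rng.uniform(0, w, n), rng.uniform(0, h, n)])
    if min_separation is not None and n > 1:
        from scipy.spatial import cKDTree

        tree = cKDTree(pos)
        pairs = tree.query_pairs(min_separation, output_type="ndarray")
        kept = np.ones(n, dtype=bool)
        for i, j in pairs:  # greedy: drop the later point of each close pair
            if kept[i] and kept[j]:
                kept[j] = False
        pos = pos[kept]
        n = len(pos)
    radii = np.full(n, radius_um)
    if radius_jitter > 0:
        radii = np.clip(radii + rng.normal(0, radius_jitter, n), 1.0, None)
    base = baseline_mean * np.clip(rng.normal(1.0, baseline_cv, n), 0.2, None)
    return CellField(pos, radii, base, background_intensity, (w, h))


def assign_onsets(
    cells: CellField,
    stim: StimulusSpec,
    wave: WaveParams,
    rng_seed: int | np.random.Generator = 0,
    *,
    pixel_size: float = 1.0,
    frame_interval: float = 1.0 / 1.2,
    loaded_area_mm2: float | None = None,
) -> GroundTruth:
    """Assign each cell its activation onset under the radial wave model.

    A cell at distance ``d <= max_extent`` from the stimulus centre is
    recruited with probability ``recruitment_probability`` and activates at
    ``stim_time + d / v(theta) + jitter``; cells under the stimulus spot
    activate at the stimulus itself (direct irradiation).  Cells beyond the
    extent, or unlucky in recruitment, get no onset (NaN).
    """
    rng = np.random.default_rng(rng_seed)
    stim_time = stim.stimulation_frame * frame_interval
    center_um = np.asarray(stim.center, dtype=float) * pixel_size
    onsets = np.full(cells.n_cells, np.nan)
    if cells.n_cells:
        delta = cells.positions - center_um
        d = np.hypot(delta[:, 0], delta[:, 1])
        theta = np.mod(np.arctan2(delta[:, 1], delta[:, 0]), 2 * np.pi)
        v = wave.velocity_at(theta)
        recruited = (d <= wave.max_extent) & (
            rng.random(cells.n_cells) < wave.recruitment_probability
        )
        in_spot = d <= stim.diameter / 2.0
        lat = d / v
        if wave.onset_jitter_sd > 0:
            lat = np.maximum(lat + rng.normal(0, wave.onset_jitter_sd, cells.n_cells), 0.0)
        onsets[recruited] = stim_time + lat[recruited]
        onsets[in_spot] = stim_time  # direct irradiation, not wave recruitment
    w, h = cells.field_size
    if loaded_area_mm2 is None:
        loaded_area_mm2 = (w * h) / 1e6
    return GroundTruth(
        onset_times=onsets,
        true_velocity=wave.velocity,
        active_cell_ids=np.flatnonzero(np.isfinite(onsets)),
        stimulus=stim,
        stimulus_time=stim_time,
        loaded_area_mm2=loaded_area_mm2,
    )


def transient_kernel(t: np.ndarray, rise_time: float, decay_time: float) -> np.ndarray:
    """Fast-rise / slow-decay calcium transient, normalized to peak 1.

    ``k(t) = (1 - exp(-t/tau_r)) * exp(-t/tau_d)`` for t >= 0, rescaled so
    its maximum (at ``t* = tau_r * ln(1 + tau_d/tau_r)``) equals 1.
    """
    t = np.asarray(t, dtype=float)
    k = np.where(t >= 0, (1.0 - np.exp(-np.clip(t, 0, None) / rise_time))
                 * np.exp(-np.clip(t, 0, None) / decay_time), 0.0)
    t_peak = rise_time * math.log1p(decay_time / rise_time)
    peak = (1.0 - math.exp(-t_peak / rise_time)) * math.exp(-t_peak / decay_time)
    return k / peak


def render_stack(
    cells: CellField,
    truth: GroundTruth,
    wave: WaveParams,
    acq: AcquisitionParams,
    rng_seed: int | np.random.Generator = 0,
    *,
    render_stimulus_artifact: bool = True,
    stimulus_duration_s: float = 3.0,
) -> ImageStack:
    """Rasterize the field into a T x H x W movie.

    Cells are uniform disks (overlap resolved by maximum); an activated cell
    follows ``F(t) = baseline * (1 + amplitude * kernel(t - onset))``.  Rigid
    drift shifts the whole scene per frame; noise is added last.  The
    stimulus spot is rendered as an immediately saturating disk during the
    irradiation period, emulating the bleaching-routine artifact.
    """
    rng = np.random.default_rng(rng_seed)
    T, H, W = acq.frame_count, acq.height, acq.width
    px = acq.pixel_size
    frames = np.full((T, H, W), cells.background_intensity, dtype=np.float64)
    times = np.arange(T) * acq.frame_interval

    drift = np.asarray(acq.drift_per_frame, dtype=float)
    total_drift = drift * (T - 1)
    if cells.n_cells:
        cx = cells.positions[:, 0] / px
        cy = cells.positions[:, 1] / px
        if (np.all(cx + total_drift[0] < 0) or np.all(cx + total_drift[0] >= W)
                or np.all(cy + total_drift[1] < 0) or np.all(cy + total_drift[1] >= H)):
            warnings.warn("drift pushes every cell out of the frame", stacklevel=2)

    # Per-cell per-frame intensity, then scatter disks frame by frame.
    onset = truth.onset_times
    for ti, t in enumerate(times):
        shift = drift * ti
        for i in range(cells.n_cells):
            amp = cells.baseline_intensity[i]
            if np.isfinite(onset[i]):
                amp = amp * (1.0 + wave.amplitude
                             * transient_kernel(t - onset[i], wave.rise_time, wave.decay_time))
            _paint_disk(frames[ti],
                        cells.positions[i, 0] / px + shift[0],
                        cells.positions[i, 1] / px + shift[1],
                        cells.radii[i] / px, amp)

    if render_stimulus_artifact:
        stim = truth.stimulus
        stim_frames = max(1, int(math.ceil(stimulus_duration_s / acq.frame_interval)))
        f0 = stim.stimulation_frame
        for ti in range(f0, min(T, f0 + stim_frames)):
            shift = drift * ti
            _paint_disk(frames[ti], stim.center[0] + shift[0], stim.center[1] + shift[1],
                        (stim.diameter / 2.0) / px, SATURATION_16BIT)

    if acq.dark_margin_px > 0:
        frames[:, :, : acq.dark_margin_px] = acq.dark_level
    if acq.psf_sigma_um > 0:
        from scipy import ndimage

        sigma_px = acq.psf_sigma_um / px
        for ti in range(T):
            frames[ti] = ndimage.gaussian_filter(frames[ti], sigma_px)

    if acq.poisson_noise:
        frames = rng.poisson(np.clip(frames, 0, None) * acq.poisson_scale) / acq.poisson_scale
    sd = acq.gaussian_noise_sd
    if sd is None:
        sd = 0.05 * cells.background_intensity
    if sd > 0:
        frames = frames + rng.normal(0.0, sd, frames.shape)
    frames = np.clip(frames, 0.0, SATURATION_16BIT)
    return ImageStack(frames, frame_interval=acq.frame_interval, pixel_size=px,
                      stimulus=truth.stimulus)


def _paint_disk(img: np.ndarray, cx: float, cy: float, r: float, value: float) -> None:
    """Max-composite a uniform disk at subpixel centre (cx, cy), radius r px."""
    H, W = img.shape
    x0, x1 = int(math.floor(cx - r)), int(math.ceil(cx + r)) + 1
    y0, y1 = int(math.floor(cy - r)), int(math.ceil(cy + r)) + 1
    x0, x1 = max(x0, 0), min(x1, W)
    y0, y1 = max(y0, 0), min(y1, H)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r
    patch = img[y0:y1, x0:x1]
    np.maximum(patch, np.where(inside, value, 0.0), out=patch)


def truncated_normal(mean: float, sd: float, rng: np.random.Generator,
                     size: int | None = None) -> np.ndarray | float:
    """Draw from N(mean, sd^2) truncated at 0 (metric values are nonnegative)."""
    if sd <= 0:
        return mean if size is None else np.full(size, mean)
    a = -mean / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def truncated_normal_moments(mean: float, sd: float) -> tuple[float, float]:
    """Mean and SD of N(mean, sd^2) truncated at 0."""
    a = -mean / sd
    d = stats.truncnorm(a, np.inf, loc=mean, scale=sd)
    return float(d.mean()), float(d.std())


@dataclass
class ConditionPreset:
    """Per-condition generator settings and per-recording metric distributions.

    ``metric_distributions`` maps metric name to ``(mean, sd)`` of the
    truncated-at-zero normal from which a recording's target value is drawn.
    """

    name: str
    wave: WaveParams
    metric_distributions: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_recordings: int = 13

    def draw_metrics(self, rng: np.random.Generator) -> dict[str, float]:
        return {k: float(truncated_normal(m, s, rng))
                for k, (m, s) in self.metric_distributions.items()}


# Headline per-recording statistics for the three pharmacological conditions
# (mean, SD): active-cell density (cells/mm^2), propagation distance (um),
# propagation speed (um/s), and peak dF/F amplitude at the half-propagation
# site.  Density/distance/speed are the published condition statistics; the
# control amplitude is a free parameter (0.8 dF/F) with suramin reduced by
# 58 +/- 29 % and caffeine increased by 55 +/- 40 % relative to it.  Suramin's
# speed reuses the control distribution (no speed change is reported for it).
_CONTROL_AMPLITUDE = 0.8
_PRESETS: dict[str, dict] = {
    "control": dict(
        density=(470.0, 220.0), distance=(273.0, 68.0), speed=(119.0, 80.0),
        amplitude=(_CONTROL_AMPLITUDE, 0.15 * _CONTROL_AMPLITUDE), n=13),
    "suramin": dict(
        density=(56.0, 51.0), distance=(88.0, 44.0), speed=(119.0, 80.0),
        amplitude=(_CONTROL_AMPLITUDE * (1 - 0.58), _CONTROL_AMPLITUDE * 0.29), n=16),
    "caffeine": dict(
        density=(1190.0, 370.0), distance=(273.0 * 1.2, 68.0), speed=(194.0, 163.0),
        amplitude=(_CONTROL_AMPLITUDE * (1 + 0.55), _CONTROL_AMPLITUDE * 0.40), n=14),
}


def condition_preset(name: str) -> ConditionPreset:
    """Generator preset for one of the three pharmacological conditions.

    ``control``: vehicle injection; ``suramin``: P2 (ATP) receptor blockade,
    strongly suppressed recruitment and extent; ``caffeine``: facilitated
    intracellular calcium release, denser recruitment and larger amplitude.
    """
    try:
        p = _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}") from None
    wave = WaveParams(
        velocity=p["speed"][0],
        max_extent=p["distance"][0],
        amplitude=p["amplitude"][0],
        recruitment_probability=1.0,
    )
    dists = {k: tuple(map(float, p[k])) for k in ("density", "distance", "speed", "amplitude")}
    return ConditionPreset(name=name, wave=wave, metric_distributions=dists,
                           n_recordings=p["n"])


def simulate_recording(
    preset: ConditionPreset | str,
    rng_seed: int | np.random.Generator = 0,
    *,
    acq: AcquisitionParams | None = None,
    stim_center: tuple[float, float] | None = None,
    soma_density: float = 4000.0,
    onset_jitter_sd: float = 0.15,
) -> tuple[ImageStack, CellField, GroundTruth, dict[str, float]]:
    """Simulate one recording under a condition preset.

    A per-recording target (density, distance, speed, amplitude) is drawn
    from the preset's truncated-normal distributions and realized through the
    generator: recruitment probability = target density / soma density,
    max_extent = target distance, velocity = target speed, amplitude = target
    amplitude.  Returns the rendered stack, the cell field, the ground truth
    and the drawn target metrics.
    """
    rng = np.random.default_rng(rng_seed)
    if isinstance(preset, str):
        preset = condition_preset(preset)
    targets = preset.draw_metrics(rng)
    if acq is None:
        # Record until the wave has fully played out (plus transient decay),
        # as an imaging session would; slow waves need longer movies.
        dt = 1.0 / 1.2
        travel = max(targets["distance"], 5.0) / max(targets["speed"], 5.0)
        n = 5 + int(math.ceil((travel + 10.0) / dt))
        acq = AcquisitionParams(frame_count=int(np.clip(n, 30, 120)))
    # Somata live only in the dye-loaded region (right of the dark margin);
    # densities, both simulated and recovered, are per loaded area.
    margin_um = acq.dark_margin_px * acq.pixel_size
    w_um = acq.width * acq.pixel_size
    h_um = acq.height * acq.pixel_size
    inner = generate_cell_field((w_um - margin_um, h_um), soma_density, rng,
                                min_separation=10.0)
    pos = inner.positions.copy()
    if len(pos):
        pos[:, 0] += margin_um
    cells = CellField(pos, inner.radii, inner.baseline_intensity,
                      inner.background_intensity, (w_um, h_um))
    if stim_center is None:
        stim_center = (acq.width / 2.0, acq.height / 2.0)
    stim = StimulusSpec(center=stim_center, diameter=25.0,
                        stimulation_frame=acq.baseline_frames)
    loaded_mm2 = (w_um - margin_um) * h_um / 1e6
    realized_density = cells.n_cells / loaded_mm2 if cells.n_cells else 1.0
    extent = max(targets["distance"], 5.0)
    # Density targets are per loaded area, but only cells inside the extent
    # circle can be recruited; compensate for the part of the loaded region
    # the (possibly frame-clipped) circle does not cover.
    gx = np.linspace(margin_um, w_um, 128)
    gy = np.linspace(0.0, h_um, 128)
    cx = stim_center[0] * acq.pixel_size
    cy = stim_center[1] * acq.pixel_size
    cov = float(np.mean(np.hypot(gx[None, :] - cx, gy[:, None] - cy) <= extent))
    cov = max(cov, 1e-3)
    wave = WaveParams(
        velocity=max(targets["speed"], 5.0),
        max_extent=extent,
        amplitude=targets["amplitude"],
        onset_jitter_sd=onset_jitter_sd,
        recruitment_probability=min(1.0, targets["density"]
                                    / (realized_density * cov)),
    )
    truth = assign_onsets(cells, stim, wave, rng, pixel_size=acq.pixel_size,
                          frame_interval=acq.frame_interval,
                          loaded_area_mm2=loaded_mm2)
    stack = render_stack(cells, truth, wave, acq, rng)
    return stack, cells, truth, targets


def write_recording(out_dir: str | Path, name: str, stack: ImageStack,
                    cells: CellField, truth: GroundTruth) -> Path:
    """Write a simulated recording: 16-bit TIFF + ground-truth JSON + cells CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tif = out / f"{name}.tif"
    tifffile.imwrite(tif, np.clip(stack.data, 0, SATURATION_16BIT).astype(np.uint16))
    onsets = truth.onset_times
    pd.DataFrame({
        "id": np.arange(cells.n_cells),
        "x_um": cells.positions[:, 0] if cells.n_cells else [],
        "y_um": cells.positions[:, 1] if cells.n_cells else [],
        "onset_s": onsets,
    }).to_csv(out / f"{name}_cells.csv", index=False)
    vel = truth.true_velocity
    meta = {
        "frame_interval_s": stack.frame_interval,
        "pixel_size_um": stack.pixel_size,
        "stimulus_center_px": list(truth.stimulus.center),
        "stimulus_diameter_um": truth.stimulus.diameter,
        "stimulation_frame": truth.stimulus.stimulation_frame,
        "stimulus_time_s": truth.stimulus_time,
        "true_velocity_um_s": None if callable(vel) else float(vel),
        "active_cell_ids": truth.active_cell_ids.tolist(),
        "onset_times_s": [None if not np.isfinite(o) else float(o) for o in onsets],
        "loaded_area_mm2": truth.loaded_area_mm2,
    }
    (out / f"{name}_truth.json").write_text(json.dumps(meta, indent=1))
    return tif
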