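"""End-to-end orchestration: simulate → preprocess → analyze → compare.

`run_analyze` executes the full quantification chain on one recording in the
fixed order registration → temporal Kalman filter → dF/F → dye mask → cell
detection → wave metrics → polar transform → ROI events → front summary, and
can persist every artifact (metrics CSV row, event table, raster, front
summary JSON, shift log).  `run_compare` summarizes a metrics table across
conditions and runs the Mann-Whitney comparisons against control.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import metrics as wm
from . import polar as pol
from . import simulate as sim
from . import stats as st
from .preprocess import (ImageStack, StimulusSpec, compute_dff, kalman_filter,
                         loaded_area_mask, register_stack)

__all__ = ["RunConfig", "AnalysisResult", "run_analyze", "run_compare",
           "run_demo", "load_stack"]


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults.

    Every default is either an acquisition constant of the experimental
    design (1.2 fps, 512×512, 5 baseline frames, 20–30 μm spot, 70 μm ROIs to
    400 μm, 5 % activity threshold) or a documented analysis choice (Kalman
    gain, dye-mask threshold, annulus width, angular sampling).
    """

    pixel_size: float = 1.0              # um / pixel
    frame_interval: float = 1.0 / 1.2    # s
    baseline_frames: int = 5
    stimulus_center: tuple[float, float] | None = None  # px; None -> frame centre
    stimulus_diameter: float = 25.0      # um
    stimulation_frame: int = 5
    register: bool = True
    reference_frame: int = 0
    kalman: bool = True
    kalman_gain: float = 0.8
    kalman_variance: float = 0.05
    mask_threshold_factor: float = 2.0
    min_cell_radius: float = 2.5         # um
    max_cell_radius: float = 10.0        # um
    active_threshold: float = 0.05       # dF/F
    annulus_width: float = 40.0          # um
    roi_side: float = 70.0               # um
    radial_limit: float = 400.0          # um
    radial_step: float = 1.0             # um
    angular_samples: int | None = None   # None -> arc length at limit = step
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if raw.get("stimulus_center") is not None:
            raw["stimulus_center"] = tuple(raw["stimulus_center"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["stimulus_center"] is not None:
            d["stimulus_center"] = list(d["stimulus_center"])
        return d


@dataclass
class AnalysisResult:
    metrics: wm.WaveMetrics
    events: pd.DataFrame
    raster: np.ndarray
    raster_roi_ids: list[int]
    front: pol.FrontSummary
    n_cells_detected: int
    shifts: np.ndarray | None
    loaded_area_mm2: float

    def metrics_row(self, recording_id: str = "", condition: str = "") -> dict:
        row = {"recording_id": recording_id, "condition": condition}
        row.update(self.metrics.as_row())
        return row


def load_stack(path: str | Path, config: RunConfig) -> ImageStack:
    """Read a multi-page TIFF recording with the run's calibration."""
    data = tifffile.imread(path).astype(float)
    if data.ndim == 2:
        data = data[None]
    stim = _stimulus(config, data.shape[2], data.shape[1])
    return ImageStack(data, frame_interval=config.frame_interval,
                      pixel_size=config.pixel_size, stimulus=stim)


def _stimulus(config: RunConfig, width: int, height: int) -> StimulusSpec:
    center = config.stimulus_center or (width / 2.0, height / 2.0)
    return StimulusSpec(center=center, diameter=config.stimulus_diameter,
                        stimulation_frame=config.stimulation_frame)


def run_analyze(stack: ImageStack | str | Path, config: RunConfig | None = None,
                out_dir: str | Path | None = None,
                recording_id: str = "recording",
                condition: str = "") -> AnalysisResult:
    """Quantify one evoked-wave recording.

    Stages run in fixed order; when ``out_dir`` is given, the shift log,
    event table, raster and a JSON report (metrics, parameters, front
    summary) are written there.
    """
    config = config or RunConfig()
    if not isinstance(stack, ImageStack):
        stack = load_stack(stack, config)
    T, H, W = stack.data.shape
    stim = stack.stimulus or _stimulus(config, W, H)

    if config.register and T > 1:
        stack = register_stack(stack, config.reference_frame)
    shifts = stack.shifts

    # Cell-level branch: dF/F of the registered stack.  Soma traces average
    # many pixels, so they need no temporal denoising, and the Kalman
    # filter's group delay would bias onset times (hence speeds).
    dff = compute_dff(stack, config.baseline_frames)
    dff.stimulus = stim
    mask, area_mm2 = loaded_area_mask(dff.baseline_image,
                                      config.mask_threshold_factor,
                                      config.pixel_size)

    rois = wm.detect_cells(dff.baseline_image, mask, config.min_cell_radius,
                           config.max_cell_radius, config.pixel_size)
    wm.attach_traces(rois, dff, stim)
    active = wm.classify_active(rois, config.active_threshold,
                                stim.stimulation_frame)
    for roi in active:
        roi.onset_s = wm.threshold_onset(roi.trace, config.active_threshold,
                                         stim.stimulation_frame,
                                         config.frame_interval)
    metrics = wm.compute_wave_metrics(active, dff.frame_times, stim,
                                      area_mm2, config.frame_interval,
                                      config.annulus_width)

    # Raster branch: register -> Kalman -> dF/F -> polar, as the imaging
    # chain orders them.
    if config.kalman and config.kalman_gain < 1.0:
        filtered = kalman_filter(stack, config.kalman_gain,
                                 config.kalman_variance)
        dff_polar = compute_dff(filtered, config.baseline_frames)
    else:
        dff_polar = dff
    polar = pol.polar_transform(dff_polar.data, stim.center, config.radial_step,
                                config.angular_samples, config.radial_limit,
                                config.pixel_size, config.frame_interval)
    grid = pol.grid_rois(polar, config.roi_side, config.radial_limit,
                         r_offset_um=stim.diameter / 2.0)
    events = pol.detect_roi_events(grid, config.baseline_frames,
                                   config.active_threshold,
                                   config.frame_interval)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # empty raster is a valid outcome here
        raster, roi_order = pol.build_raster(events, grid, T,
                                             config.frame_interval)
    front = pol.front_summary(events, stim.stimulation_frame
                              * config.frame_interval)

    result = AnalysisResult(metrics, events, raster, roi_order, front,
                            len(rois), shifts, area_mm2)
    if out_dir is not None:
        _persist(result, Path(out_dir), recording_id, condition, config)
    return result


def _persist(res: AnalysisResult, out: Path, recording_id: str,
             condition: str, config: RunConfig) -> None:
    out.mkdir(parents=True, exist_ok=True)
    if res.shifts is not None:
        pd.DataFrame(res.shifts, columns=["dx_px", "dy_px"]).to_csv(
            out / f"{recording_id}_shifts.csv", index_label="frame")
    res.events.to_csv(out / f"{recording_id}_events.csv", index=False)
    pd.DataFrame(res.raster).to_csv(out / f"{recording_id}_raster.csv",
                                    index=False)
    report = {
        "recording_id": recording_id,
        "condition": condition,
        "metrics": {k: (None if isinstance(v, float) and np.isnan(v) else v)
                    for k, v in res.metrics.as_row().items()},
        "n_cells_detected": res.n_cells_detected,
        "anisotropy_index": res.front.anisotropy_index,
        "config": config.to_dict(),
    }
    (out / f"{recording_id}_report.json").write_text(json.dumps(report, indent=1))


def run_compare(metrics: pd.DataFrame | str | Path, control: str = "control",
                out_dir: str | Path | None = None, make_figure: bool = False):
    """Summarize a metrics table and test each condition against control."""
    if not isinstance(metrics, pd.DataFrame):
        metrics = pd.read_csv(metrics)
    if metrics.empty:
        raise ValueError("metrics table is empty")
    drop = [c for c in ("recording_id",) if c in metrics.columns]
    summaries, tests = st.summarize_conditions(metrics.drop(columns=drop),
                                               control=control)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for s in summaries:
            for metric, r in s.metrics.iterrows():
                rows.append(dict(condition=s.condition, metric=metric, **r))
        pd.DataFrame(rows).to_csv(out / "condition_summary.csv", index=False)
        (out / "tests.json").write_text(json.dumps(
            {f"{c}:{m}": dataclasses.asdict(t) for (c, m), t in tests.items()},
            indent=1))
        if make_figure:
            _condition_figure(metrics, out / "condition_panels.png")
    return summaries, tests


def _condition_figure(metrics: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [("density_per_mm2", "active cells / mm$^2$"),
              ("distance_um", "propagation distance (μm)"),
              ("speed_um_s", "propagation speed (μm/s)"),
              ("amp_half_dff", "ΔF/F at half distance")]
    panels = [(c, l) for c, l in panels if c in metrics.columns]
    fig, axes = plt.subplots(1, len(panels), figsize=(3.2 * len(panels), 3.4))
    conditions = list(dict.fromkeys(metrics["condition"]))
    for ax, (col, label) in zip(np.atleast_1d(axes), panels):
        data = [metrics.loc[metrics["condition"] == c, col].dropna()
                for c in conditions]
        ax.boxplot(data, tick_labels=conditions, whis=(0, 100))
        ax.set_ylabel(label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_demo(out_dir: str | Path, seed: int = 0,
             n_per_condition: dict[str, int] | None = None,
             frame_count: int = 40, size: int = 256) -> pd.DataFrame:
    """Simulate a few recordings per condition, analyze and compare them.

    A scaled-down end-to-end exercise (smaller field and fewer recordings
    than the study's 13/16/14) that writes metrics, summaries and tests
    under ``out_dir`` and returns the metrics table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_per_condition = n_per_condition or {"control": 4, "suramin": 4,
                                          "caffeine": 4}
    rng = np.random.default_rng(seed)
    acq = sim.AcquisitionParams(frame_count=frame_count, height=size,
                                width=size)
    config = RunConfig(radial_limit=min(400.0, size / 2.0 - 10),
                       angular_samples=720, seed=seed)
    rows = []
    for cond, n in n_per_condition.items():
        preset = sim.condition_preset(cond)
        for i in range(n):
            stack, cells, truth, _ = sim.simulate_recording(
                preset, rng.integers(2**31), acq=acq)
            rec = f"{cond}_{i}"
            res = run_analyze(stack, config, out_dir=out / "recordings",
                              recording_id=rec, condition=cond)
            rows.append(res.metrics_row(rec, cond))
    metrics = pd.DataFrame(rows)
    metrics.to_csv(out / "metrics.csv", index=False)
    run_compare(metrics, out_dir=out, make_figure=True)
    return metrics
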