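"""Directionality analysis: polar ROI raster and leading/lagging fronts.

Transforms a wave movie into polar coordinates about the stimulus point,
tiles it with 70-um square ROIs out to 400 um, detects half-maximum event
times per ROI, and summarizes the leading and lagging fronts per distance
block.
"""

import numpy as np

import calwave as cw
from calwave import polar

dt = 1.0 / 1.2
cells = cw.generate_cell_field((512, 512), 3200.0, 11, min_separation=10.0)
stim = cw.StimulusSpec((256, 256), 25.0, 5)
wave = cw.WaveParams(velocity=25.0, max_extent=430.0, amplitude=0.8)
truth = cw.assign_onsets(cells, stim, wave, 12)
acq = cw.AcquisitionParams(frame_count=32, height=512, width=512,
                           gaussian_noise_sd=0.0, dark_margin_px=0)
stack = cw.render_stack(cells, truth, wave, acq, 13,
                        render_stimulus_artifact=False)

p = polar.polar_transform(stack.data, stim.center, radial_step_um=2.0,
                          angular_samples=360, r_max_um=400.0,
                          frame_interval=dt)
grid = polar.grid_rois(p, side_um=70.0, limit_um=400.0,
                       r_offset_um=stim.diameter / 2)
events = polar.detect_roi_events(grid, baseline_frames=5, min_amplitude=5.0,
                                 frame_interval=dt)
raster, _ = polar.build_raster(events, grid, stack.n_frames, dt)
fronts = polar.front_summary(events, stim_time_s=5 * dt)

print(f"{len(grid)} polar ROIs in {grid.n_blocks} distance blocks "
      f"(outer ROIs clipped by the frame are dropped), {len(events)} events")
print(fronts.per_block.to_string(index=False))
print(f"anisotropy index: {fronts.anisotropy_index:.3f} "
      f"(0 = perfectly isotropic)")
for b in sorted(fronts.leading):
    print(f"block {b}: leading front {len(fronts.leading[b])} ROIs, "
          f"lagging {len(fronts.lagging[b])}")
print("raster marks per frame:", np.asarray(raster.sum(axis=0)))
# Block medians increase with radius: the wave reaches distant blocks later.
# Events at or before the block median form the leading front; for this
# isotropic wave the per-angle mean delays agree closely, so the anisotropy
# index is near zero.
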