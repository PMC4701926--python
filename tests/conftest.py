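"""Shared fixtures: small synthetic scenes built programmatically."""

import numpy as np
import pytest

import calwave as cw


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_field(positions, field_size=(200.0, 200.0), baseline=600.0,
               radius=5.0, background=100.0):
    """Cell field at explicit positions with uniform brightness."""
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    n = len(positions)
    return cw.CellField(positions, np.full(n, radius), np.full(n, baseline),
                        background, field_size)


def render_wave(velocity=100.0, max_extent=150.0, amplitude=0.8,
                field=256, frames=24, noise_sd=0.0, drift=(0.0, 0.0),
                jitter=0.0, soma_density=4000.0, seed=0, margin=0,
                stimulus_artifact=False):
    """Small isotropic evoked-wave recording with ground truth."""
    acq = cw.AcquisitionParams(frame_count=frames, height=field, width=field,
                               gaussian_noise_sd=noise_sd,
                               drift_per_frame=drift, dark_margin_px=margin)
    cells = cw.generate_cell_field((field, field), soma_density, seed,
                                   min_separation=10.0)
    stim = cw.StimulusSpec((field / 2.0, field / 2.0), 25.0, 5)
    wave = cw.WaveParams(velocity=velocity, max_extent=max_extent,
                         amplitude=amplitude, onset_jitter_sd=jitter)
    truth = cw.assign_onsets(cells, stim, wave, seed + 1)
    stack = cw.render_stack(cells, truth, wave, acq, seed + 2,
                            render_stimulus_artifact=stimulus_artifact)
    return stack, cells, truth, wave, acq


@pytest.fixture(scope="session")
def isotropic_recording():
    """Noiseless isotropic wave reused by metrics/polar/raster tests."""
    return render_wave(velocity=50.0, max_extent=110.0, field=256,
                       frames=24, seed=7)
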