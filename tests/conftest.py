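"""Shared fixtures and independent test oracles.

The oracles here deliberately avoid the package's Siddon path: chord lengths
come from analytic slab clipping, line integrals from dense midpoint
sampling of the piecewise-constant attenuation field.
"""

from __future__ import annotations

import numpy as np
import pytest

import priorphase as pp


# ----------------------------------------------------------------- oracles
def box_chord_length(volume: pp.VoxelVolume, src, dst) -> float:
    """Analytic chord length of segment src->dst through the volume box."""
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    low, high = volume.bounds()
    d = dst - src
    tmin, tmax = 0.0, 1.0
    for a in range(3):
        if d[a] != 0.0:
            t0 = (low[a] - src[a]) / d[a]
            t1 = (high[a] - src[a]) / d[a]
            t0, t1 = min(t0, t1), max(t0, t1)
            tmin = max(tmin, t0)
            tmax = min(tmax, t1)
        elif src[a] <= low[a] or src[a] >= high[a]:
            return 0.0
    if tmax <= tmin:
        return 0.0
    return float((tmax - tmin) * np.linalg.norm(d))


def sampled_line_integral(volume: pp.VoxelVolume, src, dst, step_frac: float = 0.001) -> float:
    """Midpoint-rule quadrature of the attenuation field along src->dst.

    ``step_frac`` is the sampling step as a fraction of the smallest voxel
    spacing (default spacing/1000, keeping the quadrature error well below
    the 1e-3 comparison tolerance even for short chords).
    """
    src = np.asarray(src, float)
    dst = np.asarray(dst, float)
    length = float(np.linalg.norm(dst - src))
    step = step_frac * min(volume.spacing)
    n = max(int(np.ceil(length / step)), 1)
    t = (np.arange(n) + 0.5) / n
    pts = src[None, :] + t[:, None] * (dst - src)[None, :]
    low, _ = volume.bounds()
    idx = np.floor((pts - low[None, :]) / np.asarray(volume.spacing)[None, :]).astype(int)
    inside = np.all((idx >= 0) & (idx < np.asarray(volume.shape)[None, :]), axis=1)
    vals = np.zeros(n)
    ii = idx[inside]
    vals[inside] = volume.values[ii[:, 0], ii[:, 1], ii[:, 2]]
    return float(vals.sum() * length / n)


# ---------------------------------------------------------------- fixtures
def tiny_config(**overrides) -> pp.ExperimentConfig:
    """Desk-scale experiment: coarse phantom + 32x32 panel, 60-frame arc."""
    kwargs = dict(
        phantom=pp.PhantomSpec(grid_shape=(32, 32, 32), spacing=(6.0, 6.0, 6.0)),
        detector_pixels=(32, 32),
        pixel_pitch=(12.8, 12.8),
        treatment_n_frames=60,
        prior_n_frames=100,
        noise_photons=None,
        seed=0,
    )
    kwargs.update(overrides)
    return pp.ExperimentConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_bench():
    """Noiseless end-to-end run of the tiny experiment (shared, read-only)."""
    cfg = tiny_config()
    report, art = pp.run_experiment(cfg)
    return cfg, report, art


@pytest.fixture(scope="session")
def default_noiseless_bench():
    """Noiseless run at the default study conditions (128x128 panel, 210 frames)."""
    cfg = pp.ExperimentConfig(noise_photons=None, seed=0)
    report, art = pp.run_experiment(cfg)
    return cfg, report, art


@pytest.fixture(scope="session")
def small_random_volume():
    rng = np.random.default_rng(42)
    return pp.VoxelVolume(rng.uniform(0.0, 1.0, (32, 32, 32)), spacing=(1.5, 1.1, 0.8))
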