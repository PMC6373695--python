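"""Cone-beam forward projection: Beer-Lambert line integrals through a volume.

Each detector pixel i records ``P_i = P_o * exp(-sum_j a_ij f_j)`` where
``f_j`` is the attenuation coefficient of voxel j and ``a_ij`` the exact
length of the source-to-pixel ray inside that voxel.  The per-voxel lengths
come from a Siddon-style parametric voxel walk: :func:`trace_ray` exposes
the explicit path for a single ray, while :func:`forward_project` evaluates
whole detector grids through a compiled kernel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._siddon import siddon_integrals
from .geometry import ConeBeamGeometry
from .volume import VoxelVolume

__all__ = [
    "RayPath",
    "ProjectionImage",
    "ProjectionSeries",
    "trace_ray",
    "line_integral",
    "forward_project",
    "add_noise",
    "log_transform",
]

logger = logging.getLogger(__name__)


@dataclass
class RayPath:
    """Ordered voxel visits of one ray: indices and intersection lengths [mm]."""

    voxel_indices: np.ndarray  # (n, 3) int
    lengths: np.ndarray  # (n,) mm

    def __post_init__(self) -> None:
        self.voxel_indices = np.asarray(self.voxel_indices, dtype=np.intp).reshape(-1, 3)
        self.lengths = np.asarray(self.lengths, dtype=float).reshape(-1)
        if len(self.voxel_indices) != len(self.lengths):
            raise ValueError("voxel_indices and lengths must have equal length")
        if np.any(self.lengths < 0):
            raise ValueError("intersection lengths must be non-negative")

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())


@dataclass
class ProjectionImage:
    """One detector frame: intensities P_i plus acquisition metadata."""

    intensities: np.ndarray  # (nv, nu) or ROI-sized
    angle: float
    timestamp: float = 0.0
    source_intensity: float = 1.0
    true_phase: int | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2D")


@dataclass
class ProjectionSeries:
    """Stack of frames with per-frame angle/time and optional phase labels."""

    frames: np.ndarray  # (n, nv, nu)
    angles: np.ndarray  # deg
    times: np.ndarray  # s
    source_intensity: float = 1.0
    geometry: ConeBeamGeometry | None = None
    true_phases: np.ndarray | None = None
    is_log: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n, nv, nu)")
        n = len(self.frames)
        if len(self.angles) != n or len(self.times) != n:
            raise ValueError("angles/times must match frame count")
        if self.true_phases is not None:
            self.true_phases = np.asarray(self.true_phases)
            if len(self.true_phases) != n:
                raise ValueError("true_phases must match frame count")

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> ProjectionImage:
        return ProjectionImage(
            intensities=self.frames[i],
            angle=float(self.angles[i]),
            timestamp=float(self.times[i]),
            source_intensity=self.source_intensity,
            true_phase=None if self.true_phases is None else int(self.true_phases[i]),
        )

    def subset(self, mask: np.ndarray) -> "ProjectionSeries":
        mask = np.asarray(mask)
        return ProjectionSeries(
            frames=self.frames[mask],
            angles=self.angles[mask],
            times=self.times[mask],
            source_intensity=self.source_intensity,
            geometry=self.geometry,
            true_phases=None if self.true_phases is None else self.true_phases[mask],
            is_log=self.is_log,
        )


def trace_ray(volume: VoxelVolume, src, dst) -> RayPath:
    """Exact per-voxel intersection lengths of the segment src -> dst.

    Returns an empty path when the segment misses the volume's bounding box.
    The source must lie outside the box (rays originate at the X-ray focus).
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if np.allclose(src, dst):
        raise ValueError("src and dst must differ")
    low, high = volume.bounds()
    if np.all(src > low) and np.all(src < high):
        raise ValueError("ray source must lie outside the volume bounding box")
    d = dst - src
    length = float(np.linalg.norm(d))
    tmin, tmax = 0.0, 1.0
    for a in range(3):
        if d[a] != 0.0:
            t0 = (low[a] - src[a]) / d[a]
            t1 = (high[a] - src[a]) / d[a]
            t0, t1 = min(t0, t1), max(t0, t1)
            tmin = max(tmin, t0)
            tmax = min(tmax, t1)
        elif src[a] <= low[a] or src[a] >= high[a]:
            return RayPath(np.empty((0, 3), dtype=np.intp), np.empty(0))
    if tmax <= tmin:
        return RayPath(np.empty((0, 3), dtype=np.intp), np.empty(0))

    # all axis-plane crossings inside (tmin, tmax), then segment midpoints
    ts = [np.array([tmin, tmax])]
    for a in range(3):
        if d[a] == 0.0:
            continue
        planes = low[a] + np.arange(volume.shape[a] + 1) * volume.spacing[a]
        alpha = (planes - src[a]) / d[a]
        ts.append(alpha[(alpha > tmin) & (alpha < tmax)])
    t = np.unique(np.concatenate(ts))
    mids = src[None, :] + 0.5 * (t[:-1] + t[1:])[:, None] * d[None, :]
    idx = np.floor((mids - low[None, :]) / np.asarray(volume.spacing)[None, :]).astype(np.intp)
    idx = np.clip(idx, 0, np.asarray(volume.shape) - 1)
    lengths = np.diff(t) * length
    keep = lengths > 1e-12
    return RayPath(idx[keep], lengths[keep])


def line_integral(path: RayPath, volume: VoxelVolume) -> float:
    """Evaluate sum_j a_ij f_j along a traced path."""
    if len(path.lengths) == 0:
        return 0.0
    idx = path.voxel_indices
    shape = np.asarray(volume.shape)
    if np.any(idx < 0) or np.any(idx >= shape[None, :]):
        raise IndexError("ray path contains voxel indices outside the volume")
    return float(np.dot(path.lengths, volume.values[idx[:, 0], idx[:, 1], idx[:, 2]]))


def _integral_grid(volume: VoxelVolume, geometry: ConeBeamGeometry, angle: float,
                   roi=None) -> np.ndarray:
    """Line integrals for every requested detector pixel at one angle."""
    src = geometry.source_position(angle)
    centers = geometry.pixel_centers(angle, roi=roi)
    shape = centers.shape[:2]
    dst = np.ascontiguousarray(centers.reshape(-1, 3), dtype=np.float64)
    out = np.empty(len(dst), dtype=np.float64)
    low, _ = volume.bounds()
    siddon_integrals(
        volume.values,
        low[0], low[1], low[2],
        volume.spacing[0], volume.spacing[1], volume.spacing[2],
        float(src[0]), float(src[1]), float(src[2]),
        dst, out,
    )
    return out.reshape(shape)


def forward_project(
    volume: VoxelVolume,
    geometry: ConeBeamGeometry,
    angle: float,
    source_intensity: float = 1.0,
    roi=None,
    timestamp: float = 0.0,
    true_phase: int | None = None,
) -> ProjectionImage:
    """Cone-beam projection of a volume at one gantry angle.

    Every pixel holds ``P_o * exp(-line integral)`` for the ray from the
    source to the pixel center.  ``roi`` restricts computation to a detector
    rectangle (used for template generation).
    """
    if source_intensity <= 0:
        raise ValueError("source_intensity must be positive")
    g = _integral_grid(volume, geometry, angle, roi=roi)
    return ProjectionImage(
        intensities=source_intensity * np.exp(-g),
        angle=float(angle),
        timestamp=timestamp,
        source_intensity=float(source_intensity),
        true_phase=true_phase,
    )


def add_noise(projection: ProjectionImage, photons_per_pixel_at_p0: float,
              seed: int = 0) -> ProjectionImage:
    """Poisson detector noise at a given fluence.

    The noiseless intensity is scaled so that an unattenuated pixel receives
    ``photons_per_pixel_at_p0`` expected photons, resampled from a Poisson
    law, and rescaled back to intensity units.
    """
    if photons_per_pixel_at_p0 <= 0:
        raise ValueError("photon count must be positive")
    rng = np.random.default_rng(seed)
    lam = projection.intensities / projection.source_intensity * photons_per_pixel_at_p0
    counts = rng.poisson(np.clip(lam, 0.0, None))
    noisy = counts * (projection.source_intensity / photons_per_pixel_at_p0)
    return ProjectionImage(
        intensities=noisy,
        angle=projection.angle,
        timestamp=projection.timestamp,
        source_intensity=projection.source_intensity,
        true_phase=projection.true_phase,
    )


def log_transform(projection: ProjectionImage, floor: float = 1e-9) -> np.ndarray:
    """Recover line integrals ``-ln(P_i / P_o)`` from detector intensities.

    Non-positive pixels (possible after Poisson noise) are clamped to
    ``floor * P_o`` with a logged warning.
    """
    p = projection.intensities
    if np.any(p <= 0):
        logger.warning("log_transform: clamping %d non-positive pixels", int((p <= 0).sum()))
        p = np.clip(p, floor * projection.source_intensity, None)
    return -np.log(p / projection.source_intensity)
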