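"""Digital 4D thorax phantom and parametric breathing traces.

The phantom is deliberately simple: an ellipsoidal soft-tissue body, two
low-attenuation ellipsoidal lungs, a high-attenuation diaphragm dome whose
edge gives the Amsterdam-Shroud baseline something to track, and a mobile
spherical tumor.  Tumor and diaphragm translate rigidly along one axis,
driven by an even-power-cosine breathing trace whose long dwell at peak
exhale mimics real quiet breathing.  Every simulated frame therefore has a
known ground-truth respiratory phase, which replaces human visual
verification when scoring phase recognition.

Phase convention (fixed): the respiratory cycle is split into 10 equal-
duration bins; phase 1 starts at peak exhale (displacement minimum) and
phase 6 covers peak inhale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import VoxelVolume

__all__ = [
    "PhantomSpec",
    "RespiratoryTrace",
    "Phantom4D",
    "generate_trace",
    "render_volume",
    "render_4d",
    "phase_bin_displacements",
]


@dataclass
class PhantomSpec:
    """Geometry and attenuation of the breathing thorax phantom.

    All lengths in mm, attenuation coefficients in 1/mm.  ``tumor_center``
    and ``diaphragm_z`` are *reference* (peak-exhale) positions; during the
    cycle both translate by ``displacement * motion_axis`` with displacement
    in ``[0, motion_amplitude]``.
    """

    body_half_axes: tuple[float, float, float] = (85.0, 65.0, 92.0)
    body_mu: float = 0.02
    lung_regions: tuple = (
        ((45.0, 0.0, 10.0), (32.0, 40.0, 60.0), 0.004),
        ((-45.0, 0.0, 10.0), (32.0, 40.0, 60.0), 0.004),
    )
    tumor_center: tuple[float, float, float] = (45.0, 0.0, 15.0)
    tumor_radius: float = 10.0
    tumor_mu: float = 0.025
    diaphragm_z: float = -15.0
    diaphragm_mu: float = 0.022
    motion_amplitude: float = 10.0
    motion_axis: tuple[float, float, float] = (0.0, 0.0, -1.0)
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        if any(n < 8 for n in self.grid_shape):
            raise ValueError("grid_shape must be at least 8 voxels per axis")
        if min(self.spacing) <= 0:
            raise ValueError("spacing must be positive")
        mus = [self.body_mu, self.tumor_mu, self.diaphragm_mu] + [r[2] for r in self.lung_regions]
        if any(m < 0 for m in mus):
            raise ValueError("attenuation coefficients must be non-negative")
        if self.motion_amplitude < 0:
            raise ValueError("motion_amplitude must be non-negative")
        axis = np.asarray(self.motion_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("motion_axis must be a non-zero vector")
        self.motion_axis = tuple(axis / norm)

    # diaphragm dome: upper half of an ellipsoid whose apex sits at
    # diaphragm_z inside the first lung region, moving with the tumor
    @property
    def _dome_params(self) -> tuple[np.ndarray, np.ndarray]:
        center, half, _mu = self.lung_regions[0]
        dome_half = np.array([half[0] * 1.05, half[1] * 1.05, 28.0])
        dome_center = np.array([center[0], center[1], self.diaphragm_z - dome_half[2]])
        return dome_center, dome_half

    def tumor_in_lung(self, displacement: float) -> bool:
        """Conservative check that the displaced tumor sphere fits a lung."""
        c = np.asarray(self.tumor_center) + displacement * np.asarray(self.motion_axis)
        r = self.tumor_radius
        for center, half, _mu in self.lung_regions:
            shrunk = np.asarray(half) - r
            if np.any(shrunk <= 0):
                continue
            q = np.sum(((c - np.asarray(center)) / shrunk) ** 2)
            if q <= 1.0:
                return True
        return False


@dataclass
class RespiratoryTrace:
    """Sampled cranio-caudal breathing displacement.

    ``displacement`` is 0 at peak exhale and grows toward peak inhale.
    """

    times: np.ndarray
    displacement: np.ndarray
    period: float
    model_name: str = "cospow"
    seed: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.times.shape != self.displacement.shape:
            raise ValueError("times and displacement must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class Phantom4D:
    """One volume per respiratory phase bin (phase 1 = peak exhale)."""

    volumes: list
    phase_displacements: np.ndarray | None = None
    spec: PhantomSpec | None = None

    def __post_init__(self) -> None:
        if len(self.volumes) == 0:
            raise ValueError("Phantom4D needs at least one volume")
        v0 = self.volumes[0]
        if not all(v.same_grid(v0) for v in self.volumes[1:]):
            raise ValueError("all phase volumes must share grid shape/spacing/origin")
        if self.phase_displacements is not None:
            self.phase_displacements = np.asarray(self.phase_displacements, dtype=float)
            if len(self.phase_displacements) != len(self.volumes):
                raise ValueError("phase_displacements length must match volume count")

    @property
    def n_phases(self) -> int:
        return len(self.volumes)


def _cospow(t: np.ndarray, period: float, amplitude: float, power: int) -> np.ndarray:
    return amplitude * (1.0 - np.cos(np.pi * t / period) ** (2 * power))


def generate_trace(
    period: float = 4.0,
    amplitude: float = 10.0,
    duration: float = 40.0,
    dt: float = 0.18,
    model: str = "cospow",
    irregularity: float = 0.0,
    seed: int = 0,
    power: int = 2,
) -> RespiratoryTrace:
    """Generate a breathing displacement trace.

    The default model is the even-power cosine
    ``d(t) = A * (1 - cos^(2n)(pi t / T))`` with ``n = 2``, which dwells at
    peak exhale the way quiet breathing does.  ``irregularity`` scales
    per-cycle jitter of the period (uniform +-irregularity) and a per-cycle
    amplitude reduction (uniform [0, irregularity]), keeping displacement
    inside ``[0, amplitude]``.

    Parameters
    ----------
    period, amplitude, duration, dt :
        Nominal cycle length [s], peak-to-peak excursion [mm], trace length
        [s] and sampling step [s].
    irregularity : float
        Cycle-to-cycle variability fraction in [0, 0.5].
    seed : int
        Seed for the jitter; the trace is deterministic for a fixed seed.
    power : int
        Half the cosine exponent ``n``.
    """
    if period <= 0 or dt <= 0 or duration <= 0:
        raise ValueError("period, dt and duration must be positive")
    if duration < period:
        raise ValueError("duration must cover at least one cycle")
    if not (0.0 <= irregularity <= 0.5):
        raise ValueError("irregularity must lie in [0, 0.5]")
    if model != "cospow":
        raise ValueError(f"unknown breathing model {model!r}")

    times = np.arange(0.0, duration + 0.5 * dt, dt)
    rng = np.random.default_rng(seed)
    if irregularity == 0.0:
        disp = _cospow(times, period, amplitude, power)
    else:
        # build jittered cycles until the trace is covered
        starts = [0.0]
        periods: list[float] = []
        amps: list[float] = []
        while starts[-1] <= times[-1]:
            periods.append(period * (1.0 + irregularity * rng.uniform(-1.0, 1.0)))
            amps.append(amplitude * (1.0 - irregularity * rng.uniform(0.0, 1.0)))
            starts.append(starts[-1] + periods[-1])
        starts_arr = np.asarray(starts[:-1])
        idx = np.clip(np.searchsorted(starts_arr, times, side="right") - 1, 0, len(periods) - 1)
        local = times - starts_arr[idx]
        disp = np.array(
            [_cospow(tl, periods[k], amps[k], power) for tl, k in zip(local, idx)]
        )
    disp = np.clip(disp, 0.0, amplitude)
    return RespiratoryTrace(times=times, displacement=disp, period=period,
                            model_name=model, seed=seed)


def render_volume(spec: PhantomSpec, displacement: float = 0.0,
                  soft: bool = True) -> VoxelVolume:
    """Rasterize the phantom at one breathing displacement.

    Each voxel takes the attenuation of the innermost enclosing structure
    (tumor > diaphragm > lung > body > background 0).  Tumor and diaphragm
    are translated by ``displacement`` along ``motion_axis``; body and lungs
    are static.

    With ``soft=True`` (default) boundary voxels carry a partial-volume
    blend over a half-voxel-wide transition band, so the rendered volume
    depends continuously on displacement (sub-voxel motion changes the
    volume, as it does in real CT).  ``soft=False`` gives hard binary
    membership at voxel centers.
    """
    if not (0.0 <= displacement <= max(spec.motion_amplitude, 0.0) + 1e-9):
        raise ValueError(
            f"displacement {displacement} outside [0, {spec.motion_amplitude}]"
        )
    if not spec.tumor_in_lung(displacement):
        raise ValueError("tumor sphere leaves the lung at this displacement")

    vol = VoxelVolume(
        values=np.zeros(spec.grid_shape),
        spacing=spec.spacing,
    )
    X, Y, Z = vol.meshgrid()
    shift = displacement * np.asarray(spec.motion_axis)
    width = float(np.mean(spec.spacing))  # transition band of the soft edge

    def occupancy(signed_dist: np.ndarray) -> np.ndarray:
        if soft:
            return np.clip(0.5 - signed_dist / width, 0.0, 1.0)
        return (signed_dist <= 0.0).astype(float)

    def ellipsoid_dist(center, half) -> np.ndarray:
        # approximate signed distance: (s - 1) / |grad s| with s the
        # normalized ellipsoidal radius
        dx = (X - center[0]) / half[0]
        dy = (Y - center[1]) / half[1]
        dz = (Z - center[2]) / half[2]
        s = np.sqrt(dx * dx + dy * dy + dz * dz)
        g = np.sqrt((dx / half[0]) ** 2 + (dy / half[1]) ** 2 + (dz / half[2]) ** 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(g > 1e-12, (s - 1.0) * s / np.maximum(g, 1e-12), -min(half))
        return d

    def composite(values, frac, mu):
        return values * (1.0 - frac) + mu * frac

    values = vol.values
    values = composite(values, occupancy(ellipsoid_dist((0.0, 0.0, 0.0), spec.body_half_axes)), spec.body_mu)
    lung_occ = np.zeros_like(values)
    for center, half, mu in spec.lung_regions:
        f = occupancy(ellipsoid_dist(center, half))
        values = composite(values, f, mu)
        lung_occ = np.maximum(lung_occ, f)
    dome_center, dome_half = spec._dome_params
    dc = dome_center + shift
    f_dome = np.minimum(
        occupancy(ellipsoid_dist(dc, dome_half)),
        occupancy(Z - (dc[2] + dome_half[2])),
    )
    f_dome = np.minimum(f_dome, lung_occ)  # the dome edge lives inside the lung
    values = composite(values, f_dome, spec.diaphragm_mu)
    tc = np.asarray(spec.tumor_center) + shift
    d_tumor = np.sqrt((X - tc[0]) ** 2 + (Y - tc[1]) ** 2 + (Z - tc[2]) ** 2) - spec.tumor_radius
    values = composite(values, occupancy(d_tumor), spec.tumor_mu)
    vol.values[...] = values
    return vol


def phase_bin_displacements(
    spec_or_amplitude, period: float = 4.0, n_phases: int = 10, power: int = 2,
    n_samples: int = 1000,
) -> np.ndarray:
    """Mean displacement of each phase bin over one noiseless cycle.

    Bins are left-closed equal-duration tenths of the cycle starting at peak
    exhale.  Computed by discrete sampling; with the symmetric cosine model
    the peak-inhale sample falls in bin 6, so phase 6 carries the maximum.
    """
    amplitude = (
        spec_or_amplitude.motion_amplitude
        if isinstance(spec_or_amplitude, PhantomSpec)
        else float(spec_or_amplitude)
    )
    t = np.arange(n_samples) * (period / n_samples)
    d = _cospow(t, period, amplitude, power)
    bins = np.minimum((n_phases * t / period).astype(int), n_phases - 1)
    return np.array([d[bins == k].mean() for k in range(n_phases)])


def render_4d(spec: PhantomSpec, n_phases: int = 10, period: float = 4.0,
              power: int = 2, soft: bool = True) -> Phantom4D:
    """Render the phantom at the mean displacement of each phase bin.

    Returns 10 volumes ordered phase 1 (peak exhale) to phase 10.
    """
    disps = phase_bin_displacements(spec, period=period, n_phases=n_phases, power=power)
    volumes = [render_volume(spec, d, soft=soft) for d in disps]
    return Phantom4D(volumes=volumes, phase_displacements=disps, spec=spec)
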