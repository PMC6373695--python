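"""FDK filtered backprojection for circular cone-beam data.

Standard flat-panel FDK: detector coordinates are rescaled to a virtual
detector through the isocenter, intensities are log-transformed to line
integrals, cosine pre-weighted, redundancy weighted (1/2 on a full circle,
generalized Parker weights on a short scan), ramp filtered row-wise in the
frequency domain (spatial-domain Ram-Lak kernel, optional Hann apodization),
and backprojected with bilinear detector interpolation and the usual
``sad^2 / U^2`` distance weight.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.fft

from .geometry import ConeBeamGeometry
from .phantom import Phantom4D
from .projector import ProjectionSeries, log_transform
from .volume import VoxelVolume

__all__ = ["fdk_reconstruct", "reconstruct_4d"]

logger = logging.getLogger(__name__)


def _ramp_filter_freq(n_pad: int, du: float, hann: bool) -> np.ndarray:
    """Frequency response of the band-limited ramp (Kak-Slaney spatial kernel)."""
    k = np.arange(n_pad)
    k = np.minimum(k, n_pad - k)  # signed sample offsets, wrapped
    h = np.zeros(n_pad)
    h[0] = 1.0 / (4.0 * du**2)
    odd = k % 2 == 1
    h[odd] = -1.0 / (np.pi * k[odd] * du) ** 2
    H = np.real(scipy.fft.fft(h))
    if hann:
        f = np.fft.fftfreq(n_pad)
        H *= 0.5 * (1.0 + np.cos(2.0 * np.pi * f))
    return H


def _parker_weights(beta: float, gamma: np.ndarray, span: float) -> np.ndarray:
    """Generalized Parker redundancy weights for a short scan.

    ``beta`` is the view angle from scan start, ``gamma`` the per-column fan
    angle, ``span`` the total angular coverage (all radians).  The half
    over-scan ``delta = (span - pi)/2`` plays the role of the half fan angle.
    """
    delta = max((span - np.pi) / 2.0, 1e-6)
    w = np.ones_like(gamma)
    up = beta < 2.0 * (delta - gamma)
    arg = np.clip(beta / np.maximum(2.0 * (delta - gamma), 1e-9), 0.0, 1.0)
    w[up] = np.sin(np.pi / 4.0 * 2.0 * arg[up]) ** 2
    down = beta > np.pi - 2.0 * gamma
    arg2 = np.clip(
        (np.pi + 2.0 * delta - beta) / np.maximum(2.0 * (delta + gamma), 1e-9), 0.0, 1.0
    )
    w[down] = np.sin(np.pi / 4.0 * 2.0 * arg2[down]) ** 2
    return w


def _filtered_projections(series: ProjectionSeries, geometry: ConeBeamGeometry,
                          hann: bool):
    """Cosine-weight, redundancy-weight and ramp-filter every frame."""
    R, D = geometry.sad, geometry.sdd
    u, v = geometry.pixel_coords()
    u_iso = u * R / D
    v_iso = v * R / D
    du_iso = geometry.pixel_pitch[0] * R / D
    cosw = R / np.sqrt(R**2 + u_iso[None, :] ** 2 + v_iso[:, None] ** 2)

    angles = np.deg2rad(series.angles)
    order = np.argsort(angles)
    span = float(angles.max() - angles.min())
    n_views = len(series)
    dbeta = span / max(n_views - 1, 1) if n_views > 1 else 2.0 * np.pi
    full_scan = span >= 2.0 * np.pi - 1.5 * dbeta
    gamma = np.arctan(u_iso / R)
    gamma_half = float(np.abs(gamma).max())
    if not full_scan and span < np.pi + 2.0 * gamma_half:
        logger.warning(
            "angular span %.1f deg below 180 deg + fan; limited-angle artifacts expected",
            np.rad2deg(span),
        )

    nu = len(u_iso)
    n_pad = 1 << int(np.ceil(np.log2(max(2 * nu, 64))))
    H = _ramp_filter_freq(n_pad, du_iso, hann)

    filtered = np.empty_like(series.frames)
    for i in range(n_views):
        if series.is_log:
            g = series.frames[i]
        else:
            g = log_transform(series[i])
        g = g * cosw
        if full_scan:
            g = g * 0.5
        else:
            beta = float(angles[i] - angles.min())
            g = g * _parker_weights(beta, gamma, span)[None, :]
        G = scipy.fft.fft(g, n=n_pad, axis=1)
        q = np.real(scipy.fft.ifft(G * H[None, :], axis=1))[:, :nu] * du_iso
        filtered[i] = q
    return filtered, u_iso, v_iso, angles, order


def fdk_reconstruct(
    projections: ProjectionSeries,
    geometry: ConeBeamGeometry,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    origin=None,
    hann: bool = True,
) -> VoxelVolume:
    """Reconstruct a 3D attenuation volume from cone-beam projections.

    Raw intensity frames are log-transformed automatically; frames already
    holding line integrals (``series.is_log``) are used as-is.

    Parameters
    ----------
    projections : ProjectionSeries
    geometry : ConeBeamGeometry
    shape, spacing, origin :
        Output grid (see :class:`VoxelVolume` conventions).
    hann : bool
        Apply a Hann window on top of the ramp filter (noise robustness).
    """
    if len(projections) < 2:
        raise ValueError("need at least 2 projections for reconstruction")
    filtered, u_iso, v_iso, angles, order = _filtered_projections(
        projections, geometry, hann
    )
    R = geometry.sad
    out = VoxelVolume(values=np.zeros(shape), spacing=spacing, origin=origin)
    X, Y, Z = out.meshgrid()
    X = X.reshape(-1)
    Y = Y.reshape(-1)
    Z = Z.reshape(-1)
    acc = np.zeros(X.shape)

    sorted_angles = angles[order]
    # per-view angular weight (trapezoid on the sorted angle grid)
    if len(sorted_angles) > 1:
        gaps = np.diff(sorted_angles)
        dbeta = np.empty_like(sorted_angles)
        dbeta[0] = gaps[0]
        dbeta[-1] = gaps[-1]
        dbeta[1:-1] = 0.5 * (gaps[:-1] + gaps[1:])
        dbeta = np.clip(dbeta, 0.0, None)
    else:
        dbeta = np.array([2.0 * np.pi])

    u0, v0 = float(u_iso[0]), float(v_iso[0])
    du = float(u_iso[1] - u_iso[0])
    dv = float(v_iso[1] - v_iso[0])
    nv, nu = filtered.shape[1:]
    for j, i in enumerate(order):
        th = angles[i]
        sin_t, cos_t = np.sin(th), np.cos(th)
        L = R + X * sin_t - Y * cos_t  # distance along the central axis
        L = np.maximum(L, 1e-6)
        ut = R * (X * cos_t + Y * sin_t) / L
        vt = R * Z / L
        fu = (ut - u0) / du
        fv = (vt - v0) / dv
        iu = np.clip(np.floor(fu).astype(np.intp), 0, nu - 2)
        iv = np.clip(np.floor(fv).astype(np.intp), 0, nv - 2)
        wu = np.clip(fu - iu, 0.0, 1.0)
        wv = np.clip(fv - iv, 0.0, 1.0)
        inside = (fu >= 0) & (fu <= nu - 1) & (fv >= 0) & (fv <= nv - 1)
        q = filtered[i]
        val = (
            q[iv, iu] * (1 - wu) * (1 - wv)
            + q[iv, iu + 1] * wu * (1 - wv)
            + q[iv + 1, iu] * (1 - wu) * wv
            + q[iv + 1, iu + 1] * wu * wv
        )
        acc += np.where(inside, val, 0.0) * (R**2 / L**2) * dbeta[j]
    out.values[...] = np.clip(acc.reshape(shape), 0.0, None)
    return out


def reconstruct_4d(
    projections: ProjectionSeries,
    geometry: ConeBeamGeometry,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    origin=None,
    n_phases: int = 10,
    hann: bool = True,
) -> Phantom4D:
    """Phase-sorted reconstruction: one FDK volume per respiratory phase bin.

    Every projection must carry a phase label in 1..n_phases; each phase is
    reconstructed from its own (angularly sparse) subset.
    """
    if projections.true_phases is None:
        raise ValueError("projections must carry phase labels for 4D reconstruction")
    phases = np.asarray(projections.true_phases, dtype=int)
    if phases.min() < 1 or phases.max() > n_phases:
        raise ValueError(f"phase labels must lie in 1..{n_phases}")
    volumes = []
    for k in range(1, n_phases + 1):
        mask = phases == k
        n_k = int(mask.sum())
        if n_k < 3:
            logger.warning("phase %d has only %d projections", k, n_k)
        if n_k == 0:
            raise ValueError(f"phase {k} has no projections")
        volumes.append(
            fdk_reconstruct(projections.subset(mask), geometry, shape, spacing,
                            origin=origin, hann=hann)
        )
    return Phantom4D(volumes=volumes)
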