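"""Isocentric circular cone-beam geometry.

Convention (fixed for the whole package): the gantry rotates in the axial
(x, y) plane; world z is the cranio-caudal axis.  At gantry angle ``theta``
(degrees) the X-ray source sits at ``(-sad*sin(theta), sad*cos(theta), 0)``
(angle 0 = anterior) and the flat-panel detector is orthogonal to the
source-isocenter axis at distance ``sdd`` from the source.  Detector ``u``
runs laterally (unit vector ``(cos theta, sin theta, 0)``) and ``v`` runs
cranio-caudally (world ``+z``).  Detector images are stored as ``(nv, nu)``
arrays (rows = cranio-caudal position).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ConeBeamGeometry"]


@dataclass
class ConeBeamGeometry:
    """Source/detector layout of an isocentric circular cone-beam scanner.

    Parameters
    ----------
    sad : float
        Source-to-isocenter distance [mm].
    sdd : float
        Source-to-detector distance [mm]; must exceed ``sad``.
    detector_pixels : tuple of int
        ``(nu, nv)`` pixel counts (lateral, cranio-caudal).
    pixel_pitch : tuple of float
        ``(du, dv)`` pixel size [mm].
    angles : ndarray, optional
        Gantry angles [deg] of a planned acquisition, within [-180, 180].
    detector_offset : tuple of float
        ``(u0, v0)`` lateral/cranio-caudal shift [mm] of the panel center.
    """

    sad: float = 1000.0
    sdd: float = 1536.0
    detector_pixels: tuple[int, int] = (256, 256)
    pixel_pitch: tuple[float, float] = (1.6, 1.6)
    angles: np.ndarray = field(default_factory=lambda: np.array([], dtype=float))
    detector_offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.sad < self.sdd):
            raise ValueError(f"require 0 < sad < sdd, got sad={self.sad}, sdd={self.sdd}")
        nu, nv = self.detector_pixels
        if nu < 16 or nv < 16:
            raise ValueError("detector must be at least 16 pixels per axis")
        if min(self.pixel_pitch) <= 0:
            raise ValueError("pixel pitch must be positive")
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.size and (self.angles.min() < -180.0 or self.angles.max() > 180.0):
            raise ValueError("gantry angles must lie in [-180, 180] degrees")

    @property
    def magnification(self) -> float:
        """Geometric magnification of an object at the isocenter."""
        return self.sdd / self.sad

    def source_position(self, angle_deg: float) -> np.ndarray:
        th = np.deg2rad(angle_deg)
        return np.array([-self.sad * np.sin(th), self.sad * np.cos(th), 0.0])

    def detector_axes(self, angle_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (u_hat, v_hat, w_hat): detector axes and source->detector direction."""
        th = np.deg2rad(angle_deg)
        u_hat = np.array([np.cos(th), np.sin(th), 0.0])
        v_hat = np.array([0.0, 0.0, 1.0])
        w_hat = np.array([np.sin(th), -np.cos(th), 0.0])
        return u_hat, v_hat, w_hat

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical detector coordinates (u [mm] per column, v [mm] per row)."""
        nu, nv = self.detector_pixels
        du, dv = self.pixel_pitch
        u0, v0 = self.detector_offset
        u = (np.arange(nu) - (nu - 1) / 2.0) * du + u0
        v = (np.arange(nv) - (nv - 1) / 2.0) * dv + v0
        return u, v

    def pixel_centers(self, angle_deg: float, roi=None) -> np.ndarray:
        """World positions of detector pixel centers at one gantry angle.

        Parameters
        ----------
        angle_deg : float
            Gantry angle [deg].
        roi : ROISpec-like, optional
            Object with ``u_min/u_max/v_min/v_max`` half-open pixel bounds;
            restricts the returned grid to that rectangle.

        Returns
        -------
        ndarray of shape (n_rows, n_cols, 3)
        """
        u, v = self.pixel_coords()
        if roi is not None:
            u = u[roi.u_min : roi.u_max]
            v = v[roi.v_min : roi.v_max]
        u_hat, v_hat, w_hat = self.detector_axes(angle_deg)
        src = self.source_position(angle_deg)
        det_center = src + self.sdd * w_hat
        return (
            det_center[None, None, :]
            + v[:, None, None] * v_hat[None, None, :]
            + u[None, :, None] * u_hat[None, None, :]
        )
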