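"""Respiratory signal handling: 10-phase labelling and the Amsterdam Shroud.

The Amsterdam Shroud (AS) collapses each kV projection into a single column
(log-transform, derivative along the cranio-caudal detector axis, absolute
sum over the lateral axis); stacking the columns over frames yields an image
in which moving high-gradient structures — above all the diaphragm edge —
trace the breathing cycle.  The extracted 1D signal is phase-labelled the
same way as a ground-truth trace, giving the diaphragm-surrogate baseline
that direct tumor-template matching is compared against.

Phase labelling is temporal (phase-angle) binning: peak-exhale anchors are
local displacement minima, and each cycle is split into 10 equal-duration
bins with phase 1 opening at the anchor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.fft
import scipy.ndimage
import scipy.signal

from .phantom import RespiratoryTrace
from .projector import ProjectionSeries, log_transform

__all__ = [
    "ShroudImage",
    "label_phases",
    "build_shroud",
    "extract_signal",
    "as_phase",
    "dominant_period",
]

logger = logging.getLogger(__name__)


@dataclass
class ShroudImage:
    """Amsterdam-Shroud image: rows = cranio-caudal position, one column per frame."""

    columns: np.ndarray  # (n_rows, n_frames)
    frame_times: np.ndarray
    frame_angles: np.ndarray
    row_pitch_mm: float = 1.0  # detector row pitch
    magnification: float = 1.0  # sdd / sad, for mm-at-isocenter conversion

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.frame_angles = np.asarray(self.frame_angles, dtype=float)
        if self.columns.shape[1] != len(self.frame_times):
            raise ValueError("one column per projection frame required")


def dominant_period(times: np.ndarray, signal: np.ndarray) -> float:
    """Dominant period of a sampled signal via the FFT magnitude peak.

    The spectrum is zero-padded (8x) and the peak refined by parabolic
    interpolation, so the estimate is much finer than the raw 1/duration
    frequency resolution of a short series.
    """
    sig = np.asarray(signal, dtype=float)
    sig = sig - sig.mean()
    dt = float(np.median(np.diff(times)))
    n_pad = 1 << int(np.ceil(np.log2(max(8 * len(sig), 64))))
    spec = np.abs(scipy.fft.rfft(sig, n=n_pad))
    freqs = scipy.fft.rfftfreq(n_pad, dt)
    spec[0] = 0.0
    k = int(np.argmax(spec))
    if k == 0 or spec[k] == 0.0:
        raise ValueError("no dominant oscillation found in signal")
    f = freqs[k]
    if 0 < k < len(spec) - 1:
        y0, y1, y2 = spec[k - 1], spec[k], spec[k + 1]
        denom = y0 - 2 * y1 + y2
        if abs(denom) > 1e-15:
            f = freqs[k] + 0.5 * (y0 - y2) / denom * (freqs[1] - freqs[0])
    return float(1.0 / f)


def _exhale_anchors(times: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Times of peak-exhale anchors (local minima of displacement)."""
    rng = np.percentile(disp, 95) - np.percentile(disp, 5)
    if rng <= 1e-9:
        raise ValueError("flat trace: no respiratory cycle detectable")
    period = dominant_period(times, disp)
    dt = float(np.median(np.diff(times)))
    min_dist = max(int(0.5 * period / dt), 1)
    idx, _ = scipy.signal.find_peaks(-disp, distance=min_dist, prominence=0.25 * rng)
    if len(idx) == 0:
        raise ValueError("no peak-exhale anchors detected")
    return times[idx]


def label_phases(trace: RespiratoryTrace, n_phases: int = 10) -> np.ndarray:
    """Assign a respiratory phase 1..n_phases to every trace sample.

    Within each cycle (anchor to anchor) the phase advances through
    n_phases equal-duration bins, opening at phase 1 on the peak-exhale
    anchor.  Samples before the first / after the last detected anchor are
    covered by extrapolating the neighboring cycle length.
    """
    times, disp = trace.times, trace.displacement
    anchors = list(_exhale_anchors(times, disp))
    if len(anchors) == 1:
        period = dominant_period(times, disp)
        anchors = [anchors[0] - period, anchors[0], anchors[0] + period]
    # extend anchors to cover the full time range
    while anchors[0] > times[0]:
        anchors.insert(0, anchors[0] - (anchors[1] - anchors[0]))
    while anchors[-1] <= times[-1]:
        anchors.append(anchors[-1] + (anchors[-1] - anchors[-2]))
    a = np.asarray(anchors)
    k = np.clip(np.searchsorted(a, times, side="right") - 1, 0, len(a) - 2)
    frac = (times - a[k]) / (a[k + 1] - a[k])
    # epsilon keeps samples sitting exactly on a bin edge in the later bin
    bins = np.floor(n_phases * np.clip(frac, 0.0, 1.0) + 1e-9).astype(int)
    return 1 + np.minimum(bins, n_phases - 1)


def build_shroud(projections: ProjectionSeries) -> ShroudImage:
    """Stack per-frame cranio-caudal derivative profiles into a shroud image."""
    if len(projections) < 2:
        raise ValueError("need at least 2 frames to build a shroud")
    cols = []
    for i in range(len(projections)):
        g = log_transform(projections[i])
        cols.append(np.abs(np.diff(g, axis=0)).sum(axis=1))
    geom = projections.geometry
    return ShroudImage(
        columns=np.stack(cols, axis=1),
        frame_times=projections.times,
        frame_angles=projections.angles,
        row_pitch_mm=geom.pixel_pitch[1] if geom is not None else 1.0,
        magnification=geom.magnification if geom is not None else 1.0,
    )


def extract_signal(shroud: ShroudImage, smooth_rows: int = 5,
                   band_halfwidth: int = 20) -> RespiratoryTrace:
    """Extract the breathing trace from a shroud image.

    Each column is smoothed over ``smooth_rows`` rows; the row band with the
    largest temporal variance is selected, and within it the per-frame
    maximum is refined to sub-pixel precision by parabolic interpolation.
    Row positions are converted to mm at the isocenter (pitch divided by
    magnification), sign-flipped so that caudal diaphragm motion (inhale)
    gives positive displacement, detrended linearly and shifted to start at
    zero at peak exhale.
    """
    sm = scipy.ndimage.uniform_filter1d(shroud.columns, size=max(smooth_rows, 1), axis=0)
    var = sm.var(axis=1)
    if var.max() <= 1e-18:
        logger.warning("flat shroud: static scene, returning zero-amplitude trace")
        return RespiratoryTrace(
            times=shroud.frame_times,
            displacement=np.zeros_like(shroud.frame_times),
            period=np.inf,
            model_name="amsterdam-shroud",
        )
    center = int(np.argmax(var))
    lo = max(center - band_halfwidth, 0)
    hi = min(center + band_halfwidth + 1, sm.shape[0])
    band = sm[lo:hi]
    rows = np.argmax(band, axis=0).astype(float)
    # parabolic sub-pixel refinement of each column's peak
    for j in range(band.shape[1]):
        r = int(rows[j])
        if 0 < r < band.shape[0] - 1:
            y0, y1, y2 = band[r - 1, j], band[r, j], band[r + 1, j]
            denom = y0 - 2 * y1 + y2
            if abs(denom) > 1e-12:
                rows[j] = r + 0.5 * (y0 - y2) / denom
    mm = rows * shroud.row_pitch_mm / shroud.magnification
    signal = -mm  # caudal edge motion (inhale) -> positive displacement
    t = shroud.frame_times
    coeff = np.polyfit(t, signal, 1)
    signal = signal - np.polyval(coeff, t)
    signal = signal - signal.min()
    try:
        period = dominant_period(t, signal)
    except ValueError:
        period = np.inf
    return RespiratoryTrace(
        times=t, displacement=signal, period=period, model_name="amsterdam-shroud"
    )


def as_phase(projections: ProjectionSeries, n_phases: int = 10,
             smooth_rows: int = 5) -> np.ndarray:
    """Amsterdam-Shroud phase per frame: build_shroud -> extract_signal -> label_phases."""
    shroud = build_shroud(projections)
    trace = extract_signal(shroud, smooth_rows=smooth_rows)
    if not np.isfinite(trace.period) or trace.displacement.max() <= 0:
        raise ValueError("no respiratory cycle detectable in the projection series")
    return label_phases(trace, n_phases=n_phases)
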