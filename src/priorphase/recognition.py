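"""Prior-image-based phase recognition: re-projected templates + NCC matching.

Before treatment, each of the 10 phase volumes of a prior 4D-CBCT is
re-projected at integer gantry angles and cropped to a detector region of
interest (ROI) covering the tumor's anticipated motion range, yielding a
10-phase x per-degree template bank.  During treatment, every incoming kV
frame is compared (normalized cross-correlation on the ROI) against the 10
templates at the nearest integer angle; the best-correlated phase is the
recognized respiratory phase.

A recognized phase is scored against a reference phase with two criteria:

* two-phase criterion — cyclic phase distance <= 2 counts as a match
  (phases 10 and 1 are both peak exhale, so distance wraps around);
* relative phase criterion — an out-of-order phase still counts as a match
  when its correlation differs from the reference phase's correlation by
  <= 0.01, since mirror phases of the cycle (mid-inhale vs mid-exhale) show
  nearly identical tumor position and shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ConeBeamGeometry
from .phantom import Phantom4D
from .projector import ProjectionImage, forward_project

__all__ = [
    "ROISpec",
    "TemplateBank",
    "MatchResult",
    "MatchAssessment",
    "build_templates",
    "ncc",
    "recognize_phase",
    "cyclic_phase_distance",
    "two_phase_match",
    "relative_phase_match",
    "assess_sequence",
    "auto_roi",
]

REL_CC_TOLERANCE = 0.01  # relative phase criterion threshold on |CC_ref - CC_obt|


@dataclass
class ROISpec:
    """Half-open detector rectangle [u_min,u_max) x [v_min,v_max), 0-based pixels."""

    u_min: int
    u_max: int
    v_min: int
    v_max: int

    def __post_init__(self) -> None:
        if self.u_min >= self.u_max or self.v_min >= self.v_max:
            raise ValueError("ROI must be non-empty")
        if min(self.u_min, self.v_min) < 0:
            raise ValueError("ROI indices must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.v_max - self.v_min, self.u_max - self.u_min)

    def crop(self, image: np.ndarray) -> np.ndarray:
        if image.shape[0] < self.v_max or image.shape[1] < self.u_max:
            raise ValueError("ROI exceeds image bounds")
        return image[self.v_min : self.v_max, self.u_min : self.u_max]

    def validate_against(self, geometry: ConeBeamGeometry) -> None:
        nu, nv = geometry.detector_pixels
        if self.u_max > nu or self.v_max > nv:
            raise ValueError("ROI lies outside the detector")


@dataclass
class TemplateBank:
    """ROI templates indexed by (phase 1..10, integer gantry angle)."""

    templates: dict  # (phase, angle) -> 2D ndarray
    roi: ROISpec
    source: str = "ideal"  # "ideal" (ground-truth phantom) | "fdk" (reconstruction)
    n_phases: int = 10

    def __post_init__(self) -> None:
        if not self.templates:
            raise ValueError("empty template bank")
        shapes = {t.shape for t in self.templates.values()}
        if len(shapes) != 1:
            raise ValueError("all templates must share the ROI shape")

    @property
    def angles(self) -> np.ndarray:
        return np.array(sorted({a for (_p, a) in self.templates}))

    def __len__(self) -> int:
        return len(self.templates)

    def get(self, phase: int, angle: int) -> np.ndarray:
        return self.templates[(phase, angle)]


@dataclass
class MatchResult:
    """NCC of one in-treatment frame against the 10 phase templates."""

    frame_index: int
    angle: float
    template_angle: int
    cc_by_phase: np.ndarray  # 10 values, nan where undefined
    obtained_phase: int
    cc_obtained: float


@dataclass
class MatchAssessment:
    """Criteria outcome of one frame against a reference phase."""

    reference_phase: int
    cc_reference: float
    cyclic_distance: int
    two_phase_ok: bool
    relative_ok: bool
    final_matched: bool


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation of two equal-shape images.

    ``sum((A - A_av)(B - B_av)) / sqrt(sum((A - A_av)^2) sum((B - B_av)^2))``
    with the plain image means; symmetric and invariant to positive affine
    intensity maps of either argument.

    Raises
    ------
    ValueError
        If either image is constant (zero variance): the correlation is
        undefined, not a number.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share shape")
    if a.size < 2:
        raise ValueError("need at least 2 pixels")
    da = a - a.mean()
    db = b - b.mean()
    va = float(np.sum(da * da))
    vb = float(np.sum(db * db))
    if va == 0.0 or vb == 0.0:
        raise ValueError("undefined correlation: constant image")
    r = float(np.sum(da * db) / np.sqrt(va * vb))
    return min(1.0, max(-1.0, r))


def cyclic_phase_distance(p: int, q: int, n_phases: int = 10) -> int:
    """Distance on the cyclic phase scale: min(|p-q|, n_phases - |p-q|)."""
    if not (1 <= p <= n_phases and 1 <= q <= n_phases):
        raise ValueError(f"phases must lie in 1..{n_phases}")
    d = abs(int(p) - int(q))
    return min(d, n_phases - d)


def two_phase_match(p_obt: int, p_ref: int, n_phases: int = 10) -> bool:
    """Match when obtained and reference phase are within two cyclic phases."""
    return cyclic_phase_distance(p_obt, p_ref, n_phases) <= 2


def relative_phase_match(cc_ref: float, cc_obt: float,
                         tol: float = REL_CC_TOLERANCE) -> bool:
    """Match when the two correlation values differ by at most ``tol``."""
    return abs(float(cc_ref) - float(cc_obt)) <= tol


def build_templates(
    prior: Phantom4D,
    geometry: ConeBeamGeometry,
    roi: ROISpec,
    angle_step: float = 1.0,
    angles=None,
    source: str = "ideal",
    source_intensity: float = 1.0,
) -> TemplateBank:
    """Re-project a prior 4D volume set into a phase x angle template bank.

    By default covers integer angles -180..+180 at 1 degree steps (361 per
    phase); ``angles`` restricts the bank to a declared subset (e.g. the
    planned treatment arc).
    """
    roi.validate_against(geometry)
    if angles is None:
        angles = np.arange(-180.0, 180.0 + 0.5 * angle_step, angle_step)
    angles = [int(round(a)) for a in np.asarray(angles, dtype=float)]
    templates = {}
    for k, vol in enumerate(prior.volumes, start=1):
        for a in angles:
            proj = forward_project(vol, geometry, float(a),
                                   source_intensity=source_intensity, roi=roi)
            templates[(k, a)] = proj.intensities
    return TemplateBank(templates=templates, roi=roi, source=source,
                        n_phases=prior.n_phases)


def _to_log(img: np.ndarray) -> np.ndarray:
    # NCC is affine-invariant, so -ln(P) equals -ln(P/P_o) up to a constant
    return -np.log(np.clip(img, 1e-9, None))


def _nearest_template_angle(angle: float, available: np.ndarray) -> int:
    """Nearest integer template angle; exact half-degree ties resolve toward 0."""
    lo = int(np.floor(angle))
    hi = lo + 1
    frac = angle - lo
    if abs(frac - 0.5) < 1e-9:
        cand = lo if abs(lo) <= abs(hi) else hi
    else:
        cand = lo if frac < 0.5 else hi
    if cand in available:
        return cand
    return int(available[np.argmin(np.abs(available - angle))])


def recognize_phase(
    image: ProjectionImage,
    bank: TemplateBank,
    previous_phase: int | None = None,
    frame_index: int = 0,
    match_domain: str = "log",
) -> MatchResult:
    """Recognize the respiratory phase of one in-treatment frame.

    The frame's ROI crop is correlated with the 10 templates at the nearest
    integer angle; the phase with the largest correlation wins.  Exact ties
    are broken toward the smallest cyclic distance to ``previous_phase``
    (toward phase 1 when there is none) — respiration moves in order, so the
    neighbor of the previous phase is the likelier candidate.

    ``match_domain`` selects the intensity scale the correlation is computed
    on: ``"log"`` (default) correlates line-integral images, which are
    linear in attenuation and markedly more robust when templates come from
    an imperfect reconstruction; ``"intensity"`` correlates raw detector
    intensities.
    """
    if match_domain not in ("log", "intensity"):
        raise ValueError(f"unknown match_domain {match_domain!r}")
    avail = bank.angles
    if image.angle < avail.min() - 0.5 or image.angle > avail.max() + 0.5:
        raise ValueError(
            f"frame angle {image.angle} outside template bank span "
            f"[{avail.min()}, {avail.max()}]"
        )
    t_angle = _nearest_template_angle(image.angle, avail)
    if image.intensities.shape == bank.roi.shape:
        roi_img = image.intensities  # already ROI-cropped
    else:
        roi_img = bank.roi.crop(image.intensities)
    if match_domain == "log":
        roi_img = _to_log(roi_img)
    cc = np.full(bank.n_phases, np.nan)
    for k in range(1, bank.n_phases + 1):
        tmpl = bank.get(k, t_angle)
        if match_domain == "log":
            tmpl = _to_log(tmpl)
        try:
            cc[k - 1] = ncc(roi_img, tmpl)
        except ValueError:
            continue
    if np.all(np.isnan(cc)):
        raise ValueError("no match: correlation undefined for all 10 phases")
    best = np.nanmax(cc)
    candidates = [k + 1 for k in range(bank.n_phases) if cc[k] == best]
    if len(candidates) > 1:
        anchor = previous_phase if previous_phase is not None else 1
        candidates.sort(
            key=lambda p: (cyclic_phase_distance(p, anchor, bank.n_phases), p)
        )
    obtained = candidates[0]
    return MatchResult(
        frame_index=frame_index,
        angle=float(image.angle),
        template_angle=t_angle,
        cc_by_phase=cc,
        obtained_phase=obtained,
        cc_obtained=float(cc[obtained - 1]),
    )


def assess_sequence(results, reference_phases, n_phases: int = 10):
    """Score a tracked frame sequence against reference phases.

    Per frame the two-phase criterion is applied first; only frames failing
    it (phases that 'suddenly appear' out of respiratory order) fall back to
    the relative phase criterion, comparing the obtained phase's correlation
    with the reference phase's correlation from the same frame.
    """
    reference_phases = np.asarray(reference_phases, dtype=int)
    if len(results) != len(reference_phases):
        raise ValueError("results and reference_phases must have equal length")
    out = []
    for res, ref in zip(results, reference_phases):
        dist = cyclic_phase_distance(res.obtained_phase, int(ref), n_phases)
        two_ok = dist <= 2
        cc_ref = float(res.cc_by_phase[int(ref) - 1])
        rel_ok = False
        if not two_ok and np.isfinite(cc_ref):
            rel_ok = relative_phase_match(cc_ref, res.cc_obtained)
        out.append(
            MatchAssessment(
                reference_phase=int(ref),
                cc_reference=cc_ref,
                cyclic_distance=dist,
                two_phase_ok=two_ok,
                relative_ok=rel_ok,
                final_matched=two_ok or rel_ok,
            )
        )
    return out


def auto_roi(
    spec,
    geometry: ConeBeamGeometry,
    angles,
    displacements,
    pad_px: int = 5,
) -> ROISpec:
    """Detector ROI covering the tumor's projected motion range.

    Projects the tumor sphere (center +- radius, magnified) at every given
    angle and displacement, takes the union rectangle and dilates it by
    ``pad_px`` pixels — the synthetic analog of outlining the anticipated
    tumor motion range on the panel.
    """
    u, v = geometry.pixel_coords()
    du, dv = geometry.pixel_pitch
    us, vs, mags = [], [], []
    axis = np.asarray(spec.motion_axis)
    for ang in np.atleast_1d(angles):
        src = geometry.source_position(ang)
        u_hat, v_hat, w_hat = geometry.detector_axes(ang)
        for d in np.atleast_1d(displacements):
            c = np.asarray(spec.tumor_center) + d * axis
            p = c - src
            l = float(p @ w_hat)
            mag = geometry.sdd / l
            us.append(float(p @ u_hat) * mag)
            vs.append(float(p @ v_hat) * mag)
            mags.append(mag)
    r_px_u = max(mags) * spec.tumor_radius / du
    r_px_v = max(mags) * spec.tumor_radius / dv
    iu = np.interp(us, u, np.arange(len(u)))
    iv = np.interp(vs, v, np.arange(len(v)))
    nu, nv = geometry.detector_pixels
    u_min = int(max(np.floor(iu.min() - r_px_u) - pad_px, 0))
    u_max = int(min(np.ceil(iu.max() + r_px_u) + pad_px + 1, nu))
    v_min = int(max(np.floor(iv.min() - r_px_v) - pad_px, 0))
    v_max = int(min(np.ceil(iv.max() + r_px_v) + pad_px + 1, nv))
    return ROISpec(u_min=u_min, u_max=u_max, v_min=v_min, v_max=v_max)
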