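"""Deterministic surrogate for VMAT planning and 3D dose calculation.

The commercial inverse optimizer and convolution dose algorithm are replaced
by a declared two-parameter surrogate: per-angle conformal apertures (the
beam's-eye-view projection of the target), a water-equivalent exponential
depth attenuation, and a Gaussian penumbra applied as an error function of
the signed distance to the aperture edge. The claims this package examines
are geometric and motion-driven, not optimizer-driven, so the surrogate
keeps the plan geometry (two full arcs, conformal apertures, prescription to
the target covering isodose, simultaneous-integrated-protection handling of
target/OAR overlap) while radically simplifying the physics.

Dose model per sampled gantry angle (axial-plane rotation about the SI
axis, parallel beam)::

    D(x) = w * exp(-mu * depth(x)) * T(u(x), z(x))

where ``depth`` is the radiological depth from the body surface along the
beam direction (geometric depth through the body mask, water-equivalent),
``T`` the penumbra-smoothed aperture transmission in beam's-eye-view
coordinates (lateral ``u``, longitudinal ``z``) and ``w`` the per-angle
monitor-unit weight. The total plan dose is scaled so that D95 of the PTV
equals the prescribed dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .dosemetrics import (
    ConstraintReport, ConstraintSet, check_constraints, dose_at_volume_percent,
    structure_doses, summarize_metrics,
)
from .errors import (
    DegeneratePlanError, EmptyStructureError, GeometryError, InvalidConfigError,
    NormalizationError,
)
from .structures import Mask, StructureSet, VoxelGrid, center_of_volume, expand_margin

__all__ = [
    "ArcSpec", "BeamModel", "Prescription", "Plan", "DoseGrid", "DoseEngine",
    "bev_aperture", "make_plan", "compute_arc_dose", "normalize_prescription",
    "apply_sip_adjustment", "plan_itv", "plan_track", "PlanResult",
]


@dataclass(frozen=True)
class ArcSpec:
    """One full or partial treatment arc (collimator angle is metadata only)."""

    start_deg: float = 0.0
    extent_deg: float = 360.0
    direction: int = 1  # +1 clockwise, -1 counter-clockwise
    step_deg: float = 5.0
    collimator_deg: float = 5.0

    def __post_init__(self) -> None:
        if self.extent_deg <= 0:
            raise InvalidConfigError("arc must have nonzero angular extent")
        n = self.extent_deg / self.step_deg
        if abs(n - round(n)) > 1e-9:
            raise InvalidConfigError("step must divide the arc extent")
        if self.direction not in (1, -1):
            raise InvalidConfigError("direction must be +1 or -1")

    @property
    def n_control_points(self) -> int:
        return int(round(self.extent_deg / self.step_deg))

    def control_angles(self) -> np.ndarray:
        """Control-point angles in delivery order, degrees in [0, 360)."""
        i = np.arange(self.n_control_points)
        return (self.start_deg + self.direction * self.step_deg * i) % 360.0


def default_arcs(step_deg: float = 5.0) -> list[ArcSpec]:
    """Two full arcs, opposite rotation, collimator 5 deg / 355 deg."""
    return [
        ArcSpec(0.0, 360.0, 1, step_deg, collimator_deg=5.0),
        ArcSpec(360.0 % 360.0, 360.0, -1, step_deg, collimator_deg=355.0),
    ]


@dataclass(frozen=True)
class BeamModel:
    """Two-parameter surrogate beam: effective linear attenuation and
    penumbra width, plus an optional conformal aperture margin."""

    mu_per_mm: float = 0.004
    penumbra_sigma_mm: float = 3.0
    aperture_margin_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.mu_per_mm <= 0 or self.penumbra_sigma_mm <= 0:
            raise InvalidConfigError("mu and penumbra sigma must be positive")


@dataclass(frozen=True)
class Prescription:
    """SBRT prescription: 25 Gy in 5 fractions to the 60% isodose, with the
    simultaneous-integrated-protection dose window for PTV/OAR overlap."""

    dose_per_fraction_gy: float = 5.0
    n_fractions: int = 5
    prescription_isodose: float = 0.60
    max_dose_cap_gy: float = 41.5
    overlap_min_gy: float = 25.0
    overlap_max_gy: float = 27.5
    nonoverlap_min_gy: float = 27.5
    coverage_fraction: float = 0.95

    @property
    def prescribed_dose_gy(self) -> float:
        return self.dose_per_fraction_gy * self.n_fractions

    def __post_init__(self) -> None:
        ceiling = self.prescribed_dose_gy / self.prescription_isodose
        if self.max_dose_cap_gy > ceiling + 1e-9:
            raise InvalidConfigError("dose cap exceeds the prescription-isodose ceiling")


@dataclass
class DoseGrid:
    """Absorbed dose (Gy) on the planning grid with a provenance tag."""

    data: np.ndarray
    grid: VoxelGrid
    provenance: str = "3D"

    def __post_init__(self) -> None:
        if self.data.shape != tuple(self.grid.shape):
            raise GeometryError("dose shape does not match grid")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < -1e-9):
            raise GeometryError("dose must be finite and non-negative")


@dataclass
class Plan:
    """Arc geometry, per-angle apertures and monitor-unit weights.

    ``apertures``/``weights`` are keyed by the unique control-point angle
    (degrees in [0, 360), rounded); weights sum to 1 over the plan.
    ``scale_gy`` converts unit-weight dose to Gy after normalization.
    ``boost_apertures`` carry the silhouette of the dose-escalation region
    (the pre-margin target): fluence through it is raised by
    ``boost_factor``, reproducing the hot-core dose heterogeneity of a
    prescription to a covering isodose line.
    """

    arcs: list[ArcSpec]
    apertures: dict[float, np.ndarray]
    weights: dict[float, float]
    isocenter_mm: np.ndarray
    beam_model: BeamModel
    grid: VoxelGrid
    scale_gy: float = 1.0
    label: str = ""
    boost_apertures: dict[float, np.ndarray] | None = None
    boost_factor: float = 0.0

    def angle_keys(self) -> list[float]:
        return list(self.apertures)

    def aperture_area_mm2(self, angle: float) -> float:
        sp = self.grid.spacing
        return float(self.apertures[angle].sum()) * sp[0] * sp[2]


def _akey(theta: float) -> float:
    return round(float(theta) % 360.0, 4)


class DoseEngine:
    """Per-patient dose calculator with cached per-angle attenuation.

    The attenuation volumes depend only on the (static) body mask and the
    beam direction, so one engine is shared by both planning arms, all
    breathing phases and all 4D sub-doses of a patient.
    """

    def __init__(self, grid: VoxelGrid, body_mask: np.ndarray,
                 beam_model: BeamModel | None = None):
        if abs(grid.spacing[0] - grid.spacing[1]) > 1e-9:
            raise GeometryError("in-plane spacing must be isotropic")
        self.grid = grid
        self.body = np.asarray(body_mask, dtype=bool)
        if self.body.shape != tuple(grid.shape):
            raise GeometryError("body mask does not match grid")
        self.beam = beam_model or BeamModel()
        nx, ny, nz = grid.shape
        self.sp = float(grid.spacing[0])
        self.spz = float(grid.spacing[2])
        n_u = int(np.ceil(np.hypot(nx, ny))) + 3
        self.n_u = n_u + (1 - n_u % 2)  # odd, covers the grid diagonal
        self.n_v = self.n_u
        cx, cy, _ = grid.center_mm
        x = grid.axis_coords(0)[:, None]
        y = grid.axis_coords(1)[None, :]
        self._xc, self._yc = x - cx, y - cy
        self._ucoord = (np.arange(self.n_u) - (self.n_u - 1) / 2.0) * self.sp
        self._att_cache: dict[float, np.ndarray] = {}
        self._lat_cache: dict[float, np.ndarray] = {}

    # -- geometry helpers ---------------------------------------------------

    @staticmethod
    def _axes(theta_deg: float) -> tuple[np.ndarray, np.ndarray]:
        """Beam propagation axis v and canonical lateral axis u (shared by
        theta and theta+180 so opposed beams index one aperture frame)."""
        tv = np.radians(theta_deg % 360.0)
        tu = np.radians(theta_deg % 180.0)
        v = np.array([np.sin(tv), np.cos(tv)])
        u = np.array([np.cos(tu), -np.sin(tu)])
        return u, v

    def lateral_index(self, theta_deg: float) -> np.ndarray:
        """(nx, ny) fractional index of each voxel column into the lateral
        aperture axis for this beam direction."""
        key = round(float(theta_deg) % 180.0, 4)
        if key not in self._lat_cache:
            u, _ = self._axes(key)
            lat = self._xc * u[0] + self._yc * u[1]
            self._lat_cache[key] = lat / self.sp + (self.n_u - 1) / 2.0
        return self._lat_cache[key]

    def _rotated_coords(self, theta_deg: float) -> np.ndarray:
        """Sampling coordinates (3, n_u, n_v, nz) of the beam-aligned frame."""
        u, v = self._axes(theta_deg)
        cx, cy, _ = self.grid.center_mm
        ua = self._ucoord[:, None]
        va = self._ucoord[None, :]
        px = (cx + ua * u[0] + va * v[0] - self.grid.origin[0]) / self.sp
        py = (cy + ua * u[1] + va * v[1] - self.grid.origin[1]) / self.sp
        nz = self.grid.shape[2]
        coords = np.empty((3, self.n_u, self.n_v, nz))
        coords[0] = px[..., None]
        coords[1] = py[..., None]
        coords[2] = np.arange(nz)[None, None, :]
        return coords

    # -- attenuation --------------------------------------------------------

    def attenuation(self, theta_deg: float) -> np.ndarray:
        """exp(-mu * radiological depth) on the fixed grid for one angle."""
        key = _akey(theta_deg)
        if key in self._att_cache:
            return self._att_cache[key]
        coords = self._rotated_coords(key)
        rho = ndimage.map_coordinates(
            self.body.astype(np.float32), coords, order=1, mode="constant", cval=0.0
        )
        depth_rot = (np.cumsum(rho, axis=1, dtype=np.float32) - 0.5 * rho) * self.sp
        # sample the depth back at fixed voxel centers
        u, v = self._axes(key)
        au = (self._xc * u[0] + self._yc * u[1]) / self.sp + (self.n_u - 1) / 2.0
        bv = (self._xc * v[0] + self._yc * v[1]) / self.sp + (self.n_v - 1) / 2.0
        nz = self.grid.shape[2]
        fix = np.empty((3, *self.grid.shape))
        fix[0] = au[..., None]
        fix[1] = bv[..., None]
        fix[2] = np.arange(nz)[None, None, :]
        depth = ndimage.map_coordinates(depth_rot, fix, order=1, mode="nearest")
        att = np.exp(-self.beam.mu_per_mm * depth).astype(np.float32)
        self._att_cache[key] = att
        return att

    # -- apertures and transmission -----------------------------------------

    def bev_projection(self, mask_data: np.ndarray, theta_deg: float) -> np.ndarray:
        """Orthographic projection of a mask along the beam direction:
        (n_u, nz) boolean beam's-eye-view occupancy."""
        coords = self._rotated_coords(theta_deg)
        occ = ndimage.map_coordinates(
            mask_data.astype(np.float32), coords, order=1, mode="constant", cval=0.0
        )
        return occ.max(axis=1) >= 0.5

    def transmission_map(self, aperture: np.ndarray) -> np.ndarray:
        """Penumbra transmission: erf of the signed distance (mm) to the
        aperture edge, positive inside."""
        sigma = self.beam.penumbra_sigma_mm
        sampling = (self.sp, self.spz)
        if not aperture.any():
            return np.zeros(aperture.shape, dtype=np.float32)
        d_out = ndimage.distance_transform_edt(~aperture, sampling=sampling)
        d_in = ndimage.distance_transform_edt(aperture, sampling=sampling)
        signed = np.where(aperture, d_in, -d_out)
        return (0.5 * (1.0 + erf(signed / (np.sqrt(2.0) * sigma)))).astype(np.float32)

    def transmission_volume(self, theta_deg: float, tmap: np.ndarray,
                            shift_mm: np.ndarray | None = None) -> np.ndarray:
        """Evaluate a 2D transmission map at every voxel, optionally with the
        aperture rigidly shifted by ``shift_mm`` (tracking isocenter shift).

        The lateral index depends only on the in-plane voxel position and the
        longitudinal index only on the slice, so the bilinear interpolation
        is a separable four-corner gather (much cheaper than a generic
        resampling of the volume).
        """
        au = self.lateral_index(theta_deg)
        nz = self.grid.shape[2]
        zi = np.arange(nz, dtype=float)
        if shift_mm is not None and np.any(shift_mm):
            u, _ = self._axes(theta_deg % 180.0)
            du = (shift_mm[0] * u[0] + shift_mm[1] * u[1]) / self.sp
            dz = shift_mm[2] / self.spz
            au = au - du
            zi = zi - dz
        # zero-pad so samples outside the map clamp onto a zero border
        tp = np.zeros((tmap.shape[0] + 2, tmap.shape[1] + 2), dtype=np.float32)
        tp[1:-1, 1:-1] = tmap
        a = np.clip(au + 1.0, 0.0, tp.shape[0] - 1.0)
        c = np.clip(zi + 1.0, 0.0, tp.shape[1] - 1.0)
        ia = np.minimum(a.astype(np.intp), tp.shape[0] - 2)
        ic = np.minimum(c.astype(np.intp), tp.shape[1] - 2)
        fa = (a - ia).astype(np.float32)[:, :, None]
        fc = (c - ic).astype(np.float32)[None, None, :]
        rows0, rows1 = tp[ia], tp[ia + 1]  # (nx, ny, nz_padded)
        g00, g01 = rows0[:, :, ic], rows0[:, :, ic + 1]
        g10, g11 = rows1[:, :, ic], rows1[:, :, ic + 1]
        return ((1.0 - fa) * ((1.0 - fc) * g00 + fc * g01)
                + fa * ((1.0 - fc) * g10 + fc * g11))


def bev_aperture(engine: DoseEngine, target: Mask, gantry_angle_deg: float,
                 margin_mm: float = 0.0) -> np.ndarray:
    """Conformal beam's-eye-view aperture: the target projection along the
    beam direction, dilated isotropically by ``margin_mm``."""
    if target.n_voxels == 0:
        raise EmptyStructureError("cannot shape an aperture to an empty target")
    proj = engine.bev_projection(target.data, gantry_angle_deg)
    if margin_mm > 0 and proj.any():
        dist = ndimage.distance_transform_edt(~proj, sampling=(engine.sp, engine.spz))
        proj = dist <= margin_mm
    return proj


def make_plan(engine: DoseEngine, target: Mask, arcs: list[ArcSpec] | None = None,
              label: str = "", boost_target: Mask | None = None,
              boost_factor: float = 0.4) -> Plan:
    """Conformal arc plan: one aperture per unique control-point angle and
    uniform monitor-unit weight per control point (weights sum to 1).

    When ``boost_target`` is given (the pre-margin target volume), fluence
    through its silhouette is raised by ``boost_factor``, emulating the dose
    escalation inside the tumor that a prescription to a covering isodose
    implies.
    """
    arcs = arcs if arcs is not None else default_arcs()
    cps = np.concatenate([a.control_angles() for a in arcs])
    n_cp = len(cps)
    weights: dict[float, float] = {}
    for t in cps:
        k = _akey(t)
        weights[k] = weights.get(k, 0.0) + 1.0 / n_cp
    apertures = {
        k: bev_aperture(engine, target, k, engine.beam.aperture_margin_mm)
        for k in weights
    }
    if not any(a.any() for a in apertures.values()):
        raise DegeneratePlanError("all apertures are empty")
    boost = None
    if boost_target is not None:
        boost = {k: bev_aperture(engine, boost_target, k) & apertures[k]
                 for k in weights}
    return Plan(
        arcs=arcs, apertures=apertures, weights=weights,
        isocenter_mm=center_of_volume(target), beam_model=engine.beam,
        grid=engine.grid, label=label, boost_apertures=boost,
        boost_factor=boost_factor if boost is not None else 0.0,
    )


def _angle_tmap(engine: DoseEngine, plan: Plan, key: float) -> np.ndarray:
    """Penumbra-smoothed fluence for one angle: open aperture plus the
    boosted silhouette of the escalation region."""
    tm = engine.transmission_map(plan.apertures[key])
    if plan.boost_apertures is not None and plan.boost_factor > 0:
        tm = tm + plan.boost_factor * engine.transmission_map(
            plan.boost_apertures[key])
    return tm


def plan_transmissions(engine: DoseEngine, plan: Plan) -> dict[float, np.ndarray]:
    """Per-angle 2D transmission maps for a plan's apertures."""
    return {k: _angle_tmap(engine, plan, k) for k in plan.apertures}


def compute_arc_dose(engine: DoseEngine, plan: Plan,
                     tmaps: dict[float, np.ndarray] | None = None,
                     provenance: str = "3D") -> DoseGrid:
    """Sum the per-angle surrogate dose over all control points.

    Dose is linear in the weights, non-negative, deterministic, and zero
    outside the body.
    """
    tmaps = tmaps if tmaps is not None else plan_transmissions(engine, plan)
    dose = np.zeros(engine.grid.shape, dtype=np.float64)
    for k, w in plan.weights.items():
        if w == 0.0:
            continue
        dose += w * engine.attenuation(k) * engine.transmission_volume(k, tmaps[k])
    dose *= engine.body
    dose *= plan.scale_gy
    return DoseGrid(dose, engine.grid, provenance=provenance)


def normalize_prescription(dose: DoseGrid, ptv: Mask, rx: Prescription,
                           ) -> tuple[DoseGrid, float, bool]:
    """Scale the dose so D95 of the PTV equals the prescribed dose exactly.

    Returns (scaled dose, scale factor, cap_ok) where ``cap_ok`` reports
    whether the resulting maximum dose respects the prescription cap; the
    cap is reported, not enforced by clipping.
    """
    d95 = dose_at_volume_percent(dose.data, 95.0, ptv)
    if d95 <= 0:
        raise NormalizationError("zero dose in the PTV; cannot normalize")
    scale = rx.prescribed_dose_gy / d95
    scaled = DoseGrid(dose.data * scale, dose.grid, provenance=dose.provenance)
    cap_ok = float(scaled.data.max()) <= rx.max_dose_cap_gy
    return scaled, scale, cap_ok


# ---------------------------------------------------------------------------
# SIP overlap handling and the per-arm planning drivers


@dataclass
class PlanResult:
    plan: Plan
    dose: DoseGrid
    scale: float
    objectives_met: bool
    report: ConstraintReport
    overlap_d01cc_history: list[float] = field(default_factory=list)


#: OARs whose overlap with the PTV is handled by the protection window:
#: the serial/luminal organs carrying a maximum-dose constraint
SIP_ORGANS = ("duodenum", "stomach", "bowel", "cord")


def _sip_overlap(ptv: Mask, oars: dict[str, Mask]) -> np.ndarray:
    serial = [oars[l].data for l in SIP_ORGANS if l in oars]
    if not serial:
        return np.zeros(ptv.data.shape, dtype=bool)
    return ptv.data & np.any(serial, axis=0)


def _objective_report(dose: np.ndarray, ptv: Mask, oars: dict[str, Mask],
                      rx: Prescription, constraints: ConstraintSet,
                      sset: StructureSet) -> ConstraintReport:
    """Evaluate all planning objectives on a normalized dose."""
    oar_labels = [l for l in oars]
    metrics = summarize_metrics(dose, sset, "3D", structures=oar_labels)
    ptv_vox = np.sort(structure_doses(dose, ptv))
    # coverage = 1 - F(Rx) with F the generalized inverse of the linear-
    # interpolation quantile, so D95 = Rx implies coverage = 95% exactly
    n = ptv_vox.size
    d_rx = rx.prescribed_dose_gy
    i = int(np.searchsorted(ptv_vox, d_rx, side="left"))
    if i == 0:
        cdf = 0.0
    elif i == n:
        cdf = 1.0
    else:
        lo, hi = ptv_vox[i - 1], ptv_vox[i]
        frac = 0.0 if hi == lo else (d_rx - lo) / (hi - lo)
        cdf = (i - 1 + frac) / (n - 1)
    coverage = float(1.0 - cdf)
    report = check_constraints(metrics, constraints,
                               coverage_fraction_at_rx=coverage,
                               coverage_target=rx.coverage_fraction)
    overlap = _sip_overlap(ptv, oars)
    vv_cc = ptv.grid.voxel_volume_mm3 / 1000.0
    if overlap.any():
        ov = dose[overlap]
        cc = min(0.1, ov.size * vv_cc)
        srt = np.sort(ov)[::-1]
        d01 = float(np.interp(cc, vv_cc * np.arange(1, ov.size + 1), srt))
        d98_ov = float(np.quantile(ov, 0.02))
        report.add("overlap D0.1cc <= window max", d01, rx.overlap_max_gy,
                   d01 <= rx.overlap_max_gy + 1e-9)
        report.add("overlap D98 >= window min", d98_ov, rx.overlap_min_gy,
                   d98_ov >= rx.overlap_min_gy - 1e-9)
        non = ptv.data & ~overlap
        if non.any():
            d95_non = float(np.quantile(dose[non], 0.05))
            report.add("non-overlap PTV D95 >= prescription", d95_non,
                       rx.prescribed_dose_gy,
                       d95_non >= rx.prescribed_dose_gy - 1e-9)
    return report


def apply_sip_adjustment(engine: DoseEngine, plan: Plan, dose: DoseGrid | None,
                         ptv: Mask, oars: dict[str, Mask], rx: Prescription,
                         constraints: ConstraintSet | None = None,
                         sset: StructureSet | None = None,
                         tmaps: dict[float, np.ndarray] | None = None,
                         max_iter: int = 20) -> PlanResult:
    """Iterative simultaneous-integrated-protection heuristic.

    While the hottest 0.1 cc of the PTV/OAR overlap exceeds the window
    maximum, the beam's-eye-view projection of the overlap (expanded 2 mm)
    is subtracted from the apertures of the angles contributing most to the
    excess, and the plan is renormalized. Deterministic: fixed angle
    ordering, fixed iteration cap. The returned flag mirrors whether all
    optimization objectives could be satisfied.
    """
    constraints = constraints or ConstraintSet()
    if sset is None:
        sset = StructureSet(ptv.grid, {"ptv": ptv, **oars})
    tmaps = tmaps if tmaps is not None else plan_transmissions(engine, plan)
    # per-angle transmission volumes, kept current as apertures change
    t3 = {k: engine.transmission_volume(k, tm) for k, tm in tmaps.items()}
    raw = np.zeros(engine.grid.shape, dtype=np.float64)
    for k, w in plan.weights.items():
        raw += w * engine.attenuation(k) * t3[k]
    raw *= engine.body
    vv_cc = ptv.grid.voxel_volume_mm3 / 1000.0

    overlap = _sip_overlap(ptv, oars)
    history: list[float] = []
    if overlap.any():
        blocker = expand_margin(
            Mask(ptv.grid, overlap, label="overlap"), 2.0
        ).data
        blocker_proj: dict[float, np.ndarray] = {}
        blocked: set[float] = set()
        d95_floor = 0.5 * float(np.quantile(raw[ptv.data], 0.05))

        def _overlap_d01cc(raw_dose):
            ov = raw_dose[overlap]
            srt = np.sort(ov)[::-1]
            cc = min(0.1, ov.size * vv_cc)
            return float(np.interp(cc, vv_cc * np.arange(1, ov.size + 1), srt))

        history.append(_overlap_d01cc(raw))
        for _ in range(max_iter):
            d95 = float(np.quantile(raw[ptv.data], 0.05))
            if d95 <= d95_floor:
                break  # coverage compromise reached; give up on the window
            scale = rx.prescribed_dose_gy / d95
            if scale * history[-1] <= rx.overlap_max_gy:
                break
            hot = overlap & (raw * scale > rx.overlap_max_gy)
            if not hot.any():
                break
            # rank angles by their contribution to the hot overlap voxels
            contrib = []
            for k, w in plan.weights.items():
                if k in blocked:
                    continue
                c = w * float((engine.attenuation(k)[hot] * t3[k][hot]).sum())
                contrib.append((c, k))
            contrib.sort(reverse=True)
            n_block = max(1, len(plan.weights) // 8)
            changed = False
            for _, k in contrib:
                if n_block == 0:
                    break
                if k not in blocker_proj:
                    blocker_proj[k] = engine.bev_projection(blocker, k)
                new_ap = plan.apertures[k] & ~blocker_proj[k]
                blocked.add(k)
                if new_ap.sum() == plan.apertures[k].sum() or not new_ap.any():
                    continue
                plan.apertures[k] = new_ap
                if plan.boost_apertures is not None:
                    plan.boost_apertures[k] = plan.boost_apertures[k] & new_ap
                tmaps[k] = _angle_tmap(engine, plan, k)
                new_t3 = engine.transmission_volume(k, tmaps[k])
                raw += plan.weights[k] * engine.attenuation(k) * (new_t3 - t3[k])
                t3[k] = new_t3
                np.maximum(raw, 0.0, out=raw)
                changed = True
                n_block -= 1
            if not changed:
                break
            history.append(_overlap_d01cc(raw))

    provenance = dose.provenance if dose is not None else f"3D|{plan.label}"
    raw_grid = DoseGrid(raw * engine.body, engine.grid, provenance=provenance)
    final, scale, _cap_ok = normalize_prescription(raw_grid, ptv, rx)
    plan.scale_gy = scale
    report = _objective_report(final.data, ptv, oars, rx, constraints, sset)
    return PlanResult(plan=plan, dose=final, scale=scale,
                      objectives_met=report.objectives_met, report=report,
                      overlap_d01cc_history=history)


def _plan_arm(phantom, sset: StructureSet, engine: DoseEngine | None,
              rx: Prescription, constraints: ConstraintSet,
              arcs: list[ArcSpec] | None, label: str) -> PlanResult:
    if engine is None:
        engine = DoseEngine(phantom.grid, phantom.body_mask)
    ptv = sset["ptv"]
    # dose escalation inside the pre-margin target (ITV or tracked GTV)
    boost = sset["itv"] if "itv" in sset else sset["gtv_track"]
    plan = make_plan(engine, ptv, arcs=arcs, label=label, boost_target=boost)
    tmaps = plan_transmissions(engine, plan)
    oars = {l: sset[l] for l in sset.masks
            if l in ("duodenum", "stomach", "bowel", "kidney_l", "kidney_r",
                     "liver", "cord")}
    return apply_sip_adjustment(engine, plan, None, ptv, oars, rx, constraints,
                                sset=sset, tmaps=tmaps)


def plan_itv(phantom, structure_sets: dict[str, StructureSet],
             engine: DoseEngine | None = None,
             rx: Prescription | None = None,
             constraints: ConstraintSet | None = None,
             arcs: list[ArcSpec] | None = None) -> PlanResult:
    """ITV-concept plan: target PTV_itv, planned on the average geometry.

    In this phantom family the body outline is static, so the average
    reconstruction shares the planning body mask with every phase.
    """
    return _plan_arm(phantom, structure_sets["itv"], engine,
                     rx or Prescription(), constraints or ConstraintSet(),
                     arcs, "itv")


def plan_track(phantom, structure_sets: dict[str, StructureSet],
               engine: DoseEngine | None = None,
               rx: Prescription | None = None,
               constraints: ConstraintSet | None = None,
               arcs: list[ArcSpec] | None = None) -> PlanResult:
    """Tracking-concept plan: target PTV_track on the contouring phase."""
    return _plan_arm(phantom, structure_sets["tracking"], engine,
                     rx or Prescription(), constraints or ConstraintSet(),
                     arcs, "tracking")
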