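"""4D dose accumulation: interplay between arc delivery and breathing.

Each arc is divided into angular segments at every breathing-phase-bin
transition (constant gantry speed, uniform monitor units per degree), the
segments are temporally assigned to breathing phases, per-phase sub-doses
are computed with the 3D surrogate engine restricted to the segment's
angles — with the isocenter and apertures rigidly shifted to the current
GTV center-of-volume in tracking mode — and all phase doses are warped to
the contouring (reference) phase with the phantom's ground-truth
displacement fields and summed.

Tracking is assumed perfect (zero latency, zero tracking error); dose
warping interpolates dose values without mass/energy rescaling, matching a
deformable dose-summation workflow, and is documented as an approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dose3d import DoseEngine, DoseGrid, Plan, _akey, plan_transmissions
from .errors import GeometryError, InvalidConfigError
from .phantom4d import DisplacementField, FourDPhantom

__all__ = [
    "ArcSegment", "AccumulatedDose", "segment_arc_by_phase",
    "phase_subdose", "warp_dose_to_reference", "accumulate_4d",
]

#: default gantry speed (deg/s): one full arc in 120 s. A config value of the
#: simulated delivery, not a clinical claim.
DEFAULT_GANTRY_SPEED_DEG_S = 3.0

#: per-fraction starting breathing phases emulating interplay averaging over
#: the five fractions
DEFAULT_FRACTION_START_PHASES = (0, 2, 4, 6, 8)


@dataclass(frozen=True)
class ArcSegment:
    """One angular segment of an arc assigned to a single breathing phase."""

    theta_start_deg: float  # unwrapped delivery angle at segment start
    theta_end_deg: float
    phase: int
    mu_share: float  # fraction of the total plan monitor units
    t_start_s: float
    t_end_s: float

    @property
    def theta_mid_deg(self) -> float:
        return 0.5 * (self.theta_start_deg + self.theta_end_deg)


@dataclass
class AccumulatedDose:
    """4D-accumulated dose on the reference phase plus provenance."""

    dose: DoseGrid
    mode: str
    per_phase_share: dict[int, float]
    mu_share_total: float
    phase_doses: dict[int, np.ndarray] = field(default_factory=dict)


def segment_arc_by_phase(arc, gantry_speed_deg_s: float, breathing_period_s: float,
                         n_phases: int, start_phase: float = 0.0,
                         mu_total: float = 1.0, t0_s: float = 0.0,
                         ) -> list[ArcSegment]:
    """Split one arc into segments at every breathing-phase-bin transition.

    ``start_phase`` is the (possibly fractional) phase-bin coordinate at the
    start of the treatment; ``t0_s`` the delivery time already elapsed when
    this arc begins, so sequential arcs continue the same breathing trace.
    Monitor-unit shares are proportional to angular extent (constant gantry
    speed, uniform MU per degree) and sum to ``mu_total`` exactly up to
    floating point.
    """
    if gantry_speed_deg_s <= 0 or breathing_period_s <= 0:
        raise InvalidConfigError("gantry speed and breathing period must be positive")
    if n_phases < 1:
        raise InvalidConfigError("need at least one breathing phase")
    duration = arc.extent_deg / gantry_speed_deg_s
    bin_s = breathing_period_s / n_phases
    phi0 = start_phase + t0_s / bin_s  # phase-bin coordinate at local t = 0

    # boundaries where the phase bin changes, clipped to [0, duration]
    m_lo = int(np.floor(phi0))
    m_hi = int(np.ceil(phi0 + duration / bin_s))
    trans = bin_s * (np.arange(m_lo, m_hi + 1) - phi0)
    trans = trans[(trans > 1e-12) & (trans < duration - 1e-12)]
    bounds = np.concatenate(([0.0], trans, [duration]))

    segments = []
    for ta, tb in zip(bounds[:-1], bounds[1:]):
        tm = 0.5 * (ta + tb)
        phase = int(np.floor(tm / bin_s + phi0)) % n_phases
        segments.append(ArcSegment(
            theta_start_deg=arc.start_deg + arc.direction * gantry_speed_deg_s * ta,
            theta_end_deg=arc.start_deg + arc.direction * gantry_speed_deg_s * tb,
            phase=phase,
            mu_share=mu_total * (tb - ta) / duration,
            t_start_s=t0_s + ta, t_end_s=t0_s + tb,
        ))
    return segments


def _segment_cp_shares(plan: Plan, arc, segment: ArcSegment,
                       gantry_speed_deg_s: float) -> dict[float, float]:
    """Distribute a segment's MU share over the plan's control-point angles.

    Control point j of an arc covers the delivery-time window
    [(j - 1/2) dt, (j + 1/2) dt) with dt = step/speed; the segment's share is
    split proportionally to its overlap with each window, so summing over all
    segments of an arc restores the plan's per-angle weights exactly.
    """
    dt = arc.step_deg / gantry_speed_deg_s
    ta = segment.t_start_s - (
        abs(segment.theta_start_deg - arc.start_deg) / gantry_speed_deg_s
    )
    ta = segment.t_start_s - ta  # arc-local start time
    tb = ta + (segment.t_end_s - segment.t_start_s)
    n_cp = arc.n_control_points
    full_arc = abs(arc.extent_deg - 360.0) < 1e-9
    duration = n_cp * dt
    shares: dict[float, float] = {}
    for j in range(int(np.floor(ta / dt - 0.5)), int(np.ceil(tb / dt + 0.5)) + 1):
        w0, w1 = (j - 0.5) * dt, (j + 0.5) * dt
        if full_arc:
            # a full rotation closes on itself: the window straddling the arc
            # end belongs to control point 0 again (angle 360 == 0)
            j_eff = j % n_cp
        else:
            if j < 0 or j > n_cp - 1:
                continue
            j_eff = j
            # edge windows absorb the half-step overhang at open arc ends
            if j == 0:
                w0 = 0.0
            if j == n_cp - 1:
                w1 = duration
        ov = min(tb, w1) - max(ta, w0)
        if ov <= 0:
            continue
        theta = _akey(arc.start_deg + arc.direction * arc.step_deg * j_eff)
        frac = ov / (tb - ta)
        shares[theta] = shares.get(theta, 0.0) + segment.mu_share * frac
    return shares


def warp_dose_to_reference(phase_dose: np.ndarray | DoseGrid,
                           displacement: DisplacementField,
                           grid=None) -> np.ndarray:
    """Pull-back warp of a phase dose to the reference phase.

    D_ref(x) = D_phase(x + u(x)) with trilinear interpolation; samples that
    fall outside the grid contribute zero.
    """
    if isinstance(phase_dose, DoseGrid):
        grid = phase_dose.grid
        data = phase_dose.data
    else:
        data = np.asarray(phase_dose, dtype=float)
        if grid is None:
            raise GeometryError("grid required for a bare dose array")
    u = displacement.vectors
    if u.shape != (3, *data.shape):
        raise GeometryError("displacement field does not match the dose grid")
    if displacement.is_zero:
        return data.copy()
    sp = np.asarray(grid.spacing)
    idx = np.indices(data.shape, dtype=float)
    coords = idx + u / sp[:, None, None, None]
    return ndimage.map_coordinates(data, coords, order=1, mode="constant", cval=0.0)


def _tracking_shift(phantom: FourDPhantom, phase: int) -> np.ndarray:
    ref = phantom.reference_phase
    return np.asarray(phantom.phases[phase].gtv_cov) - np.asarray(
        phantom.phases[ref].gtv_cov
    )


def phase_subdose(engine: DoseEngine, plan: Plan, segment: ArcSegment,
                  phantom: FourDPhantom, mode: str, arc=None,
                  gantry_speed_deg_s: float = DEFAULT_GANTRY_SPEED_DEG_S,
                  tmaps: dict[float, np.ndarray] | None = None) -> np.ndarray:
    """Dose delivered during one segment, on that segment's breathing phase.

    In tracking mode the apertures (and isocenter) are rigidly shifted by
    the phase's GTV center-of-volume displacement relative to the reference
    phase; in ITV mode the beam is left untouched. The segment's monitor
    units are spread over the plan's control-point angles it covers.
    """
    if mode not in ("itv", "tracking"):
        raise InvalidConfigError(f"mode must be 'itv' or 'tracking', got {mode!r}")
    if arc is None:
        arc = plan.arcs[0]
    tmaps = tmaps if tmaps is not None else plan_transmissions(engine, plan)
    shift = _tracking_shift(phantom, segment.phase) if mode == "tracking" else None
    dose = np.zeros(engine.grid.shape, dtype=np.float64)
    for theta, share in _segment_cp_shares(plan, arc, segment,
                                           gantry_speed_deg_s).items():
        if share == 0.0:
            continue
        t3 = engine.transmission_volume(theta, tmaps[theta], shift_mm=shift)
        dose += share * engine.attenuation(theta) * t3
    dose *= engine.body
    dose *= plan.scale_gy
    return dose


def accumulate_4d(engine: DoseEngine, plan: Plan, phantom: FourDPhantom, mode: str,
                  gantry_speed_deg_s: float = DEFAULT_GANTRY_SPEED_DEG_S,
                  fraction_start_phases: tuple = DEFAULT_FRACTION_START_PHASES,
                  store_phase_doses: bool = False,
                  tmaps: dict[float, np.ndarray] | None = None) -> AccumulatedDose:
    """Full 4D dose accumulation for one planning arm.

    Arcs are delivered sequentially against a continuing breathing trace;
    fractions are identical apart from their starting breathing phase. The
    per-(angle, phase) monitor-unit shares of all fractions are aggregated
    first, so the computation cost is independent of the number of breathing
    cycles per arc.
    """
    if mode not in ("itv", "tracking"):
        raise InvalidConfigError(f"mode must be 'itv' or 'tracking', got {mode!r}")
    tmaps = tmaps if tmaps is not None else plan_transmissions(engine, plan)
    n_ph = phantom.n_phases
    period = phantom.config.breathing_period_s
    n_cp_total = sum(a.n_control_points for a in plan.arcs)
    n_frac = len(fraction_start_phases)

    # aggregate MU shares over fractions, arcs and segments
    table: dict[tuple[float, int], float] = {}
    per_phase_share: dict[int, float] = {p: 0.0 for p in range(n_ph)}
    for start in fraction_start_phases:
        t0 = 0.0
        for arc in plan.arcs:
            mu_arc = arc.n_control_points / n_cp_total / n_frac
            segs = segment_arc_by_phase(arc, gantry_speed_deg_s, period, n_ph,
                                        start_phase=float(start), mu_total=mu_arc,
                                        t0_s=t0)
            for seg in segs:
                for theta, share in _segment_cp_shares(
                        plan, arc, seg, gantry_speed_deg_s).items():
                    key = (theta, seg.phase)
                    table[key] = table.get(key, 0.0) + share
                per_phase_share[seg.phase] += seg.mu_share
            t0 += arc.extent_deg / gantry_speed_deg_s

    # per-phase doses, then warp everything to the reference phase
    ref = phantom.reference_phase
    phase_doses: dict[int, np.ndarray] = {}
    t3_base: dict[float, np.ndarray] = {}  # unshifted transmissions, shared
    for (theta, phase), share in table.items():
        if phase not in phase_doses:
            phase_doses[phase] = np.zeros(engine.grid.shape, dtype=np.float64)
        shift = _tracking_shift(phantom, phase) if mode == "tracking" else None
        if shift is None or not np.any(shift):
            if theta not in t3_base:
                t3_base[theta] = engine.transmission_volume(theta, tmaps[theta])
            t3 = t3_base[theta]
        else:
            t3 = engine.transmission_volume(theta, tmaps[theta], shift_mm=shift)
        phase_doses[phase] += share * engine.attenuation(theta) * t3

    total = np.zeros(engine.grid.shape, dtype=np.float64)
    for phase, d in sorted(phase_doses.items()):
        d *= engine.body
        d *= plan.scale_gy
        if phase == ref:
            total += d
        else:
            total += warp_dose_to_reference(d, phantom.fields[phase], engine.grid)

    acc = AccumulatedDose(
        dose=DoseGrid(total, engine.grid, provenance=f"4D|{mode}"),
        mode=mode,
        per_phase_share=per_phase_share,
        mu_share_total=float(sum(table.values())),
        phase_doses=phase_doses if store_phase_doses else {},
    )
    return acc
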