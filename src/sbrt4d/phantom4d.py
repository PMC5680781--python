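"""Synthetic 4D abdominal phantoms with known, invertible respiratory motion.

The generator stands in for respiration-resolved CT (4DCT) acquisition: it
produces ten (configurable) equal-duration breathing-phase volumes of a
simplified abdominal anatomy — a tumor (GTV) with adjacent duodenum, stomach,
bowel, kidneys, liver and spinal cord — on a ~2 mm voxel grid, together with
ground-truth displacement fields to a mid-ventilation reference phase. The
ground-truth fields replace deformable image registration entirely, so every
downstream stage (envelope construction, 4D dose accumulation, dose warping)
is exactly testable.

Breathing model: a single-frequency cosine, sampled at the midpoints of the
equal-duration phase bins. Motion is rigid-dominant, largest along the
superior-inferior axis; ``rigid_plus_local`` adds a smooth Gaussian-windowed
perturbation near the diaphragm to exercise the warping code. The body
outline is held static across phases (chest-wall motion is small compared to
internal organ motion), so the density grid is shared by all phases except
for an optional tumor density contrast that travels with the GTV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .errors import GeometryError, InvalidConfigError
from .structures import Mask, VoxelGrid, center_of_volume

__all__ = [
    "PhantomConfig",
    "DisplacementField",
    "PhantomPhase",
    "FourDPhantom",
    "make_breathing_trace",
    "make_phantom",
    "displacement_to_phase",
    "average_geometry",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Configuration of one synthetic 4D patient.

    ``motion_amplitude_mm`` is the peak-to-peak tumor excursion per axis in
    (AP, SI, LR) order, matching how respiratory amplitudes are reported
    clinically. ``duodenum_gap_mm`` is the closest surface-to-surface distance
    between GTV and duodenum at the reference phase; values below the PTV
    margin make the duodenum abut or overlap the PTV.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 2.0
    motion_amplitude_mm: tuple[float, float, float] = (2.0, 5.0, 1.0)  # (AP, SI, LR)
    breathing_period_s: float = 4.0
    n_phases: int = 10
    reference_phase: int | None = None  # None -> mid-ventilation bin
    deformation_mode: str = "rigid"  # "rigid" | "rigid_plus_local"
    seed: int = 0  # reserved; the generator itself is noise-free
    # anatomy
    gtv_center_mm: tuple[float, float, float] | None = None  # None -> grid center
    gtv_semiaxes_mm: tuple[float, float, float] = (14.0, 14.0, 16.0)
    body_semiaxes_mm: tuple[float, float] | None = None  # None -> 94%/86% of grid
    duodenum_radius_mm: float = 7.0
    duodenum_gap_mm: float = 6.0
    tumor_density: float = 1.0
    local_amp_mm: tuple[float, float, float] = (0.0, 0.0, 3.0)  # x,y,z extra at diaphragm
    local_sigma_mm: float = 20.0

    def __post_init__(self) -> None:
        if self.n_phases < 2:
            raise InvalidConfigError("n_phases must be >= 2")
        if self.breathing_period_s <= 0:
            raise InvalidConfigError("breathing period must be positive")
        if self.spacing_mm <= 0:
            raise InvalidConfigError("voxel spacing must be positive")
        if any(a < 0 for a in self.motion_amplitude_mm):
            raise InvalidConfigError("motion amplitudes must be non-negative")
        if self.reference_phase is not None and not (
            0 <= self.reference_phase < self.n_phases
        ):
            raise InvalidConfigError("reference_phase outside [0, n_phases)")
        if self.deformation_mode not in ("rigid", "rigid_plus_local"):
            raise InvalidConfigError(f"unknown deformation mode {self.deformation_mode!r}")

    @property
    def amplitude_xyz(self) -> np.ndarray:
        """Amplitudes reordered to grid axes (LR, AP, SI)."""
        ap, si, lr = self.motion_amplitude_mm
        return np.array([lr, ap, si], dtype=float)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        for key in ("grid_shape", "motion_amplitude_mm", "gtv_center_mm",
                    "gtv_semiaxes_mm", "body_semiaxes_mm", "local_amp_mm"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class DisplacementField:
    """Ground-truth vector field (mm) mapping reference-phase coordinates to
    phase-k coordinates (pull-back convention): tissue at reference position
    x sits at x + u(x) in phase k."""

    phase: int
    vectors: np.ndarray  # (3, nx, ny, nz), mm

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.vectors)):
            raise GeometryError("displacement field must be finite")

    @property
    def is_zero(self) -> bool:
        return not np.any(self.vectors)


@dataclass
class PhantomPhase:
    """One breathing phase: density grid (water = 1.0), structure masks and
    the GTV center-of-volume in mm."""

    density: np.ndarray
    masks: dict[str, np.ndarray]
    gtv_cov: np.ndarray | None


@dataclass
class FourDPhantom:
    config: PhantomConfig
    grid: VoxelGrid
    trace: np.ndarray  # per-phase normalized displacement scalar in [0, 1]
    reference_phase: int
    phases: list[PhantomPhase]
    fields: list[DisplacementField]
    body_mask: np.ndarray
    #: smooth GTV level function at the reference phase (<= 1 inside); the
    #: sub-voxel carrier for ground-truth structure propagation
    gtv_level: np.ndarray | None = None

    @property
    def n_phases(self) -> int:
        return len(self.phases)

    def cov_trajectory(self) -> np.ndarray:
        """(n_phases, 3) GTV center-of-volume positions in mm (LR, AP, SI)."""
        return np.array([ph.gtv_cov for ph in self.phases])

    def gtv_mask(self, phase: int) -> Mask:
        return Mask(self.grid, self.phases[phase].masks["gtv"], label="gtv")


def make_breathing_trace(period_s: float, n_phases: int) -> np.ndarray:
    """Normalized breathing displacement at the midpoint of each phase bin.

    The cycle is split into ``n_phases`` equal-duration bins; the trace is
    s(t) = (1 - cos(2*pi*t/T)) / 2 evaluated at bin midpoints, so s = 0 at
    full inhale (t = 0) and the maximum corresponds to full exhale.
    """
    if period_s <= 0:
        raise InvalidConfigError("breathing period must be positive")
    if n_phases < 2:
        raise InvalidConfigError("need at least two breathing phases")
    t_mid = (np.arange(n_phases) + 0.5) / n_phases  # in units of T
    return (1.0 - np.cos(2.0 * np.pi * t_mid)) / 2.0


# ---------------------------------------------------------------------------
# anatomy primitives


def _support(semi: np.ndarray, u: np.ndarray) -> float:
    """Support distance of an origin-centered ellipsoid along unit vector u."""
    return float(np.sqrt(((semi * u) ** 2).sum()))


def _clear_of_gtv(center: np.ndarray, semi: np.ndarray, gc: np.ndarray,
                  gs: np.ndarray, clearance: float) -> np.ndarray:
    """Push an ellipsoid outward along its center offset until its surface
    keeps at least ``clearance`` mm from the GTV surface."""
    d = np.asarray(center, dtype=float) - gc
    dist = float(np.linalg.norm(d))
    u = d / dist if dist > 0 else np.array([1.0, 0.0, 0.0])
    required = _support(gs, u) + _support(semi, u) + clearance
    if dist < required:
        return gc + u * required
    return np.asarray(center, dtype=float)


def _shrink_to_grid(center: np.ndarray, semi: np.ndarray, grid: VoxelGrid,
                    dmax: np.ndarray) -> np.ndarray:
    """Shrink ellipsoid semiaxes so the organ stays on the grid at its
    motion extremes."""
    lo = np.asarray(grid.origin) - 0.5 * np.asarray(grid.spacing)
    hi = (np.asarray(grid.origin)
          + (np.array(grid.shape) - 0.5) * np.asarray(grid.spacing))
    out = np.array(semi, dtype=float)
    for ax in range(3):
        room = min(center[ax] - (lo[ax] + dmax[ax]),
                   (hi[ax] - dmax[ax]) - center[ax])
        out[ax] = max(3.0, min(out[ax], room))
    return out


def _layout(config: PhantomConfig, grid: VoxelGrid,
            dmax: np.ndarray | None = None) -> dict:
    """Analytic organ layout: label -> primitive spec (mm).

    Primitives: ("ellipsoid", center, semiaxes), ("zcyl", cx, cy, rx, ry,
    z0, z1) and ("xcyl", cy, cz, r, x0, x1). Positions scale with the body
    so the same layout works on compact grids; the non-duodenal serial
    organs (stomach, bowel) are kept clear of the tracking PTV so the
    duodenum gap is the scenario's only adjacency dial.
    """
    c = grid.center_mm
    half = 0.5 * np.array(
        [grid.spacing[i] * (grid.shape[i] - 1) for i in range(3)]
    )
    if config.body_semiaxes_mm is not None:
        bx, by = config.body_semiaxes_mm
    else:
        bx, by = 0.94 * half[0], 0.86 * half[1]
    hz = half[2]
    gc = np.array(config.gtv_center_mm) if config.gtv_center_mm is not None else c.copy()
    gs = np.array(config.gtv_semiaxes_mm, dtype=float)
    rd = config.duodenum_radius_mm
    gap = config.duodenum_gap_mm

    duo_x = gc[0] + gs[0] + gap + rd  # vertical limb axis
    duo_z = gc[2] - (gs[2] + gap + rd)  # horizontal limb axis (inferior cap)
    lay = {
        "body": ("zcyl", c[0], c[1], bx, by, c[2] - hz, c[2] + hz),
        "gtv": ("ellipsoid", gc, gs),
        "duodenum_v": ("zcyl", duo_x, gc[1], rd, rd, duo_z, gc[2] + gs[2] + 8.0),
        "duodenum_h": ("xcyl", gc[1], duo_z, rd, gc[0] - gs[0], duo_x),
        "cord": ("zcyl", c[0], c[1] + 0.76 * by, 6.0, 6.0, c[2] - hz, c[2] + hz),
    }
    if dmax is None:
        dmax = config.amplitude_xyz / 2.0
    # parallel organs: fractional placement, shrunk for motion headroom
    for name, ctr, semi in (
        ("liver",
         np.array([c[0] + 0.42 * bx, c[1] - 0.12 * by, c[2] + 0.48 * hz]),
         np.array([0.42 * bx, 0.40 * by, 0.34 * hz])),
        ("kidney_l",
         np.array([c[0] - 0.55 * bx, c[1] + 0.45 * by, c[2] - 0.30 * hz]),
         np.array([0.16 * bx, 0.18 * by, 0.26 * hz])),
        ("kidney_r",
         np.array([c[0] + 0.55 * bx, c[1] + 0.45 * by, c[2] - 0.30 * hz]),
         np.array([0.16 * bx, 0.18 * by, 0.26 * hz])),
    ):
        lay[name] = ("ellipsoid", ctr, _shrink_to_grid(ctr, semi, grid, dmax))
    # serial organs other than the duodenum: placed by body fractions, then
    # pushed clear of the tracking PTV (GTV + 5 mm margin + slop) and shrunk
    # to stay on the grid at the motion extremes
    clearance = 8.0
    for name, ctr, semi in (
        ("stomach",
         np.array([c[0] - 0.45 * bx, c[1] - 0.30 * by, c[2] + 0.18 * hz]),
         np.array([0.28 * bx, 0.22 * by, 0.30 * hz])),
        ("bowel",
         np.array([c[0], c[1] - 0.48 * by, c[2] - 0.48 * hz]),
         np.array([0.48 * bx, 0.26 * by, 0.30 * hz])),
    ):
        ctr = _clear_of_gtv(ctr, semi, gc, gs, clearance)
        # a very large tumor may push the organ off the grid: clamp the
        # center back to a feasible band (such anatomies legitimately abut)
        lo_c = (np.asarray(grid.origin) - 0.5 * np.asarray(grid.spacing)
                + dmax + 3.0)
        hi_c = (np.asarray(grid.origin)
                + (np.array(grid.shape) - 0.5) * np.asarray(grid.spacing)
                - dmax - 3.0)
        ctr = np.clip(ctr, lo_c, hi_c)
        semi = _shrink_to_grid(ctr, semi, grid, dmax)
        lay[name] = ("ellipsoid", ctr, semi)
    return lay


def _primitive_bbox(spec) -> tuple[np.ndarray, np.ndarray]:
    kind = spec[0]
    if kind == "ellipsoid":
        _, ctr, semi = spec
        return ctr - semi, ctr + semi
    if kind == "zcyl":
        _, cx, cy, rx, ry, z0, z1 = spec
        return np.array([cx - rx, cy - ry, z0]), np.array([cx + rx, cy + ry, z1])
    if kind == "xcyl":
        _, cy, cz, r, x0, x1 = spec
        return np.array([x0, cy - r, cz - r]), np.array([x1, cy + r, cz + r])
    raise ValueError(kind)


def _rasterize(spec, xs, ys, zs) -> np.ndarray:
    """Evaluate a primitive's indicator at (possibly displaced) coordinates."""
    kind = spec[0]
    if kind == "ellipsoid":
        _, ctr, semi = spec
        return (((xs - ctr[0]) / semi[0]) ** 2
                + ((ys - ctr[1]) / semi[1]) ** 2
                + ((zs - ctr[2]) / semi[2]) ** 2) <= 1.0
    if kind == "zcyl":
        _, cx, cy, rx, ry, z0, z1 = spec
        inside = (((xs - cx) / rx) ** 2 + ((ys - cy) / ry) ** 2) <= 1.0
        return inside & (zs >= z0) & (zs <= z1)
    if kind == "xcyl":
        _, cy, cz, r, x0, x1 = spec
        inside = ((ys - cy) ** 2 + (zs - cz) ** 2) <= r * r
        return inside & (xs >= x0) & (xs <= x1)
    raise ValueError(kind)


# ---------------------------------------------------------------------------
# generation


def make_phantom(config: PhantomConfig) -> FourDPhantom:
    """Generate a 4D phantom from a configuration.

    Deterministic: the anatomy is rasterized analytically per phase with
    organ centers displaced along the breathing trace, so the measured GTV
    center-of-volume trajectory recovers the configured peak-to-peak
    amplitudes to within half a voxel. Raises :class:`GeometryError` when an
    organ (at its motion extremes) would leave the grid.
    """
    sp = float(config.spacing_mm)
    grid = VoxelGrid(tuple(config.grid_shape), (sp, sp, sp))
    trace = make_breathing_trace(config.breathing_period_s, config.n_phases)

    if config.reference_phase is not None:
        ref = int(config.reference_phase)
    else:
        # mid-ventilation: the bin whose displacement is nearest the
        # time-averaged displacement (mean of s over a cycle is 1/2)
        ref = int(np.argmin(np.abs(trace - 0.5)))

    amp = config.amplitude_xyz  # (LR, AP, SI) peak-to-peak, grid axis order
    offsets = amp[None, :] * (trace[:, None] - trace[ref])  # (n_phases, 3)
    dmax = np.abs(offsets).max(axis=0)

    lay = _layout(config, grid, dmax=dmax)
    moving = [k for k in lay if k != "body"]

    # fit check at motion extremes
    lo_lim = np.asarray(grid.origin) - 0.5 * sp
    hi_lim = np.asarray(grid.origin) + (np.array(grid.shape) - 0.5) * sp
    for name in moving:
        lo, hi = _primitive_bbox(lay[name])
        centers_lo = np.asarray(grid.origin)
        centers_hi = centers_lo + (np.array(grid.shape) - 1) * sp
        for ax in range(3):
            # structures spanning the whole field of view (e.g. the cord) are
            # clipped by the scan extent, not contained by it
            if lo[ax] <= centers_lo[ax] and hi[ax] >= centers_hi[ax]:
                continue
            if (lo[ax] - dmax[ax] < lo_lim[ax] - 1e-6
                    or hi[ax] + dmax[ax] > hi_lim[ax] + 1e-6):
                raise GeometryError(
                    f"organ {name!r} exceeds the grid at motion extremes"
                )

    x, y, z = grid.coordinate_grids()
    body = _rasterize(lay["body"], x, y, z)

    # diaphragm window for the local deformation component
    c = grid.center_mm
    hz = 0.5 * grid.spacing[2] * (grid.shape[2] - 1)
    z_dia = c[2] + 0.55 * hz
    window = np.exp(-((z - z_dia) ** 2) / (2.0 * config.local_sigma_mm**2))
    local_amp = np.array(config.local_amp_mm, dtype=float)

    phases: list[PhantomPhase] = []
    fields: list[DisplacementField] = []
    base_density = body.astype(np.float32)

    for k in range(config.n_phases):
        d = offsets[k]
        if config.deformation_mode == "rigid":
            ux, uy, uz = (np.full((1, 1, 1), d[i]) for i in range(3))
        else:
            s = trace[k] - trace[ref]
            ux = d[0] + s * local_amp[0] * window
            uy = d[1] + s * local_amp[1] * window
            uz = d[2] + s * local_amp[2] * window
        # pull-back rasterization: phase-k occupancy at x is the reference
        # primitive evaluated at x - u(x) (exact for rigid motion)
        xs, ys, zs = x - ux, y - uy, z - uz
        masks: dict[str, np.ndarray] = {}
        gtv = _rasterize(lay["gtv"], xs, ys, zs) & body
        masks["gtv"] = gtv
        duo = (_rasterize(lay["duodenum_v"], xs, ys, zs)
               | _rasterize(lay["duodenum_h"], xs, ys, zs))
        masks["duodenum"] = duo & body & ~gtv
        for name in ("stomach", "liver", "kidney_l", "kidney_r", "bowel", "cord"):
            masks[name] = _rasterize(lay[name], xs, ys, zs) & body & ~gtv
        if not gtv.any():
            raise GeometryError("GTV mask is empty")

        density = base_density.copy()
        if config.tumor_density != 1.0:
            density[gtv] = config.tumor_density
        cov = center_of_volume(Mask(grid, gtv, label="gtv"))
        phases.append(PhantomPhase(density=density, masks=masks, gtv_cov=cov))

        shape3 = (3, *grid.shape)
        vec = np.zeros(shape3, dtype=np.float32)
        if config.deformation_mode == "rigid":
            vec += d[:, None, None, None].astype(np.float32)
        else:
            vec[0] = np.broadcast_to(ux, grid.shape)
            vec[1] = np.broadcast_to(uy, grid.shape)
            vec[2] = np.broadcast_to(uz, grid.shape)
        if k == ref:
            vec[:] = 0.0  # the reference maps to itself exactly
        fields.append(DisplacementField(phase=k, vectors=vec))

    # smooth level function of the reference-phase GTV for sub-voxel
    # structure propagation (the quadratic form of the ellipsoid)
    _, gc_lay, gs_lay = lay["gtv"]
    level = np.sqrt(((x - gc_lay[0]) / gs_lay[0]) ** 2
                    + ((y - gc_lay[1]) / gs_lay[1]) ** 2
                    + ((z - gc_lay[2]) / gs_lay[2]) ** 2).astype(np.float32)

    return FourDPhantom(
        config=config, grid=grid, trace=trace, reference_phase=ref,
        phases=phases, fields=fields, body_mask=body, gtv_level=level,
    )


def scenario_high_overlap(grid: int = 48) -> PhantomConfig:
    """Packaged scenario: large superior-inferior motion with the duodenum
    close to the tumor, so the motion-envelope PTV overlaps the duodenum
    envelope deeply while the tracking PTV stays clear of it.

    Mirrors the cohort cases in which the ITV-concept plan could not satisfy
    all optimization objectives while the tracking plan could.
    """
    return PhantomConfig(
        grid_shape=(grid, grid, grid),
        motion_amplitude_mm=(2.4, 10.4, 3.3),
        gtv_semiaxes_mm=(12.0, 12.0, 14.0),
        # 8 mm: beyond the 5 mm PTV margin plus voxelization slop, but far
        # inside the ~10 mm envelope sweep of the large SI amplitude
        duodenum_gap_mm=8.0,
    )


def displacement_to_phase(phantom: FourDPhantom, phase_k: int) -> DisplacementField:
    """The stored ground-truth field reference -> ``phase_k``."""
    if not (0 <= phase_k < phantom.n_phases):
        raise IndexError(f"phase {phase_k} outside [0, {phantom.n_phases})")
    return phantom.fields[phase_k]


def propagate_gtv(phantom: FourDPhantom, phase_k: int) -> Mask:
    """Propagate the reference GTV to a phase through the ground-truth field.

    Warps the phantom's smooth GTV level function (trilinear interpolation at
    the displaced positions, threshold at the unit level), which keeps the
    propagated surface sub-voxel accurate — the idealized stand-in for
    deformable structure propagation.
    """
    if not (0 <= phase_k < phantom.n_phases):
        raise IndexError(f"phase {phase_k} outside [0, {phantom.n_phases})")
    from scipy import ndimage

    u = phantom.fields[phase_k].vectors
    sp = np.asarray(phantom.grid.spacing)
    idx = np.indices(phantom.grid.shape, dtype=float)
    coords = idx - np.asarray(u, dtype=float) / sp[:, None, None, None]
    level = ndimage.map_coordinates(phantom.gtv_level, coords, order=1,
                                    mode="constant", cval=1e6)
    return Mask(phantom.grid, (level <= 1.0) & phantom.body_mask, label="gtv")


def average_geometry(phantom: FourDPhantom) -> PhantomPhase:
    """Voxel-wise mean of the phase density grids (the "average CT").

    Carries no structure masks: ITV-arm structures come from the motion
    envelopes, not from the average reconstruction.
    """
    if phantom.n_phases < 1:
        raise InvalidConfigError("phantom has no phases")
    density = np.mean([ph.density for ph in phantom.phases], axis=0)
    return PhantomPhase(density=density.astype(np.float32), masks={}, gtv_cov=None)


# ---------------------------------------------------------------------------
# optional export


def save_phantom(phantom: FourDPhantom, out_dir: str | Path) -> None:
    """Export phase volumes as NIfTI plus a JSON sidecar of COV trajectories.

    Requires nibabel; import is deferred so the core pipeline has no imaging
    I/O dependency.
    """
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*phantom.grid.spacing, 1.0])
    for k, ph in enumerate(phantom.phases):
        nib.save(nib.Nifti1Image(ph.density, affine), out / f"phase_{k:02d}.nii")
    traj = phantom.cov_trajectory()
    from .structures import motion_amplitudes

    summary = motion_amplitudes(traj)
    sidecar = {
        "reference_phase": phantom.reference_phase,
        "cov_trajectory_mm": traj.tolist(),
        "measured_amplitudes_mm": {
            "ap": summary.ap_mm, "si": summary.si_mm, "lr": summary.lr_mm,
            "motion3d": summary.motion3d_mm,
        },
    }
    (out / "phantom.json").write_text(json.dumps(sidecar, indent=2))
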