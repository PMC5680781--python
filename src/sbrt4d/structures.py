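"""Voxel-mask geometry and respiratory-motion metrics.

This module owns the geometric vocabulary of the pipeline: the voxel grid,
binary structure masks, the internal-target-volume (ITV) motion envelope,
isotropic margin expansion, structure volumes, and the per-axis motion
quantification used for the cohort analysis.

Coordinate convention (used throughout the package): axis 0 = x = left-right
(LR), axis 1 = y = anterior-posterior (AP), axis 2 = z = superior-inferior
(SI); units mm; voxel-center sampling; 0-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DomainError, EmptyStructureError, GeometryError

__all__ = [
    "VoxelGrid",
    "Mask",
    "MotionSummary",
    "StructureSet",
    "center_of_volume",
    "motion_3d",
    "motion_amplitudes",
    "union_envelope",
    "expand_margin",
    "volume_cc",
    "ptv_reduction_percent",
    "propagate_mask",
    "build_structure_sets",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid in mm, axes (LR, AP, SI), voxel-center sampling."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.shape):
            raise GeometryError(f"grid shape must be >= 1 per axis, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise GeometryError(f"grid spacing must be positive, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centers along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (x, y, z) coordinate arrays in mm."""
        x = self.axis_coords(0)[:, None, None]
        y = self.axis_coords(1)[None, :, None]
        z = self.axis_coords(2)[None, None, :]
        return x, y, z

    @property
    def center_mm(self) -> np.ndarray:
        """Physical center of the grid."""
        return np.array(
            [
                self.origin[i] + 0.5 * self.spacing[i] * (self.shape[i] - 1)
                for i in range(3)
            ]
        )

    def mm_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Convert physical points (…, 3) to fractional voxel indices."""
        p = np.asarray(points_mm, dtype=float)
        return (p - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass
class Mask:
    """Binary occupancy of one structure on a :class:`VoxelGrid`."""

    grid: VoxelGrid
    data: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != tuple(self.grid.shape):
            raise GeometryError(
                f"mask shape {self.data.shape} does not match grid {self.grid.shape}"
            )
        if self.data.dtype != bool:
            self.data = self.data.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def same_grid(self, other: "Mask") -> bool:
        return self.grid == other.grid


@dataclass(frozen=True)
class MotionSummary:
    """Per-axis maximal (peak-to-peak) displacement and the 3D motion norm."""

    ap_mm: float
    si_mm: float
    lr_mm: float

    def __post_init__(self) -> None:
        if min(self.ap_mm, self.si_mm, self.lr_mm) < 0:
            raise DomainError("motion amplitudes must be non-negative")

    @property
    def motion3d_mm(self) -> float:
        return motion_3d(self.ap_mm, self.si_mm, self.lr_mm)


@dataclass
class StructureSet:
    """Named masks on a shared grid, with construction provenance notes."""

    grid: VoxelGrid
    masks: dict[str, Mask]
    provenance: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, label: str) -> Mask:
        return self.masks[label]

    def __contains__(self, label: str) -> bool:
        return label in self.masks


# ---------------------------------------------------------------------------
# mask operations


def center_of_volume(mask: Mask) -> np.ndarray:
    """Unweighted centroid of occupied voxel centers, in mm.

    Raises :class:`EmptyStructureError` for an empty mask.
    """
    if mask.n_voxels == 0:
        raise EmptyStructureError(f"mask {mask.label!r} is empty")
    idx = np.argwhere(mask.data).mean(axis=0)
    return np.asarray(mask.grid.origin) + idx * np.asarray(mask.grid.spacing)


def motion_3d(ap: float, si: float, lr: float) -> float:
    """3D motion vector magnitude sqrt(LR^2 + AP^2 + SI^2)."""
    if min(ap, si, lr) < 0:
        raise DomainError("motion components must be non-negative")
    return float(np.sqrt(ap * ap + si * si + lr * lr))


def motion_amplitudes(cov_trajectory: np.ndarray) -> MotionSummary:
    """Per-axis maximal displacement of a center-of-volume trajectory.

    ``cov_trajectory`` is an (n_phases, 3) array of COV positions in mm in
    (LR, AP, SI) axis order. The per-direction motion is the peak-to-peak
    range (max - min) over phases, i.e. the displacement from maximum
    inspiration to maximum expiration.
    """
    traj = np.atleast_2d(np.asarray(cov_trajectory, dtype=float))
    if traj.shape[1] != 3:
        raise DomainError("trajectory must have three columns (LR, AP, SI)")
    p2p = traj.max(axis=0) - traj.min(axis=0)
    return MotionSummary(ap_mm=float(p2p[1]), si_mm=float(p2p[2]), lr_mm=float(p2p[0]))


def union_envelope(masks: list[Mask], label: str = "envelope") -> Mask:
    """Voxel-wise OR of per-phase masks — the motion envelope.

    The envelope enclosing all per-phase GTVs defines the ITV.
    """
    if not masks:
        raise EmptyStructureError("need at least one mask")
    grid = masks[0].grid
    for m in masks[1:]:
        if m.grid != grid:
            raise GeometryError("envelope masks must share one grid")
    data = np.zeros(grid.shape, dtype=bool)
    for m in masks:
        data |= m.data
    return Mask(grid, data, label=label)


def expand_margin(mask: Mask, margin_mm: float, label: str | None = None) -> Mask:
    """Isotropic Euclidean expansion of a mask by ``margin_mm``.

    A voxel is included when its center lies within ``margin_mm`` (inclusive)
    of the input set, computed with a Euclidean distance transform on voxel
    centers.
    """
    if margin_mm < 0:
        raise DomainError("margin must be non-negative")
    out_label = label if label is not None else mask.label
    if margin_mm == 0 or mask.n_voxels == 0:
        return Mask(mask.grid, mask.data.copy(), label=out_label)
    dist = ndimage.distance_transform_edt(~mask.data, sampling=mask.grid.spacing)
    return Mask(mask.grid, dist <= margin_mm, label=out_label)


def volume_cc(mask: Mask) -> float:
    """Structure volume in cm^3 (occupied voxels x voxel volume)."""
    return mask.n_voxels * mask.grid.voxel_volume_mm3 / 1000.0


def ptv_reduction_percent(v_itv: float, v_track: float) -> float:
    """Signed PTV size reduction, tracking relative to the ITV concept.

    Returns -100 * (v_itv - v_track) / v_itv: negative when tracking shrinks
    the PTV (the sign convention of the reduction-vs-motion regression axis).
    Prose summaries report the absolute value.
    """
    if v_itv <= 0:
        raise DomainError("ITV-concept PTV volume must be positive")
    return -100.0 * (v_itv - v_track) / v_itv


def propagate_mask(mask: Mask, displacement_mm: np.ndarray) -> Mask:
    """Propagate a reference-phase mask through a displacement field.

    ``displacement_mm`` has shape (3, nx, ny, nz) and maps reference-phase
    coordinates to phase-k coordinates (pull-back convention). The mask is
    carried by its signed Euclidean distance map: the distance field is
    resampled with trilinear interpolation at the displaced positions and
    re-thresholded at zero. Interpolating the (locally smooth) distance
    rather than the binary indicator keeps the propagated surface accurate
    to a fraction of a voxel, which binary resampling cannot achieve.
    """
    u = np.asarray(displacement_mm, dtype=float)
    if u.shape != (3, *mask.grid.shape):
        raise GeometryError("displacement field does not match the mask grid")
    if mask.n_voxels == 0 or mask.n_voxels == mask.data.size:
        return Mask(mask.grid, mask.data.copy(), label=mask.label)
    sp = np.asarray(mask.grid.spacing)
    signed = (ndimage.distance_transform_edt(mask.data, sampling=sp)
              - ndimage.distance_transform_edt(~mask.data, sampling=sp))
    idx = np.indices(mask.grid.shape, dtype=float)
    # Phase-k occupancy at x is the reference occupancy at x - u(x)
    # (first-order inverse of the mapping x -> x + u(x)).
    coords = idx - u / sp[:, None, None, None]
    warped = ndimage.map_coordinates(
        signed, coords, order=1, mode="constant", cval=-1e6
    )
    return Mask(mask.grid, warped >= 0.0, label=mask.label)


# ---------------------------------------------------------------------------
# study structure sets


#: organ-at-risk labels shared with the phantom generator
OAR_LABELS = ("duodenum", "stomach", "bowel", "kidney_l", "kidney_r", "liver", "cord")


def build_structure_sets(phantom, margin_mm: float = 5.0) -> dict[str, StructureSet]:
    """Build the two planning structure sets from a 4D phantom.

    ITV concept: the GTV motion envelope over all phases is the ITV; OARs are
    likewise motion envelopes; the PTV is the ITV plus an isotropic margin
    (default 5 mm). Tracking concept: the reference ("contouring") phase
    structures are used directly, with the PTV a fixed margin around the
    reference GTV.

    Returns ``{"itv": StructureSet, "tracking": StructureSet}``. Both sets
    live on the phantom grid and carry the reference GTV under the label
    ``gtv`` for 4D evaluation.
    """
    grid = phantom.grid
    ref = phantom.reference_phase
    labels = ["gtv", *[l for l in OAR_LABELS if l in phantom.phases[ref].masks]]

    ref_masks = {
        lab: Mask(grid, phantom.phases[ref].masks[lab], label=lab) for lab in labels
    }

    # tracking arm: contouring-phase structures + fixed margin
    gtv_track = Mask(grid, ref_masks["gtv"].data, label="gtv_track")
    ptv_track = expand_margin(gtv_track, margin_mm, label="ptv")
    tracking = StructureSet(
        grid,
        masks={"gtv": ref_masks["gtv"], "gtv_track": gtv_track, "ptv": ptv_track,
               **{lab: ref_masks[lab] for lab in labels if lab != "gtv"}},
        provenance={
            "ptv": f"gtv_track + {margin_mm} mm isotropic margin",
            "oars": "reference (contouring) phase structures",
        },
    )

    # ITV arm: motion envelopes + margin
    env = {}
    for lab in labels:
        per_phase = [Mask(grid, ph.masks[lab], label=lab) for ph in phantom.phases]
        env[lab] = union_envelope(per_phase, label=("itv" if lab == "gtv" else lab))
    ptv_itv = expand_margin(env["gtv"], margin_mm, label="ptv")
    itv = StructureSet(
        grid,
        masks={"gtv": ref_masks["gtv"], "itv": env["gtv"], "ptv": ptv_itv,
               **{lab: env[lab] for lab in labels if lab != "gtv"}},
        provenance={
            "itv": "motion envelope of the GTV over all breathing phases",
            "ptv": f"itv + {margin_mm} mm isotropic margin",
            "oars": "motion envelopes over all breathing phases",
        },
    )
    return {"itv": itv, "tracking": tracking}
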