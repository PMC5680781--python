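"""Cumulative DVHs, dose-volume parameters and planning-constraint reports.

Dose parameters follow the SBRT reporting set: Dmin, Dmax, Dmean, D2, D95,
D98 (dose received by x% of the structure) and D0.1cc (dose to the hottest
0.1 cm^3). Dx% uses descending-sort linear interpolation (equivalently the
(1 - x/100) quantile of the voxel doses); D0.1cc uses partial-voxel linear
interpolation on the descending cumulative-volume curve; Dmin/Dmax are true
voxel extrema.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, EmptyStructureError, GeometryError
from .structures import Mask, StructureSet

__all__ = [
    "DVHCurve",
    "DoseMetrics",
    "ConstraintSet",
    "ConstraintReport",
    "cumulative_dvh",
    "dose_at_volume_percent",
    "dose_at_absolute_volume",
    "structure_doses",
    "summarize_metrics",
    "check_constraints",
]

PARAMETER_NAMES = ("Dmean", "Dmin", "Dmax", "D2", "D95", "D98", "D0.1cc")


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram: fraction of the structure receiving
    at least each dose edge."""

    edges_gy: np.ndarray
    cum_fraction: np.ndarray

    def volume_at_dose(self, dose_gy: float) -> float:
        """Fractional volume receiving >= ``dose_gy`` (linear interpolation)."""
        return float(np.interp(dose_gy, self.edges_gy, self.cum_fraction))


@dataclass(frozen=True)
class DoseMetrics:
    """The seven reported dose parameters for one structure (Gy)."""

    structure: str
    mode: str  # "3D" | "4D"
    dmean: float
    dmin: float
    dmax: float
    d2: float
    d95: float
    d98: float
    d01cc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "Dmean": self.dmean, "Dmin": self.dmin, "Dmax": self.dmax,
            "D2": self.d2, "D95": self.d95, "D98": self.d98, "D0.1cc": self.d01cc,
        }


@dataclass(frozen=True)
class ConstraintSet:
    """Planning OAR constraints: serial-organ maximum doses and kidney mean."""

    cord_dmax_gy: float = 25.0
    hollow_organ_dmax_gy: float = 27.5  # bowel, duodenum, stomach
    kidney_dmean_gy: float = 10.0


@dataclass
class ConstraintReport:
    """Per-objective pass/fail entries; the overall flag is their conjunction."""

    entries: list[tuple[str, float, float, bool]] = field(default_factory=list)

    def add(self, name: str, value: float, limit: float, ok: bool) -> None:
        self.entries.append((name, float(value), float(limit), bool(ok)))

    @property
    def objectives_met(self) -> bool:
        return all(ok for *_, ok in self.entries)

    def failed(self) -> list[str]:
        return [name for name, *_, ok in self.entries if not ok]


# ---------------------------------------------------------------------------
# voxel extraction


def structure_doses(dose: np.ndarray, mask) -> np.ndarray:
    """Voxel doses inside a structure as a flat array."""
    m = mask.data if isinstance(mask, Mask) else np.asarray(mask, dtype=bool)
    d = np.asarray(dose, dtype=float)
    if m.shape != d.shape:
        raise GeometryError("dose and mask shapes differ")
    vox = d[m]
    if vox.size == 0:
        raise EmptyStructureError("structure has no voxels")
    return vox


def cumulative_dvh(dose: np.ndarray, mask, bin_width_gy: float = 0.05) -> DVHCurve:
    """Cumulative DVH of a structure with the given dose-bin width."""
    if bin_width_gy <= 0:
        raise DomainError("bin width must be positive")
    vox = structure_doses(dose, mask)
    top = float(vox.max())
    edges = np.arange(0.0, top + 2 * bin_width_gy, bin_width_gy)
    # fraction of voxels receiving >= edge
    sorted_doses = np.sort(vox)
    cum = 1.0 - np.searchsorted(sorted_doses, edges, side="left") / vox.size
    return DVHCurve(edges_gy=edges, cum_fraction=cum)


def dose_at_volume_percent(voxels_or_dose, x_percent: float, mask=None) -> float:
    """Dx%: largest dose received by at least x% of the structure.

    Computed as the (1 - x/100) quantile of the structure's voxel doses with
    linear interpolation between sorted voxel values. Accepts either a flat
    voxel-dose array or a (dose grid, mask) pair.
    """
    if not (0.0 < x_percent <= 100.0):
        raise DomainError("x must be in (0, 100]")
    vox = (structure_doses(voxels_or_dose, mask) if mask is not None
           else np.asarray(voxels_or_dose, dtype=float).ravel())
    if vox.size == 0:
        raise EmptyStructureError("no voxel doses given")
    return float(np.quantile(vox, 1.0 - x_percent / 100.0, method="linear"))


def dose_at_absolute_volume(dose, mask, cc: float,
                            voxel_volume_cc: float | None = None) -> float:
    """Dose to the hottest ``cc`` cm^3 of a structure.

    Voxel doses are sorted descending; the value is read off the piecewise-
    linear curve of dose versus cumulative volume at ``cc`` (partial-voxel
    interpolation within the voxel where the cumulative volume crosses cc).
    """
    if isinstance(mask, Mask):
        vox = structure_doses(dose, mask)
        vv = mask.grid.voxel_volume_mm3 / 1000.0
    else:
        vox = structure_doses(dose, mask)
        if voxel_volume_cc is None:
            raise DomainError("voxel_volume_cc required for a bare mask array")
        vv = float(voxel_volume_cc)
    total = vox.size * vv
    if not (0.0 < cc <= total):
        raise DomainError(f"cc must be in (0, {total:.4g}] for this structure")
    srt = np.sort(vox)[::-1]
    cum = vv * np.arange(1, vox.size + 1)
    return float(np.interp(cc, cum, srt))


def _metrics_from_voxels(vox: np.ndarray, vv_cc: float, structure: str,
                         mode: str) -> DoseMetrics:
    cc = min(0.1, vox.size * vv_cc)
    srt = np.sort(vox)[::-1]
    cum = vv_cc * np.arange(1, vox.size + 1)
    return DoseMetrics(
        structure=structure, mode=mode,
        dmean=float(vox.mean()), dmin=float(vox.min()), dmax=float(vox.max()),
        d2=float(np.quantile(vox, 0.98, method="linear")),
        d95=float(np.quantile(vox, 0.05, method="linear")),
        d98=float(np.quantile(vox, 0.02, method="linear")),
        d01cc=float(np.interp(cc, cum, srt)),
    )


def summarize_metrics(dose: np.ndarray, structure_set: StructureSet, mode: str,
                      structures: list[str] | None = None) -> list[DoseMetrics]:
    """Dose parameters for each requested structure of a structure set.

    ``mode`` is a provenance tag ("3D" evaluates planning structures, "4D"
    reference-phase structures); the caller selects the appropriate set.
    """
    vv_cc = structure_set.grid.voxel_volume_mm3 / 1000.0
    labels = structures if structures is not None else list(structure_set.masks)
    out = []
    for lab in labels:
        if lab not in structure_set:
            raise KeyError(f"structure {lab!r} not in set")
        vox = structure_doses(dose, structure_set[lab])
        out.append(_metrics_from_voxels(vox, vv_cc, lab, mode))
    return out


def check_constraints(metrics: list[DoseMetrics], constraints: ConstraintSet,
                      coverage_fraction_at_rx: float | None = None,
                      coverage_target: float = 0.95) -> ConstraintReport:
    """Evaluate OAR constraints (strict inequalities) and PTV coverage.

    ``coverage_fraction_at_rx`` is the fraction of the PTV receiving at least
    the prescribed dose; when given, coverage >= ``coverage_target`` is added
    as an objective.
    """
    by_name = {m.structure: m for m in metrics}
    report = ConstraintReport()
    if "cord" in by_name:
        v = by_name["cord"].dmax
        report.add("cord Dmax < limit", v, constraints.cord_dmax_gy,
                   v < constraints.cord_dmax_gy)
    for organ in ("bowel", "duodenum", "stomach"):
        if organ in by_name:
            v = by_name[organ].dmax
            report.add(f"{organ} Dmax < limit", v, constraints.hollow_organ_dmax_gy,
                       v < constraints.hollow_organ_dmax_gy)
    for organ in ("kidney_l", "kidney_r"):
        if organ in by_name:
            v = by_name[organ].dmean
            report.add(f"{organ} Dmean < limit", v, constraints.kidney_dmean_gy,
                       v < constraints.kidney_dmean_gy)
    if coverage_fraction_at_rx is not None:
        report.add("PTV coverage at prescription", coverage_fraction_at_rx,
                   coverage_target,
                   coverage_fraction_at_rx >= coverage_target - 1e-9)
    return report
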