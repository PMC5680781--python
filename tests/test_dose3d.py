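"""Surrogate arc dose engine: apertures, kernel physics, normalization, SIP."""

import numpy as np
import pytest

from sbrt4d.dose3d import (
    ArcSpec, DoseEngine, Prescription, bev_aperture, compute_arc_dose,
    make_plan, normalize_prescription, plan_transmissions,
)
from sbrt4d.dosemetrics import dose_at_volume_percent
from sbrt4d.errors import (
    DegeneratePlanError, EmptyStructureError, InvalidConfigError,
    NormalizationError,
)
from sbrt4d.structures import Mask, VoxelGrid


@pytest.fixture(scope="module")
def box_engine():
    """Uniform water box: isolates the kernel physics from anatomy."""
    grid = VoxelGrid((32, 32, 32), (2.0, 2.0, 2.0))
    return DoseEngine(grid, np.ones(grid.shape, dtype=bool))


def sphere(grid, center, radius):
    x, y, z = grid.coordinate_grids()
    d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    return Mask(grid, d2 <= radius**2, label="target")


class TestPrescription:
    def test_defaults_consistent(self):
        rx = Prescription()
        assert rx.prescribed_dose_gy == 25.0
        assert rx.max_dose_cap_gy <= rx.prescribed_dose_gy / rx.prescription_isodose

    def test_cap_above_isodose_ceiling_rejected(self):
        with pytest.raises(InvalidConfigError):
            Prescription(max_dose_cap_gy=45.0)


class TestArcSpec:
    def test_control_angles(self):
        arc = ArcSpec(0.0, 360.0, 1, 5.0)
        angles = arc.control_angles()
        assert len(angles) == 72 and angles[0] == 0.0 and angles[-1] == 355.0

    def test_invalid(self):
        with pytest.raises(InvalidConfigError):
            ArcSpec(0.0, 0.0)
        with pytest.raises(InvalidConfigError):
            ArcSpec(0.0, 360.0, 1, 7.0)  # step does not divide extent


class TestBevAperture:
    def test_sphere_projects_to_disk(self, box_engine):
        grid = box_engine.grid
        target = sphere(grid, grid.center_mm, 10.0)
        for theta in (0.0, 37.0, 90.0, 213.0):
            ap = bev_aperture(box_engine, target, theta)
            area = ap.sum() * box_engine.sp * box_engine.spz
            assert area == pytest.approx(np.pi * 100.0, rel=0.15)

    def test_opposed_beams_share_aperture(self, box_engine):
        grid = box_engine.grid
        target = sphere(grid, grid.center_mm + np.array([6, -4, 2]), 8.0)
        for theta in (0.0, 55.0, 120.0):
            np.testing.assert_array_equal(
                bev_aperture(box_engine, target, theta),
                bev_aperture(box_engine, target, theta + 180.0))

    def test_margin_strict_superset(self, box_engine):
        target = sphere(box_engine.grid, box_engine.grid.center_mm, 8.0)
        a0 = bev_aperture(box_engine, target, 40.0, margin_mm=0.0)
        a2 = bev_aperture(box_engine, target, 40.0, margin_mm=2.0)
        assert (a0 & ~a2).sum() == 0 and a2.sum() > a0.sum()

    def test_empty_target_rejected(self, box_engine):
        empty = Mask(box_engine.grid, np.zeros(box_engine.grid.shape, dtype=bool))
        with pytest.raises(EmptyStructureError):
            bev_aperture(box_engine, empty, 0.0)


class TestKernel:
    def test_central_axis_exponential_decay(self, box_engine):
        """Single anterior beam through a uniform box: dose along the beam
        axis decays as exp(-mu * depth)."""
        grid = box_engine.grid
        arc = [ArcSpec(0.0, 360.0, 1, 360.0)]  # one control point at 0 deg
        target = sphere(grid, grid.center_mm, 10.0)
        plan = make_plan(box_engine, target, arcs=arc)
        # huge open aperture: transmission 1 everywhere
        plan.apertures[0.0] = np.ones_like(plan.apertures[0.0])
        dose = compute_arc_dose(box_engine, plan).data
        ix = iz = grid.shape[0] // 2
        profile = dose[ix, 2:-2, iz]
        depth = np.arange(profile.size) * 2.0
        expected = profile[0] * np.exp(-box_engine.beam.mu_per_mm * depth)
        np.testing.assert_allclose(profile, expected, rtol=0.01)

    def test_linearity_and_zero_weights(self, box_engine):
        grid = box_engine.grid
        target = sphere(grid, grid.center_mm, 8.0)
        plan = make_plan(box_engine, target)
        tmaps = plan_transmissions(box_engine, plan)
        d1 = compute_arc_dose(box_engine, plan, tmaps).data
        plan.weights = {k: 2 * w for k, w in plan.weights.items()}
        d2 = compute_arc_dose(box_engine, plan, tmaps).data
        np.testing.assert_allclose(d2, 2 * d1, atol=1e-12)
        plan.weights = {k: 0.0 for k in plan.weights}
        assert not compute_arc_dose(box_engine, plan, tmaps).data.any()
        assert np.all(d1 >= 0)

    def test_determinism(self, box_engine):
        target = sphere(box_engine.grid, box_engine.grid.center_mm, 8.0)
        plan = make_plan(box_engine, target)
        a = compute_arc_dose(box_engine, plan).data
        b = compute_arc_dose(box_engine, plan).data
        np.testing.assert_array_equal(a, b)


class TestNormalization:
    def test_uniform_dose_scale(self, box_engine):
        from sbrt4d.dose3d import DoseGrid

        grid = box_engine.grid
        ptv = sphere(grid, grid.center_mm, 8.0)
        dose = DoseGrid(np.full(grid.shape, 10.0), grid)
        scaled, scale, _ = normalize_prescription(dose, ptv, Prescription())
        assert scale == pytest.approx(2.5)
        assert dose_at_volume_percent(scaled.data, 95.0, ptv) == pytest.approx(25.0)

    def test_d95_exact_on_computed_plan(self, hi_pack):
        for arm in ("itv", "tracking"):
            res = hi_pack[arm]
            ptv = hi_pack["ssets"][arm]["ptv"]
            d95 = dose_at_volume_percent(res.dose.data, 95.0, ptv)
            assert d95 == pytest.approx(25.0, abs=0.01)
            # scale factor equals prescription over the pre-scale D95
            pre = dose_at_volume_percent(res.dose.data / res.scale, 95.0, ptv)
            assert res.scale == pytest.approx(25.0 / pre)

    def test_zero_dose_rejected(self, box_engine):
        from sbrt4d.dose3d import DoseGrid

        grid = box_engine.grid
        ptv = sphere(grid, grid.center_mm, 8.0)
        with pytest.raises(NormalizationError):
            normalize_prescription(DoseGrid(np.zeros(grid.shape), grid), ptv,
                                   Prescription())


class TestPlannedArms:
    def test_tracking_apertures_never_larger(self, hi_pack):
        """PTV_track inside PTV_itv implies aperture areas <= at every angle
        (before SIP editing, both conformal to their target)."""
        engine = hi_pack["engine"]
        ssets = hi_pack["ssets"]
        for theta in (0.0, 45.0, 135.0, 270.0):
            a_itv = bev_aperture(engine, ssets["itv"]["ptv"], theta)
            a_trk = bev_aperture(engine, ssets["tracking"]["ptv"], theta)
            assert (a_trk & ~a_itv).sum() == 0

    def test_dose_conformity(self, hi_pack):
        """Mean dose inside the PTV exceeds the mean in a 10 mm shell."""
        from sbrt4d.structures import expand_margin

        for arm in ("itv", "tracking"):
            ptv = hi_pack["ssets"][arm]["ptv"]
            shell = expand_margin(ptv, 10.0).data & ~ptv.data
            dose = hi_pack[arm].dose.data
            assert dose[ptv.data].mean() > dose[shell].mean()

    def test_oar_sparing_direction(self, hi_pack):
        """Tracking spares the (planning) duodenum relative to the ITV arm."""
        d_itv = hi_pack["itv"].dose.data
        d_trk = hi_pack["tracking"].dose.data
        duo_itv = hi_pack["ssets"]["itv"]["duodenum"].data
        duo_trk = hi_pack["ssets"]["tracking"]["duodenum"].data
        assert d_trk[duo_trk].mean() <= d_itv[duo_itv].mean() + 0.1


class TestSIP:
    def test_no_overlap_plan_untouched(self):
        """Without PTV/serial-OAR overlap the apertures stay conformal and
        the base objectives decide the flag."""
        from sbrt4d.dose3d import plan_track
        from sbrt4d.phantom4d import PhantomConfig, make_phantom
        from sbrt4d.structures import build_structure_sets

        ph = make_phantom(PhantomConfig(grid_shape=(40, 40, 40),
                                        motion_amplitude_mm=(1.0, 2.0, 0.5),
                                        gtv_semiaxes_mm=(10.0, 10.0, 10.0),
                                        duodenum_gap_mm=12.0))
        ssets = build_structure_sets(ph)
        engine = DoseEngine(ph.grid, ph.body_mask)
        res = plan_track(ph, ssets, engine=engine)
        ptv = ssets["tracking"]["ptv"]
        for theta, ap in res.plan.apertures.items():
            np.testing.assert_array_equal(ap, bev_aperture(engine, ptv, theta))
        assert res.overlap_d01cc_history == []
        assert res.objectives_met

    def test_overlap_blocking_monotone(self, hi_pack):
        """Aperture blocking never increases the raw overlap D0.1cc."""
        hist = hi_pack["itv"].overlap_d01cc_history
        assert len(hist) >= 2
        assert all(a >= b - 1e-12 for a, b in zip(hist, hist[1:]))

    def test_scenario_flags(self, hi_pack):
        """High-overlap scenario: the ITV arm cannot satisfy all objectives,
        the tracking arm can."""
        assert not hi_pack["itv"].objectives_met
        assert hi_pack["tracking"].objectives_met


def test_empty_target_plan_rejected(box_engine):
    empty = Mask(box_engine.grid, np.zeros(box_engine.grid.shape, dtype=bool))
    with pytest.raises((EmptyStructureError, DegeneratePlanError)):
        make_plan(box_engine, empty)
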