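"""Arc segmentation, dose warping and 4D accumulation."""

import numpy as np
import pytest

from sbrt4d.dose4d import (
    accumulate_4d, phase_subdose, segment_arc_by_phase, warp_dose_to_reference,
)
from sbrt4d.dose3d import ArcSpec
from sbrt4d.errors import GeometryError, InvalidConfigError
from sbrt4d.phantom4d import DisplacementField
from sbrt4d.structures import VoxelGrid


class TestSegmentation:
    def test_one_period_ten_segments(self):
        """Arc time equal to one breathing period: ten 36-degree segments
        with one tenth of the monitor units each."""
        arc = ArcSpec(0.0, 360.0, 1, 5.0)
        segs = segment_arc_by_phase(arc, gantry_speed_deg_s=90.0,
                                    breathing_period_s=4.0, n_phases=10)
        assert len(segs) == 10
        for k, s in enumerate(segs):
            assert s.phase == k
            assert s.theta_end_deg - s.theta_start_deg == pytest.approx(36.0)
            assert s.mu_share == pytest.approx(0.1)

    def test_whole_periods_uniform_phase_shares(self):
        """Arc spanning k whole breathing periods: every phase receives
        exactly 1/n of the monitor units."""
        arc = ArcSpec(0.0, 360.0, 1, 5.0)
        segs = segment_arc_by_phase(arc, gantry_speed_deg_s=360.0 / 12.0,
                                    breathing_period_s=4.0, n_phases=10)
        shares = np.zeros(10)
        for s in segs:
            shares[s.phase] += s.mu_share
        np.testing.assert_allclose(shares, 0.1, atol=1e-12)

    def test_shares_sum_to_one(self):
        arc = ArcSpec(0.0, 360.0, 1, 5.0)
        segs = segment_arc_by_phase(arc, 3.0, 3.7, 10, start_phase=4)
        assert sum(s.mu_share for s in segs) == pytest.approx(1.0, abs=1e-12)

    def test_long_delivery_approaches_uniformity(self):
        """Per-phase shares approach 1/n as arc time grows: exact at 50
        whole periods (any phase offset), and within 2% with a leftover
        half period."""
        arc = ArcSpec(0.0, 360.0, 1, 5.0)
        segs = segment_arc_by_phase(arc, 360.0 / (50 * 4.0), 4.0, 10,
                                    start_phase=3.7)
        shares = np.zeros(10)
        for s in segs:
            shares[s.phase] += s.mu_share
        np.testing.assert_allclose(shares, 0.1, rtol=0.01)
        segs = segment_arc_by_phase(arc, 360.0 / (50.5 * 4.0), 4.0, 10)
        shares = np.zeros(10)
        for s in segs:
            shares[s.phase] += s.mu_share
        np.testing.assert_allclose(shares, 0.1, rtol=0.02)

    def test_invalid_config(self):
        arc = ArcSpec(0.0, 360.0, 1, 5.0)
        with pytest.raises(InvalidConfigError):
            segment_arc_by_phase(arc, 0.0, 4.0, 10)
        with pytest.raises(InvalidConfigError):
            segment_arc_by_phase(arc, 3.0, -1.0, 10)


class TestWarp:
    def test_zero_field_identity(self, rng):
        grid = VoxelGrid((12, 12, 12), (2.0, 2.0, 2.0))
        dose = rng.random(grid.shape)
        field = DisplacementField(0, np.zeros((3, *grid.shape), dtype=np.float32))
        np.testing.assert_array_equal(
            warp_dose_to_reference(dose, field, grid), dose)

    def test_constant_shift_on_ramp(self):
        """A linear dose ramp a*z warped by a constant SI shift s gives
        a*(z + s) away from the grid boundary."""
        grid = VoxelGrid((16, 16, 16), (2.0, 2.0, 2.0))
        z = grid.coordinate_grids()[2]
        dose = np.broadcast_to(0.7 * z, grid.shape).copy()
        vec = np.zeros((3, *grid.shape), dtype=np.float32)
        vec[2] = 3.0
        warped = warp_dose_to_reference(dose, DisplacementField(1, vec), grid)
        inner = warped[:, :, 2:-3]
        expected = 0.7 * (z + 3.0)
        np.testing.assert_allclose(
            inner, np.broadcast_to(expected, grid.shape)[:, :, 2:-3], atol=1e-6)

    def test_preserves_non_negativity(self, rng):
        grid = VoxelGrid((10, 10, 10), (2.0, 2.0, 2.0))
        dose = rng.random(grid.shape)
        vec = rng.normal(0, 2, size=(3, *grid.shape)).astype(np.float32)
        warped = warp_dose_to_reference(dose, DisplacementField(1, vec), grid)
        assert np.all(warped >= 0)

    def test_shape_mismatch_rejected(self):
        grid = VoxelGrid((10, 10, 10), (2.0, 2.0, 2.0))
        field = DisplacementField(0, np.zeros((3, 8, 8, 8), dtype=np.float32))
        with pytest.raises(GeometryError):
            warp_dose_to_reference(np.zeros(grid.shape), field, grid)


class TestAccumulation:
    def test_mu_conservation(self, hi_acc):
        for mode in ("itv", "tracking"):
            assert hi_acc[mode].mu_share_total == pytest.approx(1.0, abs=1e-12)
            per_phase = sum(hi_acc[mode].per_phase_share.values())
            assert per_phase == pytest.approx(1.0, abs=1e-12)

    def test_zero_motion_4d_equals_3d(self, zero_pack):
        """Degenerate case: without motion the accumulated 4D dose equals
        the planned 3D dose everywhere."""
        for arm, acc_key in (("itv", "acc_itv"), ("tracking", "acc_tracking")):
            d3 = zero_pack[arm].dose.data
            d4 = zero_pack[acc_key].dose.data
            assert np.abs(d4 - d3).max() < 1e-6

    def test_tracking_invariance_under_rigid_motion(self, hi_pack, hi_acc):
        """Perfect tracking of rigid motion reproduces the static tumor dose:
        GTV Dmean of the 4D tracking dose within 2% of prescription of the
        3D tracking plan."""
        gtv = hi_pack["ssets"]["tracking"]["gtv"].data
        d3 = hi_pack["tracking"].dose.data[gtv].mean()
        d4 = hi_acc["tracking"].dose.data[gtv].mean()
        assert abs(d4 - d3) <= 0.02 * 25.0

    def test_itv_4d_coverage_bounds(self, hi_pack, hi_acc):
        """ITV-mode 4D GTV coverage is non-negative and bounded by the
        static plan's maximum: phase averaging and warping redistribute the
        static dose, they cannot create dose above its peak."""
        from sbrt4d.dosemetrics import dose_at_volume_percent

        gtv = hi_pack["ssets"]["tracking"]["gtv"]
        d95_4d = dose_at_volume_percent(hi_acc["itv"].dose.data, 95.0, gtv)
        dmax_3d = hi_pack["itv"].dose.data.max()
        assert d95_4d >= 0.0
        assert d95_4d <= dmax_3d + 0.25
        # and the 4D maximum itself stays below the static maximum
        assert hi_acc["itv"].dose.data.max() <= dmax_3d + 0.25

    def test_invalid_mode(self, hi_pack):
        with pytest.raises(InvalidConfigError):
            accumulate_4d(hi_pack["engine"], hi_pack["itv"].plan,
                          hi_pack["phantom"], "gated")


class TestPhaseSubdose:
    def test_zero_mu_segment(self, zero_pack):
        from sbrt4d.dose4d import ArcSegment

        seg = ArcSegment(0.0, 36.0, 0, 0.0, 0.0, 0.4)
        dose = phase_subdose(zero_pack["engine"], zero_pack["itv"].plan, seg,
                             zero_pack["phantom"], "itv")
        assert not dose.any()

    def test_reference_phase_modes_agree(self, hi_pack):
        """On the reference phase the tracking shift vanishes, so both modes
        give the identical angular slice of the 3D dose."""
        from sbrt4d.dose4d import ArcSegment

        ref = hi_pack["phantom"].reference_phase
        seg = ArcSegment(40.0, 76.0, ref, 0.1, 0.0, 0.4)
        kw = dict(engine=hi_pack["engine"], plan=hi_pack["tracking"].plan,
                  segment=seg, phantom=hi_pack["phantom"])
        np.testing.assert_allclose(phase_subdose(mode="itv", **kw),
                                   phase_subdose(mode="tracking", **kw),
                                   atol=1e-9)

    def test_tracking_subdose_is_shifted_reference(self, hi_pack):
        """Rigid motion + tracking: the sub-dose on a displaced phase is the
        reference sub-dose rigidly translated by the phase displacement."""
        from scipy import ndimage

        from sbrt4d.dose4d import ArcSegment

        phantom = hi_pack["phantom"]
        engine = hi_pack["engine"]
        plan = hi_pack["tracking"].plan
        ref = phantom.reference_phase
        k = int(np.argmax(np.abs(phantom.trace - phantom.trace[ref])))
        shift = phantom.fields[k].vectors.reshape(3, -1)[:, 0]
        seg_ref = ArcSegment(90.0, 126.0, ref, 0.1, 0.0, 0.4)
        seg_k = ArcSegment(90.0, 126.0, k, 0.1, 0.0, 0.4)
        d_ref = phase_subdose(engine, plan, seg_ref, phantom, "tracking")
        d_k = phase_subdose(engine, plan, seg_k, phantom, "tracking")
        translated = ndimage.shift(d_ref, shift / 2.0, order=1)  # mm -> voxels
        gtv_k = phantom.phases[k].masks["gtv"]
        np.testing.assert_allclose(d_k[gtv_k], translated[gtv_k],
                                   atol=0.06 * d_ref.max())
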