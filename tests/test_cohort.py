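"""Fixture loading, cohort summaries, and statistics versus brute-force
oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from sbrt4d.cohort import (
    PatientRecord, linear_fit, load_table1, percentile, reproduce_table1_report,
    spearman_rho, summarize_cohort, wilcoxon_signed_rank,
)
from sbrt4d.errors import (
    DomainError, FixtureCorruptionError, UndefinedStatisticError,
)


def brute_force_wilcoxon_p(d):
    """Independent oracle: full enumeration over all 2^n sign vectors."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n_le = n_ge = 0
    for bits in range(2**n):
        signs = np.array([(bits >> i) & 1 for i in range(n)])
        w = ranks[signs == 1].sum()
        n_le += w <= w_obs + 1e-9
        n_ge += w >= w_obs - 1e-9
    return min(1.0, 2.0 * min(n_le, n_ge) / 2**n)


class TestFixture:
    def test_twelve_records(self, table1_records):
        assert len(table1_records) == 12
        assert [r.patient for r in table1_records] == list(range(1, 13))

    def test_patient7_row(self, table1_records):
        r = table1_records[6]
        assert (r.ptv_itv_cc, r.ptv_track_cc) == (83.0, 70.6)
        assert (r.ap_mm, r.si_mm, r.lr_mm) == (1.0, 1.6, 0.8)
        assert r.motion3d_printed_mm == 2.1
        # recomputed magnitude sits within a tenth of the printed value
        assert r.motion3d_mm == pytest.approx(2.05, abs=0.01)

    def test_recomputed_motion_matches_printed(self, table1_records):
        for r in table1_records:
            assert abs(r.motion3d_mm - r.motion3d_printed_mm) <= 0.11

    def test_checksum_guard(self, monkeypatch):
        import sbrt4d.cohort as cohort_mod

        monkeypatch.setattr(cohort_mod, "_FIXTURE_SHA256", "0" * 64)
        with pytest.raises(FixtureCorruptionError):
            load_table1()

    def test_invalid_record_rejected(self):
        with pytest.raises(DomainError):
            PatientRecord(1, -5.0, 3.0, 1, 1, 1)


class TestCohortSummary:
    def test_volume_rows(self, table1_records):
        s = summarize_cohort(table1_records)
        itv = s.columns["ptv_itv_cc"]
        assert itv["median"] == pytest.approx(131.3, abs=0.06)
        assert itv["mean"] == pytest.approx(142.8, abs=0.06)
        assert itv["sd"] == pytest.approx(71.2, abs=0.06)
        # quartiles follow the averaged-inverted-CDF rule
        assert itv["p25"] == pytest.approx(96.4, abs=0.06)
        assert itv["p75"] == pytest.approx(207.2, abs=0.06)
        trk = s.columns["ptv_track_cc"]
        assert trk["median"] == pytest.approx(109.0, abs=0.06)
        assert trk["mean"] == pytest.approx(121.7, abs=0.06)
        assert trk["p25"] == pytest.approx(80.4, abs=0.06)
        assert trk["p75"] == pytest.approx(182.4, abs=0.06)

    def test_motion_rows(self, table1_records):
        s = summarize_cohort(table1_records)
        assert s.columns["si_mm"]["median"] == pytest.approx(4.5, abs=0.06)
        assert s.columns["motion3d_mm"]["mean"] == pytest.approx(5.6, abs=0.06)

    def test_reduction_statistics(self, table1_records):
        s = summarize_cohort(table1_records)
        assert s.reduction_mean_abs == pytest.approx(16.8, abs=0.1)
        assert s.reduction_sd_abs == pytest.approx(8.4, abs=0.1)
        assert s.reduction_min_abs == pytest.approx(4.7, abs=0.05)
        assert s.reduction_max_abs == pytest.approx(39.2, abs=0.05)
        assert np.all(s.reduction_signed_percent < 0)

    def test_median_between_quartiles(self, table1_records):
        s = summarize_cohort(table1_records)
        for col in s.columns.values():
            assert col["p25"] <= col["median"] <= col["p75"]

    def test_percentile_rule(self):
        # q*n integer: midpoint of the two adjacent order statistics
        assert percentile(np.arange(1, 13), 25.0) == pytest.approx(3.5)
        assert percentile(np.arange(1, 13), 50.0) == pytest.approx(6.5)


class TestWilcoxon:
    def test_all_one_sign_exact_p(self, table1_records):
        itv = [r.ptv_itv_cc for r in table1_records]
        trk = [r.ptv_track_cc for r in table1_records]
        res = wilcoxon_signed_rank(itv, trk)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2.0 / 4096.0, rel=1e-12)
        assert res.p_value < 0.01

    def test_identical_inputs_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    def test_matches_enumeration_oracle(self, rng):
        """200 random paired samples (n <= 12, with ties and zeros) against
        the full 2^n enumeration."""
        for _ in range(200):
            n = int(rng.integers(3, 13))
            a = rng.integers(0, 6, size=n).astype(float)
            b = rng.integers(0, 6, size=n).astype(float)
            if np.all(a == b):
                continue
            res = wilcoxon_signed_rank(a, b)
            assert res.p_value == pytest.approx(brute_force_wilcoxon_p(a - b),
                                                abs=1e-10)

    def test_large_n_matches_normal_approximation(self, rng):
        a = rng.normal(10, 2, size=40)
        b = a + rng.normal(0.5, 1, size=40)
        res = wilcoxon_signed_rank(a, b)
        ref = sps.wilcoxon(a, b, correction=True, mode="approx")
        assert res.method == "normal-approx"
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)


class TestSpearman:
    def test_fixture_correlation(self, table1_records):
        red = np.array([r.reduction_percent for r in table1_records])
        m3d = np.array([r.motion3d_printed_mm for r in table1_records])
        res = spearman_rho(m3d, red)
        assert res.statistic == pytest.approx(-0.46, abs=0.01)
        assert res.p_value == pytest.approx(0.131, abs=0.01)

    def test_monotone_pairs(self):
        x = np.arange(10.0)
        assert spearman_rho(x, x**3).statistic == pytest.approx(1.0)
        assert spearman_rho(x, -np.exp(x)).statistic == pytest.approx(-1.0)

    def test_tie_free_closed_form(self, rng):
        x = rng.permutation(20).astype(float)
        y = rng.permutation(20).astype(float)
        d = sps.rankdata(x) - sps.rankdata(y)
        closed = 1 - 6 * (d**2).sum() / (20 * (20**2 - 1))
        assert spearman_rho(x, y).statistic == pytest.approx(closed, abs=1e-12)

    def test_constant_input_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_exact_permutation_small_n(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 1, 4, 3, 6, 5])
        res = spearman_rho(x, y, p_method="permutation")
        assert res.method == "exact-permutation"
        assert 0.0 < res.p_value <= 1.0


class TestLinearFit:
    def test_exact_line(self):
        x = np.linspace(-3, 7, 15)
        res = linear_fit(x, 3.0 * x + 1.0)
        assert res.extra["slope"] == pytest.approx(3.0)
        assert res.extra["intercept"] == pytest.approx(1.0)
        assert res.extra["r2"] == pytest.approx(1.0)

    def test_residual_orthogonality(self, rng):
        x = rng.normal(size=30)
        y = 2 * x + rng.normal(size=30)
        res = linear_fit(x, y)
        resid = y - (res.extra["slope"] * x + res.extra["intercept"])
        assert abs(resid @ x) < 1e-9 * np.linalg.norm(x) * np.linalg.norm(y)

    def test_constant_x_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            linear_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestReport:
    def test_report_values(self, table1_records):
        rep = reproduce_table1_report(table1_records)
        assert rep["n_patients"] == 12
        assert rep["motion3d_min_mm"] == pytest.approx(1.3, abs=0.05)
        assert rep["motion3d_max_mm"] == pytest.approx(11.2, abs=0.05)
        assert rep["reduction_max_abs_percent"] == pytest.approx(39.2, abs=0.05)
        assert rep["wilcoxon_ptv_p"] < 0.01
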