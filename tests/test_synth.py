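"""Synthetic cohort generator: determinism, calibration recovery,
trajectory construction and frame geometry."""

import math

import numpy as np
import pytest

from qsea_morph import (
    TABLE1_CALIBRATIONS,
    CohortConfig,
    FrameSpec,
    assign_grade,
    frame_spec_for,
    gardner_tier,
    render_mask,
    sample_cohorts,
    sample_group,
    sample_trajectory,
)
from qsea_morph.synth import (
    MILESTONES,
    CalibrationError,
    draw_anchors,
    draw_timings,
)


class TestDeterminismAndStructure:
    def test_same_seed_same_cohort(self):
        cfg = CohortConfig(n_cycles=30, seed=99)
        a = sample_cohorts(cfg)
        b = sample_cohorts(cfg)
        assert a.to_frame().to_csv() == b.to_frame().to_csv()
        assert a.trajectories_frame().to_csv() == b.trajectories_frame().to_csv()

    def test_different_seed_differs(self):
        a = sample_cohorts(CohortConfig(n_cycles=10, seed=1))
        b = sample_cohorts(CohortConfig(n_cycles=10, seed=2))
        assert a.to_frame().to_csv() != b.to_frame().to_csv()

    def test_zero_cycles_rejected(self):
        with pytest.raises(ValueError, match="empty cohort"):
            CohortConfig(n_cycles=0, seed=1)

    def test_missing_calibration_raises(self):
        cals = {"aneuploid": TABLE1_CALIBRATIONS["aneuploid"]}
        with pytest.raises(CalibrationError, match="euploid"):
            sample_cohorts(CohortConfig(n_cycles=50, seed=3), cals)

    def test_each_embryo_in_exactly_one_cycle(self, small_cohort):
        df = small_cohort.to_frame()
        assert df["embryo_id"].is_unique
        assert set(df["cycle_id"]) == set(small_cohort.cycles)

    def test_cohort_filters_are_disjoint_selections(self, small_cohort):
        mixed = set(small_cohort.mixed_ploidy_cycles())
        multi_eu = set(small_cohort.multi_euploid_transferred_cycles())
        df = small_cohort.to_frame()
        for cid in mixed:
            sub = df[df.cycle_id == cid]
            assert set(sub.ploidy) == {"euploid", "aneuploid"}
        for cid in multi_eu:
            sub = df[(df.cycle_id == cid) & (df.ploidy == "euploid")]
            assert len(sub) >= 2 and sub.transferred.any()

    def test_euploid_fraction_within_binomial_99_interval(self):
        cohort = sample_cohorts(CohortConfig(n_cycles=786, seed=17))
        df = cohort.to_frame()
        n = len(df)
        p = 886 / 2184
        frac = (df.ploidy == "euploid").mean()
        half = 2.576 * math.sqrt(p * (1 - p) / n)
        assert abs(frac - p) < half


class TestTransfers:
    def test_only_euploids_transferred_and_lb_requires_transfer(self, small_cohort):
        for e in small_cohort.embryos:
            if e.transferred:
                assert e.ploidy == "euploid"
                assert e.live_birth is not None
            else:
                assert e.live_birth is None and e.transfer_order is None

    def test_transfer_orders_consecutive_and_stop_at_live_birth(self, small_cohort):
        for embs in small_cohort.cycles.values():
            tr = sorted(
                (e for e in embs if e.transferred), key=lambda e: e.transfer_order
            )
            if not tr:
                continue
            assert [e.transfer_order for e in tr] == list(range(1, len(tr) + 1))
            for e in tr[:-1]:  # a live birth ends the sequence
                assert e.live_birth is False


class TestTimingsAndAnchors:
    def test_timings_ordered_with_assay_window(self, small_cohort):
        for e in small_cohort.embryos:
            t = e.timings
            assert t["tSB"] <= t["tB"] <= t["tEB"] <= t["t_biopsy"]
            assert t["t_biopsy"] - t["tB"] >= 5.5

    def test_draw_timings_deterministic(self):
        cal = TABLE1_CALIBRATIONS["euploid"]
        a = draw_timings(cal, np.random.default_rng(5), 0.85)
        b = draw_timings(cal, np.random.default_rng(5), 0.85)
        assert a == b

    def test_anchor_nesting_per_embryo(self, rng):
        cal = TABLE1_CALIBRATIONS["aneuploid"]
        for _ in range(200):
            a = draw_anchors(cal, rng)
            for ms in MILESTONES:
                assert a["zp_A"][ms] > a["emb_A"][ms] >= a["ICM_A"][ms] > 0

    def test_calibration_recovery_within_3se(self):
        """Sample means of the drawn anchors recover the configured group
        means within 3 standard errors at n=500."""
        cal = TABLE1_CALIBRATIONS["euploid"]
        embs = sample_group(cal, 500, seed=11)
        for metric in ("zp_A", "emb_A", "zp_T", "ICM_A"):
            for ms in MILESTONES:
                mean, sd = cal.anchors[metric][ms]
                draws = [e.anchors[metric][ms] for e in embs]
                se = sd / math.sqrt(len(draws))
                assert abs(np.mean(draws) - mean) < 3 * se, (metric, ms)

    def test_anchor_recovery_in_trajectories(self, small_cohort):
        for e in small_cohort.embryos[:50]:
            for metric, ts in e.trajectories.items():
                for ms in MILESTONES:
                    v = ts.value_at(e.timings[ms])
                    assert v == pytest.approx(e.anchors[metric][ms], rel=1e-9)


class TestTrajectories:
    TIMINGS = {"tSB": 104.0, "tB": 110.0, "tEB": 118.0, "t_biopsy": 133.0}

    def test_passes_through_anchors_exactly(self):
        anchors = {"tB": 14288.0, "tEB": 17435.0, "t_biopsy": 24082.0}
        ts = sample_trajectory(anchors, self.TIMINGS, 10.0)
        for ms, v in anchors.items():
            assert ts.value_at(self.TIMINGS[ms]) == pytest.approx(v, rel=1e-12)

    def test_constant_anchors_give_constant_series(self):
        ts = sample_trajectory(
            {"tB": 5.0, "tEB": 5.0, "t_biopsy": 5.0}, self.TIMINGS, 15.0
        )
        assert np.allclose(ts.values, 5.0)

    def test_midpoint_is_geometric_mean(self):
        # exponential interpolation: halfway in time -> sqrt(a*b)
        a, b = 10.0, 40.0
        ts = sample_trajectory({"tB": a, "tEB": b, "t_biopsy": b}, self.TIMINGS, 1.0)
        mid = (self.TIMINGS["tB"] + self.TIMINGS["tEB"]) / 2
        assert ts.value_at(mid) == pytest.approx(math.sqrt(a * b), rel=1e-6)

    def test_monotone_between_ordered_anchors(self):
        up = sample_trajectory({"tB": 10.0, "tEB": 20.0, "t_biopsy": 30.0}, self.TIMINGS, 5.0)
        assert np.all(np.diff(up.values) >= -1e-12)
        down = sample_trajectory({"tB": 16.4, "tEB": 12.9, "t_biopsy": 8.1}, self.TIMINGS, 5.0)
        assert np.all(np.diff(down.values) <= 1e-12)

    def test_zero_anchor_rejected(self):
        with pytest.raises(ValueError, match="anchors"):
            sample_trajectory({"tB": 0.0, "tEB": 1.0, "t_biopsy": 2.0}, self.TIMINGS, 10.0)

    def test_unordered_timings_rejected(self):
        bad = dict(self.TIMINGS, tEB=150.0)
        with pytest.raises(ValueError, match="ordered"):
            sample_trajectory({"tB": 1.0, "tEB": 1.0, "t_biopsy": 1.0}, bad, 10.0)


class TestGrades:
    def test_letter_grade_tier_mapping(self):
        assert gardner_tier("AA") == "excellent"
        assert gardner_tier("BA") == "good"
        assert gardner_tier("AB") == "good"
        assert gardner_tier("CA") == "average"
        assert gardner_tier("CB") == "low"
        with pytest.raises(ValueError):
            gardner_tier("AD")

    def test_strength_one_is_deterministic_dominance(self, rng):
        tiers_eu = {assign_grade(c, 1.0, rng) for c in (1, 2) for _ in range(50)}
        tiers_an = {assign_grade(0, 1.0, rng) for _ in range(50)}
        assert tiers_eu == {"excellent", "good"}
        assert tiers_an == {"average"}

    def test_strength_zero_is_independent_of_competence(self, rng):
        from scipy.stats import chi2_contingency

        tiers = ("excellent", "good", "average", "low")
        counts = np.zeros((2, 4))
        for i, comp in enumerate((0, 2)):
            for _ in range(2000):
                counts[i, tiers.index(assign_grade(comp, 0.0, rng))] += 1
        assert chi2_contingency(counts).pvalue > 0.001


class TestFrameGeometry:
    def test_spec_realizes_requested_quantities(self):
        spec = frame_spec_for(zp_A=24082.0, zp_T=8.1, emb_A=23612.0)
        assert math.pi * spec.r_out**2 == pytest.approx(24082.0, rel=1e-12)
        assert spec.analytic_zp_thickness == pytest.approx(8.1, abs=1e-9)

    def test_area_faithful_branch_when_geometry_allows(self):
        # wide annulus: both areas and the thickness can be honored
        spec = frame_spec_for(zp_A=math.pi * 80**2, zp_T=25.0, emb_A=math.pi * 60**2)
        assert spec.r_in == pytest.approx(60.0, rel=1e-9)
        assert spec.analytic_zp_thickness == pytest.approx(25.0, abs=1e-9)

    def test_tiny_thickness_floors_at_margin(self):
        spec = frame_spec_for(zp_A=math.pi * 80**2, zp_T=0.5, min_gap=2.0)
        assert spec.analytic_zp_thickness == pytest.approx(2.0, abs=1e-9)

    def test_nonnested_spec_rejected(self):
        with pytest.raises(ValueError):
            FrameSpec(r_out=50, r_in=60)
        with pytest.raises(ValueError):
            FrameSpec(r_out=50, r_in=40, offset=20)

    def test_contour_exceeding_frame_rejected(self):
        with pytest.raises(ValueError, match="frame"):
            render_mask(FrameSpec(r_out=80, r_in=60), scale=1.0, side=100)
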