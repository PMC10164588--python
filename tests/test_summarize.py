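"""Tests of per-clone/cohort statistics, union coverage and linkage."""

import math

import numpy as np
import pytest

from oracles import bitmap_union, point_coverage_mc
from ctcnt import reference_cohort as ref
from ctcnt import summarize
from ctcnt.types import LinkageCurve, TransferSegment, ValidationError

G = ref.DONOR_GENOME_LENGTH


class TestCloneSummary:
    @pytest.mark.parametrize("clone", ref.MULTI_MARKER_COHORT, ids=lambda c: c.clone_id)
    def test_reference_cohort_identities(self, clone):
        """mean = total/n and pct = 100*total/G (2 dp) reproduce every
        derived column of the published nine-clone reference table."""
        assert summarize.mean_event_kb(clone.total_transferred_kb, clone.n_events) == (
            clone.mean_event_kb
        )
        assert summarize.pct_of_genome(clone.total_transferred_kb, G) == clone.pct_genome

    def test_cohort_overall_mean_pools_events(self):
        totals = sum(c.total_transferred_kb for c in ref.MULTI_MARKER_COHORT)
        events = sum(c.n_events for c in ref.MULTI_MARKER_COHORT)
        assert round(totals / events, 2) == ref.OVERALL_MEAN_EVENT_KB  # 27.58

    def test_empty_is_zeros(self):
        s = summarize.clone_summary([], G)
        assert (s.n_events, s.total_transferred_kb, s.pct_genome) == (0, 0.0, 0.0)

    def test_summary_from_intervals(self):
        segs = [(1, 10_000), (20_001, 30_000)]
        s = summarize.clone_summary(segs, G, clone_id="x")
        assert s.n_events == 2
        assert s.total_transferred_kb == 20.0
        assert s.mean_event_kb == 10.0
        assert s.pct_genome == round(100 * 20_000 / G, 2)

    def test_mean_times_n_equals_total_to_rounding(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(1, 60))
            lengths = rng.integers(600, 300_000, size=n)
            segs, pos = [], 1
            for L in lengths:
                segs.append((pos, pos + int(L) - 1))
                pos += int(L) + 1_000
            s = summarize.clone_summary(segs, G)
            assert s.mean_event_kb * s.n_events == pytest.approx(
                s.total_transferred_kb, abs=0.005 * n
            )


class TestUnionCoverage:
    def test_identical_clones_collapse(self):
        clone = [(1_000, 5_000), (8_000, 9_000)]
        union, _ = summarize.union_coverage([clone, clone], 100_000)
        assert union == 4_001 + 1_001

    def test_disjoint_clones_add(self):
        union, pct = summarize.union_coverage(
            [[(1, 1_000)], [(5_001, 6_000)]], 100_000
        )
        assert union == 2_000
        assert pct == 2.0

    def test_matches_bitmap_oracle_on_random_sets(self):
        rng = np.random.default_rng(9)
        Gsmall = 100_000
        for _ in range(20):
            clones = []
            for _ in range(5):
                n = int(rng.integers(0, 8))
                clone = []
                for _ in range(n):
                    s = int(rng.integers(1, Gsmall + 1))
                    L = int(rng.integers(1, 20_000))
                    e = s + L - 1
                    clone.append((s, e - Gsmall) if e > Gsmall else (s, e))
                clones.append(clone)
            union, _ = summarize.union_coverage(clones, Gsmall)
            assert union == bitmap_union(clones, Gsmall)

    def test_wrapped_interval_on_linear_genome_rejected(self):
        with pytest.raises(ValidationError):
            summarize.union_coverage([[(90_000, 5_000)]], 100_000, circular=False)


class TestCoInheritance:
    def test_query_equals_selected_locus_is_one(self):
        clones = [[(100, 2_000)], [(500, 1_500)], [(90_000, 95_000)]]
        ci = summarize.co_inheritance_ratio(clones, 1_000, 1_000)
        assert ci.ratio == 1.0
        assert ci.n_selected == 2  # third clone not selected -> filtered

    def test_unconverted_query_is_zero(self):
        clones = [[(100, 2_000)], [(500, 1_500)]]
        ci = summarize.co_inheritance_ratio(clones, 1_000, 50_000)
        assert ci.ratio == 0.0
        assert ci.ci_low == 0.0 and ci.ci_high < 1.0

    def test_closed_form_identities(self):
        lam, L = 3.0, 50_000.0
        assert summarize.expected_coinheritance(0, lam, L, G) == pytest.approx(1.0)
        plateau = 1 - math.exp(-lam * L / G)
        far = summarize.expected_coinheritance(2_000_000, lam, L, G)
        assert far == pytest.approx(plateau, rel=1e-6)

    def test_monte_carlo_matches_closed_form(self):
        """Direct simulation of the segment process reproduces the analytic
        co-inheritance ratio at one intermediate distance within 3 SE."""
        lam, L, d = 3.0, 50_000.0, 150_000
        rng = np.random.default_rng(1)
        A, B = 2_000_000, 2_000_000 + d
        cov = point_coverage_mc(rng, 120_000, np.array([A, B]), lam, L, G)
        sel = cov[:, 0]
        ratio = cov[sel, 1].mean()
        expected = summarize.expected_coinheritance(d, lam, L, G)
        se = math.sqrt(expected * (1 - expected) / sel.sum())
        assert abs(ratio - expected) < 3 * se

    def test_simulated_cohort_against_closed_form(self):
        """co_inheritance_ratio on truth segment sets from the cohort
        simulator agrees with the closed form at d = 3*L within 3 SE."""
        from ctcnt import simulate
        from ctcnt.types import SimulationConfig

        lam, L = 6.0, 20_000.0
        Gs = 1_000_000
        A = 500_000
        d = int(3 * L)
        cfg = SimulationConfig(
            genome_length=Gs, segments_per_clone_mean=lam, segment_length_mean=L,
            n_clones=1, rng_seed=1,
        )
        rng = np.random.default_rng(2)
        clones = [simulate._draw_segments(cfg, rng) for _ in range(30_000)]
        ci = summarize.co_inheritance_ratio(clones, A, A + d)
        expected = summarize.expected_coinheritance(d, lam, L, Gs)
        se = math.sqrt(expected * (1 - expected) / ci.n_selected)
        assert abs(ci.ratio - expected) < 3 * se
        assert ci.ci_low < expected < ci.ci_high


class TestLinkageDecomposition:
    def test_flat_curve(self):
        curve = LinkageCurve(
            distances=np.array([1e5, 6e5, 1e6]),
            ratios=np.array([0.11, 0.11, 0.11]),
            n_selected=np.array([100, 100, 100]),
        )
        plateau, excess = summarize.linkage_decomposition(curve)
        assert plateau == pytest.approx(0.11)
        assert np.allclose(excess, 0.0)

    def test_single_far_point_sets_plateau(self):
        curve = LinkageCurve(
            distances=np.array([600_000.0]),
            ratios=np.array([0.12]),
            n_selected=np.array([50]),
        )
        plateau, _ = summarize.linkage_decomposition(curve)
        assert plateau == 0.12

    def test_no_far_point_raises(self):
        curve = LinkageCurve(
            distances=np.array([100.0]), ratios=np.array([0.5]), n_selected=np.array([10])
        )
        with pytest.raises(ValidationError):
            summarize.linkage_decomposition(curve)

    def test_analytic_curve_decays_then_plateaus(self):
        """Excess over the plateau is non-increasing with distance and the
        observed reference ratios show the same decay-then-plateau shape."""
        lam, L = 15.0, 30_000.0
        ds = np.array([0, 30_000, 62_000, 150_000, 475_000, 988_000, 1_950_000], float)
        ratios = np.array([summarize.expected_coinheritance(d, lam, L, G) for d in ds])
        curve = LinkageCurve(distances=ds, ratios=ratios, n_selected=np.full(ds.size, 1))
        plateau, excess = summarize.linkage_decomposition(curve)
        assert np.all(np.diff(excess) <= 1e-12)
        assert ratios[0] == pytest.approx(1.0)
        assert ratios[-1] == pytest.approx(plateau, abs=1e-3)
        # same qualitative shape as the published marker co-inheritance data
        obs = [r for _, _, r in ref.TRPC_COINHERITANCE]
        assert all(a >= b for a, b in zip(obs, obs[1:]))
        assert obs[0] > 2 * obs[-1]

    def test_farthest_mode_matches_published_plateau_estimate(self):
        ds = np.array([d for _, d, _ in ref.TRPC_COINHERITANCE], float)
        rs = np.array([r for _, _, r in ref.TRPC_COINHERITANCE])
        curve = LinkageCurve(distances=ds, ratios=rs, n_selected=np.full(ds.size, 1))
        plateau, _ = summarize.linkage_decomposition(curve, mode="farthest")
        assert plateau == ref.DOUBLE_TRANSFORMATION_RATIO  # trpC-cysE point


class TestTransformationEfficiency:
    def test_zero_colonies(self):
        assert summarize.transformation_efficiency(0, 0.1, 0.46) == 0.0

    def test_donor_culture_arithmetic(self):
        # 100 colonies from 0.1 ml of a 0.46 ug/ml donor culture
        eff = summarize.transformation_efficiency(100, 0.1, ref.DONOR_CULTURE_DNA_UG_PER_ML)
        assert eff == pytest.approx(2_173.9, abs=0.05)

    def test_linear_in_colonies(self):
        one = summarize.transformation_efficiency(10, 0.1, 0.46)
        ten = summarize.transformation_efficiency(100, 0.1, 0.46)
        assert ten == pytest.approx(10 * one)

    def test_invalid_volume_rejected(self):
        with pytest.raises(ValidationError):
            summarize.transformation_efficiency(10, 0.0, 0.46)
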