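import itertools
import warnings

import numpy as np
import pytest
from scipy import stats

from wormneurite import (
    CohortSpec,
    EventPositions,
    NeuronSpec,
    association_test,
    bootstrap_ci_mean,
    classify_plm,
    detect_bends,
    empty_space_cdf,
    ks_two_sample,
    make_neuron,
    nearest_bend_distances,
    positions_from_distal,
    sample_cohort_positions,
)
from wormneurite.classification import NodeLabel, branch_inventory
from wormneurite.morphometry import MainBranchGeometry


def ep(bends, outs, L, nid="n"):
    return EventPositions(nid, np.asarray(bends, float),
                          np.asarray(outs, float), L)


def signed_rank_enumeration(diffs):
    """Exact one-sided signed-rank p by exhaustive 2^n sign enumeration."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w >= w_obs:
            count += 1
    return w_obs, count / 2**n


class TestPositionsFromDistal:
    def _classified(self):
        tree, _ = make_neuron(
            NeuronSpec(
                main_length=100.0,
                bend_list=((10.0, 120.0),),
                branch_list=((40.0, 5.0, "neuriteoutgrowth"),),
                rng_seed=1,
            )
        )
        return classify_plm(tree)

    def test_positions_measured_from_distal_tip(self):
        ct = self._classified()
        bends = detect_bends(MainBranchGeometry.from_classified(ct))
        outs = [
            b for b in branch_inventory(ct)
            if b.label == NodeLabel.NEURITE_OUTGROWTH
        ]
        pos = positions_from_distal(ct, bends, outs)
        L = ct.main_length
        assert pos.bend_positions[0] == pytest.approx(L - 10.0, abs=0.5)
        assert pos.outgrowth_positions[0] == pytest.approx(L - 40.0, abs=0.5)

    def test_orientation_consistency(self):
        ct = self._classified()
        bends = detect_bends(MainBranchGeometry.from_classified(ct))
        pos = positions_from_distal(ct, bends, [])
        assert (
            pos.bend_positions[0] + bends[0].arclength
            == pytest.approx(ct.main_length)
        )

    def test_event_at_tip_maps_to_zero(self):
        class E:
            arclength = 100.0

        ct = self._classified()
        L = ct.main_length

        class E2:
            arclength = L

        pos = positions_from_distal(ct, [E2], [])
        assert pos.bend_positions[0] == 0.0


class TestNearestBendDistances:
    def test_simple_cases(self):
        assert nearest_bend_distances(ep([10, 50], [12], 100))[0] == 2.0
        assert nearest_bend_distances(ep([10], [10], 100))[0] == 0.0

    def test_no_bends_errors(self):
        with pytest.raises(ValueError):
            nearest_bend_distances(ep([], [5], 100))

    def test_matches_brute_force(self, rng):
        for _ in range(100):
            L = rng.uniform(50, 200)
            bends = rng.uniform(0, L, rng.integers(1, 10))
            outs = rng.uniform(0, L, rng.integers(1, 8))
            d = nearest_bend_distances(ep(bends, outs, L))
            brute = [min(abs(o - b) for b in bends) for o in outs]
            assert np.allclose(d, brute)


class TestEmptySpaceCdf:
    def test_single_midpoint_bend_analytic(self):
        e = ep([50.0], [], 100.0)
        r = np.array([0.0, 10.0, 25.0, 50.0, 80.0])
        assert np.allclose(
            empty_space_cdf(e, r), [0.0, 0.2, 0.5, 1.0, 1.0]
        )

    def test_dense_bends_saturate(self):
        e = ep(np.arange(1.0, 100.0, 1.0), [], 100.0)
        assert empty_space_cdf(e, [1.0])[0] == 1.0

    def test_non_decreasing_to_one(self, rng):
        e = ep(rng.uniform(0, 100, 6), [], 100.0)
        grid = np.linspace(0, 120, 200)
        F = empty_space_cdf(e, grid)
        assert np.all(np.diff(F) >= -1e-12)
        assert F[-1] == pytest.approx(1.0)

    def test_matches_dense_sampling(self, rng):
        for _ in range(20):
            L = 100.0
            bends = rng.uniform(0, L, rng.integers(1, 12))
            e = ep(bends, [], L)
            grid = np.array([0.5, 1.0, 2.0, 5.0])
            F = empty_space_cdf(e, grid)
            x = np.arange(0.005, L, 0.01)
            dmin = np.min(np.abs(x[:, None] - bends[None, :]), axis=1)
            mc = [(dmin <= r).mean() for r in grid]
            assert np.allclose(F, mc, atol=0.005)


class TestAssociationTest:
    def test_outgrowths_on_bends_reject(self):
        cohort = []
        rng = np.random.default_rng(0)
        for j in range(8):
            bends = np.sort(rng.uniform(10, 290, 4))
            cohort.append(ep(bends, bends[:2], 300.0, nid=str(j)))
        res = association_test(cohort, r=1.0)
        assert np.all(res.observed_fractions == 1.0)
        assert np.all(res.expected_fractions < 1.0)
        assert res.p_value < 0.05

    def test_exact_signed_rank_example(self):
        # 8 all-positive differences: W = 36, one-sided p = 1/256
        diffs = [0.2, 0.1, 0.3, 0.15, 0.05, 0.25, 0.1, 0.2]
        w, p = signed_rank_enumeration(diffs)
        assert w == 36.0
        assert p == pytest.approx(1 / 256)
        res = stats.wilcoxon(diffs, alternative="greater", method="exact")
        assert res.statistic == w
        assert res.pvalue == pytest.approx(p)

    def test_statistic_matches_enumeration_on_mixed_signs(self, rng):
        for _ in range(5):
            diffs = rng.normal(0.05, 0.2, 9)
            w, p = signed_rank_enumeration(diffs)
            res = stats.wilcoxon(
                diffs[diffs != 0], alternative="greater", method="exact"
            )
            assert res.statistic == w
            assert res.pvalue == pytest.approx(p)

    def test_degenerate_all_zero_differences(self):
        cohort = [ep([10.0], [10.0], 20.0, nid=str(j)) for j in range(6)]
        # obs fraction 1 everywhere; F(1) = 2/20 = 0.1, so diffs nonzero —
        # construct true zeros instead: bends everywhere
        cohort = [
            ep(np.arange(0.5, 20.0, 1.0), [3.0], 20.0, nid=str(j))
            for j in range(6)
        ]
        res = association_test(cohort, r=1.0)
        assert res.degenerate
        assert res.p_value == 1.0

    def test_conservative_in_sparse_outgrowth_regime(self):
        """With few outgrowths per neuron the paired differences are skewed
        (P(diff>0) < 1/2 although E[diff] = 0) and the signed-rank test
        under-rejects; it must never over-reject."""
        rng = np.random.default_rng(42)
        rej = []
        for _ in range(300):
            cohort = sample_cohort_positions(
                CohortSpec(coupling_prob=0.0), rng
            )
            usable = [
                e for e in cohort
                if e.bend_positions.size and e.outgrowth_positions.size
            ]
            if len(usable) < 6:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rej.append(association_test(usable).p_value <= 0.05)
        assert np.mean(rej) <= 0.05

    def test_pooled_curves_shapes(self):
        rng = np.random.default_rng(1)
        cohort = sample_cohort_positions(CohortSpec(rng_seed=2), rng)
        usable = [
            e for e in cohort
            if e.bend_positions.size and e.outgrowth_positions.size
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = association_test(usable)
        assert res.grid.shape == res.nearest_distance_cdf.shape
        assert res.grid.shape == res.empty_space_curve.shape
        assert np.all(np.diff(res.empty_space_curve) >= -1e-12)
        assert np.all(np.diff(res.nearest_distance_cdf) >= -1e-12)


class TestKsTwoSample:
    def test_identical_samples(self):
        d, p = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0
        assert p == 1.0

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert d == 1.0

    def test_shifted_uniforms_match_analytic_sup(self, rng):
        a = rng.uniform(0, 1, 200)
        b = rng.uniform(0.3, 1.3, 200)
        d, p = ks_two_sample(a, b)
        assert d == pytest.approx(0.3, abs=0.08)
        assert p < 1e-6

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


class TestBootstrapCiMean:
    def test_constant_values_zero_width(self):
        lo, hi = bootstrap_ci_mean([3.0] * 10, n_boot=1000, seed=0)
        assert lo == hi == 3.0

    def test_matches_t_interval_width(self, rng):
        x = rng.normal(0, 1, 100)
        lo, hi = bootstrap_ci_mean(x, n_boot=10_000, seed=1)
        t_half = stats.t.ppf(0.975, 99) * x.std(ddof=1) / 10
        width = hi - lo
        assert width == pytest.approx(2 * t_half, rel=0.15)
        assert lo < x.mean() < hi

    def test_deterministic_under_seed(self, rng):
        x = rng.normal(size=30)
        assert bootstrap_ci_mean(x, seed=7) == bootstrap_ci_mean(x, seed=7)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            bootstrap_ci_mean([1.0], n_boot=1000)
        with pytest.raises(ValueError):
            bootstrap_ci_mean([1.0, 2.0], n_boot=10)
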