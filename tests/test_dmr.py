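"""DMR caller: filtering, effect measure, region formation, inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methlink.dmr import (
    CallerParams,
    bh_adjust,
    call_dmrs,
    filter_cpgs,
    find_candidate_regions,
    group_beta_diff,
    permutation_test,
)
from methlink.io import CpGMethylation, SampleSheet


def make_meth(n_meth, n_total, pos=None, samples=None):
    n_meth = np.atleast_2d(np.asarray(n_meth))
    n_total = np.atleast_2d(np.asarray(n_total))
    m = n_meth.shape[0]
    if pos is None:
        pos = np.arange(100, 100 + m * 50, 50)
    if samples is None:
        samples = [f"s{i}" for i in range(n_meth.shape[1])]
    return CpGMethylation(
        np.full(m, "chr1", dtype=object), np.asarray(pos), samples, n_meth, n_total
    )


class TestFilter:
    def test_no_threshold_is_identity(self):
        meth = make_meth([[3, 0], [1, 5]], [[6, 0], [2, 10]])
        sheet = SampleSheet(["s0", "s1"], ["NN", "RM"])
        # frac=0 keeps everything, even zero-coverage cells
        params = CallerParams(min_cov=1, min_cov_frac=0.0)
        out = filter_cpgs(meth, sheet, "RM", "NN", params)
        assert out.n_cpgs == 2

    def test_single_group_coverage_removed(self):
        # covered only in NN; RM group at zero coverage
        meth = make_meth([[3, 0], [2, 4]], [[6, 0], [4, 8]])
        sheet = SampleSheet(["s0", "s1"], ["NN", "RM"])
        params = CallerParams(min_cov=1, min_cov_frac=0.5)
        out = filter_cpgs(meth, sheet, "RM", "NN", params)
        assert out.pos.tolist() == [150]

    def test_nine_of_ten_meets_ninety_percent(self):
        # one sample at 4 reads among 10, min_cov=5, frac=0.9 -> 9/10 passes
        totals = np.full((1, 20), 10)
        totals[0, 0] = 4  # one NN sample below min_cov
        meth = make_meth(np.zeros((1, 20), int), totals)
        sheet = SampleSheet([f"s{i}" for i in range(20)],
                            ["NN"] * 10 + ["RM"] * 10)
        params = CallerParams(min_cov=5, min_cov_frac=0.9)
        out = filter_cpgs(meth, sheet, "NN", "RM", params)
        assert out.n_cpgs == 1

    def test_empty_result_advises(self):
        meth = make_meth([[0, 0]], [[1, 1]])
        sheet = SampleSheet(["s0", "s1"], ["NN", "RM"])
        with pytest.raises(ValueError, match="lower"):
            filter_cpgs(meth, sheet, "NN", "RM", CallerParams(min_cov=50))


class TestGroupBetaDiff:
    def test_identical_groups_zero(self):
        meth = make_meth([[3, 3], [1, 1]], [[6, 6], [4, 4]])
        sheet = SampleSheet(["s0", "s1"], ["NN", "RM"])
        d = group_beta_diff(meth, sheet, "NN", "RM")
        np.testing.assert_allclose(d, 0.0)

    def test_hand_arithmetic(self):
        meth = make_meth([[8, 2]], [[10, 10]])
        sheet = SampleSheet(["s0", "s1"], ["NN", "RM"])
        d = group_beta_diff(meth, sheet, "NN", "RM")
        assert d[0] == pytest.approx(0.6)

    def test_coverage_weighted_not_mean_of_betas(self):
        # group A samples (3/10, 1/90): weighted 4/100 = 0.04,
        # unweighted mean of betas would be (0.3 + 1/90)/2 ~ 0.155
        meth = make_meth([[3, 1, 0]], [[10, 90, 10]],
                         samples=["a1", "a2", "b1"])
        sheet = SampleSheet(["a1", "a2", "b1"], ["NN", "NN", "RM"])
        d = group_beta_diff(meth, sheet, "NN", "RM")
        assert d[0] == pytest.approx(0.04)

    def test_zero_coverage_group_gives_nan(self):
        meth = make_meth([[3, 0]], [[6, 0]])
        sheet = SampleSheet(["s0", "s1"], ["NN", "RM"])
        d = group_beta_diff(meth, sheet, "NN", "RM")
        assert np.isnan(d[0])


class TestCandidateRegions:
    def test_hand_trace_run_rule(self):
        d = np.array([0.15, 0.2, 0.12, -0.05, 0.3])
        pos = np.array([100, 150, 200, 250, 300])
        params = CallerParams(delta=0.1, min_cpgs=3)
        cands = find_candidate_regions(d, pos, params)
        assert len(cands) == 1
        c = cands[0]
        assert (c.first, c.last, c.n_cpgs) == (0, 2, 3)
        assert c.stat == pytest.approx(0.47)

    def test_all_below_delta_empty(self):
        d = np.full(6, 0.05)
        pos = np.arange(100, 400, 50)
        assert find_candidate_regions(d, pos, CallerParams(delta=0.1)) == []

    def test_large_gap_splits_and_discards_short_runs(self):
        d = np.full(4, 0.2)
        pos = np.array([100, 150, 1700, 1750])  # 1550 bp gap after CpG 2
        params = CallerParams(delta=0.1, max_gap=1000, min_cpgs=3)
        assert find_candidate_regions(d, pos, params) == []
        params2 = CallerParams(delta=0.1, max_gap=1000, min_cpgs=2)
        cands = find_candidate_regions(d, pos, params2)
        assert [(c.first, c.last) for c in cands] == [(0, 1), (2, 3)]

    def test_sign_change_splits(self):
        d = np.array([0.2, 0.2, -0.2, -0.2, -0.2])
        pos = np.arange(100, 350, 50)
        cands = find_candidate_regions(d, pos, CallerParams(min_cpgs=2))
        assert [(c.first, c.last) for c in cands] == [(0, 1), (2, 4)]
        assert cands[1].stat == pytest.approx(-0.6)

    def test_chromosome_change_splits(self):
        d = np.full(4, 0.2)
        pos = np.array([100, 150, 100, 150])
        chroms = np.array(["chr1", "chr1", "chr2", "chr2"], dtype=object)
        cands = find_candidate_regions(
            d, pos, CallerParams(min_cpgs=2), chroms=chroms
        )
        assert [(c.first, c.last) for c in cands] == [(0, 1), (2, 3)]

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_raising_delta_never_grows_total_cpg_count(self, data):
        n = data.draw(st.integers(5, 40))
        d = np.array(data.draw(st.lists(
            st.floats(-0.5, 0.5, allow_nan=False), min_size=n, max_size=n)))
        pos = np.cumsum(
            np.array(data.draw(st.lists(st.integers(10, 400), min_size=n,
                                        max_size=n)))) + 100
        lo, hi = sorted(data.draw(st.tuples(st.floats(0.01, 0.4),
                                            st.floats(0.01, 0.4))))
        total = lambda delta: sum(
            c.n_cpgs for c in find_candidate_regions(
                d, pos, CallerParams(delta=delta, min_cpgs=2)))
        assert total(hi) <= total(lo)


class TestPermutationTest:
    def test_p_matches_independent_reimplementation(self):
        rng = np.random.default_rng(0)
        m, n = 60, 12
        n_total = rng.integers(5, 30, size=(m, n))
        n_meth = rng.binomial(n_total, 0.5)
        n_meth[:10, :6] = n_total[:10, :6]  # strong planted block
        meth = make_meth(n_meth, n_total, pos=np.arange(100, 100 + m * 40, 40))
        idx_a, idx_b = np.arange(6), np.arange(6, 12)
        params = CallerParams(min_cpgs=2, n_perm=30, seed=42)
        from methlink.dmr import _beta_diff_by_index

        d = _beta_diff_by_index(meth.n_meth, meth.n_total, idx_a, idx_b)
        cands = find_candidate_regions(d, meth.pos, params)
        assert cands
        p = permutation_test(meth, idx_a, idx_b, cands, params)
        # independent replay of the pooled-null definition
        rng2 = np.random.default_rng(params.seed)
        pool = []
        all_idx = np.concatenate([idx_a, idx_b])
        for _ in range(params.n_perm):
            perm = rng2.permutation(all_idx)
            dp = _beta_diff_by_index(meth.n_meth, meth.n_total,
                                     perm[:6], perm[6:])
            keep = ~np.isnan(dp)
            pool += [abs(c.stat) for c in find_candidate_regions(
                dp[keep], meth.pos[keep], params)]
        expected = [
            (1 + sum(v >= abs(c.stat) for v in pool)) / (1 + len(pool))
            for c in cands
        ]
        np.testing.assert_allclose(p, expected)
        assert np.all((p > 0) & (p <= 1))

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            CallerParams(n_perm=5)


class TestBHAdjust:
    def test_single_p(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_step_up_hand_example(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, 0.04)

    def test_empty(self):
        assert bh_adjust(np.array([])).size == 0

    @staticmethod
    def brute_force(p):
        # q_(i) = min_{k >= i} p_(k) * m / k, capped at 1, in input order
        m = len(p)
        order = np.argsort(p, kind="stable")
        q = np.empty(m)
        for rank_i, idx in enumerate(order, start=1):
            q[idx] = min(
                min(p[order[k - 1]] * m / k for k in range(rank_i, m + 1)), 1.0
            )
        return q

    @given(st.lists(st.floats(1e-12, 1.0, allow_nan=False), min_size=1,
                    max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_brute_force(self, p):
        p = np.array(p)
        np.testing.assert_allclose(bh_adjust(p), self.brute_force(p),
                                   atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))


class TestCallDmrs:
    def test_same_group_rejected(self, default_cohort):
        meth, _, _, sheet, _ = default_cohort
        with pytest.raises(ValueError, match="differ"):
            call_dmrs(meth, sheet, "RM", "RM", CallerParams())

    def test_deterministic_given_seed(self, default_cohort):
        meth, _, _, sheet, _ = default_cohort
        params = CallerParams(seed=9)
        a = call_dmrs(meth, sheet, "RM", "NN", params)
        b = call_dmrs(meth, sheet, "RM", "NN", params)
        assert a == b and len(a) > 0

    def test_sign_coherence_and_sorted(self, default_cohort):
        meth, _, _, sheet, _ = default_cohort
        dmrs = call_dmrs(meth, sheet, "RM", "NN", CallerParams(seed=2))
        assert dmrs
        starts = [d.interval.start for d in dmrs]
        assert starts == sorted(starts)
        for d in dmrs:
            assert np.sign(d.stat) == np.sign(
                d.group_mean_beta[0] - d.group_mean_beta[1])
            assert 0 < d.q <= 1 and 0 < d.p <= 1
            assert d.n_cpgs >= 3
            assert abs(d.stat) >= d.n_cpgs * 0.1  # delta bound by construction
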