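"""Promoter windows, DMR-gene linking, and Kendall tau-b."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kendalltau

from methlink.dmr import DMR
from methlink.integrate import MergedDMR
from methlink.io import GeneModel, GenomicInterval, SampleSheet
from methlink.promoter import (
    kendall_tau_b,
    link_dmrs_to_genes,
    select_links,
    upstream_window,
)


def tau_oracle(x, y):
    """Pure-python pair counting: tau-b and the exact permutation p."""
    n = len(x)
    pairs = list(itertools.combinations(range(n), 2))

    def s_of(yv):
        s = 0
        for i, j in pairs:
            s += np.sign(x[j] - x[i]) * np.sign(yv[j] - yv[i])
        return s

    s = s_of(y)
    n0 = len(pairs)
    n1 = sum(1 for i, j in pairs if x[i] == x[j])
    n2 = sum(1 for i, j in pairs if y[i] == y[j])
    tau = s / math.sqrt((n0 - n1) * (n0 - n2))
    hits = total = 0
    for perm in itertools.permutations(y):
        total += 1
        hits += abs(s_of(perm)) >= abs(s)
    return tau, hits / total


def make_merged(dmr_id, beta_by_sample, start=8100, end=8200):
    m = MergedDMR(
        GenomicInterval("chr1", start, end),
        frozenset({"RMvsNN", "RMvsUC"}),
        [],
        dmr_id=dmr_id,
    )
    m.sample_mean_beta = pd.Series(beta_by_sample)
    return m


class TestUpstreamWindow:
    def test_plus_strand_convention(self):
        w = upstream_window(GeneModel("G", "chr1", "+", 10001))
        assert (w.start, w.end) == (8000, 10000)

    def test_minus_strand_convention(self):
        w = upstream_window(GeneModel("G", "chr1", "-", 10001))
        assert (w.start, w.end) == (10001, 12001)

    def test_clipped_at_zero(self):
        w = upstream_window(GeneModel("G", "chr1", "+", 1001))
        assert (w.start, w.end) == (0, 1000)

    def test_fully_clipped_window_is_none(self):
        assert upstream_window(GeneModel("G", "chr1", "+", 1)) is None

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            upstream_window(GeneModel("G", "chr1", "+", 10001), width=0)


class TestLinking:
    gene = GeneModel("G1", "chr1", "+", 10001)

    def _link(self, start, end):
        m = make_merged("chr1.1", {}, start, end)
        return link_dmrs_to_genes([m], [self.gene])

    def test_dmr_inside_window_linked(self):
        assert len(self._link(8100, 8200)) == 1

    def test_dmr_downstream_of_tss_not_linked(self):
        assert self._link(10050, 10100) == []

    def test_partial_overlap_linked(self):
        assert len(self._link(9950, 10050)) == 1

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_every_link_shares_a_base_with_window(self, data):
        genes = [
            GeneModel(f"G{i}", "chr1",
                      data.draw(st.sampled_from("+-")),
                      data.draw(st.integers(1, 30000)))
            for i in range(data.draw(st.integers(1, 5)))
        ]
        merged = []
        for i in range(data.draw(st.integers(1, 5))):
            s = data.draw(st.integers(0, 30000))
            merged.append(make_merged(f"d{i}", {}, s,
                                      s + data.draw(st.integers(1, 3000))))
        pairs = link_dmrs_to_genes(merged, genes)
        linked = {(g.gene_id, m.dmr_id) for g, m in pairs}
        for g in genes:
            w = upstream_window(g)
            for m in merged:
                expected = w is not None and any(
                    w.start <= p < w.end
                    for p in range(m.interval.start, m.interval.end)
                )
                assert ((g.gene_id, m.dmr_id) in linked) == expected


class TestKendallTauB:
    def test_perfect_discordance(self):
        tau, _ = kendall_tau_b(np.array([1, 2, 3, 4]), np.array([4, 3, 2, 1]))
        assert tau == pytest.approx(-1.0)

    def test_perfect_concordance(self):
        tau, _ = kendall_tau_b(np.array([1, 2, 3, 4]), np.array([1, 2, 3, 4]))
        assert tau == pytest.approx(1.0)

    def test_tie_case_matches_enumeration_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([3.0, 3.0, 2.0, 1.0])
        tau, p = kendall_tau_b(x, y)
        tau_exp, p_exp = tau_oracle(x, y)
        assert tau == pytest.approx(tau_exp, abs=1e-12)
        assert p == pytest.approx(p_exp, abs=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_exact_small_n_agrees_with_oracle(self, n, seed):
        rng = np.random.default_rng(100 * n + seed)
        x = rng.integers(0, 4, size=n).astype(float)  # ties likely
        y = rng.integers(0, 4, size=n).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            pytest.skip("constant vector, tau undefined")
        tau, p = kendall_tau_b(x, y)
        tau_exp, p_exp = tau_oracle(x, y)
        assert tau == pytest.approx(tau_exp, abs=1e-12)
        assert p == pytest.approx(p_exp, abs=1e-9)

    def test_large_n_matches_scipy_asymptotics(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.integers(0, 10, size=45).astype(float)
            y = x * -0.5 + rng.normal(size=45)
            tau, p = kendall_tau_b(x, y)
            ref = kendalltau(x, y, method="asymptotic")
            assert tau == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-9)

    @given(st.lists(st.integers(0, 5), min_size=4, max_size=12),
           st.lists(st.integers(0, 5), min_size=4, max_size=12))
    @settings(max_examples=80, deadline=None)
    def test_range_and_antisymmetry(self, xs, ys):
        n = min(len(xs), len(ys))
        x = np.array(xs[:n], dtype=float)
        y = np.array(ys[:n], dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            tau, p = kendall_tau_b(x, y)
            assert math.isnan(tau)
            return
        tau, p = kendall_tau_b(x, y)
        tau_neg, p_neg = kendall_tau_b(x, -y)
        assert -1.0 - 1e-12 <= tau <= 1.0 + 1e-12
        assert tau_neg == pytest.approx(-tau, abs=1e-12)
        assert p_neg == pytest.approx(p, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            kendall_tau_b(np.array([1.0, 2.0, 3.0]), np.array([3.0, 2.0, 1.0]))


class TestSelectLinks:
    def _setup(self, betas, expr, deg=True):
        samples = list(betas.keys())
        sheet = SampleSheet(samples, ["NN"] * len(samples))
        gene = GeneModel("G1", "chr1", "+", 10001)
        m = make_merged("chr1.1", betas)
        e = pd.DataFrame([expr], index=["G1"], columns=samples)
        degs = {"G1"} if deg else set()
        return select_links([(gene, m)], e, sheet, degs)

    def test_negative_correlated_deg_selected(self):
        betas = {f"s{i}": b for i, b in enumerate(
            [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9])}
        expr = [9, 8, 7, 6, 5, 4, 3, 2, 1]
        links = self._setup(betas, expr)
        assert links.loc[0, "selected"]
        assert links.loc[0, "tau"] == pytest.approx(-1.0)

    def test_non_deg_not_selected(self):
        betas = {f"s{i}": b for i, b in enumerate(
            [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9])}
        expr = [9, 8, 7, 6, 5, 4, 3, 2, 1]
        links = self._setup(betas, expr, deg=False)
        assert not links.loc[0, "selected"]

    def test_weak_correlation_not_selected(self):
        # tau < 0 but p above the 0.1 cut
        betas = {f"s{i}": b for i, b in enumerate(
            [0.1, 0.5, 0.3, 0.4, 0.2, 0.6])}
        expr = [2, 1, 4, 3, 6, 5]
        links = self._setup(betas, expr)
        assert links.loc[0, "tau"] < 0
        assert links.loc[0, "p_tau"] > 0.1
        assert not links.loc[0, "selected"]

    def test_constant_input_dropped_with_warning(self):
        betas = {f"s{i}": 0.5 for i in range(6)}
        expr = [1, 2, 3, 4, 5, 6]
        with pytest.warns(UserWarning, match="constant|complete"):
            links = self._setup(betas, expr)
        assert links.empty
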