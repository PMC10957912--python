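"""Permutation-based differentially methylated region (DMR) caller.

The caller detects runs of CpGs whose coverage-weighted group mean
methylation differs consistently between two sample groups, scores each
candidate region by the area statistic (sum of per-CpG beta
differences), and assigns significance by whole-sample label
permutation: candidate statistics from permuted labels are pooled into
one genome-wide null, each observed region's p-value is its add-one
rank in that pool, and Benjamini-Hochberg adjustment yields q-values.
Regions with q below ``q_cut`` (default 0.05) are reported.

This is a transparent stand-in for smoothed-GLS DMR callers: the
downstream contract is only the set of regions at q < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CpGMethylation, GenomicInterval, SampleSheet


@dataclass
class CallerParams:
    """Tuning parameters of the DMR caller.

    min_cov / min_cov_frac: per-CpG coverage QC, applied per group.
    delta: minimum absolute per-CpG group beta difference inside a region.
    max_gap: maximum bp between consecutive CpGs of one region.
    min_cpgs: minimum region size in CpGs.
    n_perm: number of label permutations B.
    q_cut: BH q-value retention threshold.
    """

    min_cov: int = 5
    min_cov_frac: float = 0.8
    delta: float = 0.1
    max_gap: int = 1000
    min_cpgs: int = 3
    n_perm: int = 100
    seed: int = 0
    q_cut: float = 0.05
    smooth: bool = False  # optional running-mean (window 3) smoothing of d

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must lie in (0, 1)")
        if self.min_cpgs < 2:
            raise ValueError("min_cpgs must be >= 2")
        if self.n_perm < 10:
            raise ValueError("n_perm must be >= 10")
        if not 0.0 <= self.min_cov_frac <= 1.0:
            raise ValueError("min_cov_frac must lie in [0, 1]")
        if not 0.0 < self.q_cut <= 1.0:
            raise ValueError("q_cut must lie in (0, 1]")


@dataclass
class DMR:
    """One called region with its test summary."""

    interval: GenomicInterval
    comparison: str
    n_cpgs: int
    stat: float
    p: float
    q: float
    group_mean_beta: tuple[float, float]


@dataclass(frozen=True)
class Candidate:
    """A candidate region: indices into the filtered CpG arrays."""

    first: int  # inclusive row index
    last: int  # inclusive row index
    stat: float
    n_cpgs: int


def filter_cpgs(
    meth: CpGMethylation,
    sheet: SampleSheet,
    group_a: str,
    group_b: str,
    params: CallerParams,
) -> CpGMethylation:
    """Keep CpGs covered >= min_cov in >= min_cov_frac of each group's samples."""
    mask = np.ones(meth.n_cpgs, dtype=bool)
    for group in (group_a, group_b):
        idx = [meth.sample_ids.index(s) for s in sheet.members(group)]
        ok = (meth.n_total[:, idx] >= params.min_cov).mean(axis=1)
        mask &= ok >= params.min_cov_frac
    if not mask.any():
        raise ValueError(
            "no CpGs pass the coverage filter; lower min_cov or min_cov_frac"
        )
    return meth.subset_rows(mask)


def group_beta_diff(
    meth: CpGMethylation, sheet: SampleSheet, group_a: str, group_b: str
) -> np.ndarray:
    """Per-CpG difference of coverage-weighted group mean betas (A - B).

    The group mean is sum(n_meth)/sum(n_total) over the group's samples,
    i.e. read-weighted, not the mean of per-sample betas.  NaN where a
    group has zero total coverage (such CpGs are dropped by the caller).
    """
    idx_a = [meth.sample_ids.index(s) for s in sheet.members(group_a)]
    idx_b = [meth.sample_ids.index(s) for s in sheet.members(group_b)]
    return _beta_diff_by_index(meth.n_meth, meth.n_total, idx_a, idx_b)


def _beta_diff_by_index(n_meth, n_total, idx_a, idx_b) -> np.ndarray:
    ma = n_meth[:, idx_a].sum(axis=1)
    ta = n_total[:, idx_a].sum(axis=1)
    mb = n_meth[:, idx_b].sum(axis=1)
    tb = n_total[:, idx_b].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = ma / ta - mb / tb
    d[(ta == 0) | (tb == 0)] = np.nan
    return d


def _smooth3(d: np.ndarray) -> np.ndarray:
    """Running mean over a window of 3, edges kept as-is."""
    out = d.copy()
    if len(d) >= 3:
        out[1:-1] = (d[:-2] + d[1:-1] + d[2:]) / 3.0
    return out


def find_candidate_regions(
    d: np.ndarray,
    positions: np.ndarray,
    params: CallerParams,
    chroms: np.ndarray | None = None,
) -> list[Candidate]:
    """Maximal runs of same-sign CpGs with |d| >= delta and gaps <= max_gap.

    ``positions`` are 1-based and strictly increasing per chromosome;
    NaN entries of ``d`` must already be dropped.  Runs shorter than
    min_cpgs are discarded.
    """
    m = len(d)
    if m == 0:
        return []
    if params.smooth:
        d = _smooth3(d)
    ok = np.abs(d) >= params.delta
    sign = np.sign(d)
    # break between i-1 and i when either side fails, signs differ,
    # the gap exceeds max_gap, or the chromosome changes
    brk = np.zeros(m, dtype=bool)
    brk[0] = True
    if m > 1:
        gap = np.diff(positions) > params.max_gap
        flip = sign[1:] != sign[:-1]
        brk[1:] = gap | flip | ~ok[1:] | ~ok[:-1]
        if chroms is not None:
            brk[1:] |= chroms[1:] != chroms[:-1]
    # every maximal valid run is one segment of the cumulative break count,
    # restricted to positions passing the |d| threshold
    seg = np.cumsum(brk)
    idx_valid = np.flatnonzero(ok)
    if len(idx_valid) == 0:
        return []
    seg_ids = seg[idx_valid]
    starts = np.flatnonzero(np.concatenate([[True], np.diff(seg_ids) != 0]))
    counts = np.diff(np.append(starts, len(seg_ids)))
    sums = np.add.reduceat(d[idx_valid], starts)
    out: list[Candidate] = []
    for s, c, stat in zip(starts, counts, sums):
        if c >= params.min_cpgs:
            out.append(
                Candidate(int(idx_valid[s]), int(idx_valid[s + c - 1]), float(stat), int(c))
            )
    return out


def permutation_test(
    meth: CpGMethylation,
    idx_a: np.ndarray,
    idx_b: np.ndarray,
    candidates: list[Candidate],
    params: CallerParams,
    chroms: np.ndarray | None = None,
) -> np.ndarray:
    """Pooled-null permutation p-values for observed candidate regions.

    For each of B permutations of the two groups' sample labels
    (group sizes preserved), the per-CpG difference and candidate
    regions are recomputed and all null |stat| values pooled.  Then
    ``p_j = (1 + #{null |stat| >= |stat_j|}) / (1 + N_null)``.
    """
    rng = np.random.default_rng(params.seed)
    all_idx = np.concatenate([idx_a, idx_b])
    n_a = len(idx_a)
    null_stats: list[float] = []
    for _ in range(params.n_perm):
        perm = rng.permutation(all_idx)
        d = _beta_diff_by_index(meth.n_meth, meth.n_total, perm[:n_a], perm[n_a:])
        keep = ~np.isnan(d)
        cands = find_candidate_regions(
            d[keep],
            meth.pos[keep],
            params,
            None if chroms is None else chroms[keep],
        )
        null_stats.extend(abs(c.stat) for c in cands)
    null = np.sort(np.asarray(null_stats))
    n_null = len(null)
    obs = np.array([abs(c.stat) for c in candidates])
    # count of null values >= each observed |stat|
    ge = n_null - np.searchsorted(null, obs, side="left")
    return (1.0 + ge) / (1.0 + n_null)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_dmrs(
    meth: CpGMethylation,
    sheet: SampleSheet,
    group_a: str,
    group_b: str,
    params: CallerParams,
) -> list[DMR]:
    """Full caller: filter, difference, candidates, permutation p, BH, cut.

    Deterministic given the seed in ``params``.  The reported statistic
    is signed (positive = group A more methylated over the region) and
    its sign always matches the sign of the region-level group beta
    difference.
    """
    if group_a == group_b:
        raise ValueError("group_a and group_b must differ")
    members_a, members_b = sheet.members(group_a), sheet.members(group_b)
    if len(members_a) < 2 or len(members_b) < 2:
        raise ValueError("each group needs >= 2 samples")

    filtered = filter_cpgs(meth, sheet, group_a, group_b, params)
    idx_a = np.array([filtered.sample_ids.index(s) for s in members_a])
    idx_b = np.array([filtered.sample_ids.index(s) for s in members_b])

    d = _beta_diff_by_index(filtered.n_meth, filtered.n_total, idx_a, idx_b)
    keep = ~np.isnan(d)
    filtered = filtered.subset_rows(keep)
    d = d[keep]

    candidates = find_candidate_regions(d, filtered.pos, params, filtered.chrom)
    if not candidates:
        return []
    p = permutation_test(filtered, idx_a, idx_b, candidates, params, filtered.chrom)
    q = bh_adjust(p)

    comparison = f"{group_a}vs{group_b}"
    out: list[DMR] = []
    for cand, pj, qj in zip(candidates, p, q):
        if qj >= params.q_cut:
            continue
        rows = slice(cand.first, cand.last + 1)
        ma = filtered.n_meth[rows][:, idx_a].sum()
        ta = filtered.n_total[rows][:, idx_a].sum()
        mb = filtered.n_meth[rows][:, idx_b].sum()
        tb = filtered.n_total[rows][:, idx_b].sum()
        interval = GenomicInterval(
            str(filtered.chrom[cand.first]),
            int(filtered.pos[cand.first]) - 1,
            int(filtered.pos[cand.last]),
        )
        out.append(
            DMR(
                interval=interval,
                comparison=comparison,
                n_cpgs=cand.n_cpgs,
                stat=cand.stat,
                p=float(pj),
                q=float(qj),
                group_mean_beta=(float(ma / ta), float(mb / tb)),
            )
        )
    out.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return out
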