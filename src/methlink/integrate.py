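"""Three-comparison DMR merging and remission-specificity testing.

DMRs from the three pairwise comparisons (RMvsNN, RMvsUC, UCvsNN) are
pooled and clustered by single-linkage genomic overlap (any shared
base, half-open intervals).  A merged region survives only if its
members come from at least two distinct comparisons — overlap across
comparisons is the integration signal; isolated DMRs are discarded.

Each surviving region gets per-sample coverage-weighted mean
methylation and three pairwise Welch t-tests on those values; a region
is flagged remission-specific when the RM group differs from both NN
and UC at p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import DMR
from .io import CpGMethylation, GenomicInterval, SampleSheet


@dataclass
class MergedDMR:
    """A cluster of overlapping DMRs from >= 2 comparisons."""

    interval: GenomicInterval
    sources: frozenset[str]
    members: list[DMR]
    dmr_id: str = ""
    sample_mean_beta: pd.Series | None = None
    t_rm_nn_p: float = np.nan
    t_rm_uc_p: float = np.nan
    t_uc_nn_p: float = np.nan
    rm_specific: bool | None = None

    def group_means(self, sheet: SampleSheet) -> tuple[float, float, float]:
        """(m_NN, m_RM, m_UC): unweighted group means of sample_mean_beta."""
        if self.sample_mean_beta is None:
            raise ValueError("sample_mean_beta not computed; run flag_rm_specific")
        out = []
        for g in ("NN", "RM", "UC"):
            vals = self.sample_mean_beta.loc[sheet.members(g)].dropna()
            out.append(float(vals.mean()) if len(vals) else np.nan)
        return tuple(out)


def merge_dmrs(
    dmrs_by_comparison: dict[str, list[DMR]],
    keep_single_source: bool = False,
) -> list[MergedDMR]:
    """Single-linkage overlap clustering of the pooled DMR set.

    Since members are intervals, a left-to-right sweep over the sorted
    pool is exactly transitive-closure clustering: a new DMR joins the
    open cluster iff it starts before the cluster's running end.
    """
    pool: list[tuple[DMR, str]] = [
        (d, comp) for comp, dmrs in dmrs_by_comparison.items() for d in dmrs
    ]
    pool.sort(key=lambda t: (t[0].interval.chrom, t[0].interval.start, t[0].interval.end))
    clusters: list[list[tuple[DMR, str]]] = []
    cur_chrom, cur_end = None, -1
    for d, comp in pool:
        iv = d.interval
        if iv.chrom == cur_chrom and iv.start < cur_end:
            clusters[-1].append((d, comp))
            cur_end = max(cur_end, iv.end)
        else:
            clusters.append([(d, comp)])
            cur_chrom, cur_end = iv.chrom, iv.end
    out: list[MergedDMR] = []
    for members in clusters:
        sources = frozenset(comp for _, comp in members)
        if len(sources) < 2 and not keep_single_source:
            continue
        ivs = [d.interval for d, _ in members]
        interval = GenomicInterval(
            ivs[0].chrom, min(iv.start for iv in ivs), max(iv.end for iv in ivs)
        )
        out.append(MergedDMR(interval, sources, [d for d, _ in members]))
    out.sort(key=lambda m: (m.interval.chrom, m.interval.start))
    for i, m in enumerate(out):
        m.dmr_id = f"{m.interval.chrom}.{i + 1}"
    return out


def sample_mean_methylation(
    meth: CpGMethylation, interval: GenomicInterval
) -> pd.Series:
    """Per-sample coverage-weighted mean beta over CpGs in the interval.

    ``sum(n_meth) / sum(n_total)`` per sample; NaN for samples with zero
    total coverage in the interval (excluded pairwise from tests).
    """
    mask = meth.interval_mask(interval)
    if not mask.any():
        raise ValueError(f"interval {interval} contains no CpGs")
    met = meth.n_meth[mask].sum(axis=0)
    tot = meth.n_total[mask].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(tot > 0, met / tot, np.nan)
    return pd.Series(beta, index=meth.sample_ids)


def welch_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Welch two-sample t with Welch-Satterthwaite df; two-sided p.

    Degenerate inputs (both variances zero): equal means give (0, 1),
    unequal means give (inf-signed t, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_t requires >= 2 observations per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)


def flag_rm_specific(
    merged: list[MergedDMR], meth: CpGMethylation, sheet: SampleSheet
) -> list[MergedDMR]:
    """Fill per-sample means, the three pairwise tests, and rm_specific.

    rm_specific is true iff both RM-vs-NN and RM-vs-UC Welch tests on
    the region's per-sample mean methylation have p < 0.05.
    """
    nn = sheet.members("NN")
    rm = sheet.members("RM")
    uc = sheet.members("UC")
    for m in merged:
        beta = sample_mean_methylation(meth, m.interval)
        m.sample_mean_beta = beta
        b_nn = beta.loc[nn].to_numpy()
        b_rm = beta.loc[rm].to_numpy()
        b_uc = beta.loc[uc].to_numpy()
        _, m.t_rm_nn_p = welch_t(b_rm, b_nn)
        _, m.t_rm_uc_p = welch_t(b_rm, b_uc)
        _, m.t_uc_nn_p = welch_t(b_uc, b_nn)
        m.rm_specific = bool(m.t_rm_nn_p < 0.05 and m.t_rm_uc_p < 0.05)
    return merged


def merged_frame(merged: list[MergedDMR], sheet: SampleSheet | None = None) -> pd.DataFrame:
    """Flat table of merged regions for writing/reporting."""
    rows = []
    for m in merged:
        row = {
            "dmr_id": m.dmr_id,
            "chrom": m.interval.chrom,
            "start": m.interval.start,
            "end": m.interval.end,
            "sources": ";".join(sorted(m.sources)),
            "n_members": len(m.members),
            "t_rm_nn_p": m.t_rm_nn_p,
            "t_rm_uc_p": m.t_rm_uc_p,
            "t_uc_nn_p": m.t_uc_nn_p,
            "rm_specific": m.rm_specific,
        }
        if sheet is not None and m.sample_mean_beta is not None:
            m_nn, m_rm, m_uc = m.group_means(sheet)
            row.update({"mean_nn": m_nn, "mean_rm": m_rm, "mean_uc": m_uc})
        rows.append(row)
    columns = [
        "dmr_id", "chrom", "start", "end", "sources", "n_members",
        "t_rm_nn_p", "t_rm_uc_p", "t_uc_nn_p", "rm_specific",
    ]
    if sheet is not None:
        columns += ["mean_nn", "mean_rm", "mean_uc"]
    return pd.DataFrame(rows, columns=columns)
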