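"""Promoter-window DMR-gene linking and Kendall correlation.

A gene's promoter window is the 2000 bp immediately upstream of its
TSS, strand-aware, in 0-based half-open coordinates.  A merged DMR is
linked to every gene whose window it overlaps by at least one base.
For each link, Kendall tau-b between per-sample region mean
methylation and log2-normalized expression is computed over the pooled
cohort; links with tau < 0 at two-sided p < 0.1 whose gene is a DEG in
at least one comparison are selected.

tau-b is computed from concordant/discordant pair counts with the
standard tie correction.  The p-value is exact for n <= 8 (enumeration
of all n! orderings of y, valid under ties because the tie structure is
permutation-invariant) and otherwise uses the tie-corrected normal
approximation of the S = C - D statistic.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .integrate import MergedDMR
from .io import GeneModel, GenomicInterval, SampleSheet

EXACT_MAX_N = 8


def upstream_window(gene: GeneModel, width: int = 2000) -> GenomicInterval | None:
    """Strand-aware upstream window, 0-based half-open, clipped at zero.

    ``+`` strand: [tss-1-width, tss-1); ``-`` strand: [tss, tss+width).
    Returns None when clipping leaves an empty window.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if gene.strand == "+":
        start, end = max(0, gene.tss - 1 - width), gene.tss - 1
    else:
        start, end = gene.tss, gene.tss + width
    if start >= end:
        return None
    return GenomicInterval(gene.chrom, start, end)


def link_dmrs_to_genes(
    merged: list[MergedDMR], genes: list[GeneModel], width: int = 2000
) -> list[tuple[GeneModel, MergedDMR]]:
    """All (gene, merged DMR) pairs whose upstream window overlaps the DMR.

    Many-to-many: a DMR may hit several genes and a gene several DMRs.
    """
    pairs: list[tuple[GeneModel, MergedDMR]] = []
    for gene in genes:
        window = upstream_window(gene, width)
        if window is None:
            continue
        for m in merged:
            if m.interval.overlaps(window):
                pairs.append((gene, m))
    return pairs


def _pair_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int, int]:
    """(S, n0, n1, n2, n) where S = C - D over all i<j pairs."""
    n = len(x)
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(n, k=1)
    s = int(np.sum(dx[iu] * dy[iu]))
    n0 = n * (n - 1) // 2
    # ties: pairs tied within x, within y
    n1 = int(np.sum(dx[iu] == 0))
    n2 = int(np.sum(dy[iu] == 0))
    return s, n0, n1, n2, n


def _tie_sizes(v: np.ndarray) -> np.ndarray:
    _, counts = np.unique(v, return_counts=True)
    return counts[counts > 1]


def _exact_p(x: np.ndarray, y: np.ndarray, s_obs: int) -> float:
    """P(|S| >= |S_obs|) over all n! orderings of y."""
    n = len(y)
    perms = np.array(list(itertools.permutations(range(n))))
    yp = y[perms]  # (n!, n)
    iu, ju = np.triu_indices(n, k=1)
    dx = np.sign(x[ju] - x[iu])
    dy = np.sign(yp[:, ju] - yp[:, iu])
    s_all = (dy * dx).sum(axis=1)
    return float(np.mean(np.abs(s_all) >= abs(s_obs)))


def _asymptotic_p(x: np.ndarray, y: np.ndarray, s_obs: int) -> float:
    """Two-sided normal p with the tie-corrected variance of S."""
    n = len(x)
    t = _tie_sizes(x).astype(float)
    u = _tie_sizes(y).astype(float)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = np.sum(t * (t - 1) * (2 * t + 5))
    vu = np.sum(u * (u - 1) * (2 * u + 5))
    v1 = np.sum(t * (t - 1)) * np.sum(u * (u - 1)) / (2.0 * n * (n - 1))
    v2 = (
        np.sum(t * (t - 1) * (t - 2))
        * np.sum(u * (u - 1) * (u - 2))
        / (9.0 * n * (n - 1) * (n - 2))
    )
    var = (v0 - vt - vu) / 18.0 + v1 + v2
    if var <= 0:
        return 1.0
    z = s_obs / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def kendall_tau_b(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Kendall tau-b with tie correction and its two-sided p-value.

    Raises on fewer than 4 complete pairs; returns (nan, nan) when
    either vector is constant (tau undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError("kendall_tau_b requires >= 4 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    s, n0, n1, n2, n = _pair_counts(x, y)
    tau = s / math.sqrt((n0 - n1) * (n0 - n2))
    if n <= EXACT_MAX_N:
        p = _exact_p(x, y, s)
    else:
        p = _asymptotic_p(x, y, s)
    return float(tau), float(p)


def select_links(
    pairs: list[tuple[GeneModel, MergedDMR]],
    expression: pd.DataFrame,
    sheet: SampleSheet,
    deg_genes: set[str],
    p_cut: float = 0.1,
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Correlate every candidate pair and flag selections.

    ``expression`` is the log2-normalized genes x samples matrix.  The
    correlation pools all samples (optionally restricted to ``groups``).
    A link is selected iff tau < 0, p < p_cut, and the gene is in
    ``deg_genes``.  The full audit table is returned, selected or not;
    links with undefined tau or < 4 complete pairs are dropped with a
    warning.
    """
    samples = (
        sheet.sample_ids
        if groups is None
        else [s for s, g in zip(sheet.sample_ids, sheet.groups) if g in groups]
    )
    rows = []
    for gene, m in pairs:
        if m.sample_mean_beta is None:
            raise ValueError("merged DMRs lack sample_mean_beta; run flag_rm_specific")
        if gene.gene_id not in expression.index:
            continue
        x = m.sample_mean_beta.loc[samples].to_numpy(dtype=float)
        y = expression.loc[gene.gene_id, samples].to_numpy(dtype=float)
        complete = ~(np.isnan(x) | np.isnan(y))
        if complete.sum() < 4:
            warnings.warn(
                f"link {gene.gene_id}/{m.dmr_id}: fewer than 4 complete pairs; dropped",
                stacklevel=2,
            )
            continue
        tau, p = kendall_tau_b(x[complete], y[complete])
        if math.isnan(tau):
            warnings.warn(
                f"link {gene.gene_id}/{m.dmr_id}: tau undefined (constant input); dropped",
                stacklevel=2,
            )
            continue
        rows.append(
            {
                "gene_id": gene.gene_id,
                "dmr_id": m.dmr_id,
                "tau": tau,
                "p_tau": p,
                "n_pairs": int(complete.sum()),
                "in_deg": gene.gene_id in deg_genes,
                "selected": bool(tau < 0 and p < p_cut and gene.gene_id in deg_genes),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "dmr_id", "tau", "p_tau", "n_pairs", "in_deg", "selected"],
    )
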