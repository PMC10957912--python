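"""Reference-based cell-type deconvolution of DMR methylation.

Each sample's DMR-level mean methylation vector is modelled as a
mixture of cell-type reference profiles (epithelial, fibroblast,
immune).  Fractions are estimated in robust-partial-correlation style:
a Huber robust linear regression (tuning constant 1.345, iteratively
reweighted least squares) of the sample betas on the reference columns
with intercept, followed by truncation of negative coefficients at
zero and renormalization onto the unit simplex.

Group differences in the estimated fractions are assessed per cell
type with one-way ANOVA and Tukey's range test (Tukey-Kramer for the
unbalanced 11/20/14 groups).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .integrate import MergedDMR, sample_mean_methylation
from .io import CpGMethylation, SampleSheet


def rpc_fit(y: np.ndarray, reference: pd.DataFrame) -> np.ndarray:
    """Estimate one sample's cell fractions from its beta vector.

    NaN features are dropped pairwise.  Negative Huber coefficients are
    truncated to zero and the rest renormalized to sum to one; if no
    coefficient is positive the estimate falls back to uniform
    fractions with a warning.
    """
    y = np.asarray(y, dtype=float)
    R = reference.to_numpy(dtype=float)
    ok = ~np.isnan(y)
    y, R = y[ok], R[ok]
    k = R.shape[1]
    if len(y) < k:
        raise ValueError(
            f"{len(y)} usable features for {k} cell types; need at least {k}"
        )
    X = sm.add_constant(R)
    with warnings.catch_warnings():
        # noiseless inputs fit perfectly; the scale-zero notice is expected
        from statsmodels.tools.sm_exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        fit = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit(
            maxiter=100, tol=1e-8
        )
    coef = np.maximum(fit.params[1:], 0.0)
    total = coef.sum()
    if total <= 0:
        warnings.warn(
            "all robust coefficients nonpositive; returning uniform fractions",
            stacklevel=2,
        )
        return np.full(k, 1.0 / k)
    return coef / total


def deconvolve_cohort(
    meth: CpGMethylation,
    merged: list[MergedDMR],
    reference: pd.DataFrame,
    sheet: SampleSheet,
) -> pd.DataFrame:
    """Per-sample fractions from merged-DMR mean methylation.

    Features are merged DMRs whose ``dmr_id`` appears in the reference
    index; at least 3 usable features are required.
    """
    usable = [m for m in merged if m.dmr_id in reference.index]
    if len(usable) < 3:
        raise ValueError(
            f"only {len(usable)} merged DMRs match the reference; need >= 3"
        )
    betas = np.vstack(
        [
            (
                m.sample_mean_beta
                if m.sample_mean_beta is not None
                else sample_mean_methylation(meth, m.interval)
            ).to_numpy(dtype=float)
            for m in usable
        ]
    )
    ref = reference.loc[[m.dmr_id for m in usable]]
    fractions = np.vstack(
        [rpc_fit(betas[:, j], ref) for j in range(betas.shape[1])]
    )
    return pd.DataFrame(fractions, index=meth.sample_ids, columns=reference.columns)


def deconvolve_matrix(
    beta: pd.DataFrame, reference: pd.DataFrame
) -> pd.DataFrame:
    """Fractions for a plain features x samples beta matrix."""
    common = reference.index.intersection(beta.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 shared features between betas and reference")
    B = beta.loc[common]
    R = reference.loc[common]
    fractions = np.vstack([rpc_fit(B[c].to_numpy(dtype=float), R) for c in B.columns])
    return pd.DataFrame(fractions, index=B.columns, columns=reference.columns)


def group_anova_tukey(
    fractions: pd.DataFrame, sheet: SampleSheet
) -> pd.DataFrame:
    """One-way ANOVA + Tukey HSD per cell type across the three groups.

    Returns one row per cell type with F, the ANOVA p-value, and the
    three pairwise Tukey-adjusted p-values (studentized range with the
    Tukey-Kramer unbalanced-group correction).  Degenerate input where
    every group is constant with equal means yields F = 0, all p = 1.
    """
    groups = sorted(set(sheet.groups))
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    rows = []
    for cell in fractions.columns:
        per_group = [
            fractions.loc[sheet.members(g), cell].to_numpy(dtype=float)
            for g in groups
        ]
        if any(len(v) < 2 for v in per_group):
            raise ValueError("each group needs >= 2 samples")
        means = [v.mean() for v in per_group]
        if all(v.var(ddof=1) == 0 for v in per_group) and len(set(means)) == 1:
            f_stat, p_anova = 0.0, 1.0
            pairwise = {
                f"tukey_{groups[i]}_{groups[j]}": 1.0
                for i in range(len(groups))
                for j in range(i + 1, len(groups))
            }
        else:
            f_stat, p_anova = stats.f_oneway(*per_group)
            hsd = stats.tukey_hsd(*per_group)
            pairwise = {
                f"tukey_{groups[i]}_{groups[j]}": float(hsd.pvalue[i, j])
                for i in range(len(groups))
                for j in range(i + 1, len(groups))
            }
        rows.append(
            {"cell_type": cell, "F": float(f_stat), "p_anova": float(p_anova), **pairwise}
        )
    return pd.DataFrame(rows)
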