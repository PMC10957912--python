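"""Count normalization and two-group differential expression.

Normalization is median-of-ratios: a pseudo-reference sample is the
per-gene geometric mean over samples (genes with any zero excluded),
and each sample's size factor is the median ratio of its counts to the
reference.  Expression enters all downstream stages as
``log2(count / size_factor + 1)``.

Testing is a per-gene Welch two-sample t-test on the log2-normalized
values with Benjamini-Hochberg adjustment over all tested genes; the
DEG set is ``padj < alpha``.  This transparent stage is isolated behind
this module's interface so a negative-binomial GLM test could be
swapped in without touching the rest of the pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import bh_adjust
from .io import SampleSheet


def size_factors(counts: pd.DataFrame, pseudocount: float = 0.0) -> pd.Series:
    """Median-of-ratios size factors, one per sample.

    Genes with a zero count in any sample are excluded from the
    reference; if none remain, pass ``pseudocount > 0`` to offset all
    counts when forming the reference and ratios.
    """
    x = counts.to_numpy(dtype=float) + pseudocount
    all_positive = (x > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "every gene has a zero count in some sample; "
            "use a pseudocount (e.g. size_factors(counts, pseudocount=0.5))"
        )
    ref = np.exp(np.log(x[all_positive]).mean(axis=1))
    ratios = x[all_positive] / ref[:, None]
    s = np.median(ratios, axis=0)
    if np.any(s <= 0):
        raise ValueError("nonpositive size factor; check the counts matrix")
    return pd.Series(s, index=counts.columns, name="size_factor")


def log_norm(counts: pd.DataFrame, s: pd.Series) -> pd.DataFrame:
    """log2(count / size_factor + 1), genes x samples."""
    if np.any(s.to_numpy() <= 0):
        raise ValueError("size factors must be positive")
    return np.log2(counts / s + 1.0)


def de_test(
    e: pd.DataFrame,
    sheet: SampleSheet,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch t-test per gene on log2-normalized expression, BH-adjusted.

    Returns one row per tested gene: log2fc (mean A - mean B), p, padj,
    and ``is_deg = padj < alpha``.  Genes where both groups have zero
    variance get p = 1 when the means agree and p = 0 (flagged
    ``degenerate``) when they do not.
    """
    ga, gb = sheet.members(group_a), sheet.members(group_b)
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each group needs >= 2 samples")
    xa = e[ga].to_numpy(dtype=float)
    xb = e[gb].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
    log2fc = xa.mean(axis=1) - xb.mean(axis=1)
    degenerate = (xa.std(axis=1) == 0) & (xb.std(axis=1) == 0)
    p = np.asarray(p, dtype=float)
    p[degenerate & (log2fc == 0)] = 1.0
    p[degenerate & (log2fc != 0)] = 0.0
    p = np.where(np.isnan(p), 1.0, p)
    # permutation p-values live in (0,1]; keep BH well-defined here too
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    padj = bh_adjust(p)
    return pd.DataFrame(
        {
            "gene_id": e.index,
            "comparison": f"{group_a}vs{group_b}",
            "log2fc": log2fc,
            "p": p,
            "padj": padj,
            "is_deg": padj < alpha,
            "degenerate": degenerate,
        }
    ).set_index("gene_id")


def differential_expression(
    counts: pd.DataFrame,
    sheet: SampleSheet,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    max_zero_frac: float = 0.9,
) -> tuple[pd.DataFrame, list[str]]:
    """Normalize and test; returns (results, untested gene ids).

    Genes with zero counts in more than ``max_zero_frac`` of samples are
    excluded from testing and reported separately.
    """
    s = size_factors(counts)
    e = log_norm(counts, s)
    zero_frac = (counts == 0).mean(axis=1)
    tested = zero_frac <= max_zero_frac
    untested = counts.index[~tested].tolist()
    res = de_test(e.loc[tested], sheet, group_a, group_b, alpha=alpha)
    return res, untested
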