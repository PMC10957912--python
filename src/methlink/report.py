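"""Cohort-level summaries: PCA of selected genes, stage counts, audits.

PCA runs on centred (per gene), unscaled log2 expression with genes as
features and samples as observations; explained-variance ratios are
non-increasing and sum to one over the full rank.  The per-DMR audit
reproduces, as tables, the per-sample methylation / expression panels
used to inspect individual methylation-regulated genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .integrate import MergedDMR
from .io import CpGMethylation, SampleSheet


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x PCs, with a 'group' column
    explained_variance_ratio: np.ndarray


def pca_expression(
    e: pd.DataFrame,
    sheet: SampleSheet,
    n_components: int | None = None,
    scale: bool = False,
) -> PCAResult:
    """PCA of a genes x samples log2-expression matrix.

    Constant gene rows are dropped with a warning; ``scale=True``
    additionally divides each gene by its standard deviation.
    """
    if e.shape[0] < 2 or e.shape[1] < 3:
        raise ValueError("PCA needs >= 2 genes and >= 3 samples")
    constant = e.std(axis=1) == 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant gene(s) before PCA",
            stacklevel=2,
        )
        e = e.loc[~constant]
    X = e.to_numpy(dtype=float).T  # samples x genes
    if scale:
        X = X / e.std(axis=1).to_numpy(dtype=float)
    k = min(X.shape[0] - 1, X.shape[1]) if n_components is None else n_components
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    df = pd.DataFrame(
        scores, index=e.columns, columns=[f"PC{i + 1}" for i in range(scores.shape[1])]
    )
    df["group"] = [sheet.group_of[s] for s in e.columns]
    return PCAResult(df, pca.explained_variance_ratio_)


def pipeline_summary(
    dmrs_by_comparison: dict[str, list],
    degs_by_comparison: dict[str, pd.DataFrame],
    merged: list[MergedDMR],
    links: pd.DataFrame,
    calls: pd.DataFrame,
) -> pd.DataFrame:
    """Counts per stage: DMRs and DEGs per comparison, merged regions,
    remission-specific regions, selected links, genes per profile."""
    rows = [
        {"stage": f"dmrs_{comp}", "count": len(dmrs)}
        for comp, dmrs in dmrs_by_comparison.items()
    ]
    rows += [
        {"stage": f"degs_{comp}", "count": int(res["is_deg"].sum())}
        for comp, res in degs_by_comparison.items()
    ]
    rows.append({"stage": "merged_dmrs", "count": len(merged)})
    rows.append(
        {"stage": "rm_specific_dmrs", "count": sum(bool(m.rm_specific) for m in merged)}
    )
    n_selected = int(links["selected"].sum()) if len(links) else 0
    rows.append({"stage": "selected_links", "count": n_selected})
    for profile in (
        "specific_hyper",
        "specific_hypo",
        "transitional_nn_high",
        "transitional_uc_high",
        "unclassified",
    ):
        n = calls.loc[calls["profile"] == profile, "gene_id"].nunique() if len(calls) else 0
        rows.append({"stage": f"genes_{profile}", "count": int(n)})
    return pd.DataFrame(rows, columns=["stage", "count"])


def dmr_gene_audit(
    gene_id: str,
    merged_dmr: MergedDMR,
    meth: CpGMethylation,
    e: pd.DataFrame,
    sheet: SampleSheet,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample, per-CpG data behind a single gene/DMR panel.

    Returns ``(points, trends)``: ``points`` has one row per covered
    (CpG, sample) cell with its beta and the sample's expression;
    ``trends`` has the per-group ordinary least-squares beta-vs-position
    line (slope NaN and flagged when the region has a single CpG).
    """
    mask = meth.interval_mask(merged_dmr.interval)
    pos = meth.pos[mask]
    beta = meth.beta()[mask]
    expr = e.loc[gene_id]
    group_of = sheet.group_of
    rows = []
    for i, p in enumerate(pos):
        for j, sample in enumerate(meth.sample_ids):
            if np.isnan(beta[i, j]):
                continue
            rows.append(
                {
                    "gene_id": gene_id,
                    "dmr_id": merged_dmr.dmr_id,
                    "pos": int(p),
                    "sample_id": sample,
                    "group": group_of[sample],
                    "beta": float(beta[i, j]),
                    "log2_expression": float(expr[sample]),
                }
            )
    points = pd.DataFrame(
        rows,
        columns=["gene_id", "dmr_id", "pos", "sample_id", "group",
                 "beta", "log2_expression"],
    )
    trends = []
    for group in sorted(set(sheet.groups)):
        sub = points[points["group"] == group]
        if sub.empty:
            continue
        x = sub["pos"].to_numpy(dtype=float)
        y = sub["beta"].to_numpy(dtype=float)
        if len(np.unique(x)) < 2:
            trends.append(
                {"group": group, "slope": np.nan, "intercept": float(y.mean()),
                 "single_position": True}
            )
        else:
            slope, intercept = np.polyfit(x, y, 1)
            trends.append(
                {"group": group, "slope": float(slope), "intercept": float(intercept),
                 "single_position": False}
            )
    return points, pd.DataFrame(
        trends, columns=["group", "slope", "intercept", "single_position"]
    )
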