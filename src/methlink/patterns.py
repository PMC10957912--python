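"""Methylation-profile classification of selected gene-DMR links.

Each selected link is assigned one of four profiles from the geometry
of its region's group mean methylation (m_NN, m_RM, m_UC):

* ``specific_hyper`` / ``specific_hypo`` — the remission group is the
  extreme (max / min) and the region is remission-specific (both RM
  t-tests p < 0.05);
* ``transitional_nn_high`` / ``transitional_uc_high`` — RM lies
  strictly between NN and UC and the two extremes differ
  (UC-vs-NN t-test p < 0.05), labelled by which extreme is higher;
* ``unclassified`` otherwise.

The profiles are mutually exclusive; expression direction is carried
along for reporting but is not a classification criterion — the gene
already had to be a negatively correlated DEG to be selected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .integrate import MergedDMR
from .io import SampleSheet

PROFILES = (
    "specific_hyper",
    "specific_hypo",
    "transitional_nn_high",
    "transitional_uc_high",
    "unclassified",
)


def classify_region(m: MergedDMR, sheet: SampleSheet) -> tuple[str, tuple[float, float, float]]:
    """Profile of one merged DMR from its group means and t-tests."""
    if np.isnan(m.t_rm_nn_p) or np.isnan(m.t_rm_uc_p) or np.isnan(m.t_uc_nn_p):
        raise ValueError(f"{m.dmr_id}: missing t-test p-values; run flag_rm_specific")
    m_nn, m_rm, m_uc = m.group_means(sheet)
    if m.rm_specific and m_rm > max(m_nn, m_uc):
        return "specific_hyper", (m_nn, m_rm, m_uc)
    if m.rm_specific and m_rm < min(m_nn, m_uc):
        return "specific_hypo", (m_nn, m_rm, m_uc)
    if min(m_nn, m_uc) < m_rm < max(m_nn, m_uc) and m.t_uc_nn_p < 0.05:
        profile = "transitional_nn_high" if m_nn > m_uc else "transitional_uc_high"
        return profile, (m_nn, m_rm, m_uc)
    return "unclassified", (m_nn, m_rm, m_uc)


def classify(
    merged: list[MergedDMR],
    links: pd.DataFrame,
    sheet: SampleSheet,
) -> pd.DataFrame:
    """Profile every selected link; one row per (gene, DMR) pair.

    ``links`` is the audit table from :func:`methlink.promoter.select_links`;
    only rows with ``selected`` are classified.  A gene with several
    qualifying DMRs gets one row per DMR (conflicting profiles are
    visible per-DMR, not collapsed).
    """
    by_id = {m.dmr_id: m for m in merged}
    rows = []
    for r in links[links["selected"]].itertuples():
        m = by_id[r.dmr_id]
        profile, (m_nn, m_rm, m_uc) = classify_region(m, sheet)
        rows.append(
            {
                "gene_id": r.gene_id,
                "dmr_id": r.dmr_id,
                "profile": profile,
                "tau": r.tau,
                "p_tau": r.p_tau,
                "mean_nn": m_nn,
                "mean_rm": m_rm,
                "mean_uc": m_uc,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "dmr_id", "profile", "tau", "p_tau",
            "mean_nn", "mean_rm", "mean_uc",
        ],
    )


def summarize_genes(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-level rollup and per-profile counts.

    Returns ``(gene_table, profile_counts)``.  A gene appears once, with
    its distinct profiles joined by ';' and its DMR count; the counts
    table reports genes and DMR calls per profile (a gene with DMRs in
    two profiles is counted in both).
    """
    if calls.empty:
        gene_table = pd.DataFrame(
            columns=["gene_id", "profiles", "dmr_count", "mean_tau"]
        )
        profile_counts = pd.DataFrame(
            {"profile": list(PROFILES), "n_genes": 0, "n_dmrs": 0}
        )
        return gene_table, profile_counts
    gene_table = (
        calls.groupby("gene_id")
        .agg(
            profiles=("profile", lambda s: ";".join(sorted(set(s)))),
            dmr_count=("dmr_id", "nunique"),
            mean_tau=("tau", "mean"),
        )
        .reset_index()
    )
    profile_counts = pd.DataFrame(
        {
            "profile": list(PROFILES),
            "n_genes": [
                calls.loc[calls["profile"] == p, "gene_id"].nunique() for p in PROFILES
            ],
            "n_dmrs": [
                calls.loc[calls["profile"] == p, "dmr_id"].nunique() for p in PROFILES
            ],
        }
    )
    return gene_table, profile_counts
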