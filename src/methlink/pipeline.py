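"""End-to-end orchestration of the integration analysis.

simulate (or load) -> DMR calling for the three comparisons ->
differential expression for the three comparisons -> overlap merge +
remission-specificity -> promoter-window Kendall linking -> pattern
classification -> deconvolution -> summaries.  All stage outputs are
written as TSV/BED with fixed float formatting so that identical
configs and seeds produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, io as mio, patterns, promoter, report
from .deconvolve import deconvolve_cohort, group_anova_tukey
from .dmr import CallerParams, call_dmrs
from .integrate import flag_rm_specific, merge_dmrs, merged_frame
from .simulate import SimulationConfig, simulate_cohort

COMPARISON_PAIRS = {
    "RMvsNN": ("RM", "NN"),
    "RMvsUC": ("RM", "UC"),
    "UCvsNN": ("UC", "NN"),
}

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Everything `run_pipeline` needs, loadable from YAML."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    caller: CallerParams = field(default_factory=CallerParams)
    de_alpha: float = 0.05
    link_p_cut: float = 0.1
    promoter_width: int = 2000
    keep_single_source: bool = False
    reference_path: str | None = None

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            simulation=SimulationConfig(**raw.get("simulation", {})),
            caller=CallerParams(**raw.get("caller", {})),
            **{
                k: raw[k]
                for k in ("de_alpha", "link_p_cut", "promoter_width",
                          "keep_single_source", "reference_path")
                if k in raw
            },
        )

    def to_yaml(self, path: Path | str) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "simulation": asdict(self.simulation),
                    "caller": asdict(self.caller),
                    "de_alpha": self.de_alpha,
                    "link_p_cut": self.link_p_cut,
                    "promoter_width": self.promoter_width,
                    "keep_single_source": self.keep_single_source,
                    "reference_path": self.reference_path,
                },
                sort_keys=True,
            )
        )


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig, outdir: Path | str) -> dict[str, object]:
    """Run the full analysis on a simulated cohort; write all stage tables.

    Returns the in-memory stage objects keyed by name.  Deterministic:
    per-comparison caller seeds are derived from the one caller seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    meth, counts, genes, sheet, truths = simulate_cohort(config.simulation)
    from .simulate import ground_truth_frame, make_cell_reference

    mio.write_sheet(sheet, outdir / "samples.tsv")
    mio.write_counts(counts, outdir / "counts.tsv")
    mio.write_annotation(genes, outdir / "annotation.tsv")
    _write(ground_truth_frame(truths), outdir / "ground_truth.tsv")

    # DMR calling, three comparisons
    dmrs_by_comparison = {}
    for k, (comp, (ga, gb)) in enumerate(COMPARISON_PAIRS.items()):
        params = self_seed(config.caller, k)
        dmrs = call_dmrs(meth, sheet, ga, gb, params)
        dmrs_by_comparison[comp] = dmrs
        mio.write_dmr_bed(dmrs, outdir / f"dmrs_{comp}.bed")

    # differential expression, three comparisons
    degs_by_comparison = {}
    s = diffexpr.size_factors(counts)
    e = diffexpr.log_norm(counts, s)
    for comp, (ga, gb) in COMPARISON_PAIRS.items():
        res, _ = diffexpr.differential_expression(
            counts, sheet, ga, gb, alpha=config.de_alpha
        )
        degs_by_comparison[comp] = res
        _write(res.reset_index(), outdir / f"degs_{comp}.tsv")

    # merge + remission specificity
    merged = merge_dmrs(dmrs_by_comparison, keep_single_source=config.keep_single_source)
    merged = flag_rm_specific(merged, meth, sheet)
    _write(merged_frame(merged, sheet), outdir / "merged_dmrs.tsv")

    # promoter linking
    deg_genes = {
        g for res in degs_by_comparison.values() for g in res.index[res["is_deg"]]
    }
    pairs = promoter.link_dmrs_to_genes(merged, genes, width=config.promoter_width)
    links = promoter.select_links(
        pairs, e, sheet, deg_genes, p_cut=config.link_p_cut
    )
    _write(links, outdir / "links.tsv")

    # classification
    calls = patterns.classify(merged, links, sheet)
    _write(calls, outdir / "patterns.tsv")
    gene_table, profile_counts = patterns.summarize_genes(calls)
    _write(gene_table, outdir / "genes_by_profile.tsv")
    _write(profile_counts, outdir / "profile_counts.tsv")

    # deconvolution: with a real cell-type reference, on merged-DMR
    # methylation; without one, demonstrated on simulated DMR-level
    # mixtures (the bulk simulator does not model cell composition)
    fractions = anova = true_fractions = None
    if config.reference_path is not None and len(merged) >= 3:
        reference = pd.read_csv(config.reference_path, sep="\t", index_col=0)
        fractions = deconvolve_cohort(meth, merged, reference, sheet)
    else:
        from .simulate import simulate_fraction_cohort, simulate_mixtures
        from .deconvolve import deconvolve_matrix

        seed = config.simulation.seed
        reference = make_cell_reference(100, seed=seed + 1)
        true_fractions = simulate_fraction_cohort(sheet, seed=seed + 2)
        beta = simulate_mixtures(reference, true_fractions, noise_sd=0.02, seed=seed + 3)
        fractions = deconvolve_matrix(beta, reference)
        _write(true_fractions, outdir / "cell_fractions_true.tsv", index=True)
    _write(fractions, outdir / "cell_fractions.tsv", index=True)
    anova = group_anova_tukey(fractions, sheet)
    _write(anova, outdir / "cell_fraction_tests.tsv")

    # PCA of selected genes' expression
    pca = None
    selected_genes = sorted(set(calls["gene_id"])) if len(calls) else []
    if len(selected_genes) >= 2:
        pca = report.pca_expression(e.loc[selected_genes], sheet)
        _write(pca.scores.reset_index(names="sample_id"), outdir / "pca_scores.tsv")
        _write(
            pd.DataFrame(
                {
                    "component": [f"PC{i+1}" for i in range(len(pca.explained_variance_ratio))],
                    "explained_variance_ratio": pca.explained_variance_ratio,
                }
            ),
            outdir / "pca_variance.tsv",
        )

    summary = report.pipeline_summary(
        dmrs_by_comparison, degs_by_comparison, merged, links, calls
    )
    _write(summary, outdir / "summary.tsv")
    config.to_yaml(outdir / "config.yaml")

    return {
        "meth": meth,
        "counts": counts,
        "genes": genes,
        "sheet": sheet,
        "truths": truths,
        "expression": e,
        "dmrs": dmrs_by_comparison,
        "degs": degs_by_comparison,
        "merged": merged,
        "links": links,
        "calls": calls,
        "fractions": fractions,
        "anova": anova,
        "pca": pca,
        "summary": summary,
    }


def self_seed(params: CallerParams, offset: int) -> CallerParams:
    """Per-comparison caller params with a distinct derived seed."""
    return replace(params, seed=(params.seed * 7919 + offset) % (2**31 - 1))
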