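"""Synthetic three-group cohort generator.

Emulates the data model of a targeted-bisulfite + RNA-seq study of
inactive ulcerative colitis: three groups of samples (NN controls, RM
remission, UC active disease), clustered CpG positions with
beta-binomial methylated counts, negative-binomial gene expression
counts, and planted promoter regions whose methylation differs between
groups in one of four pattern classes and is negatively coupled to the
linked gene's expression.

Group sizes default to 11/20/14 (NN/RM/UC), the cohort composition the
analysis is designed around.  Every draw comes from a single
`numpy.random.Generator` seeded from the config, so the same config
always produces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CpGMethylation, GeneModel, SampleSheet

PATTERNS = (
    "specific_hyper",
    "specific_hypo",
    "transitional_nn_high",
    "transitional_uc_high",
)

#: Fixed negative-binomial dispersion of per-CpG sequencing depth.
COVERAGE_DISPERSION = 0.2

_GENE_SPACING = 10_000
_FIRST_TSS = 10_000
_PROMOTER_WIDTH = 2_000
_BETA_CLIP = (0.02, 0.98)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults are the study conditions: 11/20/14 samples, a planted
    methylation difference of 0.3 between groups on 10-CpG promoter
    clusters, ~30x coverage, and a methylation->expression coupling
    that shifts a planted gene's log2 mean by
    ``-coupling_slope * (sample promoter beta - baseline_beta)``.
    """

    seed: int = 0
    n_nn: int = 11
    n_rm: int = 20
    n_uc: int = 14
    n_genes: int = 60
    genes_per_pattern: int = 5
    n_null_genes: int = 40
    cpgs_per_promoter: int = 10
    baseline_beta: float = 0.5
    effect_delta: float = 0.3
    bb_dispersion: float = 0.05
    mean_coverage: float = 30.0
    nb_mean: float = 100.0
    nb_dispersion: float = 0.05
    coupling_slope: float = 2.0

    def __post_init__(self) -> None:
        for name in ("n_nn", "n_rm", "n_uc", "n_genes", "genes_per_pattern",
                     "cpgs_per_promoter"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_null_genes < 0:
            raise ValueError("n_null_genes must be >= 0")
        if self.genes_per_pattern * 4 + self.n_null_genes > self.n_genes:
            raise ValueError(
                "genes_per_pattern*4 + n_null_genes exceeds n_genes: "
                f"{self.genes_per_pattern * 4} + {self.n_null_genes} > {self.n_genes}"
            )
        for name in ("baseline_beta", "effect_delta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.bb_dispersion < 1.0:
            raise ValueError("bb_dispersion must lie in (0, 1)")
        if self.mean_coverage <= 0 or self.nb_mean <= 0:
            raise ValueError("mean_coverage and nb_mean must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.coupling_slope < 0:
            raise ValueError("coupling_slope must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.n_nn + self.n_rm + self.n_uc


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth for one gene."""

    gene_id: str
    pattern: str  # one of PATTERNS or "null"
    chrom: str
    start: int  # 0-based half-open planted region (promoter CpG cluster)
    end: int
    beta_nn: float
    beta_rm: float
    beta_uc: float


def _pattern_betas(pattern: str, base: float, delta: float) -> tuple[float, float, float]:
    lo, hi = _BETA_CLIP
    clip = lambda x: float(np.clip(x, lo, hi))
    if pattern == "specific_hyper":
        return clip(base), clip(base + delta), clip(base)
    if pattern == "specific_hypo":
        return clip(base), clip(base - delta), clip(base)
    if pattern == "transitional_nn_high":
        return clip(base + delta), clip(base), clip(base - delta)
    if pattern == "transitional_uc_high":
        return clip(base - delta), clip(base), clip(base + delta)
    if pattern == "null":
        return clip(base), clip(base), clip(base)
    raise ValueError(f"unknown pattern {pattern!r}")


def _beta_binomial(
    rng: np.random.Generator, n: np.ndarray, mean: np.ndarray, rho: float
) -> np.ndarray:
    """Beta-binomial draws with mean/overdispersion parameterization.

    alpha = mean*(1-rho)/rho, beta = (1-mean)*(1-rho)/rho, so the
    marginal mean is ``mean`` and the intraclass correlation is rho.
    """
    a = mean * (1.0 - rho) / rho
    b = (1.0 - mean) * (1.0 - rho) / rho
    p = rng.beta(np.broadcast_to(a, n.shape), np.broadcast_to(b, n.shape))
    return rng.binomial(n, p)


def _neg_binomial(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson draws with Var = mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[CpGMethylation, pd.DataFrame, list[GeneModel], SampleSheet, list[GroundTruth]]:
    """Generate methylation counts, expression counts, annotation, sheet, truth.

    All genes live on one chromosome with TSSs spaced 10 kb apart and
    alternating strand.  Each gene receives a CpG cluster centred inside
    its 2000 bp upstream window (sites spaced 20-100 bp); planted genes
    get group-specific mean betas, null genes the baseline.  Background
    CpGs midway between genes exercise the DMR caller on non-promoter
    sequence.
    """
    rng = np.random.default_rng(config.seed)
    chrom = "chr1"

    sample_ids = (
        [f"NN{i + 1:02d}" for i in range(config.n_nn)]
        + [f"RM{i + 1:02d}" for i in range(config.n_rm)]
        + [f"UC{i + 1:02d}" for i in range(config.n_uc)]
    )
    groups = ["NN"] * config.n_nn + ["RM"] * config.n_rm + ["UC"] * config.n_uc
    sheet = SampleSheet(sample_ids, groups)
    group_index = {"NN": 0, "RM": 1, "UC": 2}
    sample_group_idx = np.array([group_index[g] for g in groups])
    n_samples = len(sheet)

    patterns = [p for p in PATTERNS for _ in range(config.genes_per_pattern)]
    patterns += ["null"] * (config.n_genes - len(patterns))

    genes: list[GeneModel] = []
    truths: list[GroundTruth] = []
    cpg_pos: list[int] = []
    cpg_group_means: list[tuple[float, float, float]] = []
    gene_cluster_rows: dict[str, tuple[int, int]] = {}

    row = 0
    for i, pattern in enumerate(patterns):
        gene_id = f"G{i + 1:04d}"
        tss = _FIRST_TSS + i * _GENE_SPACING
        strand = "+" if i % 2 == 0 else "-"
        genes.append(GeneModel(gene_id, chrom, strand, tss))

        # 0-based half-open upstream window.
        if strand == "+":
            win_start, win_end = max(0, tss - 1 - _PROMOTER_WIDTH), tss - 1
        else:
            win_start, win_end = tss, tss + _PROMOTER_WIDTH

        spacings = rng.integers(20, 101, size=config.cpgs_per_promoter - 1)
        span = int(spacings.sum())
        centre = (win_start + win_end) // 2
        first = centre - span // 2
        offsets = np.concatenate([[0], np.cumsum(spacings)])
        positions0 = first + offsets  # 0-based site coordinates
        betas = _pattern_betas(pattern, config.baseline_beta, config.effect_delta)

        cpg_pos.extend(int(p) + 1 for p in positions0)  # store 1-based
        cpg_group_means.extend([betas] * config.cpgs_per_promoter)
        gene_cluster_rows[gene_id] = (row, row + config.cpgs_per_promoter)
        row += config.cpgs_per_promoter

        truths.append(
            GroundTruth(
                gene_id,
                pattern,
                chrom,
                int(positions0[0]),
                int(positions0[-1]) + 1,
                *betas,
            )
        )

        # background CpGs in the intergenic stretch downstream of the window
        bg_lo = tss + _PROMOTER_WIDTH + 500
        bg_hi = tss + _GENE_SPACING - 500
        bg = np.sort(rng.integers(bg_lo, bg_hi, size=3))
        bg = bg[np.concatenate([[True], np.diff(bg) > 1])]
        base = _pattern_betas("null", config.baseline_beta, 0.0)
        cpg_pos.extend(int(p) + 1 for p in bg)
        cpg_group_means.extend([base] * len(bg))
        row += len(bg)

    order = np.argsort(cpg_pos, kind="stable")
    pos = np.asarray(cpg_pos, dtype=int)[order]
    means3 = np.asarray(cpg_group_means, dtype=float)[order]
    # positions are constructed non-colliding, but guard against duplicates
    if np.any(np.diff(pos) <= 0):
        keep = np.concatenate([[True], np.diff(pos) > 0])
        pos, means3 = pos[keep], means3[keep]
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    m = len(pos)

    coverage = _neg_binomial(
        rng, np.full((m, n_samples), config.mean_coverage), COVERAGE_DISPERSION
    )
    mean_per_cell = means3[:, sample_group_idx]
    n_meth = _beta_binomial(rng, coverage, mean_per_cell, config.bb_dispersion)

    meth = CpGMethylation(
        np.full(m, chrom, dtype=object), pos, list(sample_ids), n_meth, coverage
    )

    # expression: per-sample log2 mean shifted by the realized promoter beta
    counts = np.zeros((config.n_genes, n_samples), dtype=int)
    for i, truth in enumerate(truths):
        if truth.pattern != "null" and config.coupling_slope > 0:
            lo, hi = gene_cluster_rows[truth.gene_id]
            rows = inv[np.arange(lo, hi)]
            tot = meth.n_total[rows].sum(axis=0)
            met = meth.n_meth[rows].sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                sample_beta = np.where(tot > 0, met / tot, config.baseline_beta)
            shift = -config.coupling_slope * (sample_beta - config.baseline_beta)
        else:
            shift = np.zeros(n_samples)
        mu = config.nb_mean * np.exp2(shift)
        counts[i] = _neg_binomial(rng, mu, config.nb_dispersion)

    counts_df = pd.DataFrame(
        counts, index=[g.gene_id for g in genes], columns=sample_ids
    )
    counts_df.index.name = "gene_id"
    return meth, counts_df, genes, sheet, truths


def ground_truth_frame(truths: Sequence[GroundTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": t.gene_id,
                "pattern": t.pattern,
                "chrom": t.chrom,
                "start": t.start,
                "end": t.end,
                "beta_nn": t.beta_nn,
                "beta_rm": t.beta_rm,
                "beta_uc": t.beta_uc,
            }
            for t in truths
        ]
    )


def write_cohort(
    outdir: Path | str, config: SimulationConfig
) -> dict[str, object]:
    """Simulate and write every pipeline input format under ``outdir``."""
    from . import io as mio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meth, counts, genes, sheet, truths = simulate_cohort(config)
    cov_dir = outdir / "coverage"
    paths = mio.write_bismark_coverage(meth, cov_dir)
    mio.write_counts(counts, outdir / "counts.tsv")
    mio.write_annotation(genes, outdir / "annotation.tsv")
    mio.write_sheet(sheet, outdir / "samples.tsv")
    ground_truth_frame(truths).to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    return {
        "coverage_dir": cov_dir,
        "coverage_paths": paths,
        "counts": outdir / "counts.tsv",
        "annotation": outdir / "annotation.tsv",
        "sheet": outdir / "samples.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
    }


# ---------------------------------------------------------------------------
# Cell-mixture fixtures for deconvolution
# ---------------------------------------------------------------------------

CELL_TYPES = ("Epi", "Fib", "IC")


def make_cell_reference(
    n_features: int,
    cell_types: Sequence[str] = CELL_TYPES,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic cell-type methylation reference (features x cell types).

    Entries are drawn from a U-shaped Beta(0.4, 0.4), mimicking the
    bimodal betas of discriminating CpGs in sorted-cell references.
    """
    rng = np.random.default_rng(seed)
    values = rng.beta(0.4, 0.4, size=(n_features, len(cell_types)))
    return pd.DataFrame(
        values,
        index=[f"F{i + 1:04d}" for i in range(n_features)],
        columns=list(cell_types),
    )


def simulate_mixtures(
    reference: pd.DataFrame,
    fractions: pd.DataFrame,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Mix reference profiles into per-sample beta vectors.

    ``fractions`` is samples x cell types, each row on the unit simplex
    (checked to 1e-9).  Output is features x samples, clipped to [0, 1].
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if list(fractions.columns) != list(reference.columns):
        raise ValueError("fraction columns must match reference cell types")
    sums = fractions.to_numpy().sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-9):
        bad = fractions.index[np.abs(sums - 1.0) > 1e-9].tolist()
        raise ValueError(f"fraction vectors not on the simplex: {bad}")
    if np.any(fractions.to_numpy() < 0):
        raise ValueError("fractions must be nonnegative")
    rng = np.random.default_rng(seed)
    mixed = reference.to_numpy() @ fractions.to_numpy().T
    if noise_sd > 0:
        mixed = mixed + rng.normal(0.0, noise_sd, size=mixed.shape)
    mixed = np.clip(mixed, 0.0, 1.0)
    return pd.DataFrame(mixed, index=reference.index, columns=fractions.index)


def simulate_fraction_cohort(
    sheet: SampleSheet,
    seed: int = 0,
    concentration: float = 60.0,
    profiles: dict[str, Sequence[float]] | None = None,
) -> pd.DataFrame:
    """Per-sample cell fractions with an inflamed active-UC profile.

    Defaults plant the direction seen in colitis biopsies: active UC has
    a lower epithelial and higher immune-cell fraction than remission or
    controls.  Rows are Dirichlet draws around the group profile.
    """
    if profiles is None:
        profiles = {
            "NN": (0.70, 0.12, 0.18),
            "RM": (0.66, 0.12, 0.22),
            "UC": (0.45, 0.13, 0.42),
        }
    rng = np.random.default_rng(seed)
    rows = []
    for sample, group in zip(sheet.sample_ids, sheet.groups):
        alpha = np.asarray(profiles[group], dtype=float) * concentration
        rows.append(rng.dirichlet(alpha))
    return pd.DataFrame(rows, index=sheet.sample_ids, columns=list(CELL_TYPES))
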