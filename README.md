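# methlink

Integration of targeted bisulfite sequencing and RNA-seq for cohorts with
three clinical groups — non-IBD controls (NN), ulcerative colitis in
remission (RM) and active ulcerative colitis (UC) — to identify genes whose
expression is plausibly regulated by promoter DNA methylation in the
remission state.

The package is aimed at computational biologists analysing Bismark-style
CpG coverage files together with a gene-level count matrix. Because patient
methylation data of this kind is usually consent-restricted, the package
ships a synthetic-cohort generator with planted, ground-truthed signal, so
every stage is testable end to end without access to clinical data.

## Method

Starting from per-CpG methylated/total read counts and raw expression
counts for *n* = 11 + 20 + 14 samples:

1. **DMR calling** (per pairwise comparison RM–NN, RM–UC, UC–NN): candidate
   regions are maximal runs of ≥ 3 CpGs, spaced ≤ 1 kb, whose
   coverage-weighted group beta difference dᵢ = β̄ₐᵢ − β̄ᵦᵢ is same-signed
   with |dᵢ| ≥ 0.1. Each region is scored by the area statistic
   S = Σᵢ dᵢ and assigned p = (1 + #{null |S| ≥ |S|}) / (1 + N_null) against
   a pooled null from B = 100 whole-sample label permutations, then
   Benjamini–Hochberg adjusted; regions with q < 0.05 are kept.
2. **Differential expression**: median-of-ratios size factors,
   e = log₂(count/s + 1), per-gene Welch t-test, BH adjustment; the DEG set
   is padj < 0.05.
3. **Integration**: the three comparisons' DMRs are merged by
   single-linkage genomic overlap; clusters supported by only one
   comparison are discarded. Each merged region gets per-sample mean
   methylation (Σ meth / Σ total over its CpGs) and is flagged
   *remission-specific* when Welch tests of RM against both NN and UC give
   p < 0.05.
4. **Promoter linking**: a merged DMR is linked to every gene whose
   strand-aware 2000 bp upstream window it overlaps; Kendall τ_b between
   region methylation and the gene's log₂ expression is computed over the
   pooled cohort (exact permutation p for n ≤ 8, tie-corrected normal
   approximation otherwise). Links with τ < 0 at p < 0.1 whose gene is a
   DEG are selected.
5. **Profile classification**: each selected gene/region is labelled
   `specific_hyper` / `specific_hypo` (RM is the methylation extreme and
   the region is remission-specific) or `transitional_nn_high` /
   `transitional_uc_high` (RM strictly between NN and UC, extremes
   differing at p < 0.05).
6. **Cell-type deconvolution**: sample beta vectors over discriminating
   features are fit as mixtures of epithelial/fibroblast/immune reference
   profiles by Huber robust regression (c = 1.345), truncated and
   renormalized onto the simplex; fractions are compared across groups by
   one-way ANOVA with Tukey's range test.
7. **Reporting**: PCA (explained variance) of the selected genes'
   expression, stage-count summaries and per-region audit tables.

## Worked example

```bash
methlink run-all --seed 3 --outdir results_demo
```

or equivalently from Python (`examples/07_full_pipeline.py`):

```python
from methlink import PipelineConfig, run_pipeline
res = run_pipeline(PipelineConfig(), "pipeline_output")
print(res["summary"].to_string(index=False))
```

On the default synthetic cohort (seed 0) this prints

```
                     stage  count
               dmrs_RMvsNN     21
               dmrs_RMvsUC     21
               dmrs_UCvsNN     11
               degs_RMvsNN     22
               degs_RMvsUC     22
               degs_UCvsNN     10
               merged_dmrs     21
          rm_specific_dmrs     21
            selected_links     21
      genes_specific_hyper      5
       genes_specific_hypo      5
genes_transitional_nn_high      5
genes_transitional_uc_high      5
        genes_unclassified      0
```

The cohort plants five genes per profile class; all twenty are recovered
with the correct profile (the extra selected link is a planted region
linked to a neighbouring gene). `examples/` holds one narrative script per
capability — simulation, DMR calling, differential expression, integration
and linking, classification, deconvolution, full pipeline — each printing
the numbers it computes and what they mean.

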