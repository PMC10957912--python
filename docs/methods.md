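# Methods

This note documents the models, defaults and design decisions behind
`methlink`, and what the synthetic-cohort tests do and do not establish
about real data.

## Data model and coordinate conventions

Methylation enters as per-CpG, per-sample methylated/total read counts
(Bismark-style coverage files, 1-based inclusive positions). Internally
every interval is 0-based half-open; a 1-based CpG at position *p*
belongs to `[s, e)` iff `s ≤ p − 1 < e`. BED output is 0-based
half-open. The coverage file's percentage column is always recomputed
from the counts (a > 0.5 point discrepancy raises a warning, counts
win). CpGs are strand-collapsed, matching coverage-file convention.
A zero total count encodes a missing observation; beta = meth/total is
undefined there and such cells are excluded pairwise downstream.

## DMR caller

The caller is a transparent permutation scheme rather than a smoothed
generalized-least-squares model: candidate regions are runs of CpGs
with same-signed, coverage-weighted group beta differences, scored by
the area statistic (sum of per-CpG differences). The group mean is
read-weighted (Σ meth / Σ total), so deeply covered samples contribute
more — the natural pooling for count data and robust to low-coverage
noise.

Inference permutes whole-sample labels (preserving group sizes and
within-sample correlation), re-forms candidate regions per permutation,
and pools all null |S| values genome-wide. Pooling is used because
candidate regions differ between permutations, so a per-region null is
not well defined; the pooled null is the standard genome-wide choice.
The add-one p-value `(1 + #{null ≥ obs}) / (1 + N_null)` keeps p in
(0, 1]. BH step-up gives q-values; regions at q < 0.05 are reported.

Defaults: `min_cov 5`, `min_cov_frac 0.8` (coverage QC per group),
`delta 0.1` (per-CpG minimum effect), `max_gap 1000` bp,
`min_cpgs 3`, `B 100` permutations. These are this package's choices;
with B = 100 permutations the smallest attainable p is bounded by the
pooled null size, which is why q-values rather than raw p drive
retention. An optional running-mean smoothing of d (window 3) exists
behind `smooth=True`, off by default.

## Differential expression

Median-of-ratios size factors (genes containing any zero are excluded
from the geometric-mean reference; a pseudocount mode covers matrices
where no such gene exists), `log2(count/s + 1)` normalization, then a
per-gene Welch t-test with BH adjustment. A negative-binomial GLM would
be more powerful at small n; the Welch-on-log stage was chosen because
the downstream logic consumes only the DEG set and the log2 expression
values, and the module boundary lets a stricter test be swapped in
without touching any other stage. Genes with zeros in > 90% of samples
are excluded and reported as untested. Under null simulation the raw
p < 0.05 rate is calibrated (asserted within [0.03, 0.07] at 2000
genes).

## Integration and remission specificity

Merging is single-linkage clustering by any-base overlap of the pooled
three-comparison DMR set (for intervals this equals a sorted sweep;
tests verify equivalence with a transitive-closure oracle). Bookended
intervals (end == start) do not overlap. A cluster survives only if its
members come from ≥ 2 distinct comparisons — cross-comparison overlap
is the integration signal; `keep_single_source=True` disables the
discard for exploration.

Remission specificity uses Welch t-tests (the unequal-variance-safe
default; the underlying requirement is only "a t-test") on per-sample
region mean methylation: RM vs NN and RM vs UC both at p < 0.05.

## Promoter linking and Kendall correlation

The promoter window is the 2000 bp strictly upstream of the TSS,
strand-aware, clipped at the chromosome start; overlap by ≥ 1 base
links a region to a gene (a containment mode exists for the strict
reading; many-to-many links are allowed). Correlation pools all 45
samples across the three groups, since the pattern of interest —
methylation tracking expression — is a cohort-level monotone trend.

Kendall τ_b is computed from pair counts with tie correction. The
p-value is exact for n ≤ 8 by enumerating all n! orderings of y (valid
under ties because the tie structure is invariant under permutation);
for larger n the tie-corrected normal approximation of S = C − D is
used and cross-checked against an independent implementation in tests.
Selection requires τ < 0 and two-sided p < 0.1 plus DEG membership in
at least one of the three comparisons (which comparison must support
the gene is deliberately not restricted).

## Profile classification

Classification uses only the methylation geometry of the merged region
(group means of per-sample region methylation) plus the already-imposed
selection constraints: `specific_hyper`/`specific_hypo` need remission
specificity and RM at the extreme; `transitional_*` needs RM strictly
between NN and UC with the two extremes differing at p < 0.05, labelled
by the higher extreme. Expression direction is reported but is not a
classification criterion — the gene already had to be a negatively
correlated DEG to reach this stage. The rules are mutually exclusive;
a remission-specific region whose RM mean is nevertheless between the
extremes classifies as transitional.

## Deconvolution

Fractions are estimated per sample by Huber robust regression
(tuning constant 1.345, IRLS, ≤ 100 iterations, tol 1e-8, via
statsmodels RLM) of the sample's beta vector on the reference columns
with intercept, followed by truncation of negative coefficients at zero
and renormalization — the robust-partial-correlation style of
reference-based methylation deconvolution. Cell types are epithelial,
fibroblast and immune (Epi/Fib/IC). The reference matrix is an input:
array-based references cannot be redistributed here, so the simulator
provides synthetic references (U-shaped Beta(0.4, 0.4) entries
mimicking discriminating CpGs). ANOVA plus Tukey's range test compare
fractions across the unbalanced groups; the Tukey–Kramer pairwise
harmonic-mean correction handles 11/20/14.

In the orchestrated run without a user reference, the bulk simulator
does not model cell composition, so the deconvolution stage is
demonstrated on simulated DMR-level mixtures with planted per-group
fractions (active UC: immune up, epithelial down — the inflamed-mucosa
direction), written alongside the estimated fractions.

## Synthetic cohort

The generator emulates the cohort design the analysis assumes: groups
of 11/20/14 (NN/RM/UC), one chromosome, genes every 10 kb with
alternating strand, a 10-CpG promoter cluster per gene (sites spaced
20–100 bp, centred in the upstream window), plus intergenic background
CpGs. Planted genes (5 per pattern class by default) get group mean
betas at baseline 0.5 ± 0.3; coverage is negative-binomial around 30×
(dispersion 0.2); methylated counts are beta-binomial with
mean/overdispersion parameterization α = β(1−ρ)/ρ, b = (1−β)(1−ρ)/ρ
and ρ = 0.05. Expression is negative-binomial (mean 100, dispersion
0.05) with the planted genes' per-sample log2 mean shifted by
−2 · (realized promoter beta − 0.5), inducing the negative
methylation–expression correlation the pipeline is designed to detect.
All draws come from one seeded generator in fixed genomic order, so a
config is reproducible to the byte.

What the generator does **not** model: read-level artifacts, alignment
error, batch effects, SNP-induced methylation artefacts, cell-type
heterogeneity of the bulk methylation signal, or correlated
gene-gene expression structure. Passing tests therefore establish
correctness of the statistical machinery and calibrated error control
under the assumed generative model — not performance under real-world
confounding.

## Problem sizes and numerical choices

The bundled validation runs use 60-gene cohorts (20 planted, 40 null,
~800 CpGs), 25 replicate cohorts for recovery rates, 20 null cohorts
for false-discovery behaviour, and 100-sample/100-feature mixtures for
deconvolution; these sizes give stable Monte-Carlo estimates while a
full run stays interactive (seconds per cohort). Degenerate cases are
defined explicitly: zero-variance Welch inputs give p = 1 (equal means)
or p = 0 flagged degenerate; constant Kendall inputs are dropped with a
warning; all-nonpositive robust coefficients fall back to uniform
fractions with a warning. PCA runs on centred, unscaled log2 expression
(already a common scale across genes); `scale=True` is available.
Result tables are written with `%.10g` float formatting, making
same-seed runs byte-identical.

## Known limitations

* The permutation caller's resolution is bounded by B and the pooled
  null size; very small q-values are not attainable at B = 100.
* Welch-on-log differential expression is less powerful than a
  negative-binomial GLM at low counts.
* Promoter linking ignores distal regulation and gene-body
  methylation by design.
* A gene linked to a neighbouring gene's planted region can produce an
  extra (correct-by-the-rules) selected link; classification is
  reported per gene-region pair to keep this visible.
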