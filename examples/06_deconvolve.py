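"""Estimate epithelial / fibroblast / immune fractions from methylation.

Sample beta vectors over discriminating features are modelled as convex
mixtures of cell-type reference profiles; a Huber robust regression
with truncation and renormalization puts the estimates on the simplex.
Group differences are tested with ANOVA and Tukey's range test.
"""

import pandas as pd

from methlink import (
    SampleSheet,
    deconvolve_matrix,
    group_anova_tukey,
    make_cell_reference,
    simulate_fraction_cohort,
    simulate_mixtures,
)

ids = ([f"NN{i}" for i in range(11)] + [f"RM{i}" for i in range(20)]
       + [f"UC{i}" for i in range(14)])
sheet = SampleSheet(ids, ["NN"] * 11 + ["RM"] * 20 + ["UC"] * 14)

reference = make_cell_reference(100, seed=0)
true_fractions = simulate_fraction_cohort(sheet, seed=1)  # UC: IC up, Epi down
beta = simulate_mixtures(reference, true_fractions, noise_sd=0.02, seed=2)

est = deconvolve_matrix(beta, reference)
rmse = ((est - true_fractions) ** 2).to_numpy().mean() ** 0.5
print(f"fraction RMSE vs planted truth: {rmse:.4f}")

print("\nestimated mean fractions per group:")
print(est.groupby(pd.Series(sheet.group_of)).mean().round(3).to_string())

print("\nANOVA + Tukey per cell type:")
print(group_anova_tukey(est, sheet).round(4).to_string(index=False))
# The immune-cell (IC) fraction is significantly higher and the
# epithelial (Epi) fraction lower in active UC than in remission or
# controls - the inflamed-mucosa signature planted in the truth.
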