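"""Simulate a repeated-measures RNA-seq dataset with known truth.

Builds a two-group, four-timepoint study (5 subjects per arm), draws
gene-level parameters from the surrogate distribution, plants interaction
effects in 20% of genes, simulates NB random-intercept counts, and applies
the low-expression CPM filter.
"""

import numpy as np

from longde import (
    StudyDesign,
    assign_de_effects,
    cpm_filter,
    draw_gene_params,
    simulate_dataset,
    truth_table,
)

design = StudyDesign.balanced(n_per_group=5)
params = draw_gene_params(n_genes=500, seed=1)
params = assign_de_effects(params, prop_de=0.2, seed=2)
counts = simulate_dataset(params, design, seed=3)
truth = truth_table(params, counts.gene_ids)

print(f"design: {design.n_subjects} subjects x {design.n_timepoints} timepoints "
      f"= {design.n_samples} samples")
print(f"simulated {counts.n_genes} genes; "
      f"{int(truth['is_de'].sum())} are truly DE (interaction effects 1/3, 2/3, 1)")
print("first DE gene's coefficients:",
      np.round(truth[truth.is_de].iloc[0][["beta5", "beta6", "beta7"]].to_numpy(float), 3))

filtered, keep = cpm_filter(counts, cpm_threshold=1.0, min_samples=5)
print(f"CPM filter (>1 CPM in >=5 samples) kept {filtered.n_genes}/{counts.n_genes} genes")
print("count matrix corner:")
print(filtered.to_frame().iloc[:4, :4])
# Each row is a gene, each column a sample; the filter removes genes too
# lowly expressed for the longitudinal models to be estimable.
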