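"""Generate a synthetic tumour cohort with a planted immune-regulator miRNA.

The generator couples one miRNA and the members of 40 immune gene sets
to a shared latent immune-activity factor, so the planted miRNA/immune
gene Pearson correlation has a known closed form.
"""

import numpy as np

import mirimmune as mi

config = mi.CohortConfig(seed=1)  # 200 patients, 4000 genes, 20 miRNAs
genes, mirnas, truth = mi.generate_cohort(config)

print(f"gene matrix:  {genes.shape[0]} genes x {genes.shape[1]} samples")
print(f"miRNA matrix: {mirnas.shape[0]} miRNAs x {mirnas.shape[1]} samples")
print(f"planted regulator: {truth.planted_regulators[0]}")
print(f"immune genes: {len(truth.immune_gene_ids)} in {len(truth.immune_set_ids)} sets")

# empirical vs theoretical planted-pair correlation
x = mirnas.vector(truth.planted_regulators[0])
rs = [mi.pearson(x, genes.vector(g))[0] for g in truth.immune_gene_ids[:100]]
print(f"mean planted-pair Pearson r: {np.mean(rs):.3f} "
      f"(theory: {truth.expected_pairwise_correlation:.3f})")
# The mean sample correlation between the planted miRNA and immune genes
# should sit near gamma*beta/sqrt((gamma^2+sigma^2)(beta^2+sigma^2)) = 0.5.
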