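"""Differential expression, differential peaks, and gene accessibility.

Runs the NB Wald test on gene counts and merged-peak counts, classifies
genes/peaks with the standard thresholds, aggregates peak fold-changes to
gene level (gene body + 750 bp promoter window), and tests whether
differential genes concentrate in switching compartments with a Yates
chi-squared.
"""

import numpy as np

from cabc import SimConfig, simulate_dataset
from cabc import annotation, compartments, differential, pipeline
from cabc.genome_model import GenomicInterval

cfg = SimConfig(seed=1)
b1, b2, truth = simulate_dataset(cfg)
res = pipeline.analyze_pair(b1, b2)

labels = differential.classify_de(res.gene_de)
print("gene classes (|log2FC| > 2, padj <= 0.05):",
      dict(labels.value_counts()))

peak_counts, cond_of = pipeline.peak_count_table(b1.atac_peaks, b2.atac_peaks)
peak_de = differential.nb_differential(peak_counts.round().astype(int), cond_of)
peak_labels = differential.classify_diff_peak(peak_de, lfc=0.5)
print("ATAC differential peaks (|log2FC| >= 0.5):",
      dict(peak_labels.value_counts()))

access = differential.gene_accessibility(
    peak_de, b1.atac_peaks, b1.genes, promoter_upstream=750
)
print("genes with differential accessibility (|avg log2FC| > 0.05):",
      int(access.differential.sum()), "of", len(access))

# 2x2 table: DE status x compartment switching of the gene's locus
gene_ivs = [g.interval for g in b1.genes]
comp = annotation.assign_compartment(
    gene_ivs, res.compartment_calls, [g.gene_id for g in b1.genes]
)
de_of = res.de_labels_fdr_only  # FDR <= 0.05, no fold-change cutoff
switching = comp.switch_class.isin(["A2B", "B2A"]).to_numpy()
is_de = np.array([de_of.get(g, "NDE") != "NDE" for g in comp.feature_id])
table = np.array([
    [(switching & is_de).sum(), (switching & ~is_de).sum()],
    [(~switching & is_de).sum(), (~switching & ~is_de).sum()],
])
resid, p = differential.enrichment_residuals(table)
print("DE x switching table:\n", table)
print(f"Pearson residual (switching, DE): {resid[0, 0]:.2f}, "
      f"chi-squared p = {p:.2e}")
# A positive residual in the (switching, DE) cell would mean differentially
# expressed genes are overrepresented in compartment-switching regions. In
# the default simulation enhancer rewiring is planted independently of
# compartment switching, so the association is expectedly near null here;
# the machinery is what real datasets would exercise.
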