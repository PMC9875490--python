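# cabc — compartment switching and Activity-by-Contact enhancer analysis

`cabc` is a Python library for asking how changes in 3D genome
organization translate into changes in transcription. It links A/B
compartment switching, measured from binned Hi-C contact matrices, to
enhancer-dependent gene regulation, measured by combining ATAC-seq and
H3K27ac ChIP-seq signal with contact frequencies through the
Activity-by-Contact (ABC) model. Its distinctive piece is a
**counterfactual decomposition**: enhancer–promoter links gained or lost
between two conditions are re-derived with Activity taken wholly from one
condition and Contact from the other, attributing the rewiring to
epigenetic change versus interaction change.

It is aimed at regulatory-genomics analysts working with two-condition
designs (perturbation vs control, differentiation time points) who want
the full chain — compartments → differential peaks/genes → enhancer
predictions → Activity/Contact attribution — as composable, tested Python
functions rather than a stack of external tools. A synthetic multi-omics
generator with planted ground truth supports end-to-end validation of
every step.

## The model

**Compartments.** For a contact matrix `O` binned at 50 kb, the
observed/expected matrix divides each entry by the mean contact at its
genomic distance; PC1 — the leading eigenvector of the Pearson correlation
matrix of O/E columns — assigns each bin A (PC1 > 0) or B (PC1 < 0), with
the sign oriented against an open-chromatin track. A bin *switches*
(A→B or B→A) when its mean PC1 changes sign between conditions with
BH-adjusted p < 0.05 from a variance-moderated t test across replicate
PC1 tracks.

**Differential testing.** Gene and merged-peak counts go through a
negative-binomial Wald test (median-of-ratios size factors,
method-of-moments dispersion moderated across features). Genes are DEG at
|log2FC| > 2 and padj ≤ 0.05; peaks are differential at |log2FC| ≥ 2
(H3K27ac) or ≥ 0.5 (ATAC) with padj ≤ 0.05; gene-level accessibility is
the mean log2FC of peaks on the gene body or its 750 bp upstream promoter
window, called beyond ±0.05.

**ABC enhancer prediction.** Candidate 500 bp elements from ATAC summits
plus TSS-centered promoters are scored against each gene `g` within 5 Mb:

    ABC(e, g) = A_e · C_eg / Σ_e' A_e' · C_e'g

with Activity `A` the geometric mean of depth-normalized ATAC and H3K27ac
counts and Contact `C` the normalized Hi-C frequency between element and
promoter bins, floored by a power-law fit `C(d) ∝ d^(−γ)`. Elements with
score ≥ 0.02 are predicted enhancers.

**Decomposition.** Links predicted in only one condition are gained/lost.
Recomputing condition-2 predictions with condition-1 Activity (constant
Activity) or condition-1 Contact (constant Contact) and counting how many
differential links survive gives the retained fraction per driver.

## Worked example

```python
from cabc import SimConfig, simulate_dataset, pipeline, compartments

cfg = SimConfig(seed=1)                  # 20 Mb chromosome, 10% switching,
b1, b2, truth = simulate_dataset(cfg)    # ~2 enhancers/gene, 2 replicates
res = pipeline.analyze_pair(b1, b2)

print(compartments.switching_fraction(res.compartment_calls))
# 0.1
from cabc.abc_model import enhancers_per_gene
print(enhancers_per_gene(res.predictions["c1"])[1]["mean"])
# 2.15
```

The estimated switching fraction (0.100) recovers the planted 10% of bins
flipping compartment, and the mean of ~2.15 predicted enhancers per gene
sits where a well-calibrated ABC run is expected to. The scripts in
`examples/` walk through each capability — simulation and export,
compartment switching, differential/accessibility integration, ABC
prediction, and the Activity/Contact decomposition — printing the numbers
they compute and what they mean.

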