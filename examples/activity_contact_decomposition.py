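"""Attribute enhancer gains/losses to Activity versus Contact changes.

Links predicted in only one condition are gained/lost; recomputing the
predictions with Activity from one condition and Contact (matrix +
power-law fit) from the other shows which component drives the rewiring:
the counterfactual that preserves the differential links identifies the
driver.
"""

from cabc import SimConfig, simulate_dataset
from cabc import decomposition, pipeline

# activity-driven scenario: both conditions share the same contact maps
cfg = SimConfig(seed=1, shared_contacts=True)
b1, b2, truth = simulate_dataset(cfg)
res = pipeline.analyze_pair(b1, b2)

links = res.links
print("DEG-linked link status:",
      dict(links.status.value_counts()))

za = decomposition.zero_activity_fraction(links)
defined = za[za.defined]
if len(defined):
    print("zero-Activity fractions by stratum:")
    for r in defined.itertuples():
        print(f"  {r.switch_class:>10} {r.status:>6}: "
              f"{100 * r.zero_fraction:.0f}% of {r.n}")

out = decomposition.run_decomposition(
    res.predictions["c1"], res.predictions["c2"],
    res.elements, res.genes, res.matrices, res.fits,
    de_labels=res.de_labels_fdr_only, de_only=True,
)
for name, r in out.items():
    print(f"{name}: gained {r.n_gained}, lost {r.n_lost} "
          f"(baseline {r.baseline_gained}/{r.baseline_lost}); "
          f"retained fraction {r.retained_fraction:.2f}")
# With purely activity-driven rewiring, the constant-Contact counterfactual
# retains 100% of differential links and the constant-Activity one retains
# none: the gain/loss of these enhancers is attributable to Activity alone.
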