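"""Open the trained network: which tracts matter, and which interact?

Permutation importance shuffles one tract column at a time in the test set
and records the drop in R2. The hidden weight matrix is inspected for
diagonal dominance (each neuron still 'belongs' to its input tract) and
for convergent neurons, where many tracts feed one hidden unit —
the network's representation of inter-tract interactions.
"""

import tractage as ta

cohort = ta.generate_cohort(ta.GeneratorConfig(n_subjects=217, seed=7))
pipe = ta.train_pipeline(cohort, seed=7, fast=True)

X, y = pipe.test_z()
rep = ta.permutation_importance(pipe.ann, X, y, n_repeats=1000, seed=0)
top = rep.display_values().sort_values(ascending=False).head(5)
print("top-5 permutation importance (R2 drop, negatives clipped for display):")
print(top.round(3).to_string())

dom = ta.diagonal_dominant(pipe.ann)
print(f"\ndiagonally dominant hidden neurons: {int(dom.sum())}/{len(dom)}")

conv = ta.convergent_neurons(pipe.ann, threshold=10)
if len(conv):
    print("\nneurons with >= 10 incoming nonzero weights (interaction hubs):")
    print(conv.to_string(index=False))
else:
    print("\nno neuron collects 10 or more inputs in this fit")
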