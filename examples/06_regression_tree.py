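"""Multivariate regression tree of lineage composition on the environment.

Sites are recursively split on covariate thresholds so that within-leaf
community composition is as homogeneous as possible; tree size is picked
by 10-fold cross-validation with the 1-SE rule.
"""

import phyloecol as pe

tree, lineage, metadata, table = pe.generate_dataset(pe.SynthSpec(seed=1))
fit = pe.mrt_fit(table, metadata, seed=13)
cov, thr = fit.root_split()
print(f"selected size: {fit.size} leaves")
print(f"explained variance (resubstitution): {fit.explained_variance():.3f}")
print(f"root split: {cov} <= {thr:.2f}")
print("\ncross-validation profile:")
print(fit.cv_table.round(3).to_string(index=False))
print("\nleaf compositions (mean lineage fractions, with habitat tallies):")
print(pe.mrt_leaf_summary(fit, metadata).round(3).to_string())
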