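"""Weighted UniFrac distances, PCoA ordination, and PERMANOVA.

Habitat identity and then each environmental covariate are tested against
the UniFrac distance matrix with 1000 label permutations.
"""

import phyloecol as pe

tree, lineage, metadata, table = pe.generate_dataset(pe.SynthSpec(seed=1))

dm = pe.weighted_unifrac(table, tree)          # normalized, in [0, 1]
ordination = pe.pcoa(dm)
print("PCoA axis 1 explains "
      f"{100 * ordination.explained[0]:.1f}% of the (positive-eigenvalue) "
      f"variance, axis 2 {100 * ordination.explained[1]:.1f}%")

hab = metadata.habitat.reindex(list(dm.ids))
res = pe.permanova(dm, hab, n_perm=1000, seed=5)
print("\nhabitat PERMANOVA:")
print(res.table.round(4).to_string())

for cov in ("salinity", "TOC", "temperature"):
    r = pe.permanova(dm, metadata.covariates([cov])[cov], n_perm=1000,
                     seed=5, mode="marginal")
    row = r.table.iloc[0]
    print(f"{cov:12s} R2 = {row['R2']:.3f}  p = {row['p']:.4f}")
print("\nR2 is the fraction of UniFrac variance the factor explains.")
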