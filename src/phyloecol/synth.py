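"""Synthetic clone-library communities with planted ecological structure.

The generator emulates a terrestrial 16S rRNA clone-library compilation:
six habitat classes with unequal numbers of sites (peat 4, soil 2, hot
spring 2, lagoon 13, mangrove 4, estuary 3 - 28 sites in total),
habitat-structured covariates (peat high in TOC, estuaries and lagoons
saline, hot springs hot), OTUs on an ultrametric pure-birth tree whose
major clades define lineages, and log-linear expected abundances with
lineage baselines, lineage x habitat effects and environmental-gradient
responses.  Three kinds of structure can be planted for power/recovery
studies: habitat-exclusive indicator lineages, a covariate threshold that
shifts a lineage's abundance, and comonotone OTU pairs that co-occur.
Counts are multinomial draws at log-uniform library sizes.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .io import OtuTable, SampleMetadata, parse_newick

DEFAULT_SITES = {"peat": 4, "soil": 2, "hot_spring": 2, "lagoon": 13,
                 "mangrove": 4, "estuary": 3}

# habitat -> covariate -> (mean, sd, lower clip)
HABITAT_ENV = {
    "peat":       {"pH": (4.5, 0.5, 2.5), "salinity": (0.3, 0.2, 0.0),
                   "temperature": (10, 3, 0), "TOC": (40, 6, 20),
                   "TN": (1.5, 0.4, 0.1)},
    "soil":       {"pH": (6.5, 0.5, 4.0), "salinity": (0.5, 0.3, 0.0),
                   "temperature": (15, 4, 0), "TOC": (3, 1, 0.2),
                   "TN": (0.3, 0.1, 0.01)},
    "hot_spring": {"pH": (7.5, 1.0, 4.0), "salinity": (1.0, 0.5, 0.0),
                   "temperature": (70, 10, 40), "TOC": (1, 0.5, 0.05),
                   "TN": (0.1, 0.05, 0.005)},
    "lagoon":     {"pH": (8.0, 0.5, 6.0), "salinity": (20, 12, 0.5),
                   "temperature": (20, 5, 0), "TOC": (2, 1, 0.1),
                   "TN": (0.2, 0.1, 0.01)},
    "mangrove":   {"pH": (7.0, 0.5, 5.0), "salinity": (15, 4, 1),
                   "temperature": (25, 3, 10), "TOC": (6, 2, 1),
                   "TN": (0.4, 0.1, 0.05)},
    "estuary":    {"pH": (7.5, 0.4, 6.0), "salinity": (25, 5, 5),
                   "temperature": (18, 4, 0), "TOC": (2, 0.8, 0.1),
                   "TN": (0.2, 0.08, 0.01)},
}


@dataclass
class SynthSpec:
    """Generative parameters for a synthetic community dataset."""

    seed: int = 0
    sites_per_habitat: dict = field(default_factory=lambda: dict(DEFAULT_SITES))
    n_otus: int = 100
    n_lineages: int = 8
    baseline_sd: float = 1.0           # lognormal lineage/OTU baselines
    habitat_effect_sd: float = 1.5     # lineage x habitat log-effects
    gradient_coef_sd: float = 0.5      # lineage responses to z-scored covariates
    gradient_covariates: tuple = ("salinity", "TOC", "temperature")
    overdispersion: float = 0.5        # per site x OTU lognormal noise
    #: (lineage index, habitat, exclusivity in [0,1], in-habitat log-boost)
    planted_indicators: tuple = ((0, "peat", 1.0, 3.0),)
    #: (covariate, threshold, lineage index, log-effect above threshold)
    planted_splits: tuple = (("TOC", 20.0, 1, 2.5),)
    #: (otu index i, otu index j, shared latent strength); the default
    #: strength makes the shared factor dominate the per-cell noise so the
    #: planted dependence is unambiguously strong (pair rank correlations
    #: typically 0.8-0.95 at default depths)
    planted_pairs: tuple = ((40, 41, 4.0), (50, 51, 4.0), (60, 61, 4.0))
    library_size_range: tuple = (50, 500)

    @property
    def habitats(self) -> list[str]:
        return list(self.sites_per_habitat)

    @property
    def n_sites(self) -> int:
        return int(sum(self.sites_per_habitat.values()))

    def child_seed(self, k: int) -> int:
        return int(np.random.SeedSequence([self.seed, k]).generate_state(1)[0]
                   % (2**31))


def generate_tree(spec: SynthSpec):
    """Seeded pure-birth (Yule) tree scaled to unit root-to-tip depth.

    Returns ``(tree, lineage_map)``: an ultrametric skbio tree whose tips
    are "OTU_0001", ..., and a Series mapping each tip to one of
    ``n_lineages`` clade-defined lineage labels ("L1", ...).
    """
    if spec.n_otus < 2:
        raise ValueError("need at least 2 OTUs")
    rng = random.Random(spec.child_seed(1))
    dtree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=spec.n_otus, rng=rng)
    for i, leaf in enumerate(dtree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"OTU_{i:04d}"
    newick = dtree.as_string(schema="newick", suppress_rooting=True)
    tree = parse_newick(newick, on_missing_length="zero")
    # rescale to unit depth
    depth = max(tree.distance(t) for t in tree.tips())
    for node in tree.traverse(include_self=False):
        node.length = (node.length or 0.0) / depth
    # split the tree into n_lineages disjoint clades (repeatedly divide the
    # largest clade into its children)
    clades = list(tree.children)
    while len(clades) < min(spec.n_lineages, spec.n_otus):
        clades.sort(key=lambda c: -c.count(tips=True))
        big = clades.pop(0)
        if big.is_tip():
            clades.append(big)
            break
        clades.extend(big.children)
    lineage = {}
    clades.sort(key=lambda c: min(t.name for t in c.tips(include_self=True)))
    for k, clade in enumerate(clades, start=1):
        for t in clade.tips(include_self=True):
            lineage[t.name] = f"L{k}"
    return tree, pd.Series(lineage, name="lineage").sort_index()


def generate_metadata(spec: SynthSpec) -> SampleMetadata:
    """Habitat-labelled sites with habitat-specific covariate draws."""
    rng = np.random.default_rng(spec.child_seed(2))
    rows = {}
    for habitat, n in spec.sites_per_habitat.items():
        env = HABITAT_ENV.get(habitat)
        for k in range(1, n + 1):
            site = f"{habitat}_{k:02d}"
            row = {"habitat": habitat}
            for cov in ("pH", "salinity", "temperature", "TOC", "TN"):
                if env is None:
                    mu, sd, lo = 7.0, 1.0, 0.0
                else:
                    mu, sd, lo = env[cov]
                row[cov] = float(np.maximum(rng.normal(mu, sd), lo))
            rows[site] = row
    return SampleMetadata(pd.DataFrame(rows).T.astype(
        {c: float for c in ("pH", "salinity", "temperature", "TOC", "TN")}))


def generate_counts(spec: SynthSpec, tree, lineage: pd.Series,
                    metadata: SampleMetadata) -> OtuTable:
    """Multinomial clone counts per site under the log-linear model."""
    otus = sorted(t.name for t in tree.tips())
    if list(lineage.index) != otus:
        raise ValueError("lineage map does not match tree tips")
    rng = np.random.default_rng(spec.child_seed(3))
    n_otus, n_sites = len(otus), len(metadata.sites)
    lineages = sorted(lineage.unique())
    lin_idx = {l: i for i, l in enumerate(lineages)}
    lin_of = np.array([lin_idx[lineage[o]] for o in otus])
    habitats = spec.habitats
    hab_idx = {h: i for i, h in enumerate(habitats)}

    baseline = rng.normal(0.0, spec.baseline_sd, size=n_otus)
    # planted pairs are planted among moderately abundant taxa, else their
    # rank dependence is invisible at clone-library sequencing depth
    for (i, j, strength) in spec.planted_pairs:
        baseline[i % n_otus] = max(baseline[i % n_otus], 1.0)
        baseline[j % n_otus] = max(baseline[j % n_otus], 1.0)
    hab_eff = rng.normal(0.0, spec.habitat_effect_sd,
                         size=(len(lineages), len(habitats)))
    coefs = rng.normal(0.0, spec.gradient_coef_sd,
                       size=(len(lineages), len(spec.gradient_covariates)))
    env = metadata.covariates(spec.gradient_covariates)
    z = (env - env.mean()) / env.std(ddof=0).replace(0, 1)

    for (lin_k, habitat, exclusivity, boost) in spec.planted_indicators:
        hab_eff[lin_k % len(lineages), hab_idx[habitat]] = boost

    log_mu = np.zeros((n_sites, n_otus))
    site_hab = [hab_idx[h] for h in metadata.habitat]
    for s in range(n_sites):
        log_mu[s] = (baseline + hab_eff[lin_of, site_hab[s]]
                     + coefs[lin_of] @ z.iloc[s].to_numpy())
    for (cov, thr, lin_k, effect) in spec.planted_splits:
        above = metadata.table[cov].to_numpy(float) > thr
        log_mu[np.ix_(above, lin_of == (lin_k % len(lineages)))] += effect
    # comonotone latent factor shared within each planted pair
    for (i, j, strength) in spec.planted_pairs:
        latent = rng.normal(0.0, 1.0, size=n_sites)
        log_mu[:, i % n_otus] += strength * latent
        log_mu[:, j % n_otus] += strength * latent
    log_mu += rng.normal(0.0, spec.overdispersion, size=log_mu.shape)

    # hard-zero exclusive indicators outside their habitat
    mask = np.ones((n_sites, n_otus))
    for (lin_k, habitat, exclusivity, boost) in spec.planted_indicators:
        outside = np.array([h != hab_idx[habitat] for h in site_hab])
        cols = lin_of == (lin_k % len(lineages))
        if exclusivity >= 1.0:
            mask[np.ix_(outside, cols)] = 0.0
        else:
            mask[np.ix_(outside, cols)] = 1.0 - exclusivity

    lo, hi = spec.library_size_range
    sizes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_sites))
    sizes = np.round(sizes).astype(int)
    counts = np.zeros((n_sites, n_otus), dtype=int)
    for s in range(n_sites):
        w = np.exp(log_mu[s] - log_mu[s].max()) * mask[s]
        p = w / w.sum()
        counts[s] = rng.multinomial(sizes[s], p)
    table = pd.DataFrame(counts, index=metadata.sites, columns=otus)
    return OtuTable(table, lineage.copy(), identity=None)


def generate_dataset(spec: SynthSpec):
    """Convenience wrapper: ``(tree, lineage, metadata, table)``."""
    tree, lineage = generate_tree(spec)
    metadata = generate_metadata(spec)
    table = generate_counts(spec, tree, lineage, metadata)
    return tree, lineage, metadata, table
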