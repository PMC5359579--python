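# Methods

This note documents the statistical machinery in `phyloecol`: the models,
the conventions chosen where the literature leaves room, the synthetic
data generator's assumptions, and the limits of what the test suite shows.

## Sequence QC and OTU construction

Sequences are kept when their **ungapped** length exceeds 700 bases and
they contain no IUPAC ambiguity codes (anything outside A/C/G/T/gap;
lowercase is upper-cased on read). The length filter counts residues, not
alignment columns, since "length" of a 16S clone means sequence length.
Filtering is idempotent and never fails; removals are reported per reason.

Pairwise distances are uncorrected p-distances: mismatches over compared
columns, where a column is dropped *pairwise* whenever either sequence has
a gap (the conservative convention; a Jukes–Cantor switch exists).
Clustering is furthest-neighbour (complete-linkage) agglomeration via
`scipy.cluster.hierarchy`: at identity threshold *t* two clusters merge
only while their maximum pairwise distance stays ≤ 1 − *t*. Complete
linkage at a larger cutoff can only coarsen the partition, so the 90%
table never has more OTUs than the 97% table on the same data (asserted
as a property test). OTU ids are assigned `OTU_0001…` in order of first
member appearance; an OTU's lineage label is the majority label of its
member sequences.

## Alpha diversity

Shannon–Wiener uses natural logarithms (H′ in nats; the base is an
option). Faith PD sums branch lengths of the minimal subtree connecting a
community's OTUs **including the stem to the root** (the classic
definition); a no-root variant stops at the MRCA. Because clone libraries
range over an order of magnitude in depth, `rarefied_pd` redraws `depth`
clones without replacement from a habitat's pooled clones (default depth:
the smallest habitat total) and reports mean ± sd of PD over 1000
subsamples. At depth = total the subsample is the full set, so the mean
equals plain PD with sd 0 — a useful self-check that the tests exercise.

## Phylogenetic species variability

PSV is computed from the phylogenetic correlation matrix C with
C_ij = (shared root-to-tip branch length of i and j) / (mean of their
root-to-tip depths); for an ultrametric tree this is the Brownian-motion
correlation and the diagonal is exactly 1. For non-ultrametric input the
same formula is used and documented as an approximation. Then
PSV = (n·tr C − ΣC) / (n(n − 1)): 1 on a star phylogeny, → 0 as taxa
become close relatives.

Two standard community nulls bracket the question "are co-occurring taxa
closer relatives than chance?": **null 1** shuffles tip labels across the
whole phylogeny, keeping community membership; **null 2** redraws each
habitat's OTU set uniformly from the full pool, preserving richness. The
one-sided p is (1 + #{null ≤ observed}) / (1 + n_rand) — the +1
correction keeps p strictly positive. Both a per-habitat test and a
pooled test on the across-habitat mean are reported, since either may be
the quantity of interest. Tests verify null 2 against exhaustive k-subset
enumeration on small trees and PSV itself against per-pair path
enumeration.

## Beta diversity

Weighted UniFrac weighs every branch by the absolute difference in the
fraction of each community's clones descending through it; the normalised
variant (default) divides by Σ bᵢ(pᵢᴬ + pᵢᴮ), bounding distances in
[0, 1]. Each clone library is one community; pooling libraries is a
site-grouping decision left to the caller.

PCoA Gower-centres the squared distances and eigendecomposes. Axis
"variance explained" is the eigenvalue share of the **positive**
eigenvalue mass; the negative-eigenvalue mass (non-Euclidean distortion)
is reported separately rather than silently corrected (a Lingoes flag
exists). A Euclidean round-trip test reconstructs pairwise distances to
1e-9.

PERMANOVA uses the distance-based linear-model decomposition: with G the
Gower-centred matrix and H the hat matrix of the design,
SS_model = tr(HGH), pseudo-F = (SS/df) / (SS_res/df_res), and p-values
come from permuting sample identities (the design is fixed; G is
permuted). Categorical factors are dummy-coded; numeric covariates enter
as single-df regressors, which is what lets the same code test habitat
and, say, salinity. With several terms the sums of squares are sequential
(Type-I, column order — recorded in output) or marginal, per flag.
Calibration: under a true null the rejection rate at α = 0.05 lies in
[0.03, 0.07] over 1000 simulations (asserted in the acceptance suite).

## Indicator values

For group g and habitat h: specificity A = (mean relative abundance of g
in h) / (sum of g's habitat means), fidelity B = fraction of h's sites
containing g, IndVal = A·B ∈ [0, 1]. The abundance-based (classic
Dufrêne–Legendre) form is the default; presence-based specificity is a
flag. A group's reported statistic is its maximum over habitats, with
p = (1 + #{permuted max ≥ observed}) / (1 + n_perm) under permutation of
the site → habitat labels (habitat sizes fixed). An `OtuTable` input is
converted to per-site relative abundances; a plain matrix is used as-is
so callers control normalisation.

## Multivariate regression trees

Greedy binary partitioning of the site × group abundance matrix: each
split minimises total within-child squared Euclidean deviation from child
mean vectors, searching all covariates × all midpoints of consecutive
sorted values (an exhaustive-search oracle confirms every split for small
n). Growth is best-first, which yields a nested tree sequence; size is
chosen by 10-fold cross-validated relative error with the 1-SE rule (fold
assignment seeded; per-fold errors scaled by fold count to estimate the
relative error, SE across folds). Both resubstitution and CV error are
reported, since "variance explained" can mean either. Sites missing the
splitting covariate follow the majority child; there are no surrogate
splits. Euclidean geometry on relative abundances is the default response
scale.

## Co-occurrence networks

Spearman ρ (midrank ties, two-sided t-approximation p) is computed
between all OTU pairs after dropping OTUs with ≤ 5 clones in total.
Profiles are **per-site relative abundances** by default: with library
sizes spanning 50–500, raw counts of even independent OTUs co-rank
through sequencing depth alone (empirically mean pairwise ρ ≈ 0.38 in
depth-varying null data), which would manufacture edges out of sampling
effort. A raw-count flag restores the uncorrected behaviour. Edges
require ρ > 0.6 **and** p < 0.01 — positive correlations only by default
(a signed flag exists), and no multiple-testing correction by default (a
BH flag exists), matching common practice for these networks.

Topology indices are computed on the unweighted graph, per connected
component: diameter and average path length for the largest component and
as component-size-weighted means; "number of shortest paths" counts
unordered connected node pairs. Degree is the incident edge count;
closeness is (n_c − 1)/Σd within the component (a reciprocal-farness
variant 1/Σd is also emitted, since published closeness values are not
always normalised the same way); betweenness is the unnormalised
pair-dependency sum.

Louvain is implemented with its two classic phases — local ΔQ-maximising
node moves in seeded-shuffled order, then aggregation of communities into
super-nodes with intra-edges as self-loops — iterated until Q stops
increasing. Q = Σ_c (e_c/m − (d_c/2m)²); the returned Q always equals an
independent evaluation of this formula on the returned partition (and
networkx's implementation, in tests). Module–habitat association uses a
two-sided Fisher exact test on the 2×2 table (OTU in/out of module ×
detected/undetected in the habitat's pooled sites), validated against
hypergeometric enumeration.

## Synthetic communities

The generator emulates a terrestrial clone-library compilation:

* **Design**: 6 habitats with unequal site counts (peat 4, soil 2,
  hot spring 2, lagoon 13, mangrove 4, estuary 3 = 28 sites), library
  sizes log-uniform in [50, 500] clones.
* **Covariates**: habitat-specific normal draws with clipping — peat
  acidic and TOC-rich, estuaries/lagoons saline (lagoons with large
  salinity spread), hot springs hot, soils lean. Units: pH unitless,
  salinity PSU, temperature °C, TOC/TN % dry weight.
* **Phylogeny**: seeded pure-birth (Yule) tree scaled to unit root-to-tip
  depth; the k largest clades (splitting the biggest repeatedly) define k
  lineages, so lineage labels are monophyletic.
* **Abundances**: log-linear — OTU baseline N(0, 1), lineage × habitat
  effects N(0, 1.5), lineage responses N(0, 0.5) to z-scored salinity /
  TOC / temperature, per-cell overdispersion N(0, 0.5); counts are one
  multinomial draw per site.
* **Planted structure**: (i) an indicator lineage with a +3 log-boost in
  its habitat and, at exclusivity 1, hard-zero probability elsewhere —
  the invariant "zero counts outside the habitat in every realisation"
  holds by construction; (ii) a covariate threshold effect (+2.5 on a
  lineage where TOC exceeds a cut); (iii) co-occurring OTU pairs sharing
  a per-site latent factor with weight 4.0, chosen so the shared factor
  dominates the noise and the planted rank dependence is unambiguously
  strong (pair ρ typically 0.8–0.95); pair members get a baseline floor
  so they are abundant enough for rank correlation to be observable at
  clone-library depth.

What the generator does **not** emulate: sequencing/alignment error (the
clustering code is tested on hand-made alignments instead), chimeras,
compositional correlation structure beyond the multinomial, spatial or
temporal autocorrelation among sites, and phylogenetic signal in the
habitat effects themselves. Passing recovery tests therefore show the
estimators detect the stated structure at realistic sample sizes — not
that real compilations are this clean.

The MRT recovery experiment runs in a single-habitat design (28 lagoon
sites, habitat and gradient effects off, one planted TOC threshold inside
the habitat's TOC range). In the 6-habitat design the planted TOC cut
separates exactly the peat sites — which pH separates identically — so
the split is a perfect SS tie resolved only by covariate order; a
"single planted effect" is well-defined only without that confound.

## Numerical conventions

* Permutation p-values always use the +1 correction.
* Agglomeration and split ties resolve deterministically (scipy's
  ordering; first covariate / lowest threshold for MRT).
* All randomness flows through `numpy.random.Generator`s seeded from a
  single seed via `SeedSequence`; the pipeline derives one child seed per
  stage so single stages re-run identically.
* Outputs are written with `%.10g` floats; two runs with identical config
  and seed are byte-identical (tested).

## Problem sizes in the test suite

Oracle checks run on 8–10-tip trees (20 random replicates each);
calibration uses 1000 PERMANOVA null simulations at n = 12 with 199
permutations, 200 IndVal null datasets, and 3 × 40-OTU independent-null
networks at 28 sites; recovery uses 40 seeds (MRT) and 20 replicate
datasets (network sensitivity). These sizes were chosen to make the
Monte-Carlo tolerances in the assertions meaningful while keeping the
default `pytest` run around a minute.

## Known limitations

* PSV's correlation matrix is exact only for ultrametric trees.
* PERMANOVA permutes raw identities (no residual permutation schemes);
  with strongly unbalanced groups pseudo-F can be conservative.
* The MRT CV standard error is a simple across-fold estimate; very small
  n makes the 1-SE rule coarse.
* Louvain is a greedy heuristic: Q is a local optimum and the partition
  can vary with the seed on weakly modular graphs (the returned Q is
  always the exact modularity of the returned partition).
* Closeness values are not comparable across publications without
  knowing which normalisation was used; both variants are emitted.
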