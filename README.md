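# quartetcoal

Species-tree inference for four closely related species under incomplete
lineage sorting (ILS) and post-divergence gene flow, built around the
multispecies coalescent (MSC).  The package targets the situation of the
black-and-white flycatcher complex — collared (C), pied (P), Atlas (A) and
semicollared (S) flycatchers plus two outgroups — where gene-tree
topologies change on a small physical scale and the most frequent gene
tree need not match the species tree.

It is aimed at population/phylogenomics researchers who want to exercise,
compare, or teach the full battery of coalescent-based species-tree
approaches on fully synthetic data with known truth, or to run the
statistics on their own phased data.

## What it does

* **`simulate`** — structured-coalescent synthetic studies (msprime-backed)
  under a 4-species isolation-with-migration demography: per-branch diploid
  `Ne`, split times, directional migration `Nm` (migrants/generation),
  infinite-sites mutation at `mu = 2.5e-9` /site/generation; emits
  genealogies (newick), alignments (FASTA) and polarized variant tables.
* **`treestats`** — windowed gene-tree discordance: canonical keys for the
  15 rooted / 3 unrooted quartet topologies, 200-round leaf subsampling
  into topology spectra, the genealogical sorting index

  `gsi = (gs − min gs)/(1 − min gs)`, `gs = (n−1)/Σ_u(d_u−2)`,

  the topology diversity index `tdi = (1 − Σ p_i²)/(1 − Σ (1/I)²)`,
  relative depth of the ingroup common ancestor, 500-kb aggregation, and
  genome-partition topology rankings.
* **`mscmodel`** — ranked-history analytics (18 ranked histories; star-tree
  topology probabilities 1/18 and 2/18) and a pseudo-likelihood
  species-tree estimator from rooted-triple counts, with
  triple concordance `P = 1 − (2/3)e^{−t}`, plus the loci-resubsampling
  consistency experiment.
* **`popgen`** — two-outgroup parsimony polarization, the published site
  filters with an audit trail, the 15-cell shared-derived-allele
  partition, `pi`/Watterson's `theta`, and pairwise `S`, shared/fixed
  polymorphism, `dXY` and AMOVA `PhiST`, assembled into the 60-statistic
  summary vector (mean + variance of 5 statistics x 6 species pairs).
* **`sfsfit`** — six pairwise 2D site-frequency spectra (hypergeometric
  projection, monomorphic cells included), simulation-based expected
  spectra, composite likelihood, multistart derivative-free fitting of the
  four candidate topologies, `ΔAIC`/Akaike weights, and block-resampling
  confidence intervals.
* **`abcsel`** — ABC model choice (rejection + multinomial logistic
  regression on the 60 statistics), PLS reduction, local-linear
  regression-adjusted posteriors with 90% HPD intervals, and
  cross-validation.
* **`pipeline` / CLI** — end-to-end replay on synthetic data with a
  checksummed manifest: `quartetcoal simulate|treestats|mscfit|sfsfit|abc|replay`.

## Worked example

```python
from quartetcoal import flycatcher_demography, SampleDesign
from quartetcoal import simulate, mscmodel
from quartetcoal.treestats import canonical_key

dem = flycatcher_demography("PA_C_S", "mle")   # (((P,A),C),S) point estimates
design = SampleDesign(haplotypes_per_species=2, n_loci=300,
                      locus_length=1000, include_outgroups=True, seed=1)
quartets = [mscmodel.reduce_to_quartet(
                simulate.simulate_genealogy(dem, design, i), seed=i)
            for i in range(300)]
fit = mscmodel.fit_species_tree(quartets)
print(fit.topology, tuple(round(x, 3) for x in fit.branch_lengths))
```

prints

```
(((A,P),C),S) (0.045, 0.04)
```

the recovered species-tree topology (pied–Atlas cherry, collared next,
semicollared outermost) and its two internal branch lengths in coalescent
units — short branches, i.e. heavy ILS, as expected under the generating
demography.  The analytic star-tree reference for how often a single
gene-tree topology would appear with *zero* internal branches:

```python
from quartetcoal.mscmodel import star_tree_topology_probs
p = star_tree_topology_probs()
print(round(100 * p["(((A,P),C),S)"], 2), round(100 * p["((A,P),(C,S))"], 2))
# 5.56 11.11   (% per asymmetric and per symmetric topology)
```

## Layout

```
src/quartetcoal/   demography, simulate, treestats, mscmodel, popgen,
                   sfsfit, abcsel, io, pipeline, cli
tests/             pytest suite (unit, property and acceptance tests)
docs/methods.md    models, assumptions, parameter choices, limitations
```
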