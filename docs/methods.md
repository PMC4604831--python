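# Models and methods

## The demographic model

The core object is a rooted four-species isolation-with-migration (IM)
demography over the flycatcher complex (collared C, pied P, Atlas A,
semicollared S).  Parameters, in the schema used throughout
(`quartetcoal.demography.PARAM_NAMES`):

| parameter | meaning | unit | bundled default (prior) |
|---|---|---|---|
| `N_C..N_S` | current diploid effective sizes | individuals | log-uniform 3e4–1e6 |
| `N_ANC1`, `N_ANC2` | ancestral sizes of the two inner branches | individuals | log-uniform 1e5–3e6 |
| `N_ROOT` | root population size | individuals | log-uniform 3e4–1e6 |
| `T1 < T2 < T3` | split times (cherry, inner, root) | years | uniform, nested ranges |
| `Nm_XY` | migrants per generation into X from Y, pairs C↔P, P↔A, C↔S | migrants/gen | log-uniform 1e-3–10 |
| `mu` | mutation rate | /site/gen | 2.5e-9 |
| `gen_time` | years per generation | yr | 2.0 |

All internal computation is in generations; years appear only on
input/output through `gen_time`.  No published generation time exists for
this system, so it is an explicit, user-settable parameter; the package
default of 2 yr/gen follows common usage for small passerines.  Migration
is implemented backward in time as a per-lineage rate
`m = Nm / (2 Ne_recipient)` between extant species only; it ceases at the
pair's divergence (msprime deactivates migration at population splits).
Split-time ordering, positive sizes and non-negative rates are validated
at construction.

Two preset parameterizations are bundled: the composite-likelihood point
estimates (`values="mle"`) and the likelihood-free posterior modes
(`values="abc_mode"`); prior midpoints serve as the neutral fixture
demography.  Four candidate topologies are first-class:
`(((P,A),C),S)`, `((P,A),(C,S))`, `(((C,P),A),S)`, `(((P,A),S),C)`.

Outgroups: two synthetic outgroup lineages ("O1", "O2") join the ingroup
stem at 2.5 and 3.5 million generations (~5 and ~7 My) with Ne 5e5.  These
values are package defaults chosen so that residual ingroup lineages have
almost always coalesced below the joins; they are *not* published
estimates.

## Simulation

Genealogies come from msprime's structured coalescent; each locus is an
independent single genealogy (loci are unlinked; within-locus
recombination is not modeled, matching designs that space loci ≥50 kb
apart).  Mutations are dropped by the package itself: Poisson
(`mu · L · total branch length`) mutations, each placed on a branch with
probability proportional to its length and at a distinct integer position
(infinite sites on a finite sequence; collisions avoided by sampling
positions without replacement).  Derived carriers are exactly the leaves
below the mutated branch, so every variant is a biallelic clade marker.
A single master seed determines everything; per-locus streams are derived
deterministically, making emitted studies bit-identical across runs.

What the generator deliberately omits: sequencing error, genotype-calling
noise, within-locus recombination, selection, and base-composition
effects.  Passing tests therefore demonstrate correctness of the
*inference machinery under the model*, not robustness to real-data
artifacts (optional random genotype masking emulates callability gaps
only).

A consequence worth knowing: with truly coalescent outgroups, an ingroup
lineage occasionally persists above the first outgroup join, so a
mutation there leaves *both* outgroups monomorphic for the derived allele
and the parsimony rule mispolarizes the site.  With the default joins
this affects well under 2% of determined ingroup SNPs; the test suite
checks both the rate and the mechanism.

## Discordance statistics

Windowed statistics use 0-based half-open intervals.  Subsampling draws
one leaf per species (outgroups included), roots on the deepest outgroup
(mean path length to the ingroup; ties broken lexicographically; with no
outgroups the tree is taken as rooted), drops the outgroups and records
the canonical rooted key.  Canonical keys sort children lexicographically
(`(((A,P),C),S)` style), which makes them invariant to branch lengths,
rotation and within-species relabeling.  Polytomies flag a round as
unresolved rather than being resolved arbitrarily.

* `tdi = (1 − Σ p_i²) / (1 − Σ (1/I)²)` with `I = 15` rooted quartet
  classes: 0 for a single topology, 1 for all classes equifrequent.
  500-kb aggregation averages member-window *frequencies* and recomputes
  the tdi on the average (not an average of member tdi values).
* `gsi` follows the genealogical-sorting formulation:
  `gs = (n−1)/Σ_u (d_u − 2)` over the internal nodes of the minimal
  subtree uniting the focal leaves from their MRCA (`d_u` = degree);
  normalized by `max gs = 1` and the minimum obtained when the uniting
  subtree spans every internal node.  1 iff the species is monophyletic.
* Genome rankings report the 15-key frequency table per genomic partition
  plus cherry-pairing classes: a topology contributes to each species
  pair forming a cherry (symmetric topologies count under two pairs) and
  polytomy-flagged rounds fall into an `unresolved` class.

## Pseudo-likelihood species tree

For each of the 15 candidate rooted quartets, the two internal branch
lengths (coalescent units) maximize the product of multinomial
likelihoods of the four rooted-triple count vectors with concordance
probability `1 − (2/3)e^{−t}`, where a triple's `t` is the sum of the
candidate's internal branches separating the pair from the third taxon
(for a caterpillar one triple spans both branches, so the optimization is
coordinate-wise bounded 1-D search iterated to convergence rather than a
single decoupled pass).  Score ties within 1e-9 are reported as a tie
set, never broken silently.  The estimator deliberately ignores gene
flow — that is the point of comparing it against the IM-model-based
routes: under the bundled point-estimate demography with `Nm_SC ≈ 0.5`,
gene-tree frequencies favor a wrong topology when the truth places C
outermost, and the estimator inherits that bias.

## SFS composite likelihood

Observed data are six pairwise 2D-SFS of derived-allele counts projected
to a fixed chromosome count by hypergeometric expectation, with the
monomorphic (0,0) cell filled from the total scanned sites.  Expected
per-site configuration probabilities for a candidate demography are
estimated from simulated genealogies: the branch length subtending
exactly (i, j) tips of the pair, relative to total length, averaged over
genealogies (per-genealogy ratio by default; ratio-of-sums via
`ratio_of_means=True`, which is the unbiased choice when comparing to
closed forms), scaled by `mu · E[T_total]`, remainder to (0,0).  When
outgroup-aware polarization is modeled, branches subtending both
outgroups flip their configuration (mispolarization) and
single-outgroup branches are dropped (undetermined sites).  All six
pairs are read off one set of four-species genealogies per evaluation.

Fitting is a multistart derivative-free search under common random
numbers: a method-of-moments warm start (current sizes from per-species diversity `Ne = pi/4mu`; split
times from pairwise `dXY`; ancestral sizes at the mean current size;
migration at 0.05), then bounded 1-D golden-section polish over a
configurable parameter block.  Each proposed move must improve an
independently seeded, higher-precision validation score before it is
accepted — this "validated acceptance" stops the search from optimizing
into the Monte-Carlo noise of a fixed simulation seed.  Runs end when the
relative improvement falls below 0.001 (configurable) or the sweep budget
is exhausted; every model is finally re-scored under one shared seed so
AIC comparisons are fair.  Two numerical guards matter: expectation cells
are floored at 1e-12 before logs, and the plug-in estimate
`Σ c·ln p̂` is biased downward by O(1/n_sims), so final scoring uses
substantially more genealogies than the search.

Desk-scale defaults (6-chromosome projection, 2e5 sites, hundreds of
genealogies per evaluation) keep a four-model comparison near half a
minute.  At that scale the comparison is decisive for well-separated
demographies; for the bundled point-estimate demographies the genuine
per-site separation between the best models is of order 1e-4 nats/site
(the published ΔAIC values divided by ~1e7 sites), which no desk-scale
simulation budget can resolve reliably — the acceptance suite records
this honestly rather than claiming otherwise.

## ABC

Model choice follows rejection plus weighted multinomial logistic
regression on the 60 summary statistics (mean and variance over loci of
segregating sites, shared and fixed polymorphism proportions, `dXY`,
`PhiST`, for the six pairs; label order is fixed and documented in
`popgen.summary_labels`).  Distances use median-absolute-deviation
standardization (robust to heavy-tailed statistics; an explicit package
choice).  Parameter estimation reduces statistics to partial-least-squares
components (default 10, with a held-out RMSE curve reported per added
component), rejects in component space and applies a Beaumont-style
weighted local-linear adjustment with Epanechnikov weights — used here as
the regression-adjustment engine for the general-linear-model
post-sampling step.  Posterior modes come from a weighted KDE; 90% HPD
intervals from the density grid, clipped to the prior support.
Cross-validation is leave-one-out within the reference tables.
Shared/fixed proportions are normalized by the pooled number of
segregating sites.

## Problem sizes

The shipped tests run everything at reduced scale as a deliberate design
choice: 50,000 genealogies for star-tree calibration; 800–2,000 loci for
Watterson and triple-concordance checks; 1,000 loci × 20 replicates for
pseudo-likelihood recovery; 2e5 sites, 6-chromosome projection and ~1.5e4
genealogies per model fit for the SFS comparison; reference tables of 150
rows/model at 160 loci × 2 kb × 8 haplotypes for ABC.  The published
analyses behind the presets used ~1e7 SFS sites, 2e6 ABC simulations per
model and 2,962 loci; all sizes here are configurable back up to that
scale.  Recovery experiments draw their observed spectra multinomially
from a high-precision expectation under the truth — the unlinked-sites
limit of window subsampling — while `build_sfs` on emitted studies is
oracle-checked separately.

## Known limitations

* The SFS expected-spectrum engine is simulation-based; its O(1/n_sims)
  likelihood bias and Monte-Carlo noise bound the resolvable model
  separation (see above).  A deterministic diffusion/moments engine would
  remove this but is out of scope.
* The pseudo-likelihood route is intentionally blind to gene flow.
* PLS components are fit to log-scaled parameters; parameters spanning
  zero would need a different transform.
* ABC model choice at desk-scale reference-table sizes has limited power;
  the cross-validation tooling quantifies exactly how much.
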