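"""Analytic multispecies-coalescent expectations and pseudo-likelihood
species-tree estimation for four taxa.

Under a star species tree (both internal branches of length zero) the four
sampled lineages coalesce in a single exchangeable population, so every
ranked labeled coalescent history is equally likely.  There are 18 such
histories; each asymmetric (caterpillar) rooted topology corresponds to
exactly one history (probability 1/18 ~ 5.6%) and each symmetric (balanced)
topology to two (2/18 ~ 11.1%).

The species-tree estimator maximizes, over the 15 candidate rooted
topologies and their two internal branch lengths (coalescent units), the
product of multinomial likelihoods of the four rooted-triple counts, with
triple concordance probability ``1 - (2/3) exp(-t)``.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .treestats import canonical_key_nested, enumerate_topologies, nested_clades
from .trees import GeneTree
from . import treestats

__all__ = [
    "ranked_histories", "star_tree_topology_probs", "triple_prob",
    "count_triples", "triples_of_key", "SpeciesTreeFit", "fit_species_tree",
    "resubsample_consistency",
]

TIE_TOL = 1e-9


# ---------------------------------------------------------------------------
# Ranked histories and star-tree probabilities
# ---------------------------------------------------------------------------

def ranked_histories(species=("C", "P", "A", "S")):
    """All ranked labeled coalescent histories of one lineage per species.

    A history is the ordered sequence of coalescing pairs; each maps to a
    rooted topology.  Returns ``[(history, topology_key), ...]`` with 18
    entries for 4 species.
    """
    out = []

    def recurse(lineages, history):
        if len(lineages) == 1:
            nested = lineages[0]
            out.append((tuple(history), canonical_key_nested(nested)))
            return
        for i, j in itertools.combinations(range(len(lineages)), 2):
            merged = (lineages[i], lineages[j])
            rest = [l for k, l in enumerate(lineages) if k not in (i, j)]
            recurse(rest + [merged], history + [merged])

    recurse(sorted(species), [])
    return out


def star_tree_topology_probs(species=("C", "P", "A", "S")) -> dict:
    """Rooted-topology probabilities under a star species tree.

    Uniform over ranked histories: asymmetric keys get 1/18, symmetric keys
    2/18.  Sums to 1 over the 15 keys.
    """
    hists = ranked_histories(species)
    probs: dict = {}
    for _, key in hists:
        probs[key] = probs.get(key, 0.0) + 1.0 / len(hists)
    return probs


# ---------------------------------------------------------------------------
# Rooted-triple machinery
# ---------------------------------------------------------------------------

def triple_prob(t: float):
    """(concordant, discordant, discordant) probabilities for a rooted
    triple whose species-tree internal branch is ``t`` coalescent units."""
    if t < 0:
        raise ValueError("internal branch length must be >= 0")
    e = math.exp(-t)
    return (1.0 - 2.0 * e / 3.0, e / 3.0, e / 3.0)


def _nested_from_key(key: str):
    """Parse a canonical rooted key back into a nested tuple."""
    pos = 0

    def parse():
        nonlocal pos
        if key[pos] == "(":
            pos += 1
            left = parse()
            assert key[pos] == ","
            pos += 1
            right = parse()
            assert key[pos] == ")"
            pos += 1
            return (left, right)
        start = pos
        while pos < len(key) and key[pos] not in ",()":
            pos += 1
        return key[start:pos]

    return parse()


def triples_of_key(key: str):
    """Triple structure of a candidate rooted 4-taxon topology.

    For each species triple: the concordant (first-coalescing) pair and the
    indices of the candidate's internal branches whose lengths sum to the
    triple's internal branch.  Branch 0 sits above the smaller/first
    internal clade, branch 1 above the second.
    """
    nested = _nested_from_key(key)
    clades = [c for c in nested_clades(nested) if len(c) < 4]
    clades = sorted(clades, key=lambda c: (len(c), sorted(c)))
    species = sorted({s for c in nested_clades(nested) if len(c) == 4 for s in c})
    out = {}
    for triple in itertools.combinations(species, 3):
        tset = set(triple)
        # concordant pair: pair contained in a clade excluding the third
        pair = None
        for c in clades:
            inter = tset & c
            if len(inter) == 2:
                pair = frozenset(inter)
                break
        assert pair is not None
        # smallest clade containing the pair, and containing the triple
        containing_pair = [c for c in clades if pair <= c]
        cp = min(containing_pair, key=len)
        ct_candidates = [c for c in clades if tset <= c]
        ct = min(ct_candidates, key=len) if ct_candidates else frozenset(species)
        # branches on the path: clades c with cp <= c and c strictly inside ct
        branch_idx = [i for i, c in enumerate(clades) if cp <= c and not ct <= c]
        out[frozenset(triple)] = (pair, tuple(branch_idx))
    return out, clades


def reduce_to_quartet(gt: GeneTree, species=("C", "P", "A", "S"),
                      outgroups=("O1", "O2"), seed: int = 0) -> GeneTree:
    """One-leaf-per-species rooted quartet from a multi-leaf gene tree.

    Picks a uniform leaf per ingroup species, roots on the deepest
    available outgroup leaf, then drops the outgroups.
    """
    from . import treestats
    by_sp = gt.leaves_by_species()
    rng = np.random.default_rng(seed)
    chosen = [by_sp[sp][rng.integers(len(by_sp[sp]))]
              for sp in species if sp in by_sp]
    og = [by_sp[o][0] for o in outgroups if o in by_sp]
    sub = gt.restrict(chosen + og)
    if og:
        deepest = treestats._deepest_outgroup(sub, og)
        sub = sub.rerooted_at_leaf(deepest).drop_species(set(outgroups))
    return sub


def count_triples(gene_trees) -> dict:
    """Rooted-triple counts from one-leaf-per-species rooted gene trees.

    Returns ``{triple(frozenset): {pair(frozenset): count}}``; unresolved
    (polytomous) triples are skipped.
    """
    counts: dict = {}
    for gt in gene_trees:
        if isinstance(gt, GeneTree):
            nested = treestats.nested_from_genetree(gt)
        else:
            nested = gt
        clades = [c for c in nested_clades(nested) if len(c) < 4]
        species = sorted({s for c in nested_clades(nested) for s in c})
        for triple in itertools.combinations(species, 3):
            tset = set(triple)
            pair = None
            for c in clades:
                inter = tset & c
                if len(inter) == 2:
                    pair = frozenset(inter)
                    break
            if pair is None:
                continue
            tkey = frozenset(triple)
            counts.setdefault(tkey, {})
            counts[tkey][pair] = counts[tkey].get(pair, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Pseudo-likelihood species-tree fit
# ---------------------------------------------------------------------------

@dataclass
class SpeciesTreeFit:
    """Result of the pseudo-likelihood species-tree fit."""

    topology: str
    branch_lengths: tuple
    log_pseudolikelihood: float
    candidate_scores: dict
    candidate_branches: dict
    ties: tuple = ()

    @property
    def is_tie(self) -> bool:
        return len(self.ties) > 1


def _candidate_loglik(counts, structure, x):
    """Multinomial log-likelihood of triple counts for branch lengths x."""
    ll = 0.0
    for triple, (conc_pair, branch_idx) in structure.items():
        obs = counts.get(triple, {})
        if not obs:
            continue
        t = sum(x[i] for i in branch_idx)
        p_conc, p_disc, _ = triple_prob(t)
        for pair, c in obs.items():
            ll += c * math.log(p_conc if pair == conc_pair else p_disc)
    return ll


def _fit_candidate(counts, structure, max_t=30.0, tol=1e-6, max_iter=200):
    """Maximize the candidate's pseudo-likelihood over its two internal
    branch lengths by iterated bounded 1-D optimization per branch."""
    x = [0.5, 0.5]
    prev = _candidate_loglik(counts, structure, x)
    for _ in range(max_iter):
        for i in (0, 1):
            res = minimize_scalar(
                lambda v: -_candidate_loglik(
                    counts, structure, [v if j == i else x[j] for j in (0, 1)]),
                bounds=(0.0, max_t), method="bounded",
                options={"xatol": tol})
            x[i] = float(res.x)
        cur = _candidate_loglik(counts, structure, x)
        if cur - prev < tol:
            break
        prev = cur
    # snap near-zero branches
    x = [0.0 if v < 1e-5 else v for v in x]
    return tuple(x), _candidate_loglik(counts, structure, x)


def fit_species_tree(gene_trees_or_counts, species=None) -> SpeciesTreeFit:
    """Pseudo-likelihood species-tree estimate from gene trees or a
    rooted-triple count table.

    For each of the 15 candidate rooted topologies the two internal branch
    lengths (coalescent units) maximizing the product of multinomial triple
    likelihoods are found; the best-scoring candidate is returned.
    Candidates within ``1e-9`` of the best score are reported as a tie set,
    never silently broken.
    """
    if isinstance(gene_trees_or_counts, dict):
        counts = gene_trees_or_counts
    else:
        counts = count_triples(gene_trees_or_counts)
    if not counts or all(not v for v in counts.values()):
        raise ValueError("no resolved triples in input")
    if species is None:
        species = sorted({s for t in counts for s in t})
    scores = {}
    branches = {}
    for key in enumerate_topologies(species, rooted=True):
        structure, _ = triples_of_key(key)
        x, ll = _fit_candidate(counts, structure)
        scores[key] = ll
        branches[key] = x
    best_key = max(scores, key=scores.get)
    best = scores[best_key]
    ties = tuple(sorted(k for k, v in scores.items() if best - v < TIE_TOL))
    return SpeciesTreeFit(
        topology=best_key, branch_lengths=branches[best_key],
        log_pseudolikelihood=best, candidate_scores=scores,
        candidate_branches=branches, ties=ties)


def resubsample_consistency(gene_trees, loci_grid, n_reps: int = 100,
                            seed: int = 0, species=None):
    """Fraction of loci-resubsampled fits matching the full-data topology.

    Gene trees are re-subsampled without replacement ``n_reps`` times at
    each grid size; grid values exceeding the available loci are skipped
    with a warning.  Returns ``{n_loci: proportion}``.
    """
    trees = list(gene_trees)
    # precompute per-tree triple outcomes once; a subsample is a row sum
    per_tree = []
    for gt in trees:
        per_tree.append(count_triples([gt]))
    full = fit_species_tree(_merge_counts(per_tree), species=species)
    rng = np.random.default_rng(seed)
    out = {}
    for m in loci_grid:
        if m > len(trees):
            warnings.warn(f"grid value {m} exceeds available loci ({len(trees)}); skipped")
            continue
        if m == len(trees):
            out[m] = 1.0
            continue
        hits = 0
        for _ in range(n_reps):
            idx = rng.choice(len(trees), size=m, replace=False)
            fit = fit_species_tree(_merge_counts([per_tree[i] for i in idx]),
                                   species=species)
            hits += fit.topology == full.topology
        out[m] = hits / n_reps
    return out


def _merge_counts(count_dicts):
    merged: dict = {}
    for c in count_dicts:
        for triple, pairs in c.items():
            merged.setdefault(triple, {})
            for pair, n in pairs.items():
                merged[triple][pair] = merged[triple].get(pair, 0) + n
    return merged
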