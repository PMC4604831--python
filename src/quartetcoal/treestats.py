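"""Windowed gene-tree discordance statistics.

Implements canonical topology classification for 3-6 species, leaf
subsampling into topology spectra, the genealogical sorting index (gsi),
the topology diversity index (tdi), relative depth of the ingroup common
ancestor, stepping-window aggregation and genome-wide topology rankings.

Conventions: genomic intervals are 0-based half-open; rooted topology keys
are canonical nested strings such as ``(((A,P),C),S)`` (children sorted
lexicographically); unrooted keys are canonical split strings such as
``A,P|C,S``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .trees import (GeneTree, IncompleteSubsampleError, PolytomyError,
                    RootingError)

__all__ = [
    "enumerate_topologies", "canonical_key", "nested_from_genetree",
    "canonical_key_nested", "unrooted_key_nested", "TopologySpectrum",
    "subsample_spectrum", "tdi", "gsi", "lca_relative_depth",
    "WindowStats", "window_scan", "aggregate_spectra",
    "genome_topology_ranking", "cherry_pairs",
]

UNRESOLVED = "unresolved"


# ---------------------------------------------------------------------------
# Canonical topology keys
# ---------------------------------------------------------------------------

def _canon(node) -> str:
    if isinstance(node, str):
        return node
    parts = sorted(_canon(c) for c in node)
    return "(" + ",".join(parts) + ")"


def canonical_key_nested(node) -> str:
    """Canonical rooted key of a nested-tuple topology."""
    return _canon(node)


def _nested_leaves(node):
    if isinstance(node, str):
        return {node}
    out = set()
    for c in node:
        out |= _nested_leaves(c)
    return out


def _nested_clades(node, acc):
    if isinstance(node, str):
        return {node}
    leaves = set()
    for c in node:
        leaves |= _nested_clades(c, acc)
    acc.append(frozenset(leaves))
    return leaves


def nested_clades(node):
    """All internal clades (frozensets of leaf labels), root included."""
    acc = []
    _nested_clades(node, acc)
    return acc


def unrooted_key_nested(node) -> str:
    """Canonical unrooted key: sorted non-trivial splits, ``side|side``."""
    leaves = frozenset(_nested_leaves(node))
    n = len(leaves)
    if n == 3:          # a single unrooted 3-leaf topology exists
        return ",".join(sorted(leaves))
    splits = set()
    for clade in nested_clades(node):
        for side in (clade, leaves - clade):
            if 2 <= len(side) <= n - 2:
                other = leaves - side
                a, b = sorted([",".join(sorted(side)), ",".join(sorted(other))])
                splits.add(f"{a}|{b}")
    if not splits:
        raise ValueError("tree has no non-trivial split")
    return ";".join(sorted(splits))


def _all_rooted_shapes(labels):
    labels = tuple(labels)
    if len(labels) == 1:
        yield labels[0]
        return
    first, rest = labels[0], labels[1:]
    # unordered bipartitions: the side containing `first`
    for r in range(len(rest) + 1):
        for extra in itertools.combinations(rest, r):
            left = (first,) + extra
            right = tuple(x for x in rest if x not in extra)
            if not right:
                continue
            for lt in _all_rooted_shapes(left):
                for rt in _all_rooted_shapes(right):
                    yield (lt, rt)


def enumerate_topologies(species, rooted: bool = True):
    """All distinct leaf-labeled binary topology keys, deterministically ordered.

    ``species`` is a label collection (3-6 species) or an integer count (in
    which case labels ``T1..Tn`` are used).  Rooted count is ``(2n-3)!!``,
    unrooted ``(2n-5)!!``.
    """
    if isinstance(species, int):
        labels = tuple(f"T{i+1}" for i in range(species))
    else:
        labels = tuple(species)
    n = len(labels)
    if not 3 <= n <= 6:
        raise ValueError(f"supported species counts are 3..6, got {n}")
    if rooted:
        keys = {canonical_key_nested(t) for t in _all_rooted_shapes(sorted(labels))}
    else:
        keys = {unrooted_key_nested(t) for t in _all_rooted_shapes(sorted(labels))}
    return sorted(keys)


def nested_from_genetree(gt: GeneTree, use_species: bool = True):
    """Nested-tuple topology of a GeneTree, leaves renamed to species."""
    def build(node):
        if node.is_leaf():
            lbl = node.taxon.label
            return gt.species_map[lbl] if use_species else lbl
        children = node.child_nodes()
        if len(children) != 2:
            raise PolytomyError(
                f"non-binary node with {len(children)} children")
        return (build(children[0]), build(children[1]))
    return build(gt.tree.seed_node)


def canonical_key(gt: GeneTree, rooted: bool = True) -> str:
    """Canonical topology key of a one-leaf-per-species gene tree.

    Invariant to branch lengths, child order and leaf relabeling within a
    species.  Raises :class:`PolytomyError` on multifurcations and
    :class:`IncompleteSubsampleError` if any species has != 1 leaf.
    """
    by_sp = gt.leaves_by_species()
    for sp, leaves in by_sp.items():
        if len(leaves) != 1:
            raise IncompleteSubsampleError(
                f"species {sp!r} has {len(leaves)} leaves (need exactly 1)")
    nested = nested_from_genetree(gt)
    return canonical_key_nested(nested) if rooted else unrooted_key_nested(nested)


def cherry_pairs(key: str):
    """Species pairs forming a cherry in a canonical rooted key."""
    import re
    return [frozenset(m.groups())
            for m in re.finditer(r"\(([A-Za-z0-9]+),([A-Za-z0-9]+)\)", key)]


# ---------------------------------------------------------------------------
# Topology spectra
# ---------------------------------------------------------------------------

@dataclass
class TopologySpectrum:
    """Topology frequencies for one genomic window.

    ``counts`` maps canonical keys to subsampling-round counts;
    ``unresolved`` counts rounds that hit a polytomy.  Frequencies are
    normalized over resolved rounds.
    """

    interval: tuple | None
    counts: dict
    n_rounds: int
    unresolved: int = 0

    @property
    def frequencies(self) -> dict:
        tot = sum(self.counts.values())
        if tot == 0:
            return {}
        return {k: v / tot for k, v in self.counts.items()}


def _deepest_outgroup(gt: GeneTree, outgroup_labels):
    """Outgroup leaf to root on: farthest (mean path length) from the
    ingroup leaves; falls back to the last-listed outgroup without branch
    lengths.  Ties broken lexicographically."""
    if len(outgroup_labels) == 1:
        return outgroup_labels[0]
    if not gt.has_branch_lengths():
        return outgroup_labels[-1]
    pdm = gt.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in gt.tree.taxon_namespace}
    ingroup = [l for l in gt.leaf_labels if l not in outgroup_labels]
    best = None
    for og in sorted(outgroup_labels):
        d = np.mean([pdm.distance(taxa[og], taxa[l]) for l in ingroup])
        if best is None or d > best[0] + 1e-12:
            best = (d, og)
    return best[1]


def subsample_spectrum(gt: GeneTree, n_rounds: int = 200, seed: int = 0,
                       outgroups=("O1", "O2"), rooted: bool = True,
                       interval=None) -> TopologySpectrum:
    """Spectrum of ingroup topologies over rounds of one-leaf-per-species
    subsampling.

    Each round draws one leaf uniformly per species (outgroups included),
    roots the restricted tree on the deepest outgroup, drops the outgroups
    and records the canonical ingroup key.  With ``outgroups=()`` the
    input trees are taken as already rooted; requesting outgroups that are
    absent from the tree raises :class:`RootingError`.
    """
    rng = np.random.default_rng(seed)
    by_sp = gt.leaves_by_species()
    og_species = [sp for sp in outgroups if sp in by_sp]
    if rooted and outgroups and not og_species:
        raise RootingError("no outgroup leaves available for rooting")
    in_species = sorted(sp for sp in by_sp if sp not in set(outgroups))
    counts: dict = {}
    unresolved = 0
    for _ in range(n_rounds):
        chosen = {sp: by_sp[sp][rng.integers(len(by_sp[sp]))]
                  for sp in in_species + og_species}
        sub = gt.restrict(chosen.values())
        try:
            if rooted:
                if og_species:
                    og_label = _deepest_outgroup(
                        sub, [chosen[sp] for sp in og_species])
                    sub = sub.rerooted_at_leaf(og_label)
                    sub = sub.drop_species(og_species)
                key = canonical_key(sub, rooted=True)
            else:
                sub = sub.drop_species(og_species)
                key = canonical_key(sub, rooted=False)
        except PolytomyError:
            unresolved += 1
            continue
        counts[key] = counts.get(key, 0) + 1
    return TopologySpectrum(interval=interval, counts=counts,
                            n_rounds=n_rounds, unresolved=unresolved)


# ---------------------------------------------------------------------------
# Scalar indices
# ---------------------------------------------------------------------------

def tdi(spectrum, n_topologies: int | None = None):
    """Topology diversity index ``(1 - sum p_i^2) / (1 - sum (1/I)^2)``.

    ``spectrum`` is a :class:`TopologySpectrum` or a frequency mapping.  0
    means a single topology; 1 means all ``I`` possible topologies at equal
    frequency.  Returns ``None`` for an empty spectrum.
    """
    freqs = spectrum.frequencies if isinstance(spectrum, TopologySpectrum) \
        else dict(spectrum)
    if not freqs:
        return None
    if n_topologies is None:
        n_topologies = 15
    p = np.asarray(list(freqs.values()), dtype=float)
    p = p / p.sum()
    denom = 1.0 - n_topologies * (1.0 / n_topologies) ** 2
    return float((1.0 - np.sum(p ** 2)) / denom)


def _degree(node, is_root):
    k = len(node.child_nodes())
    return k if is_root else k + 1


def gsi(gt: GeneTree, focal_species: str) -> float:
    """Genealogical sorting index of a species on a rooted gene tree.

    Observed ``gs = (n-1) / sum_u (d_u - 2)`` over internal nodes of the
    minimal subtree uniting the ``n`` focal leaves from their MRCA (``d_u``
    = node degree).  Normalized as ``(gs - min gs) / (1 - min gs)`` where
    ``min gs`` takes the uniting subtree over every internal node of the
    tree.  1 iff the focal leaves are monophyletic.
    """
    root = gt.tree.seed_node
    focal = [leaf for leaf in gt.tree.leaf_node_iter()
             if gt.species_map[leaf.taxon.label] == focal_species]
    n = len(focal)
    if n < 2:
        raise ValueError(f"gsi undefined for {n} focal leaves")
    focal_set = set(id(l) for l in focal)
    # postorder count of focal leaves below each node
    below = {}
    for node in gt.tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = 1 if id(node) in focal_set else 0
        else:
            below[id(node)] = sum(below[id(c)] for c in node.child_nodes())
    # MRCA: deepest node with all focal below
    mrca = root
    changed = True
    while changed:
        changed = False
        for c in mrca.child_nodes():
            if below[id(c)] == n:
                mrca = c
                changed = True
                break
    # uniting subtree: internal nodes u with mrca >= u (ancestor) and >=1 focal below
    denom_obs = 0.0
    denom_max = 0.0
    in_uniting = {id(mrca)}
    for node in gt.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        d = _degree(node, node is root) - 2
        denom_max += d
        if node is mrca:
            denom_obs += d
            continue
        anc = node.parent_node
        while anc is not None and id(anc) not in in_uniting:
            anc = anc.parent_node
        if anc is not None and below[id(node)] >= 1:
            in_uniting.add(id(node))
            denom_obs += d
    gs_obs = (n - 1) / denom_obs
    gs_min = (n - 1) / denom_max
    if gs_obs >= 1.0:
        return 1.0
    return float((gs_obs - gs_min) / (1.0 - gs_min))


def lca_relative_depth(gt: GeneTree, ingroup_species):
    """Height of the ingroup MRCA divided by the height of the root.

    Height = maximum path length to a descendant leaf.  Returns ``None``
    when branch lengths are absent.
    """
    if not gt.has_branch_lengths():
        return None
    ingroup = set(ingroup_species)
    root = gt.tree.seed_node
    focal = [l for l in gt.tree.leaf_node_iter()
             if gt.species_map[l.taxon.label] in ingroup]
    n = len(focal)
    below = {}
    height = {}
    for node in gt.tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = 1 if gt.species_map[node.taxon.label] in ingroup else 0
            height[id(node)] = 0.0
        else:
            below[id(node)] = sum(below[id(c)] for c in node.child_nodes())
            height[id(node)] = max(height[id(c)] + (c.edge.length or 0.0)
                                   for c in node.child_nodes())
    mrca = root
    changed = True
    while changed:
        changed = False
        for c in mrca.child_nodes():
            if not c.is_leaf() and below[id(c)] == n:
                mrca = c
                changed = True
                break
    if height[id(root)] == 0:
        return None
    return float(height[id(mrca)] / height[id(root)])


# ---------------------------------------------------------------------------
# Window scan and aggregation
# ---------------------------------------------------------------------------

@dataclass
class WindowStats:
    """Per-window discordance statistics (interval 0-based half-open)."""

    interval: tuple
    gsi: dict
    tdi: float | None
    lca_relative_depth: float | None
    mean_internal_support: float | None = None
    passes_support: bool = True
    spectrum: TopologySpectrum | None = None


def _internal_supports(gt: GeneTree, outgroups):
    """Mean support of the two internal ingroup branches of a rooted
    one-leaf-per-species tree, if supports are annotated."""
    try:
        sub = gt.drop_species(outgroups) if outgroups else gt
        by_sp = sub.leaves_by_species()
        if any(len(v) != 1 for v in by_sp.values()):
            return None
    except Exception:
        return None
    supports = []
    for node in sub.tree.preorder_internal_node_iter():
        if node is sub.tree.seed_node:
            continue
        val = node.label
        if val is None and node.edge.head_node.label is not None:
            val = node.edge.head_node.label
        if val is not None:
            try:
                supports.append(float(val))
            except ValueError:
                pass
    if not supports:
        return None
    return float(np.mean(supports))


def restrict_to_top_coverage(gt: GeneTree, coverage: dict, top_n: int,
                             outgroups=()):
    """Keep the haplotypes of the ``top_n`` highest-coverage individuals
    per ingroup species (ties broken by label; outgroups untouched).

    ``coverage`` maps an individual id (``SPECIES_individual``) to its
    sequencing depth; leaves of individuals without an entry rank last.
    """
    keep = []
    og = set(outgroups)
    by_sp = gt.leaves_by_species()
    for sp, leaves in by_sp.items():
        if sp in og:
            keep.extend(leaves)
            continue
        individuals = {}
        for label in leaves:
            ind = "_".join(label.split("_")[:2])
            individuals.setdefault(ind, []).append(label)
        ranked = sorted(individuals,
                        key=lambda i: (-coverage.get(i, float("-inf")), i))
        for ind in ranked[:top_n]:
            keep.extend(individuals[ind])
    return gt.restrict(keep)


def window_scan(windows, species=("C", "P", "A", "S"), outgroups=("O1", "O2"),
                n_rounds: int = 200, seed: int = 0,
                support_threshold: float | None = None,
                n_topologies: int = 15,
                coverage: dict | None = None, top_n: int | None = None):
    """Per-window gsi/tdi/LCA-depth over ``[(interval, GeneTree), ...]``.

    Input intervals must be sorted and non-overlapping.  Windows whose mean
    internal support falls below ``support_threshold`` are flagged (not
    removed).  With a ``coverage`` table and ``top_n``, each window keeps
    only the ``top_n`` highest-coverage individuals per species; by
    default all leaves are used.  Returns a list of
    :class:`WindowStats`.
    """
    prev_end = None
    for (start, end), _ in windows:
        if prev_end is not None and start < prev_end:
            raise ValueError("window intervals must be sorted and non-overlapping")
        prev_end = end
    rng = np.random.default_rng(seed)
    out = []
    for (start, end), gt in windows:
        if coverage is not None and top_n is not None:
            gt = restrict_to_top_coverage(gt, coverage, top_n, outgroups)
        spec = subsample_spectrum(gt, n_rounds=n_rounds,
                                  seed=int(rng.integers(2 ** 31)),
                                  outgroups=outgroups, interval=(start, end))
        g = {}
        for sp in species:
            leaves = gt.leaves_by_species().get(sp, [])
            g[sp] = gsi(gt, sp) if len(leaves) >= 2 else None
        sup = _internal_supports(gt, outgroups)
        passes = True
        if support_threshold is not None and sup is not None:
            passes = sup >= support_threshold
        out.append(WindowStats(
            interval=(start, end), gsi=g,
            tdi=tdi(spec, n_topologies=n_topologies),
            lca_relative_depth=lca_relative_depth(gt, species),
            mean_internal_support=sup, passes_support=passes,
            spectrum=spec))
    return out


def aggregate_spectra(spectra, span: int = 500_000, n_topologies: int = 15):
    """Aggregate window spectra over ``span``-bp blocks.

    Frequencies are averaged across member windows (not member tdi values)
    and the tdi recomputed on the averaged frequencies.  Returns a list of
    ``(block_interval, averaged_frequencies, tdi)``.
    """
    blocks: dict = {}
    for spec in spectra:
        if spec.interval is None:
            raise ValueError("spectra need intervals for aggregation")
        block = int(spec.interval[0] // span)
        blocks.setdefault(block, []).append(spec)
    out = []
    for block in sorted(blocks):
        members = blocks[block]
        acc: dict = {}
        for spec in members:
            for k, f in spec.frequencies.items():
                acc[k] = acc.get(k, 0.0) + f
        avg = {k: v / len(members) for k, v in acc.items()}
        out.append(((block * span, (block + 1) * span), avg,
                    tdi(avg, n_topologies=n_topologies)))
    return out


def genome_topology_ranking(spectra, partitions: dict | None = None,
                            thin_every_other: bool = False,
                            species=("C", "P", "A", "S")):
    """Per-partition topology frequency ranking and cherry-pairing classes.

    ``partitions`` maps a name to a list of 0-based half-open intervals (a
    window belongs when its start lies in any interval); ``None`` gives the
    single partition ``"all"``.  Pairing classes are the 6 species pairs
    (a topology contributes to each pair forming a cherry, so a symmetric
    topology counts under two classes) plus an ``unresolved`` class.

    Returns ``(ranking, pairing)``: two nested dicts keyed by partition.
    """
    import pandas as pd
    if partitions is None:
        partitions = {"all": None}
    keys = enumerate_topologies(species, rooted=True)
    pair_names = [frozenset(p) for p in itertools.combinations(sorted(species), 2)]
    ranking = {}
    pairing = {}
    for name, intervals in partitions.items():
        members = []
        for i, spec in enumerate(spectra):
            if thin_every_other and i % 2 == 1:
                continue
            if intervals is not None:
                start = spec.interval[0] if spec.interval else 0
                if not any(a <= start < b for a, b in intervals):
                    continue
            members.append(spec)
        if not members:
            import warnings
            warnings.warn(f"partition {name!r} is empty")
            ranking[name] = {}
            pairing[name] = {}
            continue
        tot = {k: 0.0 for k in keys}
        unresolved = 0.0
        weight = 0.0
        for spec in members:
            for k, f in spec.frequencies.items():
                tot[k] += f
            if spec.n_rounds:
                unresolved += spec.unresolved / spec.n_rounds
            weight += 1.0
        freqs = {k: v / weight for k, v in tot.items()}
        ranking[name] = dict(sorted(freqs.items(), key=lambda kv: -kv[1]))
        pcls = {tuple(sorted(p)): 0.0 for p in pair_names}
        for k, f in freqs.items():
            for cherry in cherry_pairs(k):
                if cherry in pair_names:
                    pcls[tuple(sorted(cherry))] += f
        pcls[UNRESOLVED] = unresolved / weight
        pairing[name] = pcls
    return ranking, pairing
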