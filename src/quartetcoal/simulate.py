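"""Structured-coalescent simulation of the four-species study design.

Genealogies come from msprime's structured coalescent under a
:class:`~quartetcoal.demography.Demography`; mutation dropping is an
infinite-sites scheme on a finite sequence (Poisson number of mutations,
branch chosen proportionally to length, distinct integer positions, i.e.
collisions re-drawn).  Loci are unlinked: each locus is an independent
genealogy; recombination within loci is not modeled.

A single master seed drives everything; per-locus streams are derived
deterministically, so studies are bit-identically reproducible.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
import msprime

from .demography import (Demography, SampleDesign, InvalidDesignError)
from .trees import GeneTree
from . import treestats

__all__ = [
    "haplotype_labels", "simulate_genealogy", "simulate_tree_sequence",
    "drop_mutations", "LocusVariants", "SyntheticStudy", "emit_study",
    "simulate_topology_counts", "pairwise_tmrca",
]

_NUCS = np.array(list("ACGT"))


def _locus_seed(master_seed: int, locus_index: int, stream: int = 0) -> int:
    """Deterministic per-locus seed below 2**31 derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(locus_index), stream])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31 - 1)) + 1


def haplotype_labels(demography: Demography, design: SampleDesign):
    """Leaf labels (``SPECIES_individual_hap``) and their species, in the
    order haplotypes are sampled."""
    labels, species = [], []
    for sp in demography.species:
        for j in range(design.haplotypes_per_species):
            labels.append(f"{sp}_{j // 2 + 1:03d}_{j % 2 + 1}")
            species.append(sp)
    if design.include_outgroups:
        for og in demography.outgroups:
            for j in range(og.n_haplotypes):
                labels.append(f"{og.name}_{j // 2 + 1:03d}_{j % 2 + 1}")
                species.append(og.name)
    return labels, species


def simulate_tree_sequence(demography: Demography, design: SampleDesign,
                           locus_index: int = 0,
                           include_outgroups: bool | None = None):
    """One unlinked locus genealogy as a single-tree tree sequence."""
    if design.haplotypes_per_species < 1:
        raise InvalidDesignError("zero sampled haplotypes")
    if include_outgroups is None:
        include_outgroups = design.include_outgroups
    samples = [msprime.SampleSet(design.haplotypes_per_species,
                                 population=sp, ploidy=1)
               for sp in demography.species]
    if include_outgroups:
        samples += [msprime.SampleSet(og.n_haplotypes, population=og.name,
                                      ploidy=1)
                    for og in demography.outgroups]
    return msprime.sim_ancestry(
        samples=samples,
        demography=demography.to_msprime(include_outgroups=include_outgroups),
        ploidy=2, sequence_length=design.locus_length,
        random_seed=_locus_seed(design.seed, locus_index))


def batch_tree_sequences(demography: Demography, design: SampleDesign,
                         include_outgroups: bool | None = None,
                         n_loci: int | None = None):
    """Generator of unlinked locus genealogies from one msprime stream.

    Parses the demography once, so bulk generation is much faster than
    per-locus :func:`simulate_tree_sequence` calls; the stream is fully
    determined by ``design.seed``.
    """
    if include_outgroups is None:
        include_outgroups = design.include_outgroups
    samples = [msprime.SampleSet(design.haplotypes_per_species,
                                 population=sp, ploidy=1)
               for sp in demography.species]
    if include_outgroups:
        samples += [msprime.SampleSet(og.n_haplotypes, population=og.name,
                                      ploidy=1)
                    for og in demography.outgroups]
    return msprime.sim_ancestry(
        samples=samples,
        demography=demography.to_msprime(include_outgroups=include_outgroups),
        ploidy=2, sequence_length=design.locus_length,
        num_replicates=n_loci or design.n_loci,
        random_seed=_locus_seed(design.seed, 0, stream=4))


def simulate_locus_batch(demography: Demography, design: SampleDesign,
                         include_outgroups: bool | None = None):
    """All loci of a study as :class:`LocusVariants` (fast bulk path)."""
    if include_outgroups is None:
        include_outgroups = design.include_outgroups
    labels, species = haplotype_labels(
        demography,
        design if include_outgroups == design.include_outgroups else
        SampleDesign(**{**design.__dict__, "include_outgroups": include_outgroups}))
    out = []
    for i, ts in enumerate(batch_tree_sequences(demography, design,
                                                include_outgroups)):
        rng = np.random.default_rng(_locus_seed(design.seed, i, stream=1))
        lengths, masks = _ts_branch_arrays(ts)
        positions, genotypes = _drop_on_branches(
            lengths, masks, demography.mu, design.locus_length, rng)
        anc, der = _draw_alleles(len(positions), rng)
        out.append(LocusVariants(
            chrom=f"locus_{i:04d}", positions=positions, anc=anc, der=der,
            genotypes=genotypes, labels=labels, species=species,
            length=design.locus_length))
    return out


def _ts_to_genetree(ts, labels, species) -> GeneTree:
    """Convert a single-tree tree sequence to a GeneTree (lengths in
    generations)."""
    tree = ts.first()
    time = ts.tables.nodes.time

    def render(u):
        children = tree.children(u)
        if not children:
            return labels[u]
        inner = ",".join(
            f"{render(v)}:{time[u] - time[v]:.6f}" for v in children)
        return f"({inner})"

    newick = render(tree.root) + ";"
    return GeneTree.from_newick(
        newick, species_map=dict(zip(labels, species)))


def simulate_genealogy(demography: Demography, design: SampleDesign,
                       locus_index: int = 0,
                       include_outgroups: bool | None = None) -> GeneTree:
    """Simulate one locus genealogy as a rooted binary :class:`GeneTree`.

    Branch lengths are in generations.  Coalescence between lineages of
    different species never predates their divergence unless migration
    moved a lineage.
    """
    ts = simulate_tree_sequence(demography, design, locus_index,
                                include_outgroups)
    if include_outgroups is None:
        include_outgroups = design.include_outgroups
    labels, species = haplotype_labels(
        demography,
        design if include_outgroups == design.include_outgroups else
        SampleDesign(**{**design.__dict__, "include_outgroups": include_outgroups}))
    return _ts_to_genetree(ts, labels, species)


# ---------------------------------------------------------------------------
# Mutation dropping
# ---------------------------------------------------------------------------

@dataclass
class LocusVariants:
    """Biallelic variants of one locus (positions 1-based)."""

    chrom: str
    positions: np.ndarray
    anc: np.ndarray           # ancestral base per site
    der: np.ndarray           # derived base per site
    genotypes: np.ndarray     # (n_sites, n_haplotypes) uint8 0=anc 1=der
    labels: list
    species: list
    length: int = 0           # locus length in bp


def _drop_on_branches(branch_lengths, carrier_masks, mu, length, rng):
    """Core infinite-sites dropper: Poisson(mu*L*T) mutations, branch chosen
    proportional to length, distinct integer positions in [1, L]."""
    total = float(branch_lengths.sum())
    n_mut = rng.poisson(mu * length * total)
    n_mut = min(n_mut, length)   # finite sequence: at most one mutation per site
    if n_mut == 0:
        return (np.empty(0, dtype=np.int64),
                np.empty((0, carrier_masks.shape[1]), dtype=np.uint8))
    branch_idx = rng.choice(len(branch_lengths), size=n_mut,
                            p=branch_lengths / total)
    positions = rng.choice(length, size=n_mut, replace=False) + 1
    order = np.argsort(positions)
    return positions[order], carrier_masks[branch_idx[order]].astype(np.uint8)


def _ts_branch_arrays(ts):
    """Branch lengths and per-branch carrier masks of a single-tree ts."""
    tree = ts.first()
    time = ts.tables.nodes.time
    n = ts.num_samples
    nodes = [u for u in tree.nodes() if u != tree.root]
    lengths = np.array([time[tree.parent(u)] - time[u] for u in nodes])
    masks = np.zeros((len(nodes), n), dtype=bool)
    below = {}
    for u in tree.nodes(order="postorder"):
        m = np.zeros(n, dtype=bool)
        if tree.is_sample(u):
            m[u] = True
        for v in tree.children(u):
            m |= below[v]
        below[u] = m
    for i, u in enumerate(nodes):
        masks[i] = below[u]
    return lengths, masks


def drop_mutations(gt: GeneTree, mu: float, length: int, seed: int = 0,
                   chrom: str = "locus", bases: bool = True) -> LocusVariants:
    """Drop infinite-sites mutations on a gene tree with branch lengths in
    generations.

    Each mutation is biallelic; its derived carriers are exactly the leaves
    below the mutated branch (a clade of the genealogy).
    """
    if mu < 0 or length < 0:
        raise ValueError("mu and length must be non-negative")
    rng = np.random.default_rng(seed)
    leaves = gt.leaf_labels
    index = {l: i for i, l in enumerate(leaves)}
    lengths, masks = [], []
    for edge in gt.tree.preorder_edge_iter():
        node = edge.head_node
        if node is gt.tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("drop_mutations requires branch lengths")
        m = np.zeros(len(leaves), dtype=bool)
        for leaf in node.leaf_iter():
            m[index[leaf.taxon.label]] = True
        lengths.append(edge.length)
        masks.append(m)
    positions, genotypes = _drop_on_branches(
        np.asarray(lengths, dtype=float), np.asarray(masks), mu, length, rng)
    anc, der = _draw_alleles(len(positions), rng, bases)
    return LocusVariants(chrom=chrom, positions=positions, anc=anc, der=der,
                         genotypes=genotypes, labels=list(leaves),
                         species=[gt.species_map[l] for l in leaves],
                         length=length)


def _draw_alleles(n, rng, bases=True):
    if not bases:
        return np.full(n, "0"), np.full(n, "1")
    anc_idx = rng.integers(0, 4, size=n)
    shift = rng.integers(1, 4, size=n)
    return _NUCS[anc_idx], _NUCS[(anc_idx + shift) % 4]


def _simulate_locus_variants(demography, design, locus_index,
                             include_outgroups=None) -> LocusVariants:
    """Fast path: simulate genealogy + mutations without dendropy."""
    ts = simulate_tree_sequence(demography, design, locus_index,
                                include_outgroups)
    rng = np.random.default_rng(_locus_seed(design.seed, locus_index, stream=1))
    lengths, masks = _ts_branch_arrays(ts)
    positions, genotypes = _drop_on_branches(
        lengths, masks, demography.mu, design.locus_length, rng)
    anc, der = _draw_alleles(len(positions), rng)
    if include_outgroups is None:
        include_outgroups = design.include_outgroups
    labels, species = haplotype_labels(
        demography,
        design if include_outgroups == design.include_outgroups else
        SampleDesign(**{**design.__dict__, "include_outgroups": include_outgroups}))
    return LocusVariants(chrom=f"locus_{locus_index:04d}", positions=positions,
                         anc=anc, der=der, genotypes=genotypes,
                         labels=labels, species=species,
                         length=design.locus_length)


# ---------------------------------------------------------------------------
# Study emission
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """A complete synthetic study: genealogies, per-locus variants and
    alignments, plus the generating demography as ground truth."""

    demography: Demography
    design: SampleDesign
    genealogies: list            # newick strings, one per locus
    loci: list                   # LocusVariants per locus
    labels: list
    species: list

    @property
    def truth(self) -> Demography:
        return self.demography

    def variants_table(self):
        """All loci as one tab-friendly table: chrom, pos, anc, der, then
        one 0/1/. column per haplotype."""
        import pandas as pd
        rows = []
        for lv in self.loci:
            for s in range(len(lv.positions)):
                rows.append((lv.chrom, int(lv.positions[s]),
                             str(lv.anc[s]), str(lv.der[s]),
                             *lv.genotypes[s].astype(str)))
        return pd.DataFrame(rows, columns=["chrom", "pos", "anc", "der",
                                           *self.labels])

    def alignments(self) -> dict:
        """Per-locus dict label -> sequence string (monomorphic background
        drawn per locus; variant columns substituted)."""
        out = {}
        for i, lv in enumerate(self.loci):
            rng = np.random.default_rng(
                _locus_seed(self.design.seed, i, stream=2))
            background = _NUCS[rng.integers(0, 4, size=self.design.locus_length)]
            seqs = np.tile(background, (len(self.labels), 1))
            for s in range(len(lv.positions)):
                col = lv.positions[s] - 1
                seqs[:, col] = np.where(lv.genotypes[s] == 1,
                                        lv.der[s], lv.anc[s])
            out[lv.chrom] = {lbl: "".join(seqs[j])
                             for j, lbl in enumerate(self.labels)}
        return out

    def write(self, outdir):
        """Write the study: newick genealogies, FASTA alignments, a variant
        TSV and a species-map TSV."""
        from . import io as qio
        import pathlib
        out = pathlib.Path(outdir)
        (out / "trees").mkdir(parents=True, exist_ok=True)
        (out / "alignments").mkdir(parents=True, exist_ok=True)
        for i, nwk in enumerate(self.genealogies):
            (out / "trees" / f"locus_{i:04d}.nwk").write_text(nwk + "\n")
        for chrom, seqs in self.alignments().items():
            qio.write_fasta(out / "alignments" / f"{chrom}.fa", seqs)
        qio.write_variants(out / "variants.tsv", self.variants_table())
        qio.write_species_map(out / "species_map.tsv",
                              dict(zip(self.labels, self.species)))
        return out


def emit_study(demography: Demography, design: SampleDesign,
               missing_rate: float = 0.0) -> SyntheticStudy:
    """Generate a full synthetic study under the design.

    Identical seeds give bit-identical output.  Outgroup haplotypes carry
    the true ancestral allele at every ingroup SNP (infinite sites), plus
    outgroup-private mutations.  ``missing_rate`` randomly masks genotype
    calls (coded ``.``) to emulate callability gaps.
    """
    labels, species = haplotype_labels(demography, design)
    genealogies, loci = [], []
    for i, ts in enumerate(batch_tree_sequences(demography, design)):
        rng = np.random.default_rng(_locus_seed(design.seed, i, stream=1))
        lengths, masks = _ts_branch_arrays(ts)
        positions, genotypes = _drop_on_branches(
            lengths, masks, demography.mu, design.locus_length, rng)
        anc, der = _draw_alleles(len(positions), rng)
        lv = LocusVariants(chrom=f"locus_{i:04d}", positions=positions,
                           anc=anc, der=der, genotypes=genotypes,
                           labels=labels, species=species,
                           length=design.locus_length)
        if missing_rate > 0:
            rng2 = np.random.default_rng(_locus_seed(design.seed, i, stream=3))
            mask = rng2.random(lv.genotypes.shape) < missing_rate
            g = lv.genotypes.astype(object)
            g[mask] = "."
            lv.genotypes = g
        loci.append(lv)
        genealogies.append(_ts_to_genetree(ts, labels, species).to_newick())
    return SyntheticStudy(demography=demography, design=design,
                          genealogies=genealogies, loci=loci,
                          labels=labels, species=species)


# ---------------------------------------------------------------------------
# Calibration helpers
# ---------------------------------------------------------------------------

def simulate_topology_counts(demography: Demography, n_reps: int,
                             seed: int = 1, rooted: bool = True) -> dict:
    """Empirical rooted-topology counts for one lineage per species.

    Uses the canonical keys of :mod:`quartetcoal.treestats`; the tree is
    read straight off the simulated genealogy (its root is the true root).
    """
    design = SampleDesign(haplotypes_per_species=2, n_loci=1,
                          locus_length=1, include_outgroups=False, seed=seed)
    samples = [msprime.SampleSet(1, population=sp, ploidy=1)
               for sp in demography.species]
    reps = msprime.sim_ancestry(
        samples=samples, demography=demography.to_msprime(),
        ploidy=2, num_replicates=n_reps, random_seed=_locus_seed(seed, 0))
    sp_list = list(demography.species)
    counts: dict = {}
    for ts in reps:
        tree = ts.first()

        def nest(u):
            ch = tree.children(u)
            if not ch:
                return sp_list[u]
            return tuple(nest(v) for v in ch)

        key = (treestats.canonical_key_nested(nest(tree.root)) if rooted
               else treestats.unrooted_key_nested(nest(tree.root)))
        counts[key] = counts.get(key, 0) + 1
    return counts


def pairwise_tmrca(demography: Demography, species_pair, n_reps: int,
                   seed: int = 1) -> np.ndarray:
    """TMRCA (generations) of one lineage from each of two populations
    (or two lineages from one population if both entries are equal)."""
    a, b = species_pair
    if a == b:
        samples = [msprime.SampleSet(2, population=a, ploidy=1)]
    else:
        samples = [msprime.SampleSet(1, population=p, ploidy=1)
                   for p in (a, b)]
    reps = msprime.sim_ancestry(
        samples=samples, demography=demography.to_msprime(), ploidy=2,
        num_replicates=n_reps, random_seed=_locus_seed(seed, 1))
    return np.array([ts.first().time(ts.first().root) for ts in reps])
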