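"""Gene-tree container shared by the simulation and tree-statistics modules.

A :class:`GeneTree` is a rooted, leaf-labeled tree (dendropy-backed) with
optional branch lengths and internal support values, plus a leaf→species
map.  Leaf labels follow the ``SPECIES_individual_hap`` convention
(e.g. ``C_003_1``); the species map makes the convention optional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

__all__ = ["GeneTree", "species_from_label", "PolytomyError",
           "IncompleteSubsampleError", "RootingError"]


class PolytomyError(ValueError):
    """A tree contains an unresolved multifurcation where a binary node is required."""


class IncompleteSubsampleError(ValueError):
    """A one-leaf-per-species subsample is missing a species."""


class RootingError(ValueError):
    """No outgroup leaf available for rooting."""


def species_from_label(label: str) -> str:
    """Species prefix of a ``SPECIES_individual_hap`` leaf label."""
    return label.split("_", 1)[0]


@dataclass
class GeneTree:
    """A rooted gene tree with a leaf→species map.

    Branch lengths, when present, are in generations (simulator output) or
    substitutions (user input); the statistics here only ever use ratios or
    ignore lengths, so the unit is the caller's concern.
    """

    tree: dendropy.Tree
    species_map: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.species_map:
            self.species_map = {
                leaf.taxon.label: species_from_label(leaf.taxon.label)
                for leaf in self.tree.leaf_node_iter()
            }
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon.label not in self.species_map:
                raise ValueError(f"leaf {leaf.taxon.label!r} missing from species map")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, species_map: dict | None = None) -> "GeneTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True,
                                 suppress_internal_node_taxa=True)
        return cls(tree=tree, species_map=dict(species_map) if species_map else {})

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", unquoted_underscores=True,
                                   suppress_rooting=True).strip()

    # -- basic queries -----------------------------------------------------

    @property
    def leaf_labels(self):
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def species_of(self, label: str) -> str:
        return self.species_map[label]

    def leaves_by_species(self) -> dict:
        out = {}
        for label in self.leaf_labels:
            out.setdefault(self.species_map[label], []).append(label)
        return out

    def has_branch_lengths(self) -> bool:
        return all(e.length is not None
                   for e in self.tree.preorder_edge_iter()
                   if e.head_node is not self.tree.seed_node)

    # -- manipulation ------------------------------------------------------

    def restrict(self, labels) -> "GeneTree":
        """Copy of the tree restricted to the given leaf labels."""
        labels = set(labels)
        sub = self.tree.extract_tree(
            node_filter_fn=lambda nd: (not nd.is_leaf())
            or (nd.taxon is not None and nd.taxon.label in labels),
            suppress_unifurcations=True)
        return GeneTree(tree=sub,
                        species_map={l: self.species_map[l] for l in labels})

    def rerooted_at_leaf(self, label: str) -> "GeneTree":
        """Copy rerooted on the pendant edge of ``label`` (midpoint of that edge)."""
        clone = self.tree.clone(depth=1)
        leaf = next(nd for nd in clone.leaf_node_iter() if nd.taxon.label == label)
        edge = leaf.edge
        if edge.length is not None:
            clone.reroot_at_edge(edge, length1=edge.length / 2.0,
                                 length2=edge.length / 2.0,
                                 update_bipartitions=False)
        else:
            clone.reroot_at_edge(edge, update_bipartitions=False)
        return GeneTree(tree=clone, species_map=dict(self.species_map))

    def drop_species(self, species) -> "GeneTree":
        """Copy with all leaves of the given species removed (root kept)."""
        species = set(species)
        keep = [l for l in self.leaf_labels if self.species_map[l] not in species]
        return self.restrict(keep)
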