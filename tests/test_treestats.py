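"""Topology classification, spectra, gsi/tdi/LCA-depth, windows."""

import itertools

import numpy as np
import pytest

from quartetcoal.trees import (GeneTree, IncompleteSubsampleError,
                               PolytomyError, RootingError)
from quartetcoal import treestats as ts


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def gsi_bruteforce(gt: GeneTree, focal_species: str) -> float:
    """Direct transcription of the genealogical-sorting-index definition:
    gs = (n-1) / sum of (degree-2) over the nodes of the union of the
    MRCA->leaf paths; normalized with max gs = 1 and min gs from the
    all-internal-nodes subtree."""
    tree = gt.tree
    focal = [l for l in tree.leaf_node_iter()
             if gt.species_map[l.taxon.label] == focal_species]
    n = len(focal)
    mrca = tree.mrca(taxa=[l.taxon for l in focal])
    union = set()
    for leaf in focal:
        node = leaf.parent_node
        while node is not None:
            union.add(id(node))
            if node is mrca:
                break
            node = node.parent_node

    def degree(node):
        d = len(node.child_nodes())
        return d if node.parent_node is None else d + 1

    obs = sum(degree(nd) - 2 for nd in tree.preorder_internal_node_iter()
              if id(nd) in union)
    total = sum(degree(nd) - 2 for nd in tree.preorder_internal_node_iter())
    gs = (n - 1) / obs
    gs_min = (n - 1) / total
    if gs >= 1.0:
        return 1.0
    return (gs - gs_min) / (1.0 - gs_min)


def exhaustive_spectrum(gt: GeneTree, outgroups):
    """Enumerate every one-leaf-per-species choice (oracle for the
    subsampled spectrum)."""
    by_sp = gt.leaves_by_species()
    og = [sp for sp in outgroups if sp in by_sp]
    ingroup = sorted(sp for sp in by_sp if sp not in set(outgroups))
    counts = {}
    total = 0
    for combo in itertools.product(*(by_sp[sp] for sp in ingroup + og)):
        sub = gt.restrict(combo)
        og_labels = [l for l in combo if gt.species_map[l] in og]
        deepest = ts._deepest_outgroup(sub, og_labels)
        sub = sub.rerooted_at_leaf(deepest).drop_species(og)
        counts[ts.canonical_key(sub)] = counts.get(ts.canonical_key(sub), 0) + 1
        total += 1
    return {k: v / total for k, v in counts.items()}


# ---------------------------------------------------------------------------
# Enumeration and canonical keys
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n,rooted,expected", [
    (4, True, 15), (4, False, 3), (3, True, 3), (3, False, 1),
    (5, True, 105), (5, False, 15), (6, True, 945), (6, False, 105),
])
def test_enumeration_counts_follow_double_factorial(n, rooted, expected):
    keys = ts.enumerate_topologies(n, rooted=rooted)
    assert len(keys) == expected
    assert keys == sorted(keys)          # deterministic order


def test_enumeration_rejects_unsupported_sizes():
    with pytest.raises(ValueError):
        ts.enumerate_topologies(2)
    with pytest.raises(ValueError):
        ts.enumerate_topologies(7)


def test_canonical_key_invariant_to_rotation_and_lengths():
    a = GeneTree.from_newick("(((P_1_1:1,A_1_1:2):3,C_1_1:1):2,S_1_1:9);")
    b = GeneTree.from_newick("(S_1_1:1,((A_1_1:5,P_1_1:5):1,C_1_1:2):1);")
    assert ts.canonical_key(a) == ts.canonical_key(b) == "(((A,P),C),S)"


def test_canonical_key_invariant_to_leaf_relabeling_within_species():
    a = GeneTree.from_newick("(((P_1_1,A_1_1),C_1_1),S_1_1);")
    b = GeneTree.from_newick("(((P_7_2,A_3_1),C_9_2),S_2_1);")
    assert ts.canonical_key(a) == ts.canonical_key(b)


def test_all_15_rooted_shapes_give_distinct_keys():
    shapes = list(ts._all_rooted_shapes(("A", "C", "P", "S")))
    keys = {ts.canonical_key_nested(s) for s in shapes}
    assert len(keys) == 15


def test_canonical_key_errors():
    with pytest.raises(IncompleteSubsampleError):
        ts.canonical_key(GeneTree.from_newick("((P_1_1,P_2_1),(C_1_1,S_1_1));"))
    with pytest.raises(PolytomyError):
        ts.canonical_key(GeneTree.from_newick("((P_1_1,A_1_1,C_1_1),S_1_1);"))


def test_unrooted_key_is_the_cherry_split():
    gt = GeneTree.from_newick("(((P_1_1,A_1_1),C_1_1),S_1_1);")
    assert ts.canonical_key(gt, rooted=False) == "A,P|C,S"


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------

def _two_per_species_tree():
    # species monophyletic -> every subsample yields the same shape
    nwk = ("((((P_1_1:1,P_2_1:1):1,(A_1_1:1,A_2_1:1):1):1,"
           "(C_1_1:1,C_2_1:1):2):1,((S_1_1:1,S_2_1:1):3,"
           "(O1_1_1:1,(O2_1_1:1,O2_2_1:1):1):4):1);")
    return GeneTree.from_newick(nwk)


def test_spectrum_mass_one_when_single_shape():
    gt = _two_per_species_tree()
    spec = ts.subsample_spectrum(gt, n_rounds=40, seed=1,
                                 outgroups=("O1", "O2"))
    assert spec.frequencies == {"(((A,P),C),S)": 1.0}


def test_spectrum_reproducible_for_fixed_seed():
    gt = _two_per_species_tree()
    a = ts.subsample_spectrum(gt, n_rounds=200, seed=7, outgroups=("O1", "O2"))
    b = ts.subsample_spectrum(gt, n_rounds=200, seed=7, outgroups=("O1", "O2"))
    assert a.counts == b.counts


def test_spectrum_requires_outgroup_for_rooting():
    gt = GeneTree.from_newick("(((P_1_1:1,A_1_1:1):1,C_1_1:1):1,S_1_1:1);")
    with pytest.raises(RootingError):
        ts.subsample_spectrum(gt, n_rounds=5, seed=0, outgroups=("O1", "O2"))


def test_subsampled_spectrum_converges_to_exhaustive(mle_demography):
    """On a small mixed tree the subsampled spectrum must approach the
    exhaustive one-leaf-per-species enumeration (binomial error)."""
    from quartetcoal.demography import SampleDesign
    from quartetcoal import simulate
    design = SampleDesign(haplotypes_per_species=2, n_loci=1,
                          locus_length=100, include_outgroups=True, seed=5)
    gt = simulate.simulate_genealogy(mle_demography, design, 0)
    oracle = exhaustive_spectrum(gt, ("O1", "O2"))
    spec = ts.subsample_spectrum(gt, n_rounds=2000, seed=3,
                                 outgroups=("O1", "O2"))
    for key in set(oracle) | set(spec.frequencies):
        p = oracle.get(key, 0.0)
        se = np.sqrt(max(p * (1 - p), 1e-4) / 2000)
        assert abs(spec.frequencies.get(key, 0.0) - p) < 4 * se


# ---------------------------------------------------------------------------
# tdi / gsi / LCA depth
# ---------------------------------------------------------------------------

def test_tdi_definitional_limits():
    keys = ts.enumerate_topologies(4, rooted=True)
    assert ts.tdi({keys[0]: 1.0}) == pytest.approx(0.0)
    assert ts.tdi({k: 1 / 15 for k in keys}) == pytest.approx(1.0)
    assert ts.tdi({}) is None


def test_tdi_two_equal_topologies_hand_value():
    # (1 - 0.5) / (1 - 1/15) = 15/28
    val = ts.tdi({"a": 0.5, "b": 0.5})
    assert val == pytest.approx(15 / 28)


def test_gsi_monophyletic_is_one():
    gt = _two_per_species_tree()
    for sp in "CPAS":
        assert ts.gsi(gt, sp) == 1.0


def test_gsi_two_sisters_in_larger_tree_is_one():
    nwk = "(((C_1_1,C_2_1),(P_1_1,A_1_1)),(S_1_1,(P_2_1,A_2_1)));"
    assert ts.gsi(GeneTree.from_newick(nwk), "C") == 1.0


def test_gsi_single_leaf_undefined():
    gt = GeneTree.from_newick("((C_1_1,P_1_1),S_1_1);")
    with pytest.raises(ValueError):
        ts.gsi(gt, "C")


def test_gsi_matches_bruteforce_on_interleaved_trees():
    fixtures = [
        "((((C_1_1,P_1_1),C_2_1),(P_2_1,C_3_1)),((P_3_1,C_4_1),P_4_1));",
        "(((C_1_1,(P_1_1,P_2_1)),(C_2_1,P_3_1)),((C_3_1,C_4_1),P_4_1));",
        "((((A_1_1,C_1_1),(A_2_1,P_1_1)),(S_1_1,A_3_1)),(A_4_1,S_2_1));",
    ]
    for nwk in fixtures:
        gt = GeneTree.from_newick(nwk)
        for sp in {s for s in gt.species_map.values()}:
            if len([l for l, s in gt.species_map.items() if s == sp]) >= 2:
                assert ts.gsi(gt, sp) == pytest.approx(
                    gsi_bruteforce(gt, sp)), (nwk, sp)


def test_gsi_invariant_to_branch_length_rescaling():
    nwk = "((((C_1_1:1,P_1_1:2):1,C_2_1:4):1,P_2_1:1):1,(C_3_1:2,P_3_1:1):1);"
    gt1 = GeneTree.from_newick(nwk)
    gt2 = GeneTree.from_newick(nwk.replace(":1", ":10").replace(":2", ":20")
                               .replace(":4", ":40"))
    assert ts.gsi(gt1, "C") == pytest.approx(ts.gsi(gt2, "C"))


def test_lca_relative_depth_trivials():
    # ingroup MRCA = root
    gt = GeneTree.from_newick("(((P_1_1:1,A_1_1:1):1,C_1_1:2):1,S_1_1:3);")
    assert ts.lca_relative_depth(gt, "CPAS") == pytest.approx(1.0)
    # ultrametric, ingroup MRCA at half the root age
    nwk = ("((((P_1_1:1,A_1_1:1):0.5,(C_1_1:1,S_1_1:1):0.5):0.5,"
           "O1_1_1:2):1,O2_1_1:3);")
    gt = GeneTree.from_newick(nwk)
    assert ts.lca_relative_depth(gt, "CPAS") == pytest.approx(0.5)


def test_lca_relative_depth_matches_path_length_oracle():
    nwk = ("(((P_1_1:0.7,A_1_1:2.1):0.4,(C_1_1:1.3,S_1_1:0.2):1.9):2.2,"
           "(O1_1_1:0.5,O2_1_1:3.3):1.1);")
    gt = GeneTree.from_newick(nwk)
    # oracle: max root-to-leaf path minus max mrca-to-leaf path, via pdm
    pdm = gt.tree.phylogenetic_distance_matrix()
    ingroup = [l for l in gt.tree.leaf_node_iter()
               if gt.species_map[l.taxon.label] in set("CPAS")]
    mrca = gt.tree.mrca(taxa=[l.taxon for l in ingroup])

    def height(node):
        return max(sum(e.length for e in l.ancestor_iter_with_edge(node))
                   for l in node.leaf_iter())

    def height_simple(node):
        best = 0.0
        for leaf in node.leaf_iter():
            d = 0.0
            cur = leaf
            while cur is not node:
                d += cur.edge.length
                cur = cur.parent_node
            best = max(best, d)
        return best

    expected = height_simple(mrca) / height_simple(gt.tree.seed_node)
    assert ts.lca_relative_depth(gt, "CPAS") == pytest.approx(expected)


def test_lca_depth_missing_without_branch_lengths():
    gt = GeneTree.from_newick("(((P_1_1,A_1_1),C_1_1),S_1_1);")
    assert ts.lca_relative_depth(gt, "CPAS") is None


# ---------------------------------------------------------------------------
# Window scan, aggregation, ranking
# ---------------------------------------------------------------------------

def test_window_scan_rejects_unsorted_intervals():
    gt = _two_per_species_tree()
    with pytest.raises(ValueError):
        ts.window_scan([((50_000, 60_000), gt), ((0, 10_000), gt)])


def test_aggregate_alternating_pure_topologies():
    """Two alternating pure topologies: member tdi 0, aggregate 15/28."""
    s1 = ts.TopologySpectrum((0, 10_000), {"(((A,P),C),S)": 200}, 200)
    s2 = ts.TopologySpectrum((50_000, 60_000), {"((A,P),(C,S))": 200}, 200)
    assert ts.tdi(s1) == 0.0 and ts.tdi(s2) == 0.0
    blocks = ts.aggregate_spectra([s1, s2], span=500_000)
    assert len(blocks) == 1
    _, freqs, agg_tdi = blocks[0]
    assert freqs == {"(((A,P),C),S)": 0.5, "((A,P),(C,S))": 0.5}
    assert agg_tdi == pytest.approx(15 / 28)


def test_support_filter_flags_low_support_windows():
    high = GeneTree.from_newick(
        "(((P_1_1:1,A_1_1:1)90:1,C_1_1:1)80:1,S_1_1:1);")
    low = GeneTree.from_newick(
        "(((P_1_1:1,A_1_1:1)30:1,C_1_1:1)40:1,S_1_1:1);")
    stats = ts.window_scan(
        [((0, 10_000), high), ((50_000, 60_000), low)],
        outgroups=(), n_rounds=4, seed=0, support_threshold=50)
    assert stats[0].mean_internal_support == pytest.approx(85.0)
    assert stats[0].passes_support
    assert stats[1].mean_internal_support == pytest.approx(35.0)
    assert not stats[1].passes_support


def test_single_window_ranking_equals_its_spectrum():
    spec = ts.TopologySpectrum((0, 10_000),
                               {"(((A,P),C),S)": 150, "((A,P),(C,S))": 50},
                               200)
    ranking, pairing = ts.genome_topology_ranking([spec])
    assert ranking["all"]["(((A,P),C),S)"] == pytest.approx(0.75)
    assert ranking["all"]["((A,P),(C,S))"] == pytest.approx(0.25)
    # pairing: A-P cherry in both topologies; C-S cherry only in the
    # symmetric one
    assert pairing["all"][("A", "P")] == pytest.approx(1.0)
    assert pairing["all"][("C", "S")] == pytest.approx(0.25)
    assert pairing["all"]["unresolved"] == 0.0


def test_empty_partition_warns():
    spec = ts.TopologySpectrum((0, 10_000), {"(((A,P),C),S)": 10}, 10)
    with pytest.warns(UserWarning):
        ranking, _ = ts.genome_topology_ranking(
            [spec], partitions={"z": [(10 ** 9, 10 ** 9 + 1)]})
    assert ranking["z"] == {}


def test_star_tree_pairing_probability_matches_analytics():
    """Cherry-pairing class frequency under the star tree equals 2/9 per
    pair (two asymmetric histories at 1/18 plus one symmetric at 2/18)."""
    from quartetcoal import mscmodel
    probs = mscmodel.star_tree_topology_probs()
    spec = ts.TopologySpectrum(
        (0, 10_000), {k: int(round(p * 18)) for k, p in probs.items()}, 18)
    _, pairing = ts.genome_topology_ranking([spec])
    for pair in itertools.combinations(sorted("CPAS"), 2):
        assert pairing["all"][pair] == pytest.approx(2 / 9)


def test_canonical_key_invariance_property():
    """Property: the canonical key of any 4-taxon rooted shape is invariant
    to child order, branch lengths and within-species leaf renaming."""
    from hypothesis import given, settings, strategies as st

    shapes = list(ts._all_rooted_shapes(("A", "C", "P", "S")))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(idx=st.integers(0, len(shapes) - 1),
           swap=st.booleans(),
           hap=st.integers(1, 9),
           data=st.data())
    def check(idx, swap, hap, data):
        nested = shapes[idx]

        def to_newick(node):
            if isinstance(node, str):
                length = data.draw(st.floats(0.1, 9.9))
                return f"{node}_1_{hap}:{length:.2f}"
            a, b = node
            if swap:
                a, b = b, a
            length = data.draw(st.floats(0.1, 9.9))
            return f"({to_newick(a)},{to_newick(b)}):{length:.2f}"

        gt = GeneTree.from_newick(to_newick(nested) + ";")
        assert ts.canonical_key(gt) == ts.canonical_key_nested(nested)

    check()


def test_gsi_increases_as_ne_decreases(strong_signal_demography):
    """Smaller Ne accelerates lineage sorting: mean gsi rises along a
    decreasing-Ne ladder (paired loci, rank comparison)."""
    from dataclasses import replace
    from quartetcoal.demography import SampleDesign
    from quartetcoal import simulate
    base = strong_signal_demography
    means = []
    for scale in (4.0, 1.0, 0.25):
        ne = {sp: v * scale for sp, v in base.ne_current.items()}
        anc = {k: v * scale for k, v in base.ne_ancestral.items()}
        dem = replace(base, ne_current=ne, ne_ancestral=anc)
        vals = []
        design = SampleDesign(haplotypes_per_species=4, n_loci=25,
                              locus_length=100, include_outgroups=False,
                              seed=77)
        for i in range(design.n_loci):
            gt = simulate.simulate_genealogy(dem, design, i)
            vals.append(np.mean([ts.gsi(gt, sp) for sp in "CPAS"]))
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]


def test_top_coverage_subsampling_keeps_best_individuals():
    gt = _two_per_species_tree()
    coverage = {"C_1": 20.0, "C_2": 5.0, "P_1": 8.0, "P_2": 9.0,
                "A_1": 3.0, "A_2": 30.0, "S_1": 7.0, "S_2": 1.0}
    sub = ts.restrict_to_top_coverage(gt, coverage, top_n=1,
                                      outgroups=("O1", "O2"))
    kept = set(sub.leaf_labels)
    assert {"C_1_1", "P_2_1", "A_2_1", "S_1_1"} <= kept
    assert "C_2_1" not in kept and "A_1_1" not in kept
    # outgroup leaves untouched
    assert any(l.startswith("O1") for l in kept)
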