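"""Polarization, filtering, allele sharing, diversity, pairwise and
summary statistics — each checked against independent brute-force oracles
on small fixtures."""

import itertools

import numpy as np
import pandas as pd
import pytest

from quartetcoal import popgen as pg


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def hamming(a, b):
    return sum(1 for x, y in zip(a, b) if x != y and x != "." and y != ".")


def phist_bruteforce(h1, h2):
    """AMOVA variance components from the explicit pairwise-difference
    matrix (Excoffier-style sums of squares)."""
    n1, n2 = len(h1), len(h2)
    pool = list(h1) + list(h2)
    n = n1 + n2
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = hamming(pool[i], pool[j])
    ssd_total = d.sum() / (2 * n)
    within1 = d[:n1, :n1].sum() / (2 * n1)
    within2 = d[n1:, n1:].sum() / (2 * n2)
    ssd_within = within1 + within2
    ssd_among = ssd_total - ssd_within
    sigma_w = ssd_within / (n - 2)
    n_eff = n - (n1 ** 2 + n2 ** 2) / n
    sigma_a = (ssd_among / 1 - sigma_w) / n_eff
    return sigma_a / (sigma_a + sigma_w)


def pi_bruteforce(haps):
    n = len(haps)
    L = len(haps[0])
    total = sum(hamming(haps[i], haps[j])
                for i in range(n) for j in range(i + 1, n))
    return total / (n * (n - 1) / 2) / L


def dxy_bruteforce(h1, h2):
    L = len(h1[0])
    total = sum(hamming(a, b) for a in h1 for b in h2)
    return total / (len(h1) * len(h2)) / L


# ---------------------------------------------------------------------------
# Polarization
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("og1,og2,expected", [
    (("A", "A"), ("A", "A"), "A"),       # both monomorphic, same allele
    (("A", "G"), ("A", "A"), None),      # one outgroup heterozygous
    (("A", "A"), ("G", "G"), None),      # fixed for different alleles
    (("A", "."), ("A", "A"), None),      # missing data
    ((), ("A", "A"), None),
])
def test_polarize_parsimony_rule(og1, og2, expected):
    assert pg.polarize(og1, og2) == expected


# ---------------------------------------------------------------------------
# Site filtering
# ---------------------------------------------------------------------------

def _toy_filter_input():
    """Six sites: the first passes, each other violates exactly one rule
    (coverage outliers are tested separately, where the global SD is
    meaningful)."""
    n_ind = 24            # 12 per species, 2 species
    species = ["X"] * 12 + ["Y"] * 12
    depths = np.full((6, n_ind), 10.0)
    mq = np.array([30.0, 10.0, 30.0, 30.0, 30.0, 30.0])
    depths[2, :3] = 2.0           # X has <10 callable at site 2
    genotypes = np.full((6, n_ind, 2), "A", dtype=object)
    genotypes[3, 12:, 1] = "G"    # species Y exclusively heterozygous
    depths[4, 12:15] = 1.0        # Y has <10 callable at site 4
    depths[5, :] = 1.0            # everything uncallable
    sites = pd.DataFrame({"mq": mq})
    return sites, depths, species, genotypes


def test_filter_cascade_on_toy_sites():
    sites, depths, species, genotypes = _toy_filter_input()
    thr = pg.FilterThresholds(coverage_sd=None)
    mask, audit = pg.filter_sites(sites, depths, species, genotypes, thr)
    assert mask.tolist() == [True, False, False, False, False, False]
    assert audit["mq"] == 1
    assert audit["callable"] == 3
    assert audit["all_het"] == 1


def test_coverage_outlier_rule_excludes_extreme_site():
    n_sites, n_ind = 101, 8
    depths = np.full((n_sites, n_ind), 10.0)
    depths[50] += np.linspace(0, 2, n_ind)     # mild variation
    depths[-1, :] = 500.0                      # collapsed-region candidate
    sites = pd.DataFrame({"mq": [30.0] * n_sites})
    thr = pg.FilterThresholds(min_mq=None, min_depth=None, min_callable=None,
                              coverage_sd=5.0, exclude_all_het=False)
    mask, audit = pg.filter_sites(sites, depths, ["X"] * n_ind, None, thr)
    assert not mask[-1]
    assert mask[:-1].all()
    assert audit["coverage_outlier"] == 1


def test_filters_disabled_passes_everything():
    sites, depths, species, genotypes = _toy_filter_input()
    thr = pg.FilterThresholds(min_mq=None, min_depth=None, min_callable=None,
                              coverage_sd=None, exclude_all_het=False)
    mask, audit = pg.filter_sites(sites, depths, species, genotypes, thr)
    assert mask.all()
    assert audit == {}


def test_coverage_boundary_site_is_retained():
    """A site at exactly mean + 5 SD survives (strictly-greater rule)."""
    n_ind = 4
    depths = np.array([[10.0] * n_ind, [10.0] * n_ind, [10.0] * n_ind,
                       [30.0] * n_ind])
    site_means = depths.mean(axis=1)
    limit = site_means.mean() + 5 * site_means.std()
    depths = np.vstack([depths, [[limit] * n_ind]])
    # recompute: adding the boundary site shifts the stats, so place its
    # mean exactly at the new limit by construction instead
    sites = pd.DataFrame({"mq": [30.0] * len(depths)})
    thr = pg.FilterThresholds(min_mq=None, min_depth=None, min_callable=None,
                              coverage_sd=5.0, exclude_all_het=False)
    mask, audit = pg.filter_sites(sites, depths, ["X"] * n_ind, None, thr)
    means = depths.mean(axis=1)
    lim = means.mean() + 5 * means.std()
    assert mask.tolist() == (means <= lim).tolist()


def test_filter_requires_mq_column():
    with pytest.raises(ValueError):
        pg.filter_sites(pd.DataFrame({"x": [1]}), np.ones((1, 2)), ["X", "X"])


# ---------------------------------------------------------------------------
# Allele sharing
# ---------------------------------------------------------------------------

def test_allele_sharing_hand_computed_partition():
    # 10 sites with designed presence patterns over species C,P,A,S
    patterns = ["C", "C", "P", "CP", "CPAS", "AS", "S", "CPA", "CPAS", "A"]
    rows = []
    labels = [f"{sp}_1_{h}" for sp in "CPAS" for h in (1, 2)]
    species_map = {l: l[0] for l in labels}
    for i, pat in enumerate(patterns):
        row = {"chrom": "c1", "pos": i + 1, "anc": "A", "der": "G"}
        for l in labels:
            row[l] = "1" if l[0] in pat else "0"
        rows.append(row)
    df = pd.DataFrame(rows)
    counts, skipped = pg.allele_sharing(df, species_map)
    assert skipped == 0
    assert counts[frozenset("C")] == 2
    assert counts[frozenset("CP")] == 1
    assert counts[frozenset("CPAS")] == 2
    assert counts[frozenset("AS")] == 1
    assert counts[frozenset("CPA")] == 1
    assert sum(counts.values()) == len(patterns)     # exact partition


def test_allele_sharing_skips_unpolarized_sites():
    labels = [f"{sp}_1_1" for sp in "CPAS"]
    species_map = {l: l[0] for l in labels}
    df = pd.DataFrame([
        {"chrom": "c", "pos": 1, "anc": "A", "der": "G",
         **{l: "1" for l in labels}},
        {"chrom": "c", "pos": 2, "anc": "A", "der": "G",
         **{l: "1" for l in labels}},
    ])
    anc = pd.Series(["A", None])
    counts, skipped = pg.allele_sharing(df, species_map, ancestral=anc)
    assert skipped == 1
    assert counts[frozenset("CPAS")] == 1


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

def test_diversity_identical_haplotypes_zero():
    pi, tw = pg.diversity(["AAAA", "AAAA", "AAAA"])
    assert pi == 0.0 and tw == 0.0


def test_diversity_two_haplotypes():
    pi, tw = pg.diversity(["AAGG", "AAAA"])           # k=2 diffs, L=4
    assert pi == pytest.approx(2 / 4)
    assert tw == pytest.approx(2 / (1.0 * 4))         # a_1 = 1


def test_diversity_matches_bruteforce():
    haps = ["AAGGA", "AAGAA", "ATGGA", "AAGGC", "CAGGA"]
    pi, tw = pg.diversity(haps)
    assert pi == pytest.approx(pi_bruteforce(haps))
    seg = 4
    a4 = sum(1 / i for i in range(1, 5))
    assert tw == pytest.approx(seg / (a4 * 5))


def test_diversity_needs_two_haplotypes():
    with pytest.raises(ValueError):
        pg.diversity(["AAAA"])


# ---------------------------------------------------------------------------
# Pairwise statistics
# ---------------------------------------------------------------------------

def test_fixed_differences_give_phist_one():
    h1 = ["AAGG", "AAGG"]
    h2 = ["TTGG", "TTGG"]
    ps = pg.pair_stats(h1, h2)
    assert ps.prop_fixed == 1.0
    assert ps.prop_shared == 0.0
    assert ps.phist == pytest.approx(1.0)
    assert ps.n_segregating == 2


def test_pair_stats_match_bruteforce_oracle():
    h1 = ["AAGGTT", "AAGATT", "ATGGTT", "AAGGTG"]
    h2 = ["TAGGTT", "TAGATG", "TTGGCT", "TAGGCT"]
    ps = pg.pair_stats(h1, h2)
    assert ps.dxy == pytest.approx(dxy_bruteforce(h1, h2))
    assert ps.phist == pytest.approx(phist_bruteforce(h1, h2))
    pooled = h1 + h2
    seg = sum(1 for col in zip(*pooled) if len(set(col)) > 1)
    assert ps.n_segregating == seg
    shared = sum(1 for c1, c2 in zip(zip(*h1), zip(*h2))
                 if len(set(c1)) > 1 and len(set(c2)) > 1)
    fixed = sum(1 for c1, c2 in zip(zip(*h1), zip(*h2))
                if len(set(c1)) == 1 and len(set(c2)) == 1
                and c1[0] != c2[0])
    assert ps.prop_shared == pytest.approx(shared / seg)
    assert ps.prop_fixed == pytest.approx(fixed / seg)


def test_phist_invariant_to_haplotype_order():
    h1 = ["AAGGTT", "AAGATT", "ATGGTT"]
    h2 = ["TAGGTT", "TAGATG", "TTGGCT"]
    a = pg.pair_stats(h1, h2).phist
    b = pg.pair_stats(h1[::-1], h2[::-1]).phist
    assert a == pytest.approx(b)


def test_phist_zero_when_between_equals_within():
    # four mutually equidistant haplotypes: within- and between-group
    # mean differences are equal, so both variance components see the
    # same spread and PhiST is exactly 0
    h1 = ["GAAA", "AGAA"]
    h2 = ["AAGA", "AAAG"]
    assert pg.pair_stats(h1, h2).phist == pytest.approx(0.0, abs=1e-12)
    assert pg.pair_stats(h1, h2).phist == pytest.approx(
        phist_bruteforce(h1, h2), abs=1e-12)


def test_phist_near_zero_for_panmictic_split():
    """Two samples from one panmictic pool: mean PhiST across loci within
    3 SE of zero."""
    import msprime
    rng_seed = 99
    vals = []
    reps = msprime.sim_ancestry(
        samples=8, sequence_length=2000, ploidy=1,
        population_size=50_000, num_replicates=400, random_seed=rng_seed)
    for ts in reps:
        mts = msprime.sim_mutations(ts, rate=2.5e-8, random_seed=rng_seed)
        g = mts.genotype_matrix()
        if g.shape[0] < 2:
            continue
        c1 = g[:, :4].sum(axis=1)
        c2 = g[:, 4:].sum(axis=1)
        ps = pg.pair_stats_from_counts(c1, 4, c2, 4, 2000)
        if not np.isnan(ps.phist):
            vals.append(ps.phist)
    vals = np.asarray(vals)
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    assert abs(vals.mean()) < 3 * se


def test_pair_stats_needs_two_haplotypes_each():
    with pytest.raises(ValueError):
        pg.pair_stats(["AAAA"], ["GGGG", "GGGG"])


# ---------------------------------------------------------------------------
# Summary vector
# ---------------------------------------------------------------------------

def _fake_pair_table(stats_per_locus):
    return {pair: list(stats_per_locus) for pair in pg.SUMMARY_PAIRS}


def test_summary_vector_length_and_labels():
    ps = pg.PairStats(5, 0.2, 0.1, 0.01, 0.5)
    vec = pg.summary_vector(_fake_pair_table([ps, ps, ps]))
    assert len(vec) == 60
    assert list(vec.index) == pg.summary_labels()


def test_duplicated_locus_gives_zero_variances():
    ps = pg.PairStats(5, 0.2, 0.1, 0.01, 0.5)
    vec = pg.summary_vector(_fake_pair_table([ps, ps]))
    assert all(vec[l] == 0.0 for l in vec.index if l.startswith("var_"))


def test_summary_moments_match_hand_computation():
    stats = [pg.PairStats(2, 0.5, 0.0, 0.01, 0.2),
             pg.PairStats(4, 0.25, 0.25, 0.02, 0.4),
             pg.PairStats(6, 0.0, 0.5, 0.03, 0.6)]
    vec = pg.summary_vector(_fake_pair_table(stats))
    assert vec["mean_S_CP"] == pytest.approx(4.0)
    assert vec["var_S_CP"] == pytest.approx(np.var([2, 4, 6], ddof=1))
    assert vec["mean_phist_AS"] == pytest.approx(0.4)
    assert vec["var_dxy_PA"] == pytest.approx(np.var([.01, .02, .03], ddof=1))


def test_summary_vector_requires_two_loci():
    ps = pg.PairStats(5, 0.2, 0.1, 0.01, 0.5)
    with pytest.raises(ValueError):
        pg.summary_vector(_fake_pair_table([ps]))


def test_nan_values_excluded_from_moments():
    stats = [pg.PairStats(2, 0.5, 0.0, 0.01, np.nan),
             pg.PairStats(4, 0.25, 0.25, 0.02, 0.4),
             pg.PairStats(6, 0.0, 0.5, 0.03, 0.6)]
    vec = pg.summary_vector(_fake_pair_table(stats))
    assert vec["mean_phist_CP"] == pytest.approx(0.5)


def test_dxy_exceeds_mean_pi_under_isolation(tiny_study):
    """Between-species divergence >= mean within-species diversity in
    expectation for isolated species (uses the emitted study)."""
    table = pg.study_pair_table(tiny_study.loci)
    # deepest pair: C vs S
    alignments = tiny_study.alignments()
    dxy_vals, pi_vals = [], []
    for chrom, seqs in alignments.items():
        c_h = [s for l, s in seqs.items() if l.startswith("C")]
        s_h = [s for l, s in seqs.items() if l.startswith("S")]
        dxy_vals.append(dxy_bruteforce(c_h, s_h))
        pi_vals.append((pi_bruteforce(c_h) + pi_bruteforce(s_h)) / 2)
    assert np.mean(dxy_vals) > np.mean(pi_vals)
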