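"""Variant-level population-genetic computations.

Covers outgroup-parsimony polarization, site filtering with an audit
trail, the 15-cell shared-derived-allele partition, within-species
diversity (pi, Watterson's theta), pairwise statistics (segregating sites,
shared/fixed polymorphism, dXY, PhiST) and the 60-element summary-statistic
vector used by the likelihood-free model-selection stage.

PhiST is the AMOVA fixation index computed from pairwise haplotype sequence
differences (haploid units).  A site enters a pairwise statistic only if
callable in at least two haplotypes per species.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "polarize", "polarize_table", "FilterThresholds", "filter_sites",
    "allele_sharing", "diversity", "PairStats", "pair_stats",
    "pair_stats_from_counts", "SUMMARY_PAIRS", "SUMMARY_STATS",
    "summary_labels", "summary_vector", "study_pair_table",
]

MISSING = "."


# ---------------------------------------------------------------------------
# Polarization
# ---------------------------------------------------------------------------

def polarize(outgroup1, outgroup2):
    """Parsimony ancestral state from two outgroup genotypes.

    Each argument is the collection of called alleles of one outgroup
    individual (e.g. ``("A", "A")``).  Returns the ancestral allele iff
    both outgroups are fully called and monomorphic for the same allele;
    otherwise ``None`` (undetermined: missing data, a polymorphic
    outgroup, or outgroups fixed for different alleles).
    """
    sets = []
    for og in (outgroup1, outgroup2):
        alleles = [a for a in og]
        if not alleles or any(a == MISSING or a is None for a in alleles):
            return None
        u = set(alleles)
        if len(u) != 1:
            return None
        sets.append(u.pop())
    return sets[0] if sets[0] == sets[1] else None


def polarize_table(variants: pd.DataFrame, species_map: dict,
                   outgroups=("O1", "O2")) -> pd.Series:
    """Ancestral allele per site of a variant table (``None`` when
    undetermined).  Undetermined sites are to be treated as missing in all
    individuals by downstream consumers.

    The table codes haplotype states 0/1/. with explicit ``anc``/``der``
    allele columns; outgroup haplotype states are decoded to alleles before
    applying the two-outgroup parsimony rule.
    """
    og_names = sorted({sp for sp in set(species_map.values()) if sp in outgroups})
    og_cols = {og: [c for c in variants.columns
                    if c in species_map and species_map[c] == og]
               for og in og_names}
    if len(og_names) != 2 or any(not cols for cols in og_cols.values()):
        raise ValueError("polarize_table needs haplotypes from two outgroups")

    def decode(row, cols):
        out = []
        for c in cols:
            v = str(row[c])
            out.append(MISSING if v == MISSING
                       else (row["anc"] if v == "0" else row["der"]))
        return out

    result = []
    for _, row in variants.iterrows():
        result.append(polarize(decode(row, og_cols[og_names[0]]),
                               decode(row, og_cols[og_names[1]])))
    return pd.Series(result, index=variants.index, name="ancestral")


# ---------------------------------------------------------------------------
# Site filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterThresholds:
    """Site/genotype filters; any rule is disabled by setting it to None.

    Defaults: site RMS mapping quality >= 20, per-individual depth >= 5x,
    >= 10 callable individuals per species, exclusion of sites with mean
    coverage strictly greater than (dataset mean + 5 SD), and exclusion of
    sites where any species' called genotypes are exclusively heterozygous.
    """

    min_mq: float | None = 20.0
    min_depth: float | None = 5.0
    min_callable: int | None = 10
    coverage_sd: float | None = 5.0
    exclude_all_het: bool = True


def filter_sites(sites: pd.DataFrame, depths: np.ndarray,
                 individual_species: list,
                 genotypes: np.ndarray | None = None,
                 thresholds: FilterThresholds = FilterThresholds()):
    """Apply the documented filter cascade; returns (mask, audit counts).

    ``sites`` needs an ``mq`` column; ``depths`` is (n_sites,
    n_individuals); ``genotypes`` (needed for the all-heterozygous rule) is
    (n_sites, n_individuals, 2) allele codes.  Rules are applied in order
    mq -> depth/callable -> coverage outlier -> all-heterozygous, each rule
    counting the sites it alone would remove.
    """
    if "mq" not in sites.columns:
        raise ValueError("sites table must have an 'mq' column")
    n_sites = len(sites)
    depths = np.asarray(depths, dtype=float)
    species = np.asarray(individual_species)
    audit = {}
    mask = np.ones(n_sites, dtype=bool)

    if thresholds.min_mq is not None:
        ok = sites["mq"].to_numpy() >= thresholds.min_mq
        audit["mq"] = int((~ok).sum())
        mask &= ok

    callable_ = np.ones_like(depths, dtype=bool)
    if thresholds.min_depth is not None:
        callable_ = depths >= thresholds.min_depth
    if thresholds.min_callable is not None:
        ok = np.ones(n_sites, dtype=bool)
        for sp in np.unique(species):
            ok &= callable_[:, species == sp].sum(axis=1) >= thresholds.min_callable
        audit["callable"] = int((~ok).sum())
        mask &= ok

    if thresholds.coverage_sd is not None:
        site_mean = depths.mean(axis=1)
        # global SD estimated once per dataset; strictly-greater exclusion
        limit = site_mean.mean() + thresholds.coverage_sd * site_mean.std()
        ok = site_mean <= limit
        audit["coverage_outlier"] = int((~ok).sum())
        mask &= ok

    if thresholds.exclude_all_het and genotypes is not None:
        g = np.asarray(genotypes)
        het = g[:, :, 0] != g[:, :, 1]
        called = (g[:, :, 0] != MISSING) & (g[:, :, 1] != MISSING)
        ok = np.ones(n_sites, dtype=bool)
        for sp in np.unique(species):
            idx = species == sp
            n_called = (called[:, idx]).sum(axis=1)
            n_het = (het[:, idx] & called[:, idx]).sum(axis=1)
            ok &= ~((n_called > 0) & (n_het == n_called))
        audit["all_het"] = int((~ok).sum())
        mask &= ok

    return mask, audit


# ---------------------------------------------------------------------------
# Allele sharing
# ---------------------------------------------------------------------------

def allele_sharing(variants: pd.DataFrame, species_map: dict,
                   species=("C", "P", "A", "S"),
                   ancestral: pd.Series | None = None):
    """15-cell partition of polarized SNPs by derived-allele presence.

    A species is counted as carrying the derived allele when >= 1 of its
    haplotypes does.  Sites with undetermined ancestral state (when
    ``ancestral`` is given) are skipped and counted.  Returns
    ``(counts: {frozenset: int}, n_skipped)``.
    """
    cols = {sp: [c for c in variants.columns
                 if c in species_map and species_map[c] == sp]
            for sp in species}
    presence = {}
    for sp in species:
        sub = variants[cols[sp]].to_numpy().astype(str)
        presence[sp] = (sub == "1").any(axis=1)
    keep = np.ones(len(variants), dtype=bool)
    n_skipped = 0
    if ancestral is not None:
        keep = ancestral.notna().to_numpy()
        n_skipped = int((~keep).sum())
    counts = {frozenset(c): 0
              for r in range(1, len(species) + 1)
              for c in itertools.combinations(species, r)}
    any_present = np.zeros(len(variants), dtype=bool)
    stacked = np.stack([presence[sp] for sp in species], axis=1)
    any_present = stacked.any(axis=1)
    for i in np.nonzero(keep & any_present)[0]:
        cell = frozenset(sp for j, sp in enumerate(species) if stacked[i, j])
        counts[cell] += 1
    return counts, n_skipped


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

def _harmonic(n: int) -> float:
    return float(sum(1.0 / i for i in range(1, n)))


def diversity(haplotypes, length: int | None = None):
    """Nucleotide diversity pi and Watterson's theta per base pair.

    ``haplotypes`` is a list of equal-length sequence strings or a
    (n, L) array of states; ``length`` defaults to the sequence length
    (callable sites).  Needs >= 2 haplotypes.
    """
    arr = np.asarray([list(h) for h in haplotypes]) \
        if isinstance(haplotypes[0], str) else np.asarray(haplotypes)
    n, L = arr.shape
    if n < 2:
        raise ValueError("diversity needs >= 2 haplotypes")
    if length is None:
        length = L
    seg = 0
    pi_sum = 0.0
    for col in range(L):
        alleles, counts = np.unique(arr[:, col], return_counts=True)
        keep = alleles != MISSING
        alleles, counts = alleles[keep], counts[keep]
        m = counts.sum()
        if m < 2 or len(alleles) < 2:
            continue
        seg += 1
        pi_sum += 1.0 - float((counts * (counts - 1)).sum()) / (m * (m - 1))
    return pi_sum / length, seg / (_harmonic(n) * length)


# ---------------------------------------------------------------------------
# Pairwise statistics
# ---------------------------------------------------------------------------

@dataclass
class PairStats:
    """Per-locus statistics for one species pair."""

    n_segregating: int
    prop_shared: float
    prop_fixed: float
    dxy: float
    phist: float

    def as_tuple(self):
        return (self.n_segregating, self.prop_shared, self.prop_fixed,
                self.dxy, self.phist)


def _phist_from_sums(w1, w2, b, n1, n2):
    """AMOVA PhiST from summed pairwise differences within (w1, w2, over
    unordered pairs) and between (b, over n1*n2 pairs)."""
    n = n1 + n2
    ssd_total = (w1 + w2 + b) / n
    ssd_within = w1 / n1 + w2 / n2
    ssd_among = ssd_total - ssd_within
    df_within = n - 2
    if df_within <= 0:
        return np.nan
    sigma_within = ssd_within / df_within
    n_eff = (n - (n1 ** 2 + n2 ** 2) / n)  # / (P-1) with P=2
    sigma_among = (ssd_among - sigma_within) / n_eff
    denom = sigma_among + sigma_within
    if denom == 0:
        return 0.0
    return float(sigma_among / denom)


def pair_stats_from_counts(c1, m1, c2, m2, length: int) -> PairStats:
    """Pairwise statistics from per-site derived counts.

    ``c1``/``c2`` are derived-allele counts and ``m1``/``m2`` called-
    haplotype counts per site for the two species; sites callable in < 2
    haplotypes of either species are excluded.
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    m1 = np.broadcast_to(np.asarray(m1, dtype=float), c1.shape)
    m2 = np.broadcast_to(np.asarray(m2, dtype=float), c2.shape)
    ok = (m1 >= 2) & (m2 >= 2)
    c1, c2, m1, m2 = c1[ok], c2[ok], m1[ok], m2[ok]
    poly1 = (c1 > 0) & (c1 < m1)
    poly2 = (c2 > 0) & (c2 < m2)
    fixed_diff = ((c1 == 0) & (c2 == m2)) | ((c1 == m1) & (c2 == 0))
    pooled_poly = ~(((c1 == 0) & (c2 == 0)) | ((c1 == m1) & (c2 == m2)))
    S = int(pooled_poly.sum())
    shared = int((poly1 & poly2).sum())
    fixed = int(fixed_diff.sum())
    between = c1 * (m2 - c2) + c2 * (m1 - c1)
    dxy = float(np.sum(between / (m1 * m2))) / length
    # PhiST needs equal sample sizes across sites; use the modal counts
    n1 = int(np.median(m1)) if len(m1) else 0
    n2 = int(np.median(m2)) if len(m2) else 0
    if n1 >= 2 and n2 >= 2 and len(c1):
        use = (m1 == n1) & (m2 == n2)
        w1 = float(np.sum(c1[use] * (n1 - c1[use])))
        w2 = float(np.sum(c2[use] * (n2 - c2[use])))
        b = float(np.sum(c1[use] * (n2 - c2[use]) + c2[use] * (n1 - c1[use])))
        phist = _phist_from_sums(w1, w2, b, n1, n2)
    else:
        phist = np.nan
    return PairStats(n_segregating=S,
                     prop_shared=shared / S if S else np.nan,
                     prop_fixed=fixed / S if S else np.nan,
                     dxy=dxy, phist=phist)


def pair_stats(haplotypes1, haplotypes2, length: int | None = None) -> PairStats:
    """Pairwise statistics from two species' haplotype sequences.

    Sequences are equal-length strings (or state arrays); ``.`` marks
    missing data.  Statistics follow the pooled-S normalization for
    shared/fixed proportions.
    """
    a1 = np.asarray([list(h) for h in haplotypes1]) \
        if isinstance(haplotypes1[0], str) else np.asarray(haplotypes1)
    a2 = np.asarray([list(h) for h in haplotypes2]) \
        if isinstance(haplotypes2[0], str) else np.asarray(haplotypes2)
    if a1.shape[0] < 2 or a2.shape[0] < 2:
        raise ValueError("pair_stats needs >= 2 haplotypes per species")
    L = a1.shape[1]
    if length is None:
        length = L
    pooled = np.vstack([a1, a2])
    c1 = np.zeros(L)
    c2 = np.zeros(L)
    m1 = np.zeros(L)
    m2 = np.zeros(L)
    for col in range(L):
        col_states = pooled[:, col]
        alleles = np.unique(col_states[col_states != MISSING])
        if len(alleles) == 0:
            continue
        if len(alleles) > 2:
            raise ValueError("pair_stats assumes biallelic sites")
        ref = alleles[0]
        alt = alleles[1] if len(alleles) == 2 else None
        s1, s2 = a1[:, col], a2[:, col]
        m1[col] = (s1 != MISSING).sum()
        m2[col] = (s2 != MISSING).sum()
        if alt is not None:
            c1[col] = (s1 == alt).sum()
            c2[col] = (s2 == alt).sum()
    return pair_stats_from_counts(c1, m1, c2, m2, length)


# ---------------------------------------------------------------------------
# Summary-statistic vector
# ---------------------------------------------------------------------------

SUMMARY_PAIRS = (("C", "P"), ("C", "A"), ("C", "S"),
                 ("P", "A"), ("P", "S"), ("A", "S"))
SUMMARY_STATS = ("S", "shared", "fixed", "dxy", "phist")


def summary_labels(pairs=SUMMARY_PAIRS):
    """The fixed, documented label order of the 60-element vector."""
    labels = []
    for a, b in pairs:
        for stat in SUMMARY_STATS:
            for moment in ("mean", "var"):
                labels.append(f"{moment}_{stat}_{a}{b}")
    return labels


def summary_vector(per_locus: dict) -> pd.Series:
    """Mean and variance over loci of the five pairwise statistics for the
    six species pairs: a labeled 60-element vector.

    ``per_locus`` maps a species pair tuple to a list of
    :class:`PairStats` (>= 2 loci).  Missing per-locus values are excluded
    from the moments; variance is the ddof=1 sample variance.
    """
    values = {}
    for a, b in SUMMARY_PAIRS:
        stats = per_locus.get((a, b)) or per_locus.get((b, a))
        if stats is None:
            raise KeyError(f"missing pair ({a},{b})")
        if len(stats) < 2:
            raise ValueError("summary_vector needs >= 2 loci")
        arr = np.array([ps.as_tuple() for ps in stats], dtype=float)
        for j, stat in enumerate(SUMMARY_STATS):
            col = arr[:, j]
            col = col[~np.isnan(col)]
            if len(col) == 0:
                mean = var = np.nan
            else:
                mean = float(col.mean())
                var = float(col.var(ddof=1)) if len(col) > 1 else 0.0
            values[f"mean_{stat}_{a}{b}"] = mean
            values[f"var_{stat}_{a}{b}"] = var
    return pd.Series([values[l] for l in summary_labels()],
                     index=summary_labels(), name="summary")


def study_pair_table(loci, species=("C", "P", "A", "S")) -> dict:
    """Per-locus :class:`PairStats` for all six pairs of a simulated study.

    ``loci`` is a list of :class:`~quartetcoal.simulate.LocusVariants`;
    derived counts are read off the 0/1 genotype matrices directly.
    """
    out = {pair: [] for pair in SUMMARY_PAIRS}
    idx = None
    idx_key = None
    for lv in loci:
        g = lv.genotypes
        if g.dtype == object:
            called = g != MISSING
            gnum = np.where(called, g, 0).astype(np.int64)
        else:
            called = np.ones_like(g, dtype=bool)
            gnum = g.astype(np.int64)
        if idx is None or idx_key != tuple(lv.species):
            idx = {sp: [i for i, s in enumerate(lv.species) if s == sp]
                   for sp in species}
            idx_key = tuple(lv.species)
        length = None
        for a, b in SUMMARY_PAIRS:
            ia, ib = idx[a], idx[b]
            c1 = gnum[:, ia].sum(axis=1)
            m1 = called[:, ia].sum(axis=1)
            c2 = gnum[:, ib].sum(axis=1)
            m2 = called[:, ib].sum(axis=1)
            out[(a, b)].append(pair_stats_from_counts(
                c1, m1, c2, m2, length or _locus_length(lv)))
    return out


def _locus_length(lv) -> int:
    # locus length is not stored on LocusVariants; infer from max position
    return int(getattr(lv, "length", 0)) or int(max(lv.positions, default=1))
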