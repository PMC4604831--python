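"""Joint site-frequency-spectrum construction and simulation-based
composite-likelihood demographic model comparison.

The observed data are six pairwise 2D-SFS (one per species pair) of
derived-allele counts projected to a fixed number of chromosomes per
species, with monomorphic cells included.  For a candidate demography the
expected per-site configuration probabilities are obtained by simulating
genealogies: the branch length subtending exactly (i, j) sampled tips,
relative to total genealogy length, averaged over genealogies, scaled by
the per-site mutation probability mu * E[T_total]; the remainder goes to
the (0, 0) cell.  Polarization against outgroup lineages is modeled
explicitly, so shared-derived "fixed" cells and mispolarization are part
of the expectation.

Model comparison uses AIC differences and Akaike weights across the four
candidate species-tree topologies; confidence intervals come from
re-subsampling the window pool.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import msprime
from scipy.stats import hypergeom, qmc

from .demography import (Demography, PARAM_NAMES, PARAM_PRIORS,
                         CANDIDATE_TOPOLOGIES, demography_from_params, SPECIES)

__all__ = [
    "Sfs2D", "build_sfs", "observed_sfs_from_loci", "expected_sfs",
    "expected_sfs_all_pairs", "composite_loglik", "ModelFit", "fit_model",
    "compare_models", "block_resample_ci", "sample_observed_sfs",
    "PAIRS",
]

PAIRS = tuple(itertools.combinations(SPECIES, 2))
PROB_FLOOR = 1e-12


@dataclass
class Sfs2D:
    """Joint derived-allele spectrum for one species pair.

    ``matrix[i, j]`` counts sites with i derived copies in ``pair[0]`` (of
    n1 sampled chromosomes) and j in ``pair[1]``; the (0, 0) cell holds
    monomorphic-ancestral sites so that the matrix sums to ``total_sites``.
    """

    pair: tuple
    n1: int
    n2: int
    matrix: np.ndarray
    total_sites: float

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.n1 + 1, self.n2 + 1):
            raise ValueError("SFS matrix shape must be (n1+1, n2+1)")

    @property
    def polymorphic_sites(self) -> float:
        m = self.matrix.copy()
        m[0, 0] = 0.0
        return float(m.sum())


def _projection_weights(count, size, project_to):
    """Hypergeometric projection of (count derived / size chromosomes) to
    ``project_to`` chromosomes: expected mass per derived count."""
    i = np.arange(project_to + 1)
    return hypergeom.pmf(i, size, count, project_to)


def build_sfs(variants, species_map: dict, pair, project_to: int = 24,
              ancestral=None, total_sites: float | None = None,
              species=SPECIES) -> Sfs2D:
    """Observed 2D-SFS from a polarized variant table.

    A site enters only if all four focal species have >= ``project_to``
    callable chromosomes (sites failing in one species are dropped in
    all); counts are projected to ``project_to`` by hypergeometric
    expectation.  ``total_sites`` (sites scanned, callable monomorphic
    included) fills the (0, 0) cell; it defaults to the polymorphic count
    (pure-shape spectrum).
    """
    a, b = pair
    if a not in species or b not in species:
        raise KeyError(f"pair {pair!r} not in dataset species {species!r}")
    cols = {sp: [c for c in variants.columns
                 if c in species_map and species_map[c] == sp]
            for sp in species}
    n = project_to
    matrix = np.zeros((n + 1, n + 1))
    used = 0
    keep = np.ones(len(variants), dtype=bool) if ancestral is None \
        else ancestral.notna().to_numpy()
    states = {sp: variants[cols[sp]].to_numpy().astype(str) for sp in species}
    called = {sp: states[sp] != "." for sp in species}
    derived = {sp: states[sp] == "1" for sp in species}
    m_all = np.stack([called[sp].sum(axis=1) for sp in species], axis=1)
    enough = (m_all >= n).all(axis=1) & keep
    ca = derived[a].sum(axis=1)
    cb = derived[b].sum(axis=1)
    ma = called[a].sum(axis=1)
    mb = called[b].sum(axis=1)
    for i in np.nonzero(enough)[0]:
        wa = _projection_weights(int(ca[i]), int(ma[i]), n)
        wb = _projection_weights(int(cb[i]), int(mb[i]), n)
        matrix += np.outer(wa, wb)
        used += 1
    if total_sites is not None:
        if total_sites < used:
            raise ValueError("total_sites smaller than polymorphic sites used")
        matrix[0, 0] += total_sites - used
    return Sfs2D(pair=(a, b), n1=n, n2=n, matrix=matrix,
                 total_sites=float(total_sites if total_sites is not None else used))


def select_window_sites(chroms, positions, *, window_bp: int = 100,
                        n_windows: int | None = 100_000,
                        repeat_intervals=None, repeat_threshold: float = 0.2,
                        seed: int = 1) -> np.ndarray:
    """Site mask implementing the window subsampling scheme.

    Sites are grouped into ``window_bp`` windows per chromosome; windows
    whose repeat-masked fraction exceeds ``repeat_threshold`` are
    excluded, and ``n_windows`` of the remainder are sampled without
    replacement (all kept when fewer exist).  ``repeat_intervals`` maps a
    chromosome to 0-based half-open masked intervals.
    """
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=np.int64)
    win = (positions - 1) // window_bp
    keys = np.array([f"{c}:{w}" for c, w in zip(chroms, win)])
    unique = np.unique(keys)
    allowed = []
    for key in unique:
        chrom, w = key.rsplit(":", 1)
        start = int(w) * window_bp
        masked = 0
        for a, b in (repeat_intervals or {}).get(chrom, []):
            masked += max(0, min(b, start + window_bp) - max(a, start))
        if masked / window_bp <= repeat_threshold:
            allowed.append(key)
    rng = np.random.default_rng(seed)
    if n_windows is not None and n_windows < len(allowed):
        chosen = set(rng.choice(allowed, size=n_windows, replace=False))
    else:
        chosen = set(allowed)
    return np.isin(keys, list(chosen))


def observed_sfs_from_loci(loci, project_to: int = 8,
                           species=SPECIES) -> dict:
    """Six observed 2D-SFS straight from simulated loci (0/1 genotypes,
    truth-polarized), with monomorphic cells from the locus lengths."""
    n = project_to
    idx = None
    mats = {pair: np.zeros((n + 1, n + 1)) for pair in PAIRS}
    totals = {pair: 0.0 for pair in PAIRS}
    for lv in loci:
        if idx is None or lv.species is not species:
            idx = {sp: [i for i, s in enumerate(lv.species) if s == sp]
                   for sp in species}
        g = lv.genotypes.astype(np.int64)
        counts = {sp: g[:, idx[sp]].sum(axis=1) for sp in species}
        sizes = {sp: len(idx[sp]) for sp in species}
        for pair in PAIRS:
            a, b = pair
            ca, cb = counts[a], counts[b]
            na, nb = sizes[a], sizes[b]
            poly = ~(((ca == 0) & (cb == 0)) | ((ca == na) & (cb == nb)))
            for s in np.nonzero(poly)[0]:
                wa = _projection_weights(int(ca[s]), na, n)
                wb = _projection_weights(int(cb[s]), nb, n)
                mats[pair] += np.outer(wa, wb)
            mono_anc = int(((ca == 0) & (cb == 0)).sum())
            mats[pair][0, 0] += lv.length - len(ca) + mono_anc
            mats[pair][n, n] += int(((ca == na) & (cb == nb)).sum())
            totals[pair] += lv.length
    return {pair: Sfs2D(pair=pair, n1=n, n2=n, matrix=mats[pair],
                        total_sites=totals[pair]) for pair in PAIRS}


# ---------------------------------------------------------------------------
# Expected SFS by genealogy simulation
# ---------------------------------------------------------------------------

def _pair_expectation_from_afs(afs3, n1, n2):
    """Fold a (n1+1, n2+1, k_og+1) branch-AFS into the polarized pair
    spectrum: outgroup-free branches keep (i, j); branches subtending all
    outgroup lineages flip to (n1-i, n2-j) (mispolarization); branches
    subtending a strict outgroup subset are undetermined (dropped)."""
    k = afs3.shape[2] - 1
    callable_part = afs3[:, :, 0].copy()
    if k >= 1:
        flipped = afs3[::-1, ::-1, k]
        callable_part += flipped
    return callable_part


def expected_sfs_all_pairs(demography: Demography, n_per_species: int,
                           n_sims: int = 1000, seed: int = 1,
                           include_outgroups: bool = True,
                           ratio_of_means: bool = False) -> dict:
    """Expected configuration probabilities for all six pairs at once.

    One set of 4-species genealogies (plus one lineage per outgroup when
    modeling polarization) serves every pair: for a pair, branches
    subtending none or all of its samples and no outgroup are the
    monomorphic background; the remaining branch-length ratios give the
    polymorphic probabilities, scaled by mu * E[T_total].
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    n = n_per_species
    samples = [msprime.SampleSet(n, population=sp, ploidy=1)
               for sp in demography.species]
    og_count = 0
    if include_outgroups and demography.outgroups:
        for og in demography.outgroups:
            samples.append(msprime.SampleSet(1, population=og.name, ploidy=1))
            og_count += 1
    reps = msprime.sim_ancestry(
        samples=samples,
        demography=demography.to_msprime(include_outgroups=og_count > 0),
        ploidy=2, num_replicates=n_sims, random_seed=seed)
    sets = [list(range(n * i, n * (i + 1))) for i in range(4)]
    og_set = list(range(4 * n, 4 * n + og_count))
    sampled_order = list(demography.species)   # msprime sample-set order
    pair_idx = {pair: (sampled_order.index(pair[0]),
                       sampled_order.index(pair[1]))
                for pair in PAIRS}
    ratio_sum = {pair: np.zeros((n + 1, n + 1)) for pair in PAIRS}
    len_sum = {pair: 0.0 for pair in PAIRS}
    raw_sum = {pair: np.zeros((n + 1, n + 1)) for pair in PAIRS}
    for ts in reps:
        for pair in PAIRS:
            ia, ib = pair_idx[pair]
            sample_sets = [sets[ia], sets[ib]] + ([og_set] if og_count else [])
            afs = ts.allele_frequency_spectrum(
                sample_sets=sample_sets, mode="branch", polarised=True,
                span_normalise=False)
            mat = _pair_expectation_from_afs(afs, n, n) if og_count \
                else afs.copy()
            # (0,0) holds branches subtending no pair sample: that mass is
            # monomorphic background for this pair, not polymorphism
            mat[0, 0] = 0.0
            tot = mat.sum()
            if tot > 0:
                ratio_sum[pair] += mat / tot
            raw_sum[pair] += mat
            len_sum[pair] += tot
    out = {}
    mu = demography.mu
    for pair in PAIRS:
        t_mean = len_sum[pair] / n_sims
        if ratio_of_means:
            r = raw_sum[pair] / len_sum[pair]
        else:
            r = ratio_sum[pair] / n_sims
        p = r * mu * t_mean
        p[0, 0] = max(1.0 - p.sum(), PROB_FLOOR)
        out[pair] = p
    return out


def expected_sfs(demography: Demography, pair, n_per_species: int,
                 n_sims: int = 1000, seed: int = 1,
                 include_outgroups: bool = True,
                 ratio_of_means: bool = False) -> np.ndarray:
    """Expected configuration probabilities for one species pair.

    Cells sum to 1; the polymorphic mass is ``mu * E[T_total]`` times the
    mean per-genealogy branch-length ratios (``ratio_of_means`` toggles
    ratio-of-sums instead).
    """
    return expected_sfs_all_pairs(
        demography, n_per_species, n_sims=n_sims, seed=seed,
        include_outgroups=include_outgroups,
        ratio_of_means=ratio_of_means)[tuple(pair)]


def composite_loglik(observed, expectations) -> float:
    """Composite log likelihood: sum over pairs and cells of
    ``count * ln(p)``, with a floor on expectation cells.

    ``observed`` maps pair -> :class:`Sfs2D` (or is a list); zero-count
    cells contribute nothing regardless of p.
    """
    if isinstance(observed, dict):
        items = observed.items()
    else:
        items = [(sfs.pair, sfs) for sfs in observed]
    ll = 0.0
    for pair, sfs in items:
        p = np.maximum(np.asarray(expectations[pair], dtype=float), PROB_FLOOR)
        if p.shape != sfs.matrix.shape:
            raise ValueError(f"expectation shape {p.shape} != observed "
                             f"{sfs.matrix.shape} for pair {pair}")
        counts = sfs.matrix
        ll += float(np.sum(np.where(counts > 0, counts * np.log(p), 0.0)))
    return ll


# ---------------------------------------------------------------------------
# Model fitting and comparison
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """Best composite-likelihood fit of one candidate topology."""

    model: str
    params: dict
    loglik: float
    n_params: int
    aic: float
    trace: list = field(default_factory=list)
    n_runs: int = 1

    @property
    def run_logliks(self):
        return [t[1] for t in self.trace if t[0] == "run"]


def _ordering_ok(topology_id, params):
    if len(CANDIDATE_TOPOLOGIES[topology_id][0]) == 2 and \
            isinstance(CANDIDATE_TOPOLOGIES[topology_id][1], tuple):
        return params["T1"] < params["T3"] and params["T2"] < params["T3"]
    return params["T1"] < params["T2"] < params["T3"]


def _ordering_violation(topology_id, params):
    t1, t2, t3 = params["T1"], params["T2"], params["T3"]
    if len(CANDIDATE_TOPOLOGIES[topology_id][0]) == 2 and \
            isinstance(CANDIDATE_TOPOLOGIES[topology_id][1], tuple):
        return max(0.0, t1 - t3) + max(0.0, t2 - t3)
    return max(0.0, t1 - t2) + max(0.0, t2 - t3)


def sfs_moments(observed: dict) -> tuple:
    """Per-species diversity (pi) and per-pair divergence (dXY) per site,
    read off the six observed 2D-SFS."""
    pis: dict = {}
    dxy: dict = {}
    for pair, sfs in observed.items():
        n1, n2 = sfs.n1, sfs.n2
        M = sfs.matrix
        tot = sfs.total_sites
        i = np.arange(n1 + 1)[:, None]
        j = np.arange(n2 + 1)[None, :]
        dxy[pair] = float((M * (i * (n2 - j) + j * (n1 - i))).sum()
                          / (n1 * n2) / tot)
        pis.setdefault(pair[0], []).append(
            float((M * (2 * i * (n1 - i))).sum() / (n1 * (n1 - 1)) / tot))
        pis.setdefault(pair[1], []).append(
            float((M * (2 * j * (n2 - j))).sum() / (n2 * (n2 - 1)) / tot))
    return {k: float(np.mean(v)) for k, v in pis.items()}, dxy


def moment_start(model_id: str, observed: dict, *, mu: float = 2.5e-9,
                 gen_time: float = 2.0, search_ranges=None,
                 nm_start: float = 0.05) -> dict:
    """Method-of-moments starting point for :func:`fit_model`.

    Current sizes come from Watterson-style per-species diversity
    (``Ne = pi / 4 mu``); split times from the pairwise divergence of the
    clades the candidate topology joins (``T ~ (dXY/2mu - 2 Nbar) x
    gen_time``); ancestral sizes start at the mean current size and
    migration at ``nm_start``.  The same rule is applied to every
    candidate, so fits stay comparable.
    """
    ranges = search_ranges or PARAM_PRIORS
    pis, dxy = sfs_moments(observed)
    box = lambda name, v: float(np.clip(
        v, ranges[name][1] * 1.02, ranges[name][2] * 0.98))
    N = {sp: box(f"N_{sp}", pis[sp] / (4 * mu)) for sp in SPECIES}
    nbar = float(np.mean(list(N.values())))

    def t_from(pairs):
        d = float(np.mean([dxy[p] if p in dxy else dxy[(p[1], p[0])]
                           for p in pairs]))
        return (d / (2 * mu) - 2 * nbar) * gen_time

    topo = CANDIDATE_TOPOLOGIES[model_id]
    symmetric = isinstance(topo[0], tuple) and isinstance(topo[1], tuple)
    if symmetric:
        c1 = sorted(topo[0] if "P" in topo[0] else topo[1])
        c2 = sorted(topo[1] if "P" in topo[0] else topo[0])
        t1 = t_from([tuple(c1)])
        t2 = t_from([tuple(c2)])
        t3 = t_from([(a, b) for a in c1 for b in c2])
    else:
        from .demography import _internal_clades
        clades = sorted((c for c in _internal_clades(topo) if len(c) < 4),
                        key=len)
        cherry = sorted(clades[0])
        third = next(iter(clades[1] - clades[0]))
        outer = next(iter(set(SPECIES) - clades[1]))
        t1 = t_from([tuple(cherry)])
        t2 = t_from([(cherry[0], third), (cherry[1], third)])
        t3 = t_from([(outer, s) for s in clades[1]])
    params = {f"N_{sp}": N[sp] for sp in SPECIES}
    params.update({"N_ANC1": box("N_ANC1", nbar),
                   "N_ANC2": box("N_ANC2", nbar),
                   "N_ROOT": box("N_ROOT", nbar),
                   "T1": box("T1", t1), "T2": box("T2", t2),
                   "T3": box("T3", t3)})
    if symmetric:
        params["T3"] = box("T3", max(params["T3"],
                                     1.1 * max(params["T1"], params["T2"])))
    else:
        params["T2"] = box("T2", max(params["T2"], 1.05 * params["T1"]))
        params["T3"] = box("T3", max(params["T3"], 1.05 * params["T2"]))
    for name in PARAM_NAMES[10:]:
        params[name] = nm_start
    return params


DEFAULT_POLISH = ("N_ANC1", "N_ANC2", "N_ROOT", "T3")


def fit_model(model_id: str, observed: dict, *, search_ranges=None,
              n_runs: int = 1, seed: int = 1, n_sims_search: int = 200,
              n_sims_valid: int = 800, n_sims_final: int = 3000,
              polish_params=DEFAULT_POLISH, n_sweeps: int = 1,
              line_evals: int = 7, rel_tol: float = 0.001,
              gen_time: float = 2.0, mu: float = 2.5e-9,
              include_outgroups: bool = True,
              project_to: int | None = None) -> ModelFit:
    """Maximize the composite likelihood of one candidate topology.

    Derivative-free search with common random numbers: the first run
    starts from the method-of-moments point (:func:`moment_start`), extra
    runs (``n_runs > 1``) from screened Latin-hypercube draws.  Each run
    polishes the listed parameters by bounded 1-D golden-section searches;
    a proposed move is accepted only if it improves an independently
    seeded, higher-precision validation score, which keeps the search from
    chasing Monte-Carlo noise.  Sweeps stop early when the relative
    improvement falls below ``rel_tol``.  Every run is finally re-scored
    with ``n_sims_final`` genealogies under one fixed seed, so fits of
    different models (given the same ``seed``) are directly comparable.
    """
    from scipy.optimize import minimize_scalar
    ranges = search_ranges or PARAM_PRIORS
    for name, (kind, a, b) in ranges.items():
        if a >= b:
            raise ValueError(f"invalid search range for {name}: [{a}, {b}]")
    rng = np.random.default_rng(seed)
    final_seed = int(rng.integers(1, 2 ** 31 - 1))  # shared across models
    any_sfs = next(iter(observed.values()))
    n_proj = project_to or any_sfs.n1

    from .demography import DEFAULT_OUTGROUPS
    og = DEFAULT_OUTGROUPS if include_outgroups else ()

    def score(params, n_sims, sim_seed):
        viol = _ordering_violation(model_id, params)
        if viol > 0:
            return -1e6 * (1.0 + viol / 1e5)
        dem = demography_from_params(model_id, params, gen_time=gen_time,
                                     mu=mu, outgroups=og)
        exps = expected_sfs_all_pairs(
            dem, n_proj, n_sims=n_sims, seed=sim_seed,
            include_outgroups=include_outgroups)
        return composite_loglik(observed, exps)

    def polish(params):
        params = dict(params)
        vseed = int(rng.integers(1, 2 ** 31 - 1))
        best = score(params, n_sims_valid, vseed)
        for _ in range(n_sweeps):
            start = best
            for name in polish_params:
                _, a, b = ranges[name]
                sseed = int(rng.integers(1, 2 ** 31 - 1))

                def neg(v10, _name=name, _seed=sseed):
                    q = dict(params)
                    q[_name] = 10.0 ** v10
                    return -score(q, n_sims_search, _seed)

                res = minimize_scalar(
                    neg, bounds=(np.log10(a), np.log10(b)), method="bounded",
                    options={"maxiter": line_evals, "xatol": 0.02})
                cand = dict(params)
                cand[name] = 10.0 ** float(res.x)
                cand_score = score(cand, n_sims_valid, vseed)
                if cand_score > best:
                    params, best = cand, cand_score
            if best - start <= rel_tol * abs(best):
                break
        return params

    trace = []
    best_params, best_ll = None, -np.inf
    starts = [moment_start(model_id, observed, mu=mu, gen_time=gen_time,
                           search_ranges=ranges)]
    if n_runs > 1:
        sampler = qmc.LatinHypercube(d=len(PARAM_NAMES),
                                     seed=int(rng.integers(2 ** 31)))
        llo = np.log10([ranges[p][1] for p in PARAM_NAMES])
        lhi = np.log10([ranges[p][2] for p in PARAM_NAMES])
        draws = llo + sampler.random(4 * (n_runs - 1)) * (lhi - llo)
        screened = []
        sseed = int(rng.integers(1, 2 ** 31 - 1))
        for x in draws:
            p = dict(zip(PARAM_NAMES, 10.0 ** x))
            screened.append((score(p, n_sims_search, sseed), p))
        screened.sort(key=lambda t: -t[0])
        starts += [p for _, p in screened[:n_runs - 1]]
    for p0 in starts:
        fitted = polish(p0)
        ll = score(fitted, n_sims_final, final_seed)
        trace.append(("run", ll, dict(fitted)))
        if ll > best_ll:
            best_ll, best_params = ll, fitted
    k = len(PARAM_NAMES)
    return ModelFit(model=model_id, params=best_params, loglik=best_ll,
                    n_params=k, aic=2 * k - 2 * best_ll, trace=trace,
                    n_runs=len(starts))


def compare_models(fits) -> "pd.DataFrame":
    """AIC comparison table: ``delta_aic`` relative to the best model and
    Akaike weights ``w = exp(-dAIC/2) / sum``."""
    import pandas as pd
    if len(fits) < 2:
        raise ValueError("need >= 2 fits to compare")
    rows = []
    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    w = w / w.sum()
    for f, d, wi in zip(fits, delta, w):
        rows.append({"model": f.model, "loglik": f.loglik, "aic": f.aic,
                     "delta_aic": float(d), "akaike_weight": float(wi)})
    return pd.DataFrame(rows).sort_values("delta_aic").reset_index(drop=True)


def sample_observed_sfs(demography: Demography, n_per_species: int,
                        n_sites: float, n_sims: int = 3000, seed: int = 7,
                        include_outgroups: bool = True) -> dict:
    """Draw a synthetic observed dataset: multinomial counts of ``n_sites``
    unlinked sites from a high-precision expected SFS under ``demography``
    (the unlinked-sites limit of window subsampling)."""
    rng = np.random.default_rng(seed)
    exps = expected_sfs_all_pairs(
        demography, n_per_species, n_sims=n_sims,
        seed=int(rng.integers(1, 2 ** 31 - 1)),
        include_outgroups=include_outgroups)
    out = {}
    for pair, p in exps.items():
        flat = np.maximum(p.ravel(), 0)
        flat = flat / flat.sum()
        counts = rng.multinomial(int(n_sites), flat).reshape(p.shape)
        out[pair] = Sfs2D(pair=pair, n1=n_per_species, n2=n_per_species,
                          matrix=counts.astype(float), total_sites=float(n_sites))
    return out


def block_resample_ci(window_loci, fit_fn, n_reps: int = 50,
                      sample_size: int | None = None, seed: int = 1,
                      lower: float = 5.0, upper: float = 95.0):
    """Percentile confidence intervals by re-subsampling the window pool.

    ``window_loci`` is the pool (list) of per-window data; each replicate
    samples ``sample_size`` windows without replacement, calls
    ``fit_fn(windows, replicate_seed)`` (returning a parameter dict) and
    the 5th-95th percentile per parameter over replicates is reported.
    """
    if n_reps < 2:
        raise ValueError("need n_reps >= 2")
    pool = list(window_loci)
    k = sample_size or max(1, len(pool) // 2)
    if k > len(pool):
        raise ValueError("sample_size exceeds pool")
    rng = np.random.default_rng(seed)
    results = []
    for rep in range(n_reps):
        idx = rng.choice(len(pool), size=k, replace=False)
        results.append(fit_fn([pool[i] for i in idx],
                              int(rng.integers(1, 2 ** 31 - 1))))
    params = sorted(results[0])
    ci = {}
    for p in params:
        vals = np.array([r[p] for r in results], dtype=float)
        ci[p] = (float(np.percentile(vals, lower)),
                 float(np.percentile(vals, upper)))
    return ci, results
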