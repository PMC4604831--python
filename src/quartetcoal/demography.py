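"""Isolation-with-migration demographies for a four-species complex.

The model family mirrors a four-taxon species tree with per-branch diploid
effective sizes, split times in generations, directional migration expressed
as migrants per generation (Nm) between extant species, and a per-site,
per-generation mutation rate.  Internal computation is always in
generations; years enter only through ``gen_time`` when converting
user-facing split times.

Bundled presets (:func:`flycatcher_demography`, :data:`PARAM_PRIORS`)
describe the black-and-white flycatcher complex (collared C, pied P, Atlas
A, semicollared S) with published point estimates and prior ranges; they
serve as defaults for the synthetic-study generator and the inference
modules.
"""

from __future__ import annotations


from dataclasses import dataclass, field

import msprime

__all__ = [
    "Demography",
    "Outgroup",
    "SampleDesign",
    "InvalidDemographyError",
    "InvalidDesignError",
    "CANDIDATE_TOPOLOGIES",
    "SPECIES",
    "MIGRATION_PAIRS",
    "PARAM_NAMES",
    "PARAM_PRIORS",
    "MLE_PARAMS",
    "ABC_MODE",
    "flycatcher_demography",
    "demography_from_params",
    "topology_newick",
]


class InvalidDemographyError(ValueError):
    """Raised when a demography violates its structural invariants."""


class InvalidDesignError(ValueError):
    """Raised when a sampling design is unusable."""


#: Ingroup species labels, fixed order.
SPECIES = ("C", "P", "A", "S")

#: Directional migration pairs (recipient, donor) with nonzero rates in the
#: bundled model family: C<->P, P<->A, C<->S.
MIGRATION_PAIRS = (
    ("C", "P"), ("P", "C"),
    ("P", "A"), ("A", "P"),
    ("C", "S"), ("S", "C"),
)

#: The four candidate rooted species-tree topologies compared throughout,
#: as nested tuples.  Keys are short ids used by the fitting modules.
CANDIDATE_TOPOLOGIES = {
    "PA_C_S": ((("P", "A"), "C"), "S"),     # asymmetric, (((P,A),C),S)
    "PA_CS": (("P", "A"), ("C", "S")),      # symmetric,  ((P,A),(C,S))
    "CP_A_S": ((("C", "P"), "A"), "S"),     # asymmetric, (((C,P),A),S)
    "PA_S_C": ((("P", "A"), "S"), "C"),     # asymmetric, (((P,A),S),C)
}


def _leaves(node):
    if isinstance(node, str):
        return (node,)
    out = ()
    for child in node:
        out += _leaves(child)
    return out


def _internal_clades(node):
    """Post-order internal clades (as frozensets of species) of a nested tuple."""
    if isinstance(node, str):
        return []
    clades = []
    for child in node:
        clades.extend(_internal_clades(child))
    clades.append(frozenset(_leaves(node)))
    return clades


def topology_newick(topology) -> str:
    """Render a nested-tuple topology as a newick string (no branch lengths)."""
    def render(node):
        if isinstance(node, str):
            return node
        return "(" + ",".join(render(c) for c in node) + ")"
    return render(topology) + ";"


def _clade_name(clade: frozenset) -> str:
    return "anc_" + "".join(sorted(clade))


@dataclass(frozen=True)
class Outgroup:
    """An outgroup species joining the ingroup stem at ``join_time`` generations."""

    name: str
    join_time: float
    ne: float
    n_haplotypes: int = 2


@dataclass(frozen=True)
class Demography:
    """A rooted 4-species isolation-with-migration demography.

    Parameters
    ----------
    topology
        Nested tuple of species labels, e.g. ``((("P","A"),"C"),"S")``.
    ne_current
        Diploid effective size per extant species.
    ne_ancestral
        Diploid effective size per internal branch, keyed by the frozenset
        of descendant species.
    split_times
        Time (generations before present) of each internal node, keyed like
        ``ne_ancestral``.
    migration
        ``(recipient, donor) -> Nm`` migrants per generation; only between
        extant species, active until the pair's divergence.
    mu
        Mutation rate per site per generation.
    gen_time
        Years per generation; used only for converting input/output years.
    outgroups
        Optional outgroups joining the ingroup stem, shallowest first.
    """

    topology: tuple
    ne_current: dict
    ne_ancestral: dict
    split_times: dict
    migration: dict = field(default_factory=dict)
    mu: float = 2.5e-9
    gen_time: float = 2.0
    outgroups: tuple = ()

    def __post_init__(self):
        self.validate()

    @property
    def species(self):
        return _leaves(self.topology)

    @property
    def clades(self):
        return _internal_clades(self.topology)

    def divergence_time(self, a: str, b: str) -> float:
        """Split time (generations) of the most recent clade containing both species."""
        times = [self.split_times[c] for c in self.clades if a in c and b in c]
        if not times:
            raise InvalidDemographyError(f"species {a!r}/{b!r} never share a clade")
        return min(times)

    def validate(self):
        species = self.species
        if len(set(species)) != len(species):
            raise InvalidDemographyError("duplicate species labels in topology")
        for sp in species:
            if sp not in self.ne_current:
                raise InvalidDemographyError(f"missing ne_current for {sp!r}")
        for clade in self.clades:
            if clade not in self.split_times:
                raise InvalidDemographyError(f"missing split time for clade {sorted(clade)}")
            if clade not in self.ne_ancestral:
                raise InvalidDemographyError(f"missing ne_ancestral for clade {sorted(clade)}")
        for name, value in list(self.ne_current.items()) + list(self.ne_ancestral.items()):
            if value <= 0:
                raise InvalidDemographyError(f"Ne must be > 0 (got {value!r} for {name!r})")
        if self.mu <= 0:
            raise InvalidDemographyError("mu must be > 0")
        # split times must strictly increase toward the root along every path
        def check(node):
            if isinstance(node, str):
                return 0.0
            t = self.split_times[frozenset(_leaves(node))]
            for child in node:
                tc = check(child)
                if t <= tc:
                    raise InvalidDemographyError(
                        "split times must strictly increase toward the root")
            return t
        root_t = check(self.topology)
        for recipient, donor in self.migration:
            if recipient not in species or donor not in species:
                raise InvalidDemographyError(
                    f"migration between non-extant species {recipient!r}<-{donor!r}")
            if self.migration[(recipient, donor)] < 0:
                raise InvalidDemographyError("Nm must be >= 0")
        prev = root_t
        for og in self.outgroups:
            if og.join_time <= prev:
                raise InvalidDemographyError(
                    "outgroup join times must exceed the ingroup root and increase")
            prev = og.join_time

    def to_msprime(self, include_outgroups: bool = False) -> msprime.Demography:
        """Translate to an :class:`msprime.Demography`.

        Backward-in-time per-lineage migration rate into *recipient* is
        ``m = Nm / (2 Ne_recipient)``; msprime deactivates migration with a
        population once it merges, which enforces "extant branches only".
        """
        dem = msprime.Demography()
        for sp in self.species:
            dem.add_population(name=sp, initial_size=self.ne_current[sp])
        clades = sorted(self.clades, key=lambda c: self.split_times[c])
        for clade in clades:
            dem.add_population(name=_clade_name(clade),
                               initial_size=self.ne_ancestral[clade])
        for (recipient, donor), nm in self.migration.items():
            if nm > 0:
                dem.set_migration_rate(recipient, donor,
                                       nm / (2.0 * self.ne_current[recipient]))
        # splits: each clade's immediate children
        def children_names(node):
            return [c if isinstance(c, str) else _clade_name(frozenset(_leaves(c)))
                    for c in node]
        def walk(node):
            if isinstance(node, str):
                return
            for child in node:
                walk(child)
            dem.add_population_split(
                time=self.split_times[frozenset(_leaves(node))],
                derived=children_names(node),
                ancestral=_clade_name(frozenset(_leaves(node))))
        walk(self.topology)
        if include_outgroups and self.outgroups:
            current = _clade_name(frozenset(self.species))
            accum = set(self.species)
            for og in self.outgroups:
                dem.add_population(name=og.name, initial_size=og.ne)
                accum.add(og.name)
                anc = "anc_" + "".join(sorted(accum))
                dem.add_population(name=anc, initial_size=og.ne)
                dem.add_population_split(time=og.join_time,
                                         derived=[current, og.name], ancestral=anc)
                current = anc
        dem.sort_events()
        return dem


@dataclass(frozen=True)
class SampleDesign:
    """Sampling design of a synthetic study.

    Defaults follow the sequence-locus design used for likelihood-free
    inference in this system: 2-kb loci, 12 diploid individuals (24
    haplotypes) per species, loci spaced far enough apart to be unlinked.
    """

    haplotypes_per_species: int = 24
    n_loci: int = 2962
    locus_length: int = 2000
    locus_spacing: int = 50_000
    include_outgroups: bool = True
    seed: int = 1

    def __post_init__(self):
        if self.haplotypes_per_species < 2:
            raise InvalidDesignError("need >= 2 haplotypes per ingroup species")
        if self.locus_length < 1:
            raise InvalidDesignError("locus_length must be >= 1")
        if self.n_loci < 1:
            raise InvalidDesignError("n_loci must be >= 1")


# ---------------------------------------------------------------------------
# Flycatcher presets
# ---------------------------------------------------------------------------

#: Fit/prior parameter order used by sfsfit and abcsel (16 parameters).
PARAM_NAMES = (
    "N_C", "N_P", "N_A", "N_S",
    "N_ANC1", "N_ANC2", "N_ROOT",
    "T1", "T2", "T3",
    "Nm_CP", "Nm_PC", "Nm_PA", "Nm_AP", "Nm_CS", "Nm_SC",
)

#: Prior specification per parameter: (kind, low, high).  Times are in years.
PARAM_PRIORS = {
    "N_C": ("log-uniform", 30_000, 1_000_000),
    "N_P": ("log-uniform", 30_000, 1_000_000),
    "N_A": ("log-uniform", 30_000, 1_000_000),
    "N_S": ("log-uniform", 30_000, 1_000_000),
    "N_ANC1": ("log-uniform", 100_000, 3_000_000),
    "N_ANC2": ("log-uniform", 100_000, 3_000_000),
    "N_ROOT": ("log-uniform", 30_000, 1_000_000),
    "T1": ("uniform", 144_000, 720_000),
    "T2": ("uniform", 360_000, 1_080_000),
    "T3": ("uniform", 720_000, 1_800_000),
    "Nm_CP": ("log-uniform", 0.001, 10.0),
    "Nm_PC": ("log-uniform", 0.001, 10.0),
    "Nm_PA": ("log-uniform", 0.001, 10.0),
    "Nm_AP": ("log-uniform", 0.001, 10.0),
    "Nm_CS": ("log-uniform", 0.001, 10.0),
    "Nm_SC": ("log-uniform", 0.001, 10.0),
}

#: Published composite-likelihood point estimates for the preferred topology
#: (times in years; Ne diploid; Nm migrants/generation).
MLE_PARAMS = {
    "N_C": 449_385, "N_P": 304_853, "N_A": 244_520, "N_S": 238_722,
    "N_ANC1": 256_334, "N_ANC2": 1_067_020, "N_ROOT": 304_660,
    "T1": 561_326, "T2": 638_933, "T3": 1_218_623,
    "Nm_CP": 0.538, "Nm_PC": 0.124, "Nm_PA": 0.047,
    "Nm_AP": 0.168, "Nm_CS": 0.156, "Nm_SC": 0.515,
}

#: Published likelihood-free posterior modes for the same topology.
ABC_MODE = {
    "N_C": 365_831, "N_P": 185_836, "N_A": 138_299, "N_S": 108_211,
    "N_ANC1": 1_205_841, "N_ANC2": 648_500, "N_ROOT": 268_974,
    "T1": 392_380, "T2": 577_909, "T3": 1_336_990,
    "Nm_CP": 0.025, "Nm_PC": 0.008, "Nm_PA": 0.006,
    "Nm_AP": 0.016, "Nm_CS": 0.004, "Nm_SC": 0.340,
}


def prior_midpoints() -> dict:
    """Midpoint of each prior (geometric for log-uniform, arithmetic else)."""
    out = {}
    for name, (kind, lo, hi) in PARAM_PRIORS.items():
        out[name] = (lo * hi) ** 0.5 if kind == "log-uniform" else 0.5 * (lo + hi)
    return out


DEFAULT_OUTGROUPS = (
    # Synthetic stand-ins for the two outgroup taxa used for polarization;
    # join times (generations; ~5 and ~7 My at 2 yr/gen) and Ne are package
    # defaults, not published values.  Joins deep enough that residual
    # ingroup lineages have essentially always coalesced below them keep
    # deep-ILS mispolarization rare.
    Outgroup(name="O1", join_time=2_500_000, ne=500_000, n_haplotypes=2),
    Outgroup(name="O2", join_time=3_500_000, ne=500_000, n_haplotypes=2),
)


def demography_from_params(topology_id: str, params: dict, *,
                           gen_time: float = 2.0, mu: float = 2.5e-9,
                           outgroups: tuple = DEFAULT_OUTGROUPS) -> Demography:
    """Build a :class:`Demography` from the 16-parameter schema.

    ``params`` carries times in YEARS (as the priors and published tables
    do); they are converted to generations with ``gen_time``.  For the
    asymmetric topologies ``T1 < T2 < T3`` are cherry, three-species and
    root splits, with ``N_ANC1``/``N_ANC2``/``N_ROOT`` the corresponding
    ancestral sizes.  For the symmetric topology ``T1``/``T2`` are the two
    cherry splits (N_ANC1/N_ANC2) and ``T3`` the root.
    """
    topology = CANDIDATE_TOPOLOGIES[topology_id]
    clades = _internal_clades(topology)  # post-order: inner before root
    # order clades by size then by containment for parameter assignment
    inner = sorted((c for c in clades if len(c) < 4), key=len)
    root = next(c for c in clades if len(c) == 4)
    t = {name: params[name] / gen_time for name in ("T1", "T2", "T3")}
    split_times = {}
    ne_anc = {}
    if len(inner[0]) == 2 and len(inner[1]) == 2:       # symmetric
        # assign cherries deterministically: the one containing "P" gets T1
        first = inner[0] if "P" in inner[0] else inner[1]
        second = inner[1] if first is inner[0] else inner[0]
        split_times[first], ne_anc[first] = t["T1"], params["N_ANC1"]
        split_times[second], ne_anc[second] = t["T2"], params["N_ANC2"]
    else:                                               # caterpillar
        split_times[inner[0]], ne_anc[inner[0]] = t["T1"], params["N_ANC1"]
        split_times[inner[1]], ne_anc[inner[1]] = t["T2"], params["N_ANC2"]
    split_times[root], ne_anc[root] = t["T3"], params["N_ROOT"]
    migration = {pair: params[f"Nm_{pair[0]}{pair[1]}"] for pair in MIGRATION_PAIRS}
    return Demography(
        topology=topology,
        ne_current={sp: params[f"N_{sp}"] for sp in SPECIES},
        ne_ancestral=ne_anc,
        split_times=split_times,
        migration=migration,
        mu=mu,
        gen_time=gen_time,
        outgroups=outgroups,
    )


def flycatcher_demography(topology_id: str = "PA_C_S", values: str = "mle", *,
                          gen_time: float = 2.0,
                          outgroups: tuple = DEFAULT_OUTGROUPS) -> Demography:
    """Preset demography for the flycatcher complex.

    ``values`` is ``"mle"`` (composite-likelihood point estimates),
    ``"abc_mode"`` (likelihood-free posterior modes) or ``"prior_mid"``
    (prior midpoints, the default fixture demography).
    """
    params = {"mle": MLE_PARAMS, "abc_mode": ABC_MODE,
              "prior_mid": prior_midpoints()}[values]
    return demography_from_params(topology_id, params, gen_time=gen_time,
                                  outgroups=outgroups)
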