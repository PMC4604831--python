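"""End-to-end orchestration of the synthetic-study replay.

Stages run in dependency order (simulate -> popgen -> treestats/mscmodel
-> sfsfit -> abc); every artifact is recorded in a manifest with a sha256
checksum, so identical config + seed reproduces identical checksums for
the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np

from .demography import SampleDesign, flycatcher_demography
from . import popgen, simulate, treestats, mscmodel, sfsfit, abcsel

__all__ = ["RunConfig", "run_pipeline", "DependencyError"]

STAGE_ORDER = ["simulate", "popgen", "treestats", "mscmodel", "sfsfit", "abc"]


class DependencyError(RuntimeError):
    """A stage was requested without its upstream artifact."""


@dataclass
class RunConfig:
    """Pipeline configuration; ``stages`` is a subset of the known stages."""

    stages: tuple = ("simulate", "popgen", "treestats", "mscmodel")
    out_dir: str = "run"
    seed: int = 1
    topology_id: str = "PA_C_S"
    values: str = "mle"
    desk_scale: bool = True
    n_loci: int = 60
    locus_length: int = 2000
    haplotypes_per_species: int = 8
    sfs_project_to: int = 8
    sfs_sites: int = 100_000
    abc_n_sims: int = 150

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        data = yaml.safe_load(pathlib.Path(path).read_text()) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(pathlib.Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; returns the manifest dict (also written
    to ``<out>/manifest.json``)."""
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in config.__dict__.items()},
                "artifacts": {}}
    stages = [s for s in STAGE_ORDER if s in config.stages]

    def record(name, path):
        manifest["artifacts"][name] = {
            "path": str(path), "sha256": _sha256(path)}

    study = None
    demography = flycatcher_demography(config.topology_id, config.values)
    if "simulate" in stages:
        design = SampleDesign(
            haplotypes_per_species=config.haplotypes_per_species,
            n_loci=config.n_loci, locus_length=config.locus_length,
            include_outgroups=True, seed=config.seed)
        study = simulate.emit_study(demography, design)
        study_dir = study.write(out / "study")
        record("variants", study_dir / "variants.tsv")
        record("species_map", study_dir / "species_map.tsv")

    if "popgen" in stages:
        if study is None:
            raise DependencyError("popgen requires the simulate stage")
        table = popgen.study_pair_table(study.loci)
        vec = popgen.summary_vector(table)
        vec.to_csv(out / "summary_stats.tsv", sep="\t", header=False)
        record("summary_stats", out / "summary_stats.tsv")

    spectra = None
    trees = None
    if "treestats" in stages:
        if study is None:
            raise DependencyError("treestats requires gene-tree input "
                                  "(run the simulate stage)")
        trees = [simulate.simulate_genealogy(demography, study.design, i)
                 for i in range(min(len(study.genealogies), config.n_loci))]
        og = [o.name for o in demography.outgroups]
        windows = [((i * 50_000, i * 50_000 + 10_000), gt)
                   for i, gt in enumerate(trees)]
        stats = treestats.window_scan(windows, outgroups=og, n_rounds=50,
                                      seed=config.seed)
        with open(out / "window_stats.tsv", "w") as fh:
            fh.write("start\tend\ttdi\tlca_depth\t" +
                     "\t".join(f"gsi_{sp}" for sp in "CPAS") + "\n")
            for ws in stats:
                gsis = "\t".join("" if ws.gsi.get(sp) is None
                                 else f"{ws.gsi[sp]:.4f}" for sp in "CPAS")
                fh.write(f"{ws.interval[0]}\t{ws.interval[1]}\t"
                         f"{'' if ws.tdi is None else f'{ws.tdi:.4f}'}\t"
                         f"{'' if ws.lca_relative_depth is None else f'{ws.lca_relative_depth:.4f}'}\t"
                         f"{gsis}\n")
        record("window_stats", out / "window_stats.tsv")
        spectra = [ws.spectrum for ws in stats]

    if "mscmodel" in stages:
        if spectra is None and trees is None:
            raise DependencyError("mscmodel requires gene trees "
                                  "(run the treestats stage)")
        og_names = sorted(o.name for o in demography.outgroups)
        rng = np.random.default_rng(config.seed)
        quartets = [mscmodel.reduce_to_quartet(
            gt, outgroups=og_names, seed=int(rng.integers(2 ** 31)))
            for gt in trees]
        fit = mscmodel.fit_species_tree(quartets)
        report = {"topology": fit.topology,
                  "branch_lengths": list(fit.branch_lengths),
                  "log_pseudolikelihood": fit.log_pseudolikelihood,
                  "ties": list(fit.ties),
                  "scores": fit.candidate_scores}
        (out / "species_tree_fit.json").write_text(
            json.dumps(report, indent=2, sort_keys=True))
        record("species_tree_fit", out / "species_tree_fit.json")

    if "sfsfit" in stages:
        obs = sfsfit.sample_observed_sfs(
            demography, config.sfs_project_to, config.sfs_sites,
            seed=config.seed, include_outgroups=False)
        fits = []
        for model in ("PA_C_S", "PA_CS", "CP_A_S", "PA_S_C"):
            fits.append(sfsfit.fit_model(
                model, obs, n_runs=1, seed=config.seed,
                n_sims_search=60, n_sims_valid=150, n_sims_final=400,
                polish_params=("N_ANC2", "N_ROOT"),
                include_outgroups=False))
        table = sfsfit.compare_models(fits)
        table.to_csv(out / "sfs_model_comparison.tsv", sep="\t", index=False)
        record("sfs_model_comparison", out / "sfs_model_comparison.tsv")

    if "abc" in stages:
        cfg = abcsel.AbcConfig(
            n_sims=config.abc_n_sims, tolerance=0.05, seed=config.seed,
            design=SampleDesign(haplotypes_per_species=8, n_loci=40,
                                locus_length=2000, include_outgroups=False,
                                seed=config.seed))
        tables = {m: abcsel.simulate_reference_table(cfg, m)
                  for m in cfg.models}
        import pandas as pd
        pooled = pd.concat(tables.values(), ignore_index=True)
        obs_stats = pooled[popgen.summary_labels()].iloc[0]
        res = abcsel.model_posterior(obs_stats, pooled,
                                     tolerance=cfg.tolerance)
        (out / "abc_model_posteriors.json").write_text(
            json.dumps(res.model_posteriors, indent=2, sort_keys=True))
        record("abc_model_posteriors", out / "abc_model_posteriors.json")

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
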