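"""End-to-end orchestration: simulate/load -> filter -> group -> train -> validate -> FRR.

One configuration drives the full workflow; every stage's outputs are
written as TSV tables plus a JSON manifest, and a run-metadata file records
the seed, a hash of the configuration and the package version, so a rerun
with the same configuration is reproducible stage for stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import GroupBurdenModel
from .cohort import (Cohort, filter_subjects, read_cohort, split_train_validation,
                     write_cohort, write_report)
from .errors import ConfigurationError
from .familial import frr_estimate
from .grouping import RiskGroupScheme, assign_groups, builtin_scheme
from .mixture import MissenseMixtureModel, MixtureSpec
from .validation import (adjusted_alpha, calibration_gof, composite_fit,
                         mixture_category_logor, pp_weighted_or)
from .simulate import SimulationConfig, config_from_yaml, default_config, simulate


@dataclass
class GenePipelineConfig:
    gene: str
    scheme: str = "standard"          # builtin kind or a YAML scheme file path
    mixture_mode: str = "constrained"


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 20220518
    simulation: SimulationConfig | None = None
    variants_path: str | None = None
    subjects_path: str | None = None
    split_fraction: float = 0.2
    eligible_strata: tuple = ()
    genes: list = field(default_factory=list)   # GenePipelineConfig entries
    n_starts: int = 1

    def validate(self):
        if self.simulation is None and not (self.variants_path and self.subjects_path):
            raise ConfigurationError("need either a simulation config or input paths")
        for g in self.genes:
            if g.scheme not in ("standard", "sge", "hdr") and not Path(g.scheme).exists():
                raise ConfigurationError(f"scheme file not found: {g.scheme}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        sim = doc.get("simulation")
        cfg = cls(
            out_dir=doc["out_dir"],
            seed=doc.get("seed", 20220518),
            simulation=(default_config() if sim == "default"
                        else config_from_yaml(yaml.safe_dump(sim)) if sim else None),
            variants_path=doc.get("variants_path"),
            subjects_path=doc.get("subjects_path"),
            split_fraction=doc.get("split_fraction", 0.2),
            eligible_strata=tuple(doc.get("eligible_strata", ())),
            genes=[GenePipelineConfig(**g) for g in doc.get("genes", [])],
            n_starts=doc.get("n_starts", 1),
        )
        cfg.validate()
        return cfg


def default_pipeline_config(out_dir, seed: int = 20220518) -> PipelineConfig:
    sim = default_config()
    return PipelineConfig(
        out_dir=str(out_dir), seed=seed, simulation=sim,
        eligible_strata=tuple(s.label for s in sim.strata if s.design == "population"),
        genes=[GenePipelineConfig(g.gene) for g in sim.genes],
    )


def _scheme_for(entry: GenePipelineConfig) -> RiskGroupScheme:
    if entry.scheme in ("standard", "sge", "hdr"):
        return builtin_scheme(entry.gene, kind=entry.scheme)
    return RiskGroupScheme.from_yaml(entry.scheme)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the manifest of written result files."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes = [g.gene for g in config.genes]

    # stage 1: obtain the cohort
    if config.simulation is not None:
        cohort, _ = simulate(config.simulation, seed=config.seed)
        write_cohort(cohort, out / "cohort")
    else:
        cohort = read_cohort(config.variants_path, config.subjects_path)

    # stage 2: training/validation split (validation: population strata only)
    eligible = (config.eligible_strata
                or tuple(sorted(set(cohort.subjects.loc[
                    cohort.subjects["design"] == "population", "stratum"]))))
    training, validation_all = split_train_validation(
        cohort, config.split_fraction, eligible, seed=config.seed)
    # carriers of PTVs in any analysed gene are excluded everywhere except
    # the mixture fits; the validation set excludes them outright
    training_lr = filter_subjects(training, drop_ptv_carriers_in=genes,
                                  drop_multi_missense_genes=False)
    validation = filter_subjects(validation_all, drop_ptv_carriers_in=genes)
    population_training_lr = training_lr.subset_subjects(
        training_lr.subjects.loc[training_lr.subjects["design"] == "population",
                                 "subject_id"])
    population_training = training.subset_subjects(
        training.subjects.loc[training.subjects["design"] == "population",
                              "subject_id"])

    tables: dict[str, pd.DataFrame] = {}
    frr_inputs = []
    assignments = []
    for entry in config.genes:
        scheme = _scheme_for(entry)
        assignment = assign_groups(cohort.variants, scheme)
        assignments.append(assignment)

        # headline estimates from population-design training subjects; the
        # "_ALL" table additionally includes familial-design studies
        burden = GroupBurdenModel(population_training_lr, assignment).fit()
        tables[f"burden_{entry.gene}"] = burden.table
        tables[f"burden_{entry.gene}_ALL"] = GroupBurdenModel(
            training_lr, assignment).fit().table

        spec = MixtureSpec(gene=entry.gene, mode=entry.mixture_mode)
        mix = MissenseMixtureModel(population_training, assignment, spec=spec).fit(
            n_starts=config.n_starts, seed=config.seed)
        mix_dict = mix.to_dict()
        with open(out / f"mixture_{entry.gene}.json", "w") as fh:
            json.dump(mix_dict, fh, indent=2)
        post = mix.posteriors
        tables[f"posteriors_{entry.gene}"] = (
            post.rename("posterior").rename_axis("variant_id").reset_index()
            if isinstance(post, pd.Series)
            else post.rename_axis("variant_id").reset_index())

        # validation calibration with frozen mixture parameters
        fractions = mix.carrier_pathogenic_fractions()
        case_frac = float((validation.subjects["status"] == "case").mean())
        alpha_val = {}
        for cat in assignment.labels:
            ca = fractions.loc[cat, "case_alpha"]
            co = fractions.loc[cat, "control_alpha"]
            a = float(mix.alpha[cat]) if not isinstance(mix.alpha, pd.DataFrame) \
                else float(mix.alpha.loc[cat].sum())
            ca = a if np.isnan(ca) else ca
            co = a if np.isnan(co) else co
            alpha_val[cat] = adjusted_alpha(ca, co, case_frac)
        logor = mixture_category_logor(alpha_val, mix.beta_mis)
        report = calibration_gof(validation, assignment, logor)
        tables[f"validation_{entry.gene}"] = report.table
        if isinstance(post, pd.Series):
            ppor = pp_weighted_or(validation, post, mix.beta_mis, assignment)
            tables[f"pp_or_{entry.gene}"] = ppor.reset_index()

        # FRR inputs: pathogenic allele frequency from control carriers,
        # relative risk approximated by the fitted missense OR
        counts = burden.table.set_index("category")
        ctrl_total = float((population_training_lr.subjects["status"] == "control").sum())
        alpha_vec = (mix.alpha if isinstance(mix.alpha, pd.Series)
                     else mix.alpha.sum(axis=1))
        carrier_freq = float(sum(alpha_vec[c] * counts.loc[c, "n_control_carriers"]
                                 for c in assignment.labels) / ctrl_total)
        frr_inputs.append((entry.gene, carrier_freq / 2, float(np.exp(mix.beta_mis))))

    composite = composite_fit(validation, assignments)
    tables["composite"] = composite.table

    frr = frr_estimate(frr_inputs)
    tables["frr"] = frr.table()

    manifest = write_report(tables, out)
    meta = {
        "seed": config.seed,
        "package_version": __version__,
        "config_hash": hashlib.sha256(
            repr(config).encode()).hexdigest()[:16],
        "n_training": training.n_subjects,
        "n_validation": validation.n_subjects,
    }
    with open(out / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    manifest["run_metadata"] = {"path": str(out / "run_metadata.json"), "rows": 1}
    return manifest
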