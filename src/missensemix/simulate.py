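"""Synthetic variant catalogs and case-control cohorts.

The generator reproduces the statistical structure the analyses assume, so
every downstream stage can be exercised without controlled-access data:

* per-gene catalogs of rare missense variants whose scores and domain labels
  realise the published risk-category definitions, with latent pathogenicity
  drawn Bernoulli(alpha) per category;
* subjects simulated *prospectively* -- carrier status from allele
  frequencies (heterozygote probability ~ 2f, at most one eligible missense
  per gene per subject), disease status from a logistic model with a
  population-scale stratum baseline plus log-OR terms for pathogenic
  missense and PTV carriage -- and then sampled *retrospectively* to the
  target case/control counts, with optional oversampling of cases from
  familial-design strata.

Simulating the population first and ascertaining afterwards makes the
logistic model literally true and reproduces the ascertainment effects the
mixture model corrects for: pathogenic variants are both more likely to
enter the observed catalog and more case-enriched once there.

The default configuration mirrors the published five-gene study: category
sizes, alpha values and odds ratios from the training-set results table, at
the same sample scale (~35,000 cases and ~38,000 controls drawn from a
~400,000-subject prospective pool with ~10% disease probability).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, SCORE_COLUMNS, VARIANT_COLUMNS
from .errors import ConfigurationError
from .grouping import ATM_CADD_Q5_BOUNDARY

DEFAULT_SEED = 20220518

#: generic sampling ranges for score columns not pinned by a category template
_SCORE_RANGES = {"cadd": (0.0, 12.0), "helix": (0.0, 1.0), "bayesdel": (-1.0, 1.0),
                 "revel": (0.0, 1.0), "align_gvgd": (0.0, 100.0)}


@dataclass
class CategorySimConfig:
    """One risk category: size, pathogenic proportion, and the score/domain
    template that makes its variants land in the right category."""

    label: str
    n_variants: int
    alpha: float
    template: dict = field(default_factory=dict)

    def validate(self):
        if not 0 <= self.alpha <= 1:
            raise ConfigurationError(f"alpha must be in [0,1]: {self.label}")
        if self.n_variants <= 0:
            raise ConfigurationError(f"n_variants must be positive: {self.label}")


@dataclass
class GeneSimConfig:
    gene: str
    categories: list
    or_missense: float
    or_ptv: float
    ptv_carrier_freq: float
    freq_dist: tuple = (2e-6, 1e-4)   # log-uniform allele-frequency bounds

    def validate(self):
        if self.or_missense <= 0 or self.or_ptv <= 0:
            raise ConfigurationError(f"odds ratios must be positive: {self.gene}")
        lo, hi = self.freq_dist
        if not 0 < lo < hi <= 0.05:
            raise ConfigurationError(f"freq_dist bounds must lie in (0, 0.05]: {self.gene}")
        if not 0 <= self.ptv_carrier_freq < 0.5:
            raise ConfigurationError(f"bad ptv_carrier_freq: {self.gene}")
        for c in self.categories:
            c.validate()


@dataclass
class StratumConfig:
    label: str
    baseline_logodds: float
    n_subjects: int
    design: str = "population"


@dataclass
class SimulationConfig:
    genes: list
    strata: list
    target_cases: int
    target_controls: int
    familial_oversample: float = 1.0
    splice_excluded_rate: float = 0.0
    seed: int = DEFAULT_SEED

    def validate(self):
        if self.target_cases <= 0 or self.target_controls <= 0:
            raise ConfigurationError("target counts must be positive")
        if self.familial_oversample < 1:
            raise ConfigurationError("familial_oversample must be >= 1")
        if not self.strata or not self.genes:
            raise ConfigurationError("need at least one stratum and one gene")
        for g in self.genes:
            g.validate()

    def subset(self, genes) -> "SimulationConfig":
        """Config restricted to the named genes (other settings unchanged)."""
        keep = [g for g in self.genes if g.gene in set(genes)]
        if not keep:
            raise ConfigurationError(f"no configured gene among {genes}")
        return SimulationConfig(genes=keep, strata=self.strata,
                                target_cases=self.target_cases,
                                target_controls=self.target_controls,
                                familial_oversample=self.familial_oversample,
                                splice_excluded_rate=self.splice_excluded_rate,
                                seed=self.seed)


def default_config() -> SimulationConfig:
    """Five-gene configuration at published training-set scale.

    Category sizes, pathogenic proportions (alpha) and odds ratios follow the
    published population training results; PTV carrier frequencies follow the
    published carrier-frequency comparisons.  The CHEK2 missense OR (1.75) is
    deliberately below its PTV OR so the unconstrained-vs-constrained model
    contrast is realised in simulated data.
    """
    b = ATM_CADD_Q5_BOUNDARY
    genes = [
        GeneSimConfig(
            gene="ATM", or_missense=2.16, or_ptv=2.16, ptv_carrier_freq=0.0034,
            categories=[
                CategorySimConfig("outside_FAT_PIK", 714, 0.0041,
                                  {"domain": ["none"]}),
                CategorySimConfig("FAT_PIK_CADD1-4", 171, 0.055,
                                  {"domain": ["FAT", "PIK"], "cadd": [0.0, b]}),
                CategorySimConfig("FAT_PIK_CADD5", 103, 0.54,
                                  {"domain": ["FAT", "PIK"], "cadd": [b, 12.0]}),
            ]),
        GeneSimConfig(
            gene="BRCA1", or_missense=10.61, or_ptv=10.61, ptv_carrier_freq=0.00144,
            categories=[
                CategorySimConfig("outside_RING_BRCT", 479, 0.0015,
                                  {"domain": ["none"]}),
                CategorySimConfig("RING_BRCT_Helix-low", 79, 1e-11,
                                  {"domain": ["RING", "BRCT"], "helix": [0.0, 0.5]}),
                CategorySimConfig("RING_BRCT_Helix-high", 23, 0.48,
                                  {"domain": ["RING", "BRCT"], "helix": [0.5, 1.0]}),
            ]),
        GeneSimConfig(
            gene="BRCA2", or_missense=5.87, or_ptv=5.87, ptv_carrier_freq=0.0031,
            categories=[
                CategorySimConfig("Helix-low", 1160, 5.1e-5, {"helix": [0.0, 0.5]}),
                CategorySimConfig("Helix-high", 62, 0.11, {"helix": [0.5, 1.0]}),
            ]),
        GeneSimConfig(
            gene="CHEK2", or_missense=1.75, or_ptv=2.54, ptv_carrier_freq=0.0031,
            categories=[
                CategorySimConfig("Helix-low", 157, 0.33, {"helix": [0.0, 0.5]}),
                CategorySimConfig("Helix-high", 121, 0.95, {"helix": [0.5, 1.0]}),
            ]),
        GeneSimConfig(
            gene="PALB2", or_missense=4.87, or_ptv=4.87, ptv_carrier_freq=0.0013,
            categories=[
                CategorySimConfig("carriers", 424, 1.1e-4, {})]),
    ]
    strata = [
        StratumConfig("UK", -2.20, 150_000),
        StratumConfig("DE", -2.25, 90_000),
        StratumConfig("DK", -2.15, 60_000),
        StratumConfig("SE", -2.30, 60_000),
        StratumConfig("FR-FAM", -2.25, 40_000, design="familial"),
    ]
    return SimulationConfig(genes=genes, strata=strata,
                            target_cases=35_000, target_controls=38_000,
                            familial_oversample=2.0)


# ---------------------------------------------------------------------------
# catalog simulation
# ---------------------------------------------------------------------------

def _draw_scores(rng, template: dict, n: int) -> dict:
    out = {}
    for score, (lo, hi) in _SCORE_RANGES.items():
        if score in template:
            lo, hi = template[score]
        # open lower bound keeps boundary scores (e.g. Helix 0.5) on one side
        out[score] = lo + (hi - lo) * rng.uniform(1e-9, 1.0, size=n)
    return out


def simulate_catalog(config: SimulationConfig, seed: int | None = None):
    """Draw the variant catalog and the latent pathogenicity truth map.

    Returns ``(catalog, truth)``: a DataFrame with the canonical variant
    columns and a dict variant_id -> bool.  The truth map exists for test
    assertions only; analyses never see it.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows, truth = [], {}
    for g in config.genes:
        lo, hi = g.freq_dist
        for cat in g.categories:
            n = cat.n_variants
            freqs = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
            scores = _draw_scores(rng, cat.template, n)
            domains = rng.choice(cat.template.get("domain", ["none"]), size=n)
            pathogenic = rng.random(n) < cat.alpha
            splice = rng.random(n) < config.splice_excluded_rate
            for i in range(n):
                vid = f"{g.gene}:{cat.label}:{i}"
                truth[vid] = bool(pathogenic[i])
                rows.append({
                    "gene": g.gene, "variant_id": vid, "consequence": "missense",
                    "frequency": float(freqs[i]),
                    **{s: float(scores[s][i]) for s in SCORE_COLUMNS},
                    "domain": str(domains[i]),
                    "splice_excluded": bool(splice[i]),
                    "sge_class": "NA", "hdr_class": "NA", "clinvar_class": "NA",
                })
        if g.ptv_carrier_freq > 0:
            vid = f"{g.gene}:PTV"
            truth[vid] = True
            rows.append({
                "gene": g.gene, "variant_id": vid, "consequence": "PTV",
                "frequency": g.ptv_carrier_freq / 2,
                **{s: np.nan for s in SCORE_COLUMNS},
                "domain": "none", "splice_excluded": False,
                "sge_class": "NA", "hdr_class": "NA", "clinvar_class": "NA",
            })
    catalog = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return catalog, truth


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _weighted_topk(rng, weights: np.ndarray, k: int) -> np.ndarray:
    """Indices of a weighted sample of size k without replacement."""
    keys = np.log(weights) + rng.gumbel(size=len(weights))
    return np.argpartition(-keys, k - 1)[:k]


def simulate_cohort(catalog: pd.DataFrame, truth: dict, config: SimulationConfig,
                    seed: int | None = None) -> Cohort:
    """Prospective simulation followed by retrospective case-control sampling."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    n_pool = sum(s.n_subjects for s in config.strata)
    stratum_lab = np.concatenate([
        np.full(s.n_subjects, s.label, dtype=object) for s in config.strata])
    baseline = np.concatenate([
        np.full(s.n_subjects, s.baseline_logodds) for s in config.strata])
    familial = np.concatenate([
        np.full(s.n_subjects, s.design == "familial") for s in config.strata])

    logit = baseline.copy()
    carried: dict[int, list[str]] = {}
    for g in config.genes:
        mis = catalog.loc[(catalog["gene"] == g.gene)
                          & (catalog["consequence"] == "missense")]
        vids = mis["variant_id"].to_numpy()
        freqs = mis["frequency"].to_numpy()
        p_carrier = 2 * freqs
        total = p_carrier.sum()
        if total > 0.5:
            raise ConfigurationError(
                f"total missense carrier probability {total:.2f} too high for {g.gene}")
        is_car = rng.random(n_pool) < total
        idx = np.flatnonzero(is_car)
        if len(idx):
            choice = rng.choice(len(vids), size=len(idx), p=p_carrier / total)
            path = np.array([truth[v] for v in vids])[choice]
            logit[idx[path]] += np.log(g.or_missense)
            for i, c in zip(idx, choice):
                carried.setdefault(int(i), []).append(vids[c])
        if g.ptv_carrier_freq > 0:
            is_ptv = rng.random(n_pool) < g.ptv_carrier_freq
            pidx = np.flatnonzero(is_ptv)
            logit[pidx] += np.log(g.or_ptv)
            pvid = f"{g.gene}:PTV"
            for i in pidx:
                carried.setdefault(int(i), []).append(pvid)

    y = rng.random(n_pool) < 1 / (1 + np.exp(-logit))
    case_idx = np.flatnonzero(y)
    ctrl_idx = np.flatnonzero(~y)
    if len(case_idx) < config.target_cases or len(ctrl_idx) < config.target_controls:
        raise ConfigurationError(
            f"prospective pool too small: {len(case_idx)} cases / "
            f"{len(ctrl_idx)} controls available; enlarge the strata")

    case_w = np.where(familial[case_idx], config.familial_oversample, 1.0)
    keep_cases = case_idx[_weighted_topk(rng, case_w, config.target_cases)]
    keep_ctrls = ctrl_idx[rng.choice(len(ctrl_idx), size=config.target_controls,
                                     replace=False)]
    keep = np.sort(np.concatenate([keep_cases, keep_ctrls]))

    age = np.clip(rng.normal(60.0, 10.0, size=len(keep)), 25, 85).round(1)
    subjects = pd.DataFrame({
        "subject_id": [f"S{i:07d}" for i in keep],
        "stratum": stratum_lab[keep],
        "status": np.where(y[keep], "case", "control"),
        "age": age,
        "design": np.where(familial[keep], "familial", "population"),
        "carried": [tuple(carried.get(int(i), ())) for i in keep],
    })
    return Cohort(catalog, subjects)


def simulate(config: SimulationConfig, seed: int | None = None):
    """Catalog + cohort in one call; returns (cohort, truth)."""
    use = config.seed if seed is None else seed
    catalog, truth = simulate_catalog(config, seed=use)
    cohort = simulate_cohort(catalog, truth, config, seed=use + 1)
    return cohort, truth


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------

def config_to_yaml(config: SimulationConfig, path=None) -> str:
    doc = asdict(config)
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def config_from_yaml(source) -> SimulationConfig:
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        text = str(source)
        if "\n" not in text and text.endswith((".yaml", ".yml")):
            with open(text) as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(text)
    genes = [GeneSimConfig(
        gene=g["gene"],
        categories=[CategorySimConfig(**c) for c in g["categories"]],
        or_missense=g["or_missense"], or_ptv=g["or_ptv"],
        ptv_carrier_freq=g["ptv_carrier_freq"],
        freq_dist=tuple(g.get("freq_dist", (2e-6, 1e-4))),
    ) for g in doc["genes"]]
    strata = [StratumConfig(**s) for s in doc["strata"]]
    cfg = SimulationConfig(
        genes=genes, strata=strata,
        target_cases=doc["target_cases"], target_controls=doc["target_controls"],
        familial_oversample=doc.get("familial_oversample", 1.0),
        splice_excluded_rate=doc.get("splice_excluded_rate", 0.0),
        seed=doc.get("seed", DEFAULT_SEED))
    cfg.validate()
    return cfg
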