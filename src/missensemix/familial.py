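"""Familial relative risk decomposition and pathogenic-carrier summaries.

For a single gene with deleterious-variant allele frequency ``p`` (so the
carrier frequency is ~2p under rarity) and carrier relative risk ``r``, the
familial relative risk contributed by the locus is

    lambda = (p r^2 + q (p r + q)^2) / (2 p r + 1 - 2 p)^2,    q = 1 - p,

which reduces to the familiar ``1 + p (r - 1)^2`` as p -> 0.  Gene
contributions combine additively on the excess scale,
``lambda_mis = 1 + sum(lambda_j - 1)``, and the share of an overall familial
relative risk of 2 explained is ``log(lambda_mis) / log(2)`` (multiplicative
combination with the remaining familial factors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GeneRiskSummary:
    gene: str
    p: float            # deleterious allele frequency
    r: float            # carrier relative risk
    lambda_gene: float

    @property
    def q(self) -> float:
        return 1.0 - self.p


@dataclass
class FrrEstimate:
    genes: list
    lambda_mis: float
    frr_fraction: float

    def table(self) -> pd.DataFrame:
        rows = [{"gene": g.gene, "p": g.p, "r": g.r, "lambda": g.lambda_gene}
                for g in self.genes]
        rows.append({"gene": "TOTAL", "p": np.nan, "r": np.nan,
                     "lambda": self.lambda_mis})
        return pd.DataFrame(rows)


def lambda_gene(p: float, r: float) -> float:
    """Single-locus familial relative risk for allele frequency p, risk r."""
    if not 0 <= p <= 0.5:
        raise ValueError(f"allele frequency must lie in [0, 0.5], got {p}")
    if r <= 0:
        raise ValueError(f"relative risk must be positive, got {r}")
    q = 1.0 - p
    num = p * r ** 2 + q * (p * r + q) ** 2
    den = (2 * p * r + 1 - 2 * p) ** 2
    return num / den


def lambda_missense_total(lambdas) -> float:
    """Additive-excess aggregation: 1 + sum(lambda_j - 1)."""
    lambdas = list(lambdas)
    if any(l < 0 for l in lambdas):
        raise ValueError("lambda values must be non-negative")
    return 1.0 + sum(l - 1.0 for l in lambdas)


def frr_proportion(lambda_mis: float, overall_frr: float = 2.0) -> float:
    """Share of the overall familial relative risk explained."""
    if lambda_mis < 1:
        raise ValueError(f"lambda_mis must be >= 1, got {lambda_mis}")
    return float(np.log(lambda_mis) / np.log(overall_frr))


def frr_estimate(gene_inputs, overall_frr: float = 2.0) -> FrrEstimate:
    """Full decomposition from (gene, p, r) rows."""
    genes = [GeneRiskSummary(gene=g, p=p, r=r, lambda_gene=lambda_gene(p, r))
             for g, p, r in gene_inputs]
    lam = lambda_missense_total([g.lambda_gene for g in genes])
    return FrrEstimate(genes=genes, lambda_mis=lam,
                       frr_fraction=frr_proportion(lam, overall_frr))


def pathogenic_carrier_stats(case_counts, control_counts, noncarrier_cases: int,
                             noncarrier_controls: int, alpha, or_missense: float):
    """Population summaries from per-category counts and mixture parameters.

    ``case_counts`` / ``control_counts`` / ``alpha`` are aligned per-category
    sequences (or dicts with common keys).  Returns

    * the pathogenic-variant carrier frequency among controls,
      ``sum_c alpha_c * controls_c / total_controls``, and
    * the expected fraction of cases carrying a pathogenic variant,
      ``sum_c w_c * cases_c / total_cases`` with
      ``w_c = alpha_c*OR / (alpha_c*OR + 1 - alpha_c)`` -- the probability a
      carrier's variant is pathogenic given case status, by Bayes' rule.
    """
    if isinstance(case_counts, dict):
        keys = list(case_counts)
        case_counts = [case_counts[k] for k in keys]
        control_counts = [control_counts[k] for k in keys]
        alpha = [alpha[k] for k in keys]
    case_counts = np.asarray(case_counts, dtype=float)
    control_counts = np.asarray(control_counts, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if ((alpha < 0) | (alpha > 1)).any():
        raise ValueError("alpha values must lie in [0,1]")
    if (case_counts < 0).any() or (control_counts < 0).any():
        raise ValueError("counts must be non-negative")
    total_cases = case_counts.sum() + noncarrier_cases
    total_controls = control_counts.sum() + noncarrier_controls
    if total_cases <= 0 or total_controls <= 0:
        raise ValueError("zero subject totals")
    control_freq = float((alpha * control_counts).sum() / total_controls)
    w = alpha * or_missense / (alpha * or_missense + 1 - alpha)
    case_fraction = float((w * case_counts).sum() / total_cases)
    return control_freq, case_fraction
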