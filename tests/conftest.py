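"""Shared fixtures: hand-built micro cohorts and scaled-down simulations."""

import numpy as np
import pandas as pd
import pytest

import missensemix as mm
from missensemix.cohort import Cohort, VARIANT_COLUMNS


def variant_row(vid, gene="G", consequence="missense", frequency=1e-4,
                cadd=np.nan, helix=0.5, domain="none", splice_excluded=False,
                sge_class="NA", hdr_class="NA", clinvar_class="NA"):
    return {"gene": gene, "variant_id": vid, "consequence": consequence,
            "frequency": frequency, "cadd": cadd, "helix": helix,
            "bayesdel": np.nan, "revel": np.nan, "align_gvgd": np.nan,
            "domain": domain, "splice_excluded": splice_excluded,
            "sge_class": sge_class, "hdr_class": hdr_class,
            "clinvar_class": clinvar_class}


def make_cohort(variant_rows, subject_rows):
    variants = pd.DataFrame(variant_rows, columns=VARIANT_COLUMNS)
    subjects = pd.DataFrame(subject_rows,
                            columns=["subject_id", "stratum", "status", "age",
                                     "design", "carried"])
    return Cohort(variants, subjects)


def subject_row(sid, status, carried=(), stratum="X", age=55.0,
                design="population"):
    return {"subject_id": sid, "stratum": stratum, "status": status,
            "age": age, "design": design, "carried": tuple(carried)}


def counts_cohort(gene, carrier_counts, noncarrier_cases, noncarrier_controls,
                  helix=0.3):
    """Single-stratum cohort realising given per-variant carrier counts.

    ``carrier_counts``: {variant_id: (n_case_carriers, n_control_carriers)}.
    """
    vrows = [variant_row(v, gene=gene, helix=helix) for v in carrier_counts]
    srows, i = [], 0
    for vid, (n_case, n_ctrl) in carrier_counts.items():
        for _ in range(n_case):
            srows.append(subject_row(f"s{i}", "case", (vid,))); i += 1
        for _ in range(n_ctrl):
            srows.append(subject_row(f"s{i}", "control", (vid,))); i += 1
    for _ in range(noncarrier_cases):
        srows.append(subject_row(f"s{i}", "case")); i += 1
    for _ in range(noncarrier_controls):
        srows.append(subject_row(f"s{i}", "control")); i += 1
    return make_cohort(vrows, srows)


def single_category_scheme(gene="G"):
    return mm.RiskGroupScheme(gene=gene,
                              categories=[("all", {"match_all": True})],
                              baseline_label="all")


@pytest.fixture
def tiny_cohort():
    """3 variants, 5 subjects; exercises io round trips and filters."""
    vrows = [
        variant_row("G:m1", helix=0.7, frequency=5e-4),
        variant_row("G:m2", helix=0.2, frequency=2e-3, splice_excluded=True),
        variant_row("G:ptv", consequence="PTV", frequency=1e-4, helix=np.nan),
    ]
    srows = [
        subject_row("s1", "case", ("G:m1",), stratum="UK"),
        subject_row("s2", "control", ("G:m2",), stratum="UK", age=np.nan),
        subject_row("s3", "case", ("G:ptv",), stratum="DE"),
        subject_row("s4", "control", (), stratum="DE", design="familial"),
        subject_row("s5", "case", ("G:m1", "G:m2"), stratum="UK"),
    ]
    return make_cohort(vrows, srows)


def small_two_gene_config(target=6000, pool=80_000):
    """Scaled-down ATM-like + CHEK2-like configuration for fast end-to-end runs."""
    b = mm.grouping.ATM_CADD_Q5_BOUNDARY
    return mm.SimulationConfig(
        genes=[
            mm.GeneSimConfig(
                "ATM", or_missense=2.2, or_ptv=2.2, ptv_carrier_freq=0.003,
                categories=[
                    mm.CategorySimConfig("outside_FAT_PIK", 60, 0.01,
                                         {"domain": ["none"]}),
                    mm.CategorySimConfig("FAT_PIK_CADD1-4", 30, 0.05,
                                         {"domain": ["FAT", "PIK"], "cadd": [0.0, b]}),
                    mm.CategorySimConfig("FAT_PIK_CADD5", 30, 0.5,
                                         {"domain": ["FAT", "PIK"], "cadd": [b, 12.0]}),
                ],
                freq_dist=(5e-5, 5e-4)),
            mm.GeneSimConfig(
                "CHEK2", or_missense=1.8, or_ptv=2.5, ptv_carrier_freq=0.003,
                categories=[
                    mm.CategorySimConfig("Helix-low", 40, 0.3, {"helix": [0.0, 0.5]}),
                    mm.CategorySimConfig("Helix-high", 30, 0.9, {"helix": [0.5, 1.0]}),
                ],
                freq_dist=(5e-5, 5e-4)),
        ],
        strata=[mm.StratumConfig("A", -2.2, pool // 2),
                mm.StratumConfig("B", -2.0, pool * 3 // 8),
                mm.StratumConfig("F", -2.1, pool // 8, design="familial")],
        target_cases=target, target_controls=target,
        familial_oversample=2.0)


@pytest.fixture(scope="session")
def small_cohort():
    cohort, truth = mm.simulate(small_two_gene_config(), seed=20220518)
    return cohort, truth
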