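"""Burden, trend, frequency, and age analyses built on stratified logistic fits.

The central object is :class:`GroupBurdenModel`: a joint logistic model with
one carrier indicator per risk category (non-carriers as baseline) and
country/ethnicity strata as covariates, whose :meth:`~GroupBurdenModel.fit`
returns a :class:`BurdenResults` table of per-category odds ratios.  The
remaining analyses are carrier-only score trends, frequency-group burdens and
case-only age trends, each a small stratified logistic fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import DesignError
from .grouping import (FREQUENCY_BIN_EDGES, FREQUENCY_BIN_LABELS, GroupAssignment,
                       classify_frequency)
from .logistic import LogisticFit, fit_logistic, stratum_design


# ---------------------------------------------------------------------------
# exposure helpers
# ---------------------------------------------------------------------------

def gene_exposure(cohort: Cohort, assignment: GroupAssignment):
    """Per-subject risk-category exposure for one gene.

    Returns ``(labels, dropped)``: a numpy object array aligned with
    ``cohort.subjects`` holding the carried category label or ``None``, and
    the number of subjects dropped for carrying more than one eligible
    missense variant of the gene (their label is also ``None``).
    """
    mapping = assignment.mapping
    labels = np.full(len(cohort.subjects), None, dtype=object)
    dropped = 0
    for i, carried in enumerate(cohort.subjects["carried"]):
        cats = [mapping[c] for c in carried if c in mapping]
        if len(cats) == 1:
            labels[i] = cats[0]
        elif len(cats) > 1:
            dropped += 1
    return labels, dropped


def ptv_carrier_mask(cohort: Cohort, gene: str) -> np.ndarray:
    v = cohort.variants
    ptv_ids = set(v.loc[(v["gene"] == gene) & (v["consequence"] == "PTV"), "variant_id"])
    return np.array([any(c in ptv_ids for c in carried)
                     for carried in cohort.subjects["carried"]])


@dataclass
class TrendResult:
    """One odds ratio with its Wald interval, for a single exposure term."""

    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    unbounded: bool = False
    fit: LogisticFit | None = None

    def as_series(self) -> pd.Series:
        return pd.Series({"term": self.term, "OR": self.odds_ratio,
                          "ci_low": self.ci_low, "ci_high": self.ci_high,
                          "p": self.p, "n": self.n, "unbounded": self.unbounded})


def _trend_from_fit(fit: LogisticFit, term: str) -> TrendResult:
    tab = fit.or_table()
    row = tab.loc[term]
    return TrendResult(term=term, odds_ratio=float(row["OR"]),
                       ci_low=float(row["ci_low"]), ci_high=float(row["ci_high"]),
                       p=float(row["p"]), n=fit.n, fit=fit)


# ---------------------------------------------------------------------------
# category burden
# ---------------------------------------------------------------------------

class GroupBurdenModel:
    """Joint stratified logistic model of risk-category carrier status.

    Parameters
    ----------
    cohort : Cohort
        Subjects to analyse.  Carriers of PTVs in the gene should already
        have been removed (see :func:`missensemix.cohort.filter_subjects`);
        subjects carrying more than one eligible missense variant of the
        gene are dropped here with a logged count.
    assignment : GroupAssignment
        The variant -> category map for the gene.
    """

    def __init__(self, cohort: Cohort, assignment: GroupAssignment):
        self.cohort = cohort
        self.assignment = assignment
        self.exposure, self.n_dropped_multi = gene_exposure(cohort, assignment)

    def fit(self) -> "BurdenResults":
        subj = self.cohort.subjects
        # drop only multi-missense subjects (label None but carrying >=2)
        multi = np.array([
            lab is None and sum(c in self.assignment.mapping for c in carried) > 1
            for lab, carried in zip(self.exposure, subj["carried"])])
        keep = ~multi
        subj = subj.loc[keep].reset_index(drop=True)
        exposure = self.exposure[keep]
        y = (subj["status"] == "case").astype(float).to_numpy()

        counts = self.assignment.counts()
        rows = []
        X = stratum_design(subj["stratum"])
        fitted_labels = []
        for label in self.assignment.labels:
            is_cat = exposure == label
            n_case = int((is_cat & (y == 1)).sum())
            n_ctrl = int((is_cat & (y == 0)).sum())
            rows.append({"category": label, "n_variants": int(counts[label]),
                         "n_case_carriers": n_case, "n_control_carriers": n_ctrl})
            if n_case + n_ctrl > 0:
                X[f"cat[{label}]"] = is_cat.astype(float)
                fitted_labels.append(label)

        fit = fit_logistic(y, X)
        tab = fit.or_table()
        table = pd.DataFrame(rows).set_index("category")
        for col in ("OR", "ci_low", "ci_high", "p"):
            table[col] = np.nan
        for label in fitted_labels:
            term = f"cat[{label}]"
            table.loc[label, ["OR", "ci_low", "ci_high", "p"]] = (
                tab.loc[term, ["OR", "ci_low", "ci_high", "p"]].to_numpy())
        return BurdenResults(model=self, table=table.reset_index(), fit=fit,
                             n_dropped_multi=int(multi.sum()))


@dataclass
class BurdenResults:
    """Per-category carrier counts and odds ratios from a joint fit."""

    model: GroupBurdenModel
    table: pd.DataFrame
    fit: LogisticFit
    n_dropped_multi: int

    @property
    def loglik(self) -> float:
        return self.fit.loglik

    def summary(self) -> str:
        lines = [f"group burden for {self.model.assignment.gene}: "
                 f"n={self.fit.n}, loglik={self.loglik:.2f}, "
                 f"multi-missense subjects dropped={self.n_dropped_multi}"]
        header = (f"{'category':<26}{'variants':>9}{'cases':>8}{'controls':>9}"
                  f"{'OR':>8}{'95% CI':>18}{'p':>11}")
        lines.append(header)
        for _, r in self.table.iterrows():
            if np.isnan(r["OR"]):
                or_s, ci_s, p_s = "NA", "NA", "NA"
            else:
                or_s = f"{r['OR']:.2f}"
                ci_s = f"({r['ci_low']:.2f}–{r['ci_high']:.2f})"
                p_s = f"{r['p']:.3g}"
            lines.append(f"{r['category']:<26}{r['n_variants']:>9}"
                         f"{r['n_case_carriers']:>8}{r['n_control_carriers']:>9}"
                         f"{or_s:>8}{ci_s:>18}{p_s:>11}")
        return "\n".join(lines)


def group_burden(cohort: Cohort, assignment: GroupAssignment) -> BurdenResults:
    """Functional wrapper: fit the per-category burden model."""
    return GroupBurdenModel(cohort, assignment).fit()


# ---------------------------------------------------------------------------
# carrier-only score trend
# ---------------------------------------------------------------------------

def carrier_score_trend(cohort: Cohort, gene: str, score_name: str,
                        rare_threshold: float = 0.001) -> TrendResult:
    """Logistic trend of case status on a continuous in silico score,
    among carriers of a rare missense variant of ``gene`` only."""
    from .grouping import eligible_missense

    eligible = eligible_missense(cohort.variants, gene, rare_threshold)
    scores = cohort.variants.set_index("variant_id")[score_name]
    subj = cohort.subjects
    carrier_score = np.full(len(subj), np.nan)
    for i, carried in enumerate(subj["carried"]):
        vals = [scores[c] for c in carried if c in eligible and not np.isnan(scores[c])]
        if len(vals) == 1:
            carrier_score[i] = vals[0]
    keep = ~np.isnan(carrier_score)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 scored carriers")
    sub = subj.loc[keep]
    x = carrier_score[keep]
    if np.ptp(x) == 0:
        raise ValueError(f"score {score_name!r} is constant among carriers")
    X = stratum_design(sub["stratum"])
    X[score_name] = x
    fit = fit_logistic(sub["status"], X)
    return _trend_from_fit(fit, score_name)


# ---------------------------------------------------------------------------
# frequency analyses
# ---------------------------------------------------------------------------

@dataclass
class FrequencyBurden:
    """Per-bin burden ORs plus carrier-only frequency tests."""

    table: pd.DataFrame
    carrier_tests: dict = field(default_factory=dict)


def frequency_burden(cohort: Cohort, gene: str, bins=None,
                     adjust_assignment: GroupAssignment | None = None) -> FrequencyBurden:
    """Burden by allele-frequency group, and carrier-only frequency tests.

    The burden part fits one indicator per frequency bin (non-carriers as
    baseline).  The carrier-only part, restricted to frequencies < 0.5%,
    tests frequency on a continuous scale, a log scale, and as a two-group
    contrast (0.1–0.5% vs < 0.1%), optionally adjusted for the risk-group
    covariates of ``adjust_assignment``.
    """
    edges = FREQUENCY_BIN_EDGES if bins is None else list(bins)
    labels = FREQUENCY_BIN_LABELS if bins is None else [str(b) for b in bins[:-1]]
    v = cohort.variants
    use = ((v["gene"] == gene) & (v["consequence"] == "missense")
           & ~v["splice_excluded"] & (v["frequency"] <= edges[-1]))
    freq = v.loc[use].set_index("variant_id")["frequency"]

    subj = cohort.subjects
    carrier_freq = np.full(len(subj), np.nan)
    multi = np.zeros(len(subj), dtype=bool)
    for i, carried in enumerate(subj["carried"]):
        vals = [freq[c] for c in carried if c in freq.index]
        if len(vals) == 1:
            carrier_freq[i] = vals[0]
        elif len(vals) > 1:
            multi[i] = True
    subj = subj.loc[~multi].reset_index(drop=True)
    carrier_freq = carrier_freq[~multi]

    y = (subj["status"] == "case").astype(float).to_numpy()
    bin_idx = np.full(len(subj), -1)
    carrier = ~np.isnan(carrier_freq)
    bin_idx[carrier] = [
        labels.index(classify_frequency(f)) if bins is None
        else classify_frequency(f, edges) for f in carrier_freq[carrier]]

    X = stratum_design(subj["stratum"])
    rows, fitted = [], []
    for b, label in enumerate(labels):
        inb = bin_idx == b
        n_case, n_ctrl = int((inb & (y == 1)).sum()), int((inb & (y == 0)).sum())
        rows.append({"bin": label, "n_case_carriers": n_case,
                     "n_control_carriers": n_ctrl})
        if n_case + n_ctrl > 0:
            X[f"freq[{label}]"] = inb.astype(float)
            fitted.append(label)
    fit = fit_logistic(y, X)
    tab = fit.or_table()
    table = pd.DataFrame(rows).set_index("bin")
    for col in ("OR", "ci_low", "ci_high", "p"):
        table[col] = np.nan
    for label in fitted:
        table.loc[label, ["OR", "ci_low", "ci_high", "p"]] = (
            tab.loc[f"freq[{label}]", ["OR", "ci_low", "ci_high", "p"]].to_numpy())

    # carrier-only tests, frequencies < 0.5%
    tests: dict[str, TrendResult] = {}
    sel = (~np.isnan(carrier_freq)) & (carrier_freq < 0.005)
    if sel.sum() >= 2 and np.ptp(carrier_freq[sel]) > 0:
        sub = subj.loc[sel]
        base = stratum_design(sub["stratum"])
        if adjust_assignment is not None:
            labels_adj, _ = gene_exposure(
                Cohort(cohort.variants, sub.reset_index(drop=True)), adjust_assignment)
            for cat in adjust_assignment.labels[1:]:
                col = (labels_adj == cat).astype(float)
                if 0 < col.sum() < len(col):
                    base[f"adj[{cat}]"] = col
        for name, x in (("continuous", carrier_freq[sel]),
                        ("log", np.log(carrier_freq[sel])),
                        ("two_group", (carrier_freq[sel] >= 0.001).astype(float))):
            if np.ptp(x) == 0:
                continue
            Xc = base.copy()
            Xc[name] = x
            try:
                tests[name] = _trend_from_fit(fit_logistic(sub["status"], Xc), name)
            except DesignError:
                continue
    return FrequencyBurden(table=table.reset_index(), carrier_tests=tests)


# ---------------------------------------------------------------------------
# single variants and age trends
# ---------------------------------------------------------------------------

def single_variant_or(cohort: Cohort, variant_id: str) -> TrendResult:
    """Stratum-adjusted OR for carriers of one variant vs gene non-carriers."""
    rec = cohort.variant(variant_id)
    gene = rec["gene"]
    v = cohort.variants
    gene_mis = set(v.loc[(v["gene"] == gene) & (v["consequence"] == "missense"),
                         "variant_id"])
    subj = cohort.subjects
    carries_v = np.array([variant_id in c for c in subj["carried"]])
    carries_other = np.array([
        any(x in gene_mis and x != variant_id for x in c) for c in subj["carried"]])
    keep = carries_v | ~carries_other
    sub = subj.loc[keep]
    x = carries_v[keep].astype(float)
    y = (sub["status"] == "case").to_numpy()
    n_case = int((x[y] > 0).sum())
    n_ctrl = int((x[~y] > 0).sum())
    if n_case + n_ctrl == 0:
        raise ValueError(f"variant {variant_id!r} has no carriers")
    if n_case == 0 or n_ctrl == 0:
        return TrendResult(term=variant_id,
                           odds_ratio=np.inf if n_ctrl == 0 else 0.0,
                           ci_low=np.nan, ci_high=np.nan, p=np.nan,
                           n=len(sub), unbounded=True)
    X = stratum_design(sub["stratum"])
    X["carrier"] = x
    fit = fit_logistic(sub["status"], X)
    res = _trend_from_fit(fit, "carrier")
    res.term = variant_id
    return res


def case_only_age_trend(cohort: Cohort, assignment: GroupAssignment,
                        top_category: str) -> TrendResult:
    """Case-only logistic trend: membership in the top risk category vs the
    other carrier categories, as a function of age at diagnosis."""
    if top_category not in assignment.labels:
        raise ValueError(f"unknown category {top_category!r}")
    exposure, _ = gene_exposure(cohort, assignment)
    subj = cohort.subjects
    keep = ((subj["status"] == "case").to_numpy()
            & np.array([lab is not None for lab in exposure])
            & subj["age"].notna().to_numpy())
    sub = subj.loc[keep]
    labs = exposure[keep]
    if len(set(labs)) < 2:
        raise ValueError("case carriers present in fewer than two categories")
    age = sub["age"].to_numpy(dtype=float)
    if np.ptp(age) == 0:
        raise ValueError("age is constant among case carriers")
    y = (labs == top_category).astype(float)
    X = stratum_design(sub["stratum"])
    X["age"] = age
    fit = fit_logistic(y, X)
    return _trend_from_fit(fit, "age")
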