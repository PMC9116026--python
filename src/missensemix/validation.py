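"""Held-out evaluation of trained risk models.

Effect sizes learned on the training set are *frozen* and entered as offsets
in the validation cohort; only the intercept and stratum coefficients are
re-estimated (case-control proportions may differ between the splits).  The
refit yields a per-subject case probability, hence expected case/control
counts per risk category and a goodness-of-fit chi-squared statistic against
the observed counts.  For mixture models the carrier disease-odds multiplier
is ``alpha * OR + (1 - alpha)`` -- exact for a two-component mixture of
carrier odds ratios -- with ``alpha`` re-weighted to the validation
case/control mix.  A composite model fits all risk categories across genes
jointly, excluding the (counted) subjects who carry eligible missense
variants in more than one gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import GroupBurdenModel, gene_exposure
from .cohort import Cohort
from .errors import DesignError
from .grouping import GroupAssignment
from .logistic import LogisticFit, fit_logistic, stratum_design


def adjusted_alpha(case_alpha: float, control_alpha: float,
                   validation_case_fraction: float) -> float:
    """Alpha transported to a cohort with a different case/control mix.

    ``case_alpha`` / ``control_alpha`` are the posterior-weighted proportions
    of training case / control carriers whose variant is risk-associated;
    the validation alpha is their mixture at the validation case fraction.
    """
    for name, v in (("case_alpha", case_alpha), ("control_alpha", control_alpha),
                    ("validation_case_fraction", validation_case_fraction)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0,1], got {v}")
    f = validation_case_fraction
    return f * case_alpha + (1 - f) * control_alpha


def mixture_category_logor(alpha_val, beta_mis: float) -> dict:
    """Per-category log carrier-odds multiplier log(alpha*e^beta + 1 - alpha)."""
    return {cat: float(np.log(a * np.exp(beta_mis) + (1 - a)))
            for cat, a in dict(alpha_val).items()}


def refit_nuisance(validation: Cohort, assignment: GroupAssignment,
                   fixed_betas: dict) -> LogisticFit:
    """Re-estimate intercept and stratum coefficients with category effects
    fixed as an offset."""
    exposure, _ = gene_exposure(validation, assignment)
    subj = validation.subjects
    if len(subj) == 0:
        raise ValueError("empty validation cohort")
    for lab, grp in subj.groupby("stratum"):
        if grp["status"].nunique() < 2:
            raise ValueError(f"validation stratum {lab!r} has a single outcome class")
    offset = np.array([fixed_betas.get(lab, 0.0) if lab is not None else 0.0
                       for lab in exposure])
    X = stratum_design(subj["stratum"])
    return fit_logistic(subj["status"], X, offset=offset)


@dataclass
class ValidationReport:
    """Observed vs expected category counts with the goodness-of-fit test."""

    table: pd.DataFrame
    chi_sq: float
    df: int
    p: float
    excluded_multigene: int = 0

    def summary(self) -> str:
        lines = [f"calibration: chi2={self.chi_sq:.3f} on df={self.df}, "
                 f"p={self.p:.3g}"]
        lines.append(f"{'category':<26}{'obs case':>9}{'exp case':>10}"
                     f"{'obs ctrl':>9}{'exp ctrl':>10}{'obs OR':>8}{'pred OR':>9}")
        for _, r in self.table.iterrows():
            obs_or = "NA" if np.isnan(r["obs_OR"]) else f"{r['obs_OR']:.2f}"
            lines.append(f"{r['category']:<26}{r['obs_cases']:>9.0f}"
                         f"{r['exp_cases']:>10.1f}{r['obs_controls']:>9.0f}"
                         f"{r['exp_controls']:>10.1f}{obs_or:>8}"
                         f"{r['pred_OR']:>9.2f}")
        return "\n".join(lines)


def gof_chisq(observed, expected) -> float:
    """Pearson chi-squared over paired observed/expected cells."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if (expected <= 0).any():
        raise ValueError("expected counts must be positive")
    return float(((observed - expected) ** 2 / expected).sum())


def calibration_gof(validation: Cohort, assignment: GroupAssignment,
                    category_logor: dict, df: int | None = None) -> ValidationReport:
    """Goodness of fit of frozen category effects on the validation cohort.

    ``category_logor`` maps category label to the frozen log carrier-odds
    term (a plain log-OR for logistic models; the mixture multiplier from
    :func:`mixture_category_logor` for mixture models).  Expected counts sum
    the refit model's predicted case probabilities within each category;
    the chi-squared statistic runs over category x outcome cells with
    ``df = #categories - 1`` unless overridden.
    """
    fit = refit_nuisance(validation, assignment, category_logor)
    exposure, _ = gene_exposure(validation, assignment)
    subj = validation.subjects
    X = stratum_design(subj["stratum"])
    eta = X.to_numpy() @ fit.params.to_numpy() + np.array(
        [category_logor.get(lab, 0.0) if lab is not None else 0.0
         for lab in exposure])
    prob = 1 / (1 + np.exp(-eta))
    y = (subj["status"] == "case").to_numpy()

    observed_or = GroupBurdenModel(validation, assignment).fit().table.set_index("category")

    rows, chi = [], 0.0
    labels = assignment.labels
    for lab in labels:
        inb = exposure == lab
        o_case, o_ctrl = float(y[inb].sum()), float((~y[inb]).sum())
        e_case, e_ctrl = float(prob[inb].sum()), float((1 - prob[inb]).sum())
        for o, e in ((o_case, e_case), (o_ctrl, e_ctrl)):
            if e == 0:
                raise ValueError(f"expected count of zero in category {lab!r}")
            if e < 5:
                warnings.warn(f"expected count {e:.2f} < 5 in category {lab!r}")
        chi += gof_chisq([o_case, o_ctrl], [e_case, e_ctrl])
        rows.append({"category": lab,
                     "obs_cases": o_case, "exp_cases": e_case,
                     "obs_controls": o_ctrl, "exp_controls": e_ctrl,
                     "obs_OR": observed_or.loc[lab, "OR"],
                     "obs_ci_low": observed_or.loc[lab, "ci_low"],
                     "obs_ci_high": observed_or.loc[lab, "ci_high"],
                     "pred_OR": float(np.exp(category_logor.get(lab, 0.0)))})
    use_df = (len(labels) - 1) if df is None else df
    use_df = max(use_df, 1)
    p = float(stats.chi2.sf(chi, use_df))
    return ValidationReport(table=pd.DataFrame(rows), chi_sq=float(chi),
                            df=use_df, p=p)


def pp_weighted_or(validation: Cohort, posteriors: pd.Series, beta_mis: float,
                   assignment: GroupAssignment) -> pd.DataFrame:
    """Predicted per-category ORs from training posterior probabilities.

    Each training variant's predicted carrier OR is ``PP * e^beta + (1-PP)``;
    the category prediction averages these over the validation carriers of
    its variants (carrier-count weighting).  Validation carriers of variants
    unseen in training are dropped, mirroring the restriction to the
    training-variant subset.
    """
    pp = dict(posteriors)
    exposure, _ = gene_exposure(validation, assignment)
    carriage = validation.carriage()
    mapping = assignment.mapping
    carriage = carriage.loc[carriage["variant_id"].isin(mapping)]
    rows = []
    for lab in assignment.labels:
        vids = carriage.loc[[mapping[v] == lab for v in carriage["variant_id"]],
                            "variant_id"]
        known = vids[vids.isin(pp)]
        n_dropped = int(len(vids) - len(known))
        if len(known) == 0:
            rows.append({"category": lab, "pred_OR": np.nan,
                         "n_carriers": 0, "n_dropped": n_dropped})
            continue
        pred = np.array([pp[v] * np.exp(beta_mis) + (1 - pp[v]) for v in known])
        rows.append({"category": lab, "pred_OR": float(pred.mean()),
                     "n_carriers": int(len(known)), "n_dropped": n_dropped})
    return pd.DataFrame(rows).set_index("category")


@dataclass
class CompositeResults:
    """Joint cross-gene category ORs with non-carriers as the baseline."""

    table: pd.DataFrame
    fit: LogisticFit
    excluded_multigene: int

    def summary(self) -> str:
        lines = [f"composite model: n={self.fit.n}, "
                 f"multi-gene carriers excluded={self.excluded_multigene}"]
        for _, r in self.table.iterrows():
            if np.isnan(r["OR"]):
                lines.append(f"  {r['gene']} {r['category']}: NA")
            else:
                lines.append(f"  {r['gene']} {r['category']}: OR {r['OR']:.2f} "
                             f"({r['ci_low']:.2f}–{r['ci_high']:.2f}) p={r['p']:.3g}")
        return "\n".join(lines)


def composite_fit(validation: Cohort, assignments) -> CompositeResults:
    """Single unconstrained logistic model over all genes' risk categories."""
    genes = [a.gene for a in assignments]
    if len(set(genes)) != len(genes):
        raise ValueError("assignments must cover distinct genes")
    per_gene = {}
    for a in assignments:
        per_gene[a.gene], _ = gene_exposure(validation, a)
    n = len(validation.subjects)
    carried_genes = np.zeros(n, dtype=int)
    for labs in per_gene.values():
        carried_genes += np.array([lab is not None for lab in labs])
    multi = carried_genes >= 2
    # subjects with two missense variants in ONE gene have exposure None there;
    # count them via raw carriage so they are excluded too
    keep = ~multi
    subj = validation.subjects.loc[keep].reset_index(drop=True)
    y = (subj["status"] == "case").astype(float).to_numpy()
    X = stratum_design(subj["stratum"])
    rows, fitted = [], []
    for a in assignments:
        labs = per_gene[a.gene][keep]
        for cat in a.labels:
            inb = labs == cat
            n_case, n_ctrl = int(inb[y == 1].sum()), int(inb[y == 0].sum())
            rows.append({"gene": a.gene, "category": cat,
                         "n_case_carriers": n_case, "n_control_carriers": n_ctrl})
            if n_case + n_ctrl > 0:
                X[f"{a.gene}:{cat}"] = inb.astype(float)
                fitted.append((a.gene, cat))
    try:
        fit = fit_logistic(y, X)
    except DesignError:
        raise
    tab = fit.or_table()
    table = pd.DataFrame(rows)
    for col in ("OR", "ci_low", "ci_high", "p"):
        table[col] = np.nan
    for gene, cat in fitted:
        sel = (table["gene"] == gene) & (table["category"] == cat)
        table.loc[sel, ["OR", "ci_low", "ci_high", "p"]] = (
            tab.loc[f"{gene}:{cat}", ["OR", "ci_low", "ci_high", "p"]].to_numpy())
    return CompositeResults(table=table, fit=fit, excluded_multigene=int(multi.sum()))
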