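"""EM-fitted mixture model of variant pathogenicity.

The model assumes that within each risk category only a proportion ``alpha``
of the observed missense variants is risk-associated; risk-associated
variants share a single carrier log-odds-ratio ``beta_mis`` while the rest
confer no risk.  Three forms are supported:

* ``constrained``   -- the missense OR is tied to the PTV OR (one shared
                       risk coefficient);
* ``unconstrained`` -- the missense OR is free, the PTV OR separate;
* ``two_level``     -- two latent risk states: a "high" state tied to the
                       PTV OR and a "moderate" state with its own OR, each
                       with its own per-category proportion.

Fitting alternates an expectation step -- the posterior probability that
each variant is risk-associated given the case-control data on its carriers
-- with a maximisation step in which each missense carrier is expanded into
posterior-weighted pseudo-observations and all coefficients are refit by
weighted logistic regression; ``alpha`` is updated as the unweighted mean
posterior over the unique variants of each category.  Carriers of PTVs in
the gene are retained (weight one) so the missense OR can be tied to the
PTV OR; subjects carrying several eligible missense variants of the gene
are excluded with a logged count, and subjects with both a PTV and a
missense variant enter as PTV carriers only.

The observed-data log-likelihood is monitored every iteration and is
guaranteed non-decreasing (standard EM argument); confidence intervals for
``alpha`` use the profile likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, log_expit, logsumexp

from .association import ptv_carrier_mask
from .cohort import Cohort
from .grouping import GroupAssignment
from .logistic import fit_logistic, stratum_design

MODES = ("constrained", "unconstrained", "two_level")


@dataclass
class MixtureSpec:
    """Configuration of one mixture fit."""

    gene: str
    mode: str = "constrained"
    include_ptv_carriers: bool = True
    tol: float = 1e-6
    max_iter: int = 500

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class VariantLikelihoods:
    """Carrier-data likelihood of one variant under each latent state."""

    variant_id: str
    L1: float
    L0: float


def component_likelihoods(cohort: Cohort, variant_id: str, nuisance: dict,
                          beta_state: float) -> VariantLikelihoods:
    """Likelihood of a variant's carrier data under one risk state.

    ``nuisance`` maps "intercept" and "stratum[<label>]" to log-odds terms
    (absent stratum keys contribute zero -- the reference stratum).
    ``L1`` multiplies Bernoulli terms with the state's log-OR added to each
    carrier's linear predictor; ``L0`` uses a log-OR of zero.  Non-carriers
    are excluded: their terms cancel in the posterior ratio.  A variant with
    no carriers has ``L1 == L0 == 1``.
    """
    cohort.variant(variant_id)  # raises on unknown id
    subj = cohort.subjects
    carries = np.array([variant_id in c for c in subj["carried"]])
    logL1 = logL0 = 0.0
    for _, row in subj.loc[carries].iterrows():
        eta = nuisance.get("intercept", 0.0) + nuisance.get(
            f"stratum[{row['stratum']}]", 0.0)
        y = 1.0 if row["status"] == "case" else 0.0
        for beta, acc in ((beta_state, "L1"), (0.0, "L0")):
            ll = y * log_expit(eta + beta) + (1 - y) * log_expit(-(eta + beta))
            if acc == "L1":
                logL1 += ll
            else:
                logL0 += ll
    return VariantLikelihoods(variant_id, float(np.exp(logL1)), float(np.exp(logL0)))


def e_step(likelihoods: VariantLikelihoods, alpha: float) -> float:
    """Posterior probability that the variant is risk-associated."""
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0,1]")
    num = alpha * likelihoods.L1
    den = num + (1 - alpha) * likelihoods.L0
    return num / den if den > 0 else 0.0


def compare_loglik(fitA: "MixtureResults | object", fitB) -> float:
    """2 x (loglik A - loglik B); both fits must be on identical data."""
    key_a, key_b = getattr(fitA, "data_key", None), getattr(fitB, "data_key", None)
    if key_a is not None and key_b is not None and key_a != key_b:
        raise ValueError("fits were computed on different subject sets")
    return 2.0 * (fitA.loglik - fitB.loglik)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class MissenseMixtureModel:
    """Per-category pathogenicity mixture for one gene, fitted by EM."""

    def __init__(self, cohort: Cohort, assignment: GroupAssignment,
                 spec: MixtureSpec | None = None, mode: str | None = None):
        if spec is None:
            spec = MixtureSpec(gene=assignment.gene, mode=mode or "constrained")
        elif mode is not None:
            raise ValueError("give either spec or mode, not both")
        if spec.gene != assignment.gene:
            raise ValueError("spec gene does not match assignment gene")
        self.spec = spec
        self.cohort = cohort
        self.assignment = assignment
        self._prepare()

    # -- data preparation --------------------------------------------------
    def _prepare(self) -> None:
        spec, subj = self.spec, self.cohort.subjects
        self.categories = list(self.assignment.labels)
        self.var_ids = list(self.assignment.mapping)
        var_index = {v: i for i, v in enumerate(self.var_ids)}
        self.var_cat = np.array(
            [self.categories.index(self.assignment.mapping[v]) for v in self.var_ids])

        ptv = ptv_carrier_mask(self.cohort, spec.gene)
        mis_count = np.array([sum(c in var_index for c in carried)
                              for carried in subj["carried"]])
        multi = (mis_count > 1) & ~ptv
        keep = ~multi
        if not spec.include_ptv_carriers:
            keep &= ~ptv
        self.n_excluded_multi = int(multi.sum())

        sub = subj.loc[keep].reset_index(drop=True)
        ptv = ptv[keep]
        y = (sub["status"] == "case").to_numpy().astype(int)
        strata = sub["stratum"].astype(str)
        self.strata_labels = sorted(set(strata))
        self.reference = strata.value_counts().idxmax()
        code = {lab: i for i, lab in enumerate(self.strata_labels)}
        scode = strata.map(code).to_numpy()
        n_strat = len(self.strata_labels)

        car_var, car_y, car_s = [], [], []
        is_carrier = np.zeros(len(sub), dtype=bool)
        for i, carried in enumerate(sub["carried"]):
            if ptv[i]:
                continue  # PTV status dominates joint carriers
            hits = [var_index[c] for c in carried if c in var_index]
            if hits:
                is_carrier[i] = True
                car_var.append(hits[0])
                car_y.append(y[i])
                car_s.append(scode[i])
        self.car_var = np.array(car_var, dtype=int)
        self.car_y = np.array(car_y, dtype=float)
        self.car_s = np.array(car_s, dtype=int)
        if len(self.car_var) == 0 and not ptv.any():
            raise ValueError("no carriers at all: nothing to fit")

        def cells(mask):
            idx = scode[mask] * 2 + y[mask]
            counts = np.bincount(idx, minlength=2 * n_strat)
            out = [(s, yy, counts[s * 2 + yy])
                   for s in range(n_strat) for yy in (0, 1) if counts[s * 2 + yy] > 0]
            return out

        self.nc_cells = cells(~is_carrier & ~ptv)
        self.ptv_cells = cells(ptv)
        self.has_ptv = len(self.ptv_cells) > 0
        self.n_subjects = int(len(sub))
        self.data_key = (spec.gene, self.n_subjects,
                         hash(tuple(sub["subject_id"])))

        # per-variant carrier bookkeeping
        nv = len(self.var_ids)
        self.var_n_carriers = np.bincount(self.car_var, minlength=nv)
        self.var_has_control = np.bincount(
            self.car_var, weights=(1 - self.car_y), minlength=nv) > 0

        # Fixed design matrix; only the weight vector changes across EM steps.
        # Carrier pseudo-observations are aggregated into (stratum, outcome)
        # cells per latent state -- the weighted logistic fit depends on the
        # rows only through these sufficient-statistic cells, so the collapse
        # is exact and keeps the M-step matrix tiny.
        self.exposure_cols = {
            "constrained": ["risk"], "unconstrained": ["mis", "ptv"],
            "two_level": ["high", "moderate"]}[spec.mode]
        if not self.has_ptv and "ptv" in self.exposure_cols:
            self.exposure_cols = ["mis"]
        cols = (["intercept"]
                + [f"stratum[{lab}]" for lab in self.strata_labels
                   if lab != self.reference]
                + self.exposure_cols)
        self._columns = cols
        scol = {lab: cols.index(f"stratum[{lab}]") for lab in self.strata_labels
                if lab != self.reference}

        n_states = 2 if spec.mode == "two_level" else 1
        self._n_states = n_states
        self._car_cell = self.car_s * 2 + self.car_y.astype(int)
        n_cells = 2 * n_strat
        mis_cols = {"constrained": ["risk"], "unconstrained": ["mis"],
                    "two_level": ["high", "moderate"]}[spec.mode]
        nrows = len(self.nc_cells) + len(self.ptv_cells) + (n_states + 1) * n_cells
        X = np.zeros((nrows, len(cols)))
        X[:, 0] = 1.0
        y_rows = np.zeros(nrows)
        w_fixed = np.zeros(nrows)
        r = 0
        for s, yy, cnt in self.nc_cells:
            if self.strata_labels[s] != self.reference:
                X[r, scol[self.strata_labels[s]]] = 1.0
            y_rows[r], w_fixed[r] = yy, cnt
            r += 1
        ptv_col = {"constrained": "risk", "unconstrained": "ptv",
                   "two_level": "high"}[spec.mode]
        for s, yy, cnt in self.ptv_cells:
            if self.strata_labels[s] != self.reference:
                X[r, scol[self.strata_labels[s]]] = 1.0
            X[r, cols.index(ptv_col)] = 1.0
            y_rows[r], w_fixed[r] = yy, cnt
            r += 1
        self._car_row_start = r
        for state_col in mis_cols + [None]:   # one cell block per state + benign
            for cell in range(n_cells):
                s, yy = divmod(cell, 2)
                lab = self.strata_labels[s]
                if lab != self.reference:
                    X[r, scol[lab]] = 1.0
                if state_col is not None:
                    X[r, cols.index(state_col)] = 1.0
                y_rows[r] = yy
                r += 1
        self._X = pd.DataFrame(X, columns=cols)
        self._y_rows = y_rows
        self._w_fixed = w_fixed
        self._n_cells = n_cells

    # -- likelihood machinery ----------------------------------------------
    def _stratum_eta(self, params: pd.Series) -> np.ndarray:
        eta = np.full(len(self.strata_labels), float(params["intercept"]))
        for i, lab in enumerate(self.strata_labels):
            if lab != self.reference:
                eta[i] += float(params[f"stratum[{lab}]"])
        return eta

    def _betas(self, params: pd.Series) -> tuple[list[float], float]:
        """Risk-state log-ORs for missense carriers, and the PTV log-OR."""
        mode = self.spec.mode
        if mode == "constrained":
            b = float(params["risk"])
            return [b], b
        if mode == "two_level":
            return [float(params["high"]), float(params["moderate"])], float(params["high"])
        b_mis = float(params["mis"])
        b_ptv = float(params["ptv"]) if "ptv" in params.index else np.nan
        return [b_mis], b_ptv

    def _variant_logL(self, params: pd.Series) -> np.ndarray:
        """(n_states+1, n_variants) log carrier-data likelihoods."""
        eta = self._stratum_eta(params)[self.car_s]
        betas, _ = self._betas(params)
        nv = len(self.var_ids)
        out = np.zeros((len(betas) + 1, nv))
        for k, b in enumerate(list(betas) + [0.0]):
            ll = (self.car_y * log_expit(eta + b)
                  + (1 - self.car_y) * log_expit(-(eta + b)))
            out[k] = np.bincount(self.car_var, weights=ll, minlength=nv)
        return out

    def _posteriors(self, params: pd.Series, alpha: np.ndarray) -> np.ndarray:
        """(n_states, n_variants) posterior state probabilities."""
        logL = self._variant_logL(params)
        a = alpha[:, self.var_cat]                       # (n_states, nv)
        benign = np.clip(1.0 - a.sum(axis=0), 0.0, 1.0)  # (nv,)
        with np.errstate(divide="ignore"):
            terms = np.vstack([np.log(a) + logL[:-1], np.log(benign) + logL[-1]])
        den = logsumexp(terms, axis=0)
        post = np.exp(terms[:-1] - den)
        return post

    def _obs_loglik(self, params: pd.Series, alpha: np.ndarray) -> float:
        eta_s = self._stratum_eta(params)
        _, b_ptv = self._betas(params)
        ll = 0.0
        for s, yy, cnt in self.nc_cells:
            ll += cnt * (log_expit(eta_s[s]) if yy else log_expit(-eta_s[s]))
        for s, yy, cnt in self.ptv_cells:
            e = eta_s[s] + b_ptv
            ll += cnt * (log_expit(e) if yy else log_expit(-e))
        logL = self._variant_logL(params)
        a = alpha[:, self.var_cat]
        benign = np.clip(1.0 - a.sum(axis=0), 0.0, 1.0)
        with np.errstate(divide="ignore"):
            terms = np.vstack([np.log(a) + logL[:-1], np.log(benign) + logL[-1]])
        ll += logsumexp(terms, axis=0).sum()
        return float(ll)

    # -- fitting -------------------------------------------------------------
    def _initial_params(self, rng=None) -> tuple[pd.Series, np.ndarray]:
        # nuisance from the non-carrier cells, PTV coefficient from a PTV fit
        ys, ws, strat = [], [], []
        for s, yy, cnt in self.nc_cells:
            strat.append(self.strata_labels[s]); ys.append(yy); ws.append(cnt)
        params = pd.Series(0.0, index=self._columns)
        try:
            X0 = stratum_design(strat, reference=self.reference)
            base = fit_logistic(ys, X0, weights=ws)
            for term in base.params.index:
                params[term] = base.params[term]
        except ValueError:
            # degenerate tiny data (one outcome class among non-carriers):
            # smoothed crude intercept, stratum effects start at zero
            n1 = sum(w for yy, w in zip(ys, ws) if yy == 1)
            n0 = sum(w for yy, w in zip(ys, ws) if yy == 0)
            params["intercept"] = np.log((n1 + 0.5) / (n0 + 0.5))
        b_ptv = np.log(2.0)
        if self.has_ptv:
            try:
                strat2, ys2, ws2, ind = list(strat), list(ys), list(ws), [0.0] * len(ys)
                for s, yy, cnt in self.ptv_cells:
                    strat2.append(self.strata_labels[s]); ys2.append(yy)
                    ws2.append(cnt); ind.append(1.0)
                X1 = stratum_design(strat2, reference=self.reference)
                X1["ptv_ind"] = ind
                b_ptv = float(fit_logistic(ys2, X1, weights=ws2,
                                           check_separation=False
                                           ).params["ptv_ind"])
                b_ptv = float(np.clip(b_ptv, -5.0, 5.0))
            except ValueError:
                pass
        mode = self.spec.mode
        if mode == "constrained":
            params["risk"] = b_ptv
        elif mode == "two_level":
            params["high"] = b_ptv
            params["moderate"] = np.log(1.3)
        else:
            params["mis"] = np.log(1.5)
            if "ptv" in params.index:
                params["ptv"] = b_ptv
        n_states = self._n_states
        alpha = np.full((n_states, len(self.categories)),
                        0.05 if n_states == 2 else 0.1)
        if rng is not None:
            alpha = rng.uniform(0.02, 0.5, size=alpha.shape)
            if n_states == 2:
                alpha *= 0.5
            for colname in self.exposure_cols:
                params[colname] += rng.normal(0, 0.5)
        return params, alpha

    def fit(self, init=None, n_starts: int = 3, seed: int = 0,
            fix_alpha=None) -> "MixtureResults":
        """Run EM, optionally from several jittered starts, keep the best.

        ``fix_alpha`` freezes per-category proportions: a scalar applies to
        every category, a mapping {label: value} to selected ones (for the
        two-level model, values may be (high, moderate) pairs).
        """
        best = None
        rng = np.random.default_rng(seed)
        for s in range(max(1, n_starts)):
            if init is not None and s == 0:
                start = init
            else:
                start = self._initial_params(rng if s > 0 else None)
            out = self._em(start, fix_alpha=fix_alpha)
            if best is None or out.loglik > best.loglik:
                best = out
        return best

    def _fixed_alpha_mask(self, fix_alpha):
        mask = np.zeros((self._n_states, len(self.categories)), dtype=bool)
        values = np.zeros_like(mask, dtype=float)
        if fix_alpha is None:
            return mask, values
        if np.isscalar(fix_alpha):
            fix_alpha = {c: fix_alpha for c in self.categories}
        for label, val in fix_alpha.items():
            j = self.categories.index(label)
            val = np.atleast_1d(val).astype(float)
            for k in range(self._n_states):
                mask[k, j] = True
                values[k, j] = val[k] if len(val) > 1 else (
                    val[0] if k == 0 else 0.0)
        return mask, values

    def _em(self, start, fix_alpha=None) -> "MixtureResults":
        spec = self.spec
        params, alpha = start
        params = params.copy()
        alpha = np.array(alpha, dtype=float)
        if alpha.ndim == 1:
            alpha = alpha[None, :]
        fmask, fvals = self._fixed_alpha_mask(fix_alpha)
        alpha[fmask] = fvals[fmask]

        nv = len(self.var_ids)
        cat_sizes = np.bincount(self.var_cat, minlength=len(self.categories))
        ll = self._obs_loglik(params, alpha)
        trace = [ll]
        converged = False
        start_params = params.to_numpy()
        for _ in range(spec.max_iter):
            post = self._posteriors(params, alpha)            # E step
            # alpha update: unweighted mean posterior over unique variants
            for k in range(self._n_states):
                sums = np.bincount(self.var_cat, weights=post[k],
                                   minlength=len(self.categories))
                new = np.divide(sums, cat_sizes, out=np.zeros_like(sums),
                                where=cat_sizes > 0)
                alpha[k] = np.where(fmask[k], alpha[k], new)
            # M step: weighted logistic refit on the aggregated cells
            w = self._w_fixed.copy()
            r0 = self._car_row_start
            nc = self._n_cells
            p_car = post[:, self.car_var]
            for k in range(self._n_states):
                w[r0 + k * nc: r0 + (k + 1) * nc] = np.bincount(
                    self._car_cell, weights=p_car[k], minlength=nc)
            w[r0 + self._n_states * nc:] = np.bincount(
                self._car_cell, weights=1.0 - p_car.sum(axis=0), minlength=nc)
            # exposure columns with no remaining weight (alpha pinned at 0 and
            # no PTV rows) are held at their current value rather than fitted
            active = [c for c in self._columns
                      if c not in self.exposure_cols
                      or (w * self._X[c].to_numpy()).sum() > 1e-12]
            if len(active) == len(self._columns):
                fit = fit_logistic(self._y_rows, self._X, weights=w,
                                   check_separation=False, check_rank=False,
                                   start_params=start_params)
                params = fit.params
                start_params = params.to_numpy()
            else:
                fit = fit_logistic(self._y_rows, self._X[active], weights=w,
                                   check_separation=False, check_rank=False)
                params = params.copy()
                params[active] = fit.params
                start_params = None
            self._last_mstep = fit
            ll_new = self._obs_loglik(params, alpha)
            trace.append(ll_new)
            if abs(ll_new - ll) < spec.tol:
                converged = True
                ll = ll_new
                break
            ll = ll_new
        post = self._posteriors(params, alpha)
        return MixtureResults(model=self, params=params, alpha_matrix=alpha.copy(),
                              posterior_matrix=post, loglik=ll,
                              loglik_trace=np.array(trace), converged=converged,
                              mstep_fit=self._last_mstep)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class MixtureResults:
    """Fitted mixture: proportions, odds ratios, posteriors, diagnostics."""

    model: MissenseMixtureModel
    params: pd.Series
    alpha_matrix: np.ndarray          # (n_states, n_categories)
    posterior_matrix: np.ndarray      # (n_states, n_variants)
    loglik: float
    loglik_trace: np.ndarray
    converged: bool
    mstep_fit: object = None

    # -- identity ----------------------------------------------------------
    @property
    def data_key(self):
        return self.model.data_key

    @property
    def mode(self) -> str:
        return self.model.spec.mode

    # -- parameters ---------------------------------------------------------
    @property
    def alpha(self):
        cats = self.model.categories
        if self.mode == "two_level":
            return pd.DataFrame(self.alpha_matrix.T, index=cats,
                                columns=["high", "moderate"])
        return pd.Series(self.alpha_matrix[0], index=cats, name="alpha")

    @property
    def beta_mis(self) -> float:
        return self.model._betas(self.params)[0][0]

    @property
    def beta_ptv(self) -> float:
        return self.model._betas(self.params)[1]

    @property
    def nuisance(self) -> dict:
        keys = ["intercept"] + [f"stratum[{lab}]" for lab in self.model.strata_labels
                                if lab != self.model.reference]
        return {k: float(self.params[k]) for k in keys}

    @property
    def posteriors(self):
        ids = self.model.var_ids
        if self.mode == "two_level":
            benign = 1 - self.posterior_matrix.sum(axis=0)
            return pd.DataFrame({"high": self.posterior_matrix[0],
                                 "moderate": self.posterior_matrix[1],
                                 "benign": benign}, index=ids)
        return pd.Series(self.posterior_matrix[0], index=ids, name="posterior")

    @property
    def n_iter(self) -> int:
        return len(self.loglik_trace) - 1

    def or_table(self, level: float = 0.95) -> pd.DataFrame:
        """Wald odds ratios for the risk-state coefficients.

        Standard errors come from the final weighted M-step fit; they ignore
        the uncertainty in alpha and are therefore approximate.
        """
        fit = self.mstep_fit
        tab = fit.or_table(level)
        return tab.loc[[c for c in self.model.exposure_cols if c in tab.index]]

    # -- alpha summaries -----------------------------------------------------
    def naive_alpha(self):
        """Mean posterior over all catalog variants per category (biased
        upward under case enrichment)."""
        return self.alpha

    def control_only_alpha(self):
        """Per-category mean posterior over variants with >=1 control carrier.

        Restricting to variants observed in controls counteracts the upward
        ascertainment bias of the naive proportions in case-enriched data.
        """
        m = self.model
        has_ctrl = m.var_has_control
        cats = m.categories
        out = np.full((m._n_states, len(cats)), np.nan)
        for j in range(len(cats)):
            sel = (m.var_cat == j) & has_ctrl
            if sel.any():
                out[:, j] = self.posterior_matrix[:, sel].mean(axis=1)
            else:
                warnings.warn(f"category {cats[j]!r} has no control-carrying "
                              "variants; control-only alpha is NA")
        if self.mode == "two_level":
            return pd.DataFrame(out.T, index=cats, columns=["high", "moderate"])
        return pd.Series(out[0], index=cats, name="control_only_alpha")

    def carrier_pathogenic_fractions(self) -> pd.DataFrame:
        """Posterior-weighted fraction of case / control carriers whose variant
        is risk-associated, per category (feeds the validation alpha
        adjustment)."""
        m = self.model
        p_car = self.posterior_matrix.sum(axis=0)[m.car_var]
        rows = []
        for j, cat in enumerate(m.categories):
            sel = m.var_cat[m.car_var] == j
            case = sel & (m.car_y == 1)
            ctrl = sel & (m.car_y == 0)
            rows.append({
                "category": cat,
                "case_alpha": float(p_car[case].mean()) if case.any() else np.nan,
                "control_alpha": float(p_car[ctrl].mean()) if ctrl.any() else np.nan,
                "n_case_carriers": int(case.sum()),
                "n_control_carriers": int(ctrl.sum()),
            })
        return pd.DataFrame(rows).set_index("category")

    # -- profile CI ----------------------------------------------------------
    def alpha_profile_ci(self, category: str, level: float = 0.95,
                         tol: float = 1e-3) -> tuple[float, float]:
        """Profile-likelihood confidence interval for one category's alpha.

        The category's proportion is fixed on a sequence of values while all
        other parameters are re-maximised by EM; the interval is the set
        where twice the log-likelihood drop stays within the chi-square(1)
        quantile.  Clipped to [0, 1].
        """
        m = self.model
        if category not in m.categories:
            raise ValueError(f"unknown category {category!r}")
        cut = self.loglik - stats.chi2.ppf(level, df=1) / 2
        a_hat = (float(self.alpha.loc[category]) if self.mode != "two_level"
                 else float(self.alpha.loc[category, "high"]))

        cache: dict[float, float] = {}

        def profile(a: float) -> float:
            a = round(float(a), 10)
            if a not in cache:
                res = m._em((self.params, self.alpha_matrix),
                            fix_alpha={category: a})
                cache[a] = res.loglik
            return cache[a]

        if profile(0.0) >= cut and profile(1.0) >= cut:
            warnings.warn(f"profile likelihood flat for {category!r}; "
                          "returning the full [0, 1] interval")
            return 0.0, 1.0

        def bisect(lo, hi):
            # exactly one endpoint lies inside {a: profile(a) >= cut}
            in_lo = profile(lo) >= cut
            while hi - lo > tol:
                mid = 0.5 * (lo + hi)
                if (profile(mid) >= cut) == in_lo:
                    lo = mid
                else:
                    hi = mid
            return 0.5 * (lo + hi)

        lower = 0.0 if profile(0.0) >= cut else bisect(0.0, a_hat)
        upper = 1.0 if profile(1.0) >= cut else bisect(a_hat, 1.0)
        return float(min(lower, a_hat)), float(max(upper, a_hat))

    def alpha_bootstrap_ci(self, category: str, B: int = 200,
                           level: float = 0.95, seed: int = 0):
        """Percentile bootstrap interval for one category's alpha.

        Variants are resampled with replacement within each category (their
        carriers travel with them; the non-carrier background is held fixed)
        and the EM refit from the full-data solution.  Slower than the
        profile interval; intended as an independent cross-check.
        """
        m = self.model
        if category not in m.categories:
            raise ValueError(f"unknown category {category!r}")
        rng = np.random.default_rng(seed)
        cat_idx = m.categories.index(category)
        nv = len(m.var_ids)
        car_by_var = [np.flatnonzero(m.car_var == v) for v in range(nv)]
        orig = (m.car_var, m.car_y, m.car_s, m._car_cell, m.var_cat)
        draws = []
        try:
            for _ in range(B):
                new_var_cat = np.empty(nv, dtype=int)
                src = np.empty(nv, dtype=int)
                pos = 0
                for j in range(len(m.categories)):
                    members = np.flatnonzero(orig[4] == j)
                    pick = rng.choice(members, size=len(members), replace=True)
                    src[pos:pos + len(pick)] = pick
                    new_var_cat[pos:pos + len(pick)] = j
                    pos += len(pick)
                car_var, car_rows = [], []
                for new_v, old_v in enumerate(src):
                    rows = car_by_var[old_v]
                    car_var.extend([new_v] * len(rows))
                    car_rows.extend(rows)
                car_rows = np.asarray(car_rows, dtype=int)
                m.car_var = np.asarray(car_var, dtype=int)
                m.car_y = orig[1][car_rows]
                m.car_s = orig[2][car_rows]
                m._car_cell = m.car_s * 2 + m.car_y.astype(int)
                m.var_cat = new_var_cat
                res = m._em((self.params, self.alpha_matrix))
                a = (res.alpha_matrix[0, cat_idx] if m._n_states == 1
                     else res.alpha_matrix[:, cat_idx].sum())
                draws.append(float(a))
        finally:
            m.car_var, m.car_y, m.car_s, m._car_cell, m.var_cat = orig
        lo, hi = np.quantile(draws, [(1 - level) / 2, (1 + level) / 2])
        return float(lo), float(hi)

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        m = self.model
        head = (f"mixture fit ({self.mode}) for {m.spec.gene}: "
                f"n={m.n_subjects}, loglik={self.loglik:.4f}, "
                f"iterations={self.n_iter}, converged={self.converged}, "
                f"multi-missense excluded={m.n_excluded_multi}")
        ors = self.or_table()
        lines = [head, f"missense OR {np.exp(self.beta_mis):.3f}"
                 + (f", PTV OR {np.exp(self.beta_ptv):.3f}"
                    if np.isfinite(self.beta_ptv) else "")]
        for term, row in ors.iterrows():
            lines.append(f"  {term}: OR {row['OR']:.3f} "
                         f"({row['ci_low']:.3f}–{row['ci_high']:.3f})")
        lines.append("alpha (naive / control-only):")
        co = self.control_only_alpha()
        if self.mode == "two_level":
            for cat in m.categories:
                lines.append(f"  {cat}: high {self.alpha.loc[cat, 'high']:.4f}"
                             f"/{co.loc[cat, 'high']:.4f}, "
                             f"moderate {self.alpha.loc[cat, 'moderate']:.4f}"
                             f"/{co.loc[cat, 'moderate']:.4f}")
        else:
            for cat in m.categories:
                c = co[cat]
                lines.append(f"  {cat}: {self.alpha[cat]:.4f} / "
                             + (f"{c:.4f}" if np.isfinite(c) else "NA"))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        alpha = self.alpha
        co = self.control_only_alpha()
        post = self.posteriors
        return {
            "gene": self.model.spec.gene,
            "mode": self.mode,
            "loglik": self.loglik,
            "converged": self.converged,
            "beta_mis": self.beta_mis,
            "beta_ptv": None if not np.isfinite(self.beta_ptv) else self.beta_ptv,
            "alpha": (alpha.to_dict() if isinstance(alpha, pd.Series)
                      else {k: list(v) for k, v in alpha.iterrows()}),
            "control_only_alpha": (
                {k: (None if not np.isfinite(v) else v) for k, v in co.items()}
                if isinstance(co, pd.Series)
                else {k: list(v) for k, v in co.iterrows()}),
            "posteriors": (post.to_dict() if isinstance(post, pd.Series)
                           else {k: list(v) for k, v in post.iterrows()}),
            "loglik_trace": [float(x) for x in self.loglik_trace],
            "nuisance": self.nuisance,
        }


def fit_mixture(cohort: Cohort, assignment: GroupAssignment,
                spec: MixtureSpec | None = None, init=None,
                n_starts: int = 3, seed: int = 0,
                fix_alpha=None) -> MixtureResults:
    """Functional wrapper around :class:`MissenseMixtureModel`."""
    return MissenseMixtureModel(cohort, assignment, spec=spec).fit(
        init=init, n_starts=n_starts, seed=seed, fix_alpha=fix_alpha)


def control_only_alpha(fit: MixtureResults, cohort=None, assignment=None):
    """Per-category alpha over variants seen in at least one control."""
    return fit.control_only_alpha()


def alpha_profile_ci(cohort, assignment, spec, fit: MixtureResults,
                     category: str, level: float = 0.95):
    """Profile-likelihood interval for one category's alpha (wrapper)."""
    return fit.alpha_profile_ci(category, level=level)
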