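"""Maximum-likelihood stratified logistic regression.

Thin, strict surface over statsmodels' binomial GLM (IRLS): it adds the rank
and separation checks the analyses rely on, accepts fractional observation
weights (needed by the EM M-step), and packages estimates with Wald
confidence intervals on the odds-ratio scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DesignError, SeparationError

#: |coefficient| beyond which a binary-exposure logit fit is treated as separated
SEPARATION_BOUND = 15.0


@dataclass
class LogisticFit:
    """Coefficients (log-odds), their covariance, and fit diagnostics."""

    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    n: int
    converged: bool

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def wald_p(self) -> pd.Series:
        z = self.params / self.se()
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)

    def or_table(self, level: float = 0.95) -> pd.DataFrame:
        """Odds ratios with Wald confidence limits and p-values per term."""
        z = stats.norm.ppf(0.5 + level / 2)
        se = self.se()
        return pd.DataFrame({
            "OR": np.exp(self.params),
            "ci_low": np.exp(self.params - z * se),
            "ci_high": np.exp(self.params + z * se),
            "p": self.wald_p(),
        })

    def summary(self) -> str:
        tab = self.or_table()
        lines = [f"logistic fit: n={self.n}, loglik={self.loglik:.4f}, "
                 f"converged={self.converged}",
                 f"{'term':<28}{'OR':>10}{'95% CI':>22}{'p':>12}"]
        for term, row in tab.iterrows():
            lines.append(f"{term:<28}{row['OR']:>10.4f}"
                         f"{'(' + format(row['ci_low'], '.4f') + '–' + format(row['ci_high'], '.4f') + ')':>22}"
                         f"{row['p']:>12.3g}")
        return "\n".join(lines)


def fit_logistic(outcome, design: pd.DataFrame, weights=None, offset=None,
                 check_separation: bool = True, check_rank: bool = True,
                 start_params=None) -> LogisticFit:
    """Fit a logistic model by IRLS.

    ``outcome`` is a 0/1 (or case/control string) vector; ``design`` a term
    matrix including any intercept; ``weights`` optional non-negative
    frequency weights (fractional allowed); ``offset`` an optional fixed
    linear-predictor component (used when effect sizes are frozen).
    """
    y = np.asarray(
        [1 if v in (1, True, "case") else 0 for v in np.asarray(outcome).ravel()],
        dtype=float)
    X = pd.DataFrame(design).astype(float)
    w = None if weights is None else np.asarray(weights, dtype=float)
    if w is not None:
        if (w < 0).any():
            raise ValueError("negative weights")
        keep = w > 0
        y, X, w = y[keep], X.loc[keep], w[keep]
        if offset is not None:
            offset = np.asarray(offset, dtype=float)[keep]
    wts = np.ones(len(y)) if w is None else w
    if min(wts[y == 1].sum() if (y == 1).any() else 0,
           wts[y == 0].sum() if (y == 0).any() else 0) <= 0:
        raise ValueError("both outcome classes must be present with positive weight")
    if check_rank and np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise DesignError(f"design matrix is rank deficient (columns: {list(X.columns)})")

    model = sm.GLM(y, X, family=sm.families.Binomial(),
                   freq_weights=w, offset=offset)
    import warnings as _warnings
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always", PerfectSeparationWarning)
        res = model.fit(maxiter=100, tol=1e-10, start_params=start_params)
    params = pd.Series(res.params, index=X.columns)
    if check_separation:
        if any(issubclass(c.category, PerfectSeparationWarning) for c in caught):
            raise SeparationError("perfect separation detected by IRLS")
        # diverging indicator-term coefficients (continuous covariates can
        # carry legitimately large per-unit slopes and are exempt)
        binary = [c for c in X.columns
                  if np.isin(X[c].to_numpy(), (0.0, 1.0)).all()]
        big = {t: float(params[t]) for t in binary
               if abs(params[t]) > SEPARATION_BOUND}
        if big:
            raise SeparationError(
                "diverging coefficient(s) suggest complete separation: "
                + ", ".join(f"{t}={v:.2f}" for t, v in big.items()))
    cov = pd.DataFrame(np.asarray(res.cov_params()), index=X.columns, columns=X.columns)
    return LogisticFit(params=params, cov=cov, loglik=float(res.llf),
                       n=int(round(wts.sum())), converged=bool(res.converged))


def stratum_design(strata, reference: str | None = None) -> pd.DataFrame:
    """Intercept + dummy columns for all strata except the reference.

    The reference defaults to the largest stratum, which keeps the intercept
    well determined when small country strata are present.
    """
    s = pd.Series(strata).astype(str).reset_index(drop=True)
    if reference is None:
        reference = s.value_counts().idxmax()
    X = pd.DataFrame({"intercept": np.ones(len(s))})
    for label in sorted(set(s)):
        if label != reference:
            X[f"stratum[{label}]"] = (s == label).astype(float)
    return X
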