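"""Logistic/linear model fitting, instrument-strength testing, contingency
odds ratios and population attributable fractions.

Maximum-likelihood fits are delegated to statsmodels; this module wraps them
in a uniform :class:`FitResult` (per-term :class:`Estimate`, log-likelihood,
n, convergence flag) so the MR layer can compose them.  Confidence intervals
use the normal approximation beta +- 1.96*se throughout, matching the
arithmetic of printed epidemiological tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "Estimate",
    "FitResult",
    "ImprovementChisq",
    "ADJUSTMENT_SETS",
    "adjustment_covariates",
    "fit_logistic",
    "fit_linear",
    "two_by_two_or",
    "improvement_chisq",
    "paf",
]

_Z95 = 1.959963984540054  # Phi^-1(0.975)

PRIMARY_COVARIATES = ["age", "sex", "education", "apoe4", "pc1", "pc2", "pc3", "pc4", "pc5"]
HEALTH_COVARIATES = PRIMARY_COVARIATES + ["stroke", "hypertension", "bmi", "smoking", "drinking"]

#: The paper-style adjustment sets.  Smoking enters as ordered 0/1/2
#: (never/former/current); the AD polygenic score joins in ``ad_genetics``.
ADJUSTMENT_SETS: Mapping[str, list[str]] = {
    "crude": [],
    "primary": PRIMARY_COVARIATES,
    "health_status": HEALTH_COVARIATES,
    "ad_genetics": HEALTH_COVARIATES + ["ad_pgs"],
}


def adjustment_covariates(label: str) -> list[str]:
    try:
        return list(ADJUSTMENT_SETS[label])
    except KeyError:
        raise KeyError(
            f"unknown adjustment set {label!r}; expected one of {list(ADJUSTMENT_SETS)}"
        ) from None


@dataclass(frozen=True)
class Estimate:
    """A coefficient on the log-odds (or linear) scale with its SE."""

    beta: float
    se: float

    @property
    def z(self) -> float:
        return self.beta / self.se if self.se > 0 else np.inf * np.sign(self.beta)

    @property
    def pvalue(self) -> float:
        if self.se == 0:
            return 0.0 if self.beta != 0 else 1.0
        return float(2.0 * stats.norm.sf(abs(self.z)))

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        z = stats.norm.ppf(1 - alpha / 2)
        return self.beta - z * self.se, self.beta + z * self.se

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    def or_conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        lo, hi = self.conf_int(alpha)
        return float(np.exp(lo)), float(np.exp(hi))


@dataclass
class FitResult:
    """Per-term estimates plus fit diagnostics."""

    params: Mapping[str, Estimate]
    llf: float
    n: int
    converged: bool
    model: str = "logit"
    flags: tuple = ()

    def __getitem__(self, term: str) -> Estimate:
        return self.params[term]

    @property
    def k_params(self) -> int:
        return len(self.params)


class RankDeficientError(ValueError):
    """Design matrix is not of full column rank."""


def _check_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the offending columns: those whose removal restores the rank
        bad = [
            c
            for c in design.columns
            if np.linalg.matrix_rank(design.drop(columns=c).to_numpy(float)) == rank
        ]
        raise RankDeficientError(f"design matrix is rank deficient; collinear columns: {bad}")


def _design(X, add_intercept: bool) -> pd.DataFrame:
    X = pd.DataFrame(X).astype(float)
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    return X


def fit_logistic(
    outcome: Sequence, design, *, add_intercept: bool = True, maxiter: int = 50
) -> FitResult:
    """Maximum-likelihood logistic regression with observed-information SEs.

    Separation and non-convergence are surfaced via ``converged=False`` and
    ``flags``, never silently.
    """
    y = np.asarray(outcome, float)
    X = _design(design, add_intercept)
    if len(y) != len(X):
        raise ValueError("outcome and design have different lengths")
    if np.unique(y).size < 2:
        raise ValueError("outcome must contain both classes")
    _check_rank(X)
    flags: list[str] = []
    converged = True
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = sm.Logit(y, X).fit(method="newton", maxiter=maxiter, tol=1e-8, disp=0)
        for w in caught:
            if "separation" in str(w.message).lower():
                flags.append("separation")
                converged = False
            elif "converge" in str(w.message).lower():
                flags.append("non_convergence")
                converged = False
    except (PerfectSeparationError, np.linalg.LinAlgError) as err:
        return FitResult(params={}, llf=np.nan, n=len(y), converged=False,
                         model="logit", flags=("separation", str(err)))
    converged = converged and bool(res.mle_retvals.get("converged", True))
    if np.abs(res.params).max() > 20:
        flags.append("separation_suspected")
        converged = False
    params = {
        name: Estimate(float(b), float(se))
        for name, b, se in zip(X.columns, res.params, res.bse)
    }
    return FitResult(params=params, llf=float(res.llf), n=len(y),
                     converged=converged, model="logit", flags=tuple(flags))


def fit_linear(outcome: Sequence, design, *, add_intercept: bool = True) -> FitResult:
    """Ordinary least squares with classical SEs."""
    y = np.asarray(outcome, float)
    X = _design(design, add_intercept)
    if len(y) != len(X):
        raise ValueError("outcome and design have different lengths")
    _check_rank(X)
    res = sm.OLS(y, X).fit()
    params = {
        name: Estimate(float(b), float(se))
        for name, b, se in zip(X.columns, res.params, res.bse)
    }
    return FitResult(params=params, llf=float(res.llf), n=len(y),
                     converged=True, model="ols")


def two_by_two_or(a: int, b: int, c: int, d: int, *, continuity: bool = False) -> Estimate:
    """Cross-product odds ratio with the Woolf SE.

    Cells are (exposed cases, unexposed cases, exposed controls, unexposed
    controls).  A zero cell raises unless ``continuity=True`` adds 0.5 to
    every cell.
    """
    cells = np.array([a, b, c, d], float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be non-negative")
    if np.any(cells == 0):
        if not continuity:
            raise ValueError("zero cell; pass continuity=True to add 0.5 to all cells")
        cells = cells + 0.5
    a, b, c, d = cells
    return Estimate(float(np.log(a * d / (b * c))), float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)))


@dataclass(frozen=True)
class ImprovementChisq:
    """Likelihood-ratio relevance check for adding the instrument.

    Values at or below 10 flag a weak instrument.
    """

    statistic: float
    df: int
    pvalue: float
    weak_instrument: bool


def improvement_chisq(
    full: FitResult, reduced: FitResult, *, weak_threshold: float = 10.0
) -> ImprovementChisq:
    """2*(llf_full - llf_reduced) on the same observations."""
    if full.n != reduced.n:
        raise ValueError(
            "full and reduced fits use different n; align complete cases before fitting"
        )
    stat = 2.0 * (full.llf - reduced.llf)
    if stat < -1e-6:
        raise ValueError("reduced model has higher likelihood; models are not nested")
    stat = max(stat, 0.0)
    df = full.k_params - reduced.k_params
    p = float(stats.chi2.sf(stat, df)) if df > 0 else float("nan")
    return ImprovementChisq(stat, df, p, weak_instrument=stat <= weak_threshold)


def paf(odds_ratio: float, exposure_fraction: float, method: str = "levin") -> float:
    """Population attributable fraction.

    ``levin`` uses the exposure prevalence p in the sample:
    ``p(OR-1) / (1 + p(OR-1))``.  ``miettinen`` uses the prevalence among
    cases p_c: ``p_c (OR-1)/OR``.
    """
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    if not 0.0 < exposure_fraction < 1.0:
        raise ValueError("exposure fraction must lie in (0, 1)")
    if method == "levin":
        x = exposure_fraction * (odds_ratio - 1.0)
        return x / (1.0 + x)
    if method == "miettinen":
        return exposure_fraction * (odds_ratio - 1.0) / odds_ratio
    raise ValueError("method must be 'levin' or 'miettinen'")
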