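"""Mendelian-randomization estimators.

One-sample analysis uses the Wald-type ratio: the instrument-outcome log-OR
divided by the instrument-exposure log-OR, with a first-order Delta-method
standard error

    se_ratio^2 = se_ZY^2 / b_ZX^2 + b_ZY^2 * se_ZX^2 / b_ZX^4.

Two-sample analysis on harmonized summary statistics provides fixed-effect
inverse-variance weighting, MR-Egger (directional-pleiotropy intercept) and
the weighted median, with a seeded parametric bootstrap for the median SE.

The model-object layer (:class:`OneSampleMR`, :class:`TwoSampleMR`) follows
the fit()/results convention: construct the model from data, call ``fit``,
inspect the results object or its ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import AnalysisSubset
from .regression import Estimate, FitResult, ImprovementChisq, fit_logistic, improvement_chisq

__all__ = [
    "MRResult",
    "HeterogeneityResult",
    "estimate_from_ci",
    "wald_ratio",
    "heterogeneity_test",
    "OneSampleMR",
    "OneSampleMRResults",
    "run_one_sample_mr",
    "reverse_mr",
    "negative_control",
    "score_correlation",
    "harmonize_two_sample",
    "ivw",
    "egger",
    "weighted_median",
    "TwoSampleMR",
    "TwoSampleMRResults",
]

_Z95 = 1.959963984540054


def estimate_from_ci(odds_ratio: float, lcl: float, ucl: float) -> Estimate:
    """Recover (log-OR, SE) from a printed OR and 95% CI.

    ``beta = ln(OR)``; ``se = (ln UCL - ln LCL) / (2 * 1.96)``.  This is how
    published table rows are consumed as inputs.
    """
    if not 0 < lcl <= odds_ratio <= ucl:
        raise ValueError("require 0 < lcl <= OR <= ucl")
    if lcl == ucl:
        raise ValueError("degenerate confidence interval")
    return Estimate(float(np.log(odds_ratio)), float((np.log(ucl) - np.log(lcl)) / (2 * _Z95)))


@dataclass
class MRResult:
    """A ratio-type causal estimate on the log-OR scale."""

    estimate: Estimate
    first_stage: Optional[Estimate] = None
    reduced_form: Optional[Estimate] = None
    method: str = "wald_ratio"
    n_snps: int = 1
    weak_instrument: bool = False
    flags: tuple = ()

    @property
    def odds_ratio(self) -> float:
        return self.estimate.odds_ratio

    def or_conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        return self.estimate.or_conf_int(alpha)

    @property
    def pvalue(self) -> float:
        return self.estimate.pvalue


def wald_ratio(
    first_stage: Estimate, reduced_form: Estimate, *, weak_se_multiple: float = 10.0
) -> MRResult:
    """Wald-type ratio estimator with first-order Delta-method SE."""
    bzx, szx = first_stage.beta, first_stage.se
    bzy, szy = reduced_form.beta, reduced_form.se
    if bzx == 0:
        raise ZeroDivisionError("first-stage coefficient is zero; no instrument relevance")
    ratio = bzy / bzx
    var = szy**2 / bzx**2 + bzy**2 * szx**2 / bzx**4
    weak = abs(bzx) < weak_se_multiple * szx
    return MRResult(
        estimate=Estimate(float(ratio), float(np.sqrt(var))),
        first_stage=first_stage,
        reduced_form=reduced_form,
        weak_instrument=weak,
        flags=("weak_instrument",) if weak else (),
    )


@dataclass(frozen=True)
class HeterogeneityResult:
    """Altman-Bland interaction test between two estimates on one scale."""

    z: float
    pvalue: float
    a: Estimate
    b: Estimate


def heterogeneity_test(a: Estimate, b: Estimate) -> HeterogeneityResult:
    """z = (beta_a - beta_b) / sqrt(se_a^2 + se_b^2), two-sided normal p."""
    z = (a.beta - b.beta) / float(np.sqrt(a.se**2 + b.se**2))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return HeterogeneityResult(float(z), p, a, b)


# ---------------------------------------------------------------------------
# one-sample MR as a model object


@dataclass
class OneSampleMRResults:
    """Results of a one-sample Wald-ratio MR fit."""

    mr: MRResult
    first_stage_fit: FitResult
    reduced_form_fit: FitResult
    relevance: ImprovementChisq
    outcome: str
    exposure: str
    instrument: str
    covariates: tuple
    n: int

    @property
    def estimate(self) -> Estimate:
        return self.mr.estimate

    @property
    def odds_ratio(self) -> float:
        return self.mr.odds_ratio

    def or_conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        return self.mr.or_conf_int(alpha)

    @property
    def weak_instrument(self) -> bool:
        return self.relevance.weak_instrument or self.mr.weak_instrument

    def summary(self) -> str:
        lo, hi = self.or_conf_int()
        fs = self.mr.first_stage
        rf = self.mr.reduced_form
        lines = [
            "One-sample Mendelian randomization (Wald-type ratio, Delta SE)",
            "=" * 62,
            f"outcome: {self.outcome}   exposure: {self.exposure}   "
            f"instrument: {self.instrument}",
            f"covariates: {', '.join(self.covariates) or '(crude)'}",
            f"n (complete cases): {self.n}",
            "-" * 62,
            f"first stage   log-OR {fs.beta: .4f}  se {fs.se:.4f}  "
            f"OR {fs.odds_ratio:.2f}",
            f"reduced form  log-OR {rf.beta: .4f}  se {rf.se:.4f}  "
            f"OR {rf.odds_ratio:.2f}",
            f"causal ratio  log-OR {self.estimate.beta: .4f}  se {self.estimate.se:.4f}",
            f"causal OR {self.odds_ratio:.2f}  95% CI ({lo:.2f}, {hi:.2f})  "
            f"p {self.mr.pvalue:.3f}",
            f"improvement chi2 {self.relevance.statistic:.1f} "
            f"(df {self.relevance.df}); weak instrument: {self.weak_instrument}",
        ]
        return "\n".join(lines)


class OneSampleMR:
    """One-sample MR model: binary exposure and outcome, PGS instrument.

    Both logistic regressions (exposure ~ instrument + covariates and
    outcome ~ instrument + covariates) are restricted to the identical
    complete-case sample before fitting; the relevance of the instrument is
    measured by the improvement chi-square of the first stage.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        *,
        outcome: str,
        exposure: str,
        instrument: str,
        covariates: Sequence[str] = (),
        weak_chisq_threshold: float = 10.0,
    ):
        self.outcome = outcome
        self.exposure = exposure
        self.instrument = instrument
        self.covariates = tuple(covariates)
        self.weak_chisq_threshold = weak_chisq_threshold
        cols = [outcome, exposure, instrument, *self.covariates]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise KeyError(f"data is missing columns {missing}")
        self.data = data.loc[data[cols].notna().all(axis=1), cols].reset_index(drop=True)

    @classmethod
    def from_subset(
        cls, subset: AnalysisSubset, *, instrument: str, covariates: Sequence[str] = (), **kw
    ) -> "OneSampleMR":
        if not subset.usable:
            raise ValueError(f"subset {subset.label!r} is unusable (single outcome class)")
        data = subset.data.copy()
        data["_outcome"] = subset.outcome.to_numpy()
        return cls(
            data,
            outcome="_outcome",
            exposure="t2dm" if "t2dm" in data.columns else subset.label,
            instrument=instrument,
            covariates=covariates,
            **kw,
        )

    def fit(self) -> OneSampleMRResults:
        d = self.data
        X_full = d[[self.instrument, *self.covariates]]
        first = fit_logistic(d[self.exposure], X_full)
        if self.covariates:
            first_reduced = fit_logistic(d[self.exposure], d[list(self.covariates)])
        else:
            first_reduced = fit_logistic(
                d[self.exposure], pd.DataFrame(index=d.index), add_intercept=True
            )
        relevance = improvement_chisq(
            first, first_reduced, weak_threshold=self.weak_chisq_threshold
        )
        reduced = fit_logistic(d[self.outcome], X_full)
        mr = wald_ratio(first[self.instrument], reduced[self.instrument])
        if relevance.weak_instrument:
            mr.weak_instrument = True
            mr.flags = tuple(set(mr.flags) | {"weak_instrument"})
        return OneSampleMRResults(
            mr=mr,
            first_stage_fit=first,
            reduced_form_fit=reduced,
            relevance=relevance,
            outcome=self.outcome,
            exposure=self.exposure,
            instrument=self.instrument,
            covariates=self.covariates,
            n=len(d),
        )


def run_one_sample_mr(
    subset: AnalysisSubset,
    *,
    instrument: str = "pgs",
    covariates: Sequence[str] = (),
) -> OneSampleMRResults:
    """Functional wrapper over :class:`OneSampleMR` for an analysis subset."""
    return OneSampleMR.from_subset(
        subset, instrument=instrument, covariates=covariates
    ).fit()


def reverse_mr(
    subset: AnalysisSubset,
    *,
    instrument: str = "ad_pgs",
    covariates: Sequence[str] = (),
) -> OneSampleMRResults:
    """Reverse-direction MR: cognitive status as exposure, T2DM as outcome,
    instrumented by the Alzheimer's-disease polygenic score."""
    if not subset.usable:
        raise ValueError(f"subset {subset.label!r} is unusable")
    data = subset.data.copy()
    data["_impaired"] = subset.outcome.to_numpy()
    model = OneSampleMR(
        data,
        outcome="t2dm",
        exposure="_impaired",
        instrument=instrument,
        covariates=covariates,
    )
    return model.fit()


def negative_control(
    cohort: pd.DataFrame,
    outcome: Sequence,
    *,
    instrument: str = "pgs",
    covariates: Sequence[str] = (),
    exposure: str = "t2dm",
) -> Optional[FitResult]:
    """Fit outcome ~ instrument + covariates among the unexposed only.

    With a valid instrument the score coefficient should be null here.
    Returns ``None`` (flagged degenerate) when the restriction is empty or
    has a single outcome class.
    """
    mask = cohort[exposure].to_numpy() == 0
    y = np.asarray(outcome)[mask]
    if mask.sum() == 0 or np.unique(y).size < 2:
        return None
    X = cohort.loc[mask, [instrument, *covariates]]
    return fit_logistic(y, X)


def score_correlation(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation between two score vectors with two-sided t p."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("score vectors must have equal length >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a score vector")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# two-sample MR on harmonized summary statistics

_PAIR_COLUMNS = ["snp", "beta_exp", "se_exp", "beta_out", "se_out"]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def harmonize_two_sample(
    exposure_stats: pd.DataFrame,
    outcome_stats: pd.DataFrame,
    *,
    palindromic: str = "keep",
) -> tuple[pd.DataFrame, dict]:
    """Intersect two summary-statistics tables on variant id and align the
    outcome effects to the exposure effect allele (sign flip on swap).

    No LD clumping is performed.  Returns the harmonized pair table and a
    report of kept/flipped/dropped counts.
    """
    if exposure_stats.empty or outcome_stats.empty:
        raise ValueError("both summary-statistics tables must be non-empty")
    if palindromic not in ("keep", "drop"):
        raise ValueError("palindromic policy must be 'keep' or 'drop'")
    out = outcome_stats.set_index("snp")
    report = {"n_kept": 0, "n_flipped": 0, "n_dropped": 0, "n_palindromic": 0}
    rows = []
    for rec in exposure_stats.itertuples(index=False):
        if rec.snp not in out.index:
            continue
        o = out.loc[rec.snp]
        e1, e2 = str(rec.a1).upper(), str(rec.a2).upper()
        o1, o2 = str(o["a1"]).upper(), str(o["a2"]).upper()
        pal = _COMPLEMENT.get(e1) == e2
        if pal:
            report["n_palindromic"] += 1
            if palindromic == "drop":
                report["n_dropped"] += 1
                continue
        beta_out = None
        if (o1, o2) == (e1, e2):
            beta_out = o["beta"]
        elif (o1, o2) == (e2, e1):
            beta_out = -o["beta"]
            report["n_flipped"] += 1
        elif not pal:
            c1, c2 = _COMPLEMENT.get(o1), _COMPLEMENT.get(o2)
            if (c1, c2) == (e1, e2):
                beta_out = o["beta"]
            elif (c1, c2) == (e2, e1):
                beta_out = -o["beta"]
                report["n_flipped"] += 1
        if beta_out is None:
            report["n_dropped"] += 1
            continue
        report["n_kept"] += 1
        rows.append(
            {
                "snp": rec.snp,
                "beta_exp": float(rec.beta),
                "se_exp": float(rec.se),
                "beta_out": float(beta_out),
                "se_out": float(o["se"]),
            }
        )
    if not rows:
        raise ValueError("no overlapping variants between the two studies")
    pair = pd.DataFrame(rows, columns=_PAIR_COLUMNS)
    if (pair[["se_exp", "se_out"]] <= 0).any().any():
        raise ValueError("standard errors must be positive")
    return pair, report


def _require_pair(pair: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _PAIR_COLUMNS[1:] if c not in pair.columns]
    if missing:
        raise KeyError(f"harmonized pair table missing columns {missing}")
    return pair


def ivw(pair: pd.DataFrame, *, random_effects: bool = False) -> MRResult:
    """Fixed-effect inverse-variance-weighted pooling of per-variant ratios.

    Per variant: ratio r_j = beta_out_j / beta_exp_j with first-order
    se_j = se_out_j / |beta_exp_j|; pooled beta = sum(w r)/sum(w) with
    w = 1/se^2 and pooled se = 1/sqrt(sum w).  With ``random_effects=True``
    the pooled SE is inflated by the multiplicative over-dispersion factor
    when heterogeneity exceeds its expectation.
    """
    pair = _require_pair(pair)
    flags = ()
    nonzero = pair["beta_exp"] != 0
    if not nonzero.all():
        flags = ("excluded_zero_exposure_beta",)
        pair = pair.loc[nonzero]
    if pair.empty:
        raise ValueError("no variants with nonzero exposure beta")
    r = pair["beta_out"].to_numpy() / pair["beta_exp"].to_numpy()
    se = pair["se_out"].to_numpy() / np.abs(pair["beta_exp"].to_numpy())
    w = 1.0 / se**2
    beta = float(np.sum(w * r) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    if random_effects and len(r) > 1:
        q = float(np.sum(w * (r - beta) ** 2))
        phi = max(q / (len(r) - 1), 1.0)
        pooled_se *= float(np.sqrt(phi))
    return MRResult(
        estimate=Estimate(beta, pooled_se),
        method="ivw_re" if random_effects else "ivw",
        n_snps=len(r),
        flags=flags,
    )


def egger(pair: pd.DataFrame) -> tuple[Estimate, Estimate]:
    """MR-Egger: WLS of outcome betas on exposure betas with a free intercept.

    Weights are 1/se_out^2; orientation forces exposure betas positive first
    (the estimator is defined up to allele orientation).  Returns
    ``(slope, intercept)``; the intercept tests directional pleiotropy.
    """
    pair = _require_pair(pair)
    if len(pair) < 3:
        raise ValueError("MR-Egger requires at least 3 variants")
    sign = np.sign(pair["beta_exp"].to_numpy())
    sign[sign == 0] = 1.0
    bx = pair["beta_exp"].to_numpy() * sign
    by = pair["beta_out"].to_numpy() * sign
    w = 1.0 / pair["se_out"].to_numpy() ** 2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ by)
    resid = by - X @ coef
    dof = len(bx) - 2
    sigma2 = float(np.sum(w * resid**2) / dof)
    cov = np.linalg.inv(xtwx) * max(sigma2, 1.0)  # no deflation below chi2 expectation
    intercept = Estimate(float(coef[0]), float(np.sqrt(cov[0, 0])))
    slope = Estimate(float(coef[1]), float(np.sqrt(cov[1, 1])))
    return slope, intercept


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= np.sum(w)
    return float(np.interp(0.5, cum, v))


def weighted_median(
    pair: pd.DataFrame, *, n_boot: int = 1000, seed: int = 0
) -> MRResult:
    """Weighted-median estimator with a seeded parametric-bootstrap SE.

    The estimate is the per-variant ratio at the inverse-variance-weighted
    50th percentile (linear interpolation between order statistics); it is
    consistent when at least half the weight comes from valid instruments.
    """
    pair = _require_pair(pair)
    if len(pair) < 3:
        raise ValueError("weighted median requires at least 3 variants")
    bx = pair["beta_exp"].to_numpy(float)
    by = pair["beta_out"].to_numpy(float)
    sx = pair["se_exp"].to_numpy(float)
    sy = pair["se_out"].to_numpy(float)
    if np.any(bx == 0):
        raise ValueError("exposure betas must be nonzero for ratio estimates")
    r = by / bx
    se_r = sy / np.abs(bx)
    est = _weighted_median(r, 1.0 / se_r**2)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bx_i = rng.normal(bx, sx)
        by_i = rng.normal(by, sy)
        bx_i[bx_i == 0] = np.finfo(float).tiny
        r_i = by_i / bx_i
        se_i = sy / np.abs(bx_i)
        boots[i] = _weighted_median(r_i, 1.0 / se_i**2)
    return MRResult(
        estimate=Estimate(est, float(boots.std(ddof=1))),
        method="weighted_median",
        n_snps=len(r),
    )


@dataclass
class TwoSampleMRResults:
    """Pooled two-sample causal estimates across requested methods."""

    results: dict
    egger_intercept: Optional[Estimate]
    n_snps: int
    harmonization: Optional[dict] = None

    def __getitem__(self, method: str) -> MRResult:
        return self.results[method]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for method, res in self.results.items():
            lo, hi = res.or_conf_int()
            rows.append(
                {
                    "method": method,
                    "n_snps": res.n_snps,
                    "beta": res.estimate.beta,
                    "se": res.estimate.se,
                    "OR": res.odds_ratio,
                    "lcl": lo,
                    "ucl": hi,
                    "p": res.pvalue,
                }
            )
        if self.egger_intercept is not None:
            ic = self.egger_intercept
            lo, hi = ic.conf_int()
            rows.append(
                {
                    "method": "egger_intercept",
                    "n_snps": self.n_snps,
                    "beta": ic.beta,
                    "se": ic.se,
                    "OR": np.nan,
                    "lcl": lo,
                    "ucl": hi,
                    "p": ic.pvalue,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        return self.to_frame().to_string(index=False, float_format=lambda v: f"{v:.4f}")


class TwoSampleMR:
    """Two-sample MR model over a harmonized summary-statistics pair."""

    def __init__(self, pair: pd.DataFrame, *, harmonization: Optional[dict] = None):
        self.pair = _require_pair(pair)
        self.harmonization = harmonization

    @classmethod
    def from_summary_stats(
        cls,
        exposure_stats: pd.DataFrame,
        outcome_stats: pd.DataFrame,
        *,
        palindromic: str = "keep",
    ) -> "TwoSampleMR":
        pair, report = harmonize_two_sample(
            exposure_stats, outcome_stats, palindromic=palindromic
        )
        return cls(pair, harmonization=report)

    def fit(
        self,
        methods: Sequence[str] = ("ivw", "egger", "weighted_median"),
        *,
        seed: int = 0,
        n_boot: int = 1000,
    ) -> TwoSampleMRResults:
        results: dict = {}
        intercept = None
        for method in methods:
            if method == "ivw":
                results["ivw"] = ivw(self.pair)
            elif method == "ivw_re":
                results["ivw_re"] = ivw(self.pair, random_effects=True)
            elif method == "egger":
                slope, intercept = egger(self.pair)
                results["egger"] = MRResult(
                    estimate=slope, method="egger", n_snps=len(self.pair)
                )
            elif method == "weighted_median":
                results["weighted_median"] = weighted_median(
                    self.pair, n_boot=n_boot, seed=seed
                )
            else:
                raise ValueError(f"unknown two-sample method {method!r}")
        return TwoSampleMRResults(
            results=results,
            egger_intercept=intercept,
            n_snps=len(self.pair),
            harmonization=self.harmonization,
        )
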