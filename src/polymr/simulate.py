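"""Synthetic genotype/phenotype generator for the MR analysis.

Emulates the structure of a Health-and-Retirement-Study-like cross-sectional
wave: Hardy-Weinberg genotype dosages, an external GWAS weight table observed
with estimation noise, a binary exposure (type 2 diabetes) driven by the true
polygenic signal plus confounders, and a graded cognition score produced by a
latent index and classified downstream with the Langa-Weir rules.

Every generator is a pure function of ``(params, seed)``; randomness is drawn
from per-stage :class:`numpy.random.SeedSequence` children so the individual
generators are reproducible whether called alone or via the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "SimParams",
    "GenotypeMatrix",
    "WEIGHT_COLUMNS",
    "generate_genotypes",
    "generate_weights",
    "generate_cohort",
    "generate_summary_stats",
    "write_weights",
    "read_weights",
    "write_genotypes",
    "read_genotypes",
    "write_cohort",
    "read_cohort",
]

#: column order of the tab-delimited GWAS weight table dialect
WEIGHT_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P"]

_BASES = np.array(list("ACGT"))

# Latent cognition cut points (index scale).  With the default confounder
# effects the latent index has SD ~2.1, putting ~17% of self-respondents at or
# below the CIND cut and ~3.5% below the dementia cut, close to the impairment
# fractions of the emulated wave.
CUT_CIND = -2.0
CUT_DEMENTIA = -3.8
_LATENT_SPAN = 14.0  # latent values beyond +-span map to the score endpoints

# effects are (log-OR on exposure, log-OR on outcome risk) per transformed
# covariate unit: age per decade, education per year, binary indicators as-is
_DEFAULT_CONFOUNDERS: Mapping[str, tuple[float, float]] = {
    "age": (0.15, 0.85),
    "sex": (-0.35, -0.05),
    "education": (-0.04, -0.20),
    "apoe4": (0.0, 0.60),
}


class InvalidParameterError(ValueError):
    """Raised when simulation parameters violate their constraints."""


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic study.

    ``theta`` is the causal log-OR of the outcome per unit of the binary
    exposure; ``theta = delta_pleio = 0`` defines the global null.
    ``alpha_pgs`` is the exposure log-OR per SD of the *true* polygenic
    signal; the published (noisy) score attenuates it slightly.
    """

    n_individuals: int = 8000
    n_variants: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: Optional[int] = None  # default: half the variants
    alpha0: float = -1.5
    alpha_pgs: float = float(np.log(1.66))
    theta: float = 0.0
    delta_pleio: float = 0.0
    alpha_ad: float = 0.0
    confounder_effects: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_CONFOUNDERS)
    )
    gwas_noise_sd: float = 0.02
    true_effect_sd: float = 0.08
    proxy_rate: float = 0.05
    n_gwas: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 0 or self.n_variants <= 0:
            raise InvalidParameterError(
                "n_individuals must be >= 0 and n_variants > 0"
            )
        if self.n_causal is None:
            object.__setattr__(self, "n_causal", self.n_variants // 2)
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidParameterError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.n_causal <= self.n_variants:
            raise InvalidParameterError("n_causal must be in [0, n_variants]")
        if self.gwas_noise_sd < 0 or self.true_effect_sd < 0:
            raise InvalidParameterError("noise SDs must be non-negative")
        if not 0.0 <= self.proxy_rate < 1.0:
            raise InvalidParameterError("proxy_rate must be in [0, 1)")

    def with_(self, **kwargs) -> "SimParams":
        return replace(self, **kwargs)


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with variant metadata.

    ``variants`` columns: snp, chr, bp, a1 (counted allele), a2, freq.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: pd.Index

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-dimensional")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("dosage columns must match variant records")
        if self.dosages.size and not np.isin(self.dosages, (0, 1, 2)).all():
            raise ValueError("dosages must be in {0, 1, 2}")
        if self.variants["snp"].duplicated().any():
            raise ValueError("variant ids must be unique")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


def _rng(params: SimParams, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(params.seed), stage]))


def generate_genotypes(params: SimParams) -> GenotypeMatrix:
    """Draw Hardy-Weinberg dosages: per variant, two Bernoulli(f) allele draws."""
    rng = _rng(params, 0)
    m = params.n_variants
    lo, hi = params.maf_range
    freqs = rng.uniform(lo, hi, size=m)
    dosages = rng.binomial(2, freqs, size=(params.n_individuals, m)).astype(np.int8)

    chrom = rng.integers(1, 23, size=m)
    pos = rng.integers(1, 50_000_000, size=m)
    a_idx = rng.integers(0, 4, size=m)
    b_idx = (a_idx + rng.integers(1, 4, size=m)) % 4
    variants = pd.DataFrame(
        {
            "snp": [f"rs{i:06d}" for i in range(m)],
            "chr": chrom,
            "bp": pos,
            "a1": _BASES[a_idx],
            "a2": _BASES[b_idx],
            "freq": freqs,
        }
    )
    sample_ids = pd.Index([f"id{i:06d}" for i in range(params.n_individuals)], name="id")
    return GenotypeMatrix(dosages, variants, sample_ids)


def generate_weights(
    genotypes: GenotypeMatrix, params: SimParams
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate the external GWAS weight table.

    Returns the published table (true effect + Normal noise, with a Wald-type
    p-value) and the vector of true per-allele effects.  ``n_causal`` variants
    carry nonzero true effects; p-values shrink with |true effect| so that
    p-threshold sweeps behave like real summary statistics.
    """
    if params.n_causal > genotypes.n_variants:
        raise InvalidParameterError("n_causal exceeds the number of variants")
    rng = _rng(params, 1)
    m = genotypes.n_variants
    true = np.zeros(m)
    causal = rng.choice(m, size=params.n_causal, replace=False)
    true[causal] = rng.normal(0.0, params.true_effect_sd, size=params.n_causal)

    noise_sd = params.gwas_noise_sd
    published = true + rng.normal(0.0, noise_sd, size=m) if noise_sd > 0 else true.copy()
    if noise_sd > 0:
        z = published / noise_sd
        pvals = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
        se = np.full(m, noise_sd)
    else:
        # noiseless limit: zero effects are maximally non-significant
        pvals = np.where(published == 0.0, 1.0, 1e-300)
        se = np.zeros(m)

    table = pd.DataFrame(
        {
            "snp": genotypes.variants["snp"].to_numpy(),
            "chr": genotypes.variants["chr"].to_numpy(),
            "bp": genotypes.variants["bp"].to_numpy(),
            "a1": genotypes.variants["a1"].to_numpy(),
            "a2": genotypes.variants["a2"].to_numpy(),
            "beta": published,
            "se": se,
            "p": pvals,
        }
    )
    return table, true


def _standardized_true_score(genotypes: GenotypeMatrix, true_effects: np.ndarray) -> np.ndarray:
    raw = genotypes.dosages @ true_effects
    sd = raw.std(ddof=1) if len(raw) > 1 else 0.0
    if sd == 0:
        return np.zeros_like(raw, dtype=float)
    return (raw - raw.mean()) / sd


def _covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    age = stats.truncnorm.rvs(-2.0, 2.0, loc=70.0, scale=10.0, size=n, random_state=rng)
    sex = rng.binomial(1, 0.58, size=n)  # 1 = female
    education = np.clip(np.rint(rng.normal(13.3, 2.5, size=n)), 0, 20)
    apoe4 = rng.binomial(1, 0.265, size=n)
    pcs = rng.normal(0.0, 1.0, size=(n, 5))
    # health covariates (Table-1-like marginals); independent of the score by
    # default so the confounder screen is null-calibrated
    stroke = rng.binomial(1, 0.07, size=n)
    hypertension = rng.binomial(1, 0.58, size=n)
    bmi = rng.normal(28.0, 5.8, size=n)
    smoking = rng.choice(3, size=n, p=[0.435, 0.449, 0.116])  # never/former/current
    drinking = rng.binomial(1, 0.567, size=n)
    cov = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "education": education,
            "apoe4": apoe4,
            "stroke": stroke,
            "hypertension": hypertension,
            "bmi": bmi,
            "smoking": smoking,
            "drinking": drinking,
        }
    )
    for k in range(5):
        cov[f"pc{k + 1}"] = pcs[:, k]
    return cov


def _confounder_terms(cov: pd.DataFrame, effects, which: int) -> np.ndarray:
    """Centered linear combination of confounders (which: 0=exposure, 1=outcome)."""
    out = np.zeros(len(cov))
    transforms = {
        "age": (cov["age"] - 70.0) / 10.0,
        "sex": cov["sex"] - 0.58,
        "education": cov["education"] - 13.3,
        "apoe4": cov["apoe4"] - 0.265,
        "bmi": (cov["bmi"] - 28.0) / 5.8 if "bmi" in cov else None,
    }
    for name, pair in effects.items():
        if name not in transforms or transforms[name] is None:
            raise InvalidParameterError(f"unknown confounder {name!r}")
        out = out + pair[which] * transforms[name].to_numpy()
    return out


def _latent_to_score(latent: np.ndarray, proxy: np.ndarray) -> np.ndarray:
    """Fixed monotone piecewise-linear map from the latent index to the
    27-point (self) or 11-point (proxy, reverse-oriented) integer scale."""
    xp = np.array([-_LATENT_SPAN, CUT_DEMENTIA, CUT_CIND, _LATENT_SPAN])
    self_score = np.rint(np.interp(latent, xp, [0.0, 6.5, 11.5, 27.0]))
    proxy_score = np.rint(np.interp(latent, xp, [11.0, 5.5, 2.5, 0.0]))
    score = np.where(proxy == 1, proxy_score, self_score)
    return score.astype(int)


def generate_cohort(
    genotypes: GenotypeMatrix,
    weights_true: np.ndarray,
    params: SimParams,
) -> pd.DataFrame:
    """Generate the per-participant phenotype/covariate table.

    The exposure follows a logistic model on the standardized true score and
    the confounders; the cognition latent index is linear in
    ``theta * t2dm + delta_pleio * score + confounders`` plus standard
    logistic noise and is mapped monotonically to the integer scales.
    ``weights_true`` is the true-effect vector returned by
    :func:`generate_weights`.
    """
    rng = _rng(params, 2)
    n = genotypes.n_individuals
    cov = _covariates(rng, n)
    score = _standardized_true_score(genotypes, np.asarray(weights_true, float))

    lin_x = params.alpha0 + params.alpha_pgs * score + _confounder_terms(
        cov, params.confounder_effects, 0
    )
    t2dm = rng.binomial(1, expit(lin_x))

    ad_pgs = rng.normal(0.0, 1.0, size=n)
    risk = (
        params.theta * t2dm
        + params.delta_pleio * score
        + params.alpha_ad * ad_pgs
        + _confounder_terms(cov, params.confounder_effects, 1)
    )
    latent = rng.logistic(0.0, 1.0, size=n) - risk
    proxy = rng.binomial(1, params.proxy_rate, size=n)
    cog = _latent_to_score(latent, proxy)

    # prior-wave dementia flag, enriched in currently impaired participants so
    # the reversion exclusion has work to do
    impaired_now = latent < CUT_CIND
    demented_now = latent < CUT_DEMENTIA
    p_prior = np.where(demented_now, 0.5, np.where(impaired_now, 0.05, 0.01))
    prior = rng.binomial(1, p_prior)

    out = pd.DataFrame({"id": genotypes.sample_ids})
    out = pd.concat([out, cov.reset_index(drop=True)], axis=1)
    out["ancestry"] = "EUR"
    out["t2dm"] = t2dm
    out["proxy"] = proxy
    out["cognition_score"] = cog
    out["prior_wave_dementia"] = prior
    out["ad_pgs"] = ad_pgs
    # latent truth, kept for recovery tests
    out["true_score"] = score
    out["latent_cognition"] = latent
    return out


def generate_summary_stats(
    params: SimParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-sample GWAS summary statistics from disjoint simulated samples.

    Sample 1 regresses a continuous exposure on each variant; sample 2 does
    the same for the outcome ``theta * exposure + delta_pleio * score/SD``.
    Under ``theta`` the expected outcome beta is ``theta`` times the exposure
    beta for valid instruments.
    """
    rng = _rng(params, 3)
    m = params.n_variants
    n = params.n_gwas
    lo, hi = params.maf_range
    freqs = rng.uniform(lo, hi, size=m)
    true = np.zeros(m)
    causal = rng.choice(m, size=params.n_causal, replace=False)
    true[causal] = rng.normal(0.0, params.true_effect_sd, size=params.n_causal)

    def one_study(y_fn) -> pd.DataFrame:
        g = rng.binomial(2, freqs, size=(n, m)).astype(np.int8)
        gscore = g @ true
        y = y_fn(g, gscore)
        gc = g - g.mean(axis=0)
        yc = y - y.mean()
        var_g = (gc**2).sum(axis=0)
        beta = gc.T @ yc / var_g
        resid_var = (
            (yc**2).sum() - 2 * beta * (gc.T @ yc) + beta**2 * var_g
        ) / (n - 2)
        se = np.sqrt(resid_var / var_g)
        z = beta / se
        p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
        return pd.DataFrame(
            {
                "snp": [f"rs{i:06d}" for i in range(m)],
                "chr": np.ones(m, dtype=int),
                "bp": np.arange(1, m + 1) * 1000,
                "a1": "A",
                "a2": "G",
                "beta": beta,
                "se": se,
                "p": p,
            }
        )

    exp_stats = one_study(lambda g, s: s + rng.normal(0.0, 1.0, size=n))
    sd_s = np.sqrt(np.sum(true**2 * 2 * freqs * (1 - freqs))) or 1.0

    def outcome(g, s):
        exposure = s + rng.normal(0.0, 1.0, size=n)
        return (
            params.theta * exposure
            + params.delta_pleio * s / sd_s
            + rng.normal(0.0, 1.0, size=n)
        )

    out_stats = one_study(outcome)
    return exp_stats, out_stats


# ---------------------------------------------------------------------------
# text I/O (tab-delimited weights and dosages, CSV cohort)

def write_weights(weights: pd.DataFrame, path) -> None:
    out = weights.rename(
        columns=dict(zip(["snp", "chr", "bp", "a1", "a2", "beta", "se", "p"], WEIGHT_COLUMNS))
    )
    out[WEIGHT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_weights(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower() for c in df.columns]
    return df


def write_genotypes(genotypes: GenotypeMatrix, dosage_path, meta_path) -> None:
    pd.DataFrame(
        genotypes.dosages, index=genotypes.sample_ids, columns=genotypes.variants["snp"]
    ).to_csv(dosage_path, sep="\t")
    genotypes.variants.to_csv(meta_path, sep="\t", index=False)


def read_genotypes(dosage_path, meta_path) -> GenotypeMatrix:
    dosages = pd.read_csv(dosage_path, sep="\t", index_col=0)
    variants = pd.read_csv(meta_path, sep="\t")
    return GenotypeMatrix(
        dosages.to_numpy(dtype=np.int8), variants, pd.Index(dosages.index, name="id")
    )


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)
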