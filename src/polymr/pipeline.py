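"""Configuration-driven end-to-end runner.

Chains simulation (or file inputs) through weight harmonization, scoring,
standardization, Langa-Weir classification, sample selection, observational
models, one-sample MR, diagnostics, and optional two-sample / reverse MR,
emitting descriptive, first-stage, score-outcome, and MR tables shaped like
a published analysis, plus a machine-readable JSON mirror.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import cohort as cohort_mod
from . import mr as mr_mod
from . import pgs as pgs_mod
from . import simulate as sim_mod
from .regression import (
    ADJUSTMENT_SETS,
    Estimate,
    adjustment_covariates,
    fit_linear,
    fit_logistic,
    improvement_chisq,
)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "make_descriptive_table",
           "write_reports", "demo_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending field."""


_KNOWN_ANALYSES = {
    "descriptive",
    "observational",
    "one_sample_mr",
    "diagnostics",
    "two_sample_mr",
    "reverse_mr",
}


@dataclass
class RunConfig:
    """Versioned run configuration (one YAML document)."""

    sim: dict = field(default_factory=dict)
    thresholds: Sequence[float] = (1.0,)
    adjustments: Sequence[str] = ("crude", "primary", "health_status", "ad_genetics")
    analyses: Sequence[str] = (
        "descriptive",
        "observational",
        "one_sample_mr",
        "diagnostics",
    )
    age_window: Optional[tuple[float, float]] = None
    region_mask: Optional[str] = None
    palindromic: str = "keep"
    seed: int = 0
    schema_version: int = 1

    def __post_init__(self) -> None:
        if not self.thresholds:
            raise ConfigError("thresholds: list must be non-empty")
        for t in self.thresholds:
            if not 0.0 < t <= 1.0:
                raise ConfigError(f"thresholds: cutoff {t} outside (0, 1]")
        for a in self.adjustments:
            if a not in ADJUSTMENT_SETS:
                raise ConfigError(f"adjustments: unknown set {a!r}")
        for a in self.analyses:
            if a not in _KNOWN_ANALYSES:
                raise ConfigError(f"analyses: unknown analysis {a!r}")
        if self.palindromic not in ("keep", "drop"):
            raise ConfigError("palindromic: must be 'keep' or 'drop'")
        if self.age_window is not None:
            lo, hi = self.age_window
            if lo > hi:
                raise ConfigError("age_window: lower bound exceeds upper bound")
        try:
            sim_mod.SimParams(**{**self.sim, "seed": self.seed})
        except TypeError as err:
            raise ConfigError(f"sim: {err}") from None
        except sim_mod.InvalidParameterError as err:
            raise ConfigError(f"sim: {err}") from None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigError("config document must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        if "age_window" in doc and doc["age_window"] is not None:
            doc["age_window"] = tuple(doc["age_window"])
        return cls(**doc)

    def params(self) -> sim_mod.SimParams:
        return sim_mod.SimParams(**{**self.sim, "seed": self.seed})


@dataclass
class ReportBundle:
    """All tables plus diagnostics and a per-stage run log."""

    descriptive: Optional[pd.DataFrame]
    first_stage: Optional[pd.DataFrame]
    score_outcome: Optional[pd.DataFrame]
    mr_table: Optional[pd.DataFrame]
    mr_sweep: Optional[pd.DataFrame]
    two_sample: Optional[pd.DataFrame]
    reverse: Optional[pd.DataFrame]
    diagnostics: dict
    log: list

    def to_json_dict(self) -> dict:
        def df(d):
            return None if d is None else json.loads(d.to_json(orient="records"))

        return {
            "descriptive": df(self.descriptive),
            "first_stage": df(self.first_stage),
            "score_outcome": df(self.score_outcome),
            "mr_table": df(self.mr_table),
            "mr_sweep": df(self.mr_sweep),
            "two_sample": df(self.two_sample),
            "reverse": df(self.reverse),
            "diagnostics": self.diagnostics,
            "log": self.log,
        }


def _or_row(est: Estimate) -> dict:
    lo, hi = est.or_conf_int()
    return {
        "beta": est.beta,
        "se": est.se,
        "OR": est.odds_ratio,
        "lcl": lo,
        "ucl": hi,
        "p": est.pvalue,
    }


# ---------------------------------------------------------------------------
# descriptive (Table-1 shaped) summary

_BINARY_VARS = [
    ("t2dm", "History of T2DM (yes)"),
    ("apoe4", "APOE-e4 carrier (yes)"),
    ("sex", "Sex (female)"),
    ("stroke", "Stroke history (yes)"),
    ("hypertension", "Hypertension history (yes)"),
    ("drinking", "Ever drinker"),
]
_CONTINUOUS_VARS = [
    ("pgs", "T2DM polygenic score", 2),
    ("ad_pgs", "AD polygenic score", 2),
    ("age", "Age (years)", 1),
    ("education", "Years of education", 1),
    ("bmi", "Body mass index", 1),
]


def _fmt_count(k: int, n: int) -> str:
    if n == 0:
        return "0 (-)"
    return f"{k:,} ({100.0 * k / n:.1f}%)"


def _fmt_mean(x: pd.Series, dec: int) -> str:
    if len(x) == 0:
        return "-"
    return f"{x.mean():.{dec}f} ({x.std(ddof=1):.{dec}f})"


def _chi2_p(table: pd.DataFrame) -> float:
    # drop empty strata; chi-square without continuity correction
    tab = table.loc[:, table.sum(axis=0) > 0]
    if tab.shape[1] < 2 or tab.shape[0] < 2:
        return np.nan
    stat, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
    return float(p)


def _anova_p(groups: list[pd.Series]) -> float:
    groups = [g.dropna() for g in groups if len(g.dropna()) > 1]
    if len(groups) < 2:
        return np.nan
    return float(stats.f_oneway(*groups).pvalue)


def make_descriptive_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Counts/percentages and mean (SD), stratified by cognitive status and
    by exposure, with chi-square (categorical) or one-way ANOVA (continuous)
    homogeneity tests.  Empty strata render zero counts and skip the test
    with a note."""
    df = cohort
    if "cognitive_status" not in df.columns:
        df = cohort_mod.classify_cohort(df)
    status_levels = ["normal", "cind", "dementia"]
    strata = {s: df.loc[df["cognitive_status"].astype(str) == s] for s in status_levels}
    t2dm_strata = {v: df.loc[df["t2dm"] == v] for v in (1, 0)} if "t2dm" in df else {}

    rows = []

    def add_row(label, overall, by_status, p_status, by_t2dm, p_t2dm, note=""):
        rows.append(
            {
                "variable": label,
                "overall": overall,
                "normal": by_status[0],
                "cind": by_status[1],
                "dementia": by_status[2],
                "p_status": p_status,
                "t2dm_yes": by_t2dm[0],
                "t2dm_no": by_t2dm[1],
                "p_t2dm": p_t2dm,
                "note": note,
            }
        )

    n_status_nonempty = sum(len(s) > 0 for s in strata.values())
    note_single = "single stratum; test skipped" if n_status_nonempty < 2 else ""

    for col, label in _BINARY_VARS:
        if col not in df.columns:
            continue
        by_status = [
            _fmt_count(int((strata[s][col] == 1).sum()), len(strata[s]))
            for s in status_levels
        ]
        tab = pd.DataFrame(
            {s: [(strata[s][col] == 1).sum(), (strata[s][col] == 0).sum()] for s in status_levels}
        )
        p_status = np.nan if note_single else _chi2_p(tab)
        if col == "t2dm" or not t2dm_strata:
            by_t2dm, p_t2dm = ["-", "-"], np.nan
        else:
            by_t2dm = [
                _fmt_count(int((t2dm_strata[v][col] == 1).sum()), len(t2dm_strata[v]))
                for v in (1, 0)
            ]
            tab2 = pd.DataFrame(
                {v: [(t2dm_strata[v][col] == 1).sum(), (t2dm_strata[v][col] == 0).sum()]
                 for v in (1, 0)}
            )
            p_t2dm = _chi2_p(tab2)
        add_row(label, _fmt_count(int((df[col] == 1).sum()), len(df)),
                by_status, p_status, by_t2dm, p_t2dm, note_single)

    if "smoking" in df.columns:
        for level, name in enumerate(["never", "former", "current"]):
            by_status = [
                _fmt_count(int((strata[s]["smoking"] == level).sum()), len(strata[s]))
                for s in status_levels
            ]
            by_t2dm = (
                [
                    _fmt_count(int((t2dm_strata[v]["smoking"] == level).sum()),
                               len(t2dm_strata[v]))
                    for v in (1, 0)
                ]
                if t2dm_strata
                else ["-", "-"]
            )
            tab = pd.DataFrame(
                {s: [(strata[s]["smoking"] == k).sum() for k in range(3)]
                 for s in status_levels}
            )
            p_status = np.nan if note_single else (_chi2_p(tab) if level == 0 else np.nan)
            p_t2dm = np.nan
            if level == 0 and t2dm_strata:
                tab2 = pd.DataFrame(
                    {v: [(t2dm_strata[v]["smoking"] == k).sum() for k in range(3)]
                     for v in (1, 0)}
                )
                p_t2dm = _chi2_p(tab2)
            add_row(
                f"Smoking: {name}",
                _fmt_count(int((df["smoking"] == level).sum()), len(df)),
                by_status, p_status, by_t2dm, p_t2dm, note_single,
            )

    for col, label, dec in _CONTINUOUS_VARS:
        if col not in df.columns:
            continue
        by_status = [_fmt_mean(strata[s][col], dec) for s in status_levels]
        p_status = np.nan if note_single else _anova_p([strata[s][col] for s in status_levels])
        if t2dm_strata:
            by_t2dm = [_fmt_mean(t2dm_strata[v][col], dec) for v in (1, 0)]
            p_t2dm = _anova_p([t2dm_strata[v][col] for v in (1, 0)])
        else:
            by_t2dm, p_t2dm = ["-", "-"], np.nan
        add_row(label, _fmt_mean(df[col], dec), by_status, p_status, by_t2dm, p_t2dm,
                note_single)

    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the runner

def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis in fixed stage order; deterministic given
    the config seed.  Per-stage record counts land in the run log."""
    log: list[dict] = []
    params = config.params()

    genotypes = sim_mod.generate_genotypes(params)
    weights, true_effects = sim_mod.generate_weights(genotypes, params)
    cohort = sim_mod.generate_cohort(genotypes, true_effects, params)
    log.append({"stage": "simulate", "n_individuals": genotypes.n_individuals,
                "n_variants": genotypes.n_variants})

    aligned, report = pgs_mod.harmonize_weights(
        weights, genotypes.variants, palindromic=config.palindromic
    )
    log.append({"stage": "harmonize", **dataclasses.asdict(report)})

    if config.region_mask:
        mask = pgs_mod.RegionMask.parse(config.region_mask)
        before = len(aligned)
        aligned = pgs_mod.apply_region_mask(aligned, mask)
        log.append({"stage": "region_mask", "n_removed": before - len(aligned)})

    scores = {}
    for thr in config.thresholds:
        subset_w = pgs_mod.apply_threshold(aligned, thr)
        if subset_w.empty:
            log.append({"stage": "score", "threshold": thr, "n_variants": 0,
                        "error": "no variants at this threshold"})
            continue
        sv = pgs_mod.compute_score(genotypes, subset_w, threshold=thr)
        sv = pgs_mod.standardize(sv, cohort["ancestry"])
        scores[thr] = sv
        log.append({"stage": "score", "threshold": thr, "n_variants": sv.n_variants_used})
    if not scores:
        raise RuntimeError("no threshold produced a non-empty score")

    main_thr = config.thresholds[0] if config.thresholds[0] in scores else next(iter(scores))
    cohort = cohort.copy()
    cohort["pgs"] = scores[main_thr].standardized

    cohort = cohort_mod.classify_cohort(cohort)
    cohort, tally = cohort_mod.apply_exclusions(cohort)
    log.append({"stage": "exclusions", **dataclasses.asdict(tally)})

    subsets = cohort_mod.make_subsets(cohort, config.age_window)
    for s in subsets:
        log.append({"stage": "subset", "label": s.label, "n": s.n, "usable": s.usable})

    descriptive = None
    if "descriptive" in config.analyses:
        descriptive = make_descriptive_table(cohort)
        log.append({"stage": "descriptive", "n_rows": len(descriptive)})

    first_stage_rows = []
    score_rows = []
    mr_rows = []
    sweep_rows = []
    reverse_rows = []
    diagnostics: dict = {}

    if "observational" in config.analyses or "one_sample_mr" in config.analyses:
        for s in subsets:
            if not s.usable:
                log.append({"stage": "models", "subset": s.label,
                            "skipped": "unusable subset"})
                continue
            for adj in config.adjustments:
                cov = [c for c in adjustment_covariates(adj) if c in s.data.columns]
                # first stage (instrument relevance) per subset
                cols = ["pgs", "t2dm", *cov]
                d = s.data.loc[s.data[cols].notna().all(axis=1)]
                full = fit_logistic(d["t2dm"], d[["pgs", *cov]])
                red = (
                    fit_logistic(d["t2dm"], d[cov])
                    if cov
                    else fit_logistic(d["t2dm"], pd.DataFrame(index=d.index))
                )
                rel = improvement_chisq(full, red)
                first_stage_rows.append(
                    {"subset": s.label, "adjustment": adj, "n": full.n,
                     **_or_row(full["pgs"]), "improvement_chisq": rel.statistic,
                     "weak_instrument": rel.weak_instrument}
                )
                if "observational" in config.analyses:
                    for effect in ("total", "direct"):
                        cov_eff = cov + (["t2dm"] if effect == "direct" else [])
                        dd = s.data.loc[
                            s.data[["pgs", *cov_eff]].notna().all(axis=1)
                        ]
                        y = s.outcome[dd.index]
                        fit = fit_logistic(y, dd[["pgs", *cov_eff]])
                        score_rows.append(
                            {"subset": s.label, "adjustment": adj, "effect": effect,
                             "n": fit.n, **_or_row(fit["pgs"])}
                        )
                if "one_sample_mr" in config.analyses:
                    obs_fit = fit_logistic(
                        s.outcome[d.index], d[["t2dm", *cov]]
                    )
                    res = mr_mod.OneSampleMR(
                        pd.concat([d, s.outcome[d.index].rename("_y")], axis=1),
                        outcome="_y", exposure="t2dm", instrument="pgs",
                        covariates=cov,
                    ).fit()
                    het = mr_mod.heterogeneity_test(obs_fit["t2dm"], res.estimate)
                    row = {"subset": s.label, "adjustment": adj, "n": res.n}
                    row.update({f"logistic_{k}": v for k, v in _or_row(obs_fit["t2dm"]).items()})
                    row.update({f"wald_{k}": v for k, v in _or_row(res.estimate).items()})
                    row["p_heterogeneity"] = het.pvalue
                    row["improvement_chisq"] = res.relevance.statistic
                    row["weak_instrument"] = res.weak_instrument
                    mr_rows.append(row)
        log.append({"stage": "models", "first_stage_rows": len(first_stage_rows),
                    "score_rows": len(score_rows), "mr_rows": len(mr_rows)})

    if "one_sample_mr" in config.analyses:
        cov = [c for c in adjustment_covariates("primary") if c in cohort.columns]
        for thr, sv in scores.items():
            tmp = cohort.copy()
            tmp["pgs"] = np.nan
            tmp.loc[:, "pgs"] = pd.Series(
                sv.standardized, index=pd.Index(sv.ids, name="id")
            ).reindex(tmp["id"]).to_numpy()
            for s in cohort_mod.make_subsets(tmp, config.age_window):
                if not s.usable:
                    continue
                res = mr_mod.OneSampleMR(
                    pd.concat([s.data, s.outcome.rename("_y")], axis=1),
                    outcome="_y", exposure="t2dm", instrument="pgs", covariates=cov,
                ).fit()
                sweep_rows.append(
                    {"threshold": thr, "subset": s.label,
                     "n_variants": sv.n_variants_used, "n": res.n,
                     **_or_row(res.estimate),
                     "improvement_chisq": res.relevance.statistic,
                     "weak_instrument": res.weak_instrument}
                )
        log.append({"stage": "mr_sweep", "rows": len(sweep_rows)})

    if "diagnostics" in config.analyses:
        screen_rows = []
        screen_vars = [
            ("age", 1), ("sex", 1), ("education", 1), ("apoe4", 1), ("stroke", 1),
            ("hypertension", 1), ("bmi", 1), ("smoking", 1), ("drinking", 1),
        ]
        for var, _ in screen_vars:
            if var not in cohort.columns:
                continue
            fit = fit_linear(cohort[var], cohort[["pgs"]])
            est = fit["pgs"]
            lo, hi = est.conf_int()
            screen_rows.append({"confounder": var, "beta": est.beta, "se": est.se,
                                "lcl": lo, "ucl": hi, "p": est.pvalue})
        diagnostics["confounder_screen"] = screen_rows

        cov = [c for c in adjustment_covariates("primary") if c in cohort.columns]
        for s in subsets:
            if not s.usable:
                continue
            nc = mr_mod.negative_control(
                s.data, s.outcome, instrument="pgs", covariates=cov
            )
            diagnostics[f"negative_control_{s.label}"] = (
                {"flagged_degenerate": True}
                if nc is None
                else {"n": nc.n, **_or_row(nc["pgs"])}
            )

        r, p = mr_mod.score_correlation(cohort["pgs"], cohort["ad_pgs"])
        diagnostics["score_correlation"] = {"r": r, "p": p}
        log.append({"stage": "diagnostics", "keys": sorted(diagnostics)})

    two_sample = None
    if "two_sample_mr" in config.analyses:
        exp_stats, out_stats = sim_mod.generate_summary_stats(params)
        model = mr_mod.TwoSampleMR.from_summary_stats(
            exp_stats, out_stats, palindromic=config.palindromic
        )
        two_sample = model.fit(seed=config.seed).to_frame()
        log.append({"stage": "two_sample_mr", "n_snps": len(model.pair)})

    if "reverse_mr" in config.analyses:
        cov = [c for c in adjustment_covariates("primary") if c in cohort.columns]
        for s in subsets:
            if not s.usable:
                continue
            res = mr_mod.reverse_mr(s, instrument="ad_pgs", covariates=cov)
            reverse_rows.append(
                {"subset": s.label, "n": res.n, **_or_row(res.estimate),
                 "improvement_chisq": res.relevance.statistic,
                 "weak_instrument": res.weak_instrument}
            )
        log.append({"stage": "reverse_mr", "rows": len(reverse_rows)})

    return ReportBundle(
        descriptive=descriptive,
        first_stage=pd.DataFrame(first_stage_rows) if first_stage_rows else None,
        score_outcome=pd.DataFrame(score_rows) if score_rows else None,
        mr_table=pd.DataFrame(mr_rows) if mr_rows else None,
        mr_sweep=pd.DataFrame(sweep_rows) if sweep_rows else None,
        two_sample=two_sample,
        reverse=pd.DataFrame(reverse_rows) if reverse_rows else None,
        diagnostics=diagnostics,
        log=log,
    )


_TABLE_FILES = {
    "descriptive": "table1_descriptive.tsv",
    "first_stage": "table2_first_stage.tsv",
    "score_outcome": "table3_score_outcome.tsv",
    "mr_table": "table4_mr.tsv",
    "mr_sweep": "mr_threshold_sweep.tsv",
    "two_sample": "two_sample_mr.tsv",
    "reverse": "reverse_mr.tsv",
}


def write_reports(bundle: ReportBundle, outdir) -> list[Path]:
    """Write the TSV tables, a JSON mirror and the run log; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for attr, fname in _TABLE_FILES.items():
        df = getattr(bundle, attr)
        if df is None:
            continue
        path = outdir / fname
        df.to_csv(path, sep="\t", index=False)
        written.append(path)
    diag = outdir / "diagnostics.json"
    diag.write_text(json.dumps(bundle.diagnostics, indent=2, sort_keys=True))
    written.append(diag)
    mirror = outdir / "report.json"
    mirror.write_text(json.dumps(bundle.to_json_dict(), indent=2, sort_keys=True))
    written.append(mirror)
    logp = outdir / "run_log.json"
    logp.write_text(json.dumps(bundle.log, indent=2))
    written.append(logp)
    return written


def demo_config(**overrides) -> RunConfig:
    """A small end-to-end demonstration configuration."""
    base = dict(
        sim={"n_individuals": 2000, "n_variants": 80, "n_causal": 40},
        thresholds=[1.0, 0.05],
        adjustments=["crude", "primary"],
        analyses=["descriptive", "observational", "one_sample_mr", "diagnostics"],
        seed=7,
    )
    base.update(overrides)
    return RunConfig(**base)
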