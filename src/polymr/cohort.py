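"""Langa-Weir cognitive-status classification and sample-selection filters.

Cognitive status is classified in three levels from the summary score:
27-point scale for self-respondents (normal 12-27, CIND 7-11, dementia 0-6)
and 11-point scale for proxy respondents (normal 0-2, CIND 3-5, dementia
6-11).  Selection keeps ages 50-90 inclusive and removes implausible
dementia-to-normal reversions relative to the prior wave.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CognitiveStatus",
    "ExclusionTally",
    "AnalysisSubset",
    "classify_cognition",
    "classify_cohort",
    "apply_exclusions",
    "make_subsets",
]


class CognitiveStatus(str, enum.Enum):
    NORMAL = "normal"
    CIND = "cind"
    DEMENTIA = "dementia"


def classify_cognition(total_score, proxy):
    """Map a cognition summary score to normal / CIND / dementia.

    Accepts scalars or arrays; raises on scores outside the respondent type's
    range ([0, 27] self, [0, 11] proxy).
    """
    score = np.asarray(total_score)
    prox = np.asarray(proxy)
    if np.any((prox == 0) & ((score < 0) | (score > 27))):
        raise ValueError("self-respondent score outside [0, 27]")
    if np.any((prox == 1) & ((score < 0) | (score > 11))):
        raise ValueError("proxy-respondent score outside [0, 11]")
    self_status = np.where(score >= 12, "normal", np.where(score >= 7, "cind", "dementia"))
    proxy_status = np.where(score <= 2, "normal", np.where(score <= 5, "cind", "dementia"))
    status = np.where(prox == 1, proxy_status, self_status)
    if score.ndim == 0:
        return CognitiveStatus(str(status))
    return pd.Categorical(status, categories=[s.value for s in CognitiveStatus])


def classify_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``cognitive_status`` column derived from score and proxy flag."""
    out = cohort.copy()
    out["cognitive_status"] = classify_cognition(
        cohort["cognition_score"].to_numpy(), cohort["proxy"].to_numpy()
    )
    return out


@dataclass
class ExclusionTally:
    """Per-rule removal counts, recorded in application order."""

    n_input: int = 0
    missing_required: int = 0
    age_window: int = 0
    reversion: int = 0
    n_retained: int = 0
    order: tuple = ("missing_required", "age_window", "reversion")


def apply_exclusions(
    cohort: pd.DataFrame, *, age_min: float = 50.0, age_max: float = 90.0
) -> tuple[pd.DataFrame, ExclusionTally]:
    """Apply the study's selection filters.

    Keeps 50 <= age <= 90 (bounds inclusive: the rule excludes those *younger
    than* 50 or *over* 90) and removes participants with a prior-wave dementia
    record who present as cognitively normal in the current wave.  Rows with
    missing required fields are tallied separately, never silently excluded.
    """
    tally = ExclusionTally(n_input=len(cohort))
    if cohort.empty:
        return cohort.copy(), tally
    required = ["age", "cognition_score", "proxy", "prior_wave_dementia"]
    missing_cols = [c for c in required if c not in cohort.columns]
    if missing_cols:
        raise KeyError(f"cohort is missing required columns {missing_cols}")
    ok = cohort[required].notna().all(axis=1)
    tally.missing_required = int((~ok).sum())
    df = cohort.loc[ok]

    in_window = (df["age"] >= age_min) & (df["age"] <= age_max)
    tally.age_window = int((~in_window).sum())
    df = df.loc[in_window]

    status = classify_cognition(df["cognition_score"].to_numpy(), df["proxy"].to_numpy())
    revert = (df["prior_wave_dementia"].to_numpy() == 1) & (np.asarray(status) == "normal")
    tally.reversion = int(revert.sum())
    df = df.loc[~revert]

    tally.n_retained = len(df)
    return df.reset_index(drop=True), tally


@dataclass
class AnalysisSubset:
    """One binary contrast: impaired (CIND or dementia) = 1 vs normal = 0."""

    label: str
    data: pd.DataFrame = field(repr=False)
    outcome: pd.Series = field(repr=False)
    usable: bool = True
    n_dropped_missing_exposure: int = 0

    @property
    def n(self) -> int:
        return len(self.data)


def make_subsets(
    cohort: pd.DataFrame,
    age_window: tuple[float, float] | None = None,
    *,
    exposure: str = "t2dm",
) -> list[AnalysisSubset]:
    """Build the CIND-vs-normal and dementia-vs-normal analysis subsets.

    The optional age window is applied first; members with missing exposure
    are dropped and counted.  A subset without both outcome classes is flagged
    unusable.
    """
    df = cohort if "cognitive_status" in cohort.columns else classify_cohort(cohort)
    if exposure not in df.columns:
        raise KeyError(f"exposure column {exposure!r} not present in cohort")
    if age_window is not None:
        lo, hi = age_window
        df = df.loc[(df["age"] >= lo) & (df["age"] <= hi)]
    subsets = []
    for label, drop in (("cind_vs_normal", "dementia"), ("dementia_vs_normal", "cind")):
        sub = df.loc[df["cognitive_status"].astype(str) != drop].copy()
        n_missing = int(sub[exposure].isna().sum())
        sub = sub.loc[sub[exposure].notna()]
        case = "cind" if label == "cind_vs_normal" else "dementia"
        y = (sub["cognitive_status"].astype(str) == case).astype(int)
        y.name = label
        usable = y.nunique() == 2
        subsets.append(
            AnalysisSubset(
                label=label,
                data=sub.reset_index(drop=True),
                outcome=y.reset_index(drop=True),
                usable=usable,
                n_dropped_missing_exposure=n_missing,
            )
        )
    return subsets
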