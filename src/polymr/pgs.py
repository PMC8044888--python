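"""Polygenic score construction: harmonization, p-value thresholding, region
masking, dot-product scoring and within-group standardization.

The score for individual *i* is ``PGS_i = sum_j W_j G_ij`` over the retained
variants, where ``W_j`` is the external GWAS effect size aligned to the
counted allele and ``G_ij`` the dosage (0, 1, 2).  Scores are standardized to
mean 0, SD 1 within each ancestry group before modelling.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix

__all__ = [
    "RegionMask",
    "ScoreVector",
    "HarmonizationReport",
    "harmonize_weights",
    "apply_threshold",
    "apply_region_mask",
    "compute_score",
    "standardize",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(str(a1).upper()) == str(a2).upper()


@dataclass(frozen=True)
class RegionMask:
    """Inclusive, 1-based genomic interval to excise from a weight table."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("RegionMask start must be <= end")

    @classmethod
    def parse(cls, text: str) -> "RegionMask":
        """Parse e.g. ``chr19:45384477-45432606`` (commas tolerated)."""
        m = re.fullmatch(r"(chr)?(\w+):([\d,]+)-([\d,]+)", text.strip())
        if not m:
            raise ValueError(f"cannot parse region {text!r}")
        return cls(m.group(2), int(m.group(3).replace(",", "")), int(m.group(4).replace(",", "")))


#: APOE region (build 37/hg19), excised from the Alzheimer's-disease score so
#: the single locus does not dominate it.
APOE_REGION = RegionMask("19", 45_384_477, 45_432_606)


@dataclass
class HarmonizationReport:
    n_input: int = 0
    n_kept: int = 0
    n_flipped: int = 0
    n_strand_flipped: int = 0
    n_palindromic: int = 0
    n_dropped: int = 0
    policy: str = "keep"


@dataclass
class ScoreVector:
    """Raw (and optionally standardized) polygenic scores."""

    ids: pd.Index
    raw: np.ndarray
    standardized: Optional[np.ndarray] = None
    threshold: float = 1.0
    n_variants_used: int = 0
    groups: Optional[pd.Series] = field(default=None, repr=False)

    @property
    def values(self) -> np.ndarray:
        """Standardized scores if available, raw otherwise."""
        return self.raw if self.standardized is None else self.standardized

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.ids, "raw": self.raw})
        df["standardized"] = np.nan if self.standardized is None else self.standardized
        df["threshold"] = self.threshold
        df["n_variants_used"] = self.n_variants_used
        return df


def harmonize_weights(
    weights: pd.DataFrame,
    variant_meta: pd.DataFrame,
    *,
    palindromic: str = "keep",
) -> tuple[pd.DataFrame, HarmonizationReport]:
    """Align a weight table to the genotype matrix's counted alleles.

    Restricts to the id intersection.  Where the effect allele equals the
    counted allele the weight is unchanged; where the alleles are swapped the
    weight is negated (equivalent to scoring the complementary dosage
    ``2 - G``); otherwise the strand complement is tried.  Strand-ambiguous
    (A/T, C/G) variants are kept by default or dropped with
    ``palindromic="drop"``.  Irreconcilable variants are dropped and counted,
    never silently kept.
    """
    if weights.empty or variant_meta.empty:
        raise ValueError("harmonize_weights requires non-empty inputs")
    if palindromic not in ("keep", "drop"):
        raise ValueError("palindromic policy must be 'keep' or 'drop'")

    report = HarmonizationReport(n_input=len(weights), policy=palindromic)
    meta = variant_meta.set_index("snp")
    rows = []
    for rec in weights.itertuples(index=False):
        if rec.snp not in meta.index:
            continue
        counted = str(meta.at[rec.snp, "a1"]).upper()
        other = str(meta.at[rec.snp, "a2"]).upper()
        a1, a2 = str(rec.a1).upper(), str(rec.a2).upper()
        pal = _is_palindromic(a1, a2)
        if pal:
            report.n_palindromic += 1
            if palindromic == "drop":
                report.n_dropped += 1
                continue
        beta = None
        strand = False
        if (a1, a2) == (counted, other):
            beta = rec.beta
        elif (a1, a2) == (other, counted):
            beta = -rec.beta
        elif not pal:  # try the opposite strand (meaningless for palindromes)
            ca1, ca2 = _COMPLEMENT.get(a1), _COMPLEMENT.get(a2)
            if (ca1, ca2) == (counted, other):
                beta, strand = rec.beta, True
            elif (ca1, ca2) == (other, counted):
                beta, strand = -rec.beta, True
        if beta is None:
            report.n_dropped += 1
            continue
        report.n_kept += 1
        if beta == -rec.beta and rec.beta != 0:
            report.n_flipped += 1
        if strand:
            report.n_strand_flipped += 1
        row = rec._asdict()
        row["beta"] = beta
        row["a1"], row["a2"] = counted, other
        rows.append(row)

    aligned = pd.DataFrame(rows, columns=weights.columns)
    return aligned, report


def apply_threshold(weights: pd.DataFrame, p_cutoff: float) -> pd.DataFrame:
    """Retain exactly the variants with GWAS p-value <= ``p_cutoff``."""
    if not 0.0 < p_cutoff <= 1.0:
        raise ValueError("p_cutoff must lie in (0, 1]")
    return weights.loc[weights["p"] <= p_cutoff].reset_index(drop=True)


def apply_region_mask(weights: pd.DataFrame, mask: RegionMask) -> pd.DataFrame:
    """Remove variants inside the masked interval (inclusive bounds)."""
    chrom = weights["chr"].astype(str).str.replace("chr", "", regex=False)
    inside = (
        (chrom == str(mask.chromosome).replace("chr", ""))
        & (weights["bp"] >= mask.start)
        & (weights["bp"] <= mask.end)
    )
    return weights.loc[~inside].reset_index(drop=True)


def compute_score(
    genotypes: GenotypeMatrix, weights: pd.DataFrame, *, threshold: float = 1.0
) -> ScoreVector:
    """Exact dot product of dosages and aligned weights."""
    idx = pd.Index(genotypes.variants["snp"])
    missing = weights.loc[~weights["snp"].isin(idx), "snp"]
    if len(missing):
        raise KeyError(
            f"{len(missing)} weight(s) reference variants absent from the "
            f"genotype matrix (harmonize first): {list(missing[:3])}..."
        )
    positions = idx.get_indexer(weights["snp"])
    raw = genotypes.dosages[:, positions].astype(float) @ weights["beta"].to_numpy(float)
    return ScoreVector(
        ids=genotypes.sample_ids,
        raw=raw,
        threshold=threshold,
        n_variants_used=len(weights),
    )


def standardize(scores: ScoreVector, groups: Optional[Sequence] = None) -> ScoreVector:
    """Z-score within each group (n-1 denominator), e.g. within ancestry."""
    raw = np.asarray(scores.raw, float)
    if groups is None:
        groups = pd.Series(["all"] * len(raw))
    groups = pd.Series(np.asarray(groups), index=range(len(raw)))
    if len(groups) != len(raw):
        raise ValueError("group labels must match score length")
    std = np.empty_like(raw)
    for label, members in groups.groupby(groups).groups.items():
        vals = raw[np.asarray(members)]
        if len(vals) < 2:
            raise ValueError(f"group {label!r} has fewer than 2 members")
        sd = vals.std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero score variance within group {label!r}")
        std[np.asarray(members)] = (vals - vals.mean()) / sd
    return ScoreVector(
        ids=scores.ids,
        raw=raw,
        standardized=std,
        threshold=scores.threshold,
        n_variants_used=scores.n_variants_used,
        groups=groups,
    )
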