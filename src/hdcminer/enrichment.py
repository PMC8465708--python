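"""Disease-enrichment analysis of histamine-secreting species.

Count tables are filtered (samples with fewer than one million reads are
excluded; a taxon is retained only if it reaches 0.01% relative abundance
in at least 10% of the remaining samples), per-method differential-
abundance calls are thresholded with the method-specific criteria
(DESeq2-like: log2FC > 1, q < 0.05, HMP2 cohorts log2FC > 0.5;
MaAsLin2-like: coef > 0.2, q < 0.05, HMP2 coef > 0; LEfSe-like: LDA > 2,
q < 0.001 — all inequalities strict), and the proportion of
disease-enriched species among histamine-secreting species is compared
with the proportion among all species by a one-tailed two-proportion
Z-test with continuity correction.

A small built-in rank-sum differential-abundance routine is provided as
plumbing so fully synthetic end-to-end runs need no external DESeq2/
MaAsLin2/LEfSe fits; real analyses should supply those methods' result
tables instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from hdcminer.annotation_io import ValidationError

CONDITIONS = ("control", "disease")


class EmptyResultError(ValueError):
    """Filtering removed every sample (or taxon)."""


@dataclass
class CountTable:
    """Species x sample counts plus per-sample (study, condition) metadata."""

    counts: pd.DataFrame  # index: species_id, columns: sample_id
    sample_meta: pd.DataFrame  # index: sample_id, columns: study, condition

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)[:5]}")
        bad = set(self.sample_meta["condition"]) - set(CONDITIONS)
        if bad:
            raise ValidationError(f"unknown conditions: {sorted(bad)}")

    def samples_by_condition(self, condition: str) -> list[str]:
        meta = self.sample_meta.loc[list(self.counts.columns)]
        return [s for s in self.counts.columns if meta.at[s, "condition"] == condition]


@dataclass
class FilterParams:
    """Sample depth and rare-taxon filter settings."""

    min_library_size: int = 1_000_000
    rare_rel_abundance: float = 1e-4  # 0.01%
    rare_sample_fraction: float = 0.10

    def __post_init__(self) -> None:
        if min(self.min_library_size, self.rare_rel_abundance, self.rare_sample_fraction) <= 0:
            raise ValueError("all filter parameters must be positive")


@dataclass(frozen=True)
class DAResult:
    """One species' differential-abundance call from one method."""

    species_id: str
    method: str  # deseq2_like | maaslin2_like | lefse_like | builtin
    effect: float  # log2FC, coefficient or LDA score, per method
    qvalue: float
    direction: str  # disease | control

    def __post_init__(self) -> None:
        if not 0 <= self.qvalue <= 1:
            raise ValidationError(f"{self.species_id}: qvalue outside [0,1]")


@dataclass(frozen=True)
class MethodCriterion:
    min_effect: float
    max_q: float

    def __post_init__(self) -> None:
        if not 0 < self.max_q <= 1:
            raise ValueError("max_q must be in (0,1]")


@dataclass
class EnrichCriteria:
    """Per-method enrichment thresholds, with HMP2-cohort variants.

    A species is enriched when direction is disease, effect strictly
    exceeds min_effect and q is strictly below max_q.
    """

    base: dict[str, MethodCriterion] = field(
        default_factory=lambda: {
            "deseq2_like": MethodCriterion(1.0, 0.05),
            "maaslin2_like": MethodCriterion(0.2, 0.05),
            "lefse_like": MethodCriterion(2.0, 0.001),
            "builtin": MethodCriterion(1.0, 0.05),
        }
    )
    hmp2: dict[str, MethodCriterion] = field(
        default_factory=lambda: {
            "deseq2_like": MethodCriterion(0.5, 0.05),
            "maaslin2_like": MethodCriterion(0.0, 0.05),
        }
    )
    hmp2_studies: frozenset[str] = frozenset({"HMP2"})

    def criterion(self, method: str, study: str = "") -> MethodCriterion:
        if study in self.hmp2_studies and method in self.hmp2:
            return self.hmp2[method]
        if method not in self.base:
            raise KeyError(f"no enrichment criteria for method {method!r}")
        return self.base[method]


@dataclass(frozen=True)
class EnrichmentResult:
    """Over-representation of HSB among disease-enriched species."""

    study: str
    method: str
    x_hsb: int
    n_hsb: int
    x_all: int
    n_all: int
    z: float
    p_one_tailed: float
    label: str


# ---------------------------------------------------------------------------
# Filtering and thresholding
# ---------------------------------------------------------------------------

def filter_table(table: CountTable, params: FilterParams | None = None) -> CountTable:
    """Apply the sample-depth filter, then the rare-taxon filter.

    Samples with total counts below ``min_library_size`` are removed
    first (a sample at exactly one million is kept).  A taxon is then
    retained iff its within-sample relative abundance reaches
    ``rare_rel_abundance`` in at least ``rare_sample_fraction`` of the
    remaining samples.
    """
    params = params or FilterParams()
    totals = table.counts.sum(axis=0)
    keep_samples = totals[totals >= params.min_library_size].index
    if len(keep_samples) == 0:
        raise EmptyResultError("sample-depth filter removed every sample")
    counts = table.counts[keep_samples]
    rel = counts / counts.sum(axis=0)
    frac_present = (rel >= params.rare_rel_abundance).mean(axis=1)
    keep_taxa = frac_present[frac_present >= params.rare_sample_fraction].index
    return CountTable(
        counts=counts.loc[keep_taxa],
        sample_meta=table.sample_meta.loc[keep_samples],
    )


def flag_enriched(
    results: Iterable[DAResult], criteria: EnrichCriteria | None = None, study: str = ""
) -> set[str]:
    """Species flagged disease-enriched under the method-specific criteria."""
    criteria = criteria or EnrichCriteria()
    enriched = set()
    for r in results:
        crit = criteria.criterion(r.method, study)
        if r.direction == "disease" and r.effect > crit.min_effect and r.qvalue < crit.max_q:
            enriched.add(r.species_id)
    return enriched


# ---------------------------------------------------------------------------
# Two-proportion Z-test with continuity correction
# ---------------------------------------------------------------------------

def two_proportion_ztest(
    x1: int, n1: int, x2: int, n2: int, alternative: str = "greater"
) -> tuple[float, float]:
    """Continuity-corrected two-proportion Z-test.

    With p1 = x1/n1, p2 = x2/n2 and pooled proportion pi, the difference
    d = p1 - p2 is shrunk toward zero by c = (1/n1 + 1/n2)/2 (clamped so
    the correction never flips the sign), and z is the corrected
    difference over sqrt(pi(1-pi)(1/n1+1/n2)).  When the pooled
    proportion is degenerate (0 or 1) the statistic is defined as z = 0,
    p = 0.5.  ``alternative`` "greater" tests p1 > p2.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 0.5
    d = x1 / n1 - x2 / n2
    c = 0.5 * (1 / n1 + 1 / n2)
    numerator = math.copysign(max(abs(d) - c, 0.0), d) if d != 0 else 0.0
    z = numerator / math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if alternative == "greater":
        p = stats.norm.sf(z)
    elif alternative == "less":
        p = stats.norm.cdf(z)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return z, float(p)


def p_to_label(p: float) -> str:
    """Map a p-value to the conventional significance asterisks."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0,1]")
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "n.s."


def hsb_enrichment_test(
    enriched: set[str],
    hsb: set[str],
    universe: set[str],
    study: str = "",
    method: str = "",
    overlap: bool = True,
) -> EnrichmentResult:
    """Test whether HSB are over-represented among disease-enriched species.

    With ``overlap=True`` (the default) the comparison is HSB vs ALL
    species, the HSB being a subset of the reference group.  With
    ``overlap=False`` the reference group is the non-HSB species — a
    sensitivity variant in which the two proportions are independent.
    """
    if not hsb <= universe:
        raise ValidationError("HSB set must be a subset of the species universe")
    if not enriched <= universe:
        raise ValidationError("enriched set must be a subset of the species universe")
    x1, n1 = len(enriched & hsb), len(hsb)
    if overlap:
        x2, n2 = len(enriched), len(universe)
    else:
        x2, n2 = len(enriched - hsb), len(universe - hsb)
    z, p = two_proportion_ztest(x1, n1, x2, n2, alternative="greater")
    return EnrichmentResult(
        study=study,
        method=method,
        x_hsb=x1,
        n_hsb=n1,
        x_all=x2,
        n_all=n2,
        z=z,
        p_one_tailed=p,
        label=p_to_label(p),
    )


def enrichment_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "study": r.study,
            "method": r.method,
            "x_hsb": r.x_hsb,
            "n_hsb": r.n_hsb,
            "x_all": r.x_all,
            "n_all": r.n_all,
            "z": r.z,
            "p_one_tailed": r.p_one_tailed,
            "label": r.label,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["study", "method", "x_hsb", "n_hsb", "x_all", "n_all", "z", "p_one_tailed", "label"],
    )


# ---------------------------------------------------------------------------
# Built-in differential abundance (plumbing for synthetic end-to-end runs)
# ---------------------------------------------------------------------------

def builtin_da(table: CountTable, epsilon: float = 1e-6) -> list[DAResult]:
    """Rank-sum differential abundance on relative abundances.

    Per species: a two-sided rank-sum test of disease vs control relative
    abundances (normal approximation with tie correction), Benjamini-
    Hochberg q-values across species, and effect
    log2((mean_rel_disease + eps) / (mean_rel_control + eps)).  Direction
    follows the sign of the effect.  Constant species get p = 1.
    """
    control = table.samples_by_condition("control")
    disease = table.samples_by_condition("disease")
    if len(control) < 2 or len(disease) < 2:
        raise ValueError("builtin_da needs >= 2 samples per condition")
    counts = table.counts
    rel = counts.to_numpy(dtype=float) / counts.sum(axis=0).to_numpy(dtype=float)
    rel = pd.DataFrame(rel, index=counts.index, columns=counts.columns)
    d_mat = rel[disease].to_numpy()
    c_mat = rel[control].to_numpy()
    constant = np.ptp(np.concatenate([d_mat, c_mat], axis=1), axis=1) == 0
    pvals = np.ones(len(rel))
    if (~constant).any():
        res = stats.mannwhitneyu(
            d_mat[~constant],
            c_mat[~constant],
            axis=1,
            alternative="two-sided",
            method="asymptotic",
        )
        pvals[~constant] = res.pvalue
    qvals = multipletests(pvals, method="fdr_bh")[1]
    effects = np.log2((d_mat.mean(axis=1) + epsilon) / (c_mat.mean(axis=1) + epsilon))
    return [
        DAResult(
            species_id=str(sp),
            method="builtin",
            effect=float(eff),
            qvalue=float(min(q, 1.0)),
            direction="disease" if eff > 0 else "control",
        )
        for sp, eff, q in zip(rel.index, effects, qvals)
    ]


def da_results_to_frame(results: Iterable[DAResult]) -> pd.DataFrame:
    rows = [
        {
            "species_id": r.species_id,
            "method": r.method,
            "effect": r.effect,
            "qvalue": r.qvalue,
            "direction": r.direction,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=["species_id", "method", "effect", "qvalue", "direction"])
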