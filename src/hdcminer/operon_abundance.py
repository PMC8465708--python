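"""Operon read-depth abundance in counts per million mapped reads (CPM).

Per-sample operon abundance is the number of reads mapped to the
histidine decarboxylase operon divided by the total number of reads
mapped to the reference genomes, scaled to one million
(reads_on_operon / total_mapped x 1e6).  Samples with fewer than one
million mapped reads are excluded.  Patients are compared with controls
by a one-sided Wilcoxon rank-sum test with continuity correction
(alternative: disease > control); for small tie-free datasets the exact
permutation distribution is enumerated instead of the normal
approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from hdcminer.annotation_io import ValidationError


@dataclass(frozen=True)
class OperonReadCounts:
    sample_id: str
    condition: str  # control | disease
    reads_on_operon: int
    total_mapped: int

    def __post_init__(self) -> None:
        if not 0 <= self.reads_on_operon <= self.total_mapped:
            raise ValidationError(
                f"sample {self.sample_id}: reads_on_operon must be in [0, total_mapped]"
            )


def compute_cpm(
    counts: Iterable[OperonReadCounts], min_total: int = 1_000_000
) -> pd.DataFrame:
    """Per-sample operon CPM after the minimum-depth filter.

    Returns a frame with columns sample_id, condition, cpm (samples with
    total_mapped below *min_total* are dropped).  Duplicate sample ids
    are an error.
    """
    records = list(counts)
    seen: set[str] = set()
    for rec in records:
        if rec.sample_id in seen:
            raise ValidationError(f"duplicate sample_id {rec.sample_id}")
        seen.add(rec.sample_id)
    rows = [
        {
            "sample_id": r.sample_id,
            "condition": r.condition,
            "cpm": r.reads_on_operon / r.total_mapped * 1e6,
        }
        for r in records
        if r.total_mapped >= min_total
    ]
    return pd.DataFrame(rows, columns=["sample_id", "condition", "cpm"])


def ranksum_one_sided(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """One-sided rank-sum test of x (disease) greater than y (control).

    Returns (W, p) where W is the rank sum of x in the combined sample
    (midranks for ties).  ``method`` is "exact" (exhaustive enumeration
    of rank assignments; requires a tie-free sample), "approx" (normal
    approximation with tie-corrected variance and a 0.5 continuity
    correction) or "auto" (exact when n1 + n2 <= 12 and there are no
    ties, approximate otherwise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    n1, n2 = x.size, y.size
    n = n1 + n2
    ranks = stats.rankdata(combined)
    w = float(ranks[:n1].sum())
    has_ties = np.unique(combined).size < n

    if method == "auto":
        method = "exact" if (n <= 12 and not has_ties) else "approx"
    if method == "exact":
        if has_ties:
            raise ValueError("exact enumeration requires a tie-free sample")
        total = math.comb(n, n1)
        count = sum(1 for comb in combinations(range(1, n + 1), n1) if sum(comb) >= w)
        return w, count / total
    if method != "approx":
        raise ValueError(f"unknown method {method!r}")

    mean = n1 * (n + 1) / 2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n1 * n2 / 12 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 0.5
    z = (w - mean - 0.5) / math.sqrt(var)
    return w, float(stats.norm.sf(z))


def compare_groups(cpm: pd.DataFrame, method: str = "auto") -> tuple[float, float]:
    """Rank-sum comparison of disease vs control CPM values."""
    x = cpm.loc[cpm["condition"] == "disease", "cpm"].to_numpy()
    y = cpm.loc[cpm["condition"] == "control", "cpm"].to_numpy()
    return ranksum_one_sided(x, y, method=method)
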