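"""Evaluation statistics for adaptive EMA studies.

Covers the quantities used to characterize an adaptive protocol and its
simulation studies: pairwise survey-content similarity (Jaccard index and
overlap coefficient, averaged within participant), one-way random-effects
intraclass correlation via ANOVA mean squares, truth-vs-estimate recovery
statistics, compliance rates against the expected prompt count, and
descriptive statistics recovered from published frequency tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .adaptive import SessionRecord


@dataclass
class OverlapSummary:
    """Per-participant mean pairwise survey-content similarity."""

    participant_id: str
    mean_jaccard: float
    mean_overlap_coefficient: float
    n_pairs: int


def jaccard_and_overlap(a: Iterable, b: Iterable) -> tuple[float, float]:
    """Jaccard index |a&b|/|a|b| and overlap coefficient |a&b|/min(|a|,|b|).

    The Jaccard index is the share of items common to both surveys among
    all unique items across the two; the overlap coefficient replaces the
    union with the shorter survey's size, so Jaccard <= overlap always.
    """
    sa, sb = set(a), set(b)
    if not sa or not sb:
        raise ValueError("both item sets must be nonempty")
    inter = len(sa & sb)
    return inter / len(sa | sb), inter / min(len(sa), len(sb))


def overlap_summary(
    sessions: Sequence[SessionRecord], participant_id: str | None = None
) -> OverlapSummary:
    """Average pairwise similarity over all unordered session pairs."""
    if len(sessions) < 2:
        raise ValueError("need at least 2 completed sessions")
    sets = [s.item_set for s in sessions]
    jacc, over = [], []
    for i in range(len(sets)):
        for k in range(i + 1, len(sets)):
            j, o = jaccard_and_overlap(sets[i], sets[k])
            jacc.append(j)
            over.append(o)
    pid = participant_id or sessions[0].participant_id
    return OverlapSummary(
        participant_id=pid,
        mean_jaccard=float(np.mean(jacc)),
        mean_overlap_coefficient=float(np.mean(over)),
        n_pairs=len(jacc),
    )


def icc_oneway(groups: Mapping | Sequence[Sequence[float]]) -> float:
    """One-way random-effects ICC(1) from ANOVA mean squares.

    ICC = (MSB - MSW) / (MSB + (k0 - 1) MSW), where k0 is the standard
    unbalanced-design group-size adjustment
    k0 = (N - sum n_i^2 / N) / (a - 1); clipped to [0, 1].  Invariant to
    adding a constant to all values and to positive rescaling.
    """
    if isinstance(groups, Mapping):
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, dtype=float) for v in groups]
    arrays = [a for a in arrays if a.size > 0]
    a = len(arrays)
    if a < 2:
        raise ValueError("need at least 2 groups")
    n_i = np.array([len(x) for x in arrays], dtype=float)
    N = n_i.sum()
    grand = sum(x.sum() for x in arrays) / N
    ssb = float(sum(n * (x.mean() - grand) ** 2 for n, x in zip(n_i, arrays)))
    ssw = float(sum(((x - x.mean()) ** 2).sum() for x in arrays))
    if N <= a:
        raise ValueError("need replicate values within groups")
    msb = ssb / (a - 1)
    msw = ssw / (N - a)
    k0 = (N - float(n_i @ n_i) / N) / (a - 1)
    if msw == 0.0:
        return 1.0 if msb > 0 else 0.0
    icc = (msb - msw) / (msb + (k0 - 1) * msw)
    return float(np.clip(icc, 0.0, 1.0))


def recovery_stats(
    true_theta: np.ndarray | pd.DataFrame,
    estimated_theta: np.ndarray | pd.DataFrame,
    domain_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-domain bias, RMSE, and Pearson correlation of estimates vs truth.

    Inputs are aligned (n_observations, m) arrays (or DataFrames with
    matching columns).  A zero-variance column yields NaN correlation
    (undefined, not 0).
    """
    if isinstance(true_theta, pd.DataFrame):
        domain_names = domain_names or list(true_theta.columns)
        true_theta = true_theta.to_numpy()
    if isinstance(estimated_theta, pd.DataFrame):
        estimated_theta = estimated_theta.to_numpy()
    t = np.atleast_2d(np.asarray(true_theta, float))
    e = np.atleast_2d(np.asarray(estimated_theta, float))
    if t.shape != e.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {e.shape}")
    m = t.shape[1]
    names = list(domain_names) if domain_names else [str(g) for g in range(m)]
    rows = []
    for g in range(m):
        err = e[:, g] - t[:, g]
        if t[:, g].std() == 0 or e[:, g].std() == 0:
            corr = np.nan
        else:
            corr = float(np.corrcoef(t[:, g], e[:, g])[0, 1])
        rows.append(
            {
                "domain": names[g],
                "bias": float(err.mean()),
                "rmse": float(np.sqrt(np.mean(err**2))),
                "correlation": corr,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class FrequencyTableStats:
    mean: float
    sd: float
    median: float
    q1: float
    q3: float


def frequency_table_stats(
    counts: Sequence[int], scores: Sequence[float] = (1, 2, 3, 4, 5)
) -> FrequencyTableStats:
    """Mean, sample SD, median, and quartiles from a frequency table.

    The table is expanded to the raw score vector; SD uses the n-1
    denominator and quantiles use nearest-observation (no interpolation),
    matching integer medians/IQRs as printed in survey descriptive tables.
    """
    counts = np.asarray(counts, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(np.diff(scores) <= 0):
        raise ValueError("scores must be strictly increasing")
    n = int(counts.sum())
    if n < 2:
        raise ValueError("need a total count of at least 2")
    expanded = np.repeat(scores, counts)
    q1, med, q3 = np.quantile(expanded, [0.25, 0.5, 0.75], method="nearest")
    return FrequencyTableStats(
        mean=float(expanded.mean()),
        sd=float(expanded.std(ddof=1)),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
    )


def compliance_rate(completed: int, expected: int = 126) -> float:
    """Share of expected surveys completed (126 = 6/day for 21 days)."""
    if expected <= 0:
        raise ValueError("expected must be positive")
    if not 0 <= completed <= expected:
        raise ValueError("completed must lie in [0, expected]")
    return completed / expected
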