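"""The two significance procedures applied to per-isolate rate vectors.

Mann-Whitney U: exact two-tailed p by full enumeration of rank
assignments for small tie-free samples (n1 + n2 <= 16), otherwise the
tie-corrected normal approximation with continuity correction. The
two-tailed p doubles the smaller tail and caps at 1, the convention of
common statistics software. Unpaired t: Student's pooled-variance test.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .genome_io import DataError

__all__ = ["TestResult", "mann_whitney", "t_unpaired"]

EXACT_THRESHOLD = 16  # largest n1 + n2 enumerated exactly


@dataclass
class TestResult:
    statistic: float
    p_two_tailed: float
    method: str
    n1: int
    n2: int


@lru_cache(maxsize=None)
def _exact_u_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Number of rank assignments giving each U value, u = 0..n1*n2.

    Enumerates all C(n1+n2, n1) ways to place the first sample's ranks;
    cheap for n1 + n2 <= 16 and cached per sample-size pair.
    """
    n = n1 + n2
    counts = [0] * (n1 * n2 + 1)
    offset = n1 * (n1 - 1) // 2  # sum of the n1 smallest 0-based ranks
    for ranks in combinations(range(n), n1):
        counts[sum(ranks) - offset] += 1
    return tuple(counts)


def _exact_two_tailed_p(u: float, n1: int, n2: int) -> float:
    counts = np.asarray(_exact_u_counts(n1, n2), dtype=float)
    total = counts.sum()
    ui = int(round(u))
    p_le = counts[: ui + 1].sum() / total
    p_ge = counts[ui:].sum() / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def mann_whitney(
    x: Sequence[float], y: Sequence[float], exact_threshold: int = EXACT_THRESHOLD
) -> TestResult:
    """Two-tailed Mann-Whitney U test of two independent samples.

    The reported statistic is U of the first sample, so that
    U(x, y) + U(y, x) = n1 * n2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise DataError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    has_ties = len(np.unique(combined)) < n1 + n2
    if not has_ties and n1 + n2 <= exact_threshold:
        return TestResult(
            statistic=float(u1),
            p_two_tailed=_exact_two_tailed_p(u1, n1, n2),
            method="mann_whitney_exact",
            n1=n1,
            n2=n2,
        )
    # tie-corrected normal approximation with continuity correction
    mu = n1 * n2 / 2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    n = n1 + n2
    var = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return TestResult(float(u1), 1.0, "mann_whitney_normal", n1, n2)
    z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / np.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult(float(u1), float(p), "mann_whitney_normal", n1, n2)


def t_unpaired(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Student's two-sample t test with pooled variance, df = n1 + n2 - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise DataError("both samples need at least two observations")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        warnings.warn("zero pooled variance in t test")
        if x.mean() == y.mean():
            return TestResult(0.0, 1.0, "t_unpaired", n1, n2)
        return TestResult(
            float(np.inf) if x.mean() > y.mean() else float(-np.inf),
            float(np.finfo(float).tiny),
            "t_unpaired",
            n1,
            n2,
        )
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = float(min(1.0, 2.0 * sps.t.sf(abs(t), df)))
    return TestResult(float(t), p, "t_unpaired", n1, n2)
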