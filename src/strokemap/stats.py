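"""Nonparametric cohort comparisons: Kolmogorov-Smirnov, Mann-Whitney U, Bonferroni."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["TestResult", "ks_two_sample", "mann_whitney_u", "bonferroni"]

#: sample-size ceiling for exact Mann-Whitney p-values (normal approximation above)
EXACT_MW_MAX_N = 20


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str


def _check_samples(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    return a, b


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided two-sample KS test: D = maximal ECDF gap, asymptotic p."""
    a, b = _check_samples(a, b)
    res = sps.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n1=a.size,
        n2=b.size,
        method="ks_2samp_asymptotic",
    )


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Mann-Whitney U for the first sample: U = #{a_i > b_j} + 0.5 #{ties}.

    Exact p for small tie-free samples, otherwise the tie-corrected normal
    approximation (two-sided).
    """
    a, b = _check_samples(a, b)
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    if not has_ties and max(a.size, b.size) <= EXACT_MW_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n1=a.size,
        n2=b.size,
        method=f"mannwhitneyu_{method}",
    )


def bonferroni(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m) elementwise; m defaults to len(p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, p * m)
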