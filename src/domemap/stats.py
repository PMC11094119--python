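"""Statistical primitives shared by every pipeline stage.

Conventions used throughout the package:

* intensities are variance-stabilised with ``asinh(x / cofactor)`` (mass-cytometry
  convention, default cofactor 5);
* group comparisons are two-tailed; the unpaired t test uses the Welch
  (unequal-variance) convention unless ``equal_var=True``;
* the Wilcoxon rank-sum test is exact (full enumeration of the rank-sum null)
  for small samples and a tie-corrected, continuity-corrected normal
  approximation above ``exact_limit`` total observations;
* family-wise corrections are Holm's step-down method or Bonferroni;
* Spearman's rho is the Pearson correlation of midranks, with p from the
  t approximation ``t = rho * sqrt((n-2) / (1-rho^2))``.

Degenerate inputs (zero variance, all-tied data) are reported through the
``degenerate`` flag on :class:`TestResult` rather than raised, so batch reports
over many markers/genes can proceed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Literal, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "AdjustedPVector",
    "arcsinh_transform",
    "inverse_arcsinh",
    "t_test",
    "wilcoxon_rank_sum",
    "adjust_pvalues",
    "spearman_correlation",
]

#: total-observation count at or below which the rank-sum test is exact
WILCOXON_EXACT_LIMIT = 16


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-group hypothesis test."""

    statistic: float
    p_value: float
    df: float | None
    n_per_group: tuple[int, int]
    tails: Literal["one", "two"] = "two"
    method: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class AdjustedPVector:
    """Raw and family-wise adjusted p values, in input order."""

    raw: np.ndarray
    adjusted: np.ndarray
    method: Literal["holm", "bonferroni"]

    def __post_init__(self) -> None:
        if np.any(self.adjusted + 1e-15 < self.raw):
            raise ValueError("adjusted p values must dominate raw p values")


def arcsinh_transform(x, cofactor: float = 5.0):
    """Variance-stabilising ``asinh(x / cofactor)`` transform, elementwise.

    Parameters
    ----------
    x
        Raw intensity scalar or array.
    cofactor
        Positive divisor; 5 is the mass-cytometry convention.
    """
    if cofactor <= 0:
        raise ValueError(f"cofactor must be positive, got {cofactor}")
    return np.arcsinh(np.asarray(x, dtype=float) / cofactor)


def inverse_arcsinh(y, cofactor: float = 5.0):
    """Inverse of :func:`arcsinh_transform`: ``sinh(y) * cofactor``."""
    if cofactor <= 0:
        raise ValueError(f"cofactor must be positive, got {cofactor}")
    return np.sinh(np.asarray(y, dtype=float)) * cofactor


def t_test(
    a: Sequence[float],
    b: Sequence[float],
    mode: Literal["paired", "unpaired"] = "paired",
    equal_var: bool = False,
) -> TestResult:
    """Two-tailed Student/Welch t test.

    ``mode="paired"`` tests the mean of the elementwise differences;
    ``mode="unpaired"`` defaults to the Welch unequal-variance convention
    (``equal_var=True`` switches to the pooled Student form).

    A zero-variance comparison (e.g. ``a == b`` elementwise in paired mode)
    is returned with ``degenerate=True``, statistic 0 and p 1 rather than a
    division error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if mode == "paired":
        if a.shape != b.shape:
            raise ValueError("paired t test requires equal-length vectors")
        if a.size < 2:
            raise ValueError("paired t test requires n >= 2")
        diffs = a - b
        if np.allclose(diffs.std(ddof=1), 0.0):
            mean = float(diffs.mean())
            if mean == 0.0:
                return TestResult(0.0, 1.0, float(a.size - 1), (a.size, b.size),
                                  method="paired t", degenerate=True)
            # perfectly consistent nonzero shift: report it as degenerate
            return TestResult(np.inf if mean > 0 else -np.inf, 0.0,
                              float(a.size - 1), (a.size, b.size),
                              method="paired t", degenerate=True)
        res = sps.ttest_rel(a, b)
        return TestResult(float(res.statistic), float(res.pvalue),
                          float(res.df), (a.size, b.size), method="paired t")
    elif mode == "unpaired":
        if a.size < 2 or b.size < 2:
            raise ValueError("unpaired t test requires n >= 2 per group")
        if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
            equal = np.isclose(a.mean(), b.mean())
            return TestResult(0.0 if equal else np.inf, 1.0 if equal else 0.0,
                              None, (a.size, b.size),
                              method="unpaired t", degenerate=True)
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        return TestResult(float(res.statistic), float(res.pvalue),
                          float(res.df), (a.size, b.size),
                          method="Student t" if equal_var else "Welch t")
    raise ValueError(f"unknown mode {mode!r}")


def wilcoxon_rank_sum(
    a: Sequence[float],
    b: Sequence[float],
    exact_limit: int = WILCOXON_EXACT_LIMIT,
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test with midrank ties.

    Exact null enumeration when ``len(a) + len(b) <= exact_limit`` and the
    data are tie-free; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return TestResult(float(a.size * b.size / 2), 1.0, None,
                          (a.size, b.size), method="wilcoxon", degenerate=True)
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (a.size + b.size) <= exact_limit and not has_ties
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if use_exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)), None,
                      (a.size, b.size),
                      method="wilcoxon exact" if use_exact else "wilcoxon normal")


def adjust_pvalues(
    raw: Sequence[float],
    method: Literal["holm", "bonferroni"] = "holm",
) -> AdjustedPVector:
    """Family-wise p-value adjustment.

    Holm: sort raw p ascending, multiply p_(i) by (m - i), take the running
    maximum, cap at 1, and map back to input order. Bonferroni: min(1, m*p).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1:
        raise ValueError("raw p values must be a 1-D vector")
    if np.any((raw < 0) | (raw > 1)) or np.any(np.isnan(raw)):
        raise ValueError("p values must lie in [0, 1]")
    m = raw.size
    if method == "bonferroni":
        adjusted = np.minimum(1.0, m * raw)
    elif method == "holm":
        order = np.argsort(raw, kind="stable")
        factors = m - np.arange(m)
        stepped = np.maximum.accumulate(raw[order] * factors)
        adjusted = np.empty(m)
        adjusted[order] = np.minimum(1.0, stepped)
    else:
        raise ValueError(f"unknown method {method!r}")
    return AdjustedPVector(raw=raw, adjusted=adjusted, method=method)


def spearman_correlation(
    x: Sequence[float],
    y: Sequence[float],
) -> tuple[float, float]:
    """Spearman rank correlation with p from the t approximation.

    Returns ``(rho, p)``. Zero rank variance in either vector yields
    ``(nan, nan)`` — an explicitly undefined correlation, never an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan"), float("nan")
    rho, _ = sps.spearmanr(x, y)
    rho = float(rho)
    n = x.size
    if n <= 7:
        # exact permutation null on the ranks
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        obs = abs(_pearson(rx, ry))
        count = 0
        total = 0
        for perm in permutations(ry):
            total += 1
            if abs(_pearson(rx, np.asarray(perm))) >= obs - 1e-12:
                count += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    u = u - u.mean()
    v = v - v.mean()
    denom = np.sqrt((u @ u) * (v @ v))
    return float(u @ v / denom) if denom > 0 else 0.0
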