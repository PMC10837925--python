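"""Association of per-patient qualifying-variant counts with phenotype severity.

Two views of the same question — does carrying more qualifying variants
track a more severe presentation (earlier onset, higher FSH)?

* :func:`correlate` — rank correlation (Spearman by default; Pearson by
  flag) between variant count and a continuous phenotype, with an exact
  permutation p-value at very small n.
* :func:`compare_groups` — two-sided Wilcoxon rank-sum comparison of the
  phenotype between samples with fewer than ``cut`` variants and those
  with at least ``cut`` (default: one-or-none vs two-or-more).

Nonparametric defaults are deliberate: FSH is right-skewed and the
variant counts are small integers with heavy ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats

_EXACT_PERM_MAX_N = 9  # 9! = 362,880 orderings; exact enumeration is instant
_EXACT_RANKSUM_MAX_N = 20


@dataclass(frozen=True)
class AssociationResult:
    statistic_name: str
    estimate: float
    p_value: float
    n_used: int

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0 < self.p_value <= 1):
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")


def _paired_nonmissing(counts, values) -> tuple[np.ndarray, np.ndarray]:
    counts = np.asarray(counts, dtype=float)
    values = np.asarray(values, dtype=float)
    if counts.shape != values.shape:
        raise ValueError("counts and values must have equal length")
    keep = ~(np.isnan(counts) | np.isnan(values))
    return counts[keep], values[keep]


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, observed_rho: float) -> float:
    """Exact permutation p for |rho| >= |observed| over all pairings of y to x."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    # Spearman rho is monotone-decreasing in sum((rx - perm(ry))^2), but ties
    # make the classic d^2 formula inexact, so correlate rank vectors directly.
    rx_c = rx - rx.mean()
    denom = math.sqrt(float((rx_c**2).sum()) * float(((ry - ry.mean()) ** 2).sum()))
    target = abs(observed_rho) * (1 - 1e-12)
    hits = 0
    total = 0
    for perm in permutations(ry):
        rho = float(rx_c @ (np.asarray(perm) - ry.mean())) / denom
        hits += abs(rho) >= target
        total += 1
    return hits / total


def correlate(counts, values, method: str = "spearman") -> AssociationResult:
    """Correlation between variant counts and a phenotype.

    Spearman (default) uses average ranks for ties, with the t
    approximation for p and an exhaustive permutation null when n <= 9.
    Constant input on either side leaves the estimate undefined (NaN)
    with p = 1.
    """
    x, y = _paired_nonmissing(counts, values)
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 paired non-missing observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        name = "spearman_rho" if method == "spearman" else "pearson_r"
        return AssociationResult(statistic_name=name, estimate=math.nan, p_value=1.0, n_used=n)
    if method == "spearman":
        rho, p = stats.spearmanr(x, y)
        rho, p = float(rho), float(p)
        if n <= _EXACT_PERM_MAX_N:
            p = _exact_spearman_p(x, y, rho)
        return AssociationResult("spearman_rho", rho, min(1.0, max(p, 5e-324)), n)
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
        return AssociationResult("pearson_r", float(r), float(min(1.0, max(p, 5e-324))), n)
    raise ValueError(f"unknown method {method!r}")


def compare_groups(counts, values, cut: int = 2, method: str = "ranksum") -> AssociationResult:
    """Two-group phenotype comparison: variant count < cut vs >= cut.

    Default is the two-sided Wilcoxon/Mann-Whitney rank-sum test: exact
    null when combined n <= 20 and the data are tie-free, else the normal
    approximation with tie and continuity corrections. ``method="welch"``
    gives Welch's t instead. The estimate is the U statistic of the
    low-count group (or Welch's t).
    """
    x, y = _paired_nonmissing(counts, values)
    low = y[x < cut]
    high = y[x >= cut]
    if low.size == 0 or high.size == 0:
        raise ValueError(
            f"both groups must be non-empty (cut={cut}: {low.size} vs {high.size})"
        )
    n_used = low.size + high.size
    if method == "welch":
        t, p = stats.ttest_ind(low, high, equal_var=False)
        return AssociationResult("welch_t", float(t), float(min(1.0, p)), n_used)
    if method != "ranksum":
        raise ValueError(f"unknown method {method!r}")
    tie_free = np.unique(np.concatenate([low, high])).size == n_used
    mode = "exact" if (n_used <= _EXACT_RANKSUM_MAX_N and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(low, high, alternative="two-sided", method=mode,
                             use_continuity=True)
    return AssociationResult(
        "rank_sum_U", float(res.statistic), float(min(1.0, res.pvalue)), n_used
    )
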