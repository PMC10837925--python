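"""Exact 2x2 carrier statistics and the per-gene burden table.

Every association in the pipeline reduces to a 2x2 carrier table

    =============  =========  ============
                   carriers   non-carriers
    cases          a          b
    controls       c          d
    =============  =========  ============

tested with the two-sided Fisher exact test (PMF-ordering convention:
the p-value sums the hypergeometric probabilities of every table with
the observed margins whose probability does not exceed the observed
table's, with a relative slack of 1e-7 against floating-point ties).
Effect size is the sample odds ratio ad/bc with a 95% Woolf (logit)
confidence interval exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)).
All probability arithmetic is in log space: cohort-scale factorials
(N > 500) overflow double precision otherwise.

Zero-cell contract: with no control carriers (c = 0 < a) the odds ratio
is +inf and the CI is (NaN, +inf); with no carriers at all the odds
ratio is undefined (NaN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

Z_95 = 1.959964  # two-sided 95% normal quantile
_TIE_SLACK = 1e-7  # relative slack for PMF-ordering ties


def _log_comb(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def _logsumexp(logs: np.ndarray) -> float:
    m = float(np.max(logs))
    if m == -math.inf:
        return -math.inf
    return m + math.log(float(np.exp(logs - m).sum()))


def log_hypergeom_pmf(k: int, N: int, K: int, n: int) -> float:
    """log P[X = k] for X ~ Hypergeometric(N, K, n), -inf off support."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if k < max(0, K + n - N) or k > min(K, n):
        return -math.inf
    return _log_comb(K, k) + _log_comb(N - K, n - k) - _log_comb(N, n)


def _check_cells(a: int, b: int, c: int, d: int) -> None:
    for name, v in zip("abcd", (a, b, c, d)):
        if v < 0 or v != int(v):
            raise ValueError(f"cell {name} must be a nonnegative integer, got {v}")


def fisher_two_sided(a: int, b: int, c: int, d: int, method: str = "pmf") -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    ``method="pmf"`` (default) sums, over all tables with the observed
    margins, the probabilities not exceeding the observed one
    (x 1 + 1e-7). ``method="double"`` doubles the smaller tail instead
    (capped at 1), offered for comparison. Returns 1.0 when either margin
    is degenerate (only one table possible on that axis).
    """
    _check_cells(a, b, c, d)
    N = a + b + c + d
    K = a + c  # carriers margin
    n = a + b  # cases margin
    if N == 0 or K == 0 or K == N or n == 0 or n == N:
        return 1.0
    lo = max(0, K + n - N)
    hi = min(K, n)
    ks = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(K + 1) - gammaln(ks + 1) - gammaln(K - ks + 1)
        + gammaln(N - K + 1) - gammaln(n - ks + 1) - gammaln(N - K - n + ks + 1)
        + gammaln(n + 1) + gammaln(N - n + 1) - gammaln(N + 1)
    )
    log_obs = logpmf[a - lo]
    if method == "pmf":
        keep = logpmf <= log_obs + math.log1p(_TIE_SLACK)
    elif method == "double":
        lower = logpmf[: a - lo + 1]
        upper = logpmf[a - lo:]
        tail = min(_logsumexp(lower), _logsumexp(upper))
        return min(1.0, 2 * math.exp(tail))
    else:
        raise ValueError(f"unknown method {method!r}")
    # log-sum-exp over the kept tables
    p = math.exp(_logsumexp(logpmf[keep]))
    return min(1.0, p)


def sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio ad/bc; +inf when bc = 0 < ad, NaN when both vanish."""
    _check_cells(a, b, c, d)
    num = a * d
    den = b * c
    if den > 0:
        return num / den
    return math.inf if num > 0 else math.nan


def woolf_ci(a: int, b: int, c: int, d: int, level: float = 0.95) -> tuple[float, float]:
    """Woolf logit confidence interval for the odds ratio.

    Log-symmetric about ln(ad/bc); any zero cell makes the interval
    undefined and the contractual (NaN, +inf) is returned.
    """
    _check_cells(a, b, c, d)
    if min(a, b, c, d) == 0:
        return (math.nan, math.inf)
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if level == 0.95:
        z = Z_95
    else:
        from scipy.stats import norm

        z = float(norm.ppf(0.5 + level / 2))
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (math.exp(log_or - z * se), math.exp(log_or + z * se))


@dataclass(frozen=True)
class ContingencyResult:
    """A 2x2 carrier table with exact p, sample OR and Woolf 95% CI."""

    a: int
    b: int
    c: int
    d: int
    p_value: float
    odds_ratio: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_cells(cls, a: int, b: int, c: int, d: int) -> "ContingencyResult":
        lo, hi = woolf_ci(a, b, c, d)
        return cls(
            a=a, b=b, c=c, d=d,
            p_value=fisher_two_sided(a, b, c, d),
            odds_ratio=sample_odds_ratio(a, b, c, d),
            ci_low=lo, ci_high=hi,
        )


@dataclass
class BurdenTable:
    """Per-gene ContingencyResults ranked by ascending p-value.

    ``rank`` is 1..G (ties broken by descending odds ratio, then gene
    symbol); ``quantile`` is rank / G.
    """

    rows: dict[str, ContingencyResult]
    rank: dict[str, int]
    quantile: dict[str, float]

    def to_frame(self) -> "pd.DataFrame":  # noqa: F821
        import pandas as pd

        order = sorted(self.rank, key=self.rank.get)
        return pd.DataFrame(
            [
                {
                    "gene": g,
                    "case_carriers": self.rows[g].a,
                    "control_carriers": self.rows[g].c,
                    "p_value": self.rows[g].p_value,
                    "odds_ratio": self.rows[g].odds_ratio,
                    "ci_low": self.rows[g].ci_low,
                    "ci_high": self.rows[g].ci_high,
                    "rank": self.rank[g],
                    "quantile": self.quantile[g],
                }
                for g in order
            ]
        )

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        # match the study's print convention for degenerate values
        for col in ("odds_ratio", "ci_low", "ci_high"):
            df[col] = df[col].map(
                lambda v: "Inf" if v == math.inf else ("NaN" if math.isnan(v) else repr(v))
            )
        df.to_csv(path, sep="\t", index=False)


def _rank_key(item: tuple[str, ContingencyResult]) -> tuple[float, float, str]:
    gene, r = item
    # NaN odds ratios (no carriers anywhere) sort after finite/inf ones at equal p
    or_key = -math.inf if math.isnan(r.odds_ratio) else r.odds_ratio
    return (r.p_value, -or_key, gene)


def gene_burden(matrix) -> BurdenTable:
    """Per-gene carrier burden over the whole panel of a CarrierMatrix.

    Genes with no carriers in either group are retained with p = 1 and an
    undefined odds ratio so that quantiles are computed over the full panel.
    """
    mask = matrix.case_mask
    n_cases = int(mask.sum())
    n_controls = len(matrix.samples) - n_cases
    if n_cases == 0 or n_controls == 0:
        raise ValueError("gene_burden requires both cases and controls")
    case_carriers = matrix.carries[mask].sum(axis=0)
    control_carriers = matrix.carries[~mask].sum(axis=0)
    rows = {
        g: ContingencyResult.from_cells(
            int(case_carriers[j]), n_cases - int(case_carriers[j]),
            int(control_carriers[j]), n_controls - int(control_carriers[j]),
        )
        for j, g in enumerate(matrix.genes)
    }
    ordered = sorted(rows.items(), key=_rank_key)
    G = len(ordered)
    rank = {g: i + 1 for i, (g, _) in enumerate(ordered)}
    quantile = {g: (i + 1) / G for i, (g, _) in enumerate(ordered)}
    return BurdenTable(rows=rows, rank=rank, quantile=quantile)


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (offered for reporting; raw p is the default)."""
    from scipy.stats import false_discovery_control

    return false_discovery_control(np.asarray(p_values), method="bh")
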