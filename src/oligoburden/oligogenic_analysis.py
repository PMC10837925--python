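"""Multi-variant carrier enrichment, digenic combinations and gene-set burden.

Works on a qualified :class:`~oligoburden.cohort_data.CarrierMatrix`:

* the case-vs-control enrichment of samples carrying more than one
  qualifying variant across the panel,
* the per-group distribution of qualifying-variant counts,
* enumeration and exact testing of digenic (gene-pair) co-carriage,
* burden of carrying multiple variants within each biological-function
  gene set of the panel.

"More than one variant" is counted at the variant level: a sample with
two qualifying variants in one gene is a multi-variant carrier even
though it carries only one gene. A gene-level alternative is available
via ``count_genes=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .burden_stats import ContingencyResult, benjamini_hochberg
from .cohort_data import CATEGORIES, CarrierMatrix, GenePanel


@dataclass(frozen=True)
class CombinationResult:
    """Co-carriage of one unordered gene pair, exact-tested vs non-co-carriers."""

    gene_pair: tuple[str, str]
    case_cocarriers: int
    control_cocarriers: int
    contingency: ContingencyResult
    carrier_ids: tuple[tuple[str, ...], tuple[str, ...]]  # (case ids, control ids)


@dataclass(frozen=True)
class GeneSetResult:
    category: str
    case_multicarriers: int
    control_multicarriers: int
    contingency: ContingencyResult


def variant_count_distribution(
    matrix: CarrierMatrix, group: str
) -> dict[int, tuple[int, float]]:
    """count -> (n samples, proportion of the group) for one group."""
    mask = matrix.case_mask if group == "case" else ~matrix.case_mask
    counts = matrix.variant_count[mask]
    if counts.size == 0:
        raise ValueError(f"group {group!r} is empty")
    values, freqs = np.unique(counts, return_counts=True)
    total = int(counts.size)
    return {int(v): (int(f), f / total) for v, f in zip(values, freqs)}


def _multicarrier_cells(
    matrix: CarrierMatrix,
    min_variants: int,
    gene_subset: np.ndarray | None = None,
    count_genes: bool = False,
) -> tuple[int, int, int, int]:
    mask = matrix.case_mask
    if gene_subset is None and not count_genes:
        per_sample = matrix.variant_count
    else:
        cols = slice(None) if gene_subset is None else gene_subset
        if count_genes or not matrix.variant_details:
            # without per-variant detail the gene count is the variant count
            per_sample = matrix.carries[:, cols].sum(axis=1)
        else:
            per_sample = np.zeros(len(matrix.samples), dtype=int)
            subset = set(
                matrix.genes if gene_subset is None
                else [matrix.genes[j] for j in gene_subset]
            )
            for (sid, gene), recs in matrix.variant_details.items():
                if gene in subset:
                    per_sample[_sample_index(matrix, sid)] += len(recs)
    multi = per_sample >= min_variants
    a = int(multi[mask].sum())
    c = int(multi[~mask].sum())
    return a, int(mask.sum()) - a, c, int((~mask).sum()) - c


def _sample_index(matrix: CarrierMatrix, sid: str) -> int:
    idx = getattr(matrix, "_sid_index", None)
    if idx is None:
        idx = {s.sample_id: i for i, s in enumerate(matrix.samples)}
        object.__setattr__(matrix, "_sid_index", idx)
    return idx[sid]


def multicarrier_enrichment(
    matrix: CarrierMatrix, min_variants: int = 2, count_genes: bool = False
) -> ContingencyResult:
    """Exact test of carrying >= min_variants qualifying variants, cases vs controls."""
    if matrix.n_cases == 0 or matrix.n_controls == 0:
        raise ValueError("both groups must be non-empty")
    a, b, c, d = _multicarrier_cells(matrix, min_variants, count_genes=count_genes)
    return ContingencyResult.from_cells(a, b, c, d)


def enumerate_combinations(
    matrix: CarrierMatrix,
    order: int = 2,
    include_control_only: bool = False,
    adjust: bool = False,
) -> list[CombinationResult]:
    """All gene pairs co-carried by >=1 case, each exact-tested 2x2.

    A pair's table counts samples carrying qualifying variants in BOTH
    genes versus all remaining samples, cases against controls. Pairs seen
    only in controls are skipped unless ``include_control_only``. Sorted by
    ascending p, then pair name. ``adjust=True`` replaces each p-value with
    its Benjamini-Hochberg adjusted value (raw p is the default, and no
    multiplicity correction is applied otherwise).
    """
    if order != 2:
        raise NotImplementedError("only pairwise (order=2) combinations are supported")
    mask = matrix.case_mask
    n_cases = int(mask.sum())
    n_controls = len(matrix.samples) - n_cases
    carried = matrix.carries
    results: list[CombinationResult] = []
    # restrict to genes with any carrier to keep the double loop tight
    active = np.flatnonzero(carried.any(axis=0))
    for j, k in combinations(active, 2):
        both = carried[:, j] & carried[:, k]
        a = int(both[mask].sum())
        c = int(both[~mask].sum())
        if a == 0 and not (include_control_only and c > 0):
            continue
        pair = tuple(sorted((matrix.genes[j], matrix.genes[k])))
        case_ids = tuple(
            s.sample_id for s, hit in zip(matrix.samples, both & mask) if hit
        )
        control_ids = tuple(
            s.sample_id for s, hit in zip(matrix.samples, both & ~mask) if hit
        )
        results.append(
            CombinationResult(
                gene_pair=pair,
                case_cocarriers=a,
                control_cocarriers=c,
                contingency=ContingencyResult.from_cells(
                    a, n_cases - a, c, n_controls - c
                ),
                carrier_ids=(case_ids, control_ids),
            )
        )
    results.sort(key=lambda r: (r.contingency.p_value, r.gene_pair))
    if adjust and results:
        adj = benjamini_hochberg([r.contingency.p_value for r in results])
        results = [
            CombinationResult(
                gene_pair=r.gene_pair,
                case_cocarriers=r.case_cocarriers,
                control_cocarriers=r.control_cocarriers,
                contingency=ContingencyResult(
                    a=r.contingency.a, b=r.contingency.b,
                    c=r.contingency.c, d=r.contingency.d,
                    p_value=float(p),
                    odds_ratio=r.contingency.odds_ratio,
                    ci_low=r.contingency.ci_low, ci_high=r.contingency.ci_high,
                ),
                carrier_ids=r.carrier_ids,
            )
            for r, p in zip(results, adj)
        ]
    return results


def geneset_burden(
    matrix: CarrierMatrix,
    panel: GenePanel,
    min_variants: int = 2,
    count_genes: bool = False,
) -> list[GeneSetResult]:
    """Multi-variant carrier burden within each biological-function gene set.

    Per category, a sample counts when it carries >= min_variants
    qualifying variants in that category's genes. An empty table
    (no multicarriers in either group) yields p = 1 with undefined OR.
    """
    results = []
    for category in CATEGORIES:
        genes = [g for g in panel.genes_in_category(category) if g in matrix.genes]
        if genes:
            gidx = matrix.gene_index(genes)
            a, b, c, d = _multicarrier_cells(
                matrix, min_variants, gene_subset=gidx, count_genes=count_genes
            )
        else:
            a, c = 0, 0
            b, d = matrix.n_cases, matrix.n_controls
        results.append(
            GeneSetResult(
                category=category,
                case_multicarriers=a,
                control_multicarriers=c,
                contingency=ContingencyResult.from_cells(a, b, c, d),
            )
        )
    return results
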