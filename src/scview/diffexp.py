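"""On-the-fly two-group differential expression.

Genes are compared between two manually defined cell groups with a
two-sided Wilcoxon rank-sum (Mann-Whitney U) test on the normalized
expression layer: exact null enumeration for small tie-free samples,
otherwise a tie-corrected normal approximation without continuity
correction. P-values are adjusted with the Benjamini-Hochberg step-up
procedure over the genes actually tested; genes expressed in less than a
minimum fraction of cells in both groups are excluded up front.

The fold change is computed on the de-logged scale: group means of
``expm1(normalized)`` enter ``log2((mean_A + eps) / (mean_B + eps))`` with a
small regularizer so all-zero groups stay finite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .dataset import CellDataset
from .errors import ScviewError, SpecificationError
from .select import GroupAssignment

__all__ = [
    "DiffExpParams",
    "DiffExpResult",
    "rank_sum_test",
    "benjamini_hochberg",
    "differential_expression",
]

#: sample sizes up to this total use exact enumeration (when tie-free)
EXACT_ENUMERATION_MAX_N = 12

#: regularizer added to de-logged group means in the fold change
FOLD_CHANGE_EPS = 1e-9

RESULT_COLUMNS = [
    "symbol",
    "statistic",
    "p",
    "p_adj",
    "log2fc",
    "mean_a",
    "mean_b",
    "frac_a",
    "frac_b",
]


@dataclass
class DiffExpParams:
    """Tunable parameters of the two-group comparison."""

    min_cells_per_group: int = 3
    min_fraction_expressed: float = 0.1
    top_n: Optional[int] = None
    fold_change_eps: float = FOLD_CHANGE_EPS

    def __post_init__(self):
        if self.min_cells_per_group < 2:
            raise SpecificationError("min_cells_per_group must be >= 2")
        if not 0 <= self.min_fraction_expressed <= 1:
            raise SpecificationError("min_fraction_expressed must lie in [0, 1]")


@dataclass
class DiffExpResult:
    """Per-gene test table plus bookkeeping about the comparison."""

    table: pd.DataFrame  # columns RESULT_COLUMNS, sorted
    n_untested: int
    group_sizes: dict[str, int] = field(default_factory=dict)

    def to_tsv(self) -> str:
        return self.table.to_csv(sep="\t", index=False)


# ----------------------------------------------------------------------
# the test


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    ranks = rankdata(np.concatenate([x, y]))
    n1 = len(x)
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Returns the Mann-Whitney U statistic of ``x`` and a two-sided p-value.
    For tie-free samples with ``len(x) + len(y) <= 12`` the null is
    enumerated exhaustively; otherwise a tie-corrected normal approximation
    without continuity correction is used. The p-value is clamped to (0, 1].
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise SpecificationError("rank_sum_test requires at least 2 values per group")
    n = n1 + n2
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n
    u = _u_statistic(x, y)

    if n <= EXACT_ENUMERATION_MAX_N and not has_ties:
        ranks = rankdata(pooled)
        offset = n1 * (n1 + 1) / 2.0
        n_le = n_ge = total = 0
        for combo in itertools.combinations(range(n), n1):
            u_null = sum(ranks[i] for i in combo) - offset
            total += 1
            if u_null <= u + 1e-12:
                n_le += 1
            if u_null >= u - 1e-12:
                n_ge += 1
        p = 2.0 * min(n_le, n_ge) / total
    else:
        mean = n1 * n2 / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            return u, 1.0
        z = (u - mean) / math.sqrt(var)
        p = math.erfc(abs(z) / math.sqrt(2.0))
    return u, min(max(p, np.nextafter(0, 1)), 1.0)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sorted p-values are scaled by ``m / rank``, made monotone by a running
    minimum from the largest down, and capped at 1.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise SpecificationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


# ----------------------------------------------------------------------
# the full comparison


def _group_matrix(ds: CellDataset, indices: np.ndarray) -> sp.csr_matrix:
    return sp.csr_matrix(ds.normalized)[indices]


def differential_expression(
    ds: CellDataset,
    groups: GroupAssignment,
    params: DiffExpParams | None = None,
    labels: tuple[str, str] = ("A", "B"),
) -> DiffExpResult:
    """Compare normalized expression between two labeled cell groups.

    Genes below ``min_fraction_expressed`` in both groups are excluded
    before testing (and before the multiple-testing correction, so m equals
    the number of genes actually tested). The result table is sorted by
    ascending p, ties broken by descending absolute log2 fold change, then
    by symbol; with ``top_n`` set it is truncated after sorting.
    """
    params = params or DiffExpParams()
    la, lb = labels
    for label in (la, lb):
        if label not in groups.groups:
            raise ScviewError(f"group {label!r} is not defined")
        size = len(groups.groups[label])
        if size < params.min_cells_per_group:
            raise ScviewError(
                f"group {label} has {size} cells; "
                f"at least {params.min_cells_per_group} required"
            )
    idx_a = np.asarray(sorted(groups.groups[la]), dtype=int)
    idx_b = np.asarray(sorted(groups.groups[lb]), dtype=int)
    if idx_a.size and idx_a.max() >= ds.n_cells or idx_b.size and idx_b.max() >= ds.n_cells:
        raise ScviewError("group contains cell indices outside the dataset")

    xa = _group_matrix(ds, idx_a)
    xb = _group_matrix(ds, idx_b)
    na, nb = len(idx_a), len(idx_b)

    frac_a = np.asarray((xa > 0).sum(axis=0)).ravel() / na
    frac_b = np.asarray((xb > 0).sum(axis=0)).ravel() / nb
    mean_a = np.asarray(xa.mean(axis=0)).ravel()
    mean_b = np.asarray(xb.mean(axis=0)).ravel()

    expm1_a = xa.copy()
    expm1_a.data = np.expm1(expm1_a.data)
    expm1_b = xb.copy()
    expm1_b.data = np.expm1(expm1_b.data)
    delog_mean_a = np.asarray(expm1_a.mean(axis=0)).ravel()
    delog_mean_b = np.asarray(expm1_b.mean(axis=0)).ravel()
    eps = params.fold_change_eps
    log2fc = np.log2((delog_mean_a + eps) / (delog_mean_b + eps))

    tested = np.flatnonzero(
        (frac_a >= params.min_fraction_expressed)
        | (frac_b >= params.min_fraction_expressed)
    )
    n_untested = ds.n_genes - tested.size

    xa_dense = np.asarray(xa[:, tested].todense())
    xb_dense = np.asarray(xb[:, tested].todense())
    stats = np.empty(tested.size)
    pvals = np.empty(tested.size)
    for k in range(tested.size):
        stats[k], pvals[k] = rank_sum_test(xa_dense[:, k], xb_dense[:, k])
    p_adj = benjamini_hochberg(pvals)

    symbols = ds.gene_table["symbol"].to_numpy()[tested]
    table = pd.DataFrame(
        {
            "symbol": symbols,
            "statistic": stats,
            "p": pvals,
            "p_adj": p_adj,
            "log2fc": log2fc[tested],
            "mean_a": mean_a[tested],
            "mean_b": mean_b[tested],
            "frac_a": frac_a[tested],
            "frac_b": frac_b[tested],
        }
    )
    table = table.sort_values(
        by=["p", "log2fc", "symbol"],
        key=lambda col: -col.abs() if col.name == "log2fc" else col,
        ascending=[True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    if params.top_n is not None:
        table = table.iloc[: params.top_n].reset_index(drop=True)
    return DiffExpResult(
        table=table[RESULT_COLUMNS],
        n_untested=int(n_untested),
        group_sizes={la: na, lb: nb},
    )
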