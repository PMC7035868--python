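"""Plot-ready summary statistics behind every view.

These functions compute the numbers the scatter / violin / box / bar / dot
plots display: per-group mean expression and fraction of expressing cells
(dot plots, optionally split by a condition), cross-tabulated composition of
one categorical within another (bar plots), per-group value distributions
with quartiles (violin/box plots), species-mixing statistics with doublet
calls, and reproducible scatter downsampling. "Expressing" means a strictly
positive stored value; dot-plot means are taken over all cells of a group,
zeros included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .dataset import CellDataset
from .errors import AmbiguityError, ScviewError, SpecificationError

__all__ = [
    "DotPlotSummary",
    "CompositionTable",
    "SpeciesMixStats",
    "dot_plot_summary",
    "composition_table",
    "species_mix_stats",
    "distribution_panel",
    "downsample_cells",
]


def _resolve_cells(ds: CellDataset, cells: Optional[Sequence[int]]) -> np.ndarray:
    if cells is None:
        return np.arange(ds.n_cells)
    idx = np.asarray(sorted(int(i) for i in cells), dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= ds.n_cells):
        raise SpecificationError("cell indices outside the dataset")
    return idx


def _require_categorical(ds: CellDataset, column: str) -> pd.Series:
    if column not in ds.cell_table.columns:
        raise SpecificationError(f"unknown column {column!r}")
    series = ds.cell_table[column]
    if not isinstance(series.dtype, pd.CategoricalDtype):
        raise SpecificationError(f"column {column!r} is not categorical")
    return series


def _levels(series: pd.Series) -> list[str]:
    return [str(c) for c in series.cat.categories]


# ----------------------------------------------------------------------
# dot plots


@dataclass
class DotPlotSummary:
    """Mean expression and fraction expressing per (group[, split]) x gene."""

    table: pd.DataFrame  # columns: group[, split], gene, mean, fraction
    group_by: str
    split_by: Optional[str] = None

    def to_tsv(self) -> str:
        return self.table.to_csv(sep="\t", index=False)


def dot_plot_summary(
    ds: CellDataset,
    genes: Sequence[str],
    group_by: str,
    split_by: Optional[str] = None,
    cells: Optional[Sequence[int]] = None,
) -> DotPlotSummary:
    """Summarize expression of a gene list per group (and optional split).

    For every (group[, split]) combination observed in the selected cells
    and every requested gene, reports the mean normalized expression over
    all cells of that combination (zeros included) and the fraction of
    those cells with a strictly positive value. Combinations with no cells
    are omitted rather than zero-filled.
    """
    unknown = [g for g in genes if g not in set(ds.gene_table["symbol"])]
    if unknown:
        raise SpecificationError(f"unknown gene symbol(s): {unknown}")
    group_series = _require_categorical(ds, group_by)
    split_series = _require_categorical(ds, split_by) if split_by else None

    idx = _resolve_cells(ds, cells)
    gene_idx = [ds.gene_index(g) for g in genes]
    X = sp.csr_matrix(ds.normalized)[idx][:, gene_idx]
    dense = np.asarray(X.todense())
    grp = group_series.iloc[idx].astype(str).to_numpy()

    if split_series is not None:
        spl = split_series.iloc[idx].astype(str).to_numpy()
        combos = [
            (g, s)
            for g in _levels(group_series)
            for s in _levels(split_series)
            if np.any((grp == g) & (spl == s))
        ]
    else:
        combos = [(g,) for g in _levels(group_series) if np.any(grp == g)]

    rows = []
    for combo in combos:
        mask = grp == combo[0]
        if split_series is not None:
            mask &= spl == combo[1]
        sub = dense[mask]
        for j, gene in enumerate(genes):
            col = sub[:, j]
            row = {"group": combo[0]}
            if split_series is not None:
                row["split"] = combo[1]
            row.update(
                gene=gene,
                mean=float(col.mean()),
                fraction=float((col > 0).mean()),
            )
            rows.append(row)
    cols = ["group"] + (["split"] if split_by else []) + ["gene", "mean", "fraction"]
    return DotPlotSummary(
        table=pd.DataFrame(rows, columns=cols), group_by=group_by, split_by=split_by
    )


# ----------------------------------------------------------------------
# composition


@dataclass
class CompositionTable:
    """Counts and within-primary proportions of a secondary categorical."""

    counts: pd.DataFrame  # primary levels x secondary levels
    proportions: pd.DataFrame
    empty_levels: list[str] = field(default_factory=list)

    def to_tsv(self) -> str:
        merged = self.counts.copy()
        merged.columns = [f"count_{c}" for c in merged.columns]
        props = self.proportions.copy()
        props.columns = [f"prop_{c}" for c in props.columns]
        return pd.concat([merged, props], axis=1).to_csv(sep="\t")


def composition_table(
    ds: CellDataset,
    primary: str,
    secondary: str,
    cells: Optional[Sequence[int]] = None,
) -> CompositionTable:
    """Cross-tabulate two categoricals, normalizing within primary levels.

    Primary levels with no selected cells are retained with zero counts and
    zero proportions and listed in ``empty_levels``.
    """
    ps = _require_categorical(ds, primary)
    ss = _require_categorical(ds, secondary)
    idx = _resolve_cells(ds, cells)
    p = ps.iloc[idx].astype(str)
    s = ss.iloc[idx].astype(str)
    counts = (
        pd.crosstab(p, s)
        .reindex(index=_levels(ps), columns=_levels(ss), fill_value=0)
        .astype(int)
    )
    totals = counts.sum(axis=1)
    empty = [lvl for lvl, t in totals.items() if t == 0]
    props = counts.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    counts.index.name = primary
    props.index.name = primary
    return CompositionTable(counts=counts, proportions=props, empty_levels=empty)


# ----------------------------------------------------------------------
# species mixing


@dataclass
class SpeciesMixStats:
    """Per-cell species calls and the aggregate doublet rate."""

    h_counts: np.ndarray
    m_counts: np.ndarray
    calls: np.ndarray  # "species1" | "species2" | "doublet"
    doublet_rate: float
    n_species1: int
    n_species2: int
    n_doublet: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"h_umis": self.h_counts, "m_umis": self.m_counts, "call": self.calls}
        )


def species_mix_stats(
    h_counts, m_counts, purity_threshold: float = 0.9
) -> SpeciesMixStats:
    """Call each cell of a species-mixing experiment and estimate doublets.

    A cell is called species 1 when its species-1 purity ``h / (h + m)``
    reaches the threshold, species 2 symmetrically, and a doublet otherwise.
    """
    h = np.asarray(h_counts, dtype=np.int64)
    m = np.asarray(m_counts, dtype=np.int64)
    if h.shape != m.shape:
        raise SpecificationError("count vectors must have equal length")
    if np.any(h < 0) or np.any(m < 0):
        raise SpecificationError("counts must be non-negative")
    total = h + m
    zero = np.flatnonzero(total == 0)
    if zero.size:
        raise ScviewError(f"cell(s) with zero total UMIs: {zero[:5].tolist()}")
    purity1 = h / total
    purity2 = m / total
    calls = np.where(
        purity1 >= purity_threshold,
        "species1",
        np.where(purity2 >= purity_threshold, "species2", "doublet"),
    )
    n_doublet = int((calls == "doublet").sum())
    return SpeciesMixStats(
        h_counts=h,
        m_counts=m,
        calls=calls,
        doublet_rate=n_doublet / len(h),
        n_species1=int((calls == "species1").sum()),
        n_species2=int((calls == "species2").sum()),
        n_doublet=n_doublet,
    )


# ----------------------------------------------------------------------
# distributions


@dataclass
class DistributionPanel:
    """Per-group raw values plus summary rows for violin/box panels."""

    values: dict[str, np.ndarray]
    summary: pd.DataFrame  # columns: group, count, median, q1, q3

    def to_tsv(self) -> str:
        return self.summary.to_csv(sep="\t", index=False)


def distribution_panel(
    ds: CellDataset,
    value: str,
    group_by: str,
    cells: Optional[Sequence[int]] = None,
) -> DistributionPanel:
    """Per-group distribution of a gene's expression or a numeric column.

    ``value`` may name a gene display symbol (resolved on the normalized
    layer) or a numeric cell column; a name matching both requires an
    explicit ``gene:``/``column:`` qualifier. Quartiles use linear
    interpolation; groups appear in their declared level order.
    """
    group_series = _require_categorical(ds, group_by)
    idx = _resolve_cells(ds, cells)

    symbols = set(ds.gene_table["symbol"])
    numeric_cols = {
        c
        for c in ds.cell_table.columns
        if pd.api.types.is_numeric_dtype(ds.cell_table[c])
    }
    name, forced = value, None
    if value.startswith("gene:"):
        name, forced = value[5:], "gene"
    elif value.startswith("column:"):
        name, forced = value[7:], "column"
    is_gene = name in symbols and forced != "column"
    is_col = name in numeric_cols and forced != "gene"
    if is_gene and is_col:
        raise AmbiguityError(
            f"{name!r} is both a gene and a column; qualify as 'gene:{name}' "
            f"or 'column:{name}'"
        )
    if is_gene:
        col = ds.gene_index(name)
        vec = np.asarray(
            sp.csr_matrix(ds.normalized)[idx][:, [col]].todense()
        ).ravel()
    elif is_col:
        vec = ds.cell_table[name].iloc[idx].to_numpy(dtype=float)
    else:
        raise SpecificationError(f"{name!r} is neither a gene nor a numeric column")

    grp = group_series.iloc[idx].astype(str).to_numpy()
    values: dict[str, np.ndarray] = {}
    rows = []
    for level in _levels(group_series):
        sub = vec[grp == level]
        if sub.size == 0:
            continue
        values[level] = sub
        q1, med, q3 = np.quantile(sub, [0.25, 0.5, 0.75])  # linear interpolation
        rows.append(
            {"group": level, "count": int(sub.size), "median": float(med),
             "q1": float(q1), "q3": float(q3)}
        )
    return DistributionPanel(
        values=values,
        summary=pd.DataFrame(rows, columns=["group", "count", "median", "q1", "q3"]),
    )


# ----------------------------------------------------------------------
# downsampling


def downsample_cells(n_cells_total: int, max_points: int, seed: int) -> set[int]:
    """Reproducible uniform subsample for responsive scatter rendering.

    Identity when the dataset fits; otherwise a uniform sample without
    replacement of exactly ``max_points`` cells, determined by ``seed``.
    """
    if max_points < 1:
        raise SpecificationError("max_points must be >= 1")
    if n_cells_total <= max_points:
        return set(range(n_cells_total))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_cells_total, size=max_points, replace=False)
    return set(int(i) for i in chosen)
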