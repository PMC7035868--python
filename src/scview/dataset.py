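"""Annotated single-cell expression container and its HDF5 (h5ad) persistence.

The :class:`CellDataset` is the contract every other module consumes: a
cells x genes count matrix, a depth-normalized log-transformed expression
layer, per-cell and per-gene annotation tables, named 2-D embeddings, an
optional marker-gene table and free-text metadata.

On disk the container uses the AnnData h5ad dialect: the normalized layer in
``X``, raw counts in ``layers/counts``, the cell table in ``obs`` (cell
identifiers as the index), the gene table in ``var``, embeddings in ``obsm``
under ``X_<name>`` keys, the marker table in ``uns/markers`` and the metadata
block in ``uns/about``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import FormatError, ValidationError

__all__ = [
    "About",
    "CellDataset",
    "normalize_counts",
    "validate_dataset",
    "save_dataset",
    "load_dataset_file",
    "dataset_differences",
    "datasets_equal",
    "subset_cells",
]

#: total per-cell count the normalized layer is scaled to before log1p
NORMALIZE_TARGET_SUM = 10_000.0

MARKER_REQUIRED_COLUMNS = ("cluster", "gene")


@dataclass
class About:
    """Descriptive dataset metadata shown on the 'about' view."""

    title: str = ""
    short: str = ""
    long: str = ""


@dataclass
class CellDataset:
    """In-memory annotated expression container.

    Parameters
    ----------
    counts
        cells x genes matrix of non-negative integer UMI counts (dense or
        sparse), or ``None`` when the input carried only processed values.
    normalized
        cells x genes matrix of per-cell depth-normalized, log1p-transformed
        expression. This is the layer every summary and the differential
        expression operate on.
    cell_table
        One row per cell; the index holds the unique cell identifiers.
        Columns are categorical (finite level set) or numeric.
    gene_table
        One row per gene; the index holds the unique gene identifiers and a
        ``symbol`` column holds the display symbols (unique).
    embeddings
        Mapping from embedding name (e.g. ``"tsne"``, ``"umap"``) to a
        cells x 2 coordinate array.
    markers
        Optional marker-gene table with at least ``cluster`` and ``gene``
        columns; score columns (``p``, ``p_adj``, ``log2fc``, ``score``) are
        schema-flexible because upstream pipelines differ.
    about
        Title / short description / long markdown description.
    cluster_column
        Name of the designated clustering column in ``cell_table``, if any;
        marker-table cluster labels are validated against its levels.
    """

    counts: sp.spmatrix | np.ndarray | None
    normalized: sp.spmatrix | np.ndarray
    cell_table: pd.DataFrame
    gene_table: pd.DataFrame
    embeddings: dict[str, np.ndarray] = field(default_factory=dict)
    markers: pd.DataFrame | None = None
    about: About = field(default_factory=About)
    cluster_column: str | None = None

    def __post_init__(self) -> None:
        if self.markers is None:
            self.markers = empty_markers()

    # -- basic geometry -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.cell_table.shape[0]

    @property
    def n_genes(self) -> int:
        return self.gene_table.shape[0]

    @property
    def cell_ids(self) -> pd.Index:
        return self.cell_table.index

    @property
    def gene_symbols(self) -> pd.Index:
        return pd.Index(self.gene_table["symbol"])

    def gene_index(self, symbol: str) -> int:
        """0-based column index of a gene display symbol."""
        hits = np.flatnonzero(self.gene_table["symbol"].to_numpy() == symbol)
        if hits.size == 0:
            raise KeyError(symbol)
        return int(hits[0])

    @classmethod
    def from_counts(
        cls,
        counts,
        cell_table: pd.DataFrame,
        gene_table: pd.DataFrame,
        **kwargs,
    ) -> "CellDataset":
        """Build a dataset from raw counts, deriving the normalized layer."""
        return cls(
            counts=counts,
            normalized=normalize_counts(counts),
            cell_table=cell_table,
            gene_table=gene_table,
            **kwargs,
        )


def empty_markers() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in MARKER_REQUIRED_COLUMNS})


def normalize_counts(counts) -> sp.csr_matrix:
    """Depth-normalize and log-transform a count matrix.

    Each cell is scaled to a total of ``NORMALIZE_TARGET_SUM`` counts, then
    ``log(1 + x)`` is applied. Cells with zero total counts stay all-zero.
    """
    mat = sp.csr_matrix(counts, dtype=np.float64)
    totals = np.asarray(mat.sum(axis=1)).ravel()
    scale = np.divide(
        NORMALIZE_TARGET_SUM, totals, out=np.zeros_like(totals), where=totals > 0
    )
    mat = sp.diags(scale) @ mat
    mat.data = np.log1p(mat.data)
    return sp.csr_matrix(mat)


# ----------------------------------------------------------------------
# validation


def _matrix_values(mat) -> np.ndarray:
    if sp.issparse(mat):
        return mat.data
    return np.asarray(mat).ravel()


def validate_dataset(ds: CellDataset) -> list[str]:
    """Check every structural invariant; return human-readable violations.

    Validation never raises: an empty list means the dataset is well formed.
    """
    out: list[str] = []
    n_cells = ds.cell_table.shape[0]
    n_genes = ds.gene_table.shape[0]

    if ds.normalized is None:
        out.append("normalized: layer is missing")
    else:
        if ds.normalized.shape != (n_cells, n_genes):
            out.append(
                f"normalized: shape {ds.normalized.shape} does not match "
                f"(cells={n_cells}, genes={n_genes})"
            )
        vals = _matrix_values(ds.normalized)
        if vals.size and not np.all(np.isfinite(vals)):
            out.append("normalized: contains non-finite entries")
        elif vals.size and vals.min() < 0:
            out.append("normalized: contains negative entries")

    if ds.counts is not None:
        if ds.counts.shape != (n_cells, n_genes):
            out.append(
                f"counts: shape {ds.counts.shape} does not match "
                f"(cells={n_cells}, genes={n_genes})"
            )
        vals = _matrix_values(ds.counts)
        if vals.size:
            if np.any(vals < 0):
                out.append("counts: contains negative entries")
            if not np.allclose(vals, np.round(vals)):
                out.append("counts: contains non-integer entries")

    if not ds.cell_table.index.is_unique:
        out.append("cell_table: cell identifiers are not unique")
    if "symbol" not in ds.gene_table.columns:
        out.append("gene_table: missing 'symbol' column")
    else:
        if ds.gene_table["symbol"].duplicated().any():
            dups = ds.gene_table["symbol"][ds.gene_table["symbol"].duplicated()]
            out.append(
                f"gene_table: duplicated gene symbols: {sorted(set(dups))[:5]}"
            )
    if not ds.gene_table.index.is_unique:
        out.append("gene_table: gene identifiers are not unique")

    for name, coords in ds.embeddings.items():
        arr = np.asarray(coords)
        if arr.ndim != 2 or arr.shape[1] != 2:
            out.append(
                f"embeddings[{name!r}]: expected cells x 2 coordinates, "
                f"got shape {arr.shape}"
            )
        elif arr.shape[0] != n_cells:
            out.append(
                f"embeddings[{name!r}]: {arr.shape[0]} rows for {n_cells} cells"
            )

    markers = ds.markers
    if markers is not None and len(markers):
        missing = [c for c in MARKER_REQUIRED_COLUMNS if c not in markers.columns]
        if missing:
            out.append(f"markers: missing required columns {missing}")
        elif ds.cluster_column is not None:
            if ds.cluster_column not in ds.cell_table.columns:
                out.append(
                    f"markers: designated cluster column {ds.cluster_column!r} "
                    "not present in cell_table"
                )
            else:
                col = ds.cell_table[ds.cluster_column]
                levels = set(
                    col.cat.categories.astype(str)
                    if isinstance(col.dtype, pd.CategoricalDtype)
                    else col.astype(str).unique()
                )
                unknown = set(markers["cluster"].astype(str)) - levels
                if unknown:
                    out.append(
                        "markers: cluster labels not in "
                        f"{ds.cluster_column!r} levels: {sorted(unknown)[:5]}"
                    )
    return out


def _require_valid(ds: CellDataset) -> None:
    violations = validate_dataset(ds)
    if violations:
        raise ValidationError(violations)


# ----------------------------------------------------------------------
# persistence


def _to_anndata(ds: CellDataset) -> ad.AnnData:
    X = sp.csr_matrix(ds.normalized, dtype=np.float64)
    adata = ad.AnnData(
        X=X,
        obs=ds.cell_table.copy(),
        var=ds.gene_table.copy(),
    )
    if ds.counts is not None:
        adata.layers["counts"] = sp.csr_matrix(ds.counts)
    for name, coords in ds.embeddings.items():
        adata.obsm[f"X_{name}"] = np.asarray(coords, dtype=np.float64)
    if ds.markers is not None and len(ds.markers):
        adata.uns["markers"] = ds.markers.copy()
    adata.uns["about"] = {
        "title": ds.about.title,
        "short": ds.about.short,
        "long": ds.about.long,
    }
    if ds.cluster_column is not None:
        adata.uns["cluster_column"] = ds.cluster_column
    return adata


def save_dataset(ds: CellDataset, destination) -> None:
    """Write a validated dataset to an AnnData-layout HDF5 (h5ad) file."""
    _require_valid(ds)
    destination = Path(destination)
    if not destination.parent.is_dir():
        raise IOError(f"destination directory does not exist: {destination.parent}")
    _to_anndata(ds).write_h5ad(destination)


def load_dataset_file(source) -> CellDataset:
    """Read an h5ad file into a :class:`CellDataset`.

    Missing optional components become empty defaults; when no ``about``
    block is stored the file stem becomes the title. An h5ad without any
    embedding loads fine but a warning is recorded.
    """
    source = Path(source)
    if not source.is_file():
        raise IOError(f"no such file: {source}")
    try:
        adata = ad.read_h5ad(source)
    except Exception as exc:  # malformed HDF5 / not h5ad
        raise FormatError(f"{source} is not a readable h5ad file: {exc}") from exc

    if "counts" in adata.layers:
        counts = sp.csr_matrix(adata.layers["counts"])
    else:
        counts = None
    normalized = sp.csr_matrix(adata.X)

    embeddings = {}
    for key in adata.obsm.keys():
        name = key[2:] if key.startswith("X_") else key
        arr = np.asarray(adata.obsm[key])
        if arr.ndim == 2 and arr.shape[1] == 2:
            embeddings[name] = arr.astype(np.float64)
    if not embeddings:
        warnings.warn(f"{source.name}: no 2-D embedding found", stacklevel=2)

    markers = adata.uns.get("markers")
    if markers is not None:
        markers = pd.DataFrame(markers).reset_index(drop=True)

    about_raw = adata.uns.get("about", {})
    about = About(
        title=str(about_raw.get("title") or source.stem),
        short=str(about_raw.get("short", "")),
        long=str(about_raw.get("long", "")),
    )
    cluster_column = adata.uns.get("cluster_column")

    ds = CellDataset(
        counts=counts,
        normalized=normalized,
        cell_table=adata.obs.copy(),
        gene_table=adata.var.copy(),
        embeddings=embeddings,
        markers=markers,
        about=about,
        cluster_column=str(cluster_column) if cluster_column is not None else None,
    )
    violations = validate_dataset(ds)
    if violations:
        raise FormatError(f"{source}: invalid container: {'; '.join(violations)}")
    return ds


# ----------------------------------------------------------------------
# equality contract & subsetting


def _dense(mat) -> np.ndarray:
    if mat is None:
        return None
    if sp.issparse(mat):
        return mat.toarray()
    return np.asarray(mat)


def _series_equal(a: pd.Series, b: pd.Series) -> bool:
    # categorical level order is not part of the contract; values are
    if isinstance(a.dtype, pd.CategoricalDtype) or isinstance(
        b.dtype, pd.CategoricalDtype
    ):
        return list(a.astype(str)) == list(b.astype(str))
    if pd.api.types.is_numeric_dtype(a) and pd.api.types.is_numeric_dtype(b):
        return np.allclose(a.to_numpy(float), b.to_numpy(float), atol=1e-12, rtol=0)
    return list(a.astype(str)) == list(b.astype(str))


def dataset_differences(a: CellDataset, b: CellDataset, atol: float = 1e-12) -> list[str]:
    """Compare two datasets under the persistence equality contract.

    Counts must match exactly, the normalized layer within ``atol``; tables,
    embeddings, markers and the about block must be equal (categorical level
    order is immaterial). Returns a list of difference descriptions.
    """
    out: list[str] = []
    ca, cb = _dense(a.counts), _dense(b.counts)
    if (ca is None) != (cb is None):
        out.append("counts: present in one dataset only")
    elif ca is not None:
        if ca.shape != cb.shape:
            out.append(f"counts: shapes differ {ca.shape} vs {cb.shape}")
        elif not np.array_equal(ca, cb):
            out.append("counts: values differ")
    na, nb = _dense(a.normalized), _dense(b.normalized)
    if na.shape != nb.shape:
        out.append(f"normalized: shapes differ {na.shape} vs {nb.shape}")
    elif not np.allclose(na, nb, atol=atol, rtol=0):
        out.append("normalized: values differ beyond tolerance")

    if list(a.cell_ids.astype(str)) != list(b.cell_ids.astype(str)):
        out.append("cell_table: identifiers differ")
    if sorted(a.cell_table.columns) != sorted(b.cell_table.columns):
        out.append(
            f"cell_table: columns differ {sorted(a.cell_table.columns)} vs "
            f"{sorted(b.cell_table.columns)}"
        )
    else:
        for col in a.cell_table.columns:
            if not _series_equal(a.cell_table[col], b.cell_table[col]):
                out.append(f"cell_table[{col!r}]: values differ")
    if list(a.gene_table["symbol"]) != list(b.gene_table["symbol"]):
        out.append("gene_table: symbols differ")

    if sorted(a.embeddings) != sorted(b.embeddings):
        out.append(f"embeddings: names differ {sorted(a.embeddings)} vs {sorted(b.embeddings)}")
    else:
        for name in a.embeddings:
            if not np.allclose(a.embeddings[name], b.embeddings[name], atol=atol, rtol=0):
                out.append(f"embeddings[{name!r}]: coordinates differ")

    ma = a.markers if a.markers is not None else empty_markers()
    mb = b.markers if b.markers is not None else empty_markers()
    if len(ma) != len(mb):
        out.append(f"markers: row counts differ {len(ma)} vs {len(mb)}")
    elif len(ma):
        if sorted(ma.columns) != sorted(mb.columns):
            out.append("markers: columns differ")
        else:
            for col in ma.columns:
                if not _series_equal(ma[col], mb[col]):
                    out.append(f"markers[{col!r}]: values differ")

    for part in ("title", "short", "long"):
        if getattr(a.about, part) != getattr(b.about, part):
            out.append(f"about.{part}: differs")
    return out


def datasets_equal(a: CellDataset, b: CellDataset, atol: float = 1e-12) -> bool:
    return not dataset_differences(a, b, atol=atol)


def subset_cells(ds: CellDataset, indices) -> CellDataset:
    """Return a new dataset physically restricted to the given cell positions.

    Categorical level sets are preserved so that group orderings and
    zero-count levels behave identically before and after subsetting.
    """
    idx = np.asarray(sorted(int(i) for i in indices), dtype=int)
    return CellDataset(
        counts=ds.counts[idx] if ds.counts is not None else None,
        normalized=sp.csr_matrix(ds.normalized)[idx],
        cell_table=ds.cell_table.iloc[idx].copy(),
        gene_table=ds.gene_table.copy(),
        embeddings={k: np.asarray(v)[idx] for k, v in ds.embeddings.items()},
        markers=ds.markers.copy() if ds.markers is not None else None,
        about=About(ds.about.title, ds.about.short, ds.about.long),
        cluster_column=ds.cluster_column,
    )
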