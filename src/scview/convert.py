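"""Converters that build :class:`~scview.dataset.CellDataset` objects from
CellRanger output directories, loom files and raw delimited text.

Every converter returns ``(dataset, report)`` where the report carries the
resulting dimensions, the source format and any warnings (dropped cells,
de-duplicated gene symbols, non-expression features removed, ...).
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from . import _loom
from .dataset import About, CellDataset, normalize_counts
from .errors import ConsistencyError, FormatError

__all__ = [
    "ConversionReport",
    "convert_cellranger",
    "convert_loom",
    "convert_text",
    "detect_format",
]

#: numeric annotation columns with at most this many distinct values are
#: treated as cluster-like categoricals
CLUSTER_LIKE_MAX_LEVELS = 20


@dataclass
class ConversionReport:
    n_cells: int
    n_genes: int
    warnings: list[str] = field(default_factory=list)
    source_format: str = ""


def deduplicate_symbols(symbols, warnings: list[str]) -> list[str]:
    """Make display symbols unique by suffixing repeats with .1, .2, ..."""
    seen: dict[str, int] = {}
    out = []
    for sym in symbols:
        sym = str(sym)
        if sym in seen:
            seen[sym] += 1
            new = f"{sym}.{seen[sym]}"
            warnings.append(f"duplicated gene symbol {sym!r} renamed to {new!r}")
            out.append(new)
            seen.setdefault(new, 0)
        else:
            seen[sym] = 0
            out.append(sym)
    return out


def _categorize(values: pd.Series) -> pd.Series:
    levels = sorted(values.astype(str).unique())
    return pd.Series(
        pd.Categorical(values.astype(str), categories=levels), index=values.index
    )


def type_annotation_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Apply the categorical-vs-numeric typing heuristic to annotation columns.

    Non-numeric columns become categoricals; numeric columns with at most
    ``CLUSTER_LIKE_MAX_LEVELS`` distinct integral values are flagged as
    cluster-like and also become categoricals (of their string form).
    """
    out = df.copy()
    for col in out.columns:
        series = out[col]
        if pd.api.types.is_numeric_dtype(series):
            values = series.to_numpy()
            distinct = np.unique(values[~pd.isna(values)])
            if len(distinct) <= CLUSTER_LIKE_MAX_LEVELS and np.allclose(
                distinct, np.round(distinct)
            ):
                out[col] = _categorize(series.astype(np.int64))
        else:
            out[col] = _categorize(series)
    return out


def extract_embeddings(
    df: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Pair numeric ``<name>_X``/``<name>_Y`` columns into 2-D embeddings.

    Pairing is by exact suffix, case-insensitive; unpaired suffixed columns
    are left in place as plain numeric columns.
    """
    suffix_map: dict[str, dict[str, str]] = {}
    for col in df.columns:
        m = re.match(r"^(.*)_([xy])$", str(col), flags=re.IGNORECASE)
        if m and pd.api.types.is_numeric_dtype(df[col]):
            suffix_map.setdefault(m.group(1).lower(), {})[m.group(2).lower()] = col
    embeddings: dict[str, np.ndarray] = {}
    drop: list[str] = []
    for base, pair in suffix_map.items():
        if "x" in pair and "y" in pair:
            embeddings[base] = np.column_stack(
                [df[pair["x"]].to_numpy(float), df[pair["y"]].to_numpy(float)]
            )
            drop += [pair["x"], pair["y"]]
    return df.drop(columns=drop), embeddings


# ----------------------------------------------------------------------
# CellRanger


def _find_input(directory: Path, names: tuple[str, ...]) -> Path:
    for name in names:
        for candidate in (directory / name, directory / f"{name}.gz"):
            if candidate.is_file():
                return candidate
    raise FormatError(f"{directory}: missing input file {names[0]}[.gz]")


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode if "b" not in mode else mode)


def _read_tsv(path: Path) -> pd.DataFrame:
    with _open_maybe_gzip(path) as fh:
        return pd.read_csv(fh, sep="\t", header=None, dtype=str)


def _single_candidate(directory: Path, preferred: str, pattern: str) -> Path | None:
    hit = directory / preferred
    if hit.is_file():
        return hit
    candidates = sorted(directory.glob(pattern))
    if len(candidates) > 1:
        raise FormatError(
            f"{directory}: ambiguous analysis inputs {sorted(str(c) for c in candidates)}"
        )
    return candidates[0] if candidates else None


def _parse_cellranger_diffexp(path: Path) -> pd.DataFrame:
    """Flatten CellRanger's wide differential_expression.csv to long form."""
    wide = pd.read_csv(path)
    name_col = "Feature Name" if "Feature Name" in wide.columns else wide.columns[1]
    rows = []
    for col in wide.columns:
        m = re.match(r"Cluster (\S+) Log2 fold change", col)
        if not m:
            continue
        cluster = m.group(1)
        padj_col = f"Cluster {cluster} Adjusted p value"
        for gene, lfc, padj in zip(
            wide[name_col],
            wide[col],
            wide[padj_col] if padj_col in wide.columns else [np.nan] * len(wide),
        ):
            rows.append(
                {"cluster": cluster, "gene": gene, "log2fc": lfc, "p_adj": padj}
            )
    return pd.DataFrame(rows)


def convert_cellranger(
    directory, about: About | None = None
) -> tuple[CellDataset, ConversionReport]:
    """Convert a CellRanger filtered feature-barcode matrix directory.

    The Matrix Market triplets (gene-major) are transposed to cells x genes;
    if an ``analysis`` subdirectory is present its clustering CSV becomes a
    categorical ``cluster`` column, projection CSVs become embeddings and
    the differential-expression CSV becomes the marker table. Gzipped and
    plain inputs produce identical datasets.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FormatError(f"no such directory: {directory}")
    warnings: list[str] = []

    matrix_path = _find_input(directory, ("matrix.mtx",))
    barcodes_path = _find_input(directory, ("barcodes.tsv",))
    features_path = _find_input(directory, ("features.tsv", "genes.tsv"))

    with _open_maybe_gzip(matrix_path, "rb") as fh:
        mat = scipy.io.mmread(io.BytesIO(fh.read()))
    counts = sp.csr_matrix(mat.T)  # cells x genes
    if counts.data.size and np.allclose(counts.data, np.round(counts.data)):
        counts = counts.astype(np.int64)

    barcodes = _read_tsv(barcodes_path)[0].tolist()
    features = _read_tsv(features_path)
    if len(barcodes) != counts.shape[0]:
        raise ConsistencyError(
            f"{len(barcodes)} barcodes but matrix has {counts.shape[0]} columns"
        )
    if len(features) != counts.shape[1]:
        raise ConsistencyError(
            f"{len(features)} features but matrix has {counts.shape[1]} rows"
        )

    gene_ids = features[0].tolist()
    symbols = features[1].tolist() if features.shape[1] > 1 else gene_ids
    if features.shape[1] > 2:
        keep = features[2] == "Gene Expression"
        if not keep.all():
            dropped = int((~keep).sum())
            warnings.append(
                f"dropped {dropped} non-'Gene Expression' feature(s)"
            )
            counts = counts[:, keep.to_numpy()]
            gene_ids = [g for g, k in zip(gene_ids, keep) if k]
            symbols = [s for s, k in zip(symbols, keep) if k]
    symbols = deduplicate_symbols(symbols, warnings)

    cell_table = pd.DataFrame(index=pd.Index(barcodes, name="cell"))
    gene_table = pd.DataFrame(
        {"symbol": symbols}, index=pd.Index(gene_ids, name="gene_id")
    )
    embeddings: dict[str, np.ndarray] = {}
    markers = None
    cluster_column = None

    analysis = directory / "analysis"
    if analysis.is_dir():
        cpath = _single_candidate(
            analysis, "clustering/graphclust/clusters.csv", "clustering/*/clusters.csv"
        )
        if cpath is not None:
            table = pd.read_csv(cpath, dtype=str).set_index("Barcode")
            try:
                labels = table.loc[barcodes, "Cluster"]
            except KeyError as exc:
                raise ConsistencyError(
                    f"{cpath}: barcodes missing from clustering table: {exc}"
                ) from exc
            cell_table["cluster"] = _categorize(labels).to_numpy()
            cluster_column = "cluster"
        for name in ("tsne", "umap"):
            ppath = _single_candidate(
                analysis, f"{name}/2_components/projection.csv", f"{name}/*/projection.csv"
            )
            if ppath is not None:
                table = pd.read_csv(ppath).set_index("Barcode")
                try:
                    coords = table.loc[barcodes].iloc[:, :2].to_numpy(float)
                except KeyError as exc:
                    raise ConsistencyError(
                        f"{ppath}: barcodes missing from projection: {exc}"
                    ) from exc
                embeddings[name] = coords
        dpath = _single_candidate(
            analysis,
            "diffexp/graphclust/differential_expression.csv",
            "diffexp/*/differential_expression.csv",
        )
        if dpath is not None:
            markers = _parse_cellranger_diffexp(dpath)

    ds = CellDataset(
        counts=counts,
        normalized=normalize_counts(counts),
        cell_table=cell_table,
        gene_table=gene_table,
        embeddings=embeddings,
        markers=markers,
        about=about or About(title=directory.name),
        cluster_column=cluster_column,
    )
    report = ConversionReport(ds.n_cells, ds.n_genes, warnings, "cellranger")
    return ds, report


# ----------------------------------------------------------------------
# loom


def convert_loom(file, about: About | None = None) -> tuple[CellDataset, ConversionReport]:
    """Convert a loom file (genes x cells main matrix) to a dataset.

    Row attributes populate the gene table (``Gene`` as display symbol,
    ``Accession`` as identifier when present), column attributes populate
    the cell table, and ``<name>_X``/``<name>_Y`` attribute pairs are
    assembled into 2-D embeddings.
    """
    file = Path(file)
    warnings: list[str] = []
    matrix, row_attrs, col_attrs = _loom.read_loom(file)
    n_genes, n_cells = matrix.shape
    if n_cells == 0 or n_genes == 0:
        raise FormatError(f"{file}: empty dataset")

    counts = sp.csr_matrix(np.asarray(matrix).T)
    if counts.data.size and np.allclose(counts.data, np.round(counts.data)):
        counts = counts.astype(np.int64)

    symbols = row_attrs.get("Gene")
    if symbols is None:
        symbols = [f"gene_{i}" for i in range(n_genes)]
    symbols = deduplicate_symbols(symbols, warnings)
    gene_ids = row_attrs.get("Accession", symbols)

    cell_ids = col_attrs.get("CellID", [f"cell_{i}" for i in range(n_cells)])
    cell_table = pd.DataFrame(index=pd.Index([str(c) for c in cell_ids], name="cell"))
    for name, values in col_attrs.items():
        if name == "CellID":
            continue
        cell_table[name] = values
    cell_table, embeddings = extract_embeddings(cell_table)
    cell_table = type_annotation_columns(cell_table)

    ds = CellDataset(
        counts=counts,
        normalized=normalize_counts(counts),
        cell_table=cell_table,
        gene_table=pd.DataFrame(
            {"symbol": symbols}, index=pd.Index([str(g) for g in gene_ids], name="gene_id")
        ),
        embeddings=embeddings,
        about=about or About(title=file.stem),
        cluster_column="cluster" if "cluster" in cell_table.columns else None,
    )
    return ds, ConversionReport(ds.n_cells, ds.n_genes, warnings, "loom")


# ----------------------------------------------------------------------
# raw text


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def convert_text(
    matrix_file, annotation_file, about: About | None = None
) -> tuple[CellDataset, ConversionReport]:
    """Convert a delimited matrix/annotation file pair to a dataset.

    The matrix has gene rows and cell columns (first column the gene
    symbol); the annotation has one row per cell (first column the cell
    identifier). Cells are aligned by identifier — the intersection is kept
    in matrix order and dropped cells are counted in the warnings.
    """
    matrix_file, annotation_file = Path(matrix_file), Path(annotation_file)
    warnings: list[str] = []

    mat = pd.read_csv(matrix_file, sep=_sniff_sep(matrix_file), index_col=0)
    annot = pd.read_csv(
        annotation_file, sep=_sniff_sep(annotation_file), index_col=0
    )
    annot.index = annot.index.astype(str)
    mat.columns = mat.columns.astype(str)

    shared = [c for c in mat.columns if c in set(annot.index)]
    if not shared:
        raise ConsistencyError(
            "no overlapping cell identifiers between matrix and annotation"
        )
    dropped = (len(mat.columns) - len(shared)) + (len(annot.index) - len(shared))
    if dropped:
        warnings.append(f"dropped {dropped} cell(s) without matching identifier")
    mat = mat[shared]
    annot = annot.loc[shared]

    symbols = deduplicate_symbols(mat.index, warnings)
    values = mat.to_numpy().T  # cells x genes
    integral = np.allclose(values, np.round(values))
    if integral:
        counts = sp.csr_matrix(values.astype(np.int64))
        normalized = normalize_counts(counts)
    else:
        counts = None
        normalized = sp.csr_matrix(np.asarray(values, dtype=np.float64))
        warnings.append("matrix has non-integer values; stored as normalized only")

    annot, embeddings = extract_embeddings(annot)
    annot = type_annotation_columns(annot)
    annot.index.name = "cell"

    ds = CellDataset(
        counts=counts,
        normalized=normalized,
        cell_table=annot,
        gene_table=pd.DataFrame(
            {"symbol": symbols}, index=pd.Index(symbols, name="gene_id")
        ),
        embeddings=embeddings,
        about=about or About(title=matrix_file.stem),
        cluster_column="cluster" if "cluster" in annot.columns else None,
    )
    return ds, ConversionReport(ds.n_cells, ds.n_genes, warnings, "text")


def detect_format(paths: list) -> str:
    """Guess the converter to use for the CLI: cellranger / loom / text / h5ad."""
    first = Path(paths[0])
    if first.is_dir():
        return "cellranger"
    if first.suffix == ".loom":
        return "loom"
    if first.suffix == ".h5ad":
        return "h5ad"
    if len(paths) == 2:
        return "text"
    raise FormatError(
        "cannot detect input format; pass --format cellranger|loom|text"
    )
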