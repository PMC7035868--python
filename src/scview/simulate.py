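"""Synthetic single-cell data generators and on-disk fixture writers.

Everything the test-bench needs is generated here: clustered expression
datasets with planted marker genes (negative-binomial counts, so the
over-dispersion of droplet scRNA-seq is represented), species-mixing UMI
tables with a known doublet rate, and CellRanger- / loom- / text-format
fixtures that round-trip bit-exact through the converters.

All generators are pure functions of their parameters plus a seed.
"""

from __future__ import annotations

import csv
import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from . import _loom
from .dataset import About, CellDataset, normalize_counts
from .errors import SpecificationError, ValidationError

__all__ = [
    "SimSpec",
    "GroundTruth",
    "SpeciesMixTruth",
    "generate_clustered_dataset",
    "generate_species_mix",
    "write_cellranger_fixture",
    "write_loom_fixture",
    "write_text_fixture",
]


@dataclass
class SimSpec:
    """Parameters of the clustered-expression simulation.

    Counts are negative binomial with mean ``baseline_mean`` and variance
    ``mu + dispersion * mu**2``; each cluster's planted marker genes have
    their mean multiplied by ``fold_change`` in that cluster's cells.
    """

    n_cells: int = 300
    n_genes: int = 200
    k_clusters: int = 3
    de_genes_per_cluster: int = 10
    fold_change: float = 4.0
    baseline_mean: float = 2.0
    dispersion: float = 0.3
    condition_fraction: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < self.k_clusters:
            raise SpecificationError("n_cells must be >= k_clusters")
        if self.de_genes_per_cluster * self.k_clusters > self.n_genes:
            raise SpecificationError(
                "de_genes_per_cluster * k_clusters must not exceed n_genes"
            )
        if self.fold_change <= 1 and self.fold_change != 1.0:
            raise SpecificationError("fold_change must be >= 1")
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise SpecificationError("baseline_mean and dispersion must be > 0")
        if self.condition_fraction is not None and not (
            0 < self.condition_fraction < 1
        ):
            raise SpecificationError("condition_fraction must lie in (0, 1)")


@dataclass
class GroundTruth:
    """What the simulation planted: cluster labels and marker genes."""

    cluster_labels: np.ndarray  # per-cell label, e.g. "1", "2", ...
    planted_markers: dict[str, list[str]]  # cluster label -> gene symbols

    @property
    def all_planted(self) -> set[str]:
        return {g for genes in self.planted_markers.values() for g in genes}


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    # NB parameterized by mean and dispersion phi: var = mu + phi mu^2
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_clustered_dataset(spec: SimSpec) -> tuple[CellDataset, GroundTruth]:
    """Simulate a clustered dataset with planted differential genes.

    Cells are assigned to clusters round-robin; a synthetic 2-D "tsne"
    layout places cluster centroids 10 units from the origin with unit
    Gaussian spread around each centroid (cluster structure, not a real
    manifold embedding). The marker table is filled from the planted truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    k = spec.k_clusters
    labels_int = np.arange(spec.n_cells) % k  # round-robin
    labels = (labels_int + 1).astype(str)
    cluster_levels = sorted({str(c + 1) for c in range(k)})

    mean = np.full((spec.n_cells, spec.n_genes), spec.baseline_mean)
    planted: dict[str, list[str]] = {}
    symbols = [f"G{i:04d}" for i in range(spec.n_genes)]
    for c in range(k):
        genes = list(
            range(c * spec.de_genes_per_cluster, (c + 1) * spec.de_genes_per_cluster)
        )
        mean[np.ix_(labels_int == c, genes)] *= spec.fold_change
        planted[str(c + 1)] = [symbols[g] for g in genes]

    counts = _nb_sample(rng, mean, spec.dispersion).astype(np.int64)

    angles = 2 * np.pi * labels_int / k
    centroids = 10.0 * np.column_stack([np.cos(angles), np.sin(angles)])
    embedding = centroids + rng.normal(size=(spec.n_cells, 2))

    cell_table = pd.DataFrame(index=pd.Index(
        [f"cell_{i:05d}" for i in range(spec.n_cells)], name="cell"
    ))
    cell_table["cluster"] = pd.Categorical(labels, categories=cluster_levels)
    cell_table["n_counts"] = counts.sum(axis=1)
    if spec.condition_fraction is not None:
        cond = np.where(
            rng.random(spec.n_cells) < spec.condition_fraction,
            "stimulated",
            "control",
        )
        cell_table["condition"] = pd.Categorical(
            cond, categories=["control", "stimulated"]
        )

    gene_table = pd.DataFrame(
        {"symbol": symbols},
        index=pd.Index([f"GID{i:05d}" for i in range(spec.n_genes)], name="gene_id"),
    )

    markers = pd.DataFrame(
        [
            {"cluster": c, "gene": g, "log2fc": float(np.log2(spec.fold_change))}
            for c in cluster_levels
            for g in planted[c]
        ]
    )
    if spec.fold_change == 1.0:
        markers = markers.iloc[0:0]

    ds = CellDataset(
        counts=sp.csr_matrix(counts),
        normalized=normalize_counts(counts),
        cell_table=cell_table,
        gene_table=gene_table,
        embeddings={"tsne": embedding},
        markers=markers if len(markers) else None,
        about=About(
            title="synthetic clustered dataset",
            short=f"{spec.n_cells} cells, {spec.n_genes} genes, {k} clusters",
            long=(
                "Simulated negative-binomial counts with planted cluster "
                f"markers at {spec.fold_change}-fold change (seed {spec.seed})."
            ),
        ),
        cluster_column="cluster",
    )
    return ds, GroundTruth(cluster_labels=labels, planted_markers=planted)


# ----------------------------------------------------------------------
# species mixing


@dataclass
class SpeciesMixTruth:
    h_counts: np.ndarray
    m_counts: np.ndarray
    true_calls: np.ndarray = field(default_factory=lambda: np.array([]))


def generate_species_mix(
    n_cells: int, doublet_rate: float, mean_umis: float, seed: int
) -> SpeciesMixTruth:
    """Simulate per-cell human/mouse UMI counts from a 1:1 species mixture.

    Singlets get Poisson(``mean_umis``) counts from their own species and a
    1% ambient contamination Poisson(0.01 * ``mean_umis``) from the other;
    doublets are the sum of two independent singlets of opposite species.
    """
    if not 0 <= doublet_rate < 1:
        raise SpecificationError("doublet_rate must lie in [0, 1)")
    if mean_umis <= 0:
        raise SpecificationError("mean_umis must be > 0")
    rng = np.random.default_rng(seed)
    is_doublet = rng.random(n_cells) < doublet_rate
    is_human = rng.random(n_cells) < 0.5  # 1:1 mixture

    own = rng.poisson(mean_umis, size=n_cells)
    ambient = rng.poisson(0.01 * mean_umis, size=n_cells)
    h = np.where(is_human, own, ambient)
    m = np.where(is_human, ambient, own)
    # a doublet adds one singlet of the opposite species
    extra_own = rng.poisson(mean_umis, size=n_cells)
    extra_ambient = rng.poisson(0.01 * mean_umis, size=n_cells)
    h = np.where(is_doublet, h + np.where(is_human, extra_ambient, extra_own), h)
    m = np.where(is_doublet, m + np.where(is_human, extra_own, extra_ambient), m)

    calls = np.where(is_doublet, "doublet", np.where(is_human, "species1", "species2"))
    return SpeciesMixTruth(
        h_counts=h.astype(np.int64), m_counts=m.astype(np.int64), true_calls=calls
    )


# ----------------------------------------------------------------------
# fixture writers


def _open_text(path: Path, gz: bool):
    if gz:
        return io.TextIOWrapper(
            gzip.GzipFile(path, "wb", mtime=0), encoding="utf-8", newline=""
        )
    return open(path, "w", newline="")


def _require_nonempty(ds: CellDataset) -> None:
    if ds.counts is None:
        raise ValidationError(["fixture writers require raw counts"])
    if ds.n_cells == 0 or ds.n_genes == 0:
        raise ValidationError(["refusing to write a fixture for an empty dataset"])


def write_cellranger_fixture(
    ds: CellDataset, directory, gzip_files: bool = False, include_analysis: bool = True
) -> None:
    """Write a CellRanger-style filtered feature-barcode matrix directory.

    Emits ``matrix.mtx``, ``barcodes.tsv`` and ``features.tsv`` (optionally
    gzipped) with the matrix stored gene-major, as CellRanger does. When the
    dataset has a ``cluster`` column and/or a ``tsne``/``umap`` embedding and
    ``include_analysis`` is set, a matching ``analysis/`` subdirectory is
    written too.
    """
    _require_nonempty(ds)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = ".gz" if gzip_files else ""

    mat = sp.coo_matrix(ds.counts).T  # genes x cells
    buf = io.BytesIO()
    scipy.io.mmwrite(buf, mat, field="integer")
    raw = buf.getvalue()
    if gzip_files:
        raw = gzip.compress(raw, mtime=0)
    (directory / f"matrix.mtx{suffix}").write_bytes(raw)

    with _open_text(directory / f"barcodes.tsv{suffix}", gzip_files) as fh:
        for cid in ds.cell_ids:
            fh.write(f"{cid}\n")
    with _open_text(directory / f"features.tsv{suffix}", gzip_files) as fh:
        for gid, sym in zip(ds.gene_table.index, ds.gene_table["symbol"]):
            fh.write(f"{gid}\t{sym}\tGene Expression\n")

    if not include_analysis:
        return
    if "cluster" in ds.cell_table.columns:
        cdir = directory / "analysis" / "clustering" / "graphclust"
        cdir.mkdir(parents=True)
        with open(cdir / "clusters.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["Barcode", "Cluster"])
            for cid, label in zip(ds.cell_ids, ds.cell_table["cluster"].astype(str)):
                w.writerow([cid, label])
    for name in ("tsne", "umap"):
        if name in ds.embeddings:
            pdir = directory / "analysis" / name / "2_components"
            pdir.mkdir(parents=True)
            with open(pdir / "projection.csv", "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["Barcode", f"{name.upper()}-1", f"{name.upper()}-2"])
                for cid, (x, y) in zip(ds.cell_ids, np.asarray(ds.embeddings[name])):
                    w.writerow([cid, repr(float(x)), repr(float(y))])


def write_loom_fixture(ds: CellDataset, path) -> None:
    """Write the dataset as a loom file (genes x cells main matrix).

    Cell-table columns become column attributes, the gene symbol/identifier
    become ``Gene``/``Accession`` row attributes, and each 2-D embedding is
    stored as a ``<name>_X`` / ``<name>_Y`` attribute pair.
    """
    _require_nonempty(ds)
    matrix = np.asarray(
        ds.counts.toarray() if sp.issparse(ds.counts) else ds.counts
    ).T
    row_attrs = {
        "Gene": ds.gene_table["symbol"].to_numpy(str),
        "Accession": ds.gene_table.index.to_numpy(str),
    }
    col_attrs: dict[str, np.ndarray] = {"CellID": ds.cell_ids.to_numpy(str)}
    for col in ds.cell_table.columns:
        series = ds.cell_table[col]
        if isinstance(series.dtype, pd.CategoricalDtype):
            col_attrs[col] = series.astype(str).to_numpy()
        else:
            col_attrs[col] = series.to_numpy()
    for name, coords in ds.embeddings.items():
        coords = np.asarray(coords, dtype=np.float64)
        col_attrs[f"{name}_X"] = coords[:, 0]
        col_attrs[f"{name}_Y"] = coords[:, 1]
    _loom.write_loom(path, matrix, row_attrs, col_attrs)


def write_text_fixture(ds: CellDataset, matrix_path, annotation_path) -> None:
    """Write the dataset as a delimited text pair (matrix + annotation).

    The matrix file has gene rows and cell columns (first column the gene
    symbol); the annotation file has one row per cell (first column the cell
    identifier) with embeddings flattened to ``<name>_X``/``<name>_Y``.
    """
    _require_nonempty(ds)
    counts = np.asarray(
        ds.counts.toarray() if sp.issparse(ds.counts) else ds.counts
    )
    with open(matrix_path, "w", newline="") as fh:
        fh.write("gene\t" + "\t".join(map(str, ds.cell_ids)) + "\n")
        for j, sym in enumerate(ds.gene_table["symbol"]):
            fh.write(sym + "\t" + "\t".join(str(int(v)) for v in counts[:, j]) + "\n")

    annot = ds.cell_table.copy()
    for col in annot.columns:
        if isinstance(annot[col].dtype, pd.CategoricalDtype):
            annot[col] = annot[col].astype(str)
    for name, coords in ds.embeddings.items():
        coords = np.asarray(coords, dtype=np.float64)
        annot[f"{name}_X"] = coords[:, 0]
        annot[f"{name}_Y"] = coords[:, 1]
    annot.index.name = "cell"
    annot.to_csv(annotation_path, sep="\t")
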