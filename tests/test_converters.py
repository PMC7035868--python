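"""CellRanger / loom / raw-text conversion and format equivalence."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import scview as sv
from scview.convert import deduplicate_symbols
from scview.errors import ConsistencyError, FormatError


@pytest.fixture()
def tiny():
    """3 cells x 2 genes with counts [[1,0],[0,2],[3,0]]."""
    counts = sp.csr_matrix(np.array([[1, 0], [0, 2], [3, 0]], dtype=np.int64))
    return sv.CellDataset.from_counts(
        counts,
        cell_table=pd.DataFrame(index=pd.Index(["b1", "b2", "b3"], name="cell")),
        gene_table=pd.DataFrame(
            {"symbol": ["ACTB", "GAPDH"]},
            index=pd.Index(["g1", "g2"], name="gene_id"),
        ),
    )


class TestCellRanger:
    def test_fixture_round_trips_counts_bit_exact(self, tmp_path, tiny):
        sv.write_cellranger_fixture(tiny, tmp_path / "cr")
        ds, report = sv.convert_cellranger(tmp_path / "cr")
        assert np.array_equal(ds.counts.toarray(), tiny.counts.toarray())
        assert (report.n_cells, report.n_genes) == (3, 2)
        assert report.source_format == "cellranger"

    def test_gzipped_fixture_converts_identically(self, tmp_path, tiny):
        sv.write_cellranger_fixture(tiny, tmp_path / "plain", gzip_files=False)
        sv.write_cellranger_fixture(tiny, tmp_path / "gz", gzip_files=True)
        about = sv.About(title="same")
        a, _ = sv.convert_cellranger(tmp_path / "plain", about=about)
        b, _ = sv.convert_cellranger(tmp_path / "gz", about=about)
        assert sv.datasets_equal(a, b)

    def test_missing_matrix_is_a_format_error(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(FormatError, match="matrix.mtx"):
            sv.convert_cellranger(tmp_path / "empty")

    def test_barcode_count_mismatch_is_a_consistency_error(self, tmp_path, tiny):
        sv.write_cellranger_fixture(tiny, tmp_path / "cr")
        (tmp_path / "cr" / "barcodes.tsv").write_text("b1\nb2\n")
        with pytest.raises(ConsistencyError):
            sv.convert_cellranger(tmp_path / "cr")

    def test_analysis_directory_yields_cluster_and_embedding(self, tmp_path, clustered):
        ds, _ = clustered
        sv.write_cellranger_fixture(ds, tmp_path / "cr", include_analysis=True)
        got, _ = sv.convert_cellranger(tmp_path / "cr")
        assert got.cluster_column == "cluster"
        assert list(got.cell_table["cluster"].astype(str)) == list(
            ds.cell_table["cluster"].astype(str)
        )
        assert np.allclose(got.embeddings["tsne"], ds.embeddings["tsne"])

    def test_non_expression_features_are_dropped_with_warning(self, tmp_path, tiny):
        sv.write_cellranger_fixture(tiny, tmp_path / "cr", include_analysis=False)
        features = tmp_path / "cr" / "features.tsv"
        features.write_text("g1\tACTB\tGene Expression\ng2\tCD3-AB\tAntibody Capture\n")
        ds, report = sv.convert_cellranger(tmp_path / "cr")
        assert ds.n_genes == 1
        assert any("Gene Expression" in w for w in report.warnings)

    def test_cellranger_diffexp_csv_becomes_markers(self, tmp_path, tiny):
        sv.write_cellranger_fixture(tiny, tmp_path / "cr", include_analysis=False)
        ddir = tmp_path / "cr" / "analysis" / "diffexp" / "graphclust"
        ddir.mkdir(parents=True)
        (ddir / "differential_expression.csv").write_text(
            "Feature ID,Feature Name,"
            "Cluster 1 Mean Counts,Cluster 1 Log2 fold change,Cluster 1 Adjusted p value,"
            "Cluster 2 Mean Counts,Cluster 2 Log2 fold change,Cluster 2 Adjusted p value\n"
            "g1,ACTB,5.0,2.0,0.001,1.0,-2.0,0.04\n"
            "g2,GAPDH,1.0,-0.5,0.9,2.0,0.5,0.8\n"
        )
        ds, _ = sv.convert_cellranger(tmp_path / "cr")
        markers = ds.markers
        assert set(markers["cluster"]) == {"1", "2"}
        row = markers[(markers["cluster"] == "1") & (markers["gene"] == "ACTB")]
        assert float(row["log2fc"].iloc[0]) == 2.0
        assert float(row["p_adj"].iloc[0]) == 0.001

    def test_ambiguous_analysis_candidates_raise(self, tmp_path, tiny):
        sv.write_cellranger_fixture(tiny, tmp_path / "cr", include_analysis=False)
        for variant in ("kmeans_2", "kmeans_3"):
            d = tmp_path / "cr" / "analysis" / "clustering" / variant
            d.mkdir(parents=True)
            (d / "clusters.csv").write_text("Barcode,Cluster\nb1,1\nb2,1\nb3,2\n")
        with pytest.raises(FormatError, match="ambiguous"):
            sv.convert_cellranger(tmp_path / "cr")


class TestLoom:
    def test_loom_round_trip_matches_source(self, tmp_path, clustered):
        ds, _ = clustered
        sv.write_loom_fixture(ds, tmp_path / "ds.loom")
        got, report = sv.convert_loom(tmp_path / "ds.loom")
        assert np.array_equal(got.counts.toarray(), ds.counts.toarray())
        assert "tsne" in got.embeddings
        assert np.allclose(got.embeddings["tsne"], ds.embeddings["tsne"])
        assert report.source_format == "loom"

    def test_xy_attribute_pair_becomes_embedding(self, tmp_path):
        from scview import _loom

        matrix = np.arange(6).reshape(2, 3) + 1  # genes x cells
        _loom.write_loom(
            tmp_path / "t.loom",
            matrix,
            row_attrs={"Gene": np.array(["A", "B"])},
            col_attrs={
                "CellID": np.array(["c1", "c2", "c3"]),
                "tsne_X": np.array([0.0, 1.0, 2.0]),
                "tsne_Y": np.array([3.0, 4.0, 5.0]),
            },
        )
        ds, _ = sv.convert_loom(tmp_path / "t.loom")
        assert np.allclose(ds.embeddings["tsne"], [[0, 3], [1, 4], [2, 5]])
        assert "tsne_X" not in ds.cell_table.columns

    def test_zero_cell_loom_is_refused(self, tmp_path):
        from scview import _loom

        _loom.write_loom(
            tmp_path / "empty.loom", np.zeros((2, 0)), {"Gene": ["A", "B"]}, {}
        )
        with pytest.raises(FormatError, match="empty dataset"):
            sv.convert_loom(tmp_path / "empty.loom")

    def test_file_without_matrix_is_a_format_error(self, tmp_path):
        import h5py

        with h5py.File(tmp_path / "bad.loom", "w") as f:
            f.create_group("row_attrs")
        with pytest.raises(FormatError, match="matrix"):
            sv.convert_loom(tmp_path / "bad.loom")


class TestText:
    def _write_pair(self, tmp_path, matrix_text, annot_text):
        (tmp_path / "m.tsv").write_text(matrix_text)
        (tmp_path / "a.tsv").write_text(annot_text)
        return tmp_path / "m.tsv", tmp_path / "a.tsv"

    def test_simple_tsv_pair_converts(self, tmp_path):
        m, a = self._write_pair(
            tmp_path,
            "gene\tc1\tc2\tc3\nACTB\t1\t0\t3\nGAPDH\t0\t2\t0\n",
            "cell\tgroup\nc1\tx\nc2\ty\nc3\tx\n",
        )
        ds, report = sv.convert_text(m, a)
        assert ds.n_cells == 3 and ds.n_genes == 2
        assert report.warnings == []
        assert np.array_equal(
            ds.counts.toarray(), np.array([[1, 0], [0, 2], [3, 0]])
        )
        assert str(ds.cell_table["group"].dtype) == "category"

    def test_extra_annotation_cell_is_dropped_with_warning(self, tmp_path):
        m, a = self._write_pair(
            tmp_path,
            "gene\tc1\tc2\nACTB\t1\t2\n",
            "cell\tgroup\nc1\tx\nc2\ty\nc9\tz\n",
        )
        ds, report = sv.convert_text(m, a)
        assert ds.n_cells == 2
        assert len(report.warnings) == 1 and "1 cell" in report.warnings[0]

    def test_duplicate_gene_symbols_get_suffixes(self, tmp_path):
        m, a = self._write_pair(
            tmp_path,
            "gene\tc1\tc2\nMT-CO1\t1\t2\nMT-CO1\t3\t4\n",
            "cell\tgroup\nc1\tx\nc2\ty\n",
        )
        ds, report = sv.convert_text(m, a)
        assert list(ds.gene_table["symbol"]) == ["MT-CO1", "MT-CO1.1"]
        assert any("MT-CO1" in w for w in report.warnings)

    def test_zero_overlap_is_a_consistency_error(self, tmp_path):
        m, a = self._write_pair(
            tmp_path,
            "gene\tc1\nACTB\t1\n",
            "cell\tgroup\nother\tx\n",
        )
        with pytest.raises(ConsistencyError):
            sv.convert_text(m, a)

    def test_comma_delimiter_is_sniffed(self, tmp_path):
        (tmp_path / "m.csv").write_text("gene,c1,c2\nACTB,1,2\n")
        (tmp_path / "a.csv").write_text("cell,group\nc1,x\nc2,y\n")
        ds, _ = sv.convert_text(tmp_path / "m.csv", tmp_path / "a.csv")
        assert ds.n_cells == 2

    def test_cluster_like_numeric_column_becomes_categorical(self, tmp_path):
        m, a = self._write_pair(
            tmp_path,
            "gene\tc1\tc2\tc3\nACTB\t1\t2\t3\n",
            "cell\tcluster\tdepth\nc1\t1\t1000.5\nc2\t2\t2000.5\nc3\t1\t1500.5\n",
        )
        ds, _ = sv.convert_text(m, a)
        assert str(ds.cell_table["cluster"].dtype) == "category"
        assert pd.api.types.is_numeric_dtype(ds.cell_table["depth"])
        assert ds.cluster_column == "cluster"


class TestFormatEquivalence:
    def test_same_data_via_all_three_formats_is_equal(self, tmp_path):
        ds, _ = sv.generate_clustered_dataset(
            sv.SimSpec(n_cells=24, n_genes=20, k_clusters=2,
                       de_genes_per_cluster=3, seed=5)
        )
        # restrict to what every format can carry: counts, cluster, embedding
        import dataclasses

        ds = dataclasses.replace(
            ds,
            cell_table=ds.cell_table[["cluster"]],
            markers=None,
            about=sv.About(),
        )
        sv.write_cellranger_fixture(ds, tmp_path / "cr")
        sv.write_loom_fixture(ds, tmp_path / "d.loom")
        sv.write_text_fixture(ds, tmp_path / "m.tsv", tmp_path / "a.tsv")
        about = sv.About()
        from_cr, _ = sv.convert_cellranger(tmp_path / "cr", about=about)
        from_loom, _ = sv.convert_loom(tmp_path / "d.loom", about=about)
        from_text, _ = sv.convert_text(tmp_path / "m.tsv", tmp_path / "a.tsv", about=about)
        assert sv.dataset_differences(from_cr, from_loom) == []
        assert sv.dataset_differences(from_cr, from_text) == []

    def test_conversion_is_deterministic(self, tmp_path, clustered):
        ds, _ = clustered
        sv.write_cellranger_fixture(ds, tmp_path / "cr")
        a, _ = sv.convert_cellranger(tmp_path / "cr")
        b, _ = sv.convert_cellranger(tmp_path / "cr")
        sv.save_dataset(a, tmp_path / "a.h5ad")
        sv.save_dataset(b, tmp_path / "b.h5ad")
        assert sv.datasets_equal(a, b)


def test_symbol_deduplication_rule():
    warnings = []
    assert deduplicate_symbols(["A", "A", "A", "B"], warnings) == ["A", "A.1", "A.2", "B"]
    assert len(warnings) == 2
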