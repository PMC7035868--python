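"""Dot-plot, composition, species-mix, distribution and downsampling."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.stats import binom

import scview as sv
from scview.errors import AmbiguityError, ScviewError, SpecificationError


def _four_cell_dataset():
    """Two groups of two cells with normalized values set by hand."""
    normalized = sp.csr_matrix(np.array([[0.0], [2.0], [1.0], [3.0]]))
    cell_table = pd.DataFrame(
        {"grp": pd.Categorical(["A", "A", "B", "B"])},
        index=pd.Index([f"c{i}" for i in range(4)], name="cell"),
    )
    gene_table = pd.DataFrame(
        {"symbol": ["GENE"]}, index=pd.Index(["g"], name="gene_id")
    )
    return sv.CellDataset(
        counts=None, normalized=normalized, cell_table=cell_table,
        gene_table=gene_table,
    )


class TestDotPlot:
    def test_hand_computed_means_and_fractions(self):
        ds = _four_cell_dataset()
        out = sv.dot_plot_summary(ds, ["GENE"], "grp").table.set_index("group")
        assert out.loc["A", "fraction"] == pytest.approx(0.5)
        assert out.loc["B", "fraction"] == pytest.approx(1.0)
        assert out.loc["A", "mean"] == pytest.approx(1.0)
        assert out.loc["B", "mean"] == pytest.approx(2.0)

    def test_all_zero_gene_gives_zero_everywhere(self, clustered):
        ds, _ = clustered
        import dataclasses

        norm = ds.normalized.toarray()
        norm[:, 0] = 0.0
        zeroed = dataclasses.replace(ds, normalized=sp.csr_matrix(norm))
        sym = ds.gene_table["symbol"].iloc[0]
        table = sv.dot_plot_summary(zeroed, [sym], "cluster").table
        assert (table["mean"] == 0).all() and (table["fraction"] == 0).all()

    def test_split_rows_count_observed_pairs(self, clustered):
        ds, _ = clustered
        genes = list(ds.gene_table["symbol"].iloc[:3])
        table = sv.dot_plot_summary(ds, genes, "cluster", split_by="condition").table
        observed = (
            ds.cell_table.groupby(["cluster", "condition"], observed=True)
            .size()
            .pipe(lambda s: int((s > 0).sum()))
        )
        assert len(table) == observed * len(genes)

    def test_unknown_gene_is_listed_in_the_error(self, clustered):
        ds, _ = clustered
        with pytest.raises(SpecificationError, match="NOSUCH"):
            sv.dot_plot_summary(ds, ["NOSUCH"], "cluster")

    def test_non_categorical_group_column_is_rejected(self, clustered):
        ds, _ = clustered
        with pytest.raises(SpecificationError, match="n_counts"):
            sv.dot_plot_summary(ds, [ds.gene_table["symbol"].iloc[0]], "n_counts")


class TestComposition:
    def test_hand_tally_proportions(self):
        cell_table = pd.DataFrame(
            {
                "cluster": pd.Categorical(["1"] * 3 + ["2"] * 3),
                "species": pd.Categorical(
                    ["human", "human", "mouse", "mouse", "mouse", "mouse"]
                ),
            },
            index=pd.Index([f"c{i}" for i in range(6)], name="cell"),
        )
        ds = sv.CellDataset(
            counts=None,
            normalized=sp.csr_matrix(np.zeros((6, 1))),
            cell_table=cell_table,
            gene_table=pd.DataFrame(
                {"symbol": ["G"]}, index=pd.Index(["g"], name="gene_id")
            ),
        )
        out = sv.composition_table(ds, "cluster", "species")
        assert out.proportions.loc["1", "human"] == pytest.approx(2 / 3)
        assert out.proportions.loc["1", "mouse"] == pytest.approx(1 / 3)
        assert out.proportions.loc["2", "human"] == pytest.approx(0.0)
        assert out.proportions.loc["2", "mouse"] == pytest.approx(1.0)
        assert out.counts.to_numpy().sum() == 6

    def test_pure_cluster_has_proportion_one(self, clustered):
        ds, truth = clustered
        out = sv.composition_table(ds, "cluster", "cluster")
        for level in out.proportions.index:
            assert out.proportions.loc[level, level] == pytest.approx(1.0)

    def test_proportions_sum_to_one_per_nonempty_level(self, clustered):
        ds, _ = clustered
        out = sv.composition_table(ds, "cluster", "condition")
        sums = out.proportions.sum(axis=1)
        for level, s in sums.items():
            if level not in out.empty_levels:
                assert s == pytest.approx(1.0, abs=1e-12)

    def test_empty_subset_reports_zero_with_flag(self, clustered):
        ds, _ = clustered
        out = sv.composition_table(ds, "cluster", "condition", cells=[])
        assert (out.counts.to_numpy() == 0).all()
        assert (out.proportions.to_numpy() == 0).all()
        assert set(out.empty_levels) == set(out.counts.index)


class TestSpeciesMix:
    def test_pure_and_balanced_cells(self):
        stats = sv.species_mix_stats([100, 50], [0, 50], purity_threshold=0.9)
        assert stats.calls.tolist() == ["species1", "doublet"]
        assert stats.doublet_rate == pytest.approx(0.5)

    def test_zero_total_cell_is_a_domain_error(self):
        with pytest.raises(ScviewError, match="zero total"):
            sv.species_mix_stats([1, 0], [1, 0])

    def test_recovers_simulated_doublet_rate(self):
        mix = sv.generate_species_mix(1000, 0.02, mean_umis=5000, seed=9)
        stats = sv.species_mix_stats(mix.h_counts, mix.m_counts)
        lo = binom.ppf(0.025, 1000, 0.02) / 1000
        hi = binom.ppf(0.975, 1000, 0.02) / 1000
        assert lo <= stats.doublet_rate <= hi
        assert np.array_equal(stats.calls, mix.true_calls)


class TestDistribution:
    def test_quartiles_by_linear_interpolation(self):
        ds = _four_cell_dataset()
        import dataclasses

        one_group = dataclasses.replace(
            ds,
            cell_table=ds.cell_table.assign(
                grp=pd.Categorical(["A"] * 4)
            ),
            normalized=sp.csr_matrix(np.array([[1.0], [2.0], [3.0], [4.0]])),
        )
        out = sv.distribution_panel(one_group, "GENE", "grp")
        row = out.summary.iloc[0]
        assert row["median"] == pytest.approx(2.5)
        assert row["q1"] == pytest.approx(1.75)
        assert row["q3"] == pytest.approx(3.25)

    def test_singleton_group_quartiles_collapse(self):
        ds = _four_cell_dataset()
        out = sv.distribution_panel(ds, "GENE", "grp", cells=[0, 2])
        row = out.summary.set_index("group").loc["A"]
        assert row["median"] == row["q1"] == row["q3"] == 0.0
        assert row["count"] == 1

    def test_numeric_column_resolution(self, clustered):
        ds, _ = clustered
        out = sv.distribution_panel(ds, "n_counts", "cluster")
        assert set(out.values) == set(ds.cell_table["cluster"].cat.categories.astype(str))

    def test_ambiguous_name_requires_qualifier(self, clustered):
        ds, _ = clustered
        import dataclasses

        renamed = dataclasses.replace(
            ds, cell_table=ds.cell_table.rename(columns={"n_counts": "G0000"})
        )
        with pytest.raises(AmbiguityError):
            sv.distribution_panel(renamed, "G0000", "cluster")
        gene_way = sv.distribution_panel(renamed, "gene:G0000", "cluster")
        col_way = sv.distribution_panel(renamed, "column:G0000", "cluster")
        assert not np.allclose(
            gene_way.summary["median"], col_way.summary["median"]
        )

    def test_unknown_name_is_an_error(self, clustered):
        ds, _ = clustered
        with pytest.raises(SpecificationError):
            sv.distribution_panel(ds, "NOPE", "cluster")


class TestDownsample:
    def test_identity_when_everything_fits(self):
        assert sv.downsample_cells(100, 200, seed=1) == set(range(100))

    def test_deterministic_given_seed(self):
        a = sv.downsample_cells(1000, 100, seed=42)
        b = sv.downsample_cells(1000, 100, seed=42)
        assert a == b and len(a) == 100

    def test_inclusion_is_uniform_across_seeds(self):
        n, k, n_seeds = 2000, 200, 50
        freq = np.zeros(n)
        for seed in range(n_seeds):
            for i in sv.downsample_cells(n, k, seed=seed):
                freq[i] += 1
        freq /= n_seeds
        p = k / n
        se = np.sqrt(p * (1 - p) / n_seeds)
        assert freq.mean() == pytest.approx(p)  # each draw takes exactly k cells
        assert (np.abs(freq - p) <= 3 * se).mean() > 0.98


class TestSubsetConsistency:
    @pytest.mark.parametrize("trial", range(5))
    def test_summaries_commute_with_physical_subsetting(self, clustered, trial):
        ds, _ = clustered
        rng = np.random.default_rng(trial)
        size = int(rng.integers(10, ds.n_cells))
        cells = sorted(rng.choice(ds.n_cells, size=size, replace=False).tolist())
        physical = sv.subset_cells(ds, cells)
        genes = list(ds.gene_table["symbol"].iloc[:4])

        via_subset = sv.dot_plot_summary(ds, genes, "cluster", cells=cells).table
        direct = sv.dot_plot_summary(physical, genes, "cluster").table
        pd.testing.assert_frame_equal(via_subset, direct)

        via_subset = sv.composition_table(ds, "cluster", "condition", cells=cells)
        direct = sv.composition_table(physical, "cluster", "condition")
        pd.testing.assert_frame_equal(via_subset.counts, direct.counts)
        pd.testing.assert_frame_equal(via_subset.proportions, direct.proportions)

        via_subset = sv.distribution_panel(ds, genes[0], "cluster", cells=cells)
        direct = sv.distribution_panel(physical, genes[0], "cluster")
        pd.testing.assert_frame_equal(via_subset.summary, direct.summary)
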