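import numpy as np
import pytest
from scipy import stats

from otunet import (
    compare_alpha,
    log_relative_abundance,
    parse_lineage,
    prevalence_filter,
    read_otu_table,
    shannon,
    simpson,
)
from otunet.otu_table import OtuTableError

from .conftest import make_table, write_metadata_tsv, write_otu_tsv


class TestReadOtuTable:
    def test_parses_counts_and_greengenes_lineage(self, tmp_path):
        write_otu_tsv(
            tmp_path / "otu.tsv",
            [
                "OTU_1\t10\t0\tk__Bacteria; p__Firmicutes; g__Blautia",
                "OTU_2\t5\t3\tk__Bacteria; p__Bacteroidetes",
                "OTU_3\t0\t7\tk__Bacteria",
            ],
            comments=["# Constructed from biom file"],
        )
        write_metadata_tsv(tmp_path / "meta.tsv", ["S1", "S2"])
        table = read_otu_table(tmp_path / "otu.tsv", tmp_path / "meta.tsv")
        assert table.n_otus == 3 and table.n_samples == 2
        assert table.counts.loc["OTU_1", "S1"] == 10
        assert table.taxonomy.loc["OTU_1", "phylum"] == "Firmicutes"
        assert table.taxonomy.loc["OTU_1", "genus"] == "Blautia"
        assert table.taxonomy.loc["OTU_3", "phylum"] == "Unclassified"

    def test_silva_style_lineage(self):
        ranks = parse_lineage("D_0__Bacteria;D_1__Proteobacteria;D_5__Vibrio")
        assert ranks["phylum"] == "Proteobacteria"
        assert ranks["genus"] == "Vibrio"
        assert ranks["class"] == "Unclassified"

    def test_unparseable_lineage_keeps_otu(self, tmp_path):
        write_otu_tsv(
            tmp_path / "otu.tsv", ["OTU_1\t1\t2\tgibberish-without-prefixes"]
        )
        write_metadata_tsv(tmp_path / "meta.tsv", ["S1", "S2"])
        table = read_otu_table(tmp_path / "otu.tsv", tmp_path / "meta.tsv")
        assert (table.taxonomy.loc["OTU_1"] == "Unclassified").all()

    @pytest.mark.parametrize(
        "rows, header",
        [
            (["OTU_1\t1\t2\tk__B", "OTU_1\t3\t4\tk__B"], None),  # dup OTU
            (["OTU_1\t1\t2\tk__B"], "#OTU ID\tS1\tS1\ttaxonomy"),  # dup sample
            (["OTU_1\t-1\t2\tk__B"], None),  # negative count
            (["OTU_1\tx\t2\tk__B"], None),  # non-numeric
        ],
    )
    def test_malformed_tables_rejected(self, tmp_path, rows, header):
        kwargs = {"header": header} if header else {}
        write_otu_tsv(tmp_path / "otu.tsv", rows, **kwargs)
        write_metadata_tsv(tmp_path / "meta.tsv", ["S1", "S2"])
        with pytest.raises(OtuTableError):
            read_otu_table(tmp_path / "otu.tsv", tmp_path / "meta.tsv")

    def test_sample_without_metadata_rejected(self, tmp_path):
        write_otu_tsv(tmp_path / "otu.tsv", ["OTU_1\t1\t2\tk__B"])
        write_metadata_tsv(tmp_path / "meta.tsv", ["S1"])
        with pytest.raises(OtuTableError, match="metadata"):
            read_otu_table(tmp_path / "otu.tsv", tmp_path / "meta.tsv")


class TestPrevalenceFilter:
    def test_half_prevalence_boundary_kept(self):
        # prevalences 4/4, 3/4, 2/4, 1/4, 0/4 -> three survive at 0.5
        table = make_table(
            [
                [1, 1, 1, 1],
                [1, 1, 1, 0],
                [1, 1, 0, 0],
                [1, 0, 0, 0],
                [0, 0, 0, 0],
            ]
        )
        kept = prevalence_filter(table, 0.5)
        assert kept.otu_ids == ["OTU0", "OTU1", "OTU2"]

    def test_full_prevalence_keeps_only_everywhere_present(self):
        table = make_table([[1, 1, 1, 1], [1, 1, 1, 0]])
        assert prevalence_filter(table, 1.0).otu_ids == ["OTU0"]

    @pytest.mark.parametrize("min_prev", [0.01, 0.5, 1.0])
    def test_all_zero_otu_always_removed(self, min_prev):
        table = make_table([[1, 1, 1, 1], [0, 0, 0, 0]])
        assert "OTU1" not in prevalence_filter(table, min_prev).otu_ids

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(0)
        table = make_table(rng.integers(0, 3, size=(30, 8)))
        once = prevalence_filter(table, 0.5)
        assert prevalence_filter(once, 0.5).otu_ids == once.otu_ids
        sets = [
            set(prevalence_filter(table, p).otu_ids) for p in (0.25, 0.5, 0.75)
        ]
        assert sets[0] >= sets[1] >= sets[2]

    def test_empty_result_is_error(self):
        table = make_table([[1, 0, 0, 0]])
        with pytest.raises(OtuTableError, match="no OTUs survive"):
            prevalence_filter(table, 0.5)


class TestLogRelativeAbundance:
    def test_simple_column(self):
        table = make_table([[10, 10], [90, 90]])
        ab = log_relative_abundance(table)
        np.testing.assert_allclose(ab.values["S1"], [-1.0, np.log10(0.9)])

    def test_zero_replacement_rule(self):
        # min nonzero relative abundance 1/1000 -> pseudo 1e-5
        table = make_table([[1, 0], [999, 1000]])
        ab = log_relative_abundance(table)
        assert ab.zero_replacement == pytest.approx(1e-5)
        assert ab.values.loc["OTU0", "S1"] == pytest.approx(-5.0)

    def test_positive_table_ignores_zero_factor(self):
        table = make_table([[10, 20], [90, 80]])
        a = log_relative_abundance(table, zero_factor=0.01)
        b = log_relative_abundance(table, zero_factor=0.5)
        np.testing.assert_array_equal(a.values.values, b.values.values)

    def test_zero_total_sample_named(self):
        table = make_table([[1, 0], [2, 0]])
        with pytest.raises(OtuTableError, match="S1"):
            log_relative_abundance(table)

    def test_sample_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        table = make_table(rng.integers(0, 50, size=(10, 6)))
        ab = log_relative_abundance(table)
        perm = ["S3", "S0", "S5", "S1", "S4", "S2"]
        ab_perm = log_relative_abundance(table.subset_samples(perm))
        np.testing.assert_array_equal(
            ab.values[perm].values, ab_perm.values.values
        )

    def test_full_table_denominator(self):
        # relative abundance uses the unfiltered sample totals
        table = make_table([[50, 50], [50, 50], [0, 0]])
        filt = prevalence_filter(table, 0.5)
        ab = log_relative_abundance(filt, full_table=table)
        np.testing.assert_allclose(ab.values["S1"], [np.log10(0.5)] * 2)


class TestAlphaDiversity:
    @pytest.mark.parametrize(
        "p, base, expected",
        [
            ([0.25] * 4, 2, 2.0),
            ([1.0], 2, 0.0),
            ([0.5, 0.25, 0.25], 2, 1.5),
            ([0.25] * 4, np.e, np.log(4)),
        ],
    )
    def test_shannon_closed_forms(self, p, base, expected):
        assert shannon(p, base=base) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "p, expected",
        [([0.25] * 4, 0.75), ([1.0], 0.0), ([0.5, 0.5], 0.5)],
    )
    def test_simpson_closed_forms(self, p, expected):
        assert simpson(p) == pytest.approx(expected)

    def test_shannon_maximal_at_uniform(self):
        rng = np.random.default_rng(2)
        for s in range(2, 11):
            h_max = shannon([1.0 / s] * s)
            assert h_max == pytest.approx(np.log2(s))
            for _ in range(20):
                p = rng.dirichlet(np.ones(s))
                assert shannon(p) <= h_max + 1e-9

    def test_simpson_taxon_order_invariant(self):
        p = [0.4, 0.3, 0.2, 0.1]
        assert simpson(p) == pytest.approx(simpson(p[::-1]))

    def test_diversity_rejects_all_zero(self):
        with pytest.raises(ValueError):
            shannon([0, 0])
        with pytest.raises(ValueError):
            simpson([0, 0])


class TestCompareAlpha:
    def test_identical_groups(self):
        out = compare_alpha([[1, 2, 3], [1, 2, 3]])
        assert out["F"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 1, 12)
        out = compare_alpha([a, b])
        t, p_t = stats.ttest_ind(a, b)
        assert out["F"] == pytest.approx(t**2)
        assert out["p"] == pytest.approx(p_t)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_alpha([[1.0], [1, 2, 3]])

    def test_type_one_error_rate(self):
        # three groups drawn from one distribution: ~5% rejections
        rng = np.random.default_rng(4)
        rejections = sum(
            compare_alpha(list(rng.normal(size=(3, 6))))["p"] < 0.05
            for _ in range(1000)
        )
        assert 30 <= rejections <= 70
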