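import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nichebreadth.community_io import (FormatError, OTUTable, SampleMetadata,
                                       filter_rare, rarefy, read_otu_table,
                                       relative_abundances)


class TestReadWrite:
    def test_tsv_round_trip_is_bit_identical(self, tmp_path, tiny_table):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        tiny_table.write_tsv(p1)
        again = read_otu_table(p1, "tsv")
        again.write_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()
        np.testing.assert_array_equal(again.counts, tiny_table.counts)

    def test_simple_counts_round_trip(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("#OTU_ID\tsA\tsB\notu1\t3\t0\notu2\t1\t2\n")
        t = read_otu_table(path, "tsv")
        np.testing.assert_array_equal(t.counts, [[3, 0], [1, 2]])
        assert list(t.taxon_ids) == ["otu1", "otu2"]

    def test_all_zero_taxon_retained_on_read(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("#OTU_ID\tsA\tsB\notu1\t3\t2\notu2\t0\t0\n")
        t = read_otu_table(path, "tsv")
        assert t.n_taxa == 2  # filtering must be explicit

    def test_negative_cell_names_offender(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("#OTU_ID\tsA\tsB\notu1\t3\t-1\notu2\t1\t2\n")
        with pytest.raises(FormatError, match="otu1.*sB"):
            read_otu_table(path, "tsv")

    def test_duplicate_ids_rejected(self):
        with pytest.raises(FormatError, match="duplicate taxon"):
            OTUTable(["a", "a"], ["s1", "s2"], np.ones((2, 2), dtype=int))

    def test_taxonomy_column_preserved(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("#OTU_ID\tsA\ttaxonomy\notu1\t3\tk__Bacteria\n")
        t = read_otu_table(path, "tsv")
        assert t.taxonomy == {"otu1": "k__Bacteria"}

    def test_biom_hdf5_matches_tsv(self, tmp_path, tiny_table):
        import h5py
        from scipy.sparse import csr_matrix

        path = tmp_path / "t.biom"
        mat = csr_matrix(tiny_table.counts)
        with h5py.File(path, "w") as fh:
            fh.create_dataset("observation/ids",
                              data=[t.encode() for t in tiny_table.taxon_ids])
            fh.create_dataset("sample/ids",
                              data=[s.encode() for s in tiny_table.sample_ids])
            fh.create_dataset("observation/matrix/data", data=mat.data)
            fh.create_dataset("observation/matrix/indices", data=mat.indices)
            fh.create_dataset("observation/matrix/indptr", data=mat.indptr)
        t = read_otu_table(path, "biom")
        np.testing.assert_array_equal(t.counts, tiny_table.counts)
        assert list(t.sample_ids) == list(tiny_table.sample_ids)


class TestRelativeAbundances:
    def test_closed_forms(self):
        t = OTUTable(["a", "b", "c"], ["s1", "s2"],
                     np.array([[2, 1], [2, 0], [0, 0]]))
        p = relative_abundances(t)
        np.testing.assert_allclose(p.values[:, 0], [0.5, 0.5, 0.0])
        np.testing.assert_allclose(p.values[:, 1], [1.0, 0.0, 0.0])

    def test_random_columns_sum_to_one(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, size=(50, 10))
        counts[0] += 1  # no empty sample
        t = OTUTable([f"t{i}" for i in range(50)],
                     [f"s{j}" for j in range(10)], counts)
        p = relative_abundances(t)
        np.testing.assert_allclose(p.values.sum(axis=0), 1.0, atol=1e-12)

    def test_zero_total_sample_lists_ids(self):
        t = OTUTable(["a"], ["s1", "s2"], np.array([[3, 0]]))
        with pytest.raises(ValueError, match="s2"):
            relative_abundances(t)


class TestRarefy:
    def test_depth_equal_to_total_is_identity(self, tiny_table):
        depth = int(tiny_table.sample_sums().min())  # s3 has exactly 4 reads
        out = rarefy(tiny_table, depth, seed=1)
        j = list(out.sample_ids).index("s3")
        np.testing.assert_array_equal(
            out.counts[:, j],
            tiny_table.counts[:, list(tiny_table.sample_ids).index("s3")])
        assert np.all(out.sample_sums() == depth)

    def test_depth_one_leaves_single_read(self, tiny_table):
        out = rarefy(tiny_table, 1, seed=3)
        assert np.all(out.sample_sums() == 1)
        assert np.all((out.counts > 0).sum(axis=0) == 1)

    def test_hypergeometric_mean(self):
        # one sample (8000, 2000) rarefied to 1000: taxon-1 mean = 800
        t = OTUTable(["a", "b"], ["s"], np.array([[8000], [2000]]))
        draws = np.array([rarefy(t, 1000, seed=s).counts[0, 0]
                          for s in range(500)])
        var = 1000 * 0.8 * 0.2 * (10000 - 1000) / (10000 - 1)
        se = np.sqrt(var / 500)
        assert abs(draws.mean() - 800) <= 3 * se

    def test_taxon_identity_subset_and_reproducibility(self, tiny_table):
        a = rarefy(tiny_table, 4, seed=9)
        b = rarefy(tiny_table, 4, seed=9)
        np.testing.assert_array_equal(a.counts, b.counts)
        assert np.all(a.counts <= tiny_table.counts[:, [0, 1, 2, 3]])

    def test_shallow_samples_dropped_with_warning(self, tiny_table):
        with pytest.warns(UserWarning, match="below depth"):
            out = rarefy(tiny_table, 10, seed=0)  # s1 has 10, others fewer
        assert list(out.sample_ids) == ["s1", "s4"]

    def test_shallow_samples_error_when_requested(self, tiny_table):
        with pytest.raises(ValueError, match="below rarefaction depth"):
            rarefy(tiny_table, 10, seed=0, drop_below_depth=False)

    def test_all_samples_too_shallow(self, tiny_table):
        with pytest.raises(ValueError, match="fewer than"):
            rarefy(tiny_table, 10_000)


class TestFilterRare:
    def test_boundary_equality_retained(self):
        # taxon b: mean relative abundance exactly 0.25 -> retained at 0.25
        t = OTUTable(["a", "b"], ["s1", "s2"], np.array([[3, 3], [1, 1]]))
        kept, removed = filter_rare(None, t, threshold=0.25)
        assert list(kept.taxon_ids) == ["a", "b"] and removed == []
        kept, removed = filter_rare(None, t, threshold=0.2500001)
        assert removed == ["b"]

    def test_all_zero_taxon_removed(self):
        t = OTUTable(["a", "z"], ["s1", "s2"], np.array([[3, 3], [0, 0]]))
        kept, removed = filter_rare(None, t, threshold=1e-9)
        assert removed == ["z"]

    def test_constructed_split_counts(self):
        # 3764 taxa over 13 samples at depth 22310: mean relative abundance
        # = total/(13*22310), so totals <= 5 fall strictly below 2e-5
        rng = np.random.default_rng(5)
        n_rare, n_keep, n_samp, depth = 956, 2808, 13, 22310
        totals = np.concatenate([rng.integers(1, 6, n_rare),
                                 rng.integers(6, 90, n_keep)])
        counts = np.zeros((totals.size, n_samp), dtype=int)
        for i, tot in enumerate(totals):
            counts[i] = rng.multinomial(tot, np.full(n_samp, 1 / n_samp))
        pad = depth * n_samp  # top up columns so each sums to depth
        filler = depth - counts.sum(axis=0)
        assert np.all(filler >= 0)
        counts = np.vstack([counts, filler])
        t = OTUTable([f"t{i}" for i in range(totals.size)] + ["pad"],
                     [f"s{j}" for j in range(n_samp)], counts)
        kept, removed = filter_rare(None, t, threshold=2e-5)
        # brute-force oracle
        mean_ra = (counts / counts.sum(axis=0)).mean(axis=1)
        assert len(removed) == int((mean_ra < 2e-5).sum()) == n_rare
        assert kept.n_taxa == n_keep + 1

    def test_idempotent(self, tiny_table):
        once, _ = filter_rare(None, tiny_table, threshold=0.1)
        twice, removed = filter_rare(None, once, threshold=0.1)
        assert removed == []
        np.testing.assert_array_equal(once.counts, twice.counts)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1), st.integers(2, 8), st.integers(2, 6))
def test_rarefaction_columns_hit_depth_exactly(seed, n_taxa, n_samples):
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 40, size=(n_taxa, n_samples))
    counts[0] += 5
    t = OTUTable([f"t{i}" for i in range(n_taxa)],
                 [f"s{j}" for j in range(n_samples)], counts)
    depth = int(t.sample_sums().min())
    out = rarefy(t, depth, seed=seed)
    assert np.all(out.sample_sums() == depth)
    assert set(out.taxon_ids) <= set(t.taxon_ids)


def test_metadata_alignment_and_missing_sample(tiny_table, tiny_metadata):
    aligned = tiny_metadata.align_to(tiny_table)
    assert list(aligned.sample_ids) == list(tiny_table.sample_ids)
    dropped = SampleMetadata(tiny_metadata.frame.drop(index="s3").reset_index())
    with pytest.raises(KeyError, match="s3"):
        dropped.align_to(tiny_table)
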