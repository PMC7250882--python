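"""Expression container, cRPKM normalization and sample clustering."""

import numpy as np
import pandas as pd
import pytest

from coexmap import (ExpressionMatrix, average_replicates, cluster_samples,
                     compute_crpkm, filter_by_cv, read_expression_tsv,
                     standardize_genes, write_expression_tsv)
from conftest import make_matrix


def counts_matrix(values, samples, genes=None):
    return make_matrix(values, samples=samples, genes=genes, unit="counts")


class TestContainer:
    def test_rejects_negative_and_duplicates(self):
        with pytest.raises(ValueError, match="negative"):
            make_matrix([[1, -2]], unit="counts")
        df = pd.DataFrame([[1, 2], [3, 4]], index=["g", "g"], columns=["a", "b"])
        with pytest.raises(ValueError, match="duplicate gene"):
            ExpressionMatrix(df, pd.Series(["a", "b"], index=["a", "b"]))

    def test_every_sample_needs_condition(self):
        df = pd.DataFrame([[1, 2]], index=["g"], columns=["a", "b"])
        with pytest.raises(ValueError, match="condition"):
            ExpressionMatrix(df, pd.Series(["x"], index=["a"]))


class TestReadWrite:
    def test_round_trip(self, tmp_path):
        em = counts_matrix([[1, 2], [3, 4]], ["gill.1", "gill.2"])
        p, mp = tmp_path / "m.tsv", tmp_path / "meta.tsv"
        write_expression_tsv(em, p, mp)
        back = read_expression_tsv(p, mp)
        pd.testing.assert_frame_equal(back.values, em.values, check_names=False)
        assert list(back.condition) == list(em.condition)

    def test_toy_shape_and_name_convention(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("gene\tgill.1\tgill.2\ng1\t1\t2\ng2\t3\t4\n")
        em = read_expression_tsv(p)
        assert em.values.shape == (2, 2)
        assert set(em.condition) == {"gill"}
        assert list(em.replicate) == [1, 2]

    def test_duplicate_gene_row_errors(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("gene\ts1\ts2\ng1\t1\t2\ng1\t3\t4\n")
        with pytest.raises(ValueError, match="g1"):
            read_expression_tsv(p)

    def test_ragged_row_errors(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("gene\ts1\ts2\ng1\t1\t2\ng2\t3\n")
        with pytest.raises(ValueError, match="g2"):
            read_expression_tsv(p)


class TestCrpkm:
    def test_formula(self):
        # count 100, length 1 kb, sample total forced to 1e6
        vals = np.zeros((2, 1))
        vals[0, 0] = 100
        vals[1, 0] = 1e6 - 100
        em = counts_matrix(vals, ["s1"])
        lens = pd.Series([1.0, 2.0], index=em.genes)
        out = compute_crpkm(em, lens)
        assert out.values.iloc[0, 0] == pytest.approx(100.0)
        assert out.unit == "cRPKM"

    def test_zero_count_stays_zero(self):
        em = counts_matrix([[0], [10]], ["s1"])
        out = compute_crpkm(em, pd.Series([5.0, 1.0], index=em.genes))
        assert out.values.iloc[0, 0] == 0.0

    def test_per_million_scale_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(1, 100, size=(20, 4)).astype(float)
        em = counts_matrix(vals, [f"s{j}" for j in range(4)])
        lens = pd.Series(rng.uniform(0.5, 3, 20), index=em.genes)
        doubled = counts_matrix(vals * 2, [f"s{j}" for j in range(4)],
                                genes=em.genes)
        a = compute_crpkm(em, lens).values
        b = compute_crpkm(doubled, lens).values
        pd.testing.assert_frame_equal(a, b)

    def test_errors(self):
        em = counts_matrix([[1], [2]], ["s1"])
        with pytest.raises(ValueError, match="missing"):
            compute_crpkm(em, pd.Series([1.0], index=[em.genes[0]]))
        zero = counts_matrix([[0], [0]], ["s1"])
        with pytest.raises(ValueError, match="zero total"):
            compute_crpkm(zero, pd.Series([1.0, 1.0], index=zero.genes))
        crpkm = make_matrix([[1.0]], unit="cRPKM")
        with pytest.raises(ValueError, match="counts"):
            compute_crpkm(crpkm, pd.Series([1.0], index=crpkm.genes))


class TestReplicatesAndFilters:
    def test_average_replicates(self):
        df = pd.DataFrame([[1.0, 3.0, 7.0]], index=["g"],
                          columns=["gut.1", "gut.2", "brain.1"])
        cond = pd.Series(["gut", "gut", "brain"], index=df.columns)
        em = ExpressionMatrix(df, cond, unit="cRPKM")
        avg = average_replicates(em)
        assert avg.values.loc["g", "gut"] == 2.0
        assert list(avg.samples) == ["gut", "brain"]  # metadata order

    def test_single_replicate_identity(self):
        em = make_matrix([[1, 2], [3, 4]], samples=["a", "b"])
        avg = average_replicates(em)
        assert np.allclose(avg.values.to_numpy(), em.values.to_numpy())

    def test_cv_examples(self):
        em = make_matrix([[2, 2, 2], [0, 0, 10], [0, 0, 0]])
        kept = filter_by_cv(em, 1.0)
        # [0,0,10]: mean 10/3, sample sd 5.7735 -> cv 1.732
        assert kept.genes == ["g1"]
        assert filter_by_cv(em, 0.0).genes == ["g0", "g1"]  # zero-mean gone

    def test_cv_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        em = make_matrix(rng.lognormal(1, 1, size=(50, 6)))
        low = set(filter_by_cv(em, 0.5).genes)
        high = set(filter_by_cv(em, 1.5).genes)
        assert high <= low


class TestStandardize:
    def test_hand_row(self):
        em = make_matrix([[1, 2, 3]])
        out = standardize_genes(em)
        assert np.allclose(out.values.to_numpy(), [[-1, 0, 1]])
        assert out.unit == "zscore"

    def test_constant_row_dropped_with_warning(self):
        em = make_matrix([[5, 5, 5], [1, 2, 3]])
        with pytest.warns(UserWarning, match="constant"):
            out = standardize_genes(em)
        assert out.genes == ["g1"]

    def test_rows_centered_and_idempotent(self):
        rng = np.random.default_rng(4)
        em = make_matrix(rng.normal(size=(30, 8)), unit="zscore")
        out = standardize_genes(em)
        assert np.abs(out.values.mean(axis=1)).max() < 1e-12
        twice = standardize_genes(out)
        assert np.abs(twice.values - out.values).to_numpy().max() < 1e-10


def newick_siblings(nwk: str, a: str, b: str) -> bool:
    import dendropy
    tree = dendropy.Tree.get(data=nwk, schema="newick",
                             preserve_underscores=True)
    leaf = next(l for l in tree.leaf_node_iter() if l.taxon.label == a)
    sibs = {l.taxon.label for l in leaf.parent_node.leaf_iter()}
    return sibs == {a, b}


class TestClusterSamples:
    def test_correlated_pair_are_siblings(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=200)
        vals = np.column_stack([x, x + rng.normal(0, 0.1, 200),
                                rng.normal(size=200)])
        em = make_matrix(np.abs(vals), samples=["s1", "s2", "s3"])
        nwk = cluster_samples(em, log_transform=False)
        assert newick_siblings(nwk, "s1", "s2")

    def test_duplicated_samples_merge_at_height_zero(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(1, 10, size=50)
        vals = np.column_stack([x, x, rng.uniform(1, 10, 50)])
        em = make_matrix(vals, samples=["a", "b", "c"])
        nwk = cluster_samples(em)
        assert newick_siblings(nwk, "a", "b")
        import dendropy
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        leaf = next(l for l in tree.leaf_node_iter() if l.taxon.label == "a")
        assert leaf.edge.length < 1e-9  # merged at height ~0

    def test_zero_variance_sample_errors(self):
        vals = np.column_stack([np.ones(10), np.arange(10.0), np.arange(10.0) ** 2])
        em = make_matrix(vals, samples=["flat", "b", "c"])
        with pytest.raises(ValueError, match="flat"):
            cluster_samples(em, log_transform=False)
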