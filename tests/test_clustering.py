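import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from sklearn.metrics import adjusted_rand_score

from lyschase.clustering import (
    abundance_cluster,
    linkage_to_newick,
    longevity_cluster,
    ward_linkage,
    zscore_rows,
)
from lyschase.synthetic import generate_aging_abundance, generate_longevity_profiles


class TestZscoreRows:
    def test_hand_example(self):
        z = zscore_rows(pd.DataFrame([[1.0, 2.0, 3.0]], index=["P1"]))
        np.testing.assert_allclose(z.iloc[0], [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_already_standardized_unchanged(self):
        row = np.array([-1.0, 0.0, 1.0]) / np.std([-1.0, 0.0, 1.0])
        z = zscore_rows(pd.DataFrame([row]))
        np.testing.assert_allclose(z.iloc[0], row, atol=1e-12)

    def test_every_row_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        z = zscore_rows(pd.DataFrame(rng.normal(2, 5, size=(20, 6))))
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=0), 1.0, atol=1e-12)

    def test_constant_rows_dropped_with_warning(self):
        df = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "ok"])
        with pytest.warns(UserWarning, match="constant"):
            z = zscore_rows(df)
        assert list(z.index) == ["ok"]


class TestLongevityCluster:
    def test_planted_archetypes_recovered(self):
        mat, truth = generate_longevity_profiles(n_per_archetype=50, seed=4)
        cl = longevity_cluster(mat, k=3)
        ref = truth.set_index("protein_id").loc[cl.protein_id, "archetype"]
        assert adjusted_rand_score(ref, cl.label) >= 0.9

    def test_labels_follow_retention_order(self):
        mat, truth = generate_longevity_profiles(n_per_archetype=20, seed=4)
        cl = longevity_cluster(mat, k=3).set_index("protein_id")
        merged = mat.mean(axis=1).to_frame("mean").join(cl)
        means = merged.groupby("label")["mean"].mean()
        assert means["high"] > means["intermediate"] > means["low"]

    def test_scale_invariance_percent_vs_fraction(self):
        mat, _ = generate_longevity_profiles(n_per_archetype=15, seed=4)
        a = longevity_cluster(mat, k=3)
        b = longevity_cluster(mat / 100.0, k=3)
        assert adjusted_rand_score(a.label, b.label) == pytest.approx(1.0)

    def test_degenerate_identical_rows_still_returns_k_labels(self):
        mat = pd.DataFrame(np.full((6, 4), 50.0),
                           columns=[42.0, 63.0, 84.0, 210.0],
                           index=[f"P{i}" for i in range(6)])
        cl = longevity_cluster(mat, k=3)
        assert len(cl) == 6
        assert set(cl.label) <= {"high", "intermediate", "low"}

    def test_k_larger_than_n_rejected(self):
        mat, _ = generate_longevity_profiles(n_per_archetype=1, seed=0)
        with pytest.raises(ValueError):
            longevity_cluster(mat, k=10)

    def test_early_columns_excluded(self):
        mat, _ = generate_longevity_profiles(n_per_archetype=5, seed=0)
        mat.insert(0, 7.0, np.full(len(mat), 99.0))  # pre-6-week column
        cl = longevity_cluster(mat, k=3)
        assert len(cl) == len(mat)


class TestAbundanceCluster:
    def make_z(self, seed=3, n_per=50):
        tab, truth = generate_aging_abundance(n_per_archetype=n_per, seed=seed)
        wide = tab.groupby(["protein_id", "age_days"])["rel_abundance"].mean().unstack()
        return zscore_rows(wide), truth

    def test_planted_trends_recovered(self):
        z, truth = self.make_z()
        cl = abundance_cluster(z, k=6)
        ref = truth.set_index("protein_id").loc[cl.protein_id, "archetype"]
        assert adjusted_rand_score(ref, cl.label) >= 0.9

    def test_k1_single_cluster(self):
        z, _ = self.make_z(n_per=5)
        cl = abundance_cluster(z, k=1)
        assert set(cl.label) == {1}

    def test_row_permutation_invariance(self):
        z, _ = self.make_z(n_per=10)
        a = abundance_cluster(z, k=6)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(z))
        b = abundance_cluster(z.iloc[perm], k=6)
        joined = a.set_index("protein_id").join(b.set_index("protein_id"),
                                                lsuffix="_a", rsuffix="_b")
        assert adjusted_rand_score(joined.label_a, joined.label_b) == pytest.approx(1.0)


class TestDendrogram:
    def test_ward_merge_heights_nondecreasing(self):
        mat, _ = generate_longevity_profiles(n_per_archetype=10, seed=1)
        link = ward_linkage(mat.to_numpy())
        assert np.all(np.diff(link[:, 2]) >= -1e-12)

    def test_newick_export_parses(self):
        from io import StringIO

        from Bio import Phylo

        X = np.array([[0.0, 1.0], [0.1, 1.1], [5.0, 5.0], [5.1, 5.2]])
        link = linkage(X, method="ward")
        nwk = linkage_to_newick(link, ["a", "b", "c", "d"])
        tree = Phylo.read(StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["a", "b", "c", "d"]
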