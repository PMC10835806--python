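"""Correlation/VIF, confusion matrices, embeddings and variety clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cpdus.varietyspace import (
    confusion,
    pearson_report,
    tsne_summary,
    variety_clustering,
    vif_report,
)


def _frame(arrays: dict) -> pd.DataFrame:
    return pd.DataFrame(arrays)


class TestPearson:
    def test_affine_relation_is_perfect(self):
        x = np.linspace(0, 1, 50)
        rep = pearson_report(_frame({"T1": x, "T2": 2 * x + 1, "T3": np.cos(9 * x)}))
        assert rep.matrix.loc["T1", "T2"] == pytest.approx(1.0)

    def test_independent_columns_uncorrelated(self):
        rng = np.random.default_rng(0)
        rep = pearson_report(
            _frame({f"T{i}": rng.standard_normal(1000) for i in range(1, 5)})
        )
        off = rep.matrix.values[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.1
        assert rep.n_flagged == 0

    def test_threshold_flags_exactly_strong_pairs(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(500)
        t = _frame(
            {
                "T1": x,
                "T2": 0.9 * x + 0.44 * rng.standard_normal(500),  # r ~ 0.9
                "T3": rng.standard_normal(500),
            }
        )
        rep = pearson_report(t, threshold=0.5)
        corr = np.corrcoef(t.T.values)
        expected = {
            tuple(sorted((f"T{i+1}", f"T{j+1}")))
            for i in range(3)
            for j in range(i + 1, 3)
            if abs(corr[i, j]) >= 0.5
        }
        got = {tuple(sorted((a, b))) for a, b in rep.flagged[["trait_a", "trait_b"]].values}
        assert got == expected

    def test_constant_column_warned_and_zeroed(self):
        t = _frame({"T1": np.arange(10.0), "T2": np.ones(10)})
        with pytest.warns(UserWarning):
            rep = pearson_report(t)
        assert rep.matrix.loc["T1", "T2"] == 0.0


class TestVIF:
    def test_orthogonal_columns_have_unit_vif(self):
        rng = np.random.default_rng(2)
        q, _ = np.linalg.qr(rng.standard_normal((100, 3)))
        rep = vif_report(_frame({"T1": q[:, 0], "T2": q[:, 1], "T3": q[:, 2]}))
        assert np.allclose(rep.vif.values, 1.0, atol=0.05)
        assert rep.flagged == []

    def test_exact_collinearity_is_inf_sentinel(self):
        rng = np.random.default_rng(3)
        x1, x2 = rng.standard_normal((2, 60))
        rep = vif_report(_frame({"T1": x1, "T2": x2, "T3": x1 + x2}))
        assert np.isinf(rep.vif["T3"])

    def test_matches_normal_equations_oracle(self):
        """VIF of a nearly collinear column equals 1/(1-R^2) with R^2 from an
        explicit least-squares solve, to 6 significant digits."""
        rng = np.random.default_rng(4)
        x1, x2 = rng.standard_normal((2, 200))
        x3 = x1 + x2 + 0.01 * rng.standard_normal(200)
        rep = vif_report(_frame({"T1": x1, "T2": x2, "T3": x3}))
        A = np.column_stack([np.ones(200), x1, x2])
        beta = np.linalg.solve(A.T @ A, A.T @ x3)
        resid = x3 - A @ beta
        r2 = 1 - resid @ resid / ((x3 - x3.mean()) @ (x3 - x3.mean()))
        assert rep.vif["T3"] == pytest.approx(1.0 / (1.0 - r2), rel=1e-6)


class TestConfusion:
    def test_perfect_predictions(self):
        y = np.array([1, 1, 2, 2, 3, 3])
        rep = confusion(y, y)
        assert rep.accuracy == 100.0
        assert (np.diag(rep.matrix) == 2).all()
        assert rep.most_confused.empty

    def test_single_known_error(self):
        truth = np.array([1, 1, 2, 2, 3, 3])
        pred = np.array([1, 1, 2, 3, 3, 3])
        rep = confusion(pred, truth)
        assert rep.matrix.loc[2, 3] == 1
        assert rep.accuracy == pytest.approx(100 * 5 / 6)
        assert rep.per_class_recall[2] == pytest.approx(0.5)
        assert tuple(rep.most_confused.iloc[0][["truth", "predicted"]]) == (2, 3)

    def test_accuracy_equals_trace_over_total(self):
        rng = np.random.default_rng(5)
        truth = rng.integers(0, 4, 200)
        pred = np.where(rng.random(200) < 0.8, truth, rng.integers(0, 4, 200))
        rep = confusion(pred, truth)
        assert rep.accuracy == pytest.approx(
            100.0 * np.trace(rep.matrix.values) / rep.matrix.values.sum()
        )
        assert (rep.matrix.sum(axis=1).values == np.bincount(truth, minlength=4)).all()

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.array([1, 9]), np.array([1, 2]))


class TestTsneSummary:
    def test_far_clouds_well_separated(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 0.5, (60, 4)), rng.normal(30, 0.5, (60, 4))])
        t = pd.DataFrame(X, columns=["T1", "T2", "T3", "T4"])
        labels = np.array([0] * 60 + [1] * 60)
        summ = tsne_summary(t, labels, seed=0)
        assert summ.method == "tsne"
        inter = summ.inter_centroid.loc[0, 1]
        assert inter > 5 * summ.intra_radius.mean()
        assert summ.overlap_pairs == []

    def test_duplicated_class_flagged_as_overlap(self):
        rng = np.random.default_rng(7)
        X = rng.normal(0, 1, (40, 3))
        t = pd.DataFrame(np.vstack([X, X]), columns=["T1", "T2", "T3"])
        labels = np.array([0] * 40 + [1] * 40)
        summ = tsne_summary(t, labels, seed=0)
        assert (0, 1) in summ.overlap_pairs

    def test_summary_is_seed_deterministic(self):
        rng = np.random.default_rng(8)
        t = pd.DataFrame(rng.standard_normal((80, 3)), columns=["T1", "T2", "T3"])
        labels = np.tile([0, 1], 40)
        s1 = tsne_summary(t, labels, seed=3)
        s2 = tsne_summary(t, labels, seed=3)
        pd.testing.assert_series_equal(s1.intra_radius, s2.intra_radius)

    def test_small_sample_falls_back_to_pca(self):
        rng = np.random.default_rng(9)
        t = pd.DataFrame(rng.standard_normal((20, 3)), columns=["T1", "T2", "T3"])
        with pytest.warns(UserWarning):
            summ = tsne_summary(t, np.tile([0, 1], 10), seed=0)
        assert summ.method == "pca"


class TestVarietyClustering:
    def test_recovers_built_in_colour_groups(self):
        """K-means on variety means of the inner-perianth colour block finds
        the three constructed groups."""
        from cpdus.synthetic_flora import sample_trait_table

        colour_cols = [f"F{i}" for i in range(34, 43)]
        for seed in range(3):
            t = sample_trait_table(12, 20, seed=seed)
            vc = variety_clustering(t, k=3, seed=seed, columns=colour_cols)
            groups = [(v - 1) % 3 for v in vc.assignments.index]
            assert adjusted_rand_score(groups, vc.assignments.values) > 0.8

    def test_k_equal_to_varieties_gives_singletons(self):
        from cpdus.synthetic_flora import sample_trait_table

        t = sample_trait_table(5, 10, seed=1)
        vc = variety_clustering(t, k=5, seed=0)
        assert vc.assignments.nunique() == 5

    def test_k_above_varieties_rejected(self):
        from cpdus.synthetic_flora import sample_trait_table

        t = sample_trait_table(4, 5, seed=2)
        with pytest.raises(ValueError):
            variety_clustering(t, k=9)

    def test_newick_round_trip(self):
        from io import StringIO

        from skbio.tree import TreeNode

        from cpdus.synthetic_flora import sample_trait_table

        t = sample_trait_table(6, 10, seed=3)
        vc = variety_clustering(t, k=3, seed=0)
        tree = TreeNode.read(StringIO(vc.newick))
        tips = {tip.name for tip in tree.tips()}
        assert tips == {str(v) for v in sorted(t["variety_id"].unique())}
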