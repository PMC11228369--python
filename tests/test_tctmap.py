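import numpy as np
import pandas as pd
import pytest
from scipy.stats import ttest_ind

from scexemplar.grouping import GroupAssignment
from scexemplar.synthdata import simulate_survival
from scexemplar.tctmap import (
    adjusted_rand_index,
    cluster_survival_comparisons,
    differential_exemplars,
    layout_samples,
    spatial_clusters,
)


def two_block_scores(rng, n_per_block=50, spread=1.0):
    a = np.hstack([rng.normal(10, spread, (n_per_block, 3)),
                   rng.normal(0, spread, (n_per_block, 5))])
    b = np.hstack([rng.normal(0, spread, (n_per_block, 5)),
                   rng.normal(10, spread, (n_per_block, 3))])
    scores = pd.DataFrame(
        np.vstack([a, b]), index=[f"p{i}" for i in range(2 * n_per_block)]
    )
    truth = pd.Series(["a"] * n_per_block + ["b"] * n_per_block, index=scores.index)
    return scores, truth


class TestLayout:
    def test_deterministic_given_seed(self, rng):
        scores, _ = two_block_scores(rng, 20)
        a = layout_samples(scores, seed=4)
        b = layout_samples(scores, seed=4)
        pd.testing.assert_frame_equal(a.coords, b.coords)

    def test_blocks_separate_in_the_plane(self, rng):
        scores, truth = two_block_scores(rng, 30)
        coords = layout_samples(scores, seed=0).coords.to_numpy()
        from scipy.spatial.distance import cdist

        within_a = cdist(coords[:30], coords[:30]).mean()
        within_b = cdist(coords[30:], coords[30:]).mean()
        between = cdist(coords[:30], coords[30:]).mean()
        assert between > max(within_a, within_b)

    def test_duplicated_samples_land_together(self, rng):
        scores, _ = two_block_scores(rng, 20)
        dup = scores.copy()
        dup.loc["p_dup"] = scores.iloc[0]
        layout = layout_samples(dup, seed=1)
        coords = layout.coords
        d = np.linalg.norm(coords.loc["p_dup"] - coords.iloc[0])
        diameter = np.linalg.norm(
            coords.max(axis=0).to_numpy() - coords.min(axis=0).to_numpy()
        )
        assert d < 0.05 * diameter

    def test_constant_matrix_rejected(self):
        scores = pd.DataFrame(np.ones((12, 4)), index=[f"p{i}" for i in range(12)])
        with pytest.raises(ValueError, match="constant"):
            layout_samples(scores, seed=0)

    def test_too_few_samples_rejected(self, rng):
        scores = pd.DataFrame(rng.random((5, 4)))
        with pytest.raises(ValueError, match="10 samples"):
            layout_samples(scores, seed=0)


class TestSpatialClusters:
    def test_planted_blobs_recovered(self, rng):
        scores, truth = two_block_scores(rng, 50)
        layout = layout_samples(scores, seed=0)
        cl = spatial_clusters(layout, min_cluster_size=20)
        assert cl.n_clusters == 2
        assert cl.n_unassigned == 0
        assert adjusted_rand_index(cl.labels, truth) == 1.0

    def test_min_cluster_size_above_n_all_unassigned(self, rng):
        scores, _ = two_block_scores(rng, 10)
        layout = layout_samples(scores, seed=0)
        cl = spatial_clusters(layout, min_cluster_size=100)
        assert cl.n_unassigned == 20


class TestAri:
    def test_identical_labelings(self):
        a = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        assert adjusted_rand_index(a, a) == 1.0

    def test_label_permutation_invariance(self):
        a = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        b = a.map({"x": "q", "y": "r"})
        assert adjusted_rand_index(a, b) == 1.0

    def test_random_shuffles_near_zero(self, rng):
        labels = pd.Series(["x"] * 10 + ["y"] * 10, index=[f"s{i}" for i in range(20)])
        aris = []
        for _ in range(100):
            shuffled = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
            aris.append(adjusted_rand_index(labels, shuffled))
        # at n=20 a shuffle can reproduce the partition outright (p ~ 1e-5),
        # which correctly scores 1; the bulk of the null must sit near zero
        assert np.quantile(np.abs(aris), 0.9) < 0.2
        assert abs(np.mean(aris)) < 0.05

    def test_unassigned_excluded(self):
        a = pd.Series(["x", "x", "unassigned", "y"], index=list("abcd"))
        b = pd.Series(["q", "q", "q", "r"], index=list("abcd"))
        assert adjusted_rand_index(a, b) == 1.0

    def test_single_cluster_in_both_defined_as_one(self):
        a = pd.Series(["x", "x", "x"], index=list("abc"))
        b = pd.Series(["y", "y", "y"], index=list("abc"))
        assert adjusted_rand_index(a, b) == 1.0


class TestDifferentialExemplars:
    def test_strongly_elevated_exemplar_ranked_first(self, rng):
        scores = pd.DataFrame(
            rng.normal(0, 1, (40, 6)),
            index=[f"s{i}" for i in range(40)],
            columns=[f"X{j}" for j in range(6)],
        )
        scores.loc[scores.index[:20], "X3"] += 10.0
        out = differential_exemplars(scores, list(scores.index[:20]),
                                     list(scores.index[20:]))
        assert out.iloc[0]["exemplar"] == "X3"
        assert out.iloc[0]["direction"] == "highest"

    def test_statistics_match_scipy_oracle(self, rng):
        scores = pd.DataFrame(
            rng.normal(0, 1, (30, 8)),
            index=[f"s{i}" for i in range(30)],
            columns=[f"X{j}" for j in range(8)],
        )
        a, b = list(scores.index[:15]), list(scores.index[15:])
        out = differential_exemplars(scores, a, b).set_index("exemplar")
        for ex in out.index:
            t, p = ttest_ind(scores.loc[a, ex], scores.loc[b, ex], equal_var=True)
            assert out.loc[ex, "t"] == pytest.approx(t)
            assert out.loc[ex, "p"] == pytest.approx(p)

    def test_identical_clusters_statistics_near_zero(self, rng):
        base = rng.normal(0, 1, (10, 7))
        scores = pd.DataFrame(
            np.vstack([base, base]),
            index=[f"s{i}" for i in range(20)],
            columns=[f"X{j}" for j in range(7)],
        )
        out = differential_exemplars(scores, list(scores.index[:10]),
                                     list(scores.index[10:]))
        assert np.allclose(out["t"], 0.0)

    def test_small_clusters_rejected(self, rng):
        scores = pd.DataFrame(rng.normal(0, 1, (6, 3)),
                              index=[f"s{i}" for i in range(6)])
        with pytest.raises(ValueError, match=">= 3"):
            differential_exemplars(scores, ["s0", "s1"], ["s2", "s3", "s4"])


class TestClusterSurvival:
    def _setup(self, rng, hr, n=100):
        ids = [f"s{i}" for i in range(2 * n)]
        labels = pd.Series(["c0"] * n + ["c1"] * n, index=ids)
        diseases = pd.Series("gbm", index=ids)
        grp = pd.Series(np.where(labels == "c1", "up", "down"), index=ids)
        surv = simulate_survival(grp, hr=hr, censor_frac=0.2, seed=9)
        surv["subtype"] = rng.choice(["m1", "m2"], 2 * n)

        class FakeClustering:
            pass

        cl = FakeClustering()
        cl.labels = labels
        return cl, diseases, surv

    def test_planted_cluster_difference_detected(self, rng):
        cl, diseases, surv = self._setup(rng, hr=3.0)
        results = cluster_survival_comparisons(cl, diseases, surv)
        assert len(results) == 1
        assert results[0].p_value < 0.05
        assert results[0].hazard_ratio > 1.5

    def test_null_difference_hr_near_one(self, rng):
        cl, diseases, surv = self._setup(rng, hr=1.0)
        results = cluster_survival_comparisons(cl, diseases, surv)
        assert 0.6 < results[0].hazard_ratio < 1.6

    def test_below_five_samples_no_comparison(self, rng):
        cl, diseases, surv = self._setup(rng, hr=3.0)
        # second cluster holds only 4 samples of a second disease
        diseases.iloc[100:104] = "lgg"
        diseases.iloc[:4] = "lgg"  # main cluster still qualifies elsewhere
        results = cluster_survival_comparisons(cl, diseases, surv)
        assert all(r.cohort != "lgg" for r in results)
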