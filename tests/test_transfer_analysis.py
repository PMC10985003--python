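"""Transfer decomposition, clustering, and group-comparison statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import methplier as mp
from methplier.transfer_analysis import LoadingResult


class TestTransferLoadings:
    def test_equals_update_b_on_same_inputs(self, rng):
        Z = pd.DataFrame(np.abs(rng.normal(size=(12, 3))),
                         index=[f"f{i}" for i in range(12)], columns=["LV1", "LV2", "LV3"])
        D = pd.DataFrame(rng.normal(size=(12, 5)), index=Z.index,
                         columns=[f"s{i}" for i in range(5)])
        res = mp.transfer_loadings(D, Z, lambda2=0.3)
        oracle = mp.update_B(D.to_numpy(), Z.to_numpy(), 0.3)
        np.testing.assert_array_equal(res.B.to_numpy(), oracle)

    def test_small_lambda_recovers_true_loadings(self, rng):
        Z = pd.DataFrame(np.abs(rng.normal(size=(20, 3))),
                         index=[f"f{i}" for i in range(20)])
        Bt = rng.normal(size=(3, 6))
        D = pd.DataFrame(Z.to_numpy() @ Bt, index=Z.index)
        res = mp.transfer_loadings(D, Z, lambda2=1e-10)
        np.testing.assert_allclose(res.B.to_numpy(), Bt, atol=1e-6)

    def test_single_sample_matches_columnwise_solve(self, rng):
        Z = pd.DataFrame(np.abs(rng.normal(size=(10, 2))),
                         index=[f"f{i}" for i in range(10)])
        d = rng.normal(size=10)
        D = pd.DataFrame({"only": d}, index=Z.index)
        res = mp.transfer_loadings(D, Z, lambda2=0.5)
        Zm = Z.to_numpy()
        oracle = np.linalg.solve(Zm.T @ Zm + 0.5 * np.eye(2), Zm.T @ d)
        np.testing.assert_allclose(res.B["only"].to_numpy(), oracle, atol=1e-10)

    def test_sample_permutation_equivariance(self, rng):
        Z = pd.DataFrame(np.abs(rng.normal(size=(8, 2))),
                         index=[f"f{i}" for i in range(8)])
        D = pd.DataFrame(rng.normal(size=(8, 4)), index=Z.index,
                         columns=list("abcd"))
        res = mp.transfer_loadings(D, Z, lambda2=0.2)
        res_perm = mp.transfer_loadings(D[list("dcab")], Z, lambda2=0.2)
        np.testing.assert_allclose(
            res_perm.B[list("abcd")].to_numpy(), res.B.to_numpy(), atol=1e-12
        )

    def test_label_mismatch_lists_offenders(self, rng):
        Z = pd.DataFrame(np.abs(rng.normal(size=(6, 2))),
                         index=[f"f{i}" for i in range(6)])
        D = pd.DataFrame(rng.normal(size=(6, 2)),
                         index=[f"g{i}" for i in range(6)])
        with pytest.raises(ValueError, match="first offenders"):
            mp.transfer_loadings(D, Z, lambda2=0.1)

    def test_model_transfer_standardizes_with_training_stats(self, default_fit):
        K, D, model = default_fit
        res = mp.transfer_loadings(D, model)
        assert isinstance(res, LoadingResult)
        assert res.provenance["k"] == model.k
        Ds = D.values.sub(model.row_means, axis=0).div(model.row_sds, axis=0)
        expected = mp.update_B(
            Ds.to_numpy(), model.Z.to_numpy(), model.lambdas["lambda2"]
        )
        np.testing.assert_array_equal(res.B.to_numpy(), expected)


class TestClustering:
    def blobs(self, rng, n=20, sep=5.0):
        X = np.vstack([
            rng.normal(0, 0.3, size=(n // 2, 2)),
            rng.normal(sep, 0.3, size=(n - n // 2, 2)),
        ])
        labels = np.array([0] * (n // 2) + [1] * (n - n // 2))
        df = pd.DataFrame(X, index=[f"s{i}" for i in range(n)])
        return df, labels

    @staticmethod
    def agree_up_to_swap(a, b):
        a, b = np.asarray(a), np.asarray(b)
        return np.all(a == b) or np.all(a == 1 - b)

    def test_hca_separates_blobs(self, rng):
        X, truth = self.blobs(rng)
        labels, link = mp.hca_clusters(X, 2)
        assert self.agree_up_to_swap(labels.to_numpy(), truth)
        assert link.shape == (len(X) - 1, 4)

    def test_hca_merge_heights_match_naive_ward(self, rng):
        """Agglomeration order on 6 points equals a brute-force Ward oracle."""
        X = pd.DataFrame(rng.normal(size=(6, 2)), index=list("abcdef"))
        _, link = mp.hca_clusters(X, 2)

        # naive O(n^3) Ward agglomeration: merge the pair minimizing the
        # increase in within-cluster sum of squares
        clusters = {i: [i] for i in range(6)}
        pts = X.to_numpy()
        heights = []
        while len(clusters) > 1:
            best = None
            for i, j in itertools.combinations(sorted(clusters), 2):
                a, b = pts[clusters[i]], pts[clusters[j]]
                na, nb = len(a), len(b)
                d2 = ((a.mean(0) - b.mean(0)) ** 2).sum()
                cost = (na * nb) / (na + nb) * d2
                if best is None or cost < best[0]:
                    best = (cost, i, j)
            cost, i, j = best
            heights.append(np.sqrt(2 * cost))  # scipy's ward height convention
            new_key = max(clusters) + 1
            clusters[new_key] = clusters.pop(i) + clusters.pop(j)
        np.testing.assert_allclose(sorted(link[:, 2]), sorted(heights), atol=1e-10)

    def test_hca_duplicate_labels_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(4, 2)), index=["a", "a", "b", "c"])
        with pytest.raises(ValueError, match="duplicate"):
            mp.hca_clusters(X, 2)

    def test_kmeans_single_cluster(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 2)))
        labels = mp.kmeans_clusters(X, 1, seed=0)
        assert set(labels) == {0}

    def test_kmeans_matches_exhaustive_partition(self, rng):
        X, _ = self.blobs(rng, n=8)
        labels = mp.kmeans_clusters(X, 2, seed=3)

        def wss(assign):
            s = 0.0
            pts = X.to_numpy()
            for c in (0, 1):
                sel = pts[np.asarray(assign) == c]
                if len(sel):
                    s += ((sel - sel.mean(0)) ** 2).sum()
            return s

        best = min(
            wss(assign)
            for assign in itertools.product((0, 1), repeat=8)
            if 0 < sum(assign) < 8
        )
        np.testing.assert_allclose(wss(labels.to_numpy()), best, rtol=1e-10)

    def test_kmeans_label_permutation_stability(self, rng):
        X, truth = self.blobs(rng, n=12)
        l1 = mp.kmeans_clusters(X, 2, seed=1)
        perm = X.sample(frac=1.0, random_state=4)
        l2 = mp.kmeans_clusters(perm, 2, seed=1).loc[X.index]
        assert self.agree_up_to_swap(l1.to_numpy(), l2.to_numpy())


class TestUmap:
    def test_embedding_contract(self, rng):
        """Determinism, duplicate invariance and blob separation in one pass."""
        n = 40
        X = np.vstack([
            rng.normal(0, 0.25, size=(n // 2, 4)),
            rng.normal(10, 0.25, size=(n // 2, 4)),  # between/within ratio ~20
        ])
        X[1] = X[0]  # planted duplicate pair
        df = pd.DataFrame(X, index=[f"s{i}" for i in range(n)])
        emb1 = mp.umap_embed(df, seed=5)
        emb2 = mp.umap_embed(df, seed=5)
        np.testing.assert_array_equal(emb1.to_numpy(), emb2.to_numpy())
        assert np.isfinite(emb1.to_numpy()).all()

        scale = emb1.to_numpy().std()
        dup_dist = np.linalg.norm(emb1.iloc[0] - emb1.iloc[1])
        assert dup_dist < scale / 10

        from sklearn.metrics import silhouette_score

        labels = [0] * (n // 2) + [1] * (n // 2)
        assert silhouette_score(emb1.to_numpy(), labels) > 0.5

    def test_too_few_samples_suggests_lower_neighbors(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError, match="lower n_neighbors"):
            mp.umap_embed(df)


class TestBhAdjust:
    def test_hand_enumerated_step_up_values(self):
        np.testing.assert_allclose(
            mp.bh_adjust([0.01, 0.02, 0.03, 0.8]), [0.04, 0.04, 0.04, 0.8]
        )
        np.testing.assert_allclose(
            mp.bh_adjust([0.005, 0.011, 0.02, 0.04, 0.5]),
            [0.025, 0.0275, 0.02 * 5 / 3, 0.05, 0.5],
        )

    def test_degenerate_vectors(self):
        np.testing.assert_allclose(mp.bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
        np.testing.assert_allclose(mp.bh_adjust([0.42]), [0.42])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mp.bh_adjust([0.1, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12), st.randoms())
    def test_permutation_invariance(self, ps, pyrandom):
        q = mp.bh_adjust(ps)
        perm = list(range(len(ps)))
        pyrandom.shuffle(perm)
        q_perm = mp.bh_adjust([ps[i] for i in perm])
        np.testing.assert_allclose(q_perm, q[perm], atol=1e-12)


def logrank_oracle(times, events, groups):
    """Direct O/E/V summation over distinct event times."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    g1 = np.asarray(groups) == np.unique(groups)[0]
    O = E = V = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & g1).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V if V > 0 else 0.0


class TestLogrank:
    def test_identical_groups_give_null(self):
        times = [1, 2, 3, 1, 2, 3]
        events = [1, 1, 1, 1, 1, 1]
        groups = list("AAABBB")
        stat, p = mp.logrank_test(times, events, groups)
        assert stat < 1e-10 and abs(p - 1.0) < 1e-10

    def test_six_subject_worked_example(self):
        # all events, groups fully separated in time
        times = [1, 2, 3, 10, 11, 12]
        events = [1] * 6
        groups = list("AAABBB")
        stat, p = mp.logrank_test(times, events, groups)
        np.testing.assert_allclose(stat, logrank_oracle(times, events, groups), rtol=1e-10)
        assert p < 0.05

    def test_single_event_risk_table(self):
        # one event at t=2 while everyone else is censored later: the whole
        # statistic comes from that single hypergeometric risk table
        times = [3, 3, 3, 2]
        events = [0, 0, 0, 1]
        groups = list("AABB")
        stat, _ = mp.logrank_test(times, events, groups)
        np.testing.assert_allclose(stat, logrank_oracle(times, events, groups), rtol=1e-10)

    def test_group_label_swap_invariance(self):
        times = [1, 4, 2, 5, 3, 6]
        events = [1, 0, 1, 1, 0, 1]
        g = list("ABABAB")
        swapped = ["B" if x == "A" else "A" for x in g]
        assert mp.logrank_test(times, events, g)[0] == pytest.approx(
            mp.logrank_test(times, events, swapped)[0]
        )

    def test_requires_events_and_two_groups(self):
        with pytest.raises(ValueError, match="event"):
            mp.logrank_test([1, 2], [0, 0], ["A", "B"])
        with pytest.raises(ValueError, match="groups"):
            mp.logrank_test([1, 2], [1, 1], ["A", "A"])


class TestDifferentialLv:
    def test_identical_groups_are_null(self):
        B = pd.DataFrame(
            np.tile(np.arange(4.0), (3, 1)), index=["LV1", "LV2", "LV3"],
            columns=list("abcd"),
        )
        groups = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        # make both groups see the same values
        B[["c", "d"]] = B[["a", "b"]].to_numpy()
        res = mp.differential_lv(B, groups)
        np.testing.assert_allclose(res["t"], 0.0)
        np.testing.assert_allclose(res["p"], 1.0)

    def test_overwhelming_effect_is_significant(self, rng):
        k, n = 5, 40
        B = pd.DataFrame(rng.normal(size=(k, n)), index=[f"LV{i}" for i in range(k)],
                         columns=[f"s{i}" for i in range(n)])
        groups = pd.Series(["g1"] * 20 + ["g2"] * 20, index=B.columns)
        B.iloc[0, 20:] += 5.0
        res = mp.differential_lv(B, groups)
        assert res.loc["LV0", "q"] < 0.05
        assert res.index[0] == "LV0"  # sorted by q then |t|

    def test_detects_planted_group_lvs_on_fixture(self, default_fit, default_dataset):
        _, _, truth = default_dataset
        _, _, model = default_fit
        res = mp.differential_lv(model.B, truth.groups)
        assert (res["q"] < 0.05).any()


class TestDmpTest:
    def test_extreme_separation_direction_and_q(self, rng):
        n = 10
        probes = [f"cg{i}" for i in range(5)]
        cols = [f"s{i}" for i in range(2 * n)]
        beta = pd.DataFrame(
            rng.uniform(0.4, 0.6, size=(5, 2 * n)), index=probes, columns=cols
        )
        beta.iloc[0, :n] = rng.normal(0.1, 0.02, n).clip(0, 1)
        beta.iloc[0, n:] = rng.normal(0.9, 0.02, n).clip(0, 1)
        groups = pd.Series(["ref"] * n + ["cmp"] * n, index=cols)
        res = mp.dmp_test(beta, probes, groups, reference_group="ref")
        assert res.loc["cg0", "direction"] == "hyper"
        assert res.loc["cg0", "q"] < 1e-6

    def test_equal_means_sentinel(self):
        beta = pd.DataFrame(
            [[0.2, 0.4, 0.2, 0.4]], index=["cg0"], columns=list("abcd")
        )
        groups = pd.Series(["r", "r", "c", "c"], index=list("abcd"))
        res = mp.dmp_test(beta, ["cg0"], groups, reference_group="r")
        assert res.loc["cg0", "direction"] == "none"
        assert res.loc["cg0", "p"] > 0.99

    def test_planted_shifts_recovered(self):
        """3 planted 0.3 shifts among 20 probes: the planted probes are always
        called, and usually nothing else is (a null probe sneaks under the
        adaptive BH cutoff p < 4/20 * 0.05 in roughly 16% of replicates)."""
        n = 15
        exact = 0
        always_found = True
        reps = 40
        for rep in range(reps):
            rng = np.random.default_rng(500 + rep)
            beta = rng.normal(0.5, 0.05, size=(20, 2 * n)).clip(0, 1)
            beta[:3, n:] += 0.3
            beta = beta.clip(0, 1)
            df = pd.DataFrame(beta, index=[f"cg{i}" for i in range(20)],
                              columns=[f"s{i}" for i in range(2 * n)])
            groups = pd.Series(["a"] * n + ["b"] * n, index=df.columns)
            res = mp.dmp_test(df, df.index, groups, reference_group="a")
            hits = set(res.index[res["q"] < 0.05])
            always_found &= {"cg0", "cg1", "cg2"} <= hits
            exact += hits == {"cg0", "cg1", "cg2"}
        assert always_found
        assert exact >= 0.7 * reps

    def test_probe_missing_in_one_group_excluded(self, rng):
        beta = pd.DataFrame(
            rng.uniform(size=(2, 8)), index=["cg0", "cg1"],
            columns=[f"s{i}" for i in range(8)],
        )
        beta.iloc[1, :4] = np.nan
        groups = pd.Series(["r"] * 4 + ["c"] * 4, index=beta.columns)
        res = mp.dmp_test(beta, ["cg0", "cg1"], groups, reference_group="r")
        assert "cg1" not in res.index
        assert res.attrs["n_excluded"] == 1
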