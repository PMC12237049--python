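"""Bray-Curtis, PERMANOVA, ordination and the community network."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from skbio import DistanceMatrix as SkbioDM
from skbio.stats.distance import permanova as skbio_permanova

import gelflux as gf
from gelflux import (
    CommunityMatrix,
    DissimilarityMatrix,
    bray_curtis,
    bray_curtis_matrix,
    build_similarity_network,
    mds_embed,
    network_cluster_composition,
    permanova,
)
from gelflux.errors import UserInputError


def _random_community(rng, n=8, p=5):
    X = rng.gamma(2.0, 1.0, size=(n, p))
    ids = [f"s{i}" for i in range(n)]
    return pd.DataFrame(X, index=ids, columns=[f"t{j}" for j in range(p)])


class TestBrayCurtis:
    def test_identity_and_disjoint(self):
        assert bray_curtis([2.0, 1.0, 3.0], [2.0, 1.0, 3.0]) == 0.0
        assert bray_curtis([1.0, 0.0], [0.0, 2.0]) == 1.0

    def test_hand_arithmetic(self):
        assert bray_curtis([2, 1, 0], [1, 1, 1]) == pytest.approx(2 / 6)

    def test_all_zero_pair_rejected(self):
        with pytest.raises(UserInputError):
            bray_curtis([0.0, 0.0], [0.0, 0.0])

    @settings(derandomize=True, max_examples=50)
    @given(
        x=st.lists(st.floats(0, 1e6), min_size=3, max_size=8),
        y=st.lists(st.floats(0, 1e6), min_size=3, max_size=8),
        c=st.floats(0.01, 100.0),
    )
    def test_symmetric_bounded_scale_invariant(self, x, y, c):
        n = min(len(x), len(y))
        x, y = np.array(x[:n]) + 0.1, np.array(y[:n]) + 0.1
        d = bray_curtis(x, y)
        assert 0 <= d <= 1
        assert bray_curtis(y, x) == pytest.approx(d)
        assert bray_curtis(c * x, c * y) == pytest.approx(d, rel=1e-9)

    def test_matches_independent_reference_on_random_matrices(self):
        # distance oracle: scipy's Bray-Curtis on 10 random small matrices
        rng = np.random.default_rng(0)
        for _ in range(10):
            df = _random_community(rng, n=6, p=4)
            D = bray_curtis_matrix(df)
            for i in range(6):
                for j in range(6):
                    expected = 0.0 if i == j else scipy_braycurtis(
                        df.iloc[i].to_numpy(), df.iloc[j].to_numpy()
                    )
                    assert abs(D.values[i, j] - expected) < 1e-10


class TestPermanova:
    def test_no_structure_guard(self):
        # identical samples in both groups: pseudo-F guarded to 0, p ~ 1
        X = np.tile([1.0, 2.0, 3.0], (6, 1))
        df = pd.DataFrame(X, index=[f"s{i}" for i in range(6)], columns=list("abc"))
        D = bray_curtis_matrix(df)
        res = permanova(D, ["g1"] * 3 + ["g2"] * 3, n_perm=199, seed=0)
        assert res.pseudo_f == 0.0
        assert res.p_value > 0.9

    def test_complete_separation(self):
        # two tight, fully separated clusters of 4: minimal attainable p
        rng = np.random.default_rng(1)
        a = np.abs(rng.normal(10.0, 0.01, size=(4, 3)))
        b = np.abs(rng.normal(0.1, 0.001, size=(4, 3))) + [[50, 0, 0]]
        df = pd.DataFrame(np.vstack([a, b]), index=[f"s{i}" for i in range(8)])
        D = bray_curtis_matrix(df)
        n_perm = 999
        res = permanova(D, ["A"] * 4 + ["B"] * 4, n_perm=n_perm, seed=2)
        # group-preserving permutations make ties with F_obs possible, so p
        # can only approach C(8,4)-limited granularity; demand a small p
        assert res.p_value <= 0.05

    def test_exhaustive_enumeration_matches_monte_carlo(self):
        # brute-force oracle: all 720 orderings at n = 6 vs permutation p
        rng = np.random.default_rng(3)
        df = _random_community(rng, n=6, p=4)
        D = bray_curtis_matrix(df)
        groups = ["A", "A", "A", "B", "B", "B"]
        exact = permanova(D, groups, method="exact")
        n_perm = 4999
        mc = permanova(D, groups, n_perm=n_perm, seed=4)
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / n_perm)
        assert abs(mc.p_value - exact.p_value) < 4 * se + 2 / n_perm

    def test_pseudo_f_matches_reference_implementation(self):
        # statistic oracle: scikit-bio PERMANOVA on 10 random matrices
        rng = np.random.default_rng(5)
        for _ in range(10):
            df = _random_community(rng, n=8, p=5)
            D = bray_curtis_matrix(df)
            groups = ["A"] * 4 + ["B"] * 4
            ours = permanova(D, groups, n_perm=99, seed=0)
            ref = skbio_permanova(
                SkbioDM(D.values, ids=list(D.ids)), grouping=list(groups), permutations=9
            )
            assert abs(ours.pseudo_f - ref["test statistic"]) < 1e-10

    def test_type_one_error_calibrated(self):
        # under a null of exchangeable samples the rejection rate at
        # alpha = 0.05 stays within [0.03, 0.07] over 1000 simulations
        rng = np.random.default_rng(0)
        groups = ["A"] * 5 + ["B"] * 5
        rejections = 0
        n_sims = 1000
        for _ in range(n_sims):
            df = _random_community(rng, n=10, p=4)
            D = bray_curtis_matrix(df)
            res = permanova(D, groups, n_perm=199, seed=int(rng.integers(2**31)))
            rejections += res.p_value <= 0.05
        assert 0.03 <= rejections / n_sims <= 0.07

    def test_degenerate_grouping_rejected(self):
        rng = np.random.default_rng(6)
        D = bray_curtis_matrix(_random_community(rng, n=5, p=3))
        with pytest.raises(UserInputError):
            permanova(D, ["A", "A", "A", "A", "B"], n_perm=99, seed=0)


class TestMDS:
    def test_equidistant_triple_embeds_as_equilateral(self):
        D = DissimilarityMatrix(
            values=np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]]),
            ids=("a", "b", "c"),
        )
        res = mds_embed(D)
        X = res.coordinates.to_numpy()
        d01 = np.linalg.norm(X[0] - X[1])
        d02 = np.linalg.norm(X[0] - X[2])
        d12 = np.linalg.norm(X[1] - X[2])
        assert d01 == pytest.approx(d02, rel=1e-6)
        assert d01 == pytest.approx(d12, rel=1e-6)
        assert res.stress < 1e-6

    def test_duplicate_samples_coincide(self):
        rng = np.random.default_rng(7)
        df = _random_community(rng, n=5, p=4)
        df.iloc[1] = df.iloc[0]  # duplicate
        D = bray_curtis_matrix(df)
        X = mds_embed(D).coordinates.to_numpy()
        assert np.linalg.norm(X[0] - X[1]) < 1e-8

    def test_embedding_preserves_rank_order_on_clustered_data(self):
        rng = np.random.default_rng(8)
        a = rng.gamma(5, 1, size=(5, 4)) + [10, 0, 0, 0]
        b = rng.gamma(5, 1, size=(5, 4)) + [0, 10, 0, 0]
        df = pd.DataFrame(np.vstack([a, b]), index=[f"s{i}" for i in range(10)])
        D = bray_curtis_matrix(df)
        res = mds_embed(D)
        X = res.coordinates.to_numpy()
        iu = np.triu_indices(10, 1)
        embed_d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))[iu]
        from scipy.stats import spearmanr

        assert spearmanr(embed_d, D.values[iu]).statistic > 0.95

    def test_too_few_samples_rejected(self):
        D = DissimilarityMatrix(values=np.array([[0, 0.3], [0.3, 0]]), ids=("a", "b"))
        with pytest.raises(UserInputError):
            mds_embed(D)


class TestNetwork:
    def _dm(self, values, ids):
        return DissimilarityMatrix(values=np.array(values, dtype=float), ids=ids)

    def test_threshold_extremes(self):
        D = self._dm([[0, 0.4, 0.9], [0.4, 0, 0.6], [0.9, 0.6, 0]], ("a", "b", "c"))
        tiny = build_similarity_network(D, threshold=1e-9)
        assert all(len(m) == 1 for m in tiny.clusters.values())
        full = build_similarity_network(D, threshold=1.0)
        assert len(full.clusters) == 1

    def test_strict_inequality_at_threshold(self):
        D = self._dm([[0, 0.25], [0.25, 0]], ("a", "b"))
        net = build_similarity_network(D, threshold=0.25)
        assert len(net.edges) == 0  # tie at the threshold excluded

    def test_monotonic_under_threshold_increase(self):
        # raising the threshold never splits an existing component
        rng = np.random.default_rng(9)
        df = _random_community(rng, n=10, p=5)
        D = bray_curtis_matrix(df)
        prev = None
        for thr in (0.1, 0.3, 0.5, 0.8, 1.0):
            net = build_similarity_network(D, threshold=thr)
            comp_of = {
                sid: lab for lab, mem in net.clusters.items() for sid in mem
            }
            if prev is not None:
                for members in prev.values():
                    labs = {comp_of[m] for m in members}
                    assert len(labs) == 1
            prev = net.clusters
        assert len(prev) == 1  # all below 1.0 eventually connected

    def test_deep_layer_forms_disjoint_cluster(self, np_like_dataset, sample_meta):
        # the translating deep diatom layer yields deep samples whose
        # communities cluster apart from every shallow sample
        ds = np_like_dataset
        ft = gf.fluxes_from_counts(ds.counts, ds.samples_by_id)
        meta = sample_meta(ds)
        wide = ft.pivot(index="sample_id", columns="taxon", values="flux").fillna(0.0)
        cm = CommunityMatrix(data=wide, meta=meta.loc[wide.index])
        D = bray_curtis_matrix(cm)
        net = build_similarity_network(D, cm.meta, threshold=0.25)
        deep = set(meta.index[meta["depth_m"] >= 500])
        shallow = set(meta.index[meta["depth_m"] <= 100])
        for members in net.clusters.values():
            ms = set(members)
            assert not (ms & deep and ms & shallow)

    def test_cluster_labels_ordered_by_deployment_then_depth(self, default_dataset, sample_meta):
        ds = default_dataset
        ft = gf.fluxes_from_counts(ds.counts, ds.samples_by_id)
        meta = sample_meta(ds)
        wide = ft.pivot(index="sample_id", columns="taxon", values="flux").fillna(0.0)
        D = bray_curtis_matrix(wide)
        net = build_similarity_network(D, meta.loc[wide.index], threshold=0.25)
        keys = [
            min(
                (meta.loc[m, "deployment"], meta.loc[m, "depth_m"])
                for m in members
            )
            for members in net.clusters.values()
        ]
        assert keys == sorted(keys)


class TestClusterComposition:
    def _net_from(self, df, thr=0.25):
        return build_similarity_network(bray_curtis_matrix(df), threshold=thr)

    def test_single_sample_cluster_is_that_sample(self):
        df = pd.DataFrame(
            [[8.0, 2.0], [0.5, 9.5]], index=["a", "b"], columns=["t1", "t2"]
        )
        net = self._net_from(df, thr=0.01)  # all singletons
        comp = network_cluster_composition(net, df, display_min=0.0)
        row_a = comp.loc[[lab for lab, m in net.clusters.items() if "a" in m][0]]
        assert row_a["t1"] == pytest.approx(0.8)
        assert row_a["t2"] == pytest.approx(0.2)

    def test_mean_of_mirrored_pair_is_even(self):
        df = pd.DataFrame(
            [[60.0, 40.0], [40.0, 60.0]], index=["a", "b"], columns=["t1", "t2"]
        )
        net = self._net_from(df, thr=1.0)  # one cluster
        comp = network_cluster_composition(net, df, display_min=0.0)
        assert comp.iloc[0]["t1"] == pytest.approx(0.5)
        assert comp.iloc[0]["t2"] == pytest.approx(0.5)

    def test_compositions_sum_to_one_with_pooling(self):
        rng = np.random.default_rng(10)
        df = _random_community(rng, n=8, p=6)
        net = self._net_from(df, thr=0.6)
        for dmin in (0.0, 0.05, 0.2):
            comp = network_cluster_composition(net, df, display_min=dmin)
            assert np.allclose(comp.sum(axis=1), 1.0, atol=1e-12)
        comp0 = network_cluster_composition(net, df, display_min=0.0)
        assert (comp0["other"] == 0).all()  # nothing pooled at threshold 0
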