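"""Pseudo-populations, embeddings, centroid separations, LOSO inference."""

import numpy as np
import pytest

from schemapop import geometry
from schemapop.geometry import (
    EmbeddingFailure, build_pseudopopulation, centroid_distance, embed_3d,
    holm_bonferroni, loso_rule_separation, rule_masks, rule_separation,
    two_cluster_cut, type_centroids, ward_dendrogram,
)
from schemapop.taskgen import CUE_ID, NON_MATCH


def _rat_data(rng, n_units=10, n_per_type=5, delta_nm=0.0, delta_ci=0.0):
    types = np.repeat(np.arange(16), n_per_type)
    rng.shuffle(types)
    s_nm = np.where(types < 8, 1.0, -1.0)
    s_ci = np.where(types % 8 < 4, 1.0, -1.0)
    rates = (
        10.0 + 0.5 * delta_nm * s_nm[:, None] + 0.5 * delta_ci * s_ci[:, None]
        + rng.normal(0, 1.0, size=(len(types), n_units))
    )
    return rates, types


class TestPseudoPopulation:
    def test_shape_and_standardization(self):
        rng = np.random.default_rng(0)
        data = {f"r{i}": _rat_data(rng) for i in range(2)}
        pop = build_pseudopopulation(data, n_trials_per_type=5, seed=1)
        assert pop.X.shape == (16 * 5, 20)
        np.testing.assert_allclose(pop.X.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(pop.X.std(axis=0), 1.0, atol=1e-9)

    def test_seeded_subsampling_reproducible(self):
        rng = np.random.default_rng(2)
        data = {f"r{i}": _rat_data(rng, n_per_type=8) for i in range(2)}
        a = build_pseudopopulation(data, n_trials_per_type=4, seed=7)
        b = build_pseudopopulation(data, n_trials_per_type=4, seed=7)
        assert np.array_equal(a.X, b.X)

    def test_missing_type_excluded_with_warning(self):
        rng = np.random.default_rng(3)
        r1 = _rat_data(rng)
        rates2, types2 = _rat_data(rng)
        keep = types2 != 5
        with pytest.warns(UserWarning, match="excluded"):
            pop = build_pseudopopulation(
                {"a": r1, "b": (rates2[keep], types2[keep])},
                n_trials_per_type=3, seed=0,
            )
        assert 5 not in pop.included_types

    def test_oversized_request_reduced(self):
        rng = np.random.default_rng(4)
        data = {"a": _rat_data(rng, n_per_type=4)}
        with pytest.warns(UserWarning, match="reduced"):
            pop = build_pseudopopulation(data, n_trials_per_type=10, seed=0)
        assert pop.n_trials_per_type == 4


class TestEmbedding:
    def test_linear_identical_rows_coincide(self):
        X = np.vstack([np.tile([1.0, 2.0, 3.0, 4.0], (4, 1)),
                       np.tile([5.0, 1.0, 0.0, 2.0], (4, 1))])
        emb = embed_3d(X, method="linear")
        assert np.allclose(emb.coords[0], emb.coords[1])
        assert not np.allclose(emb.coords[0], emb.coords[-1])

    def test_linear_deterministic(self):
        X = np.random.default_rng(5).normal(size=(30, 8))
        a = embed_3d(X, method="linear")
        b = embed_3d(X, method="linear")
        assert np.array_equal(a.coords, b.coords)

    def test_constant_matrix_fails(self):
        with pytest.raises(EmbeddingFailure):
            embed_3d(np.ones((10, 4)), method="linear")

    def test_cluster_separation_preserved(self):
        rng = np.random.default_rng(6)
        centers = rng.normal(0, 5, size=(2, 50))
        X = np.vstack([centers[i] + rng.normal(0, 1, size=(40, 50))
                       for i in range(2)])
        emb = embed_3d(X, method="linear")
        labels = np.repeat([0, 1], 40)
        between = np.linalg.norm(
            emb.coords[labels == 0].mean(0) - emb.coords[labels == 1].mean(0)
        )
        within = np.mean([
            np.linalg.norm(emb.coords[labels == i]
                           - emb.coords[labels == i].mean(0), axis=1).mean()
            for i in range(2)
        ])
        assert between > within

    def test_umap_backend_separates_clusters(self):
        rng = np.random.default_rng(14)
        X = np.vstack([rng.normal(0, 1, (40, 10)), rng.normal(8, 1, (40, 10))])
        emb = embed_3d(X, method="umap", seed=4)
        assert emb.coords.shape == (80, 3)
        lab = np.repeat([0, 1], 40)
        between = np.linalg.norm(
            emb.coords[lab == 0].mean(0) - emb.coords[lab == 1].mean(0)
        )
        within = np.mean([
            np.linalg.norm(emb.coords[lab == i]
                           - emb.coords[lab == i].mean(0), axis=1).mean()
            for i in (0, 1)
        ])
        assert between > within

    def test_linear_backend_matches_direct_projection(self):
        """Oracle equivalence: centroid distances computed on the linear
        embedding equal a direct computation on mean-centered data projected
        onto the top-3 right singular vectors."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 12))
        emb = embed_3d(X, method="linear")
        Xc = X - X.mean(axis=0)
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        proj = Xc @ Vt[:3].T
        mask = np.zeros(60, bool)
        mask[:30] = True
        d_emb = centroid_distance(emb.coords, mask, ~mask)
        d_dir = centroid_distance(proj * np.sign(proj[0]) ** 0, mask, ~mask)
        # sign convention cannot change a distance
        assert d_emb == pytest.approx(d_dir, rel=1e-9)


class TestCentroidDistance:
    def test_known_separation(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, size=(4000, 3))
        b = rng.normal(0, 1, size=(4000, 3)) + np.array([3.0, 0, 0])
        mask = np.r_[np.ones(4000, bool), np.zeros(4000, bool)]
        coords = np.vstack([a, b])
        assert centroid_distance(coords, mask, ~mask) == pytest.approx(3.0, abs=0.15)

    def test_identical_groups_near_zero(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(size=(200, 3))
        mask = np.zeros(200, bool)
        mask[::2] = True
        assert centroid_distance(coords, mask, ~mask) < 0.5

    def test_scale_invariance(self):
        rng = np.random.default_rng(10)
        coords = rng.normal(size=(100, 3))
        mask = rng.random(100) < 0.5
        d1 = centroid_distance(coords, mask, ~mask)
        d2 = centroid_distance(2.0 * coords, mask, ~mask)
        assert d1 == pytest.approx(d2, rel=1e-9)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            centroid_distance(np.zeros((4, 3)), np.zeros(4, bool), np.ones(4, bool))


class TestDendrogram:
    def test_two_centroids_single_merge(self):
        c = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        link = ward_dendrogram(c)
        assert link.shape == (1, 4)
        assert link[0, 2] == pytest.approx(4.0)

    def _coded_pop(self, delta_nm, delta_ci, seed):
        rng = np.random.default_rng(seed)
        data = {f"r{i}": _rat_data(rng, delta_nm=delta_nm, delta_ci=delta_ci)
                for i in range(3)}
        return build_pseudopopulation(data, n_trials_per_type=5, seed=seed)

    def test_nm_coded_cut_separates_configurations(self):
        pop = self._coded_pop(delta_nm=6.0, delta_ci=0.0, seed=11)
        emb = embed_3d(pop.X, method="linear")
        types, cents = type_centroids(emb.coords, pop.type_index)
        cut = two_cluster_cut(ward_dendrogram(cents))
        nm_side = cut[types < 8]
        m_side = cut[types >= 8]
        assert len(set(nm_side)) == 1 and len(set(m_side)) == 1
        assert nm_side[0] != m_side[0]

    def test_ci_coded_cut_separates_odor_groups(self):
        pop = self._coded_pop(delta_nm=0.0, delta_ci=6.0, seed=12)
        emb = embed_3d(pop.X, method="linear")
        types, cents = type_centroids(emb.coords, pop.type_index)
        cut = two_cluster_cut(ward_dendrogram(cents))
        grp = (types % 8) < 4
        assert len(set(cut[grp])) == 1 and len(set(cut[~grp])) == 1
        assert cut[grp][0] != cut[~grp][0]


class TestLOSO:
    def test_nm_coding_detected_ci_not(self, fixtures):
        by_rat = fixtures["nm_only"]["by_rat"]
        obs_nm, null_nm = loso_rule_separation(by_rat, NON_MATCH, n_perm=99, seed=0)
        obs_ci, null_ci = loso_rule_separation(by_rat, CUE_ID, n_perm=99, seed=0)
        ps = holm_bonferroni([null_nm.p_two_tailed, null_ci.p_two_tailed])
        assert ps[0] <= 0.05
        assert null_ci.p_two_tailed > 0.05

    def test_single_rat_degenerates_with_warning(self, fixtures):
        rat, data = next(iter(fixtures["nm_only"]["by_rat"].items()))
        with pytest.warns(UserWarning, match="single rat"):
            obs, null = loso_rule_separation({rat: data}, NON_MATCH,
                                             n_perm=19, seed=1)
        assert np.isfinite(obs)

    def test_loso_robust_to_leaving_one_rat_out(self, fixtures):
        """With identically generated rats, any single rat's removal moves the
        LOSO mean by less than the null SD."""
        by_rat = fixtures["nm_only"]["by_rat"]
        obs, null = loso_rule_separation(by_rat, NON_MATCH, n_perm=60, seed=2)
        rats = list(by_rat)
        drop = {r: by_rat[r] for r in rats[1:]}
        obs2, _ = loso_rule_separation(drop, NON_MATCH, n_perm=1, seed=2)
        assert abs(obs - obs2) < max(3 * null.null.std(ddof=1), 0.5 * obs)

    def test_group_difference_identical_groups(self, fixtures):
        by_rat = fixtures["nm_only"]["by_rat"]
        obs, null = loso_rule_separation(by_rat, NON_MATCH, n_perm=60, seed=3)
        diff, p, _ = geometry.group_difference_test(obs, obs, null.null, null.null)
        assert diff == 0.0
        assert p == pytest.approx(1.0)

    def test_group_difference_detects_residual_coding(self, fixtures):
        nm = fixtures["nm_only"]["by_rat"]
        ctl = fixtures["null"]["by_rat"]
        o1, n1 = loso_rule_separation(nm, NON_MATCH, n_perm=99, seed=4)
        o2, n2 = loso_rule_separation(ctl, NON_MATCH, n_perm=99, seed=5)
        _, p, _ = geometry.group_difference_test(o1, o2, n1.null, n2.null)
        assert p <= 0.05


def test_holm_monotonicity():
    rng = np.random.default_rng(13)
    raw = rng.uniform(size=12)
    adj = holm_bonferroni(raw)
    assert np.all(adj >= raw)
    order = np.argsort(raw)
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_rule_masks_partition():
    types = np.arange(16)
    for rule in (NON_MATCH, CUE_ID):
        a, b = rule_masks(types, rule)
        assert a.sum() == 8 and np.all(a ^ b)
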