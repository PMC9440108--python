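import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist, squareform

import paleoseason as ps
from paleoseason.community import DissimilarityMatrix, EnvTable
from paleoseason.ordination import ca, nmds_project


def dm(mat, ids=None):
    mat = np.asarray(mat, float)
    ids = ids or [f"s{i}" for i in range(mat.shape[0])]
    return DissimilarityMatrix(tuple(ids), mat)


def unimodal_matrix(span_tols, n_sites=60, n_species=25, seed=0):
    """Gaussian species packages along one gradient measured in tolerance
    units; the compositional turnover oracle is the span itself."""
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, span_tols, n_sites)
    opt = rng.uniform(-1.0, span_tols + 1.0, n_species)
    peak = rng.lognormal(0.0, 0.4, n_species)
    mu = peak[None, :] * np.exp(-0.5 * (x[:, None] - opt[None, :]) ** 2)
    y = rng.poisson(400 * mu / mu.sum(axis=1, keepdims=True)).astype(float)
    return y[:, y.sum(axis=0) > 0]


class TestPCoA:
    def test_three_collinear_points(self):
        # d(1,2)=1, d(2,3)=1, d(1,3)=2: a line, scores (-1, 0, 1)
        res = ps.pcoa(dm([[0, 1, 2], [1, 0, 1], [2, 1, 0]]))
        assert res.eigenvalues[0] == pytest.approx(2.0)
        s = res.site_scores[:, 0]
        s = s * np.sign(s[2] - s[0])
        np.testing.assert_allclose(s, [-1.0, 0.0, 1.0], atol=1e-10)

    def test_identical_sites_all_zero_scores(self):
        res = ps.pcoa(dm(np.zeros((4, 4))), n_axes=2)
        np.testing.assert_allclose(res.site_scores, 0.0, atol=1e-12)

    def test_reproduces_euclidean_distances(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 2))
        d = squareform(pdist(pts))
        res = ps.pcoa(dm(d))
        rebuilt = squareform(pdist(res.site_scores[:, :2]))
        np.testing.assert_allclose(rebuilt, d, atol=1e-8)

    def test_matches_pca_on_euclidean_distances(self):
        # PCoA of Euclidean distances == PCA scores up to sign
        rng = np.random.default_rng(5)
        x = rng.normal(size=(15, 4))
        xc = x - x.mean(axis=0)
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        pca_scores = u * s
        res = ps.pcoa(dm(squareform(pdist(x))), n_axes=3)
        for k in range(3):
            a, b = res.site_scores[:, k], pca_scores[:, k]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_cailliez_makes_bray_curtis_embeddable(self, small_training):
        _, _, taxa, _ = small_training
        d = ps.pairwise_dissimilarity(ps.to_percentages(taxa), "bray_curtis")
        res = ps.pcoa(d)
        assert res.extras["correction"] > 0
        assert np.all(res.eigenvalues > -1e-8)


class TestGradientLength:
    def test_identical_sites_zero(self):
        assert ps.dca_gradient_length(np.tile([4.0, 3.0, 2.0], (6, 1))) == 0.0

    def test_long_gradient_exceeds_four_sd(self):
        assert ps.dca_gradient_length(unimodal_matrix(6.0)) > 4.0

    def test_short_gradient_below_two_sd(self):
        assert ps.dca_gradient_length(unimodal_matrix(1.0)) < 2.0

    def test_complete_turnover_at_least_four_sd(self):
        assert ps.dca_gradient_length(np.eye(2)) >= 4.0

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            ps.dca_gradient_length(np.array([[1.0, 2.0]]))


class TestCCA:
    def test_ca_axis_as_predictor_recovers_ca_eigenvalue(self, small_training):
        _, _, taxa, _ = small_training
        y = ps.sqrt_transform(ps.to_percentages(taxa))
        ca_res = ca(y)
        env = EnvTable(taxa.site_ids, ("ax1",), ca_res.site_scores[:, :1])
        cca_res = ps.cca(y, env, ["ax1"])
        assert cca_res.eigenvalues[0] == pytest.approx(ca_res.eigenvalues[0],
                                                       abs=1e-8)

    def test_relabeling_invariance(self, small_training):
        _, _, taxa, env = small_training
        y = ps.sqrt_transform(ps.to_percentages(taxa))
        perm = np.random.default_rng(0).permutation(y.shape[0])
        res1 = ps.cca(y, env, ["T_winter", "T_summer"])
        env2 = env.select_sites(perm)
        res2 = ps.cca(y[perm], EnvTable(tuple(f"p{i}" for i in range(len(perm))),
                                        env2.variables, env2.values),
                      ["T_winter", "T_summer"])
        np.testing.assert_allclose(res1.eigenvalues, res2.eigenvalues, atol=1e-10)

    def test_noise_predictor_explains_little(self, small_training):
        _, _, taxa, env = small_training
        y = ps.sqrt_transform(ps.to_percentages(taxa))
        noise = EnvTable(taxa.site_ids, ("z",),
                         np.random.default_rng(1).normal(size=(taxa.n_sites, 1)))
        frac_noise = ps.cca(y, noise, ["z"]).explained_fraction
        frac_signal = ps.cca(y, env, ["T_winter"]).explained_fraction
        assert frac_noise < 0.05
        assert frac_signal > 5 * frac_noise

    def test_explained_fraction_monotone_in_variables(self, small_training):
        _, _, taxa, env = small_training
        y = ps.sqrt_transform(ps.to_percentages(taxa))
        fracs = [ps.cca(y, env, list(env.variables[:k])).explained_fraction
                 for k in range(1, 5)]
        assert all(b >= a - 1e-12 for a, b in zip(fracs, fracs[1:]))

    def test_collinear_predictors_rejected_by_name(self, small_training):
        _, _, taxa, env = small_training
        y = ps.sqrt_transform(ps.to_percentages(taxa))
        dup = EnvTable(taxa.site_ids, ("a", "b"),
                       np.column_stack([env["T_winter"], env["T_winter"]]))
        with pytest.raises(ValueError, match="'b'"):
            ps.cca(y, dup, ["a", "b"])

    def test_matches_reference_cca_eigenvalues(self, small_training):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        import pandas as pd
        _, _, taxa, env = small_training
        y = ps.sqrt_transform(ps.to_percentages(taxa))
        vars_ = ["T_winter", "T_summer"]
        mine = ps.cca(y, env, vars_)
        ref = skbio_ord.cca(pd.DataFrame(y), env.to_frame()[vars_])
        k = len(mine.eigenvalues)
        np.testing.assert_allclose(mine.eigenvalues,
                                   ref.eigvals.to_numpy()[:k], atol=1e-8)


class TestVif:
    def test_identical_variables_one_dropped(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=30)
        env = EnvTable(tuple(f"s{i}" for i in range(30)), ("a", "b"),
                       np.column_stack([a, a]))
        assert len(ps.vif_filter(env, ["a", "b"])) == 1

    def test_orthogonal_variables_all_retained(self):
        n = 40
        x = np.arange(n, dtype=float)
        env = EnvTable(tuple(f"s{i}" for i in range(n)), ("c1", "c2"),
                       np.column_stack([np.cos(2 * np.pi * x / n),
                                        np.sin(2 * np.pi * x / n)]))
        assert ps.vif_filter(env, ["c1", "c2"], threshold=5.0) == ["c1", "c2"]

    def test_near_collinear_triplet_pruned_to_low_vif(self):
        from paleoseason.ordination import variance_inflation_factors
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(2, 60))
        z = x + y + rng.normal(0, 0.01, 60)
        env = EnvTable(tuple(f"s{i}" for i in range(60)), ("x", "y", "z"),
                       np.column_stack([x, y, z]))
        kept = ps.vif_filter(env, ["x", "y", "z"], threshold=20.0)
        assert len(kept) == 2
        assert max(variance_inflation_factors(env, kept).values()) <= 20.0


class TestPermutationAndForwardSelection:
    def test_dominant_gradient_reaches_minimum_p(self, small_training):
        _, _, taxa, env = small_training
        y = ps.sqrt_transform(ps.to_percentages(taxa))
        res = ps.permutation_test(y, env, "T_winter", n_perm=999, seed=4)
        assert res.p_value == pytest.approx(1.0 / 1000.0)

    def test_p_respects_lower_bound_and_determinism(self, small_training):
        _, _, taxa, env = small_training
        y = ps.sqrt_transform(ps.to_percentages(taxa))
        with pytest.warns(UserWarning):
            r1 = ps.permutation_test(y, env, "MAP", n_perm=9, seed=7)
        with pytest.warns(UserWarning):
            r2 = ps.permutation_test(y, env, "MAP", n_perm=9, seed=7)
        assert 1.0 / 10.0 <= r1.p_value <= 1.0
        assert r1.p_value == r2.p_value

    def test_forward_selection_finds_true_driver_first(self):
        rng = np.random.default_rng(8)
        g = np.linspace(0, 6, 50)
        y = unimodal_matrix(6.0, n_sites=50, seed=8)
        env = EnvTable(tuple(f"s{i}" for i in range(50)),
                       ("driver", "n1", "n2"),
                       np.column_stack([g, rng.normal(size=50),
                                        rng.normal(size=50)]))
        sel = ps.forward_select(y, env, ["n1", "driver", "n2"],
                                alpha=0.05, n_perm=99, seed=8)
        assert sel and sel[0][0] == "driver"

    def test_duplicate_of_selected_adds_nothing(self):
        g = np.linspace(0, 6, 50)
        y = unimodal_matrix(6.0, n_sites=50, seed=9)
        env = EnvTable(tuple(f"s{i}" for i in range(50)), ("g", "g2"),
                       np.column_stack([g, g * 2.0 + 1.0]))
        sel = ps.forward_select(y, env, ["g", "g2"], alpha=0.05,
                                n_perm=99, seed=9)
        assert [s[0] for s in sel] == ["g"]

    def test_alpha_one_selects_all_in_gain_order(self, small_training):
        _, _, taxa, env = small_training
        y = ps.sqrt_transform(ps.to_percentages(taxa))
        cands = ["T_winter", "MAP", "T_summer"]
        sel = ps.forward_select(y, env, cands, alpha=1.0, n_perm=99, seed=3)
        assert sorted(s[0] for s in sel) == sorted(cands)
        gains = [s[1] for s in sel]
        # later additions cannot add more than an earlier greedy pick did
        assert all(b <= a + 1e-9 for a, b in zip(gains, gains[1:]))


class TestNMDS:
    def test_perfect_embedding_has_near_zero_stress(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 2))
        res = ps.nmds(dm(squareform(pdist(pts))), k=2, n_starts=8, seed=0)
        assert res.stress < 0.01

    def test_square_configuration_stress_near_zero(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
        res = ps.nmds(dm(squareform(pdist(pts))), k=2, n_starts=8, seed=0)
        assert res.stress < 1e-3

    def test_stress_invariant_to_input_rotation(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(9, 2))
        th = 0.7
        rot = pts @ np.array([[np.cos(th), -np.sin(th)],
                              [np.sin(th), np.cos(th)]])
        r1 = ps.nmds(dm(squareform(pdist(pts))), k=2, n_starts=6, seed=2)
        r2 = ps.nmds(dm(squareform(pdist(rot))), k=2, n_starts=6, seed=2)
        assert r1.stress == pytest.approx(r2.stress, abs=1e-6)

    def test_stress_nonincreasing_in_dimension(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(14, 3))
        d = dm(squareform(pdist(pts)))
        s2 = ps.nmds(d, k=2, n_starts=6, seed=5).stress
        s3 = ps.nmds(d, k=3, n_starts=6, seed=5).stress
        assert s3 <= s2 + 1e-6

    def test_passive_projection_lands_on_twin_point(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(12, 2))
        d = squareform(pdist(pts))
        res = ps.nmds(dm(d), k=2, n_starts=8, seed=6)
        # fossil identical to modern point 3: distance row = d[3]; placement
        # error is of the order of the (near-zero) configuration stress
        proj = nmds_project(res, d[3][None, :])
        gaps = np.linalg.norm(res.site_scores - proj[0], axis=1)
        assert np.argmin(gaps) == 3
        assert gaps[3] < 0.05 * np.ptp(res.site_scores)


class TestRda:
    def test_rank_one_response_fully_explained(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        y = np.outer(x, rng.normal(size=5))
        assert ps.rda_explained_variance(y, x) == pytest.approx(1.0)

    def test_orthogonal_predictor_explains_nothing(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.column_stack([[1.0, 1.0, -1.0, -1.0], [2.0, 2.0, 0.0, 0.0]])
        assert ps.rda_explained_variance(y, x) == pytest.approx(0.0, abs=1e-12)

    def test_matches_projection_oracle_on_toy(self):
        rng = np.random.default_rng(7)
        y = rng.normal(size=(5, 3))
        x = rng.normal(size=5)
        yc = y - y.mean(axis=0)
        xd = np.column_stack([np.ones(5), x])
        fitted = xd @ np.linalg.lstsq(xd, yc, rcond=None)[0]
        oracle = (fitted ** 2).sum() / (yc ** 2).sum()
        assert ps.rda_explained_variance(y, x) == pytest.approx(oracle, abs=1e-10)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            ps.rda_explained_variance(np.eye(4), np.ones(4))
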