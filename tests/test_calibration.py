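import numpy as np
import pytest

import paleoseason as ps
from paleoseason.calibration import MethodSpec


def table(vals, kind="counts", ids=None):
    vals = np.atleast_2d(np.asarray(vals, float))
    ids = ids or [f"s{i}" for i in range(vals.shape[0])]
    return ps.TaxonTable(ids, [f"t{j}" for j in range(vals.shape[1])],
                         vals, kind=kind)


def naive_wapls_predict(y, x, samples, n_components):
    """Independent step-by-step reference implementation of the published
    WA-PLS algorithm, written with explicit loops for clarity: residuals of
    the previous fit become site scores, taxon scores are their weighted
    averages, new site scores are orthogonalized and standardized (weights
    = site totals), and the environment is regressed on the components."""
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    n, m = y.shape
    rowsum = y.sum(axis=1)
    colsum = y.sum(axis=0)
    w = rowsum / rowsum.sum()
    x_mean = sum(w[i] * x[i] for i in range(n))
    resid = x - x_mean
    comps = []          # per component: (u, ortho coefs, mean, sd, beta)
    f = np.zeros((n, n_components))
    for a in range(n_components):
        u = np.array([sum(y[i, k] * resid[i] for i in range(n)) / colsum[k]
                      for k in range(m)])
        s = np.array([sum(y[i, k] * u[k] for k in range(m)) / rowsum[i]
                      for i in range(n)])
        coefs = []
        for b in range(a):
            c = sum(w[i] * s[i] * f[i, b] for i in range(n))
            s = s - c * f[:, b]
            coefs.append(c)
        mean = sum(w[i] * s[i] for i in range(n))
        sd = np.sqrt(sum(w[i] * (s[i] - mean) ** 2 for i in range(n)))
        f[:, a] = (s - mean) / sd
        beta = sum(w[i] * x[i] * f[i, a] for i in range(n))
        comps.append((u, coefs, mean, sd, beta))
        fitted = x_mean + f[:, :a + 1] @ np.array([c[4] for c in comps])
        resid = x - fitted
    # replay the score construction for new samples
    samples = np.atleast_2d(np.asarray(samples, float))
    fs = np.zeros((samples.shape[0], n_components))
    for j, row in enumerate(samples):
        for a, (u, coefs, mean, sd, beta) in enumerate(comps):
            s = sum(row[k] * u[k] for k in range(m)) / row.sum()
            for b, c in enumerate(coefs):
                s = s - c * fs[j, b]
            fs[j, a] = (s - mean) / sd
    betas = np.array([c[4] for c in comps])
    return x_mean + fs @ betas


class TestWA:
    def test_monospecific_optima_and_raw_prediction(self):
        t = table([[10, 0], [0, 10.0]])
        model = ps.wa_fit(t, np.array([10.0, 20.0]))
        np.testing.assert_allclose(model.optima, [10.0, 20.0])
        assert model.raw_predict(np.array([[5.0, 5.0]]))[0] == pytest.approx(15.0)

    def test_training_site_recovered_on_clean_gradient(self, linear_system):
        taxa, x = linear_system
        model = ps.wa_fit(taxa, x)
        pred = model.predict(taxa.values)
        np.testing.assert_allclose(pred, x, atol=1e-8)

    def test_classical_deshrinking_also_recovers_clean_gradient(self, linear_system):
        taxa, x = linear_system
        model = ps.wa_fit(taxa, x, deshrinking="classical")
        np.testing.assert_allclose(model.predict(taxa.values), x, atol=1e-8)

    def test_constant_env_degenerate(self):
        t = table([[5, 5], [6, 4.0]])
        with pytest.raises(ValueError, match="deshrinking"):
            ps.wa_fit(t, np.array([7.0, 7.0]))


class TestWAPLS:
    def test_component_one_equals_wa_inverse(self, small_training):
        _, _, taxa, env = small_training
        pct = ps.to_percentages(taxa)
        for target in ("T_winter", "T_summer"):
            wa = ps.wa_fit(pct, env[target], deshrinking="inverse")
            wapls = ps.wapls_fit(pct, env[target], n_components=3)
            np.testing.assert_allclose(
                ps.wapls_predict(wapls, pct.values, n_components=1),
                wa.predict(pct.values), atol=1e-10)

    def test_training_rmse_nonincreasing_in_components(self, small_training):
        _, _, taxa, env = small_training
        pct = ps.to_percentages(taxa)
        model = ps.wapls_fit(pct, env["T_winter"], n_components=4)
        allc = model.predict_all_components(pct.values)
        rmse = np.sqrt(((allc - env["T_winter"][:, None]) ** 2).mean(axis=0))
        assert all(b <= a + 1e-9 for a, b in zip(rmse, rmse[1:]))

    def test_component_two_matches_independent_implementation(self):
        rng = np.random.default_rng(42)
        y = rng.uniform(0.0, 10.0, size=(5, 3))
        x = np.array([2.0, 4.0, 5.5, 7.0, 9.0])
        samples = rng.uniform(0.0, 10.0, size=(4, 3))
        t = table(y)
        model = ps.wapls_fit(t, x, n_components=2)
        mine = ps.wapls_predict(model, samples, n_components=2)
        oracle = naive_wapls_predict(y, x, samples, 2)
        np.testing.assert_allclose(mine, oracle, atol=1e-10)

    def test_component_limit_enforced(self):
        t = table([[5, 5], [6, 4.0], [2, 8.0]])
        with pytest.raises(ValueError, match="n_components"):
            ps.wapls_fit(t, np.array([1.0, 2.0, 3.0]), n_components=5)


class TestMAT:
    def test_exact_analogue_returns_its_value(self, linear_system):
        taxa, x = linear_system
        pred, dmin = ps.mat_predict(taxa, x, taxa.values[7], k=1)
        assert pred[0] == pytest.approx(x[7])
        assert dmin[0] == pytest.approx(0.0, abs=1e-12)

    def test_equal_distances_give_arithmetic_mean(self):
        # two training sites symmetric around the sample composition
        t = table([[60, 40.0], [40, 60.0]], kind="percent")
        x = np.array([10.0, 30.0])
        pred, _ = ps.mat_predict(t, x, np.array([50.0, 50.0]), k=2)
        assert pred[0] == pytest.approx(20.0)

    def test_inverse_distance_weighted_mean(self):
        # single-taxon counts with Bray-Curtis: d(9,11)=0.1, d(9,b)=0.3
        b = 9.0 * 1.3 / 0.7
        t = table([[11.0], [b]])
        pred, dmin = ps.mat_predict(t, np.array([10.0, 20.0]),
                                    np.array([9.0]), k=2, metric="bray_curtis")
        assert pred[0] == pytest.approx(12.5)
        assert dmin[0] == pytest.approx(0.1)


class TestLocallyWeighted:
    def test_full_neighborhood_equals_global_model(self, small_training):
        _, _, taxa, env = small_training
        pct = ps.to_percentages(taxa)
        samples = pct.values[:10]
        for base, fit in (("WA", lambda: ps.wa_fit(pct, env["T_winter"])),
                          ("WAPLS", lambda: ps.wapls_fit(pct, env["T_winter"],
                                                         n_components=2))):
            local, _, flags = ps.lw_predict(pct, env["T_winter"], samples,
                                            base=base, m_local=pct.n_sites,
                                            n_components=2)
            np.testing.assert_allclose(local, fit().predict(samples), atol=1e-10)
            assert not flags.any()

    def test_twin_sample_predicted_at_its_environment(self, linear_system):
        taxa, x = linear_system
        pred, _, _ = ps.lw_predict(taxa, x, taxa.values[12], base="WA",
                                   m_local=8)
        assert pred[0] == pytest.approx(x[12], abs=1e-6)

    def test_local_subset_stays_in_matching_regime(self):
        # two well-separated compositional regimes (cold / warm clusters)
        rng = np.random.default_rng(0)
        cold = np.column_stack([rng.uniform(80, 95, 20),
                                rng.uniform(5, 20, 20),
                                np.zeros(20)])
        warm = np.column_stack([np.zeros(20),
                                rng.uniform(5, 20, 20),
                                rng.uniform(80, 95, 20)])
        vals = np.vstack([cold, warm])
        ids = [f"cold{i}" for i in range(20)] + [f"warm{i}" for i in range(20)]
        taxa = ps.to_percentages(table(vals, ids=ids))
        x = np.concatenate([rng.uniform(-10, -5, 20), rng.uniform(15, 20, 20)])
        fossil = ps.to_percentages(table([[0.0, 12.0, 88.0]])).values
        _, prov, _ = ps.lw_predict(taxa, x, fossil, base="WA", m_local=10)
        assert all(s.startswith("warm") for s in prov[0])

    def test_constant_local_environment_falls_back_to_mat(self):
        t = ps.to_percentages(table([[90, 10], [80, 20], [10, 90.0]]))
        x = np.array([5.0, 5.0, 12.0])
        pred, _, flags = ps.lw_predict(t, x, t.values[0], base="WA", m_local=2)
        assert flags[0]
        assert pred[0] == pytest.approx(5.0)


class TestBootstrapValidation:
    def test_same_seed_bit_identical(self, small_training):
        _, _, taxa, env = small_training
        pct = ps.to_percentages(taxa)
        spec = MethodSpec(method="WAPLS", n_components=2)
        s1, _ = ps.bootstrap_validate(spec, pct, env["T_winter"], n_boot=40,
                                      seed=9)
        s2, _ = ps.bootstrap_validate(spec, pct, env["T_winter"], n_boot=40,
                                      seed=9)
        assert s1.rmsep == s2.rmsep and s1.r2 == s2.r2
        np.testing.assert_array_equal(s1.predicted, s2.predicted)

    def test_noise_free_linear_system_near_zero_rmsep(self, linear_system):
        taxa, x = linear_system
        spec = MethodSpec(method="WA")
        stats, _ = ps.bootstrap_validate(spec, taxa, x, n_boot=500, seed=0)
        assert stats.rmsep < 0.1
        assert stats.r2 > 0.999
        assert abs(stats.avg_bias) < 0.05 and stats.max_bias < 0.1

    def test_rmsep_stable_under_site_relabeling(self, small_training):
        _, _, taxa, env = small_training
        pct = ps.to_percentages(taxa)
        perm = np.random.default_rng(1).permutation(pct.n_sites)
        spec = MethodSpec(method="WAPLS", n_components=2)
        a, _ = ps.bootstrap_validate(spec, pct, env["T_winter"], n_boot=150,
                                     seed=2)
        b, _ = ps.bootstrap_validate(spec, pct.select_sites(perm),
                                     env["T_winter"][perm], n_boot=150, seed=2)
        assert b.rmsep == pytest.approx(a.rmsep, rel=0.15)

    def test_predictions_invariant_to_taxon_permutation(self, small_training):
        _, _, taxa, env = small_training
        pct = ps.to_percentages(taxa)
        perm = np.random.default_rng(3).permutation(pct.n_taxa)
        shuffled = ps.TaxonTable(pct.site_ids,
                                 tuple(pct.taxon_ids[j] for j in perm),
                                 pct.values[:, perm], kind="percent")
        m1 = ps.wapls_fit(pct, env["T_winter"], 2)
        m2 = ps.wapls_fit(shuffled, env["T_winter"], 2)
        np.testing.assert_allclose(m1.predict(pct.values),
                                   m2.predict(shuffled.values), atol=1e-10)

    def test_per_component_table_present_for_wapls(self, small_training):
        _, _, taxa, env = small_training
        pct = ps.to_percentages(taxa)
        spec = MethodSpec(method="WAPLS", n_components=3)
        stats, _ = ps.bootstrap_validate(spec, pct, env["T_winter"], n_boot=40,
                                         seed=5)
        assert list(stats.per_component["n_components"]) == [1, 2, 3]


class TestComponentSelection:
    @pytest.mark.parametrize("rmseps,expected", [
        ((2.0, 1.5, 1.49, 1.6), 2),       # 1.5 within 5% of the 1.49 minimum
        ((3.0, 2.0, 1.0, 1.0, 1.0), 3),   # first near-minimum after descent
        ((1.7,), 1),
    ])
    def test_rule(self, rmseps, expected):
        assert ps.select_n_components(list(rmseps)) == expected


class TestReconstruct:
    def test_training_copy_reproduces_environment(self, linear_system):
        taxa, x = linear_system
        fossil = ps.TaxonTable(tuple(f"f{i}" for i in range(taxa.n_sites)),
                               taxa.taxon_ids, taxa.values, kind="percent",
                               ages=np.arange(taxa.n_sites) * 100.0)
        series = ps.reconstruct(MethodSpec(method="WA"), taxa, {"T": x}, fossil)
        np.testing.assert_allclose(series.predictions["T"].to_numpy(), x,
                                   atol=1e-6)
        assert series.errors is None

    def test_with_errors_adds_sd_column_without_changing_predictions(
            self, small_training):
        _, _, taxa, env = small_training
        pct = ps.to_percentages(taxa)
        fossil = ps.TaxonTable(("f0", "f1"), pct.taxon_ids, pct.values[:2],
                               kind="percent", ages=np.array([100.0, 300.0]))
        spec = MethodSpec(method="WAPLS", n_components=2)
        plain = ps.reconstruct(spec, pct, {"T_winter": env["T_winter"]}, fossil)
        with_e = ps.reconstruct(spec, pct, {"T_winter": env["T_winter"]},
                                fossil, with_errors=True, n_boot=60, seed=1)
        np.testing.assert_allclose(plain.predictions["T_winter"],
                                   with_e.predictions["T_winter"], atol=1e-12)
        assert (with_e.errors["T_winter"] > 0).all()

    def test_unmatched_taxa_warn_and_flag_low_coverage(self, small_training):
        _, _, taxa, env = small_training
        pct = ps.to_percentages(taxa)
        vals = np.column_stack([pct.values[:2], [5.0, 400.0]])
        fossil = ps.TaxonTable(("f0", "f1"), pct.taxon_ids + ("ghost",), vals,
                               ages=np.array([0.0, 100.0]))
        with pytest.warns(UserWarning, match="not in training"):
            series = ps.reconstruct(MethodSpec(method="WA"), pct,
                                    {"T_winter": env["T_winter"]}, fossil)
        assert not series.flagged_low_coverage[0]
        assert series.flagged_low_coverage[1]
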