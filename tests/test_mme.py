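"""REML and BLUP engine against closed-form and duality oracles."""

import numpy as np
import pytest

from pigpred.core import DataError, RelationshipMatrix
from pigpred.mme import (ModelSpec, RandomTerm, VarianceComponents, fit_gfblup,
                         genomic_term, identity_term, intercept_model, reml,
                         solve_blup)
from pigpred.relmat import g_matrix, h_inverse, make_gw

from conftest import random_panel, random_pedigree


class TestReml:
    def test_genomic_heritability_recovery(self):
        """h2-hat from a marker-based G is near the simulated truth."""
        ests = []
        for seed in range(5):
            panel = random_panel(400, 600, seed=seed)
            G = g_matrix(panel)
            rng = np.random.default_rng(1000 + seed)
            g = rng.multivariate_normal(np.zeros(400), 0.5 * G.values)
            y = 2.0 + g + rng.normal(0, np.sqrt(0.5), size=400)
            vc = reml(intercept_model(y, [genomic_term("g", panel.ids, G)]))
            ests.append(vc.h2("g"))
        assert abs(np.mean(ests) - 0.5) < 0.1

    def test_balanced_oneway_closed_form(self):
        """REML on balanced groups equals the closed-form ANOVA REML."""
        rng = np.random.default_rng(3)
        k, r = 10, 8  # 10 groups of 8
        group_eff = rng.normal(0, 1.0, size=k)
        y = np.concatenate([ge + rng.normal(0, 0.7, size=r) for ge in group_eff])
        groups = np.repeat(np.arange(k), r)
        term = identity_term("g", groups)
        vc = reml(intercept_model(y, [term]))
        # closed form from the ANOVA mean squares (REML = ANOVA for
        # balanced one-way designs when estimates are interior)
        gm = y.reshape(k, r).mean(axis=1)
        msb = r * np.sum((gm - y.mean()) ** 2) / (k - 1)
        msw = np.sum((y.reshape(k, r) - gm[:, None]) ** 2) / (k * (r - 1))
        sig_g = (msb - msw) / r
        assert vc.sigma2_e == pytest.approx(msw, rel=1e-4)
        assert vc.sigma2["g"] == pytest.approx(sig_g, rel=1e-4)

    def test_residual_only_degenerate_model(self):
        """With the genetic variance pinned at the floor, sigma2_e matches
        the restricted variance of the fixed-effects residuals."""
        rng = np.random.default_rng(4)
        y = rng.normal(size=200)
        X = np.ones((200, 1))
        # one random term whose covariance is ~0 (floored): all variance
        # flows to the residual
        term = RandomTerm(label="g", Z=np.eye(200) * 1e-8,
                          level_ids=list(range(200)), identity=True)
        vc = reml(ModelSpec(y=y, X=X, terms=[term]))
        expected = np.sum((y - y.mean()) ** 2) / (200 - 1)
        assert vc.sigma2_e == pytest.approx(expected, rel=1e-3)

    def test_spectral_matches_ai_path(self):
        """The fast single-term path and the AI iteration agree."""
        panel = random_panel(120, 300, seed=5)
        G = g_matrix(panel)
        rng = np.random.default_rng(5)
        u = rng.multivariate_normal(np.zeros(120), 0.4 * G.values)
        y = 1.0 + u + rng.normal(0, np.sqrt(0.6), 120)
        model = intercept_model(y, [genomic_term("g", panel.ids, G)])
        vc_fast = reml(model)
        vc_ai = reml(model, use_ai=False, max_iter=3000, par_tol=1e-5)
        assert vc_fast.h2("g") == pytest.approx(vc_ai.h2("g"), abs=0.02)

    def test_em_loglik_monotone(self):
        """EM fallback iterations never decrease the restricted likelihood."""
        panel = random_panel(80, 150, seed=6)
        G = g_matrix(panel)
        rng = np.random.default_rng(6)
        y = rng.normal(size=80) + rng.multivariate_normal(np.zeros(80),
                                                          0.5 * G.values)
        terms = [genomic_term("g", panel.ids, G),
                 identity_term("pe", panel.ids)]
        from pigpred.mme import RemlNonConvergence

        try:
            vc = reml(ModelSpec(y=y, X=np.ones((80, 1)), terms=terms),
                      use_ai=False, max_iter=60)
            trace = vc.trace
        except RemlNonConvergence as exc:
            trace = exc.trace
        diffs = np.diff(trace)
        assert np.all(diffs > -1e-9)


class TestSolveBlup:
    def test_shrinkage_closed_form(self):
        """G = I, lambda = 1: each centred record is halved."""
        y = np.array([1.0, -1.0])
        term = identity_term("g", ["a", "b"])
        vc = VarianceComponents(sigma2={"g": 1.0}, sigma2_e=1.0, loglik=0.0)
        sol = solve_blup(intercept_model(y, [term]), vc)
        assert sol.beta[0] == pytest.approx(0.0, abs=1e-12)
        assert sol.u["g"] == pytest.approx([0.5, -0.5])

    def test_constant_response_gives_zero_predictions(self):
        y = np.full(6, 3.7)
        term = identity_term("g", list("abcdef"))
        vc = VarianceComponents(sigma2={"g": 0.5}, sigma2_e=0.5, loglik=0.0)
        sol = solve_blup(intercept_model(y, [term]), vc)
        assert sol.beta[0] == pytest.approx(3.7)
        assert np.allclose(sol.u["g"], 0.0, atol=1e-10)

    def test_gblup_equals_snp_blup_ridge(self):
        """GEBV from G = ZZ'/c match Z @ (ridge marker effects) (duality)."""
        panel = random_panel(50, 200, seed=7)
        rng = np.random.default_rng(7)
        y = rng.normal(size=50)
        G = g_matrix(panel)
        c = G.meta["scale"]
        vc = VarianceComponents(sigma2={"g": 0.3}, sigma2_e=0.7, loglik=0.0)
        model = intercept_model(y, [genomic_term("g", panel.ids, G)])
        sol = solve_blup(model, vc)
        # ridge-regression oracle with the matched penalty
        p = panel.dosages.mean(axis=0) / 2
        Z = panel.dosages - 2 * p
        lam = c * vc.sigma2_e / vc.sigma2["g"]
        n, m = Z.shape
        yc = y - y.mean()
        # absorb the intercept by centring; solve (Z'Z + lam I) a = Z'yc
        # jointly with the mean via GLS equivalence on centred data
        one = np.ones(n)
        V = vc.sigma2["g"] / c * (Z @ Z.T) + vc.sigma2_e * np.eye(n)
        Vi = np.linalg.inv(V)
        mu = (one @ Vi @ y) / (one @ Vi @ one)
        a = np.linalg.solve(Z.T @ Z + lam * np.eye(m), Z.T @ (y - mu * one))
        assert np.allclose(sol.u["g"], Z @ a, atol=1e-8)

    def test_prediction_invariant_to_response_shift(self):
        panel = random_panel(40, 100, seed=8)
        G = g_matrix(panel)
        rng = np.random.default_rng(8)
        y = rng.normal(size=40)
        vc = VarianceComponents(sigma2={"g": 0.4}, sigma2_e=0.6, loglik=0.0)
        m1 = intercept_model(y, [genomic_term("g", panel.ids, G)])
        m2 = intercept_model(y + 100.0, [genomic_term("g", panel.ids, G)])
        s1, s2 = solve_blup(m1, vc), solve_blup(m2, vc)
        assert np.allclose(s1.u["g"], s2.u["g"], atol=1e-8)
        assert s2.beta[0] - s1.beta[0] == pytest.approx(100.0)


class TestSsgblupDegeneracies:
    def test_all_genotyped_equals_gblup_on_gw(self):
        ped = random_pedigree(30, seed=9)
        panel = random_panel(30, 200, seed=9)
        panel.ids = ped.ids
        Gw = make_gw(panel, ped)
        rng = np.random.default_rng(9)
        y = rng.normal(size=30)
        vc = VarianceComponents(sigma2={"g": 0.4}, sigma2_e=0.6, loglik=0.0)
        gblup = solve_blup(intercept_model(y, [genomic_term("g", ped.ids, Gw)]), vc)
        parts = h_inverse(ped, Gw, ped.ids)
        from pigpred.mme import incidence

        Z, _ = incidence(ped.ids, ped.ids)
        ss_term = RandomTerm(label="g", Z=Z, level_ids=ped.ids, inv_parts=parts)
        ss = solve_blup(intercept_model(y, [ss_term]), vc)
        assert np.allclose(gblup.u["g"], ss.u["g"], atol=1e-8)

    def test_none_genotyped_equals_pedigree_blup(self):
        ped = random_pedigree(25, seed=10)
        rng = np.random.default_rng(10)
        y = rng.normal(size=25)
        vc = VarianceComponents(sigma2={"g": 0.3}, sigma2_e=0.7, loglik=0.0)
        from pigpred.core import RelationshipMatrix
        from pigpred.mme import incidence
        from pigpred.relmat import a_matrix

        A = a_matrix(ped)
        ped_blup = solve_blup(intercept_model(y, [genomic_term("g", ped.ids, A)]),
                              vc)
        parts = h_inverse(ped, RelationshipMatrix(ids=[], values=np.zeros((0, 0))),
                          [])
        Z, _ = incidence(ped.ids, ped.ids)
        term = RandomTerm(label="g", Z=Z, level_ids=ped.ids, inv_parts=parts)
        ss = solve_blup(intercept_model(y, [term]), vc)
        assert np.allclose(ped_blup.u["g"], ss.u["g"], atol=1e-8)


class TestGfblup:
    def test_full_feature_reduces_to_gblup(self):
        panel = random_panel(40, 120, seed=11)
        rng = np.random.default_rng(11)
        y = rng.normal(size=40)
        sol, vc, ids = fit_gfblup(y, panel.ids, panel.marker_ids, panel)
        G = g_matrix(panel)
        gb = solve_blup(intercept_model(y, [genomic_term("f", panel.ids, G)]), vc)
        assert vc.sigma2["r"] == 0.0
        assert np.allclose(sol.total(["f", "r"]), gb.u["f"], atol=1e-8)

    def test_empty_feature_rejected(self):
        panel = random_panel(20, 50, seed=12)
        with pytest.raises(DataError, match="GBLUP"):
            fit_gfblup(np.zeros(20), panel.ids, [], panel)

    def test_random_split_symmetric_under_null(self):
        """A random 50/50 marker split should not favour either half."""
        diffs = []
        for seed in range(8):
            panel = random_panel(60, 200, seed=100 + seed)
            rng = np.random.default_rng(200 + seed)
            y = rng.normal(size=60)
            half = panel.marker_ids[:100]
            _, vc, _ = fit_gfblup(y, panel.ids, half, panel)
            tot = vc.sigma2["f"] + vc.sigma2["r"]
            if tot > 0:
                diffs.append((vc.sigma2["f"] - vc.sigma2["r"]) / (tot + vc.sigma2_e))
        assert abs(np.mean(diffs)) < 0.15

    def test_causal_feature_enriched(self):
        """A feature holding the causal markers should absorb more variance
        than its marker share."""
        rng = np.random.default_rng(13)
        enrich = []
        for seed in range(3):
            panel = random_panel(150, 300, seed=300 + seed)
            causal = list(range(0, 30))
            eff = np.random.default_rng(400 + seed).normal(size=30)
            g = panel.dosages[:, causal] @ eff
            g = (g - g.mean()) / g.std() * np.sqrt(0.4)
            y = g + np.random.default_rng(500 + seed).normal(
                0, np.sqrt(0.6), 150)
            feat = [panel.marker_ids[j] for j in causal]
            _, vc, _ = fit_gfblup(y, panel.ids, feat, panel)
            share = vc.sigma2["f"] / (vc.sigma2["f"] + vc.sigma2["r"] + 1e-12)
            enrich.append(share)
        assert np.mean(enrich) > 30 / 300
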