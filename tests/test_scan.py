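"""REML, Wald tests, effective markers, threshold, scan and selection."""

import numpy as np
import pytest

from hybridqtl import (
    base_fixed_matrix,
    build_model_designs,
    build_population_design,
    effective_marker_count,
    fit_lsmeans,
    forward_backward_select,
    genomewide_threshold,
    hybrid_founder_probs,
    origin_posteriors,
    reml_fit,
    single_marker_scan,
)
from hybridqtl.mixedmodel import added_block_test, wald_from_cov


def _crossed_design(n, reuse, rng):
    npar = max(n // reuse, 1)
    idx_d = np.resize(np.repeat(np.arange(npar), reuse), n)
    idx_f = rng.permutation(idx_d)
    ZD = np.zeros((n, npar))
    ZF = np.zeros((n, npar))
    ZD[np.arange(n), idx_d] = 1
    ZF[np.arange(n), idx_f] = 1
    return ZD, ZF


class TestREML:
    def test_zero_components_hit_boundary_and_match_ols(self):
        rng = np.random.default_rng(2)
        n = 300
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = X @ np.array([1.0, 0.5, -0.5]) + rng.normal(0, 1.5, n)
        ZD, ZF = _crossed_design(n, 3, rng)
        fit = reml_fit(y, X, ZD, ZF)
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        mse = np.sum((y - X @ beta) ** 2) / (n - X.shape[1])
        assert fit.vc.boundary
        assert fit.vc.sigma2_D < 0.2 and fit.vc.sigma2_F < 0.2
        assert fit.vc.sigma2_e == pytest.approx(mse, rel=0.05)

    def test_each_parent_once_flags_confounding(self):
        rng = np.random.default_rng(3)
        n = 100
        ZD, ZF = _crossed_design(n, 1, rng)
        X = np.ones((n, 1))
        fit = reml_fit(rng.normal(size=n), X, ZD, ZF)
        assert fit.vc.confounded

    def test_parameter_recovery_with_reuse(self):
        # parents reused twice on average; REML estimates scatter widely at
        # this size, so compare the replicate mean to truth within its own
        # Monte-Carlo standard error
        rng = np.random.default_rng(11)
        truth = np.array([4.0, 2.0, 8.0])
        est = []
        for _ in range(20):
            n = 500
            ZD, ZF = _crossed_design(n, 2, rng)
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
            y = (
                X @ np.array([1.0, 2.0, 0.0])
                + ZD @ rng.normal(0, np.sqrt(truth[0]), ZD.shape[1])
                + ZF @ rng.normal(0, np.sqrt(truth[1]), ZF.shape[1])
                + rng.normal(0, np.sqrt(truth[2]), n)
            )
            f = reml_fit(y, X, ZD, ZF)
            est.append([f.vc.sigma2_D, f.vc.sigma2_F, f.vc.sigma2_e])
        est = np.asarray(est)
        se = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        assert np.all(np.abs(est.mean(axis=0) - truth) < 4 * se)

    def test_determinism(self):
        rng = np.random.default_rng(7)
        n = 150
        ZD, ZF = _crossed_design(n, 2, rng)
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = rng.normal(size=n) + ZD @ rng.normal(0, 1, ZD.shape[1])
        f1 = reml_fit(y, X, ZD, ZF)
        f2 = reml_fit(y, X, ZD, ZF)
        assert f1.vc.sigma2_D == pytest.approx(f2.vc.sigma2_D, abs=1e-8)
        assert np.allclose(f1.beta, f2.beta, atol=1e-8)


class TestWald:
    def test_wald_equals_q_times_f_when_components_zero(self):
        rng = np.random.default_rng(4)
        n, q = 200, 3
        X0 = np.column_stack([np.ones(n), rng.normal(size=(n, 4))])
        B = rng.normal(size=(n, q))
        y = X0 @ rng.normal(size=5) + 0.3 * B[:, 0] + rng.normal(size=n)
        fit = reml_fit(y, np.hstack([X0, B]), None, None, fix_zero=True)
        # OLS F for the block
        full = np.hstack([X0, B])
        b_full, _, _, _ = np.linalg.lstsq(full, y, rcond=None)
        rss1 = np.sum((y - full @ b_full) ** 2)
        b0, _, _, _ = np.linalg.lstsq(X0, y, rcond=None)
        rss0 = np.sum((y - X0 @ b0) ** 2)
        F = ((rss0 - rss1) / q) / (rss1 / (n - full.shape[1]))
        # added-last Wald on the residualized block
        Q, _ = np.linalg.qr(X0)
        y_res = y - Q @ (Q.T @ y)
        B_res = B - Q @ (Q.T @ B)
        glob, _, _ = added_block_test(y_res, B_res, fit.vc.sigma2_e)
        assert glob.df == q
        assert glob.W == pytest.approx(q * F, rel=1e-10)

    def test_reference_founder_choice_leaves_p_invariant(self, small_design):
        d = small_design
        probs = origin_posteriors(d.lines, d.founders, d.gmap, 1e-3)
        hp = hybrid_founder_probs(d.pedigree, probs)
        pop = build_population_design(d.pedigree)
        X0, _ = base_fixed_matrix(pop)
        ls = fit_lsmeans(d.plots)
        y = ls.aligned_to(d.pedigree.table["hybrid_id"])
        j = 12
        D, Fp = hp.dent[:, j, :], hp.flint[:, j, :]
        X_DF = (D[:, :, None] * Fp[:, None, :]).reshape(len(y), 16)

        def reduced(ref):
            keep_g = [k for k in range(4) if k != ref]
            keep_sca = [4 * a + b for a in keep_g for b in keep_g]
            return np.hstack([D[:, keep_g], Fp[:, keep_g], X_DF[:, keep_sca]])

        fit = reml_fit(y, X0, pop.Z_D, pop.Z_F)
        Q, _ = np.linalg.qr(fit.whiten(X0))
        yw = fit.whiten(y)
        y_res = yw - Q @ (Q.T @ yw)
        results = []
        for ref in (0, 2):
            Bw = fit.whiten(reduced(ref))
            B_res = Bw - Q @ (Q.T @ Bw)
            glob, _, _ = added_block_test(y_res, B_res, fit.vc.sigma2_e)
            results.append(glob)
        assert results[0].df == results[1].df
        assert results[0].W == pytest.approx(results[1].W, rel=1e-8)

    def test_singular_block_uses_reduced_rank(self):
        rng = np.random.default_rng(6)
        n = 80
        b = rng.normal(size=3)
        cov = np.diag([1.0, 1.0, 0.0])  # third contrast inestimable
        res = wald_from_cov(b, cov, np.arange(3))
        assert res.df == 2
        assert res.W == pytest.approx(b[0] ** 2 + b[1] ** 2)


class TestEffectiveMarkers:
    def test_independent_markers_count_fully(self):
        rng = np.random.default_rng(9)
        M = rng.normal(size=(4000, 12))
        chrom = np.ones(12)
        m_eff = effective_marker_count(M, chrom, cutoff=0.999)
        assert m_eff >= 11  # near-identity correlation

    def test_identical_markers_collapse_to_one(self):
        col = np.random.default_rng(1).normal(size=500)
        M = np.tile(col[:, None], (1, 8))
        assert effective_marker_count(M, np.ones(8)) == 1.0

    def test_matches_independent_eigendecomposition(self, small_design):
        d = small_design
        probs = origin_posteriors(d.lines, d.founders, d.gmap, 1e-3)
        hp = hybrid_founder_probs(d.pedigree, probs)
        ds = build_model_designs("founder_alleles", d.pedigree, d.gmap, hybrid_probs=hp)
        got = effective_marker_count(ds.predictor_summary, d.gmap.chrom, 0.995)
        # oracle: dense recount per chromosome
        expected = 0
        for c in (1, 2):
            cols = np.flatnonzero(d.gmap.chrom == c)
            sub = ds.predictor_summary[:, cols]
            sub = sub[:, sub.std(axis=0) > 0]
            lam = np.sort(np.linalg.eigvalsh(np.corrcoef(sub, rowvar=False)))[::-1]
            k = 1
            while lam[:k].sum() < 0.995 * len(lam):
                k += 1
            expected += k
        assert got == expected

    @pytest.mark.parametrize("m_eff,expected", [(1, 1.3010), (1000, 4.3010)])
    def test_threshold_values(self, m_eff, expected):
        assert genomewide_threshold(m_eff) == pytest.approx(expected, abs=2e-4)

    def test_threshold_monotone(self):
        vals = [genomewide_threshold(m) for m in (1, 10, 100, 1000)]
        assert all(a < b for a, b in zip(vals, vals[1:]))


@pytest.fixture(scope="module")
def scan_inputs(small_design):
    d = small_design
    probs = origin_posteriors(d.lines, d.founders, d.gmap, 1e-3)
    hp = hybrid_founder_probs(d.pedigree, probs)
    pop = build_population_design(d.pedigree)
    X0, _ = base_fixed_matrix(pop)
    y = fit_lsmeans(d.plots).aligned_to(d.pedigree.table["hybrid_id"])
    return d, hp, pop, X0, y


class TestScanAndSelection:
    def test_founder_scan_localizes_the_qtl(self, scan_inputs):
        d, hp, pop, X0, y = scan_inputs
        ds = build_model_designs("founder_alleles", d.pedigree, d.gmap, hybrid_probs=hp)
        scan = single_marker_scan(y, X0, pop.Z_D, pop.Z_F, ds, vc_mode="profile")
        top = scan.top_marker()
        true_pos = d.truth.qtl["pos_cM"].iloc[0]
        assert top["chrom"] == 1
        assert abs(top["pos_cM"] - true_pos) <= 10.0
        assert (scan.table["df"] == 15).all()
        assert (scan.table["df_GCA_D"] == 3).all()
        assert (scan.table["df_SCA"] == 9).all()

    def test_reestimate_vs_profile_modes(self, scan_inputs):
        # off-QTL the two variance-component strategies agree closely; at a
        # strong QTL the profiled scan is the conservative one (the base
        # model's inflated residual lowers its statistics)
        d, hp, pop, X0, y = scan_inputs
        mask = np.zeros(d.gmap.n_markers, dtype=bool)
        mask[10:14] = True  # spans the simulated QTL
        mask[30:34] = True  # chromosome 2, no QTL
        ds_small = build_model_designs(
            "founder_alleles", d.pedigree, d.gmap, hybrid_probs=hp, scan_mask=mask
        )
        s1 = single_marker_scan(y, X0, pop.Z_D, pop.Z_F, ds_small, vc_mode="reestimate").table
        s2 = single_marker_scan(y, X0, pop.Z_D, pop.Z_F, ds_small, vc_mode="profile").table
        null_side = s1["chrom"] == 2
        assert np.allclose(
            s1.loc[null_side, "neglog10p"], s2.loc[null_side, "neglog10p"], rtol=0.2, atol=0.3
        )
        assert (s2.loc[~null_side, "neglog10p"] <= s1.loc[~null_side, "neglog10p"] + 1e-9).all()
        assert s1["neglog10p"].idxmax() == s2["neglog10p"].idxmax()

    def test_no_marker_above_threshold_gives_empty_model(self, scan_inputs):
        d, hp, pop, X0, y = scan_inputs
        ds = build_model_designs("founder_alleles", d.pedigree, d.gmap, hybrid_probs=hp)
        fit = forward_backward_select(y, X0, pop.Z_D, pop.Z_F, ds, threshold=50.0)
        assert fit.selected == []
        assert fit.converged

    def test_selection_recovers_qtl_and_conditional_tests(self, scan_inputs):
        d, hp, pop, X0, y = scan_inputs
        ds = build_model_designs("founder_alleles", d.pedigree, d.gmap, hybrid_probs=hp)
        m_eff = effective_marker_count(ds.predictor_summary, d.gmap.chrom)
        thr = genomewide_threshold(m_eff)
        fit = forward_backward_select(y, X0, pop.Z_D, pop.Z_F, ds, thr)
        assert len(fit.selected) >= 1
        best = fit.qtl_table.sort_values("neglog10p", ascending=False).iloc[0]
        assert best["chrom"] == 1
        assert abs(best["pos_cM"] - d.truth.qtl["pos_cM"].iloc[0]) <= 10.0
        assert (fit.qtl_table["neglog10p"] > thr).all()

    def test_component_flags_follow_thresholds(self, scan_inputs):
        from hybridqtl import component_tests

        d, hp, pop, X0, y = scan_inputs
        ds = build_model_designs("founder_alleles", d.pedigree, d.gmap, hybrid_probs=hp)
        fit = forward_backward_select(y, X0, pop.Z_D, pop.Z_F, ds, threshold=3.0)
        flags = component_tests(fit, alpha_individual=0.05)
        for name in ("GCA_D", "GCA_F", "SCA"):
            expect = flags[f"neglog10p_{name}"] > -np.log10(0.05)
            assert (flags[f"{name}_sig_individual"] == expect).all()
            # genome-wide significance implies individual significance
            assert not (
                flags[f"{name}_sig_genomewide"] & ~flags[f"{name}_sig_individual"]
            ).any()
        # the simulated QTL is a pure Dent GCA effect
        top = flags.sort_values("neglog10p", ascending=False).iloc[0]
        assert top["GCA_D_sig_individual"]
        assert not top["SCA_sig_individual"]

    def test_perfect_ld_retains_exactly_one(self, scan_inputs):
        d, hp, pop, X0, y = scan_inputs
        # duplicate the QTL marker's design at another map position
        ds = build_model_designs("founder_alleles", d.pedigree, d.gmap, hybrid_probs=hp)
        j_true = int(d.truth.qtl["marker_index"].iloc[0])
        mask = np.zeros(d.gmap.n_markers, dtype=bool)
        j_copy = d.gmap.n_markers - 1  # other chromosome
        mask[[j_true, j_copy]] = True
        ds.designs[j_copy] = ds.designs[j_true]
        ds.scan_mask = mask
        fit = forward_backward_select(y, X0, pop.Z_D, pop.Z_F, ds, threshold=2.0)
        assert len(fit.selected) == 1
        assert fit.selected[0] == j_true  # tie broken by lower map position
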