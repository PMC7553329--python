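"""Pseudo-AIC/BIC machinery: moment estimates, residual variance, df, criteria."""

import copy

import numpy as np
import pandas as pd
import pytest

from prsum import (
    InputError,
    PenaltySpec,
    ProvenanceError,
    PRSModel,
    ReferencePanel,
    SimConfig,
    compute_gwas,
    degrees_of_freedom,
    estimate_moments,
    estimate_sigma2,
    estimate_sse,
    fit_path,
    harmonize,
    pseudo_criteria,
    select_sigma2_subset,
    simulate_study,
    split_reference_panel,
)
from prsum.io import blocks_from_sizes
from prsum.pipeline import problem_from_study


def _exact_setup(seed=21, n=400, m=25, h2=0.4):
    """Training data reused as its own unregularized panel, moment-matched stats."""
    rng = np.random.default_rng(seed)
    cfg = SimConfig(
        n_snps=m, splits={"train": n}, block_sizes=[m],
        within_block_rho=0.4, p_causal=0.2, h2=h2, seed=seed,
    )
    study = simulate_study(cfg)
    X = study.genotypes["train"].astype(float)
    y = study.phenotypes["train"]
    ss = compute_gwas(X, y, snps=study.snps, se_method="ml")
    panel = ReferencePanel(X, study.snps.copy(), provenance="train-as-panel")
    problem = harmonize(ss, panel, blocks_from_sizes([m]), ld_clump_r2=1.0)
    moments = estimate_moments(problem, panel, reg=0.0)
    return study, X, y, problem, panel, moments


class TestMoments:
    def test_null_snp_algebra(self):
        # single SNP with beta=0 and var(beta) = 1/(N s^2): yty = N s^2/(N s^2) = 1
        from prsum import SummaryStats

        rng = np.random.default_rng(0)
        meta = pd.DataFrame(
            {"snp_id": ["rs0"], "chrom": ["1"], "pos": [1], "a1": ["A"], "a2": ["G"]}
        )
        panel = ReferencePanel(rng.integers(0, 3, size=(500, 1)).astype(float), meta)
        s2 = panel.sd()[0] ** 2
        n = 100.0
        df = meta.assign(beta=0.0, se=np.sqrt(1.0 / (n * s2)), n=n, pvalue=1.0)
        prob = harmonize(SummaryStats(df), panel)
        mom = estimate_moments(prob, panel, reg=0.0)
        assert mom.yty_per_n == pytest.approx(1.0, rel=1e-9)

    def test_yty_tracks_phenotype_variance(self, small_study):
        problem, _ = problem_from_study(small_study)
        panel = small_study.panel("tune2")
        mom = estimate_moments(problem, panel)
        var_y = small_study.phenotypes["train"].var()
        assert mom.yty_per_n == pytest.approx(var_y, rel=0.1)

    def test_xty_matches_individual_level(self):
        _, X, y, problem, panel, moments = _exact_setup()
        rows = moments.rows
        cols = problem.df["panel_col"].to_numpy()[rows]
        Xc = X[:, cols] - X[:, cols].mean(axis=0)
        yc = y - y.mean()
        np.testing.assert_allclose(moments.xty_per_n, Xc.T @ yc / len(y), atol=1e-10)

    def test_binary_unconverted_rejected(self, small_study):
        problem, _ = problem_from_study(small_study)
        problem.is_binary_trait = True
        with pytest.raises(InputError, match="binary"):
            estimate_moments(problem, small_study.panel("tune2"))

    def test_provenance_guard(self, small_study):
        problem, panel_fit = problem_from_study(small_study)
        with pytest.raises(ProvenanceError):
            estimate_moments(
                problem, panel_fit, fit_panel_provenance=panel_fit.provenance
            )


class TestSigma2:
    def test_empty_subset_returns_yty(self, small_study):
        problem, _ = problem_from_study(small_study)
        mom = estimate_moments(problem, small_study.panel("tune2"))
        got = estimate_sigma2(mom, np.array([], dtype=int))
        assert got == pytest.approx(mom.yty_per_n)

    def test_null_trait_sigma2_near_var_y(self):
        rng = np.random.default_rng(31)
        cfg = SimConfig(
            n_snps=100, splits={"train": 2000, "tune2": 800}, block_sizes=[25] * 4,
            p_causal=0.01, h2=0.0, seed=31,
        )
        study = simulate_study(cfg)
        y = rng.standard_normal(2000)
        ss = compute_gwas(study.genotypes["train"], y, snps=study.snps)
        panel = study.panel("tune2")
        prob = harmonize(ss, panel, study.blocks)
        mom = estimate_moments(prob, panel)
        subset = select_sigma2_subset(prob, panel)
        sigma2 = estimate_sigma2(mom, subset)
        assert sigma2 == pytest.approx(y.var(), rel=0.1)

    def test_heritable_trait_residual_variance_bracketed(self):
        # h2=0.5: the pruned-and-thresholded subset captures part of the signal,
        # so sigma2 sits between 40% and 80% of var(y); checked against the
        # individual-level OLS MSE on the same subset (the deliberate covariance
        # regularization biases sigma2 up by ~10%, so the comparison is on the
        # median deviation)
        hits, deviations = 0, []
        n_seeds = 5
        for seed in range(n_seeds):
            cfg = SimConfig(
                n_snps=200, splits={"train": 2000, "tune2": 800}, block_sizes=[25] * 8,
                p_causal=0.05, h2=0.5, seed=100 + seed,
            )
            study = simulate_study(cfg)
            X, y = study.genotypes["train"].astype(float), study.phenotypes["train"]
            ss = compute_gwas(X, y, snps=study.snps)
            panel = study.panel("tune2")
            prob = harmonize(ss, panel, study.blocks)
            mom = estimate_moments(prob, panel)
            subset = select_sigma2_subset(prob, panel)
            if subset.size == 0:
                continue
            sigma2 = estimate_sigma2(mom, subset)
            if 0.4 * y.var() < sigma2 < 0.8 * y.var():
                hits += 1
            cols = prob.df["panel_col"].to_numpy()[subset]
            Xc = X[:, cols] - X[:, cols].mean(axis=0)
            yc = y - y.mean()
            coef, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
            mse = np.sum((yc - Xc @ coef) ** 2) / (len(y) - len(subset))
            deviations.append(abs(sigma2 - mse) / mse)
        assert hits >= n_seeds - 1
        assert np.median(deviations) < 0.15

    def test_q_at_least_n_rejected(self, small_study):
        problem, _ = problem_from_study(small_study)
        mom = estimate_moments(problem, small_study.panel("tune2"))
        with pytest.raises(InputError):
            estimate_sigma2(mom, np.array([0]), q=int(mom.N))


class TestExactRecovery:
    """With the training genotypes as an unregularized panel and moment-matched
    summary statistics, the summary-level SSE and residual variance reproduce
    their individual-level counterparts exactly."""

    def test_sse_matches_individual_level(self):
        study, X, y, problem, panel, moments = _exact_setup()
        rng = np.random.default_rng(5)
        beta = np.zeros(len(problem.df))
        nz = rng.choice(len(beta), size=6, replace=False)
        beta[nz] = rng.normal(0, 0.1, size=6)
        model = PRSModel(beta, PenaltySpec("lasso", 0.01), objective_value=0.0)
        got = estimate_sse(model, moments)
        b = beta[moments.rows] * moments.sd_y / np.sqrt(moments.s2)
        cols = problem.df["panel_col"].to_numpy()[moments.rows]
        Xc = X[:, cols] - X[:, cols].mean(axis=0)
        yc = y - y.mean()
        true_sse = float(np.sum((yc - Xc @ b) ** 2))
        assert got == pytest.approx(true_sse, rel=1e-9)

    def test_sigma2_matches_ols_mse(self):
        study, X, y, problem, panel, moments = _exact_setup()
        subset = np.arange(5)
        got = estimate_sigma2(moments, subset)
        cols = problem.df["panel_col"].to_numpy()[subset]
        Xc = X[:, cols] - X[:, cols].mean(axis=0)
        yc = y - y.mean()
        coef = np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)
        mse = float(np.sum((yc - Xc @ coef) ** 2) / (len(y) - 5))
        assert got == pytest.approx(mse, rel=1e-9)

    def test_null_model_sse_is_n_times_yty(self, small_study):
        problem, _ = problem_from_study(small_study)
        mom = estimate_moments(problem, small_study.panel("tune2"))
        model = PRSModel(np.zeros(len(problem.df)), PenaltySpec("lasso", 1.0), 0.0)
        assert estimate_sse(model, mom) == pytest.approx(mom.N * mom.yty_per_n)

    def test_sse_nonnegative_for_random_models(self, small_study, rng):
        problem, _ = problem_from_study(small_study)
        mom = estimate_moments(problem, small_study.panel("tune2"))
        for _ in range(10):
            beta = rng.normal(0, 0.3, size=len(problem.df))
            model = PRSModel(beta, PenaltySpec("lasso", 0.01), 0.0)
            assert estimate_sse(model, mom) >= 0.0


class TestDegreesOfFreedom:
    def _model_and_moments(self, small_study, lam=0.03, s=0.1):
        problem, panel = problem_from_study(small_study)
        (model,) = fit_path(problem, panel, [PenaltySpec("lasso", lam, s)])
        mom = estimate_moments(problem, small_study.panel("tune2"))
        return model, mom

    def test_nonzero_mode_counts(self, small_study):
        model, mom = self._model_and_moments(small_study)
        assert degrees_of_freedom(model, mom, mode="nonzero") == model.n_nonzero

    def test_large_shrinkage_drives_df_to_zero(self, small_study):
        model, mom = self._model_and_moments(small_study)
        assert degrees_of_freedom(model, mom, mode="ridge", lam_s=1e9) < 1e-5

    def test_zero_shrinkage_full_rank_counts_snps(self, small_study):
        model, mom = self._model_and_moments(small_study)
        got = degrees_of_freedom(model, mom, mode="ridge", lam_s=0.0)
        assert got == pytest.approx(model.n_nonzero, abs=1e-6)

    def test_trace_matches_eigenvalue_sum(self, small_study):
        model, mom = self._model_and_moments(small_study)
        lam_s = 0.5
        got = degrees_of_freedom(model, mom, mode="ridge", lam_s=lam_s)
        nz = model.beta != 0
        s = np.sqrt(mom.s2)
        expect = 0.0
        for pos, C in mom.cov_blocks_raw:
            active = np.flatnonzero(nz[mom.rows[pos]])
            if active.size == 0:
                continue
            Rsub = C[np.ix_(active, active)] / np.outer(s[pos[active]], s[pos[active]])
            d = np.linalg.eigvalsh(Rsub)
            expect += float(np.sum(d / (d + lam_s)))
        assert got == pytest.approx(expect, rel=1e-10)


class TestCriteria:
    def test_aic_bic_identity(self, small_study):
        problem, panel = problem_from_study(small_study)
        models = fit_path(
            problem, panel, [PenaltySpec("lasso", l, s=0.1) for l in (0.08, 0.04, 0.02)]
        )
        panel_sel = small_study.panel("tune2")
        mom = estimate_moments(problem, panel_sel)
        rep = pseudo_criteria(models, mom, panel_half=panel_sel, problem=problem)
        diff = rep.table["pseudo_bic"] - rep.table["pseudo_aic"]
        expect = (np.log(mom.N) - 2.0) * rep.table["k"]
        np.testing.assert_allclose(diff, expect, rtol=1e-12)

    def test_single_candidate_selected(self, small_study):
        problem, panel = problem_from_study(small_study)
        models = fit_path(problem, panel, [PenaltySpec("lasso", 0.05)])
        panel_sel = small_study.panel("tune2")
        mom = estimate_moments(problem, panel_sel)
        rep = pseudo_criteria(models, mom, panel_half=panel_sel, problem=problem)
        assert rep.selected_aic == rep.selected_bic == 0

    def test_penalty_prefers_sparser_model_at_equal_fit(self, small_study):
        problem, panel = problem_from_study(small_study)
        (base,) = fit_path(problem, panel, [PenaltySpec("lasso", 0.04, s=0.1)])
        bloated = copy.deepcopy(base)
        zeros = np.flatnonzero(bloated.beta == 0)[:5]
        bloated.beta[zeros] = 1e-12  # negligible SSE change, 5 extra parameters
        panel_sel = small_study.panel("tune2")
        mom = estimate_moments(problem, panel_sel)
        rep = pseudo_criteria([base, bloated], mom, panel_half=panel_sel, problem=problem)
        assert rep.selected_aic == 0
        assert rep.selected_bic == 0

    def test_fit_half_reuse_raises(self, small_study):
        problem, panel_fit = problem_from_study(small_study)
        models = fit_path(problem, panel_fit, [PenaltySpec("lasso", 0.05)])
        mom_bad = estimate_moments(problem, panel_fit)  # same provenance as fit
        with pytest.raises(ProvenanceError):
            pseudo_criteria(models, mom_bad, panel_half=panel_fit, problem=problem)

    def test_noise_snps_never_help_bic_on_average(self, small_study):
        problem, panel = problem_from_study(small_study)
        (base,) = fit_path(problem, panel, [PenaltySpec("lasso", 0.04, s=0.1)])
        panel_sel = small_study.panel("tune2")
        mom = estimate_moments(problem, panel_sel)
        subset = select_sigma2_subset(problem, panel_sel)
        sigma2 = estimate_sigma2(mom, subset) if subset.size else mom.yty_per_n
        rng = np.random.default_rng(123)
        deltas = []
        for _ in range(20):
            noisy = copy.deepcopy(base)
            zeros = np.flatnonzero(noisy.beta == 0)
            picks = rng.choice(zeros, size=10, replace=False)
            noisy.beta[picks] = rng.normal(0, 0.01, size=10)
            rep = pseudo_criteria([base, noisy], mom, sigma2=sigma2)
            deltas.append(rep.table["pseudo_bic"][1] - rep.table["pseudo_bic"][0])
        assert np.mean(deltas) > 0


class TestSplitPanel:
    def test_halves_disjoint_and_even(self, small_study):
        panel = small_study.panel("tune2")
        a, b = split_reference_panel(panel, seed=9)
        assert a.n_ref + b.n_ref == panel.n_ref
        assert abs(a.n_ref - b.n_ref) <= 1
        # disjoint: stacking the halves reproduces the panel rows as a multiset
        combined = np.vstack([a.genotypes, b.genotypes])
        assert sorted(map(tuple, combined)) == sorted(map(tuple, panel.genotypes))

    def test_same_seed_same_split(self, small_study):
        panel = small_study.panel("tune2")
        a1, _ = split_reference_panel(panel, seed=9)
        a2, _ = split_reference_panel(panel, seed=9)
        np.testing.assert_array_equal(a1.genotypes, a2.genotypes)
        assert a1.provenance == a2.provenance

    def test_too_small_panel(self, small_study):
        panel = small_study.panel("tune2").take_individuals(np.arange(3), "tiny")
        with pytest.raises(InputError):
            split_reference_panel(panel, seed=0)
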