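"""GLM, Freedman-Lane max-T permutation inference, effect sizes, edge-wise
mixed models, the MST/extra paired tests and the split-half null."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from hodgecycles.inference import (
    build_design,
    edgewise_lme,
    effect_sizes,
    fit_glm,
    freedman_lane_maxT,
    paired_t_mst_extra,
    pvalue_convergence,
    split_half_null,
)


def _phenotype(n_per_site, n_sites, seed=0, groups=None):
    rng = np.random.default_rng(seed)
    n = n_per_site * n_sites
    if groups is None:
        groups = np.tile([0, 1], n // 2 + 1)[:n]
    return pd.DataFrame(
        {
            "subject": [f"s{k}" for k in range(n)],
            "group": groups,
            "age": rng.standard_normal(n),
            "sex": rng.integers(0, 2, n),
            "fd": rng.standard_normal(n),
            "site": np.repeat([f"site{j}" for j in range(n_sites)], n_per_site),
        }
    )


class TestBuildDesign:
    def test_single_site_no_dummies(self):
        d = build_design(_phenotype(20, 1))
        assert d.columns == ("const", "group", "age", "sex", "fd")

    def test_three_sites_two_dummies(self):
        d = build_design(_phenotype(10, 3))
        assert sum(c.startswith("site[") for c in d.columns) == 2

    def test_missing_column_named(self):
        with pytest.raises(ValueError, match="fd"):
            build_design(_phenotype(10, 1).drop(columns=["fd"]))

    def test_tiny_stratum_rejected(self):
        pheno = _phenotype(10, 1)
        pheno.loc[0, "site"] = "lonely"
        with pytest.raises(ValueError, match="lonely"):
            build_design(pheno)

    def test_rank_deficiency_reported(self):
        pheno = _phenotype(20, 1)
        pheno["age"] = 0.0  # collinear with nothing to estimate
        with pytest.raises(ValueError, match="rank deficient"):
            build_design(pheno)

    def test_row_shuffle_equivariance(self):
        pheno = _phenotype(12, 2, seed=3)
        rng = np.random.default_rng(1)
        Y = rng.standard_normal((len(pheno), 5))
        perm = rng.permutation(len(pheno))
        f1 = fit_glm(Y, build_design(pheno))
        f2 = fit_glm(Y[perm], build_design(pheno.iloc[perm].reset_index(drop=True)))
        assert np.allclose(f1.t_stat, f2.t_stat, atol=1e-10)


class TestFitGlm:
    def test_reduces_to_two_sample_t(self):
        # intercept + group only: t equals the classical pooled t statistic
        rng = np.random.default_rng(5)
        y = rng.standard_normal(30)
        g = np.repeat([0, 1], 15)
        pheno = pd.DataFrame(
            {
                "subject": [f"s{k}" for k in range(30)],
                "group": g,
                "age": 0.0,
                "sex": 0.0,
                "fd": 0.0,
                "site": "s0",
            }
        )
        # age/sex/fd constant => drop them by building a minimal design
        X = np.column_stack([np.ones(30), g])
        from hodgecycles.inference import DesignMatrix

        d = DesignMatrix(X=X, columns=("const", "group"), site=pheno["site"].to_numpy())
        fit = fit_glm(y[:, None], d)
        t_oracle = scipy.stats.ttest_ind(y[g == 1], y[g == 0], equal_var=True)
        assert fit.t_stat[0] == pytest.approx(t_oracle.statistic, abs=1e-10)

    def test_orthogonal_covariate_leaves_beta_unchanged(self):
        # Frisch-Waugh: a covariate orthogonal to group and Y leaves the
        # group coefficient unchanged
        rng = np.random.default_rng(8)
        n = 40
        g = np.repeat([0.0, 1.0], n // 2)
        y = rng.standard_normal(n)
        X1 = np.column_stack([np.ones(n), g])
        cov = rng.standard_normal(n)
        cov -= X1 @ np.linalg.lstsq(X1, cov, rcond=None)[0]
        from hodgecycles.inference import DesignMatrix

        site = np.array(["s0"] * n)
        d1 = DesignMatrix(X=X1, columns=("const", "group"), site=site)
        d2 = DesignMatrix(
            X=np.column_stack([X1, cov]), columns=("const", "group", "cov"), site=site
        )
        b1 = fit_glm(y[:, None], d1).betas[1, 0]
        b2 = fit_glm(y[:, None], d2).betas[1, 0]
        assert b1 == pytest.approx(b2, abs=1e-10)

    def test_exact_interpolation_recovers_beta(self):
        pheno = _phenotype(12, 2, seed=2)
        d = build_design(pheno)
        rng = np.random.default_rng(0)
        beta = rng.standard_normal((d.X.shape[1], 3))
        Y = d.X @ beta
        fit = fit_glm(Y, d)
        assert np.allclose(fit.betas, beta, atol=1e-10)


class TestEffectSizes:
    def test_zero_beta_gives_zero_effects(self):
        pheno = _phenotype(12, 2, seed=2)
        d = build_design(pheno)
        Y = np.ones((len(pheno), 2)) + 0.001 * np.random.default_rng(0).standard_normal(
            (len(pheno), 2)
        )
        fit = fit_glm(Y, d)
        dd, pr2 = effect_sizes(fit)
        assert np.all(np.abs(dd) < 1.0)
        assert np.all(pr2 >= 0) and np.all(pr2 <= 1)
        assert np.allclose(pr2, fit.t_stat**2 / (fit.t_stat**2 + fit.df))

    def test_matches_classical_cohens_d_two_group(self):
        rng = np.random.default_rng(3)
        y = np.concatenate([rng.standard_normal(40), rng.standard_normal(40) + 0.7])
        g = np.repeat([0, 1], 40)
        from hodgecycles.inference import DesignMatrix

        d = DesignMatrix(
            X=np.column_stack([np.ones(80), g]),
            columns=("const", "group"),
            site=np.array(["s0"] * 80),
        )
        fit = fit_glm(y[:, None], d)
        dd, _ = effect_sizes(fit)
        # classical pooled-SD Cohen's d
        s_pooled = np.sqrt(
            (39 * y[g == 0].var(ddof=1) + 39 * y[g == 1].var(ddof=1)) / 78
        )
        d_oracle = (y[g == 1].mean() - y[g == 0].mean()) / s_pooled
        assert dd[0] == pytest.approx(d_oracle, rel=0.02)

    def test_planted_standardized_shift_recovered(self):
        # d ~ 0.5 for a 0.5-SD shift at large N
        rng = np.random.default_rng(11)
        n = 4000
        g = np.repeat([0, 1], n // 2)
        y = rng.standard_normal(n) + 0.5 * g
        from hodgecycles.inference import DesignMatrix

        d = DesignMatrix(
            X=np.column_stack([np.ones(n), g]),
            columns=("const", "group"),
            site=np.array(["s0"] * n),
        )
        dd, _ = effect_sizes(fit_glm(y[:, None], d))
        assert dd[0] == pytest.approx(0.5, abs=0.08)


class TestFreedmanLane:
    def test_deterministic_under_seed(self, null_cohort):
        from hodgecycles.projection import project

        A = project(null_cohort.edge_matrix, null_cohort.template_basis)
        d = build_design(null_cohort.phenotype)
        r1 = freedman_lane_maxT(A, d, n_perm=120, seed=7)
        r2 = freedman_lane_maxT(A, d, n_perm=120, seed=7)
        assert np.array_equal(r1.p_perm, r2.p_perm)
        assert np.array_equal(r1.p_fwer, r2.p_fwer)

    def test_fwer_dominates_uncorrected_and_global_is_min(self, null_cohort):
        from hodgecycles.projection import project

        A = project(null_cohort.edge_matrix, null_cohort.template_basis)
        d = build_design(null_cohort.phenotype)
        r = freedman_lane_maxT(A, d, n_perm=150, seed=1)
        assert np.all(r.p_fwer >= r.p_perm)
        assert r.global_p == r.p_fwer.min()
        assert np.all(r.p_perm > 0) and np.all(r.p_fwer <= 1)

    def test_huge_effect_hits_estimator_floor(self, effect_cohort):
        from hodgecycles.projection import project

        A = project(effect_cohort.edge_matrix, effect_cohort.template_basis)
        d = build_design(effect_cohort.phenotype)
        r = freedman_lane_maxT(A, d, n_perm=200, seed=3)
        floor = 1.0 / 201.0
        for k in effect_cohort.truth["effect_cycles"]:
            assert r.p_fwer[k] == pytest.approx(floor)

    def test_permutations_stay_within_site(self):
        from hodgecycles.inference import _site_strata, _stratified_permutation

        site = np.repeat(["a", "b", "c"], [4, 6, 5])
        strata = _site_strata(site)
        rng = np.random.default_rng(0)
        for _ in range(20):
            perm = _stratified_permutation(rng, strata, site.size)
            assert np.array_equal(site[perm], site)
            assert np.array_equal(np.sort(perm), np.arange(site.size))

    def test_stratum_of_one_rejected(self):
        pheno = _phenotype(8, 2)
        pheno.loc[0, "site"] = "site1"
        pheno.loc[1:, "site"] = "site0"
        from hodgecycles.inference import DesignMatrix

        d = DesignMatrix(
            X=np.column_stack([np.ones(16), pheno["group"]]),
            columns=("const", "group"),
            site=pheno["site"].to_numpy(),
        )
        with pytest.raises(ValueError, match="size 1"):
            freedman_lane_maxT(np.zeros((16, 2)), d, n_perm=100, seed=0)

    def test_too_few_permutations_rejected(self, null_cohort):
        d = build_design(null_cohort.phenotype)
        with pytest.raises(ValueError, match="n_perm"):
            freedman_lane_maxT(np.zeros((len(null_cohort.phenotype), 2)), d, n_perm=10)


class TestEdgewise:
    def test_single_site_equals_plain_glm(self):
        rng = np.random.default_rng(4)
        pheno = _phenotype(30, 1, seed=4)
        W = rng.standard_normal((30, 6))
        with pytest.warns(UserWarning, match="single site"):
            ew = edgewise_lme(W, pheno)
        d = build_design(pheno)
        fit = fit_glm(W, d)
        p_oracle = 2 * scipy.stats.t.sf(np.abs(fit.t_stat), fit.df)
        assert np.allclose(ew.p, p_oracle, atol=1e-12)
        assert ew.tested.all()

    def test_bh_fdr_matches_step_up_oracle(self):
        # brute-force BH step-up on a fixed p-vector
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.01, 0.02, 0.03, 0.04, 0.5])
        reject = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        # oracle: largest k with p_(k) <= k/m * alpha, reject the k smallest
        order = np.argsort(p)
        thresh = (np.arange(1, 6) / 5) * 0.05
        passed = np.flatnonzero(p[order] <= thresh)
        k = passed.max() + 1 if passed.size else 0
        oracle = np.zeros(5, dtype=bool)
        oracle[order[:k]] = True
        assert np.array_equal(reject, oracle)
        assert np.array_equal(oracle, [True, True, True, True, False])

    def test_mixed_model_detects_planted_edge_effect(self):
        rng = np.random.default_rng(9)
        pheno = _phenotype(20, 3, seed=9)
        n = len(pheno)
        W = rng.normal(0, 0.1, size=(n, 5))
        site_off = {"site0": 0.2, "site1": -0.1, "site2": 0.05}
        W += np.array([site_off[s] for s in pheno["site"]])[:, None]
        W[:, 2] += 0.4 * pheno["group"].to_numpy()
        ew = edgewise_lme(W, pheno, n_contrasts=9)
        assert ew.threshold == pytest.approx(0.05 / 9)
        assert ew.significant[2]
        assert ew.significant.sum() == 1

    def test_q_dominates_p(self):
        rng = np.random.default_rng(2)
        pheno = _phenotype(15, 2, seed=2)
        W = rng.standard_normal((30, 8))
        ew = edgewise_lme(W, pheno)
        ok = ew.tested
        assert np.all(ew.q[ok] >= ew.p[ok] - 1e-12)


class TestPairedMstExtra:
    def test_identical_parts_give_zero_paired_t(self, null_cohort):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((len(null_cohort.phenotype), 6))
        d = build_design(null_cohort.phenotype)
        out = paired_t_mst_extra(A, A.copy(), np.arange(3), d)
        assert np.allclose(out["t_paired"], 0.0, atol=1e-12) or np.all(
            np.isnan(out["t_paired"])
        )

    def test_effect_through_closing_edge_only_flags_extra(self, effect_cohort):
        # the planted shift enters through off-tree edges of each subject's
        # MST far more than through tree edges
        from hodgecycles.projection import subject_splits

        co = effect_cohort
        splits = subject_splits(co.edge_matrix, co.fc_matrices.shape[1], co.template_basis)
        d = build_design(co.phenotype)
        out = paired_t_mst_extra(
            splits.alpha_mst, splits.alpha_extra, np.array(co.truth["effect_cycles"]), d
        )
        assert (out["q_extra"] < 0.05).all()

    def test_empty_selection_rejected(self, null_cohort):
        d = build_design(null_cohort.phenotype)
        with pytest.raises(ValueError, match="empty"):
            paired_t_mst_extra(np.zeros((48, 4)), np.zeros((48, 4)), np.array([]), d)

    def test_fdr_mask_monotone_in_q(self, null_cohort):
        rng = np.random.default_rng(1)
        N = len(null_cohort.phenotype)
        d = build_design(null_cohort.phenotype)
        out = paired_t_mst_extra(
            rng.standard_normal((N, 10)), rng.standard_normal((N, 10)), np.arange(10), d
        )
        for qcol in ("q_mst", "q_extra", "q_paired"):
            loose = out[qcol] < 0.2
            tight = out[qcol] < 0.05
            assert np.all(loose[tight])


class TestSplitHalf:
    def test_deterministic_and_halves_disjoint(self, null_cohort):
        W = null_cohort.edge_matrix
        r1 = split_half_null(W, null_cohort.phenotype, seed=5, n_perm=120)
        r2 = split_half_null(W, null_cohort.phenotype, seed=5, n_perm=120)
        assert r1.global_p == r2.global_p

    def test_homogeneous_controls_not_significant_typically(self, null_cohort):
        # one replicate: p should usually be far from the floor
        r = split_half_null(null_cohort.edge_matrix, null_cohort.phenotype, seed=1, n_perm=200)
        assert r.global_p > 1.0 / 201.0

    def test_small_site_rejected(self):
        pheno = _phenotype(3, 1, groups=np.zeros(3, dtype=int))
        with pytest.raises(ValueError, match=">= 4"):
            split_half_null(np.zeros((3, 6)), pheno, seed=0)


class TestPvalueConvergence:
    def test_final_checkpoint_matches_full_run(self, null_cohort):
        from hodgecycles.projection import project

        A = project(null_cohort.edge_matrix, null_cohort.template_basis)
        d = build_design(null_cohort.phenotype)
        trace = pvalue_convergence(A, d, checkpoints=[100, 150, 200], seed=9)
        full = freedman_lane_maxT(A, d, n_perm=200, seed=9)
        assert trace["global_p"].iloc[-1] == pytest.approx(full.global_p, abs=1e-12)
        assert list(trace["iteration"]) == [100, 150, 200]

    def test_null_trace_within_binomial_envelope(self, null_cohort):
        from hodgecycles.projection import project

        A = project(null_cohort.edge_matrix, null_cohort.template_basis)
        d = build_design(null_cohort.phenotype)
        trace = pvalue_convergence(A, d, checkpoints=[100, 200, 400], seed=2)
        p_final = trace["global_p"].iloc[-1]
        for _, row in trace.iterrows():
            se = np.sqrt(p_final * (1 - p_final) / row["iteration"])
            assert abs(row["global_p"] - p_final) < 4 * se + 2 / row["iteration"]

    def test_bad_checkpoints_rejected(self, null_cohort):
        d = build_design(null_cohort.phenotype)
        with pytest.raises(ValueError, match="increasing"):
            pvalue_convergence(np.zeros((48, 2)), d, checkpoints=[200, 100], seed=0)
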