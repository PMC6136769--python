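import numpy as np
import pandas as pd
import pytest

import rrpersist as rr
from rrpersist.longitudinal_design import ModelSpec, PhenotypeTable, build_design
from rrpersist.reml_engine import (
    FitOptions,
    VarianceParameters,
    _CompactData,
    predict_genetic_coefficients,
    restricted_loglik,
    solve_mme,
)

from _oracles import error_contrast_reml, gls_blup
from conftest import small_config, tiny_table


def random_params(rng, ma, mp, nh, structure):
    """Random valid variance parameters (PD via A A' + eps I)."""
    def rand_pd(k, scale=1.0):
        A = rng.normal(size=(k, k))
        return scale * (A @ A.T + 0.5 * np.eye(k))

    if structure == "homogeneous":
        residual = np.asarray(rng.uniform(0.5, 3.0))
    elif structure == "diagonal":
        residual = rng.uniform(0.5, 3.0, size=nh)
    else:
        residual = rand_pd(nh, 0.5)
    return VarianceParameters(
        K_g=rand_pd(ma), K_p=rand_pd(mp), residual=residual, structure=structure
    )


def small_design(paper_cfg, spec, ng=3, seed=0, death_prob=0.0):
    sim = rr.simulate(small_config(paper_cfg, ng=ng, seed=seed, death_prob=death_prob))
    return build_design(sim.table, paper_cfg.schedule, spec)


# ---------------------------------------------------------------------------
# restricted log-likelihood
# ---------------------------------------------------------------------------


class TestRestrictedLoglik:
    @pytest.mark.parametrize("structure", ["homogeneous", "diagonal", "unstructured"])
    def test_matches_error_contrast_oracle(self, paper_cfg, structure):
        """Dense REML equals the brute-force error-contrast density on
        small instances, for every residual structure."""
        rng = np.random.default_rng(1)
        spec = ModelSpec(2, 1, structure)
        for seed in range(5):
            design = small_design(paper_cfg, spec, ng=3, seed=seed)
            params = random_params(rng, 2, 1, 5, structure)
            ll = restricted_loglik(params, design)
            oracle = error_contrast_reml(params, design)
            assert ll == pytest.approx(oracle, abs=1e-8)

    @pytest.mark.parametrize("structure", ["homogeneous", "diagonal", "unstructured"])
    def test_absorption_path_equals_dense_path(self, paper_cfg, structure):
        """The batched absorption evaluator used by the fitter is
        algebraically identical to the dense V-based definition,
        including under missing records."""
        rng = np.random.default_rng(2)
        spec = ModelSpec(3, 2, structure)
        for seed in range(3):
            design = small_design(
                paper_cfg, spec, ng=4, seed=seed, death_prob=0.15
            )
            params = random_params(rng, 3, 2, 5, structure)
            compact = _CompactData(design, spec)
            fast = -0.5 * compact.neg2_restricted_loglik(params)
            dense = restricted_loglik(params, design)
            assert fast == pytest.approx(dense, abs=1e-8)

    def test_zero_random_effects_reduce_to_fixed_model(self, paper_cfg):
        """With K_g = K_p = 0 the restricted likelihood is that of the
        fixed model alone (V = R)."""
        spec = ModelSpec(2, 1, "homogeneous")
        design = small_design(paper_cfg, spec, ng=3, seed=3)
        sigma2 = 2.0
        params = VarianceParameters(
            K_g=np.zeros((2, 2)),
            K_p=np.zeros((1, 1)),
            residual=np.asarray(sigma2),
            structure="homogeneous",
        )
        fixed_only = VarianceParameters(
            K_g=None, K_p=None, residual=np.asarray(sigma2), structure="homogeneous"
        )
        assert restricted_loglik(params, design) == pytest.approx(
            error_contrast_reml(fixed_only, design), abs=1e-8
        )

    def test_scale_equivariance(self, paper_cfg):
        """Scaling y and all variance parameters by c^2 shifts logL by
        -(n - rank_X) log c."""
        spec = ModelSpec(2, 1, "diagonal")
        design = small_design(paper_cfg, spec, ng=3, seed=4)
        rng = np.random.default_rng(3)
        params = random_params(rng, 2, 1, 5, "diagonal")
        c = 3.7
        ll = restricted_loglik(params, design)
        ll_scaled = restricted_loglik(
            params.scaled(c * c), design, y=design.y * c
        )
        n_eff = design.n_records - len(
            rr.reml_engine._fullrank_columns(design.X)
        )
        assert ll_scaled - ll == pytest.approx(-n_eff * np.log(c), abs=1e-8)

    def test_invalid_params_rejected(self, paper_cfg):
        spec = ModelSpec(2, 1, "homogeneous")
        design = small_design(paper_cfg, spec, ng=3, seed=5)
        bad = VarianceParameters(
            K_g=np.array([[1.0, 2.0], [2.0, 1.0]]),  # indefinite
            K_p=np.eye(1),
            residual=np.asarray(1.0),
            structure="homogeneous",
        )
        with pytest.raises(ValueError, match="positive semidefinite"):
            restricted_loglik(bad, design)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


class TestFitReml:
    @pytest.fixture(scope="class")
    def modest_fit(self, paper_cfg):
        """A 30-genotype fit reused by several structural checks."""
        sim = rr.simulate(small_config(paper_cfg, ng=30, seed=11))
        spec = ModelSpec(3, 1, "diagonal")
        fit = rr.fit_reml(
            sim.table, paper_cfg.schedule, spec, FitOptions(n_starts=1)
        )
        assert fit.converged
        return sim, fit

    def test_estimates_are_psd(self, modest_fit):
        _, fit = modest_fit
        np.linalg.cholesky(fit.params.K_g)
        np.linalg.cholesky(fit.params.K_p)

    def test_pev_shrinkage_order(self, modest_fit):
        """0 <= PEV block <= K_g in the PSD order, for every genotype."""
        _, fit = modest_fit
        tol = 1e-8 * np.trace(fit.params.K_g)
        for block in fit.pev_blocks:
            assert np.min(np.linalg.eigvalsh(block)) >= -tol
            assert np.min(np.linalg.eigvalsh(fit.params.K_g - block)) >= -tol

    def test_blup_coefficients_centered(self, modest_fit):
        _, fit = modest_fit
        means = fit.alpha_hat.mean(axis=0)
        assert np.abs(means).max() < 1e-6 * np.sqrt(np.trace(fit.params.K_g))

    def test_record_order_invariance(self, paper_cfg):
        sim = rr.simulate(small_config(paper_cfg, ng=8, seed=12))
        spec = ModelSpec(2, 1, "diagonal")
        opts = FitOptions(n_starts=1)
        fit1 = rr.fit_reml(sim.table, paper_cfg.schedule, spec, opts)
        shuffled = PhenotypeTable(
            sim.table.data.sample(frac=1.0, random_state=99).reset_index(drop=True)
        )
        fit2 = rr.fit_reml(shuffled, paper_cfg.schedule, spec, opts)
        assert fit1.logL == pytest.approx(fit2.logL, abs=1e-8)
        np.testing.assert_allclose(fit1.alpha_hat, fit2.alpha_hat, atol=1e-8)
        np.testing.assert_allclose(fit1.params.K_g, fit2.params.K_g, atol=1e-8)

    def test_reported_loglik_consistent_with_dense_definition(self, modest_fit):
        sim, fit = modest_fit
        design = build_design(sim.table, fit.schedule, fit.spec)
        assert restricted_loglik(fit.params, design) == pytest.approx(
            fit.logL, abs=1e-6
        )

    def test_overparameterized_spec_rejected(self, paper_cfg):
        sim = rr.simulate(small_config(paper_cfg, ng=3, seed=13))
        short = rr.HarvestSchedule.from_days([250, 500, 815])
        trimmed = PhenotypeTable(
            sim.table.data[sim.table.data.day.isin([250, 500, 815])]
        )
        with pytest.raises(ValueError, match="measured harvests"):
            rr.fit_reml(trimmed, short, ModelSpec(4, 1, "diagonal"))

    def test_underdetermined_fit_warns(self, paper_cfg):
        sim = rr.simulate(small_config(paper_cfg, ng=2, seed=14))
        with pytest.warns(UserWarning, match="poorly identified"):
            rr.fit_reml(
                sim.table,
                paper_cfg.schedule,
                ModelSpec(4, 2, "unstructured"),
                FitOptions(n_starts=1, max_iter=30),
            )

    def test_null_genetic_variance_shrinks_to_boundary(self, paper_cfg):
        """Data simulated without genetic effects: the estimated genetic
        variance collapses and the genetic LRT is not significant."""
        from rrpersist.model_selection import lrt
        from rrpersist.synthetic_data import SimulationConfig, simulate

        cfg = small_config(paper_cfg, ng=25, seed=15)
        null_cfg = SimulationConfig(
            ng=cfg.ng, n_rep=cfg.n_rep, schedule=cfg.schedule, beta=cfg.beta,
            rep_effects=cfg.rep_effects, K_g=np.zeros((2, 2)), K_p=cfg.K_p,
            residual_structure=cfg.residual_structure, residual=cfg.residual,
            death_prob=0.0, seed=16,
        )
        sim = simulate(null_cfg)
        spec = ModelSpec(2, 1, "diagonal")
        full = rr.fit_reml(sim.table, cfg.schedule, spec, FitOptions(n_starts=1))
        reduced = rr.fit_reml(
            sim.table, cfg.schedule, spec,
            FitOptions(n_starts=1, include_genetic=False),
        )
        phen_var = sim.table.data["yield"].var()
        assert np.trace(full.params.K_g) < 0.25 * phen_var
        assert not lrt(full, reduced).significant_1pct


# ---------------------------------------------------------------------------
# BLUP solutions
# ---------------------------------------------------------------------------


class TestBlup:
    def test_matches_gls_oracle(self, paper_cfg):
        """Henderson-equation BLUPs equal textbook GLS computed from the
        marginal covariance."""
        spec = ModelSpec(2, 1, "diagonal")
        design = small_design(paper_cfg, spec, ng=4, seed=20)
        rng = np.random.default_rng(5)
        params = random_params(rng, 2, 1, 5, "diagonal")
        beta, alpha, p_hat, pev, keep = solve_mme(
            design.X, design.Z, design.W, design.y, params,
            design.harvest_index, design.records["plot_idx"].to_numpy(),
            len(design.genotype_ids), len(design.plot_ids),
        )
        oracle = gls_blup(
            params, design.X, design.Z, design.W, design.y,
            design.harvest_index, design.records["plot_idx"].to_numpy(),
        )
        np.testing.assert_allclose(beta, oracle["beta"], atol=1e-8)
        ma = 2
        np.testing.assert_allclose(
            alpha.ravel(), oracle["u"][: alpha.size], atol=1e-8
        )

    def test_duplicating_every_record_leaves_blups_unchanged(self, paper_cfg):
        """Sufficiency: stacking each record twice while doubling the
        residual variance preserves every weighted cross-product, so the
        BLUP solutions are identical while the likelihood is not."""
        spec = ModelSpec(2, 1, "diagonal")
        design = small_design(paper_cfg, spec, ng=3, seed=21)
        rng = np.random.default_rng(6)
        params = random_params(rng, 2, 1, 5, "diagonal")
        params_dup = VarianceParameters(
            K_g=params.K_g, K_p=params.K_p,
            residual=2.0 * np.asarray(params.residual), structure="diagonal",
        )
        args = (
            design.harvest_index,
            design.records["plot_idx"].to_numpy(),
            len(design.genotype_ids),
            len(design.plot_ids),
        )
        beta1, alpha1, p1, _, _ = solve_mme(
            design.X, design.Z, design.W, design.y, params, *args
        )
        dup = lambda M: np.vstack([M, M])
        beta2, alpha2, p2, _, _ = solve_mme(
            dup(design.X), dup(design.Z), dup(design.W),
            np.concatenate([design.y, design.y]), params_dup,
            np.concatenate([design.harvest_index] * 2),
            np.concatenate([design.records["plot_idx"].to_numpy()] * 2),
            len(design.genotype_ids), len(design.plot_ids),
        )
        np.testing.assert_allclose(beta1, beta2, atol=1e-8)
        np.testing.assert_allclose(alpha1, alpha2, atol=1e-8)
        np.testing.assert_allclose(p1, p2, atol=1e-8)


class TestPredictGeneticCoefficients:
    def test_known_genotype(self, paper_cfg):
        sim = rr.simulate(small_config(paper_cfg, ng=5, seed=22))
        spec = ModelSpec(2, 1, "diagonal")
        fit = rr.fit_reml(sim.table, paper_cfg.schedule, spec, FitOptions(n_starts=1))
        coef, pev = predict_genetic_coefficients(fit, fit.genotype_ids[0])
        np.testing.assert_allclose(coef, fit.alpha_hat[0])
        assert pev.shape == (2, 2)

    def test_unknown_genotype_raises(self, paper_cfg):
        sim = rr.simulate(small_config(paper_cfg, ng=3, seed=23))
        fit = rr.fit_reml(
            sim.table, paper_cfg.schedule, ModelSpec(2, 1, "diagonal"),
            FitOptions(n_starts=1),
        )
        with pytest.raises(KeyError):
            predict_genetic_coefficients(fit, "nope")

    def test_no_record_genotype_fully_shrunk(self, paper_cfg):
        """A genotype with no usable records is predicted at zero with
        PEV equal to the full genetic covariance (no information)."""
        sim = rr.simulate(small_config(paper_cfg, ng=4, seed=24))
        df = sim.table.data.copy()
        df.loc[df.genotype == "G004", "yield"] = np.nan
        fit = rr.fit_reml(
            PhenotypeTable(df), paper_cfg.schedule, ModelSpec(2, 1, "diagonal"),
            FitOptions(n_starts=1),
        )
        coef, pev = predict_genetic_coefficients(fit, "G004")
        np.testing.assert_allclose(coef, 0.0)
        np.testing.assert_allclose(pev, fit.params.K_g)

    def test_information_monotonicity(self, paper_cfg):
        """At fixed variance parameters, adding harvests for a genotype
        cannot increase the trace of its coefficient prediction-error
        covariance (nested designs, common parameters)."""
        spec = ModelSpec(2, 1, "diagonal")
        rng = np.random.default_rng(7)
        params = random_params(rng, 2, 1, 5, "diagonal")
        sim = rr.simulate(small_config(paper_cfg, ng=4, seed=25))
        traces = []
        for n_days in (2, 3, 5):
            keep_days = list(paper_cfg.schedule.measured_days[:n_days])
            df = sim.table.data.copy()
            mask = (df.genotype == "G001") & (~df.day.isin(keep_days))
            df = df[~mask]
            design = build_design(PhenotypeTable(df), paper_cfg.schedule, spec)
            _, _, _, pev, _ = solve_mme(
                design.X, design.Z, design.W, design.y, params,
                design.harvest_index, design.records["plot_idx"].to_numpy(),
                len(design.genotype_ids), len(design.plot_ids),
            )
            i = design.genotype_ids.index("G001")
            traces.append(np.trace(pev[i]))
        assert traces[0] >= traces[1] - 1e-10 >= traces[2] - 2e-10
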