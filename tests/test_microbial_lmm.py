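"""REML fitting, microbiability, LRT, and the fixed-effect screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microbiability import (
    ModelSpec,
    MicrobialRelationshipMatrix,
    SimulationConfig,
    build_relationship_matrix,
    filter_otus,
    fit_microbiability,
    fixed_effect_screen,
    lrt_microbial_effect,
    microbiability,
    mixture_pvalue,
    reml_fit,
    reml_loglik,
    simulate_dataset,
    simulate_metadata,
    to_model_matrix,
)
from microbiability.microbial_lmm import (
    DesignError,
    OptimizationError,
    VarianceComponents,
    build_design,
)

from grid_oracle import batch_reml_loglik, grid_search_reml


def _identity_mrm(ids):
    return MicrobialRelationshipMatrix(np.eye(len(ids)), list(ids), 1)


def _tiny_problem(seed=42, n_per_line=(6, 6), n_otus=30, sigma2_m=1.0):
    cfg = SimulationConfig(
        n_animals_per_line=n_per_line,
        n_otus=n_otus,
        library_size=2000,
        sigma2_m=sigma2_m,
        sigma2_e_by_line={"HFP": 0.7, "LFP": 0.4},
        seed=seed,
    )
    ds = simulate_dataset(cfg)
    M = build_relationship_matrix(to_model_matrix(filter_otus(ds.otu_table)))
    return ds, M


class TestDesign:
    def test_reference_level_coding_is_full_rank(self):
        md = simulate_metadata(SimulationConfig(n_animals_per_line=(6, 6), seed=0))
        X, names = build_design(md, include_line=True, include_run_pen=True)
        assert names[0] == "intercept"
        assert np.linalg.matrix_rank(X) == X.shape[1]

    def test_confounded_columns_are_named(self):
        md = pd.DataFrame(
            {
                "animal_id": ["a", "b", "c", "d"],
                "line": ["HFP", "HFP", "LFP", "LFP"],
                # run:pen perfectly aligned with line
                "run": ["r1", "r1", "r2", "r2"],
                "pen": ["p1", "p1", "p1", "p1"],
            }
        )
        with pytest.raises(DesignError, match="run:pen"):
            build_design(md, include_line=True, include_run_pen=True)


class TestRemlFit:
    def test_identity_kernel_degenerates_to_ols_reml(self):
        """With M = I and homogeneous residuals only the sum sigma2_m +
        sigma2_e is identifiable and must equal the OLS REML variance."""
        rng = np.random.default_rng(1)
        n = 40
        md = pd.DataFrame(
            {
                "animal_id": [f"a{i}" for i in range(n)],
                "line": ["HFP"] * (n // 2) + ["LFP"] * (n // 2),
                "run": ["r1"] * n,
                "pen": ["p1"] * n,
            }
        )
        y = rng.standard_normal(n) + np.where(md["line"] == "HFP", 1.0, 0.0)
        vc, _ = reml_fit(
            y, md, _identity_mrm(md["animal_id"]), homogeneous_residuals=True
        )
        X, _ = build_design(md)
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        s2_ols = float(resid @ resid) / (n - X.shape[1])
        total = vc.sigma2_m + vc.sigma2_e["all"]
        assert total == pytest.approx(s2_ols, rel=1e-6)
        # closed-form single-variance REML log-likelihood
        _, logdet_xtx = np.linalg.slogdet(X.T @ X)
        p = X.shape[1]
        expected_logl = -0.5 * (
            (n - p) * np.log(s2_ols) + logdet_xtx + (n - p)
        ) - 0.5 * (n - p) * np.log(2 * np.pi)
        assert vc.loglik == pytest.approx(expected_logl, abs=1e-6)

    def test_optimum_matches_profiled_grid_oracle(self):
        """n=12 toy problem, homogeneous residuals: the (sigma2_m, sigma2_e)
        optimum must agree with an exhaustive profiled grid to 1e-4."""
        ds, M = _tiny_problem(seed=42)
        y = ds.traits["TD"].to_numpy()
        vc, _ = reml_fit(y, ds.metadata, M, homogeneous_residuals=True)
        X, _ = build_design(ds.metadata)
        kernels = [M.matrix, np.eye(len(y))]
        v = float(np.var(y))
        _, best = grid_search_reml(
            y, X, kernels,
            bounds=[(1e-6 * v, 3 * v), (1e-3 * v, 3 * v)],
            n_points=200, n_zooms=2,
        )
        assert vc.loglik == pytest.approx(best, abs=1e-4)
        assert vc.loglik >= best - 1e-4

    def test_returned_loglik_matches_direct_dense_evaluation(self):
        ds, M = _tiny_problem(seed=3, n_per_line=(15, 15))
        y = ds.traits["APD"].to_numpy()
        vc, fit = reml_fit(y, ds.metadata, M)
        X, _ = build_design(ds.metadata)
        lines = ds.metadata["line"].to_numpy()
        kernels = [M.matrix] + [
            np.diag((lines == l).astype(float)) for l in sorted(set(lines))
        ]
        direct = reml_loglik(fit.theta, y, X, kernels)
        assert vc.loglik == pytest.approx(direct, abs=1e-8)
        oracle = batch_reml_loglik(fit.theta[None, :], y, X, kernels)[0]
        assert vc.loglik == pytest.approx(oracle, abs=1e-8)

    def test_scale_equivariance(self):
        """y -> c*y multiplies every component by c^2 and leaves m2, D, p
        unchanged."""
        ds, M = _tiny_problem(seed=10, n_per_line=(25, 25))
        y = ds.traits["FPD"].to_numpy()
        c = 3.0
        r1 = fit_microbiability(y, ds.metadata, M, include_run_pen=False)
        r2 = fit_microbiability(c * y, ds.metadata, M, include_run_pen=False)
        assert r2.components.sigma2_m == pytest.approx(
            c**2 * r1.components.sigma2_m, rel=1e-6
        )
        for l in r1.components.sigma2_e:
            assert r2.components.sigma2_e[l] == pytest.approx(
                c**2 * r1.components.sigma2_e[l], rel=1e-6
            )
            assert r2.m2[l] == pytest.approx(r1.m2[l], abs=1e-6)
        assert r2.d_statistic == pytest.approx(r1.d_statistic, abs=1e-6)
        assert r2.p_value == pytest.approx(r1.p_value, abs=1e-6)

    def test_per_line_fit_without_line_effect(self):
        ds, M = _tiny_problem(seed=4, n_per_line=(20, 20))
        md = ds.metadata[ds.metadata["line"] == "HFP"].reset_index(drop=True)
        ids = md["animal_id"].tolist()
        y = ds.traits.set_index("animal_id").loc[ids, "APD"].to_numpy()
        vc, _ = reml_fit(
            y, md, M.reorder(ids), spec=ModelSpec(trait="APD", include_line=False)
        )
        assert set(vc.sigma2_e) == {"HFP"}
        assert vc.sigma2_e["HFP"] > 0

    def test_zero_variance_trait_rejected(self):
        ds, M = _tiny_problem(seed=5)
        with pytest.raises(ValueError, match="zero variance"):
            reml_fit(np.ones(len(ds.metadata)), ds.metadata, M)


class TestMicrobiability:
    def test_fraction_of_phenotypic_variance(self):
        vc = VarianceComponents(
            sigma2_m=0.19,
            sigma2_e={"HFP": 1.04, "LFP": 0.35},
            se_m=0.12,
            se_e={"HFP": 0.17, "LFP": 0.10},
            boundary={},
            loglik=0.0,
            n_iter=1,
            grad_norm=0.0,
        )
        m2 = microbiability(vc)
        assert m2["HFP"] == pytest.approx(0.19 / 1.23)
        assert m2["LFP"] == pytest.approx(0.19 / 0.54)

    def test_zero_microbial_variance_gives_zero(self):
        vc = VarianceComponents(
            sigma2_m=0.0,
            sigma2_e={"HFP": 0.5, "LFP": 0.2},
            se_m=np.nan,
            se_e={},
            boundary={},
            loglik=0.0,
            n_iter=1,
            grad_norm=0.0,
        )
        assert all(v == 0.0 for v in microbiability(vc).values())


class TestLrt:
    def test_chi2_quantile(self):
        d, p = lrt_microbial_effect(1.9207295, 0.0)
        assert d == pytest.approx(3.841459, abs=1e-6)
        assert p == pytest.approx(0.05, abs=1e-6)

    def test_equal_likelihoods_give_p_one(self):
        d, p = lrt_microbial_effect(-10.0, -10.0)
        assert d == 0.0 and p == 1.0

    def test_inconsistent_likelihoods_error(self):
        with pytest.raises(OptimizationError):
            lrt_microbial_effect(-10.0, -9.5)

    def test_mixture_pvalue_halves_the_tail(self):
        assert mixture_pvalue(0.0) == 1.0
        d = 2.706  # ~90th percentile of chi2(1)
        assert mixture_pvalue(d) == pytest.approx(
            0.5 * stats.chi2.sf(d, 1), abs=1e-12
        )

    def test_null_calibration_is_conservative(self):
        """Under sigma2_m = 0 the chi2(1) convention rejects at most ~5%."""
        n_sims, alpha = 120, 0.05
        rejections = 0
        for rep in range(n_sims):
            cfg = SimulationConfig(
                n_animals_per_line=(15, 15),
                n_otus=40,
                library_size=2000,
                sigma2_m=0.0,
                sigma2_e_by_line={"HFP": 0.7, "LFP": 0.4},
                seed=30_000 + rep,
            )
            ds = simulate_dataset(cfg)
            M = build_relationship_matrix(
                to_model_matrix(filter_otus(ds.otu_table))
            )
            res = fit_microbiability(
                ds.traits["FPD"].to_numpy(), ds.metadata, M, include_run_pen=False
            )
            rejections += res.p_value <= alpha
        limit = alpha + 2 * np.sqrt(alpha * (1 - alpha) / n_sims)
        assert rejections / n_sims <= limit


class TestFixedEffectScreen:
    @staticmethod
    def _metadata(n_per_line=(40, 40), n_runs=2, n_pens=4):
        return simulate_metadata(
            SimulationConfig(
                n_animals_per_line=n_per_line, n_runs=n_runs, n_pens=n_pens, seed=0
            )
        )

    def test_single_level_factor_never_included(self):
        md = self._metadata(n_runs=1, n_pens=1)
        rng = np.random.default_rng(0)
        spec = fixed_effect_screen(rng.standard_normal(len(md)), md)
        assert not spec.include_run_pen
        assert spec.screen_pvalue == 1.0

    def test_strong_pen_effects_detected(self):
        md = self._metadata()
        combo = (md["run"].astype(str) + ":" + md["pen"].astype(str)).to_numpy()
        levels = sorted(set(combo))
        rng = np.random.default_rng(77)
        hits = 0
        n_reps = 200
        for _ in range(n_reps):
            effects = dict(zip(levels, rng.normal(0, 2.0, len(levels))))
            y = (
                np.where(md["line"] == "HFP", 1.0, 0.0)
                + np.array([effects[c] for c in combo])
                + rng.standard_normal(len(md))
            )
            hits += fixed_effect_screen(y, md).include_run_pen
        assert hits / n_reps >= 0.95

    def test_null_pen_effects_at_nominal_rate(self):
        md = self._metadata()
        rng = np.random.default_rng(78)
        hits = 0
        n_reps = 200
        for _ in range(n_reps):
            y = np.where(md["line"] == "HFP", 1.0, 0.0) + rng.standard_normal(
                len(md)
            )
            hits += fixed_effect_screen(y, md).include_run_pen
        rate = hits / n_reps
        se2 = 2 * np.sqrt(0.05 * 0.95 / n_reps)
        assert 0.05 - se2 <= rate <= 0.05 + se2
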