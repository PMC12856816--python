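"""Tests for the comparative extinction-risk model and its data prep."""

import itertools

import dendropy
import numpy as np
import pandas as pd
import pytest

from latentplan import risk
from latentplan.grids import Grid
from latentplan.risk import (
    CATEGORIES,
    TRENDS,
    PhyloSpatialGLS,
    aicc,
    build_covariance,
    encode_threat_ordinal,
    filter_occurrences,
    filter_species,
    fit_gls,
    latent_risk,
    stepwise_mam,
    summarize_predictors,
    transform_standardize,
    vif_screen,
)
from latentplan.simulate import simulate_phylogenies


class TestOrdinalCoding:
    def test_full_mapping_image_is_1_to_10(self):
        vals = {
            encode_threat_ordinal(c, t)
            for c, t in itertools.product(CATEGORIES, TRENDS)
        }
        assert vals == set(range(1, 11))

    def test_extremes(self):
        assert encode_threat_ordinal("LC", "increasing") == 1
        assert encode_threat_ordinal("CR", "decreasing") == 10

    def test_monotone_in_category_at_fixed_trend(self):
        for t in TRENDS:
            vals = [encode_threat_ordinal(c, t) for c in CATEGORIES]
            assert vals == sorted(vals)
            assert len(set(vals)) == len(vals)

    def test_unknown_labels_rejected(self):
        with pytest.raises(ValueError):
            encode_threat_ordinal("EX", "stable")
        with pytest.raises(ValueError):
            encode_threat_ordinal("LC", "cyclic")


class TestSpeciesFilters:
    def test_exclusion_arithmetic(self):
        n = 178
        table = pd.DataFrame(
            {
                "data_deficient": [False] * n,
                "criterion_b": [False] * n,
                "unresolved_phylogeny": [False] * n,
                "insufficient_overlap": [False] * n,
            },
            index=[f"sp{i}" for i in range(n)],
        )
        table.iloc[0:2, 0] = True
        table.iloc[2:16, 1] = True
        table.iloc[16:32, 2] = True
        table.iloc[32:50, 3] = True
        kept = filter_species(table)
        assert len(kept) == 128

    def test_occurrence_cleaning(self):
        occ = pd.DataFrame(
            {
                "lon": [10.0, 10.0, np.nan, 11.0, 12.0],
                "lat": [20.0, 20.0, 21.0, 21.0, 22.0],
                "uncertainty_km": [1.0, 1.0, 0.5, 5.0, np.nan],
            }
        )
        out = filter_occurrences(occ)
        # duplicate dropped, missing coordinate dropped, >2 km dropped,
        # missing uncertainty dropped
        assert len(out) == 1
        assert out.iloc[0]["lon"] == 10.0


class TestPredictorConstruction:
    @staticmethod
    def _tiny_system():
        g = lambda a: Grid(np.asarray(a, dtype=float))
        env = {
            "temp_wettest": g([[1.0, 3.0], [5.0, 7.0]]),
            "fire_total": g([[2.0, 2.0], [2.0, 2.0]]),
            "fire_lds": g([[0.0, 1.0], [0.0, 1.0]]),
            "hii": g([[4.0, 4.0], [4.0, 4.0]]),
            "mei": g([[9.0, 9.0], [9.0, 9.0]]),
            "fox": g([[0.0, 0.0], [0.0, 0.0]]),
            "cane_toad": g([[1.0, 0.0], [0.0, 0.0]]),
        }
        ranges = {
            "spA": np.array([[True, True], [False, False]]),
            "spB": np.array([[False, False], [False, True]]),
        }
        traits = pd.DataFrame(
            {
                "body_mass_g": [100.0, 200.0],
                "age_first_repro_d": [300.0, 400.0],
                "litters_per_year": [1.0, 2.0],
                "litter_size": [3.0, 4.0],
            },
            index=pd.Index(["spA", "spB"], name="species"),
        )
        return ranges, env, traits

    def test_two_cell_mean_and_overlaps(self):
        ranges, env, traits = self._tiny_system()
        pred, cents = summarize_predictors(ranges, env, traits)
        assert pred.loc["spA", "temp_wettest"] == 2.0  # mean of 1 and 3
        assert pred.loc["spA", "fox_overlap"] == 0.0  # fox absent everywhere
        assert pred.loc["spA", "toad_overlap"] == 0.5
        assert pred.loc["spA", "fire_total"] == 2.0  # constant layer
        assert pred.loc["spA", "range_size_km2"] == 2.0
        # centroid of the two top cells: x = 1.0, y = 1.5
        assert cents.loc["spA", "x"] == 1.0
        assert cents.loc["spA", "y"] == 1.5

    def test_empty_range_rejected(self):
        ranges, env, traits = self._tiny_system()
        ranges["spA"] = np.zeros((2, 2), dtype=bool)
        with pytest.raises(ValueError):
            summarize_predictors(ranges, env, traits)

    def test_standardization_moments(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "normal": rng.standard_normal(200),
                "lognormal": rng.lognormal(0, 1, 200),
            }
        )
        from scipy.stats import skew

        out, tlog = transform_standardize(df, quadratic=("normal",))
        for col in out.columns:
            assert abs(out[col].mean()) < 1e-8
            assert abs(out[col].std(ddof=0) - 1) < 1e-8
        assert tlog["lognormal"].startswith("log")
        assert abs(skew(out["lognormal"])) < abs(skew(df["lognormal"]))
        assert "normal_sq" in out.columns

    def test_already_standardized_unchanged(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(300)
        x = (x - x.mean()) / x.std()
        df = pd.DataFrame({"z": x})
        out, tlog = transform_standardize(df)
        assert tlog["z"] == "identity"
        np.testing.assert_allclose(out["z"], df["z"], atol=1e-8)

    def test_constant_column_rejected_by_name(self):
        df = pd.DataFrame({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            transform_standardize(df)


class TestVIF:
    def test_near_orthogonal_predictors_kept(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((500, 4)), columns=list("abcd"))
        cols, report = vif_screen(X)
        assert cols == list("abcd")
        assert (report["vif"] < 1.2).all()

    def test_duplicated_column_removed(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal(100)
        X = pd.DataFrame({"a": a, "dup": a, "b": rng.standard_normal(100)})
        with pytest.warns(UserWarning):
            cols, _ = vif_screen(X)
        assert "b" in cols
        assert len(cols) == 2

    def test_vif_matches_direct_regression_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        z = rng.standard_normal(150)
        X = pd.DataFrame(
            {
                "a": z + 0.5 * rng.standard_normal(150),
                "b": z + 0.5 * rng.standard_normal(150),
                "c": rng.standard_normal(150),
            }
        )
        _, report = vif_screen(X, threshold=np.inf)
        first = report[report["round"] == 0].set_index("predictor")["vif"]
        for col in X.columns:
            others = sm.add_constant(X.drop(columns=[col]))
            r2 = sm.OLS(X[col], others).fit().rsquared
            assert first[col] == pytest.approx(1.0 / (1.0 - r2), rel=1e-8)


class TestCovariance:
    @staticmethod
    def _centroids(n, seed=0):
        rng = np.random.default_rng(seed)
        labels = [f"sp{i + 1:04d}" for i in range(n)]
        return pd.DataFrame(
            rng.uniform(0, 50, (n, 2)), columns=["x", "y"],
            index=pd.Index(labels, name="species"),
        ), labels

    def test_zero_weights_give_identity(self, small_trees):
        cents, labels = self._centroids(12)
        cov = build_covariance(small_trees[0], labels, cents, 0.0, 0.0, rho=10.0)
        np.testing.assert_allclose(cov.V, np.eye(12), atol=1e-12)

    def test_star_phylogeny_gives_identity(self):
        tree = dendropy.Tree.get(data="(a:1,b:1,c:1);", schema="newick")
        cents = pd.DataFrame(
            {"x": [0.0, 1.0, 2.0], "y": [0.0, 0.0, 0.0]}, index=["a", "b", "c"]
        )
        cov = build_covariance(tree, ["a", "b", "c"], cents, 1.0, 0.0, rho=10.0)
        np.testing.assert_allclose(cov.V, np.eye(3), atol=1e-12)

    def test_large_rho_limit_all_ones(self):
        cents = pd.DataFrame(
            {"x": [0.0, 1.0, 2.0], "y": [0.0, 1.0, 0.5]}, index=["a", "b", "c"]
        )
        tree = dendropy.Tree.get(data="(a:1,b:1,c:1);", schema="newick")
        cov = build_covariance(tree, ["a", "b", "c"], cents, 0.0, 1.0, rho=1e9)
        np.testing.assert_allclose(cov.V, np.ones((3, 3)), atol=1e-6)

    def test_missing_species_listed(self, small_trees):
        cents, labels = self._centroids(12)
        with pytest.raises(ValueError, match="ghost"):
            build_covariance(small_trees[0], labels + ["ghost"], cents, 0.5, 0.0, 10.0)

    def test_unit_diagonal(self, small_trees):
        cents, labels = self._centroids(12)
        cov = build_covariance(small_trees[0], labels, cents, 0.4, 0.3, rho=15.0)
        np.testing.assert_allclose(np.diag(cov.V), 1.0, atol=1e-9)
        # symmetric positive definite
        np.testing.assert_allclose(cov.V, cov.V.T)
        assert np.linalg.eigvalsh(cov.V).min() > 0


class TestGLSFit:
    def test_identity_covariance_reduces_to_ols(self):
        rng = np.random.default_rng(5)
        n = 40
        X = pd.DataFrame(rng.standard_normal((n, 3)), columns=list("abc"))
        y = rng.standard_normal(n)
        res = fit_gls(X, y, np.eye(n))
        A = np.column_stack([np.ones(n), X.to_numpy()])
        beta_ols = np.linalg.lstsq(A, y, rcond=None)[0]
        np.testing.assert_allclose(res.params.to_numpy(), beta_ols, atol=1e-10)

    def test_three_observation_hand_oracle(self):
        # V and data small enough to invert by hand: beta = (X'V^-1X)^-1 X'V^-1 y
        X = np.array([[1.0], [2.0], [3.0]])
        y = np.array([1.0, 2.0, 2.0])
        V = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.0], [0.0, 0.0, 1.0]])
        res = fit_gls(X, y, V)
        Xc = np.column_stack([np.ones(3), X])
        Vi = np.linalg.inv(V)
        beta_hand = np.linalg.solve(Xc.T @ Vi @ Xc, Xc.T @ Vi @ y)
        np.testing.assert_allclose(res.params.to_numpy(), beta_hand, atol=1e-12)
        resid = y - Xc @ beta_hand
        sigma2_hand = resid @ Vi @ resid / 3
        assert res.sigma2 == pytest.approx(sigma2_hand, abs=1e-12)

    def test_matches_statsmodels_gls(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        n = 50
        X = pd.DataFrame(rng.standard_normal((n, 2)), columns=["a", "b"])
        y = 1.0 + X["a"].to_numpy() - 0.5 * X["b"].to_numpy() + rng.standard_normal(n)
        u = rng.uniform(0, 10, n)
        D = np.abs(u[:, None] - u[None, :])
        V = 0.5 * np.exp(-D / 5.0) + 0.5 * np.eye(n)
        np.fill_diagonal(V, 1.0)
        res = fit_gls(X, y, V)
        sm_res = sm.GLS(y, sm.add_constant(X), sigma=V).fit()
        np.testing.assert_allclose(res.params.to_numpy(), sm_res.params.to_numpy(), atol=1e-9)
        np.testing.assert_allclose(res.bse.to_numpy(), sm_res.bse.to_numpy(), atol=1e-9)
        np.testing.assert_allclose(res.pvalues.to_numpy(), sm_res.pvalues.to_numpy(), atol=1e-9)

    def test_loglik_is_maximal_over_beta(self):
        rng = np.random.default_rng(7)
        n = 30
        X = pd.DataFrame(rng.standard_normal((n, 2)), columns=["a", "b"])
        y = rng.standard_normal(n)
        V = np.eye(n)
        res = fit_gls(X, y, V)

        def llf_at(beta):
            Xc = np.column_stack([np.ones(n), X.to_numpy()])
            r = y - Xc @ beta
            s2 = r @ r / n
            return -0.5 * (n * np.log(2 * np.pi * s2) + n)

        b = res.params.to_numpy()
        for shift in ([0.1, 0, 0], [0, -0.1, 0], [0, 0, 0.05]):
            assert llf_at(b + np.array(shift)) < res.llf

    def test_collinear_design_raises(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal(20)
        X = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(np.linalg.LinAlgError):
            fit_gls(X, rng.standard_normal(20), np.eye(20))

    def test_simulation_recovery_with_known_covariance(self):
        # estimates across replicates centre on the truth
        rng = np.random.default_rng(9)
        n, reps = 64, 50
        beta_true = np.array([2.0, 0.8, -0.5])
        u = rng.uniform(0, 20, n)
        D = np.abs(u[:, None] - u[None, :])
        V = 0.4 * np.exp(-D / 5.0) + 0.6 * np.eye(n)
        np.fill_diagonal(V, 1.0)
        L = np.linalg.cholesky(V)
        X = pd.DataFrame(rng.standard_normal((n, 2)), columns=["a", "b"])
        Xc = np.column_stack([np.ones(n), X.to_numpy()])
        est = np.zeros((reps, 3))
        for r in range(reps):
            y = Xc @ beta_true + L @ rng.standard_normal(n)
            est[r] = fit_gls(X, y, V).params.to_numpy()
        mc_se = est.std(axis=0, ddof=1) / np.sqrt(reps)
        assert (np.abs(est.mean(axis=0) - beta_true) < 3 * mc_se).all()


class TestAICc:
    def test_hand_value(self):
        assert aicc(-10.0, 3, 20) == pytest.approx(27.5)

    def test_zero_parameters(self):
        assert aicc(-10.0, 0, 20) == pytest.approx(20.0)

    def test_reduces_to_aic_for_large_n(self):
        assert aicc(-10.0, 3, 10**9) == pytest.approx(26.0, abs=1e-6)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


class TestStepwise:
    def test_true_predictor_retained(self):
        # one strong predictor among pure noise: the MAM keeps it almost always
        kept = 0
        n = 80
        for rep in range(100):
            rng = np.random.default_rng(rep)
            X = pd.DataFrame(
                rng.standard_normal((n, 6)),
                columns=["true"] + [f"noise{i}" for i in range(5)],
            )
            y = 2.0 * X["true"].to_numpy() + rng.standard_normal(n)
            res, _ = stepwise_mam(y, X, np.eye(n))
            if "true" in res.params.index:
                kept += 1
        assert kept >= 90

    def test_full_model_kept_when_every_deletion_hurts(self):
        rng = np.random.default_rng(11)
        n = 100
        X = pd.DataFrame(rng.standard_normal((n, 3)), columns=list("abc"))
        y = (
            3.0 * X["a"].to_numpy()
            - 3.0 * X["b"].to_numpy()
            + 3.0 * X["c"].to_numpy()
            + 0.5 * rng.standard_normal(n)
        )
        res, trace = stepwise_mam(y, X, np.eye(n))
        assert set(res.params.index) == {"const", "a", "b", "c"}
        assert not trace[0]["accepted"]

    def test_trace_aiccs_match_refits(self):
        rng = np.random.default_rng(12)
        n = 60
        X = pd.DataFrame(rng.standard_normal((n, 4)), columns=list("abcd"))
        y = X["a"].to_numpy() + rng.standard_normal(n)
        res, trace = stepwise_mam(y, X, np.eye(n))
        # replay the trace: every recorded AICc must equal a fresh fit
        cols = list(X.columns)
        for step in trace:
            if step["phase"] == "backward":
                trial = [c for c in cols if c != step["predictor"]]
            else:
                trial = cols + [step["predictor"]]
            refit = fit_gls(X[trial], y, np.eye(n)) if trial else None
            assert refit.aicc == pytest.approx(step["aicc_after"], abs=1e-10)
            if step["accepted"]:
                cols = trial
        assert set(cols) | {"const"} == set(res.params.index) | {"const"}

    def test_degenerate_returns_intercept_only(self):
        # predictors constructed exactly orthogonal to y and the
        # intercept: deleting them costs no likelihood, so at small n the
        # small-sample AICc penalty drop always exceeds the threshold
        rng = np.random.default_rng(13)
        n = 12
        y = 5.0 + rng.standard_normal(n)
        basis = np.column_stack([np.ones(n), y, rng.standard_normal((n, 2))])
        Q, _ = np.linalg.qr(basis)
        X = pd.DataFrame(Q[:, 2:4], columns=["a", "b"])  # orthogonal to y, const
        res, _ = stepwise_mam(y, X, np.eye(n))
        assert list(res.params.index) == ["const"]

    def test_quadratic_never_without_linear(self):
        rng = np.random.default_rng(14)
        n = 150
        z = rng.standard_normal(n)
        X = pd.DataFrame(
            {"body_mass_g": z, "body_mass_g_sq": z**2 - 1, "other": rng.standard_normal(n)}
        )
        # response depends only on the quadratic; the linear term must survive
        y = 1.5 * X["body_mass_g_sq"].to_numpy() + 0.5 * rng.standard_normal(n)
        res, _ = stepwise_mam(y, X, np.eye(n))
        if "body_mass_g_sq" in res.params.index:
            assert "body_mass_g" in res.params.index


class TestLatentRisk:
    def test_perfect_fit_gives_zero_latent(self, small_trees):
        n = 12
        labels = [f"sp{i + 1:04d}" for i in range(n)]
        rng = np.random.default_rng(15)
        X = pd.DataFrame(
            rng.standard_normal((n, 1)), columns=["a"],
            index=pd.Index(labels, name="species"),
        )
        y = pd.Series(2.0 + 3.0 * X["a"].to_numpy(), index=X.index)
        cents = pd.DataFrame(rng.uniform(0, 10, (n, 2)), columns=["x", "y"], index=X.index)
        out = latent_risk(y, X, ["a"], [small_trees[0]], cents, 0.0, 0.0, 10.0)
        np.testing.assert_allclose(out["latent"], 0.0, atol=1e-9)

    def test_latent_is_fitted_minus_observed(self, small_trees):
        n = 12
        labels = [f"sp{i + 1:04d}" for i in range(n)]
        rng = np.random.default_rng(16)
        X = pd.DataFrame(
            rng.standard_normal((n, 2)), columns=["a", "b"],
            index=pd.Index(labels, name="species"),
        )
        y = pd.Series(rng.integers(1, 11, n).astype(float), index=X.index)
        cents = pd.DataFrame(rng.uniform(0, 10, (n, 2)), columns=["x", "y"], index=X.index)
        out = latent_risk(y, X, ["a", "b"], list(small_trees), cents, 0.3, 0.2, 10.0)
        np.testing.assert_allclose(
            out["latent"], out["fitted_mean"] - out["observed"], atol=1e-12
        )
        np.testing.assert_allclose(out["latent_positive"], out["latent"].clip(lower=0))
        # linearity: mean latent equals mean fitted minus mean observed
        assert out["latent"].mean() == pytest.approx(
            out["fitted_mean"].mean() - y.mean(), abs=1e-12
        )
        # averaging across trees: per-species spread is finite and recorded
        assert np.isfinite(out["fitted_sd"]).all()

    def test_empty_tree_sample_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]}, index=["s1", "s2", "s3"])
        y = pd.Series([1.0, 2.0, 3.0], index=X.index)
        with pytest.raises(ValueError):
            latent_risk(y, X, ["a"], [], None, 0.0, 0.0, 1.0)
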