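"""Validation battery: oracle equivalence and recovery simulations."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

import inbuilt_rubric as ir
from inbuilt_rubric.psychometrics import (ModelSpec, fit_cfa,
                                          minres_loadings,
                                          tucker_congruence)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def icc_oracle(X, type_, definition):
    """From-scratch two-way ANOVA mean squares, scalar loops only."""
    n, r = len(X), len(X[0])
    grand = sum(X[i][j] for i in range(n) for j in range(r)) / (n * r)
    row_m = [sum(X[i]) / r for i in range(n)]
    col_m = [sum(X[i][j] for i in range(n)) / n for j in range(r)]
    ssr = r * sum((m - grand) ** 2 for m in row_m)
    ssc = n * sum((m - grand) ** 2 for m in col_m)
    sst = sum((X[i][j] - grand) ** 2 for i in range(n) for j in range(r))
    sse = sst - ssr - ssc
    msr, msc = ssr / (n - 1), ssc / (r - 1)
    mse = sse / ((n - 1) * (r - 1))
    if (type_, definition) == ("single", "consistency"):
        return (msr - mse) / (msr + (r - 1) * mse)
    if (type_, definition) == ("average", "consistency"):
        return (msr - mse) / msr
    if (type_, definition) == ("single", "agreement"):
        return (msr - mse) / (msr + (r - 1) * mse + r * (msc - mse) / n)
    return (msr - mse) / (msr + (msc - mse) / n)


def paired_oracle(x, y):
    n = len(x)
    d = [a - b for a, b in zip(x, y)]
    md = sum(d) / n
    sd = math.sqrt(sum((v - md) ** 2 for v in d) / (n - 1))
    t = md / (sd / math.sqrt(n))
    return t, md / sd


class TestICC:
    def test_identical_raters_consistency_one(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [0.0, 0.0], [1.5, 1.5]])
        res = ir.icc_two_way_mixed(x)
        assert res.icc == pytest.approx(1.0)

    def test_constant_shift_consistency_vs_agreement(self):
        base = np.array([0.0, 1.0, 2.0, 1.0, 0.5, 1.5])
        x = np.column_stack([base, base + 0.7])
        cons = ir.icc_two_way_mixed(x, "single", "consistency")
        agr = ir.icc_two_way_mixed(x, "single", "agreement")
        assert cons.icc == pytest.approx(1.0)
        assert agr.icc < 1.0

    @pytest.mark.parametrize("type_", ["single", "average"])
    @pytest.mark.parametrize("definition", ["consistency", "agreement"])
    def test_matches_anova_oracle(self, type_, definition, rng):
        for _ in range(100):
            X = rng.integers(0, 3, size=(8, 3)).astype(float)
            X += rng.standard_normal((8, 3)) * 0.3
            res = ir.icc_two_way_mixed(X, type_, definition)
            assert res.icc == pytest.approx(
                icc_oracle(X.tolist(), type_, definition), abs=1e-12)

    def test_matches_pingouin(self, rng):
        """Independent cross-check against an established implementation."""
        pingouin = pytest.importorskip("pingouin")
        X = rng.standard_normal((12, 3)) + rng.standard_normal((12, 1))
        df = pd.DataFrame(X, columns=["r1", "r2", "r3"])
        df["target"] = range(12)
        long = df.melt(id_vars="target", var_name="rater", value_name="y")
        pg = pingouin.intraclass_corr(long, targets="target", raters="rater",
                                      ratings="y").set_index("Type")["ICC"]
        expected = {
            ("single", "consistency"): "ICC(C,1)",
            ("average", "consistency"): "ICC(C,k)",
            ("single", "agreement"): "ICC(A,1)",
            ("average", "agreement"): "ICC(A,k)",
        }
        for (typ, definition), label in expected.items():
            ours = ir.icc_two_way_mixed(X, typ, definition)
            assert ours.icc == pytest.approx(float(pg[label]), abs=1e-10)

    def test_zero_between_target_variance_errors(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        with pytest.raises(ValueError, match="undefined"):
            ir.icc_two_way_mixed(x)


class TestPairedContrast:
    def test_identical_samples(self, rng):
        x = rng.standard_normal(10)
        res = ir.paired_contrast(x, x.copy())
        assert res["t"] == 0.0 and res["cohens_d"] == 0.0

    def test_antisymmetry(self, rng):
        x, y = rng.standard_normal(15), rng.standard_normal(15)
        a = ir.paired_contrast(x, y)
        b = ir.paired_contrast(y, x)
        assert a["t"] == pytest.approx(-b["t"])
        assert a["cohens_d"] == pytest.approx(-b["cohens_d"])

    def test_matches_textbook_formulas(self, rng):
        for _ in range(50):
            x = rng.standard_normal(30)
            y = x * 0.5 + rng.standard_normal(30)
            res = ir.paired_contrast(x, y)
            t, d = paired_oracle(x.tolist(), y.tolist())
            assert res["t"] == pytest.approx(t, abs=1e-10)
            assert res["cohens_d"] == pytest.approx(d, abs=1e-10)

    def test_constant_nonzero_difference_errors(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            ir.paired_contrast(x, x + 1.0)


# ---------------------------------------------------------------------------
# parallel analysis
# ---------------------------------------------------------------------------

class TestParallelAnalysis:
    def test_eigenvalue_trace_identity(self, rng):
        X = rng.standard_normal((120, 7))
        res = ir.parallel_analysis(X, n_sims=20, seed=0)
        assert res.pca_eigenvalues.sum() == pytest.approx(7.0)

    def test_pure_noise_retains_zero_factors(self):
        hits = 0
        runs = 12
        for s in range(runs):
            rng = np.random.default_rng(1000 + s)
            X = rng.standard_normal((500, 10))
            res = ir.parallel_analysis(X, n_sims=60, seed=s)
            hits += res.n_factors_retained == 0
        assert hits >= round(0.9 * runs)

    def test_three_factor_structure_retained(self):
        hits = 0
        runs = 12
        for s in range(runs):
            rng = np.random.default_rng(2000 + s)
            F = rng.standard_normal((500, 3))
            L = np.zeros((9, 3))
            for j in range(3):
                L[3 * j: 3 * (j + 1), j] = 0.7
            X = F @ L.T + rng.standard_normal((500, 9)) * np.sqrt(1 - 0.49)
            res = ir.parallel_analysis(X, n_sims=60, seed=s)
            hits += res.n_factors_retained == 3
        assert hits >= round(0.9 * runs)

    def test_constant_variable_errors(self, rng):
        X = rng.standard_normal((50, 4))
        X[:, 2] = 1.0
        with pytest.raises(ValueError, match="constant"):
            ir.parallel_analysis(X, n_sims=5, seed=0)

    def test_seeded_reproducibility(self, rng):
        X = rng.standard_normal((100, 6))
        a = ir.parallel_analysis(X, n_sims=30, seed=5)
        b = ir.parallel_analysis(X, n_sims=30, seed=5)
        assert np.array_equal(a.fa_thresholds, b.fa_thresholds)


# ---------------------------------------------------------------------------
# EFA
# ---------------------------------------------------------------------------

def _two_factor_data(rng, n=1000, loading=0.8):
    L = np.zeros((8, 2))
    L[:4, 0] = loading
    L[4:, 1] = loading
    F = rng.standard_normal((n, 2))
    E = rng.standard_normal((n, 8)) * np.sqrt(1 - loading ** 2)
    return F @ L.T + E, L


class TestEFA:
    def test_two_factor_recovery_congruence(self):
        rng = np.random.default_rng(42)
        X, L_true = _two_factor_data(rng)
        res = ir.efa(X, 2)
        C = np.abs(tucker_congruence(res.loadings.to_numpy(), L_true))
        # best match per true factor, up to permutation/sign
        assert np.all(C.max(axis=0) > 0.95)

    def test_one_factor_rmsea_small(self):
        hits = 0
        runs = 10
        for s in range(runs):
            rng = np.random.default_rng(300 + s)
            F = rng.standard_normal((400, 1))
            L = np.full((6, 1), 0.7)
            X = F @ L.T + rng.standard_normal((400, 6)) * np.sqrt(0.51)
            res = ir.efa(X, 1)
            hits += res.rmsea < 0.05
        assert hits >= round(0.9 * runs)

    def test_loadings_invariant_to_rescaling(self):
        rng = np.random.default_rng(9)
        X, _ = _two_factor_data(rng, n=500)
        a = ir.efa(X, 2)
        b = ir.efa(X * np.array([1, 10, 0.1, 5, 2, 1, 3, 0.5]), 2)
        assert np.allclose(a.loadings.to_numpy(), b.loadings.to_numpy(),
                           atol=1e-6)

    def test_minres_estimator_recovers_structure(self):
        rng = np.random.default_rng(10)
        X, L_true = _two_factor_data(rng)
        res = ir.efa(X, 2, estimator="minres")
        C = np.abs(tucker_congruence(res.loadings.to_numpy(), L_true))
        assert np.all(C.max(axis=0) > 0.95)

    def test_factor_scores_track_factors(self):
        rng = np.random.default_rng(11)
        L = np.zeros((8, 2))
        L[:4, 0], L[4:, 1] = 0.8, 0.8
        F = rng.standard_normal((800, 2))
        X = F @ L.T + rng.standard_normal((800, 8)) * 0.6
        res = ir.efa(X, 2)
        C = np.abs(np.corrcoef(res.factor_scores.T, F.T)[:2, 2:])
        assert np.all(C.max(axis=1) > 0.85)

    def test_oblimin_phi_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(12)
        X, _ = _two_factor_data(rng, n=400)
        res = ir.efa(X, 2)
        assert np.allclose(res.phi, res.phi.T)
        assert np.allclose(np.diag(res.phi), 1.0)

    def test_minres_one_factor_matches_truth(self):
        # population correlation of a one-factor model
        lam = np.array([0.8, 0.7, 0.6, 0.5])
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        est = minres_loadings(R, 1).ravel()
        assert np.allclose(np.abs(est), lam, atol=1e-6)


# ---------------------------------------------------------------------------
# standardized regression
# ---------------------------------------------------------------------------

class TestStandardizedRegression:
    def test_single_predictor_equals_pearson_r(self, rng):
        x = rng.standard_normal(60)
        y = 0.6 * x + rng.standard_normal(60)
        row = ir.standardized_regression(y, pd.DataFrame({"x": x}))
        assert row["beta"]["x"] == pytest.approx(
            st.pearsonr(x, y).statistic, abs=1e-10)

    def test_orthogonal_predictors_betas_equal_r(self, rng):
        # centered columns are orthogonal to the ones vector, so QR of a
        # centered matrix yields exactly orthogonal mean-zero predictors
        M = rng.standard_normal((80, 3))
        q, _ = np.linalg.qr(M - M.mean(axis=0))
        X = pd.DataFrame(q, columns=["a", "b", "c"])
        y = rng.standard_normal(80)
        row = ir.standardized_regression(y, X)
        for c in X.columns:
            assert row["beta"][c] == pytest.approx(
                st.pearsonr(X[c], y).statistic, abs=1e-8)

    def test_matches_normal_equations(self, rng):
        for _ in range(50):
            X = rng.standard_normal((40, 4))
            y = X @ rng.standard_normal(4) + rng.standard_normal(40)
            Xd = pd.DataFrame(X, columns=list("abcd"))
            row = ir.standardized_regression(y, Xd)
            Z = (X - X.mean(0)) / X.std(0, ddof=1)
            zy = (y - y.mean()) / y.std(ddof=1)
            beta = np.linalg.solve(Z.T @ Z, Z.T @ zy)
            for j, c in enumerate("abcd"):
                assert row["beta"][c] == pytest.approx(beta[j], abs=1e-10)

    def test_exact_collinearity_names_columns(self, rng):
        x = rng.standard_normal(30)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.standard_normal(30)})
        with pytest.raises(ValueError, match="collinear"):
            ir.standardized_regression(rng.standard_normal(30), X)


# ---------------------------------------------------------------------------
# ULS CFA / SEM
# ---------------------------------------------------------------------------

def _population_sample(Sigma, names, n=1000, seed=0):
    """Exactly model-implied 'sample': returns a DataFrame whose sample
    covariance equals Sigma to machine precision."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, len(names)))
    X -= X.mean(axis=0)
    # whiten, then color with the target covariance
    C = np.cov(X, rowvar=False, ddof=1)
    W = np.linalg.cholesky(np.linalg.inv(C))
    L = np.linalg.cholesky(Sigma)
    return pd.DataFrame(X @ W @ L.T, columns=names)


class TestULSCFA:
    def test_saturated_model_perfect_fit(self, rng):
        X = rng.standard_normal((200, 3)) @ rng.standard_normal((3, 3))
        data = pd.DataFrame(X, columns=["a", "b", "c"])
        spec = ModelSpec(regressions={"a": ["b", "c"]},
                         covariances=[("b", "c")])
        res = fit_cfa(spec, data, standard_errors=False)
        assert res.fit.df == 0
        assert res.fit.chi2 == pytest.approx(0.0, abs=1e-8)
        assert res.fit.cfi == 1.0 and res.fit.tli == 1.0
        assert res.fit.rmsea == 0.0
        assert res.fit.srmr < 1e-6

    def test_population_covariance_recovery(self):
        """One factor, four indicators, loadings 0.7, uniqueness 0.51."""
        lam = np.full(4, 0.7)
        Sigma = np.outer(lam, lam) + np.diag(np.full(4, 0.51))
        data = _population_sample(Sigma, ["x1", "x2", "x3", "x4"])
        spec = ModelSpec(factors={"F": ["x1", "x2", "x3", "x4"]})
        res = fit_cfa(spec, data)
        assert res.fit.srmr < 1e-6
        # free loadings are relative to the fixed first (=1); the
        # standardized solution recovers 0.7 for every indicator
        for xi in ["x1", "x2", "x3", "x4"]:
            std = float(res.estimates[
                (res.estimates.op == "=~") & (res.estimates.lhs == xi)
            ]["std"].iloc[0]) if xi != "x1" else None
        loads = res.estimates[res.estimates.op == "=~"]
        assert np.allclose(loads["est"], 1.0, atol=1e-4)
        fvar = res.estimates[(res.estimates.op == "~~") &
                             (res.estimates.lhs == "F")]["est"].iloc[0]
        assert fvar == pytest.approx(0.49, abs=1e-4)

    def test_independence_baseline_edge_case(self, rng):
        """Fitting an independence-style model to independent data:
        CFI/TLI take their defined degenerate values instead of NaN."""
        X = rng.standard_normal((300, 3)) @ np.diag([1.0, 2.0, 0.5])
        data = pd.DataFrame(X, columns=["a", "b", "c"])
        spec = ModelSpec(regressions={"a": ["b"]},
                         fixed_covariances=[("a", "c", 0.0),
                                            ("b", "c", 0.0)])
        res = fit_cfa(spec, data, standard_errors=False)
        assert 0.0 <= res.fit.cfi <= 1.0
        assert np.isfinite(res.fit.tli)

    def test_rmsea_zero_when_chi2_below_df(self):
        lam = np.full(4, 0.6)
        Sigma = np.outer(lam, lam) + np.diag(1 - lam ** 2)
        data = _population_sample(Sigma, [f"x{i}" for i in range(4)])
        res = fit_cfa(ModelSpec(factors={"F": [f"x{i}" for i in range(4)]}),
                      data, standard_errors=False)
        assert res.fit.chi2 <= res.fit.df or res.fit.rmsea == 0.0
        assert res.fit.rmsea == 0.0


class TestCrossLoadingSEM:
    def test_k1_matches_disattenuated_correlation(self):
        """Latent simple regression on a population covariance.

        One IR score x predicts a human factor with two parallel rater
        indicators (loading l, uniqueness 1-l^2); cov(x, rating) = b*l.
        The standardized structural path must equal the disattenuated
        correlation b = r_xy / l.
        """
        b, l = 0.6, 0.8
        # variables: r1__c, r2__c, x ; human factor H = b*x + e
        Sigma = np.array([
            [1.0, l * l * 1.0, b * l],
            [l * l, 1.0, b * l],
            [b * l, b * l, 1.0],
        ])
        # Var(H)=1 -> cov(r1,r2) = l^2 * Var(H)
        names = ["r1__c", "r2__c", "x"]
        data = _population_sample(Sigma, names, n=2000)
        scores = pd.DataFrame({"score__c": data["x"]}, index=data.index)
        table = ir.ScoreTable(scores, pd.Series(0.0, index=data.index),
                              pd.Series(False, index=data.index),
                              {"labels": ["c"]})
        wide = data[["r1__c", "r2__c"]]
        res = ir.fit_sem_crossloading(table, wide, standard_errors=False)
        path = res.path("HR_c", "~", "ir__c")
        assert float(path["std"]) == pytest.approx(b, abs=1e-3)
        assert res.convergent_paths == {"HR_c": "ir__c"}

    def test_null_signal_paths_near_zero(self):
        """Independent scores and ratings: structural paths hug zero."""
        ok = 0
        runs = 5
        for s in range(runs):
            rng = np.random.default_rng(700 + s)
            n = 500
            idx = pd.Index([f"d{i}" for i in range(n)], name="doc_id")
            scores = pd.DataFrame(
                rng.standard_normal((n, 3)),
                columns=[f"score__c{j}" for j in range(3)], index=idx)
            table = ir.ScoreTable(scores, pd.Series(0.0, index=idx),
                                  pd.Series(False, index=idx),
                                  {"labels": [f"c{j}" for j in range(3)]})
            F = rng.standard_normal((n, 3))
            wide = {}
            for j in range(3):
                for r in (1, 2):
                    wide[f"r{r}__c{j}"] = 0.8 * F[:, j] + \
                        0.6 * rng.standard_normal(n)
            wide = pd.DataFrame(wide, index=idx)
            res = ir.fit_sem_crossloading(table, wide,
                                          standard_errors=False)
            paths = res.estimates[res.estimates.op == "~"]["std"]
            ok += bool(np.all(np.abs(paths) < 0.15))
        assert ok >= round(0.9 * runs)

    def test_matched_effects_recovered(self):
        """Each human factor depends only on its matching score."""
        hits = 0
        runs = 8
        for s in range(runs):
            rng = np.random.default_rng(900 + s)
            n = 400
            idx = pd.Index([f"d{i}" for i in range(n)], name="doc_id")
            S = rng.standard_normal((n, 3))
            scores = pd.DataFrame(
                S, columns=[f"score__c{j}" for j in range(3)], index=idx)
            table = ir.ScoreTable(scores, pd.Series(0.0, index=idx),
                                  pd.Series(False, index=idx),
                                  {"labels": [f"c{j}" for j in range(3)]})
            F = 0.6 * S + 0.8 * rng.standard_normal((n, 3))
            wide = {}
            for j in range(3):
                for r in (1, 2):
                    wide[f"r{r}__c{j}"] = 0.8 * F[:, j] + \
                        0.6 * rng.standard_normal(n)
            wide = pd.DataFrame(wide, index=idx)
            res = ir.fit_sem_crossloading(table, wide,
                                          standard_errors=False)
            hits += all(res.convergent_paths[f"HR_c{j}"] == f"ir__c{j}"
                        for j in range(3))
        assert hits >= round(0.95 * runs)

    def test_unmatched_doc_ids_error(self, rng):
        idx1 = pd.Index([f"d{i}" for i in range(20)], name="doc_id")
        idx2 = pd.Index([f"e{i}" for i in range(20)], name="doc_id")
        scores = pd.DataFrame(rng.standard_normal((20, 2)),
                              columns=["score__a", "score__b"], index=idx1)
        table = ir.ScoreTable(scores, pd.Series(0.0, index=idx1),
                              pd.Series(False, index=idx1),
                              {"labels": ["a", "b"]})
        wide = pd.DataFrame(rng.standard_normal((20, 4)),
                            columns=["r1__a", "r1__b", "r2__a", "r2__b"],
                            index=idx2)
        with pytest.raises(ValueError, match="doc_id"):
            ir.fit_sem_crossloading(table, wide)

    def test_model_spec_yaml_round_trip(self):
        spec = ModelSpec(factors={"F": ["a", "b"]},
                         regressions={"F": ["x"]},
                         fixed_covariances=[("F", "x", 0.0)])
        again = ModelSpec.from_yaml(spec.to_yaml())
        assert again.factors == spec.factors
        assert again.regressions == spec.regressions
        assert [tuple(c) for c in again.fixed_covariances] == \
            spec.fixed_covariances
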