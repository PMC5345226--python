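import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from mesnet import survival as surv
from mesnet.containers import ExpressionMatrix
from mesnet.errors import ValidationError
from mesnet.survival import _breslow_quantities


def _clinical(times, events, ages=None, types=None):
    n = len(times)
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "age_years": ages if ages is not None else np.full(n, 50.0),
        "type": types if types is not None else ["LGG"] * n,
        "os_days": times,
        "event": events,
    })


class TestFitCox:
    def test_null_covariate_not_significant(self, rng):
        n = 500
        x = rng.standard_normal(n)
        t = rng.exponential(100.0, size=n)
        fit = surv.fit_cox(pd.DataFrame({"x": x}), t, np.ones(n, dtype=int))
        row = fit.summary.loc["x"]
        assert abs(row["coef"]) < 2 * row["se"]

    def test_recovers_planted_rate_ratio_three(self, rng):
        n = 500
        x = (rng.uniform(size=n) < 0.5).astype(float)
        t = rng.exponential(1.0 / (0.01 * np.exp(np.log(3) * x)))
        fit = surv.fit_cox(pd.DataFrame({"x": x}), t, np.ones(n, dtype=int))
        assert 2.0 <= fit.summary.loc["x", "hr"] <= 4.5
        row = fit.summary.loc["x"]
        assert row["hr_ci_low"] <= row["hr"] <= row["hr_ci_high"]

    def test_matches_grid_search_of_partial_likelihood(self):
        # 6 subjects, one binary covariate, no separation
        X = pd.DataFrame({"x": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0]})
        t = np.array([2.0, 3.0, 4.0, 6.0, 7.0, 9.0])
        e = np.array([1, 1, 0, 1, 1, 1])
        fit = surv.fit_cox(X, t, e)
        grid = np.linspace(-4, 4, 8001)
        lls = [_breslow_quantities(np.array([b]), X.to_numpy(), t, e)[0] for b in grid]
        assert fit.summary.loc["x", "coef"] == pytest.approx(
            grid[int(np.argmax(lls))], abs=1e-3)

    def test_matches_lifelines_on_tie_free_data(self, rng):
        from lifelines import CoxPHFitter
        n = 120
        X = pd.DataFrame(rng.standard_normal((n, 2)), columns=["a", "b"])
        t = rng.exponential(1.0 / (0.02 * np.exp(0.6 * X["a"])))
        e = (rng.uniform(size=n) < 0.8).astype(int)
        e[0] = 1
        fit = surv.fit_cox(X, t, e)
        df = X.copy()
        df["t"], df["e"] = t, e
        ll = CoxPHFitter().fit(df, "t", "e")  # Efron == Breslow without ties
        np.testing.assert_allclose(fit.summary["coef"], ll.summary["coef"], atol=1e-5)
        np.testing.assert_allclose(fit.summary["se"], ll.summary["se(coef)"], atol=1e-5)

    def test_separation_flagged(self):
        X = pd.DataFrame({"x": [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]})
        t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        e = np.ones(6, dtype=int)
        fit = surv.fit_cox(X, t, e)
        assert fit.flags.get("separation")

    def test_no_events_rejected(self):
        with pytest.raises(ValidationError):
            surv.fit_cox(pd.DataFrame({"x": [1.0, 2.0]}), [5.0, 6.0], [0, 0])

    def test_score_test_closed_form_single_event(self):
        """2x2 design, one event: score and information at beta=0 are closed form.

        Four subjects, x = (1, 1, 0, 0); the x=1 subject dying first has
        the full risk set of 4 with mean(x) = 1/2, so U(0) = 1 - 1/2 and
        I(0) = E[x^2] - E[x]^2 = 1/2 - 1/4; the score statistic
        U^2/I = 1.0 exactly.
        """
        X = np.array([[1.0], [1.0], [0.0], [0.0]])
        t = np.array([1.0, 5.0, 6.0, 7.0])
        e = np.array([1, 0, 0, 0])
        ll, grad, hess = _breslow_quantities(np.zeros(1), X, t, e)
        assert grad[0] == pytest.approx(0.5)
        assert -hess[0, 0] == pytest.approx(0.25)
        assert grad[0] ** 2 / -hess[0, 0] == pytest.approx(1.0)


class TestLassoCox:
    @staticmethod
    def _signal_data(rng, n=200, g=30, n_signal=3, beta=1.0):
        G = rng.standard_normal((n, g))
        lp = G[:, :n_signal] @ np.full(n_signal, beta)
        t = rng.exponential(1.0 / (0.01 * np.exp(lp)))
        c = rng.uniform(0, np.quantile(t, 0.95) * 2, size=n)
        clin = _clinical(np.minimum(t, c), (t <= c).astype(int),
                         ages=rng.normal(50, 8, n).clip(20),
                         types=rng.choice(["LGG", "GBM"], n))
        genes = pd.DataFrame(G, columns=[f"g{i}" for i in range(g)])
        return genes, clin

    def test_huge_penalty_zeroes_genes_keeps_clinical(self, rng):
        genes, clin = self._signal_data(rng)
        fit = surv.lasso_cox(genes, clin, alphas=[1e4], seed=0)
        gene_coefs = fit.summary.loc[[c for c in genes.columns
                                      if c in fit.summary.index], "coef"]
        assert (gene_coefs == 0).all()
        # clinical coefficients match the unpenalized two-covariate fit
        clin_cov = pd.concat([clin[["age_years"]],
                              surv.encode_type(clin["type"])], axis=1)
        ref = surv.fit_cox(clin_cov, clin["os_days"], clin["event"])
        for c in clin_cov.columns:
            assert fit.summary.loc[c, "coef"] == pytest.approx(
                ref.summary.loc[c, "coef"], abs=5e-3)

    def test_support_contains_signal_genes(self, rng):
        genes, clin = self._signal_data(rng, n=300, g=30, n_signal=3)
        fit = surv.lasso_cox(genes, clin, seed=1)
        assert {"g0", "g1", "g2"} <= set(fit.support)

    def test_duplicate_null_gene_stays_out_of_support(self, rng):
        genes, clin = self._signal_data(rng, n=250, g=20, n_signal=2)
        genes["g19_copy"] = genes["g19"]  # pure-noise gene duplicated
        hits = 0
        for s in range(3):
            fit = surv.lasso_cox(genes, clin, seed=s)
            hits += "g19_copy" in fit.support
        assert hits == 0

    def test_all_censored_rejected(self, rng):
        genes, clin = self._signal_data(rng, n=40, g=5)
        clin["event"] = 0
        with pytest.raises(ValidationError):
            surv.lasso_cox(genes, clin, seed=0)

    def test_penalized_flags_mark_genes_not_clinical(self, rng):
        genes, clin = self._signal_data(rng, n=120, g=8)
        fit = surv.lasso_cox(genes, clin, seed=0)
        assert fit.penalized[list(genes.columns)].all()
        assert not fit.penalized["age_years"]


class TestPrognosticIndex:
    @staticmethod
    def _fit(coefs):
        summary = pd.DataFrame({
            "coef": list(coefs.values()), "se": np.nan, "hr": np.nan,
            "hr_ci_low": np.nan, "hr_ci_high": np.nan, "p": np.nan,
        }, index=list(coefs))
        return surv.CoxFit(summary, 0.0)

    def test_all_zero_coefficients_give_zero_pi(self, rng):
        cov = pd.DataFrame(rng.standard_normal((6, 2)), columns=["a", "b"])
        res = surv.prognostic_index(cov, self._fit({"a": 0.0, "b": 0.0}))
        np.testing.assert_allclose(res.pi, 0.0)
        assert (res.risk_group == "low").all()  # ties go to low risk

    def test_single_unit_coefficient_is_identity(self, rng):
        cov = pd.DataFrame({"a": rng.standard_normal(9)})
        res = surv.prognostic_index(cov, self._fit({"a": 1.0}))
        np.testing.assert_allclose(res.pi, cov["a"])

    def test_hand_computed_dot_product(self):
        cov = pd.DataFrame({"a": [1.0, 2.0], "b": [0.5, -1.0], "c": [3.0, 0.0]})
        fit = self._fit({"a": 2.0, "b": -1.0, "c": 0.5})
        res = surv.prognostic_index(cov, fit)
        np.testing.assert_allclose(res.pi, [2 - 0.5 + 1.5, 4 + 1 + 0])

    def test_median_split_balanced(self, rng):
        cov = pd.DataFrame({"a": rng.standard_normal(20)})
        res = surv.prognostic_index(cov, self._fit({"a": 1.0}))
        counts = res.risk_group.value_counts()
        assert abs(counts.get("high", 0) - counts.get("low", 0)) <= 1

    def test_missing_covariate_named(self, rng):
        cov = pd.DataFrame({"a": rng.standard_normal(4)})
        with pytest.raises(ValidationError, match="b"):
            surv.prognostic_index(cov, self._fit({"a": 1.0, "b": 2.0}))


class TestLogrank:
    def test_identical_groups_are_null(self):
        # the same four subjects appear in both groups
        times = np.array([3.0, 5.0, 8.0, 9.0] * 2)
        events = np.array([1, 1, 0, 1] * 2)
        groups = ["a"] * 4 + ["b"] * 4
        res = surv.logrank(groups, times, events)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_six_subject_observed_expected_table(self):
        """Hand computation of the O-E log-rank statistic.

        Group A times (1, 3, 5) all events; group B times (2, 4, 6) all
        events.  Walking the six event times gives O_A = 3 and
        E_A = 6/6 + 4/5 + 3/4 + 1/3 + 1/2 = 2.8833..., V = sum of
        n1*n2*(n-d)/(n^2*(n-1)) terms = 1.4289...; chi2 = (O-E)^2/V.
        """
        times = np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
        events = np.ones(6, dtype=int)
        groups = ["A"] * 3 + ["B"] * 3
        n_at_risk = [(6, 1, 1), (5, 1, 0), (4, 1, 1), (3, 1, 0), (2, 1, 1), (1, 1, 0)]
        e_a = v = 0.0
        n1 = 3  # group A at risk
        n = 6
        o_a = 0
        for t, d, is_a in sorted(zip(times, events, [1, 1, 1, 0, 0, 0])):
            e_a += d * n1 / n
            if n > 1:
                v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
            o_a += is_a
            n1 -= is_a
            n -= 1
        expected_chi2 = (o_a - e_a) ** 2 / v
        res = surv.logrank(groups, times, events)
        assert res.chi2 == pytest.approx(expected_chi2, rel=1e-10)

    def test_power_against_planted_hazard_ratio(self, rng):
        hits = 0
        for _ in range(50):
            g = rng.uniform(size=200) < 0.5
            t = rng.exponential(1 / (0.005 * np.exp(np.log(3) * g)))
            c = rng.uniform(0, np.quantile(t, 0.9) * 2, size=200)
            res = surv.logrank(np.where(g, "high", "low"),
                               np.minimum(t, c), (t <= c).astype(int))
            hits += res.p < 0.05
        assert hits >= 45  # >= 90% of replicates

    def test_zero_event_group_flagged(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 0, 0])
        res = surv.logrank(["a", "a", "b", "b"], times, events)
        assert res.flags.get("zero_event_group") == "b"

    def test_needs_exactly_two_groups(self):
        with pytest.raises(ValidationError):
            surv.logrank(["a", "b", "c"], [1.0, 2.0, 3.0], [1, 1, 1])


class TestPerGeneCox:
    def test_single_gene_reduces_to_fit_cox(self, rng):
        n = 80
        g = pd.DataFrame({"gene": rng.standard_normal(n)})
        t = rng.exponential(100, size=n)
        clin = _clinical(t, np.ones(n, dtype=int),
                         ages=rng.normal(50, 5, n).clip(20),
                         types=rng.choice(["LGG", "GBM"], n))
        table = surv.per_gene_cox(g, clin)
        cov = pd.concat([g, clin[["age_years"]],
                         surv.encode_type(clin["type"])], axis=1)
        ref = surv.fit_cox(cov, clin["os_days"], clin["event"])
        assert table.loc[0, "coef"] == pytest.approx(ref.summary.loc["gene", "coef"])
        assert table.loc[0, "p"] == pytest.approx(ref.summary.loc["gene", "p"])

    def test_signal_gene_flagged(self, rng):
        n = 300
        x = rng.standard_normal(n)
        t = rng.exponential(1 / (0.01 * np.exp(1.0 * x)))
        clin = _clinical(t, np.ones(n, dtype=int))
        genes = pd.DataFrame({"signal": x, "noise": rng.standard_normal(n)})
        table = surv.per_gene_cox(genes, clin).set_index("gene_id")
        assert bool(table.loc["signal", "flagged"])


class TestReportEmbedding:
    def test_two_planted_clusters_recovered(self, rng):
        a = rng.normal(0, 0.3, size=(10, 12))
        a[:5] += 4.0  # half the genes high in group A samples
        b = rng.normal(0, 0.3, size=(10, 12))
        b[5:] += 4.0
        expr = ExpressionMatrix([f"g{i}" for i in range(10)],
                                [f"s{j}" for j in range(24)],
                                np.hstack([a, b]))
        labels = surv.report_embedding(expr, "hierarchical", k=2)
        truth = [0] * 12 + [1] * 12
        assert adjusted_rand_score(truth, labels) > 0.9

    def test_pca_scores_centered(self, rng):
        expr = ExpressionMatrix([f"g{i}" for i in range(6)],
                                [f"s{j}" for j in range(9)],
                                rng.standard_normal((6, 9)))
        scores = surv.report_embedding(expr, "pca")
        np.testing.assert_allclose(scores.mean(axis=0), 0.0, atol=1e-10)

    def test_duplicate_samples_identical_coordinates(self, rng):
        vals = rng.standard_normal((5, 4))
        vals[:, 3] = vals[:, 0]
        expr = ExpressionMatrix([f"g{i}" for i in range(5)], list("abcd"), vals)
        scores = surv.report_embedding(expr, "pca")
        np.testing.assert_allclose(scores.loc["a"], scores.loc["d"], atol=1e-10)

    def test_constant_matrix_rejected(self):
        expr = ExpressionMatrix(["g1", "g2"], ["a", "b"], np.full((2, 2), 3.0))
        with pytest.raises(ValidationError):
            surv.report_embedding(expr, "pca")
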