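"""Proportional-odds fitting, feature screening, pruning, prediction, evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from gaitscore.ordinal_stats import (
    evaluate,
    fit_multivariate,
    fit_proportional_odds,
    predict_category,
    prune_correlated,
    select_features,
    univariate_screen,
)


def draw_ordinal(X, beta, theta, rng):
    """Sample y from logit P(y <= j) = theta_j - x.beta."""
    eta = X @ beta
    cum = expit(np.asarray(theta)[None, :] - eta[:, None])
    return (rng.random(len(X))[:, None] > cum).sum(axis=1)


def brute_force_mle(X, y):
    """Independent numerical MLE: plain loop log-likelihood, grid + polish.

    Deliberately naive: scalar loops for the likelihood, a coarse grid on
    the slopes for initialization, Nelder-Mead for the polish.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    cats = np.unique(y)
    k = cats.size - 1
    p = X.shape[1]

    def loglike(params):
        beta, theta = params[:p], params[p:]
        if any(theta[i + 1] <= theta[i] for i in range(k - 1)):
            return -np.inf
        total = 0.0
        for xi, yi in zip(X, y):
            j = int(np.searchsorted(cats, yi))
            eta = float(np.dot(xi, beta))
            hi = expit(theta[j] - eta) if j < k else 1.0
            lo = expit(theta[j - 1] - eta) if j > 0 else 0.0
            total += np.log(max(hi - lo, 1e-300))
        return total

    counts = np.array([(y == c).sum() for c in cats], float)
    cum = np.clip(np.cumsum(counts)[:-1] / len(y), 1e-3, 1 - 1e-3)
    theta0 = np.log(cum / (1 - cum))
    best = None
    grid = [-1.0, 0.0, 1.0]
    from itertools import product

    for betas in product(grid, repeat=p):
        params = np.concatenate([betas, theta0])
        val = loglike(params)
        if best is None or val > best[1]:
            best = (params, val)
    res = minimize(
        lambda q: -loglike(q),
        best[0],
        method="Nelder-Mead",
        options={"maxiter": 20000, "xatol": 1e-8, "fatol": 1e-10},
    )
    return -res.fun


class TestProportionalOdds:
    def test_symmetric_binary_null(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(100, 1)) * 0.0  # constant predictor
        y = np.array([0] * 50 + [1] * 50)
        fit = fit_proportional_odds(X, y)
        assert fit.coefficients.iloc[0] == pytest.approx(0.0, abs=1e-4)
        assert fit.cutpoints.iloc[0] == pytest.approx(0.0, abs=1e-4)

    def test_matches_brute_force_mle(self):
        rng = np.random.default_rng(3)
        for _ in range(8):
            n = int(rng.integers(40, 101))
            p = int(rng.integers(1, 4))
            k = int(rng.integers(2, 5))
            X = rng.normal(size=(n, p))
            theta = np.sort(rng.normal(0, 1.2, size=k - 1))
            theta += 1e-3 * np.arange(k - 1)
            beta = rng.normal(0, 0.8, size=p)
            y = draw_ordinal(X, beta, theta, rng)
            if np.unique(y).size < 2:
                continue
            fit = fit_proportional_odds(X, y)
            ll_oracle = brute_force_mle(X, y)
            assert fit.log_likelihood == pytest.approx(ll_oracle, abs=1e-4)

    def test_matches_statsmodels(self):
        from statsmodels.miscmodels.ordinal_model import OrderedModel

        rng = np.random.default_rng(5)
        X = rng.normal(size=(300, 2))
        y = draw_ordinal(X, np.array([0.8, -0.6]), np.array([-1.0, 0.2, 1.5]), rng)
        fit = fit_proportional_odds(X, y)
        sm = OrderedModel(y, X, distr="logit").fit(method="bfgs", disp=0)
        assert fit.log_likelihood == pytest.approx(sm.llf, abs=1e-5)
        np.testing.assert_allclose(fit.coefficients.to_numpy(), sm.params[:2], atol=1e-4)
        np.testing.assert_allclose(fit.std_errors.to_numpy()[:2], sm.bse[:2], atol=1e-4)

    def test_parameter_recovery_large_n(self):
        rng = np.random.default_rng(11)
        beta = np.array([1.0, -0.5])
        theta = np.array([-1.0, 0.0, 1.0, 2.0])
        X = rng.normal(size=(2000, 2))
        y = draw_ordinal(X, beta, theta, rng)
        fit = fit_proportional_odds(X, y)
        for est, se, true in zip(
            np.concatenate([fit.coefficients, fit.cutpoints]),
            fit.std_errors,
            np.concatenate([beta, theta]),
        ):
            assert abs(est - true) < 3 * se

    def test_t_and_p_consistency(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 1))
        y = draw_ordinal(X, np.array([0.7]), np.array([-0.5, 0.8]), rng)
        fit = fit_proportional_odds(X, y)
        np.testing.assert_allclose(
            fit.t_values.to_numpy(),
            (pd.concat([fit.coefficients, fit.cutpoints]) / fit.std_errors).to_numpy(),
            rtol=1e-9,
        )
        assert ((fit.p_values >= 0) & (fit.p_values <= 1)).all()

    def test_refit_deterministic(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(150, 2))
        y = draw_ordinal(X, np.array([0.5, 0.5]), np.array([-0.5, 0.5]), rng)
        f1 = fit_proportional_odds(X, y)
        f2 = fit_proportional_odds(X, y)
        assert f1.log_likelihood == f2.log_likelihood
        assert (f1.coefficients == f2.coefficients).all()

    def test_cutpoints_increasing_and_probs_normalized(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(400, 2))
        y = draw_ordinal(X, np.array([1.2, -0.3]), np.array([-1.5, 0.0, 1.0, 2.2]), rng)
        fit = fit_proportional_odds(X, y)
        assert (np.diff(fit.cutpoints.to_numpy()) > 0).all()
        probs = fit.category_probabilities(rng.normal(size=(1000, 2)))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert (probs >= 0).all()


class TestScreen:
    def test_alpha_zero_selects_nothing(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame({"f": rng.normal(size=300), "y": rng.integers(0, 5, 300)})
        rep = univariate_screen(tab, ["f"], "y", alpha=0.0)
        assert rep.selected_by_p == []

    def test_informative_feature_strongly_selected(self):
        rng = np.random.default_rng(1)
        sev = rng.normal(size=500)
        y = draw_ordinal(sev[:, None], np.array([1.5]), np.array([-1.0, 0.0, 1.0, 2.0]), rng)
        tab = pd.DataFrame({"f": np.tanh(sev), "y": y})
        rep = univariate_screen(tab, ["f"], "y", alpha=0.05)
        assert rep.selected_by_p == ["f"]
        assert rep.univariate.loc["f", "p_value"] < 1e-3

    def test_null_selection_rate_calibrated(self):
        # binomial 95% band around alpha=0.05 for 200 replicates of n=500
        rng = np.random.default_rng(123)
        hits = 0
        for _ in range(200):
            tab = pd.DataFrame(
                {"f": rng.normal(size=500), "y": rng.integers(0, 5, 500)}
            )
            hits += len(univariate_screen(tab, ["f"], "y", alpha=0.05).selected_by_p)
        rate = hits / 200
        band = 1.96 * np.sqrt(0.05 * 0.95 / 200)
        assert abs(rate - 0.05) <= band

    def test_constant_feature_logged_not_fatal(self):
        rng = np.random.default_rng(4)
        tab = pd.DataFrame(
            {"c": np.ones(200), "f": rng.normal(size=200), "y": rng.integers(0, 3, 200)}
        )
        rep = univariate_screen(tab, ["c", "f"], "y")
        assert "c" in rep.failed and "f" in rep.univariate.index


def brute_force_prune(corr, out_corr, names, thr):
    """Literal re-application of the pruning rule for cross-checking."""
    pairs = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pairs.append((abs(corr.loc[a, b]), a, b))
    pairs.sort(key=lambda t: -t[0])
    alive = list(names)
    for r, a, b in pairs:
        if r <= thr or a not in alive or b not in alive:
            continue
        drop = b if abs(out_corr[a]) >= abs(out_corr[b]) else a
        alive.remove(drop)
    return alive


class TestPruning:
    def _table(self, rng, n=300, k=6, rho=0.7):
        cov = rho * np.ones((k, k)) + (1 - rho) * np.eye(k)
        X = rng.multivariate_normal(np.zeros(k), cov, size=n)
        names = [f"f{i}" for i in range(k)]
        tab = pd.DataFrame(X, columns=names)
        tab["y"] = (X[:, 0] + rng.normal(0, 1, n) > 0).astype(int)
        return tab, names

    def test_orthogonal_features_untouched(self):
        rng = np.random.default_rng(0)
        tab, names = self._table(rng, rho=0.0)
        kept, dropped = prune_correlated(tab, names, "y", r_threshold=0.5)
        if all(
            abs(tab[names].corr().loc[a, b]) <= 0.5 for i, a in enumerate(names) for b in names[i + 1 :]
        ):
            assert kept == names and dropped == []

    def test_duplicated_column_single_copy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        tab = pd.DataFrame({"a": x, "b": x.copy(), "y": (x > 0).astype(int)})
        kept, dropped = prune_correlated(tab, ["a", "b"], "y", 0.5)
        assert kept == ["a"]
        assert dropped[0][:2] == ("a", "b")

    def test_no_retained_pair_exceeds_threshold(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            tab, names = self._table(rng, rho=float(rng.uniform(0.2, 0.9)))
            kept, _ = prune_correlated(tab, names, "y", 0.5)
            corr = tab[kept].corr().to_numpy()
            off = corr[~np.eye(len(kept), dtype=bool)]
            assert (np.abs(off) <= 0.5).all()

    def test_matches_brute_force_rule(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            tab, names = self._table(rng, k=5, rho=float(rng.uniform(0.3, 0.9)))
            kept, _ = prune_correlated(tab, names, "y", 0.5)
            corr = tab[names].corr()
            out_corr = {f: tab[[f, "y"]].corr().iloc[0, 1] for f in names}
            assert kept == brute_force_prune(corr, out_corr, names, 0.5)


class TestMultivariateAndEvaluation:
    def _cohort(self, rng, n=400, informative=True):
        sev = rng.normal(size=n)
        cad = (-2.0 * sev if informative else 0.0) + rng.normal(0, 1, n)
        noise1 = rng.normal(0, 1, n)
        y = draw_ordinal(sev[:, None], np.array([2.0]), np.array([-1.5, -0.3, 1.0, 2.2]), rng)
        return pd.DataFrame(
            {
                "participant_id": np.repeat([f"p{i}" for i in range(10)], n // 10),
                "age": rng.normal(76, 9, n).clip(60, 95),
                "sex": rng.choice(["male", "female"], n),
                "cadence": cad,
                "noise1": noise1,
                "updrs_gait": y,
            }
        )

    def test_informative_feature_significant_noise_not(self):
        rng = np.random.default_rng(10)
        tab = self._cohort(rng)
        fit = fit_multivariate(tab, ["cadence", "noise1"], "updrs_gait")
        assert fit.p_values["cadence"] < 0.05
        assert fit.p_values["noise1"] > 0.05

    def test_permuted_outcome_rarely_significant(self):
        rng = np.random.default_rng(20)
        sig = 0
        reps = 40
        for _ in range(reps):
            tab = self._cohort(rng, n=300, informative=False)
            tab["updrs_gait"] = rng.permutation(tab["updrs_gait"].to_numpy())
            fit = fit_multivariate(tab, ["cadence", "noise1"], "updrs_gait")
            sig += int(fit.p_values[["cadence", "noise1"]].min() < 0.05)
        assert sig <= 0.25 * reps  # ~10% expected under the null for two tests

    def test_predict_extreme_linear_predictor(self):
        rng = np.random.default_rng(30)
        X = rng.normal(size=(300, 1))
        y = draw_ordinal(X, np.array([1.0]), np.array([-1.0, 0.0, 1.0, 2.0]), rng)
        fit = fit_proportional_odds(X, y)
        pred, probs = predict_category(fit, np.array([[-50.0]]))
        assert pred[0] == 0 and probs[0, 0] > 0.999

    def test_argmax_is_max_of_probabilities(self):
        rng = np.random.default_rng(31)
        X = rng.normal(size=(300, 2))
        y = draw_ordinal(X, np.array([1.0, -0.5]), np.array([-1.0, 0.5, 1.5]), rng)
        fit = fit_proportional_odds(X, y)
        pred, probs = predict_category(fit, rng.normal(size=(50, 2)))
        cats = np.asarray(fit.categories)
        np.testing.assert_array_equal(pred, cats[np.argmax(probs, axis=1)])

    def test_evaluation_identities(self):
        rng = np.random.default_rng(40)
        tab = self._cohort(rng)
        fit = fit_multivariate(tab, ["cadence"], "updrs_gait")
        ev = evaluate(tab, fit, "updrs_gait")
        conf = ev.confusion.to_numpy()
        assert conf.sum() == len(tab)
        assert ev.accuracy == pytest.approx(np.trace(conf) / conf.sum() * 100)
        # bout-count-weighted per-participant accuracies equal overall accuracy
        per = ev.per_participant
        weighted = (per["accuracy"] * per["n_walks"]).sum() / per["n_walks"].sum()
        assert weighted == pytest.approx(ev.accuracy)

    def test_select_features_full_report(self):
        rng = np.random.default_rng(50)
        tab = self._cohort(rng)
        tab["cadence_twin"] = tab["cadence"] + rng.normal(0, 0.1, len(tab))
        rep = select_features(tab, ["cadence", "cadence_twin", "noise1"], "updrs_gait")
        assert set(rep.final_features) <= set(rep.selected_by_p)
        assert len([f for f in ("cadence", "cadence_twin") if f in rep.final_features]) == 1
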