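"""Proportional-odds modelling of ordinal severity scores on gait features.

The modelling procedure mirrors common clinical-gait practice for ordinal
outcomes:

1. *Univariate screen*: one single-predictor proportional-odds fit per
   gait feature; features with p < alpha (no multiplicity correction —
   the screen is a gatekeeper for the multivariate model, not a
   hypothesis test) move forward.
2. *Collinearity pruning*: among screened features, for every pair with
   Pearson |r| above a threshold, only the feature with the larger
   magnitude correlation to the outcome is retained.
3. *Multivariate model*: a proportional-odds fit of the outcome on age,
   sex (male = 1) and the pruned feature set, reported with coefficients,
   standard errors, t-values, Wald p-values and labelled cut-points.

The model uses the polr-style parameterization
``logit P(y <= j | x) = theta_j - x . beta``, so a positive beta means
larger values of the predictor shift probability mass toward higher
(more severe) scores.  Cut-points are estimated only between categories
observed in the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm
from statsmodels.tools.numdiff import approx_hess

__all__ = [
    "OrdinalFit",
    "SelectionReport",
    "EvaluationResult",
    "fit_proportional_odds",
    "univariate_screen",
    "prune_correlated",
    "fit_multivariate",
    "predict_category",
    "evaluate",
]


@dataclass
class OrdinalFit:
    """A fitted proportional-odds model.

    ``coefficients`` hold the slopes beta (one per predictor);
    ``cutpoints`` the ordered thresholds theta_j, labelled "0|1" ...
    between adjacent *observed* categories.  ``std_errors``, ``t_values``
    (coef/SE) and two-sided Wald ``p_values`` cover both groups, indexed
    by the same names.
    """

    coefficients: pd.Series
    cutpoints: pd.Series
    std_errors: pd.Series
    t_values: pd.Series
    p_values: pd.Series
    log_likelihood: float
    n_obs: int
    converged: bool
    categories: tuple[int, ...]

    @property
    def feature_names(self) -> list[str]:
        return list(self.coefficients.index)

    def summary_frame(self) -> pd.DataFrame:
        """Coefficient table in the conventional layout: slopes then intercepts."""
        order = list(self.coefficients.index) + list(self.cutpoints.index)
        return pd.DataFrame(
            {
                "coefficient": pd.concat([self.coefficients, self.cutpoints]),
                "std_error": self.std_errors.reindex(order),
                "t_value": self.t_values.reindex(order),
                "p_value": self.p_values.reindex(order),
            }
        ).loc[order]

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coefficients.to_numpy()

    def category_probabilities(self, X: np.ndarray) -> np.ndarray:
        """(n, K) matrix of P(y = category_k | x); rows sum to 1."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if not np.isfinite(X).all():
            raise ValueError("predictors must be finite/complete for prediction")
        eta = self.linear_predictor(X)
        theta = self.cutpoints.to_numpy()
        cum = expit(theta[None, :] - eta[:, None])  # P(y <= j), j over K-1 cutpoints
        cum = np.hstack([np.zeros((len(eta), 1)), cum, np.ones((len(eta), 1))])
        return np.diff(cum, axis=1)


@dataclass
class SelectionReport:
    """Outcome of the univariate screen and the collinearity pruning."""

    univariate: pd.DataFrame  # index feature; columns coefficient, std_error, p_value, n_obs
    selected_by_p: list[str]
    dropped_by_correlation: list[tuple[str, str, float]] = field(default_factory=list)
    final_features: list[str] = field(default_factory=list)
    failed: dict[str, str] = field(default_factory=dict)


def _neg_loglike_and_grad(
    params: np.ndarray, X: np.ndarray, y_idx: np.ndarray, n_cut: int
) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and gradient in the (beta, theta) parameterization."""
    p = X.shape[1]
    beta, theta = params[:p], params[p:]
    if np.any(np.diff(theta) <= 0):
        return np.inf, np.zeros_like(params)
    eta = X @ beta
    thetae = np.concatenate([[-np.inf], theta, [np.inf]])
    z1 = thetae[y_idx + 1] - eta
    z0 = thetae[y_idx] - eta
    F1, F0 = expit(z1), expit(z0)
    prob = np.clip(F1 - F0, 1e-300, None)
    ll = np.sum(np.log(prob))

    f1 = F1 * (1 - F1)
    f0 = F0 * (1 - F0)
    w = (f1 - f0) / prob
    grad_beta = -X.T @ w
    grad_theta = np.zeros(n_cut)
    r1 = f1 / prob
    r0 = f0 / prob
    for j in range(n_cut):
        grad_theta[j] = np.sum(r1[y_idx == j]) - np.sum(r0[y_idx == j + 1])
    grad = np.concatenate([grad_beta, grad_theta])
    return -ll, -grad


def fit_proportional_odds(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray | pd.Series,
    feature_names: list[str] | None = None,
) -> OrdinalFit:
    """Maximum-likelihood proportional-odds fit of an ordinal outcome.

    Parameterization: ``logit P(y <= j) = theta_j - x . beta``.  Standard
    errors come from the observed information (numerical Hessian of the
    log-likelihood at the MLE); t = coef/SE and p-values are two-sided
    normal-approximation Wald tests.  Non-convergence or (quasi-)complete
    separation is flagged via ``converged`` rather than raised.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        feature_names = feature_names or [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(y)
    if not np.isfinite(X).all():
        raise ValueError("predictors must be finite")
    cats = np.unique(y)
    if cats.size < 2:
        raise ValueError("need at least 2 outcome categories")
    y_idx = np.searchsorted(cats, y)
    n, p = X.shape
    n_cut = cats.size - 1
    if n <= p + n_cut:
        raise ValueError(f"too few observations ({n}) for {p} predictors and {n_cut} cutpoints")

    # centre/scale predictors for optimizer conditioning; invert afterwards
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd

    cum = np.cumsum(np.bincount(y_idx, minlength=cats.size))[:-1] / n
    cum = np.clip(cum, 1e-3, 1 - 1e-3)
    theta0 = np.log(cum / (1 - cum))
    theta0 = np.maximum.accumulate(theta0 + 1e-6 * np.arange(n_cut))
    x0 = np.concatenate([np.zeros(p), theta0])

    res = minimize(
        _neg_loglike_and_grad,
        x0,
        args=(Xs, y_idx, n_cut),
        jac=True,
        method="BFGS",
        options={"maxiter": 500, "gtol": 1e-8},
    )
    beta_s, theta_s = res.x[:p], res.x[p:]
    # undo the standardization: beta = beta_s / sd, theta = theta_s + beta . mu
    beta = beta_s / sd
    theta = theta_s + float(beta @ mu)

    params = np.concatenate([beta, theta])
    hess = approx_hess(params, lambda q: -_neg_loglike_and_grad(q, X, y_idx, n_cut)[0])
    separated = bool(np.max(np.abs(beta_s)) > 30)
    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.diag(cov))
        se_ok = np.isfinite(se).all()
    except np.linalg.LinAlgError:
        se = np.full(params.size, np.nan)
        se_ok = False
    converged = bool(res.success or res.status == 2) and se_ok and not separated

    cut_labels = [f"{cats[j]}|{cats[j + 1]}" for j in range(n_cut)]
    names = feature_names + cut_labels
    with np.errstate(divide="ignore", invalid="ignore"):
        t = params / se
    pvals = 2 * norm.sf(np.abs(t))
    return OrdinalFit(
        coefficients=pd.Series(beta, index=feature_names),
        cutpoints=pd.Series(theta, index=cut_labels),
        std_errors=pd.Series(se, index=names),
        t_values=pd.Series(t, index=names),
        p_values=pd.Series(pvals, index=names),
        log_likelihood=float(-res.fun),
        n_obs=n,
        converged=converged,
        categories=tuple(int(c) for c in cats),
    )


def univariate_screen(
    table: pd.DataFrame,
    features: list[str],
    outcome: str,
    alpha: float = 0.05,
    min_obs: int = 20,
) -> SelectionReport:
    """One single-predictor proportional-odds fit per feature; select p < alpha.

    No multiplicity adjustment is applied.  Features whose fit fails
    (constant column, too few rows, non-convergence) are excluded with a
    logged reason rather than aborting the screen.
    """
    rows = {}
    failed: dict[str, str] = {}
    for feat in features:
        sub = table[[feat, outcome]].dropna()
        if len(sub) < min_obs:
            failed[feat] = f"only {len(sub)} complete observations"
            continue
        if sub[feat].nunique() < 2:
            failed[feat] = "constant feature"
            continue
        try:
            fit = fit_proportional_odds(sub[[feat]], sub[outcome].to_numpy())
        except (ValueError, np.linalg.LinAlgError) as exc:
            failed[feat] = str(exc)
            continue
        if not fit.converged:
            failed[feat] = "fit did not converge"
            continue
        rows[feat] = {
            "coefficient": fit.coefficients[feat],
            "std_error": fit.std_errors[feat],
            "p_value": fit.p_values[feat],
            "n_obs": fit.n_obs,
        }
    uni = pd.DataFrame.from_dict(rows, orient="index").reindex(
        [f for f in features if f in rows]
    )
    selected = [f for f in uni.index if uni.loc[f, "p_value"] < alpha]
    return SelectionReport(univariate=uni, selected_by_p=selected, failed=failed)


def prune_correlated(
    table: pd.DataFrame,
    candidates: list[str],
    outcome: str,
    r_threshold: float = 0.5,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Drop one feature of every pair with Pearson |r| above the threshold.

    Within a violating pair, the feature with the larger magnitude Pearson
    correlation to the outcome is kept (ties break toward the earlier
    column).  Pairs are processed in order of descending |r|; a feature
    already dropped triggers no further drops.  Zero-variance candidates
    are dropped outright.  Returns (retained, dropped-pairs) where each
    dropped pair is (kept, dropped, r).
    """
    dropped_pairs: list[tuple[str, str, float]] = []
    live = []
    for f in candidates:
        col = table[f].dropna()
        if col.nunique() < 2:
            dropped_pairs.append((f, f, float("nan")))  # degenerate: no defined r
            continue
        live.append(f)
    if len(live) < 2:
        return live, dropped_pairs
    corr = table[live].corr(method="pearson")
    out_corr = {f: table[[f, outcome]].dropna().corr().iloc[0, 1] for f in live}
    pairs = [
        (abs(corr.loc[a, b]), i, j, a, b)
        for i, a in enumerate(live)
        for j, b in enumerate(live[i + 1 :], start=i + 1)
    ]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    alive = set(live)
    for r_abs, _, _, a, b in pairs:
        if r_abs <= r_threshold or a not in alive or b not in alive:
            continue
        ca, cb = abs(out_corr[a]), abs(out_corr[b])
        keep, drop = (a, b) if ca >= cb else (b, a)
        alive.discard(drop)
        dropped_pairs.append((keep, drop, float(corr.loc[a, b])))
    retained = [f for f in live if f in alive]
    return retained, dropped_pairs


def select_features(
    table: pd.DataFrame,
    features: list[str],
    outcome: str,
    alpha: float = 0.05,
    r_threshold: float = 0.5,
) -> SelectionReport:
    """Full screen-then-prune feature selection, returning a complete report."""
    report = univariate_screen(table, features, outcome, alpha)
    retained, dropped = prune_correlated(table, report.selected_by_p, outcome, r_threshold)
    report.dropped_by_correlation = dropped
    report.final_features = retained
    return report


def fit_multivariate(
    table: pd.DataFrame,
    final_features: list[str],
    outcome: str,
) -> OrdinalFit:
    """Proportional-odds fit of the outcome on age, sex (male = 1) and the
    selected gait features, reported with labelled cut-point intercepts."""
    cols = ["age", "sex"] + final_features + [outcome]
    sub = table[cols].dropna()
    X = pd.DataFrame(
        {
            "age": sub["age"].astype(float),
            "sex (male)": (sub["sex"] == "male").astype(float),
        }
    )
    for f in final_features:
        X[f] = sub[f].astype(float)
    return fit_proportional_odds(X, sub[outcome].to_numpy())


def predict_category(fit: OrdinalFit, x: np.ndarray | pd.Series | pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Most probable category and the per-category probability rows.

    Prediction is restricted to the categories observed when fitting.
    Returns (predicted scores, probabilities) with probabilities of shape
    (n, n_categories).
    """
    if not fit.converged:
        raise ValueError("refusing to predict from a non-converged fit")
    if isinstance(x, (pd.Series, pd.DataFrame)):
        x = x.to_numpy(dtype=float)
    probs = fit.category_probabilities(x)
    cats = np.asarray(fit.categories)
    return cats[np.argmax(probs, axis=1)], probs


@dataclass
class EvaluationResult:
    """In-sample agreement between model predictions and annotated scores."""

    confusion: pd.DataFrame  # annotated (rows) x predicted (columns), counts
    accuracy: float  # percent
    adjacent_agreement: float  # percent with |pred - true| <= 1
    per_participant: pd.DataFrame  # accuracy (percent) and share of walks per participant


def evaluate(
    table: pd.DataFrame,
    fit: OrdinalFit,
    outcome: str,
    feature_columns: list[str] | None = None,
) -> EvaluationResult:
    """Confusion matrix, overall/per-participant accuracy and adjacent agreement.

    Evaluation is in-sample on the fitted rows: the model here is a
    descriptive regression of annotated severity, not a held-out
    classifier.  The confusion matrix is 5x5 over the full 0-4 scale.
    """
    cols = feature_columns if feature_columns is not None else list(fit.feature_names)
    sub = table.copy()
    if "sex (male)" in cols and "sex (male)" not in sub.columns:
        sub["sex (male)"] = (sub["sex"] == "male").astype(float)
    sub = sub.dropna(subset=[c for c in cols if c in sub.columns] + [outcome])
    X = sub[cols].to_numpy(dtype=float)
    y = sub[outcome].to_numpy(dtype=int)
    pred, _ = predict_category(fit, X)

    scale = list(range(5))
    confusion = pd.DataFrame(0, index=scale, columns=scale)
    for t, p_ in zip(y, pred):
        confusion.loc[t, p_] += 1
    accuracy = float(np.trace(confusion.to_numpy()) / len(y) * 100.0)
    adjacent = float(np.mean(np.abs(pred - y) <= 1) * 100.0)

    per = []
    for pid, grp_idx in sub.groupby("participant_id").groups.items():
        mask = sub.index.isin(grp_idx)
        per.append(
            {
                "participant_id": pid,
                "accuracy": float(np.mean(pred[mask] == y[mask]) * 100.0),
                "percent_of_walks": float(mask.mean() * 100.0),
                "n_walks": int(mask.sum()),
            }
        )
    per_df = pd.DataFrame(per).set_index("participant_id")
    return EvaluationResult(
        confusion=confusion,
        accuracy=accuracy,
        adjacent_agreement=adjacent,
        per_participant=per_df,
    )
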