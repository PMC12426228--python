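"""Global-score vs individual-dimension predictor comparison.

Each outcome is modeled two ways on identical bootstrap resamples: the
standardized latent path from the structural model (global score arm)
and the training R^2 of an L1-penalized regression on the ten dimension
composites (individual arm).  A fixed-effect meta-regression with a
model-type moderator then tests whether the pooled effects differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

from .sem import SEMSpec, fit_sem

logger = logging.getLogger(__name__)

__all__ = [
    "LassoConfig",
    "LassoFit",
    "Metrics",
    "fit_lasso_cv",
    "prediction_metrics",
    "kkt_residual",
    "bootstrap_effects",
    "meta_compare",
    "MetaComparison",
]


@dataclass(frozen=True)
class LassoConfig:
    n_folds: int = 10
    n_lambdas: int = 100
    decades: float = 4.0
    alpha: float | None = None  # fixed penalty; skips CV when set


@dataclass
class Metrics:
    r2: float
    f2: float
    mse: float
    mae: float
    f2_defined: bool = True


@dataclass
class LassoFit:
    """L1-penalized linear model in sklearn's parameterization:

    (1 / 2n) ||y - Xb - b0||^2 + alpha ||b||_1
    """

    coef: pd.Series
    intercept: float
    alpha: float
    alpha_grid: np.ndarray | None = None
    cv_mse: np.ndarray | None = None
    metrics: Metrics | None = None

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        return np.asarray(pd.DataFrame(X), dtype=float) @ self.coef.to_numpy() + self.intercept


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which every slope is exactly zero."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    return float(np.max(np.abs(Xc.T @ yc)) / len(y))


def _solve_lasso(X: np.ndarray, y: np.ndarray, alpha: float) -> tuple[np.ndarray, float]:
    if alpha <= 0:
        Xd = np.column_stack([np.ones(len(y)), X])
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        return beta[1:], float(beta[0])
    model = Lasso(alpha=alpha, max_iter=100_000, tol=1e-10)
    model.fit(X, y)
    return model.coef_, float(model.intercept_)


def fit_lasso_cv(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    config: LassoConfig = LassoConfig(),
    seed: int | None = None,
) -> LassoFit:
    """Fit the Lasso with the penalty chosen by k-fold cross-validation.

    The grid runs from lambda_max down ``config.decades`` decades on a
    log scale; the minimizing mean CV error wins.  ``alpha=0`` reduces
    exactly to OLS.
    """
    Xa = np.asarray(pd.DataFrame(X), dtype=float)
    ya = np.asarray(y, dtype=float)
    n = len(ya)
    if np.std(ya) == 0:
        raise ValueError("constant outcome")
    cols = list(pd.DataFrame(X).columns)

    grid = None
    cv_mse = None
    if config.alpha is not None:
        alpha = config.alpha
    else:
        if n < config.n_folds:
            raise ValueError("n smaller than the number of CV folds")
        lam_hi = lambda_max(Xa, ya)
        grid = np.geomspace(lam_hi, lam_hi * 10 ** (-config.decades), config.n_lambdas)
        folds = KFold(config.n_folds, shuffle=True, random_state=seed)
        errs = np.zeros((config.n_folds, grid.size))
        for f, (tr, te) in enumerate(folds.split(Xa)):
            for a, lam in enumerate(grid):
                b, b0 = _solve_lasso(Xa[tr], ya[tr], lam)
                errs[f, a] = np.mean((ya[te] - Xa[te] @ b - b0) ** 2)
        cv_mse = errs.mean(axis=0)
        alpha = float(grid[int(np.argmin(cv_mse))])
    b, b0 = _solve_lasso(Xa, ya, alpha)
    fit = LassoFit(pd.Series(b, index=cols), b0, alpha, grid, cv_mse)
    fit.metrics = prediction_metrics(fit, Xa, ya)
    return fit


def prediction_metrics(fit: LassoFit, X, y) -> Metrics:
    """Training-scale R^2, Cohen's f^2 = R^2/(1-R^2), MSE and MAE."""
    ya = np.asarray(y, dtype=float)
    pred = fit.predict(X)
    sst = float(np.sum((ya - ya.mean()) ** 2))
    if sst == 0:
        raise ValueError("outcome has zero variance (SST = 0)")
    sse = float(np.sum((ya - pred) ** 2))
    r2 = 1.0 - sse / sst
    if r2 >= 1.0:
        return Metrics(1.0, np.inf, 0.0, 0.0, f2_defined=False)
    return Metrics(
        r2=r2,
        f2=r2 / (1.0 - r2),
        mse=float(np.mean((ya - pred) ** 2)),
        mae=float(np.mean(np.abs(ya - pred))),
    )


def cohens_f2(r2: float) -> float:
    if r2 >= 1:
        raise ValueError("f^2 undefined at R^2 = 1")
    return r2 / (1.0 - r2)


def kkt_residual(fit: LassoFit, X, y) -> float:
    """Max violation of the Lasso stationarity conditions at the solution.

    For sklearn's objective the subgradient conditions are
    ``|X_j'(y - yhat)| / n <= alpha`` with equality (and matching sign)
    for active coordinates.
    """
    Xa = np.asarray(pd.DataFrame(X), dtype=float)
    ya = np.asarray(y, dtype=float)
    n = len(ya)
    resid = ya - fit.predict(Xa)
    g = Xa.T @ resid / n
    viol = np.abs(resid.mean())  # intercept stationarity
    b = fit.coef.to_numpy()
    for j in range(len(b)):
        if b[j] == 0:
            viol = max(viol, max(abs(g[j]) - fit.alpha, 0.0))
        else:
            viol = max(viol, abs(g[j] - fit.alpha * np.sign(b[j])))
    return float(viol)


def bootstrap_effects(
    data: pd.DataFrame,
    sem_spec: SEMSpec,
    lasso_config: LassoConfig = LassoConfig(),
    B: int = 400,
    seed: int | None = None,
    max_failure_rate: float = 0.2,
) -> pd.DataFrame:
    """Paired bootstrap draws of the two effect families.

    Both families see the identical resampled subjects per replicate.
    Returns a long frame with columns replicate / outcome / model_type /
    effect, where the global arm's effect is the standardized latent
    path and the individual arm's is the Lasso training R^2.

    The Lasso penalty is chosen once per outcome by CV on the full
    sample (unless fixed in the config) and reused across replicates.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    n = len(data)
    dims = list(sem_spec.indicators)
    outcomes = list(sem_spec.outcomes)

    alphas = {}
    for k, out in enumerate(outcomes):
        if lasso_config.alpha is not None:
            alphas[out] = lasso_config.alpha
        else:
            full = fit_lasso_cv(
                data[dims], data[out], lasso_config,
                seed=None if seed is None else seed + 7919 * (k + 1),
            )
            alphas[out] = full.alpha

    records = []
    n_failed = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        sample = data.iloc[idx]
        try:
            fit = fit_sem(sample, sem_spec, compute_se=False)
            if not fit.converged:
                raise RuntimeError("non-convergence")
            paths = fit.paths(standardized=True)
        except Exception:
            n_failed += 1
            continue
        for out in outcomes:
            coef, b0 = _solve_lasso(
                sample[dims].to_numpy(dtype=float),
                sample[out].to_numpy(dtype=float),
                alphas[out],
            )
            lfit = LassoFit(pd.Series(coef, index=dims), b0, alphas[out])
            m = prediction_metrics(lfit, sample[dims], sample[out])
            records.append(
                {"replicate": b, "outcome": out, "model_type": "global_MSE", "effect": paths[out]}
            )
            records.append(
                {"replicate": b, "outcome": out, "model_type": "individual_dimensions", "effect": m.r2}
            )
    if n_failed > max_failure_rate * B:
        raise RuntimeError(f"{n_failed}/{B} bootstrap replicates failed")
    if n_failed:
        logger.warning("%d/%d bootstrap replicates failed and were excluded", n_failed, B)
    return pd.DataFrame.from_records(records)


@dataclass
class MetaComparison:
    """Fixed-effect pooled effects per arm and the moderator Wald test."""

    table: pd.DataFrame  # per model_type: common_effect, ci_low, ci_high
    qm: float
    p_value: float
    outcome: str | None = None


def meta_compare(
    effects: pd.DataFrame,
    outcome: str | None = None,
    weighting: str = "inverse_variance",
) -> MetaComparison:
    """Fixed-effect meta-regression of bootstrap draws on model type.

    Per-draw sampling variances are set to each arm's empirical
    bootstrap variance (constant within arm), so the common effect is
    the arm mean and QM is the equal-variance Wald chi-square with 1 df:
    ``(mean_1 - mean_2)^2 / (v_1/B_1 + v_2/B_2)``.  ``weighting="equal"``
    uses the pooled variance for both arms instead.
    """
    frame = effects
    if outcome is not None:
        frame = frame.loc[frame["outcome"] == outcome]
    arms = frame.groupby("model_type")["effect"]
    if len(arms) != 2:
        raise ValueError("need exactly two model types")
    stats_rows = {}
    for name, draws in arms:
        draws = draws.dropna().to_numpy()
        if draws.size < 2:
            raise ValueError(f"arm {name!r} needs >= 2 replicates")
        stats_rows[name] = (draws.mean(), draws.var(ddof=1), draws.size)
    variances = np.array([v for _, v, _ in stats_rows.values()])
    if np.all(variances == 0):
        raise ValueError("zero variance in both arms")
    if weighting == "equal":
        pooled = float(variances.mean())
        stats_rows = {k: (m, pooled, b) for k, (m, v, b) in stats_rows.items()}
    elif weighting != "inverse_variance":
        raise ValueError("weighting must be 'inverse_variance' or 'equal'")
    rows = []
    for name, (mean, var, b) in stats_rows.items():
        se = np.sqrt(var / b)
        rows.append(
            {
                "model_type": name,
                "common_effect": mean,
                "ci_low": mean - 1.959963984540054 * se,
                "ci_high": mean + 1.959963984540054 * se,
                "n_replicates": b,
            }
        )
    (m1, v1, b1), (m2, v2, b2) = stats_rows.values()
    denom = v1 / b1 + v2 / b2
    qm = float((m1 - m2) ** 2 / denom) if denom > 0 else np.inf
    p = float(stats.chi2.sf(qm, 1))
    return MetaComparison(pd.DataFrame(rows), qm, p, outcome)


def compare_all_outcomes(
    effects: pd.DataFrame, weighting: str = "inverse_variance"
) -> pd.DataFrame:
    """Table-shaped summary: one block of rows per outcome."""
    rows = []
    for out in effects["outcome"].unique():
        mc = meta_compare(effects, outcome=out, weighting=weighting)
        for r in mc.table.to_dict("records"):
            r.update({"outcome": out, "qm_chi2": mc.qm, "p_value": mc.p_value})
            rows.append(r)
    return pd.DataFrame(rows)
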