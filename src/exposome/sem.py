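"""Maximum-likelihood one-factor structural equation model.

Ten bounded dimension composites load on a single latent adversity
factor which simultaneously predicts three outcomes; exogenous
covariates may additionally be regressed on the latent and the
outcomes (sensitivity models).  The model is parameterized in RAM form

    v = A v + u,    u ~ N(0, S0),    Sigma = F (I-A)^-1 S0 (I-A)^-T F^T

and estimated by minimizing the normal-theory discrepancy

    F_ML(theta) = log|Sigma| + tr(S Sigma^-1) - log|S| - p

with an analytic gradient.  chi2 = (n - 1) F_ML at the optimum
(covariances use the n - 1 denominator throughout).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .scoring import DIMENSIONS

logger = logging.getLogger(__name__)

__all__ = [
    "SEMSpec",
    "SEMFit",
    "FitIndices",
    "fit_sem_ml",
    "fit_sem",
    "compute_fit_indices",
    "extract_factor_scores",
    "modification_index",
    "bootstrap_sem",
    "BootstrapResult",
]

DEFAULT_OUTCOMES = ("cognition", "functional_ability", "neuropsychiatric")

F_TOL = 1e-11
GRAD_TOL = 1e-5
MAX_ITER = 10_000


class HeywoodWarning(UserWarning):
    pass


@dataclass(frozen=True)
class SEMSpec:
    """Structure of the one-latent model."""

    indicators: tuple[str, ...] = DIMENSIONS
    fixed_indicator: str = "access_healthcare"
    outcomes: tuple[str, ...] = DEFAULT_OUTCOMES
    freed_residual_covariances: tuple[tuple[str, str], ...] = ()
    covariates: tuple[str, ...] = ()
    latent_name: str = "MSE"

    def __post_init__(self) -> None:
        if self.fixed_indicator not in self.indicators:
            raise ValueError(
                f"fixed indicator {self.fixed_indicator!r} is not among the indicators"
            )
        obs = self.observed
        if len(set(obs)) != len(obs):
            raise ValueError("observed variable names must be unique")
        for a, b in self.freed_residual_covariances:
            if a == b:
                raise ValueError("freed covariance must link two distinct variables")
            if a not in obs or b not in obs:
                raise ValueError(f"freed covariance pair ({a}, {b}) not observed")

    @property
    def observed(self) -> tuple[str, ...]:
        return tuple(self.indicators) + tuple(self.outcomes) + tuple(self.covariates)


@dataclass(frozen=True)
class _Param:
    label: str
    kind: str  # loading | path | gamma_latent | gamma_outcome | latent_var | resid_var | resid_cov | cov_var | cov_cov
    mat: str  # "A" or "S"
    i: int
    j: int


class _Model:
    """RAM matrices, free-parameter bookkeeping, F_ML and its gradient."""

    def __init__(self, spec: SEMSpec):
        self.spec = spec
        self.obs = list(spec.observed)
        self.p = len(self.obs)
        self.m = self.p + 1
        self.latent = self.p  # latent variable index
        self.idx = {v: i for i, v in enumerate(self.obs)}
        self.params: list[_Param] = []
        A0 = np.zeros((self.m, self.m))
        S0 = np.zeros((self.m, self.m))

        lat = self.latent
        for name in spec.indicators:
            i = self.idx[name]
            if name == spec.fixed_indicator:
                A0[i, lat] = 1.0  # identification constraint
            else:
                self.params.append(_Param(f"{name}~{spec.latent_name}", "loading", "A", i, lat))
        for name in spec.outcomes:
            i = self.idx[name]
            self.params.append(_Param(f"{name}~{spec.latent_name}", "path", "A", i, lat))
        for cov in spec.covariates:
            j = self.idx[cov]
            self.params.append(_Param(f"{spec.latent_name}~{cov}", "gamma_latent", "A", lat, j))
            for name in spec.outcomes:
                i = self.idx[name]
                self.params.append(_Param(f"{name}~{cov}", "gamma_outcome", "A", i, j))
        self.params.append(_Param(f"var({spec.latent_name})", "latent_var", "S", lat, lat))
        for name in list(spec.indicators) + list(spec.outcomes):
            i = self.idx[name]
            self.params.append(_Param(f"resid({name})", "resid_var", "S", i, i))
        ncov = len(spec.covariates)
        for a in range(ncov):
            i = self.idx[spec.covariates[a]]
            self.params.append(_Param(f"var({spec.covariates[a]})", "cov_var", "S", i, i))
            for b in range(a + 1, ncov):
                j = self.idx[spec.covariates[b]]
                self.params.append(
                    _Param(f"cov({spec.covariates[a]},{spec.covariates[b]})", "cov_cov", "S", i, j)
                )
        for a, b in spec.freed_residual_covariances:
            self.params.append(_Param(f"resid_cov({a},{b})", "resid_cov", "S", self.idx[a], self.idx[b]))

        self.A0, self.S0 = A0, S0
        self.q = len(self.params)
        dof = self.p * (self.p + 1) // 2 - self.q
        if dof < 0:
            raise ValueError(f"model has negative degrees of freedom ({dof})")

    # -- matrix assembly ----------------------------------------------------
    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        A = self.A0.copy()
        S = self.S0.copy()
        for val, prm in zip(theta, self.params):
            if prm.mat == "A":
                A[prm.i, prm.j] = val
            else:
                S[prm.i, prm.j] = val
                S[prm.j, prm.i] = val
        return A, S

    def implied(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(Sigma_obs, Sigma_all, B) for a parameter vector."""
        A, S = self.matrices(theta)
        B = np.linalg.inv(np.eye(self.m) - A)
        sigma_all = B @ S @ B.T
        return sigma_all[: self.p, : self.p], sigma_all, B

    # -- discrepancy and gradient ------------------------------------------
    def fml(self, theta: np.ndarray, S: np.ndarray, logdet_s: float) -> float:
        sigma, _, _ = self.implied(theta)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return 1e12
        try:
            sigma_inv = np.linalg.inv(sigma)
        except np.linalg.LinAlgError:
            return 1e12
        return float(logdet + np.trace(S @ sigma_inv) - logdet_s - self.p)

    def fml_grad(
        self, theta: np.ndarray, S: np.ndarray, logdet_s: float
    ) -> tuple[float, np.ndarray]:
        sigma, sigma_all, B = self.implied(theta)
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return 1e12, np.zeros_like(theta)
        sigma_inv = np.linalg.inv(sigma)
        f = float(logdet + np.trace(S @ sigma_inv) - logdet_s - self.p)
        M = sigma_inv - sigma_inv @ S @ sigma_inv
        W = np.zeros((self.m, self.m))
        W[: self.p, : self.p] = M
        GA = 2.0 * (sigma_all @ W @ B).T
        GS = B.T @ W @ B
        grad = np.empty(self.q)
        for k, prm in enumerate(self.params):
            if prm.mat == "A":
                grad[k] = GA[prm.i, prm.j]
            elif prm.i == prm.j:
                grad[k] = GS[prm.i, prm.i]
            else:
                grad[k] = 2.0 * GS[prm.i, prm.j]
        return f, grad

    # -- start values -------------------------------------------------------
    def start_values(self, S: np.ndarray) -> np.ndarray:
        spec = self.spec
        d = np.sqrt(np.diag(S))
        theta = np.zeros(self.q)
        ind_idx = [self.idx[v] for v in spec.indicators]
        S_ind = S[np.ix_(ind_idx, ind_idx)]
        # one round of principal-axis factoring on the indicator block
        R = S_ind / np.outer(d[ind_idx], d[ind_idx])
        Rr = R.copy()
        np.fill_diagonal(Rr, np.clip(1 - 1 / np.diag(np.linalg.inv(R)), 0.05, 0.95))
        w, V = np.linalg.eigh(Rr)
        pa = V[:, -1] * np.sqrt(max(w[-1], 0.1))
        if pa.sum() < 0:
            pa = -pa
        load_std = dict(zip(spec.indicators, np.clip(pa, 0.1, 0.95)))
        fi = self.idx[spec.fixed_indicator]
        psi0 = max(load_std[spec.fixed_indicator] ** 2 * S[fi, fi], 1e-3)
        for k, prm in enumerate(self.params):
            if prm.kind == "loading":
                name = self.obs[prm.i]
                theta[k] = load_std[name] * d[prm.i] / np.sqrt(psi0)
            elif prm.kind == "path":
                theta[k] = 0.1 * d[prm.i] / np.sqrt(psi0)
            elif prm.kind == "latent_var":
                theta[k] = psi0
            elif prm.kind == "resid_var":
                theta[k] = 0.5 * S[prm.i, prm.i]
            elif prm.kind == "cov_var":
                theta[k] = S[prm.i, prm.i]
            elif prm.kind == "cov_cov":
                theta[k] = S[prm.i, prm.j]
            # gamma_* and resid_cov start at 0
        return theta


@dataclass
class FitIndices:
    cfi: float
    tli: float | None
    rmsea: float
    srmr: float
    chi2_model: float
    df_model: int
    chi2_baseline: float
    df_baseline: int
    tli_defined: bool = True


@dataclass
class SEMFit:
    """Estimated model: parameter table, implied covariance, fit indices."""

    spec: SEMSpec
    params: pd.DataFrame
    sigma: np.ndarray
    sample_cov: np.ndarray
    n: int
    chi2: float
    df: int
    fml: float
    indices: FitIndices
    converged: bool
    heywood: bool
    theta: np.ndarray = field(repr=False, default=None)
    model: _Model = field(repr=False, default=None)
    grad_norm: float = np.nan
    means: pd.Series | None = None

    def estimate(self, label: str) -> float:
        row = self.params.loc[self.params["label"] == label]
        if row.empty:
            raise KeyError(label)
        return float(row["estimate"].iloc[0])

    def standardized(self, label: str) -> float:
        row = self.params.loc[self.params["label"] == label]
        if row.empty:
            raise KeyError(label)
        return float(row["std_estimate"].iloc[0])

    def loadings(self, standardized: bool = True) -> pd.Series:
        col = "std_estimate" if standardized else "estimate"
        sel = self.params["kind"].isin(["loading", "fixed_loading"])
        out = self.params.loc[sel]
        return pd.Series(out[col].to_numpy(), index=[l.split("~")[0] for l in out["label"]])

    def paths(self, standardized: bool = True) -> pd.Series:
        col = "std_estimate" if standardized else "estimate"
        out = self.params.loc[self.params["kind"] == "path"]
        return pd.Series(out[col].to_numpy(), index=[l.split("~")[0] for l in out["label"]])


def compute_fit_indices(
    chi2_m: float,
    df_m: int,
    chi2_b: float,
    df_b: int,
    n: int,
    S: np.ndarray | None = None,
    sigma: np.ndarray | None = None,
) -> FitIndices:
    """Closed-form CFI / TLI / RMSEA / SRMR from chi-square statistics.

    CFI and RMSEA use the max-clamped definitions; TLI is flagged
    undefined when the baseline ratio degenerates (chi2_b <= df_b).
    SRMR is the RMS of standardized residual covariances (diagonal
    included) and requires S and Sigma.
    """
    if df_m <= 0 or df_b <= 0:
        raise ValueError("degrees of freedom must be positive")
    num = max(chi2_m - df_m, 0.0)
    den = max(chi2_b - df_b, chi2_m - df_m, 0.0)
    cfi = 1.0 if den == 0 else 1.0 - num / den
    tli_defined = chi2_b > df_b
    tli = None
    if tli_defined:
        tli = ((chi2_b / df_b) - (chi2_m / df_m)) / ((chi2_b / df_b) - 1.0)
    rmsea = float(np.sqrt(max(chi2_m - df_m, 0.0) / (df_m * (n - 1))))
    srmr = np.nan
    if S is not None and sigma is not None:
        d = np.sqrt(np.diag(S))
        resid = (S - sigma) / np.outer(d, d)
        iu = np.triu_indices(S.shape[0])
        srmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
    return FitIndices(cfi, tli, rmsea, srmr, chi2_m, df_m, chi2_b, df_b, tli_defined)


def _baseline_chi2(S: np.ndarray, n: int) -> tuple[float, int]:
    """Independence model: free variances, zero covariances."""
    p = S.shape[0]
    sign, logdet_s = np.linalg.slogdet(S)
    f_b = float(np.sum(np.log(np.diag(S))) - logdet_s)
    return (n - 1) * f_b, p * (p + 1) // 2 - p


def fit_sem_ml(
    S: np.ndarray | pd.DataFrame,
    n: int,
    spec: SEMSpec,
    bound_residuals: bool = False,
    compute_se: bool = True,
) -> SEMFit:
    """Fit the model to a sample covariance matrix by ML.

    Parameters are estimated with L-BFGS-B on the free vector using the
    analytic gradient; convergence requires the gradient infinity-norm
    below 1e-5 at the solution.  Negative residual variances (Heywood
    cases) are flagged, not clipped, unless ``bound_residuals`` is set.
    """
    model = _Model(spec)
    if isinstance(S, pd.DataFrame):
        S = S.loc[list(spec.observed), list(spec.observed)].to_numpy(dtype=float)
    S = np.asarray(S, dtype=float)
    if S.shape != (model.p, model.p):
        raise ValueError(f"covariance must be {model.p}x{model.p}")
    if np.abs(S - S.T).max() > 1e-8:
        raise ValueError("covariance matrix must be symmetric")
    eigmin = float(np.linalg.eigvalsh(S).min())
    if eigmin <= 0:
        raise ValueError(f"covariance matrix is not positive definite (min eig {eigmin:.3g})")
    if n <= model.p:
        raise ValueError("n must exceed the number of observed variables")
    sign, logdet_s = np.linalg.slogdet(S)

    theta0 = model.start_values(S)
    bounds = None
    if bound_residuals:
        bounds = [
            (1e-8, None) if prm.kind in ("resid_var", "latent_var", "cov_var") else (None, None)
            for prm in model.params
        ]
    res = optimize.minimize(
        model.fml_grad,
        theta0,
        args=(S, logdet_s),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": MAX_ITER, "ftol": F_TOL, "gtol": GRAD_TOL * 1e-2},
    )
    theta = res.x
    f_val, grad = model.fml_grad(theta, S, logdet_s)
    if bounds is not None:
        # project the gradient at active bounds
        grad = grad.copy()
        for k, (lo, _) in enumerate(bounds):
            if lo is not None and theta[k] <= lo + 1e-10 and grad[k] > 0:
                grad[k] = 0.0
    grad_norm = float(np.abs(grad).max())
    # F_ML >= 0 with minimum 0, so a near-zero value certifies the optimum
    # even when near-singular residual variances distort the gradient scale
    converged = bool(np.isfinite(f_val)) and (grad_norm < GRAD_TOL or f_val < 1e-9)
    if not converged and bounds is None:
        # one polishing pass from the L-BFGS solution
        res2 = optimize.minimize(
            model.fml_grad, theta, args=(S, logdet_s), jac=True, method="BFGS",
            options={"maxiter": MAX_ITER, "gtol": GRAD_TOL * 1e-2},
        )
        if res2.fun <= f_val:
            theta = res2.x
            f_val, grad = model.fml_grad(theta, S, logdet_s)
            grad_norm = float(np.abs(grad).max())
            converged = grad_norm < GRAD_TOL

    sigma, sigma_all, _ = model.implied(theta)
    chi2 = max((n - 1) * f_val, 0.0)
    df = model.p * (model.p + 1) // 2 - model.q
    heywood = any(
        theta[k] < 0
        for k, prm in enumerate(model.params)
        if prm.kind in ("resid_var", "latent_var")
    )
    if heywood:
        logger.warning("Heywood case: negative residual/latent variance at the solution")

    if compute_se:
        se = _standard_errors(model, theta, S, logdet_s, n)
    else:
        se = np.full(model.q, np.nan)
    params = _parameter_table(model, theta, se, sigma_all)
    chi2_b, df_b = _baseline_chi2(S, n)
    indices = None
    if df > 0 and df_b > 0:
        indices = compute_fit_indices(chi2, df, chi2_b, df_b, n, S, sigma)
    return SEMFit(
        spec=spec,
        params=params,
        sigma=sigma,
        sample_cov=S,
        n=n,
        chi2=chi2,
        df=df,
        fml=f_val,
        indices=indices,
        converged=converged,
        heywood=heywood,
        theta=theta,
        model=model,
        grad_norm=grad_norm,
    )


def fit_sem(data: pd.DataFrame, spec: SEMSpec, **kwargs) -> SEMFit:
    """Fit from raw (listwise-complete) data; covariance uses n - 1."""
    cols = list(spec.observed)
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"data lacks columns {missing}")
    frame = data[cols]
    if frame.isna().any().any():
        raise ValueError("data contains missing values; impute upstream")
    S = np.cov(frame.to_numpy(dtype=float), rowvar=False, ddof=1)
    fit = fit_sem_ml(S, len(frame), spec, **kwargs)
    fit.means = frame.mean()
    return fit


def _numeric_hessian(model: _Model, theta: np.ndarray, S, logdet_s, eps: float = 1e-5) -> np.ndarray:
    """Central finite differences of the analytic gradient."""
    q = theta.size
    H = np.zeros((q, q))
    for k in range(q):
        step = eps * max(1.0, abs(theta[k]))
        tp, tm = theta.copy(), theta.copy()
        tp[k] += step
        tm[k] -= step
        _, gp = model.fml_grad(tp, S, logdet_s)
        _, gm = model.fml_grad(tm, S, logdet_s)
        H[k] = (gp - gm) / (2 * step)
    return (H + H.T) / 2


def _standard_errors(model, theta, S, logdet_s, n) -> np.ndarray:
    """SEs from the observed information: cov(theta) = 2 H^-1 / (n - 1)."""
    try:
        H = _numeric_hessian(model, theta, S, logdet_s)
        cov = 2.0 * np.linalg.pinv(H) / (n - 1)
        var = np.clip(np.diag(cov), 0.0, None)
        return np.sqrt(var)
    except np.linalg.LinAlgError:
        return np.full(theta.size, np.nan)


def _parameter_table(model: _Model, theta, se, sigma_all) -> pd.DataFrame:
    sd_all = np.sqrt(np.clip(np.diag(sigma_all), 1e-300, None))
    rows = []
    for k, prm in enumerate(model.params):
        est = theta[k]
        if prm.mat == "A":
            std = est * sd_all[prm.j] / sd_all[prm.i]
        elif prm.i == prm.j:
            std = est / sigma_all[prm.i, prm.i]
        else:
            std = est / (sd_all[prm.i] * sd_all[prm.j])
        scale = abs(std / est) if est != 0 else 1.0
        rows.append(
            {
                "label": prm.label,
                "kind": prm.kind,
                "estimate": est,
                "se": se[k],
                "ci_low": est - 1.959963984540054 * se[k],
                "ci_high": est + 1.959963984540054 * se[k],
                "std_estimate": std,
                "std_ci_low": std - 1.959963984540054 * se[k] * scale,
                "std_ci_high": std + 1.959963984540054 * se[k] * scale,
            }
        )
    # the fixed loading, standardized
    fi = model.idx[model.spec.fixed_indicator]
    lat = model.latent
    rows.append(
        {
            "label": f"{model.spec.fixed_indicator}~{model.spec.latent_name}",
            "kind": "fixed_loading",
            "estimate": 1.0,
            "se": 0.0,
            "ci_low": 1.0,
            "ci_high": 1.0,
            "std_estimate": sd_all[lat] / sd_all[fi],
            "std_ci_low": np.nan,
            "std_ci_high": np.nan,
        }
    )
    return pd.DataFrame(rows)


def extract_factor_scores(
    data: pd.DataFrame,
    fit: SEMFit,
    method: str = "regression",
) -> pd.Series:
    """Per-subject latent scores from a converged fit on complete data.

    ``regression`` scores are E[latent | observed] under the fitted
    Gaussian model; ``bartlett`` scores weight by inverse residual
    variances of the loaded variables.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    model = fit.model
    cols = list(fit.spec.observed)
    frame = data[cols]
    if frame.isna().any().any():
        raise ValueError("factor scores require complete data")
    Z = frame.to_numpy(dtype=float)
    Z = Z - Z.mean(axis=0)
    _, sigma_all, _ = model.implied(fit.theta)
    p, lat = model.p, model.latent
    if method == "regression":
        cov_zl = sigma_all[:p, lat]
        weights = np.linalg.solve(sigma_all[:p, :p], cov_zl)
        scores = Z @ weights
    elif method == "bartlett":
        A, S0 = model.matrices(fit.theta)
        lam = A[:p, lat]
        theta_res = S0[:p, :p].copy()
        loaded = lam != 0
        lam_l = lam[loaded]
        theta_l = theta_res[np.ix_(loaded, loaded)]
        w = np.linalg.solve(theta_l, lam_l)
        scores = (Z[:, loaded] @ w) / float(lam_l @ w)
    else:
        raise ValueError("method must be 'regression' or 'bartlett'")
    return pd.Series(scores, index=frame.index, name="mse_score")


def _free_hessian_inv(fit: SEMFit) -> np.ndarray:
    """Pseudo-inverse of the free-parameter Hessian of F_ML at the fit."""
    _, logdet_s = np.linalg.slogdet(fit.sample_cov)
    H = _numeric_hessian(fit.model, fit.theta, fit.sample_cov, logdet_s)
    return np.linalg.pinv(H)


def modification_index(
    fit: SEMFit,
    mat: str,
    var_a: str,
    var_b: str,
    _h_aa_inv: np.ndarray | None = None,
) -> float:
    """Score-test estimate of the chi-square drop from freeing a parameter.

    ``mat`` selects the matrix: "S" frees a residual covariance between
    two variables; "A" frees a directed path var_a <- var_b.  The
    candidate must currently be constrained; the statistic is the
    expected chi-square improvement from one Newton step along the freed
    direction (re-optimizing the free parameters), and is >= 0.
    """
    model = fit.model
    names = {**model.idx, fit.spec.latent_name: model.latent}
    i, j = names[var_a], names[var_b]
    for prm in model.params:
        if prm.mat != mat:
            continue
        same = (prm.i, prm.j) == (i, j) or (mat == "S" and (prm.j, prm.i) == (i, j))
        if same:
            raise ValueError(f"parameter {var_a}, {var_b} is already free")
    if mat == "A" and model.A0[i, j] != 0:
        raise ValueError(f"parameter {var_a}, {var_b} is fixed to a nonzero constant")
    ext = _Model(fit.spec)
    cand = _Param(f"candidate({var_a},{var_b})", "candidate", mat, i, j)
    ext.params = list(model.params) + [cand]
    ext.q = len(ext.params)
    theta_ext = np.concatenate([fit.theta, [0.0]])
    S = fit.sample_cov
    _, logdet_s = np.linalg.slogdet(S)
    _, g = ext.fml_grad(theta_ext, S, logdet_s)
    qfree = model.q
    # Hessian column for the candidate (finite difference on its coordinate)
    eps = 1e-5
    tp, tm = theta_ext.copy(), theta_ext.copy()
    tp[qfree] += eps
    tm[qfree] -= eps
    _, gp = ext.fml_grad(tp, S, logdet_s)
    _, gm = ext.fml_grad(tm, S, logdet_s)
    h_col = (gp - gm) / (2 * eps)
    h_aa_inv = _h_aa_inv if _h_aa_inv is not None else _free_hessian_inv(fit)
    h_ac = h_col[:qfree]
    h_eff = float(h_col[qfree] - h_ac @ h_aa_inv @ h_ac)
    if h_eff <= 0:
        return 0.0
    mi = (fit.n - 1) * g[qfree] ** 2 / (2.0 * h_eff)
    return float(max(mi, 0.0))


def top_modification_index(fit: SEMFit) -> tuple[tuple[str, str], float]:
    """Best candidate residual covariance among observed variables."""
    freed = {frozenset(p) for p in fit.spec.freed_residual_covariances}
    h_aa_inv = _free_hessian_inv(fit)
    best, best_mi = None, -1.0
    obs = fit.spec.observed
    for a in range(len(obs)):
        for b in range(a + 1, len(obs)):
            pair = (obs[a], obs[b])
            if frozenset(pair) in freed:
                continue
            mi = modification_index(fit, "S", *pair, _h_aa_inv=h_aa_inv)
            if mi > best_mi:
                best, best_mi = pair, mi
    return best, best_mi


@dataclass
class BootstrapResult:
    paths: pd.DataFrame  # replicate x outcome standardized paths
    n_failed: int
    indices: list[np.ndarray] = field(repr=False, default=None)

    def percentile_ci(self, outcome: str, level: float = 0.95) -> tuple[float, float]:
        lo = (1 - level) / 2
        draws = self.paths[outcome].dropna()
        return tuple(np.quantile(draws, [lo, 1 - lo]))


def bootstrap_sem(
    data: pd.DataFrame,
    spec: SEMSpec,
    B: int = 400,
    seed: int | None = None,
    max_failure_rate: float = 0.2,
) -> BootstrapResult:
    """Case-resampling bootstrap of the standardized outcome paths."""
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    n = len(data)
    rows = []
    indices = []
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        indices.append(idx)
        sample = data.iloc[idx]
        try:
            fit = fit_sem(sample, spec, compute_se=False)
            if not fit.converged:
                raise RuntimeError("non-convergence")
            rows.append(fit.paths(standardized=True))
        except Exception:
            n_failed += 1
            rows.append(pd.Series({o: np.nan for o in spec.outcomes}))
    if n_failed > max_failure_rate * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap replicates failed to converge"
        )
    if n_failed:
        logger.warning("%d/%d bootstrap replicates failed and were excluded", n_failed, B)
    return BootstrapResult(pd.DataFrame(rows).reset_index(drop=True), n_failed, indices)
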