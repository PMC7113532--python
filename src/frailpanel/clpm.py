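"""Two-wave cross-lagged panel models (CLPM) with ML and FIML estimation.

The model regresses each wave-2 variable (frailty, behaviour) on both
wave-1 variables plus covariates:

    frailty_t2   = a_f * frailty_t1 + c_bf * behaviour_t1 + covariates + e_f
    behaviour_t2 = a_b * behaviour_t1 + c_fb * frailty_t1 + covariates + e_b

with the two wave-2 residuals freely covarying and the wave-1 variables
and covariates treated as a saturated exogenous block (free means and
covariances).  The autoregressive paths (a_f, a_b) capture stability; the
cross-lagged paths (c_bf: behaviour -> frailty, c_fb: frailty ->
behaviour) carry the temporal-precedence evidence.

Estimation maximises the multivariate-normal likelihood.  With complete
data and both equations containing the same regressors the model is
saturated, the ML solution is available in closed form and coincides with
equation-by-equation least squares.  With missing data, full-information
maximum likelihood (FIML) lets each case contribute the marginal normal
density of its observed variables; the saturated-model FIML solution is
obtained by an EM algorithm on the mean vector and covariance matrix,
and constrained models are fitted by quasi-Newton optimisation of the
casewise (pattern-grouped) log-likelihood.

Standard errors come from the observed information (numerically
differentiated at the optimum); standardized coefficients use
model-implied standard deviations with delta-method standard errors.
Fit indices (chi-square, RMSEA, SRMR, CFI, TLI) are computed against the
saturated and independence models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CLPMSpec",
    "CLPMModel",
    "CLPMResult",
    "FitIndices",
    "build_model",
    "fit_ml",
    "fit_fiml",
    "standardized_paths",
    "wald_ci",
    "fit_indices_from_chi2",
    "classify_hypothesis",
]

# optimizer / numerical settings
GRAD_TOL = 1e-6
MAX_ITER = 500
N_STARTS = 3
EM_TOL = 1e-10
EM_MAX_ITER = 2000
HESS_STEP = 1e-4
DEGENERATE_VAR = 1e-10


# ---------------------------------------------------------------------------
# specification and model structure
# ---------------------------------------------------------------------------

@dataclass
class CLPMSpec:
    """Specification of one cross-lagged panel model.

    ``covariates`` enter both wave-2 equations (the usual adjustment set);
    per-equation overrides make the model non-saturated and switch the
    fitter to constrained optimisation.  Covariate names are resolved
    against the data: a bare name ``c`` uses column ``c`` if present,
    otherwise ``c_t2`` (each wave's outcome is adjusted for that wave's
    covariate values; sex is time-invariant by construction).
    """

    behaviour_name: str = "mvpa"
    covariates: list[str] = field(default_factory=list)
    covariates_frailty: list[str] | None = None
    covariates_behaviour: list[str] | None = None
    include_wear_time: bool = False
    alpha: float = 0.05
    estimator: str = "fiml"  # "ml" (complete cases) or "fiml"

    def equation_covariates(self) -> tuple[list[str], list[str]]:
        cf = self.covariates if self.covariates_frailty is None else self.covariates_frailty
        cb = self.covariates if self.covariates_behaviour is None else self.covariates_behaviour
        if self.include_wear_time:
            cf = list(cf) + ["wear"] if "wear" not in cf else cf
            cb = list(cb) + ["wear"] if "wear" not in cb else cb
        return list(cf), list(cb)


@dataclass
class CLPMModel:
    """Resolved model structure: variable ordering and free-path mask."""

    y_names: list[str]                  # [frailty_t2, behaviour_t2]
    x_names: list[str]                  # [frailty_t1, behaviour_t1, covariate columns...]
    free: np.ndarray                    # (2, p) bool, free regression paths
    spec: CLPMSpec
    categorical_map: dict[str, list[str]] = field(default_factory=dict)

    @property
    def p(self) -> int:
        return len(self.x_names)

    @property
    def d(self) -> int:
        return 2 + self.p

    @property
    def var_names(self) -> list[str]:
        return self.y_names + self.x_names

    @property
    def saturated(self) -> bool:
        return bool(self.free.all())

    @property
    def n_free_params(self) -> int:
        # alpha(2) + free paths + Psi(3) + mu_x(p) + Sigma_xx(p(p+1)/2)
        return 2 + int(self.free.sum()) + 3 + self.p + self.p * (self.p + 1) // 2

    def path_names(self) -> list[tuple[str, str]]:
        return [
            (self.y_names[j], self.x_names[k])
            for j in range(2)
            for k in range(self.p)
            if self.free[j, k]
        ]


def _resolve_column(df: pd.DataFrame, name: str) -> str:
    if name in df.columns:
        return name
    if f"{name}_t2" in df.columns:
        return f"{name}_t2"
    raise KeyError(f"covariate {name!r} not found in dataset (tried {name!r}, '{name}_t2')")


def _expand_categoricals(df: pd.DataFrame, cols: list[str]) -> tuple[pd.DataFrame, dict]:
    """Reference-code categorical columns; numeric columns pass through."""
    out = {}
    cat_map: dict[str, list[str]] = {}
    for c in cols:
        s = df[c]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=c, drop_first=True, dtype=float)
            # propagate missingness into every indicator
            dummies[s.isna()] = np.nan
            cat_map[c] = list(dummies.columns)
            for dc in dummies.columns:
                out[dc] = dummies[dc]
        else:
            out[c] = s.astype(float)
    return pd.DataFrame(out, index=df.index), cat_map


def build_model(spec: CLPMSpec, df: pd.DataFrame) -> CLPMModel:
    """Resolve a spec against a panel table into a model structure.

    Expands categorical covariates into reference-coded indicators,
    checks for duplicate and aliased (collinear) columns, and builds the
    free-path mask.  Raises with the offending names on a rank-deficient
    exogenous block.
    """
    cf, cb = spec.equation_covariates()
    all_cov = list(dict.fromkeys(cf + cb))  # ordered union
    if len(set(cf)) != len(cf) or len(set(cb)) != len(cb):
        dupes = [c for c in set(cf + cb) if cf.count(c) > 1 or cb.count(c) > 1]
        raise ValueError(f"duplicated covariates: {sorted(dupes)}")
    resolved = {c: _resolve_column(df, c) for c in all_cov}
    cov_df, cat_map = _expand_categoricals(df, [resolved[c] for c in all_cov])

    x_names = ["frailty_t1", "behaviour_t1"] + list(cov_df.columns)
    for base in ("frailty_t1", "behaviour_t1", "frailty_t2", "behaviour_t2"):
        if base not in df.columns:
            raise KeyError(f"panel table lacks required column {base!r}")

    # map each original covariate to its expanded column names
    expanded: dict[str, list[str]] = {}
    for c in all_cov:
        rc = resolved[c]
        expanded[c] = cat_map.get(rc, [rc])

    free = np.zeros((2, len(x_names)), dtype=bool)
    free[:, :2] = True  # autoregressive + cross paths always free
    idx = {name: i for i, name in enumerate(x_names)}
    for j, eq_cov in enumerate((cf, cb)):
        for c in eq_cov:
            for col in expanded[c]:
                free[j, idx[col]] = True

    model = CLPMModel(
        y_names=["frailty_t2", "behaviour_t2"],
        x_names=x_names,
        free=free,
        spec=spec,
        categorical_map=cat_map,
    )
    _check_rank(model, df, cov_df)
    return model


def _check_rank(model: CLPMModel, df: pd.DataFrame, cov_df: pd.DataFrame) -> None:
    X = pd.concat(
        [df[["frailty_t1", "behaviour_t1"]].astype(float), cov_df], axis=1
    ).dropna()
    if X.empty:
        return
    mat = np.column_stack([np.ones(len(X)), X.to_numpy()])
    names = ["(const)"] + list(X.columns)
    aliased = []
    rank = 0
    for k in range(mat.shape[1]):
        r = np.linalg.matrix_rank(mat[:, : k + 1])
        if r == rank:
            aliased.append(names[k])
        rank = r
    if aliased:
        raise ValueError(f"rank-deficient exogenous block; aliased columns: {aliased}")


# ---------------------------------------------------------------------------
# data preparation and missingness patterns
# ---------------------------------------------------------------------------

@dataclass
class _Pattern:
    obs: np.ndarray     # observed variable indices
    n: int
    s1: np.ndarray      # sum of observed vectors
    s2: np.ndarray      # sum of outer products


def _model_matrix(df: pd.DataFrame, model: CLPMModel) -> np.ndarray:
    cf, cb = model.spec.equation_covariates()
    all_cov = list(dict.fromkeys(cf + cb))
    resolved = [_resolve_column(df, c) for c in all_cov]
    cov_df, _ = _expand_categoricals(df, resolved)
    Z = pd.concat(
        [
            df[["frailty_t2", "behaviour_t2", "frailty_t1", "behaviour_t1"]].astype(float),
            cov_df,
        ],
        axis=1,
    )
    # column order must match model.var_names
    Z = Z[model.var_names]
    return Z.to_numpy(dtype=float)


def _pattern_stats(Z: np.ndarray) -> list[_Pattern]:
    obs_mask = ~np.isnan(Z)
    patterns: list[_Pattern] = []
    keys, inverse = np.unique(obs_mask, axis=0, return_inverse=True)
    for k, key in enumerate(keys):
        rows = Z[inverse == k][:, key]
        obs = np.flatnonzero(key)
        if obs.size == 0:
            continue
        patterns.append(
            _Pattern(obs=obs, n=rows.shape[0], s1=rows.sum(axis=0), s2=rows.T @ rows)
        )
    return patterns


def _pattern_loglik(mu: np.ndarray, Sigma: np.ndarray, patterns: list[_Pattern]) -> float:
    """Total log-likelihood, each case contributing its observed margin."""
    ll = 0.0
    for pat in patterns:
        o = pat.obs
        mo = mu[o]
        So = Sigma[np.ix_(o, o)]
        sign, logdet = np.linalg.slogdet(So)
        if sign <= 0:
            return -np.inf
        M = pat.s2 - np.outer(pat.s1, mo) - np.outer(mo, pat.s1) + pat.n * np.outer(mo, mo)
        ll += -0.5 * (
            pat.n * o.size * np.log(2 * np.pi)
            + pat.n * logdet
            + np.trace(np.linalg.solve(So, M))
        )
    return float(ll)


# ---------------------------------------------------------------------------
# saturated multivariate-normal MLE (closed form / EM)
# ---------------------------------------------------------------------------

def _saturated_mle(
    patterns: list[_Pattern], d: int
) -> tuple[np.ndarray, np.ndarray, float, bool, int]:
    """MLE of (mu, Sigma) of the unrestricted MVN given missingness patterns.

    Complete data: sample moments (1/n covariance).  Otherwise: EM, each
    E-step filling the expected sufficient statistics of the missing
    blocks from the current conditional distributions.
    Returns (mu, Sigma, loglik, converged, n_iter).
    """
    n = sum(p.n for p in patterns)
    if len(patterns) == 1 and patterns[0].obs.size == d:
        p0 = patterns[0]
        mu = p0.s1 / n
        Sigma = p0.s2 / n - np.outer(mu, mu)
        return mu, Sigma, _pattern_loglik(mu, Sigma, patterns), True, 0

    # start from per-variable available-case moments, zero covariances
    mu = np.zeros(d)
    var = np.ones(d)
    cnt = np.zeros(d)
    s = np.zeros(d)
    ss = np.zeros(d)
    for pat in patterns:
        cnt[pat.obs] += pat.n
        s[pat.obs] += pat.s1
        ss[pat.obs] += np.diag(pat.s2)
    if np.any(cnt < 2):
        bad = [int(i) for i in np.flatnonzero(cnt < 2)]
        raise ValueError(f"variables observed fewer than 2 times: indices {bad}")
    mu = s / cnt
    var = np.maximum(ss / cnt - mu**2, 1e-8)
    Sigma = np.diag(var)

    ll_old = -np.inf
    converged = False
    for it in range(1, EM_MAX_ITER + 1):
        T1 = np.zeros(d)
        T2 = np.zeros((d, d))
        for pat in patterns:
            o = pat.obs
            m = np.setdiff1d(np.arange(d), o, assume_unique=True)
            T1[o] += pat.s1
            T2[np.ix_(o, o)] += pat.s2
            if m.size:
                Soo = Sigma[np.ix_(o, o)]
                B = np.linalg.solve(Soo, Sigma[np.ix_(o, m)]).T  # (|m|, |o|)
                C = Sigma[np.ix_(m, m)] - B @ Sigma[np.ix_(o, m)]
                dev1 = pat.s1 - pat.n * mu[o]
                em_sum = pat.n * mu[m] + B @ dev1                     # sum of cond. means
                T1[m] += em_sum
                S2c = (
                    pat.s2
                    - np.outer(pat.s1, mu[o])
                    - np.outer(mu[o], pat.s1)
                    + pat.n * np.outer(mu[o], mu[o])
                )  # centred observed scatter
                Eom = np.outer(pat.s1, mu[m]) + (pat.s2 - np.outer(pat.s1, mu[o])) @ B.T
                T2[np.ix_(o, m)] += Eom
                T2[np.ix_(m, o)] += Eom.T
                Emm = (
                    pat.n * np.outer(mu[m], mu[m])
                    + np.outer(B @ dev1, mu[m])
                    + np.outer(mu[m], B @ dev1)
                    + B @ S2c @ B.T
                    + pat.n * C
                )
                T2[np.ix_(m, m)] += Emm
        mu = T1 / n
        Sigma = T2 / n - np.outer(mu, mu)
        Sigma = 0.5 * (Sigma + Sigma.T)
        ll = _pattern_loglik(mu, Sigma, patterns)
        if abs(ll - ll_old) < EM_TOL * (1.0 + abs(ll)):
            converged = True
            break
        ll_old = ll
    return mu, Sigma, _pattern_loglik(mu, Sigma, patterns), converged, it


def _independence_loglik(patterns: list[_Pattern], d: int) -> tuple[float, int]:
    """FIML log-likelihood of the independence model (free means/variances,
    zero covariances); factorises into per-variable normal MLEs over the
    observed values."""
    cnt = np.zeros(d)
    s = np.zeros(d)
    ss = np.zeros(d)
    for pat in patterns:
        cnt[pat.obs] += pat.n
        s[pat.obs] += pat.s1
        ss[pat.obs] += np.diag(pat.s2)
    mu = s / cnt
    var = np.maximum(ss / cnt - mu**2, 1e-300)
    ll = float(np.sum(-0.5 * cnt * (np.log(2 * np.pi) + np.log(var) + 1.0)))
    return ll, 2 * d


# ---------------------------------------------------------------------------
# structured parameterisation
# ---------------------------------------------------------------------------

@dataclass
class _Theta:
    """Structural parameters of the CLPM."""

    alpha: np.ndarray      # (2,) intercepts
    Gamma: np.ndarray      # (2, p) paths, zeros where fixed
    Psi: np.ndarray        # (2, 2) residual covariance
    mu_x: np.ndarray       # (p,)
    Sigma_xx: np.ndarray   # (p, p)

    def implied(self) -> tuple[np.ndarray, np.ndarray]:
        p = self.mu_x.size
        d = 2 + p
        mu = np.empty(d)
        mu[:2] = self.alpha + self.Gamma @ self.mu_x
        mu[2:] = self.mu_x
        Sigma = np.empty((d, d))
        Syx = self.Gamma @ self.Sigma_xx
        Sigma[:2, :2] = Syx @ self.Gamma.T + self.Psi
        Sigma[:2, 2:] = Syx
        Sigma[2:, :2] = Syx.T
        Sigma[2:, 2:] = self.Sigma_xx
        return mu, Sigma


def _struct_from_moments(mu: np.ndarray, Sigma: np.ndarray, model: CLPMModel) -> _Theta:
    """Map saturated (mu, Sigma) to structural parameters (exact when the
    model is saturated; a consistent start otherwise)."""
    p = model.p
    Sxx = Sigma[2:, 2:]
    Syx = Sigma[:2, 2:]
    Gamma = np.linalg.solve(Sxx, Syx.T).T
    Gamma = np.where(model.free, Gamma, 0.0)
    Psi = Sigma[:2, :2] - Gamma @ Syx.T - Syx @ Gamma.T + Gamma @ Sxx @ Gamma.T
    Psi = 0.5 * (Psi + Psi.T)
    alpha = mu[:2] - Gamma @ mu[2:]
    return _Theta(alpha=alpha, Gamma=Gamma, Psi=Psi, mu_x=mu[2:].copy(), Sigma_xx=Sxx.copy())


def _pack(theta: _Theta, model: CLPMModel) -> np.ndarray:
    sd = np.sqrt(np.maximum(np.diag(theta.Psi), 1e-12))
    rho = np.clip(theta.Psi[0, 1] / (sd[0] * sd[1]), -0.999999, 0.999999)
    L = np.linalg.cholesky(theta.Sigma_xx)
    p = model.p
    tril = np.tril_indices(p, -1)
    return np.concatenate(
        [
            theta.alpha,
            theta.Gamma[model.free],
            np.log(sd),
            [np.arctanh(rho)],
            theta.mu_x,
            np.log(np.diag(L)),
            L[tril],
        ]
    )


def _unpack(vec: np.ndarray, model: CLPMModel) -> _Theta:
    p = model.p
    i = 0
    alpha = vec[i : i + 2]; i += 2
    nfree = int(model.free.sum())
    Gamma = np.zeros((2, p))
    Gamma[model.free] = vec[i : i + nfree]; i += nfree
    sd = np.exp(vec[i : i + 2]); i += 2
    rho = np.tanh(vec[i]); i += 1
    Psi = np.array(
        [[sd[0] ** 2, rho * sd[0] * sd[1]], [rho * sd[0] * sd[1], sd[1] ** 2]]
    )
    mu_x = vec[i : i + p]; i += p
    L = np.zeros((p, p))
    np.fill_diagonal(L, np.exp(vec[i : i + p])); i += p
    tril = np.tril_indices(p, -1)
    L[tril] = vec[i : i + p * (p - 1) // 2]
    return _Theta(alpha=alpha.copy(), Gamma=Gamma, Psi=Psi, mu_x=mu_x.copy(), Sigma_xx=L @ L.T)


def _neg_loglik(vec: np.ndarray, model: CLPMModel, patterns: list[_Pattern]) -> float:
    mu, Sigma = _unpack(vec, model).implied()
    ll = _pattern_loglik(mu, Sigma, patterns)
    return -ll if np.isfinite(ll) else 1e12


# ---------------------------------------------------------------------------
# standardisation, intervals, fit indices, verdicts
# ---------------------------------------------------------------------------

def standardized_paths(
    Gamma: np.ndarray, Sigma_xx: np.ndarray, Psi: np.ndarray
) -> np.ndarray:
    """Standardize regression paths with model-implied standard deviations.

    std beta_jk = b_jk * sd(x_k) / sd(y_j), where sd(y_j) comes from the
    implied outcome variance (Gamma Sigma_xx Gamma' + Psi).
    """
    sd_x = np.sqrt(np.diag(Sigma_xx))
    var_y = np.diag(Gamma @ Sigma_xx @ Gamma.T + Psi)
    if np.any(var_y <= 0) or np.any(sd_x <= 0):
        raise ValueError("zero model-implied variance; cannot standardize")
    return Gamma * sd_x[None, :] / np.sqrt(var_y)[:, None]


def wald_ci(estimate: float, se: float, alpha: float = 0.05) -> tuple[float, float]:
    """Two-sided Wald interval; SE of 0 gives a degenerate interval."""
    z = stats.norm.ppf(1 - alpha / 2)
    return estimate - z * se, estimate + z * se


def _wald_p(estimate: float, se: float) -> float:
    if se == 0:
        return 0.0 if estimate != 0 else 1.0
    return float(2 * stats.norm.sf(abs(estimate) / se))


@dataclass
class FitIndices:
    chi2_model: float
    df_model: int
    chi2_baseline: float
    df_baseline: int
    rmsea: float
    srmr: float
    cfi: float
    tli: float
    n_effective: int


def fit_indices_from_chi2(
    chi2_m: float, df_m: int, chi2_b: float, df_b: int, n_eff: int, srmr: float = np.nan
) -> FitIndices:
    """Closed-form fit indices from model and baseline chi-squares.

    RMSEA = sqrt(max(chi2 - df, 0) / (df * n)); a just-identified model
    (df = 0) has RMSEA 0, CFI 1, TLI 1 by convention.
    """
    if df_b <= 0:
        raise ValueError("baseline model must be restrictive (df_baseline > 0)")
    if df_m == 0:
        rmsea, cfi, tli = 0.0, 1.0, 1.0
    else:
        rmsea = float(np.sqrt(max(chi2_m - df_m, 0.0) / (df_m * n_eff)))
        denom = max(chi2_b - df_b, chi2_m - df_m, 0.0)
        cfi = 1.0 if denom == 0 else 1.0 - max(chi2_m - df_m, 0.0) / denom
        rb = chi2_b / df_b
        rm = chi2_m / df_m
        tli = (rb - rm) / (rb - 1.0) if rb != 1.0 else 1.0
    return FitIndices(
        chi2_model=float(chi2_m),
        df_model=int(df_m),
        chi2_baseline=float(chi2_b),
        df_baseline=int(df_b),
        rmsea=rmsea,
        srmr=float(srmr),
        cfi=float(cfi),
        tli=float(tli),
        n_effective=int(n_eff),
    )


def _srmr(S: np.ndarray, Sigma: np.ndarray) -> float:
    d = S.shape[0]
    sd = np.sqrt(np.diag(S))
    resid = (S - Sigma) / np.outer(sd, sd)
    iu = np.triu_indices(d)
    return float(np.sqrt(np.mean(resid[iu] ** 2)))


def classify_hypothesis(p_behaviour_to_frailty: float, p_frailty_to_behaviour: float,
                        alpha: float = 0.05) -> str:
    """Verdict over the two cross-lagged paths.

    H0: neither cross path significant; H1: only frailty -> behaviour;
    H2: only behaviour -> frailty; H3: both (reciprocal).
    """
    sig_bf = p_behaviour_to_frailty < alpha
    sig_fb = p_frailty_to_behaviour < alpha
    if sig_bf and sig_fb:
        return "H3"
    if sig_bf:
        return "H2"
    if sig_fb:
        return "H1"
    return "H0"


# ---------------------------------------------------------------------------
# result assembly and the fitting drivers
# ---------------------------------------------------------------------------

@dataclass
class CLPMResult:
    params: pd.DataFrame           # one row per free path
    residual_cov: np.ndarray       # Psi-hat
    fit: FitIndices
    verdict: str
    alpha: float
    estimator: str
    n_used: int
    n_dropped: int
    converged: bool
    loglik: float
    warnings: list[str]
    behaviour_name: str

    def path(self, outcome: str, predictor: str) -> pd.Series:
        m = (self.params["outcome"] == outcome) & (self.params["predictor"] == predictor)
        if not m.any():
            raise KeyError(f"no path {outcome} ~ {predictor}")
        return self.params[m].iloc[0]

    def to_dict(self) -> dict:
        return {
            "behaviour": self.behaviour_name,
            "estimator": self.estimator,
            "n_used": self.n_used,
            "n_dropped": self.n_dropped,
            "converged": self.converged,
            "loglik": self.loglik,
            "alpha": self.alpha,
            "verdict": self.verdict,
            "warnings": self.warnings,
            "residual_covariance": self.residual_cov.tolist(),
            "fit": self.fit.__dict__,
            "paths": self.params.to_dict(orient="records"),
        }


def _numeric_hessian(f, x0: np.ndarray) -> np.ndarray:
    q = x0.size
    h = HESS_STEP * (1.0 + np.abs(x0))
    H = np.empty((q, q))
    for i in range(q):
        for j in range(i, q):
            ei = np.zeros(q); ei[i] = h[i]
            ej = np.zeros(q); ej[j] = h[j]
            val = (
                f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
            ) / (4 * h[i] * h[j])
            H[i, j] = H[j, i] = val
    return H


def _numeric_jacobian(g, x0: np.ndarray) -> np.ndarray:
    q = x0.size
    h = 1e-6 * (1.0 + np.abs(x0))
    g0 = np.asarray(g(x0))
    J = np.empty((g0.size, q))
    for i in range(q):
        e = np.zeros(q); e[i] = h[i]
        J[:, i] = (np.asarray(g(x0 + e)) - np.asarray(g(x0 - e))) / (2 * h[i])
    return J


def _fit(df: pd.DataFrame, model: CLPMModel, estimator: str) -> CLPMResult:
    warnings_: list[str] = []
    Z = _model_matrix(df, model)
    n_total = Z.shape[0]
    d = model.d

    # inclusion: wave-1 endogenous pair must be observed; categorical
    # indicators are handled listwise (their normal likelihood is not
    # appropriate), which here means rows missing an indicator are kept
    # only if the estimator can ignore that cell -- we drop them.
    base_ok = ~np.isnan(Z[:, 2]) & ~np.isnan(Z[:, 3])
    cat_cols = [model.var_names.index(c) for cols in model.categorical_map.values() for c in cols]
    if cat_cols:
        base_ok &= ~np.isnan(Z[:, cat_cols]).any(axis=1)
    if estimator == "ml":
        base_ok &= ~np.isnan(Z).any(axis=1)
    Z = Z[base_ok]
    n = Z.shape[0]
    n_dropped = n_total - n
    if n < model.n_free_params:
        raise ValueError(
            f"n = {n} below the number of free parameters ({model.n_free_params})"
        )

    patterns = _pattern_stats(Z)
    mu_sat, Sigma_sat, ll_sat, em_ok, em_iter = _saturated_mle(patterns, d)
    if not em_ok:
        warnings_.append(f"saturated-model EM did not converge in {em_iter} iterations")

    if model.saturated:
        theta = _struct_from_moments(mu_sat, Sigma_sat, model)
        ll_model = ll_sat
        converged = em_ok
    else:
        x0 = _pack(_struct_from_moments(mu_sat, Sigma_sat, model), model)
        best = None
        rng = np.random.default_rng(0)
        for attempt in range(N_STARTS):
            start = x0 if attempt == 0 else x0 + rng.normal(0, 0.05, x0.size)
            res = optimize.minimize(
                _neg_loglik, start, args=(model, patterns), method="L-BFGS-B",
                options={"maxiter": MAX_ITER, "ftol": 1e-12, "gtol": GRAD_TOL},
            )
            if best is None or res.fun < best.fun:
                best = res
            if res.success:
                break
        converged = bool(best.success)
        if not converged:
            warnings_.append(
                f"optimizer did not converge (status {best.status}: {best.message})"
            )
        theta = _unpack(best.x, model)
        ll_model = -best.fun

    # admissibility
    psi_eig = np.linalg.eigvalsh(theta.Psi)
    degenerate = psi_eig.min() < DEGENERATE_VAR * max(psi_eig.max(), 1.0)
    if degenerate:
        warnings_.append("inadmissible or degenerate residual covariance; SEs set to 0")

    # parameter covariance via observed information, then delta method
    pn = model.path_names()
    npaths = len(pn)
    x_hat = _pack(theta, model)

    def report_map(vec: np.ndarray) -> np.ndarray:
        th = _unpack(vec, model)
        unstd = th.Gamma[model.free]
        std = standardized_paths(th.Gamma, th.Sigma_xx, th.Psi)[model.free]
        return np.concatenate([unstd, std])

    est = report_map(x_hat)
    if degenerate:
        se = np.zeros(2 * npaths)
    else:
        H = _numeric_hessian(lambda v: _neg_loglik(v, model, patterns), x_hat)
        H = 0.5 * (H + H.T)
        try:
            cov_theta = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov_theta = np.linalg.pinv(H)
            warnings_.append("information matrix singular; pseudo-inverse used")
        J = _numeric_jacobian(report_map, x_hat)
        cov_rep = J @ cov_theta @ J.T
        var_rep = np.clip(np.diag(cov_rep), 0.0, None)
        se = np.sqrt(var_rep)

    rows = []
    for i, (out, pred) in enumerate(pn):
        b, sb = est[i], se[i]
        s, ss_ = est[npaths + i], se[npaths + i]
        lo, hi = wald_ci(b, sb, model.spec.alpha)
        slo, shi = wald_ci(s, ss_, model.spec.alpha)
        rows.append(
            {
                "outcome": out,
                "predictor": pred,
                "estimate": b,
                "se": sb,
                "z": b / sb if sb > 0 else np.inf * np.sign(b) if b else 0.0,
                "pvalue": _wald_p(b, sb),
                "ci_low": lo,
                "ci_high": hi,
                "std_estimate": s,
                "std_se": ss_,
                "std_ci_low": slo,
                "std_ci_high": shi,
                "std_pvalue": _wald_p(s, ss_),
            }
        )
    params = pd.DataFrame(rows)

    # fit indices
    _, Sigma_model = theta.implied()
    ll_base, k_base = _independence_loglik(patterns, d)
    k_sat = d + d * (d + 1) // 2
    df_model = k_sat - model.n_free_params
    df_base = k_sat - k_base
    chi2_m = 0.0 if model.saturated else max(2.0 * (ll_sat - ll_model), 0.0)
    chi2_b = max(2.0 * (ll_sat - ll_base), 0.0)
    fit = fit_indices_from_chi2(
        chi2_m, df_model, chi2_b, df_base, n, srmr=_srmr(Sigma_sat, Sigma_model)
    )

    p_bf = params.loc[
        (params.outcome == "frailty_t2") & (params.predictor == "behaviour_t1"), "pvalue"
    ].iloc[0]
    p_fb = params.loc[
        (params.outcome == "behaviour_t2") & (params.predictor == "frailty_t1"), "pvalue"
    ].iloc[0]
    verdict = classify_hypothesis(p_bf, p_fb, model.spec.alpha)

    return CLPMResult(
        params=params,
        residual_cov=theta.Psi,
        fit=fit,
        verdict=verdict,
        alpha=model.spec.alpha,
        estimator=estimator,
        n_used=n,
        n_dropped=n_dropped,
        converged=converged,
        loglik=ll_model,
        warnings=warnings_,
        behaviour_name=model.spec.behaviour_name,
    )


def fit_ml(df: pd.DataFrame, model: CLPMModel | None = None,
           spec: CLPMSpec | None = None) -> CLPMResult:
    """Complete-case maximum-likelihood fit.

    For the saturated (same-regressors) model the ML solution equals
    equation-by-equation least squares; constrained models are optimised
    numerically.
    """
    if model is None:
        model = build_model(spec or CLPMSpec(), df)
    return _fit(df, model, "ml")


def fit_fiml(df: pd.DataFrame, model: CLPMModel | None = None,
             spec: CLPMSpec | None = None) -> CLPMResult:
    """Full-information maximum-likelihood fit.

    Each case contributes the marginal normal density of its observed
    variables, which gives consistent estimates under MAR-on-observed
    missingness; with no missing data this reduces exactly to
    :func:`fit_ml`.
    """
    if model is None:
        model = build_model(spec or CLPMSpec(), df)
    return _fit(df, model, "fiml")
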