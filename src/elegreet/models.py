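"""Mixed-effects logit models for modality choice and combination use.

Three model families drive the analysis:

* a multinomial logit of body-act modality (silent-visual / audible /
  tactile, tactile as reference) on recipient visual attention, with
  per-category random intercepts within signaller — "does the signaller
  pick a channel the recipient can perceive?";
* binomial logit GLMMs for the tail-type assessment (tail vs silent-visual
  response on recipient attention, random intercept and attention slope
  within signaller);
* binomial logit GLMMs for the combination questions (vocal-first order,
  and Rumble+Ear-Flapping use, on signaller sex x sex-dyad and dyadic
  association strength, with signaller and event random effects).

Random effects are integrated out of the likelihood by a Laplace
approximation over the joint random-effect vector (the lme4
relative-covariance parameterisation ``b = Lambda u``, ``u ~ N(0, I)``,
which stays smooth at the zero-variance boundary).  For a single grouping
factor with a scalar random effect, adaptive Gauss-Hermite quadrature is
available and serves as an independent high-accuracy route.  Wald standard
errors come from the numerically differentiated marginal likelihood;
parametric-bootstrap confidence intervals, likelihood-ratio tests,
variance-inflation factors, leave-one-level-out stability and the
latent-scale marginal R-squared complete the diagnostic suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess3

__all__ = [
    "ModelSpec",
    "ModelFit",
    "fit_binomial_glmm",
    "fit_multinomial",
    "fit_multinomial_attention",
    "lrt",
    "vif",
    "bootstrap_ci",
    "stability",
    "marginal_r2",
    "dummy_centre",
    "z_transform",
    "build_combination_frame",
]

_LOGIT_CLIP = 30.0


# ---------------------------------------------------------------------------
# Specification and fit containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response, fixed-effect columns, random-effect structure.

    ``fixed`` lists numeric design columns (categoricals should be dummy
    coded and centred first; see :func:`dummy_centre`); an intercept is
    always prepended.  ``random`` is a sequence of ``(factor_column,
    term_columns)`` pairs, where ``"Intercept"`` in the terms denotes the
    constant.  For the multinomial family the random terms are expanded per
    non-reference category (a random "modality" slope within the factor),
    and only a single grouping factor is supported.
    """

    response: str
    fixed: tuple = ()
    random: tuple = ()
    family: str = "binomial_logit"
    reference: str | None = None
    method: str = "auto"  # auto | laplace | agq | fixed
    agq_points: int = 21

    def __post_init__(self):
        object.__setattr__(self, "fixed", tuple(self.fixed))
        object.__setattr__(
            self, "random", tuple((f, tuple(t)) for f, t in self.random)
        )


@dataclass
class ModelFit:
    """A fitted model: estimates, uncertainty, and everything refits need."""

    spec: ModelSpec
    params: pd.Series
    se: pd.Series
    loglik: float
    n_obs: int
    n_params: int
    converged: bool
    method: str
    notes: list = field(default_factory=list)
    random_cov: dict = field(default_factory=dict)  # factor -> (terms, Sigma)
    vcov: np.ndarray | None = None
    data: pd.DataFrame | None = None
    theta: np.ndarray | None = None

    @property
    def fixed_names(self) -> list[str]:
        return list(self.params.index)

    def wald_ci(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2)
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.se,
                "lower": self.params - z * self.se,
                "upper": self.params + z * self.se,
            }
        )

    def summary(self) -> pd.DataFrame:
        tab = self.wald_ci()
        tab["z"] = self.params / self.se
        tab["p"] = 2 * stats.norm.sf(np.abs(tab["z"]))
        tab["odds_ratio"] = np.exp(self.params)
        return tab


# ---------------------------------------------------------------------------
# Design-matrix helpers
# ---------------------------------------------------------------------------


def dummy_centre(df: pd.DataFrame, column: str, level) -> pd.Series:
    """Dummy-code ``column == level`` and centre it (mean removed).

    Centring dummy predictors before they enter interaction terms or random
    slopes keeps main effects interpretable at the sample average and the
    random-slope covariance well conditioned.
    """
    d = (df[column] == level).astype(float)
    return d - d.mean()


def z_transform(values: pd.Series | np.ndarray) -> np.ndarray:
    """Standardise to mean 0, sample (n-1) SD 1 within the modelling sample."""
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-transform a constant covariate")
    return (v - v.mean()) / sd


def _design(data: pd.DataFrame, columns: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(data))]
    for c in columns:
        cols.append(data[c].to_numpy(dtype=float))
    return np.column_stack(cols)


def _fixed_names(columns: Sequence[str]) -> list[str]:
    return ["Intercept"] + list(columns)


def _term_matrix(data: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    cols = []
    for t in terms:
        if t == "Intercept":
            cols.append(np.ones(len(data)))
        else:
            cols.append(data[t].to_numpy(dtype=float))
    return np.column_stack(cols)


def _chol_from_params(params: np.ndarray, k: int) -> np.ndarray:
    L = np.zeros((k, k))
    L[np.tril_indices(k)] = params
    return L


def _n_chol(k: int) -> int:
    return k * (k + 1) // 2


# ---------------------------------------------------------------------------
# Random-effect bookkeeping
# ---------------------------------------------------------------------------


class _REStructure:
    """Dense Z matrix and slicing info for the joint random-effect vector."""

    def __init__(self, data: pd.DataFrame, random, per_category: int = 1):
        self.factors = []
        blocks = []
        self.slices = []
        self.level_maps = []
        self.ks = []
        offset = 0
        for factor, terms in random:
            levels, level_idx = np.unique(
                data[factor].astype(str).to_numpy(), return_inverse=True
            )
            T = _term_matrix(data, terms)  # n x k0
            k0 = T.shape[1]
            k = k0 * per_category
            n, L = len(data), len(levels)
            Z = np.zeros((n, L * k0))
            for j in range(k0):
                Z[np.arange(n), level_idx * k0 + j] = T[:, j]
            self.factors.append((factor, tuple(terms), levels))
            blocks.append(Z)
            self.slices.append(slice(offset, offset + L * k))
            self.level_maps.append(level_idx)
            self.ks.append((k0, L, k))
            offset += L * k
        self.per_category = per_category
        self.q = offset
        self.Z_blocks = blocks  # per factor, n x (L*k0)

    def n_theta(self) -> int:
        return sum(_n_chol(k) for (_, _, k) in self.ks)

    def lambda_blocks(self, theta: np.ndarray) -> list[np.ndarray]:
        """Per-factor k x k Cholesky factor of the relative covariance."""
        out = []
        pos = 0
        for (_, _, k) in self.ks:
            m = _n_chol(k)
            out.append(_chol_from_params(theta[pos : pos + m], k))
            pos += m
        return out

    def covariances(self, theta: np.ndarray) -> dict:
        out = {}
        for (factor, terms, _), L in zip(self.factors, self.lambda_blocks(theta)):
            out[factor] = (terms, L @ L.T)
        return out


# ---------------------------------------------------------------------------
# Binomial Laplace machinery
# ---------------------------------------------------------------------------


def _binom_ll(eta: np.ndarray, y: np.ndarray, w: np.ndarray | None = None) -> float:
    eta = np.clip(eta, -_LOGIT_CLIP, _LOGIT_CLIP)
    terms = y * eta - np.log1p(np.exp(eta))
    return float(np.sum(terms if w is None else w * terms))


def _collapse(data: pd.DataFrame, cols) -> tuple[pd.DataFrame, np.ndarray]:
    """Aggregate duplicated design rows into frequency-weighted cells.

    The likelihood, its derivatives and the Laplace correction are all sums
    of per-observation terms given the random effects, so identical rows
    can carry a single weighted term — a large saving when every predictor
    is categorical.
    """
    cols = [c for c in dict.fromkeys(cols) if c != "Intercept"]
    g = (
        data.groupby(cols, sort=True, dropna=False, observed=True)
        .size()
        .reset_index(name="_weight")
    )
    if len(g) > len(data) // 2:
        out = data.copy()
        out["_weight"] = 1.0
        return out, np.ones(len(data))
    return g, g["_weight"].to_numpy(dtype=float)


def _binom_mu(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -_LOGIT_CLIP, _LOGIT_CLIP)))


def _scaled_Z(theta, re: _REStructure, n: int):
    Lams = re.lambda_blocks(theta)
    parts = []
    for Z, (k0, L, k), Lam in zip(re.Z_blocks, re.ks, Lams):
        ZL = Z.reshape(n, L, k0) @ Lam
        parts.append(ZL.reshape(n, L * k0))
    return np.hstack(parts) if parts else np.zeros((n, 0))


def _profile_binomial(theta, X, y, re: _REStructure, w=None, start=None,
                      max_inner: int = 100):
    """Profiled Laplace loglik: jointly maximise (beta, u) for given theta.

    The penalized problem is jointly concave in (beta, u), so a damped
    Newton with analytic derivatives converges quadratically; the outer
    optimiser then only searches the low-dimensional covariance space.
    """
    n, p = X.shape
    if w is None:
        w = np.ones(n)
    ZL = _scaled_Z(theta, re, n)
    q = ZL.shape[1]
    C = np.hstack([X, ZL])  # n x (p + q)
    v = np.zeros(p + q) if start is None or start.shape != (p + q,) else start.copy()
    pen = np.concatenate([np.zeros(p), np.ones(q)])

    def h(vec):
        return _binom_ll(C @ vec, y, w) - 0.5 * float(vec[p:] @ vec[p:])

    h_v = h(v)
    for _ in range(max_inner):
        eta = C @ v
        mu = _binom_mu(eta)
        grad = C.T @ (w * (y - mu)) - pen * v
        if np.max(np.abs(grad)) < 1e-10:
            break
        wirls = np.clip(w * mu * (1 - mu), 1e-12, None)
        H = C.T @ (C * wirls[:, None]) + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = grad
        t = 1.0
        for _ in range(40):
            v_new = v + t * step
            h_new = h(v_new)
            if h_new >= h_v - 1e-12:
                break
            t *= 0.5
        if h_new < h_v:
            break
        v, h_v = v_new, h_new
    eta = C @ v
    mu = _binom_mu(eta)
    wirls = w * mu * (1 - mu)
    Hu = ZL.T @ (ZL * wirls[:, None]) + np.eye(q)
    _, logdet = np.linalg.slogdet(Hu)
    u = v[p:]
    ll = _binom_ll(eta, y, w) - 0.5 * float(u @ u) - 0.5 * logdet
    return ll, v


def _laplace_binomial(beta, theta, X, y, re: _REStructure, w=None, u0=None,
                      max_inner: int = 50, tol: float = 1e-10):
    """Laplace-approximate marginal loglik for a binomial logit GLMM.

    Works in the scaled coordinates ``b = Lambda u``: the penalty is always
    ``u'u/2`` and a zero variance component is an interior smooth point.
    """
    Lams = re.lambda_blocks(theta)
    # ZL: n x q in u-coordinates
    parts = []
    for Z, (k0, L, k), Lam in zip(re.Z_blocks, re.ks, Lams):
        # expand Lam (k0 x k0 here since per_category=1) across levels
        ZL = Z.reshape(len(y), L, k0) @ Lam  # n x L x k0
        parts.append(ZL.reshape(len(y), L * k0))
    ZL = np.hstack(parts) if parts else np.zeros((len(y), 0))
    q = ZL.shape[1]
    if w is None:
        w = np.ones(len(y))
    u = np.zeros(q) if u0 is None or u0.shape != (q,) else u0.copy()
    xb = X @ beta

    def h(uvec):
        return _binom_ll(xb + ZL @ uvec, y, w) - 0.5 * uvec @ uvec

    h_u = h(u)
    for _ in range(max_inner):
        eta = xb + ZL @ u
        mu = _binom_mu(eta)
        wirls = w * mu * (1 - mu)
        grad = ZL.T @ (w * (y - mu)) - u
        # converge the mode to machine precision so the outer objective is
        # smooth enough for finite-difference gradients
        if np.max(np.abs(grad)) < 1e-10:
            break
        H = ZL.T @ (ZL * wirls[:, None]) + np.eye(q)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = grad
        t = 1.0
        for _ in range(30):
            u_new = u + t * step
            h_new = h(u_new)
            if h_new >= h_u - 1e-12:
                break
            t *= 0.5
        if h_new < h_u:
            break
        u, h_u = u_new, h_new
    eta = xb + ZL @ u
    mu = _binom_mu(eta)
    wirls = w * mu * (1 - mu)
    H = ZL.T @ (ZL * wirls[:, None]) + np.eye(q)
    sign, logdet = np.linalg.slogdet(H)
    ll = _binom_ll(eta, y, w) - 0.5 * u @ u - 0.5 * logdet
    return ll, u


def _agq_binomial(beta, sigma, X, y, level_idx, zcol, n_points: int, w=None):
    """Adaptive Gauss-Hermite marginal loglik; one factor, scalar effect."""
    nodes, weights = np.polynomial.hermite.hermgauss(n_points)
    xb = X @ beta
    if w is None:
        w = np.ones(len(y))
    ll = 0.0
    for l in np.unique(level_idx):
        rows = level_idx == l
        yl, xbl, zl, wl = y[rows], xb[rows], zcol[rows], w[rows]

        if sigma <= 1e-8:
            ll += _binom_ll(xbl, yl, wl)
            continue
        # 1-D Newton for the conditional mode
        b = 0.0
        for _ in range(50):
            eta = xbl + zl * b
            mu = _binom_mu(eta)
            g = np.sum(wl * zl * (yl - mu)) - b / sigma**2
            hcurv = np.sum(wl * zl**2 * mu * (1 - mu)) + 1 / sigma**2
            step = g / hcurv
            b += step
            if abs(step) < 1e-12:
                break
        shat = 1.0 / math.sqrt(hcurv)
        pts = b + math.sqrt(2.0) * shat * nodes
        eta = xbl[None, :] + np.outer(pts, zl)
        eta = np.clip(eta, -_LOGIT_CLIP, _LOGIT_CLIP)
        logf = (
            np.sum(wl[None, :] * (yl[None, :] * eta - np.log1p(np.exp(eta))), axis=1)
            - 0.5 * (pts / sigma) ** 2
            - math.log(sigma)
            - 0.5 * math.log(2 * math.pi)
        )
        terms = np.log(weights) + nodes**2 + logf
        m = terms.max()
        ll += m + math.log(np.sum(np.exp(terms - m))) + math.log(
            math.sqrt(2.0) * shat
        )
    return ll


def fit_binomial_glmm(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Maximum-likelihood binomial logit model, mixed when random terms given.

    Method resolution: ``fixed`` when no random effects (or a grouping
    factor has < 3 levels — too few to estimate a variance); ``agq`` when a
    single scalar random effect is requested; ``laplace`` otherwise.
    Non-convergence and boundary (zero-variance) estimates are flagged in
    ``notes`` rather than silently returned.
    """
    if spec.family != "binomial_logit":
        raise ValueError("spec.family must be 'binomial_logit'")
    y = data[spec.response].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binomial response must be 0/1")
    X = _design(data, spec.fixed)
    names = _fixed_names(spec.fixed)
    notes: list[str] = []

    random = list(spec.random)
    for factor, _ in list(random):
        if data[factor].nunique() < 3:
            notes.append(
                f"random factor {factor!r} has <3 levels; dropped to fixed-only"
            )
            random = [r for r in random if r[0] != factor]
    method = spec.method
    if method == "auto":
        if not random:
            method = "fixed"
        elif len(random) == 1 and len(random[0][1]) == 1:
            method = "agq"
        else:
            method = "laplace"
    if method != "fixed" and not random:
        method = "fixed"

    if method == "fixed":
        import statsmodels.api as sm

        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit()
        params = pd.Series(res.params, index=names)
        se = pd.Series(res.bse, index=names)
        if (np.abs(params) > 15).any():
            notes.append("possible complete separation (|estimate| > 15)")
        return ModelFit(
            spec=spec, params=params, se=se, loglik=float(res.llf),
            n_obs=len(y), n_params=X.shape[1], converged=res.converged,
            method="fixed", notes=notes, vcov=np.asarray(res.cov_params()),
            data=data, theta=np.zeros(0),
        )

    # aggregate duplicated design rows into frequency-weighted cells
    used_cols = [spec.response, *spec.fixed]
    for factor, terms in random:
        used_cols.append(factor)
        used_cols.extend(t for t in terms if t != "Intercept")
    cells, wts = _collapse(data, used_cols)
    yw = cells[spec.response].to_numpy(dtype=float)
    Xw = _design(cells, spec.fixed)

    re = _REStructure(cells, random)
    n_theta = re.n_theta()
    p = Xw.shape[1]
    warm = {"u": None, "v": None}

    import statsmodels.api as sm

    try:
        beta_start = np.asarray(
            sm.GLM(yw, Xw, family=sm.families.Binomial(), freq_weights=wts)
            .fit().params
        )
    except Exception:
        beta_start = np.zeros(p)

    if method == "agq":
        factor, terms = random[0]
        _, level_idx = np.unique(
            cells[factor].astype(str).to_numpy(), return_inverse=True
        )
        zcol = _term_matrix(cells, terms)[:, 0]

        def negll(par):
            beta, sigma = par[:p], abs(par[p])
            return -_agq_binomial(beta, sigma, Xw, yw, level_idx, zcol,
                                  spec.agq_points, w=wts)

        x0 = np.append(beta_start, 0.3)
        opt = optimize.minimize(
            negll, x0, method="BFGS", options={"gtol": 1e-6, "maxiter": 200}
        )
        grad_ok = opt.jac is not None and np.max(np.abs(opt.jac)) < 1e-2
        if not (opt.success or grad_ok):
            opt2 = optimize.minimize(
                negll, opt.x, method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 800},
            )
            if opt2.fun <= opt.fun:
                opt = opt2
            grad_ok = True
        converged = bool(np.isfinite(opt.fun))
        if not converged:
            notes.append("optimizer did not converge")
        par_hat = opt.x
    else:
        # profile beta and u out of the inner penalized problem (analytic
        # Newton); the outer search runs over covariance parameters only
        theta0 = np.zeros(n_theta)
        pos = 0
        for (_, _, k) in re.ks:
            block = np.zeros(_n_chol(k))
            block[np.cumsum([0] + list(range(2, k + 1)))[:k]] = 0.3  # diagonal
            theta0[pos : pos + _n_chol(k)] = block
            pos += _n_chol(k)

        def prof_negll(theta):
            ll, v = _profile_binomial(theta, Xw, yw, re, w=wts, start=warm["v"])
            warm["v"] = v
            return -ll

        opt = optimize.minimize(
            prof_negll, theta0, method="BFGS",
            options={"gtol": 1e-5, "maxiter": 200, "eps": 1e-6},
        )
        grad_ok = opt.jac is not None and np.max(np.abs(opt.jac)) < 1e-2
        if not (opt.success or grad_ok):
            opt2 = optimize.minimize(
                prof_negll, opt.x, method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 600},
            )
            if opt2.fun <= opt.fun:
                opt = opt2
        theta_opt = opt.x
        _, v_hat = _profile_binomial(theta_opt, Xw, yw, re, w=wts, start=warm["v"])
        par_hat = np.concatenate([v_hat[:p], theta_opt])
        converged = bool(np.isfinite(opt.fun))
        if not converged:
            notes.append("optimizer did not converge")

        def negll(par):  # full marginal, for SEs and reporting
            beta, theta = par[:p], par[p:]
            ll, u = _laplace_binomial(beta, theta, Xw, yw, re, w=wts,
                                      u0=warm["u"])
            warm["u"] = u
            return -ll
    beta_hat = par_hat[:p]
    theta_hat = np.abs(par_hat[p:]) if method == "agq" else par_hat[p:]
    if method == "agq":
        random_cov = {random[0][0]: (tuple(random[0][1]),
                                     np.array([[theta_hat[0] ** 2]]))}
        if theta_hat[0] < 1e-3:
            notes.append("random variance at boundary (~0)")
    else:
        random_cov = re.covariances(theta_hat)
        for factor, (_, Sig) in random_cov.items():
            if np.any(np.sqrt(np.clip(np.diag(Sig), 0, None)) < 1e-3):
                notes.append(f"random variance for {factor!r} at boundary (~0)")
    if (np.abs(beta_hat) > 15).any():
        notes.append("possible complete separation (|estimate| > 15)")

    H = approx_hess3(par_hat, negll)
    try:
        vcov_full = np.linalg.inv(H)
        se_beta = np.sqrt(np.clip(np.diag(vcov_full)[:p], 0, None))
    except np.linalg.LinAlgError:
        vcov_full = np.full((len(par_hat), len(par_hat)), np.nan)
        se_beta = np.full(p, np.nan)
        notes.append("Hessian singular; no Wald SEs")
    return ModelFit(
        spec=spec,
        params=pd.Series(beta_hat, index=names),
        se=pd.Series(se_beta, index=names),
        loglik=float(-opt.fun),
        n_obs=len(y),
        n_params=len(par_hat),
        converged=converged and not any("not converge" in n for n in notes),
        method=method,
        notes=notes,
        random_cov=random_cov,
        vcov=vcov_full[:p, :p] if np.ndim(vcov_full) == 2 else None,
        data=data,
        theta=theta_hat,
    )


# ---------------------------------------------------------------------------
# Multinomial logit (fixed and mixed)
# ---------------------------------------------------------------------------


def _mnl_loglik_and_probs(eta_free):
    """Row loglik pieces for a multinomial logit; eta_free is n x (J-1)."""
    eta = np.clip(eta_free, -_LOGIT_CLIP, _LOGIT_CLIP)
    denom = np.log1p(np.exp(eta).sum(axis=1))
    probs = np.exp(eta) / (1.0 + np.exp(eta).sum(axis=1, keepdims=True))
    return eta, denom, probs


def _group_onehot(re_levels, L):
    G = np.zeros((L, len(re_levels)))
    G[re_levels, np.arange(len(re_levels))] = 1.0
    return G


def _mnl_blocks(probs, re_Z, G, L, k0, n_free, w=None):
    """Per-level k x k negative-Hessian blocks sum_i kron(z z', W_i)."""
    n = probs.shape[0]
    W = -probs[:, :, None] * probs[:, None, :]
    W[:, np.arange(n_free), np.arange(n_free)] += probs
    if w is not None:
        W = W * w[:, None, None]
    zz = re_Z[:, :, None] * re_Z[:, None, :]  # n x k0 x k0
    contrib = zz[:, :, :, None, None] * W[:, None, None, :, :]
    acc = (G @ contrib.reshape(n, -1)).reshape(L, k0, k0, n_free, n_free)
    # ordering (t, j): block[(t,j),(s,m)] = zz[t,s] * W[j,m]
    return acc.transpose(0, 1, 3, 2, 4).reshape(L, k0 * n_free, k0 * n_free)


def _laplace_multinomial(beta, X, ycode, re_Z, re_levels, Lam,
                         n_free, w=None, u0=None, max_inner: int = 60):
    """Laplace marginal loglik; one grouping factor, per-category effects.

    ``beta``: (J-1) x p.  Random vector per level: k0 x (J-1) components,
    covariance ``Lam @ Lam.T`` over those k dims; scaled coordinates u.
    """
    n, p = X.shape
    k0 = re_Z.shape[1]
    L = re_levels.max() + 1
    k = k0 * n_free
    q = L * k
    u = np.zeros(q) if u0 is None or u0.shape != (q,) else u0.copy()
    if w is None:
        w = np.ones(n)
    xb = X @ beta.T  # n x (J-1)
    G = _group_onehot(re_levels, L)
    onehot = np.zeros((n, n_free))
    mask = ycode >= 0
    onehot[np.arange(n)[mask], ycode[mask]] = 1.0

    def eta_of(uvec):
        b = (uvec.reshape(L, k) @ Lam.T)  # L x k in b-coordinates
        bmat = b.reshape(L, k0, n_free)
        # contribution: sum_t z_t(i) * b[level, t, j]
        contrib = np.einsum("it,itj->ij", re_Z, bmat[re_levels])
        return xb + contrib

    def h(uvec):
        eta, denom, _ = _mnl_loglik_and_probs(eta_of(uvec))
        ll = float(np.sum(w * (np.sum(eta * onehot, axis=1) - denom)))
        return ll - 0.5 * uvec @ uvec

    h_u = h(u)
    eye = np.eye(q)
    for _ in range(max_inner):
        eta, denom, probs = _mnl_loglik_and_probs(eta_of(u))
        resid = w[:, None] * (onehot - probs)  # n x (J-1)
        gb = np.einsum("it,ij->itj", re_Z, resid)  # n x k0 x (J-1)
        grad_b = G @ gb.reshape(n, k)
        grad = (grad_b @ Lam).reshape(q) - u
        if np.max(np.abs(grad)) < 1e-10:
            break
        blocks = _mnl_blocks(probs, re_Z, G, L, k0, n_free, w=w)
        H = np.zeros((q, q))
        for l in range(L):
            sl = slice(l * k, (l + 1) * k)
            H[sl, sl] = Lam.T @ blocks[l] @ Lam
        H += eye
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = grad
        t = 1.0
        h_new = h_u
        for _ in range(30):
            u_new = u + t * step
            h_new = h(u_new)
            if h_new >= h_u - 1e-12:
                break
            t *= 0.5
        if h_new < h_u:
            break
        gain = h_new - h_u
        u, h_u = u_new, h_new
        if gain < 1e-10:
            break
    eta, denom, probs = _mnl_loglik_and_probs(eta_of(u))
    blocks = _mnl_blocks(probs, re_Z, G, L, k0, n_free, w=w)
    H = np.zeros((q, q))
    for l in range(L):
        sl = slice(l * k, (l + 1) * k)
        H[sl, sl] = Lam.T @ blocks[l] @ Lam
    H += eye
    sign, logdet = np.linalg.slogdet(H)
    ll = (
        float(np.sum(w * (np.sum(eta * onehot, axis=1) - denom)))
        - 0.5 * u @ u
        - 0.5 * logdet
    )
    return ll, u


def _profile_multinomial(Lam, X, ycode, re_Z, re_levels, n_free,
                         w=None, start=None, max_inner: int = 100):
    """Profiled Laplace loglik: joint Newton over (beta, u) for given Lam."""
    n, p = X.shape
    k0 = re_Z.shape[1]
    L = re_levels.max() + 1
    k = k0 * n_free
    q = L * k
    nb = p * n_free
    v = np.zeros(nb + q) if start is None or start.shape != (nb + q,) else start.copy()
    if w is None:
        w = np.ones(n)
    G = _group_onehot(re_levels, L)
    onehot = np.zeros((n, n_free))
    mask = ycode >= 0
    onehot[np.arange(n)[mask], ycode[mask]] = 1.0

    def eta_of(vec):
        beta = vec[:nb].reshape(n_free, p)
        b = (vec[nb:].reshape(L, k) @ Lam.T).reshape(L, k0, n_free)
        return X @ beta.T + np.einsum("it,itj->ij", re_Z, b[re_levels])

    def h(vec):
        eta, denom, _ = _mnl_loglik_and_probs(eta_of(vec))
        return float(np.sum(w * (np.sum(eta * onehot, axis=1) - denom))) - 0.5 * float(
            vec[nb:] @ vec[nb:]
        )

    h_v = h(v)
    for _ in range(max_inner):
        eta, denom, probs = _mnl_loglik_and_probs(eta_of(v))
        resid = w[:, None] * (onehot - probs)
        grad_beta = np.einsum("ia,ij->ja", X, resid).reshape(nb)
        gb = np.einsum("it,ij->itj", re_Z, resid).reshape(n, k)
        grad_b = G @ gb
        grad_u = (grad_b @ Lam).reshape(q) - v[nb:]
        grad = np.concatenate([grad_beta, grad_u])
        if np.max(np.abs(grad)) < 1e-10:
            break
        W = -probs[:, :, None] * probs[:, None, :]
        W[:, np.arange(n_free), np.arange(n_free)] += probs
        W = W * w[:, None, None]
        Hbb = np.einsum("ia,ijm,ib->jamb", X, W, X).reshape(nb, nb)
        cross = np.einsum("ia,ijm,it->ijatm", X, W, re_Z).reshape(n, nb * k)
        acc = (G @ cross).reshape(L, nb, k)
        Hbu = np.zeros((nb, q))
        blocks = _mnl_blocks(probs, re_Z, G, L, k0, n_free, w=w)
        Huu = np.zeros((q, q))
        for l in range(L):
            sl = slice(l * k, (l + 1) * k)
            Hbu[:, sl] = acc[l] @ Lam
            Huu[sl, sl] = Lam.T @ blocks[l] @ Lam
        H = np.block([[Hbb, Hbu], [Hbu.T, Huu + np.eye(q)]])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = grad
        t = 1.0
        for _ in range(40):
            v_new = v + t * step
            h_new = h(v_new)
            if h_new >= h_v - 1e-12:
                break
            t *= 0.5
        if h_new < h_v:
            break
        v, h_v = v_new, h_new
    eta, denom, probs = _mnl_loglik_and_probs(eta_of(v))
    blocks = _mnl_blocks(probs, re_Z, G, L, k0, n_free, w=w)
    Huu = np.zeros((q, q))
    for l in range(L):
        sl = slice(l * k, (l + 1) * k)
        Huu[sl, sl] = Lam.T @ blocks[l] @ Lam
    Huu += np.eye(q)
    _, logdet = np.linalg.slogdet(Huu)
    u = v[nb:]
    ll = (
        float(np.sum(w * (np.sum(eta * onehot, axis=1) - denom)))
        - 0.5 * float(u @ u)
        - 0.5 * logdet
    )
    return ll, v


def fit_multinomial(data: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """Multinomial logit, optionally with per-category random effects.

    The response column is categorical; ``spec.reference`` names the
    baseline category (log-odds of every other category are modelled
    against it).  With random terms and a grouping factor of >= 3 levels
    the random effects are integrated out by a Laplace approximation;
    otherwise the fit falls back to fixed effects via statsmodels MNLogit.
    """
    if spec.family != "multinomial_logit":
        raise ValueError("spec.family must be 'multinomial_logit'")
    yraw = data[spec.response].astype(str).to_numpy()
    cats = sorted(set(yraw))
    ref = spec.reference if spec.reference is not None else cats[0]
    if ref not in cats:
        raise ValueError(f"reference category {ref!r} not present")
    free = [c for c in cats if c != ref]
    if not free:
        raise ValueError("response has a single level")
    n_free = len(free)
    code = {c: j for j, c in enumerate(free)}
    ycode = np.array([code.get(v, -1) for v in yraw])
    X = _design(data, spec.fixed)
    p = X.shape[1]
    base_names = _fixed_names(spec.fixed)
    names = [f"{c}~{nm}" for c in free for nm in base_names]
    notes: list[str] = []

    random = list(spec.random)
    for factor, _ in list(random):
        if data[factor].nunique() < 3:
            notes.append(
                f"random factor {factor!r} has <3 levels; dropped to fixed-only"
            )
            random = [r for r in random if r[0] != factor]
    if len(random) > 1:
        raise ValueError("multinomial mixed fit supports one grouping factor")

    if not random or spec.method == "fixed":
        import statsmodels.api as sm

        # order categories so the reference is statsmodels' base (code 0)
        order = [ref] + free
        ynum = np.array([order.index(v) for v in yraw])
        res = sm.MNLogit(ynum, X).fit(disp=0, maxiter=500, method="newton")
        params = pd.Series(np.asarray(res.params).T.ravel(), index=names)
        se = pd.Series(np.asarray(res.bse).T.ravel(), index=names)
        return ModelFit(
            spec=spec, params=params, se=se, loglik=float(res.llf),
            n_obs=len(yraw), n_params=p * n_free,
            converged=bool(res.mle_retvals.get("converged", True)),
            method="fixed", notes=notes, data=data, theta=np.zeros(0),
            vcov=np.asarray(res.cov_params()),
        )

    factor, terms = random[0]
    used_cols = [spec.response, *spec.fixed, factor]
    used_cols.extend(t for t in terms if t != "Intercept")
    cells, wts = _collapse(data, used_cols)
    yw = cells[spec.response].astype(str).to_numpy()
    ycw = np.array([code.get(vv, -1) for vv in yw])
    Xw = _design(cells, spec.fixed)
    _, level_idx = np.unique(
        cells[factor].astype(str).to_numpy(), return_inverse=True
    )
    re_Z = _term_matrix(cells, terms)
    k = re_Z.shape[1] * n_free
    n_theta = _n_chol(k)
    warm = {"u": None, "v": None}

    def negll(par):  # full marginal in (beta, theta), for SEs
        beta = par[: p * n_free].reshape(n_free, p)
        Lam = _chol_from_params(par[p * n_free :], k)
        ll, u = _laplace_multinomial(
            beta, Xw, ycw, re_Z, level_idx, Lam, n_free, w=wts, u0=warm["u"]
        )
        warm["u"] = u
        return -ll

    def prof_negll(theta):
        Lam = _chol_from_params(theta, k)
        ll, v = _profile_multinomial(
            Lam, Xw, ycw, re_Z, level_idx, n_free, w=wts, start=warm["v"]
        )
        warm["v"] = v
        return -ll

    theta0 = np.zeros(n_theta)
    diag_pos = np.cumsum([0] + list(range(2, k + 1)))[:k]
    theta0[diag_pos] = 0.3
    opt = optimize.minimize(
        prof_negll, theta0, method="BFGS",
        options={"gtol": 1e-5, "maxiter": 200, "eps": 1e-6},
    )
    grad_ok = opt.jac is not None and np.max(np.abs(opt.jac)) < 1e-2
    if not (opt.success or grad_ok):
        opt2 = optimize.minimize(
            prof_negll, opt.x, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 600},
        )
        if opt2.fun <= opt.fun:
            opt = opt2
    theta_opt = opt.x
    _, v_hat = _profile_multinomial(
        _chol_from_params(theta_opt, k), Xw, ycw, re_Z, level_idx, n_free,
        w=wts, start=warm["v"],
    )
    par_hat = np.concatenate([v_hat[: p * n_free], theta_opt])
    beta_hat = par_hat[: p * n_free]
    Lam_hat = _chol_from_params(theta_opt, k)
    Sigma = Lam_hat @ Lam_hat.T
    if np.any(np.sqrt(np.clip(np.diag(Sigma), 0, None)) < 1e-3):
        notes.append(f"random variance for {factor!r} at boundary (~0)")
    if not (opt.success or grad_ok):
        notes.append("optimizer reported non-convergence")
    H = approx_hess3(par_hat, negll)
    try:
        vcov_full = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(vcov_full)[: p * n_free], 0, None))
    except np.linalg.LinAlgError:
        vcov_full = None
        se = np.full(p * n_free, np.nan)
        notes.append("Hessian singular; no Wald SEs")
    term_names = [f"{c}~{t}" for t in terms for c in free]
    return ModelFit(
        spec=spec,
        params=pd.Series(beta_hat, index=names),
        se=pd.Series(se, index=names),
        loglik=float(-opt.fun),
        n_obs=len(yraw),
        n_params=len(par_hat),
        converged=np.isfinite(opt.fun),
        method="laplace",
        notes=notes,
        random_cov={factor: (tuple(term_names), Sigma)},
        vcov=vcov_full[: p * n_free, : p * n_free] if vcov_full is not None else None,
        data=data,
        theta=par_hat[p * n_free :],
    )


def fit_multinomial_attention(
    records,
    reference: str = "tactile",
    random_effects: bool = True,
    restrict_complete_signallers: bool = True,
) -> ModelFit:
    """Modality-choice model: body-act modality on recipient attention.

    Builds the modelling frame from coded signals (body acts with a known
    recipient-attention state, modalities silent-visual / audible /
    tactile), optionally restricted to signallers contributing every
    modality, then fits the multinomial logit with per-category random
    intercepts within signaller (the random "modality" slope).
    """
    from .records import as_frame

    df = as_frame(records)
    frame = df[
        (df["category"] == "body_act")
        & df["recipient_attending"].isin(("yes", "no"))
        & df["modality"].isin(("silent_visual", "audible", "tactile"))
    ].copy()
    if restrict_complete_signallers:
        ok = frame.groupby("signaller_id")["modality"].nunique() == 3
        frame = frame[frame["signaller_id"].map(ok)]
    frame["attending"] = (frame["recipient_attending"] == "yes").astype(float)
    frame = frame.reset_index(drop=True)
    spec = ModelSpec(
        response="modality",
        fixed=("attending",),
        random=(("signaller_id", ("Intercept",)),) if random_effects else (),
        family="multinomial_logit",
        reference=reference,
    )
    return fit_multinomial(frame, spec)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def lrt(full: ModelFit, reduced: ModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits on the same data.

    chi2 = 2 (ll_full - ll_reduced); df = parameter-count difference.
    """
    if full.n_obs != reduced.n_obs:
        raise ValueError("fits are not on the same data (n differs)")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("reduced model has more parameters than full")
    chi2 = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, df, p


def vif(data: pd.DataFrame, columns: Sequence[str]) -> pd.Series:
    """Variance-inflation factor 1/(1-R2_j) per fixed-effect column.

    Each column is regressed (with intercept) on the remaining columns; a
    singular design yields ``inf`` for the offending terms.
    """
    if len(columns) < 2:
        raise ValueError("VIF needs at least two fixed-effect terms")
    out = {}
    M = np.column_stack([data[c].to_numpy(float) for c in columns])
    n = M.shape[0]
    for j, c in enumerate(columns):
        yj = M[:, j]
        Xj = np.column_stack([np.ones(n), np.delete(M, j, axis=1)])
        bhat, *_ = np.linalg.lstsq(Xj, yj, rcond=None)
        resid = yj - Xj @ bhat
        tss = np.sum((yj - yj.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / tss if tss > 0 else 1.0
        out[c] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def _refit(fit: ModelFit, data: pd.DataFrame) -> ModelFit:
    if fit.spec.family == "binomial_logit":
        return fit_binomial_glmm(data, fit.spec)
    return fit_multinomial(data, fit.spec)


def simulate_response(fit: ModelFit, rng: np.random.Generator) -> pd.DataFrame:
    """Draw a new response from the fitted model (new random effects too)."""
    data = fit.data.copy()
    spec = fit.spec
    X = _design(data, spec.fixed)
    if spec.family == "binomial_logit":
        eta = X @ fit.params.to_numpy()
        for factor, (terms, Sigma) in fit.random_cov.items():
            term_cols = [t for t in terms]
            T = _term_matrix(data, term_cols)
            levels, idx = np.unique(
                data[factor].astype(str).to_numpy(), return_inverse=True
            )
            b = rng.multivariate_normal(
                np.zeros(len(term_cols)), Sigma, size=len(levels)
            )
            eta = eta + np.einsum("it,it->i", T, b[idx])
        data[spec.response] = rng.binomial(1, _binom_mu(eta)).astype(float)
        return data
    # multinomial
    yraw = data[spec.response].astype(str)
    cats = sorted(set(yraw))
    ref = spec.reference if spec.reference is not None else cats[0]
    free = [c for c in cats if c != ref]
    p = X.shape[1]
    beta = fit.params.to_numpy().reshape(len(free), p)
    eta = X @ beta.T
    for factor, (terms, Sigma) in fit.random_cov.items():
        k = Sigma.shape[0]
        base_terms = []
        for t in terms:
            nm = t.split("~", 1)[1] if "~" in t else t
            if nm not in base_terms:
                base_terms.append(nm)
        T = _term_matrix(data, base_terms)
        levels, idx = np.unique(
            data[factor].astype(str).to_numpy(), return_inverse=True
        )
        b = rng.multivariate_normal(np.zeros(k), Sigma, size=len(levels))
        bmat = b.reshape(len(levels), len(base_terms), len(free))
        eta = eta + np.einsum("it,itj->ij", T, bmat[idx])
    eta = np.clip(eta, -_LOGIT_CLIP, _LOGIT_CLIP)
    expd = np.exp(eta)
    denom = 1.0 + expd.sum(axis=1)
    probs = np.column_stack([1.0 / denom, expd / denom[:, None]])
    draws = [rng.choice(len(free) + 1, p=pr) for pr in probs]
    labels = [ref] + free
    data[spec.response] = [labels[d] for d in draws]
    return data


def bootstrap_ci(
    fit: ModelFit,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    max_failure_rate: float = 0.2,
) -> pd.DataFrame:
    """Parametric-bootstrap percentile CIs for the fixed effects.

    Responses are simulated from the fitted model (drawing fresh random
    effects), the model is refitted, and the 2.5/97.5 percentiles taken.
    Deterministic under ``seed``.  Errors out when more than
    ``max_failure_rate`` of refits fail.
    """
    rng = np.random.default_rng(seed)
    draws = []
    failures = 0
    for _ in range(n_boot):
        sim = simulate_response(fit, rng)
        try:
            refit = _refit(fit, sim)
            if not np.isfinite(refit.loglik):
                raise RuntimeError("non-finite loglik")
            draws.append(refit.params.to_numpy())
        except Exception:
            failures += 1
    if failures > max_failure_rate * n_boot:
        raise RuntimeError(
            f"bootstrap failed: {failures}/{n_boot} refits unsuccessful"
        )
    arr = np.array(draws)
    lo = (1 - level) / 2 * 100
    return pd.DataFrame(
        {
            "estimate": fit.params,
            "lower": np.percentile(arr, lo, axis=0),
            "upper": np.percentile(arr, 100 - lo, axis=0),
            "n_boot_ok": len(draws),
        },
        index=fit.params.index,
    )


def stability(fit: ModelFit) -> pd.DataFrame:
    """Leave-one-level-out stability of the fixed-effect estimates.

    Refits the model excluding, in turn, each level of each random-effect
    grouping factor and reports the per-coefficient minimum and maximum
    across refits.  Per-level refit failures are recorded, not fatal.
    """
    factors = [f for f, _ in fit.spec.random]
    if not factors:
        raise ValueError("stability requires at least one random-effect factor")
    estimates = []
    failed = []
    for factor in factors:
        levels = fit.data[factor].unique()
        if len(levels) < 3:
            raise ValueError(f"factor {factor!r} has <3 levels")
        for lvl in levels:
            sub = fit.data[fit.data[factor] != lvl].reset_index(drop=True)
            try:
                refit = _refit(fit, sub)
                estimates.append(refit.params)
            except Exception:
                failed.append((factor, lvl))
    if not estimates:
        raise RuntimeError("all stability refits failed")
    arr = pd.DataFrame(estimates)
    out = pd.DataFrame(
        {"estimate": fit.params, "min": arr.min(axis=0), "max": arr.max(axis=0)}
    )
    out.attrs["failed_refits"] = failed
    return out


def marginal_r2(fit: ModelFit) -> float:
    """Latent-scale marginal R2 for a binomial logit mixed model.

    Fixed-effect variance over fixed + random + distribution variance
    (pi^2/3 for the logit link).
    """
    if fit.spec.family != "binomial_logit":
        raise ValueError("marginal_r2 is defined here for binomial fits")
    X = _design(fit.data, fit.spec.fixed)
    eta_fix = X @ fit.params.to_numpy()
    var_fix = float(np.var(eta_fix))
    var_rand = 0.0
    for factor, (terms, Sigma) in fit.random_cov.items():
        T = _term_matrix(fit.data, list(terms))
        var_rand += float(np.mean(np.einsum("it,ts,is->i", T, Sigma, T)))
    return var_fix / (var_fix + var_rand + math.pi**2 / 3.0)


# ---------------------------------------------------------------------------
# Combination-model frame
# ---------------------------------------------------------------------------


def build_combination_frame(
    bigrams: pd.DataFrame,
    signals,
    sexes: dict,
    nn_matrix: pd.DataFrame | None = None,
    rumble_type: str = "Rumble",
    earflap_type: str = "Ear-Flapping",
) -> pd.DataFrame:
    """Assemble the modelling frame for the two combination GLMMs.

    One row per bigram token with: ``vocal_first`` (order response),
    ``is_rumble_earflap`` (combination-type response), the dummy-coded and
    centred signaller sex and sex-dyad predictors with their interaction,
    the z-transformed average nearest-neighbour index (when a matrix is
    given), and the signaller/event grouping columns.
    """
    from .records import as_frame
    from .sociality import dyad_strength

    sig = as_frame(signals)
    dyads = sig.groupby("event_id")[["signaller_id", "recipient_id"]].first()
    frame = bigrams.merge(dyads, left_on="event_id", right_index=True, how="left")
    frame["vocal_first"] = frame["vocal_first"].astype(float)
    frame["is_rumble_earflap"] = (
        ((frame["first"] == rumble_type) & (frame["second"] == earflap_type))
        | ((frame["first"] == earflap_type) & (frame["second"] == rumble_type))
    ).astype(float)
    frame["signaller_sex"] = frame["signaller_id"].map(sexes)
    frame["sex_dyad"] = np.where(
        frame["signaller_id"].map(sexes) == frame["recipient_id"].map(sexes),
        "same",
        "different",
    )
    frame["sex_male"] = dummy_centre(frame, "signaller_sex", "male")
    frame["dyad_different"] = dummy_centre(frame, "sex_dyad", "different")
    frame["sex_x_dyad"] = frame["sex_male"] * frame["dyad_different"]
    if nn_matrix is not None:
        raw = [
            dyad_strength(nn_matrix, a, b)
            for a, b in zip(frame["signaller_id"], frame["recipient_id"])
        ]
        frame["nn_z"] = z_transform(pd.Series(raw))
    return frame.reset_index(drop=True)


COMBINATION_FIXED = ("sex_male", "dyad_different", "nn_z", "sex_x_dyad")
COMBINATION_RANDOM = (
    ("signaller_id", ("Intercept", "nn_z", "sex_x_dyad")),
    ("event_id", ("Intercept",)),
)


def combination_spec(response: str, with_nn: bool = True) -> ModelSpec:
    """Maximal spec for the order / Rumble+Ear-Flapping combination GLMMs."""
    fixed = COMBINATION_FIXED if with_nn else tuple(
        c for c in COMBINATION_FIXED if c != "nn_z"
    )
    random = COMBINATION_RANDOM if with_nn else (
        ("signaller_id", ("Intercept", "sex_x_dyad")),
        ("event_id", ("Intercept",)),
    )
    return ModelSpec(
        response=response, fixed=fixed, random=random, family="binomial_logit"
    )


def reduced_spec(spec: ModelSpec, drop: Sequence[str]) -> ModelSpec:
    """The nested null model: same random structure, named fixed terms removed."""
    keep = tuple(c for c in spec.fixed if c not in set(drop))
    return replace(spec, fixed=keep)
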