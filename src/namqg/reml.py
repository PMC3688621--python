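"""REML engines for variance-component models.

Three fitters are provided, all maximizing the restricted likelihood:

``reml_dense``
    A general engine for y = Xb + sum_i u_i + e with independent G
    structures (one variance per random term, arbitrary design matrices)
    and a residual that is iid within groups or AR1 x AR1 correlated over a
    field grid, heterogeneous across groups.  The covariance matrix is
    built densely, so this path is meant for moderate problem sizes
    (a few thousand observations).  Variance parameters use analytic
    REML gradients; AR1 correlations use finite differences.

``reml_crossed``
    A specialized fitter for the complete line x environment layout with
    one plot per cell and no field-design terms: random family,
    RIL-within-family (common or per-family variance), environment,
    family x environment, and a residual that absorbs RIL x environment
    (the two are confounded with a single plot per line and environment).
    The likelihood is evaluated in closed form through an orthonormal
    rotation of the environment dimension and family-block plus low-rank
    Woodbury identities, giving O(n_lines) cost per evaluation, which
    makes NAM-scale fits (thousands of lines) fast.

``reml_ar1_grid``
    A Kronecker-eigendecomposition fitter for a single field grid with an
    AR1(row) x AR1(col) spatial component plus a nugget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = ["reml_dense", "reml_crossed", "reml_ar1_grid",
           "DenseReml", "CrossedReml", "Ar1GridReml", "ResidGroup"]


def _ar1_corr(n: int, rho: float) -> np.ndarray:
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


# ---------------------------------------------------------------------------
# general dense engine
# ---------------------------------------------------------------------------


@dataclass
class ResidGroup:
    """Residual block: row indices of one group (e.g. one environment).

    ``kind`` is ``"iid"`` or ``"ar1"``; for AR1 the plot grid coordinates
    must be supplied and the correlation is AR1(row) x AR1(col) restricted
    to the observed cells.
    """

    rows: np.ndarray
    kind: str = "iid"
    grid_row: np.ndarray | None = None
    grid_col: np.ndarray | None = None

    def corr(self, rho_r: float, rho_c: float) -> np.ndarray:
        if self.kind == "iid":
            return np.eye(len(self.rows))
        r = np.asarray(self.grid_row)
        c = np.asarray(self.grid_col)
        return (rho_r ** np.abs(r[:, None] - r[None, :])
                * rho_c ** np.abs(c[:, None] - c[None, :]))


@dataclass
class DenseReml:
    variances: dict[str, float]
    resid: dict[str, float]
    ar1: dict[str, tuple[float, float]]
    loglik: float
    beta: np.ndarray
    converged: bool
    n: int
    # internals for BLUP / diagnostics
    Py: np.ndarray | None = None
    Vinv: np.ndarray | None = None
    message: str = ""


def reml_dense(y: np.ndarray, X: np.ndarray,
               terms: dict[str, np.ndarray],
               resid_groups: dict[str, ResidGroup] | None = None,
               max_iter: int = 200, tol: float = 1e-10,
               start: dict[str, float] | None = None) -> DenseReml:
    """Fit a variance-component mixed model by dense REML.

    ``terms`` maps term name -> design matrix Z (n x q); each term gets one
    variance.  ``resid_groups`` partitions observations into residual
    blocks with their own variance (and AR1 parameters when requested); by
    default a single iid residual over all rows.
    """
    y = np.asarray(y, float).ravel()
    n = y.size
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != n:
        X = X.T
    if resid_groups is None:
        resid_groups = {"resid": ResidGroup(rows=np.arange(n))}
    for g in resid_groups.values():
        g.rows = np.asarray(g.rows)
    term_names = list(terms)
    res_names = list(resid_groups)
    ar1_names = [k for k in res_names if resid_groups[k].kind == "ar1"]
    vy = max(y.var(), 1e-12)

    ZZ = {k: np.asarray(Z, float) for k, Z in terms.items()}
    A_fixed = {k: ZZ[k] @ ZZ[k].T for k in term_names}

    n_var = len(term_names) + len(res_names)
    n_rho = 2 * len(ar1_names)

    def unpack(theta):
        sig = dict(zip(term_names + res_names, theta[:n_var]))
        rho = {}
        for i, k in enumerate(ar1_names):
            rho[k] = (theta[n_var + 2 * i], theta[n_var + 2 * i + 1])
        return sig, rho

    def build_V(sig, rho):
        V = np.zeros((n, n))
        for k in term_names:
            if sig[k] > 0:
                V += sig[k] * A_fixed[k]
        for k, g in resid_groups.items():
            rr = g.rows
            if g.kind == "ar1":
                C = g.corr(*rho[k])
            else:
                C = np.eye(len(rr))
            V[np.ix_(rr, rr)] += sig[k] * C
        return V

    def nll_and_parts(theta):
        sig, rho = unpack(theta)
        V = build_V(sig, rho)
        try:
            L = np.linalg.cholesky(V + 1e-10 * vy * np.eye(n))
        except np.linalg.LinAlgError:
            return None
        logdetV = 2.0 * np.log(np.diag(L)).sum()
        Vi_y = np.linalg.solve(V + 1e-10 * vy * np.eye(n), y)
        Vi_X = np.linalg.solve(V + 1e-10 * vy * np.eye(n), X)
        XtViX = X.T @ Vi_X
        sign, logdetX = np.linalg.slogdet(XtViX)
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        Py = Vi_y - Vi_X @ beta
        nll = 0.5 * (logdetV + logdetX + y @ Py)
        return nll, sig, rho, V, Vi_X, XtViX, Py

    def objective(theta):
        parts = nll_and_parts(theta)
        if parts is None:
            return 1e12, np.zeros_like(theta)
        nll, sig, rho, V, Vi_X, XtViX, Py = parts
        grad = np.zeros_like(theta)
        Vreg = V + 1e-10 * vy * np.eye(n)
        # analytic gradient for variance parameters
        M = np.linalg.solve(XtViX, Vi_X.T)  # p x n
        for i, k in enumerate(term_names):
            Z = ZZ[k]
            ViZ = np.linalg.solve(Vreg, Z)
            tr = np.einsum("ij,ij->", Z, ViZ) - np.einsum(
                "ij,ij->", Vi_X.T @ Z, M @ Z)
            quad = np.square(Py @ Z).sum()
            grad[i] = 0.5 * (tr - quad)
        for j, k in enumerate(res_names):
            g = resid_groups[k]
            rr = g.rows
            if g.kind == "ar1":
                C = g.corr(*rho[k])
            else:
                C = np.eye(len(rr))
            E = np.zeros((n, len(rr)))
            E[rr, np.arange(len(rr))] = 1.0
            AE = E @ C  # n x m (columns of A for this block)
            ViA = np.linalg.solve(Vreg, AE)
            tr = np.einsum("ij,ij->", E, ViA) - np.einsum(
                "ij,ij->", Vi_X.T @ AE, M @ E)
            quad = Py[rr] @ C @ Py[rr]
            grad[len(term_names) + j] = 0.5 * (tr - quad)
        # finite differences for AR1 parameters
        for i in range(n_rho):
            t2 = theta.copy()
            h = 1e-5
            t2[n_var + i] += h
            p2 = nll_and_parts(t2)
            grad[n_var + i] = ((p2[0] - nll) / h) if p2 is not None else 0.0
        return nll, grad

    theta0 = np.empty(n_var + n_rho)
    for i, k in enumerate(term_names + res_names):
        theta0[i] = (start or {}).get(k, vy / (n_var))
    theta0[n_var:] = 0.1
    bounds = [(0.0, 50.0 * vy)] * n_var + [(-0.98, 0.98)] * n_rho

    res = optimize.minimize(objective, theta0, jac=True, method="L-BFGS-B",
                            bounds=bounds,
                            options={"maxiter": max_iter, "ftol": tol,
                                     "gtol": 1e-10})
    theta = res.x.copy()

    # average-information polish on the variance parameters (AR1 fixed):
    # Newton-type steps drive the REML gradient to ~0 so that on balanced
    # designs the estimates agree with closed-form ANOVA to high precision
    def block_A(k, rho):
        g = resid_groups[k]
        A = np.zeros((n, n))
        C = g.corr(*rho[k]) if g.kind == "ar1" else np.eye(len(g.rows))
        A[np.ix_(g.rows, g.rows)] = C
        return A

    for _ in range(40):
        parts = nll_and_parts(theta)
        if parts is None:
            break
        nll0, sig, rho, V, Vi_X, XtViX, Py = parts
        Vreg = V + 1e-10 * vy * np.eye(n)
        Amats = [A_fixed[k] for k in term_names] + \
                [block_A(k, rho) for k in res_names]
        grads = np.empty(n_var)
        Ws = []
        M = np.linalg.solve(XtViX, Vi_X.T)
        for i, A in enumerate(Amats):
            ViA = np.linalg.solve(Vreg, A)
            trPA = np.trace(ViA) - np.einsum("ij,ij->", Vi_X.T @ A, M)
            w = A @ Py
            grads[i] = -0.5 * (trPA - Py @ w)  # d loglik / d sigma_i
            Ws.append(w)
        if np.max(np.abs(grads)) < 1e-9 * max(1.0, 1.0 / vy):
            break
        W = np.column_stack(Ws)
        ViW = np.linalg.solve(Vreg, W)
        PW = ViW - Vi_X @ (M @ W)
        AI = 0.5 * (W.T @ PW)
        try:
            delta = np.linalg.solve(AI + 1e-12 * np.eye(n_var), grads)
        except np.linalg.LinAlgError:
            break
        step = 1.0
        improved = False
        for _ in range(20):
            cand = theta.copy()
            cand[:n_var] = np.maximum(theta[:n_var] + step * delta, 0.0)
            p2 = nll_and_parts(cand)
            if p2 is not None and p2[0] <= nll0 + 1e-12:
                theta = cand
                improved = True
                break
            step *= 0.5
        if not improved:
            break

    parts = nll_and_parts(theta)
    if parts is None:
        raise RuntimeError("REML likelihood not evaluable at the optimum")
    nll, sig, rho, V, Vi_X, XtViX, Py = parts
    beta = np.linalg.solve(XtViX, X.T @ np.linalg.solve(
        V + 1e-10 * vy * np.eye(n), y))
    return DenseReml(
        variances={k: float(sig[k]) for k in term_names},
        resid={k: float(sig[k]) for k in res_names},
        ar1={k: (float(rho[k][0]), float(rho[k][1])) for k in ar1_names},
        loglik=-float(nll), beta=beta, converged=bool(res.success),
        n=n, Py=Py, Vinv=np.linalg.inv(V + 1e-10 * vy * np.eye(n)),
        message=str(res.message))


# ---------------------------------------------------------------------------
# fast crossed (complete line x env) engine
# ---------------------------------------------------------------------------


def _helmert(n: int) -> np.ndarray:
    """Orthonormal n x n matrix whose first row is 1/sqrt(n)."""
    H = np.zeros((n, n))
    H[0] = 1.0 / np.sqrt(n)
    for i in range(1, n):
        H[i, :i] = 1.0
        H[i, i] = -i
        H[i] /= np.sqrt(i * (i + 1))
    return H


class _BlockLowRank:
    """M = blockdiag_f(alpha_f I + beta J) + U diag(s) U^T, line-sorted by family.

    Provides solves, log-determinant and selected traces in O(n_lines).
    """

    def __init__(self, sizes: np.ndarray, alpha: np.ndarray, beta: float,
                 U: np.ndarray | None, s: np.ndarray | None):
        self.sizes = sizes
        self.alpha = np.asarray(alpha, float)
        self.beta = float(beta)
        self.starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        self.fam_of = np.repeat(np.arange(len(sizes)), sizes)
        self.n = int(sizes.sum())
        if U is not None and s is not None:
            keep = np.asarray(s) > 0
            U = U[:, keep] if keep.any() else None
            s = np.asarray(s)[keep] if keep.any() else None
        self.U = U
        self.s = s
        if np.any(self.alpha <= 0):
            raise FloatingPointError("nonpositive block diagonal")
        self.denom = self.alpha + sizes * self.beta
        if np.any(self.denom <= 0):
            raise FloatingPointError("nonpositive block eigenvalue")
        if U is not None and s is not None and len(s) > 0:
            BiU = self._block_solve(U)
            K = np.diag(1.0 / s) + U.T @ BiU
            self._K = K
            self._BiU = BiU
            sign, ld = np.linalg.slogdet(K)
            if sign <= 0:
                raise FloatingPointError("indefinite low-rank update")
            self._ld_lr = ld + np.log(s).sum()
        else:
            self._K = None
            self._BiU = None
            self._ld_lr = 0.0

    def _group_sum(self, x: np.ndarray) -> np.ndarray:
        return np.add.reduceat(x, self.starts, axis=0)

    def _block_solve(self, rhs: np.ndarray) -> np.ndarray:
        rhs2 = rhs[:, None] if rhs.ndim == 1 else rhs
        gs = self._group_sum(rhs2)
        adj = (self.beta / self.denom)[:, None] * gs
        out = (rhs2 - adj[self.fam_of]) / self.alpha[self.fam_of][:, None]
        return out[:, 0] if rhs.ndim == 1 else out

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        x = self._block_solve(rhs)
        if self._K is None:
            return x
        rhs2 = x[:, None] if x.ndim == 1 else x
        corr = self._BiU @ np.linalg.solve(self._K, self.U.T @ rhs2)
        out = rhs2 - corr
        return out[:, 0] if rhs.ndim == 1 else out

    def logdet(self) -> float:
        ld = float(((self.sizes - 1) * np.log(self.alpha)).sum()
                   + np.log(self.denom).sum())
        return ld + self._ld_lr


@dataclass
class CrossedReml:
    """REML fit of the complete line x env crossed classification."""

    sigma_fam: float
    sigma_ril: np.ndarray         # per family (may be identical entries)
    sigma_env: float
    sigma_fam_env: float
    sigma_resid: float            # absorbs RIL x env with one plot per cell
    sigma_cov: float              # random covariate-regression component
    loglik: float
    mu: float
    converged: bool
    families: list[str] = field(default_factory=list)
    n_env: int = 0
    per_family_ril: bool = True
    # kept for BLUP computation
    _ctx: dict | None = None


def reml_crossed(Y: np.ndarray, fam_sizes: np.ndarray,
                 per_family_ril: bool = True,
                 covariate: np.ndarray | None = None,
                 families: list[str] | None = None,
                 maxiter: int = 20000) -> CrossedReml:
    """REML for a complete line x environment table, lines sorted by family.

    ``Y`` is n_lines x n_env with one plot value per cell.  Model terms:
    grand mean (fixed), family, RIL(family), environment,
    family x environment, residual (RIL x environment + plot error, which
    are confounded at one plot per cell).  ``covariate`` adds a
    line-level random-regression component on the given (centered) values.
    """
    Y = np.asarray(Y, float)
    L, E = Y.shape
    sizes = np.asarray(fam_sizes, int)
    if sizes.sum() != L:
        raise ValueError("family sizes do not sum to the number of lines")
    F = len(sizes)
    H = _helmert(E)
    T = Y @ H.T
    z0 = T[:, 0]
    Zc = T[:, 1:]
    ones = np.ones(L)
    c = None
    if covariate is not None:
        c = np.asarray(covariate, float)
        c = c - c.mean()

    vy = max(Y.var(), 1e-10)
    n_ril = F if per_family_ril else 1
    has_cov = c is not None
    # theta: log variances [fam, ril(1|F), env, fam_env, resid, (cov)]
    n_par = 4 + n_ril + (1 if has_cov else 0)

    def unpack(theta):
        s = np.exp(np.clip(theta, -40, 40)) * vy
        i = 0
        s_fam = s[i]; i += 1
        s_ril = s[i:i + n_ril]; i += n_ril
        s_env = s[i]; i += 1
        s_fe = s[i]; i += 1
        s_res = s[i]; i += 1
        s_cov = s[i] if has_cov else 0.0
        if not per_family_ril:
            s_ril = np.full(F, s_ril[0])
        return s_fam, s_ril, s_env, s_fe, s_res, s_cov

    def nll(theta):
        s_fam, s_ril, s_env, s_fe, s_res, s_cov = unpack(theta)
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return _nll_inner(s_fam, s_ril, s_env, s_fe, s_res, s_cov)

    def _nll_inner(s_fam, s_ril, s_env, s_fe, s_res, s_cov):
        try:
            # column 0: E*A + B
            Ucols, svals = [ones], [s_env]
            if has_cov:
                Ucols.append(c)
                svals.append(E * s_cov)
            M0 = _BlockLowRank(sizes, E * s_ril + s_res, E * s_fam + s_fe,
                               np.column_stack(Ucols), np.asarray(svals))
            # contrast columns: B
            M1 = _BlockLowRank(sizes, np.full(F, s_res), s_fe,
                               ones[:, None], np.asarray([s_env]))
        except FloatingPointError:
            return 1e12
        # REML for z0 with mean sqrt(E)*mu
        x = np.sqrt(E) * ones
        Mx = M0.solve(x)
        xtx = x @ Mx
        Mz = M0.solve(z0)
        mu_hat = (x @ Mz) / xtx
        resid_quad = z0 @ Mz - (x @ Mz) ** 2 / xtx
        ll = -0.5 * (M0.logdet() + np.log(xtx) + resid_quad)
        # contrasts: zero mean, iid across E-1 columns
        S = M1.solve(Zc)
        ll += -0.5 * ((E - 1) * M1.logdet() + np.einsum("ij,ij->", Zc, S))
        if not np.isfinite(ll):
            return 1e12
        return -ll

    theta0 = np.full(n_par, np.log(1.0 / n_par))
    res = optimize.minimize(nll, theta0, method="Powell",
                            options={"maxiter": maxiter, "xtol": 1e-7,
                                     "ftol": 1e-10})
    s_fam, s_ril, s_env, s_fe, s_res, s_cov = unpack(res.x)
    clamp = lambda v: 0.0 if v < 1e-8 * max(vy, 1e-8) else float(v)
    s_fam, s_env, s_fe, s_cov = map(clamp, (s_fam, s_env, s_fe, s_cov))
    s_ril = np.array([clamp(v) for v in s_ril])
    # keep the recovery solve well conditioned: floor the block diagonal
    # relative to the largest fitted component (mu is scale invariant)
    scale = s_fam + float(np.max(s_ril)) + s_env + s_fe + s_cov
    s_res = max(clamp(s_res), 1e-6 * scale, 1e-12)
    # recover mu at the optimum (clamped values avoid Woodbury blow-ups)
    Ucols, svals = [ones], [s_env]
    if has_cov:
        Ucols.append(c)
        svals.append(E * s_cov)
    M0 = _BlockLowRank(sizes, E * s_ril + s_res, E * s_fam + s_fe,
                       np.column_stack(Ucols), np.asarray(svals))
    x = np.sqrt(E) * ones
    # z0 = sqrt(E)*ybar has mean sqrt(E)*mu, so the GLS coefficient on x is mu
    mu = float((x @ M0.solve(z0)) / (x @ M0.solve(x)))
    fit = CrossedReml(
        sigma_fam=s_fam, sigma_ril=s_ril,
        sigma_env=s_env, sigma_fam_env=s_fe,
        sigma_resid=clamp(s_res), sigma_cov=s_cov,
        loglik=-float(res.fun), mu=mu,
        converged=bool(res.success),
        families=families or [f"F{i + 1:02d}" for i in range(F)],
        n_env=E, per_family_ril=per_family_ril,
        _ctx={"Y": Y, "sizes": sizes, "z0": z0, "covariate": c})
    return fit


def crossed_blup(fit: CrossedReml) -> np.ndarray:
    """BLUP of each line's genetic value (family + RIL effect) from the fit.

    Conditional expectation E[u | y] with u = family effect + RIL effect;
    only the environment-mean contrast carries information about u.
    """
    ctx = fit._ctx
    Y, sizes, z0 = ctx["Y"], ctx["sizes"], ctx["z0"]
    c = ctx["covariate"]
    L, E = Y.shape
    ones = np.ones(L)
    s_ril = fit.sigma_ril
    Ucols, svals = [ones], [fit.sigma_env]
    if c is not None:
        Ucols.append(c)
        svals.append(E * fit.sigma_cov)
    M0 = _BlockLowRank(sizes, E * s_ril + fit.sigma_resid,
                       E * fit.sigma_fam + fit.sigma_fam_env,
                       np.column_stack(Ucols), np.asarray(svals))
    x = np.sqrt(E) * ones
    resid = z0 - x * fit.mu
    w = M0.solve(resid)
    # Cov(u, z0) = sqrt(E) (sigma_fam FF^T + D_ril)
    fam_of = np.repeat(np.arange(len(sizes)), sizes)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    gs = np.add.reduceat(w, starts)
    u = np.sqrt(E) * (fit.sigma_fam * gs[fam_of]
                      + s_ril[fam_of] * w)
    return u


# ---------------------------------------------------------------------------
# AR1 x AR1 grid engine
# ---------------------------------------------------------------------------


@dataclass
class Ar1GridReml:
    rho_row: float
    rho_col: float
    sigma_spatial: float
    sigma_nugget: float
    loglik: float
    mu: float
    converged: bool


def reml_ar1_grid(Ygrid: np.ndarray, nugget: bool = True,
                  maxiter: int = 4000) -> Ar1GridReml:
    """REML fit of y = mu + AR1(row) x AR1(col) field (+ nugget) on a grid."""
    Y = np.asarray(Ygrid, float)
    nr, nc = Y.shape
    vy = max(Y.var(), 1e-12)

    def eig_ar1(n, rho):
        w, U = np.linalg.eigh(_ar1_corr(n, rho))
        return w, U

    def nll(theta):
        rr, rc = np.tanh(theta[0]), np.tanh(theta[1])
        s_sp = np.exp(np.clip(theta[2], -40, 40)) * vy
        s_ng = np.exp(np.clip(theta[3], -40, 40)) * vy if nugget else 0.0
        wr, Ur = eig_ar1(nr, rr)
        wc, Uc = eig_ar1(nc, rc)
        D = s_sp * np.outer(wr, wc) + s_ng
        Yt = Ur.T @ Y @ Uc
        Xt = Ur.T @ np.ones((nr, nc)) @ Uc
        xtx = (Xt ** 2 / D).sum()
        xty = (Xt * Yt / D).sum()
        mu = xty / xtx
        quad = (Yt ** 2 / D).sum() - xty ** 2 / xtx
        return 0.5 * (np.log(D).sum() + np.log(xtx) + quad)

    theta0 = np.array([np.arctanh(0.3), np.arctanh(0.3), 0.0, -1.0])
    if not nugget:
        theta0 = theta0[:3]

        def nll3(t):
            return nll(np.append(t, -np.inf))
        res = optimize.minimize(nll3, theta0, method="Nelder-Mead",
                                options={"maxiter": maxiter, "xatol": 1e-8,
                                         "fatol": 1e-10})
        th = np.append(res.x, -np.inf)
    else:
        res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                                options={"maxiter": maxiter, "xatol": 1e-8,
                                         "fatol": 1e-10})
        th = res.x
    rr, rc = np.tanh(th[0]), np.tanh(th[1])
    s_sp = np.exp(th[2]) * vy
    s_ng = np.exp(th[3]) * vy if nugget else 0.0
    # recover mu
    wr, Ur = np.linalg.eigh(_ar1_corr(nr, rr))
    wc, Uc = np.linalg.eigh(_ar1_corr(nc, rc))
    D = s_sp * np.outer(wr, wc) + s_ng
    Yt = Ur.T @ Y @ Uc
    Xt = Ur.T @ np.ones((nr, nc)) @ Uc
    mu = (Xt * Yt / D).sum() / (Xt ** 2 / D).sum()
    return Ar1GridReml(rho_row=float(rr), rho_col=float(rc),
                       sigma_spatial=float(s_sp), sigma_nugget=float(s_ng),
                       loglik=-float(res.fun), mu=float(mu),
                       converged=bool(res.success))
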