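"""Restricted maximum likelihood for Gaussian variance-component models.

Fits models of the form

    y = X beta + sum_c Z_c u_c + e,   u_c ~ N(0, sigma_c^2 I),  e ~ N(0, sigma_e^2 I)

where each ``Z_c`` is a 0/1 membership matrix built from an integer
coding of the rows (study, school, school-by-year-group, pupil, ...).
The covariance is ``V = sigma_e^2 I + U D U'`` with ``U = [Z_1 ... Z_C]``
low rank relative to n, so every likelihood evaluation reduces, via the
Woodbury identity, to one Cholesky factorisation of a q x q matrix
(q = total number of random-effect levels).  This keeps fits with
hundreds of schools and thousands of pupils fast without any dense
n x n algebra.

The REML criterion minimised over log-variances is

    -2 l_R = log|V| + log|X' V^-1 X| + (y - X b)' V^-1 (y - X b) + const,

with ``b`` the GLS estimate.  The covariance matrix of the variance
estimates is obtained from a finite-difference Hessian of the criterion
at the optimum (observed information).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.optimize
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._errors import EstimationError

__all__ = ["RemlResult", "fit_reml"]

_LOWER_REL = 1e-8  # variance floor relative to var(y); below = boundary zero


@dataclass
class RemlResult:
    """REML estimates for one variance-component model."""

    component_names: list[str]  # random components, then "resid"
    variances: np.ndarray  # aligned with component_names
    vcov: np.ndarray | None  # covariance of the variance estimates
    fixed_names: list[str]
    beta: np.ndarray
    beta_cov: np.ndarray
    converged: bool
    neg2_restricted_loglik: float
    n_obs: int

    def variance(self, name: str) -> float:
        return float(self.variances[self.component_names.index(name)])


class _RemlWorkspace:
    """Precomputed cross-products shared by all likelihood evaluations."""

    def __init__(self, y, X, components):
        n = len(y)
        blocks = []
        self.q_per_comp = []
        for name, codes in components.items():
            codes = np.asarray(codes)
            mask = codes >= 0
            levels, idx = np.unique(codes[mask], return_inverse=True)
            q_c = len(levels)
            if q_c == 0:
                raise EstimationError(f"component {name!r} has no members")
            rows = np.nonzero(mask)[0]
            blocks.append(
                sp.coo_matrix(
                    (np.ones(len(rows)), (rows, idx)), shape=(n, q_c)
                )
            )
            self.q_per_comp.append(q_c)
        U = sp.hstack(blocks).tocsr() if blocks else sp.csr_matrix((n, 0))
        self.n, self.p = n, X.shape[1]
        q = U.shape[1]
        # nested membership makes U'U hierarchically sparse; keep it
        # sparse and use a sparse LU per likelihood evaluation once the
        # dense Cholesky would dominate the fit
        self.sparse = q > 400
        UtU = U.T @ U
        self.UtU = UtU.tocsc() if self.sparse else UtU.toarray()
        self.UtX = np.asarray(U.T @ X)
        self.Uty = np.asarray(U.T @ y)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def neg2_reml(self, log_var: np.ndarray, want_beta: bool = False):
        v = np.exp(log_var)
        se2 = v[-1]
        d = np.repeat(v[:-1], self.q_per_comp)
        q = len(d)
        try:
            if q and self.sparse:
                M = (self.UtU + sp.diags(se2 / d)).tocsc()
                lu = spla.splu(M, permc_spec="MMD_AT_PLUS_A")
                # M is SPD, so det > 0 and |diag(U)| is safe
                logdet_M = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
                AX = lu.solve(self.UtX)
                Ay = lu.solve(self.Uty)
            elif q:
                M = self.UtU + np.diag(se2 / d)
                cho = sla.cho_factor(M, lower=True, check_finite=False)
                logdet_M = 2.0 * np.sum(np.log(np.diag(cho[0])))
                AX = sla.cho_solve(cho, self.UtX, check_finite=False)
                Ay = sla.cho_solve(cho, self.Uty, check_finite=False)
            else:
                logdet_M, AX, Ay = 0.0, np.zeros((0, self.p)), np.zeros(0)
            logdet_V = (
                (self.n - q) * np.log(se2) + logdet_M + float(np.sum(np.log(d)))
            )
            XtVX = (self.XtX - self.UtX.T @ AX) / se2
            XtVy = (self.Xty - self.UtX.T @ Ay) / se2
            ytVy = (self.yty - self.Uty @ Ay) / se2
            sign, logdet_XtVX = np.linalg.slogdet(XtVX)
            if sign <= 0:
                raise np.linalg.LinAlgError
            beta = np.linalg.solve(XtVX, XtVy)
            quad = ytVy - XtVy @ beta
            crit = logdet_V + logdet_XtVX + quad
        except np.linalg.LinAlgError:
            return (np.inf, None, None) if want_beta else np.inf
        if want_beta:
            return crit, beta, np.linalg.inv(XtVX)
        return crit


def _fd_hessian(f, x, steps):
    """Central finite-difference Hessian of scalar f at x."""
    k = len(x)
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = steps[i]
        fpp = f(x + ei)
        fmm = f(x - ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / steps[i] ** 2
        for j in range(i):
            ej = np.zeros(k)
            ej[j] = steps[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * steps[i] * steps[j])
    return H


def fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    components: dict[str, np.ndarray],
    fixed_names: list[str] | None = None,
    compute_vcov: bool = True,
) -> RemlResult:
    """Fit the variance-component model by REML.

    Parameters
    ----------
    y, X
        Response vector and fixed-effect design matrix (include the
        intercept column explicitly).
    components
        Mapping from component name to an integer membership coding of
        the rows; code -1 marks rows outside the component (used for
        year-group-specific school effects).
    compute_vcov
        Skip the finite-difference information matrix when only point
        estimates are needed (e.g. in Monte-Carlo loops).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise EstimationError("singular design: fewer observations than fixed effects")
    if np.linalg.matrix_rank(X) < p:
        raise EstimationError("singular design: fixed-effect matrix is rank deficient")
    ws = _RemlWorkspace(y, X, components)
    k = len(components) + 1  # + residual

    var_y = max(float(np.var(y)), 1e-12)
    x0 = np.log(np.full(k, var_y / k))
    lo, hi = np.log(var_y * _LOWER_REL), np.log(var_y * 50.0)
    opt = scipy.optimize.minimize(
        ws.neg2_reml,
        np.clip(x0, lo, hi),
        method="L-BFGS-B",
        bounds=[(lo, hi)] * k,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not np.isfinite(opt.fun):
        raise EstimationError("REML optimisation failed: criterion not finite")

    log_v = opt.x
    variances = np.exp(log_v)
    boundary = log_v <= lo + 1e-6
    crit, beta, beta_cov = ws.neg2_reml(log_v, want_beta=True)

    vcov = None
    if compute_vcov:
        # Hessian on the variance (not log) scale; boundary components
        # are held at their tiny floor value and reported with zero
        # sampling covariance.
        def crit_of_var(v):
            return ws.neg2_reml(np.log(np.maximum(v, var_y * _LOWER_REL / 10)))

        steps = np.maximum(variances * 1e-3, var_y * 1e-7)
        H = _fd_hessian(crit_of_var, variances, steps)
        H = 0.5 * (H + H.T)
        free = ~boundary
        vcov = np.zeros((k, k))
        if free.any():
            Hf = H[np.ix_(free, free)]
            # observed information of -2logL is H/2; vcov = 2 H^-1
            try:
                cov_f = 2.0 * np.linalg.inv(Hf)
            except np.linalg.LinAlgError:
                cov_f = 2.0 * np.linalg.pinv(Hf)
            # guard against tiny negative diagonal from FD noise
            dg = np.diag(cov_f).copy()
            if np.any(dg < 0):
                cov_f = cov_f + np.eye(len(dg)) * (1e-12 - min(dg.min(), 0.0))
            vcov[np.ix_(free, free)] = cov_f

    variances = np.where(boundary, 0.0, variances)
    names = list(components) + ["resid"]
    return RemlResult(
        component_names=names,
        variances=variances,
        vcov=vcov,
        fixed_names=fixed_names or [f"x{j}" for j in range(p)],
        beta=beta,
        beta_cov=beta_cov,
        converged=bool(opt.success),
        neg2_restricted_loglik=float(crit),
        n_obs=n,
    )
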