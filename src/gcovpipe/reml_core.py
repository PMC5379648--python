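"""Average-information REML engine.

Fits variance-component models y ~ N(X beta, sum_k theta_k V_k) by
maximizing the restricted log-likelihood

    l_R(theta) = -1/2 [ (N - p) log 2 pi + log|V| + log|X' V^-1 X| + y' P y ],

with P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1, using average-information
(AI) updates with step-halving and an expectation-maximization fallback
whenever an AI step would leave the feasible region or decrease the
likelihood.  Variance components are constrained to be non-negative
(clamped to a small floor); covariance components are unconstrained.

Two interchangeable model backends are provided:

* :class:`DenseModel` - structure matrices are explicit N x N arrays
  (arbitrary designs; used for partitioned fits and partial-overlap
  bivariate fits);
* :class:`BlockDiagModel` - after rotating the data into the eigenbasis of
  a single GRM, every structure matrix is (T x T block) x (scalar weight
  per eigenvalue), so each iteration costs O(n T^3) instead of O(n^3).
  This path is exact, not an approximation, whenever all components share
  the GRM's eigenvectors (univariate fits; bivariate fits with complete
  overlap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats

LOG2PI = np.log(2.0 * np.pi)


@dataclass
class RemlEval:
    loglik: float
    grad: np.ndarray
    ai: np.ndarray


@dataclass
class RemlFit:
    """Converged (or flagged) REML solution."""

    theta: np.ndarray
    loglik: float
    ai_inv: np.ndarray  # approximate sampling covariance of theta (free params)
    converged: bool
    n_iter: int
    grad: np.ndarray


class DenseModel:
    """Explicit structure matrices; O(N^3) per evaluation (one inverse)."""

    def __init__(self, y, X, structures, var_mask):
        self.y = np.asarray(y, float).ravel()
        self.X = np.asarray(X, float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        self.structures = [np.asarray(s, float) for s in structures]
        self.var_mask = np.asarray(var_mask, bool)
        self.n_obs = self.y.size
        self.n_params = len(structures)

    def evaluate(self, theta):
        V = sum(t * S for t, S in zip(theta, self.structures))
        try:
            c, low = linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return None
        logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
        Vi = linalg.cho_solve((c, low), np.eye(self.n_obs), check_finite=False)
        ViX = Vi @ self.X
        B = self.X.T @ ViX
        try:
            Bc, Blow = linalg.cho_factor(B, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return None
        logdet_b = 2.0 * np.sum(np.log(np.diag(Bc)))
        Viy = Vi @ self.y
        XtViy = ViX.T @ self.y
        beta = linalg.cho_solve((Bc, Blow), XtViy, check_finite=False)
        Py = Viy - ViX @ beta
        yPy = float(self.y @ Py)
        p = self.X.shape[1]
        loglik = -0.5 * ((self.n_obs - p) * LOG2PI + logdet_v + logdet_b + yPy)

        def P_apply(z):
            Viz = Vi @ z
            return Viz - ViX @ linalg.cho_solve((Bc, Blow), ViX.T @ z, check_finite=False)

        k = self.n_params
        u = [S @ Py for S in self.structures]      # V_k P y
        Pu = [P_apply(uk) for uk in u]
        grad = np.empty(k)
        for i, S in enumerate(self.structures):
            tr_ViS = float(np.sum(Vi * S))          # symmetric matrices
            M = ViX.T @ S @ ViX
            tr_corr = float(np.trace(linalg.cho_solve((Bc, Blow), M, check_finite=False)))
            yPSPy = float(Py @ u[i])
            grad[i] = -0.5 * ((tr_ViS - tr_corr) - yPSPy)
        ai = np.empty((k, k))
        for i in range(k):
            for j in range(i, k):
                ai[i, j] = ai[j, i] = 0.5 * float(u[i] @ Pu[j])
        return RemlEval(loglik, grad, ai)


class BlockDiagModel:
    """Per-eigenvalue T x T blocks: V_i = sum_k theta_k w_k[i] C_k.

    ``y`` is (n, T); ``X`` is (n, T, p); each structure is a pair
    ``(C_k, w_k)`` with C_k a symmetric T x T matrix and w_k an n-vector.
    """

    def __init__(self, y, X, structures, var_mask):
        self.y = np.asarray(y, float)
        if self.y.ndim == 1:
            self.y = self.y[:, None]
        self.X = np.asarray(X, float)
        self.structures = [(np.atleast_2d(np.asarray(C, float)), np.asarray(w, float))
                           for C, w in structures]
        self.var_mask = np.asarray(var_mask, bool)
        self.n, self.T = self.y.shape
        self.n_obs = self.n * self.T
        self.n_params = len(structures)

    def evaluate(self, theta):
        Vb = np.zeros((self.n, self.T, self.T))
        for t, (C, w) in zip(theta, self.structures):
            Vb += t * w[:, None, None] * C[None, :, :]
        # stacked Cholesky for PD check + logdet
        try:
            ch = np.linalg.cholesky(Vb)
        except np.linalg.LinAlgError:
            return None
        logdet_v = 2.0 * float(np.sum(np.log(np.einsum("nii->ni", ch))))
        Vi = np.linalg.inv(Vb)
        Viy = np.einsum("nij,nj->ni", Vi, self.y)
        ViX = np.einsum("nij,njp->nip", Vi, self.X)
        B = np.einsum("nip,niq->pq", self.X, ViX)
        try:
            Bc, Blow = linalg.cho_factor(B, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return None
        logdet_b = 2.0 * np.sum(np.log(np.diag(np.atleast_2d(Bc))))
        XtViy = np.einsum("nip,ni->p", self.X, Viy)
        beta = linalg.cho_solve((Bc, Blow), XtViy, check_finite=False)
        Py = Viy - np.einsum("nip,p->ni", ViX, beta)
        yPy = float(np.sum(self.y * Py))
        p = self.X.shape[2]
        loglik = -0.5 * ((self.n_obs - p) * LOG2PI + logdet_v + logdet_b + yPy)

        def P_apply(z):
            Viz = np.einsum("nij,nj->ni", Vi, z)
            XtViz = np.einsum("nip,ni->p", self.X, Viz)
            return Viz - np.einsum("nip,p->ni", ViX, linalg.cho_solve((Bc, Blow), XtViz, check_finite=False))

        k = self.n_params
        u, Pu = [], []
        for C, w in self.structures:
            uk = w[:, None] * np.einsum("ij,nj->ni", C, Py)
            u.append(uk)
            Pu.append(P_apply(uk))
        grad = np.empty(k)
        for i, (C, w) in enumerate(self.structures):
            tr_ViS = float(np.einsum("n,nij,ji->", w, Vi, C))
            M = np.einsum("nip,n,ij,njq->pq", ViX, w, C, ViX)
            tr_corr = float(np.trace(linalg.cho_solve((Bc, Blow), M, check_finite=False)))
            yPSPy = float(np.sum(Py * u[i]))
            grad[i] = -0.5 * ((tr_ViS - tr_corr) - yPSPy)
        ai = np.empty((k, k))
        for i in range(k):
            for j in range(i, k):
                ai[i, j] = ai[j, i] = 0.5 * float(np.sum(u[i] * Pu[j]))
        return RemlEval(loglik, grad, ai)


def fit_reml(model, start, free=None, max_iter: int = 100, tol: float = 1e-8,
             floor_scale: float | None = None) -> RemlFit:
    """Drive AI-REML to convergence from ``start``.

    ``free`` masks which parameters are optimized (others stay fixed, for
    constrained refits in likelihood-ratio tests).  Convergence is declared
    when the restricted log-likelihood changes by less than ``tol``.
    """
    theta = np.asarray(start, float).copy()
    k = theta.size
    free = np.ones(k, bool) if free is None else np.asarray(free, bool)
    floor = 1e-8 * (floor_scale if floor_scale is not None else max(abs(theta).max(), 1.0))
    theta[model.var_mask & free] = np.maximum(theta[model.var_mask & free], floor)

    ev = model.evaluate(theta)
    for _ in range(20):
        if ev is not None:
            break
        # singular start (e.g. duplicated traits): shrink covariances toward 0
        theta[~model.var_mask] *= 0.5
        ev = model.evaluate(theta)
    if ev is None:
        raise RuntimeError("REML start point gives a non-positive-definite covariance")
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = ev.grad[free]
        A = ev.ai[np.ix_(free, free)]
        try:
            delta = np.linalg.solve(A + 1e-12 * np.eye(g.size), g)
        except np.linalg.LinAlgError:
            delta = g  # fall back to plain gradient direction
        accepted = None
        step = 1.0
        for _ in range(25):
            cand = theta.copy()
            cand[free] = theta[free] + step * delta
            cand[model.var_mask & free] = np.maximum(cand[model.var_mask & free], floor)
            ev_new = model.evaluate(cand)
            if ev_new is not None and ev_new.loglik >= ev.loglik - 1e-10:
                accepted = (cand, ev_new)
                break
            step *= 0.5
        if accepted is None:
            # EM fallback for the non-negative variance components:
            # sigma2 <- sigma2 + sigma2^2 * (y'P V_k P y - tr(P V_k)) / N
            cand = theta.copy()
            em = theta[free] + theta[free] ** 2 * (2.0 * ev.grad[free]) / model.n_obs
            cand[free] = np.where(model.var_mask[free], em, theta[free])
            cand[model.var_mask & free] = np.maximum(cand[model.var_mask & free], floor)
            ev_new = model.evaluate(cand)
            if ev_new is None or ev_new.loglik < ev.loglik - 1e-6:
                break  # stuck; report last valid point, flagged below
            accepted = (cand, ev_new)
        new_theta, new_ev = accepted
        done = abs(new_ev.loglik - ev.loglik) < tol
        theta, ev = new_theta, new_ev
        if done:
            converged = True
            break

    A = ev.ai[np.ix_(free, free)]
    try:
        ai_inv_free = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        ai_inv_free = np.linalg.pinv(A)
    ai_inv = np.zeros((k, k))
    ai_inv[np.ix_(free, free)] = ai_inv_free
    return RemlFit(theta=theta, loglik=ev.loglik, ai_inv=ai_inv,
                   converged=converged, n_iter=it, grad=ev.grad.copy())


def boundary_lrt_pvalue(lrt: float) -> float:
    """P-value for a likelihood-ratio statistic when the tested variance
    component sits on the boundary of its parameter space: the null is the
    50:50 mixture of a point mass at zero and chi-square(1)."""
    if lrt <= 1e-12:
        return 1.0
    return float(0.5 * stats.chi2.sf(lrt, df=1))
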