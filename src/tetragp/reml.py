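"""REML estimation for Gaussian mixed models with factor random effects.

Fits y = X b + sum_k Z_k u_k + e with u_k ~ N(0, s2_k I) and a residual that
may be heteroscedastic across declared groups (environments), e_i ~
N(0, s2_e[g(i)]).  Estimation is an EM-to-AI hybrid on Henderson's mixed
model equations: two EM sweeps stabilise the start, then average-information
updates with step-halving take over; any step that would leave the parameter
space or lower the restricted likelihood falls back to EM.  Convergence is
declared at a relative parameter change below ``tol`` (default 1e-8) with a
200-iteration cap.

All likelihood values reported are restricted log-likelihoods up to the
usual additive constant, computed through the identity
log|V| + log|X'V^-1 X| = log|R| + log|G| + log|C|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve
from scipy.linalg.lapack import dpotri


def _chol_inverse(cf) -> np.ndarray:
    """Full inverse from a Cholesky factor via LAPACK dpotri."""
    inv, info = dpotri(cf[0], lower=True)
    if info != 0:
        raise np.linalg.LinAlgError("dpotri failed")
    # dpotri fills only the lower triangle; the upper one is workspace junk
    low = np.tril(inv)
    return low + np.tril(inv, -1).T


class SingularModelError(RuntimeError):
    """Raised when the mixed-model equations are (numerically) singular."""


class ConvergenceError(RuntimeError):
    """Raised when REML fails to converge within the iteration cap."""


def indicator_matrix(codes: np.ndarray, n_levels: int | None = None) -> sp.csr_matrix:
    """Sparse 0/1 design matrix from integer level codes (-1 = structurally absent)."""
    codes = np.asarray(codes)
    n = codes.shape[0]
    if n_levels is None:
        n_levels = int(codes.max()) + 1 if (codes >= 0).any() else 0
    rows = np.nonzero(codes >= 0)[0]
    return sp.csr_matrix(
        (np.ones(len(rows)), (rows, codes[rows])), shape=(n, n_levels))


@dataclass
class REMLResult:
    beta: np.ndarray
    fixed_names: list[str]
    varcomps: dict[str, float]
    resid_var: np.ndarray            # one entry per residual group
    blups: dict[str, np.ndarray]
    loglik: float
    converged: bool
    n_iter: int
    fixed_cov: np.ndarray            # (X' V^-1 X)^-1
    residuals: np.ndarray
    std_residuals: np.ndarray
    resid_groups: np.ndarray

    def beta_series(self) -> pd.Series:
        return pd.Series(self.beta, index=self.fixed_names)


class MixedModel:
    """A linear mixed model specified by design matrices, fitted by REML.

    Parameters
    ----------
    y
        Response vector.
    X
        Fixed-effect design (dense or sparse), full column rank.
    random
        List of ``(name, Z)`` pairs; each Z maps observations to the levels
        of one iid variance component.
    resid_groups
        Optional integer codes grouping observations into heteroscedastic
        residual strata; ``None`` fits a single residual variance.
    fixed_names
        Optional labels for the columns of X.
    """

    def __init__(self, y, X, random, resid_groups=None, fixed_names=None):
        self.y = np.asarray(y, dtype=float)
        n = self.y.shape[0]
        self.X = sp.csr_matrix(X) if not sp.issparse(X) else X.tocsr()
        if self.X.shape[0] != n:
            raise ValueError("X row count does not match y")
        self.random = [(name, Z.tocsr() if sp.issparse(Z) else sp.csr_matrix(Z))
                       for name, Z in random]
        for name, Z in self.random:
            if Z.shape[0] != n:
                raise ValueError(f"random term {name!r} row count mismatch")
        if resid_groups is None:
            resid_groups = np.zeros(n, dtype=int)
        self.resid_groups = np.asarray(resid_groups, dtype=int)
        self.n_groups = int(self.resid_groups.max()) + 1
        self.group_n = np.bincount(self.resid_groups, minlength=self.n_groups)
        if (self.group_n == 0).any():
            raise ValueError("empty residual group")
        self.fixed_names = (list(fixed_names) if fixed_names is not None
                            else [f"b{j}" for j in range(self.X.shape[1])])
        self.p = self.X.shape[1]
        self.q = [Z.shape[1] for _, Z in self.random]
        self.W = sp.hstack([self.X] + [Z for _, Z in self.random]).tocsr()
        self._Wcsc = self.W.tocsc()

    # -- likelihood machinery -------------------------------------------
    def _assemble(self, s2u: np.ndarray, s2e: np.ndarray):
        """Factorise the MME coefficient matrix for given variance parameters."""
        rinv = 1.0 / s2e[self.resid_groups]
        WtRi = self._Wcsc.T.multiply(rinv)         # dim x n sparse
        C = (WtRi @ self.W).toarray()
        offset = self.p
        ginv_diag = np.zeros(C.shape[0])
        for qk, s2 in zip(self.q, s2u):
            ginv_diag[offset:offset + qk] = 1.0 / s2
            offset += qk
        C[np.diag_indices_from(C)] += ginv_diag
        rhs = WtRi @ self.y
        try:
            cf = cho_factor(C, lower=True, check_finite=False)
        except np.linalg.LinAlgError as exc:
            raise SingularModelError("mixed model equations are singular") from exc
        diagL = np.diag(cf[0])
        if np.min(diagL) < 1e-10 * max(1.0, np.max(diagL)):
            raise SingularModelError("mixed model equations are near-singular")
        sol = cho_solve(cf, rhs, check_finite=False)
        return cf, sol, rhs, rinv

    def _loglik(self, s2u, s2e, cf, sol, rhs, rinv):
        logdetC = 2.0 * np.sum(np.log(np.diag(cf[0])))
        logdetR = float(np.dot(self.group_n, np.log(s2e)))
        logdetG = float(np.dot(self.q, np.log(s2u))) if len(s2u) else 0.0
        yPy = float(self.y @ (rinv * self.y) - sol @ rhs)
        return -0.5 * (logdetR + logdetG + logdetC + yPy)

    def _apply_P(self, v, cf, rinv):
        """P v = R^-1 v - R^-1 W C^-1 W' R^-1 v."""
        rv = rinv * v
        t = cho_solve(cf, self.W.T @ rv, check_finite=False)
        return rv - rinv * (self.W @ t)

    def loglik(self, varcomps: dict[str, float] | None = None,
               resid_var=None) -> float:
        """Restricted log-likelihood at user-supplied variance parameters."""
        s2u = np.array([varcomps[name] for name, _ in self.random]) \
            if self.random else np.array([])
        if varcomps is not None and not self.random and varcomps:
            raise ValueError("model has no random terms")
        s2e = np.atleast_1d(np.asarray(resid_var, dtype=float))
        if s2e.size == 1:
            s2e = np.full(self.n_groups, float(s2e[0]))
        cf, sol, rhs, rinv = self._assemble(s2u, s2e)
        return self._loglik(s2u, s2e, cf, sol, rhs, rinv)

    # -- fitting ---------------------------------------------------------
    def fit(self, tol: float = 1e-8, max_iter: int = 200,
            start: dict[str, float] | None = None) -> REMLResult:
        vary = float(np.var(self.y)) or 1.0
        floor = 1e-10 * vary
        pin_val = 1e-8 * vary        # value a boundary component is held at
        pin_trigger = 1e-6 * vary    # below this a component is pinned
        K = len(self.random)
        s2u = np.full(K, vary / max(1, K + 1))
        if start:
            for k, (name, _) in enumerate(self.random):
                if name in start:
                    s2u[k] = max(start[name], floor)
        s2e = np.full(self.n_groups, vary / 2.0)

        cf, sol, rhs, rinv = self._assemble(s2u, s2e)
        ll = self._loglik(s2u, s2e, cf, sol, rhs, rinv)
        active = np.ones(K + self.n_groups, dtype=bool)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            theta = np.concatenate([s2u, s2e])
            score, AI, aux = self._score_ai(s2u, s2e, cf, sol, rhs, rinv)
            # a pinned component whose score turns positive wants mass back
            active |= (~active) & (score > 0)
            new = None
            if it > 2 and active.any():
                ia = np.nonzero(active)[0]
                try:
                    step = np.linalg.solve(AI[np.ix_(ia, ia)], score[ia])
                except np.linalg.LinAlgError:
                    step = None
                if step is not None:
                    lam = 1.0
                    for _ in range(10):
                        cand = theta.copy()
                        cand[ia] = theta[ia] + lam * step
                        low = cand < pin_trigger
                        cand[low] = pin_val
                        try:
                            trial = self._assemble(cand[:K], cand[K:])
                            ll_new = self._loglik(cand[:K], cand[K:], *trial)
                        except SingularModelError:
                            ll_new = -np.inf
                        if ll_new >= ll - 1e-10:
                            new, cf_sol, ll = cand, trial, ll_new
                            active &= ~low
                            break
                        lam *= 0.5
            if new is None:
                cand = self._em_update(s2u, s2e, aux)
                cand[~active] = pin_val
                low = cand < pin_trigger
                cand[low] = pin_val
                active &= ~low
                cand = np.maximum(cand, floor)
                trial = self._assemble(cand[:K], cand[K:])
                ll = self._loglik(cand[:K], cand[K:], *trial)
                new, cf_sol = cand, trial
            s2u, s2e = new[:K], new[K:]
            cf, sol, rhs, rinv = cf_sol
            moved = active & (np.abs(new - theta) > 0)
            rel = (np.max(np.abs(new - theta)[moved]
                          / np.maximum(np.abs(theta[moved]), floor))
                   if moved.any() else 0.0)
            if rel < tol:
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"REML did not converge in {it} iterations (last ll={ll:.6g})")
        return self._package(s2u, s2e, cf, sol, rhs, rinv, ll, converged, it)

    def _blocks(self, vec):
        out, offset = [], self.p
        for qk in self.q:
            out.append(vec[offset:offset + qk])
            offset += qk
        return out

    def _score_ai(self, s2u, s2e, cf, sol, rhs, rinv):
        """REML score and average-information matrix at the current point."""
        K = len(self.random)
        resid = self.y - self.W @ sol
        Py = rinv * resid
        Cinv = _chol_inverse(cf)
        # per-observation quadratic forms w_i' C^-1 w_i for residual traces
        Q = self.W @ Cinv
        wCw = np.asarray(self.W.multiply(Q).sum(axis=1)).ravel()

        u_blocks = self._blocks(sol)
        tr_blocks = self._blocks(np.diag(Cinv))
        score = np.zeros(K + self.n_groups)
        fvecs = []
        for k in range(K):
            qk, s2 = self.q[k], s2u[k]
            trPV = (qk - np.sum(tr_blocks[k]) / s2) / s2
            Zk = self.random[k][1]
            ZtPy = Zk.T @ Py
            yPVPy = float(ZtPy @ ZtPy)
            score[k] = -0.5 * (trPV - yPVPy)
            fvecs.append(Zk @ ZtPy)           # V_k P y
        for j in range(self.n_groups):
            mask = self.resid_groups == j
            s2 = s2e[j]
            trPD = self.group_n[j] / s2 - np.sum(wCw[mask]) / s2 ** 2
            yPDPy = float(np.sum(Py[mask] ** 2))
            score[K + j] = -0.5 * (trPD - yPDPy)
            fv = np.zeros_like(Py)
            fv[mask] = Py[mask]
            fvecs.append(fv)
        # average information: AI_ts = 0.5 f_t' P f_s
        F = np.column_stack(fvecs)
        PF = np.column_stack([self._apply_P(F[:, t], cf, rinv)
                              for t in range(F.shape[1])])
        AI = 0.5 * (F.T @ PF)
        aux = dict(u_blocks=u_blocks, tr_blocks=tr_blocks, wCw=wCw,
                   Py=Py, resid=resid)
        return score, AI, aux

    def _em_update(self, s2u, s2e, aux):
        K = len(self.random)
        new = np.empty(K + self.n_groups)
        for k in range(K):
            uk = aux["u_blocks"][k]
            new[k] = (uk @ uk + np.sum(aux["tr_blocks"][k])) / self.q[k]
        for j in range(self.n_groups):
            mask = self.resid_groups == j
            s2 = s2e[j]
            trPD = self.group_n[j] / s2 - np.sum(aux["wCw"][mask]) / s2 ** 2
            yPDPy = float(np.sum(aux["Py"][mask] ** 2))
            new[K + j] = s2 + s2 ** 2 * (yPDPy - trPD) / self.group_n[j]
        return new

    def _package(self, s2u, s2e, cf, sol, rhs, rinv, ll, converged, it):
        Cinv_x = cho_solve(cf, np.eye(cf[0].shape[0])[:, :self.p],
                           check_finite=False)[:self.p, :]
        beta = sol[:self.p]
        blups = {name: u for (name, _), u in zip(self.random, self._blocks(sol))}
        resid = self.y - self.W @ sol
        std = resid / np.sqrt(s2e[self.resid_groups])
        return REMLResult(
            beta=beta,
            fixed_names=self.fixed_names,
            varcomps={name: float(v) for (name, _), v in zip(self.random, s2u)},
            resid_var=s2e.copy(),
            blups=blups,
            loglik=float(ll),
            converged=converged,
            n_iter=it,
            fixed_cov=0.5 * (Cinv_x + Cinv_x.T),
            residuals=resid,
            std_residuals=std,
            resid_groups=self.resid_groups.copy(),
        )
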