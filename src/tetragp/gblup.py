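"""Additive and additive-dominance GBLUP on adjusted entry means.

Model: y = 1 mu + a (+ d) + e with a ~ N(0, G_A s2_a), d ~ N(0, G_D s2_d),
e ~ N(0, I s2_e), fitted by REML on the training set.  Genetic values of
unphenotyped clones follow from the conditional-expectation identity

    a_VS = s2_a * G_A[VS, TS] V^-1 (y - mu)      (V on the TS block),

which is algebraically the joint mixed-model solution.  Prediction accuracy
is the Pearson correlation between AEMs and GEBVs of the validation set
divided by the square root of the trait heritability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_solve

from .containers import RelationshipMatrix

#: reciprocal-condition-number threshold below which a replicate is canceled
SINGULARITY_RCOND = 1e-12


class SingularReplicateError(RuntimeError):
    """The GBLUP coefficient matrix is numerically singular; cancel the run."""


@dataclass
class GBLUPFit:
    mu: float
    sigma2_a: float
    sigma2_d: float | None
    sigma2_eps: float
    loglik: float
    converged: bool
    ts_ids: pd.Index
    _G_A: RelationshipMatrix = None
    _G_D: RelationshipMatrix | None = None
    _Vinv_r: np.ndarray = None       # V^-1 (y - mu) on the TS block

    def predict(self, ids, components: bool = False):
        """Genetic values for any clones covered by the relationship matrices.

        With dominance in the model the GEBV is the additive plus dominance
        value; ``components=True`` returns ``(a, d)`` separately.
        """
        ids = pd.Index(ids)
        a = self.sigma2_a * (self._G_A.submatrix(ids, self.ts_ids) @ self._Vinv_r)
        d = None
        if self.sigma2_d is not None:
            d = self.sigma2_d * (self._G_D.submatrix(ids, self.ts_ids) @ self._Vinv_r)
        if components:
            return (pd.Series(a, index=ids, name="a"),
                    None if d is None else pd.Series(d, index=ids, name="d"))
        total = a if d is None else a + d
        return pd.Series(total, index=ids, name="gebv")


def _restricted_loglik(y, Gs, s2s, s2e):
    """(loglik, gradient pieces) for V = sum s2_k G_k + s2_e I, X = 1."""
    n = len(y)
    V = s2e * np.eye(n)
    for G, s2 in zip(Gs, s2s):
        V += s2 * G
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise SingularReplicateError("training-set covariance not PD") from exc
    dL = np.diag(L)
    if (dL.min() / dL.max()) ** 2 < SINGULARITY_RCOND:
        raise SingularReplicateError("training-set covariance ill-conditioned")
    Vinv = cho_solve((L, True), np.eye(n), check_finite=False)
    one = np.ones(n)
    Vi1 = Vinv @ one
    denom = float(one @ Vi1)
    mu = float(Vi1 @ y) / denom
    P = Vinv - np.outer(Vi1, Vi1) / denom
    Py = P @ y
    logdetV = 2.0 * np.sum(np.log(np.diag(L)))
    ll = -0.5 * (logdetV + np.log(denom) + float(y @ Py))
    return ll, P, Py, mu, Vinv


def fit_gblup(aems: pd.Series, G_A: RelationshipMatrix,
              G_D: RelationshipMatrix | None = None,
              include_dominance: bool = False,
              max_iter: int = 200) -> GBLUPFit:
    """REML fit of the (additive-)dominance GBLUP model on a training set.

    ``aems`` is indexed by clone id; every id must be present in the
    relationship matrices.  Raises :class:`SingularReplicateError` when the
    covariance is singular (the caller cancels the replicate) and
    ``RuntimeError`` on non-convergence.
    """
    aems = aems.dropna()
    if len(aems) < 10:
        raise ValueError("training set must contain at least 10 clones")
    ts = aems.index
    y = aems.to_numpy(dtype=float)
    mats = [G_A.submatrix(ts, ts)]
    if include_dominance:
        if G_D is None:
            raise ValueError("include_dominance=True requires G_D")
        mats.append(G_D.submatrix(ts, ts))

    vary = float(np.var(y)) or 1.0

    def negll(logtheta):
        theta = np.exp(logtheta)
        s2s, s2e = theta[:-1], theta[-1]
        try:
            ll, P, Py, _mu, _Vinv = _restricted_loglik(y, mats, s2s, s2e)
        except SingularReplicateError:
            # an ill-conditioned point visited during exploration is handled
            # with a diagonal bump to keep the search surface smooth; only
            # singularity at the optimum cancels the run
            bump = 1e-9 * sum(s2 * np.trace(G) / len(y)
                              for s2, G in zip(s2s, mats)) + 1e-12
            try:
                ll, P, Py, _mu, _Vinv = _restricted_loglik(
                    y, mats, s2s, s2e + bump)
            except SingularReplicateError:
                return 1e30, np.zeros_like(theta)
        grad = np.empty_like(theta)
        for k, G in enumerate(mats):
            grad[k] = -0.5 * (np.sum(P * G) - Py @ (G @ Py))
        grad[-1] = -0.5 * (np.trace(P) - Py @ Py)
        return -ll, -grad * theta       # chain rule for log parameters

    x0 = np.log(np.full(len(mats) + 1, vary / (len(mats) + 1)))
    bounds = [(np.log(vary) - 30.0, np.log(vary) + 12.0)] * len(x0)
    res = optimize.minimize(negll, x0, jac=True, method="L-BFGS-B",
                            bounds=bounds,
                            options=dict(maxiter=max_iter, ftol=1e-14,
                                         gtol=1e-10))
    theta = np.exp(res.x)
    s2s, s2e = theta[:-1], theta[-1]
    # a genetic variance at the boundary is truncated to exactly zero so the
    # model with and without that component give identical predictions
    s2s = np.where(s2s < 1e-7 * vary, 0.0, s2s)
    ll, _P, _Py, mu, Vinv = _restricted_loglik(y, mats, s2s, s2e)
    Vinv_r = Vinv @ (y - mu)
    return GBLUPFit(
        mu=mu,
        sigma2_a=float(s2s[0]),
        sigma2_d=float(s2s[1]) if include_dominance else None,
        sigma2_eps=float(s2e),
        loglik=float(ll),
        converged=bool(res.success),
        ts_ids=ts,
        _G_A=G_A,
        _G_D=G_D if include_dominance else None,
        _Vinv_r=Vinv_r,
    )


def gblup_loglik(aems: pd.Series, G_A: RelationshipMatrix, sigma2_a: float,
                 sigma2_eps: float,
                 G_D: RelationshipMatrix | None = None,
                 sigma2_d: float | None = None) -> float:
    """Restricted log-likelihood at user-supplied variance components."""
    ts = aems.dropna().index
    y = aems.dropna().to_numpy(dtype=float)
    mats = [G_A.submatrix(ts, ts)]
    s2s = [sigma2_a]
    if G_D is not None:
        mats.append(G_D.submatrix(ts, ts))
        s2s.append(sigma2_d)
    ll, *_ = _restricted_loglik(y, mats, np.asarray(s2s), sigma2_eps)
    return float(ll)


def prediction_accuracy(gebv: pd.Series, aem: pd.Series, h2: float) -> float:
    """PA = cor(AEM, GEBV) / sqrt(h2) over the validation set.

    Negative values are legitimate; zero variance in either vector makes the
    correlation undefined and returns ``nan``.
    """
    if not (0.0 < h2 <= 1.0):
        raise ValueError("h2 must lie in (0, 1]")
    joined = pd.concat([gebv.rename("g"), aem.rename("y")], axis=1).dropna()
    if len(joined) < 3:
        raise ValueError("need at least 3 validation clones")
    g = joined["g"].to_numpy()
    y = joined["y"].to_numpy()
    if np.std(g) == 0.0 or np.std(y) == 0.0:
        return float("nan")
    r = float(np.corrcoef(g, y)[0, 1])
    return r / float(np.sqrt(h2))


def cv_prediction_accuracy(aems: pd.Series, G_A: RelationshipMatrix, h2: float,
                           folds: np.ndarray,
                           G_D: RelationshipMatrix | None = None,
                           include_dominance: bool = False):
    """PA of one cross-validation replicate.

    ``folds`` assigns each clone of ``aems`` to a fold; each fold serves as
    validation set once.  Returns ``(pa_mean_over_folds, pa_pooled)``; raises
    :class:`SingularReplicateError` if any fold's model is singular.
    """
    aems = aems.dropna()
    folds = np.asarray(folds)
    if folds.shape[0] != len(aems):
        raise ValueError("fold assignment length mismatch")
    pas, pooled_g, pooled_y = [], [], []
    for f in np.unique(folds):
        vs_ids = aems.index[folds == f]
        ts_ids = aems.index[folds != f]
        fit = fit_gblup(aems.loc[ts_ids], G_A, G_D=G_D,
                        include_dominance=include_dominance)
        gebv = fit.predict(vs_ids)
        pas.append(prediction_accuracy(gebv, aems.loc[vs_ids], h2))
        pooled_g.append(gebv)
        pooled_y.append(aems.loc[vs_ids])
    pooled = prediction_accuracy(pd.concat(pooled_g), pd.concat(pooled_y), h2)
    return float(np.nanmean(pas)), float(pooled)


def compare_models(aems: pd.DataFrame, h2: pd.Series,
                   G_A: RelationshipMatrix, G_D: RelationshipMatrix,
                   cv_plan: list[np.ndarray]):
    """Additive vs additive-dominance GBLUP on identical folds.

    ``cv_plan`` holds one fold assignment per replicate (aligned with the
    rows of ``aems``).  Returns a long table of paired per-replicate PAs and
    a per-trait frame with Bonferroni-corrected paired-t p-values:
    ``p_bonferroni`` (two-sided difference) and ``p_improvement`` (one-sided,
    dominance model better), the direction in which the scientific question
    is asked.
    """
    rows = []
    for trait in aems.columns:
        y = aems[trait]
        for rep, folds in enumerate(cv_plan):
            fmask = folds[~y.isna().to_numpy()] if y.isna().any() else folds
            pa_a, _ = cv_prediction_accuracy(y, G_A, h2[trait], fmask)
            pa_ad, _ = cv_prediction_accuracy(y, G_A, h2[trait], fmask,
                                              G_D=G_D, include_dominance=True)
            rows.append(dict(trait=trait, replicate=rep,
                             pa_additive=pa_a, pa_add_dom=pa_ad))
    table = pd.DataFrame(rows)
    pvals = {}
    n_traits = aems.shape[1]
    for trait, grp in table.groupby("trait"):
        d = grp["pa_add_dom"].to_numpy() - grp["pa_additive"].to_numpy()
        # differences below numerical resolution are exact ties
        d = np.where(np.abs(d) < 1e-6, 0.0, d)
        if np.allclose(d, 0.0):
            p2, p1 = 1.0, 1.0
        else:
            res = stats.ttest_1samp(d, 0.0)
            p2 = float(res.pvalue)
            p1 = float(stats.ttest_1samp(d, 0.0,
                                         alternative="greater").pvalue)
        pvals[trait] = dict(p_bonferroni=min(1.0, p2 * n_traits),
                            p_improvement=min(1.0, p1 * n_traits),
                            mean_diff=float(np.mean(d)))
    return table, pd.DataFrame(pvals).T
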