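"""Plot-level corrections, adjusted entry means, and heritability.

The workflow mirrors routine analysis of augmented potato trials: raw yield
is normalised to a 16-plant plot, check-based corrections remove trial and
block shifts, a mixed model with fixed clone effects and random environment,
check-by-environment, block, row and column effects (heterogeneous residual
variance per environment) yields adjusted entry means (AEMs), and entry-mean
heritability is h2 = s2_g / (s2_g + nu/2) with nu the mean variance of a
difference of two adjusted means.

Expected plot-table columns: ``clone, env, trial, block, row, col, is_check``
plus one column per trait.  Block, row and column identifiers are local to
their parent (block within environment, row/column within block).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reml import MixedModel, REMLResult, indicator_matrix

PLOT_COLUMNS = ("clone", "env", "trial", "block", "row", "col", "is_check")


def normalize_yield(yld_raw, pn, mp):
    """Normalise raw plot yield (kg) to a 16-plant plot.

    Missing plants are only subtracted from the planted count when they
    exceed 20% of it; below that the remaining plants are assumed to
    compensate fully.  Vectorised over array inputs.
    """
    yld_raw = np.asarray(yld_raw, dtype=float)
    pn = np.asarray(pn, dtype=float)
    mp = np.asarray(mp, dtype=float)
    if np.any(pn <= 0) or np.any(mp < 0) or np.any(mp > pn):
        raise ValueError("require PN > 0 and 0 <= MP <= PN")
    denom = np.where(mp > 0.2 * pn, pn - mp, pn)
    if np.any(denom <= 0):
        raise ValueError("plot with no surviving plants after correction")
    out = yld_raw / denom * 16.0
    return float(out) if out.ndim == 0 else out


def correct_nuisance_split(table: pd.DataFrame, grouping: str, trait: str,
                           within: str = "env") -> pd.DataFrame:
    """Check-based correction for trial or block shifts.

    For every environment, check means are computed per group (trial or
    block).  With exactly two groups the absolute check-mean difference is
    subtracted from every observation of the higher-mean group; with more
    groups each one is aligned down to the minimum check mean.  A group
    without check observations is an error.
    """
    if grouping not in ("trial", "block"):
        raise ValueError("grouping must be 'trial' or 'block'")
    out = table.copy()
    for env, sub in table.groupby(within, sort=False):
        groups = sub[grouping].unique()
        if len(groups) < 2:
            continue
        means = {}
        for g in groups:
            chk = sub[(sub[grouping] == g) & sub["is_check"]][trait].dropna()
            if chk.empty:
                raise ValueError(
                    f"{grouping} {g!r} in {within} {env!r} has no check data "
                    f"for trait {trait!r}")
            means[g] = chk.mean()
        anchor = min(means.values())
        for g in groups:
            offset = means[g] - anchor
            if offset > 0:
                mask = (out[within] == env) & (out[grouping] == g)
                out.loc[mask, trait] = out.loc[mask, trait] - offset
    return out


@dataclass
class FieldModelFit:
    """A fitted plot-level mixed model plus the bookkeeping to use it."""

    result: REMLResult
    trait: str
    clones: pd.Index                 # fixed-effect clone order (model 2)
    plot_index: pd.Index             # rows of the table that entered the fit
    entry_clones: pd.Index           # clones that are entries (not checks)
    model: str                       # "model2" | "model3"

    @property
    def loglik(self) -> float:
        return self.result.loglik

    @property
    def converged(self) -> bool:
        return self.result.converged


def _nuisance_terms(table: pd.DataFrame, include_block: bool = True):
    """Random-effect design matrices for env / check-x-env / block / row / col."""
    env = table["env"].astype(str)
    blk = env + "|" + table["block"].astype(str)
    row = blk + "|r" + table["row"].astype(str)
    col = blk + "|c" + table["col"].astype(str)
    terms = [("env", _codes_matrix(env))]
    # genotype-x-environment deviations, estimable for replicated checks only
    ge_label = np.where(table["is_check"],
                        table["clone"].astype(str) + "@" + env, None)
    ge_codes = pd.factorize(pd.Series(ge_label, index=table.index))[0]
    terms.append(("check_ge", indicator_matrix(ge_codes)))
    if include_block:
        terms.append(("block", _codes_matrix(blk)))
    terms.append(("row", _codes_matrix(row)))
    terms.append(("col", _codes_matrix(col)))
    return terms


def _codes_matrix(labels: pd.Series):
    codes, _ = pd.factorize(labels)
    return indicator_matrix(codes)


def _env_codes(table: pd.DataFrame):
    codes, levels = pd.factorize(table["env"])
    return codes, list(levels)


def fit_model2(table: pd.DataFrame, trait: str, include_block: bool = True,
               **fit_kw) -> FieldModelFit:
    """Fixed-clone mixed model for outlier screening, AEMs and their variances.

    Clone effects (absorbing the intercept) are fixed; environment,
    check-by-environment, block, row and column effects are random; residual
    variance is heterogeneous across environments.  Raises
    ``SingularModelError`` for singular designs and ``ConvergenceError``
    when REML stalls.
    """
    sub = table.dropna(subset=[trait])
    if sub.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    y = sub[trait].to_numpy(dtype=float)
    clone_codes, clone_levels = pd.factorize(sub["clone"])
    X = indicator_matrix(clone_codes)
    terms = _nuisance_terms(sub, include_block=include_block)
    resid_codes, _ = _env_codes(sub)
    mm = MixedModel(y, X, terms, resid_groups=resid_codes,
                    fixed_names=list(clone_levels))
    res = mm.fit(**fit_kw)
    checks = set(sub.loc[sub["is_check"], "clone"])
    entries = pd.Index([c for c in clone_levels if c not in checks])
    return FieldModelFit(result=res, trait=trait, clones=pd.Index(clone_levels),
                         plot_index=sub.index, entry_clones=entries,
                         model="model2")


def fit_model3(table: pd.DataFrame, trait: str, **fit_kw) -> FieldModelFit:
    """Variance-component model with fixed checks and random entries.

    The clone effect is split by the check/entry indicator: check effects
    (plus the intercept) are fixed while entry effects are a random
    component whose variance is the genotypic variance of the entries.
    """
    sub = table.dropna(subset=[trait])
    y = sub[trait].to_numpy(dtype=float)
    is_check = sub["is_check"].to_numpy(bool)
    check_labels = pd.Series(np.where(is_check, sub["clone"], None),
                             index=sub.index)
    check_codes, check_levels = pd.factorize(check_labels)
    import scipy.sparse as sp
    X = sp.hstack([sp.csr_matrix(np.ones((len(sub), 1))),
                   indicator_matrix(check_codes)]).tocsr()
    entry_labels = pd.Series(np.where(~is_check, sub["clone"], None),
                             index=sub.index)
    entry_codes, entry_levels = pd.factorize(entry_labels)
    terms = [("entry", indicator_matrix(entry_codes))]
    terms += _nuisance_terms(sub)
    resid_codes, _ = _env_codes(sub)
    mm = MixedModel(y, X, terms, resid_groups=resid_codes,
                    fixed_names=["mu"] + [str(c) for c in check_levels])
    res = mm.fit(**fit_kw)
    return FieldModelFit(result=res, trait=trait,
                         clones=pd.Index(list(check_levels)),
                         plot_index=sub.index,
                         entry_clones=pd.Index(list(entry_levels)),
                         model="model3")


def detect_outliers(fit: FieldModelFit, threshold: float = 3.5) -> pd.Index:
    """Plots whose absolute standardized residual strictly exceeds ``threshold``."""
    std = np.abs(fit.result.std_residuals)
    return fit.plot_index[std > threshold]


def lrt_block_effect(table: pd.DataFrame, trait: str, alpha: float = 0.05,
                     full_fit: FieldModelFit | None = None, **fit_kw):
    """Likelihood-ratio test for the block variance component.

    The null distribution for a variance tested at the boundary is the
    0.5*chi2_0 + 0.5*chi2_1 mixture.  Returns ``(significant, p_value,
    statistic, full_fit)`` so the full fit can be reused; a pre-computed
    full fit on the same data can be passed in.
    """
    full = full_fit if full_fit is not None else fit_model2(
        table, trait, include_block=True, **fit_kw)
    reduced = fit_model2(table, trait, include_block=False, **fit_kw)
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = 1.0 if stat == 0.0 else 0.5 * stats.chi2.sf(stat, df=1)
    return p < alpha, float(p), float(stat), full


def adjusted_entry_means(fit: FieldModelFit) -> pd.Series:
    """AEM per clone: the BLUE of the clone effect across environments."""
    if fit.model != "model2":
        raise ValueError("AEMs come from the fixed-clone model")
    return pd.Series(fit.result.beta, index=fit.clones, name=fit.trait)


def mean_variance_of_difference(fit: FieldModelFit) -> float:
    """Exact mean over all entry pairs of Var(AEM_i - AEM_k).

    Uses the closed form  nu = 2 [ (n-1) tr(C) - (1'C1 - tr(C)) ] / (n(n-1))
    on the entry block C of the fixed-effect covariance, which equals the
    average of C_ii + C_kk - 2 C_ik over unordered pairs.
    """
    idx = fit.clones.get_indexer(fit.entry_clones)
    C = fit.result.fixed_cov[np.ix_(idx, idx)]
    n = C.shape[0]
    if n < 2:
        raise ValueError("need at least two entries for a difference variance")
    tr = float(np.trace(C))
    s = float(C.sum())
    return 2.0 * ((n - 1) * tr - (s - tr)) / (n * (n - 1))


def heritability(sigma_g2: float, nu_hat: float) -> float:
    """Entry-mean heritability h2 = s2_g / (s2_g + nu/2)."""
    if sigma_g2 < 0 or nu_hat < 0:
        raise ValueError("variance inputs must be nonnegative")
    if sigma_g2 == 0:
        return 0.0
    if nu_hat == 0:
        return 1.0
    return sigma_g2 / (sigma_g2 + nu_hat / 2.0)


@dataclass
class TraitAdjustment:
    """Full adjustment result for one trait."""

    aems: pd.Series
    h2: float
    sigma_g2: float
    nu_hat: float
    n_outliers: int
    block_corrected: bool
    block_lrt_p: float
    fit2: FieldModelFit
    fit3: FieldModelFit


def adjust_trait(table: pd.DataFrame, trait: str, alpha: float = 0.05,
                 outlier_sd: float = 3.5, **fit_kw) -> TraitAdjustment:
    """Run the fixed adjustment pipeline for one trait.

    Order: trial correction -> model-2 fit -> outlier removal -> block LRT
    and (if significant) check-based block correction -> refit for AEMs and
    the mean variance of a difference -> entry-variance model -> h2.
    """
    work = table.dropna(subset=[trait]).copy()
    has_trials = work.groupby("env")["trial"].nunique().max() > 1
    if has_trials:
        work = correct_nuisance_split(work, "trial", trait)
    fit = fit_model2(work, trait, **fit_kw)
    bad = detect_outliers(fit, threshold=outlier_sd)
    if len(bad):
        work = work.drop(index=bad)
        fit = fit_model2(work, trait, **fit_kw)
    significant, p, _stat, fit = lrt_block_effect(work, trait, alpha=alpha,
                                                  full_fit=fit, **fit_kw)
    if significant:
        work = correct_nuisance_split(work, "block", trait)
        fit = fit_model2(work, trait, **fit_kw)
    aems = adjusted_entry_means(fit)
    nu = mean_variance_of_difference(fit)
    start3 = dict(fit.result.varcomps)
    start3["entry"] = fit.result.beta_series().loc[
        list(fit.entry_clones)].var() if len(fit.entry_clones) > 1 else None
    start3 = {k: v for k, v in start3.items() if v is not None}
    fit3 = fit_model3(work, trait, start=start3, **fit_kw)
    s2g = fit3.result.varcomps["entry"]
    return TraitAdjustment(aems=aems, h2=heritability(s2g, nu), sigma_g2=s2g,
                           nu_hat=nu, n_outliers=len(bad),
                           block_corrected=bool(significant), block_lrt_p=p,
                           fit2=fit, fit3=fit3)


def adjust_all_traits(table: pd.DataFrame, traits: list[str],
                      **kw) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adjust every trait; returns (AEM table clones x traits, per-trait stats)."""
    aems, rows = {}, []
    for trait in traits:
        adj = adjust_trait(table, trait, **kw)
        aems[trait] = adj.aems
        rows.append(dict(trait=trait, h2=adj.h2, sigma_g2=adj.sigma_g2,
                         nu_hat=adj.nu_hat, n_outliers=adj.n_outliers,
                         block_corrected=adj.block_corrected))
    return pd.DataFrame(aems), pd.DataFrame(rows).set_index("trait")
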