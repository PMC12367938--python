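"""Self-contained verification experiments for the pipeline.

Each function sets up a small simulated study, runs the relevant part of
the package, and returns the measured quantities.  They are shared by the
test suite and by ``scripts/acceptance.py`` so that every reported number
is recomputed from scratch at run time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import DosagePanel, RelationshipMatrix
from .diversity import (HE_MAX_BIALLELIC, expected_heterozygosity, global_fst,
                        qst)
from .field_models import adjust_trait, detect_outliers, fit_model2
from .gblup import cv_prediction_accuracy, fit_gblup, gblup_loglik
from .genotype_qc import additive_grm, dominance_grm
from .scenarios import truncation_scenario
from .simdata import (LayoutSpec, SimConfig, TraitSpec, TruthSet,
                      simulate_genetic_values, simulate_population,
                      simulate_trials)

#: published variance components between (s2_m) and within (s2_m(c)) market
#: segments for 24 traits of a commercial European tetraploid potato panel;
#: used as worked-example inputs for the Q_ST statistic.
SEGMENT_VARIANCE_COMPONENTS = {
    "STA": (5.06, 1.76),   # starch content
    "SHL": (1.17, 0.57),   # tuber shape (longitudinal)
    "PPO": (1.81, 2.02),   # polyphenol oxidase activity
    "BRU": (438.38, 241.19),  # bruising susceptibility
    "FLE": (0.16, 0.40),   # flesh colour
    "EYE": (0.41, 0.39),   # eye depth
    "YLD": (1.58, 9.42),   # total tuber yield
}


def _child_seed(seed: int, k: int) -> int:
    return (seed * 100003 + k * 7919 + 1) % (2 ** 31 - 1)


# ---------------------------------------------------------------------------
# worked examples and algebraic oracles
# ---------------------------------------------------------------------------


def qst_worked_examples() -> dict[str, float]:
    """Q_ST from the published between/within segment variance components."""
    return {t: qst(vm, vmc)
            for t, (vm, vmc) in SEGMENT_VARIANCE_COMPONENTS.items()}


def _random_panel(rng, n_clones: int, n_markers: int,
                  groups: int = 1) -> DosagePanel:
    p = rng.uniform(0.1, 0.9, size=n_markers)
    dosage = rng.binomial(4, p, size=(n_clones, n_markers)).astype(float)
    ids = pd.Index([f"C{i:04d}" for i in range(n_clones)], name="clone")
    cols = pd.Index([f"M{j:05d}" for j in range(n_markers)], name="marker")
    mm = pd.DataFrame({"chrom": "chr01", "pos": np.arange(1, n_markers + 1)},
                      index=cols)
    meta = pd.DataFrame(index=ids)
    if groups > 1:
        meta["segment"] = [f"G{i % groups}" for i in range(n_clones)]
    return DosagePanel(pd.DataFrame(dosage, index=ids, columns=cols), mm, meta)


def gblup_rr_equivalence(seed: int = 1, n_clones: int = 25,
                         n_markers: int = 40, n_ts: int = 18) -> float:
    """Max |GEBV difference| between GBLUP and ridge marker predictions.

    Both routes share the centred dosage matrix W and the VanRaden
    denominator; the ridge penalty is lambda = c * s2_eps / s2_a at the
    REML estimates, which makes the two predictors algebraically identical.
    """
    rng = np.random.default_rng(seed)
    panel = _random_panel(rng, n_clones, n_markers)
    G = additive_grm(panel.dosage)
    M = panel.dosage.to_numpy()
    p = M.mean(axis=0) / 4.0
    W = M - 4.0 * p
    c = 4.0 * np.sum(p * (1 - p))
    alpha = rng.normal(0, 0.2, n_markers)
    y = pd.Series(W @ alpha + rng.normal(0, 2.0, n_clones), index=panel.clones)

    ts = panel.clones[:n_ts]
    fit = fit_gblup(y.loc[ts], G)
    gebv = fit.predict(panel.clones)

    # ridge marker-effect BLUP in its kernel form (numerically stable for
    # m > n): m_hat = W_ts' (W_ts W_ts' + lam I)^-1 r with lam = c s2e/s2a
    W_ts = W[:n_ts]
    lam = c * fit.sigma2_eps / fit.sigma2_a
    r = y.loc[ts].to_numpy() - fit.mu
    m_hat = W_ts.T @ np.linalg.solve(W_ts @ W_ts.T + lam * np.eye(n_ts), r)
    rr = W @ m_hat
    return float(np.max(np.abs(gebv.to_numpy() - rr)))


def reml_grid_margin(seed: int = 1, n_clones: int = 30, n_markers: int = 60,
                     grid_size: int = 15) -> float:
    """Smallest margin of the REML optimum over a variance-component grid.

    Returns min over the grid of (loglik at optimum - loglik at grid point);
    a correct optimiser gives a nonnegative value.
    """
    rng = np.random.default_rng(seed)
    panel = _random_panel(rng, n_clones, n_markers)
    G = additive_grm(panel.dosage)
    L = np.linalg.cholesky(G.values + 1e-8 * np.eye(n_clones))
    y = pd.Series(2.0 + L @ rng.normal(0, 1.0, n_clones)
                  + rng.normal(0, 0.7, n_clones), index=panel.clones)
    fit = fit_gblup(y, G)
    vary = float(np.var(y))
    grid = vary * np.logspace(-2, 1, grid_size)
    margin = np.inf
    for s2a in grid:
        for s2e in grid:
            ll = gblup_loglik(y, G, s2a, s2e)
            margin = min(margin, fit.loglik - ll)
    return float(margin)


# ---------------------------------------------------------------------------
# field-model experiments
# ---------------------------------------------------------------------------


def _pipeline_config(seed: int, n_families: int, trait: TraitSpec,
                     envs: int = 2, blocks: int = 4,
                     n_markers: int = 400) -> SimConfig:
    return SimConfig(
        seed=seed, n_families=n_families, n_markers=n_markers,
        n_chromosomes=4, n_qtl_per_trait=80, n_founders=40,
        company_labels=("B1",), trait_specs=[trait],
        layout=LayoutSpec(envs_per_company=envs, blocks_per_env=blocks,
                          check_reps_per_env=max(8, blocks)),
    )


def _trimmed_trial_data(cfg: SimConfig, n_entries: int):
    """Panel limited to ``n_entries`` entries (plus checks) with trials."""
    panel, _f, _p = simulate_population(cfg)
    meta = panel.clone_meta
    entries = meta.index[~meta["is_check"]][:n_entries]
    keep = entries.union(meta.index[meta["is_check"]], sort=False)
    panel = panel.subset_clones(keep)
    rng = np.random.default_rng(cfg.seed + 1)
    spec = cfg.trait_specs[0]
    truth = TruthSet(traits={spec.name: simulate_genetic_values(
        panel, spec, rng, n_qtl=cfg.n_qtl_per_trait)})
    plots = simulate_trials(panel, truth, cfg, rng)
    return panel, truth, plots


def h2_recovery(seed: int = 1, n_seeds: int = 20, n_entries: int = 800,
                target_h2: float = 0.80) -> dict:
    """Mean entry-mean heritability recovered by the adjustment pipeline.

    Each seed simulates a fresh population of ``n_entries`` unreplicated
    entries (plus replicated checks) in two environments, runs the full
    adjustment pipeline, and records the h2 estimate.
    """
    spec = TraitSpec(name="T", scale="kg", target_h2=target_h2,
                     additive_var=2.0, gxe_var=0.0, env_var=1.0,
                     block_var=0.05, row_var=0.02, col_var=0.02)
    n_fam = int(np.ceil(n_entries / 5.5))
    estimates = []
    for k in range(n_seeds):
        cfg = _pipeline_config(_child_seed(seed, k), n_fam, spec)
        _panel, _truth, plots = _trimmed_trial_data(cfg, n_entries)
        adj = adjust_trait(plots, "T", tol=1e-6)
        estimates.append(adj.h2)
    return dict(mean_h2=float(np.mean(estimates)),
                estimates=[float(h) for h in estimates],
                target=target_h2, n_entries=n_entries)


def outlier_flagging(seed: int = 1, n_seeds: int = 100,
                     n_entries: int = 120, shift_sd: float = 10.0) -> dict:
    """Detection rate for a planted ``shift_sd``-SD contaminant plot.

    Entries are observed in four environments so the fixed clone effect
    absorbs only a quarter of the contamination, as in a multi-environment
    trial series.
    """
    spec = TraitSpec(name="T", scale="kg", target_h2=0.75, additive_var=1.5,
                     env_var=0.8, block_var=0.05, row_var=0.02, col_var=0.02)
    hits = 0
    for k in range(n_seeds):
        cfg = _pipeline_config(_child_seed(seed, 500 + k),
                               int(np.ceil(n_entries / 5.5)), spec, envs=4)
        _panel, _truth, plots = _trimmed_trial_data(cfg, n_entries)
        rng = np.random.default_rng(_child_seed(seed, 900 + k))
        i = int(rng.integers(len(plots)))
        env = plots.iloc[i]["env"]
        resid_sd = float(np.sqrt(spec.resolve_resid_vars(
            cfg.layout.envs_per_company)[int(env.split("_E")[1]) - 1]))
        plots.loc[plots.index[i], "T"] += shift_sd * resid_sd
        fit = fit_model2(plots, "T", tol=1e-6)
        if plots.index[i] in detect_outliers(fit, threshold=3.5):
            hits += 1
    return dict(flag_rate=hits / n_seeds, n_seeds=n_seeds)


# ---------------------------------------------------------------------------
# GBLUP scenario experiments on simulated AEMs
# ---------------------------------------------------------------------------


def simulate_aem_panel(seed: int, n_clones: int = 1000, n_markers: int = 600,
                       h2: float = 0.8, additive_var: float = 2.0,
                       dominance_var: float = 0.0):
    """A clone panel with AEMs drawn as genetic value plus entry-mean noise.

    The noise variance is chosen so the entry-mean heritability is exactly
    ``h2``: Var(e) = Var(g) (1 - h2)/h2.  This bypasses the plot-level
    pipeline, which is exercised separately, and keeps scenario experiments
    fast.
    """
    n_fam = max(10, int(np.ceil(n_clones / 5.5)))
    spec = TraitSpec(name="T", scale="kg", target_h2=h2,
                     additive_var=additive_var, dominance_var=dominance_var)
    cfg = SimConfig(seed=seed, n_families=n_fam, n_markers=n_markers,
                    n_chromosomes=6, n_qtl_per_trait=120, n_founders=50,
                    trait_specs=[spec],
                    layout=LayoutSpec(envs_per_company=2, blocks_per_env=4))
    from .genotype_qc import filter_markers

    panel, _f, _p = simulate_population(cfg)
    entries = panel.clone_meta.index[~panel.clone_meta["is_check"]][:n_clones]
    panel = panel.subset_clones(entries)
    panel, _report = filter_markers(panel)
    rng = np.random.default_rng(seed + 13)
    tt = simulate_genetic_values(panel, spec, rng, n_qtl=cfg.n_qtl_per_trait)
    g = tt.genetic_values
    noise_var = float(np.var(g)) * (1.0 - h2) / h2
    aems = g + rng.normal(0.0, np.sqrt(noise_var), len(g))
    return panel, pd.DataFrame({"T": aems}), pd.Series({"T": h2}), tt


def truncation_selection_effect(seed: int = 1, n_clones: int = 1000,
                                ts_size: int = 200, reps: int = 50) -> dict:
    """Truncation selection in the TS: PA decline and replacement recovery.

    Measures median PA at x = 70, 50, 30 (top-x% pools, no replacement) and
    compares random vs bottom-10% replacement of 20% of a top-30% TS.
    """
    panel, aems, h2, _tt = simulate_aem_panel(seed, n_clones=n_clones)
    G = additive_grm(panel.dosage)
    rng = np.random.default_rng(seed + 101)
    res0 = truncation_scenario(panel, aems, h2, G, "T",
                               x_grid=(30, 50, 70), y_grid=(0,),
                               ts_size=ts_size, reps=reps, rng=rng)
    med0 = res0.records.groupby("x")["pa"].median()
    rng_r = np.random.default_rng(seed + 102)
    res_rand = truncation_scenario(panel, aems, h2, G, "T", x_grid=(30,),
                                   y_grid=(20,), replacement="random",
                                   ts_size=ts_size, reps=reps, rng=rng_r)
    rng_b = np.random.default_rng(seed + 103)
    res_bot = truncation_scenario(panel, aems, h2, G, "T", x_grid=(30,),
                                  y_grid=(20,), replacement="bottom10",
                                  ts_size=ts_size, reps=reps, rng=rng_b)
    return dict(
        median_pa_x70=float(med0.loc[70]),
        median_pa_x50=float(med0.loc[50]),
        median_pa_x30=float(med0.loc[30]),
        median_pa_x30_y20_random=float(res_rand.records["pa"].median()),
        median_pa_x30_y20_bottom10=float(res_bot.records["pa"].median()),
        n_canceled=res0.n_canceled + res_rand.n_canceled + res_bot.n_canceled,
    )


def dominance_null_rate(seed: int = 1, n_runs: int = 20, n_clones: int = 150,
                        n_markers: int = 400, reps: int = 10,
                        alpha: float = 0.05) -> dict:
    """Fraction of runs where dominance brings no significant improvement.

    The simulated trait is purely additive, so the one-sided paired t test
    for an improvement of the additive-dominance over the additive model
    (the direction the scientific claim is stated in) should rarely reject.
    """
    from .gblup import compare_models
    from .genotype_qc import impute_median_classes
    from .scenarios import kfold_cv

    nonsig = 0
    for k in range(n_runs):
        s = _child_seed(seed, 300 + k)
        panel, aems, h2, _tt = simulate_aem_panel(
            s, n_clones=n_clones, n_markers=n_markers, h2=0.7,
            dominance_var=0.0)
        G_A = additive_grm(panel.dosage)
        G_D = dominance_grm(impute_median_classes(panel))
        rng = np.random.default_rng(s + 7)
        plan = kfold_cv(aems.index, k=5, reps=reps, rng=rng)
        _table, pvals = compare_models(aems, h2, G_A, G_D, plan)
        if pvals.loc["T", "p_improvement"] >= alpha:
            nonsig += 1
    return dict(nonsignificant_fraction=nonsig / n_runs, n_runs=n_runs)


def diversity_bounds_sweep(seed: int = 1, n_sweeps: int = 30) -> dict:
    """He and F_ST over randomized panels, plus the fixed-alternate extreme."""
    rng = np.random.default_rng(seed)
    he_min, he_max = np.inf, -np.inf
    fst_min, fst_max = np.inf, -np.inf
    for _ in range(n_sweeps):
        n = int(rng.integers(10, 60))
        m = int(rng.integers(20, 200))
        panel = _random_panel(rng, n, m, groups=int(rng.integers(2, 5)))
        he = expected_heterozygosity(panel.dosage)
        fst = global_fst(panel, "segment")
        he_min, he_max = min(he_min, he), max(he_max, he)
        fst_min, fst_max = min(fst_min, fst), max(fst_max, fst)
    # two groups fixed for alternate alleles: H_s = 0, H_t = 0.875
    ids = pd.Index([f"C{i}" for i in range(8)], name="clone")
    cols = pd.Index([f"M{j}" for j in range(20)], name="marker")
    dosage = pd.DataFrame(np.r_[np.full((4, 20), 4.0), np.zeros((4, 20))],
                          index=ids, columns=cols)
    mm = pd.DataFrame({"chrom": "chr01", "pos": np.arange(1, 21)}, index=cols)
    meta = pd.DataFrame({"segment": ["A"] * 4 + ["B"] * 4}, index=ids)
    fixed_panel = DosagePanel(dosage, mm, meta)
    return dict(he_min=float(he_min), he_max=float(he_max),
                fst_min=float(fst_min), fst_max=float(fst_max),
                he_bound=HE_MAX_BIALLELIC,
                fst_fixed_alternate=float(global_fst(fixed_panel, "segment")),
                n_sweeps=n_sweeps)
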