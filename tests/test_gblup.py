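"""GBLUP engine: REML, prediction identities, PA, model comparison."""

import numpy as np
import pandas as pd
import pytest

from tetragp.experiments import (_random_panel, gblup_rr_equivalence,
                                 reml_grid_margin, simulate_aem_panel)
from tetragp.gblup import (SingularReplicateError, compare_models,
                           cv_prediction_accuracy, fit_gblup, gblup_loglik,
                           prediction_accuracy)
from tetragp.genotype_qc import (additive_grm, dominance_grm,
                                 impute_median_classes)
from tetragp.scenarios import kfold_cv


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(10)
    panel = _random_panel(rng, 40, 80)
    G = additive_grm(panel.dosage)
    L = np.linalg.cholesky(G.values + 1e-8 * np.eye(40))
    y = pd.Series(3.0 + L @ rng.normal(0, 1.2, 40)
                  + rng.normal(0, 0.8, 40), index=panel.clones)
    return panel, G, y


def test_constant_response_gives_zero_signal(toy):
    panel, G, _y = toy
    y = pd.Series(5.0, index=panel.clones)
    fit = fit_gblup(y, G)
    assert fit.sigma2_a == 0.0
    gebv = fit.predict(panel.clones)
    np.testing.assert_allclose(gebv.to_numpy(), 0.0, atol=1e-8)


def test_gblup_equals_ridge_marker_predictions():
    """GEBVs equal ridge marker-effect predictions to 1e-8."""
    assert gblup_rr_equivalence(seed=1) < 1e-8


def test_reml_optimum_beats_variance_grid():
    assert reml_grid_margin(seed=1) >= -1e-6


def test_gebv_invariant_to_grm_rescaling(toy):
    panel, G, y = toy
    from tetragp.containers import RelationshipMatrix
    G5 = RelationshipMatrix(G.labels, G.values * 5.0, "additive")
    f1 = fit_gblup(y.iloc[:30], G)
    f2 = fit_gblup(y.iloc[:30], G5)
    p1 = f1.predict(panel.clones[30:])
    p2 = f2.predict(panel.clones[30:])
    np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), atol=2e-4)
    # REML rescales the additive variance by the same factor
    assert f2.sigma2_a * 5.0 == pytest.approx(f1.sigma2_a, rel=0.01)


def test_conditional_identity_matches_joint_equations(toy):
    """a_VS = G[VS,TS] G[TS,TS]^-1 a_TS reproduces fit.predict."""
    panel, G, y = toy
    ts, vs = panel.clones[:30], panel.clones[30:]
    fit = fit_gblup(y.loc[ts], G)
    a_ts = fit.predict(ts).to_numpy()
    G_ts = G.submatrix(ts, ts)
    a_vs = G.submatrix(vs, ts) @ np.linalg.solve(G_ts, a_ts)
    np.testing.assert_allclose(fit.predict(vs).to_numpy(), a_vs, atol=1e-7)


def test_prediction_accuracy_values():
    y = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
    assert prediction_accuracy(y, y, 1.0) == pytest.approx(1.0)
    assert prediction_accuracy(-y, y, 1.0) == pytest.approx(-1.0)
    # cor = 0.5, h2 = 0.25 -> PA = 1.0
    rng = np.random.default_rng(0)
    a = pd.Series(rng.normal(size=2000))
    b = 0.5 * (a - a.mean()) / a.std() + np.sqrt(0.75) * pd.Series(
        rng.normal(size=2000))
    r = np.corrcoef(a, b)[0, 1]
    assert prediction_accuracy(a, b, 0.25) == pytest.approx(r / 0.5)
    assert np.isnan(prediction_accuracy(
        pd.Series([1.0, 1.0, 1.0], index=list("abc")), y.iloc[:3], 1.0))
    with pytest.raises(ValueError):
        prediction_accuracy(y, y, 0.0)
    with pytest.raises(ValueError):
        prediction_accuracy(y.iloc[:2], y.iloc[:2], 1.0)


def test_training_set_minimum_size(toy):
    panel, G, y = toy
    with pytest.raises(ValueError):
        fit_gblup(y.iloc[:5], G)


def test_singularity_cancels_replicate():
    """Duplicated clones with a noiseless response drive s2_eps to zero and
    leave a singular covariance at the optimum: the replicate cancels."""
    rng = np.random.default_rng(44)
    panel = _random_panel(rng, 30, 60)
    d = panel.dosage.copy()
    d.iloc[1] = d.iloc[0]                  # identical genotype rows
    G = additive_grm(d)
    L = np.linalg.cholesky(G.values + 1e-10 * np.eye(30))
    y = pd.Series(L @ rng.normal(0, 1.0, 30), index=panel.clones)
    y.iloc[1] = y.iloc[0]
    with pytest.raises(SingularReplicateError):
        fit_gblup(y, G)


def test_loglik_evaluator_matches_fit(toy):
    panel, G, y = toy
    fit = fit_gblup(y, G)
    ll = gblup_loglik(y, G, fit.sigma2_a, fit.sigma2_eps)
    assert ll == pytest.approx(fit.loglik, abs=1e-6)


def test_within_sample_correlation_high_heritability(toy):
    """With strong signal and TS = everyone, GEBVs track the response."""
    panel, G, _ = toy
    rng = np.random.default_rng(3)
    L = np.linalg.cholesky(G.values + 1e-8 * np.eye(40))
    y = pd.Series(L @ rng.normal(0, 2.0, 40) + rng.normal(0, 0.05, 40),
                  index=panel.clones)
    fit = fit_gblup(y, G)
    r = np.corrcoef(fit.predict(panel.clones), y)[0, 1]
    assert r > 0.99


def test_parameter_recovery_variance_ratio():
    """Median REML ratio s2_a/s2_e within 25% of truth (= 4) at n = 500."""
    ratios = []
    for s in range(3):
        rng = np.random.default_rng(100 + s)
        panel = _random_panel(rng, 500, 300)
        G = additive_grm(panel.dosage)
        L = np.linalg.cholesky(G.values + 1e-8 * np.eye(500))
        y = pd.Series(L @ rng.normal(0, 2.0, 500)
                      + rng.normal(0, 1.0, 500), index=panel.clones)
        fit = fit_gblup(y, G)
        ratios.append(fit.sigma2_a / fit.sigma2_eps)
    assert np.median(ratios) == pytest.approx(4.0, rel=0.25)


def test_identical_models_compared_give_p_one():
    panel, aems, h2, _ = simulate_aem_panel(5, n_clones=60, n_markers=150)
    G_A = additive_grm(panel.dosage)
    plan = kfold_cv(aems.index, 5, 3, np.random.default_rng(0))
    table, pvals = compare_models(aems, h2, G_A, G_A, plan)
    # same matrix on both sides: the dominance term duplicates the additive
    # one; any difference is numerical noise -> corrected p of 1 or near 1
    assert pvals.loc["T", "p_bonferroni"] > 0.9 or \
        abs(pvals.loc["T", "mean_diff"]) < 1e-3


def test_dominance_model_helps_when_dominance_present():
    """s2_d/s2_g = 0.5: add-dom PA is at least additive PA on average."""
    panel, aems, h2, _ = simulate_aem_panel(11, n_clones=250, n_markers=400,
                                            h2=0.8, additive_var=1.0,
                                            dominance_var=1.0)
    G_A = additive_grm(panel.dosage)
    G_D = dominance_grm(impute_median_classes(panel))
    plan = kfold_cv(aems.index, 5, 8, np.random.default_rng(1))
    table, pvals = compare_models(aems, h2, G_A, G_D, plan)
    assert table["pa_add_dom"].mean() >= table["pa_additive"].mean() - 0.01


def test_fold_mismatch_errors(toy):
    panel, G, y = toy
    with pytest.raises(ValueError):
        cv_prediction_accuracy(y, G, 0.8, np.zeros(10))
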