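"""Phenotype adjustment: yield normalisation, check corrections, AEMs, h2."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tetragp.field_models import (adjust_trait, adjusted_entry_means,
                                  correct_nuisance_split, detect_outliers,
                                  fit_model2, fit_model3, heritability,
                                  lrt_block_effect,
                                  mean_variance_of_difference,
                                  normalize_yield)
from tetragp.simdata import LayoutSpec, SimConfig, TraitSpec, simulate_dataset


@pytest.mark.parametrize("raw,pn,mp,expected", [
    (8.0, 16, 0, 8.0),            # identity plot size
    (8.0, 20, 2, 6.4),            # 10% missing <= 20%: no subtraction
    (8.0, 20, 5, 8.0 / 15 * 16),  # 25% missing > 20%: subtract
])
def test_normalize_yield_branches(raw, pn, mp, expected):
    assert normalize_yield(raw, pn, mp) == pytest.approx(expected)


def test_normalize_yield_errors():
    with pytest.raises(ValueError):
        normalize_yield(1.0, 0, 0)
    with pytest.raises(ValueError):
        normalize_yield(1.0, 10, 11)


def _toy_two_trials():
    rows = []
    for trial, shift in (("T1", 2.0), ("T2", 0.0)):
        for i in range(6):
            rows.append(dict(clone=f"CHK{i % 2}", env="E1", trial=trial,
                             block="B1", row=1, col=i, is_check=True,
                             y=4.0 + shift + 0.0 * i))
        rows.append(dict(clone=f"X{trial}", env="E1", trial=trial, block="B1",
                         row=2, col=0, is_check=False, y=5.0 + shift))
    return pd.DataFrame(rows)


def test_trial_correction_two_group_rule():
    """Check means 6 and 4: subtract 2 from the higher-mean trial only."""
    table = _toy_two_trials()
    out = correct_nuisance_split(table, "trial", "y")
    chk = out[out.is_check].groupby("trial")["y"].mean()
    assert chk["T1"] == pytest.approx(chk["T2"])
    # trial-2 observations untouched
    pd.testing.assert_frame_equal(out[out.trial == "T2"],
                                  table[table.trial == "T2"])
    # equal means: unchanged
    same = table.copy()
    same.loc[same.trial == "T1", "y"] -= 2.0
    pd.testing.assert_frame_equal(correct_nuisance_split(same, "trial", "y"),
                                  same)


def test_trial_correction_missing_checks_errors():
    table = _toy_two_trials()
    bad = table[~(table.is_check & (table.trial == "T2"))]
    with pytest.raises(ValueError):
        correct_nuisance_split(bad, "trial", "y")


def test_block_correction_aligns_to_minimum():
    rows = []
    for b, shift in (("B1", 0.0), ("B2", 1.5), ("B3", 3.0)):
        for i in range(4):
            rows.append(dict(clone=f"CHK{i % 2}", env="E1", trial="T1",
                             block=b, row=1, col=i, is_check=True,
                             y=4.0 + shift))
    table = pd.DataFrame(rows)
    out = correct_nuisance_split(table, "block", "y")
    means = out.groupby("block")["y"].mean()
    assert means.max() - means.min() < 1e-12
    assert means["B1"] == pytest.approx(4.0)


@pytest.fixture(scope="module")
def noiseless_ds():
    spec = TraitSpec(name="t", scale="kg", additive_var=1.0, env_var=0.0,
                     block_var=0.0, row_var=0.0, col_var=0.0, gxe_var=0.0,
                     resid_var_per_env=[1e-10, 1e-10])
    cfg = SimConfig(seed=8, n_families=12, n_markers=80, n_chromosomes=2,
                    n_founders=14, company_labels=("B1",), trait_specs=[spec],
                    layout=LayoutSpec(envs_per_company=2, blocks_per_env=2))
    return simulate_dataset(cfg)


def test_model2_noiseless_recovers_clone_effects(noiseless_ds):
    ds = noiseless_ds
    fit = fit_model2(ds.plots, "t")
    aems = adjusted_entry_means(fit)
    g = ds.truth.traits["t"].genetic_values
    mu = ds.config.trait_specs[0].mean
    diff = aems - (mu + g.loc[aems.index])
    # AEMs recover mu + g up to a common constant (env effects absorbed)
    assert np.std(diff.to_numpy()) < 1e-4
    assert fit.result.resid_var.max() < 1e-6


def test_aem_translation_equivariance(noiseless_ds):
    plots = noiseless_ds.plots.copy()
    f0 = fit_model2(plots, "t")
    plots["t"] = plots["t"] + 7.0
    f1 = fit_model2(plots, "t")
    d0 = adjusted_entry_means(f0)
    d1 = adjusted_entry_means(f1)
    diffs = (d1 - d0).to_numpy()
    assert np.allclose(diffs - diffs.mean(), 0.0, atol=1e-6)


def test_outlier_threshold_is_strict():
    """|standardized residual| exactly 3.5 is retained; above is flagged."""

    class FakeResult:
        std_residuals = np.array([0.2, 3.5, -3.6, 3.51])

    class FakeFit:
        result = FakeResult()
        plot_index = pd.Index([10, 11, 12, 13])

    flagged = detect_outliers(FakeFit(), threshold=3.5)
    assert list(flagged) == [12, 13]


def test_lrt_block_mixture_null():
    """Boundary mixture: statistic 2.706 sits exactly at p = 0.05."""
    p = 0.5 * stats.chi2.sf(2.706, df=1)
    assert p == pytest.approx(0.05, abs=2e-4)


def test_lrt_identical_likelihoods_not_significant(noiseless_ds):
    sig, p, stat, _fit = lrt_block_effect(noiseless_ds.plots, "t")
    # block variance is zero in this simulation: no significance
    assert stat >= 0.0
    assert p > 0.04 or not sig


def test_heritability_arithmetic():
    assert heritability(2.0, 2.0) == pytest.approx(2 / 3)
    assert heritability(0.0, 1.0) == 0.0
    assert 0.0 <= heritability(1.3, 0.7) <= 1.0
    with pytest.raises(ValueError):
        heritability(-1.0, 1.0)


def test_adjust_trait_pipeline_recovers_h2_and_aems():
    spec = TraitSpec(name="t", scale="kg", target_h2=0.85, additive_var=2.0,
                     env_var=1.0, block_var=0.1, row_var=0.02, col_var=0.02)
    cfg = SimConfig(seed=31, n_families=40, n_markers=200, n_chromosomes=3,
                    n_founders=30, company_labels=("B1",), trait_specs=[spec],
                    layout=LayoutSpec(envs_per_company=3, blocks_per_env=4))
    ds = simulate_dataset(cfg)
    adj = adjust_trait(ds.plots, "t", tol=1e-6)
    assert adj.h2 == pytest.approx(0.85, abs=0.08)
    assert 0.0 <= adj.h2 <= 1.0
    assert adj.sigma_g2 > 0 and adj.nu_hat > 0
    g = ds.truth.traits["t"].genetic_values
    ids = adj.aems.index
    r = np.corrcoef(adj.aems.to_numpy(), g.loc[ids].to_numpy())[0, 1]
    assert r > 0.85


def test_model3_entry_variance_close_to_truth():
    spec = TraitSpec(name="t", scale="kg", target_h2=0.8, additive_var=2.0,
                     env_var=0.5, block_var=0.05)
    cfg = SimConfig(seed=17, n_families=50, n_markers=150, n_chromosomes=3,
                    n_founders=30, company_labels=("B1",), trait_specs=[spec],
                    layout=LayoutSpec(envs_per_company=2, blocks_per_env=4))
    ds = simulate_dataset(cfg)
    fit3 = fit_model3(ds.plots, "t", tol=1e-6)
    s2g = fit3.result.varcomps["entry"]
    assert s2g == pytest.approx(2.0, rel=0.45)


def test_nu_hat_closed_form_matches_pair_average():
    rng = np.random.default_rng(2)
    C = rng.normal(size=(6, 6))
    C = C @ C.T

    class FakeResult:
        fixed_cov = C

    class FakeFit:
        result = FakeResult()
        clones = pd.Index(list("abcdef"))
        entry_clones = pd.Index(list("bdef"))
        model = "model2"

    nu = mean_variance_of_difference(FakeFit())
    idx = [1, 3, 4, 5]
    vals = [C[i, i] + C[k, k] - 2 * C[i, k]
            for a, i in enumerate(idx) for k in idx[a + 1:]]
    assert nu == pytest.approx(np.mean(vals), rel=1e-12)
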