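"""Generator correctness: meiosis, trait architecture, trial layout, discards."""

import numpy as np
import pandas as pd
import pytest

from tetragp.simdata import (LayoutSpec, SimConfig, TraitSpec,
                             assign_discard_status, simulate_cross,
                             simulate_dataset, simulate_founders,
                             simulate_genetic_values, simulate_population)

MAP1 = pd.DataFrame({"chrom": ["chr1"], "pos": [1], "cM": [0.0]},
                    index=pd.Index(["M1"], name="marker"))


def test_config_validation_errors():
    with pytest.raises(ValueError):
        SimConfig(n_markers=0)
    with pytest.raises(ValueError):
        SimConfig(n_chromosomes=0)
    with pytest.raises(ValueError):
        TraitSpec(name="x", target_h2=0.0)
    with pytest.raises(ValueError):
        TraitSpec(name="x", additive_var=-1.0)
    with pytest.raises(ValueError):
        simulate_cross(np.zeros((4, 1), dtype=np.int8),
                       np.zeros((4, 1), dtype=np.int8), 0,
                       np.random.default_rng(0), MAP1)


def test_fixed_locus_and_determinism():
    cfg = SimConfig(seed=9, n_founders=6, n_markers=1, n_chromosomes=1,
                    n_families=3)
    rng = np.random.default_rng(0)
    f = simulate_founders(cfg, rng, base_freq=np.array([1.0]))
    assert (f.haplotypes == 1).all()
    f1 = simulate_founders(SimConfig(seed=9, n_founders=6, n_markers=50,
                                     n_chromosomes=2, n_families=3))
    f2 = simulate_founders(SimConfig(seed=9, n_founders=6, n_markers=50,
                                     n_chromosomes=2, n_families=3))
    assert np.array_equal(f1.haplotypes, f2.haplotypes)


def test_founder_allele_frequency_binomial():
    # 10,000 founder alleles at declared p = 0.3: sample freq within 3 SE
    cfg = SimConfig(seed=5, n_founders=2500, n_markers=1, n_chromosomes=1,
                    n_families=3, segment_freq_shift_sd=0.0)
    f = simulate_founders(cfg, np.random.default_rng(5),
                          base_freq=np.array([0.3]))
    n_alleles = 2500 * 4
    freq = f.haplotypes.mean()
    se = np.sqrt(0.3 * 0.7 / n_alleles)
    assert abs(freq - 0.3) < 3 * se


def test_cross_monomorphic_and_forced():
    rng = np.random.default_rng(1)
    aaaa = np.zeros((4, 1), dtype=np.int8)
    AAAA = np.ones((4, 1), dtype=np.int8)
    off0 = simulate_cross(aaaa, aaaa, 200, rng, MAP1)
    assert (off0.sum(axis=1) == 0).all()
    off2 = simulate_cross(AAAA, aaaa, 200, rng, MAP1)
    assert (off2.sum(axis=1) == 2).all()


def test_bivalent_segregation_duplex_selfing():
    """AAaa x AAaa at one locus: gametes AA:Aa:aa = 1/6:4/6:1/6."""
    rng = np.random.default_rng(7)
    duplex = np.array([[1], [1], [0], [0]], dtype=np.int8)
    off = simulate_cross(duplex, duplex, 20000, rng, MAP1)
    dos = off.sum(axis=1).ravel()
    obs = np.bincount(dos, minlength=5) / len(dos)
    gam = {2: 1 / 6, 1: 4 / 6, 0: 1 / 6}
    exp = np.zeros(5)
    for i, pi in gam.items():
        for j, pj in gam.items():
            exp[i + j] += pi * pj
    se = np.sqrt(exp * (1 - exp) / 20000)
    assert np.all(np.abs(obs - exp) < 4 * se + 1e-12)


def test_gamete_frequency_conservation():
    """Offspring expected allele frequency equals the mid-parent frequency."""
    rng = np.random.default_rng(3)
    pa = (rng.random((4, 30)) < 0.8).astype(np.int8)
    pb = (rng.random((4, 30)) < 0.2).astype(np.int8)
    mm = pd.DataFrame({"chrom": "chr1", "pos": np.arange(1, 31),
                       "cM": np.linspace(0, 90, 30)},
                      index=pd.Index([f"M{i}" for i in range(30)]))
    off = simulate_cross(pa, pb, 10000, rng, mm)
    mid = (pa.mean(axis=0) + pb.mean(axis=0)) / 2
    freq = off.sum(axis=1).mean(axis=0) / 4
    se = np.sqrt(mid * (1 - mid) / (4 * 10000)) + 1e-9
    assert np.all(np.abs(freq - mid) < 4 * se + 0.01)


def test_genetic_values_additive_only_linear(small_panel):
    spec = TraitSpec(name="t", scale="kg", additive_var=1.0,
                     dominance_var=0.0)
    tt = simulate_genetic_values(small_panel, spec,
                                 np.random.default_rng(0), n_qtl=40)
    # purely additive: value is exactly linear in QTL dosages
    M = small_panel.dosage[tt.qtl_markers].to_numpy()
    np.testing.assert_allclose(tt.genetic_values.to_numpy(),
                               M @ tt.additive_effects, atol=1e-10)
    assert tt.realized_dominance_var == 0.0
    # realized additive variance matches the target exactly (rescaled draw)
    assert tt.realized_additive_var == pytest.approx(1.0, rel=1e-6)


def test_genetic_values_breeding_value_recomputable(small_dataset):
    for tt in small_dataset.truth.traits.values():
        M = small_dataset.panel.dosage[tt.qtl_markers].to_numpy()
        np.testing.assert_allclose(tt.breeding_values.to_numpy(),
                                   M @ tt.additive_effects, atol=1e-8)


def test_trial_layout_structure(small_dataset):
    plots = small_dataset.plots
    meta = small_dataset.panel.clone_meta
    # entries appear exactly once per environment of their company
    ent = plots[~plots.is_check].groupby(["env", "clone"]).size()
    assert int(ent.max()) == 1
    for clone, env in ent.index:
        pass
    # checks appear check_reps_per_env times per env, >=1 per block
    chk = plots[plots.is_check]
    per_env = chk.groupby(["env", "clone"]).size()
    assert (per_env == 8).all()
    per_block = chk.groupby(["env", "block"])["clone"].nunique()
    assert (per_block >= 1).all()
    # every env/block combination contains at least one check
    all_blocks = plots.groupby(["env", "block"]).size().index
    assert set(per_block.index) == set(all_blocks)
    # ordinal trait within scale
    assert plots["FLE"].between(1, 9).all()
    # split env has two trials, others one
    ntrials = plots.groupby("env")["trial"].nunique()
    assert (ntrials == 2).sum() == 1 and (ntrials == 1).sum() == len(ntrials) - 1


def test_noiseless_trials_equal_mean_plus_genetic():
    spec = TraitSpec(name="t", scale="kg", additive_var=1.0, env_var=0.0,
                     block_var=0.0, row_var=0.0, col_var=0.0, gxe_var=0.0,
                     resid_var_per_env=[1e-12, 1e-12])
    cfg = SimConfig(seed=2, n_families=10, n_markers=60, n_chromosomes=2,
                    n_founders=12, trait_specs=[spec],
                    company_labels=("B1",),
                    layout=LayoutSpec(envs_per_company=2, blocks_per_env=2))
    ds = simulate_dataset(cfg)
    g = ds.truth.traits["t"].genetic_values
    expected = spec.mean + g.loc[ds.plots["clone"]].to_numpy()
    np.testing.assert_allclose(ds.plots["t"].to_numpy(), expected, atol=1e-4)


def test_plot_table_bit_reproducible(small_dataset):
    cfg = small_dataset.config
    again = simulate_dataset(cfg)
    pd.testing.assert_frame_equal(small_dataset.plots, again.plots)
    pd.testing.assert_frame_equal(small_dataset.panel.dosage,
                                  again.panel.dosage)


def test_family_sizes_within_range(small_dataset):
    meta = small_dataset.panel.clone_meta
    sizes = meta[~meta.is_check].groupby("family").size()
    lo, hi = small_dataset.config.family_size_range
    assert sizes.between(lo, hi).all()


def test_discard_status_structure(small_dataset):
    panel, truth = small_dataset.panel, small_dataset.truth
    meta = panel.clone_meta
    status = meta.loc[~meta.is_check, "discard_status"]
    assert set(status.unique()) <= {0, 1, 2}
    # status 2 wipes out whole families; status 1 families keep survivors
    fam_status = meta[~meta.is_check].groupby("family")["discard_status"]
    for fam, vals in fam_status:
        if (vals == 2).any():
            assert (vals == 2).all()
    mixed = [fam for fam, vals in fam_status
             if (vals == 0).any() and (vals == 1).any()]
    assert len(mixed) > 0
    with pytest.raises(ValueError):
        assign_discard_status(panel, truth, {"nope": 1.0},
                              np.random.default_rng(0))


def test_discard_retain_all_and_pure_noise(small_dataset):
    panel, truth = small_dataset.panel, small_dataset.truth
    status = assign_discard_status(panel, truth, {"STA": 1.0},
                                   np.random.default_rng(0),
                                   discard_frac=0.0, family_discard_frac=0.0)
    assert (status == 0).all()
    # selection noise -> infinity: status independent of trait values
    s_noise = assign_discard_status(panel, truth, {"STA": 1.0},
                                    np.random.default_rng(1),
                                    noise_sd=np.inf)
    g = truth.traits["STA"].genetic_values
    entries = panel.clone_meta.index[~panel.clone_meta.is_check]
    kept = g.loc[entries[s_noise.loc[entries] == 0]].mean()
    disc = g.loc[entries[s_noise.loc[entries] > 0]].mean()
    # means differ by far less than one genetic SD under pure noise
    assert abs(kept - disc) < g.std()
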