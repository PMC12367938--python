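"""Scenario engine: CV plans, TS construction rules, selection experiments."""

import numpy as np
import pandas as pd
import pytest

from tetragp.experiments import simulate_aem_panel
from tetragp.genotype_qc import additive_grm
from tetragp.scenarios import (_truncation_ts, discard_inclusion_scenario,
                               family_balance_scenario,
                               group_transfer_scenario, kfold_cv,
                               marker_window_scan, marker_windows,
                               rank_selection_scenario, rank_sum_values,
                               round_half_away, truncation_scenario,
                               ts_size_scan)


@pytest.fixture(scope="module")
def aem_study():
    panel, aems, h2, tt = simulate_aem_panel(21, n_clones=400, n_markers=300)
    return panel, aems, h2, additive_grm(panel.dosage)


def test_round_half_away():
    assert round_half_away(0.5) == 1
    assert round_half_away(1.5) == 2
    assert round_half_away(-0.5) == -1
    assert round_half_away(2.4) == 2


def test_kfold_partition_properties():
    ids = [f"c{i}" for i in range(1000)]
    plan = kfold_cv(ids, k=5, reps=3, rng=np.random.default_rng(0))
    assert len(plan) == 3
    for labels in plan:
        counts = np.bincount(labels, minlength=5)
        assert (counts == 200).all()        # n = 1000, k = 5 -> parts of 200
    # different seeds give different partitions
    other = kfold_cv(ids, k=5, reps=1, rng=np.random.default_rng(1))
    assert not np.array_equal(plan[0], other[0])
    with pytest.raises(ValueError):
        kfold_cv(ids, k=1)
    with pytest.raises(ValueError):
        kfold_cv(ids[:3], k=5)


def test_marker_windows_counting():
    ids = [f"M{i}" for i in range(1000)]
    rng = np.random.default_rng(0)
    picked = marker_windows(ids, 8, rng)
    assert len(picked) == 125
    # one marker per consecutive block of eight
    for i, mid in enumerate(picked):
        assert int(mid[1:]) // 8 == i
    assert marker_windows(ids, 1, rng) == ids
    with pytest.raises(ValueError):
        marker_windows(ids, 2000, rng)


def test_ts_size_scan_improves_with_size(aem_study):
    panel, aems, h2, G = aem_study
    rng = np.random.default_rng(3)
    res = ts_size_scan(panel, aems, h2, G, "T", sizes=(40, 240), reps=8,
                       rng=rng)
    med = res.records.groupby("cell")["pa"].median()
    assert med.loc[240] > med.loc[40]
    cov = res.summary(by=("cell",)).set_index("cell")["cov_pa"]
    assert cov.loc[240] < cov.loc[40]


def test_marker_window_scan_small(aem_study):
    panel, aems, h2, _G = aem_study
    rng = np.random.default_rng(4)
    res = marker_window_scan(panel, aems, h2, "T", window_sizes=(1, 8),
                             reps=2, rng=rng)
    n_markers = res.records.groupby("cell")["n_markers"].first()
    m = panel.n_markers
    assert n_markers.loc[1] == m
    assert n_markers.loc[8] == int(np.ceil(m / 8))


def test_family_balance_construction(aem_study):
    panel, aems, h2, G = aem_study
    res = family_balance_scenario(panel, aems, h2, G, "T", per_family=4,
                                  vs_size=60, reps=3,
                                  rng=np.random.default_rng(5))
    fam = panel.clone_meta["family"]
    bal = res["balanced"].records
    assert set(res) == {"balanced", "stratified", "random"}
    for key in res:
        assert len(res[key].records) > 0
    # matched TS sizes across variants (within rounding slack)
    sizes = {k: res[k].records["ts_size"].iloc[0] for k in res}
    assert abs(sizes["balanced"] - sizes["random"]) == 0
    assert abs(sizes["balanced"] - sizes["stratified"]) <= \
        0.1 * sizes["balanced"]


def test_family_balance_per_family_cap(aem_study):
    panel, aems, h2, G = aem_study
    rng = np.random.default_rng(6)
    meta = panel.clone_meta
    ids = aems.index[aems["T"].notna() & ~meta.loc[aems.index, "is_check"]]
    fam = meta.loc[ids, "family"]
    vs = pd.Index(rng.choice(ids, 60, replace=False))
    pool = ids.difference(vs)
    pfam = fam.loc[pool]
    ts = []
    for f, members in pfam.groupby(pfam).groups.items():
        members = pd.Index(members)
        take = min(len(members), 4)
        ts.extend(rng.choice(members, take, replace=False))
    counts = fam.loc[pd.Index(ts)].value_counts()
    assert counts.max() <= 4


def test_group_transfer_modes(aem_study):
    panel, aems, h2, G = aem_study
    labels = panel.clone_meta["segment"]
    common = dict(ts_size=60, vs_size=20, reps=2)
    for ts_mode in ("within", "across", "between"):
        res = group_transfer_scenario(panel, aems, h2, "T", G,
                                      vs_mode="within", ts_mode=ts_mode,
                                      rng=np.random.default_rng(7), **common)
        assert len(res.records) > 0
        assert {"he_ts", "he_vs", "nei_d", "var_ts", "var_vs"} <= \
            set(res.records.columns)
    res_acr = group_transfer_scenario(panel, aems, h2, "T", G,
                                      vs_mode="across", ts_mode="across",
                                      rng=np.random.default_rng(8), **common)
    assert (res_acr.records["cell"] == "TS:all").all()


def test_group_transfer_within_beats_between_for_shifted_trait():
    """Segment-structured trait: within-segment TS predicts better."""
    panel, aems, h2, tt = simulate_aem_panel(33, n_clones=500, n_markers=300,
                                             h2=0.85)
    # add a strong segment shift to the AEMs to mimic structured QTL
    shift = panel.clone_meta["segment"].map(
        {"CR": 2.5, "FF": -2.5, "TA": 1.5, "ST": -1.5}).astype(float)
    aems = aems.add(shift, axis=0)
    G = additive_grm(panel.dosage)
    kw = dict(ts_size=80, vs_size=30, reps=8)
    within = group_transfer_scenario(panel, aems, h2, "T", G,
                                     vs_mode="within", ts_mode="within",
                                     vs_groups=["CR"],
                                     rng=np.random.default_rng(1), **kw)
    between = group_transfer_scenario(panel, aems, h2, "T", G,
                                      vs_mode="within", ts_mode="between",
                                      vs_groups=["CR"],
                                      rng=np.random.default_rng(1), **kw)
    assert within.records["pa"].median() >= between.records["pa"].median()


def test_truncation_ts_rules(aem_study):
    panel, aems, h2, G = aem_study
    meta = panel.clone_meta
    ids = aems.index[~meta.loc[aems.index, "is_check"]]
    v = aems["T"]
    rng = np.random.default_rng(9)
    # y = 0: TS entirely inside the top-x% pool
    ts = _truncation_ts(v, ids, 50, 0, "random", 100, rng)
    n_top = round_half_away(len(ids) * 0.5)
    top = v.loc[ids].sort_values(ascending=False).index[:n_top]
    assert ts.isin(top).all()
    # y = 20: exactly 40 of 200 exchanged out of the pool
    ts2 = _truncation_ts(v, ids, 70, 20, "random", 150, rng)
    n_out = (~ts2.isin(v.loc[ids].sort_values(ascending=False)
                       .index[:round_half_away(len(ids) * 0.7)])).sum()
    assert n_out == round_half_away(150 * 0.2)
    # bottom10 replacement draws from the lowest decile
    ts3 = _truncation_ts(v, ids, 70, 20, "bottom10", 150, rng)
    bot = v.loc[ids].sort_values().index[: round_half_away(len(ids) * 0.1)]
    assert ts3.isin(bot).sum() >= 1
    assert len(ts) == 100 and len(ts2) == 150 and len(ts3) == 150


def test_truncation_scenario_vs_is_complement(aem_study):
    panel, aems, h2, G = aem_study
    res = truncation_scenario(panel, aems, h2, G, "T", x_grid=(50,),
                              y_grid=(0,), ts_size=80, reps=2,
                              rng=np.random.default_rng(10))
    assert len(res.records) == 2
    assert (res.records["pa"].abs() <= 1 / np.sqrt(h2["T"]) + 1e-9).all()


def test_rank_selection_reduces_to_truncation_for_one_trait(aem_study):
    panel, aems, h2, G = aem_study
    vals = rank_sum_values(aems, ["T"])
    # single trait: rank-sum ordering equals the trait's own ordering
    order_rank = vals.sort_values(ascending=False).index
    order_trait = aems["T"].loc[vals.index].sort_values(ascending=False).index
    assert list(order_rank) == list(order_trait)
    res = rank_selection_scenario(panel, aems, h2, G, ["T"], exchanges=(0,),
                                  ts_size=80, reps=2,
                                  rng=np.random.default_rng(11))
    assert len(res.records) == 2


def test_discard_inclusion_bookkeeping(aem_study):
    panel, aems, h2, G = aem_study
    res = discard_inclusion_scenario(panel, aems, h2, G, "T",
                                     z_grid=(0, 20), ts_size=60, reps=3,
                                     rng=np.random.default_rng(12))
    rec = res.records
    assert set(rec["z"].unique()) <= {0, 20}
    meta = panel.clone_meta
    status = meta["discard_status"]
    # z = 0 cells used only status-0 clones; with exchange the records exist
    assert len(rec[rec.z == 0]) > 0


def test_scenario_median_rankings_stable(aem_study):
    """Trait ranking by PA is stable across TS sizes (Spearman > 0.8)."""
    panel, aems, h2, G = aem_study
    # build three pseudo-traits of differing heritability from the same panel
    rng = np.random.default_rng(13)
    g = aems["T"]
    traits = {}
    h2s = {}
    for name, hh in (("hi", 0.9), ("mid", 0.6), ("lo", 0.3)):
        noise = rng.normal(0, np.sqrt(float(g.var()) * (1 - hh) / hh), len(g))
        traits[name] = g + noise
        h2s[name] = hh
    aems3 = pd.DataFrame(traits)
    h23 = pd.Series(h2s)
    meds = {}
    for size in (60, 200):
        med = []
        for t in aems3.columns:
            res = ts_size_scan(panel, aems3, h23, G, t, sizes=(size,),
                               reps=6, rng=np.random.default_rng(14))
            med.append(res.records["pa"].median())
        meds[size] = pd.Series(med, index=aems3.columns)
    rho = meds[60].rank().corr(meds[200].rank(), method="spearman")
    assert rho > 0.8
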