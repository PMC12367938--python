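"""Training-set / validation-set composition experiments.

Every scenario assembles a training set (TS) and validation set (VS) of
clone ids, fits GBLUP on the TS slice of the AEMs, predicts the VS, and
records prediction accuracy together with diversity measures of both sets
(tetraploid expected heterozygosity, Nei distance TS-VS, phenotypic
variance of the AEMs).  Replicates whose model is singular are canceled,
counted, and excluded from summaries.  Percent-to-count conversions round
half away from zero so scenario cells are exactly reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DosagePanel, RelationshipMatrix
from .diversity import (expected_heterozygosity, nei_distance_panels,
                        phenotypic_variance)
from .gblup import (SingularReplicateError, cv_prediction_accuracy, fit_gblup,
                    prediction_accuracy)


def round_half_away(x: float) -> int:
    """Round half away from zero (so 0.5 -> 1, -0.5 -> -1)."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def kfold_cv(clone_ids, k: int = 5, reps: int = 50,
             rng: np.random.Generator | None = None) -> list[np.ndarray]:
    """Random k-fold partitions: one fold-label array per replicate.

    Fold sizes differ by at most one; each part serves as validation set
    exactly once downstream.
    """
    if k < 2:
        raise ValueError("need at least two folds")
    ids = list(clone_ids)
    if len(ids) < k:
        raise ValueError("fewer clones than folds")
    rng = np.random.default_rng() if rng is None else rng
    plan = []
    base = np.arange(len(ids)) % k
    for _ in range(reps):
        labels = rng.permutation(base)
        plan.append(labels)
    return plan


@dataclass
class ScenarioResult:
    """Long-format record of one scenario: replicates x cells (x traits)."""

    name: str
    records: pd.DataFrame
    n_canceled: int = 0
    notes: list[str] = field(default_factory=list)

    def summary(self, by=("cell", "trait")) -> pd.DataFrame:
        by = [b for b in by if b in self.records.columns]
        g = self.records.groupby(by)["pa"]
        out = g.agg(median_pa="median", mean_pa="mean", sd_pa="std",
                    n_reps="count")
        out["cov_pa"] = out["sd_pa"] / out["mean_pa"].abs()
        return out.reset_index()


def _diversity_record(panel: DosagePanel, ts, vs, aems_trait: pd.Series) -> dict:
    dts = panel.dosage.loc[list(ts)]
    dvs = panel.dosage.loc[list(vs)]
    return dict(
        he_ts=expected_heterozygosity(dts),
        he_vs=expected_heterozygosity(dvs),
        nei_d=nei_distance_panels(dts, dvs),
        var_ts=phenotypic_variance(aems_trait.loc[list(ts)]),
        var_vs=phenotypic_variance(aems_trait.loc[list(vs)]),
    )


def _predict_cell(aems_trait: pd.Series, h2: float, G_A: RelationshipMatrix,
                  ts, vs) -> float | None:
    """PA of one TS->VS prediction, or ``None`` when the replicate cancels."""
    try:
        fit = fit_gblup(aems_trait.loc[list(ts)].dropna(), G_A)
        gebv = fit.predict(list(vs))
        return prediction_accuracy(gebv, aems_trait.loc[list(vs)], h2)
    except SingularReplicateError:
        return None


# ---------------------------------------------------------------------------
# size and marker scans
# ---------------------------------------------------------------------------


def ts_size_scan(panel: DosagePanel, aems: pd.DataFrame, h2: pd.Series,
                 G_A: RelationshipMatrix, trait: str,
                 sizes=tuple(range(40, 761, 40)), reps: int = 50,
                 folds: int = 5,
                 rng: np.random.Generator | None = None) -> ScenarioResult:
    """Fivefold CV on random subsets so the TS size runs over ``sizes``.

    A TS of N clones under k-fold CV needs a subset of N * k/(k-1) clones,
    freshly sampled per replicate.
    """
    rng = np.random.default_rng() if rng is None else rng
    ids = aems.index[aems[trait].notna()]
    rows, canceled = [], 0
    for N in sizes:
        subset_size = round_half_away(N * folds / (folds - 1))
        if subset_size > len(ids):
            raise ValueError(f"TS size {N} needs {subset_size} clones, "
                             f"have {len(ids)}")
        for rep in range(reps):
            sub = pd.Index(rng.choice(ids, size=subset_size, replace=False))
            labels = rng.permutation(np.arange(subset_size) % folds)
            try:
                pa, pa_pooled = cv_prediction_accuracy(
                    aems.loc[sub, trait], G_A, h2[trait], labels)
            except SingularReplicateError:
                canceled += 1
                continue
            rows.append(dict(cell=N, replicate=rep, trait=trait, pa=pa,
                             pa_pooled=pa_pooled))
    return ScenarioResult("ts_size_scan", pd.DataFrame(rows), canceled)


def marker_windows(marker_ids, window: int,
                   rng: np.random.Generator) -> list:
    """One random marker per consecutive window of ``window`` markers."""
    m = len(marker_ids)
    if window > m:
        raise ValueError("window larger than the marker count")
    if window == 1:
        return list(marker_ids)
    picked = []
    for start in range(0, m, window):
        stop = min(start + window, m)
        picked.append(marker_ids[int(rng.integers(start, stop))])
    return picked


def marker_window_scan(panel: DosagePanel, aems: pd.DataFrame, h2: pd.Series,
                       trait: str, window_sizes=(2, 4, 8, 16, 32),
                       reps: int = 50, folds: int = 5,
                       rng: np.random.Generator | None = None) -> ScenarioResult:
    """Marker-subsampling scan: windows along the map, one marker per window.

    The additive GRM is rebuilt from the sampled markers for every
    replicate; all phenotyped clones participate in the fivefold CV.
    """
    from .genotype_qc import additive_grm, impute_mean

    rng = np.random.default_rng() if rng is None else rng
    full = impute_mean(panel)
    ids = aems.index[aems[trait].notna()]
    markers = list(panel.markers)
    rows, canceled = [], 0
    for w in window_sizes:
        for rep in range(reps):
            chosen = marker_windows(markers, w, rng)
            G = additive_grm(full[chosen])
            labels = rng.permutation(np.arange(len(ids)) % folds)
            try:
                pa, pa_pooled = cv_prediction_accuracy(
                    aems.loc[ids, trait], G, h2[trait], labels)
            except SingularReplicateError:
                canceled += 1
                continue
            rows.append(dict(cell=w, replicate=rep, trait=trait, pa=pa,
                             pa_pooled=pa_pooled, n_markers=len(chosen)))
    return ScenarioResult("marker_window_scan", pd.DataFrame(rows), canceled)


# ---------------------------------------------------------------------------
# family balancedness
# ---------------------------------------------------------------------------


def family_balance_scenario(panel: DosagePanel, aems: pd.DataFrame,
                            h2: pd.Series, G_A: RelationshipMatrix, trait: str,
                            per_family: int = 4, include_small: bool = True,
                            vs_size: int = 120, reps: int = 50,
                            rng: np.random.Generator | None = None
                            ) -> dict[str, ScenarioResult]:
    """Balanced vs stratified-unbalanced vs random TS at matched sizes.

    Within each replicate a common random VS is drawn first; the three TS
    variants are then built from the remaining clones, so the VS is
    identical across variants.
    """
    rng = np.random.default_rng() if rng is None else rng
    meta = panel.clone_meta
    ids = aems.index[aems[trait].notna() & ~meta.loc[aems.index, "is_check"]]
    fam = meta.loc[ids, "family"]
    results = {k: [] for k in ("balanced", "stratified", "random")}
    canceled = {k: 0 for k in results}
    for rep in range(reps):
        vs = pd.Index(rng.choice(ids, size=vs_size, replace=False))
        pool = ids.difference(vs)
        pfam = fam.loc[pool]
        # balanced: per_family per family (small families per include_small)
        ts_bal = []
        for f, members in pfam.groupby(pfam).groups.items():
            members = pd.Index(members)
            if len(members) > per_family:
                ts_bal.extend(rng.choice(members, per_family, replace=False))
            elif include_small:
                ts_bal.extend(members)
        ts_bal = pd.Index(ts_bal)
        n_ts = len(ts_bal)
        # stratified-unbalanced: family shares as in the panel, same size
        shares = pfam.value_counts(normalize=True)
        ts_str = []
        for f, share in shares.items():
            members = pfam.index[pfam == f]
            take = min(len(members), round_half_away(share * n_ts))
            if take:
                ts_str.extend(rng.choice(members, take, replace=False))
        ts_str = pd.Index(ts_str)
        ts_rand = pd.Index(rng.choice(pool, size=n_ts, replace=False))
        for key, ts in (("balanced", ts_bal), ("stratified", ts_str),
                        ("random", ts_rand)):
            pa = _predict_cell(aems[trait], h2[trait], G_A, ts, vs)
            if pa is None:
                canceled[key] += 1
                continue
            rec = dict(cell=key, replicate=rep, trait=trait, pa=pa,
                       ts_size=len(ts))
            rec.update(_diversity_record(panel, ts, vs, aems[trait]))
            results[key].append(rec)
    return {k: ScenarioResult(f"family_balance_{k}", pd.DataFrame(v),
                              canceled[k])
            for k, v in results.items()}


# ---------------------------------------------------------------------------
# group transfer (market segment / breeding company)
# ---------------------------------------------------------------------------


def group_transfer_scenario(panel: DosagePanel, aems: pd.DataFrame,
                            h2: pd.Series, trait: str,
                            G_A: RelationshipMatrix,
                            grouping: str = "segment",
                            vs_mode: str = "within",
                            ts_mode: str = "within",
                            ts_size: int = 200, vs_size: int = 45,
                            reps: int = 150,
                            vs_groups: list[str] | None = None,
                            rng: np.random.Generator | None = None
                            ) -> ScenarioResult:
    """Transfer of prediction models within/across/between groups.

    ``vs_mode='within'`` restricts the VS to one group (one scenario cell
    per group); ``ts_mode`` picks the TS from the same group (within), all
    groups (across), the other groups in equal shares (between), or each
    single other group separately (between_pairwise).  ``vs_mode='across'``
    samples the VS from all groups and the TS from one group or all.
    Groups too small for the requested sizes are skipped with a note.
    """
    rng = np.random.default_rng() if rng is None else rng
    meta = panel.clone_meta
    ids = aems.index[aems[trait].notna() & ~meta.loc[aems.index, "is_check"]]
    labels = meta.loc[ids, grouping]
    groups = sorted(labels.unique())
    rows, canceled, notes = [], 0, []

    def sample_between(excl_group, vs, pairwise_with=None):
        others = [g for g in groups if g != excl_group]
        if pairwise_with is not None:
            others = [pairwise_with]
        share = round_half_away(ts_size / len(others))
        ts = []
        for g in others:
            pool = ids[(labels == g)].difference(vs)
            take = min(share, len(pool))
            ts.extend(rng.choice(pool, size=take, replace=False))
        return pd.Index(ts[:ts_size])

    if vs_mode == "within":
        vs_group_list = vs_groups or groups
        for vg in vs_group_list:
            members = ids[labels == vg]
            if len(members) < vs_size + (ts_size if ts_mode == "within" else 0):
                notes.append(f"group {vg} too small; skipped")
                continue
            pair_targets = ([g for g in groups if g != vg]
                            if ts_mode == "between_pairwise" else [None])
            for tg in pair_targets:
                for rep in range(reps):
                    vs = pd.Index(rng.choice(members, vs_size, replace=False))
                    if ts_mode == "within":
                        pool = members.difference(vs)
                        ts = pd.Index(rng.choice(pool, ts_size, replace=False))
                    elif ts_mode == "across":
                        pool = ids.difference(vs)
                        ts = pd.Index(rng.choice(pool, ts_size, replace=False))
                    elif ts_mode in ("between", "between_pairwise"):
                        ts = sample_between(vg, vs, pairwise_with=tg)
                    else:
                        raise ValueError(f"unknown ts_mode {ts_mode!r}")
                    cell = vg if tg is None else f"{tg}->{vg}"
                    rec = _one_transfer_rep(panel, aems, h2, trait, G_A, ts,
                                            vs, cell, rep)
                    if rec is None:
                        canceled += 1
                    else:
                        rows.append(rec)
    elif vs_mode == "across":
        ts_group_list = groups if ts_mode == "within" else ["all"]
        for tg in ts_group_list:
            for rep in range(reps):
                vs = pd.Index(rng.choice(ids, vs_size, replace=False))
                pool = (ids.difference(vs) if tg == "all"
                        else ids[labels == tg].difference(vs))
                if len(pool) < ts_size:
                    notes.append(f"TS group {tg} too small; skipped")
                    break
                ts = pd.Index(rng.choice(pool, ts_size, replace=False))
                rec = _one_transfer_rep(panel, aems, h2, trait, G_A, ts, vs,
                                        f"TS:{tg}", rep)
                if rec is None:
                    canceled += 1
                else:
                    rows.append(rec)
    else:
        raise ValueError(f"unknown vs_mode {vs_mode!r}")
    name = f"transfer_{grouping}_{vs_mode}_{ts_mode}"
    return ScenarioResult(name, pd.DataFrame(rows), canceled, notes)


def _one_transfer_rep(panel, aems, h2, trait, G_A, ts, vs, cell, rep):
    pa = _predict_cell(aems[trait], h2[trait], G_A, ts, vs)
    if pa is None:
        return None
    rec = dict(cell=cell, replicate=rep, trait=trait, pa=pa, ts_size=len(ts))
    rec.update(_diversity_record(panel, ts, vs, aems[trait]))
    return rec


# ---------------------------------------------------------------------------
# truncation and rank selection
# ---------------------------------------------------------------------------


def _truncation_ts(values: pd.Series, ids: pd.Index, x_pct: int, y_pct: int,
                   replacement: str, ts_size: int,
                   rng: np.random.Generator) -> pd.Index:
    """TS from the top-x% pool with y% replaced via the chosen sampler."""
    v = values.loc[ids]
    n_top = round_half_away(len(ids) * x_pct / 100.0)
    order = v.sort_values(ascending=False, kind="mergesort").index
    top_pool = order[:n_top]
    rest_pool = order[n_top:]
    if ts_size > len(top_pool):
        raise ValueError("top-x% pool smaller than the TS size")
    ts = pd.Index(rng.choice(top_pool, ts_size, replace=False))
    n_repl = round_half_away(ts_size * y_pct / 100.0)
    if n_repl == 0:
        return ts
    if replacement == "random":
        pool = rest_pool
    elif replacement == "bottom10":
        n_bot = round_half_away(len(ids) * 0.10)
        pool = order[-n_bot:]
    elif replacement == "stratified":
        # deciles of the full phenotypic range; draw round-robin from the
        # windows not already represented in the TS so each contributes an
        # equal share, topping up from the general pool if they run dry
        lo, hi = float(v.min()), float(v.max())
        edges = np.linspace(lo, hi, 11)
        win = pd.Series(np.clip(np.digitize(v, edges[1:-1]), 0, 9),
                        index=v.index)
        occupied = set(win.loc[ts].unique())
        empty = [wd for wd in range(10) if wd not in occupied]
        buckets = {wd: list(rng.permutation(
            win.index[(win == wd) & ~win.index.isin(ts)])) for wd in empty}
        picks: list = []
        while len(picks) < n_repl and any(buckets.values()):
            for wd in empty:
                if buckets[wd] and len(picks) < n_repl:
                    picks.append(buckets[wd].pop())
        pool = pd.Index(picks)
        if len(pool) < n_repl:
            pool = pool.append(rest_pool.difference(pool))
    else:
        raise ValueError(f"unknown replacement sampler {replacement!r}")
    pool = pd.Index(pool).difference(ts)
    if len(pool) < n_repl:
        raise ValueError("replacement pool smaller than the exchange count")
    out_ids = pd.Index(rng.choice(ts, n_repl, replace=False))
    in_ids = pd.Index(rng.choice(pool, n_repl, replace=False))
    return ts.difference(out_ids).union(in_ids)


def truncation_scenario(panel: DosagePanel, aems: pd.DataFrame, h2: pd.Series,
                        G_A: RelationshipMatrix, trait: str,
                        x_grid=(30, 40, 50, 60, 70), y_grid=(0, 10, 20, 30),
                        replacement: str = "random", ts_size: int = 200,
                        reps: int = 50,
                        rng: np.random.Generator | None = None,
                        selection_values: pd.Series | None = None
                        ) -> ScenarioResult:
    """Effect of truncation selection in the TS on prediction accuracy.

    Selection operates on the AEMs of ``trait`` (or on supplied
    ``selection_values``, e.g. rank sums); the VS is everything outside the
    TS, so the TS size is constant across cells.
    """
    rng = np.random.default_rng() if rng is None else rng
    meta = panel.clone_meta
    ids = aems.index[aems[trait].notna() & ~meta.loc[aems.index, "is_check"]]
    values = aems[trait] if selection_values is None else selection_values
    rows, canceled = [], 0
    for x in x_grid:
        for y in y_grid:
            for rep in range(reps):
                ts = _truncation_ts(values, ids, x, y, replacement, ts_size,
                                    rng)
                vs = ids.difference(ts)
                pa = _predict_cell(aems[trait], h2[trait], G_A, ts, vs)
                if pa is None:
                    canceled += 1
                    continue
                rec = dict(cell=f"x{x}_y{y}", x=x, y=y, replicate=rep,
                           trait=trait, pa=pa,
                           replacement=replacement if y else "none")
                rec.update(_diversity_record(panel, ts, vs, aems[trait]))
                rows.append(rec)
    return ScenarioResult(f"truncation_{replacement}", pd.DataFrame(rows),
                          canceled)


def rank_sum_values(aems: pd.DataFrame, traits: list[str]) -> pd.Series:
    """Summed per-trait ranks (higher = better); ties broken by clone id.

    The returned values are negated rank sums so that "higher is better"
    matches the truncation machinery's top-x% convention.
    """
    sub = aems[traits].dropna()
    sub = sub.sort_index()                 # stable, documented tie-break
    ranks = sub.rank(axis=0, method="first", ascending=True)
    return -(ranks.shape[0] + 1 - ranks).sum(axis=1)


def rank_selection_scenario(panel: DosagePanel, aems: pd.DataFrame,
                            h2: pd.Series, G_A: RelationshipMatrix,
                            traits: list[str], top_frac: float = 0.5,
                            exchanges=(0, 20), ts_size: int = 200,
                            reps: int = 50,
                            rng: np.random.Generator | None = None
                            ) -> ScenarioResult:
    """Multi-trait rank-sum selection of the TS, bottom-10% exchange.

    Clones are ranked per trait, ranks summed, the top ``top_frac`` on the
    sum forms the selection pool and the bottom 10% the exchange pool; PA is
    then evaluated for every trait on the common TS.
    """
    rng = np.random.default_rng() if rng is None else rng
    values = rank_sum_values(aems, traits)
    x = round_half_away(top_frac * 100)
    rows, canceled = [], 0
    meta = panel.clone_meta
    for y in exchanges:
        for rep in range(reps):
            ids = aems.index[~meta.loc[aems.index, "is_check"]
                             & aems[traits].notna().all(axis=1)]
            ts = _truncation_ts(values, ids, x, y, "bottom10", ts_size, rng)
            vs = ids.difference(ts)
            for trait in traits:
                pa = _predict_cell(aems[trait], h2[trait], G_A, ts, vs)
                if pa is None:
                    canceled += 1
                    continue
                rec = dict(cell=f"rank_y{y}", y=y, replicate=rep, trait=trait,
                           pa=pa)
                rec.update(_diversity_record(panel, ts, vs, aems[trait]))
                rows.append(rec)
    return ScenarioResult("rank_selection", pd.DataFrame(rows), canceled)


# ---------------------------------------------------------------------------
# discard-status inclusion
# ---------------------------------------------------------------------------


def discard_inclusion_scenario(panel: DosagePanel, aems: pd.DataFrame,
                               h2: pd.Series, G_A: RelationshipMatrix,
                               trait: str,
                               z_grid=(0, 10, 20, 30, 40, 50),
                               ts_size: int = 200, reps: int = 150,
                               stratified: bool = True,
                               rng: np.random.Generator | None = None
                               ) -> ScenarioResult:
    """Exchange advanced TS clones for single-hills discards (status 1).

    The baseline TS is stratified over families among status-0 clones; for
    z > 0, z% of the TS is swapped for status-1 clones of the same families
    so per-family contributions stay constant (``stratified=False`` swaps at
    random instead).  The VS contains only status-0 clones.  Replicates
    whose family-wise exchange is infeasible are resampled and noted.
    """
    rng = np.random.default_rng() if rng is None else rng
    meta = panel.clone_meta
    ok = aems.index[aems[trait].notna() & ~meta.loc[aems.index, "is_check"]]
    status = meta.loc[ok, "discard_status"]
    s0 = ok[status == 0]
    s1 = ok[status == 1]
    fam = meta.loc[ok, "family"]
    rows, canceled, notes = [], 0, []
    shares = fam.loc[s0].value_counts(normalize=True)
    for z in z_grid:
        n_swap = round_half_away(ts_size * z / 100.0)
        for rep in range(reps):
            for attempt in range(20):
                ts0 = []
                for f, share in shares.items():
                    members = s0[fam.loc[s0] == f]
                    take = min(len(members), round_half_away(share * ts_size))
                    if take:
                        ts0.extend(rng.choice(members, take, replace=False))
                ts0 = pd.Index(ts0)
                if n_swap == 0:
                    ts = ts0
                    break
                if not stratified:
                    pool = s1
                    if len(pool) < n_swap:
                        raise ValueError("not enough status-1 clones")
                    out = pd.Index(rng.choice(ts0, n_swap, replace=False))
                    inn = pd.Index(rng.choice(pool, n_swap, replace=False))
                    ts = ts0.difference(out).union(inn)
                    break
                # family-preserving swap: walk the TS in random order and
                # exchange members whose family still has a spare status-1
                # clone, so per-family contributions stay constant
                avail = {f: list(s1[fam.loc[s1] == f]) for f in shares.index}
                out, inn = [], []
                for c in rng.permutation(np.array(ts0, dtype=object)):
                    spare = avail.get(fam.loc[c])
                    if spare:
                        out.append(c)
                        inn.append(spare.pop(int(rng.integers(len(spare)))))
                        if len(out) == n_swap:
                            break
                if len(out) < n_swap:
                    notes.append(f"z={z} rep={rep}: resampled (families "
                                 f"lack discards)")
                    continue
                ts = ts0.difference(pd.Index(out)).union(pd.Index(inn))
                break
            else:
                canceled += 1
                continue
            vs = s0.difference(ts)
            pa = _predict_cell(aems[trait], h2[trait], G_A, ts, vs)
            if pa is None:
                canceled += 1
                continue
            rec = dict(cell=f"z{z}", z=z, replicate=rep, trait=trait, pa=pa)
            rec.update(_diversity_record(panel, ts, vs, aems[trait]))
            rows.append(rec)
    return ScenarioResult("discard_inclusion", pd.DataFrame(rows), canceled,
                          notes)
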