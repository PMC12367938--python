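"""Synthetic autotetraploid breeding populations and augmented field trials.

The generator emulates the structure of a commercial tetraploid potato
breeding panel: ~171 biparental (full-sib) families of 1-38 clones derived
from founder parents, four market segments with mild allele-frequency
differentiation, three breeding companies that each test their own entries
in five environments, augmented designs in which eight replicated check
varieties calibrate blocks of otherwise unreplicated entries, ordinal (1-9),
percentage and kilogram trait scales, heterogeneous residual variances per
environment, and breeder discard labels from early-stage index selection.

Meiosis is bivalent-only: the four homologs pair at random into two
bivalents, recombination follows the Haldane map function within each
bivalent, and one chromatid per bivalent enters the gamete, so the three
heterozygote classes segregate exactly as the dominance model assumes
(no double reduction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DosagePanel

# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass
class TraitSpec:
    """Generative parameters of one trait.

    ``resid_var_per_env=None`` calibrates the mean residual variance so the
    entry-mean heritability implied by the layout matches ``target_h2``:
    with J environments per entry, h2 = s2_g / (s2_g + (s2_gxe + s2_eps)/J),
    solved for s2_eps and spread over environments with a +/-30% gradient.
    """

    name: str
    scale: str = "ordinal-1to9"          # ordinal-1to9 | percent | kg
    target_h2: float = 0.8
    additive_var: float = 1.0
    dominance_var: float = 0.0
    gxe_var: float = 0.0
    env_var: float = 0.5
    block_var: float = 0.05
    row_var: float = 0.02
    col_var: float = 0.02
    trial_var: float = 0.0
    resid_var_per_env: list[float] | None = None
    segment_shift: dict[str, float] | None = None
    mean: float | None = None

    def __post_init__(self):
        if self.scale not in ("ordinal-1to9", "percent", "kg"):
            raise ValueError(f"unknown trait scale {self.scale!r}")
        if not (0.0 < self.target_h2 <= 1.0):
            raise ValueError("target_h2 must lie in (0, 1]")
        for attr in ("additive_var", "dominance_var", "gxe_var", "env_var",
                     "block_var", "row_var", "col_var", "trial_var"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be nonnegative")
        if self.mean is None:
            self.mean = {"ordinal-1to9": 5.0, "percent": 50.0, "kg": 8.0}[self.scale]

    @property
    def genetic_var(self) -> float:
        return self.additive_var + self.dominance_var

    def resolve_resid_vars(self, n_env: int) -> np.ndarray:
        if self.resid_var_per_env is not None:
            v = np.asarray(self.resid_var_per_env, dtype=float)
            if len(v) != n_env or np.any(v <= 0):
                raise ValueError("resid_var_per_env must be positive, one per env")
            return v
        s2g = self.genetic_var
        mean_eps = max(n_env * s2g * (1.0 - self.target_h2) / self.target_h2
                       - self.gxe_var, 0.01 * s2g)
        spread = np.linspace(0.7, 1.3, n_env)
        return mean_eps * spread / spread.mean()


@dataclass
class LayoutSpec:
    """Field layout: companies x environments, blocks, checks, plot grids."""

    envs_per_company: int = 5
    blocks_per_env: int = 8
    n_checks: int = 8
    check_reps_per_env: int = 8
    plants_per_plot: int = 16
    n_trial_split_envs: int = 0       # envs of company 1 split into two trials

    def __post_init__(self):
        if self.envs_per_company < 1 or self.blocks_per_env < 1:
            raise ValueError("need at least one environment and block")
        if self.check_reps_per_env < self.blocks_per_env:
            raise ValueError("checks must appear at least once per block")


@dataclass
class SimConfig:
    """Everything needed to draw one synthetic breeding population."""

    n_founders: int = 60
    n_families: int = 171
    family_size_range: tuple[int, int] = (1, 38)
    mean_family_size: float = 6.2
    n_chromosomes: int = 12
    chrom_length_cM: float = 100.0
    n_markers: int = 3000
    n_qtl_per_trait: int = 100
    segment_labels: tuple[str, ...] = ("CR", "FF", "TA", "ST")
    segment_weights: tuple[float, ...] = (0.36, 0.25, 0.25, 0.14)
    company_labels: tuple[str, ...] = ("B1", "B2", "B3")
    segment_freq_shift_sd: float = 0.15
    trait_specs: list[TraitSpec] = field(default_factory=list)
    layout: LayoutSpec = field(default_factory=LayoutSpec)
    seed: int = 0

    def __post_init__(self):
        if self.n_founders < 2:
            raise ValueError("need at least two founders")
        if self.n_markers < 1 or self.n_chromosomes < 1:
            raise ValueError("need at least one marker and one chromosome")
        lo, hi = self.family_size_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid family size range")
        if len(self.segment_labels) != len(self.segment_weights):
            raise ValueError("segment labels and weights must align")
        if not self.trait_specs:
            self.trait_specs = default_trait_specs()

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def default_trait_specs() -> list[TraitSpec]:
    """Trait architectures spanning the heritability range of a potato panel.

    STA (starch %, h2 0.95), FLE (flesh colour 1-9, h2 0.89, with a
    segment-structured mean), YLD (kg, h2 0.78), EMR (emergence 1-9,
    h2 0.74, strongly environment-driven).
    """
    return [
        TraitSpec(name="STA", scale="percent", target_h2=0.95,
                  additive_var=9.0, env_var=2.0,
                  segment_shift={"ST": 3.0, "CR": 0.5, "FF": 0.0, "TA": -1.0}),
        TraitSpec(name="FLE", scale="ordinal-1to9", target_h2=0.89,
                  additive_var=1.2, dominance_var=0.3, env_var=0.3,
                  segment_shift={"ST": 0.0, "CR": 0.3, "FF": -0.3, "TA": 0.6}),
        TraitSpec(name="YLD", scale="kg", target_h2=0.78,
                  additive_var=1.6, gxe_var=0.8, env_var=1.5),
        TraitSpec(name="EMR", scale="ordinal-1to9", target_h2=0.74,
                  additive_var=0.8, gxe_var=0.4, env_var=0.8),
    ]


# ---------------------------------------------------------------------------
# founders and meiosis
# ---------------------------------------------------------------------------


@dataclass
class FounderSet:
    haplotypes: np.ndarray           # (n_founders, 4, n_markers) 0/1
    marker_map: pd.DataFrame         # index marker id, columns chrom, pos, cM
    founder_segment: np.ndarray      # segment label per founder


def _marker_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    per = np.full(config.n_chromosomes, config.n_markers // config.n_chromosomes)
    per[: config.n_markers % config.n_chromosomes] += 1
    rows = []
    for c, k in enumerate(per, start=1):
        cm = np.sort(rng.uniform(0.0, config.chrom_length_cM, size=k))
        for j, pos_cm in enumerate(cm):
            rows.append((f"chr{c:02d}", pos_cm))
    mm = pd.DataFrame(rows, columns=["chrom", "cM"])
    mm["pos"] = (mm["cM"] * 1e4).round().astype(int) + 1   # 1-based bp
    mm.index = pd.Index([f"M{i + 1:06d}" for i in range(len(mm))], name="marker")
    return mm[["chrom", "pos", "cM"]]


def simulate_founders(config: SimConfig,
                      rng: np.random.Generator | None = None,
                      base_freq: np.ndarray | None = None) -> FounderSet:
    """Draw founder tetraploid haplotypes.

    Allele frequencies come from Beta(2, 2) per marker (overridable), with a
    per-segment logit shift of SD ``segment_freq_shift_sd`` that induces the
    mild differentiation seen among market segments.
    """
    rng = config.rng() if rng is None else rng
    mm = _marker_map(config, rng)
    m = len(mm)
    p0 = rng.beta(2.0, 2.0, size=m) if base_freq is None \
        else np.broadcast_to(np.asarray(base_freq, float), (m,)).copy()
    segs = list(config.segment_labels)
    founder_segment = np.array(
        [segs[i % len(segs)] for i in range(config.n_founders)])
    shift = {s: rng.normal(0.0, config.segment_freq_shift_sd, size=m)
             for s in segs}
    with np.errstate(divide="ignore"):
        logit0 = np.log(p0 / (1.0 - p0))
    haps = np.empty((config.n_founders, 4, m), dtype=np.int8)
    for i, seg in enumerate(founder_segment):
        logit = logit0 + shift[seg]
        p = np.where(p0 <= 0.0, 0.0,
                     np.where(p0 >= 1.0, 1.0, 1.0 / (1.0 + np.exp(-logit))))
        haps[i] = rng.random((4, m)) < p
    return FounderSet(haplotypes=haps, marker_map=mm,
                      founder_segment=founder_segment)


def _recomb_fractions(cm: np.ndarray) -> np.ndarray:
    """Haldane recombination fractions between consecutive markers."""
    d = np.diff(cm)
    return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))


def bivalent_gametes(parent_haps: np.ndarray, n: int,
                     rng: np.random.Generator,
                     chrom_slices: list[slice],
                     rec_fracs: list[np.ndarray]) -> np.ndarray:
    """Draw ``n`` diploid gametes (n, 2, m) from one tetraploid parent.

    Per chromosome and gamete: the four homologs pair at random into two
    bivalents; within each bivalent a recombinant chromatid is formed by a
    Markov walk along markers with Haldane switch probabilities; one
    chromatid per bivalent enters the gamete.
    """
    m = parent_haps.shape[1]
    out = np.empty((n, 2, m), dtype=np.int8)
    for sl, rf in zip(chrom_slices, rec_fracs):
        haps = parent_haps[:, sl]                       # (4, mc)
        mc = haps.shape[1]
        perms = rng.permuted(np.tile(np.arange(4), (n, 1)), axis=1)
        # state 0/1 selects between the two homologs of each bivalent
        start = rng.integers(0, 2, size=(n, 2, 1))
        if mc > 1:
            switches = rng.random((n, 2, mc - 1)) < rf
            state = np.concatenate(
                [start, (start + np.cumsum(switches, axis=2)) % 2], axis=2)
        else:
            state = start
        for b in range(2):
            first = haps[perms[:, 2 * b]]               # (n, mc)
            second = haps[perms[:, 2 * b + 1]]
            out[:, b, sl] = np.where(state[:, b] == 0, first, second)
    return out


def simulate_cross(parent_a: np.ndarray, parent_b: np.ndarray, n_offspring: int,
                   rng: np.random.Generator,
                   marker_map: pd.DataFrame) -> np.ndarray:
    """Offspring tetraploid haplotypes (n, 4, m) from two parents."""
    if n_offspring < 1:
        raise ValueError("n_offspring must be at least 1")
    chrom_slices, rec_fracs = _chromosome_geometry(marker_map)
    ga = bivalent_gametes(parent_a, n_offspring, rng, chrom_slices, rec_fracs)
    gb = bivalent_gametes(parent_b, n_offspring, rng, chrom_slices, rec_fracs)
    return np.concatenate([ga, gb], axis=1)


def _chromosome_geometry(marker_map: pd.DataFrame):
    chrom_slices, rec_fracs = [], []
    startpos = 0
    for chrom, grp in marker_map.groupby("chrom", sort=False):
        k = len(grp)
        chrom_slices.append(slice(startpos, startpos + k))
        cm = grp["cM"].to_numpy() if "cM" in grp else grp["pos"].to_numpy() / 1e4
        rec_fracs.append(_recomb_fractions(cm))
        startpos += k
    return chrom_slices, rec_fracs


# ---------------------------------------------------------------------------
# population assembly
# ---------------------------------------------------------------------------


def _family_sizes(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = config.family_size_range
    p = min(1.0, 1.0 / config.mean_family_size)
    sizes = np.clip(rng.geometric(p, size=config.n_families), lo, hi)
    return sizes


def simulate_population(config: SimConfig):
    """Draw the full clone panel: founders, families, checks, metadata.

    Returns ``(panel, founders, pedigree)`` where the panel's clone metadata
    carries family, segment, company and check flags (discard status is
    assigned later from trait values).
    """
    rng = config.rng()
    founders = simulate_founders(config, rng)
    mm = founders.marker_map
    sizes = _family_sizes(config, rng)
    segs = rng.choice(len(config.segment_labels), size=config.n_families,
                      p=np.asarray(config.segment_weights))
    companies = rng.integers(0, len(config.company_labels),
                             size=config.n_families)
    seg_founders = {s: np.nonzero(founders.founder_segment == s)[0]
                    for s in config.segment_labels}

    dosages, meta_rows, pedigree = [], [], []
    clone_ids = []
    for f in range(config.n_families):
        seg = config.segment_labels[segs[f]]
        pool = seg_founders[seg]
        if len(pool) >= 2:
            pa, pb = rng.choice(pool, size=2, replace=False)
        else:
            pa, pb = rng.choice(config.n_founders, size=2, replace=False)
        offs = simulate_cross(founders.haplotypes[pa], founders.haplotypes[pb],
                              int(sizes[f]), rng, mm)
        dosages.append(offs.sum(axis=1))
        fam = f"F{f + 1:03d}"
        pedigree.append((fam, int(pa), int(pb)))
        for j in range(int(sizes[f])):
            clone_ids.append(f"{fam}_{j + 1:02d}")
            meta_rows.append((fam, seg, config.company_labels[companies[f]],
                              False, 0))
    # checks: crosses between random founders, shared across companies
    for c in range(config.layout.n_checks):
        pa, pb = rng.choice(config.n_founders, size=2, replace=False)
        offs = simulate_cross(founders.haplotypes[pa], founders.haplotypes[pb],
                              1, rng, mm)
        dosages.append(offs.sum(axis=1))
        clone_ids.append(f"CHK{c + 1:02d}")
        meta_rows.append((f"CHKFAM", "CHK", "ALL", True, 0))
        pedigree.append((f"CHKFAM{c + 1}", int(pa), int(pb)))

    dosage = pd.DataFrame(np.vstack(dosages), index=pd.Index(clone_ids, name="clone"),
                          columns=mm.index)
    meta = pd.DataFrame(meta_rows, index=dosage.index,
                        columns=["family", "segment", "company", "is_check",
                                 "discard_status"])
    panel = DosagePanel(dosage=dosage, marker_map=mm[["chrom", "pos", "cM"]],
                        clone_meta=meta)
    return panel, founders, pedigree


# ---------------------------------------------------------------------------
# genetic values
# ---------------------------------------------------------------------------


@dataclass
class TraitTruth:
    qtl_markers: list[str]
    additive_effects: np.ndarray           # a per QTL
    dominance_effects: np.ndarray          # (3, n_qtl) class deviations d1..d3
    breeding_values: pd.Series             # additive part per clone
    genetic_values: pd.Series              # additive + dominance + segment shift
    realized_additive_var: float
    realized_dominance_var: float


@dataclass
class TruthSet:
    traits: dict[str, TraitTruth]
    gxe: dict[str, pd.DataFrame] = field(default_factory=dict)

    def breeding_values(self) -> pd.DataFrame:
        return pd.DataFrame({t: tt.breeding_values
                             for t, tt in self.traits.items()})

    def genetic_values(self) -> pd.DataFrame:
        return pd.DataFrame({t: tt.genetic_values
                             for t, tt in self.traits.items()})


def simulate_genetic_values(panel: DosagePanel, spec: TraitSpec,
                            rng: np.random.Generator,
                            n_qtl: int = 100) -> TraitTruth:
    """Draw QTL effects and compute true genetic values for every clone.

    Additive effects are N(0,1) draws rescaled so the realized additive
    variance over the panel equals ``additive_var`` exactly; dominance-class
    deviations (one per heterozygous dosage class per QTL) are rescaled to
    ``dominance_var`` likewise.
    """
    n_qtl = min(n_qtl, panel.n_markers)
    qtl_idx = np.sort(rng.choice(panel.n_markers, size=n_qtl, replace=False))
    qtl_markers = list(panel.markers[qtl_idx])
    M = panel.dosage.iloc[:, qtl_idx].to_numpy(dtype=float)
    if np.isnan(M).any():
        raise ValueError("genetic values need complete dosages")

    a = rng.normal(0.0, 1.0, size=n_qtl)
    bv_raw = M @ a
    va = float(np.var(bv_raw))
    if spec.additive_var > 0 and va > 0:
        a *= np.sqrt(spec.additive_var / va)
    elif spec.additive_var == 0:
        a[:] = 0.0
    bv = M @ a
    realized_va = float(np.var(bv))

    d = rng.normal(0.0, 1.0, size=(3, n_qtl))
    het = np.stack([(M == c).astype(float) for c in (1, 2, 3)])  # (3, n, q)
    dom_raw = np.einsum("cnq,cq->n", het, d)
    vd = float(np.var(dom_raw))
    if spec.dominance_var > 0:
        if vd == 0:
            warnings.warn("dominance variance requested but no heterozygous "
                          "QTL genotypes; realized dominance variance is 0")
            d[:] = 0.0
        else:
            d *= np.sqrt(spec.dominance_var / vd)
    else:
        d[:] = 0.0
    dom = np.einsum("cnq,cq->n", het, d)
    realized_vd = float(np.var(dom))

    g = bv + dom
    if spec.segment_shift:
        shifts = panel.clone_meta["segment"].map(
            lambda s: spec.segment_shift.get(s, 0.0)).to_numpy(dtype=float)
        g = g + shifts
    return TraitTruth(
        qtl_markers=qtl_markers,
        additive_effects=a,
        dominance_effects=d,
        breeding_values=pd.Series(bv, index=panel.clones, name=spec.name),
        genetic_values=pd.Series(g, index=panel.clones, name=spec.name),
        realized_additive_var=realized_va,
        realized_dominance_var=realized_vd,
    )


# ---------------------------------------------------------------------------
# field trials
# ---------------------------------------------------------------------------


def _block_grid(n_plots: int) -> tuple[int, int]:
    rows = int(np.ceil(np.sqrt(n_plots)))
    cols = int(np.ceil(n_plots / rows))
    return rows, cols


def simulate_trials(panel: DosagePanel, truth: TruthSet, config: SimConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate the plot-level phenotype table for the whole experiment.

    Entries appear once per environment of their breeding company; the
    checks appear ``check_reps_per_env`` times per environment, at least
    once in every block.  Plot values follow
    y = mu + g_i + e_j + (ge)_ij + b_kj + r_lkj + h_mkj + eps with the
    residual variance specific to each environment.  Ordinal traits are
    rounded and clipped to 1-9, percentages clipped to 0-100; kilogram
    traits additionally record planted/missing plant counts and the raw
    (un-normalised) plot yield.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    layout = config.layout
    meta = panel.clone_meta
    checks = list(meta.index[meta["is_check"]])
    plots = []
    env_names = []
    for ci, comp in enumerate(config.company_labels):
        entries = list(meta.index[(meta["company"] == comp) & ~meta["is_check"]])
        for e in range(layout.envs_per_company):
            env = f"{comp}_E{e + 1}"
            env_names.append(env)
            n_blocks = layout.blocks_per_env
            split = (ci == 0 and e >= layout.envs_per_company
                     - layout.n_trial_split_envs)
            # entry assignment to blocks: round-robin after a shuffle
            perm = list(rng.permutation(entries))
            check_plots = []
            for rep in range(layout.check_reps_per_env):
                for chk in checks:
                    check_plots.append((chk, rep % n_blocks))
            blocks: dict[int, list[str]] = {b: [] for b in range(n_blocks)}
            for i, clone in enumerate(perm):
                blocks[i % n_blocks].append(clone)
            for chk, b in check_plots:
                blocks[b].append(chk)
            for b, members in blocks.items():
                members = list(rng.permutation(members))
                nrow, _ncol = _block_grid(len(members))
                trial = "T1"
                if split:
                    trial = "T1" if b < n_blocks // 2 else "T2"
                for i, clone in enumerate(members):
                    plots.append((clone, env, trial, f"B{b + 1}",
                                  i % nrow + 1, i // nrow + 1,
                                  bool(meta.at[clone, "is_check"])))
    table = pd.DataFrame(plots, columns=["clone", "env", "trial", "block",
                                         "row", "col", "is_check"])

    # effect draws, one stream per trait for clean bookkeeping
    env_index = pd.Index(env_names, name="env")
    for spec in config.trait_specs:
        tt = truth.traits[spec.name]
        g = tt.genetic_values
        n_env = layout.envs_per_company
        resid = spec.resolve_resid_vars(n_env)
        resid_by_env = {env: resid[int(env.split("_E")[1]) - 1]
                        for env in env_names}
        e_j = pd.Series(rng.normal(0, np.sqrt(spec.env_var), len(env_index)),
                        index=env_index)
        ge = pd.DataFrame(
            rng.normal(0, np.sqrt(spec.gxe_var), (panel.n_clones, len(env_index))),
            index=panel.clones, columns=env_index)
        truth.gxe[spec.name] = ge
        blk_key = table["env"] + "|" + table["block"].astype(str)
        trial_key = table["env"] + "|" + table["trial"]
        row_key = blk_key + "|r" + table["row"].astype(str)
        col_key = blk_key + "|c" + table["col"].astype(str)
        b_eff = _random_effect(blk_key, spec.block_var, rng)
        t_eff = _random_effect(trial_key, spec.trial_var, rng)
        r_eff = _random_effect(row_key, spec.row_var, rng)
        c_eff = _random_effect(col_key, spec.col_var, rng)
        eps_sd = table["env"].map(resid_by_env).to_numpy() ** 0.5
        y = (spec.mean
             + g.loc[table["clone"]].to_numpy()
             + e_j.loc[table["env"]].to_numpy()
             + ge.to_numpy()[panel.clones.get_indexer(table["clone"]),
                             env_index.get_indexer(table["env"])]
             + t_eff + b_eff + r_eff + c_eff
             + rng.normal(0, 1, len(table)) * eps_sd)
        if spec.scale == "ordinal-1to9":
            y = np.clip(np.round(y), 1, 9)
        elif spec.scale == "percent":
            y = np.clip(y, 0.0, 100.0)
        if spec.scale == "kg":
            pn = np.full(len(table), layout.plants_per_plot)
            mp = rng.binomial(pn, 0.04)
            denom = np.where(mp > 0.2 * pn, pn - mp, pn)
            table[spec.name + "_raw"] = y * denom / 16.0
            table["PN"] = pn
            table["MP"] = mp
        table[spec.name] = y
    return table


def _random_effect(keys: pd.Series, var: float,
                   rng: np.random.Generator) -> np.ndarray:
    codes, levels = pd.factorize(keys)
    eff = rng.normal(0.0, np.sqrt(var), size=len(levels)) if var > 0 \
        else np.zeros(len(levels))
    return eff[codes]


# ---------------------------------------------------------------------------
# discard status
# ---------------------------------------------------------------------------


def assign_discard_status(panel: DosagePanel, truth: TruthSet,
                          weights: dict[str, float],
                          rng: np.random.Generator,
                          discard_frac: float = 0.31,
                          family_discard_frac: float = 0.064,
                          noise_sd: float = 1.0) -> pd.Series:
    """Breeder discard labels from early-stage index selection.

    A selection index (weighted true genetic values plus noise, both
    standardised) ranks clones; whole families with the lowest family-mean
    index are discarded first (status 2) up to ``family_discard_frac`` of
    clones, then the worst remaining clones within retained families get
    status 1 until ``discard_frac`` of all clones is reached.  Checks are
    never discarded.
    """
    for t in weights:
        if t not in truth.traits:
            raise ValueError(f"weight refers to unknown trait {t!r}")
    meta = panel.clone_meta
    entries = meta.index[~meta["is_check"]]
    index = pd.Series(0.0, index=entries)
    for t, w in weights.items():
        g = truth.traits[t].genetic_values.loc[entries]
        sd = g.std()
        if sd > 0:
            index = index + w * (g - g.mean()) / sd
    if np.isfinite(noise_sd):
        index = index + rng.normal(0.0, noise_sd, size=len(entries))
    else:
        index = pd.Series(rng.normal(0.0, 1.0, size=len(entries)),
                          index=entries)

    status = pd.Series(0, index=meta.index, dtype=int)
    fam = meta.loc[entries, "family"]
    fam_mean = index.groupby(fam).mean().sort_values()
    fam_sizes = fam.value_counts()
    target_fam = int(round(family_discard_frac * len(entries)))
    discarded_fam, n_fam_disc = [], 0
    for f in fam_mean.index:
        if n_fam_disc >= target_fam:
            break
        discarded_fam.append(f)
        n_fam_disc += int(fam_sizes[f])
    status.loc[entries[fam.isin(discarded_fam)]] = 2

    target_total = int(round(discard_frac * len(entries)))
    n_more = max(0, target_total - int((status.loc[entries] == 2).sum()))
    remaining = index[~fam.isin(discarded_fam)]
    rem_fam = fam.loc[remaining.index]
    # keep at least one clone per retained family
    order = remaining.sort_values().index
    kept_count = rem_fam.value_counts().to_dict()
    chosen = []
    for clone in order:
        if len(chosen) >= n_more:
            break
        f = rem_fam[clone]
        if kept_count[f] > 1:
            chosen.append(clone)
            kept_count[f] -= 1
    status.loc[chosen] = 1
    return status


# ---------------------------------------------------------------------------
# one-call dataset
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    panel: DosagePanel
    truth: TruthSet
    plots: pd.DataFrame
    config: SimConfig


def simulate_dataset(config: SimConfig,
                     discard_weights: dict[str, float] | None = None) -> SimulatedDataset:
    """Population, genetic values, trials and discard labels in one call."""
    panel, _founders, _ped = simulate_population(config)
    rng = np.random.default_rng(config.seed + 1)
    traits = {spec.name: simulate_genetic_values(panel, spec, rng,
                                                 n_qtl=config.n_qtl_per_trait)
              for spec in config.trait_specs}
    truth = TruthSet(traits=traits)
    plots = simulate_trials(panel, truth, config, rng)
    if discard_weights is None:
        names = [s.name for s in config.trait_specs]
        discard_weights = {n: 1.0 for n in names[: min(2, len(names))]}
    status = assign_discard_status(panel, truth, discard_weights, rng)
    panel.clone_meta["discard_status"] = status.reindex(panel.clones).fillna(0).astype(int)
    return SimulatedDataset(panel=panel, truth=truth, plots=plots, config=config)
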