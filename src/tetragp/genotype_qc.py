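"""SNP filtering, imputation, and autotetraploid genomic relationship matrices.

The additive matrix follows the VanRaden construction generalised to ploidy
four: columns of the dosage matrix are centred by ``4 p_j`` and

    G_A = W W' / (4 * sum_j p_j (1 - p_j)).

The dominance matrix codes the three heterozygous dosage classes (1 = Aaaa,
2 = AAaa, 3 = AAAa) as separate indicator blocks X_d1, X_d2, X_d3 and uses

    G_D = [X_d1 X_d2 X_d3] [X_d1 X_d2 X_d3]' / (3 m).

Dominance coding requires integer dosages, hence the dedicated median-class
imputation that assigns every missing call to a unique genotype class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import DosagePanel, RelationshipMatrix


@dataclass
class FilterReport:
    n_markers_in: int
    n_removed_missing: int
    n_removed_maf: int
    n_markers_out: int


def filter_markers(panel: DosagePanel, max_missing: float = 0.20,
                   min_maf: float = 0.05) -> tuple[DosagePanel, FilterReport]:
    """Retain markers with missing fraction strictly below ``max_missing`` and
    minor allele frequency at least ``min_maf``.

    A marker failing both rules is counted under the missingness rule.
    Raises ``ValueError`` if no marker survives.
    """
    miss = panel.dosage.isna().mean(axis=0)
    p = panel.allele_freq()
    maf = np.minimum(p, 1.0 - p)
    ok_miss = miss < max_missing
    ok_maf = maf >= min_maf
    keep = ok_miss & ok_maf
    report = FilterReport(
        n_markers_in=panel.n_markers,
        n_removed_missing=int((~ok_miss).sum()),
        n_removed_maf=int((ok_miss & ~ok_maf).sum()),
        n_markers_out=int(keep.sum()),
    )
    if report.n_markers_out == 0:
        raise ValueError("marker filtering removed every marker")
    return panel.subset_markers(panel.markers[keep]), report


def impute_mean(panel: DosagePanel) -> pd.DataFrame:
    """Replace missing dosages by the marker mean over non-missing clones.

    Returns a real-valued complete matrix; observed cells are untouched.
    """
    means = panel.dosage.mean(axis=0, skipna=True)
    if means.isna().any():
        bad = list(means.index[means.isna()])
        raise ValueError(f"markers with all values missing: {bad[:5]}")
    return panel.dosage.fillna(means)


def impute_median_classes(panel: DosagePanel) -> pd.DataFrame:
    """Replace missing dosages by the marker median rounded to an integer class.

    Guarantees a unique genotype-class assignment (0..4) at every cell, as
    required for dominance coding.  Observed cells are rounded too only if
    they are already integers (non-integer observed dosage is an error).
    """
    vals = panel.dosage.to_numpy(dtype=float)
    obs = ~np.isnan(vals)
    if not np.allclose(vals[obs], np.round(vals[obs])):
        raise ValueError("observed dosages must be integers for class imputation")
    med = panel.dosage.median(axis=0, skipna=True)
    if med.isna().any():
        bad = list(med.index[med.isna()])
        raise ValueError(f"markers with all values missing: {bad[:5]}")
    classes = np.clip(np.round(med.to_numpy()), 0, 4)
    out = panel.dosage.fillna(pd.Series(classes, index=panel.markers))
    return out.round().astype(int)


def additive_grm(dosage: pd.DataFrame) -> RelationshipMatrix:
    """Additive autotetraploid genomic relationship matrix.

    ``dosage`` must be complete (mean-imputed); every marker must be
    polymorphic in the analysed set, i.e. p_j in (0, 1).
    """
    M = dosage.to_numpy(dtype=float)
    if M.shape[0] < 2:
        raise ValueError("need at least two clones for a relationship matrix")
    if np.isnan(M).any():
        raise ValueError("dosage matrix contains missing values; impute first")
    p = M.mean(axis=0) / 4.0
    if np.any((p <= 0.0) | (p >= 1.0)) or np.any(M.var(axis=0) == 0.0):
        raise ValueError("monomorphic marker in additive GRM input; filter first")
    W = M - 4.0 * p
    denom = 4.0 * np.sum(p * (1.0 - p))
    G = (W @ W.T) / denom
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(labels=dosage.index, values=G, kind="additive")


def dominance_grm(dosage: pd.DataFrame) -> RelationshipMatrix:
    """Dominance relationship matrix from the three heterozygote-class indicators."""
    M = dosage.to_numpy(dtype=float)
    if np.isnan(M).any() or not np.allclose(M, np.round(M)):
        raise ValueError(
            "dominance coding needs complete integer dosages; "
            "use impute_median_classes first")
    M = np.round(M).astype(int)
    m = M.shape[1]
    # X_d = [1(dosage==1), 1(dosage==2), 1(dosage==3)], shape n x 3m
    # G_D = X_d X_d' / 3m; computed classwise to avoid materialising X_d
    G = np.zeros((M.shape[0], M.shape[0]))
    for cls in (1, 2, 3):
        X = (M == cls).astype(float)
        G += X @ X.T
    G /= 3.0 * m
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(labels=dosage.index, values=G, kind="dominance")
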