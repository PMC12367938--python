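"""Genetic and phenotypic diversity statistics for tetraploid panels.

Expected heterozygosity treats a biallelic tetraploid locus as four random
allele draws: He = (1/m) * sum_j (1 - p_j^4 - q_j^4), which is bounded by
0.875 at p = 0.5.  Nei's standard genetic distance, Q_ST, and the Nei
fixation index F_ST = (H_t - H_s)/H_t are built on the same frequency
conventions as the relationship matrices (frequencies from mean dosages,
mean-imputed values included).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DosagePanel

#: maximum He of a biallelic tetrasomic locus (p = 1/2)
HE_MAX_BIALLELIC = 0.875


def _freqs(dosage: pd.DataFrame | np.ndarray) -> np.ndarray:
    arr = np.asarray(dosage, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("need a clones x markers dosage matrix")
    return np.nanmean(arr, axis=0) / 4.0


def expected_heterozygosity(dosage: pd.DataFrame | np.ndarray) -> float:
    """Tetraploid expected heterozygosity averaged over markers."""
    arr = np.asarray(dosage, dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least two clones")
    p = _freqs(arr)
    return float(np.mean(1.0 - p ** 4 - (1.0 - p) ** 4))


def expected_heterozygosity_from_freqs(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    return float(np.mean(1.0 - p ** 4 - (1.0 - p) ** 4))


def nei_distance(freqs_a: np.ndarray, freqs_b: np.ndarray) -> float:
    """Nei's standard genetic distance between two allele-frequency vectors.

    D = -ln( J_ab / sqrt(J_a * J_b) ), with identities J summed over the two
    alleles of every locus and averaged across loci.  Returns ``inf`` when
    the normalised identity is zero (sets fixed for alternate alleles at all
    loci).
    """
    pa = np.asarray(freqs_a, dtype=float)
    pb = np.asarray(freqs_b, dtype=float)
    if pa.shape != pb.shape:
        raise ValueError("frequency vectors must cover the same marker set")
    j_ab = np.mean(pa * pb + (1 - pa) * (1 - pb))
    j_a = np.mean(pa ** 2 + (1 - pa) ** 2)
    j_b = np.mean(pb ** 2 + (1 - pb) ** 2)
    if j_ab <= 0.0:
        return float("inf")
    return float(max(0.0, -np.log(j_ab / np.sqrt(j_a * j_b))))


def nei_distance_panels(set_a: pd.DataFrame | np.ndarray,
                        set_b: pd.DataFrame | np.ndarray) -> float:
    return nei_distance(_freqs(set_a), _freqs(set_b))


def qst(var_among: float, var_within: float) -> float:
    """Q_ST = sigma2_among / (sigma2_among + sigma2_within) for a quantitative trait."""
    if var_among < 0 or var_within < 0:
        raise ValueError("variance components must be nonnegative")
    total = var_among + var_within
    if total == 0:
        raise ValueError("Q_ST undefined when both components are zero")
    return var_among / total


def global_fst(panel: DosagePanel, groups: pd.Series | str = "segment") -> float:
    """Nei F_ST = (H_t - H_s) / H_t across the given grouping.

    H_t is the expected heterozygosity of the pooled panel treated as one
    meta-population; H_s the unweighted mean He of the groups.
    """
    labels = _group_labels(panel, groups)
    uniq = labels.unique()
    if len(uniq) < 2:
        raise ValueError("need at least two groups for F_ST")
    h_t = expected_heterozygosity(panel.dosage)
    h_parts = []
    for g in uniq:
        ids = labels.index[labels == g]
        if len(ids) < 2:
            raise ValueError(f"group {g!r} has fewer than two clones")
        h_parts.append(expected_heterozygosity(panel.dosage.loc[ids]))
    h_s = float(np.mean(h_parts))
    if h_t == 0:
        raise ValueError("F_ST undefined: total heterozygosity is zero")
    return (h_t - h_s) / h_t


def pairwise_fst(panel: DosagePanel, group_a: str, group_b: str,
                 groups: pd.Series | str = "segment") -> float:
    """F_ST restricted to two groups, same construction as :func:`global_fst`."""
    labels = _group_labels(panel, groups)
    ids = labels.index[labels.isin([group_a, group_b])]
    sub = panel.subset_clones(ids)
    return global_fst(sub, labels.loc[ids])


def _group_labels(panel: DosagePanel, groups) -> pd.Series:
    if isinstance(groups, str):
        return panel.clone_meta[groups]
    return pd.Series(groups).reindex(panel.clones)


def pca_panel(dosage: pd.DataFrame, n_components: int = 10):
    """PCA of the column-centred dosage matrix.

    Returns ``(coords, explained_fractions)`` with coordinates as a DataFrame
    (clones x components) and explained-variance fractions in non-increasing
    order.
    """
    X = np.asarray(dosage, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two clones for PCA")
    if np.isnan(X).any():
        raise ValueError("PCA input must be complete; mean-impute first")
    Xc = X - X.mean(axis=0)
    k = min(n_components, min(Xc.shape) - 1) or 1
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s ** 2))
    frac = (s ** 2 / total)[:k] if total > 0 else np.zeros(k)
    coords = pd.DataFrame(U[:, :k] * s[:k], index=dosage.index,
                          columns=[f"PC{i + 1}" for i in range(k)])
    return coords, frac


def phenotypic_variance(aems: pd.Series | np.ndarray) -> float:
    """Unbiased sample variance of a set of adjusted entry means."""
    x = np.asarray(aems, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValueError("need at least two values for a variance")
    return float(np.var(x, ddof=1))


def ttest_bonferroni(pairs: list[tuple[np.ndarray, np.ndarray]],
                     paired: bool = False) -> np.ndarray:
    """Two-sided t tests for a family of comparisons with Bonferroni correction.

    Returns corrected p-values (capped at 1).  Identical paired samples give
    p = 1 by convention.
    """
    ps = []
    for a, b in pairs:
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        if paired:
            d = a - b
            if np.allclose(d, 0):
                ps.append(1.0)
                continue
            p = stats.ttest_rel(a, b).pvalue
        else:
            p = stats.ttest_ind(a, b, equal_var=False).pvalue
        ps.append(float(p) if np.isfinite(p) else 1.0)
    return np.minimum(np.asarray(ps) * len(ps), 1.0)
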