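"""Core in-memory containers shared across the pipeline.

A :class:`DosagePanel` holds a clones x markers matrix of biallelic
autotetraploid allele dosages (0..4, ``NaN`` for missing) together with the
marker map and per-clone metadata (family, market segment, breeding company,
check flag, discard status).  A :class:`RelationshipMatrix` is a labelled
symmetric genomic relationship matrix (additive or dominance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: metadata columns guaranteed to exist on a panel (filled with defaults)
CLONE_META_COLUMNS = ("family", "segment", "company", "is_check", "discard_status")


@dataclass
class DosagePanel:
    """Clones x markers dosage matrix with marker map and clone metadata.

    Parameters
    ----------
    dosage
        DataFrame indexed by clone id, columns marker ids, values in
        ``{0,1,2,3,4}`` or ``NaN`` for missing calls.
    marker_map
        DataFrame indexed by marker id with columns ``chrom`` and ``pos``
        (1-based).  Must cover every dosage column, sorted within chromosome.
    clone_meta
        DataFrame indexed by clone id; missing metadata columns are filled
        with defaults (one family/segment/company, no checks, status 0).
    """

    dosage: pd.DataFrame
    marker_map: pd.DataFrame
    clone_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.dosage.index.duplicated().any():
            raise ValueError("duplicate clone ids in dosage matrix")
        if self.dosage.columns.duplicated().any():
            raise ValueError("duplicate marker ids in dosage matrix")
        vals = self.dosage.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | ((vals >= 0) & (vals <= 4)))
        if bad.any():
            raise ValueError("dosage values must lie in [0, 4] or be missing")
        if not set(self.dosage.columns) <= set(self.marker_map.index):
            raise ValueError("marker map does not cover all dosage columns")
        self.marker_map = self.marker_map.loc[list(self.dosage.columns)]
        for chrom, grp in self.marker_map.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError(f"marker map not sorted by position on {chrom!r}")
        if self.clone_meta is None or self.clone_meta.empty:
            self.clone_meta = pd.DataFrame(index=self.dosage.index)
        self.clone_meta = self.clone_meta.reindex(self.dosage.index)
        defaults = {"family": "F0", "segment": "S0", "company": "B0",
                    "is_check": False, "discard_status": 0}
        for col in CLONE_META_COLUMNS:
            if col not in self.clone_meta.columns:
                self.clone_meta[col] = defaults[col]
        self.clone_meta["is_check"] = self.clone_meta["is_check"].astype(bool)
        self.clone_meta["discard_status"] = self.clone_meta["discard_status"].astype(int)

    # -- basic accessors -------------------------------------------------
    @property
    def clones(self) -> pd.Index:
        return self.dosage.index

    @property
    def markers(self) -> pd.Index:
        return self.dosage.columns

    @property
    def n_clones(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def allele_freq(self) -> pd.Series:
        """Per-marker counted-allele frequency p = mean(dosage)/4 over non-missing."""
        return self.dosage.mean(axis=0, skipna=True) / 4.0

    def subset_clones(self, ids) -> "DosagePanel":
        ids = list(ids)
        return DosagePanel(self.dosage.loc[ids], self.marker_map.copy(),
                           self.clone_meta.loc[ids].copy())

    def subset_markers(self, ids) -> "DosagePanel":
        ids = list(ids)
        return DosagePanel(self.dosage[ids], self.marker_map.loc[ids].copy(),
                           self.clone_meta.copy())


@dataclass
class RelationshipMatrix:
    """Labelled symmetric genomic relationship matrix (additive or dominance)."""

    labels: pd.Index
    values: np.ndarray
    kind: str  # "additive" | "dominance"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("relationship matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix is not symmetric")
        if self.kind not in ("additive", "dominance"):
            raise ValueError(f"unknown relationship kind {self.kind!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def submatrix(self, rows, cols=None) -> np.ndarray:
        idx = pd.Index(self.labels)
        ri = idx.get_indexer(list(rows))
        ci = ri if cols is None else idx.get_indexer(list(cols))
        if (ri < 0).any() or (ci < 0).any():
            raise KeyError("unknown clone id in relationship matrix lookup")
        return self.values[np.ix_(ri, ci)]

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values).min())
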