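"""Reading and writing the pipeline's on-disk formats.

Dosage panels travel as TSV (clones x markers, ``NA`` for missing) with a
marker-map TSV (marker, chrom, pos; 1-based positions) and a clone-metadata
TSV, or as VCF with tetraploid genotype fields (``0/0/1/1`` -> dosage 2).
Plot tables are CSV, adjusted-entry-mean tables TSV, scenario results
long-format TSV plus a JSON summary.  Every result file carries seed,
config hash and package version in ``#`` header comments.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import DosagePanel

NA = "NA"


# ---------------------------------------------------------------------------
# dosage panels
# ---------------------------------------------------------------------------


def read_dosage(path, fmt: str | None = None,
                marker_map_path=None, clone_meta_path=None) -> DosagePanel:
    """Read a dosage panel from TSV or VCF (format inferred from suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in (".vcf", ".bcf") or \
            path.name.endswith(".vcf.gz") else "tsv"
    if fmt == "vcf":
        return _read_vcf(path)
    dosage = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])
    dosage.index.name = "clone"
    dosage.columns.name = "marker"
    if marker_map_path is not None:
        mm = pd.read_csv(marker_map_path, sep="\t", index_col=0)
    else:
        mm = pd.DataFrame({"chrom": "chr01",
                           "pos": np.arange(1, dosage.shape[1] + 1)},
                          index=dosage.columns)
    meta = (pd.read_csv(clone_meta_path, sep="\t", index_col=0)
            if clone_meta_path is not None else pd.DataFrame(index=dosage.index))
    return DosagePanel(dosage=dosage, marker_map=mm, clone_meta=meta)


def _read_vcf(path: Path) -> DosagePanel:
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        rows, map_rows, ids = [], [], []
        for rec in vf:
            mid = rec.id or f"{rec.chrom}_{rec.pos}"
            dos = np.full(len(samples), np.nan)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is None or all(a is None for a in gt):
                    continue
                if len(gt) != 4:
                    raise ValueError(
                        f"record {mid}: sample {s} has ploidy {len(gt)}, "
                        f"expected tetraploid GT")
                if any(a is None for a in gt):
                    continue
                dos[i] = sum(1 for a in gt if a > 0)
            rows.append(dos)
            map_rows.append((rec.chrom, rec.pos))
            ids.append(mid)
    dosage = pd.DataFrame(np.column_stack(rows) if rows else np.empty((len(samples), 0)),
                          index=pd.Index(samples, name="clone"),
                          columns=pd.Index(ids, name="marker"))
    mm = pd.DataFrame(map_rows, columns=["chrom", "pos"],
                      index=pd.Index(ids, name="marker"))
    return DosagePanel(dosage=dosage, marker_map=mm,
                       clone_meta=pd.DataFrame(index=dosage.index))


def write_panel(panel: DosagePanel, prefix) -> dict[str, Path]:
    """Write dosage, marker-map and metadata TSVs under a common prefix."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "dosage": prefix.with_suffix(".dosage.tsv"),
        "map": prefix.with_suffix(".markers.tsv"),
        "meta": prefix.with_suffix(".clones.tsv"),
    }
    panel.dosage.to_csv(paths["dosage"], sep="\t", na_rep=NA)
    panel.marker_map.to_csv(paths["map"], sep="\t")
    panel.clone_meta.to_csv(paths["meta"], sep="\t")
    return paths


# ---------------------------------------------------------------------------
# tables and results
# ---------------------------------------------------------------------------


def config_hash(obj) -> str:
    """Stable short hash of a configuration object for output headers."""
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


def _header_lines(seed, cfg_hash) -> str:
    from . import __version__
    return (f"# tetragp v{__version__}\n"
            f"# seed: {seed}\n"
            f"# config: {cfg_hash}\n")


def write_table(df: pd.DataFrame, path, seed=None, cfg_hash="-",
                sep="\t", index=False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(seed, cfg_hash))
        df.to_csv(fh, sep=sep, na_rep=NA, index=index)
    return path


def read_table(path, sep="\t", **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", na_values=[NA], **kw)


def write_results(result, path, seed=None, cfg_hash="-") -> dict[str, Path]:
    """Persist a ScenarioResult: long-format TSV plus a JSON summary."""
    path = Path(path)
    tsv = path.with_suffix(".tsv")
    js = path.with_suffix(".json")
    write_table(result.records, tsv, seed=seed, cfg_hash=cfg_hash)
    summary = {
        "name": result.name,
        "n_canceled": result.n_canceled,
        "cells": (result.summary().to_dict(orient="records")
                  if len(result.records) else []),
    }
    js.parent.mkdir(parents=True, exist_ok=True)
    js.write_text(json.dumps(summary, indent=2, default=float))
    return {"tsv": tsv, "json": js}
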