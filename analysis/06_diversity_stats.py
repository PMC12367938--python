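"""Stage 6 — quantitative and molecular differentiation among segments.

Estimates Q_ST per trait from a one-way mixed model on the entries' AEMs
(variance among market segments vs within), computes global and pairwise
F_ST and per-segment expected heterozygosity, and prints the worked
Q_ST examples from the published between/within segment variance
components for comparison.
"""

import argparse
import itertools
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from tetragp import io
from tetragp.diversity import (expected_heterozygosity, global_fst,
                               pairwise_fst, qst)
from tetragp.experiments import qst_worked_examples
from tetragp.genotype_qc import impute_mean
from tetragp.reml import MixedModel, indicator_matrix


def qst_from_aems(aems: pd.Series, segments: pd.Series) -> tuple[float, float, float]:
    """Variance among vs within segments for one trait by REML."""
    y = aems.dropna()
    seg = segments.loc[y.index]
    codes, _ = pd.factorize(seg)
    mm = MixedModel(y.to_numpy(), sp.csr_matrix(np.ones((len(y), 1))),
                    [("segment", indicator_matrix(codes))])
    res = mm.fit()
    s2m = res.varcomps["segment"]
    s2mc = float(res.resid_var[0])
    return qst(s2m, s2mc), s2m, s2mc


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    aems = io.read_table(args.out_dir / "aems.tsv", index_col=0)
    meta = pd.read_csv(args.out_dir / "sim" / "panel.clones.tsv", sep="\t",
                       index_col=0)
    entries = [c for c in aems.index if not meta.at[c, "is_check"]]
    aems = aems.loc[entries]
    segments = meta.loc[entries, "segment"]

    rows = []
    for trait in aems.columns:
        q, s2m, s2mc = qst_from_aems(aems[trait], segments)
        rows.append(dict(trait=trait, sigma2_m=s2m, sigma2_mc=s2mc, qst=q))
    qtab = pd.DataFrame(rows).set_index("trait")
    io.write_table(qtab.reset_index(), args.out_dir / "qst.tsv")
    print("Q_ST of the simulated traits (among vs within segments):")
    print(qtab.round(3).to_string())
    print("\nworked examples from published variance components:")
    print({t: round(v, 2) for t, v in qst_worked_examples().items()})

    panel = io.read_dosage(
        args.out_dir / "sim" / "panel.dosage.tsv",
        marker_map_path=args.out_dir / "sim" / "panel.markers.tsv",
        clone_meta_path=args.out_dir / "sim" / "panel.clones.tsv")
    panel = panel.subset_clones(entries)
    segs = sorted(segments.unique())
    he = {s: expected_heterozygosity(
        impute_mean(panel.subset_clones(segments.index[segments == s])))
        for s in segs}
    fst_pairs = {f"{a}-{b}": pairwise_fst(panel, a, b, "segment")
                 for a, b in itertools.combinations(segs, 2)}
    summary = dict(he_per_segment=he,
                   global_fst=global_fst(panel, "segment"),
                   pairwise_fst=fst_pairs)
    (args.out_dir / "segment_diversity.json").write_text(
        json.dumps(summary, indent=2, default=float))
    print(f"\nglobal F_ST = {summary['global_fst']:.4f}; pairwise F_ST:",
          {k: round(v, 4) for k, v in fst_pairs.items()})
    print("per-segment He:", {k: round(v, 3) for k, v in he.items()})


if __name__ == "__main__":
    main()
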