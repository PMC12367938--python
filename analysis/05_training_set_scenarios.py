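"""Stage 5 — training-set composition and selection experiments.

Runs scaled-down versions of the TS/VS modification scenarios on the
simulated panel: TS-size scan, marker-window scan, family balancedness,
market-segment transfer (within/across/between), truncation selection with
the three replacement samplers, multi-trait rank selection, and
discard-status inclusion.  Each scenario writes a long-format TSV plus a
JSON summary of median PA and its coefficient of variation.
"""

import argparse
from pathlib import Path

import numpy as np

from tetragp import io
from tetragp.scenarios import (discard_inclusion_scenario,
                               family_balance_scenario,
                               group_transfer_scenario,
                               rank_selection_scenario, truncation_scenario,
                               ts_size_scan, marker_window_scan)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--reps", type=int, default=10)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    import importlib.util
    spec = importlib.util.spec_from_file_location(
        "stage4", Path(__file__).parent / "04_gblup_accuracy.py")
    stage4 = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(stage4)
    aems, stats, GA, _GD = stage4.load_inputs(args.out_dir)
    h2 = stats["h2"].clip(0.05, 1.0)
    from tetragp.genotype_qc import filter_markers

    panel = io.read_dosage(
        args.out_dir / "sim" / "panel.dosage.tsv",
        marker_map_path=args.out_dir / "sim" / "panel.markers.tsv",
        clone_meta_path=args.out_dir / "sim" / "panel.clones.tsv")
    panel = panel.subset_clones(aems.index)
    panel, _ = filter_markers(panel)
    trait = "STA"
    rng = np.random.default_rng(args.seed)
    scen_dir = args.out_dir / "scenarios"

    n = len(aems)
    sizes = tuple(s for s in (40, 80, 160, 240) if s * 1.25 <= n)
    res = ts_size_scan(panel, aems, h2, GA, trait, sizes=sizes,
                       reps=args.reps, rng=rng)
    io.write_results(res, scen_dir / "ts_size", seed=args.seed)
    print("TS size scan (median PA):")
    print(res.records.groupby("cell")["pa"].median().round(3).to_string())

    res = marker_window_scan(panel, aems, h2, trait,
                             window_sizes=(1, 4, 16, 64),
                             reps=max(2, args.reps // 3), rng=rng)
    io.write_results(res, scen_dir / "marker_windows", seed=args.seed)
    print("\nmarker-window scan (median PA by window size):")
    print(res.records.groupby("cell")["pa"].median().round(3).to_string())

    fam = family_balance_scenario(panel, aems, h2, GA, trait,
                                  vs_size=min(120, n // 4),
                                  reps=args.reps, rng=rng)
    for key, r in fam.items():
        io.write_results(r, scen_dir / f"family_{key}", seed=args.seed)
    print("\nfamily balancedness (median PA):",
          {k: round(r.records["pa"].median(), 3) for k, r in fam.items()})

    # the truncation grid needs the TS to fit inside the top-30% pool
    ts_size = min(200, int(0.25 * n))
    for ts_mode in ("within", "across", "between"):
        res = group_transfer_scenario(
            panel, aems, h2, trait, GA, grouping="segment",
            vs_mode="within", ts_mode=ts_mode,
            ts_size=ts_size // 2, vs_size=30, reps=args.reps, rng=rng)
        io.write_results(res, scen_dir / f"transfer_{ts_mode}",
                         seed=args.seed)
        if len(res.records):
            print(f"segment transfer TS_{ts_mode}: median PA = "
                  f"{res.records['pa'].median():.3f} "
                  f"(He_TS = {res.records['he_ts'].mean():.3f})")

    for sampler in ("random", "stratified", "bottom10"):
        res = truncation_scenario(panel, aems, h2, GA, trait,
                                  x_grid=(30, 50, 70), y_grid=(0, 20),
                                  replacement=sampler, ts_size=ts_size,
                                  reps=args.reps, rng=rng)
        io.write_results(res, scen_dir / f"truncation_{sampler}",
                         seed=args.seed)
        med = res.records.groupby(["x", "y"])["pa"].median().round(3)
        print(f"\ntruncation ({sampler}) median PA:")
        print(med.to_string())

    res = rank_selection_scenario(panel, aems, h2, GA,
                                  [t for t in aems.columns],
                                  exchanges=(0, 20), ts_size=ts_size,
                                  reps=args.reps, rng=rng)
    io.write_results(res, scen_dir / "rank_selection", seed=args.seed)
    print("\nrank-sum selection median PA by exchange:")
    print(res.records.groupby(["y", "trait"])["pa"].median().round(3)
          .to_string())

    res = discard_inclusion_scenario(panel, aems, h2, GA, trait,
                                     z_grid=(0, 20, 40),
                                     ts_size=ts_size // 2, reps=args.reps,
                                     rng=rng)
    io.write_results(res, scen_dir / "discard_inclusion", seed=args.seed)
    print("\ndiscard-status inclusion median PA by z:")
    print(res.records.groupby("z")["pa"].median().round(3).to_string())


if __name__ == "__main__":
    main()
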