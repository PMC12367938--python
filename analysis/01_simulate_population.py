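"""Stage 1 — simulate a synthetic tetraploid breeding study.

Draws a multi-family autotetraploid clone panel with market-segment
structure, three breeding companies, augmented multi-environment field
trials (replicated checks, unreplicated entries, one split-trial
environment), four traits spanning the ordinal/percent/kg scales, and
breeder discard labels.  Writes the dosage panel, plot table and ground
truth under results/sim/.

By default the study is a desk-scale version (~60 families, 3 environments
per company, 1,500 markers); --full switches to the full panel size
(171 families, 5 environments per company).
"""

import argparse
import json
from pathlib import Path

from tetragp import io
from tetragp.simdata import LayoutSpec, SimConfig, default_trait_specs, simulate_dataset


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--out-dir", type=Path, default=Path("results/sim"))
    ap.add_argument("--full", action="store_true",
                    help="full panel: 171 families, 5 environments/company")
    args = ap.parse_args()

    if args.full:
        cfg = SimConfig(seed=args.seed, n_families=171, n_markers=3000,
                        layout=LayoutSpec(envs_per_company=5,
                                          n_trial_split_envs=1))
    else:
        cfg = SimConfig(seed=args.seed, n_families=60, n_markers=1500,
                        layout=LayoutSpec(envs_per_company=3,
                                          blocks_per_env=4,
                                          n_trial_split_envs=1))
    ds = simulate_dataset(cfg, discard_weights={"STA": 1.0, "FLE": 0.5})
    out = args.out_dir
    io.write_panel(ds.panel, out / "panel")
    ds.plots.to_csv(out / "plots.csv", index=False)
    truth = {
        "realized_variances": {
            t: dict(additive=tt.realized_additive_var,
                    dominance=tt.realized_dominance_var)
            for t, tt in ds.truth.traits.items()},
        "genetic_values": {t: tt.genetic_values.round(5).to_dict()
                           for t, tt in ds.truth.traits.items()},
    }
    (out / "truth.json").write_text(json.dumps(truth))

    meta = ds.panel.clone_meta
    n_entries = int((~meta.is_check).sum())
    print(f"simulated {n_entries} entries in "
          f"{meta[~meta.is_check].family.nunique()} families "
          f"+ {int(meta.is_check.sum())} checks, "
          f"{ds.panel.n_markers} markers, {len(ds.plots)} plots")
    print("segment sizes:",
          meta[~meta.is_check].segment.value_counts().to_dict())
    print("discard status:",
          meta[~meta.is_check].discard_status.value_counts().to_dict())
    print(f"outputs -> {out}")


if __name__ == "__main__":
    main()
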