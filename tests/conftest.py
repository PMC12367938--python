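import numpy as np
import pandas as pd
import pytest

from tetragp.containers import DosagePanel
from tetragp.simdata import LayoutSpec, SimConfig, TraitSpec, simulate_dataset


def make_panel(dosage: np.ndarray, groups=None) -> DosagePanel:
    """Small helper to wrap a raw dosage array into a DosagePanel."""
    n, m = dosage.shape
    ids = pd.Index([f"C{i:03d}" for i in range(n)], name="clone")
    cols = pd.Index([f"M{j:03d}" for j in range(m)], name="marker")
    mm = pd.DataFrame({"chrom": "chr01", "pos": np.arange(1, m + 1)},
                      index=cols)
    meta = pd.DataFrame(index=ids)
    if groups is not None:
        meta["segment"] = list(groups)
    return DosagePanel(pd.DataFrame(dosage, index=ids, columns=cols,
                                    dtype=float), mm, meta)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact simulated breeding study shared across tests.

    ~230 clones in 40 families, three traits covering the ordinal, percent
    and kilogram scales, two environments per company, one split-trial
    environment.
    """
    specs = [
        TraitSpec(name="STA", scale="percent", target_h2=0.9,
                  additive_var=6.0, env_var=1.0, block_var=0.1,
                  segment_shift={"ST": 2.0, "TA": -1.0}),
        TraitSpec(name="YLD", scale="kg", target_h2=0.75, additive_var=1.5,
                  gxe_var=0.3, env_var=1.0, trial_var=0.5),
        TraitSpec(name="FLE", scale="ordinal-1to9", target_h2=0.85,
                  additive_var=1.0, dominance_var=0.3, env_var=0.3),
    ]
    cfg = SimConfig(seed=42, n_families=40, n_markers=500, n_chromosomes=5,
                    n_founders=40, trait_specs=specs,
                    layout=LayoutSpec(envs_per_company=2, blocks_per_env=4,
                                      n_trial_split_envs=1))
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_panel(small_dataset):
    return small_dataset.panel
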