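#!/usr/bin/env python
"""OT trajectories: fate probabilities, pseudotime, drivers, stage programs.

Couples adjacent stages by growth-aware entropic optimal transport,
assembles the global transition matrix, identifies terminal macrostates and
absorption fate probabilities, estimates diffusion pseudotime, extracts
driver genes per lineage, groups them into start/middle/end programs along
the trajectory, and tests each stage's linked peaks for motif enrichment.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import SEED, core_result, terminal_branch_map, write_table

from palatrix import trajectory


def main():
    res, truth, mlist = core_result()
    ds = res.dataset
    br = ds.obs["branch"].to_numpy()
    s = ds.obs["s"].to_numpy()

    mapping = terminal_branch_map(res)
    print("terminal macrostates -> planted branches:", mapping)
    print("macrostate stability:", np.round(res.fate.stability, 3))

    rhos = {b: spearmanr(res.pseudotime[br == b], s[br == b]).statistic
            for b in range(truth.config.n_branches)}
    print("Spearman(pseudotime, latent time) per branch:",
          {b: round(r, 3) for b, r in rhos.items()})

    prog_cells = br == -1
    F = res.fate.F
    cors = {}
    import itertools
    for a, b in itertools.combinations(F.columns, 2):
        cors[(a, b)] = np.corrcoef(F.loc[prog_cells, a],
                                   F.loc[prog_cells, b])[0, 1]
    print("progenitor fate-probability correlations (all negative = "
          "antagonistic lineage competition):")
    for k, v in cors.items():
        print(f"  {k[0]} vs {k[1]}: {v:.3f}")

    # drivers and stage programs for the first lineage
    name = list(F.columns)[0]
    drivers = res.drivers[name]
    n_drv = int(drivers["driver"].sum())
    print(f"{name}: {n_drv} driver genes (corr > 0.05, padj < 0.05)")
    expr = np.asarray(ds.rna.layers["lognorm"])
    groups, profiles = trajectory.stage_profiles(
        expr, list(ds.rna.var_names), drivers, res.pseudotime,
        F[name].to_numpy(), seed=SEED)
    print("driver stage groups:",
          groups["stage_group"].value_counts().to_dict())
    enr = trajectory.stage_motif_enrichment(groups, res.sig_links, res.hits)
    top = enr.sort_values("padj").groupby("stage_group").head(2)
    print("top stage-wise motif enrichments:")
    print(top[["stage_group", "motif", "fold_change", "padj"]]
          .to_string(index=False))

    fate_out = F.copy()
    fate_out.index = ds.barcodes
    fate_out["pseudotime"] = res.pseudotime
    fate_out["macrostate"] = res.fate.macrostates
    write_table(fate_out, "fate_probabilities.tsv")
    write_table(pd.concat({k: v for k, v in res.drivers.items()},
                          names=["lineage"]), "drivers.tsv")
    write_table(groups, "driver_stage_groups.tsv")
    write_table(enr.set_index(["stage_group", "motif"]),
                "stage_motif_enrichment.tsv")


if __name__ == "__main__":
    main()
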