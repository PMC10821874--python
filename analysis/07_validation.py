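#!/usr/bin/env python
"""Validation statistics on the simulated external evidence.

Checks the pipeline's conclusions the way the bench data are used for the
real tissue: ChIP peaks of each lineage TF concentrate within 5 kb of its
predicted targets' TSSs (replicate rates + pooled Fisher), branch-linked
peaks overlap the matching ChIP track more than expected (interval Fisher),
predicted drivers overlap the curated disease-gene list (gene-set Fisher),
and the cluster composition table is reported with half-up percentages.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import DATASET_DIR, core_result, write_table

from palatrix.validation import (
    composition_summary,
    interval_overlap_fisher,
    set_overlap_fisher,
    tss_proximity_rate,
)


def read_bed(path):
    return pd.read_csv(path, sep="\t", header=None,
                       names=["contig", "start", "end"])


def main():
    res, truth, _ = core_result()
    ds = res.dataset
    ann = ds.annotation

    tf_a = truth.tf_programs.index[0]          # a branch-0 TF
    tf_off = truth.tf_programs.index[-1]       # a TF of another branch
    chip = {tf: [read_bed(DATASET_DIR / "chip" / f"{tf}_rep{i}.bed")
                 for i in (1, 2)] for tf in (tf_a, tf_off)}
    targets_a = list(truth.edges.loc[truth.edges["tf"] == tf_a, "target"])
    rates, comparison = tss_proximity_rate(chip, targets_a, ann, window=5000)
    print(f"ChIP peaks within 5 kb of {tf_a} target TSSs:")
    print(rates.to_string(index=False))
    print(f"  one-sided t-test p = {comparison['t_p']:.3g}; pooled Fisher "
          f"OR = {comparison['fisher_odds_ratio']:.2f} "
          f"(p = {comparison['fisher_p']:.2g})")

    # branch-0-linked peaks vs the branch-0 TF's ChIP track
    genes = ds.rna.var
    b0_genes = set(genes.index[genes["branch"] == 0])
    sig = res.sig_links
    linked = sig.loc[sig["gene"].isin(b0_genes), "peak"].unique()
    peaks = ann.peaks.reset_index()[["contig", "start", "end"]]
    set_a = ann.peaks.loc[linked].reset_index()[["contig", "start", "end"]]
    fisher = interval_overlap_fisher(set_a, chip[tf_a][0], peaks)
    print(f"branch-0 linked peaks vs {tf_a} ChIP: OR = "
          f"{fisher.odds_ratio:.2f}, p = {fisher.p:.2g}")

    curated = (DATASET_DIR / "curated_genes.txt").read_text().split()
    name = list(res.drivers)[0]
    drivers = list(res.drivers[name].index[res.drivers[name]["driver"]])
    gs = set_overlap_fisher(drivers, curated, list(ds.rna.var_names))
    print(f"{name} drivers vs curated list: OR = {gs.odds_ratio:.2f}, "
          f"p = {gs.p:.2g}")

    comp = composition_summary(res.clusters)
    print("cluster composition:")
    print(comp.to_string())

    write_table(rates.set_index(["tf", "replicate"]), "chip_tss_rates.tsv")
    write_table(comp, "cluster_composition.tsv")


if __name__ == "__main__":
    main()
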