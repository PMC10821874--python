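#!/usr/bin/env python
"""Simulate the default paired-multiome dataset with planted ground truth.

Five branches differentiate out of a multipotent pool sampled at four
stages (500 cells each); every branch carries one early-transient and one
late-rising lineage TF whose motifs are embedded in its targets' enhancer
sequences.  Writes the full dataset directory (count matrices, fragments,
peaks, genome FASTA, JASPAR motifs, ground truth) under results/dataset.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import DATASET_DIR, SEED

from palatrix import io
from palatrix.pipeline import simulate_default
from palatrix.synth import build_regulatory_program, simulate_validation_assets


def main():
    prog = build_regulatory_program(seed=SEED)
    ds, truth, _ = simulate_default(seed=SEED)
    print(f"simulated {ds.n_cells} barcodes "
          f"({int(ds.obs['is_junk'].sum())} junk), "
          f"{ds.rna.n_vars} genes, {ds.atac.n_vars} peaks, "
          f"{len(ds.fragments)} fragments")
    print(f"planted: {len(truth.links)} links, {len(truth.edges)} TF->target "
          f"edges, {len(truth.tf_programs)} lineage TFs")

    io.write_dataset(ds, DATASET_DIR, ground_truth=truth,
                     motif_counts=prog.motif_counts, force=True)
    print(f"wrote dataset to {DATASET_DIR}")

    assets = simulate_validation_assets(prog, truth.states, seed=SEED + 3)
    chip_dir = DATASET_DIR / "chip"
    chip_dir.mkdir(exist_ok=True)
    for tf, reps in assets["chip"].items():
        for i, rep in enumerate(reps):
            rep.to_csv(chip_dir / f"{tf}_rep{i + 1}.bed", sep="\t",
                       header=False, index=False)
    assets["bulk_deg"].to_csv(DATASET_DIR / "bulk_deg.tsv", sep="\t",
                              index=False)
    (DATASET_DIR / "curated_genes.txt").write_text(
        "\n".join(assets["curated_genes"]) + "\n")
    print(f"wrote ChIP replicates, bulk DEG table and curated list")


if __name__ == "__main__":
    main()
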