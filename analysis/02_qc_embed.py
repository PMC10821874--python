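#!/usr/bin/env python
"""Joint QC, filtering, normalization, embeddings and clustering.

Reports how many barcodes each QC criterion removes, confirms that the
dropped LSI component tracks sequencing depth, and writes the per-cell QC
table, embeddings and cluster labels.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _shared import SEED, load_dataset_and_truth, write_table

from palatrix import preprocess, qc


def main():
    ds, truth = load_dataset_and_truth()
    table = qc.compute_qc_metrics(ds)
    fds, removed = qc.filter_cells(ds, table)
    print(f"{fds.n_cells}/{ds.n_cells} barcodes pass QC; removed per "
          f"criterion:\n{removed.to_string()}")

    preprocess.normalize_rna(fds)
    emb = preprocess.reduce_dimensions(fds)
    depth = np.log(np.asarray((fds.atac.X > 0).sum(axis=1)).ravel())
    r_drop = np.corrcoef(emb.lsi_dropped, depth)[0, 1]
    print(f"dropped LSI component vs log depth: r = {r_drop:.3f} "
          "(motivates removing component 1)")

    clusters = preprocess.cluster_cells(emb.pcs, k=20, seed=SEED)
    layout = preprocess.force_layout(preprocess.knn_graph(emb.pcs, k=20),
                                     seed=SEED)
    br = fds.obs["branch"].to_numpy()
    cross = pd.crosstab(pd.Series(clusters, name="cluster"),
                        pd.Series(br, name="true_branch"))
    print(f"{len(set(clusters))} Leiden clusters; cluster x branch table:")
    print(cross.to_string())

    write_table(table, "qc_table.tsv")
    out = fds.obs.copy()
    out["cluster"] = clusters
    out[["layout_x", "layout_y"]] = layout
    write_table(out, "cells.tsv")
    write_table(pd.DataFrame(emb.pcs, index=fds.barcodes), "pca.tsv")
    write_table(pd.DataFrame(emb.lsi, index=fds.barcodes), "lsi.tsv")


if __name__ == "__main__":
    main()
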