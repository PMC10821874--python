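"""Validation assets: ChIP replicate peak sets, bulk DEG table, curated list.

These emulate the external evidence used to validate lineage regulators:
replicated TF ChIP peaks concentrated near true-target TSSs (plus a
configurable noise rate), a two-region bulk differential-expression table
over the first two branches, and a curated disease-gene list overlapping the
true targets at a configured rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from palatrix.synth.program import RegulatoryProgram


def simulate_validation_assets(program: RegulatoryProgram, states: pd.DataFrame,
                               seed: int = 0, *, noise_rate: float = 0.3,
                               keep_prob: float = 0.85, n_replicates: int = 2,
                               curated_size: int = 40,
                               curated_overlap_rate: float = 0.5) -> dict:
    """Build ChIP BED replicates per lineage TF, a bulk DEG table, a curated list.

    Returns ``{"chip": {tf: [DataFrame, ...]}, "bulk_deg": DataFrame,
    "curated_genes": list}``.  ChIP base peaks are placed within +-2 kb of a
    true-target TSS; each replicate keeps a base peak with ``keep_prob`` and
    adds ``noise_rate`` x n_true random background peaks, so replicate sets
    differ but share most true-target peaks.
    """
    if len(program.tf_programs) < 2:
        raise ValueError("need at least two lineage TFs")
    rng = np.random.default_rng(seed)
    genes = program.genes
    cfg = program.config
    main_contigs = [c for c in program.contig_sizes if c.startswith("chr")
                    and not c.startswith("chrT") and c != "chrM"]

    chip: dict[str, list] = {}
    for tf in program.tf_programs.index:
        targets = program.edges.loc[program.edges["tf"] == tf, "target"]
        centers = []
        for g in targets:
            tss = int(genes.loc[g, "tss"])
            off = int(rng.integers(-2000, 2001))
            centers.append((genes.loc[g, "contig"], tss + off))
        reps = []
        n_noise = int(round(noise_rate * len(centers)))
        for _ in range(n_replicates):
            rows = []
            for contig, c in centers:
                if noise_rate > 0 and rng.random() > keep_prob:
                    continue
                jit = int(rng.integers(-50, 51)) if noise_rate > 0 else 0
                rows.append((contig, c + jit - 150, c + jit + 150))
            for _ in range(n_noise):
                contig = main_contigs[int(rng.integers(len(main_contigs)))]
                pos = int(rng.integers(1000, program.contig_sizes[contig] - 1000))
                rows.append((contig, pos - 150, pos + 150))
            rep = pd.DataFrame(rows, columns=["contig", "start", "end"])
            reps.append(rep.sort_values(["contig", "start"]).reset_index(drop=True))
        chip[tf] = reps

    # bulk DEG table comparing the first two branches ("regions")
    rows = []
    for g, row in genes.iterrows():
        if row["branch"] == 0 and row["kind"] in ("tf", "target"):
            lfc, padj = 2.0 + rng.normal(0, 0.3), 1e-8
        elif row["branch"] == 1 and row["kind"] in ("tf", "target"):
            lfc, padj = -2.0 + rng.normal(0, 0.3), 1e-8
        else:
            lfc, padj = rng.normal(0, 0.2), float(rng.uniform(0.2, 1.0))
        rows.append((g, lfc, padj))
    bulk = pd.DataFrame(rows, columns=["gene", "log2fc", "padj"])

    # curated disease-gene list with a configured true-target overlap rate
    all_targets = genes.index[genes["kind"] == "target"].to_numpy()
    hk = genes.index[genes["kind"] == "housekeeping"].to_numpy()
    n_hit = int(round(curated_overlap_rate * curated_size))
    n_hit = min(n_hit, len(all_targets))
    curated = list(rng.choice(all_targets, size=n_hit, replace=False)) + \
        list(rng.choice(hk, size=min(curated_size - n_hit, len(hk)), replace=False))
    _ = cfg  # geometry already fixed by the program

    return {"chip": chip, "bulk_deg": bulk, "curated_genes": curated}
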