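"""Shared state for the numbered analysis scripts.

Script 01 writes the simulated dataset under ``results/dataset``; later
scripts load it from disk and re-run the core pipeline (a few tens of
seconds) rather than passing objects through pickles, so each script is a
self-contained, re-runnable record of its analysis step.
"""

from __future__ import annotations

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
DATASET_DIR = RESULTS / "dataset"
SEED = 0


def load_dataset_and_truth():
    from palatrix import io

    if not (DATASET_DIR / "rna.mtx").exists():
        raise SystemExit("run analysis/01_simulate.py first")
    return io.read_dataset(DATASET_DIR), io.read_truth(DATASET_DIR)


def load_motifs():
    from palatrix import motifs

    return motifs.read_jaspar(DATASET_DIR / "motifs.jaspar")


def core_result():
    from palatrix.pipeline import run_core

    ds, truth = load_dataset_and_truth()
    mlist = load_motifs()
    prolif = truth.prolif_genes
    res = run_core(ds, mlist, prolif, seed=SEED, n_macrostates=6)
    return res, truth, mlist


def terminal_branch_map(res):
    import numpy as np

    br = res.dataset.obs["branch"].to_numpy()
    return {name: int(np.bincount(br[cells] + 1).argmax()) - 1
            for name, cells in res.fate.terminal_cells.items()}


def write_table(df, name, float_format="%.4g"):
    RESULTS.mkdir(exist_ok=True)
    path = RESULTS / name
    df.to_csv(path, sep="\t", float_format=float_format)
    print(f"  wrote {path.relative_to(ROOT)} ({len(df)} rows)")
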