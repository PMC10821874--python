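"""Per-cell latent states: stage, latent time, branch, growth, depths."""

from __future__ import annotations

import numpy as np
import pandas as pd

from palatrix.synth.program import RegulatoryProgram


def simulate_cell_states(program: RegulatoryProgram, n_cells_per_stage,
                         seed: int = 0) -> pd.DataFrame:
    """Draw latent cell states for the four sampling stages.

    Latent time ``s`` is uniform within each stage window.  Cells with
    ``s`` below the branch point are multipotent (branch = -1); cells past
    it commit to one branch with the configured branch weights (a one-shot
    Markov branching at the branch point).  True growth rates are elevated
    for multipotent cells via the proliferation program.

    Returns a DataFrame indexed by barcode with columns
    ``stage, s, branch, g_true, rna_depth, atac_depth``.
    """
    cfg = program.config
    sizes = list(n_cells_per_stage)
    if len(sizes) != len(cfg.stage_windows):
        raise ValueError("need one cell count per sampling stage")
    if any(n <= 0 for n in sizes):
        raise ValueError("every stage must contain at least one cell")

    rng = np.random.default_rng(seed)
    probs = cfg.branch_probs()
    growth = cfg.branch_growth_multipliers()

    rows = []
    idx = 0
    for k, (n, (lo, hi)) in enumerate(zip(sizes, cfg.stage_windows)):
        s = rng.uniform(lo, hi, size=n)
        branch = np.where(
            s < cfg.branch_point, -1,
            rng.choice(cfg.n_branches, size=n, p=probs),
        )
        g = np.where(branch < 0, cfg.growth_multipotent, growth[np.clip(branch, 0, None)])
        rna_d = rng.lognormal(-cfg.rna_depth_sigma ** 2 / 2, cfg.rna_depth_sigma, n)
        atac_d = rng.lognormal(-cfg.atac_depth_sigma ** 2 / 2, cfg.atac_depth_sigma, n)
        for j in range(n):
            rows.append((f"BC{idx:06d}", f"t{k}", s[j], int(branch[j]),
                         float(g[j]), float(rna_d[j]), float(atac_d[j])))
            idx += 1

    out = pd.DataFrame(
        rows, columns=["barcode", "stage", "s", "branch", "g_true",
                       "rna_depth", "atac_depth"],
    ).set_index("barcode")
    return out
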