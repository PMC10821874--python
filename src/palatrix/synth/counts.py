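"""Render paired counts, fragments and junk barcodes from latent states."""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from palatrix.datatypes import MultiomeDataset
from palatrix.synth.program import (
    RegulatoryProgram,
    enhancer_activity,
    prolif_profile,
    ramp_activity,
)

_TF_FLOOR = 0.25  # basal expression factor of a lineage TF outside its branch


def peak_activity(program: RegulatoryProgram, states: pd.DataFrame) -> np.ndarray:
    """Latent accessibility in [0, 1] for every (cell, peak).

    Promoters are constitutively open, background peaks sit at a fixed
    per-peak level, and enhancers follow a logistic of their driving TF's
    activity ramp — high only in cells of the matching branch.
    """
    cfg = program.config
    peaks = program.peaks
    n, p = len(states), len(peaks)
    A = np.empty((n, p), dtype=np.float32)

    const = peaks["act_base"].to_numpy()
    fixed = ~np.isnan(const)
    A[:, fixed] = const[fixed][None, :]

    s = states["s"].to_numpy(dtype=float)
    branch = states["branch"].to_numpy()
    is_enh = (peaks["kind"] == "enhancer").to_numpy()
    closed = enhancer_activity(0.0, cfg.enhancer_steepness)
    for b in range(cfg.n_branches):
        on = branch == b
        for t in ("early", "late"):
            cols = is_enh & (peaks["branch"] == b).to_numpy() \
                & (peaks["timing"] == t).to_numpy()
            if not cols.any():
                continue
            act = np.full(n, closed, dtype=np.float32)
            if on.any():
                r = ramp_activity(s[on], t, cfg.branch_point)
                act[on] = enhancer_activity(r, cfg.enhancer_steepness)
            A[:, cols] = act[:, None]
    return A


def rna_mean_factor(program: RegulatoryProgram, states: pd.DataFrame,
                    A: np.ndarray) -> np.ndarray:
    """Multiplicative expression factor per (cell, gene), before depth/base."""
    cfg = program.config
    genes = program.genes
    n = len(states)
    F = np.ones((n, len(genes)), dtype=np.float32)
    gidx = {g: i for i, g in enumerate(genes.index)}
    pidx = {p: i for i, p in enumerate(program.peaks.index)}

    s = states["s"].to_numpy(dtype=float)
    branch = states["branch"].to_numpy()

    # targets: 1 + sum of planted link weights times enhancer activity
    for gene, grp in program.links.groupby("gene"):
        cols = [pidx[p] for p in grp["peak"]]
        F[:, gidx[gene]] = 1.0 + (A[:, cols] * grp["weight"].to_numpy()).sum(axis=1)

    # lineage TFs: basal floor plus activity ramp on their own branch
    for tf, row in program.tf_programs.iterrows():
        r = ramp_activity(s, row["timing"], cfg.branch_point) * (branch == row["branch"])
        F[:, gidx[tf]] = _TF_FLOOR + cfg.tf_expr_gain * r

    # proliferation program: high in multipotent cells
    pr = prolif_profile(s)
    for g in program.prolif_genes:
        F[:, gidx[g]] = 1.0 + cfg.prolif_expr_gain * pr
    return F


def _sample_nb(rng, mu, theta):
    if theta <= 0:
        raise ValueError("NB dispersion theta must be positive")
    if (mu < 0).any():
        raise ValueError("negative NB means")
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p).astype(np.int32)


def _fragments_from_counts(rng, counts: sp.csr_matrix, peaks: pd.DataFrame,
                           barcodes, cfg) -> pd.DataFrame:
    """One fragment row per ATAC count unit, placed inside its peak.

    Fragment lengths come from a sub-nucleosomal / mono-nucleosomal mixture
    so the nucleosome-signal and TSS-enrichment QC metrics are exercised.
    """
    coo = counts.tocoo()
    reps = coo.data.astype(np.int64)
    cell = np.repeat(coo.row, reps)
    peak = np.repeat(coo.col, reps)
    m = len(cell)

    short = rng.random(m) < cfg.frag_short_prob
    ln = np.where(
        short,
        rng.normal(cfg.frag_len_short[0], cfg.frag_len_short[1], m),
        rng.normal(cfg.frag_len_mono[0], cfg.frag_len_mono[1], m),
    )
    ln = np.clip(np.round(ln), 30, 340).astype(np.int64)

    p_start = peaks["start"].to_numpy()[peak]
    p_end = peaks["end"].to_numpy()[peak]
    width = p_end - p_start
    ln = np.minimum(ln, width - 1)
    start = p_start + (rng.random(m) * (width - ln)).astype(np.int64)

    frags = pd.DataFrame({
        "chrom": peaks["contig"].to_numpy()[peak],
        "start": start,
        "end": start + ln,
        "barcode": np.asarray(barcodes)[cell],
        "count": np.ones(m, dtype=np.int64),
    })
    frags = frags.sort_values(["chrom", "start"], kind="mergesort")
    return frags.reset_index(drop=True)


def render_multiome_counts(program: RegulatoryProgram, states: pd.DataFrame,
                           seed: int = 0) -> MultiomeDataset:
    """Sample the paired count matrices, fragments and junk barcodes.

    RNA counts are negative binomial around depth x baseline x regulatory
    factor; ATAC counts are Poisson around depth x accessibility, truncated
    to small integers; the fragments table is generated from the ATAC counts
    (per-cell fragment totals equal the ATAC row sums by construction).
    A configured fraction of junk barcodes violating the QC thresholds is
    appended after the real cells.
    """
    cfg = program.config
    rng = np.random.default_rng(seed)
    genes, peaks = program.genes, program.peaks
    base = genes["base"].to_numpy()

    A = peak_activity(program, states)
    F = rna_mean_factor(program, states, A)
    mu = states["rna_depth"].to_numpy()[:, None] * base[None, :] * F
    rna = _sample_nb(rng, mu, cfg.nb_theta)

    lam = states["atac_depth"].to_numpy()[:, None] * cfg.atac_rate * A
    atac = np.minimum(rng.poisson(lam), cfg.atac_max_count).astype(np.int32)

    # junk barcodes: flat, heavily under-sampled droplets
    n_junk = int(round(cfg.junk_fraction * len(states)))
    closed = float(enhancer_activity(0.0, cfg.enhancer_steepness))
    a_flat = np.where(np.isnan(peaks["act_base"].to_numpy()), closed,
                      peaks["act_base"].to_numpy())
    rna_junk = rng.poisson(np.broadcast_to(cfg.junk_rna_scale * base,
                                           (n_junk, len(genes)))).astype(np.int32)
    atac_junk = np.minimum(
        rng.poisson(np.broadcast_to(cfg.junk_atac_scale * cfg.atac_rate * a_flat,
                                    (n_junk, len(peaks)))),
        cfg.atac_max_count).astype(np.int32)

    obs = states.copy()
    obs["is_junk"] = False
    if n_junk:
        junk_obs = pd.DataFrame({
            "stage": [f"t{i % len(cfg.stage_windows)}" for i in range(n_junk)],
            "s": np.nan, "branch": -9, "g_true": np.nan,
            "rna_depth": np.nan, "atac_depth": np.nan, "is_junk": True,
        }, index=[f"JUNK{i:04d}" for i in range(n_junk)])
        obs = pd.concat([obs, junk_obs])
        rna = np.vstack([rna, rna_junk])
        atac = np.vstack([atac, atac_junk])

    atac_sp = sp.csr_matrix(atac)
    frags = _fragments_from_counts(rng, atac_sp, peaks, obs.index, cfg)

    rna_ad = AnnData(X=sp.csr_matrix(rna), obs=obs, var=genes.copy())
    atac_ad = AnnData(X=atac_sp, obs=obs.copy(), var=peaks.copy())
    return MultiomeDataset(rna=rna_ad, atac=atac_ad,
                           annotation=program.annotation, fragments=frags)
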