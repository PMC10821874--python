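"""In silico TF knockout: expression shifts, vector fields, scores.

A knockout sets the TF's expression to zero and propagates the change
through each cluster's GRN for a few linear steps (clipping expression at
zero).  The gene-space shift of each cell is translated into a 2-D
embedding shift by comparing it with the expression differences towards the
cell's neighbors; a grid-smoothed version of these shifts is compared, via
inner products, with the developmental flow (the spatial gradient of
smoothed pseudotime).  A positive perturbation score means the knockout
pushes cells against the direction of development.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


# ------------------------------------------------------------- KO deltas
def simulate_knockout(grn, expr: np.ndarray, features, clusters, tf: str,
                      n_propagation: int = 3) -> np.ndarray:
    """Per-cell gene-space shift caused by knocking out ``tf``.

    Linear signal propagation within each cell's cluster GRN: the initial
    increment sets the TF to zero; each step sends increments across
    regulator->target edges, clipped so no gene drops below zero
    expression.  The KO gene itself is held at zero throughout.
    """
    expr = np.asarray(expr, dtype=float)
    features = list(features)
    if tf not in features:
        raise ValueError(f"unknown TF {tf!r}")
    feat_idx = {f: i for i, f in enumerate(features)}
    ti = feat_idx[tf]
    clusters = np.asarray(clusters)
    delta = np.zeros_like(expr)

    present = any((e["tf"] == tf).any() or (e["target"] == tf).any()
                  for e in grn.edges.values())
    if not present:
        warnings.warn(f"{tf!r} absent from every cluster GRN; zero field")
        return delta

    delta[:, ti] = -expr[:, ti]
    for c, edges in grn.edges.items():
        cells = np.flatnonzero(clusters == c)
        if len(cells) == 0 or len(edges) == 0:
            continue
        import scipy.sparse as sp
        rows = [feat_idx[t] for t in edges["target"]]
        cols = [feat_idx[t] for t in edges["tf"]]
        W = sp.coo_matrix((edges["coef"].to_numpy(), (rows, cols)),
                          shape=(len(features), len(features))).tocsr()
        x = expr[cells]
        total = np.zeros_like(x)
        total[:, ti] = -x[:, ti]
        inc = total.copy()
        for _ in range(max(1, int(n_propagation))):
            inc = inc @ W.T
            inc[:, ti] = 0.0
            inc = np.maximum(inc, -x - total)
            total = total + inc
        delta[cells] = total
    return delta


# ------------------------------------------------------- embedding shifts
def embedding_shift(delta: np.ndarray, expr: np.ndarray, embedding2d: np.ndarray,
                    n_neighbors: int = 200, sigma_corr: float = 0.05,
                    seed: int = 0) -> np.ndarray:
    """Project gene-space shifts onto the 2-D embedding.

    For each cell, transition probabilities over its embedding neighbors are
    softmax(corr(delta_i, x_j - x_i) / sigma_corr); the shift is the
    probability-weighted mean neighbor offset minus the unweighted mean
    (so a flat correlation profile yields zero shift).
    """
    from sklearn.neighbors import NearestNeighbors

    del seed  # neighbor search is exact and deterministic
    E = np.asarray(embedding2d, dtype=float)
    X = np.asarray(expr, dtype=float)
    D = np.asarray(delta, dtype=float)
    n = len(E)
    k = n_neighbors
    if k >= n:
        warnings.warn("n_neighbors >= n_cells; clipping")
        k = n - 1
    nn = NearestNeighbors(n_neighbors=k + 1).fit(E)
    _, idx = nn.kneighbors(E)
    idx = idx[:, 1:]

    shifts = np.zeros((n, 2))
    for i in range(n):
        d = D[i]
        sd = d.std()
        if sd == 0:
            continue
        V = X[idx[i]] - X[i]
        Vc = V - V.mean(axis=1, keepdims=True)
        dc = d - d.mean()
        denom = np.linalg.norm(Vc, axis=1) * np.linalg.norm(dc)
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.where(denom > 0, Vc @ dc / denom, 0.0)
        w = np.exp((corr - corr.max()) / sigma_corr)
        P = w / w.sum()
        offs = E[idx[i]] - E[i]
        shifts[i] = P @ offs - offs.mean(axis=0)
    return shifts


# ------------------------------------------------------------ grid fields
def _grid_geometry(E: np.ndarray, n_grid: int):
    lo = E.min(axis=0)
    hi = E.max(axis=0)
    pad = 0.02 * (hi - lo + 1e-12)
    lo, hi = lo - pad, hi + pad
    gx = np.linspace(lo[0], hi[0], n_grid)
    gy = np.linspace(lo[1], hi[1], n_grid)
    GX, GY = np.meshgrid(gx, gy, indexing="ij")
    pts = np.column_stack([GX.ravel(), GY.ravel()])
    sigma = float(np.mean([(hi[0] - lo[0]) / (n_grid - 1),
                           (hi[1] - lo[1]) / (n_grid - 1)]))
    return GX, GY, pts, sigma


def _kernel_weights(E, pts, sigma):
    d2 = ((pts[:, None, :] - E[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2 * sigma ** 2))


def grid_vector_field(embedding2d: np.ndarray, vectors: np.ndarray,
                      n_grid: int = 30, min_mass_frac: float = 0.01):
    """Gaussian-kernel average of per-cell vectors on an n x n grid.

    Returns ``(GX, GY, U, V, mask)``; grid cells with too little cell mass
    are masked out.
    """
    E = np.asarray(embedding2d, dtype=float)
    vec = np.asarray(vectors, dtype=float)
    GX, GY, pts, sigma = _grid_geometry(E, n_grid)
    W = _kernel_weights(E, pts, sigma)
    mass = W.sum(axis=1)
    mask = mass > min_mass_frac * mass.max()
    with np.errstate(divide="ignore", invalid="ignore"):
        U = np.where(mass > 0, W @ vec[:, 0] / mass, 0.0)
        V = np.where(mass > 0, W @ vec[:, 1] / mass, 0.0)
    shape = GX.shape
    return GX, GY, U.reshape(shape), V.reshape(shape), mask.reshape(shape)


def developmental_flow(embedding2d: np.ndarray, tau: np.ndarray,
                       n_grid: int = 30, min_mass_frac: float = 0.01):
    """Grid flow field pointing toward increasing pseudotime.

    Pseudotime is kernel-smoothed onto the grid and the flow is its
    finite-difference spatial gradient; empty grid cells are masked.
    """
    E = np.asarray(embedding2d, dtype=float)
    tau = np.asarray(tau, dtype=float)
    GX, GY, pts, sigma = _grid_geometry(E, n_grid)
    W = _kernel_weights(E, pts, sigma)
    mass = W.sum(axis=1)
    mask = (mass > min_mass_frac * mass.max()).reshape(GX.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        tg = np.where(mass > 0, W @ tau / mass, np.nan).reshape(GX.shape)
    dx = GX[1, 0] - GX[0, 0]
    dy = GY[0, 1] - GY[0, 0]
    # fill masked values by nearest finite neighbor average for the gradient
    tg_filled = np.where(np.isfinite(tg), tg, np.nanmean(tg))
    U, V = np.gradient(tg_filled, dx, dy)
    U = np.where(mask, U, 0.0)
    V = np.where(mask, V, 0.0)
    return GX, GY, U, V, mask


def lineage_grid_mask(embedding2d: np.ndarray, membership, n_grid: int = 30,
                      min_frac: float = 0.5, min_mass_frac: float = 0.01):
    """Grid cells whose kernel-weighted cells are dominated by the lineage."""
    E = np.asarray(embedding2d, dtype=float)
    m = np.asarray(membership, dtype=float)
    GX, GY, pts, sigma = _grid_geometry(E, n_grid)
    W = _kernel_weights(E, pts, sigma)
    mass = W.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(mass > 0, W @ m / mass, 0.0)
    dense = mass > min_mass_frac * mass.max()
    return ((frac > min_frac) & dense).reshape(GX.shape)


def perturbation_score(shift_uv, flow_uv, mask) -> float:
    """Negative inner product of KO shift and developmental flow over a mask.

    Positive score: the knockout opposes development inside the masked
    region (the lineage's territory).
    """
    Us, Vs = shift_uv
    Uf, Vf = flow_uv
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty lineage mask")
    return float(-np.sum((Us * Uf + Vs * Vf)[mask]))


# ----------------------------------------------------- degree-matched null
def random_tf_scores(grn, expr, features, clusters, tf, embedding2d, tau=None,
                     flow=None, mask=None, n_random: int = 20, seed: int = 0,
                     n_grid: int = 30, n_neighbors: int = 200,
                     sigma_corr: float = 0.05, n_propagation: int = 3):
    """Scores of degree-matched random-TF knockouts (network null).

    Each draw knocks out a random gene granted the real TF's per-cluster
    out-degree and coefficient values, with targets rewired uniformly at
    random.  The pseudo-TF keeps its own expression, so the null captures
    both the network-size effect and the knockout of an arbitrary
    expression profile.
    """
    from palatrix.grn import GRNModel

    rng = np.random.default_rng(seed)
    if flow is None:
        if tau is None:
            raise ValueError("provide either a flow field or pseudotime")
        _, _, Uf, Vf, fmask = developmental_flow(embedding2d, tau, n_grid=n_grid)
        flow = (Uf, Vf)
    if mask is None:
        raise ValueError("a lineage mask is required")

    features = list(features)
    pool = [f for f in features if f != tf]
    scores = []
    for _ in range(n_random):
        pseudo = pool[int(rng.integers(len(pool)))]
        target_pool = [f for f in pool if f != pseudo]
        edges_rand = {}
        for c, edges in grn.edges.items():
            e = edges[edges["tf"] != pseudo].copy()
            mine = e["tf"] == tf
            k = int(mine.sum())
            if k:
                rewired = e[mine].copy()
                rewired["tf"] = pseudo
                rewired["target"] = rng.choice(target_pool, size=k, replace=False)
                rewired["coef"] = rng.permutation(rewired["coef"].to_numpy())
                e = pd.concat([e[~mine], rewired], ignore_index=True)
            edges_rand[c] = e
        g2 = GRNModel(edges=edges_rand, p_threshold=grn.p_threshold,
                      max_edges=grn.max_edges, n_bags=grn.n_bags)
        delta = simulate_knockout(g2, expr, features, clusters, pseudo,
                                  n_propagation=n_propagation)
        sh = embedding_shift(delta, expr, embedding2d,
                             n_neighbors=n_neighbors, sigma_corr=sigma_corr)
        _, _, Us, Vs, _ = grid_vector_field(embedding2d, sh, n_grid=n_grid)
        scores.append(perturbation_score((Us, Vs), flow, mask))
    return np.asarray(scores)
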