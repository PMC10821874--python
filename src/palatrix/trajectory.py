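"""Temporal OT trajectories: transition matrix, macrostates, fate, drivers.

The global transition matrix stitches together stage-to-stage OT couplings
(rows of stage *i* cells point into stage *i+1*) and a within-stage kNN
connectivity kernel for the last stage.  Macrostates approximate a
Perron-cluster analysis by k-means in the dominant eigenvector space of the
transition matrix; terminal macrostates are those with high coarse-grained
self-transition.  Fate probabilities are Markov absorption probabilities of
the terminal macrostates; pseudotime is a diffusion-map distance to a root
cell; driver genes are expression/fate correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import eigsh, gmres

from palatrix.preprocess import LAYER, knn_graph
from palatrix.stats import bh_adjust, pearson_columns


# ----------------------------------------------------------------- growth
def growth_rates(dataset, prolif_genes, layer: str = LAYER, gain: float = 1.0):
    """Initial growth-rate estimate from the proliferation gene set.

    Score = mean normalized expression of the set, z-scored across cells;
    g = exp(gain * z) — positive, bounded in practice, centered on 1.
    This is the initial estimate refined by the OT growth iterations.
    """
    if layer not in dataset.rna.layers:
        raise ValueError("normalized RNA layer missing; run normalize_rna first")
    idx = pd.Index(dataset.rna.var_names).get_indexer(prolif_genes)
    idx = idx[idx >= 0]
    if len(idx) == 0:
        raise ValueError("proliferation gene set disjoint from the catalog")
    score = np.asarray(dataset.rna.layers[layer])[:, idx].mean(axis=1)
    sd = score.std()
    z = (score - score.mean()) / sd if sd > 0 else np.zeros_like(score)
    return np.exp(gain * z)


# ------------------------------------------------------- transition matrix
def stage_blocks(stages) -> list[np.ndarray]:
    """Cell index blocks per stage, in sorted stage order."""
    stages = pd.Series(stages)
    return [np.flatnonzero((stages == s).to_numpy())
            for s in sorted(stages.unique())]


def transition_matrix(couplings, last_knn: sp.spmatrix, blocks) -> sp.csr_matrix:
    """Row-stochastic global transition matrix over all cells.

    ``couplings[i]`` couples ``blocks[i]`` to ``blocks[i+1]``; the last
    stage uses the symmetrized kNN connectivity within its own block.  Zero
    rows get a self-loop (with a warning).
    """
    n = sum(len(b) for b in blocks)
    rows_acc, cols_acc, data_acc = [], [], []
    for i, gamma in enumerate(couplings):
        gamma = np.asarray(gamma, dtype=float)
        if gamma.shape != (len(blocks[i]), len(blocks[i + 1])):
            raise ValueError(f"coupling {i} has the wrong shape")
        rs = gamma.sum(axis=1, keepdims=True)
        zero = rs.ravel() == 0
        if zero.any():
            warnings.warn(f"{int(zero.sum())} isolated cells in stage {i}; "
                          "inserting self-loops")
        P = np.divide(gamma, rs, out=np.zeros_like(gamma), where=rs > 0)
        rows_acc.append(np.repeat(np.asarray(blocks[i]), len(blocks[i + 1])))
        cols_acc.append(np.tile(np.asarray(blocks[i + 1]), len(blocks[i])))
        data_acc.append(P.ravel())
        rows_acc.append(np.asarray(blocks[i])[zero])
        cols_acc.append(np.asarray(blocks[i])[zero])
        data_acc.append(np.ones(int(zero.sum())))
    W = sp.csr_matrix(last_knn, dtype=float)
    W = W.maximum(W.T)
    rs = np.asarray(W.sum(axis=1)).ravel()
    zero = rs == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} isolated cells in the last stage; "
                      "inserting self-loops")
    P = sp.diags(np.divide(1.0, rs, out=np.zeros_like(rs), where=rs > 0)) @ W
    last = np.asarray(blocks[-1])
    Pc = P.tocoo()
    rows_acc.append(last[Pc.row])
    cols_acc.append(last[Pc.col])
    data_acc.append(Pc.data)
    rows_acc.append(last[zero])
    cols_acc.append(last[zero])
    data_acc.append(np.ones(int(zero.sum())))
    T = sp.coo_matrix(
        (np.concatenate(data_acc),
         (np.concatenate(rows_acc), np.concatenate(cols_acc))),
        shape=(n, n),
    ).tocsr()
    rows = np.asarray(T.sum(axis=1)).ravel()
    if not np.allclose(rows, 1.0, atol=1e-8):
        raise AssertionError("transition matrix is not row-stochastic")
    return T


# ------------------------------------------------------------ random walks
def random_walks(T, start_cells, n_sims: int = 300, n_steps: int = 50,
                 seed: int = 0):
    """Simulate categorical random walks on T.

    Returns ``(endpoints, paths)`` with ``paths`` of shape
    (n_sims, n_steps + 1).  Deterministic per seed.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    Td = np.asarray(T.todense()) if sp.issparse(T) else np.asarray(T, dtype=float)
    cum = np.cumsum(Td, axis=1)
    starts = np.asarray(start_cells)
    cur = starts[rng.integers(0, len(starts), size=n_sims)]
    paths = np.empty((n_sims, n_steps + 1), dtype=np.int64)
    paths[:, 0] = cur
    for t in range(n_steps):
        u = rng.random(n_sims)
        nxt = np.empty(n_sims, dtype=np.int64)
        for w in range(n_sims):
            nxt[w] = np.searchsorted(cum[cur[w]], u[w], side="right")
        cur = np.minimum(nxt, Td.shape[0] - 1)
        paths[:, t + 1] = cur
    return paths[:, -1], paths


# -------------------------------------------------------------- macrostates
@dataclass
class FateModel:
    macrostates: np.ndarray               # macrostate id per cell
    terminal_names: list                  # macrostate ids flagged terminal
    coarse_T: np.ndarray                  # K x K coarse-grained transitions
    F: pd.DataFrame                       # cells x terminal states
    stability: np.ndarray | None = None   # core self-transition per macrostate
    root: int | None = None
    pseudotime: np.ndarray | None = None
    terminal_cells: dict = field(default_factory=dict)


def _eigvector_features(T, k: int, seed: int = 0, max_iter: int = 400,
                        tol: float = 1e-10) -> np.ndarray:
    """Orthonormal basis of T's dominant k-dimensional invariant subspace.

    Computed by subspace iteration with QR re-orthogonalization, which is
    robust to the near-degenerate cluster of eigenvalues at 1 (one per
    metastable basin) that defeats single-vector Arnoldi iterations.  Rows
    of the basis are the spectral coordinates macrostates are clustered in.
    """
    Ts = sp.csr_matrix(T, dtype=float)
    n = Ts.shape[0]
    k = min(k, n)
    rng = np.random.default_rng(seed)
    B = np.linalg.qr(rng.normal(size=(n, k)))[0]
    for _ in range(max_iter):
        Bn = np.linalg.qr(Ts @ B)[0]
        err = np.linalg.norm(Bn - B @ (B.T @ Bn))
        B = Bn
        if err < tol:
            break
    return B / np.maximum(np.abs(B).max(axis=0), 1e-12)


def fate_probabilities(T, n_macrostates: int = 6,
                       self_transition_threshold: float = 0.95,
                       terminal_states=None, seed: int = 0) -> FateModel:
    """Macrostates, terminal-state selection and absorption probabilities.

    Macrostates are k-means clusters in the dominant eigenvector space of T
    (a practical approximation of Perron-cluster analysis).  Each
    macrostate's stability is the self-transition of its core cells — the
    members most extreme along the cluster's direction from the global
    mean, the k-means analogue of the membership-simplex vertices —
    because full-membership self-transition is diluted by boundary cells.
    Terminal macrostates are those with stability above the threshold,
    unless given explicitly.  F solves (I - Q) F = R with the cells of
    terminal macrostates absorbing.
    """
    from sklearn.cluster import KMeans

    Td = np.asarray(T.todense()) if sp.issparse(T) else np.asarray(T, dtype=float)
    n = Td.shape[0]
    X = _eigvector_features(Td, n_macrostates, seed=seed)
    km = KMeans(n_clusters=n_macrostates, n_init=50, random_state=seed)
    macro = km.fit_predict(X)

    K = n_macrostates
    M = np.zeros((n, K))
    M[np.arange(n), macro] = 1.0
    sizes = M.sum(axis=0)
    coarse = (M.T @ Td @ M) / np.maximum(sizes[:, None], 1.0)

    mu = X.mean(axis=0)
    stability = np.zeros(K)
    for a in range(K):
        cells = np.flatnonzero(macro == a)
        direction = km.cluster_centers_[a] - mu
        direction /= np.linalg.norm(direction) + 1e-12
        proj = (X[cells] - mu) @ direction
        core = cells[np.argsort(-proj)[:min(30, len(cells))]]
        stability[a] = Td[np.ix_(core, cells)].sum(axis=1).mean()

    if terminal_states is None:
        terminal = [a for a in range(K)
                    if stability[a] >= self_transition_threshold]
    else:
        terminal = list(terminal_states)
    if not terminal:
        raise ValueError("no terminal macrostate found; lower the threshold "
                         "or name terminal states explicitly")

    term_cells = {a: np.flatnonzero(macro == a) for a in terminal}
    F = absorption_probabilities(Td, [term_cells[a] for a in terminal])

    Fdf = pd.DataFrame(F, columns=[f"terminal_{a}" for a in terminal])
    return FateModel(macrostates=macro, terminal_names=terminal,
                     coarse_T=coarse, F=Fdf, stability=stability,
                     terminal_cells={f"terminal_{a}": term_cells[a]
                                     for a in terminal})


def absorption_probabilities(T, terminal_sets) -> np.ndarray:
    """Markov absorption probabilities for disjoint absorbing cell sets.

    Solves (I - Q) F = R over the transient cells (GMRES, tolerance 1e-10,
    direct fallback); cells of each terminal set get indicator rows.  Every
    row of the result sums to 1.
    """
    Td = np.asarray(T.todense()) if sp.issparse(T) else np.asarray(T, dtype=float)
    n = Td.shape[0]
    terminal_sets = [np.asarray(cset, dtype=int) for cset in terminal_sets]
    absorbing = np.concatenate(terminal_sets)
    if len(np.unique(absorbing)) != len(absorbing):
        raise ValueError("terminal sets must be disjoint")
    trans = np.setdiff1d(np.arange(n), absorbing)

    F = np.zeros((n, len(terminal_sets)))
    for si, cset in enumerate(terminal_sets):
        F[cset, si] = 1.0
    if len(trans):
        Q = Td[np.ix_(trans, trans)]
        A = np.eye(len(trans)) - Q
        R = np.column_stack([Td[np.ix_(trans, cset)].sum(axis=1)
                             for cset in terminal_sets])
        X_sol = np.empty_like(R)
        ok = True
        for c in range(R.shape[1]):
            sol, info = gmres(sp.csr_matrix(A), R[:, c], rtol=1e-10, atol=0.0,
                              maxiter=5000)
            X_sol[:, c] = sol
            ok = ok and info == 0
        if not ok or np.abs(A @ X_sol - R).max() > 1e-8:
            try:
                X_sol = np.linalg.solve(A, R)
            except np.linalg.LinAlgError as exc:
                raise ValueError("absorption system is singular: some cells "
                                 "cannot reach any terminal state") from exc
        F[trans] = X_sol
    F = np.clip(F, 0.0, None)
    rows = F.sum(axis=1)
    if np.abs(rows - 1.0).max() > 1e-6:
        raise ValueError("some cells cannot reach any terminal state "
                         "(absorption mass does not sum to 1)")
    return F / rows[:, None]


# -------------------------------------------------------------- pseudotime
def diffusion_pseudotime(X: np.ndarray, root: int, k: int = 15,
                         n_dcs: int = 10, graph=None) -> np.ndarray:
    """Diffusion-map pseudotime: diffusion distance to the root, in [0, 1].

    Builds a symmetrized kNN graph on the embedding (or uses ``graph``, a
    precomputed symmetric adjacency), density-normalizes the kernel, and
    measures distance to the root in eigenvector space with eigenvalue
    weights lambda / (1 - lambda).  Raises if the graph is disconnected
    (naming the number of components).
    """
    from scipy.sparse.csgraph import connected_components

    A = sp.csr_matrix(graph) if graph is not None \
        else knn_graph(np.asarray(X, dtype=float), k=k)
    ncomp, _ = connected_components(A, directed=False)
    if ncomp > 1:
        raise ValueError(f"kNN graph is disconnected ({ncomp} components); "
                         "increase k")
    W = A.astype(float)
    q = np.asarray(W.sum(axis=1)).ravel()
    Wn = sp.diags(1.0 / q) @ W @ sp.diags(1.0 / q)
    d = np.asarray(Wn.sum(axis=1)).ravel()
    Dm = sp.diags(1.0 / np.sqrt(d))
    Msym = Dm @ Wn @ Dm
    n_dcs = min(n_dcs, W.shape[0] - 2)
    vals, vecs = eigsh(Msym, k=n_dcs + 1, which="LA")
    order = np.argsort(-vals)
    vals, vecs = vals[order], vecs[:, order]
    psi = Dm @ vecs[:, 1:]
    lam = np.clip(vals[1:], None, 1.0 - 1e-9)
    psi = psi * (lam / (1.0 - lam))
    dist = np.linalg.norm(psi - psi[root], axis=1)
    mx = dist.max()
    return dist / mx if mx > 0 else dist


# ----------------------------------------------------------------- drivers
def driver_genes(expr: np.ndarray, features, fate: np.ndarray,
                 corr_min: float = 0.05, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene Pearson correlation with a lineage's fate probability.

    Driver flag: correlation > ``corr_min`` and BH-adjusted p < ``alpha``.
    Constant genes are reported untested (NaN statistics).
    """
    r, p = pearson_columns(np.asarray(expr, dtype=float), np.asarray(fate))
    tested = ~np.isnan(p)
    padj = np.full(len(r), np.nan)
    padj[tested] = bh_adjust(p[tested])
    return pd.DataFrame({
        "gene": list(features), "corr": r, "p": p, "padj": padj,
        "tested": tested,
        "driver": tested & (r > corr_min) & (padj < alpha),
    }).set_index("gene")


def stage_profiles(expr: np.ndarray, features, drivers: pd.DataFrame,
                   tau: np.ndarray, fate: np.ndarray, quantile: float = 0.75,
                   k: int = 3, seed: int = 0, min_window: int = 11,
                   method: str = "kmeans"):
    """Order high-fate cells by pseudotime and group drivers into k stages.

    Cells with fate probability above the per-lineage quantile are
    extracted and ordered by pseudotime; each driver's expression is
    smoothed by a centered rolling mean (window 5% of extracted cells, at
    least ``min_window``), standardized, and grouped into k stage programs
    — by seeded k-means on the smoothed profiles (default) or, with
    ``method='quantile'``, by cutting the drivers into k equal groups of
    their peak (argmax) position.  Groups are labeled start/middle/end by
    their mean argmax position.
    """
    from sklearn.cluster import KMeans

    driver_genes_ = list(drivers.index[drivers["driver"].astype(bool)])
    if len(driver_genes_) < k:
        raise ValueError(f"need at least {k} drivers for {k} stage groups")
    fate = np.asarray(fate)
    thr = np.quantile(fate, quantile)
    sel = fate >= thr if quantile == 0 else fate > thr
    order = np.argsort(np.asarray(tau)[sel], kind="mergesort")
    cells = np.flatnonzero(sel)[order]

    feat_idx = pd.Index(features).get_indexer(driver_genes_)
    E = np.asarray(expr, dtype=float)[cells][:, feat_idx]
    window = max(min_window, int(round(0.05 * len(cells))))
    sm = pd.DataFrame(E).rolling(window, center=True, min_periods=1).mean().to_numpy()
    mu, sd = sm.mean(axis=0), sm.std(axis=0)
    prof = (sm - mu) / np.where(sd == 0, 1.0, sd)

    argmax_pos_raw = prof.argmax(axis=0) / max(1, len(cells) - 1)
    if method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        cl = km.fit_predict(prof.T)
    elif method == "quantile":
        ranks = pd.Series(argmax_pos_raw).rank(method="first").to_numpy()
        cl = np.minimum(((ranks - 1) / len(ranks) * k).astype(int), k - 1)
    else:
        raise ValueError("method must be 'kmeans' or 'quantile'")
    argmax_pos = argmax_pos_raw
    cluster_pos = np.array([argmax_pos[cl == c].mean() for c in range(k)])
    labels_sorted = np.argsort(cluster_pos)
    names = ["start", "middle", "end"] if k == 3 else [f"g{i}" for i in range(k)]
    name_of = {c: names[rank] for rank, c in enumerate(labels_sorted)}

    groups = pd.DataFrame({
        "gene": driver_genes_,
        "cluster": cl,
        "stage_group": [name_of[c] for c in cl],
        "argmax_position": argmax_pos,
    }).set_index("gene")
    profiles = pd.DataFrame(prof, columns=driver_genes_)
    profiles.insert(0, "cell_index", cells)
    return groups, profiles


def stage_motif_enrichment(stage_groups: pd.DataFrame, sig_links: pd.DataFrame,
                           hits: pd.DataFrame,
                           features: pd.DataFrame | None = None) -> pd.DataFrame:
    """Motif enrichment of each stage group's linked peaks.

    Foreground: peaks significantly linked to the stage's driver genes;
    background: all peaks linked to any driver of the lineage.
    """
    from palatrix.motifs import motif_enrichment

    lineage_peaks = sig_links.loc[sig_links["gene"].isin(stage_groups.index),
                                  "peak"].unique()
    out = []
    for stage in pd.unique(stage_groups["stage_group"]):
        genes = stage_groups.index[stage_groups["stage_group"] == stage]
        fg = sig_links.loc[sig_links["gene"].isin(genes), "peak"].unique()
        if len(fg) == 0:
            warnings.warn(f"stage {stage!r} has no linked peaks")
            continue
        tab = motif_enrichment(fg, lineage_peaks, hits, features=features)
        tab = tab.reset_index()
        tab.insert(0, "stage_group", stage)
        out.append(tab)
    if not out:
        return pd.DataFrame(columns=["stage_group", "motif", "fold_change",
                                     "p", "padj"])
    return pd.concat(out, ignore_index=True)
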