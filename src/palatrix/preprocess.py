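"""Normalization, dimension reduction (PCA / LSI), clustering, gene activity.

RNA normalization is median-scaled log1p (``log1p(count / cell_total *
median(cell_totals))``) — a deliberate, documented substitution for
variance-stabilizing regression models: every downstream statistic used here
(Pearson correlations, Wilcoxon ranks) is robust to this choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import svds

from palatrix.datatypes import MultiomeDataset

LAYER = "lognorm"


def normalize_rna(dataset: MultiomeDataset, layer: str = LAYER) -> np.ndarray:
    """Add the median-scaled log1p layer in place and return it (dense)."""
    X = dataset.rna.X
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals == 0).any():
        raise ValueError("zero-total cells present; run QC filtering first")
    med = np.median(totals)
    dense = np.asarray(X.todense(), dtype=float) if sp.issparse(X) else np.asarray(X, float)
    norm = np.log1p(dense / totals[:, None] * med)
    dataset.rna.layers[layer] = norm
    return norm


def _fix_signs(u: np.ndarray, v: np.ndarray):
    """Sign convention: the largest-magnitude feature loading is positive."""
    for k in range(v.shape[1]):
        j = np.argmax(np.abs(v[:, k]))
        if v[j, k] < 0:
            v[:, k] = -v[:, k]
            u[:, k] = -u[:, k]
    return u, v


@dataclass
class EmbeddingModel:
    """Joint embedding state shared by clustering and trajectory steps."""
    pcs: np.ndarray                      # cells x d_rna
    lsi: np.ndarray                      # cells x (d_atac - 1), component 1 dropped
    lsi_dropped: np.ndarray              # the removed depth-tracking component
    hvg: list
    pca_loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    clusters: np.ndarray | None = None
    display2d: np.ndarray | None = None
    knn: dict = field(default_factory=dict)


def select_hvg(norm: np.ndarray, n_hvg: int = 3000, n_bins: int = 20) -> np.ndarray:
    """Indices of top features by standardized (mean-binned) dispersion."""
    mean = norm.mean(axis=0)
    var = norm.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    order = np.argsort(mean)
    bins = np.array_split(order, n_bins)
    z = np.zeros_like(disp)
    for b in bins:
        if len(b) == 0:
            continue
        mu, sd = disp[b].mean(), disp[b].std()
        z[b] = (disp[b] - mu) / (sd if sd > 0 else 1.0)
    top = np.argsort(z)[::-1][:min(n_hvg, norm.shape[1])]
    return np.sort(top)


def reduce_dimensions(dataset: MultiomeDataset, d_rna: int = 30, d_atac: int = 30,
                      n_hvg: int = 3000, layer: str = LAYER) -> EmbeddingModel:
    """PCA on highly variable genes and TF-IDF/SVD (LSI) on binarized ATAC.

    The first LSI component tracks sequencing depth and is dropped from the
    returned embedding (it is kept separately for diagnostics); requesting
    ``d_atac`` components therefore yields ``d_atac - 1`` usable ones.
    Component signs are fixed so the largest-magnitude loading is positive.
    """
    if layer not in dataset.rna.layers:
        raise ValueError("normalized RNA layer missing; run normalize_rna first")
    norm = np.asarray(dataset.rna.layers[layer])
    if d_rna >= min(norm.shape):
        raise ValueError("more PCA components requested than features support")

    hvg_idx = select_hvg(norm, n_hvg=n_hvg)
    Xh = norm[:, hvg_idx] - norm[:, hvg_idx].mean(axis=0)
    U, S, Vt = np.linalg.svd(Xh, full_matrices=False)
    U, V = _fix_signs(U[:, :d_rna], Vt[:d_rna].T)
    pcs = U * S[:d_rna]
    evr = S[:d_rna] ** 2 / max((S ** 2).sum(), 1e-300)

    # ---- LSI on the ATAC modality
    B = (dataset.atac.X > 0).astype(np.float64)
    B = sp.csr_matrix(B)
    cell_tot = np.asarray(B.sum(axis=1)).ravel()
    if (cell_tot == 0).any():
        raise ValueError("cells with zero accessible peaks; filter first")
    occ = np.asarray(B.sum(axis=0)).ravel()
    n_cells = B.shape[0]
    if d_atac >= min(B.shape):
        raise ValueError("more LSI components requested than peaks support")
    tf = sp.diags(1.0 / cell_tot) @ B
    idf = np.log(1.0 + n_cells / (1.0 + occ))
    Xl = tf @ sp.diags(idf)
    # log scaling of the TF-IDF matrix (the convention of the standard
    # scATAC toolchain); it also linearizes the depth signal that LSI
    # component 1 is dropped for
    Xl = Xl.tocsr()
    Xl.data = np.log1p(Xl.data * 1e4)
    v0 = np.full(min(Xl.shape), 1.0 / np.sqrt(min(Xl.shape)))
    Ul, Sl, Vlt = svds(Xl, k=d_atac, v0=v0)
    order = np.argsort(Sl)[::-1]
    Ul, Sl, Vl = Ul[:, order], Sl[order], Vlt[order].T
    Ul, Vl = _fix_signs(Ul, Vl)
    lsi_all = Ul * Sl
    return EmbeddingModel(
        pcs=pcs, lsi=lsi_all[:, 1:], lsi_dropped=lsi_all[:, 0],
        hvg=[dataset.rna.var_names[i] for i in hvg_idx],
        pca_loadings=V, explained_variance_ratio=evr,
    )


def knn_graph(X: np.ndarray, k: int = 20):
    """Symmetrized kNN adjacency (union rule) with Euclidean edges."""
    from sklearn.neighbors import NearestNeighbors

    n = X.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    A = nn.kneighbors_graph(X, mode="connectivity")
    A = A - sp.eye(n, format="csr")
    A.data = np.clip(A.data, 0, 1)
    A = A.maximum(A.T)
    A.eliminate_zeros()
    return A


def cluster_cells(embedding: np.ndarray, k: int = 20, resolution: float = 1.0,
                  seed: int = 0) -> np.ndarray:
    """Leiden modularity communities on the symmetrized kNN graph."""
    import igraph as ig
    import leidenalg

    X = np.asarray(embedding, dtype=float)
    if X.shape[0] == 1:
        return np.zeros(1, dtype=int)
    A = knn_graph(X, k=k)
    sources, targets = A.nonzero()
    keep = sources < targets
    g = ig.Graph(n=X.shape[0],
                 edges=list(zip(sources[keep].tolist(), targets[keep].tolist())))
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed, n_iterations=2,
    )
    return np.asarray(part.membership, dtype=int)


def force_layout(adjacency, seed: int = 0, niter: int = 500) -> np.ndarray:
    """Deterministic 2-D force-directed (Fruchterman-Reingold) display layout.

    Branching differentiation manifolds come out as a star of arms, which is
    what the vector-field steps downstream need from a display embedding.
    """
    import random as _random

    import igraph as ig

    A = sp.csr_matrix(adjacency)
    sources, targets = A.nonzero()
    keep = sources < targets
    g = ig.Graph(n=A.shape[0],
                 edges=list(zip(sources[keep].tolist(), targets[keep].tolist())))
    state = _random.getstate()
    try:
        _random.seed(seed)
        layout = g.layout_fruchterman_reingold(niter=niter)
    finally:
        _random.setstate(state)
    return np.asarray(layout.coords, dtype=float)


def gene_activity(dataset: MultiomeDataset, upstream: int = 2000) -> pd.DataFrame:
    """Fragment counts over gene body extended ``upstream`` bp of the TSS.

    Strand-aware: the extension runs upstream of the TSS in transcription
    direction.  Intervals are 0-based half-open; a fragment counts when it
    overlaps the window by at least one base.  Genes on contigs absent from
    the fragments table get zero activity.
    """
    frags = dataset.fragments
    if frags is None:
        raise ValueError("gene activity requires a fragments table")
    genes = dataset.annotation.genes
    barcodes = pd.Index(dataset.rna.obs_names)
    out = np.zeros((len(barcodes), len(genes)), dtype=np.int64)

    by_contig = {c: sub for c, sub in frags.groupby("chrom", sort=False)}
    for gi, (gene, row) in enumerate(genes.iterrows()):
        sub = by_contig.get(row["contig"])
        if sub is None:
            continue
        if row["strand"] == "+":
            ws, we = row["start"] - upstream, row["end"]
        else:
            ws, we = row["start"], row["end"] + upstream
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        hit = (s < we) & (e > ws)
        if hit.any():
            idx = barcodes.get_indexer(sub["barcode"].to_numpy()[hit])
            np.add.at(out[:, gi], idx[idx >= 0], sub["count"].to_numpy()[hit][idx >= 0])
    return pd.DataFrame(out, index=barcodes, columns=genes.index)
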