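"""Motif-prior GRN inference: candidate edges + bagging ridge regression.

Candidate TF->gene edges require the TF's motif to hit a peak that is
significantly linked to the gene (primary mode) or promoter-coaccessible
with it (alternate mode); promoter peaks are always eligible.  Per cluster,
each target is regressed on its candidate TFs with bootstrap-bagged ridge;
the bag t-statistic gives an edge p-value, and edges are filtered at
p < 0.001, keeping at most 2000 per cluster by absolute coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as ss


def _promoter_peaks(annotation) -> pd.Series:
    """Map promoter peak id -> gene, for peaks overlapping a TSS."""
    genes = annotation.genes
    peaks = annotation.peaks
    out = {}
    for contig, gsub in genes.groupby("contig", sort=False):
        psub = peaks[peaks["contig"] == contig]
        for pid, s, e in zip(psub.index, psub["start"], psub["end"]):
            hit = gsub.index[(gsub["tss"] >= s) & (gsub["tss"] < e)]
            if len(hit):
                out[pid] = hit[0]
    return pd.Series(out, name="gene")


def base_grn(sig_links: pd.DataFrame | None, hits: pd.DataFrame, tf_map,
             annotation, coaccess: pd.DataFrame | None = None,
             window: int = 500_000, coaccess_min: float = 0.8) -> pd.DataFrame:
    """Candidate TF->target edges with peak/motif provenance.

    ``tf_map`` maps TF gene -> motif id.  In primary mode the peak->gene
    assignment comes from significant links; in alternate mode from a
    peak-peak coaccessibility table (columns peak1, peak2, coaccess), where
    a peak is assigned to a gene when it is coaccessible
    (>= ``coaccess_min``) with the gene's promoter peak within the window.
    Promoter peaks are always eligible for their own gene.
    """
    tf_map = dict(tf_map)
    if not tf_map:
        raise ValueError("empty TF->motif map")
    prom = _promoter_peaks(annotation)
    peak2genes: dict[str, set] = {p: {g} for p, g in prom.items()}

    if sig_links is not None:
        for p, g in zip(sig_links["peak"], sig_links["gene"]):
            peak2genes.setdefault(p, set()).add(g)
    if coaccess is not None:
        prom_rev = {p: g for p, g in prom.items()}
        mid = ((annotation.peaks["start"] + annotation.peaks["end"]) // 2)
        tss = annotation.genes["tss"]
        strong = coaccess[coaccess["coaccess"] >= coaccess_min]
        for p1, p2 in zip(strong["peak1"], strong["peak2"]):
            for a, b in ((p1, p2), (p2, p1)):
                g = prom_rev.get(b)
                if g is None or a not in mid.index:
                    continue
                if abs(int(mid[a]) - int(tss[g])) <= window:
                    peak2genes.setdefault(a, set()).add(g)

    rows = []
    for tf, motif in tf_map.items():
        if motif not in hits.columns:
            continue
        for p in hits.index[hits[motif].to_numpy(dtype=bool)]:
            for g in peak2genes.get(p, ()):  # peaks without a gene are ignored
                if g != tf:
                    rows.append((tf, g, p, motif))
    cand = pd.DataFrame(rows, columns=["tf", "target", "peak", "motif"])
    return cand.drop_duplicates(subset=["tf", "target"]).reset_index(drop=True)


# ---------------------------------------------------------------- fitting
@dataclass
class GRNModel:
    """Per-cluster signed TF->target edges with bagging p-values."""
    edges: dict                                   # cluster -> DataFrame
    p_threshold: float = 1e-3
    max_edges: int = 2000
    n_bags: int = 20
    settings: dict = field(default_factory=dict)

    def clusters(self):
        return list(self.edges)

    def tf_out_degree(self, tf) -> dict:
        return {c: int((e["tf"] == tf).sum()) for c, e in self.edges.items()}


def _ridge_gcv_alpha(X, y, alphas=(0.01, 0.1, 1.0, 10.0, 100.0)):
    """Generalized cross-validation over a small ridge penalty grid."""
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    Uty = U.T @ y
    n = len(y)
    best, best_alpha = np.inf, alphas[0]
    for a in alphas:
        d = s ** 2 / (s ** 2 + a)
        yhat = U @ (d * Uty)
        df = d.sum()
        denom = max(1e-12, (1.0 - df / n)) ** 2
        gcv = ((y - yhat) ** 2).mean() / denom
        if gcv < best:
            best, best_alpha = gcv, a
    return best_alpha


def _ridge(X, y, alpha):
    p = X.shape[1]
    return np.linalg.solve(X.T @ X + alpha * np.eye(p), X.T @ y)


def fit_grn(expr: np.ndarray, features, clusters, candidates: pd.DataFrame,
            n_bags: int = 20, seed: int = 0, p_threshold: float = 1e-3,
            max_edges: int = 2000, min_cells: int = 50) -> GRNModel:
    """Bagging-ridge GRN per cluster.

    ``expr`` is the normalized cells x genes matrix; ``clusters`` the
    per-cell cluster labels.  Targets without candidate TFs are skipped.
    Edges are filtered at ``p < p_threshold`` and capped at ``max_edges``
    per cluster by |coefficient|.
    """
    expr = np.asarray(expr, dtype=float)
    feat_idx = {f: i for i, f in enumerate(features)}
    clusters = np.asarray(clusters)
    rng = np.random.default_rng(seed)

    by_target = {t: grp for t, grp in candidates.groupby("target")}
    usable = [c for c in pd.unique(clusters)
              if (clusters == c).sum() >= min_cells]
    if not usable:
        raise ValueError(f"no cluster with >= {min_cells} cells")

    out = {}
    for c in sorted(usable, key=str):
        cells = np.flatnonzero(clusters == c)
        Xc = expr[cells]
        n = len(cells)
        rows = []
        for target, grp in by_target.items():
            tfs = [t for t in grp["tf"] if t in feat_idx and target in feat_idx]
            if not tfs:
                continue
            X = Xc[:, [feat_idx[t] for t in tfs]]
            y = Xc[:, feat_idx[target]]
            Xc_ = X - X.mean(axis=0)
            yc = y - y.mean()
            if (Xc_.std(axis=0) == 0).all() or yc.std() == 0:
                continue
            alpha = _ridge_gcv_alpha(Xc_, yc)
            coefs = np.empty((n_bags, X.shape[1]))
            for b in range(n_bags):
                idx = rng.integers(0, n, size=n)
                Xb = Xc_[idx]
                yb = yc[idx]
                coefs[b] = _ridge(Xb - Xb.mean(axis=0), yb - yb.mean(), alpha)
            mean = coefs.mean(axis=0)
            # bootstrap standard error = spread of the bagged coefficients
            se = coefs.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(se > 0, mean / se, 0.0)
            p = 2.0 * ss.t.sf(np.abs(t), df=n_bags - 1)
            prov = grp.drop_duplicates("tf").set_index("tf")
            for j, tf in enumerate(tfs):
                rows.append((tf, target, mean[j], p[j],
                             prov.loc[tf, "peak"], prov.loc[tf, "motif"]))
        edges = pd.DataFrame(rows, columns=["tf", "target", "coef", "p",
                                            "peak", "motif"])
        edges = edges[edges["p"] < p_threshold]
        edges = edges.reindex(
            edges["coef"].abs().sort_values(ascending=False).index
        ).head(max_edges).reset_index(drop=True)
        out[c] = edges
    return GRNModel(edges=out, p_threshold=p_threshold, max_edges=max_edges,
                    n_bags=n_bags,
                    settings={"min_cells": min_cells, "seed": seed})
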