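"""Wilcoxon marker tests, dual-modality marker-TF calling, generic ORA."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as ss

from palatrix.stats import bh_adjust

_EXACT_MAX = 10  # exact rank-sum distribution when both groups are this small


def _wilcoxon_group(ranks: np.ndarray, tie_term: np.ndarray, in_group: np.ndarray):
    """Vectorized tie-corrected normal-approximation rank-sum p per feature."""
    n1 = int(in_group.sum())
    n = ranks.shape[0]
    n2 = n - n1
    R1 = ranks[in_group].sum(axis=0)
    U = R1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (U - mu) / sigma
    p = 2.0 * ss.norm.sf(np.abs(z))
    p = np.where(sigma == 0, 1.0, p)
    return np.minimum(p, 1.0)


def rank_sum_markers(matrix, groups, features=None, logfc_min: float = 0.1,
                     pseudocount: float = 1.0, effect: str = "logfc") -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum markers per group.

    The effect size is the natural-log fold change of pseudocounted group
    means (``effect='logfc'``) or the plain mean difference
    (``effect='diff'``, appropriate for signed inputs such as motif
    deviations, where the marker criterion becomes effect > 0).  For tiny
    tie-free groups (both sides <= 10) the exact rank-sum distribution is
    used; otherwise the tie-corrected normal approximation.
    """
    X = np.asarray(matrix, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if features is None:
        features = [f"f{i}" for i in range(X.shape[1])]

    ranks = ss.rankdata(X, axis=0)
    tie_term = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        _, counts = np.unique(X[:, j], return_counts=True)
        tie_term[j] = (counts.astype(float) ** 3 - counts).sum()

    rows = []
    for g in labels:
        in_g = groups == g
        n1, n2 = int(in_g.sum()), int((~in_g).sum())
        if n1 == 0 or n2 == 0:
            raise ValueError(f"group {g!r} is empty")
        if n1 <= _EXACT_MAX and n2 <= _EXACT_MAX:
            p = np.empty(X.shape[1])
            for j in range(X.shape[1]):
                a, b = X[in_g, j], X[~in_g, j]
                if len(np.unique(X[:, j])) == len(X):  # tie-free: exact
                    p[j] = ss.mannwhitneyu(a, b, alternative="two-sided",
                                           method="exact").pvalue
                else:
                    p[j] = ss.mannwhitneyu(a, b, alternative="two-sided",
                                           method="asymptotic",
                                           use_continuity=False).pvalue
        else:
            p = _wilcoxon_group(ranks, tie_term, in_g)

        m_in = X[in_g].mean(axis=0)
        m_out = X[~in_g].mean(axis=0)
        if effect == "logfc":
            eff = np.log((m_in + pseudocount) / (m_out + pseudocount))
        elif effect == "diff":
            eff = m_in - m_out
        else:
            raise ValueError("effect must be 'logfc' or 'diff'")
        padj = bh_adjust(p)
        thresh = logfc_min if effect == "logfc" else 0.0
        rows.append(pd.DataFrame({
            "group": g, "feature": features, "logfc": eff, "p": p, "padj": padj,
            "pct_in": (X[in_g] > 0).mean(axis=0),
            "pct_out": (X[~in_g] > 0).mean(axis=0),
            "marker": (padj < 0.05) & (eff > thresh),
        }))
    return pd.concat(rows, ignore_index=True)


def call_multiomic_markers(rna_markers: pd.DataFrame, dev_markers: pd.DataFrame,
                           tf_map, tf_genes=None):
    """Dual-modality marker TFs: enriched in RNA *and* in motif accessibility.

    ``tf_map`` maps TF gene -> motif id.  A TF is reported for a group iff
    its RNA padj < 0.05 with positive effect and its mapped motif's
    deviation padj < 0.05 with positive effect in the same group.  TFs
    without a usable motif mapping go to the side report.
    """
    tf_map = dict(tf_map)
    if tf_genes is None:
        tf_genes = list(tf_map)
    dev_feats = set(dev_markers["feature"])
    side = [tf for tf in tf_genes
            if tf not in tf_map or tf_map[tf] not in dev_feats]

    rna_up = rna_markers[(rna_markers["padj"] < 0.05) & (rna_markers["logfc"] > 0)]
    dev_up = dev_markers[(dev_markers["padj"] < 0.05) & (dev_markers["logfc"] > 0)]
    dev_key = {(r["group"], r["feature"]): r for _, r in dev_up.iterrows()}

    rows = []
    for _, r in rna_up.iterrows():
        tf = r["feature"]
        if tf not in tf_map or tf in side:
            continue
        motif = tf_map[tf]
        hit = dev_key.get((r["group"], motif))
        if hit is not None:
            rows.append((r["group"], tf, r["padj"], motif, hit["padj"]))
    out = pd.DataFrame(rows, columns=["group", "tf", "rna_padj", "motif",
                                      "motif_padj"])
    return out, side


def ora_enrichment(query, gene_sets: dict, universe, min_size: int = 5,
                   max_size: int = 500) -> pd.DataFrame:
    """Over-representation analysis by hypergeometric tail with BH.

    Enrichment ratio is (k / n_query) / (K / N_universe); sets whose
    universe-restricted size falls outside [min_size, max_size] are excluded
    before testing (and before BH).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & universe
    rows = []
    for name, members in gene_sets.items():
        mem = set(members) & universe
        K = len(mem)
        if K < min_size or K > max_size:
            continue
        k = len(query & mem)
        N, n = len(universe), len(query)
        ratio = (k / n) / (K / N) if n and K else np.nan
        p = ss.hypergeom.sf(k - 1, N, K, n)
        rows.append((name, k, K, n, N, ratio, p))
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size",
                                      "query_size", "universe_size",
                                      "enrichment_ratio", "p"]).set_index("set")
    out["padj"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.nan
    return out
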