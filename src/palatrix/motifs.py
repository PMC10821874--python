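"""PWM models, motif scanning, chromVAR-style deviations, motif enrichment.

Scanning thresholds are defined by a scan p-value (default 1e-4) under the
background base distribution rather than a raw score, so hits are comparable
across motif lengths; the score distribution is computed exactly by dynamic
programming over discretized log-odds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from palatrix.datatypes import GenomeAnnotation

_SCALE = 1000  # log-odds discretization for the DP score distribution


@dataclass
class MotifModel:
    """A position count matrix with its log-odds form.

    Probabilities use the JASPAR-style pseudocount split evenly over bases:
    ``p = (count + 0.25 * pseudocount) / (colsum + pseudocount)``.
    """

    motif_id: str
    name: str                      # TF gene symbol
    counts: np.ndarray             # 4 x L over A,C,G,T
    pseudocount: float = 1.0
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 1:
            raise ValueError("counts must be 4 x L")
        if (self.counts < 0).any():
            raise ValueError("negative motif counts")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def probs(self) -> np.ndarray:
        col = self.counts.sum(axis=0)
        return (self.counts + 0.25 * self.pseudocount) / (col + self.pseudocount)

    @property
    def log_odds(self) -> np.ndarray:
        return np.log(self.probs / self.background[:, None])

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=0))

    def score_distribution(self):
        """Exact pmf of the window score under the background model.

        Returns ``(support_scores, probabilities)`` on the discretized grid.
        """
        lo = np.round(self.log_odds * _SCALE).astype(np.int64)
        lo = lo - lo.min(axis=0)  # per-column shift; track offset separately
        shift = np.round(self.log_odds * _SCALE).astype(np.int64).min(axis=0).sum()
        pmf = np.array([1.0])
        for j in range(self.length):
            width = lo[:, j].max()
            new = np.zeros(len(pmf) + width)
            for b in range(4):
                new[lo[b, j]:lo[b, j] + len(pmf)] += self.background[b] * pmf
            pmf = new
        scores = (np.arange(len(pmf)) + shift) / _SCALE
        return scores, pmf

    def threshold_for_pvalue(self, p_value: float = 1e-4) -> float:
        """Smallest score whose background tail probability is <= p_value."""
        scores, pmf = self.score_distribution()
        tail = np.cumsum(pmf[::-1])[::-1]
        ok = np.flatnonzero(tail <= p_value)
        if len(ok) == 0:
            return scores[-1] + 1.0 / _SCALE  # nothing passes
        return float(scores[ok[0]])


def read_jaspar(path, pseudocount: float = 1.0) -> list[MotifModel]:
    """Parse JASPAR PFM text (``>ID NAME`` header + 4 count rows)."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        out.append(MotifModel(motif_id=m.matrix_id or m.name, name=m.name,
                              counts=counts, pseudocount=pseudocount))
    return out


def _window_scores(concat: np.ndarray, lo5: np.ndarray) -> np.ndarray:
    """Score every window of the concatenated sequence (N scores -inf-ish)."""
    L = lo5.shape[1]
    win = np.lib.stride_tricks.sliding_window_view(concat, L)
    return lo5[win, np.arange(L)].sum(axis=1)


def scan_motifs(genome: dict, peaks: pd.DataFrame, motif_list: list[MotifModel],
                p_threshold: float = 1e-4) -> pd.DataFrame:
    """Binary peaks x motifs hit matrix, scanning both strands.

    A peak is a hit when its best window log-odds score reaches the motif's
    p-value threshold.  The reverse strand is scanned by score-matrix
    reversal-complementation, so coordinates never move.
    """
    seqs = []
    for contig, s, e in zip(peaks["contig"], peaks["start"], peaks["end"]):
        if contig not in genome or e > len(genome[contig]):
            raise ValueError(f"peak outside contig: {contig}:{s}-{e}")
        seqs.append(genome[contig][int(s):int(e)])
    maxL = max(m.length for m in motif_list)
    sep = np.full(maxL, 4, dtype=np.uint8)
    concat = np.concatenate([x for pair in zip(seqs, [sep] * len(seqs))
                             for x in pair][:-1]) if seqs else np.empty(0, np.uint8)
    starts = np.zeros(len(seqs), dtype=np.int64)
    pos = 0
    for i, q in enumerate(seqs):
        starts[i] = pos
        pos += len(q) + maxL

    hits = np.zeros((len(peaks), len(motif_list)), dtype=bool)
    for mi, m in enumerate(motif_list):
        thr = m.threshold_for_pvalue(p_threshold)
        lo = m.log_odds
        lo5 = np.vstack([lo, np.full((1, m.length), -1e9)])
        lo5_rc = lo5.copy()
        lo5_rc[:4] = lo[::-1, ::-1]
        best = np.maximum(_window_scores(concat, lo5),
                          _window_scores(concat, lo5_rc))
        # windows crossing separators score -inf; group-max by peak segment
        grp = np.maximum.reduceat(best, np.minimum(starts, len(best) - 1))
        hits[:, mi] = grp >= thr - 1e-9
        # peaks shorter than the motif can never hit
        widths = (peaks["end"] - peaks["start"]).to_numpy()
        hits[widths < m.length, mi] = False
    return pd.DataFrame(hits, index=peaks.index,
                        columns=[m.motif_id for m in motif_list])


def gc_accessibility_bins(features: pd.DataFrame, n_bins: int = 10) -> np.ndarray:
    """Joint GC x accessibility quantile-bin id per peak."""
    def dec(x):
        ranks = pd.Series(x).rank(method="first").to_numpy()
        return np.minimum(((ranks - 1) / len(x) * n_bins).astype(int), n_bins - 1)

    return dec(features["gc"].to_numpy()) * n_bins + dec(features["accessibility"].to_numpy())


def motif_deviations(atac_counts, hits: pd.DataFrame, features: pd.DataFrame,
                     n_background: int = 50, n_bins: int = 10, seed: int = 0):
    """chromVAR-style bias-corrected per-cell motif deviation z-scores.

    Raw deviation: (observed counts in motif peaks - expected under
    cell-independent peak weights) / expected.  The z-score standardizes
    against ``n_background`` GC/accessibility-matched background peak sets.
    Motifs without hit peaks are dropped with a warning.
    """
    rng = np.random.default_rng(seed)
    X = sp.csr_matrix(atac_counts, dtype=float)
    M = hits.to_numpy(dtype=float)
    keep = M.sum(axis=0) > 0
    if not keep.all():
        dropped = list(hits.columns[~keep])
        warnings.warn(f"dropping motifs with no hit peaks: {dropped}")
    M = M[:, keep]
    cols = list(hits.columns[keep])

    cell_tot = np.asarray(X.sum(axis=1)).ravel()
    peak_tot = np.asarray(X.sum(axis=0)).ravel()
    w = peak_tot / peak_tot.sum()

    def deviation(Mat):
        obs = X @ Mat
        exp = np.outer(cell_tot, w @ Mat)
        exp = np.where(exp == 0, np.nan, exp)
        return (obs - exp) / exp

    dev = deviation(M)

    bins = gc_accessibility_bins(features, n_bins=n_bins)
    by_bin = {b: np.flatnonzero(bins == b) for b in np.unique(bins)}
    n_peaks = X.shape[1]
    bg_dev = np.empty((n_background,) + dev.shape)
    for it in range(n_background):
        mapping = np.empty(n_peaks, dtype=np.int64)
        for b, idx in by_bin.items():
            mapping[idx] = rng.choice(idx, size=len(idx), replace=True)
        Mb = np.zeros_like(M)
        for mi in range(M.shape[1]):
            np.add.at(Mb[:, mi], mapping[np.flatnonzero(M[:, mi])], 1.0)
        bg_dev[it] = deviation(Mb)

    mu = bg_dev.mean(axis=0)
    sd = bg_dev.std(axis=0, ddof=1)
    # a zero background spread means no evidence either way -> z = 0
    z = np.where(sd > 0, (dev - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.DataFrame(z, columns=cols), pd.DataFrame(dev, columns=cols)


def motif_enrichment(foreground, background, hits: pd.DataFrame,
                     features: pd.DataFrame | None = None,
                     seed: int = 0, max_background: int = 40_000) -> pd.DataFrame:
    """Per-motif fold change and one-sided hypergeometric p, BH-adjusted.

    ``foreground`` and ``background`` are peak-id sequences; the background
    is GC-matched (decile sampling to the foreground GC profile) when
    features are given and the pool is larger than ``max_background``,
    otherwise the whole pool is used.
    """
    from scipy.stats import hypergeom

    fg = pd.Index(foreground)
    if len(fg) == 0:
        raise ValueError("empty foreground")
    pool = pd.Index(background)
    if features is not None and len(pool) > max_background:
        rng = np.random.default_rng(seed)
        bins = pd.qcut(features.loc[pool, "gc"], 10, labels=False, duplicates="drop")
        fg_bins = pd.qcut(features.loc[fg, "gc"].rank(method="first"), 10,
                          labels=False, duplicates="drop")
        counts = pd.Series(fg_bins).value_counts(normalize=True)
        take = []
        for b, fr in counts.items():
            cand = pool[bins == b]
            k = int(round(fr * max_background))
            take.extend(rng.choice(cand, size=min(k, len(cand)), replace=False))
        pool = pd.Index(take)

    H = hits.loc[fg].to_numpy(dtype=bool)
    Hb = hits.loc[pool].to_numpy(dtype=bool)
    k = H.sum(axis=0)
    kb = Hb.sum(axis=0)
    n_fg, n_bg = len(fg), len(pool)
    rate_fg = k / n_fg
    rate_bg = kb / n_bg
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(rate_bg > 0, rate_fg / rate_bg, np.inf)
    p = hypergeom.sf(k - 1, n_fg + n_bg, k + kb, n_fg)
    from palatrix.stats import bh_adjust
    return pd.DataFrame({
        "motif": hits.columns, "fg_hits": k, "fg_n": n_fg,
        "bg_hits": kb, "bg_n": n_bg, "fold_change": fold,
        "p": p, "padj": bh_adjust(p),
    }).set_index("motif")
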