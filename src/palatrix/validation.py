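"""Validation statistics: ChIP TSS proximity, Fisher overlaps, composition."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats as ss


@dataclass
class ContingencyResult:
    table: np.ndarray          # 2x2 counts
    odds_ratio: float          # Haldane-Anscombe corrected when a zero cell
    p: float
    alternative: str

    def __post_init__(self):
        self.table = np.asarray(self.table, dtype=np.int64)
        if (self.table < 0).any():
            raise ValueError("negative contingency counts")


def _fisher(table, alternative="greater") -> ContingencyResult:
    table = np.asarray(table, dtype=np.int64)
    _, p = ss.fisher_exact(table, alternative=alternative)
    a, b, c, d = table.ravel().astype(float)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    oddsr = (a * d) / (b * c)
    return ContingencyResult(table=table, odds_ratio=float(oddsr), p=float(p),
                             alternative=alternative)


# --------------------------------------------------------- interval sweep
def _sorted_arrays(intervals: pd.DataFrame):
    """Per-contig (starts, prefix-max ends) sorted by start."""
    out = {}
    for contig, sub in intervals.groupby("contig", sort=False):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        order = np.argsort(s, kind="mergesort")
        s, e = s[order], e[order]
        out[contig] = (s, np.maximum.accumulate(e))
    return out


def overlaps_any(query: pd.DataFrame, track: pd.DataFrame) -> np.ndarray:
    """Boolean per query interval: overlaps >= 1 bp with the track.

    Half-open semantics: bookended intervals (end == start) do not overlap.
    Sorted-sweep via prefix maxima of track ends.
    """
    track_idx = _sorted_arrays(track)
    hit = np.zeros(len(query), dtype=bool)
    for contig, sub in query.groupby("contig", sort=False):
        if contig not in track_idx:
            continue
        ts, tmax = track_idx[contig]
        qs = sub["start"].to_numpy()
        qe = sub["end"].to_numpy()
        j = np.searchsorted(ts, qe, side="left")   # track starts < query end
        ok = np.zeros(len(sub), dtype=bool)
        nz = j > 0
        ok[nz] = tmax[j[nz] - 1] > qs[nz]          # some such track end > start
        hit[query.index.get_indexer(sub.index)] = ok
    return hit


def interval_overlap_fisher(set_a: pd.DataFrame, track_b: pd.DataFrame,
                            universe: pd.DataFrame,
                            alternative: str = "greater") -> ContingencyResult:
    """2x2 Fisher: membership in A vs overlap with track B, over a universe.

    ``set_a`` must consist of universe intervals (matched by coordinates).
    """
    if len(universe) == 0:
        raise ValueError("empty universe")
    key = lambda df: set(zip(df["contig"], df["start"], df["end"]))
    a_keys = key(set_a)
    if not a_keys <= key(universe):
        raise ValueError("set A must be a subset of the universe intervals")
    uni = universe.reset_index(drop=True)
    in_a = np.array([(c, s, e) in a_keys
                     for c, s, e in zip(uni["contig"], uni["start"], uni["end"])])
    ov = overlaps_any(uni, track_b.reset_index(drop=True))
    table = [[int((in_a & ov).sum()), int((in_a & ~ov).sum())],
             [int((~in_a & ov).sum()), int((~in_a & ~ov).sum())]]
    return _fisher(table, alternative=alternative)


def set_overlap_fisher(genes_a, genes_b, universe,
                       alternative: str = "greater") -> ContingencyResult:
    """Standard 2x2 membership Fisher test over a gene universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    A = set(genes_a) & universe
    B = set(genes_b) & universe
    both = len(A & B)
    table = [[both, len(A) - both],
             [len(B) - both, len(universe) - len(A) - len(B) + both]]
    return _fisher(table, alternative=alternative)


# ----------------------------------------------------------- TSS proximity
def tss_proximity_rate(chip_replicates: dict, gene_set, annotation,
                       window: int = 5000, mode: str = "midpoint"):
    """Rate of ChIP peaks within ``window`` bp of a gene-set TSS, per replicate.

    ``chip_replicates``: mapping TF -> list of interval DataFrames.  Peak
    position is the midpoint by default (``mode='edge'`` counts a peak when
    any part of it is within the window).  Returns ``(rates, comparison)``
    where the comparison (for exactly two TFs) holds a one-sided two-sample
    t-test on replicate rates plus a pooled-count Fisher test.
    """
    genes = annotation.genes
    tss_by_contig = {c: np.sort(sub.loc[sub.index.isin(set(gene_set)), "tss"]
                                .to_numpy())
                     for c, sub in genes.groupby("contig", sort=False)}

    rows = []
    pooled = {}
    for tf, reps in chip_replicates.items():
        pooled[tf] = [0, 0]
        for ri, peaks in enumerate(reps):
            if len(peaks) == 0:
                raise ValueError(f"replicate {ri} of {tf} has no peaks")
            near = np.zeros(len(peaks), dtype=bool)
            for contig, sub in peaks.groupby("contig", sort=False):
                tss = tss_by_contig.get(contig)
                if tss is None or len(tss) == 0:
                    continue
                if mode == "midpoint":
                    pos = ((sub["start"] + sub["end"]) // 2).to_numpy()
                    j = np.clip(np.searchsorted(tss, pos), 0, len(tss) - 1)
                    jl = np.clip(j - 1, 0, len(tss) - 1)
                    dist = np.minimum(np.abs(tss[j] - pos), np.abs(tss[jl] - pos))
                    ok = dist <= window
                else:  # edge mode: any part of the peak within the window
                    s = sub["start"].to_numpy()
                    e = sub["end"].to_numpy()
                    j = np.clip(np.searchsorted(tss, (s + e) // 2), 0, len(tss) - 1)
                    jl = np.clip(j - 1, 0, len(tss) - 1)
                    ok = np.zeros(len(sub), dtype=bool)
                    for t_arr in (tss[j], tss[jl]):
                        ok |= (s <= t_arr + window) & (e > t_arr - window)
                near[peaks.index.get_indexer(sub.index)] = ok
            rate = near.mean()
            rows.append((tf, ri, int(near.sum()), len(peaks), float(rate)))
            pooled[tf][0] += int(near.sum())
            pooled[tf][1] += len(peaks)
    rates = pd.DataFrame(rows, columns=["tf", "replicate", "n_near", "n_peaks",
                                        "rate"])

    comparison = None
    tfs = list(chip_replicates)
    if len(tfs) == 2:
        r1 = rates.loc[rates["tf"] == tfs[0], "rate"].to_numpy()
        r2 = rates.loc[rates["tf"] == tfs[1], "rate"].to_numpy()
        t, p_t = ss.ttest_ind(r1, r2, alternative="greater")
        k1, n1 = pooled[tfs[0]]
        k2, n2 = pooled[tfs[1]]
        fisher = _fisher([[k1, n1 - k1], [k2, n2 - k2]], alternative="greater")
        comparison = {"tf_high": tfs[0], "tf_low": tfs[1],
                      "t_stat": float(t), "t_p": float(p_t),
                      "fisher_odds_ratio": fisher.odds_ratio,
                      "fisher_p": fisher.p}
    return rates, comparison


# ------------------------------------------------------------ composition
def composition_summary(labels) -> pd.DataFrame:
    """Counts and half-up-rounded percentages (2 decimals) per label."""
    labels = pd.Series(list(labels))
    if labels.empty:
        raise ValueError("no labels")
    counts = labels.value_counts()
    total = int(counts.sum())
    pct = [float((Decimal(int(n)) * 100 / Decimal(total))
                 .quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
           for n in counts]
    return pd.DataFrame({"n": counts.astype(int), "pct": pct},
                        index=counts.index)
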