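"""Joint-modality per-cell QC metrics and threshold filtering.

Metric definitions follow the common fragment-based conventions:

* ``nucleosome_signal`` — mono-nucleosomal over sub-nucleosomal fragment
  counts: ``#fragments with length in [147, 294] / max(1, #fragments with
  length < 147)``.
* ``TSS.enrichment`` — mean per-base fragment coverage in TSS +-50 bp
  divided by the mean coverage in the outermost flanks
  [-1000, -901] u [901, 1000] (pseudocount 0.1 in the denominator),
  aggregated over all annotated TSSs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from palatrix.datatypes import MultiomeDataset

QC_COLUMNS = ["nCount_RNA", "nFeature_RNA", "percent.mt", "nCount_ATAC",
              "nucleosome_signal", "TSS.enrichment"]


@dataclass(frozen=True)
class QCThresholds:
    """All six bounds are strict, as conventionally quoted."""
    rna_min: float = 200
    rna_max: float = 100_000
    nfeature_max: float = 7_500
    mt_max: float = 20
    atac_min: float = 200
    atac_max: float = 100_000
    nucleosome_max: float = 2
    tss_min: float = 1


def _tss_coverage(fragments: pd.DataFrame, genes: pd.DataFrame, barcodes):
    """Per-cell summed overlap (bp) with TSS-center and flank windows.

    Each fragment is attributed to its nearest TSS on the contig; gene loci
    are assumed far enough apart that center/flank windows of different TSSs
    do not overlap.
    """
    bc_codes = pd.Index(barcodes)
    center = np.zeros(len(bc_codes))
    flank = np.zeros(len(bc_codes))
    frag_bc = bc_codes.get_indexer(fragments["barcode"])

    for contig, sub in fragments.groupby("chrom", sort=False):
        tss = np.sort(genes.loc[genes["contig"] == contig, "tss"].to_numpy())
        if len(tss) == 0:
            continue
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        mid = (s + e) // 2
        j = np.clip(np.searchsorted(tss, mid), 0, len(tss) - 1)
        jl = np.clip(j - 1, 0, len(tss) - 1)
        t = np.where(np.abs(tss[j] - mid) <= np.abs(tss[jl] - mid), tss[j], tss[jl])

        c_ov = np.clip(np.minimum(e, t + 51) - np.maximum(s, t - 50), 0, None)
        f_ov = np.clip(np.minimum(e, t - 900) - np.maximum(s, t - 1000), 0, None) \
            + np.clip(np.minimum(e, t + 1001) - np.maximum(s, t + 901), 0, None)
        idx = frag_bc[sub.index.to_numpy()]
        np.add.at(center, idx, c_ov * sub["count"].to_numpy())
        np.add.at(flank, idx, f_ov * sub["count"].to_numpy())
    return center, flank


def compute_qc_metrics(dataset: MultiomeDataset) -> pd.DataFrame:
    """Per-cell QC table over both modalities.

    When no fragments table is present the fragment-derived ATAC metrics are
    returned as NaN (flagged unavailable) rather than silently zero.
    """
    rna = dataset.rna
    X = rna.X
    ncount = np.asarray(X.sum(axis=1)).ravel()
    nfeat = np.asarray((X > 0).sum(axis=1)).ravel()
    mt_genes = dataset.annotation.chrm_genes
    mt_mask = rna.var_names.isin(mt_genes)
    mt_counts = np.asarray(X[:, mt_mask].sum(axis=1)).ravel() if mt_mask.any() \
        else np.zeros(rna.n_obs)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mt = np.where(ncount > 0, 100.0 * mt_counts / ncount, 0.0)

    ncount_atac = np.asarray(dataset.atac.X.sum(axis=1)).ravel()

    qc = pd.DataFrame({
        "nCount_RNA": ncount, "nFeature_RNA": nfeat, "percent.mt": pct_mt,
        "nCount_ATAC": ncount_atac,
    }, index=rna.obs_names)

    if dataset.fragments is None or len(dataset.fragments) == 0:
        qc["nucleosome_signal"] = np.nan
        qc["TSS.enrichment"] = np.nan
        return qc

    frags = dataset.fragments
    lengths = (frags["end"] - frags["start"]).to_numpy()
    counts = frags["count"].to_numpy()
    bc = pd.Index(rna.obs_names).get_indexer(frags["barcode"])
    mono = np.zeros(rna.n_obs)
    short = np.zeros(rna.n_obs)
    np.add.at(mono, bc, ((lengths >= 147) & (lengths <= 294)) * counts)
    np.add.at(short, bc, (lengths < 147) * counts)
    qc["nucleosome_signal"] = mono / np.maximum(1.0, short)

    center, flank = _tss_coverage(frags.reset_index(drop=True),
                                  dataset.annotation.genes, rna.obs_names)
    qc["TSS.enrichment"] = (center / 101.0) / (flank / 200.0 + 0.1)
    return qc


def qc_pass(qc: pd.DataFrame, thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """Per-criterion boolean table plus the combined ``pass`` column."""
    t = thresholds or QCThresholds()
    ok = pd.DataFrame(index=qc.index)
    ok["rna_count"] = (qc["nCount_RNA"] > t.rna_min) & (qc["nCount_RNA"] < t.rna_max)
    ok["rna_features"] = qc["nFeature_RNA"] < t.nfeature_max
    ok["mito"] = qc["percent.mt"] < t.mt_max
    ok["atac_count"] = (qc["nCount_ATAC"] > t.atac_min) & (qc["nCount_ATAC"] < t.atac_max)
    ok["nucleosome"] = qc["nucleosome_signal"] < t.nucleosome_max
    ok["tss"] = qc["TSS.enrichment"] > t.tss_min
    ok["pass"] = ok.all(axis=1)
    return ok


def filter_cells(dataset: MultiomeDataset, qc: pd.DataFrame | None = None,
                 thresholds: QCThresholds | None = None):
    """Restrict the dataset to cells passing all six criteria.

    Returns ``(filtered_dataset, removal_log)`` where the log counts cells
    removed per criterion.  Raises if no cell survives, naming the criterion
    that removed the most cells.
    """
    if qc is None:
        qc = compute_qc_metrics(dataset)
    for col in ("nucleosome_signal", "TSS.enrichment"):
        if qc[col].isna().all():
            raise ValueError(f"QC metric {col} unavailable (no fragments table)")
    ok = qc_pass(qc, thresholds)
    removed = (~ok.drop(columns="pass")).sum(axis=0).rename("n_removed")
    if not ok["pass"].any():
        worst = removed.idxmax()
        raise ValueError(f"no cells pass QC; binding criterion: {worst}")
    return dataset.subset(ok["pass"].to_numpy()), removed.to_frame()
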