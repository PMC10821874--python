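"""Shared containers: genome annotation and the paired multiome dataset."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData

# base encoding used for all sequence work: A=0, C=1, G=2, T=3, N=4
BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


def encode_seq(seq) -> np.ndarray:
    """Encode a DNA string/bytes to uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    if isinstance(seq, str):
        seq = seq.encode()
    return _CODE[np.frombuffer(bytes(seq), dtype=np.uint8)]


def decode_seq(codes: np.ndarray) -> str:
    return BASES[np.asarray(codes, dtype=np.uint8)].tobytes().decode()


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement on the integer encoding (N stays N)."""
    comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
    return comp[codes][::-1]


@dataclass
class GenomeAnnotation:
    """Gene/peak annotation plus (optionally) the genome sequence.

    genes : DataFrame indexed by gene id with columns
        ``contig, strand, tss, start, end`` (body interval, 0-based half-open)
        and any extra columns the caller carries along.
    peaks : DataFrame indexed by peak id (``contig:start-end``) with columns
        ``contig, start, end`` (0-based half-open).
    contig_sizes : mapping contig -> length.
    genome : mapping contig -> uint8 code array, or None when sequence is
        unavailable (GC-dependent steps then raise).
    """

    genes: pd.DataFrame
    peaks: pd.DataFrame
    contig_sizes: dict
    genome: dict | None = None

    def __post_init__(self):
        for col in ("contig", "strand", "tss", "start", "end"):
            if col not in self.genes.columns:
                raise ValueError(f"genes table lacks column {col!r}")
        for col in ("contig", "start", "end"):
            if col not in self.peaks.columns:
                raise ValueError(f"peaks table lacks column {col!r}")
        bad = self.peaks["start"] >= self.peaks["end"]
        if bad.any():
            raise ValueError("peak intervals must satisfy start < end")
        for contig, size in self.contig_sizes.items():
            sel = self.peaks["contig"] == contig
            if sel.any() and int(self.peaks.loc[sel, "end"].max()) > size:
                raise ValueError(f"peaks exceed bounds of contig {contig!r}")

    def peak_sequence(self, peak_id: str) -> np.ndarray:
        if self.genome is None:
            raise ValueError("annotation carries no genome sequence")
        row = self.peaks.loc[peak_id]
        return self.genome[row["contig"]][int(row["start"]):int(row["end"])]

    def peak_gc(self) -> pd.Series:
        """GC fraction of every peak, from the genome sequence."""
        if self.genome is None:
            raise ValueError("annotation carries no genome sequence")
        vals = np.empty(len(self.peaks))
        for i, (contig, s, e) in enumerate(
            zip(self.peaks["contig"], self.peaks["start"], self.peaks["end"])
        ):
            seq = self.genome[contig][int(s):int(e)]
            vals[i] = np.isin(seq, (1, 2)).mean()
        return pd.Series(vals, index=self.peaks.index, name="gc")

    @property
    def chrm_genes(self) -> pd.Index:
        return self.genes.index[self.genes["contig"] == "chrM"]


def peak_name(contig, start, end) -> str:
    return f"{contig}:{int(start)}-{int(end)}"


@dataclass
class MultiomeDataset:
    """Paired RNA/ATAC counts with fragments and annotation.

    ``rna`` and ``atac`` are AnnData objects over the *same cells in the same
    order*; per-cell metadata lives in ``rna.obs`` (mirrored onto
    ``atac.obs`` on construction). Normalized layers are added in place by
    the preprocessing functions.
    """

    rna: AnnData
    atac: AnnData
    annotation: GenomeAnnotation
    fragments: pd.DataFrame | None = None   # chrom, start, end, barcode, count

    def __post_init__(self):
        if not self.rna.obs_names.equals(self.atac.obs_names):
            raise ValueError("RNA and ATAC must share cell barcodes in order")
        if (self.rna.X < 0).sum() or (self.atac.X < 0).sum():
            raise ValueError("counts must be non-negative")
        self.atac.obs = self.rna.obs.copy()

    # -------------------------------------------------------------- basics
    @property
    def n_cells(self) -> int:
        return self.rna.n_obs

    @property
    def obs(self) -> pd.DataFrame:
        return self.rna.obs

    @property
    def barcodes(self) -> pd.Index:
        return self.rna.obs_names

    def subset(self, mask) -> "MultiomeDataset":
        """Restrict to cells selected by a boolean mask or barcode list."""
        if np.asarray(mask).dtype == bool:
            keep = self.rna.obs_names[np.asarray(mask)]
        else:
            keep = pd.Index(mask)
        rna = self.rna[keep].copy()
        atac = self.atac[keep].copy()
        frags = None
        if self.fragments is not None:
            frags = self.fragments[self.fragments["barcode"].isin(set(keep))]
            frags = frags.reset_index(drop=True)
        return MultiomeDataset(rna=rna, atac=atac, annotation=self.annotation,
                               fragments=frags)
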