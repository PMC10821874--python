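"""On-disk layout: MatrixMarket + TSV per modality, BED, FASTA, fragments, truth.

A dataset directory contains::

    rna.mtx / rna_barcodes.tsv / rna_features.tsv
    atac.mtx / atac_barcodes.tsv / atac_features.tsv
    peaks.bed            0-based half-open BED3+name
    genes.tsv            gene annotation (contig, strand, tss, body, kind...)
    genome.fa            synthetic genome
    fragments.tsv        chrom, start, end, barcode, count (sorted)
    contigs.tsv          contig sizes
    obs.tsv              per-cell metadata
    motifs.jaspar        planted TF motifs (JASPAR PFM text)
    truth.json           ground truth (when written by the simulator)
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp
from anndata import AnnData

from palatrix.datatypes import BASES, GenomeAnnotation, MultiomeDataset, encode_seq
from palatrix.synth.truth import GroundTruth


def write_fasta(genome: dict, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for contig, codes in genome.items():
            fh.write(f">{contig}\n")
            txt = BASES[codes].tobytes().decode()
            for i in range(0, len(txt), width):
                fh.write(txt[i:i + width] + "\n")


def read_fasta(path) -> dict:
    genome, name, chunks = {}, None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    genome[name] = encode_seq("".join(chunks))
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        genome[name] = encode_seq("".join(chunks))
    return genome


def write_jaspar(motif_counts: dict, path) -> None:
    """Write motifs as JASPAR PFM text (``>ID NAME`` + 4 count rows)."""
    with open(path, "w") as fh:
        for mid, (name, counts) in motif_counts.items():
            fh.write(f">{mid} {name}\n")
            for base, row in zip("ACGT", np.asarray(counts)):
                vals = " ".join(f"{v:.2f}" for v in row)
                fh.write(f"{base} [ {vals} ]\n")


def write_dataset(dataset: MultiomeDataset, directory, ground_truth=None,
                  motif_counts=None, force: bool = False) -> None:
    """Write the full dataset directory; refuses to overwrite without force."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    if not force and (d / "rna.mtx").exists():
        raise FileExistsError(f"{d} already holds a dataset (use force=True)")

    sio.mmwrite(str(d / "rna.mtx"), sp.coo_matrix(dataset.rna.X))
    sio.mmwrite(str(d / "atac.mtx"), sp.coo_matrix(dataset.atac.X))
    for name, idx in (("rna_barcodes", dataset.rna.obs_names),
                      ("atac_barcodes", dataset.atac.obs_names),
                      ("rna_features", dataset.rna.var_names),
                      ("atac_features", dataset.atac.var_names)):
        pd.Series(idx).to_csv(d / f"{name}.tsv", sep="\t", index=False, header=False)

    ann = dataset.annotation
    peaks = ann.peaks
    bed = pd.DataFrame({
        "contig": peaks["contig"], "start": peaks["start"], "end": peaks["end"],
        "name": peaks.index,
    })
    bed.to_csv(d / "peaks.bed", sep="\t", index=False, header=False)
    ann.genes.to_csv(d / "genes.tsv", sep="\t")
    pd.Series(ann.contig_sizes, name="size").rename_axis("contig") \
        .to_csv(d / "contigs.tsv", sep="\t")
    dataset.obs.to_csv(d / "obs.tsv", sep="\t")
    if ann.genome is not None:
        write_fasta(ann.genome, d / "genome.fa")
    if dataset.fragments is not None:
        dataset.fragments.to_csv(d / "fragments.tsv", sep="\t",
                                 index=False, header=False)
    if motif_counts is not None:
        write_jaspar(motif_counts, d / "motifs.jaspar")
    if ground_truth is not None:
        (d / "truth.json").write_text(ground_truth.to_json())


def read_dataset(directory) -> MultiomeDataset:
    d = Path(directory)
    rna_x = sp.csr_matrix(sio.mmread(str(d / "rna.mtx")))
    atac_x = sp.csr_matrix(sio.mmread(str(d / "atac.mtx")))
    bc = pd.read_csv(d / "rna_barcodes.tsv", sep="\t", header=None)[0]
    genes = pd.read_csv(d / "genes.tsv", sep="\t", index_col=0,
                        keep_default_na=False)
    genes["timing"] = genes["timing"].astype(str)
    bed = pd.read_csv(d / "peaks.bed", sep="\t", header=None,
                      names=["contig", "start", "end", "name"])
    peaks = bed.set_index("name")
    contigs = pd.read_csv(d / "contigs.tsv", sep="\t", index_col=0)["size"].to_dict()
    obs = pd.read_csv(d / "obs.tsv", sep="\t", index_col=0)
    genome = read_fasta(d / "genome.fa") if (d / "genome.fa").exists() else None
    frag_path = d / "fragments.tsv"
    fragments = None
    if frag_path.exists():
        fragments = pd.read_csv(frag_path, sep="\t", header=None,
                                names=["chrom", "start", "end", "barcode", "count"])

    ann = GenomeAnnotation(genes=genes, peaks=peaks, contig_sizes=contigs,
                           genome=genome)
    rna = AnnData(X=rna_x, obs=obs.loc[bc], var=genes.copy())
    atac = AnnData(X=atac_x, obs=obs.loc[bc].copy(), var=peaks.copy())
    return MultiomeDataset(rna=rna, atac=atac, annotation=ann, fragments=fragments)


def read_truth(directory) -> GroundTruth:
    return GroundTruth.from_json((Path(directory) / "truth.json").read_text())
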