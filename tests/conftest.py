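"""Shared fixtures: small simulated datasets and a hand-built dataset factory."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

from palatrix.config import SimConfig
from palatrix.datatypes import GenomeAnnotation, MultiomeDataset
from palatrix.motifs import MotifModel
from palatrix.pipeline import simulate_default
from palatrix.synth import build_regulatory_program


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig.small()


@pytest.fixture(scope="session")
def small_prog(small_cfg):
    return build_regulatory_program(small_cfg, seed=0)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """(dataset, truth, program) at reduced scale: 3 branches, 600 cells."""
    return simulate_default(seed=0, n_cells_per_stage=(150,) * 4,
                            config=small_cfg)


@pytest.fixture(scope="session")
def small_filtered(small_sim):
    """QC-filtered, normalized small dataset (read-only in tests)."""
    from palatrix import preprocess, qc

    ds, truth, prog = small_sim
    fds, _ = qc.filter_cells(ds)
    preprocess.normalize_rna(fds)
    return fds, truth, prog


@pytest.fixture(scope="session")
def small_motifs(small_prog):
    return [MotifModel(mid, name, counts)
            for mid, (name, counts) in small_prog.motif_counts.items()]


def make_dataset(rna, atac, genes, peaks, contig_sizes, genome=None,
                 fragments=None, obs=None) -> MultiomeDataset:
    """Assemble a MultiomeDataset from plain arrays/tables (for toy cases)."""
    rna = sp.csr_matrix(np.asarray(rna))
    atac = sp.csr_matrix(np.asarray(atac))
    n = rna.shape[0]
    if obs is None:
        obs = pd.DataFrame(index=[f"C{i}" for i in range(n)])
    ann = GenomeAnnotation(genes=genes, peaks=peaks,
                           contig_sizes=contig_sizes, genome=genome)
    rna_ad = AnnData(X=rna, obs=obs, var=genes.copy())
    atac_ad = AnnData(X=atac, obs=obs.copy(), var=peaks.copy())
    return MultiomeDataset(rna=rna_ad, atac=atac_ad, annotation=ann,
                           fragments=fragments)


def toy_genes(specs) -> pd.DataFrame:
    """genes table from (name, contig, strand, tss, start, end) tuples."""
    return pd.DataFrame(
        [s for s in specs],
        columns=["gene", "contig", "strand", "tss", "start", "end"],
    ).set_index("gene")


def toy_peaks(specs) -> pd.DataFrame:
    """peaks table from (contig, start, end) tuples, ids contig:start-end."""
    df = pd.DataFrame(list(specs), columns=["contig", "start", "end"])
    df.index = [f"{c}:{s}-{e}" for c, s, e in specs]
    return df
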