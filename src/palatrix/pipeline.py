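"""End-to-end orchestration of the multiome analysis on simulated data.

The stages mirror the analysis scripts: simulate -> QC/filter -> normalize ->
embed/cluster -> peak-gene links -> motif scan/deviations/markers ->
OT trajectories (fate probabilities, pseudotime, drivers) -> GRN/knockouts.
Each step lives in its own module; this file only wires them together so
tests and the acceptance script can run the identical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from palatrix import linkage, markers, motifs, perturb, preprocess, qc, trajectory
from palatrix.config import SimConfig
from palatrix.datatypes import MultiomeDataset
from palatrix.grn import GRNModel, base_grn, fit_grn
from palatrix.synth import (
    build_regulatory_program,
    make_ground_truth,
    render_multiome_counts,
    simulate_cell_states,
)
from palatrix.transport import ot_coupling


def simulate_default(seed: int = 0, n_cells_per_stage=(500, 500, 500, 500),
                     config: SimConfig | None = None):
    """Simulate a dataset with ground truth; returns (dataset, truth, program)."""
    cfg = config or SimConfig()
    program = build_regulatory_program(cfg, seed=seed)
    states = simulate_cell_states(program, n_cells_per_stage, seed=seed + 1)
    dataset = render_multiome_counts(program, states, seed=seed + 2)
    truth = make_ground_truth(program, states)
    return dataset, truth, program


@dataclass
class PipelineResult:
    dataset: MultiomeDataset
    qc_table: pd.DataFrame
    embedding: preprocess.EmbeddingModel
    clusters: np.ndarray
    layout2d: np.ndarray
    peak_features: pd.DataFrame
    links: pd.DataFrame
    sig_links: pd.DataFrame
    link_summary: dict
    hits: pd.DataFrame
    deviations: pd.DataFrame
    rna_markers: pd.DataFrame
    dev_markers: pd.DataFrame
    multiomic_markers: pd.DataFrame
    fate: trajectory.FateModel
    pseudotime: np.ndarray
    growth: np.ndarray
    drivers: dict = field(default_factory=dict)     # terminal state -> table
    extras: dict = field(default_factory=dict)


def run_core(dataset: MultiomeDataset, motif_list, prolif_genes, seed: int = 0,
             n_macrostates: int | None = None, d_rna: int = 30, d_atac: int = 30,
             link_window: int = 500_000, m_background: int = 200,
             cluster_resolution: float = 1.0, knn_k: int = 20) -> PipelineResult:
    """Run QC through fate/driver analysis on a paired dataset."""
    # ---- QC and filtering
    qc_table = qc.compute_qc_metrics(dataset)
    ds, _removed = qc.filter_cells(dataset, qc_table)

    # ---- normalization and embeddings
    preprocess.normalize_rna(ds)
    emb = preprocess.reduce_dimensions(ds, d_rna=d_rna, d_atac=d_atac)
    clusters = preprocess.cluster_cells(emb.pcs, k=knn_k,
                                        resolution=cluster_resolution, seed=seed)
    emb.clusters = clusters
    layout = preprocess.force_layout(preprocess.knn_graph(emb.pcs, k=knn_k),
                                     seed=seed)
    emb.display2d = layout

    # ---- peak-gene linkage
    feats = linkage.peak_feature_table(ds)
    pairs = linkage.candidate_pairs(ds.annotation, window=link_window)
    links = linkage.link_test(ds, pairs, m_background=m_background, seed=seed,
                              features=feats)
    sig, _per_gene, summary = linkage.filter_links(links)

    # ---- motifs: scan, deviations, markers
    hits = motifs.scan_motifs(ds.annotation.genome, ds.annotation.peaks,
                              motif_list)
    dev_z, _raw = motifs.motif_deviations(ds.atac.X, hits, feats, seed=seed)
    expr = np.asarray(ds.rna.layers[preprocess.LAYER])
    rna_mk = markers.rank_sum_markers(expr, clusters,
                                      features=list(ds.rna.var_names))
    dev_mk = markers.rank_sum_markers(dev_z.to_numpy(), clusters,
                                      features=list(dev_z.columns),
                                      effect="diff")
    tf_map = {m.name: m.motif_id for m in motif_list}
    dual, _side = markers.call_multiomic_markers(rna_mk, dev_mk, tf_map)

    # ---- optimal-transport trajectories
    g = trajectory.growth_rates(ds, prolif_genes)
    blocks = trajectory.stage_blocks(ds.obs["stage"])
    couplings = []
    for i in range(len(blocks) - 1):
        gamma, _ = ot_coupling(emb.pcs[blocks[i]], emb.pcs[blocks[i + 1]],
                               g[blocks[i]])
        couplings.append(gamma)
    last_knn = preprocess.knn_graph(emb.pcs[blocks[-1]], k=min(15, len(blocks[-1]) - 1))
    T = trajectory.transition_matrix(couplings, last_knn, blocks)

    if n_macrostates is None:
        n_macrostates = len(pd.unique(ds.obs["stage"])) + 2
    fate = trajectory.fate_probabilities(T, n_macrostates=n_macrostates,
                                         seed=seed)
    root = int(np.argmax(g))
    tau = trajectory.diffusion_pseudotime(emb.pcs, root, k=15)
    fate.root = root
    fate.pseudotime = tau

    drivers = {}
    for name in fate.F.columns:
        drivers[name] = trajectory.driver_genes(expr, list(ds.rna.var_names),
                                                fate.F[name].to_numpy())

    return PipelineResult(
        dataset=ds, qc_table=qc_table, embedding=emb, clusters=clusters,
        layout2d=layout, peak_features=feats, links=links, sig_links=sig,
        link_summary=summary, hits=hits, deviations=dev_z,
        rna_markers=rna_mk, dev_markers=dev_mk, multiomic_markers=dual,
        fate=fate, pseudotime=tau, growth=g, drivers=drivers,
    )


def run_grn(result: PipelineResult, motif_list, seed: int = 0,
            min_cells: int = 50) -> tuple[pd.DataFrame, GRNModel]:
    """Candidate edges + bagging-ridge GRN on the pipeline's own links."""
    ds = result.dataset
    tf_map = {m.name: m.motif_id for m in motif_list}
    cand = base_grn(result.sig_links, result.hits, tf_map, ds.annotation)
    expr = np.asarray(ds.rna.layers[preprocess.LAYER])
    grn = fit_grn(expr, list(ds.rna.var_names), result.clusters, cand,
                  seed=seed, min_cells=min_cells)
    return cand, grn


def knockout_scores(result: PipelineResult, grn: GRNModel, tf: str,
                    lineage_masks: dict, n_grid: int = 30,
                    n_neighbors: int = 200, seed: int = 0):
    """Perturbation score of one TF knockout against every lineage mask."""
    ds = result.dataset
    expr = np.asarray(ds.rna.layers[preprocess.LAYER])
    delta = perturb.simulate_knockout(grn, expr, list(ds.rna.var_names),
                                      result.clusters, tf)
    shifts = perturb.embedding_shift(delta, expr, result.layout2d,
                                     n_neighbors=n_neighbors)
    _, _, Us, Vs, _ = perturb.grid_vector_field(result.layout2d, shifts,
                                                n_grid=n_grid)
    _, _, Uf, Vf, _ = perturb.developmental_flow(result.layout2d,
                                                 result.pseudotime,
                                                 n_grid=n_grid)
    scores = {name: perturb.perturbation_score((Us, Vs), (Uf, Vf), mask)
              for name, mask in lineage_masks.items()}
    return scores, delta, shifts, (Uf, Vf)


def branch_masks_from_membership(layout2d, memberships: dict, n_grid: int = 30):
    """Grid masks per lineage from per-cell membership weights."""
    return {name: perturb.lineage_grid_mask(layout2d, m, n_grid=n_grid)
            for name, m in memberships.items()}
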