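"""Planted regulatory program: gene/peak catalog, lineage TFs, genome.

The program fixes everything deterministic about a simulated experiment:
which genes exist and where they live, which peaks regulate which genes with
what weight, which TF drives each enhancer through which motif, and the
genome sequence (with motif consensi embedded in the target enhancers and a
GC gradient across peaks so that GC-matched background sampling is
non-degenerate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from palatrix.config import SimConfig
from palatrix.datatypes import GenomeAnnotation, encode_seq, peak_name, revcomp

_ENH_SLOTS = (1000, 8400, 2600, 7000)   # enhancer centers within a locus
_BG_SLOTS = (2600, 7000)                # background-peak centers (E<=2)


# --------------------------------------------------------------------- ramps
def ramp_activity(s, timing: str, branch_point: float = 0.25):
    """Latent activity of a lineage TF along branch time ``s``.

    'early' TFs switch on right after the branch point and decay towards the
    end of the trajectory (transient program); 'late' TFs rise from mid
    trajectory to the terminal state.  Values lie in [0, 1].
    """
    s = np.asarray(s, dtype=float)
    if timing == "early":
        up = np.clip((s - branch_point) / 0.20, 0.0, 1.0)
        down = np.clip((1.05 - s) / 0.35, 0.0, 1.0)
        return up * down
    if timing == "late":
        return np.clip((s - 0.45) / 0.55, 0.0, 1.0)
    raise ValueError(f"unknown timing {timing!r}")


def prolif_profile(s):
    """Proliferation program: high in early (multipotent) cells, decaying."""
    return np.clip(1.0 - np.asarray(s, dtype=float) / 0.40, 0.0, 1.0)


def enhancer_activity(ramp_value, steepness: float = 6.0):
    """Bounded monotone link from summed TF activity to enhancer openness."""
    return 1.0 / (1.0 + np.exp(-steepness * (np.asarray(ramp_value) - 0.5)))


# ------------------------------------------------------------------- program
@dataclass
class RegulatoryProgram:
    config: SimConfig
    genes: pd.DataFrame        # contig,strand,tss,start,end,kind,branch,timing,base
    peaks: pd.DataFrame        # contig,start,end,kind,gene,branch,timing,gc_target,act_base
    links: pd.DataFrame        # gene, peak, weight
    edges: pd.DataFrame        # tf, target, sign
    tf_programs: pd.DataFrame  # index tf gene: branch, timing, motif_id, consensus
    motif_counts: dict         # motif_id -> (tf_name, 4xL count matrix)
    prolif_genes: list
    contig_sizes: dict
    genome: dict               # contig -> uint8 codes

    @property
    def annotation(self) -> GenomeAnnotation:
        return GenomeAnnotation(
            genes=self.genes, peaks=self.peaks,
            contig_sizes=self.contig_sizes, genome=self.genome,
        )

    def validate(self) -> None:
        """Check the structural invariants of the planted program."""
        cfg = self.config
        # planted links within the linkage window of their gene's TSS
        mid = (self.peaks["start"] + self.peaks["end"]) // 2
        for gene, peak in zip(self.links["gene"], self.links["peak"]):
            d = abs(int(mid.loc[peak]) - int(self.genes.loc[gene, "tss"]))
            assert d <= 500_000, "planted link outside the linkage window"
        # every lineage TF has >=1 target with a motif-bearing enhancer
        for tf in self.tf_programs.index:
            targets = self.edges.loc[self.edges["tf"] == tf, "target"]
            assert len(targets) > 0, f"TF {tf} has no targets"
        # mitochondrial genes only on chrM, and vice versa
        on_m = self.genes["contig"] == "chrM"
        assert (self.genes.loc[on_m, "kind"] == "mito").all()
        assert (self.genes.loc[self.genes["kind"] == "mito", "contig"] == "chrM").all()
        # contig bounds accommodate all peaks (also enforced by annotation)
        _ = self.annotation
        assert cfg.n_branches >= 2


def _draw_consensi(rng, n, length, min_hamming=4, max_tries=1000):
    """Random motif consensi with pairwise Hamming distance >= min_hamming."""
    out = []
    for _ in range(max_tries):
        cand = rng.integers(0, 4, size=length).astype(np.uint8)
        if all(int((cand != c).sum()) >= min_hamming for c in out):
            out.append(cand)
            if len(out) == n:
                return out
    raise RuntimeError("could not draw dissimilar motif consensi")


def _peak_seq(rng, length, gc):
    """Random sequence with the requested GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def build_regulatory_program(config: SimConfig | None = None, seed: int = 0) -> RegulatoryProgram:
    """Build the deterministic planted program for ``(config, seed)``.

    Raises ``ValueError`` for configurations whose peaks cannot be placed
    (too many enhancers or background peaks for the locus geometry).
    """
    cfg = config or SimConfig()
    if cfg.enhancers_per_target > len(_ENH_SLOTS):
        raise ValueError("at most 4 enhancers per target fit in one locus")
    rng = np.random.default_rng(seed)

    # ------------------------------------------------------------- gene list
    timings = ["early", "late"]
    tf_rows, tg_rows = [], []
    for b in range(cfg.n_branches):
        for i in range(cfg.tfs_per_branch):
            t = timings[i % 2]
            tf_rows.append((f"Tf_{b}_{i}_{t}", "tf", b, t))
        for j in range(cfg.targets_per_branch):
            t = timings[j % 2]
            tg_rows.append((f"Tg_{b}_{j:03d}", "target", b, t))
    hk = [(f"Hk_{i:04d}", "housekeeping", -1, "") for i in range(cfg.n_housekeeping)]
    prf = [(f"Prf_{i:03d}", "prolif", -1, "") for i in range(cfg.n_prolif)]
    mito = [(f"mt_{i}", "mito", -1, "") for i in range(cfg.n_mito)]

    # ------------------------------------------------------ layout on contigs
    # main contigs: one target per branch per contig (targets_per_branch <=
    # n_contigs guarantees same-branch targets never share a contig), with
    # housekeeping/proliferation genes round-robin; each TF gets its own
    # small contig; mitochondrial genes go to chrM.
    contig_genes: dict[str, list] = {f"chr{c + 1}": [] for c in range(cfg.n_contigs)}
    main_contigs = list(contig_genes)
    for name, kind, b, t in tg_rows:
        j = int(name.split("_")[-1])
        contig_genes[main_contigs[j]].append((name, kind, b, t))
    for i, row in enumerate(hk + prf):
        contig_genes[main_contigs[i % cfg.n_contigs]].append(row)
    for k, row in enumerate(tf_rows):
        contig_genes[f"chrT{k + 1}"] = [row]
    contig_genes["chrM"] = mito

    gene_rows, peak_rows, link_rows = [], [], []
    contig_sizes: dict[str, int] = {}
    strand_flip = 0
    bg_slots_free = []  # (contig, center) available for background peaks

    for contig, rows in contig_genes.items():
        contig_sizes[contig] = len(rows) * cfg.locus_size + 2000
        for li, (name, kind, b, t) in enumerate(rows):
            L = 1000 + li * cfg.locus_size
            strand = "+" if strand_flip % 2 == 0 else "-"
            strand_flip += 1
            if strand == "+":
                tss = L + 4000
                body = (tss, tss + 2000)
            else:
                tss = L + 6000
                body = (tss - 2000, tss)
            gene_rows.append((name, contig, strand, tss, body[0], body[1], kind, b, t))
            # promoter peak centered on the TSS
            half = cfg.promoter_width // 2
            peak_rows.append((contig, tss - half, tss + half, "promoter", name, b, t))
            if kind == "target":
                for e in range(cfg.enhancers_per_target):
                    c = L + _ENH_SLOTS[e]
                    w = int(rng.integers(150, 251))
                    peak_rows.append((contig, c - w, c + w, "enhancer", name, b, t))
                    link_rows.append((name, peak_name(contig, c - w, c + w),
                                      cfg.link_weight))
                extra = _ENH_SLOTS[cfg.enhancers_per_target:len(_ENH_SLOTS)]
                for c in extra:
                    if c in _BG_SLOTS:
                        bg_slots_free.append((contig, L + c))
            else:
                for c in _BG_SLOTS:
                    bg_slots_free.append((contig, L + c))

    if cfg.n_background_peaks > len(bg_slots_free):
        raise ValueError(
            f"cannot place {cfg.n_background_peaks} background peaks in "
            f"{len(bg_slots_free)} free slots; enlarge the gene catalog"
        )
    order = rng.permutation(len(bg_slots_free))[:cfg.n_background_peaks]
    for idx in sorted(order):
        contig, c = bg_slots_free[idx]
        w = int(rng.integers(100, 301))
        peak_rows.append((contig, c - w, c + w, "background", "", -1, ""))

    genes = pd.DataFrame(
        gene_rows,
        columns=["gene", "contig", "strand", "tss", "start", "end", "kind",
                 "branch", "timing"],
    ).set_index("gene")
    peaks = pd.DataFrame(
        peak_rows,
        columns=["contig", "start", "end", "kind", "gene", "branch", "timing"],
    )
    peaks.index = [peak_name(c, s, e)
                   for c, s, e in zip(peaks["contig"], peaks["start"], peaks["end"])]
    links = pd.DataFrame(link_rows, columns=["gene", "peak", "weight"])

    # --------------------------------------------------- baseline expression
    # Lineage TFs and their targets are modeled as well-detected genes (the
    # regime where marker/linkage analyses operate); the bulk of the
    # catalog follows a broad lognormal.
    base = rng.lognormal(0.0, 1.0, size=len(genes))
    marker_like = genes["kind"].isin(("tf", "target")).to_numpy()
    base[marker_like] = rng.lognormal(1.4, 0.5, size=int(marker_like.sum()))
    base *= cfg.rna_mean_total / base.sum()
    is_mito = (genes["kind"] == "mito").to_numpy()
    if is_mito.any():
        other = base[~is_mito].sum()
        want = cfg.mito_frac / (1 - cfg.mito_frac) * other
        base[is_mito] *= want / base[is_mito].sum()
    genes["base"] = base

    # constant component of peak accessibility
    act_base = np.full(len(peaks), np.nan)
    kinds = peaks["kind"].to_numpy()
    act_base[kinds == "promoter"] = 0.8
    nbg = int((kinds == "background").sum())
    act_base[kinds == "background"] = rng.uniform(0.05, 0.5, size=nbg)
    peaks["act_base"] = act_base

    # ------------------------------------------------------------ TF motifs
    tf_names = [r[0] for r in tf_rows]
    consensi = _draw_consensi(rng, len(tf_names), cfg.motif_length)
    motif_counts, tf_prog_rows = {}, []
    for k, (name, _, b, t) in enumerate(tf_rows):
        mid = f"SM{k:04d}.1"
        counts = np.full((4, cfg.motif_length), 5.0)
        counts[consensi[k], np.arange(cfg.motif_length)] = 85.0
        motif_counts[mid] = (name, counts)
        tf_prog_rows.append((name, b, t, mid,
                             "".join("ACGT"[c] for c in consensi[k])))
    tf_programs = pd.DataFrame(
        tf_prog_rows, columns=["tf", "branch", "timing", "motif_id", "consensus"]
    ).set_index("tf")

    # TF -> target edges: the branch TF with matching timing drives the target
    edge_rows = []
    for tf, row in tf_programs.iterrows():
        sel = (genes["kind"] == "target") & (genes["branch"] == row["branch"]) \
            & (genes["timing"] == row["timing"])
        for target in genes.index[sel]:
            edge_rows.append((tf, target, 1))
    edges = pd.DataFrame(edge_rows, columns=["tf", "target", "sign"])

    # --------------------------------------------------------------- genome
    gc_target = rng.permutation(
        np.linspace(cfg.gc_range[0], cfg.gc_range[1], len(peaks)))
    gc_target = np.clip(gc_target + rng.normal(0, 0.02, len(peaks)), 0.2, 0.8)
    peaks["gc_target"] = gc_target

    genome = {c: rng.choice(4, size=n, p=[0.29, 0.21, 0.21, 0.29]).astype(np.uint8)
              for c, n in contig_sizes.items()}
    tf_by_key = {(r["branch"], r["timing"]): (tf, r["consensus"])
                 for tf, r in tf_programs.iterrows()}
    for pid, prow in peaks.iterrows():
        s, e = int(prow["start"]), int(prow["end"])
        seq = _peak_seq(rng, e - s, float(prow["gc_target"]))
        if prow["kind"] == "enhancer":
            _, consensus = tf_by_key[(prow["branch"], prow["timing"])]
            cons = encode_seq(consensus)
            n_copies = int(rng.integers(1, 3))
            for _ in range(n_copies):
                pos = int(rng.integers(0, len(seq) - len(cons) + 1))
                ins = cons if rng.random() < 0.5 else revcomp(cons)
                seq[pos:pos + len(cons)] = ins
        genome[prow["contig"]][s:e] = seq

    prog = RegulatoryProgram(
        config=cfg, genes=genes, peaks=peaks, links=links, edges=edges,
        tf_programs=tf_programs, motif_counts=motif_counts,
        prolif_genes=[g for g in genes.index if genes.loc[g, "kind"] == "prolif"],
        contig_sizes=contig_sizes, genome=genome,
    )
    prog.validate()
    return prog
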