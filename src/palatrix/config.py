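"""Simulation configuration for the synthetic multiome generator."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


@dataclass
class SimConfig:
    """Parameters of the planted regulatory program and count model.

    The defaults describe the study conditions every recovery test runs
    under: a five-branch lineage field sampled at four stages, two lineage
    TFs per branch (one early-transient, one late-rising), two motif-bearing
    enhancers per target gene with a strong planted link weight, and
    negative-binomial RNA / sparse truncated-Poisson ATAC noise.

    Geometry note: same-branch target genes are placed on distinct contigs
    (``targets_per_branch <= n_contigs`` is required) and each lineage TF
    gene sits on its own small contig, so that within the peak-gene linkage
    window the only positively co-varying (gene, peak) pairs are the planted
    ones.  Co-regulated genes inside one linkage window would otherwise make
    "precision against planted links" an ill-posed quantity.
    """

    # lineage field
    n_branches: int = 5
    branch_point: float = 0.25
    branch_weights: tuple = ()          # empty -> uniform
    stage_windows: tuple = ((0.0, 0.30), (0.25, 0.55), (0.50, 0.80), (0.75, 1.0))

    # gene catalog
    tfs_per_branch: int = 2             # one 'early', one 'late'
    targets_per_branch: int = 40
    n_housekeeping: int = 750
    n_prolif: int = 30
    n_mito: int = 10

    # peak catalog / genome geometry
    enhancers_per_target: int = 2
    n_background_peaks: int = 1600
    n_contigs: int = 40
    locus_size: int = 10_000
    promoter_width: int = 400
    motif_length: int = 10
    gc_range: tuple = (0.30, 0.70)

    # regulatory effect sizes
    link_weight: float = 1.0            # the documented "strong" effect size
    enhancer_steepness: float = 6.0
    tf_expr_gain: float = 3.0
    prolif_expr_gain: float = 2.0

    # count noise
    nb_theta: float = 10.0              # NB dispersion (var = m + m^2/theta)
    rna_mean_total: float = 3500.0      # expected RNA counts per unit-depth cell
    rna_depth_sigma: float = 0.35
    atac_depth_sigma: float = 0.35
    atac_rate: float = 0.5              # Poisson scale per unit activity
    atac_max_count: int = 4
    mito_frac: float = 0.03

    # growth
    growth_multipotent: float = 1.8
    branch_growth: tuple = ()           # empty -> all 1.0

    # fragments
    frag_short_prob: float = 0.7
    frag_len_short: tuple = (80.0, 15.0)    # mean, sd (sub-nucleosomal)
    frag_len_mono: tuple = (200.0, 20.0)    # mean, sd (mono-nucleosomal)

    # junk barcodes appended after the real cells (violate QC thresholds)
    junk_fraction: float = 0.05
    junk_rna_scale: float = 0.012
    junk_atac_scale: float = 0.05

    def __post_init__(self):
        if self.n_branches < 2:
            raise ValueError("need at least 2 branches")
        if self.targets_per_branch > self.n_contigs:
            raise ValueError(
                "targets_per_branch must not exceed n_contigs (same-branch "
                "targets are placed on distinct contigs)"
            )
        if self.n_genes < 50:
            raise ValueError("gene catalog too small (need >= 50 genes)")
        for lo, hi in self.stage_windows:
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError("stage windows must be sub-intervals of [0, 1]")
        if len(self.stage_windows) != 4:
            raise ValueError("exactly 4 sampling stages are modeled")

    # ------------------------------------------------------------------ sizes
    @property
    def n_tfs(self) -> int:
        return self.n_branches * self.tfs_per_branch

    @property
    def n_targets(self) -> int:
        return self.n_branches * self.targets_per_branch

    @property
    def n_genes(self) -> int:
        return self.n_tfs + self.n_targets + self.n_housekeeping + self.n_prolif + self.n_mito

    @property
    def n_peaks(self) -> int:
        return self.n_genes + self.n_targets * self.enhancers_per_target + self.n_background_peaks

    def branch_probs(self):
        import numpy as np

        if self.branch_weights:
            w = np.asarray(self.branch_weights, dtype=float)
            if len(w) != self.n_branches or (w <= 0).any():
                raise ValueError("branch_weights must be positive, one per branch")
            return w / w.sum()
        return np.full(self.n_branches, 1.0 / self.n_branches)

    def branch_growth_multipliers(self):
        import numpy as np

        if self.branch_growth:
            g = np.asarray(self.branch_growth, dtype=float)
            if len(g) != self.n_branches or (g <= 0).any():
                raise ValueError("branch_growth must be positive, one per branch")
            return g
        return np.ones(self.n_branches)

    # ------------------------------------------------------------------- io
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("branch_weights", "branch_growth", "gc_range",
                    "frag_len_short", "frag_len_mono"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "stage_windows" in d:
            d["stage_windows"] = tuple(tuple(w) for w in d["stage_windows"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def small(cls, **overrides) -> "SimConfig":
        """A reduced configuration for fast unit tests (same structure)."""
        base = dict(
            n_branches=3, targets_per_branch=8, n_housekeeping=40, n_prolif=10,
            n_mito=5, n_background_peaks=100, n_contigs=8,
            # keep per-cell ATAC totals realistic at the reduced peak count
            atac_rate=6.0, atac_max_count=8,
        )
        base.update(overrides)
        return cls(**base)
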