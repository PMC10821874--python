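# Methods

This note documents the models and numerical choices behind `palatrix`:
what the synthetic multiome generator simulates (and deliberately does
not), how each statistic is defined, and where a genuinely open design
point was decided.

## The synthetic multiome generator

### Lineage field

Each cell carries a latent time *s* ∈ [0, 1]. The four sampling stages draw
*s* uniformly from overlapping windows
(t0: [0, 0.30], t1: [0.25, 0.55], t2: [0.50, 0.80], t3: [0.75, 1.0]),
mirroring a four-stage embryonic time course. Cells with
*s* < 0.25 (the branch point) are multipotent; cells past it commit once to
one of *B* = 5 branches with configurable weights (uniform by default).
True growth rates are 1.8 for multipotent cells and 1.0 (per-branch
configurable) after commitment, realized through a proliferation gene set
whose expression decays with *s* — so growth is recoverable from
expression, as the OT step assumes.

### Regulatory program

Every branch has two lineage TFs with distinct dynamics: an
**early-transient** TF (activity ramps up just after the branch point and
decays toward the end) and a **late-rising** TF (activity grows from
mid-trajectory to the terminal state). The ramps jointly cover the whole
branch time so that expression is informative about *s* everywhere — a
modeling choice made so pseudotime is identifiable along the full
trajectory, which is also the biological premise of "continuous
differentiation".

Each branch has 40 target genes (half early, half late), each with one
promoter peak and two enhancer peaks. Enhancer accessibility is a logistic
of the driving TF's activity (steepness 6, midpoint 0.5): the field gives
no canonical generative model for enhancer activation, and any bounded
monotone link suffices for recovery testing. The planted link weight
(default 1.0, the documented "strong" effect) enters RNA as
mean = depth × baseline × (1 + Σ w·activity).

**Geometry matters.** Same-branch targets are placed on *different*
contigs, and each lineage TF gene sits on its own small contig. Inside a
500-kb linkage window, the only positively co-varying (gene, peak) pairs
are then the planted ones; co-regulated genes sharing a window would make
"precision against planted links" ill-posed, since the statistical method
cannot (and should not) distinguish a planted enhancer from an equally
correlated co-regulated one. Cross-branch pairs inside a window
anti-correlate and are removed by the *r* > 0 filter, which the tests
exercise deliberately.

### Counts, genome, fragments

- RNA: negative binomial, dispersion θ = 10 (variance m + m²/θ). Lineage
  TFs and targets draw baselines from lognormal(1.4, 0.5) — markers are
  modeled as well-detected genes, the regime marker/linkage analyses
  operate in — the rest from lognormal(0, 1); per-cell depth is
  lognormal with σ = 0.35. Ten mitochondrial genes on `chrM` carry 3 % of
  counts.
- ATAC: Poisson(depth × 0.5 × accessibility), truncated at 4 (sparse,
  near-binary, like real per-peak multiome counts). Promoters are
  constitutively open (0.8), background peaks sit at fixed levels
  U(0.05, 0.5).
- Genome: ~11 Mb of synthetic sequence; peak GC targets follow a shuffled
  0.30–0.70 gradient so GC-matched background sampling is non-degenerate.
  Each enhancer carries 1–2 copies of its driving TF's 10-bp consensus on
  a random strand; the ten consensi are pairwise ≥ 4 mismatches apart.
- Fragments: one row per ATAC count (so per-cell fragment totals equal
  ATAC row sums by construction), lengths from a 70/30 mixture of
  sub-nucleosomal (80 ± 15) and mono-nucleosomal (200 ± 20) sizes.
- Junk barcodes (5 % by default) are appended with ~50-fold reduced
  depth in both assays; they fail the count thresholds.

### What the generator does *not* simulate

No doublets, batch/replicate effects, read-level data,
spliced/unspliced layers, trans (inter-contig) regulation, repressive
(negative-weight) links, TF–TF cooperation, or sequence effects beyond
the planted consensus. Passing recovery tests therefore shows the
statistics behave correctly when their assumptions hold — not that they
are robust to these real-data complications. Dispersion and depth
distributions are conventional choices, not fitted to any dataset.

## Statistical definitions and numerical choices

**QC.** nucleosome_signal = (#fragments 147–294 bp)/max(1, #fragments
< 147 bp). TSS.enrichment = mean per-base coverage in TSS ± 50 bp divided
by mean coverage in the outermost flanks [−1000, −901] ∪ [901, 1001), with
pseudocount 0.1 in the denominator, aggregated over all TSSs (each
fragment attributed to its nearest TSS; loci are far apart relative to the
windows). All six filter bounds are strict. A missing fragments table
yields NaN ATAC metrics, never silent zeros.

**Normalization.** `log1p(count / cell_total × median(cell_totals))` —
a deliberate substitution for regression-based variance stabilization;
every downstream statistic here (Pearson r, Wilcoxon ranks) is robust to
it, and it is exactly invariant to per-cell depth.

**LSI.** Binarize, TF = count/cell_total, IDF = log(1 + n/(1 + occ)), then
`log1p(tf·idf·1e4)` before the SVD — the log scaling is the standard
scATAC-toolchain convention and linearizes the depth signal that LSI
component 1 is dropped for (measured |r| with log depth ≈ 0.99 at default
scale). Component signs are fixed so the largest-magnitude loading is
positive, making runs comparable.

**Peak–gene linkage.** Candidates are all same-contig pairs with |peak
midpoint − TSS| ≤ 500 kb. The null for a pair is built from the *m* = 200
peaks nearest in z-scored (GC, accessibility, width) space (self excluded,
ties by peak index). The null location/scale are the **median and
1.4826 × MAD** of the background correlations rather than mean/sd: matched
backgrounds inevitably contain a few co-regulated peaks whose correlations
inflate a moment-based sd and halve the z of true links, while the scaled
MAD estimates the sd consistently under a clean null (type-I calibration
is unchanged: ~5 % raw p < 0.05 in the null simulation). One-sided
upper-tail p (positive regulation is the target), BH across tested pairs,
and the catalog filter r > 0 ∧ p_adj < 0.05. Constant vectors make a pair
untestable (flagged, not NaN-propagated).

**Motifs.** JASPAR probabilities use the pseudocount split
(count + 0.25)/(colsum + 1); log-odds against a uniform background. Scan
thresholds come from the exact DP distribution of the discretized window
score (grid 10⁻³) at scan p = 10⁻⁴, comparable across motif lengths. Both
strands are scanned by reverse-complementing the score matrix. chromVAR
deviations use cell-independent expected counts and 50 GC×accessibility
decile-matched background sets; zero background spread maps to z = 0.

**Markers.** One-vs-rest Wilcoxon: exact distribution for tie-free groups
with both sides ≤ 10, tie-corrected normal approximation (no continuity
correction) otherwise. Effect size is the natural-log fold change of
pseudocounted means for expression, or the plain mean difference for
signed inputs (deviations). The dual-modality TF call requires
p_adj < 0.05 with positive effect in both assays; by default the motif
side uses the deviation-based test (the peak-set enrichment test is also
available through `motif_enrichment` for callers who prefer it).

**Optimal transport.** Costs are squared Euclidean distances in the top-30
RNA PCs; ε defaults to 0.05 × mean cost; the source marginal carries
g^Δt with a KL penalty λ = 1 (softly unbalanced), the target marginal is
uniform and exact. The solver runs in the log domain (log-sum-exp
scaling), stable at small ε; growth is re-estimated from transported mass
and the problem re-solved for 3 iterations.

**Macrostates and fate.** The transition matrix stitches normalized
coupling rows with a symmetrized kNN connectivity kernel inside the last
stage. Macrostates are k-means clusters (50 restarts, seeded) over an
orthonormal basis of the dominant invariant subspace of T, computed by
subspace iteration with QR — a Perron-cluster approximation. Plain Arnoldi
eigenvectors are *unreliable* here because the eigenvalues of the
metastable basins cluster at 1 (near-degenerate), which subspace iteration
handles by construction. Each macrostate's **stability** is the
self-transition of its core cells (the 30 members most extreme along the
cluster direction from the global mean — the k-means analogue of
membership-simplex vertices); full-membership self-transition is diluted
by boundary cells. Terminal macrostates have stability ≥ 0.95 or are named
explicitly. Fate probabilities solve (I − Q)F = R by GMRES (tol 10⁻¹⁰)
with a direct fallback; unreachable transient cells raise an error rather
than renormalizing silently.

**Pseudotime.** Diffusion map of the density-normalized symmetrized kNN
kernel; τ is the eigenvalue-weighted (λ/(1−λ)) diffusion distance to the
root, rescaled to [0, 1]. The root defaults to the cell with the highest
estimated growth rate (a multipotent cell by construction). The graph must
be connected; the error names the component count.

**Drivers and stage programs.** Drivers: Pearson correlation with a
lineage's fate probability, t-approximation p, BH; flag at corr > 0.05 ∧
p_adj < 0.05. Stage programs extract cells above the per-lineage 75 %
fate quantile (quantile 0 means all cells), order by τ, smooth with a
centered rolling mean (5 % of cells, ≥ 11), standardize, and group
drivers by seeded k-means (k = 3) — a quantile cut on peak positions is
available via `method='quantile'`, since either convention appears in
practice; no claim is made that they coincide. Groups are labeled
start/middle/end by mean peak position. Stage-wise motif enrichment uses
the stage's linked peaks as foreground against all driver-linked peaks of
the lineage.

**GRN and knockouts.** Candidate edges need the TF's motif in a peak
linked to the gene (promoter peaks always eligible; a coaccessibility
table ≥ 0.8 within 500 kb is the alternate assignment mode). Per cluster
(≥ 50 cells), targets are regressed on candidate TFs by ridge with a
GCV-chosen penalty; coefficients are bagged over 20 bootstrap resamples,
and the edge p uses the **bootstrap standard error — the spread of the
bagged coefficients** (dividing by √B would treat correlated resamples as
independent and is measurably anti-conservative under permutation).
Filters: p < 0.001, then at most 2,000 edges per cluster by |coefficient|.
Knockout: TF forced to 0, increments propagated across regulator→target
edges for 3 steps (the cited propagation depth convention), cumulative
shifts floored so expression never goes negative, KO gene held at zero.
Embedding shifts compare each cell's gene-space shift with expression
offsets to its 200 embedding neighbors, softmax at σ = 0.05, minus the
unweighted mean offset (zero shift for a flat profile). Grid fields use a
Gaussian kernel at one grid-spacing bandwidth on a 30×30 grid; the
developmental flow is the finite-difference gradient of grid-smoothed τ;
the perturbation score is −Σ⟨shift, flow⟩ over a lineage's grid territory
(kernel-dominance mask). The degree-matched null knocks out random genes
granted the real TF's per-cluster out-degree and coefficient values with
rewired targets; the planted TFs share their out-degree by construction,
so one 20-draw pool serves all of them.

**Validation statistics.** Interval overlap uses half-open semantics
(bookended intervals do not overlap) with a sorted sweep over prefix
maxima. ChIP TSS proximity counts a peak when its midpoint is within
±5 kb of any gene-set TSS (edge-based counting by flag); with n = 2
replicates the t-test is underpowered, so a pooled-count Fisher test is
always reported alongside. Odds ratios apply the Haldane–Anscombe 0.5
correction when a cell is zero. Composition percentages round half-up to
two decimals.

**Display embedding.** Any 2-D embedding can be supplied; the pipeline's
own default is a seeded force-directed (Fruchterman–Reingold) layout of
the PC kNN graph, which renders a branching manifold as a star of arms —
the geometry the vector-field steps need.

## Problem sizes

Defaults are sized for a laptop-scale run: 2,000 cells (500 per stage),
1,000 genes, 3,000 peaks, ~11 Mb genome; the full pipeline including GRN
fitting and ten knockouts runs in about two minutes, and the reduced
3-branch configuration used by most unit tests in a few seconds.

## Known limitations

- Macrostate detection assumes the terminal basins are metastable under
  the within-last-stage kernel; continuous, non-discrete endpoints would
  need soft memberships (full Galerkin PCCA+), which is out of scope.
- The bagging-ridge edge p-value is a stability score, not a calibrated
  sampling p-value; it is validated against permutation behavior, not
  asymptotics.
- The matched-null linkage test corrects technical covariates (GC,
  accessibility, width) only; co-regulation between nearby genes is a
  biological confounder that no background matching removes, which is
  precisely why the generator separates co-regulated genes by more than
  the linkage window.
- Perturbation scores are comparable across TFs within one dataset and
  grid, not across datasets; only orderings and signs are meaningful.
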