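# Methods

This note documents the statistical procedures implemented in `atlastools`,
the conventions and defaults chosen where the methods admit variants, what
the synthetic-data generators do and do not emulate, and known limitations.

## Preprocessing

Cells with fewer than 200 detected genes or a mitochondrial count fraction
strictly above 30% are removed, then genes detected in fewer than 3
remaining cells; the gene filter runs after the cell filters so the result
is well defined. Mitochondrial genes are supplied as an explicit list —
no symbol-prefix convention is assumed. Normalization is the standard
log1p of counts scaled to a fixed library size (`scale_factor`, default
1e4, natural log), making every downstream statistic invariant to per-cell
sequencing depth.

## Rank-AUC gene-set activity and the cycling index

For each cell, genes are ranked by decreasing expression; with
`k = floor(top_fraction · G)` (default `top_fraction = 0.05`, the scoring
tool's usual default), the raw statistic is the area under the set-recovery
curve over the top k ranks, normalized by the maximal achievable area.
Ties in expression are broken by gene-universe order — deterministic and
seed-free. Scores depend only on within-cell ranks, so any monotone
transform of a cell's expression leaves them unchanged.

A cell is called cycling when its cycling-set score strictly exceeds its
noncycling-set score; exact ties go to noncycling (the conservative
choice). The cycling index per cell type is
`log2((n_cycling + 1)/(n_noncycling + 1))`: pseudocount 1 guards empty
classes, and base 2 gives a symmetric axis around 0.

*Small-universe caveat.* With few genes the raw AUC is a small integer and
the two set scores tie for a non-negligible fraction of cells (~6% at
G = 300, k = 15); the conservative tie rule then biases null
classification toward noncycling. At realistic universe sizes
(G ≥ 1000, k ≥ 50) the tie rate falls to ~1% and the null index is
centered at 0, which is the regime the null-calibration test uses.

## Regulon specificity (RSS/RSSZ)

`RSS(r, g) = 1 − √JSD(p, q)` where `p` is regulon r's activity normalized
to a probability vector over cells, `q` the uniform distribution over the
cells of group g, and JSD the Jensen–Shannon divergence with base-2
entropies, so RSS lies exactly in [0, 1]. RSS is invariant to positive
scaling of the activity vector and to permuting cells together with their
labels. RSSZ standardizes RSS across regulons within each group (sample
sd); a TF is group-specific when its mean activity over the group's cells
exceeds 0.1 and its RSSZ exceeds 1.0, both strictly. "Mean activity" is
the minimal aggregate pairing one activity number with one (TF, group)
decision.

## TF modules (PCC → CSI → Ward)

The CSI of a regulon pair (A, B) is the fraction of all N regulons whose
correlation with both A and B falls strictly below PCC(A, B). The
denominator includes A and B (with unit self-correlation they are never
counted, so this choice only rescales; `denominator="n-2"` gives the
excluded-pair scale). Modules come from Ward clustering of Euclidean
distances between rows of the CSI matrix after entries below `csi_floor`
are set to 0; the module count is either fixed or chosen by maximal mean
silhouette over 2..min(12, N−1).

*Scale caveat.* CSI is bounded by (N−2)/N, i.e. ~0.83 at N = 12, so the
atlas-scale floor of 0.9 — meaningful with hundreds of regulons, where CSI
saturates near 1 inside modules — zeroes the whole matrix on small panels.
Desk-scale analyses and the recovery tests therefore cluster the raw CSI
(`csi_floor=0`); the 0.9 default is kept for atlas-scale inputs.

## Highly variable genes and cross-study similarity

HVGs use variance-stabilizing standardized variance: a degree-2 polynomial
of log10(variance) on log10(mean) is fit across genes with positive mean
(a deterministic, dependency-free stand-in for a loess trend), each gene's
counts are standardized by the predicted sd and clipped at √n_cells, and
genes are ranked by the variance of the clipped values.

Neighbor-voting AUROC: cells are rank-standardized within themselves over
the HVGs, cell–cell affinity is the Spearman correlation of those ranks,
each test cell's vote for a reference type is its mean affinity to that
type's cells in the other study, and the AUROC is the probability that
cells of the target type receive higher votes than other cells of their
study (ties count ½, computed via average ranks). The explicit
vote-then-AUROC definition is the reference implementation; it is checked
exhaustively against pairwise comparison counting on small instances.
Votes only cross studies; same-study entries are undefined. Trees over
cell types use 1 − symmetrized AUROC as the distance by default.

Cross-species cell-type correlation is the Spearman correlation of the two
species' per-type mean expression over the HVGs; gene matching across
species is by a user-supplied two-column ortholog table. Markers are
called per gene by two-sided Wilcoxon rank-sum with
`log2FC = log2((mean_in + ε)/(mean_out + ε))`, ε = 1e−9, on de-logged
(expm1) means; the rule *p < 0.05 AND |log2FC| > 0.25* is strict on both
sides and, being uncorrected, admits false positives at roughly α per null
gene.

## Pathway activity with permutation null

Relative expression of gene g in type t is its mean expression in t
divided by the average of its per-type means, computed on the linear
expression scale — log-normalized input is de-logged with expm1 first,
since a ratio of log-scale means compresses true fold changes (a 4-fold
planted effect reaches a score of ~1.6 on the linear scale but only ~1.3
on the log scale). Genes are excluded when their overall mean is 0 or they
are detected in fewer than 25% of cells in *every* cell type (per-type
satisfiability keeps type-specific genes). Pathway activity is the
weighted mean of member-gene relative expressions with weights
1/(number of pathways containing the gene); uniform weights are available.
Significance of elevated activity comes from shuffling cell-type labels
globally, recomputing the full score (detection filter included), and the
add-one estimate `p = (1 + #{permuted ≥ observed})/(n_perm + 1)`, which is
always positive and valid. `n_perm` defaults to 1000.

## Metabolomics

**Tertile classes.** Per species, metabolite means over replicates are
min-max normalized across metabolites and binned at thirds (low < 1/3 ≤
intermediate < 2/3 ≤ high); bins are closed on the left and the species
maximum is high. Normalizing each metabolite across species instead is
available behind a flag. The classes are invariant to positive affine
transforms of a species' profile.

**Differential metabolites.** Welch's t-test (robust to unequal variances)
on log abundances plus VIP from a two-class PLS-DA: NIPALS on autoscaled
metabolites against centered ±1 class coding,
`VIP_j = sqrt(p · Σ_a SSY_a w_ja² / Σ_a SSY_a)` with unit weight vectors,
so mean(VIP²) = 1 identically. The component count is chosen by
leave-one-out Q² (up to 3) by default. Selection requires *p < 0.05 AND
VIP > 1*, both strict. OPLS-DA is approximated by PLS-DA: the orthogonal
signal correction rotates scores but barely moves the selected set at this
scale. *Limitation:* the two criteria measure the same group separation,
so the conjunction does not control FDR — false selections accrue at
roughly α per truly-null metabolite, and precision on wide panels degrades
accordingly; the planted-recovery scenario uses a 12-metabolite panel
where the rule's operating characteristics allow precision ≥ 0.9.

**Metabolite modules.** Abundances are log-transformed (they are
log-normal scale; raw-scale correlation attenuates block structure), the
adjacency is |Pearson cor|^β across samples (β = 6 default; the soft power
is network-specific and exposed in config), the topological overlap matrix
follows the standard convention (zero diagonal adjacency, connectivity
excluding the pair), and metabolites are clustered by average linkage on
1 − TOM. The static cut runs `cut_height` (default 0.25) below the top of
the dendrogram as a fraction of its merge-height range — the 1 − TOM scale
rarely drops below ~0.5 even for correlation-0.9 blocks, so an absolute
height would be meaningless across inputs; this replaces the full dynamic
tree cut, whose hybrid algorithm is out of scope. Branches smaller than
`min_module_size` (3) are left unassigned. The eigen-metabolite is the
first principal component of the autoscaled module submatrix, oriented to
correlate positively with the module mean. Module membership (MM) is a
metabolite's |correlation| with its module's eigen-metabolite; metabolite
significance (MS) is its |correlation| with the focal-species indicator;
key metabolites satisfy MM > 0.9 AND MS > 0.9. Module–species association
uses the exact two-sided Wilcoxon rank-sum of eigen-metabolite values
(exact for n ≤ 20).

## Synthetic data

`simulate_counts` draws negative-binomial counts (gamma–Poisson, shape
`dispersion` = 2) with per-gene baseline means drawn log-normally
(log-sd 1) around `baseline_mean` — real transcriptomes span orders of
magnitude, and a flat mean spectrum lets the HVG variance trend fit
isolated planted genes exactly. Marker genes are multiplied by
`marker_fold_change` (default 8) in their type; cycling cells get the
cycling set up-shifted (noncycling cells the noncycling set) by
`cycling_log_fold` = 2 on the natural-log scale. The cycling and
noncycling sets are interleaved in gene order and share baseline means
pairwise, so neither the rank tie-break nor baseline expression favors one
set under the null. `simulate_regulon_activity` builds activities
`clip(0.5 + noise_sd·z + shift·1[type], 0, 1)` with
`z = √ρ·module_factor + √(1−ρ)·noise`, giving pairwise within-module
correlation ≈ ρ (noise_sd = 0.15 keeps clipping rare). 
`simulate_metabolome` draws log-normal abundances: per-metabolite base
levels N(3, 1) on the log scale, shared block factors with loading √r, a
`log_fold` (default 2) species shift for planted-high sets, and residual
noise sd 0.5 — 4 species × 5 replicates by default, matching a typical
multispecies skin-metabolome design. Every generator is a pure function of
its spec including the seed.

What the generators do **not** emulate: ambient RNA, doublets, batch
effects, gene–gene co-expression beyond the planted sets, dropout beyond
NB sampling, LC/MS censoring or batch drift. Passing tests therefore
demonstrate correctness of the statistics and their operating
characteristics under clean planted structure, not robustness to those
artifacts.

## Numerical conventions

- Strict inequalities in every selection rule (activity > 0.1, RSSZ > 1,
  p < 0.05, VIP > 1, |log2FC| > 0.25, MM/MS > 0.9), matching the stated
  cutoffs; boundary values are excluded.
- Expression rank ties break by gene-universe index; cycling-score ties go
  to noncycling; linkage ties follow scipy's deterministic ordering.
- Sample (ddof = 1) standard deviations throughout; zero-sd columns yield
  0 Z-scores (with a warning) rather than NaN.
- Degenerate inputs are explicit errors (empty matrix after QC, all-zero
  cell in normalization, < 3 cells for correlation, asymmetric distance
  matrices) or NA-with-warning where the spec of the statistic admits it
  (all-zero regulon, pathway with no usable genes, type missing in one
  species).
- Validation scenario sizes (e.g. 100 random rank-AUC instances, 200 CSI
  matrices, 2000-cell regulon panels, 20-seed recovery averages, 199–999
  permutations) are chosen so the whole suite runs in well under a minute
  per scenario on one CPU while leaving comfortable statistical margins.
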