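# Methods

## Barcode cassette and amplicon model

The RNA-barcoded knockout collection replaces the deletion cassette's G418
marker with *URA3* and shortens the heterologous terminator to 43 nt, so
the *URA3* 3'UTR transcribes, in order, a 5-nt clone barcode, the 43-nt
linker, the 20-nt genotype (Downtag) barcode and a 17-nt constant flank.
The per-genotype artificial reference contig is exactly these 85 nt.
`cassette.parse_contig_template` recovers the segment lengths from any
template by locating N-runs; the last two runs are the clone and genotype
slots, earlier runs (the Uptag slot of the full cassette, whose intended
length the template does not constrain) are reported verbatim and not
interpreted.

Amplicon read 2 is modeled as a 20-nt primer prefix followed by the contig
(105 nt total). The prefix length is a parameter: the amplicon's printed
length (102 bp excluding primer overhangs) does not pin down the primer
boundary exactly, and 20 nt is the value under which the published
positional windows are reproduced — the D2 anchor (terminal 18 nt of the
linker) then starts at read position 51 ∈ [48, 51] and the D1 anchor (the
flank) at 89 ∈ [85, 90], with the clone at 21–25. All coordinates are
1-based inclusive, matching the original R-based extraction convention.

## Genotype assignment

Anchors are matched by substitution-only Hamming distance (≤3 mismatches);
on multiple matches the maximum start position is chosen. Reads lacking
either anchor, or with anchors outside the positional windows, are dropped
with a reason code. The genotype region (strictly between the D2 end and
D1 start) is compared to the library at ≤2 mismatches — whole-region
Hamming when lengths match, windowed search otherwise; zero or multiple
hits yield no call (the library generator enforces pairwise Hamming ≥5
between genotype barcodes, which makes ≤2-mismatch calling unambiguous).
Reads are UMI-deduplicated before voting (one vote per UMI/genotype/clone
triple; a flag switches to raw-read voting). Per cell, a genotype is
assigned when it is the only one observed or strictly exceeds 70% of
informative reads; otherwise the cell is discarded. The same rule applies
to expression-matrix contig UMI counts, and the two routes merge:
agreement or a single-route call assigns, disagreement marks the cell
`conflicted` and removes it from all downstream tables. The clone is the
majority clone among reads supporting the winning genotype, with a
deterministic lexicographic tie-break (flagged).

## Count simulator

`synthetic_data.gen_counts` draws gamma-Poisson (negative binomial) counts:
cell c, gene g has mean `s_c · μ_g · f_cg` and dispersion θ (variance
m + m²/θ, default θ = 2, a typical scRNA-seq value). Baseline means μ are
log-normal, scaled to a target library size of 1200 UMI/cell (the study's
median molecule count); mitochondrial genes are pinned at ~5% of reads so
that quality control has realistic headroom under its 10% rule. The factor
f applies: the cell's latent state (each of K = 5 states elevates a
disjoint 10-gene marker program 4-fold), the knockout (the genotype's own
deleted gene keeps a 2% residual of wild-type expression — reduced, not
absent), and a 15-gene stress program (4-fold, stress condition only).
Cells per genotype default to 100 (the study averaged ~93–108). Size
factors s_c are log-normal (σ = 0.25); *heterogeneity-inflated* genotypes
draw them with 3× the log-scale spread, which widens their cells'
leverage distribution without moving means. Wild-type cells (~10% of the
pool) are placed on every plate because all leverage scaling is
WT-anchored. State membership is multinomial: uniform by default,
attractor genotypes put probability 0.6 on their target state.

What the simulator does **not** model: UMI collisions and PCR duplicates,
indel sequencing errors, base-quality variation (constant Q40), doublets,
batch effects between plates beyond plate identity itself, and gene-gene
correlation beyond the planted programs. Tests passing on these data show
that the statistics recover planted structure under the stated noise
model; they do not certify performance on real chemistry artifacts.

## States and differential expression

SCTransform-style normalization is replaced by depth normalization to 10⁴
followed by log1p: every downstream statistic in scope (rank tests,
Fisher tests, SVD leverage) operates on any log-normalized matrix, and
the simple transform keeps the pipeline dependency-free and exactly
reproducible. Ribosomal genes are removed before feature selection.
Cell-cycle (or any) module scores are expression-bin-matched control
scores (24 bins, 100 controls per set gene, set genes excluded from the
control pool); phases are the argmax of S/G2M scores with G1 when neither
is positive. Covariate regression is per-gene OLS with intercept;
residuals are orthogonal to the covariates by construction.

Highly variable genes use a binned-median mean-variance trend (≥~10 genes
per bin so an outlier cannot set its own trend); the default of 2000
features is the field's convention — the source workflow's printed
"nfeatures = 1" cannot be literal (one feature cannot support 14 PCs) and
is treated as a typo. Clustering is PCA (14 components, scaled and
clipped HVG matrix) → shared-nearest-neighbor graph (k = 20, Jaccard
weights over all pairs sharing a neighbor, pruned at 1/15) → igraph
Louvain multilevel at resolution 1, seeded for determinism, labels
renumbered by decreasing size.

Wilcoxon rank-sum tests use the exact null for tie-free samples with both
sizes ≤8 and the tie-corrected normal approximation otherwise; degenerate
all-equal comparisons return p = 1. Marker log2 fold changes use de-logged
means with a 1e-9 pseudocount; BH adjustment is applied within each
state's test set (and within each clone comparison for clone-level DE),
mirroring the per-comparison behavior of the standard tools. Independent
filtering scans a grid of 100 evenly spaced quantiles of the per-gene
mean count, keeps genes at or above each threshold, BH-adjusts the
survivors and counts adjusted p < 0.05; the chosen threshold attains the
maximum count, smallest on ties. Genes with zero counts in the compared
groups are removed beforehand. Global DE counts use |log2FC| ≥ 1 at raw
p < 0.05. Clone DE considers genotypes with >200 cells and clones with
>9 cells against same-genotype clones with ≥3 cells.

The rank-based signature score clips per-cell expression ranks at
r_max + 1 (default r_max = 1500), computes U = Σ ranks(set) − n(n+1)/2 and
reports max(0, 1 − U/(n·r_max)). Note the formula's floor: a set entirely
beyond r_max scores (n−1)/(2·r_max), which is 0 exactly only for
single-gene sets.

## Enrichment

Each genotype with ≥6 cells is tested against each state with a two-sided
Fisher exact test on [in-state∧genotype, out∧genotype; in∧other,
out∧other]. The reported odds ratio is the sample cross-product ratio,
with the Haldane–Anscombe +0.5 correction applied (and flagged) only when
a cell is zero — chosen over the conditional MLE for determinism and
transparency. BH runs globally over all genotype × state tests of a
condition (the conservative scope; per-state scope is available behind a
flag). Enriched ⇔ OR > 1 and adjusted p < 0.05; depleted ⇔ OR < 1 and
adjusted p < 0.05 — the depletion cutoff is OR < 1, as an odds ratio can
never be negative.

## Leverage scores

Genes are filtered on raw mean counts (strictly > 0.25 UMI/cell — the
"UMI counts" phrasing implies the raw matrix; a flag switches to
normalized means). Per plate, the top-20 left singular vectors of the
log-normalized cells × genes matrix are computed with ARPACK partial SVD;
when k ≥ min(cells, genes) the full dense SVD is used instead (partial
algorithms need k < min, and the full decomposition also behaves correctly
on degenerate tied spectra), with the reduced k recorded and warned. Raw
leverage is the row-wise squared norm of U (summing to k by
orthonormality when rank ≥ k); normalized leverage sums to 1 per plate.
Scores are natural-log transformed (the base cancels in z-scoring) and
z-scored against each plate's wild-type cells. Genotype heterogeneity is
the sample SD of the scaled score, divided by the SD over pooled wild-type
cells across plates — pooling is the only definition that yields a single
wild-type reference, which then equals 1 exactly. Thresholds: ≥1.3
negative regulator, ≤0.7 positive regulator (±30% of wild type).

## Cross-condition classification and fitness

Marker-set similarity between conditions uses Fisher tests on set overlap
within a declared gene universe, BH across pairs; the reported odds ratio
is the uncorrected cross-product ratio so disjoint sets read as OR = 0.
Label transfer is re-implemented as PCA projection + k-NN majority vote
(k = 30, ties broken by the nearest neighbor): the reference condition's
PCA is fit on scaled log-normalized data after removing the excluded gene
set (e.g. basal-stress markers, which would otherwise absorb every
stressed cell) and renormalizing both matrices; each query cell receives
the reference state it most resembles, which preserves the scientific
contract of anchor-based transfer while remaining fully transparent.
"Paired uniquely" is interpreted as the modal query state per reference
state; a reference state is core when that modal share is ≥0.4 or when
manually overridden, responsive otherwise.

The fitness permutation test draws 1000 random equal-sized genotype sets
from the unclassified background and reports
p = (1 + #extreme) / (n_perm + 1) (add-one convention, so p ≥ 1/1001 and
never 0). The test direction is a required parameter; reduced fitness is
the usual alternative for state-biased mutants.

## Problem sizes and determinism

The packaged demonstrations and verification runs use desk-scale problem
sizes — tens of genotypes, tens to a hundred cells per genotype, 150–300
genes, 20 replicates for rate estimates — chosen so the planted effects
are recoverable with comfortable statistical margins while every run
completes in seconds. All randomness flows from explicit seeds; a master
seed derives per-stage seeds deterministically, and fixed seeds give
byte-identical simulator output and identical pipeline reports.

## Known limitations

Cell-barcode whitelists and barcode error correction are out of scope (the
simulator emits error-free cell barcodes). The clustering resolution
parameter interacts with the SNN pruning constant; on marginally separated
data the partition count can vary with seed. The Haldane-corrected odds
ratio is biased toward 1 for large imbalanced tables. Leverage-based
heterogeneity conflates expression-scale variability with any other
source of cell-to-cell spread a genotype may have; the simulator's
inflation acts on the size-factor scale only.
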