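# perturbatlas

Analysis toolkit for genome-scale **yeast Perturb-seq** screens built on an
RNA-barcoded knockout collection: every deletion strain expresses a 20-nt
genotype barcode and a 5-nt clone barcode in the 3'UTR of a *URA3* marker,
so each single cell's perturbation identity can be read from its own
transcriptome and from a targeted barcode amplicon. The package implements
the full computational chain from raw amplicon reads to biological calls:

1. **Genotype/clone assignment** — the amplicon read carries
   `primer(20) + clone(5) + linker(43) + genotype(20) + flank(17)`.
   Two constant anchors (D2 = the terminal 18 nt of the linker, D1 = the
   flank) are located with ≤3 mismatches (maximum start position on
   multiple hits) and must fall at read positions 48–51 and 85–90; the
   genotype region between them is matched to the library at ≤2
   mismatches. Per cell, a genotype must hold a strict majority of >70% of
   informative reads; amplicon and expression-matrix calls are merged,
   with disagreements marked `conflicted` and dropped.
2. **Cell states** — QC (genes detected within mean ± 2 SD, ≤10%
   mitochondrial reads), depth/log normalization, cell-cycle scoring and
   OLS regression, highly variable genes, PCA (14 dims), SNN graph and
   Louvain clustering (resolution 1), one-vs-rest Wilcoxon markers
   (log2FC > 0.25, BH-adjusted p < 0.05).
3. **Genotype × state enrichment** — two-sided Fisher exact tests for every
   genotype with ≥6 cells; odds ratio > 1 at adjusted p < 0.05 flags a
   *state attractor*, odds ratio < 1 a depletion.
4. **Transcriptional heterogeneity** — per plate, the top-20 left singular
   vectors *U* of the log-normalized cells × genes matrix give each cell
   the leverage score ℓᵢ = Σⱼ U²ᵢⱼ (normalized to sum 1 per plate), which
   is log-transformed and z-scored against the plate's wild-type cells.
   Genotypes are ranked by the SD of this scaled score with wild type ≡ 1:
   ≥ 1.3 marks a *negative regulator* of heterogeneity, ≤ 0.7 a *positive
   regulator*.
5. **Cross-condition structure** — marker-set Fisher overlap and PCA +
   k-NN label transfer classify *core* states (≥40% of transferred cells
   from one matching state) versus stress-*responsive* states, and a
   one-sided permutation test (1000 draws, add-one convention) compares a
   genotype set's mean fitness against random equal-sized sets.

A first-class **synthetic data module** generates barcode libraries,
gamma-Poisson count matrices with planted states, knockouts, attractors and
variance-inflated genotypes, and paired amplicon FASTQ with known ground
truth, so the whole pipeline is testable end to end without any downloads.

## Worked example

```python
import perturbatlas as pa

sim = pa.SimConfig(n_genotypes=8, n_cells_per_genotype=40,
                   n_genes=150, reads_per_cell=4, seed=3)
report = pa.run_pipeline(pa.PipelineConfig(seed=1), sim_config=sim)
```

prints (via `json.dumps(report, indent=2, sort_keys=True)`):

```json
{
  "assignment": {
    "assigned_fraction": 1.0,
    "conflict_rate": 0.0,
    "precision": 1.0
  },
  "fitness_p_median": 0.5194805194805195,
  "fitness_set_size": 2,
  "n_cells_control": 356,
  "n_cells_stress": 356,
  "n_core_states": 1,
  "n_enriched_genotypes": 0,
  "n_negative_regulators": 0,
  "n_positive_regulators": 1,
  "n_ref_states": 5,
  "n_states_control": 5,
  "n_states_stress": 5,
  "seed": 1,
  "wt_sd_scaled": 1.0
}
```

Every cell with error-free reads was assigned to its true genotype
(`precision` 1.0, no conflicts); clustering found 5 transcriptional states
per condition; no genotype was a state attractor in this neutral
simulation (`n_enriched_genotypes` 0); the wild-type leverage SD is exactly
1 by construction; and the fitness permutation p for an arbitrary genotype
set is near 0.5, as expected under exchangeability. The same workflow is
available from the shell:

```sh
perturbatlas simulate --n-genotypes 20 --seed 1 --outdir sim/
perturbatlas run --seed 1 --outdir run/
perturbatlas cassette parse NNNNNAACGCCGCCATCCAGTGTCGAAAACGAGCTCGAATTCATCGATNNNNNNNNNNNNNNNNNNNNCTACGAGACCGACACCG
```

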