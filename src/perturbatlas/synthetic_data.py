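"""Synthetic Perturb-seq data with known ground truth.

Generates the three kinds of inputs the pipeline consumes, with structure
emulating a pooled yeast knockout Perturb-seq screen:

* a barcode library — per-genotype 20-nt genotype barcodes (pairwise
  Hamming-separated so that calling at <=2 mismatches is unambiguous) and
  5-nt random clone barcodes;
* a sparse gene x cell count matrix — gamma-Poisson (negative binomial)
  counts organised into latent cell states with marker programs, silencing
  of each knocked-out gene in its own genotype, state-attractor genotypes,
  variance-inflated (heterogeneity) genotypes, a stress program, and
  wild-type cells on every plate;
* paired targeted-amplicon FASTQ — read 1 carries the 16-nt cell barcode and
  12-nt UMI, read 2 carries the barcode cassette (20-nt primer prefix,
  clone, 43-nt linker, genotype, 17-nt flank) with iid substitution errors
  and optionally ambient reads from other genotypes.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .cassette import (
    CLONE_LEN,
    CONTIG_LEN,
    FLANK17,
    GENOTYPE_LEN,
    LINKER43,
    build_contig,
)

__all__ = [
    "PRIMER_PREFIX",
    "WT_ID",
    "LibraryEntry",
    "BarcodeLibrary",
    "SimConfig",
    "FastqRecord",
    "gen_library",
    "gen_counts",
    "gen_amplicon_fastq",
    "gen_fitness_table",
]

#: 20 nt immediately upstream of the clone barcode in the cassette (end of
#: the *URA3* 3' region); used as the constant prefix of amplicon read 2.
PRIMER_PREFIX = "GATGCGGCCAGCAAAACTAA"

WT_ID = "WT"

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class LibraryEntry:
    genotype_id: str
    genotype_barcode: str
    clone_barcodes: list[str]
    target_gene: str | None
    target_stop_pos: int
    contig_seq: str
    cassette_seq: str


@dataclass
class BarcodeLibrary:
    """Collection of genotype/clone barcode records."""

    entries: list[LibraryEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def get(self, genotype_id: str) -> LibraryEntry:
        for e in self.entries:
            if e.genotype_id == genotype_id:
                return e
        raise KeyError(genotype_id)

    @property
    def genotype_ids(self) -> list[str]:
        return [e.genotype_id for e in self.entries]

    def barcode_map(self) -> dict[str, str]:
        """genotype barcode -> genotype id."""
        return {e.genotype_barcode: e.genotype_id for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            for clone in e.clone_barcodes:
                rows.append(
                    {
                        "genotype_id": e.genotype_id,
                        "genotype_barcode": e.genotype_barcode,
                        "clone_barcode": clone,
                        "target_gene": e.target_gene or "",
                        "target_stop_pos": e.target_stop_pos,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class SimConfig:
    """Study-design knobs for the simulator.

    Defaults mirror a desk-scale version of the screen: ~100 cells per
    genotype (the study averaged ~93–108), a handful of plates each
    containing wild-type cells, gamma-Poisson noise, a 2% residual of
    wild-type expression for each knocked-out gene, and state-attractor
    probability 0.6 toward the target state.
    """

    n_genotypes: int = 20
    clones_per_genotype: int = 2
    n_cells_per_genotype: int = 100
    wt_fraction: float = 0.10
    n_plates: int = 2
    n_genes: int = 300
    n_states: int = 5
    state_mixture: np.ndarray | None = None  # (n_states,) base probabilities
    attractor_genotypes: dict[str, int] = field(default_factory=dict)
    attractor_pi: float = 0.6
    marker_effect: float = 4.0
    n_markers_per_state: int = 10
    knockout_residual: float = 0.02
    dispersion: float = 2.0
    het_genotypes: list[str] = field(default_factory=list)
    het_inflation: float = 3.0
    size_factor_sigma: float = 0.25
    stress_n_genes: int = 15
    stress_effect: float = 4.0
    condition: str = "control"
    n_mito_genes: int = 8
    n_ribo_genes: int = 12
    lib_size: float = 1200.0
    reads_per_cell: int = 10
    error_rate: float = 0.0
    ambient_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.wt_fraction < 1):
            raise ValueError("wt_fraction must be in [0, 1)")
        if self.wt_fraction == 0:
            raise ValueError(
                "wt_fraction = 0 requests zero wild-type cells; downstream "
                "scaling requires wild-type cells in every plate"
            )
        for name in ("error_rate", "ambient_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.state_mixture is not None:
            pi = np.asarray(self.state_mixture, dtype=float)
            if pi.shape != (self.n_states,) or not np.isclose(pi.sum(), 1.0):
                raise ValueError("state_mixture must sum to 1 over n_states")
        if self.condition not in ("control", "stress"):
            raise ValueError("condition must be 'control' or 'stress'")


@dataclass
class FastqRecord:
    id: str
    seq: str
    qual: str


# ---------------------------------------------------------------------------
# barcode library
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(["A", "C", "G", "T"])[rng.integers(0, 4, length)])


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def gen_library(
    n_genotypes: int,
    clones_per_genotype: int = 2,
    min_hamming: int = 5,
    seed: int = 0,
    include_wt: bool = True,
    max_attempts: int = 10_000,
) -> BarcodeLibrary:
    """Sample a barcode library with pairwise-separated genotype barcodes.

    Genotype barcodes are rejection-sampled 20-mers with pairwise Hamming
    distance >= ``min_hamming`` (default 5, which guarantees unambiguous
    calling at <=2 mismatches).  When ``include_wt`` is set an extra
    wild-type entry (barcoded but with no deleted gene) is appended, as the
    screen's control strains were.
    """
    if min_hamming < 1:
        raise ValueError("min_hamming must be >= 1")
    if min_hamming > GENOTYPE_LEN:
        raise ValueError(
            f"min_hamming={min_hamming} unattainable for {GENOTYPE_LEN}-nt "
            "barcodes"
        )
    rng = np.random.default_rng(seed)
    n_total = n_genotypes + int(include_wt)
    barcodes: list[str] = []
    attempts = 0
    while len(barcodes) < n_total:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not sample {n_total} barcodes at pairwise Hamming "
                f">= {min_hamming} within {max_attempts} attempts"
            )
        cand = _random_seq(rng, GENOTYPE_LEN)
        if all(_hamming(cand, b) >= min_hamming for b in barcodes):
            barcodes.append(cand)

    entries = []
    for i in range(n_genotypes):
        clones = []
        while len(clones) < clones_per_genotype:
            c = _random_seq(rng, CLONE_LEN)
            if c not in clones:
                clones.append(c)
        contig = build_contig(barcodes[i], clones[0])
        entries.append(
            LibraryEntry(
                genotype_id=f"geno{i + 1:04d}",
                genotype_barcode=barcodes[i],
                clone_barcodes=clones,
                target_gene=f"g{i + 1:04d}",
                target_stop_pos=int(rng.integers(1_000, 1_000_000)),
                contig_seq=contig,
                cassette_seq=PRIMER_PREFIX + contig,
            )
        )
    if include_wt:
        clones = []
        while len(clones) < clones_per_genotype:
            c = _random_seq(rng, CLONE_LEN)
            if c not in clones:
                clones.append(c)
        contig = build_contig(barcodes[-1], clones[0])
        entries.append(
            LibraryEntry(
                genotype_id=WT_ID,
                genotype_barcode=barcodes[-1],
                clone_barcodes=clones,
                target_gene=None,
                target_stop_pos=0,
                contig_seq=contig,
                cassette_seq=PRIMER_PREFIX + contig,
            )
        )
    lib = BarcodeLibrary(entries=entries)
    assert all(len(e.contig_seq) == CONTIG_LEN for e in lib.entries)
    return lib


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

def _gene_names(config: SimConfig) -> tuple[pd.DataFrame, dict[str, int]]:
    n_regular = config.n_genes - config.n_mito_genes - config.n_ribo_genes
    if n_regular <= config.n_genotypes + config.n_states * config.n_markers_per_state + config.stress_n_genes:
        raise ValueError("n_genes too small for the requested structure")
    names = [f"g{i + 1:04d}" for i in range(n_regular)]
    names += [f"MT{i + 1:02d}" for i in range(config.n_mito_genes)]
    names += [f"RPL{i + 1:02d}" for i in range(config.n_ribo_genes)]
    var = pd.DataFrame(
        {
            "gene": names,
            "is_mito": [n.startswith("MT") for n in names],
            "is_ribosomal": [n.startswith("RPL") for n in names],
        }
    ).set_index("gene", drop=False)
    var.index.name = None
    return var, {n: i for i, n in enumerate(names)}


def gen_counts(
    library: BarcodeLibrary, config: SimConfig
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Simulate a structured gamma-Poisson count matrix.

    Returns an AnnData (cells x genes, sparse integer counts) whose ``obs``
    carries plate / condition / genotype / clone annotations, together with
    a truth table (one row per cell: true state plus per-genotype flags).

    Counts for cell c, gene g follow a gamma-Poisson law with mean
    ``s_c * mu_g * f_cg`` and dispersion theta (variance m + m^2/theta),
    where f_cg applies the cell's state-marker elevation, the knockout
    residual for the genotype's own deleted gene, and the stress program.
    Heterogeneity-inflated genotypes draw their log-normal size factor s_c
    with ``het_inflation``-times larger log-scale spread.
    """
    config.validate()
    mutant_ids = [e.genotype_id for e in library.entries if e.genotype_id != WT_ID]
    if config.n_genotypes > len(mutant_ids):
        raise ValueError("library does not cover config.n_genotypes")
    mutant_ids = mutant_ids[: config.n_genotypes]
    rng = np.random.default_rng(config.seed)

    var, gene_idx = _gene_names(config)
    n_genes = len(var)
    K = config.n_states

    # disjoint marker / stress programs drawn from non-target regular genes
    n_regular = config.n_genes - config.n_mito_genes - config.n_ribo_genes
    free = np.arange(config.n_genotypes, n_regular)
    picked = rng.choice(
        free,
        size=K * config.n_markers_per_state + config.stress_n_genes,
        replace=False,
    )
    state_markers = [
        picked[k * config.n_markers_per_state : (k + 1) * config.n_markers_per_state]
        for k in range(K)
    ]
    stress_genes = picked[K * config.n_markers_per_state :]
    var["state_marker"] = -1
    for k, idx in enumerate(state_markers):
        var.iloc[idx, var.columns.get_loc("state_marker")] = k
    var["is_stress_program"] = False
    var.iloc[stress_genes, var.columns.get_loc("is_stress_program")] = True

    # baseline gene means, scaled to the target library size
    mu = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    mito = var["is_mito"].to_numpy()
    # pin the expected mitochondrial share of reads at ~5%
    mu[mito] *= (0.05 / 0.95) * mu[~mito].sum() / mu[mito].sum()
    mu *= config.lib_size / mu.sum()

    # --- cell layout ----------------------------------------------------
    genos, clones, plates = [], [], []
    for gid in mutant_ids:
        entry = library.get(gid)
        for _ in range(config.n_cells_per_genotype):
            genos.append(gid)
            clones.append(entry.clone_barcodes[rng.integers(len(entry.clone_barcodes))])
            plates.append(int(rng.integers(config.n_plates)))
    n_mut = len(genos)
    n_wt_total = int(round(n_mut * config.wt_fraction / (1 - config.wt_fraction)))
    n_wt_per_plate = max(2, int(np.ceil(n_wt_total / config.n_plates)))
    wt_entry = library.get(WT_ID) if WT_ID in library.genotype_ids else None
    for p in range(config.n_plates):
        for _ in range(n_wt_per_plate):
            genos.append(WT_ID)
            if wt_entry is not None:
                clones.append(
                    wt_entry.clone_barcodes[rng.integers(len(wt_entry.clone_barcodes))]
                )
            else:
                clones.append("")
            plates.append(p)
    n_cells = len(genos)
    genos = np.array(genos)
    clones = np.array(clones)
    plates = np.array(plates)

    # --- state assignment ----------------------------------------------
    base_pi = (
        np.full(K, 1.0 / K)
        if config.state_mixture is None
        else np.asarray(config.state_mixture, dtype=float)
    )
    states = np.empty(n_cells, dtype=int)
    for gid in np.unique(genos):
        mask = genos == gid
        pi = base_pi.copy()
        if gid in config.attractor_genotypes:
            target = config.attractor_genotypes[gid]
            rest = 1.0 - config.attractor_pi
            pi = base_pi * rest / (base_pi.sum() - base_pi[target] + 1e-300)
            pi[target] = 0.0
            pi = pi / max(pi.sum(), 1e-300) * rest
            pi[target] = config.attractor_pi
        states[mask] = rng.choice(K, size=mask.sum(), p=pi / pi.sum())

    # --- per-cell expected means ----------------------------------------
    log_s = rng.normal(0.0, config.size_factor_sigma, size=n_cells)
    het_mask = np.isin(genos, config.het_genotypes)
    if het_mask.any():
        log_s[het_mask] = rng.normal(
            0.0, config.size_factor_sigma * config.het_inflation, size=het_mask.sum()
        )
    size_factors = np.exp(log_s - log_s.mean())

    target_idx = {
        gid: gene_idx[library.get(gid).target_gene]
        for gid in mutant_ids
        if library.get(gid).target_gene in gene_idx
    }

    theta = config.dispersion
    blocks = []
    for c in range(n_cells):
        m = mu.copy()
        m[state_markers[states[c]]] *= config.marker_effect
        if config.condition == "stress":
            m[stress_genes] *= config.stress_effect
        if genos[c] in target_idx:
            m[target_idx[genos[c]]] *= config.knockout_residual
        m *= size_factors[c]
        lam = rng.gamma(shape=theta, scale=m / theta)
        blocks.append(rng.poisson(lam))
    X = sp.csr_matrix(np.vstack(blocks).astype(np.int64))

    obs = pd.DataFrame(
        {
            "cell": [f"cell{i:06d}" for i in range(n_cells)],
            "plate": [f"plate{p + 1}" for p in plates],
            "condition": config.condition,
            "genotype": genos,
            "clone": clones,
        }
    ).set_index("cell", drop=False)
    obs.index.name = None

    adata = ad.AnnData(X=X, obs=obs, var=var)
    truth = obs.copy()
    truth["state"] = states
    truth["attractor_state"] = [
        config.attractor_genotypes.get(g, -1) for g in genos
    ]
    truth["het_inflated"] = het_mask
    return adata, truth


# ---------------------------------------------------------------------------
# targeted amplicon FASTQ
# ---------------------------------------------------------------------------

def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return arr.tobytes().decode()


def gen_amplicon_fastq(
    library: BarcodeLibrary,
    sim_truth: pd.DataFrame,
    config: SimConfig,
) -> tuple[list[FastqRecord], list[FastqRecord], pd.DataFrame]:
    """Simulate the paired targeted-amplicon library.

    Read 1 = 16-nt cell barcode + 12-nt UMI; read 2 = 20-nt primer prefix +
    clone(5) + linker(43) + genotype(20) + flank(17) = 105 nt, so the clone
    occupies read positions 21-25, the D2 anchor starts at 51 and the D1
    anchor at 89 (1-based).  iid substitutions at ``error_rate``; a fraction
    ``ambient_rate`` of reads carries a random other genotype's cassette.
    Returns (read1, read2, cell-barcode table).  Quality is constant Q40.
    """
    if config.reads_per_cell < 1:
        raise ValueError("reads_per_cell must be >= 1")
    rng = np.random.default_rng(config.seed + 1)
    cells = sim_truth["cell"].to_numpy()
    genos = sim_truth["genotype"].to_numpy()
    clones = sim_truth["clone"].to_numpy()

    cell_bcs: dict[str, str] = {}
    seen = set()
    for cell in cells:
        while True:
            bc = _random_seq(rng, 16)
            if bc not in seen:
                seen.add(bc)
                cell_bcs[cell] = bc
                break

    r1: list[FastqRecord] = []
    r2: list[FastqRecord] = []
    entries = library.entries
    n_reads = 0
    for cell, gid, clone in zip(cells, genos, clones):
        entry = library.get(gid)
        for _ in range(config.reads_per_cell):
            src = entry
            src_clone = clone
            if config.ambient_rate > 0 and rng.random() < config.ambient_rate:
                others = [e for e in entries if e.genotype_id != gid]
                src = others[rng.integers(len(others))]
                src_clone = src.clone_barcodes[rng.integers(len(src.clone_barcodes))]
            insert = PRIMER_PREFIX + build_contig(src.genotype_barcode, src_clone)
            seq2 = _mutate(insert, rng, config.error_rate)
            seq1 = cell_bcs[cell] + _random_seq(rng, 12)
            rid = f"read{n_reads:08d}"
            r1.append(FastqRecord(rid, seq1, "I" * len(seq1)))
            r2.append(FastqRecord(rid, seq2, "I" * len(seq2)))
            n_reads += 1
    bc_table = pd.DataFrame(
        {"cell": cells, "cell_barcode": [cell_bcs[c] for c in cells]}
    )
    return r1, r2, bc_table


# ---------------------------------------------------------------------------
# fitness table
# ---------------------------------------------------------------------------

def gen_fitness_table(
    genotypes: list[str],
    stressors: list[str] | None = None,
    low_fitness_set: list[str] | None = None,
    effect: float = -1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic genotype x stressor fitness-score table.

    Scores are standard normal per stressor; genotypes in
    ``low_fitness_set`` are shifted by ``effect`` in every stressor, giving
    a planted signal for the permutation test.
    """
    if stressors is None:
        stressors = [f"stressor{i + 1:02d}" for i in range(14)]
    if len(set(genotypes)) != len(genotypes):
        raise ValueError("duplicated genotype rows")
    rng = np.random.default_rng(seed)
    data = rng.normal(size=(len(genotypes), len(stressors)))
    if low_fitness_set:
        mask = np.isin(genotypes, low_fitness_set)
        data[mask] += effect
    return pd.DataFrame(data, index=pd.Index(genotypes, name="genotype"),
                        columns=stressors)
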