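"""File formats and configuration.

FASTQ (4-line, gzip-transparent), MatrixMarket count triplets with TSV
sidecars, tabular TSV writers, and the YAML-serializable pipeline
configuration holding every threshold of the workflow.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import asdict, dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .synthetic_data import FastqRecord

__all__ = [
    "read_fastq",
    "write_fastq",
    "read_mtx",
    "write_mtx",
    "PipelineConfig",
]


def _opener(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path) -> list[FastqRecord]:
    """Read a 4-line FASTQ file (plain or .gz) into records.

    Malformed records (truncation, seq/qual length mismatch, missing
    markers) raise with the offending line number.
    """
    records = []
    with _opener(path, "r") as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                break
            lines = [header] + [fh.readline() for _ in range(3)]
            lineno += 4
            if any(not ln for ln in lines):
                raise ValueError(f"{path}: truncated record at line {lineno - 3}")
            header, seq, plus, qual = (ln.rstrip("\n") for ln in lines)
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"{path}: malformed record at line {lineno - 3}")
            if len(seq) != len(qual):
                raise ValueError(
                    f"{path}: seq/qual length mismatch at line {lineno - 3}"
                )
            records.append(FastqRecord(header[1:].split()[0], seq, qual))
    return records


def write_fastq(records, path) -> None:
    """Write records as 4-line FASTQ (gzip when the path ends in .gz)."""
    with _opener(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{rec.qual}\n")


def write_mtx(adata: ad.AnnData, outdir) -> None:
    """Write counts as MatrixMarket + genes.tsv / barcodes.tsv /
    cell_metadata.tsv sidecars (genes x cells on disk, the exchange
    convention)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(adata.X.T)
    buf = _io.BytesIO()
    scipy.io.mmwrite(buf, mat, field="integer")
    (outdir / "matrix.mtx").write_bytes(buf.getvalue())
    adata.var.index.to_series().to_csv(
        outdir / "genes.tsv", sep="\t", header=False, index=False
    )
    adata.obs.index.to_series().to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    adata.obs.to_csv(outdir / "cell_metadata.tsv", sep="\t", index=False)


def read_mtx(outdir) -> ad.AnnData:
    """Read a matrix.mtx + sidecar triplet back into an AnnData
    (cells x genes)."""
    outdir = Path(outdir)
    mat = sp.csr_matrix(scipy.io.mmread(outdir / "matrix.mtx").T)
    genes = pd.read_csv(outdir / "genes.tsv", sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(outdir / "barcodes.tsv", sep="\t", header=None)[0].tolist()
    if mat.shape != (len(barcodes), len(genes)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match sidecars "
            f"({len(barcodes)} cells, {len(genes)} genes)"
        )
    obs = pd.DataFrame(index=barcodes)
    meta_path = outdir / "cell_metadata.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t")
        if len(meta) != len(barcodes):
            raise ValueError("cell_metadata.tsv length mismatch")
        obs = meta.set_index(pd.Index(barcodes))
    return ad.AnnData(X=mat, obs=obs, var=pd.DataFrame(index=genes))


@dataclass
class PipelineConfig:
    """Every tunable of the workflow, with defaults matching the study's
    printed thresholds."""

    # barcode assignment
    max_mm_anchor: int = 3
    max_mm_bc: int = 2
    majority: float = 0.70
    clone_window: tuple = (21, 25)
    d2_window: tuple = (48, 51)
    d1_window: tuple = (85, 90)
    locus_threshold: float = 300
    # QC / normalization
    qc_sd: float = 2.0
    qc_mito: float = 0.10
    norm_scale: float = 1e4
    # states
    n_hvg: int = 2000
    dims: int = 14
    resolution: float = 1.0
    k_neighbors: int = 20
    marker_lfc: float = 0.25
    de_lfc: float = 1.0
    alpha: float = 0.05
    # enrichment
    min_cells: int = 6
    # leverage
    k_svd: int = 20
    min_mean: float = 0.25
    reg_up: float = 1.3
    reg_down: float = 0.7
    # cross-condition / fitness
    core_share: float = 0.4
    transfer_k: int = 30
    n_perm: int = 1000
    fitness_side: str = "less"
    # reproducibility
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def validate(self) -> None:
        checks = [
            (0 < self.majority < 1, "majority in (0,1)"),
            (0 <= self.qc_mito <= 1, "qc_mito in [0,1]"),
            (self.qc_sd > 0, "qc_sd > 0"),
            (0 < self.alpha < 1, "alpha in (0,1)"),
            (self.reg_up > 1 > self.reg_down > 0, "reg thresholds bracket 1"),
            (0 < self.core_share <= 1, "core_share in (0,1]"),
            (self.n_perm >= 1, "n_perm >= 1"),
            (self.max_mm_anchor >= 0 and self.max_mm_bc >= 0, "mismatch >= 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"config invariant violated: {msg}")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for key in ("clone_window", "d2_window", "d1_window"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("clone_window", "d2_window", "d1_window"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def stage_seed(self, stage: str) -> int:
        """Derive a per-stage seed (< 2^31) from the master seed."""
        child = np.random.SeedSequence(
            entropy=self.seed, spawn_key=(hash(stage) % (2 ** 31),)
        )
        return int(child.generate_state(1)[0] % (2 ** 31))
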