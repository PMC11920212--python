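"""Genotype and clone calling from targeted-amplicon reads.

Each amplicon read 2 carries the expressed barcode cassette.  The genotype
barcode is located between two constant anchors (D2, the terminal 18 nt of
the linker, and D1, the 17-nt downstream flank), each matched with at most
3 mismatches; when an anchor matches several windows the maximum start
position is used.  Reads are kept only when both anchors are found and
their starts fall in the expected windows (D2 in [48, 51], D1 in [85, 90],
1-based), the clone barcode is read from positions 21-25, and the genotype
region is compared to the library at <=2 mismatches.  Per cell, a genotype
must be supported by a strict majority of more than 70% of the
genotype-informative reads; cells failing that are discarded.  Amplicon
calls are merged with expression-matrix (barcode-contig UMI count) calls:
agreement or a single-route call assigns the genotype, disagreement marks
the cell ``conflicted`` and removes it downstream.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cassette import D1_ANCHOR, D2_ANCHOR, GENOTYPE_LEN
from .synthetic_data import BarcodeLibrary, FastqRecord

__all__ = [
    "D1_WINDOW",
    "D2_WINDOW",
    "CLONE_WINDOW",
    "ParsedRead",
    "CellGenotypeCall",
    "find_pattern",
    "select_anchor",
    "parse_read",
    "call_genotype",
    "aggregate_cell",
    "matrix_call",
    "merge_sources",
    "assign_cells",
    "evaluate_assignment",
]

# 1-based inclusive positional windows on read 2
D2_WINDOW = (48, 51)
D1_WINDOW = (85, 90)
CLONE_WINDOW = (21, 25)

UNASSIGNED = "unassigned"
CONFLICTED = "conflicted"
DISCARDED_MULTI = "discarded_multi"


@dataclass
class ParsedRead:
    cell_barcode: str
    umi: str
    clone_seq: str | None
    genotype_region: str | None
    d2_start: int | None
    d1_start: int | None
    valid: bool
    reason: str | None = None


@dataclass
class CellGenotypeCall:
    cell_barcode: str
    genotype_id: str | None
    status: str | None  # unassigned / conflicted / discarded_multi, or None
    clone_barcode: str | None = None
    read_support: dict[str, int] = field(default_factory=dict)
    source: str | None = None  # amplicon / matrix / both
    clone_tie: bool = False

    @property
    def assigned(self) -> bool:
        return self.genotype_id is not None


def find_pattern(seq: str, pattern: str, max_mm: int) -> list[int]:
    """All 1-based starts where ``pattern`` matches ``seq`` with Hamming
    distance <= ``max_mm`` (substitutions only), in ascending order."""
    if len(pattern) == 0:
        raise ValueError("empty pattern")
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    n, m = len(seq), len(pattern)
    if m > n:
        return []
    s = np.frombuffer(seq.encode(), dtype="S1")
    p = np.frombuffer(pattern.encode(), dtype="S1")
    windows = np.lib.stride_tricks.sliding_window_view(s, m)
    mm = (windows != p).sum(axis=1)
    return [int(i) + 1 for i in np.nonzero(mm <= max_mm)[0]]


def select_anchor(starts: list[int]) -> int | None:
    """Pick the match to use when an anchor hits several windows: the one
    with the maximum start position; None when there is no match."""
    return max(starts) if starts else None


def parse_read(
    read2_seq: str,
    cell_barcode: str = "",
    umi: str = "",
    max_mm: int = 3,
    d2_window: tuple[int, int] = D2_WINDOW,
    d1_window: tuple[int, int] = D1_WINDOW,
    clone_window: tuple[int, int] = CLONE_WINDOW,
) -> ParsedRead:
    """Locate the anchors in one amplicon read and extract barcode fields.

    The genotype region is the substring strictly between the selected D2
    anchor's end and the D1 anchor's start.  Invalid reads carry a reason
    code (too_short / missing_anchor / position_filter).
    """
    min_len = d1_window[0] + len(D1_ANCHOR) - 1
    invalid = dict(
        cell_barcode=cell_barcode, umi=umi, clone_seq=None,
        genotype_region=None, d2_start=None, d1_start=None, valid=False,
    )
    if len(read2_seq) < min_len:
        return ParsedRead(**invalid, reason="too_short")
    d2 = select_anchor(find_pattern(read2_seq, D2_ANCHOR, max_mm))
    d1 = select_anchor(find_pattern(read2_seq, D1_ANCHOR, max_mm))
    if d2 is None or d1 is None:
        return ParsedRead(**{**invalid, "d2_start": d2, "d1_start": d1},
                          reason="missing_anchor")
    if not (d2_window[0] <= d2 <= d2_window[1]) or not (
        d1_window[0] <= d1 <= d1_window[1]
    ):
        return ParsedRead(**{**invalid, "d2_start": d2, "d1_start": d1},
                          reason="position_filter")
    d2_end = d2 + len(D2_ANCHOR) - 1  # 1-based inclusive end of D2
    region = read2_seq[d2_end : d1 - 1]
    clone = read2_seq[clone_window[0] - 1 : clone_window[1]]
    return ParsedRead(
        cell_barcode=cell_barcode, umi=umi, clone_seq=clone,
        genotype_region=region, d2_start=d2, d1_start=d1, valid=True,
    )


def call_genotype(
    genotype_region: str, library: BarcodeLibrary, max_mm: int = 2
) -> str | None:
    """Match an extracted genotype region to the library at <= ``max_mm``.

    Whole-region Hamming comparison when lengths match, windowed search
    otherwise.  A unique hit returns that genotype id; zero or multiple
    hits (ambiguity) return None.
    """
    if not genotype_region:
        raise ValueError("empty genotype region")
    hits = []
    for entry in library.entries:
        bc = entry.genotype_barcode
        if len(genotype_region) == len(bc):
            if sum(a != b for a, b in zip(genotype_region, bc)) <= max_mm:
                hits.append(entry.genotype_id)
        elif len(genotype_region) > len(bc):
            if find_pattern(genotype_region, bc, max_mm):
                hits.append(entry.genotype_id)
        else:
            if find_pattern(bc, genotype_region, max_mm):
                hits.append(entry.genotype_id)
    return hits[0] if len(hits) == 1 else None


def _majority(support: dict[str, int], majority: float) -> str | None:
    """Apply the strict >70% (by default) majority rule to per-genotype
    support counts; returns the winning genotype or None."""
    total = sum(support.values())
    if total == 0:
        return None
    if len(support) == 1:
        return next(iter(support))
    top_gid, top_n = max(support.items(), key=lambda kv: (kv[1], kv[0]))
    return top_gid if top_n > majority * total else None


def aggregate_cell(
    cell_barcode: str,
    read_calls: list[tuple[str, str | None]],
    majority: float = 0.70,
) -> CellGenotypeCall:
    """Combine per-read (genotype, clone) calls into one cell-level call.

    ``read_calls`` holds (genotype_id, clone_seq) per genotype-informative
    read.  A single observed genotype assigns directly; with several, one
    must strictly exceed ``majority`` of the informative reads, otherwise
    the cell is discarded.  The clone is the majority clone among reads
    supporting the assigned genotype (lexicographic tie-break, flagged).
    """
    support = Counter(g for g, _ in read_calls)
    if not support:
        return CellGenotypeCall(cell_barcode, None, UNASSIGNED,
                                source="amplicon")
    winner = _majority(dict(support), majority)
    if winner is None:
        return CellGenotypeCall(cell_barcode, None, DISCARDED_MULTI,
                                read_support=dict(support), source="amplicon")
    clone_counts = Counter(
        c for g, c in read_calls if g == winner and c is not None
    )
    clone, tie = None, False
    if clone_counts:
        best = max(clone_counts.values())
        tied = sorted(c for c, n in clone_counts.items() if n == best)
        clone, tie = tied[0], len(tied) > 1
    return CellGenotypeCall(
        cell_barcode, winner, None, clone_barcode=clone,
        read_support=dict(support), source="amplicon", clone_tie=tie,
    )


def matrix_call(
    cell_barcode: str,
    contig_umi_counts: dict[str, int],
    majority: float = 0.70,
) -> CellGenotypeCall:
    """Genotype call from expression-matrix barcode-contig UMI counts,
    using the same strict-majority rule as the amplicon route."""
    support = {g: int(n) for g, n in contig_umi_counts.items() if n > 0}
    if not support:
        return CellGenotypeCall(cell_barcode, None, UNASSIGNED, source="matrix")
    winner = _majority(support, majority)
    if winner is None:
        return CellGenotypeCall(cell_barcode, None, DISCARDED_MULTI,
                                read_support=support, source="matrix")
    return CellGenotypeCall(cell_barcode, winner, None,
                            read_support=support, source="matrix")


def merge_sources(
    amplicon: CellGenotypeCall, matrix: CellGenotypeCall
) -> CellGenotypeCall:
    """Merge amplicon- and matrix-route calls for one cell.

    Same genotype in both -> that genotype (source "both"); different
    genotypes -> conflicted (omitted downstream); genotype from exactly one
    route -> that genotype.
    """
    if amplicon.cell_barcode != matrix.cell_barcode:
        raise ValueError("cell barcodes differ between routes")
    a, m = amplicon.assigned, matrix.assigned
    if a and m:
        if amplicon.genotype_id == matrix.genotype_id:
            merged = CellGenotypeCall(
                amplicon.cell_barcode, amplicon.genotype_id, None,
                clone_barcode=amplicon.clone_barcode,
                read_support=amplicon.read_support, source="both",
                clone_tie=amplicon.clone_tie,
            )
            return merged
        return CellGenotypeCall(amplicon.cell_barcode, None, CONFLICTED,
                                source="both")
    if a:
        return amplicon
    if m:
        return matrix
    status = (
        UNASSIGNED
        if UNASSIGNED in (amplicon.status, matrix.status)
        and amplicon.status == matrix.status
        else (amplicon.status or matrix.status)
    )
    return CellGenotypeCall(amplicon.cell_barcode, None, status, source="both")


def assign_cells(
    r1: list[FastqRecord],
    r2: list[FastqRecord],
    library: BarcodeLibrary,
    max_mm_anchor: int = 3,
    max_mm_bc: int = 2,
    majority: float = 0.70,
    dedup_umi: bool = True,
    contig_counts: dict[str, dict[str, int]] | None = None,
) -> pd.DataFrame:
    """End-to-end per-cell genotype assignment from paired FASTQ records.

    Reads are grouped by the 16-nt cell barcode of read 1 (UMI-deduplicated
    by default: one vote per (UMI, genotype, clone)), parsed, filtered by
    the anchor/position rules, genotype-called against the library, and
    aggregated with the 70% rule.  When ``contig_counts`` (per-cell UMI
    counts over bc-contigs) is given, matrix-route calls are merged in.
    Returns a tidy calls table, one row per cell.
    """
    if len(r1) != len(r2):
        raise ValueError("read 1 / read 2 record counts differ")
    per_cell: dict[str, list[tuple[str, str | None]]] = defaultdict(list)
    seen_umi: dict[str, set] = defaultdict(set)
    for rec1, rec2 in zip(r1, r2):
        cb, umi = rec1.seq[:16], rec1.seq[16:28]
        parsed = parse_read(rec2.seq, cb, umi, max_mm=max_mm_anchor)
        if not parsed.valid:
            continue
        gid = call_genotype(parsed.genotype_region, library, max_mm=max_mm_bc)
        if gid is None:
            continue
        key = (umi, gid, parsed.clone_seq)
        if dedup_umi:
            if key in seen_umi[cb]:
                continue
            seen_umi[cb].add(key)
        per_cell[cb].append((gid, parsed.clone_seq))

    cells = set(per_cell)
    if contig_counts:
        cells |= set(contig_counts)
    rows = []
    for cb in sorted(cells):
        amp = aggregate_cell(cb, per_cell.get(cb, []), majority)
        if contig_counts is not None:
            mat = matrix_call(cb, contig_counts.get(cb, {}), majority)
            call = merge_sources(amp, mat)
        else:
            call = amp
        rows.append(
            {
                "cell_barcode": cb,
                "genotype": call.genotype_id or "",
                "clone": call.clone_barcode or "",
                "status": call.status or "assigned",
                "source": call.source or "",
                "support": ";".join(
                    f"{g}:{n}" for g, n in sorted(call.read_support.items())
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["cell_barcode", "genotype", "clone", "status",
                       "source", "support"],
    )


def evaluate_assignment(
    calls: pd.DataFrame, truth: pd.DataFrame
) -> dict[str, float | None]:
    """Score calls against simulation truth.

    ``truth`` must map cell_barcode -> genotype (columns ``cell_barcode``,
    ``genotype``).  Precision is computed over assigned cells only; None
    when nothing was assigned.
    """
    tmap = dict(zip(truth["cell_barcode"], truth["genotype"]))
    missing = set(calls["cell_barcode"]) - set(tmap)
    if missing:
        raise ValueError(f"truth table missing called cells: {sorted(missing)[:5]}")
    n = len(calls)
    assigned = calls[calls["status"] == "assigned"]
    n_assigned = len(assigned)
    n_conflict = int((calls["status"] == CONFLICTED).sum())
    correct = sum(
        tmap[cb] == g for cb, g in zip(assigned["cell_barcode"], assigned["genotype"])
    )
    return {
        "assigned_fraction": n_assigned / n if n else 0.0,
        "precision": (correct / n_assigned) if n_assigned else None,
        "conflict_rate": n_conflict / n if n else 0.0,
    }
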