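"""RNA-barcoded deletion-cassette model.

The RNA-barcoded yeast knockout collection replaces the G418 marker of the
classical deletion cassette with *URA3* and shortens the heterologous
terminator to 43 nt, so that the 3'UTR of the *URA3* transcript carries, in
order, a 5-nt clone barcode, the 43-nt terminator/linker, the 20-nt genotype
(Downtag) barcode, and a 17-nt constant downstream flank.  Each genotype is
represented in the reference by an 85-nt artificial barcode contig with that
exact layout.

This module builds and parses such contigs and validates the genomic
position of a genotype from 3'UTR read-to-STOP-codon distances.
"""

from __future__ import annotations

import re
import statistics
from dataclasses import dataclass, field

__all__ = [
    "LINKER43",
    "FLANK17",
    "D2_ANCHOR",
    "D1_ANCHOR",
    "CLONE_LEN",
    "GENOTYPE_LEN",
    "CONTIG_LEN",
    "ARTIFICIAL_CONTIG_TEMPLATE",
    "CassetteStructure",
    "LocusValidation",
    "build_contig",
    "parse_contig_template",
    "validate_locus",
]

#: 43-nt shortened heterologous terminator linking the clone barcode to the
#: genotype (Downtag) barcode.
LINKER43 = "AACGCCGCCATCCAGTGTCGAAAACGAGCTCGAATTCATCGAT"

#: 17-nt constant flank downstream of the genotype barcode (the D1 region).
FLANK17 = "CTACGAGACCGACACCG"

#: Anchor used to locate the 5' side of the genotype barcode in amplicon
#: reads: the terminal 18 nt of the linker (the D2 region).
D2_ANCHOR = LINKER43[-18:]

#: Anchor on the 3' side of the genotype barcode: the constant flank itself.
D1_ANCHOR = FLANK17

CLONE_LEN = 5
GENOTYPE_LEN = 20
CONTIG_LEN = CLONE_LEN + len(LINKER43) + GENOTYPE_LEN + len(FLANK17)  # 85

#: Template of the per-genotype artificial barcode chromosome added to the
#: reference genome; N-runs mark the clone (5) and genotype (20) slots.
ARTIFICIAL_CONTIG_TEMPLATE = (
    "N" * CLONE_LEN + LINKER43 + "N" * GENOTYPE_LEN + FLANK17
)

_DNA = set("ACGT")


@dataclass
class CassetteStructure:
    """Segment lengths recovered from a barcode-contig template.

    ``upstream_runs`` reports any N-runs occurring before the clone/genotype
    pair verbatim (the full printed cassette carries an additional upstream
    Uptag N-run that is not interpreted further).
    """

    clone_len: int
    linker_seq: str
    linker_len: int
    genotype_len: int
    suffix_seq: str
    suffix_len: int
    upstream_runs: list[int] = field(default_factory=list)


@dataclass
class LocusValidation:
    """Genomic-position check for one genotype.

    A genotype passes when the median distance between its mapped 3'UTR
    reads and the annotated STOP codon of the deleted gene is at most the
    threshold (default 300 bp); larger medians mark the strain as
    incorrectly positioned.
    """

    genotype_id: str
    distances: list[float]
    median_distance: float
    threshold: float
    passed: bool


class UnvalidatableLocusError(ValueError):
    """Raised when no distances are available to validate a locus."""


def _check_barcode(seq: str, length: int, what: str) -> None:
    if len(seq) != length:
        raise ValueError(f"{what} must be {length} nt, got {len(seq)}")
    if not set(seq) <= _DNA:
        raise ValueError(f"{what} contains non-ACGT characters: {seq!r}")


def build_contig(genotype_barcode: str, clone_barcode: str) -> str:
    """Assemble the 85-nt artificial barcode contig for one clone.

    Layout: clone (5 nt) + linker (43 nt) + genotype (20 nt) + flank (17 nt).
    """
    _check_barcode(clone_barcode, CLONE_LEN, "clone barcode")
    _check_barcode(genotype_barcode, GENOTYPE_LEN, "genotype barcode")
    return clone_barcode + LINKER43 + genotype_barcode + FLANK17


def parse_contig_template(template_seq: str) -> CassetteStructure:
    """Parse a barcode-contig template, locating barcode slots by N-runs.

    Works both on the bare 85-nt artificial contig (exactly two N-runs) and
    on the full printed cassette, where the clone and genotype slots are the
    *last two* N-runs after the coding region; earlier runs (the Uptag slot)
    are reported verbatim in ``upstream_runs``.
    """
    seq = template_seq.strip()
    runs = [(m.start(), m.end()) for m in re.finditer(r"N+", seq.upper())]
    if len(runs) < 2:
        raise ValueError(
            f"template contains {len(runs)} N-run(s); at least 2 are needed "
            "to locate the clone and genotype barcode slots"
        )
    (c_start, c_end), (g_start, g_end) = runs[-2], runs[-1]
    return CassetteStructure(
        clone_len=c_end - c_start,
        linker_seq=seq[c_end:g_start],
        linker_len=g_start - c_end,
        genotype_len=g_end - g_start,
        suffix_seq=seq[g_end:],
        suffix_len=len(seq) - g_end,
        upstream_runs=[e - s for s, e in runs[:-2]],
    )


def validate_locus(
    genotype_id: str,
    distances: list[float],
    threshold: float = 300,
) -> LocusValidation:
    """Validate a genotype's genomic position from read-to-STOP distances.

    The median (midpoint convention for even n) of the distances is compared
    to the threshold; median > threshold fails the genotype.
    """
    if len(distances) == 0:
        raise UnvalidatableLocusError(
            f"genotype {genotype_id!r}: no distances provided, unvalidatable"
        )
    if any(d < 0 for d in distances):
        raise ValueError(f"genotype {genotype_id!r}: negative distances")
    med = float(statistics.median(distances))
    return LocusValidation(
        genotype_id=genotype_id,
        distances=list(distances),
        median_distance=med,
        threshold=float(threshold),
        passed=med <= threshold,
    )
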