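"""Germline V-segment reference with region boundaries.

Every mutation in the analysis is reported in the coordinate system of a
single germline V segment (the study design targets one canonical V gene
response, so no multi-gene germline database is needed).  The reference
carries the FR1/CDR1/FR2/CDR2/FR3 boundaries and the reading frame; the end
of FR3 defines the CDR3 start, beyond which read sequence is treated as
junction and excluded from V-region mutation statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3")

VALID_BASES = set("ACGT")


@dataclass(frozen=True)
class GermlineReference:
    """A germline V segment plus the region map used for mutation reporting.

    Parameters
    ----------
    name
        Gene identifier (e.g. a V-gene allele name).
    sequence
        Nucleotide sequence of the V segment, A/C/G/T only.
    region_bounds
        Map region name -> half-open 0-based ``(start, end)`` interval on the
        germline.  Regions must be contiguous, non-overlapping, and ordered
        FR1 < CDR1 < FR2 < CDR2 < FR3.
    frame_offset
        0-based offset of the first complete codon (0, 1 or 2).
    """

    name: str
    sequence: str
    region_bounds: dict[str, tuple[int, int]] = field(hash=False)
    frame_offset: int = 0

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(f"germline sequence contains non-ACGT characters: {sorted(bad)}")
        missing = [r for r in REGION_ORDER if r not in self.region_bounds]
        if missing:
            raise ValueError(f"region_bounds missing regions: {missing}")
        prev_end = None
        for region in REGION_ORDER:
            start, end = self.region_bounds[region]
            if not (0 <= start < end <= len(seq)):
                raise ValueError(
                    f"{region} bounds [{start}, {end}) out of range for germline of length {len(seq)}"
                )
            if prev_end is not None and start != prev_end:
                raise ValueError(
                    f"{region} starts at {start} but previous region ends at {prev_end}; "
                    "regions must be contiguous and ordered FR1<CDR1<FR2<CDR2<FR3"
                )
            prev_end = end
        if self.frame_offset not in (0, 1, 2):
            raise ValueError(f"frame_offset must be 0, 1 or 2, got {self.frame_offset}")
        if (self.cdr3_start - self.frame_offset) % 3 != 0:
            raise ValueError(
                f"cdr3_start ({self.cdr3_start}) minus frame_offset ({self.frame_offset}) "
                "is not a multiple of 3"
            )

    @property
    def cdr3_start(self) -> int:
        """0-based index where CDR3 begins: the end of FR3."""
        return self.region_bounds["FR3"][1]

    def region_of(self, position: int) -> str:
        """Region name for a 0-based germline position (must lie in FR1..FR3)."""
        for region in REGION_ORDER:
            start, end = self.region_bounds[region]
            if start <= position < end:
                return region
        raise ValueError(f"position {position} outside FR1..FR3 (0..{self.cdr3_start})")

    def context_5mer(self, position: int) -> str | None:
        """Germline-centred 5-mer around ``position``, or None at sequence edges."""
        if position < 2 or position + 3 > len(self.sequence):
            return None
        return self.sequence[position - 2 : position + 3]


def load_reference(fasta_path: str | Path, bounds_table_path: str | Path) -> GermlineReference:
    """Load a germline reference from a FASTA file plus a region-boundary TSV.

    The TSV needs columns ``region``, ``start``, ``end`` (0-based, half-open)
    and may carry a ``frame_offset`` column (taken from the first row).
    """
    fasta_path = Path(fasta_path)
    bounds_table_path = Path(bounds_table_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(
            f"expected exactly one germline record in {fasta_path}, found {len(records)}"
        )
    rec = records[0]
    table = pd.read_csv(bounds_table_path, sep="\t")
    required = {"region", "start", "end"}
    if not required.issubset(table.columns):
        raise ValueError(f"bounds table must have columns {sorted(required)}")
    bounds = {
        str(row.region): (int(row.start), int(row.end)) for row in table.itertuples()
    }
    frame_offset = int(table["frame_offset"].iloc[0]) if "frame_offset" in table.columns else 0
    return GermlineReference(
        name=rec.id, sequence=str(rec.seq), region_bounds=bounds, frame_offset=frame_offset
    )


def write_reference(ref: GermlineReference, fasta_path: str | Path, bounds_table_path: str | Path) -> None:
    """Write a reference bundle (FASTA + bounds TSV) readable by :func:`load_reference`."""
    Path(fasta_path).write_text(f">{ref.name}\n{ref.sequence}\n")
    rows = [
        {"region": r, "start": s, "end": e, "frame_offset": ref.frame_offset}
        for r, (s, e) in ((r, ref.region_bounds[r]) for r in REGION_ORDER)
    ]
    pd.DataFrame(rows).to_csv(bounds_table_path, sep="\t", index=False)


# Synthetic stand-in for a murine heavy-chain germline V segment (IMGT-style
# FR/CDR layout, stop-free in frame 0, AID-hotspot-enriched CDRs).  It is NOT
# the deposited sequence of any real V gene; it exists so that simulations and
# tests are self-contained.
SYNTHETIC_VH_NAME = "synthVH-1"
SYNTHETIC_VH_SEQUENCE = (
    "TGTCTTACTCAGTCAACTTCAAACGTTCGGGTGTCACTCTGTGTTCCTAATAAACAGGCAATGCTAAACTCATCGCTA"
    "TATTACCATTATTATTGGGCTTACTCCGAGCATAGTCCTATCCATGACGCTCTATTTGATCGCAACCGGTCAATCAAC"
    "TCAAGCAGTTATTATTGGTGGAACCATTGTGACATTCTACCGACCTCTTGCTCTTTATATGCTCAAGGTGCTTTTAGT"
    "TGCATCGGGCCAAGCTATAACCATGCCCCAGTCTTGGCTGCTTCAGATCGCTACGTGTTCTGG"
)
SYNTHETIC_VH_BOUNDS = {
    "FR1": (0, 78),
    "CDR1": (78, 102),
    "FR2": (102, 153),
    "CDR2": (153, 183),
    "FR3": (183, 297),
}


def synthetic_vh_reference() -> GermlineReference:
    """The package's built-in synthetic germline V reference (297 nt, frame 0)."""
    return GermlineReference(
        name=SYNTHETIC_VH_NAME,
        sequence=SYNTHETIC_VH_SEQUENCE,
        region_bounds=dict(SYNTHETIC_VH_BOUNDS),
        frame_offset=0,
    )
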