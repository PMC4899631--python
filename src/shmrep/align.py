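"""Germline alignment, homology and productivity filters.

A self-contained single-reference stand-in for germline-database assignment:
reads are aligned semi-globally to the one germline V segment (free end gaps,
so a 3' junction overhang and 5' truncation cost nothing), identity is
computed over the aligned V portion only, and reads are filtered by the
study's rules — strict >90% V identity, full-length coverage of the V
segment, and a productive (stop-free, N-free) in-frame translation.  Reads
whose best alignment places an indel inside the V region are flagged and
excluded from mutation statistics, which are substitution-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from shmrep.reference import GermlineReference

HOMOLOGY_THRESHOLD = 0.90
MIN_V_COVERAGE = 0.50  # below this fraction of the V segment a read is "partial"


@dataclass(frozen=True)
class ReadRecord:
    """One sequenced read plus its sample metadata."""

    id: str
    sequence: str
    isotype: str = "IgM"
    tissue: str = "spleen"
    treatment: str = "control"
    animal: str = "m1"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"read {self.id}: non-ACGTN characters {sorted(bad)}")


@dataclass
class GermlineAlignment:
    """Result of aligning one read to the germline V segment.

    ``v_sequence`` is the read projected onto germline coordinates (one
    character per germline position, 'N' where the read does not cover);
    ``identity_fraction`` counts matches over aligned germline positions with
    gaps counted as mismatches; ``junction`` is the read suffix pairing
    beyond the CDR3 start.  ``flags`` collects exclusion reasons ("partial",
    "indel").
    """

    read: ReadRecord
    v_sequence: str
    identity_fraction: float
    covered_interval: tuple[int, int]
    junction: str
    productive: bool
    productive_reason: str = ""
    flags: list[str] = field(default_factory=list)

    @property
    def analyzable(self) -> bool:
        """Usable for substitution statistics: full V coverage, no indel."""
        return not self.flags


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    matrix = substitution_matrices.Array(alphabet="ACGTN", dims=2)
    for a in "ACGT":
        for b in "ACGT":
            matrix[a, b] = 2.0 if a == b else -2.0
    for b in "ACGTN":
        matrix["N", b] = 0.0
        matrix[b, "N"] = 0.0
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -2.0
    # semi-global: overhangs on either sequence end are free
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    aligner.mode = "global"
    return aligner


_ALIGNER = _make_aligner()


def align_to_germline(read: ReadRecord, ref: GermlineReference) -> GermlineAlignment:
    """Semi-global alignment of a read against the germline V segment."""
    if not read.sequence:
        raise ValueError(f"read {read.id} is empty")
    alignment = _ALIGNER.align(ref.sequence, read.sequence)[0]
    target_blocks, query_blocks = alignment.aligned

    germ_len = len(ref.sequence)
    projected = ["N"] * germ_len
    matches = 0
    aligned_positions = 0
    covered_lo, covered_hi = germ_len, 0
    junction_start_in_read: int | None = None
    indel = False

    prev_t_end: int | None = None
    prev_q_end: int | None = None
    for (t0, t1), (q0, q1) in zip(target_blocks, query_blocks):
        if prev_t_end is not None:
            t_gap = t0 - prev_t_end
            q_gap = q0 - prev_q_end
            # an internal gap on either side inside the V region is an indel
            if t_gap or q_gap:
                indel = True
                aligned_positions += t_gap  # germline positions opposite a deletion
        for t, q in zip(range(t0, t1), range(q0, q1)):
            base = read.sequence[q]
            projected[t] = base
            if base != "N":
                aligned_positions += 1
                if base == ref.sequence[t]:
                    matches += 1
            covered_lo = min(covered_lo, t)
            covered_hi = max(covered_hi, t + 1)
            if t == germ_len - 1:
                junction_start_in_read = q + 1
        prev_t_end, prev_q_end = t1, q1

    identity = matches / aligned_positions if aligned_positions else 0.0
    covered = (covered_lo, covered_hi) if covered_hi > covered_lo else (0, 0)
    junction = (
        read.sequence[junction_start_in_read:] if junction_start_in_read is not None else ""
    )

    flags: list[str] = []
    coverage = (covered[1] - covered[0]) / germ_len
    full_length = covered[0] == 0 and covered[1] >= ref.cdr3_start
    if coverage < MIN_V_COVERAGE or not full_length:
        flags.append("partial")
    if indel:
        flags.append("indel")

    productive, reason = _productivity("".join(projected), ref, full_length, indel)
    return GermlineAlignment(
        read=read,
        v_sequence="".join(projected),
        identity_fraction=identity,
        covered_interval=covered,
        junction=junction,
        productive=productive,
        productive_reason=reason,
        flags=flags,
    )


def _productivity(
    v_sequence: str, ref: GermlineReference, full_length: bool, indel: bool
) -> tuple[bool, str]:
    if not full_length:
        return False, "partial"
    coding = v_sequence[ref.frame_offset : ref.cdr3_start]
    if "N" in coding:
        return False, "ambiguous base in V"
    if indel:
        return False, "indel"
    protein = str(Seq(coding).translate())
    if "*" in protein:
        return False, "stop codon"
    return True, ""


def passes_homology_filter(
    alignment: GermlineAlignment, threshold: float = HOMOLOGY_THRESHOLD
) -> bool:
    """Strictly greater-than identity threshold (default >90% with germline)."""
    return alignment.identity_fraction > threshold


def is_productive(alignment: GermlineAlignment, ref: GermlineReference) -> bool:
    """Full-length over V, in-frame stop-free translation, no ambiguous base."""
    return alignment.productive


def extract_junction(alignment: GermlineAlignment, j_anchor: str | None = None) -> str:
    """Read subsequence pairing beyond the CDR3 start.

    On synthetic reads pass the known J-anchor to strip it; otherwise the
    junction runs to the read end.
    """
    junction = alignment.junction
    if not junction:
        raise ValueError(f"read {alignment.read.id}: no CDR3 (truncated before junction)")
    if j_anchor and junction.endswith(j_anchor):
        junction = junction[: -len(j_anchor)]
        if not junction:
            raise ValueError(f"read {alignment.read.id}: no CDR3 (junction is anchor only)")
    return junction


def read_fasta_with_metadata(
    fasta_path: str | Path, metadata_path: str | Path | None = None
) -> list[ReadRecord]:
    """Load reads from FASTA, joining per-read metadata from a sidecar TSV.

    The TSV needs a ``read_id`` column plus any of isotype / tissue /
    treatment / animal; reads absent from the table keep defaults.
    """
    meta: dict[str, dict] = {}
    if metadata_path is not None:
        table = pd.read_csv(metadata_path, sep="\t").set_index("read_id")
        meta = table.to_dict("index")
    reads = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        extra = meta.get(rec.id, {})
        reads.append(
            ReadRecord(
                id=rec.id,
                sequence=str(rec.seq),
                **{
                    k: str(extra[k])
                    for k in ("isotype", "tissue", "treatment", "animal")
                    if k in extra
                },
            )
        )
    return reads


def rearrangement_table(
    alignments: list[GermlineAlignment], threshold: float = HOMOLOGY_THRESHOLD
) -> pd.DataFrame:
    """AIRR-style rearrangement summary, one row per read."""
    rows = []
    for aln in alignments:
        rows.append(
            {
                "read_id": aln.read.id,
                "v_identity": aln.identity_fraction,
                "productive": aln.productive,
                "junction": aln.junction,
                "passes_homology": passes_homology_filter(aln, threshold),
                "filter_flags": ";".join(aln.flags),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "v_identity",
            "productive",
            "junction",
            "passes_homology",
            "filter_flags",
        ],
    )
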