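"""Clonal grouping by CDR3 junction and majority-vote consensus.

Clones are defined operationally: filtered reads sharing an identical CDR3
junction nucleotide string belong to one clone (no similarity threshold).
For mutation statistics each clone contributes a single consensus V sequence
built by strict majority vote at each mutated position, so a mutational
event shared by clonal siblings is counted once.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from shmrep.align import GermlineAlignment
from shmrep.reference import GermlineReference


@dataclass
class Clone:
    """A set of reads sharing one CDR3 junction."""

    clone_id: str
    junction: str
    member_ids: list[str]
    member_v_sequences: list[str]

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class CloneSet:
    """Disjoint partition of the filtered reads into clones."""

    clones: list[Clone]

    @property
    def total_sequences(self) -> int:
        return sum(c.size for c in self.clones)

    def __len__(self) -> int:
        return len(self.clones)

    def __iter__(self):
        return iter(self.clones)


@dataclass
class ConsensusSequence:
    """Majority-vote consensus V sequence for one clone.

    ``votes`` records, for every position where any member differs from
    germline, the tally of non-germline bases that was voted over.
    """

    clone_id: str
    sequence: str
    votes: dict[int, dict[str, int]] = field(default_factory=dict)


def group_clones(
    alignments: list[GermlineAlignment], junctions: list[str] | None = None
) -> CloneSet:
    """Partition aligned reads into clones keyed by exact junction string.

    ``junctions`` may supply pre-extracted junctions (e.g. with a J-anchor
    stripped); by default each alignment's raw junction is used.  Clones are
    ordered by size descending, ties broken by junction lexicographically.
    """
    if junctions is None:
        junctions = [aln.junction for aln in alignments]
    if len(junctions) != len(alignments):
        raise ValueError("junctions list must parallel alignments")
    groups: dict[str, list[GermlineAlignment]] = {}
    for aln, junction in zip(alignments, junctions):
        groups.setdefault(junction, []).append(aln)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    clones = [
        Clone(
            clone_id=f"C{i:04d}",
            junction=junction,
            member_ids=[a.read.id for a in members],
            member_v_sequences=[a.v_sequence for a in members],
        )
        for i, (junction, members) in enumerate(ordered)
    ]
    return CloneSet(clones=clones)


def clone_composition(clone_set: CloneSet, top_k: int = 3) -> dict:
    """Clonal composition summary (pie-chart data).

    Returns per-clone fractions of total sequences, the combined share of the
    ``top_k`` largest clones (all clones if fewer), and the unique clone
    count.  Fractions sum to 1.
    """
    if len(clone_set) == 0:
        raise ValueError("empty CloneSet has no composition")
    total = clone_set.total_sequences
    sizes = sorted((c.size for c in clone_set), reverse=True)
    fractions = [s / total for s in sizes]
    k = min(top_k, len(sizes))
    return {
        "n_sequences": total,
        "n_clones": len(clone_set),
        "fractions": fractions,
        "top_k": top_k,
        "top_k_share": sum(fractions[:k]),
    }


def clone_consensus(clone: Clone, ref: GermlineReference) -> ConsensusSequence:
    """Strict-majority consensus of a clone's aligned V sequences.

    At each germline position, if strictly more than half of the voting
    members (members with a non-N base there) carry the same non-germline
    base, the consensus takes that base; ties and sub-majority pluralities
    revert to germline.  A singleton clone's consensus is its member.
    """
    germ = ref.sequence
    for seq in clone.member_v_sequences:
        if len(seq) != len(germ):
            raise ValueError(
                f"clone {clone.clone_id}: member V sequence length {len(seq)} "
                f"!= germline length {len(germ)}"
            )
    consensus = list(germ)
    votes: dict[int, dict[str, int]] = {}
    for pos in range(len(germ)):
        column = [seq[pos] for seq in clone.member_v_sequences]
        voters = [b for b in column if b != "N"]
        if not voters or all(b == germ[pos] for b in voters):
            continue
        tally = Counter(voters)
        votes[pos + 1] = dict(tally)
        base, count = max(tally.items(), key=lambda kv: (kv[1], kv[0]))
        # strict majority of voting members, and the winner must differ
        # from germline; everything else reverts to germline
        winners = [b for b, c in tally.items() if c == count]
        if len(winners) == 1 and base != germ[pos] and count * 2 > len(voters):
            consensus[pos] = base
    return ConsensusSequence(clone_id=clone.clone_id, sequence="".join(consensus), votes=votes)


def write_clone_tables(
    clone_set: CloneSet, out_dir: str | Path, prefix: str = "clones"
) -> dict[str, Path]:
    """Write the clones TSV and composition JSON."""
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    total = clone_set.total_sequences
    table = pd.DataFrame(
        [
            {
                "clone_id": c.clone_id,
                "junction": c.junction,
                "size": c.size,
                "fraction": c.size / total if total else float("nan"),
            }
            for c in clone_set
        ]
    )
    clones_path = out_dir / f"{prefix}.tsv"
    table.to_csv(clones_path, sep="\t", index=False)
    comp_path = out_dir / f"{prefix}.composition.json"
    comp_path.write_text(json.dumps(clone_composition(clone_set), indent=2) + "\n")
    return {"clones": clones_path, "composition": comp_path}
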