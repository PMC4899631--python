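#!/usr/bin/env python
"""Align simulated reads to the germline V segment and apply the filters.

Reads each population written by 01_simulate_repertoires.py, aligns every
read, applies the full-length / productive / >90%-homology filters, and
writes the AIRR-style rearrangement table and filter funnel per population
under results/alignment/.
"""

import argparse
import json
from pathlib import Path

from shmrep.align import (
    ReadRecord,
    align_to_germline,
    is_productive,
    passes_homology_filter,
    rearrangement_table,
)
from shmrep.reference import synthetic_vh_reference
from shmrep.scenarios import LOAD_SCENARIOS
from Bio import SeqIO


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--reads-dir", type=Path, default=Path("results/simulated"))
    parser.add_argument("--out", type=Path, default=Path("results/alignment"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    ref = synthetic_vh_reference()
    for name in LOAD_SCENARIOS:
        fasta = args.reads_dir / f"{name}.fasta"
        reads = [ReadRecord(r.id, str(r.seq)) for r in SeqIO.parse(str(fasta), "fasta")]
        alignments = [align_to_germline(r, ref) for r in reads]
        table = rearrangement_table(alignments)
        table.to_csv(args.out / f"{name}.rearrangements.tsv", sep="\t", index=False)
        funnel = {
            "input": len(alignments),
            "full_length": sum("partial" not in a.flags for a in alignments),
            "productive": sum(is_productive(a, ref) for a in alignments),
            "homology_passing": sum(
                is_productive(a, ref) and passes_homology_filter(a) for a in alignments
            ),
        }
        (args.out / f"{name}.funnel.json").write_text(json.dumps(funnel, indent=2) + "\n")
        print(f"{name}: funnel {funnel}")


if __name__ == "__main__":
    main()
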