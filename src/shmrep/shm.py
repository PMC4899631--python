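"""Mutation calling and classification against the germline V segment.

Substitutions are called on aligned, indel-free V sequences at every position
up to the CDR3 start, then classified three ways:

* transition vs transversion (A<->G, C<->T are transitions);
* AID 5-mer context class of the *germline* sequence around the position —
  hotspot (WRC/GYW targeting the underlined C/G, WA/TW targeting A/T),
  coldspot (SYC/GRS), or neutral, with degenerate codes W={A,T}, R={A,G},
  Y={C,T}, S={C,G};
* replacement vs silent, by translating the germline codon with and without
  the substitution.

Per-5-mer mutabilities are estimated from clone consensuses (one consensus
per clone avoids double-counting a mutational event shared by clonal
siblings), as mutation counts adjusted for the background frequency of each
5-mer context and normalized to a background-weighted mean of 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from shmrep.reference import GermlineReference

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
W = frozenset("AT")  # weak
S = frozenset("CG")  # strong
R = frozenset("AG")  # purine
Y = frozenset("CT")  # pyrimidine

HOTSPOT_WRC_GYW = "hotspot_WRC_GYW"
HOTSPOT_WA_TW = "hotspot_WA_TW"
COLDSPOT_SYC_GRS = "coldspot_SYC_GRS"
NEUTRAL = "neutral"
UNSCORED = "unscored"

HOTSPOT_CLASSES = frozenset({HOTSPOT_WRC_GYW, HOTSPOT_WA_TW})


@dataclass(frozen=True)
class Mutation:
    """One germline-vs-observed substitution, fully classified.

    ``position`` is 1-based on the germline V segment.  ``context`` is the
    germline-centred 5-mer (None at sequence edges, where ``context_class``
    is "unscored").
    """

    position: int
    from_base: str
    to_base: str
    region: str
    substitution_class: str  # "transition" | "transversion"
    context: str | None
    context_class: str
    coding_class: str  # "replacement" | "silent"


def classify_substitution(from_base: str, to_base: str) -> str:
    """Transition (purine<->purine or pyrimidine<->pyrimidine) or transversion."""
    if from_base == to_base:
        raise ValueError(f"not a substitution: {from_base}->{to_base}")
    for base in (from_base, to_base):
        if base not in "ACGT":
            raise ValueError(f"invalid base {base!r}")
    both_purine = from_base in PURINES and to_base in PURINES
    both_pyrimidine = from_base in PYRIMIDINES and to_base in PYRIMIDINES
    return "transition" if (both_purine or both_pyrimidine) else "transversion"


def classify_context(fivemer: str) -> str:
    """AID targeting class of a 5-mer whose centre is the mutated base.

    Centre C: hotspot if preceded by W,R (WRC); coldspot if S,Y (SYC).
    Centre G: hotspot if followed by Y,W (GYW); coldspot if R,S (GRS).
    Centre A: hotspot if preceded by W (WA).  Centre T: hotspot if followed
    by W (TW).  Everything else is neutral.  Hot and cold motifs are disjoint
    because R and Y (and W and S) do not overlap.
    """
    if len(fivemer) != 5:
        raise ValueError(f"context must be a 5-mer, got {fivemer!r}")
    fivemer = fivemer.upper()
    if set(fivemer) - set("ACGT"):
        raise ValueError(f"context contains non-ACGT characters: {fivemer!r}")
    m2, m1, centre, p1, p2 = fivemer
    if centre == "C":
        if m2 in W and m1 in R:
            return HOTSPOT_WRC_GYW
        if m2 in S and m1 in Y:
            return COLDSPOT_SYC_GRS
        return NEUTRAL
    if centre == "G":
        if p1 in Y and p2 in W:
            return HOTSPOT_WRC_GYW
        if p1 in R and p2 in S:
            return COLDSPOT_SYC_GRS
        return NEUTRAL
    if centre == "A":
        return HOTSPOT_WA_TW if m1 in W else NEUTRAL
    # centre == "T"
    return HOTSPOT_WA_TW if p1 in W else NEUTRAL


def classify_rs(position: int, to_base: str, ref: GermlineReference) -> str:
    """Replacement or silent, for a substitution at a 0-based germline position.

    The codon containing the position is taken at germline state except for
    the substituted base; a changed amino acid (or a created stop) is a
    replacement.
    """
    if not (ref.frame_offset <= position < ref.cdr3_start):
        raise ValueError(
            f"position {position} outside coding range "
            f"[{ref.frame_offset}, {ref.cdr3_start})"
        )
    codon_index = (position - ref.frame_offset) // 3
    codon_start = ref.frame_offset + 3 * codon_index
    germ_codon = ref.sequence[codon_start : codon_start + 3]
    offset = position - codon_start
    mut_codon = germ_codon[:offset] + to_base + germ_codon[offset + 1 :]
    germ_aa = str(Seq(germ_codon).translate())
    mut_aa = str(Seq(mut_codon).translate())
    return "silent" if germ_aa == mut_aa else "replacement"


def call_mutations(sequence: str, ref: GermlineReference) -> list[Mutation]:
    """Call substitutions on an aligned V sequence, positions < CDR3 start only.

    ``sequence`` must be a gapless V-region sequence aligned position-for-
    position to the germline (at least ``cdr3_start`` long; any junction
    suffix beyond it is ignored).  Ns are not called as mutations.
    """
    sequence = sequence.upper()
    if len(sequence) < ref.cdr3_start:
        raise ValueError(
            f"aligned sequence length {len(sequence)} shorter than V region "
            f"({ref.cdr3_start}); mutation calling needs full V coverage"
        )
    mutations: list[Mutation] = []
    for pos in range(ref.cdr3_start):
        obs = sequence[pos]
        germ = ref.sequence[pos]
        if obs == germ or obs == "N":
            continue
        context = ref.context_5mer(pos)
        mutations.append(
            Mutation(
                position=pos + 1,
                from_base=germ,
                to_base=obs,
                region=ref.region_of(pos),
                substitution_class=classify_substitution(germ, obs),
                context=context,
                context_class=classify_context(context) if context else UNSCORED,
                coding_class=classify_rs(pos, obs, ref),
            )
        )
    return mutations


@dataclass
class MutabilityTable:
    """Background-adjusted per-5-mer mutability estimates ("hedgehog" data).

    ``table`` has one row per 5-mer observed as a germline context, with
    mutation count, background count, raw rate (count/background) and the
    rate normalized so that the background-weighted mean is 1.
    """

    table: pd.DataFrame

    def mutability(self, fivemer: str) -> float:
        row = self.table.loc[self.table["fivemer"] == fivemer]
        if row.empty:
            raise KeyError(f"5-mer {fivemer!r} not observed as a germline context")
        return float(row["normalized"].iloc[0])


def estimate_mutability(
    consensuses: Sequence, ref: GermlineReference
) -> MutabilityTable:
    """Estimate per-5-mer mutabilities from clone consensus sequences.

    For each 5-mer ``m``: the mutation count is the number of consensus
    mutations whose germline-centred context is ``m``; the background is the
    number of times ``m`` occurs as a germline context at scored positions
    (full 5-mer available, position < CDR3 start), summed over consensuses.
    Raw rate = count / background; normalized rates divide by the pooled rate
    (total mutations / total background) so their background-weighted mean
    is exactly 1.
    """
    from shmrep.clones import ConsensusSequence  # local import avoids a cycle

    scored_positions = [p for p in range(ref.cdr3_start) if ref.context_5mer(p) is not None]
    germline_context_counts: dict[str, int] = {}
    for p in scored_positions:
        m = ref.context_5mer(p)
        germline_context_counts[m] = germline_context_counts.get(m, 0) + 1

    mutation_counts: dict[str, int] = {m: 0 for m in germline_context_counts}
    n_consensus = 0
    for cons in consensuses:
        seq = cons.sequence if isinstance(cons, ConsensusSequence) else str(cons)
        n_consensus += 1
        for mut in call_mutations(seq, ref):
            if mut.context is None:
                continue
            mutation_counts[mut.context] += 1

    rows = []
    total_mut = sum(mutation_counts.values())
    total_bg = sum(c * n_consensus for c in germline_context_counts.values())
    pooled_rate = total_mut / total_bg if total_bg else float("nan")
    for m in sorted(germline_context_counts):
        background = germline_context_counts[m] * n_consensus
        count = mutation_counts[m]
        raw = count / background if background else float("nan")
        rows.append(
            {
                "fivemer": m,
                "context_class": classify_context(m),
                "mutation_count": count,
                "background_count": background,
                "raw_rate": raw,
                "normalized": raw / pooled_rate if pooled_rate else float("nan"),
            }
        )
    return MutabilityTable(table=pd.DataFrame(rows))


def summarize_hotspot_fractions(mutations: Iterable[Mutation]) -> dict[str, float]:
    """Fractions of scored mutations in hotspot / neutral / coldspot contexts.

    Unscored mutations (sequence-edge contexts) are excluded from the
    denominator.  The three fractions sum to 1.
    """
    counts = {"hotspot": 0, "neutral": 0, "coldspot": 0}
    for mut in mutations:
        if mut.context_class == UNSCORED:
            continue
        if mut.context_class in HOTSPOT_CLASSES:
            counts["hotspot"] += 1
        elif mut.context_class == COLDSPOT_SYC_GRS:
            counts["coldspot"] += 1
        else:
            counts["neutral"] += 1
    total = sum(counts.values())
    if total == 0:
        warnings.warn("no scored mutations; hotspot fractions undefined")
        return {k: float("nan") for k in counts}
    return {k: v / total for k, v in counts.items()}


def summarize_rs_by_region(
    mutations: Iterable[Mutation],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replacement/silent counts and R/S ratio per region, plus positional table.

    Returns ``(region_summary, positional)``.  ``region_summary`` has one row
    per region (R count, S count, ratio; NaN when S = 0 with the
    ``rs_undefined`` flag set).  ``positional`` is the per-position mutation
    frequency table behind region mutation-map plots.
    """
    from shmrep.reference import REGION_ORDER

    mutations = list(mutations)
    region_rows = []
    for region in REGION_ORDER:
        in_region = [m for m in mutations if m.region == region]
        r = sum(1 for m in in_region if m.coding_class == "replacement")
        s = sum(1 for m in in_region if m.coding_class == "silent")
        region_rows.append(
            {
                "region": region,
                "replacement": r,
                "silent": s,
                "rs_ratio": (r / s) if s > 0 else float("nan"),
                "rs_undefined": s == 0,
            }
        )
    positional = (
        pd.DataFrame(
            [
                {
                    "position": m.position,
                    "region": m.region,
                    "coding_class": m.coding_class,
                }
                for m in mutations
            ]
        )
        .groupby(["position", "region", "coding_class"])
        .size()
        .rename("count")
        .reset_index()
        if mutations
        else pd.DataFrame(columns=["position", "region", "coding_class", "count"])
    )
    return pd.DataFrame(region_rows), positional


def mutation_load_summary(
    loads: Mapping[str, int],
    metadata: pd.DataFrame,
    grouping: Sequence[str] = (),
) -> pd.DataFrame:
    """Per-group mutation-load statistics (mean, median, fraction unmutated).

    ``loads`` maps read id -> number of called V-region mutations for that
    read (loads are a per-sequence statistic, unlike the consensus-based
    mutability counts).  ``metadata`` is indexed by or contains ``read_id``
    plus the grouping columns (e.g. isotype, tissue, treatment); pooling
    across a column is achieved by leaving it out of ``grouping``.
    """
    meta = metadata.copy()
    if "read_id" in meta.columns:
        meta = meta.set_index("read_id")
    df = pd.DataFrame({"load": pd.Series(loads, dtype=float)})
    df = df.join(meta, how="left")

    def _summary(group: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "n_sequences": len(group),
                "mean_load": group["load"].mean(),
                "median_load": group["load"].median(),
                "fraction_unmutated": (group["load"] == 0).mean(),
            }
        )

    if not grouping:
        return _summary(df).to_frame().T
    missing = [g for g in grouping if g not in df.columns]
    if missing:
        raise KeyError(f"grouping columns not in metadata: {missing}")
    out = df.groupby(list(grouping)).apply(_summary, include_groups=False).reset_index()
    out["n_sequences"] = out["n_sequences"].astype(int)
    return out
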