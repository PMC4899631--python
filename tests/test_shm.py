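import itertools
import re

import numpy as np
import pytest
from Bio.Seq import Seq

from shmrep.clones import ConsensusSequence
from shmrep.shm import (
    COLDSPOT_SYC_GRS,
    HOTSPOT_CLASSES,
    HOTSPOT_WA_TW,
    HOTSPOT_WRC_GYW,
    NEUTRAL,
    call_mutations,
    classify_context,
    classify_rs,
    classify_substitution,
    estimate_mutability,
    mutation_load_summary,
    summarize_hotspot_fractions,
    summarize_rs_by_region,
)

BASES = "ACGT"
ALL_5MERS = ["".join(p) for p in itertools.product(BASES, repeat=5)]

# independent regex oracle for the degenerate motif codes
RE_WRC = re.compile(r"[AT][AG]C..$")
RE_SYC = re.compile(r"[CG][CT]C..$")
RE_GYW = re.compile(r"^..G[CT][AT]")
RE_GRS = re.compile(r"^..G[AG][CG]")
RE_WA = re.compile(r".[AT]A..$")
RE_TW = re.compile(r"^..T[AT].")


def regex_context_class(fivemer: str) -> str:
    centre = fivemer[2]
    if centre == "C":
        if RE_WRC.match(fivemer):
            return HOTSPOT_WRC_GYW
        if RE_SYC.match(fivemer):
            return COLDSPOT_SYC_GRS
        return NEUTRAL
    if centre == "G":
        if RE_GYW.search(fivemer):
            return HOTSPOT_WRC_GYW
        if RE_GRS.search(fivemer):
            return COLDSPOT_SYC_GRS
        return NEUTRAL
    if centre == "A":
        return HOTSPOT_WA_TW if RE_WA.match(fivemer) else NEUTRAL
    return HOTSPOT_WA_TW if RE_TW.search(fivemer) else NEUTRAL


class TestContextClassification:
    def test_exhaustive_motif_oracle(self):
        """All 1,024 5-mers agree with an independent regex enumeration."""
        for fivemer in ALL_5MERS:
            assert classify_context(fivemer) == regex_context_class(fivemer), fivemer

    def test_hot_and_cold_disjoint(self):
        classes = {m: classify_context(m) for m in ALL_5MERS}
        hot = {m for m, c in classes.items() if c in HOTSPOT_CLASSES}
        cold = {m for m, c in classes.items() if c == COLDSPOT_SYC_GRS}
        assert hot and cold
        assert not hot & cold

    @pytest.mark.parametrize(
        "fivemer, expected",
        [
            ("TACGT", HOTSPOT_WRC_GYW),  # centre C preceded by T,A = W,R
            ("AGTCA", NEUTRAL),          # centre T followed by C, not weak
            ("AGTAC", HOTSPOT_WA_TW),    # centre T followed by A = W
            ("GTCAA", COLDSPOT_SYC_GRS), # centre C preceded by G,T = S,Y
        ],
    )
    def test_known_motifs(self, fivemer, expected):
        assert classify_context(fivemer) == expected

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            classify_context("ACGT")
        with pytest.raises(ValueError):
            classify_context("ACNGT")


class TestSubstitutionClassification:
    @pytest.mark.parametrize("a, b", [("C", "T"), ("T", "C"), ("G", "A"), ("A", "G")])
    def test_transitions(self, a, b):
        assert classify_substitution(a, b) == "transition"

    def test_all_other_changes_are_transversions(self):
        for a, b in itertools.permutations(BASES, 2):
            expected = "transition" if {a, b} in ({"A", "G"}, {"C", "T"}) else "transversion"
            assert classify_substitution(a, b) == expected

    def test_identical_bases_rejected(self):
        with pytest.raises(ValueError):
            classify_substitution("A", "A")


class TestReplacementSilent:
    def test_codon_oracle_576_cases(self):
        """R/S classification matches translate-and-compare over all 64 codons
        x 9 single substitutions = 576 cases (substitutions creating a stop
        count as replacement, since Asp != * under translate-and-compare)."""
        from shmrep.reference import GermlineReference

        n_cases = 0
        for codon in ("".join(c) for c in itertools.product(BASES, repeat=3)):
            seq = "ATG" + codon + "GCA" * 18
            ref = GermlineReference(
                "codon-test",
                seq,
                {
                    "FR1": (0, 9),
                    "CDR1": (9, 15),
                    "FR2": (15, 27),
                    "CDR2": (27, 33),
                    "FR3": (33, 60),
                },
                0,
            )
            for offset in range(3):
                pos = 3 + offset
                for to_base in BASES:
                    if to_base == codon[offset]:
                        continue
                    mutated = codon[:offset] + to_base + codon[offset + 1 :]
                    expected = (
                        "silent"
                        if str(Seq(codon).translate()) == str(Seq(mutated).translate())
                        else "replacement"
                    )
                    assert classify_rs(pos, to_base, ref) == expected, (codon, pos, to_base)
                    n_cases += 1
        assert n_cases == 576

    def test_third_position_wobble_silent(self):
        # GAT -> GAC is Asp -> Asp
        from shmrep.reference import GermlineReference

        seq = "GAT" + "GCA" * 19
        ref = GermlineReference(
            "wobble",
            seq,
            {"FR1": (0, 9), "CDR1": (9, 15), "FR2": (15, 27), "CDR2": (27, 33), "FR3": (33, 60)},
            0,
        )
        assert classify_rs(2, "C", ref) == "silent"
        assert classify_rs(1, "C", ref) == "replacement"  # GAT -> GCT, Asp -> Ala

    def test_position_outside_coding_range_rejected(self, ref):
        with pytest.raises(ValueError):
            classify_rs(ref.cdr3_start, "A", ref)


class TestCallMutations:
    def test_germline_sequence_has_no_mutations(self, ref):
        assert call_mutations(ref.sequence, ref) == []

    def test_positions_match_string_diff(self, ref):
        rng = np.random.default_rng(3)
        seq = list(ref.sequence)
        positions = rng.choice(ref.cdr3_start, size=12, replace=False)
        for p in positions:
            seq[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p]]
        called = call_mutations("".join(seq), ref)
        diff = [i + 1 for i in range(ref.cdr3_start) if seq[i] != ref.sequence[i]]
        assert [m.position for m in called] == diff
        for m in called:
            assert m.from_base == ref.sequence[m.position - 1]
            assert m.to_base == seq[m.position - 1]

    def test_junction_mutations_not_reported(self, ref):
        seq = ref.sequence + "AAAATTTT"
        mutated = seq[: ref.cdr3_start] + "CCCCGGGG"
        assert call_mutations(mutated, ref) == []

    def test_transitions_plus_transversions_equal_total(self, ref):
        rng = np.random.default_rng(4)
        seq = list(ref.sequence)
        for p in rng.choice(ref.cdr3_start, size=20, replace=False):
            choices = [b for b in BASES if b != seq[p]]
            seq[p] = choices[int(rng.integers(3))]
        muts = call_mutations("".join(seq), ref)
        n_ti = sum(1 for m in muts if m.substitution_class == "transition")
        n_tv = sum(1 for m in muts if m.substitution_class == "transversion")
        assert n_ti + n_tv == len(muts) == 20


class TestMutability:
    def test_single_mutation_counting(self, ref):
        """One consensus mutation in a context occurring k times in the
        germline gives raw rate 1/k; all other 5-mers rate 0."""
        pos = 50
        context = ref.context_5mer(pos)
        k = sum(1 for p in range(ref.cdr3_start) if ref.context_5mer(p) == context)
        seq = list(ref.sequence)
        seq[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
        table = estimate_mutability(
            [ConsensusSequence(clone_id="c", sequence="".join(seq))], ref
        ).table
        row = table.loc[table["fivemer"] == context].iloc[0]
        assert row["mutation_count"] == 1
        assert row["background_count"] == k
        assert row["raw_rate"] == pytest.approx(1 / k)
        others = table.loc[table["fivemer"] != context]
        assert (others["mutation_count"] == 0).all()

    def test_counts_cross_foot_and_weighted_mean_one(self, ref, hot_model):
        from shmrep.simulate import apply_shm

        consensuses = []
        rng = np.random.default_rng(5)
        for i in range(40):
            mutated, _ = apply_shm(ref.sequence, hot_model, 8, rng)
            consensuses.append(ConsensusSequence(clone_id=f"c{i}", sequence=mutated))
        table = estimate_mutability(consensuses, ref).table
        n_scored = sum(
            1
            for cons in consensuses
            for m in call_mutations(cons.sequence, ref)
            if m.context is not None
        )
        assert table["mutation_count"].sum() == n_scored
        weighted_mean = (
            table["normalized"] * table["background_count"]
        ).sum() / table["background_count"].sum()
        assert weighted_mean == pytest.approx(1.0, abs=1e-9)


class TestSummaries:
    def test_hotspot_fractions_sum_to_one(self, ref):
        rng = np.random.default_rng(6)
        seq = list(ref.sequence)
        for p in rng.choice(ref.cdr3_start, size=25, replace=False):
            seq[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p]]
        fractions = summarize_hotspot_fractions(call_mutations("".join(seq), ref))
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_rs_ratio_arithmetic(self, ref):
        # hand-build 6 R and 2 S mutations in CDR1 via Mutation records
        from shmrep.shm import Mutation

        muts = [
            Mutation(80, "A", "C", "CDR1", "transversion", None, "unscored",
                     "replacement" if i < 6 else "silent")
            for i in range(8)
        ]
        summary, _ = summarize_rs_by_region(muts)
        row = summary.loc[summary["region"] == "CDR1"].iloc[0]
        assert row["replacement"] == 6 and row["silent"] == 2
        assert row["rs_ratio"] == pytest.approx(3.0)
        empty = summary.loc[summary["region"] == "FR2"].iloc[0]
        assert empty["replacement"] == 0 and empty["silent"] == 0
        assert empty["rs_undefined"]

    def test_load_summary_mean_and_unmutated_fraction(self):
        import pandas as pd

        meta = pd.DataFrame(
            {"read_id": ["a", "b", "c"], "isotype": ["IgM"] * 3, "tissue": ["spleen"] * 3}
        )
        out = mutation_load_summary({"a": 0, "b": 0, "c": 3}, meta, ())
        assert out["mean_load"].iloc[0] == pytest.approx(1.0)
        assert out["fraction_unmutated"].iloc[0] == pytest.approx(2 / 3)
        out2 = mutation_load_summary({"a": 2, "b": 4, "c": 3}, meta, ("isotype",))
        assert out2["mean_load"].iloc[0] == pytest.approx(3.0)
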