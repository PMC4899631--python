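"""End-to-end orchestration: align -> filter -> clone -> consensus ->
mutation summaries -> lineage trees, on real (FASTA + metadata) or simulated
input, with a report bundle of figure-level tables and full provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from shmrep.align import (
    GermlineAlignment,
    ReadRecord,
    align_to_germline,
    extract_junction,
    is_productive,
    passes_homology_filter,
    read_fasta_with_metadata,
    rearrangement_table,
)
from shmrep.clones import (
    CloneSet,
    clone_composition,
    clone_consensus,
    group_clones,
)
from shmrep.reference import GermlineReference, load_reference, synthetic_vh_reference
from shmrep.shm import (
    call_mutations,
    estimate_mutability,
    mutation_load_summary,
    summarize_hotspot_fractions,
    summarize_rs_by_region,
)
from shmrep.simulate import (
    J_ANCHOR,
    SimulationConfig,
    TargetingModel,
    simulate_repertoire,
    write_repertoire,
)
from shmrep.trees import build_lineage_tree, edge_table, total_tree_weight, write_newick

logger = logging.getLogger("shmrep.pipeline")


@dataclass
class PipelineConfig:
    """One run of the analysis, on files or on a simulation block.

    Exactly one of (``reads_fasta``) / (``simulation`` + ``targeting``) must
    be given.  The reference defaults to the package's built-in synthetic V
    segment when no bundle paths are provided.
    """

    reads_fasta: str | None = None
    metadata_tsv: str | None = None
    reference_fasta: str | None = None
    reference_bounds: str | None = None
    simulation: SimulationConfig | None = None
    targeting: TargetingModel | None = None
    homology_threshold: float = 0.90
    consensus_mode: bool = True  # spectrum stats from clone consensuses (default)
    grouping: tuple[str, ...] = ("isotype", "treatment")
    j_anchor: str | None = None
    min_clone_size_for_tree: int = 2
    out_dir: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        has_files = self.reads_fasta is not None
        has_sim = self.simulation is not None
        if has_files == has_sim:
            raise ValueError("config must specify exactly one of reads_fasta / simulation")
        if not 0.0 < self.homology_threshold < 1.0:
            raise ValueError(
                f"homology_threshold must be in (0, 1), got {self.homology_threshold}"
            )
        if has_sim and self.targeting is None:
            self.targeting = TargetingModel()

    @classmethod
    def from_file(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        sim = data.pop("simulation", None)
        targ = data.pop("targeting", None)
        if sim is not None:
            if "junction_length_range" in sim:
                sim["junction_length_range"] = tuple(sim["junction_length_range"])
            sim = SimulationConfig(**sim)
        if targ is not None:
            targ = TargetingModel(**targ)
        if "grouping" in data:
            data["grouping"] = tuple(data["grouping"])
        cfg = cls(simulation=sim, targeting=targ, **data)
        if seed is not None:
            cfg.seed = seed
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in self.__dict__.items()}, sort_keys=True
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class ReportBundle:
    """All figure-level tables from one pipeline run."""

    funnel: dict[str, int]
    rearrangements: pd.DataFrame
    load_summary: pd.DataFrame
    composition: dict
    clone_table: pd.DataFrame
    titv_table: pd.DataFrame
    mutability: pd.DataFrame
    hotspot_fractions: dict[str, float]
    rs_by_region: pd.DataFrame
    rs_positional: pd.DataFrame
    newick_trees: dict[str, str]
    tree_edges: pd.DataFrame
    per_read_mutations: pd.DataFrame
    consensus_sequences: dict[str, str]
    clone_set: CloneSet
    run_log: dict


def _resolve_reference(config: PipelineConfig) -> GermlineReference:
    if config.reference_fasta is not None:
        if config.reference_bounds is None:
            raise ValueError("reference_fasta given without reference_bounds")
        return load_reference(config.reference_fasta, config.reference_bounds)
    return synthetic_vh_reference()


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run the full analysis and return the report bundle.

    Deterministic given the config and seed; if ``out_dir`` is set, all
    intermediate artifacts and tables are written there.
    """
    ref = _resolve_reference(config)
    j_anchor = config.j_anchor

    if config.simulation is not None:
        sim_config = config.simulation
        if config.seed is not None:
            sim_config = SimulationConfig(**{**sim_config.__dict__, "seed": config.seed})
        raw_reads, truth = simulate_repertoire(ref, config.targeting, sim_config)
        reads = [ReadRecord(id=rid, sequence=seq) for rid, seq in raw_reads]
        j_anchor = J_ANCHOR if j_anchor is None else j_anchor
        if config.out_dir:
            write_repertoire(raw_reads, truth, config.out_dir, prefix="simulated")
    else:
        reads = read_fasta_with_metadata(config.reads_fasta, config.metadata_tsv)
        truth = None

    logger.info("input: %d reads", len(reads))
    alignments = [align_to_germline(r, ref) for r in reads]

    full_length = [a for a in alignments if "partial" not in a.flags]
    productive = [a for a in full_length if is_productive(a, ref)]
    homologous = [
        a for a in productive if passes_homology_filter(a, config.homology_threshold)
    ]
    analyzable = [a for a in homologous if a.analyzable]
    for a in homologous:
        if not a.analyzable:
            logger.warning(
                "read %s excluded from mutation statistics: %s",
                a.read.id,
                ";".join(a.flags),
            )
    funnel = {
        "input": len(alignments),
        "full_length": len(full_length),
        "productive": len(productive),
        "homology_passing": len(homologous),
        "analyzable": len(analyzable),
    }
    logger.info("filter funnel: %s", funnel)

    junctions = [extract_junction(a, j_anchor) for a in analyzable]
    clone_set = group_clones(analyzable, junctions)
    composition = (
        clone_composition(clone_set) if len(clone_set) else {"n_clones": 0, "n_sequences": 0}
    )

    consensuses = [clone_consensus(c, ref) for c in clone_set]
    # spectrum statistics (ti/tv, mutability, hotspot fractions, R/S) come
    # from one consensus per clone by default, so a mutational event shared
    # by clonal siblings is counted once; per-sequence mode is available
    if config.consensus_mode:
        spectrum_units = [cons.sequence for cons in consensuses]
    else:
        spectrum_units = [a.v_sequence for a in analyzable]
    spectrum_mutations = [
        m for seq in spectrum_units for m in call_mutations(seq, ref)
    ]
    mutability = estimate_mutability(spectrum_units, ref)
    hotspot_fractions = (
        summarize_hotspot_fractions(spectrum_mutations)
        if spectrum_mutations
        else {"hotspot": float("nan"), "neutral": float("nan"), "coldspot": float("nan")}
    )
    rs_by_region, rs_positional = summarize_rs_by_region(spectrum_mutations)

    n_ti = sum(1 for m in spectrum_mutations if m.substitution_class == "transition")
    n_tv = len(spectrum_mutations) - n_ti
    titv_table = pd.DataFrame(
        [
            {
                "transitions": n_ti,
                "transversions": n_tv,
                "total": n_ti + n_tv,
                "transition_fraction": n_ti / (n_ti + n_tv) if (n_ti + n_tv) else float("nan"),
            }
        ]
    )

    # per-sequence mutation loads (a per-read statistic, not per consensus)
    per_read_rows = []
    loads = {}
    for aln in analyzable:
        muts = call_mutations(aln.v_sequence, ref)
        loads[aln.read.id] = len(muts)
        for m in muts:
            per_read_rows.append(
                {
                    "read_id": aln.read.id,
                    "position": m.position,
                    "from": m.from_base,
                    "to": m.to_base,
                    "region": m.region,
                    "substitution_class": m.substitution_class,
                    "context": m.context or "",
                    "context_class": m.context_class,
                    "coding_class": m.coding_class,
                }
            )
    per_read_mutations = pd.DataFrame(
        per_read_rows,
        columns=[
            "read_id",
            "position",
            "from",
            "to",
            "region",
            "substitution_class",
            "context",
            "context_class",
            "coding_class",
        ],
    )
    metadata = pd.DataFrame(
        [
            {
                "read_id": a.read.id,
                "isotype": a.read.isotype,
                "tissue": a.read.tissue,
                "treatment": a.read.treatment,
                "animal": a.read.animal,
            }
            for a in analyzable
        ]
    )
    grouping = [g for g in config.grouping if not metadata.empty and metadata[g].nunique() > 0]
    load_summary = (
        mutation_load_summary(loads, metadata, grouping)
        if loads
        else pd.DataFrame(
            columns=["n_sequences", "mean_load", "median_load", "fraction_unmutated"]
        )
    )

    newick_trees: dict[str, str] = {}
    edge_frames = []
    for clone in clone_set:
        if clone.size < config.min_clone_size_for_tree:
            continue
        tree = build_lineage_tree(
            list(zip(clone.member_ids, clone.member_v_sequences)), ref, clone.clone_id
        )
        newick_trees[clone.clone_id] = write_newick(tree)
        edge_frames.append(edge_table(tree))
    tree_edges = (
        pd.concat(edge_frames, ignore_index=True)
        if edge_frames
        else pd.DataFrame(
            columns=["clone_id", "parent", "child", "weight", "multiplicity", "inferred"]
        )
    )

    from shmrep import __version__

    run_log = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "reference": ref.name,
        "funnel": funnel,
        "n_clones": len(clone_set),
        "consensus_mode": config.consensus_mode,
        "n_spectrum_mutations": len(spectrum_mutations),
    }

    bundle = ReportBundle(
        funnel=funnel,
        rearrangements=rearrangement_table(alignments, config.homology_threshold),
        load_summary=load_summary,
        composition=composition,
        clone_table=pd.DataFrame(
            [
                {
                    "clone_id": c.clone_id,
                    "junction": c.junction,
                    "size": c.size,
                    "fraction": c.size / clone_set.total_sequences
                    if clone_set.total_sequences
                    else float("nan"),
                }
                for c in clone_set
            ],
            columns=["clone_id", "junction", "size", "fraction"],
        ),
        titv_table=titv_table,
        mutability=mutability.table,
        hotspot_fractions=hotspot_fractions,
        rs_by_region=rs_by_region,
        rs_positional=rs_positional,
        newick_trees=newick_trees,
        tree_edges=tree_edges,
        per_read_mutations=per_read_mutations,
        consensus_sequences={c.clone_id: c.sequence for c in consensuses},
        clone_set=clone_set,
        run_log=run_log,
    )
    if config.out_dir:
        write_report(bundle, config.out_dir)
    return bundle


def write_report(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Write every report table to ``out_dir`` in stable text formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.rearrangements.to_csv(out / "rearrangements.tsv", sep="\t", index=False)
    bundle.load_summary.to_csv(out / "mutation_loads.tsv", sep="\t", index=False)
    bundle.clone_table.to_csv(out / "clones.tsv", sep="\t", index=False)
    bundle.titv_table.to_csv(out / "titv.tsv", sep="\t", index=False)
    bundle.mutability.to_csv(out / "mutability.tsv", sep="\t", index=False)
    bundle.rs_by_region.to_csv(out / "rs_by_region.tsv", sep="\t", index=False)
    bundle.rs_positional.to_csv(out / "rs_positional.tsv", sep="\t", index=False)
    bundle.per_read_mutations.to_csv(out / "mutations.tsv", sep="\t", index=False)
    bundle.tree_edges.to_csv(out / "tree_edges.tsv", sep="\t", index=False)
    with (out / "trees.nwk").open("w") as fh:
        for clone_id in sorted(bundle.newick_trees):
            fh.write(f"{bundle.newick_trees[clone_id]}\n")
    with (out / "consensus.fasta").open("w") as fh:
        for clone_id in sorted(bundle.consensus_sequences):
            fh.write(f">{clone_id}\n{bundle.consensus_sequences[clone_id]}\n")
    (out / "composition.json").write_text(json.dumps(bundle.composition, indent=2) + "\n")
    (out / "hotspot_fractions.json").write_text(
        json.dumps(bundle.hotspot_fractions, indent=2) + "\n"
    )
    (out / "funnel.json").write_text(json.dumps(bundle.funnel, indent=2) + "\n")
    (out / "run_log.json").write_text(json.dumps(bundle.run_log, indent=2) + "\n")
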