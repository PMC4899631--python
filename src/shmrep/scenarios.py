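"""Study-condition scenarios: the simulated counterparts of the sorted
plasma-cell populations and assay time courses the analysis is built around.

Four repertoire populations are modelled with per-sequence mutation loads at
each compartment's mean — heavily mutated bone-marrow IgG plasma cells,
lightly mutated IgM plasma cells with and without germinal-centre depletion,
and unmutated pre-B controls carrying only the uniform sequencing-error
floor.  A representative-mouse clonal decomposition (7 clones, top three at
38/36/15% of 100 sequences) drives the clonal-expansion summaries, and
adoptive-transfer decay courses (ELISPOT at days 7, 14, 30, 60; four
recipients per group) drive the kinetics.
"""

from __future__ import annotations

import numpy as np

from shmrep.align import ReadRecord, align_to_germline, extract_junction
from shmrep.clones import clone_composition, group_clones
from shmrep.kinetics import DecaySeries, compare_decay_slopes, estimate_half_life
from shmrep.pipeline import PipelineConfig, ReportBundle, run_pipeline
from shmrep.reference import synthetic_vh_reference
from shmrep.simulate import J_ANCHOR, SimulationConfig, TargetingModel, simulate_decay_series

# per-population mean V-region mutation loads (per sequence)
LOAD_SCENARIOS = {
    "igg_bone_marrow": {"mean_load": 25.5, "error_rate": 0.0},
    "igm": {"mean_load": 3.3, "error_rate": 0.0},
    "igm_gc_depleted": {"mean_load": 2.1, "error_rate": 0.0},
    "preb_control": {"mean_load": 0.0, "error_rate": None},  # error floor only
}
PREB_TARGET_LOAD = 0.4  # diverging V-region bases per pre-B control sequence
N_SEQUENCES_PER_SCENARIO = 400

# representative-mouse clonal decomposition: 100 sequences in 7 clones, the
# three largest holding 38%, 36% and 15%
IGG_CLONE_SIZES = [38, 36, 15, 4, 3, 2, 2]

# adoptive-transfer decay: half-lives of splenic IgG and IgM plasma cells,
# ELISPOT schedule, replicate recipients, between-replicate count CV
KINETICS_HALF_LIVES = {"igg": 145.0, "igm": 86.0}
KINETICS_TIMEPOINTS = [7, 14, 30, 60]
KINETICS_REPLICATES = 4
KINETICS_CV = 0.15


def load_scenario_config(name: str, seed: int) -> SimulationConfig:
    """Simulation config for one of the four repertoire populations."""
    params = LOAD_SCENARIOS[name]
    error_rate = params["error_rate"]
    if error_rate is None:
        # the pre-B divergence target counts V-region bases, so express it
        # as a per-base rate over the V segment
        error_rate = PREB_TARGET_LOAD / synthetic_vh_reference().cdr3_start
    return SimulationConfig(
        n_clones=N_SEQUENCES_PER_SCENARIO,
        clone_size_law="fixed",
        clone_size_param=1,
        mutations_per_lineage_step=params["mean_load"],
        sequencing_error_rate=error_rate,
        seed=seed,
    )


def run_load_scenario(name: str, seed: int, out_dir: str | None = None) -> ReportBundle:
    """Run the full pipeline on one population; optionally write the bundle."""
    config = PipelineConfig(
        simulation=load_scenario_config(name, seed),
        targeting=TargetingModel(),
        out_dir=out_dir,
    )
    return run_pipeline(config)


def representative_clonal_composition(seed: int) -> dict:
    """Clonal composition of a repertoire built at the printed clone sizes."""
    ref = synthetic_vh_reference()
    rng = np.random.default_rng(seed)
    bases = "ACGT"
    alns, junctions = [], []
    seen: set[str] = set()
    for i, size in enumerate(IGG_CLONE_SIZES):
        junction = "".join(bases[k] for k in rng.integers(0, 4, 15))
        while junction in seen:
            junction = "".join(bases[k] for k in rng.integers(0, 4, 15))
        seen.add(junction)
        for j in range(size):
            read = ReadRecord(f"c{i}_r{j}", ref.sequence + junction + J_ANCHOR)
            aln = align_to_germline(read, ref)
            alns.append(aln)
            junctions.append(extract_junction(aln, J_ANCHOR))
    return clone_composition(group_clones(alns, junctions), top_k=3)


def simulate_transfer_courses(seed: int) -> dict[str, DecaySeries]:
    """Replicate-averaged decay courses for the IgG and IgM transfer groups."""
    rng = np.random.default_rng(seed)
    pooled = {}
    for isotype, half_life in KINETICS_HALF_LIVES.items():
        counts = [
            simulate_decay_series(
                1000.0, half_life, KINETICS_TIMEPOINTS, cv_noise=KINETICS_CV, seed=rng
            ).counts
            for _ in range(KINETICS_REPLICATES)
        ]
        pooled[isotype] = DecaySeries(KINETICS_TIMEPOINTS, np.mean(counts, axis=0))
    return pooled


def kinetics_summary(seed: int) -> dict:
    """Recovered half-lives and the slope-difference p for the two groups."""
    pooled = simulate_transfer_courses(seed)
    est = {k: estimate_half_life(v) for k, v in pooled.items()}
    _, p_value = compare_decay_slopes(pooled["igg"], pooled["igm"])
    return {
        "igg_half_life": est["igg"].half_life_days,
        "igm_half_life": est["igm"].half_life_days,
        "igg_r_squared": est["igg"].r_squared,
        "igm_r_squared": est["igm"].r_squared,
        "slope_p": p_value,
        "n": len(KINETICS_TIMEPOINTS) * KINETICS_REPLICATES,
    }
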