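"""Synthetic heavy-chain repertoire generator with ground-truth tables.

Emulates the clonal and mutational structure the downstream analysis assumes:
multiple clones keyed by unique CDR3 junctions, skewed clone-size
distributions, branching lineages within clones, point mutations concentrated
in AID 5-mer hotspots with a transition excess, and a low uniform
sequencing-error floor mimicking an unmutated pre-B control baseline.

Each simulated read is germline V segment + random junction + fixed J-anchor.
Somatic mutations are drawn position-by-position with probability
proportional to the current sequence's per-5-mer mutability (hotspot WRC/GYW
and WA/TW, coldspot SYC/GRS, neutral otherwise), re-evaluated between lineage
steps as contexts drift; they are applied to the V portion only, so the
junction remains an exact clone key as the grouping step requires.
Sequencing error is applied last, uniformly over the whole read, and is
recorded separately from true SHM in the truth tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from shmrep.reference import GermlineReference
from shmrep.shm import (
    COLDSPOT_SYC_GRS,
    HOTSPOT_CLASSES,
    classify_context,
)

# Transition partner of each base (A<->G, C<->T).
TRANSITION_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
BASES = "ACGT"

# Fixed 12-nt stand-in for the J-region anchor appended 3' of the junction,
# so junction extraction is well defined on synthetic reads.
J_ANCHOR = "TGGGGTCAAGGA"


@dataclass(frozen=True)
class TargetingModel:
    """Relative per-position mutabilities by AID context class.

    ``transition_fraction`` is the probability that a substitution is the
    transition partner of the original base; the two transversions share the
    remainder equally.  ``overrides`` optionally pins specific 5-mers to an
    absolute relative rate, taking precedence over the class rates.
    """

    hot_mutability: float = 5.0
    cold_mutability: float = 0.2
    neutral_mutability: float = 1.0
    transition_fraction: float = 0.6
    overrides: dict[str, float] = field(default_factory=dict, hash=False)

    def __post_init__(self) -> None:
        for name in ("hot_mutability", "cold_mutability", "neutral_mutability"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if not 0.0 <= self.transition_fraction <= 1.0:
            raise ValueError(
                f"transition_fraction must be in [0, 1], got {self.transition_fraction}"
            )
        for fivemer, rate in self.overrides.items():
            if len(fivemer) != 5 or set(fivemer) - set(BASES):
                raise ValueError(f"override key {fivemer!r} is not a 5-mer over ACGT")
            if not rate > 0:
                raise ValueError(f"override rate for {fivemer!r} must be > 0, got {rate}")

    def position_weights(self, sequence: str) -> np.ndarray:
        """Per-position mutability of ``sequence`` under this model.

        Positions without a full 5-mer context (first/last two bases) get
        neutral mutability.  Results are memoized per sequence (callers must
        not modify the returned array).
        """
        cache = self.__dict__.setdefault("_weights_cache", {})
        cached = cache.get(sequence)
        if cached is not None:
            return cached
        weights = np.empty(len(sequence))
        for i in range(len(sequence)):
            if i < 2 or i + 3 > len(sequence):
                weights[i] = self.neutral_mutability
                continue
            fivemer = sequence[i - 2 : i + 3]
            if fivemer in self.overrides:
                weights[i] = self.overrides[fivemer]
                continue
            cls = classify_context(fivemer)
            if cls in HOTSPOT_CLASSES:
                weights[i] = self.hot_mutability
            elif cls == COLDSPOT_SYC_GRS:
                weights[i] = self.cold_mutability
            else:
                weights[i] = self.neutral_mutability
        if len(cache) < 4096:
            cache[sequence] = weights
        return weights


@dataclass(frozen=True)
class SimulationConfig:
    """Sampling plan for a synthetic repertoire.

    ``clone_size_law`` is one of ``fixed``, ``geometric``, ``zipf`` with
    ``clone_size_param`` as its parameter (the fixed size, the geometric
    success probability, or the zipf exponent).  Lineages grow as a
    branching process: each member spawns Poisson(``offspring_mean``)
    children down to ``max_depth``, every edge adding
    Poisson(``mutations_per_lineage_step``) somatic mutations.
    """

    n_clones: int = 20
    clone_size_law: str = "zipf"
    clone_size_param: float = 2.0
    max_clone_size: int = 200
    mutations_per_lineage_step: float = 2.0
    offspring_mean: float = 1.5
    max_depth: int = 6
    junction_length_range: tuple[int, int] = (12, 30)
    junction_multiple_of_3: bool = True
    sequencing_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValueError(f"n_clones must be >= 1, got {self.n_clones}")
        if self.clone_size_law not in ("fixed", "geometric", "zipf"):
            raise ValueError(
                f"clone_size_law must be fixed|geometric|zipf, got {self.clone_size_law!r}"
            )
        if self.mutations_per_lineage_step < 0:
            raise ValueError(
                f"mutations_per_lineage_step must be >= 0, got {self.mutations_per_lineage_step}"
            )
        lo, hi = self.junction_length_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid junction_length_range {self.junction_length_range}")
        if not 0.0 <= self.sequencing_error_rate < 1.0:
            raise ValueError(
                f"sequencing_error_rate must be in [0, 1), got {self.sequencing_error_rate}"
            )
        if self.offspring_mean < 0 or self.max_depth < 1:
            raise ValueError("offspring_mean must be >= 0 and max_depth >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load a config from YAML or JSON."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if "junction_length_range" in data:
            data["junction_length_range"] = tuple(data["junction_length_range"])
        return cls(**data)

    def to_json(self) -> str:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class SimulationTruth:
    """Ground truth for a simulated repertoire.

    ``reads`` maps read id -> clone id; ``mutations`` maps read id -> ordered
    list of (1-based position on the read, from_base, to_base, origin) where
    origin is "shm" or "error"; ``lineage_edges`` maps clone id -> list of
    (parent read id, child read id) pairs (the founder's parent is the
    germline, not listed); ``junctions`` maps clone id -> junction string.
    """

    reads: dict[str, str]
    mutations: dict[str, list[tuple[int, str, str, str]]]
    lineage_edges: dict[str, list[tuple[str, str]]]
    junctions: dict[str, str]
    config: SimulationConfig
    model: TargetingModel


def apply_shm(
    sequence: str,
    model: TargetingModel,
    n_mutations: int,
    rng: np.random.Generator | int,
) -> tuple[str, list[tuple[int, str, str]]]:
    """Apply exactly ``n_mutations`` context-targeted substitutions.

    Positions are sampled one at a time with probability proportional to the
    model mutability evaluated on the *current* sequence (already-mutated
    positions are excluded, so positions are distinct).  Returns the mutated
    sequence and the mutation list as (1-based position, from, to), ordered
    by position.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if n_mutations > len(sequence):
        raise ValueError(
            f"n_mutations ({n_mutations}) exceeds sequence length ({len(sequence)})"
        )
    seq = list(sequence.upper())
    hit: set[int] = set()
    mutations: list[tuple[int, str, str]] = []
    for _ in range(n_mutations):
        weights = model.position_weights("".join(seq)).copy()
        for p in hit:
            weights[p] = 0.0
        weights = weights / weights.sum()
        pos = int(rng.choice(len(seq), p=weights))
        original = seq[pos]
        if rng.random() < model.transition_fraction:
            new = TRANSITION_PARTNER[original]
        else:
            transversions = [b for b in BASES if b != original and b != TRANSITION_PARTNER[original]]
            new = transversions[int(rng.integers(2))]
        seq[pos] = new
        hit.add(pos)
        mutations.append((pos + 1, original, new))
    mutations.sort(key=lambda m: m[0])
    return "".join(seq), mutations


def _draw_clone_size(config: SimulationConfig, rng: np.random.Generator) -> int:
    if config.clone_size_law == "fixed":
        size = int(config.clone_size_param)
    elif config.clone_size_law == "geometric":
        size = int(rng.geometric(config.clone_size_param))
    else:  # zipf
        size = int(rng.zipf(config.clone_size_param))
    return max(1, min(size, config.max_clone_size))


def _draw_junction(config: SimulationConfig, rng: np.random.Generator) -> str:
    lo, hi = config.junction_length_range
    length = int(rng.integers(lo, hi + 1))
    if config.junction_multiple_of_3:
        length -= length % 3
        length = max(3, length)
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def simulate_repertoire(
    reference: GermlineReference,
    model: TargetingModel,
    config: SimulationConfig,
) -> tuple[list[tuple[str, str]], SimulationTruth]:
    """Simulate a repertoire; returns (reads, truth).

    ``reads`` is a list of (read id, sequence) in deterministic order.  Each
    clone grows as a branching lineage from an unmutated founder
    (germline V + unique junction + J anchor); every parent->child edge adds
    Poisson(``mutations_per_lineage_step``) SHM substitutions to the V
    portion.  Per-clone random substreams are derived from the root seed and
    the clone index, so output is byte-identical for identical inputs.
    """
    root_ss = np.random.SeedSequence(config.seed)
    clone_streams = root_ss.spawn(config.n_clones + 1)
    junction_rng = np.random.default_rng(clone_streams[-1])

    v_len = len(reference.sequence)
    junctions: dict[str, str] = {}
    seen_junctions: set[str] = set()
    reads: list[tuple[str, str]] = []
    truth_reads: dict[str, str] = {}
    truth_mutations: dict[str, list[tuple[int, str, str, str]]] = {}
    lineage_edges: dict[str, list[tuple[str, str]]] = {}

    for c in range(config.n_clones):
        rng = np.random.default_rng(clone_streams[c])
        clone_id = f"clone{c:04d}"
        junction = _draw_junction(config, junction_rng)
        while junction in seen_junctions:  # founders must carry distinct junctions
            junction = _draw_junction(config, junction_rng)
        seen_junctions.add(junction)
        junctions[clone_id] = junction

        size = _draw_clone_size(config, rng)
        # the founder is itself one lineage step from the germline, so even
        # singleton clones carry SHM at the configured per-step rate
        n_founder_mut = min(int(rng.poisson(config.mutations_per_lineage_step)), v_len)
        founder_v, founder_muts = apply_shm(reference.sequence, model, n_founder_mut, rng)
        # members: (read index, V sequence, shm mutation list, depth)
        members: list[tuple[int, str, list[tuple[int, str, str]], int]] = [
            (0, founder_v, founder_muts, 0)
        ]
        edges: list[tuple[int, int]] = []
        # branching process: BFS over members, each spawning Poisson children,
        # until the drawn clone size is reached
        frontier = [0]
        while len(members) < size:
            if not frontier:
                # lineage died out below target size: reseed from a random
                # existing member below max depth
                candidates = [m[0] for m in members if m[3] < config.max_depth]
                frontier = [int(rng.choice(candidates))] if candidates else [0]
            next_frontier: list[int] = []
            for parent_idx in frontier:
                if len(members) >= size:
                    break
                parent = members[parent_idx]
                if parent[3] >= config.max_depth:
                    continue
                n_children = int(rng.poisson(config.offspring_mean))
                for _ in range(n_children):
                    if len(members) >= size:
                        break
                    n_mut = min(int(rng.poisson(config.mutations_per_lineage_step)), v_len)
                    child_v, new_muts = apply_shm(parent[1], model, n_mut, rng)
                    child_idx = len(members)
                    child_muts = _merge_mutations(parent[2], new_muts)
                    members.append((child_idx, child_v, child_muts, parent[3] + 1))
                    edges.append((parent_idx, child_idx))
                    next_frontier.append(child_idx)
            frontier = next_frontier

        suffix = junction + J_ANCHOR
        edge_list: list[tuple[str, str]] = []
        for idx, v_seq, shm_muts, _depth in members:
            read_id = f"{clone_id}_r{idx:04d}"
            full = v_seq + suffix
            error_muts: list[tuple[int, str, str]] = []
            if config.sequencing_error_rate > 0:
                chars = list(full)
                hits = rng.random(len(chars)) < config.sequencing_error_rate
                for pos in np.flatnonzero(hits):
                    original = chars[pos]
                    alternatives = [b for b in BASES if b != original]
                    new = alternatives[int(rng.integers(3))]
                    chars[pos] = new
                    error_muts.append((int(pos) + 1, original, new))
                full = "".join(chars)
            reads.append((read_id, full))
            truth_reads[read_id] = clone_id
            truth_mutations[read_id] = sorted(
                [(p, f, t, "shm") for (p, f, t) in shm_muts]
                + [(p, f, t, "error") for (p, f, t) in error_muts],
                key=lambda m: m[0],
            )
        for parent_idx, child_idx in edges:
            edge_list.append(
                (f"{clone_id}_r{parent_idx:04d}", f"{clone_id}_r{child_idx:04d}")
            )
        lineage_edges[clone_id] = edge_list

    truth = SimulationTruth(
        reads=truth_reads,
        mutations=truth_mutations,
        lineage_edges=lineage_edges,
        junctions=junctions,
        config=config,
        model=model,
    )
    return reads, truth


def _merge_mutations(
    inherited: list[tuple[int, str, str]], new: list[tuple[int, str, str]]
) -> list[tuple[int, str, str]]:
    """Compose inherited and new mutations into net differences vs germline."""
    by_pos = {p: (f, t) for p, f, t in inherited}
    for p, f, t in new:
        if p in by_pos:
            orig_from = by_pos[p][0]
            if orig_from == t:  # reverted to germline
                del by_pos[p]
            else:
                by_pos[p] = (orig_from, t)
        else:
            by_pos[p] = (f, t)
    return sorted(((p, f, t) for p, (f, t) in by_pos.items()), key=lambda m: m[0])


def write_repertoire(
    reads: list[tuple[str, str]],
    truth: SimulationTruth,
    out_dir: str | Path,
    prefix: str = "repertoire",
) -> dict[str, Path]:
    """Write FASTA reads plus TSV truth tables and a JSON config echo."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / f"{prefix}.fasta"
    with fasta.open("w") as fh:
        for read_id, seq in reads:
            fh.write(f">{read_id}\n{seq}\n")

    clones_path = out_dir / f"{prefix}.truth_clones.tsv"
    pd.DataFrame(
        [{"read_id": r, "clone_id": c} for r, c in truth.reads.items()]
    ).to_csv(clones_path, sep="\t", index=False)

    mut_path = out_dir / f"{prefix}.truth_mutations.tsv"
    pd.DataFrame(
        [
            {"read_id": r, "position": p, "from": f, "to": t, "origin": o}
            for r, muts in truth.mutations.items()
            for (p, f, t, o) in muts
        ],
        columns=["read_id", "position", "from", "to", "origin"],
    ).to_csv(mut_path, sep="\t", index=False)

    edges_path = out_dir / f"{prefix}.truth_lineage.tsv"
    pd.DataFrame(
        [
            {"clone_id": c, "parent": p, "child": ch}
            for c, edges in truth.lineage_edges.items()
            for (p, ch) in edges
        ],
        columns=["clone_id", "parent", "child"],
    ).to_csv(edges_path, sep="\t", index=False)

    config_path = out_dir / f"{prefix}.config.json"
    config_path.write_text(truth.config.to_json() + "\n")
    return {
        "fasta": fasta,
        "clones": clones_path,
        "mutations": mut_path,
        "lineage": edges_path,
        "config": config_path,
    }


def simulate_decay_series(
    y0: float,
    half_life_days: float,
    timepoints,
    cv_noise: float = 0.0,
    seed: int | np.random.Generator = 0,
):
    """Exponential-decay count series with multiplicative lognormal noise.

    counts = y0 * 2**(-t / half_life) scaled by lognormal noise with the
    given coefficient of variation; noiseless when ``cv_noise`` is 0.
    Returns a :class:`shmrep.kinetics.DecaySeries`.
    """
    from shmrep.kinetics import DecaySeries

    if y0 <= 0:
        raise ValueError(f"y0 must be > 0, got {y0}")
    if half_life_days <= 0:
        raise ValueError(f"half_life_days must be > 0, got {half_life_days}")
    t = np.asarray(timepoints, dtype=float)
    if t.size == 0 or np.any(t < 0):
        raise ValueError("timepoints must be non-empty and non-negative")
    counts = y0 * np.power(2.0, -t / half_life_days)
    if cv_noise < 0:
        raise ValueError(f"cv_noise must be >= 0, got {cv_noise}")
    if cv_noise > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        sigma = np.sqrt(np.log(1.0 + cv_noise**2))
        counts = counts * rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=t.size)
    return DecaySeries(timepoints=t, counts=counts)
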