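# Methods

## Setting and model

The package analyses heavy-chain repertoires from a response dominated by a
single germline V segment. All coordinates refer to that segment;
its FR/CDR boundaries and reading frame are part of the reference
(`GermlineReference`). The end of FR3 defines the CDR3 start: substitutions
at germline positions before it are "mutations"; everything 3' of it is
junction and is used only as the clone key.

Somatic hypermutation is modelled as context-targeted point substitution.
Each position's relative mutability is set by the 5-mer centred on it:
hotspot contexts WRC/GYW (the C/G deaminated by AID) and WA/TW (polymerase-η
patch), coldspot SYC/GRS, neutral otherwise (W={A,T}, S={C,G}, R={A,G},
Y={C,T}). Substitutions are transitions (A↔G, C↔T) with probability
`transition_fraction`, otherwise one of the two transversions uniformly.

## Synthetic-repertoire generator

`simulate_repertoire` grows each clone as a branching lineage from a
founder read (germline V + random junction + fixed 12-nt J-anchor stand-in).
The founder itself is one mutation step from the germline, and every
parent→child edge adds Poisson(`mutations_per_lineage_step`) substitutions,
so singleton clones still carry mutations at the configured rate. Mutability
is re-evaluated on the *current* sequence before each substitution, so
contexts drift as mutations accrue, as in iterative SHM. Key parameters:

| parameter | default | meaning |
|---|---|---|
| `hot_mutability` | 5.0 | relative rate of WRC/GYW and WA/TW contexts |
| `cold_mutability` | 0.2 | relative rate of SYC/GRS contexts |
| `neutral_mutability` | 1.0 | all other contexts (and sequence edges) |
| `transition_fraction` | 0.6 | share of substitutions that are transitions |
| `mutations_per_lineage_step` | scenario | Poisson mean per lineage edge (and for the founder) |
| `clone_size_law` | zipf | fixed / geometric / zipf clone sizes |
| `sequencing_error_rate` | 0 | uniform per-base error, applied last |

Design choices worth stating:

- **SHM is applied to the V portion only.** The analysis counts V-region
  mutations, and the clone key is the exact junction string; mutating
  junctions would make the true partition unrecoverable by the stated
  grouping rule. Sequencing error, by contrast, hits the whole read and is
  recorded separately from SHM in the truth tables (origin `shm` vs
  `error`), mimicking an unmutated control population whose apparent
  mutations are all machine error.
- **Positions without a full 5-mer** (first/last two bases) get neutral
  mutability and are "unscored" in context statistics — a boundary
  convention with negligible mass.
- **Randomness**: one root seed; per-clone substreams derived
  deterministically from it, so output is byte-identical given the seed.

The germline reference shipped with the package is a *synthetic* V segment
(297 nt, IMGT-like FR/CDR layout, stop-free, hotspot-enriched CDRs). It is
not any real deposited gene; analyses of real data should load their own
reference bundle (`load_reference`).

What the generator does **not** emulate, and what that limits: per-sequence
mutation loads are Poisson, so a population with mean 3.3 has ~4%
unmutated sequences — a real memory/plasma-cell pool is a mixture of
GC-experienced and inexperienced cells and can pair the same mean with a
third unmutated. Indels, class-switch, paired light chains, platform-
specific (e.g. homopolymer) error models and antigen selection are all out
of scope; passing tests demonstrate correctness of the computations, not
realism of those features.

## Alignment and filters

Reads are aligned to the single germline V semi-globally (end gaps free;
match +2, mismatch −2, gap open −10, extend −2; N scores 0), so a 3'
junction overhang and 5' truncation cost nothing. Identity is computed over
aligned germline positions only, with gap-spanned germline positions
counted as mismatches. Filters: coverage of the full V ("full-length";
<50% coverage is "partial"), productive translation (no stop, no N in
frame), and identity strictly greater than 0.90 — implemented strictly
because the criterion is stated as ">90%". Reads whose best alignment puts
an indel inside V are flagged and excluded from substitution statistics,
which are substitution-only. The identity denominator is the V portion, not
the whole read (the homology statement refers to a V gene); this is an
interpretation, recorded here because the source methods do not specify it.

## Clones, consensus, double counting

Clone key = exact junction nucleotide string (no similarity threshold).
The consensus takes, at each position, the base carried by a strict
majority (> half) of non-N members if it differs from germline; ties and
sub-majority pluralities revert to germline. This is deliberately
conservative: the consensus never contains a mutation a majority does not
support, so consensus-based counts cannot double-count a shared event.
Spectrum statistics (ti/tv, mutability, hotspot fractions, R/S) default to
consensus mode; mutation *loads* are always per sequence. Both modes are
explicit (`consensus_mode` / `--consensus/--per-sequence`).

## Mutation classification and mutability

The 5-mer context of a mutation is taken from the **germline** sequence
(mutability targets the pre-mutation state); neighbouring mutations do not
exclude a position from scoring. Replacement/silent is decided by
translating the germline codon with and without the substitution (other
codon positions at germline state); stops count as replacement. Per-5-mer
mutability is mutations/background, background being the number of times
the 5-mer occurs as a germline context across analysed units; rates are
normalized so the background-weighted mean is exactly 1, and raw counts are
exported so any other normalization is recoverable.

## Lineage trees

Each unique sequence is its mutation set versus germline. Sequences attach
in order of increasing mutation count to the node sharing the largest
mutation subset; when the sharing is partial, the shared set itself is
attached first (recursively) as an inferred intermediate, and any existing
node whose mutation set strictly contains a newly inserted node is
re-parented under it when that shortens its edge. Ties break by preferring
true-ancestor (subset) nodes, then larger multiplicity, then label — fully
deterministic. Edge weight is the number of new mutations on the edge;
reversions are never inferred, so path weights from the root add up exactly
to each node's distance from germline. On perfect-phylogeny input the tree
is exact; on all exhaustively searchable instances tried (≤4 sequences,
≤6-mutation universe, up to 3 inferred nodes) the greedy weight equals the
brute-force reversion-free Steiner minimum (see the test suite). Sites
conflicting with a branch attach on the root side; back-mutations are a
known blind spot.

## Kinetics and titres

Half-life: OLS of ln(count/count₀) on days; t½ = ln 2/|slope|; a
non-negative slope flags the estimate undefined rather than returning a
negative half-life. The intercept is free by default (noise at the first
timepoint argues against forcing the ratio through 1); a through-origin
mode exists. Slopes of two series are compared with
t = (λ₁−λ₂)/√(se₁²+se₂²) on n₁+n₂−4 degrees of freedom. Neutralization
titre: threshold (OD_virus − OD_cell)/2 + OD_cell; scanning from the lowest
dilution, the titre is the last dilution of the *initial* run below
threshold — a stated decision, because "highest dilution below threshold"
is ambiguous for non-monotone series; when even the first dilution fails,
the titre is reported as "< first dilution".

## Study-condition scenarios and problem sizes

`shmrep.scenarios` fixes the simulated counterparts of the study
populations: per-sequence loads with means 25.5 (IgG), 3.3 (IgM), 2.1
(GC-depleted IgM) and a 0.4 diverging-base error floor (pre-B), 400
sequences per population; a representative clonal decomposition of 100
sequences in 7 clones (38/36/15% top three); decay courses with true
half-lives 145 and 86 days sampled at days 7/14/30/60 in four recipients
with 15% count CV. Note two systematic effects visible in the outputs: the
productivity filter removes heavily mutated sequences that acquired stops,
biasing the measured IgG mean load below the simulated 25.5; and the short
(relative to t½) follow-up window makes individual half-life estimates
noisy even though they are unbiased in the median — both are properties of
the study design being emulated, not of the estimators.

Test and acceptance problem sizes (hundreds of clones, thousands of
mutations, hundreds to a thousand replicates) were chosen to make the
statistical checks well-powered while keeping the whole suite around half a
minute.
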