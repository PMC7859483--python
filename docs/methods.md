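# Methods

## Pipeline model

`alnkit` implements plain (unweighted) progressive multiple sequence
alignment in three stages — all-pairs dynamic-programming alignment feeding
a percent-divergence distance matrix, agglomerative guide-tree construction
(UPGMA or neighbor joining), and tree-guided profile merging — followed by
an objective-function evaluation of the finished alignment. Each stage is a
named component behind a small functional interface, and a selection of
components is validated against a feature model (group cardinalities plus
dependency rules) before assembly. The assembled pipeline is pure and
deterministic: identical inputs and configuration give byte-identical
output.

The pipeline deliberately omits the heuristics that production aligners
layer on top of this skeleton: no sequence weighting, no position-specific
or residue-specific gap penalties, no iterative refinement, no k-tuple
fast distances. What remains is the exact, analysable core, which is the
point of the package.

## Pairwise alignment

Global alignment with end gaps penalized. Both gap models run through one
three-state (Gotoh) DP engine — layers M (diagonal), X (gap in the second
row), Y (gap in the first row) — compiled with numba; the linear model is
executed as affine with `extend = open`, which charges exactly `open` per
gap symbol. The engine receives a precomputed column-pair score matrix, so
the same code aligns residue strings and profiles.

Tie-breaking: at equal score the traceback prefers diagonal over up (gap in
the second row) over left (gap in the first row), and within each layer the
predecessor preference is M > X > Y. Any fixed rule would do; this one is
documented so reruns and tests are exactly reproducible. Scores are exact
when substitution and gap values are integers; floating-point comparisons
elsewhere use an absolute tolerance of 1e-9.

`rescore_pair` recomputes the score of an aligned pair directly from its
rows (substitution sum plus per-run gap costs). It shares no code with the
DP engine and serves as the self-consistency oracle: the engine's reported
score must equal the rescored value of the rows it returns.

## Distance matrix

The shipped measure is ClustalW-style percent divergence:
`d = 1 − identical/(gap-free columns)`, with `d = 1` when no gap-free
column exists. Wildcard residues (N/X) are counted as never identical —
including to themselves — because an unknown residue is evidence of
nothing. The raw DP score is deliberately not used as a distance: fractional
divergence is bounded in [0,1] and independent of sequence length, which
the clustering stage handles robustly. The measure is itself an injectable
component, so a score-based alternative can be registered without touching
the stage.

## Guide trees

*UPGMA* is true size-weighted average linkage (not WPGMA): the closest pair
merges at height d/2 and the merged cluster's distances are member-count
weighted means. Output is ultrametric by construction.

*Neighbor joining* follows Saitou–Nei with the standard Q-criterion and
limb-length formulas. Negative limb estimates (possible on non-additive
matrices) are clamped to zero with the deficit moved to the sibling edge,
preserving the joined pair's mutual distance. The unrooted result is rooted
at the midpoint of the longest leaf-to-leaf path — a parameter-free choice;
if the midpoint falls exactly on an internal node the root attaches with a
zero-length edge so the tree stays strictly binary. Merge ties in both
algorithms resolve to the lexicographically smallest (row, column) index
pair in current matrix order.

On additive input matrices NJ is exact (topology and all path lengths to
1e-9); on ultrametric inputs UPGMA is exact. Both facts are exercised by
the test suite against matrices generated from known random trees.

## Progressive alignment

Post-order traversal of the guide tree; children merge in order of subtree
height (smaller first, ties by smallest leaf id), so the most closely
related profiles align earliest. Column-pair score is the unweighted mean
of substitution scores over all residue/residue cross-pairs between the two
columns; pairings involving a gap are excluded from the mean, and a pairing
with no residue/residue combination scores 0. Gap penalties apply per
inserted column, per run, through the same gap model as the pairwise stage.
Inserting a gap into a profile inserts an all-gap column into every row of
that profile and existing gaps are never revisited, which guarantees the
projection property: restricting the merged profile to either child's rows
and deleting all-gap columns reproduces that child exactly. The final
alignment reports rows in input order.

## Objectives

Sum-of-pairs uses linear gap accounting (each residue/gap cell costs the
gap-open value, gap/gap costs 0) so the score decomposes exactly over
columns; affine SP is out of scope. On a two-row alignment SP equals the
linear pairwise score, a reduction law the tests assert. Percent identity
averages pairwise identity over gap-free columns with the same wildcard
convention as the distance stage; a pair with no gap-free column
contributes 0.

## Feature model and assembly

Seven groups: validation (exactly-one), pairwise (exactly-one), distance
(exactly-one), clustering (optional-one), progressive (optional-one),
objective (exactly-one), output (one-or-more) — 11 components in all.
Dependency rules state that progressive alignment requires a clustering
component and the distance component, and that either clustering algorithm
requires the distance component. A rule's `requires` list is satisfied by
*any* listed member (needed to say "some clustering algorithm"); `conflicts`
forbids co-selection. Leaving out the progressive and clustering components
yields a pairwise-only pipeline that demands exactly two input sequences at
run time. Constraints live in code-registered data structures rather than
external documents so they are enumerable: the tests brute-force all 2^11
selections against an independent evaluator.

Configuration documents are YAML with a strict schema (`components`,
`parameters`, `alphabet`, `scoring`); unknown keys are rejected with their
path. Validation reports are accumulated, never thrown, so a user sees all
problems at once; assembly refuses to construct a pipeline from a failing
report.

## Synthetic families

The generator evolves a uniform random root sequence down a tree whose
branch lengths are uniform on [0.05, 0.5]. Per edge of length ℓ each site
substitutes with probability `min(1, rate·ℓ)` to a uniformly chosen
*different* residue (at most one event per site per edge — no multiple
hits, no Jukes–Cantor correction; transparency of the ground-truth
bookkeeping is worth more here than realism). Indel events are thinned per
site at `min(1, indel_rate·ℓ)`, equally likely insertion or deletion, with
geometric run lengths (default mean 2); deletions remove the run *after*
the anchor site so sequences can never become empty. Wildcard symbols are
never generated — a simulated family should not contain "unknown" residues.
Site tokens carry persistent identities, so the true alignment is read off
the global token order; columns surviving in no leaf are dropped.

Defaults: root length 500 (a typical gene-fragment scale, long enough that
internal edges at low substitution rates still accumulate signal),
substitution rate 0.05 per site per unit branch length, no indels. These
defaults are the regime in which the topology-recovery property is stated:
distance + NJ must recover a random 6-leaf topology (Robinson–Foulds 0) in
at least 90% of 50 replicates (`TOPOLOGY_RECOVERY_MIN = 0.90`, a repo
constant). Measured rates sit at 92–96% depending on seed: the failures are
replicates whose shortest internal edge received no observable
substitution. What these simulations do *not* emulate: rate heterogeneity
across sites, back-substitution saturation, codon structure, realistic
indel hotspots — so a passing suite certifies the algorithmic contracts,
not alignment accuracy on real biological divergence.

## Numerical and scale choices

All DP arithmetic is float64; integer-valued schemes stay exact. Distance
matrices are validated to be symmetric, finite, non-negative and
zero-diagonal on construction. Newick serialization fixes branch lengths at
six decimals; round-trips are exact at that precision. Test and acceptance
workloads are sized to the property being demonstrated — enumeration
oracles at sequence lengths ≤ 6 (where exhaustive search is feasible and
exact), 100 random trees for NJ additivity, 50 replicates for topology
recovery, families of 6–10 sequences × 150 sites for progressive
invariants — sizes at which every property is measured at full strength.

## Known limitations

No local or semi-global alignment; no affine-gap sum-of-pairs; guide-tree
quality is limited by uncorrected percent divergence at high divergence;
the progressive stage never revisits early gaps (the classic failure mode
of progressive alignment); the feature model covers the shipped component
inventory, not arbitrary user-defined constraint languages.
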