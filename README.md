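# alnkit

Composable progressive multiple sequence alignment from interchangeable
components.

`alnkit` re-casts the classic ClustalW-style pipeline — pairwise dynamic
programming, distance matrix, guide-tree clustering, tree-guided progressive
alignment — as a set of pluggable components assembled under explicit
feature-model constraints. It is aimed at people who want to study or teach
how the stages of progressive alignment interact: every stage (the pairwise
aligner, the distance measure, the clustering algorithm, the objective
function, the output writer) is a named, independently selectable component,
and a configuration is checked against selection-cardinality and dependency
constraints *before* anything runs.

## The method

Given unaligned sequences `S₁ … Sₙ` over a DNA or protein alphabet:

1. **Pairwise alignment.** Every pair is aligned globally by dynamic
   programming — Needleman–Wunsch for linear gap costs, the three-state
   Gotoh recurrence for affine costs (a gap run of length *L* costs
   `open + extend·(L−1)`; end gaps are penalized like internal ones).
2. **Distance matrix.** Each aligned pair is reduced to a percent-divergence
   distance `d = 1 − (identical columns)/(gap-free columns)`, giving a
   symmetric matrix `D ∈ [0,1]ⁿˣⁿ`.
3. **Guide tree.** `D` is clustered into a rooted binary tree, either by
   UPGMA (size-weighted average linkage, ultrametric output) or by
   Saitou–Nei neighbor joining, which minimizes
   `Q(i,j) = (n−2)·d(i,j) − Σₖ d(i,k) − Σₖ d(j,k)` and is exact on additive
   matrices; the NJ tree is midpoint-rooted.
4. **Progressive alignment.** Leaves become one-row profiles; each internal
   node merges its children by a global DP over profile columns, scoring a
   column pair as the mean substitution score over all residue/residue
   cross-pairs. Gaps, once inserted, are never removed ("once a gap, always
   a gap"), so every intermediate profile stays recoverable from the final
   alignment.
5. **Objective.** The finished alignment is scored with the Carrillo–Lipman
   sum-of-pairs objective (`Σ` over columns and row pairs of substitution /
   gap-open / 0 for gap-gap) or with mean pairwise percent identity.

A synthetic-family generator (`alnkit.simulate`) evolves a root sequence
down a random tree with substitutions and geometric-length indels while
recording site homology, so the true alignment and true topology are known
exactly — that is what the test suite uses for ground truth.

## Worked example

```bash
cat > cfg.yaml <<'YAML'
components: [seq.validate, pairwise.global-linear, distance.identity,
             tree.nj, msa.progressive, objective.sp, out.fasta, out.clustal]
alphabet: dna
YAML

cat > in4.fasta <<'FASTA'
>s1
ACGTACGTAACGGCTA
>s2
ACGTACGAAACGCTA
>s3
ACGAACGAAACGGCTA
>s4
ACTTACGTAACGGCTA
FASTA

alnkit run --config cfg.yaml --in in4.fasta --out demo
```

prints

```
objective sp = 67
guide tree: ((s2:0.005208,s3:0.061458):0.032292,(s1:0.000000,s4:0.062500):0.031250);
```

and writes `demo.aln.clustal`:

```
CLUSTAL-style multiple sequence alignment

s1  ACGTACGTAACGGCTA
s2  ACGTACGAAAC-GCTA
s3  ACGAACGAAACGGCTA
s4  ACTTACGTAACGGCTA
```

The sum-of-pairs value 67 is the total over all 6 row pairs and 16 columns
of +1 per match, −1 per mismatch and −2 per residue/gap pairing (the default
`simple-dna` preset); the guide tree is the midpoint-rooted NJ tree of the
pairwise percent-divergence matrix, and s2's deletion relative to the others
appears as the single gap column. `alnkit list-components` shows the full
catalogue, and `alnkit validate --config cfg.yaml` checks a selection
without running it — selecting, say, both `tree.nj` and `tree.upgma` is
rejected as a cardinality violation of the `clustering` group.

The same pipeline is available as a library:

```python
from alnkit import (PipelineConfig, DEFAULT_SELECTION, assemble,
                    default_registry, read_fasta, DNA)

pipe = assemble(PipelineConfig(selected=list(DEFAULT_SELECTION)),
                default_registry())
run = pipe.run(read_fasta("in4.fasta", DNA))
print(run.objective.value, run.alignment.n_columns)
```

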