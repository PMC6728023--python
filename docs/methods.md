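# Methods

This document defines every quantity the package computes, the default
parameters, and the numerical choices behind the implementation.

## 1. Sequence distances (`metadendro.seqdist`)

### Global alignment score

Two sequences are aligned globally (Needleman–Wunsch) with an affine gap
model: a gap of length `L` costs `open + L · extend`, with `open = 10` and
`extend = 0.5` by default.  Substitution scores come from:

- nucleotide sequences: the built-in `NUC` scheme, match +5 / mismatch −4;
- protein sequences: any matrix shipped with Biopython
  (`BLOSUM62` by default; `metadendro.seqdist.available_matrices()` lists them).

The score `S(a, b)` is computed by the three-state Gotoh recurrence (match
state and two gap states), vectorized per DP row with numpy.  The
gap-in-the-longer-row state, which naively has a within-row dependency, is
resolved with a prefix-maximum scan: for row `i`,

```
u[k]     = max(M[i][k], Ix[i][k]) − open + k · extend
Iy[i][j] = max(u[0..j−1]) − j · extend
```

which makes a 2000 × 2000 alignment take ~30 ms.  Correctness is pinned by
tests against exhaustive enumeration of all global alignments for short
sequences and against an independent reference aligner.

### P-distance

```
P(a, b) = 1 − S(a, b) / M(a, b),   M(a, b) = min(S(a, a), S(b, b))
```

`M` uses ungapped self-alignment scores (the sum of diagonal substitution
scores).  `P` is 0 for identical sequences and may exceed 1 for strongly
dissimilar ones, since `S` can be negative.  `M ≤ 0` is rejected as an error.

### Many-to-one gene family distances

When organisms carry multiple copies of a family, the organism-pair distance
is a best-match average: for each sequence in the smaller list, take the
minimum `P` against all sequences of the other organism, then average.
Iterating from the smaller list makes the result symmetric by construction.

The three gene-based organism matrices:

- **DRIBO** — `P` on the single ribosomal marker (`RIBO`), nucleotide scoring.
- **DENZS** — arithmetic mean of per-family best-match distances over all EC
  families shared by *every* organism in the set (the ribosomal marker is
  excluded from this set).
- **D1ENZ** — the same, but using one shared EC family chosen uniformly at
  random (seeded; the choice is made once per matrix).

## 2. Network distances (`metadendro.netdist`)

Each organism is an undirected graph of metabolites (nodes) and
reactions/transitions (edges); self-loops are not allowed.

### PageRank edge weights

The union graph over the organism set (union of node and edge sets) is
ranked with PageRank: damping 0.85, uniform teleport, dangling mass spread
uniformly, power iteration to an L1 tolerance of 1e−10 (cap 10 000
iterations).  An undirected edge is treated as two directed arcs.  The weight
of an edge is the mean PageRank of its two endpoints.

For an organism pair `(i, j)` the union-graph edge weights are summed into

- `α` — edges present only in `i`,
- `β` — edges present only in `j`,
- `γ` — edges present in both.

### The six network matrices

| Method  | Definition |
|---------|------------|
| `DS1`   | abs(n_i − n_j), node counts |
| `DS2`   | abs(e_i − e_j), edge counts |
| `DNET1` | (number of shared nodes) / γ |
| `DNET2` | α + β |
| `DNET3` | (α + β) / γ |
| `DNET4` | node analogue of DNET3: node weight = union-graph degree / (2 · number of union edges); sum over private nodes divided by sum over shared nodes |

Ratio methods can divide by zero (e.g. γ = 0 for edge-disjoint organisms).
An infinite entry is replaced by twice the largest finite off-diagonal entry
of the matrix, with a warning; a matrix with no finite off-diagonal entry is
an error.

## 3. Dendrogram construction (`metadendro.dendro`)

A distance matrix is reduced to a minimum spanning tree with Kruskal's
algorithm (ties broken by lexicographic label pair, making construction
deterministic), and the MST edges are agglomerated in accepted order:
processing edges by increasing weight and merging the clusters containing
their endpoints at a height equal to the edge weight reproduces
single-linkage clustering exactly (verified against an independent
hierarchical-clustering implementation in the tests).  Heights are then
divided by the maximum merge height so every dendrogram has height 1; an
all-zero matrix (identical organisms) has no meaningful dendrogram and is
rejected as degenerate.

Random baseline dendrograms (`DRAND`) are built by the same pipeline from
matrices with i.i.d. Uniform(0, 1) off-diagonal entries.

## 4. Tree comparison (`metadendro.treecmp`)

The Robinson–Foulds distance is the size of the symmetric difference of the
two trees' non-trivial bipartition sets.  Bipartitions are canonicalized as
the side not containing the lexicographically smallest leaf; sides of size
< 2 or > n − 2 are trivial and excluded.  The maximum possible distance
between two binary trees on `n` leaves is `2(n − 3)`.  The implementation is
duck-typed over any rooted tree object exposing `root` / `children` /
`label`, so method dendrograms and generating trees compare directly.

## 5. Ensemble protocol (`metadendro.ensemble`)

For each organism set: build the nine method dendrograms, score all
C(9, 2) = 36 pairs with Robinson–Foulds, and score each method against
`n_random = 100` random dendrograms (reported as the mean, one `DRAND` entry
per method).  Across sets, each pair's values are aggregated as mean ±
sample standard deviation (ddof = 1; a single set reports std 0 with a
warning).

Randomness is reproducible and structured: stream `(set_index, k)` is spawned
from the master seed via `numpy.random.SeedSequence` spawn keys, with methods
at `k = 0..8` and random dendrograms at `k = 1000 + replicate`.  Adding a
method or changing `n_random` therefore never changes any other stream.

## 6. Synthetic organism evolution (`metadendro.synth`)

The generator produces a complete study — sequences, networks, ensemble file
and the generating tree — from one seed.

**Tree.** A Yule pure-birth tree on `n_organisms` leaves: with `k` lineages
the waiting time to the next split is Exponential(k · birth_rate), giving an
expected root-to-tip depth of `Σ_{k=2..n} 1/(k · birth_rate)` (≈ 2.1 at the
defaults).  Optionally a lognormal relaxed clock scales each branch.

**Sequences.** Each organism carries one nucleotide ribosomal marker and a
subset of `n_enzyme_families` protein families with EC-style identifiers.
Along a branch of length `t`, each site mutates independently with
probability `1 − exp(−rate · t)`, the replacement drawn uniformly from the
full alphabet (so expected identity decays toward the 1/|alphabet|
background, 25% for nucleotides / 5% for proteins).  At the tips, each
non-universal family is present with `family_presence_prob`, and with
`multi_copy_prob` a second, further-diverged copy is added.  Family 1 is
always present in every organism so the shared-family distances are always
defined.

**Networks.** The root organism gets a preferential-attachment metabolite
graph (`ancestor_nodes` nodes, `ancestor_edges` edges).  Along a branch of
length `t`, each edge survives with probability `exp(−edge_loss_rate · t)`;
Poisson(`edge_gain_rate · t`) new edges are added, each attaching to a fresh
metabolite with `new_metabolite_prob` and otherwise joining two existing
nodes.  Nodes are never removed, which mirrors the weak heritability of
network size: node/edge counts drift as a random walk along the tree, so
closely related organisms have similar sizes.

**Defaults** (chosen a priori so that expected per-site substitutions per
root-to-tip path ≈ 0.1 and per-branch network turnover is a few dozen
events; they are study conditions, not tuned values):

| Parameter | Default | Meaning |
|-----------|---------|---------|
| `n_organisms` | 12 | leaves of the generating tree |
| `birth_rate` | 1.0 | Yule rate (1/time) |
| `ribo_length` | 500 nt | marker length |
| `ribo_subst_rate` | 0.05 /site/time | marker substitution rate |
| `n_enzyme_families` | 8 | protein families |
| `enzyme_length` | 200 aa | family sequence length |
| `enzyme_subst_rate` | 0.05 /site/time | protein substitution rate |
| `family_presence_prob` | 0.9 | tip retention of a family |
| `multi_copy_prob` | 0.1 | chance of a second copy at a tip |
| `duplicate_divergence` | 0.2 time | extra divergence of the second copy |
| `ancestor_nodes` / `ancestor_edges` | 60 / 90 | root network size |
| `edge_loss_rate` | 0.2 /edge/time | exponential edge survival |
| `edge_gain_rate` | 18.0 /time | Poisson edge gains per branch |
| `new_metabolite_prob` | 0.2 | gained edge attaches to a fresh node |

**Scope and limits.** The generator is deliberately minimal: no selection, no
rate heterogeneity across sites, no horizontal transfer, no correlated
gain/loss between sequence and network evolution.  It is meant to provide a
known ground truth for pipeline validation and method comparison at desk
scale (tens of organisms), not to be a realistic model of prokaryote genome
evolution.

## 7. Problem sizes and runtime

The package targets desk-scale studies: tens of organisms per set, sequences
up to a few thousand residues, networks up to a few thousand nodes.  At the
defaults, one full ensemble run (one 12-organism set, 9 methods, 100 random
baselines) takes a few seconds on one CPU; alignment cost dominates and
scales as (sequence length)² per pair and (set size)² pairs per matrix.
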