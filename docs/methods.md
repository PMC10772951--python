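# Methods

## Model and procedure

`cemig` treats motif discovery as signal amplification on two k-mer
graphs. The statistical primitive is per-k-mer enrichment: under a Markov
background of order 0–2 fitted to the input sequences themselves, the
count of k-mer t is modelled as Poisson with mean λ(t) given by the chain
product M₁·M₂·M₃⋯ scaled by the number of available positions, and
significance is the upper-tail probability P(t) = Pr[X ≥ n(t)]. The
Poisson assumption ignores the dependence between overlapping windows
(self-overlapping words such as homopolymers are over-dispersed relative
to Poisson), which is acceptable here because P-values are used for
*ranking* and tiering, not as calibrated error rates; the null-calibration
test shows the realised false-positive fraction at P < 0.05 stays near
0.05 on iid input.

Counting is double-stranded throughout: n(t) accumulates over forward
windows and reverse-complement windows, and the position total in λ(t) is
doubled to match. A binding site is strand-symmetric evidence, and the
de Bruijn edge weights are defined over both strands; using one strand for
the Poisson stage and two for the graph stage would half-weight
non-palindromic motifs inconsistently. A consequence is that n(t) always
equals n(revcomp t), so motifs are typically discovered in an arbitrary
strand orientation.

Tiers: k-mers ranked by −log₁₀P (ties lexicographic, for determinism)
split into K1 = top min(100, |K2|), K2 = top ⌈total/2⌉, K3 = rest. The
ceiling is used for odd counts. When fewer than 200 distinct k-mers exist
K1 shrinks to stay inside K2, since K1 seeds the clustering whose universe
is K2.

The Hamming graph joins K2 k-mers at distance exactly 1 (distance < 2
with distinct vertices forces 1), built by enumerating each k-mer's 3k
substitution neighbours — O(|K2|·k) instead of all-pairs. Edge weight
stores the distance (always 1) and the clustering objective uses its
inverse, so a future larger distance cutoff would down-weight remote
pairs without code changes.

The cluster objective

f(C) = [−Σ_{adjacent u,v ∈ C} w(u,v)⁻¹ log(p(u)p(v))] / (|C|(|C|−1)) · log|C|

uses natural logs (base choice rescales f uniformly and cannot change an
argmax) and sums over *adjacent* member pairs only: w is defined on edges
of G, and non-adjacent pairs contribute nothing. p(u) is the k-mer's
Poisson P-value — the only per-vertex probability in the pipeline —
clipped below at the smallest positive normal double before logging. A
singleton's f is 0 (the log|C| factor vanishes; the 0/0 normalisation is
resolved by that limit). Growth from a seed: initialise with the seed and
its best pair of neighbours (all neighbours when fewer than two), then
alternate a single best improving addition of a boundary vertex with a
single best improving removal of a non-seed member, where removals must
keep the induced subgraph connected and seed-containing. Every accepted
move strictly increases f, so termination is guaranteed; ties break
lexicographically. Clusters from different seeds may overlap; overlaps
are resolved at digraph construction by assigning each k-mer to the
highest-f cluster claiming it (ties by seed).

Path extension on the cluster digraph starts at the uncovered vertex with
the highest f, and repeatedly takes the heavier of (best outgoing edge at
the downstream end, best incoming edge at the upstream end), skipping
candidates already on the path. Two caps are enforced jointly: at most 3
vertices added per direction, and at most 18 − k added edges in total, so
a spelled motif never exceeds 18 nt. The "3 in the same direction / 18−k
length" stopping rule is interpreted as a per-direction cap of 3 *and* a
global edge cap — the strictest reading that satisfies both phrasings.
Ties between directions go downstream; ties among edges go to the
lexicographically smallest target seed. Self-loops (within-cluster
de Bruijn edges) are recorded on the digraph but never traversed.

Occurrence collection for a path segment finds every window, on both
strands of every sequence, whose consecutive k-windows belong to the
corresponding clusters in order; minus-strand matches are reported in
forward coordinates. O1 covers the upstream sub-path and O2 the
downstream one, both including the start cluster (so their overlap is
generically non-empty). The intersection size |O1 ∩ O2| is defined as the
number of elements of the smaller set overlapping (same sequence, same
strand, intersecting intervals) at least one element of the other set —
occurrence tuples of different lengths cannot be intersected literally —
and the intersection motif is built from exactly those elements, which
keeps its word length uniform. Refinement thresholds are r > ½ (one
motif, whole path), ¼ < r ≤ ½ (three motifs) and r ≤ ¼ (two motifs), with
boundary values falling per the inequality signs; an empty O1 or O2 gives
r = 0. A branch whose occurrence set is empty yields no motif rather than
an empty one.

PWMs use per-column counts with a pseudocount (default 0.25) and consensus
by per-column argmax (ties A < C < G < T). The BED score column carries the
motif's mean per-column information content in bits.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 6 | word length for scoring and graphs (nt) |
| markov_order | 2 | background order; 0 and 1 collapse the chain factors |
| background pseudocount | 0.5 | added per cell of M₁/M₂/M₃; keeps λ > 0 for unseen contexts |
| top_k1 | 100 | seed-tier size |
| max_len | 18 | maximum spelled motif length (nt); path edge cap is max_len − k |
| PWM pseudocount | 0.25 | per-cell count smoothing |

## Synthetic data

`PlantSpec`/`generate_planted_dataset` emulate a motif-bearing
open-chromatin set: background drawn from a Markov process (uniform by
default), one mutated consensus instance implanted into a
Bernoulli(instance_rate) subset of sequences at a uniform offset and
strand, overwriting background bases. Defaults (500 sequences × 100 nt,
instance rate 0.3, per-position mutation rate 0.1, 8-nt consensus) are
chosen as a realistic desk-scale footprint set: a few hundred footprints
of roughly footprint length, a minority of which carry any one TF's site,
with site degeneracy near what position weight matrices typically show.
What the generator does *not* emulate: Tn5 insertion bias, footprint
shape, composition heterogeneity across loci, multiple instances per
sequence (configurable off by default), or correlated co-occurring
motifs. Passing the planted-recovery tests therefore demonstrates the
machinery is correct and sensitive at realistic signal strength, not that
performance numbers transfer to real chromatin.

Sequence-level evaluation labels a sequence positive when it received an
implant; the score is the best log-odds PWM match over both strands
against M₁, the classifier thresholds that score, and the threshold is
chosen to maximise accuracy on a calibration half of the data, evaluated
on the held-out half. The motif used for scoring is the method's
top-ranked prediction: the best-supported refinement of the first
(highest-f) path. AUPRC uses interpolation-free step summation, the
appropriate choice under class imbalance.

## Numerical choices

- P-values from the Poisson survival function (regularised incomplete
  gamma), clipped to [2.2e-308, 1] before logs.
- f(C) evaluated incrementally (edge-sum updates per added/removed
  vertex); exact ties in hill-climbing broken lexicographically, making
  the whole pipeline deterministic — identical inputs give byte-identical
  MEME/BED outputs with no seed involved.
- k-mers containing N contribute no windows anywhere (counts, graphs,
  occurrences); sequences shorter than k contribute zero positions.
- Degenerate inputs: empty FASTA, empty K2, seeds with < 2 neighbours,
  single-class evaluation inputs each fail fast or degrade as documented
  in the docstrings.

## Problem sizes in the test suite

Unit and property tests run on small random instances (graphs ≤ 2000
vertices, sequence sets ≤ 2000 × 200 nt); the end-to-end tests use the
default 500 × 100 nt planted dataset. These sizes make the full suite and
the acceptance script each complete in well under a minute while leaving
every code path exercised at realistic scale for a desk-scale footprint
set.

## Known limitations

- The Poisson model's overlap-dependence approximation (above).
- Greedy independent set and greedy path extension are heuristics; no
  optimality is claimed beyond one-move local optimality of clusters.
- Motif strand orientation is arbitrary; consumers should compare motifs
  up to reverse complement.
- Site-level precision is low on sparse planted data by construction:
  every path over covered clusters is reported, including background-only
  clusters, mirroring the permissive reporting of the underlying
  procedure. Rank (path order) is the intended filter.
- Backgrounds above order 2 and external-genome backgrounds are out of
  scope.
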