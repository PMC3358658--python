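# Methods

## Graph model

The double-stranded nature of cDNA is modelled with a bidirected De
Bruijn multigraph. A node *N* stores a forward sequence *F(N)* and its
reverse complement *R(N)*; node identity is the canonical k-mer
(lexicographic minimum of the k-mer and its reverse complement), which
makes graph construction deterministic. An arc from *N₁* to *N₂*
labelled *XY* exists when the (k−1)-suffix of side *X* of *N₁* equals
the (k−1)-prefix of side *Y* of *N₂*; the mirror arc (label FF↔RR
swapped, FR/RF fixed) always coexists, so arcs come in pairs. The one
exception is a "hairpin" self-arc whose (k−1)-overlap is its own
reverse complement; such an arc is its own mirror and is stored once.
**k must be odd** so no k-mer equals its own reverse complement.

Compression follows the unitig rule: an arc (u, v, XY) is contracted
when side X of u has out-degree 1 and side Y of v has in-degree 1. This
is the rigorous form of "merge adjacent simple nodes": the naive
neighbour-count rule is ambiguous in a multigraph with parallel arcs
and can corrupt spelled sequences. Compression preserves the spelled
sequence of every valid path, is idempotent, and a run of *i* k-mers
becomes one node of length k+(i−1). A compressed node's per-experiment
coverage is the arithmetic mean of its constituent k-mers' counts
(rounded to 2 decimals); the mean (rather than min or a vector) was an
open choice, made for robustness to length differences between merged
runs.

## k-mer counting

Occurrences are counted under the canonical form, per experiment;
k-mers containing non-ACGT characters and reads shorter than k are
skipped (with a logged warning). The minimal k-mer coverage filter
(mkC) removes k-mers whose count *summed over experiments* falls below
the threshold — discarding singletons (mkC = 2) removes most
sequencing-error k-mers at the price of sensitivity on weakly expressed
transcripts. Per-experiment filtering exists as an option but is off by
default, since a variant private to one condition would otherwise be
penalised.

## Biconnected components

Bubbles are simple cycles, and every simple cycle lies in exactly one
biconnected component of the undirected projection (mirror arc pairs
collapse to one undirected edge; parallel edges with different strand
labels stay distinct; self-loops are excluded since a bubble needs at
least three distinct nodes). The decomposition uses Tarjan's lowpoint
algorithm with an explicit stack — recursion depth on chain-like graphs
would otherwise be unbounded — and tracks the parent *edge* rather than
the parent node, so a doubled edge is correctly seen as a two-node
cycle and not a bridge. Components with a single edge (bridges) are
discarded; the rest are materialised as induced bidirected subgraphs.

## Four-node compression

Single substitutions (true SNPs and sequencing errors) each add a
four-node bubble: two anchors plus two non-branching internal nodes of
equal length at Hamming distance exactly 1 (N, introduced by earlier
merges, matches anything). Left alone, these multiply the cycle count
combinatorially. Each such bubble is reported as a SNP candidate and
its internal nodes are merged into one consensus node with `N` at the
substituted position. After every squash the component is
unitig-recompressed: collapsing one bubble can turn an overlapping
neighbour into a clean four-node bubble, so dense error tangles unravel
as a cascade. Bubbles whose arms differ at more than one position are
deliberately left to the general enumerator.

## Bubble enumeration

The enumerator returns exactly the simple cycles with ≥ 3 distinct
nodes, exactly two switching nodes, and a shorter internal path of at
most `max_shorter_path` nt (default 2k−2, the upper bound for the
junction path of an AS event). Internal path length is the number of nt
spelled by the internal nodes with (k−1)-overlaps removed; a path whose
two anchors are directly adjacent has length 0. Bubble identity — used
to report each bubble once regardless of traversal direction or start —
is the pair of switching-node ids plus the sorted pair of internal
node-id tuples.

The search is a backtracking (Tiernan-style) cycle enumeration. In its
pruned form each cycle is sought from its minimal *switching* node,
which licenses three cuts, all lossless:

1. the open path may contain at most one switching node (closure at the
   start supplies the second), and that node's id must exceed the
   start's;
2. the first-traversed arm is bounded by `max_shorter_path` — every
   bubble is discovered with its shorter arm first;
3. a state (node, strand) from which no valid continuation can reach an
   arc closing the cycle at the start with a strand switch is dead;
   these reachability sets are computed per start by BFS over the
   2·|V| (node, strand) states, ignoring node-disjointness, hence an
   over-approximation that never removes a true completion.

Neighbours are explored in order of decreasing node coverage
(deterministic tie-break on id), so if the per-component cap on
explored states (`max_cycles_per_bcc`, default 100 000) aborts a
pathological component — approximate tandem repeats can hold
exponentially many cycles — the well-supported bubbles have already
been emitted; aborted components are flagged, not errors. The unpruned
mode (plain enumeration from the minimal node, filtering on closure) is
kept for verification: pruned and unpruned results are asserted equal,
and both equal a brute-force simple-cycle oracle, on hundreds of random
multigraphs in the test suite.

## Classification

The cascade is: (1) both paths exactly 2k−1 nt at Hamming distance 1 →
SNP (a safety net; most substitutions are consumed by four-node
compression); (2) the whole shorter path matches one *end window* of
the longer path with ungapped identity ≥ 0.8 → REPEAT; (3) length
difference strictly below 3 nt → INDEL; (4) otherwise AS. The repeat
test runs before the indel test because a repeat signature is the more
specific evidence.

Two boundaries here are heuristics, and both thresholds are exposed as
parameters. The 3-nt indel bound reflects the empirical length split
between transcribed genomic indels and AS events; events ≥ 3 nt may
still be indels, and the classifier does not pretend to resolve them.
The repeat identity is deliberately *ungapped*: a gapped (edit
distance) identity would score any small insertion bubble at
1 − 2d/(2k−2) against an end window — above any reasonable threshold
for d ≤ 4 — and mislabel every short indel and short AS event as a
repeat. The ungapped comparison only scores high when the window
really is a (near-)copy of the shorter path, which is the tandem-repeat
signature; on the classic k = 5 toy examples it scores the repeat
bubble at 0.875 and the exon-skip bubble at 0.75.

## Quantification

Each path is mapped as the internal sequence flanked by up to k−1 nt of
anchor context, so junction-spanning reads anchor correctly. Mapping is
ungapped, both orientations, seeded by exact shared k-mers (a shared
read index is built once per run), with at most 2 substitutions over
the overlap by default; overlaps shorter than k nt are discarded,
matching the graph's own resolution. A read placement found through any
seed covers every overlapped position once. Because a path position
containing a consensus `N` cannot seed, reads crossing it anchor
through neighbouring k-mers; reads shorter than about 2k around an `N`
may be missed there.

Read coherence — every position of both paths covered by ≥ 1 read — is
evaluated on raw counts pooled across experiments; per-experiment
coherence is reported but does not discard, since a condition-specific
isoform is expected to be uncovered in the other condition. Discarded
bubbles are logged with their uncovered positions.

The sub-k overlap rule biases the k−1 terminal positions down by
(L−i)/L, with L the read length and i the distance to the first
unbiased position; corrected coverage multiplies those positions by
L/(L−i) (factor 1 at i = 0, L/(L−k+1) at the outermost position). Mean
path coverage averages the corrected counts over the internal sequence
(over the whole mapped window when the internal sequence is empty). L
is taken as each experiment's mean read length; when L ≤ k−1 the factor
is undefined and correction is skipped with a warning.

## Synthetic data

The generator plants one polymorphism between transcripts *a·s′·b* /
*a·b* (substitution: *a·x·b* / *a·y·b*; tandem repeat: *s′* is an
inexact copy of the tail of *a*). Flanks and insert are uniform random
DNA, rejection-sampled so that no canonical 15-mer recurs within a
transcript and no junction-spanning 15-mer of one form occurs in the
other — sufficient for a single clean bubble at any k ≥ 16. For
insertion-type events the first/last base of *s′* is forced distinct
from the adjacent flank base, pinning the shorter path to exactly 2k−2
nt. Defaults: 350-nt flanks, 200-nt insert, 75-bp single-end reads, 1%
substitution errors, 3 replicates.

Reads per transcript number ⌈coverage·length/L⌉ with uniform start
positions (Poisson-like depth fluctuation), uniform strand, and i.i.d.
substitution errors. This emulates heterogeneous coverage but not real
error-profile structure: no position-dependent error rates, no indel
errors, no quality strings, no library-preparation biases, and only a
flat per-base substitution probability. Detection thresholds measured
on this generator therefore bound what matters mechanistically (k-mer
dropout at low or uneven coverage) but do not transfer verbatim to any
particular sequencing chemistry.

The sensitivity sweep reuses one transcript pair across a
coverage × k × replicate grid, drawing reads per (coverage, replicate)
cell with seeds spawned deterministically from the base seed, and
counts a recovery when a kept AS call reproduces the planted internal
path sequences on either strand (`N` wildcarded). False positives are
AS calls not matching the truth; at mkC = 1 with dense errors these
include genuine "detour" bubbles whose long arm routes through an
error branch — they are read-coherent (the erroneous read covers the
detour) and are honestly reported, which is the practical argument for
mkC = 2.

At the protocol's scale (3 replicates per coverage) a per-coverage
detection fraction carries Monte-Carlo noise of about one part in
three, so single-point dips are expected; the test suite asserts
monotonicity of the detection fraction pooled over coverage bands
(6–9 replicates per band) and recovery thresholds at the protocol's
printed coverages. The recovered thresholds vary by ±2 fold across
seeds — the failure mode at the boundary is always a handful of path
k-mers absent from the filtered table.

## Numerical and degenerate-input choices

- k even, or k < 3, is rejected (palindromic k-mers would be their own
  reverse complement); reads shorter than k are skipped with a warning;
  a k exceeding every read length yields an empty table and an empty
  result, not an error.
- Two-node cycles through parallel edges are never reported as bubbles
  (the definition requires three distinct nodes).
- All iteration orders (node ids, arc sort keys, candidate scanning)
  are fixed, so identical inputs and seeds give byte-identical outputs.
- Coverage ties in the search order break on node id, then label.

## Known limitations

- Repeat-heavy components can exceed the cycle cap; the cap trades
  completeness inside such components for bounded runtime, and the
  abort is reported. Raising k breaks such components apart at the cost
  of sensitivity.
- In-memory k-mer counting only; datasets of hundreds of millions of
  reads need an external counter in front.
- The classifier's AS bucket knowingly contains genomic indels ≥ 3 nt;
  no splice-site motif or reading-frame evidence is consulted.
- Transcription-level variation (alternative start/polyadenylation)
  produces no bubble and is invisible to this model.
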