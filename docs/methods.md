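# Methods

This note documents the models, rules, and numerical choices behind
probegrid, stage by stage, including the points where the design was
genuinely open and the choice made here.

## Sequence model and IUPAC algebra

Sequences are strings over the 15 IUPAC nucleotide codes plus the gap
character `-` (`.` is accepted on input and converted). Input is
normalized at read time: uppercased, RNA `U` mapped to `T`. The
*degeneracy* of a gap-free string is the product of per-position base-set
sizes; it equals the number of distinct plain-ACGT expansions, and
`expand()` is guarded by a configurable cap (default 2000, matching the
default MaxDeg) to bound memory.

## Curation

A sequence is kept when, in order: its length is strictly greater than
`min_length` (default 1,200) and strictly smaller than the kingdom
maximum (1,600 prokaryote / 1,800 fungi); it carries a taxon label; its
fraction of non-ACGT characters is strictly below 1%; and its longest
run of non-ACGT characters is at most 5. The first failing rule is
reported, making the per-sequence disposition deterministic and
auditable. Bounds are deliberately strict inequalities; the run bound is
inclusive.

**Orientation.** Each kept sequence is compared against a trusted
same-kingdom reference by best local-alignment score, forward versus
reverse complement; the better-scoring orientation wins (ties keep the
input orientation). The reference is a required input — there is no
universally correct default, and the choice (e.g. a well-curated type
strain 16S) is the user's.

**Dereplication.** 100% identity with coverage required on only one
sequence of a pair reduces to exact substring containment, so
dereplication removes every member that is identical to, or an exact
substring of, another member. The longer sequence survives; among exact
duplicates, the earlier input position survives. The result provably
contains no substring pair and the operation is idempotent.

**Homogeneity screening.** Members are embedded as rows of the pairwise
distance matrix computed from the group alignment (distance = 1 −
fraction of identical columns among columns where neither row has a
gap; 1 when no such column exists). 2-means clustering with
deterministic farthest-pair initialization (scikit-learn, fixed seed,
≤ 100 iterations) proposes a split; the larger cluster is retained
(size ties: the cluster containing the earliest input member). To avoid
splitting genuinely homogeneous groups, the split is accepted only when
the RMS separation between the two cluster centroids — in units of
sequence distance — reaches a margin of 0.10. Both k and the margin are
configurable. This never removes more than half a group.

## Alignment

The pairwise core is standard dynamic programming with match +1,
mismatch −1, linear gap −2 and fixed tie-breaking (diagonal, then up,
then left), in global and local modes. Rows of the DP matrix are filled
with vectorized numpy recurrences (the within-row dependency is a
running maximum); the traceback compares move candidates with a 1e-9
tolerance because the vectorized recurrence carries ~1e-12 rounding on
fractional profile scores.

Groups of ≤ 100 sequences (configurable; "large" is not a sharply
defined notion) are aligned progressively: single-linkage guide order on
pairwise global identity, profiles merged by profile-profile DP over
expected column match/mismatch scores, gap columns penalized linearly.
Larger groups use three steps: single-linkage subgroup clustering at
98% identity over 98% coverage of the shorter sequence, progressive
alignment per subgroup, then iterative profile-profile merging of the
subgroup alignments. Merging only inserts gap columns, so every input
alignment's column order is preserved, and stripping gaps from any row
always reproduces its input sequence byte-for-byte — the invariant every
alignment operation is tested against. An adapter hook accepts an
external aligner (any command producing aligned FASTA); downstream
stages are agnostic to the alignment's origin.

## Consensus and probe enumeration

For each alignment column with m rows, let U be the number of *unknown*
characters. If U < m/2 (strictly), the consensus receives the IUPAC code
of the set of observed specific bases, and the unknown characters in
that column are corrected to that code — the consensus simultaneously
summarizes the group and repairs likely sequencing errors. Otherwise the
consensus receives a gap and the column is untouched; at exactly half,
the gap branch applies. By default "unknown" is any non-ACGT character,
the same convention the quality filters use; a strict mode restricts it
to N and gap, in which case other ambiguity codes count as observed and
contribute their base sets.

Candidate probes are all windows of length l (default 25) along the
consensus that contain no gap and have degeneracy ≤ MaxDeg (default
2000). Probe coordinates are 1-based on the consensus *including* gap
columns, so positions are stable identifiers. Each probe's weight equals
its degeneracy — the simplest cost model consistent with screening cost
being proportional to the number of expansions, and the quantity whose
per-job totals the load statistics summarize. An expansion is *known*
when it occurs as an exact forward-strand substring of a group member
and *explorative* otherwise; explorative status is judged against the
probe's own group (the database-side view is covered separately by the
screening stage, which records target-taxon hits for auditing).

## Specificity screening

The hit model is ungapped: a probe expansion cross-hybridizes with a
window of a non-target sequence when their Hamming similarity is ≥ S
(default 0.88, inclusive: 22/25 matches qualifies). Both strands are
screened. 25-mer probe/target duplexes are conventionally scored by
mismatches, and the report accordingly carries per-hit 1-based mismatch
positions on the probe; gapped hits, melting temperature, and free
energy are out of scope.

The search is seed-and-extend over a k-mer index of the database's
forward strands, with seed length w = min(7, ⌊l/(k+1)⌋) for k allowed
mismatches (k = l − ⌈S·l⌉). Tiling the query with ⌊l/w⌋ ≥ k+1 disjoint
seeds guarantees by pigeonhole that any window within k mismatches
shares an exact seed, so the search is *complete*; every candidate is
then verified by direct mismatch counting, so it is also *exact* — the
test suite asserts equality with a brute-force all-window scan on
randomized databases. Cross-hybridizations are counted as one per
(expansion, subject, position, strand) tuple and summed over all
expansions of a degenerate probe — the strictest consistent unit — and
the probe is rejected when the total exceeds MaxXH (default 100).

## Partitioning and execution

Probes are sorted descending by weight (ties: input order) and assigned
worst-fit: each probe goes to the job with the greatest remaining
capacity relative to the mean load, equivalently the currently lightest
job (ties: lowest index). Since no job may reject a probe, worst-fit
with equal-capacity bins is exactly lightest-bin assignment. The classic
greedy bound follows: max load − min load never exceeds the largest
single weight, so with unit weights job sizes differ by at most one
probe and the sample standard deviation of loads is 0 or 1/√N.

Load statistics use the sample (n−1) standard deviation — the only
convention consistent with the published per-job load tables this
package's acceptance checks recompute.

Jobs run on a local process pool (or serially for max_workers = 1). A
worker must be a pure function of its job's probe list; failed jobs are
retried up to max_retries (so attempts ≤ max_retries + 1), and a job
exhausting its retries aborts the run with a manifest of per-job states.
Merged results are sorted by (taxon, probe start, sequence), which makes
the final tables byte-identical across job counts and schedules —
parallelization cannot change the science.

## Synthetic fixtures

The generator emulates genus-level SSU rRNA data: a random root
template; per-group templates at 20% divergence from the root
(inter-genus distance); members at 2% within-group divergence
(intra-genus); sparse single-N ambiguity injections (rate 0.001, count
capped well below the 1% quality bound); and per group one planted exact
duplicate, one reverse-complemented entry, one short fragment (half the
template), and one 30% divergent outlier, with the expected curation
disposition of every record recorded in a ground-truth manifest.
Defaults use 1,400-base templates — full-length 16S inside the default
curation bounds — and ten groups of ten members. Each group also
carries a 25-base *marker* subsequence kept mutation-free within the
group and re-randomized until it stays below the similarity threshold
against every window of every other group on both strands; probes over
the marker are therefore guaranteed cross-hybridization-free.

What the fixture does *not* emulate: real rRNA secondary-structure
conservation patterns (mutations are i.i.d.), chimeras, indel variation
within groups, and realistic taxon-abundance skew. Passing tests
therefore demonstrate correctness of the algorithms under controlled
variation, not probe quality on real communities.

## Problem sizes in the test suite

The unit and acceptance tests run the pipeline at reduced scale — ten
groups of 500-base templates for the curation ground-truth check, three
groups of 600-base templates for the end-to-end runs, with curation
length bounds scaled alongside — keeping the full suite under a minute
while exercising every stage at full algorithmic fidelity. The package
itself has no scale assumptions beyond memory: the DP aligner is
O(n·m) per pair, and screening cost is linear in database size times
total probe degeneracy.

## Known limitations

- The built-in progressive aligner is intentionally simple (linear gap
  penalties, no iterative refinement); for publication-grade alignments
  substitute an external aligner via the adapter hook.
- The guide-tree stage computes all pairwise identities, so aligning a
  subgroup of n sequences costs n²/2 pairwise DPs; the subgroup
  clustering of the three-step strategy is what keeps this tractable
  for large groups.
- Orientation relies on a user-supplied reference; strongly divergent
  sequences (< ~55% identity to the reference) may orient ambiguously —
  such sequences are typically removed later by the homogeneity screen.
- Cross-hybridization screening is exact for the Hamming hit model but
  deliberately blind to gapped near-matches.
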