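# Methods

This note documents the models and procedures implemented in densfam, the
parameters that matter, the numerical choices made where the design was
genuinely open, what the synthetic benchmark does and does not emulate,
and the known limitations.

## Input model

The unit of analysis is a local pairwise alignment
`B_i = (q_i, s_i, Q_i, S_i)` with an E-value: a query sequence id, a
search (database) sequence id, and the two aligned envelopes as 1-based
inclusive intervals, exactly as in 12-column BLAST tabular output. Gap
structure inside an alignment is deliberately ignored; only the envelopes
enter the distances. Alignments with E-value `>= 0.1` are discarded at
read time (strict inequality), and reverse-strand coordinate pairs are
normalised to `start <= end`. Self-hits are kept unless the caller asks
otherwise; they simply add density to a query's own region.

Before clustering, alignments of one query to the *same* search sequence
whose query regions lie within `mu1` of each other are collapsed to the
lowest-E-value one. Resolution is greedy in ascending E-value with ties
broken by input order, so a chain of mutually overlapping duplicates
resolves deterministically: each retained alignment suppresses all
same-search-sequence alignments within `mu1` of it.

## Interval-overlap distance

All clustering rests on `d(a, b) = 1 − |a ∩ b| / |a ∪ b|` between two
intervals on the same sequence, with `|.|` counting residues
(`end − start + 1`). The union counts residues inside either interval and
never the gap between them; with the gap included, two flanking intervals
could be "closer" than their overlap warrants and the triangle inequality
would fail. As implemented the distance is a metric: 0 iff the intervals
are identical, 1 iff disjoint, symmetric, triangle inequality verified by
property test on random triples.

## Round 1: density peaks over one query's alignments

For each query, `rho_i` counts the alignments (self included, so
`rho >= 1`) within `mu1` of `B_i`; `delta_i` is the distance to the
nearest *denser* alignment and `gamma_i = rho_i * delta_i`. Because
densities are integer counts, exact ties are pervasive, and tie handling
is where a naive implementation goes wrong: if `delta` considered only
strictly denser points, every member of a plateau of co-located
equal-density alignments would take `delta = 1` and surface as a peak.
We therefore break density ties by input order — point *i* measures its
`delta` against points of strictly higher density and against earlier
points of equal density. Exactly one point (the lowest-index global
density maximum) has no reference point and takes `delta = 1`, the
distance maximum; using the metric's upper bound rather than the largest
observed distance keeps `gamma` comparable across queries.

Peaks are selected from the `gamma`-sorted list (ties ranked by input
order; zero entries dropped — they are co-located shadows of denser
points and can never be peaks). The scan looks for the largest 1-based
index `g <= g_max` with `gamma_{g−1}/gamma_g >= 10^delta_exp` and no
qualifying ratio after it; the `g − 1` entries above the gap are the
peaks. Two degenerate cases are resolved as follows:

* a single positive `gamma` (every alignment co-located): the gap to the
  dropped zero entries is effectively infinite, so that entry is the one
  peak;
* a qualifying gap existing only beyond `g_max`: no valid split exists
  and the query is skipped (it contributes no primary clusters). This is
  logged, not an error.

Each remaining alignment joins its nearest peak when closer than `mu1`
(ties to the higher-`gamma` peak) and is discarded otherwise; a peak
always belongs to its own cluster, even if another peak sits at distance
zero.

Defaults: `mu1 = 0.2` (neighbourhoods of roughly 1–2% of a typical
query's alignments), `delta_exp = 0.5` (a gap of half an order of
magnitude), `g_max = 20` peaks per query. We read the bound `g <= g_max`
as a constraint on the gap index, which allows at most `g_max − 1` peaks
through the scan; the extra cap at `g_max` peaks is therefore never
binding but kept for clarity.

## Round 2: density peaks over primary clusters

The cross-query distance `D(c, c0) = 1 − M / min(N_c, N_c0)` counts
matched alignment pairs with equal search sequence and search-region
distance `< mu_d`. The literal double sum over qualifying pairs can
exceed `min(N_c, N_c0)` when several regions of one cluster overlap one
region of the other, driving the "distance" negative; we instead count a
maximum one-to-one matching of qualifying pairs, which preserves the
intended meaning (shared support between the two clusters) and keeps `D`
in [0, 1]. Because qualifying pairs never span two search sequences, the
matching decomposes per search sequence, where it is solved exactly
(Hopcroft–Karp via `scipy.sparse.csgraph`); the all-pairs computation
uses an inverted search-sequence index and only falls back to explicit
matching on sequences where some cluster has several regions.

Densities count *other* clusters within `mu2` (self excluded): the peak
rule `rho_c > 1` reads "overlaps more than one other cluster", and
including self would let any pair of mutually close clusters qualify.
Deltas use the same tie-break as round 1. Peaks must satisfy
`delta_c = 1` — peaks may not overlap each other at all — and
`rho_c > 1`. Assignment mirrors round 1 with cutoff `mu2`; unassigned
primary clusters are discarded.

**Merging.** The metacluster distance is the mean of all cross-pair
primary-cluster distances. The alternative normalisation
`2/(N' N'')` times the sum equals twice that mean and can exceed 1; since
the quantity is meant to be "the average of the distances" we default to
the plain mean and expose the doubled variant behind the
`printed_merge_factor` flag. Pairs below the 0.9 threshold are merged
transitively (connected components), which is the only reading that
yields a well-defined partition for chains.

**Filtering and capping.** A member region survives iff another member
region of the same metacluster lies on the same search sequence within
`mu_d`; the relation is symmetric, so one pass suffices and every
retained region keeps a retained partner. The partner may come from any
other member, including one derived from the same query. When member
sequences are available, redundancy is reduced by a greedy longest-first
sweep dropping any region whose identity to a retained one reaches 95%
(identity = matched fraction of the shorter sequence in its best infix
alignment, computed with edlib; an external CD-HIT run can replace this
step). Metaclusters with fewer than 100 members are then dropped — a
density-based method cannot distinguish smaller groups from background —
and larger ones are subsampled uniformly to 5000 members. Seed sets for
profile-HMM construction are reduced at 60% identity and capped at 1000.
Subsampling draws from a per-metacluster stream seeded by
`(rng_seed, crc32(mc_id))`, so results are reproducible and independent
across metaclusters. MSA and profile-HMM construction themselves are out
of scope; the seed FASTA (headers `<seq_id>/<start>-<end>`) is the
interface to MUSCLE/HMMER.

## Evaluation against a reference classification

Reference annotations (family, clan, interval, E-value per sequence) are
first made non-overlapping: greedy by ascending E-value, an annotation is
kept iff it shares no residue with an already-kept one. Nesting is not
modelled; a nested domain loses to an enclosing annotation of lower
E-value, which is a known source of apparent inconsistency when member
regions span nested motifs.

The ground-truth architecture (GTA) of a region is the ordered list of
kept annotations overlapping it by at least one residue (family- or
clan-level labels; a clanless family uses its own id as clan). The
covered interval `P` runs from the first overlapping annotation's start
to the last one's end, including residues between them. The dominant
architecture (DA) of a metacluster is the modal GTA; empty GTAs take part
in the count but never win a tie against a nonempty architecture, and
ties among nonempty ones break lexicographically (determinism, nothing
more).

Member consistency is a cumulative ladder of percentages: `%DAF` (family
GTA equals family DA), `%DAC` (clan GTA equals clan DA; these are the "DA
members"), `%DACF` (adds proper order-preserving subsequences of the DA
clans, including wholly unannotated members — absent annotation does not
place a region outside a family), `%DACFA` (adds members carrying at
least one DA clan alongside at least one extra clan, in any order; DA
clans appearing out of order are tallied separately as
`order_violations`). The subsequence test matches repeats greedily left
to right. The ladder `%DAF <= %DAC <= %DACF <= %DACFA <= 100` holds by
construction and is property-tested.

Boundary agreement per DA member uses
`F_red = |P \ (S ∩ P)| / |P|` and `F_ext = |S \ (S ∩ P)| / |S|`; their
means over DA members place the metacluster in one of four categories at
the 0.2 thresholds: equivalent (both `< 0.2`), reduced (`F_ext < 0.2 <=
F_red`), extended (`F_red < 0.2 <= F_ext`), shifted (both `>= 0.2`).
Member-length statistics use the population standard deviation (the
reported SD summarises exactly the members at hand, not a sample of a
larger population). Low-complexity fractions are computed from
user-supplied masked intervals (e.g. segmasker output); no low-complexity
detector is implemented. Members beyond the 5000 cap are excluded from
report statistics.

Coverage curves rank metaclusters by decreasing marginal contribution: a
reference region counts as covered by a metacluster iff one of its
profile-HMM hits overlaps at least 75% (or exactly 100%) of its
residues, each region counting once however many metaclusters cover it.
Hits come from HMMER `--domtblout` files (parsed with Biopython,
envelope coordinates); full-sequence E-value < 0.01 and per-domain
independent E-value < 0.03 thresholds apply when present.

Robustness runs rerun the whole pipeline under ±10% perturbations of
`mu1`, `mu2` and `delta_exp` and compare assignments *before* member
filtering through three quantities: metaclustered alignment count,
percentage of the reference run's metaclustered alignments recovered,
and normalized mutual information `NMI = 2 I/(H1 + H2)` over the
commonly clustered alignments (scikit-learn, arithmetic normalisation;
NMI of two identical zero-entropy partitions is 1 by convention).

## The synthetic benchmark

The generator concatenates per-family domain instances and random
linkers into proteins, then emits the alignment table directly from the
planted coordinates: every ordered pair of same-family instances yields
an alignment with probability `detection_prob`, endpoints perturbed by
rounded Gaussian jitter and clipped to the protein; spurious alignments
between random unrelated regions arrive at `noise_alignment_rate` per
protein (Poisson) with near-threshold E-values. E-values are sampled,
not computed — the pipeline only thresholds and ranks them. Sequences
are per-family consensus strings with 10% point mutations, enough to
exercise identity-based redundancy reduction without an evolution model.
Optional features: C-terminal fragments (`fragment_fraction`),
above-threshold rows to exercise the reader's filter, and
architecture-spanning alignments (`join_prob`, default 0) that reproduce
the known tendency of alignment-based clustering to fuse domains that
co-occur.

Default conditions (the study benchmark): 3 families of 80–120 residues,
architectures `-A-` (40%), `-A-B-` (30%) and a third independent family
`-C-` (30%) so that all three families are populated while the
multi-domain case is present; 300 proteins; detection 0.9; jitter SD 3;
noise 0.1/protein; fragments 10%. At this scale (~50k alignments) the
full pipeline runs in a couple of seconds, and metacluster size filtering
uses `min_size = 20` in tests, scaled to the benchmark's family sizes.
The noise-free limit (detection 1, jitter 0, noise 0, fragments 0)
recovers the planted families with NMI exactly 1 over metaclustered
members.

What the benchmark does *not* emulate: realistic substitution or indel
processes, score-derived E-value statistics, repeats and nested domains,
low-complexity sequence, and alignments produced by actually aligning
the generated sequences. Alignment regions derive from the planted truth
precisely so that the planted family of every region is an exact oracle;
passing tests therefore demonstrate the correctness of the clustering
machinery under controlled noise, not performance on real proteomes.

Two consequences of the exact clean limit are worth knowing. First, in
a perfectly co-located alignment stack only one alignment has positive
`gamma`, which is why the lone-positive-`gamma` peak rule above exists.
Second, a query with architecture `-A-B-` has two `gamma` plateaus whose
ratio (the family abundance ratio) may stay below `10^0.5`; such queries
are then skipped, and family B enters the metaclusters through the
clusters of other queries. The planted-truth NMI is unaffected.

## Numerical and engineering choices

* Distances are plain float64; peak tests on `delta_c = 1` use a 1e-12
  tolerance. All other comparisons are exact.
* Determinism: identical inputs and `rng_seed` give byte-identical
  outputs; every tie in the pipeline (E-value ties, gamma ties, nearest
  peak ties, DA ties) is broken by input order or lexicographically.
* The all-pairs primary-cluster distance matrix is the computational
  bottleneck at scale; the inverted-index implementation is exactly
  equivalent to the pairwise definition (tested) and handles ~500
  clusters over ~50k alignments in about a second.
* Empty inputs are legal everywhere downstream of reading: an empty
  alignment table yields zero metaclusters and a valid manifest.

## Known limitations

* Domains that co-occur in a single architecture and are never observed
  apart cannot be split; the method clusters evolutionary modules, not
  structural domains.
* The `min_size` floor hides genuinely small families by design.
* Greedy identity reduction is order-dependent (longest first) and uses
  infix edit distance as an identity proxy; CD-HIT may prune slightly
  differently.
* The metacluster distance treats clusters as bags of alignments; two
  clusters sharing many search sequences via *different* regions of
  those sequences are correctly far apart, but partial-overlap chains
  can still bridge families through the transitive merge step.
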