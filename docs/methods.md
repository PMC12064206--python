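# Methods

## The analysis object

The unit of analysis is an undirected, weighted **activity network**:
nodes are leisure-activity items from a time-use diary instrument, and
an edge says the same people tend to do both activities on the same day
type. Four such networks are compared — {high-SWB, low-SWB} × {weekday,
weekend} — where the SWB strata are defined jointly on a 1–7 subjective
well-being item and a 1–5 health item, both scored so higher is worse:
high-SWB requires SWB ∈ [1,4] *and* health ∈ [1,2]; low-SWB requires
SWB ∈ [5,7] *and* health ∈ [3,5]. Mixed combinations (e.g. good SWB but
poor health) are excluded, which makes the strata disjoint by design and
matches the reported health-status tabulation splitting exactly along
this line.

## Projection

Each (group, day type) cell yields a persons × activities incidence
matrix; binary cells mark participation, weighted cells carry summed
minutes. Projection onto the activity mode uses cosine similarity
between person-indexed activity columns. Choices made here:

* **Mode.** The projection is onto activities. The procedure can be read
  as projecting onto persons ("similarity between individuals"), but
  every downstream result — centrality of activities, subgroups of
  activities, activity isolates — is about activity nodes, so the
  activity-mode reading is the default and the person-mode projection is
  available behind the same interface (`mode="person"`).
* **Threshold.** τ is a free parameter; no canonical value exists for
  this design, so the default is τ = 0.3 with a `tau-sweep` command for
  sensitivity reporting. Edges with similarity exactly 0 are never
  created, even at τ = 0; comparison is `≥ τ` (up to 1e-12 of float
  noise) so ties at the threshold are kept deterministically.
* **Participation floor.** Activities with fewer than 2 distinct
  participants are dropped before projection: a single-participant
  column carries no co-participation signal and would otherwise attach
  to every activity its one participant did.
* **Weights.** An edge's weight is its cosine similarity. Selecting
  `weighting="minutes"` feeds minute-weighted vectors into the same
  kernel rather than introducing a second weighting scheme.
* **Pruning.** An optional inactive-node filter (degree and centrality
  cut-offs, both must fail) exists but is **off by default**: the
  distribution indices report isolated nodes, so isolates must survive
  to metric time. The two requirements — prune inactive nodes, report
  isolates — genuinely conflict; making pruning explicit and opt-in
  resolves the conflict without guessing unreported cut-offs.

## Distribution indices

* density = 2E/(N(N−1)), presence/absence only;
* inclusiveness = (N − isolates)/N, with the exact identity
  inclusiveness ≡ 1 − isolates/N asserted in the tests;
* mean distance = average unweighted hop distance over unordered,
  **mutually reachable** pairs. The reported networks contain isolates
  yet print finite mean distances, so unreachable pairs must be excluded
  from the average; the reachable-pair count is reported alongside. A
  weighted-distance variant (1/weight lengths) was considered and
  rejected as non-default because no weighted-distance convention is
  defined for this design;
* isolated nodes = exact degree-0 census with labels.

Degree centrality is deg(v)/(N−1). Table output rounds to 2 d.p. *then*
ranks with competition ranking (min rank shared on ties, following ranks
skipped) — the tied printed rankings this mirrors operate on 2-d.p.
values, so ranking before rounding would split printed ties. `top_k`
keeps every row tied at the boundary rank, so ten activities sharing
rank 1 all appear in a top-10.

## Cohesive subgroups

The reference implementation for "cohesive structure" in the original
tooling is unnamed; the default here is greedy modularity maximisation
on edge weights, chosen because it is deterministic given the sorted
node order. A seeded Louvain-style detector and plain connected
components are pluggable alternatives, and the method label travels with
the result. Isolates become singleton groups flagged as isolates and do
not count toward `n_groups`; proper groups are numbered by descending
size, ties broken by lexicographically smallest member. Partition
agreement uses the adjusted Rand index. Exact subgroup counts depend on
the (unreported) threshold and algorithm, so only the fragmentation
*direction* — the low-SWB partition having at least as many groups — is
treated as a checkable claim.

## QAP correlation

Dyads are not independent, so significance uses the quadratic assignment
procedure: `r_observed` is the Pearson correlation of the vectorised
off-diagonal **upper triangles** (the matrices are symmetric; using both
triangles would double-count every dyad), and the null applies one
random node relabelling per iteration to the rows and columns of the
second matrix. One-matrix permutation is the standard choice.
Similarity-weighted matrices are correlated by default (binary optional).
Defaults: 1,000 permutations, two-sided, add-one p-value
(b+1)/(m+1) so a Monte-Carlo p can never be 0; for n ≤ ~8 an exhaustive
mode enumerates all n! permutations and returns the exact p instead.
Degenerate inputs (constant off-diagonal vector) raise a named error
rather than returning NaN.

## Synthetic diary generator

The generator emulates the *structure* of restricted national time-use
survey microdata: two groups of 241 adolescents aged 10–19, 49 leisure
items, one weekday and one weekend diary each, 10-minute-grid durations
(lognormal, mean 60 / sd 45 minutes), scores drawn uniformly within each
group's admissible score rectangle.

Participation is Bernoulli per (respondent, day type, activity):

* **high-SWB** — one homogeneous profile with tiered probabilities
  (core 0.80, regular 0.50, occasional 0.30, rare 0.15), scaled ×0.85 on
  weekdays and ×1.10 on weekends. Broad moderate probabilities make most
  cosine similarities clear τ = 0.3, giving a dense, inclusive network
  that densifies at the weekend.
* **low-SWB** — four universal activities (sleep 0.95, TV 0.45, video
  0.45, resting 0.40) plus four equally likely latent *interest
  segments* (screen / social / rest / outdoor), each boosting its
  six-activity block to 0.55 while everything else sits at 0.03;
  day-type shift ≈ 1. Independent marginals alone cannot fragment a
  network — under independence, cosine similarity depends only on the
  two marginals — so the segments are what create the blocky, fragmented
  low-SWB structure with many isolates and a near-identical
  weekday/weekend repertoire.

These profile values were fixed once, from the design reasoning above
(tier products relative to τ) and a Monte-Carlo check of the intended
direction across seeds, before being frozen as the package default. The
generator does **not** model: clock placement within the day (the
analysis consumes only co-participation, not sequence), survey
weighting, household structure, or any latent-trait model linking scores
to behaviour (scores are uniform within their group rectangle). Passing
tests therefore demonstrate that the pipeline recovers a *designed*
contrast of this shape — not that real diary data carries that contrast.

Diary days per day type is a parameter (`diary_days`, default 1);
multiple days aggregate to one row per (person, day type, activity) so
the downstream duplicate filter retains its meaning.

## Numerical and testing choices

* Cosine matrices are symmetrised ((S+Sᵀ)/2), clipped to [0,1], zero
  diagonal; symmetry and the brute-force double-loop oracle agree to
  1e-12 on small incidences.
* Raising τ on a fixed incidence can only remove edges, so density and
  inclusiveness are nonincreasing and isolates nondecreasing in τ; this
  monotonicity is property-tested on a τ grid.
* All graph metrics are checked against exhaustive-enumeration oracles
  (explicit pair loops, hand-rolled BFS) on 200 random graphs with
  n ≤ 8.
* The QAP Monte-Carlo null is checked against the fully enumerated
  4-node null, and its type-I error is calibrated over 500 pairs of
  independent G(12, 0.5) graphs with 999 permutations each — sizes
  chosen to keep the whole suite under a minute of QAP time while
  leaving the rejection-rate estimate's standard error near 0.01.
* End-to-end runs are deterministic given the seed: rerunning a fit
  writes byte-identical artefacts, verified via manifest checksums.

## Known limitations

* The cosine threshold τ and the minimum-participant floor are the two
  levers that most affect the indices; defaults are documented above and
  every result carries its provenance (group, day type, weighting, τ).
* Exact subgroup counts are algorithm-dependent; treat them as
  descriptive, not inferential.
* Mean distance on heavily fragmented networks averages over few pairs
  and is correspondingly noisy.
* The generator's independence-within-segment assumption understates the
  activity correlation structure of real diaries (e.g. travel items
  co-occurring with the activity travelled to).
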