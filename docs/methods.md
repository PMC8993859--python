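# Methods

## Estimators

**Match lengths.** All three entropy estimators rest on one primitive. For
a target sequence and an admissible reference history, Λᵢ = Lᵢ + 1, where
Lᵢ is the length of the longest contiguous subsequence starting at target
position *i* that occurs contiguously inside the reference; Lᵢ is capped
by the remaining suffix length, and Λ₁ = 1 when the reference is empty.
For the entropy rate the reference at position *i* is the target's own
prefix (positions 1..i−1). For the cross estimators the reference is the
prefix of the alter's sequence whose timestamps are *strictly* earlier
than the target event's timestamp — events at the identical instant are
not "previous". These conventions are fixed so that expected values in
tests are exact.

The production parser feeds the growing reference into an online suffix
automaton and walks each target suffix from the root, costing roughly
O(reference length + Σ Λᵢ) instead of quadratic time; sequences of 10⁵
events parse in well under a second. Correctness is defined by a
brute-force quadratic oracle kept in the test suite, with which the parser
agrees exactly on an exhaustive enumeration of short sequences (every
first-occurrence-canonical sequence of length ≤ 12 over ≤ 4 symbols —
sufficient because the parser compares symbols only for equality, which is
also property-tested) and on randomized longer inputs.

**Cumulative cross-entropy.** Over an alter set, Λᵢ is the maximum of the
per-alter values, and the reference length is the match-weighted mean
Σ w_B N_B / Σ w_B. The weight w_B counts target positions where alter *B*
yields a nonempty match (Λᵢ(A|B) > 1). The phrase "number of times matches
are found" admits a second reading — positions where *B* attains the set
maximum — which is implemented behind `weight_rule="argmax"`; the
any-match rule is the default because it is the simplest reading and
reduces exactly to the pairwise estimator for singleton sets either way.
If no alter matches anywhere, the reference falls back to the unweighted
mean length and the estimate is flagged rather than rejected. Including
the ego's own past is implemented by adding the ego's sequence to the
alter set under the same strict time constraint, with its weight counted
like any alter's.

**Fano inversion.** The bound Π solves S = H(Π) + (1−Π) log₂(n−1) on
[1/n, 1], where the right-hand side decreases strictly from log₂ n to 0,
so bisection is guaranteed to converge; it is run to an absolute tolerance
better than 1e−9 (round-trip residuals are below 1e−8). Corner cases:
n = 1 or S = 0 give Π = 1; S ≥ log₂ n — which the estimator can produce
on short sequences — is clipped to the random-guessing bound 1/n and
flagged instead of rejected. Cross-predictability inverts with the *ego's*
distinct-location count: the bound concerns guessing the ego's next
location among the ego's alternatives, not the alter's.

**Estimator bias.** On i.i.d. sequences the entropy-rate estimate
converges to the Shannon entropy, approaching it from below at the sample
sizes used here (about −0.09 bits at N = 10³ and −0.05 bits at 10⁵ for a
uniform 4-symbol source); the tests assert shrinking absolute error, not
a direction of approach.

## Networks

A colocation is a pair of events by different users at the same location
whose offset falls in the lag window [−T, −T+h] ∪ [T−h, T] hours
(half-width h = 1/2 by default; T = h gives the contiguous window
|Δt| ≤ 30 min, i.e. a sliding one-hour bin rather than calendar-hour
bucketing, because only the sliding form generalizes cleanly to displaced
windows). Every qualifying event pair counts once. This pair-counting rule
was chosen over "at most one colocation per ego event" because it is
exactly symmetric between the two users — for lagged windows as well,
since the interval union is symmetric under negation — and monotone in the
half-width; both properties are tested.

Social alters are declared friends with logged trajectories (check-in
data) or users with at least 30 reciprocal calls (call records, counted
as 2·min(calls a→b, calls b→a), so 15 calls each way meet the threshold);
they are ranked by colocation frequency with the ego so "top social tie"
is well defined. Colocation networks exclude declared friends and, on
call-record data, any pair that ever exchanged a call. Equal weights are
broken lexicographically by alter id for reproducibility. The retention
filter keeps alters whose cross-entropy about the ego is strictly below
log₂ n_A — i.e., whose information beats random guessing among the ego's
locations. An optional hook (`drop_single_hotspot`, off by default)
removes alters whose colocations all occur at the ego's single
most-visited location; it is a synthetic stand-in for popularity-driven
spurious-colocator cleaning, and results in this package do not depend
on it.

Population analyses use egos with at least ten retained alters in both
flavors; lag sweeps additionally intersect eligibility across the whole
lag grid.

## Pipeline choices

Accumulation curves compute one time-constrained match profile per alter
and reuse it as the top-k set grows, so a k_max = 10 curve costs ten
parses. Saturation extrapolation fits Π(k) = Π∞ − (Π∞ − Π(1))·e^{−(k−1)/κ}
with Π(1) pinned to the first point, initialized at Π∞ = max + 0.05 and
κ = 3; an exponential-saturation form was fixed (the fitted form is
recorded in the output) as the standard choice with the right limiting
behavior, and a constant curve short-circuits to its constant. Confidence
intervals over egos are nonparametric bootstrap (1000 resamples, seeded);
population curves aggregate by the mean. The per-ego flavor comparison is
a paired one-sided t-test across the k = 1..10 curve points, and the
monotonicity check is a Spearman rank correlation of Π against k on the
same points; fractions of significant egos are reported at raw p-value
thresholds without multiple-testing correction, matching how such
fractions are conventionally quoted. The overlap–predictability regression
is ordinary least squares with Pearson's R; in the bundled report it pools
(ego, k) pairs from both flavors because the planted populations drive
every ego's top-10 overlap near saturation, leaving no cross-ego spread
at fixed k.

## Synthetic data

The generator's defaults are the study conditions used by the acceptance
script: 12 egos with 400 events each at a mean spacing of 6 h (about 100
days of observation, comfortably above the 150-check-in activity filter),
a shared pool of 40 locations, an exploration/preferential-return ego
process (exploration probability 0.15, return proportional to visit
counts), 10 social alters per ego co-visiting at ρ_s = 0.6, 10 colocators
at ρ_c = 0.3, and 10 independent background users. Co-visits are jittered
by ±15 min so they fall inside the default window with certainty; lagged
co-visits are drawn uniformly inside [T−1/2, T] hours before or after the
ego's event. Non-shared alter visits go to a per-alter private pool
disjoint from every other user, so overlap and information are controlled
entirely by the co-visit rate. Ego start offsets are randomized so
distinct egos do not colocate systematically. Closed-form entropies exist
for the i.i.d. processes (log₂ n for uniform, the Shannon entropy of the
weights for Zipf) and anchor the calibration tests.

What the generator does *not* emulate: realistic geography (coordinates
are synthetic points in a ~100 km box), heavy-tailed visitation shared
across users, circadian and weekly rhythms, platform biases, or
under-sampled check-in behavior. Passing tests therefore demonstrate that
the estimators and pipeline recover planted structure under controlled
conditions — not that any particular empirical dataset will show effects
of a given size.

## Problem sizes

The bundled checks run at desk scale by design: estimator consistency
uses 20 replicates at N = 10⁴ plus 5 replicates at each of
N ∈ {10³, 10⁴, 10⁵}; oracle equivalence enumerates ~9.3 × 10⁵ canonical
sequences; parameter recovery uses 20 replicates per co-visit rate on a
five-point grid, populations of 4–6 egos for the curve checks, and 400
events per user throughout. The acceptance script's main study is the
default 262-user population (~10⁵ events).

## Known limitations

* The estimators are biased at small N; cross-entropies against short
  alter sequences are bounded by log₂ N_B and are clipped at the Fano
  stage rather than excluded.
* Reciprocal-call counting and the any-match weight rule are fixed
  readings of ambiguous conventions; both alternatives are available as
  switches.
* The spurious-colocator hook is a stand-in, not a validated cleaning
  rule.
* Lag sweeps rebuild the colocation network per lag; on large datasets
  this is the dominant cost and is linear in the number of grid points.
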