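# mobinfo

Entropy, predictability, and social information flow in human mobility
trajectories.

## The problem

A person's movement history constrains their future: knowing where someone
has been bounds how well *any* algorithm can guess where they go next.
Remarkably, much of that information also leaks sideways — into the
trajectories of their friends, and even into those of strangers who merely
visit the same places at similar times ("non-social colocators"). This
package implements the information-theoretic machinery to measure both
effects on check-in streams (location-based social-network exports or call
detail records): it is aimed at computational social scientists and
privacy researchers who want to quantify how much of an ego's mobility is
recoverable from other people's data.

## The estimators

For a trajectory *A* of *N* visits, the entropy rate is estimated
nonparametrically from match lengths:

    Ŝ_A = N log₂(N) / Σᵢ Λᵢ

where Λᵢ is one plus the length of the longest contiguous subsequence
starting at position *i* that already occurred before position *i*. The
cross-entropy of ego *A* given alter *B* replaces the reference by the part
of *B*'s sequence whose timestamps strictly precede the ego's visit:

    Ŝ_{A|B} = N_A log₂(N_B) / Σᵢ Λᵢ(A|B)

and the cumulative cross-entropy over an alter set 𝓑 takes the best match
per position, Λᵢ(A|𝓑) = max_B Λᵢ(A|B), with a match-weighted mean
reference length N_{A𝓑} = Σ w_B N_B / Σ w_B. Entropies convert to
predictability upper bounds Π by inverting Fano's inequality

    Ŝ = H(Π) + (1 − Π) log₂(n − 1)

over the ego's *n* distinct locations. Location overlap is measured by the
overlapped distinct-location ratio η_{A|B} = |Y_A ∩ Y_B| / |Y_A| and its
cumulative (union) version.

Around these estimators the package builds egocentric networks (declared
social ties vs. non-social colocators found through contiguous or
time-displaced colocation windows), retention filters, alter-accumulation
curves, saturation extrapolation of Π to infinitely many alters,
predictability ratios, lag sweeps, and a synthetic-population generator
with planted ground truth.

## Worked example

`examples/04_population_analysis.py` generates a population of 12 egos in
which declared social ties co-visit 60% of ego events and anonymous
colocators 30%, then runs the full pipeline:

```
12 eligible egos
k      social Pi   colocator Pi
 1        57.6%      45.4%
 2        61.6%      51.4%
 3        63.1%      54.0%
...
10        65.7%      59.4%
extrapolated Pi_inf: social 65.5%, colocators 59.2%
top social tie vs k colocators crosses ratio 1 at k = 5.9
overlap vs predictability: Pearson R = 0.63 (p = 5.3e-28)
100% of egos show significantly higher social-tie predictability (paired one-sided t-test, p < 0.01)
```

Reading the output: accumulating ranked alters raises the Fano bound for
both flavors; social ties dominate at every set size (they were planted
twice as informative), but about six aggregated colocators carry as much
predictive information as the single best friend, and the predictability
an alter set provides tracks how much of the ego's distinct-location set
it covers. The other examples walk through single-trajectory entropy
(`01`), pairwise and cumulative information flow (`02`), network
construction and retention (`03`), and file ingestion (`05`).

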