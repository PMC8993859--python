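"""Do social ties or anonymous colocators predict a population better?

Runs the full analysis on a synthetic population: accumulation curves of
cumulative cross-predictability over the top-10 ranked alters of each
flavor, extrapolation to infinitely many alters, the social-over-colocator
predictability ratio, and the overlap-vs-predictability regression.
"""

import numpy as np

from mobinfo import (
    SyntheticConfig,
    build_colocation_networks,
    build_social_networks,
    filter_better_than_random,
    fit_saturation,
    generate_population,
    overlap_vs_predictability,
    population_curves,
    predictability_ratio,
    select_eligible_egos,
    social_vs_colocator_test,
)

cfg = SyntheticConfig(seed=5)  # 12 egos, rho_s = 0.6 > rho_c = 0.3
ds, truth = generate_population(cfg)

social = {e: filter_better_than_random(ds.trajectories[e], n, ds.trajectories)
          for e, n in build_social_networks(ds).items()}
coloc = {e: filter_better_than_random(ds.trajectories[e], n, ds.trajectories)
         for e, n in build_colocation_networks(ds).items()}
eligible = select_eligible_egos(social, coloc, min_alters=10)
print(f"{len(eligible)} eligible egos")

soc_curves = population_curves(ds, social, eligible)
col_curves = population_curves(ds, coloc, eligible)

ks = np.arange(1, 11)
mean_soc = np.vstack([c.pi_excl for c in soc_curves.values()]).mean(axis=0)
mean_col = np.vstack([c.pi_excl for c in col_curves.values()]).mean(axis=0)
print("k      social Pi   colocator Pi")
for k, a, b in zip(ks, mean_soc, mean_col):
    print(f"{k:2d}     {a:8.1%}   {b:8.1%}")

fit_s = fit_saturation(ks, mean_soc)
fit_c = fit_saturation(ks, mean_col)
print(f"extrapolated Pi_inf: social {fit_s.pi_infinity:.1%}, "
      f"colocators {fit_c.pi_infinity:.1%}")

ratio = predictability_ratio(soc_curves, col_curves, k_social=1, seed=5)
print(f"top social tie vs k colocators crosses ratio 1 at k = {ratio.crossing:.1f}")

pooled_eta = np.concatenate([c.eta for cs in (soc_curves, col_curves) for c in cs.values()])
pooled_pi = np.concatenate([c.pi_excl for cs in (soc_curves, col_curves) for c in cs.values()])
reg = overlap_vs_predictability(pooled_eta, pooled_pi)
print(f"overlap vs predictability: Pearson R = {reg.pearson_r:.2f} (p = {reg.p_value:.1e})")

tests = social_vs_colocator_test(soc_curves, col_curves)
print(f"{tests.frac_social_higher:.0%} of egos show significantly higher "
      f"social-tie predictability (paired one-sided t-test, p < {tests.alpha_ttest})")
print()
print("Because social alters were planted with double the co-visit rate,")
print("the social curve dominates, but enough aggregated colocators match")
print("the information content of the top social tie.")
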