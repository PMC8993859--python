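"""Population-level analyses: accumulation, extrapolation, ratios, lag sweeps.

The central object is the accumulation curve of one ego: as the top-k
ranked alters of one flavor are added (k = 1..10 by default), the
cumulative cross-entropy falls, the Fano cross-predictability rises, and
the cumulative distinct-location overlap grows. Curves are computed both
with and without the ego's own past joining the alter set. On top of the
per-ego curves the module provides

* extrapolation of the predictability to infinitely many alters by a
  saturating-exponential fit,
* social-over-colocator predictability ratios with bootstrap confidence
  intervals and the crossing point where the ratio reaches one,
* sweeps over time-displaced colocation windows,
* the overlap-vs-predictability regression and the per-ego paired tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import CheckinDataset, Trajectory
from .entropy import cross_match_lengths, cumulative_from_profiles, entropy_rate
from .networks import (
    EgoNetwork,
    LagWindow,
    build_colocation_networks,
    build_social_networks,
    common_egos_across_lags,
    filter_better_than_random,
    select_eligible_egos,
)
from .overlap import codlr
from .predictability import cross_predictability, fano_predictability

__all__ = [
    "AccumulationCurve",
    "SaturationFit",
    "RatioCurve",
    "RegressionSummary",
    "PairedTestSummary",
    "accumulation_curve",
    "saturation_extrapolate",
    "fit_saturation",
    "predictability_ratio",
    "lag_sweep",
    "overlap_vs_predictability",
    "social_vs_colocator_test",
    "population_curves",
    "run_report",
]


@dataclass
class AccumulationCurve:
    """Cumulative estimates for one ego as top-k alters are accumulated.

    Arrays are indexed by ``k - 1`` for ``k = 1..k_max``. The ``_excl``
    series use only the alters; the ``_incl`` series add the ego's own
    past to the alter set.
    """

    ego: str
    flavor: str
    ks: np.ndarray
    entropy_excl: np.ndarray
    pi_excl: np.ndarray
    entropy_incl: np.ndarray
    pi_incl: np.ndarray
    eta: np.ndarray
    n_ego: int = 0

    def pi(self, include_ego_past: bool = False) -> np.ndarray:
        return self.pi_incl if include_ego_past else self.pi_excl

    def entropy(self, include_ego_past: bool = False) -> np.ndarray:
        return self.entropy_incl if include_ego_past else self.entropy_excl


@dataclass
class SaturationFit:
    """Extrapolated predictability Π_∞ from a saturating-exponential fit."""

    pi_infinity: float
    kappa: float
    rss: float
    k_range: Tuple[int, int]
    params: dict = field(default_factory=dict)


@dataclass
class RatioCurve:
    """Mean social/colocator predictability ratios over a colocator-count grid."""

    k_social: int
    k_coloc: np.ndarray
    ratio_mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_egos: int
    crossing: Optional[float] = None  # colocator count where the mean ratio reaches 1


@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int


@dataclass
class PairedTestSummary:
    n_egos: int
    n_excluded: int
    frac_social_higher: float
    alpha_ttest: float
    frac_positive_spearman_social: float
    frac_positive_spearman_coloc: float
    alpha_spearman: float


def accumulation_curve(
    ego: Trajectory,
    net: EgoNetwork,
    trajectories: Dict[str, Trajectory],
    k_max: int = 10,
    weight_rule: str = "any-match",
) -> AccumulationCurve:
    """Cumulative cross-entropy / predictability / overlap over top-k alters.

    Per-alter time-constrained match profiles are computed once and reused
    as the running set grows, so the whole curve costs one parse per
    alter. Requires at least ``k_max`` retained alters.
    """
    ties = net.top(k_max)
    if len(ties) < k_max:
        raise ValueError(
            f"ego {net.ego!r} has {len(ties)} retained alters < k_max={k_max}; "
            "use select_eligible_egos to pick analyzable egos"
        )
    alters = [trajectories[t.alter] for t in ties]
    profiles = [cross_match_lengths(ego, B, time_constrained=True) for B in alters]
    ego_profile = cross_match_lengths(ego, ego, time_constrained=True)

    ks = np.arange(1, k_max + 1)
    s_excl = np.empty(k_max)
    s_incl = np.empty(k_max)
    pi_excl = np.empty(k_max)
    pi_incl = np.empty(k_max)
    eta = np.empty(k_max)
    for k in ks:
        ids = [B.user_id for B in alters[:k]]
        lens = [B.N for B in alters[:k]]
        est_excl = cumulative_from_profiles(ego, ids, lens, profiles[:k], weight_rule)
        est_incl = cumulative_from_profiles(
            ego, ids + [ego.user_id], lens + [ego.N], profiles[:k] + [ego_profile], weight_rule
        )
        s_excl[k - 1] = est_excl.value
        s_incl[k - 1] = est_incl.value
        pi_excl[k - 1] = cross_predictability(est_excl, ego).pi
        pi_incl[k - 1] = cross_predictability(est_incl, ego).pi
        eta[k - 1] = codlr(ego, alters[:k]).eta
    return AccumulationCurve(
        ego=ego.user_id,
        flavor=net.flavor,
        ks=ks,
        entropy_excl=s_excl,
        pi_excl=pi_excl,
        entropy_incl=s_incl,
        pi_incl=pi_incl,
        eta=eta,
        n_ego=ego.n,
    )


def fit_saturation(ks: np.ndarray, pis: np.ndarray) -> SaturationFit:
    """Least-squares fit of ``Π(k) = Π_∞ - (Π_∞ - Π(1)) exp(-(k-1)/κ)``.

    ``Π(1)`` is pinned to the first curve point; the free parameters are
    ``Π_∞`` (initialized at the curve maximum + 0.05) and ``κ``
    (initialized at 3). A constant curve returns its constant with zero
    residual.
    """
    ks = np.asarray(ks, dtype=float)
    pis = np.asarray(pis, dtype=float)
    if len(ks) < 4:
        raise ValueError("need at least 4 curve points to extrapolate")
    p1 = pis[0]
    if np.ptp(pis) < 1e-12:
        return SaturationFit(
            pi_infinity=float(p1),
            kappa=float("inf"),
            rss=0.0,
            k_range=(int(ks[0]), int(ks[-1])),
            params={"pi1": float(p1), "form": "constant"},
        )

    def model(k, pi_inf, kappa):
        return pi_inf - (pi_inf - p1) * np.exp(-(k - 1.0) / kappa)

    p0 = [float(pis.max()) + 0.05, 3.0]
    popt, _ = optimize.curve_fit(model, ks, pis, p0=p0, maxfev=20000)
    resid = pis - model(ks, *popt)
    return SaturationFit(
        pi_infinity=float(popt[0]),
        kappa=float(popt[1]),
        rss=float(np.sum(resid**2)),
        k_range=(int(ks[0]), int(ks[-1])),
        params={"pi1": float(p1), "form": "exponential-saturation"},
    )


def saturation_extrapolate(
    curve: AccumulationCurve, include_ego_past: bool = False
) -> SaturationFit:
    """Extrapolate one ego's predictability curve to infinitely many alters."""
    return fit_saturation(curve.ks, curve.pi(include_ego_past))


def _bootstrap_ci(values: np.ndarray, n_boot: int, rng: np.random.Generator, level=0.95):
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    means = values[idx].mean(axis=1)
    lo, hi = np.quantile(means, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def predictability_ratio(
    social_curves: Dict[str, AccumulationCurve],
    coloc_curves: Dict[str, AccumulationCurve],
    k_social: int = 1,
    k_coloc_range: Sequence[int] = tuple(range(1, 11)),
    n_boot: int = 1000,
    seed: int = 0,
    include_ego_past: bool = False,
) -> RatioCurve:
    """Per-ego ratio of social-tie to colocator predictability, aggregated.

    For each colocator count the mean over egos is reported with a
    nonparametric bootstrap 95% CI, plus the (interpolated) colocator
    count where the mean ratio first reaches 1. Egos with a zero
    denominator at any k are excluded.
    """
    egos = sorted(set(social_curves) & set(coloc_curves))
    if not egos:
        raise ValueError("no common egos between the two curve collections")
    k_coloc = np.asarray(list(k_coloc_range), dtype=int)
    rng = np.random.default_rng(seed)

    rows = []
    for ego in egos:
        ps = social_curves[ego].pi(include_ego_past)[k_social - 1]
        pcs = coloc_curves[ego].pi(include_ego_past)[k_coloc - 1]
        if np.any(pcs <= 0):
            continue
        rows.append(ps / pcs)
    if not rows:
        raise ValueError("all egos excluded (zero denominators)")
    mat = np.vstack(rows)
    mean = mat.mean(axis=0)
    ci = np.array([_bootstrap_ci(mat[:, j], n_boot, rng) for j in range(mat.shape[1])])

    crossing = None
    below = np.nonzero(mean <= 1.0)[0]
    if len(below):
        j = below[0]
        if j == 0:
            crossing = float(k_coloc[0])
        else:
            k0, k1 = k_coloc[j - 1], k_coloc[j]
            r0, r1 = mean[j - 1], mean[j]
            crossing = float(k0 + (r0 - 1.0) / (r0 - r1) * (k1 - k0))
    return RatioCurve(
        k_social=k_social,
        k_coloc=k_coloc,
        ratio_mean=mean,
        ci_low=ci[:, 0],
        ci_high=ci[:, 1],
        n_egos=mat.shape[0],
        crossing=crossing,
    )


def population_curves(
    ds: CheckinDataset,
    networks: Dict[str, EgoNetwork],
    egos: Iterable[str],
    k_max: int = 10,
) -> Dict[str, AccumulationCurve]:
    """Accumulation curves for a set of egos under one network flavor."""
    return {
        ego: accumulation_curve(ds.trajectories[ego], networks[ego], ds.trajectories, k_max)
        for ego in sorted(egos)
    }


def lag_sweep(
    ds: CheckinDataset,
    lags: Sequence[float] = tuple(np.arange(0.5, 12.01, 0.5)),
    k_max: int = 10,
    min_alters: int = 10,
    apply_better_than_random: bool = True,
) -> Tuple[Dict[float, pd.DataFrame], set]:
    """One lagged colocation network per lag; mean curves over common egos.

    Builds the colocation network for each lag on the grid, keeps the egos
    eligible at *every* lag, and returns per-lag population-mean
    accumulation summaries (mean Π and mean η per k) plus the common ego
    set. Raises when no ego is eligible across the whole grid.
    """
    per_lag_nets: Dict[float, Dict[str, EgoNetwork]] = {}
    for lag in lags:
        nets = build_colocation_networks(ds, LagWindow(T=float(lag)))
        if apply_better_than_random:
            nets = {
                ego: filter_better_than_random(ds.trajectories[ego], net, ds.trajectories)
                for ego, net in nets.items()
            }
        per_lag_nets[float(lag)] = nets
    common = common_egos_across_lags(per_lag_nets, min_alters=max(min_alters, k_max))
    if not common:
        raise ValueError("no common eligible egos across the lag grid")

    out: Dict[float, pd.DataFrame] = {}
    for lag, nets in per_lag_nets.items():
        curves = population_curves(ds, nets, common, k_max=k_max)
        pis = np.vstack([c.pi_excl for c in curves.values()])
        etas = np.vstack([c.eta for c in curves.values()])
        out[lag] = pd.DataFrame(
            {
                "k": np.arange(1, k_max + 1),
                "pi_mean": pis.mean(axis=0),
                "pi_sem": pis.std(axis=0, ddof=1) / math.sqrt(len(curves))
                if len(curves) > 1
                else np.zeros(k_max),
                "eta_mean": etas.mean(axis=0),
            }
        )
    return out, common


def overlap_vs_predictability(
    etas: Sequence[float], pis: Sequence[float]
) -> RegressionSummary:
    """OLS fit and Pearson correlation of predictability against overlap."""
    etas = np.asarray(etas, dtype=float)
    pis = np.asarray(pis, dtype=float)
    if len(etas) != len(pis):
        raise ValueError("paired samples required")
    if len(etas) < 3:
        raise ValueError("need at least 3 egos for a regression")
    res = stats.linregress(etas, pis)
    return RegressionSummary(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=len(etas),
    )


def social_vs_colocator_test(
    social_curves: Dict[str, AccumulationCurve],
    coloc_curves: Dict[str, AccumulationCurve],
    alpha_ttest: float = 0.01,
    alpha_spearman: float = 0.05,
    include_ego_past: bool = False,
) -> PairedTestSummary:
    """Per-ego paired comparison of the two flavors across k = 1..k_max.

    Reports the fraction of egos whose social predictability is
    significantly higher than their colocator predictability (paired
    one-sided t-test over the curve points) and the fraction with a
    significantly positive Spearman rank correlation of Π against k, per
    flavor. Egos with a degenerate (constant-difference) curve pair are
    excluded and counted.
    """
    egos = sorted(set(social_curves) & set(coloc_curves))
    if not egos:
        raise ValueError("no common egos")
    n_higher = 0
    n_pos_sp_social = 0
    n_pos_sp_coloc = 0
    n_excluded = 0
    n_used = 0
    for ego in egos:
        ps = social_curves[ego].pi(include_ego_past)
        pc = coloc_curves[ego].pi(include_ego_past)
        diff = ps - pc
        if np.ptp(diff) < 1e-15:
            n_excluded += 1
            continue
        n_used += 1
        t = stats.ttest_rel(ps, pc, alternative="greater")
        if t.pvalue < alpha_ttest:
            n_higher += 1
        for pis, counter in ((ps, "s"), (pc, "c")):
            if np.ptp(pis) < 1e-15:
                continue
            rho = stats.spearmanr(social_curves[ego].ks, pis)
            if rho.statistic > 0 and rho.pvalue < alpha_spearman:
                if counter == "s":
                    n_pos_sp_social += 1
                else:
                    n_pos_sp_coloc += 1
    if n_used == 0:
        raise ValueError("all egos degenerate")
    return PairedTestSummary(
        n_egos=n_used,
        n_excluded=n_excluded,
        frac_social_higher=n_higher / n_used,
        alpha_ttest=alpha_ttest,
        frac_positive_spearman_social=n_pos_sp_social / n_used,
        frac_positive_spearman_coloc=n_pos_sp_coloc / n_used,
        alpha_spearman=alpha_spearman,
    )


def run_report(
    ds: CheckinDataset,
    out_dir,
    k_max: int = 10,
    min_alters: int = 10,
    seed: int = 0,
) -> dict:
    """End-to-end analysis of a dataset, written as deterministic CSV/JSON.

    Builds both network flavors with the default window, applies the
    better-than-random retention filter, selects eligible egos, computes
    accumulation curves, the ratio curve, the overlap regression at
    ``k = k_max``, and the paired tests. Identical inputs and seed produce
    byte-identical outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    social = build_social_networks(ds)
    coloc = build_colocation_networks(ds)
    social = {
        ego: filter_better_than_random(ds.trajectories[ego], net, ds.trajectories)
        for ego, net in social.items()
    }
    coloc = {
        ego: filter_better_than_random(ds.trajectories[ego], net, ds.trajectories)
        for ego, net in coloc.items()
    }
    eligible = select_eligible_egos(social, coloc, min_alters=min_alters)
    if not eligible:
        raise ValueError("no eligible egos; generate a denser dataset")

    social_curves = population_curves(ds, social, eligible, k_max=k_max)
    coloc_curves = population_curves(ds, coloc, eligible, k_max=k_max)

    rows = []
    for flavor, curves in (("social", social_curves), ("colocation", coloc_curves)):
        for ego in sorted(curves):
            c = curves[ego]
            for i, k in enumerate(c.ks):
                rows.append(
                    {
                        "ego": ego,
                        "flavor": flavor,
                        "k": int(k),
                        "entropy_excl_bits": c.entropy_excl[i],
                        "pi_excl": c.pi_excl[i],
                        "entropy_incl_bits": c.entropy_incl[i],
                        "pi_incl": c.pi_incl[i],
                        "eta": c.eta[i],
                    }
                )
    curves_df = pd.DataFrame(rows)
    curves_df.to_csv(out_dir / "accumulation.csv", index=False, float_format="%.12g")

    ratio = predictability_ratio(social_curves, coloc_curves, seed=seed)
    ratio_df = pd.DataFrame(
        {
            "k_coloc": ratio.k_coloc,
            "ratio_mean": ratio.ratio_mean,
            "ci_low": ratio.ci_low,
            "ci_high": ratio.ci_high,
        }
    )
    ratio_df.to_csv(out_dir / "ratio.csv", index=False, float_format="%.12g")

    # pool (ego, k) pairs from both flavors so the overlap axis has spread
    # even when every ego's top-10 union covers its whole location set
    pooled_eta = np.concatenate(
        [c.eta for cs in (social_curves, coloc_curves) for c in cs.values()]
    )
    pooled_pi = np.concatenate(
        [c.pi_excl for cs in (social_curves, coloc_curves) for c in cs.values()]
    )
    reg = overlap_vs_predictability(pooled_eta, pooled_pi)
    tests = social_vs_colocator_test(social_curves, coloc_curves)

    ego_entropies = {
        e: entropy_rate(ds.trajectories[e]).value for e in sorted(eligible)
    }
    ego_pis = {
        e: fano_predictability(s, ds.trajectories[e].n).pi for e, s in ego_entropies.items()
    }
    summary = {
        "n_eligible_egos": len(eligible),
        "mean_ego_entropy_bits": float(np.mean(list(ego_entropies.values()))),
        "mean_ego_predictability": float(np.mean(list(ego_pis.values()))),
        "ratio_crossing_k": ratio.crossing,
        "overlap_regression": {
            "slope": reg.slope,
            "pearson_r": reg.pearson_r,
            "p_value": reg.p_value,
        },
        "frac_social_higher": tests.frac_social_higher,
        "seed": seed,
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
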