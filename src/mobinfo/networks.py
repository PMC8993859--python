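"""Egocentric social and (lagged) colocation networks.

Two flavors of alter are distinguished for every ego:

* **social ties** — declared friends (check-in platforms) or users with at
  least 30 reciprocal calls (call records), ranked by how often they
  colocate with the ego;
* **non-social colocators** — users who check in at the ego's location
  within a time window but are *not* socially tied (no declared edge; for
  call records, zero calls in either direction), ranked by colocation
  count.

A colocation is a pair of events by two different users at the same
location whose time difference falls inside a lag window. The default
window is the contiguous one-hour bin ``|Δt| <= 30 min``; a lag ``T``
displaces it to ``[T - 1/2, T]`` hours after or ``[T, T - 1/2]`` hours
before the ego's visit, so ``T = 1/2`` recovers the contiguous case. Every
qualifying event pair counts once, which makes tie weights symmetric and
monotone in the window half-width.
"""

from __future__ import annotations

import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .datatypes import CheckinDataset, Trajectory
from .entropy import cross_entropy

__all__ = [
    "LagWindow",
    "AlterTie",
    "EgoNetwork",
    "colocation_pair_weights",
    "build_social_networks",
    "build_colocation_networks",
    "filter_better_than_random",
    "select_eligible_egos",
    "common_egos_across_lags",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LagWindow:
    """A (possibly time-displaced) colocation window.

    An alter event at the same location as an ego event at time ``t``
    counts if its offset ``dt`` from ``t`` lies in
    ``[-T, -T + h] ∪ [T - h, T]`` hours, with half-width ``h = 1/2`` by
    default. ``T = h`` yields the contiguous window ``[-h, h]``.
    """

    T: float = 0.5
    half_width: float = 0.5

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")
        if self.T < self.half_width:
            raise ValueError("lag T must be >= the half-width")

    @property
    def contiguous(self) -> bool:
        return self.T == self.half_width

    def intervals_seconds(self) -> List[Tuple[float, float]]:
        """Closed dt-intervals in seconds; one interval in the contiguous case."""
        h = self.half_width * 3600.0
        T = self.T * 3600.0
        if self.contiguous:
            return [(-h, h)]
        return [(-T, -T + h), (T - h, T)]


@dataclass(frozen=True)
class AlterTie:
    alter: str
    weight: float
    rank: int
    retained: bool = True


@dataclass
class EgoNetwork:
    """An ego with its ranked alters of one flavor."""

    ego: str
    flavor: str  # "social" | "colocation" | "lagged-colocation(T=..)"
    alters: List[AlterTie] = field(default_factory=list)

    @property
    def alter_ids(self) -> List[str]:
        return [t.alter for t in self.alters]

    def top(self, k: int) -> List[AlterTie]:
        return self.alters[:k]

    def __len__(self) -> int:
        return len(self.alters)


def _rank_ties(weights: Dict[str, float]) -> List[AlterTie]:
    # nonincreasing weight, lexicographic alter id on ties, ranks 1..k
    ordered = sorted(weights.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return [AlterTie(alter=a, weight=w, rank=i + 1) for i, (a, w) in enumerate(ordered)]


def colocation_pair_weights(
    ds: CheckinDataset, window: Optional[LagWindow] = None
) -> Tuple[Counter, Dict[Tuple[str, str], set]]:
    """Count colocating event pairs for every ordered (ego, alter) pair.

    Returns the pair-weight counter and, per ordered pair, the set of
    locations at which the colocations occurred (used by the optional
    spurious-colocator hook).
    """
    window = window or LagWindow()
    intervals = window.intervals_seconds()
    weights: Counter = Counter()
    pair_locations: Dict[Tuple[str, str], set] = defaultdict(set)

    by_location: Dict[str, list] = defaultdict(list)
    for uid, traj in ds.trajectories.items():
        for loc, t in zip(traj.locations, traj.timestamps):
            by_location[loc].append((t, uid))

    for loc, events in by_location.items():
        if len(events) < 2:
            continue
        events.sort()
        ts = np.array([e[0] for e in events])
        us = [e[1] for e in events]
        for k in range(len(events)):
            ego = us[k]
            for lo, hi in intervals:
                left = int(np.searchsorted(ts, ts[k] + lo, side="left"))
                right = int(np.searchsorted(ts, ts[k] + hi, side="right"))
                for j in range(left, right):
                    if us[j] == ego:
                        continue
                    weights[(ego, us[j])] += 1
                    pair_locations[(ego, us[j])].add(loc)
    return weights, pair_locations


def _reciprocal_call_counts(call_log) -> Counter:
    """Reciprocal-call totals per unordered pair: 2 * min(calls a->b, calls b->a)."""
    directed = Counter(zip(call_log["caller"].astype(str), call_log["callee"].astype(str)))
    totals: Counter = Counter()
    for (a, b), n_ab in directed.items():
        if a >= b:
            continue
        n_ba = directed.get((b, a), 0)
        totals[(a, b)] = 2 * min(n_ab, n_ba)
    return totals


def _called_pairs(call_log) -> set:
    pairs = set()
    for a, b in zip(call_log["caller"].astype(str), call_log["callee"].astype(str)):
        pairs.add((a, b) if a < b else (b, a))
    return pairs


def build_social_networks(
    ds: CheckinDataset,
    window: Optional[LagWindow] = None,
    min_reciprocal_calls: int = 30,
    pair_weights: Optional[Counter] = None,
) -> Dict[str, EgoNetwork]:
    """Social ego-networks, ranked by colocation frequency with the ego.

    On check-in data the alters are declared friends that have logged
    trajectories; on call-record data they are users with at least
    ``min_reciprocal_calls`` reciprocal calls with the ego. Friends with no
    trajectory are excluded. Ranking uses colocation counts in the given
    window (default contiguous one-hour bin); ties without any colocation
    get weight zero but remain in the network.
    """
    if ds.social_edges is None and ds.call_log is None:
        raise ValueError("dataset has neither social edges nor a call log")

    if ds.social_edges is not None:
        pairs = {
            e for e in ds.social_edges if e[0] in ds.trajectories and e[1] in ds.trajectories
        }
    else:
        reciprocal = _reciprocal_call_counts(ds.call_log)
        pairs = {
            p
            for p, total in reciprocal.items()
            if total >= min_reciprocal_calls
            and p[0] in ds.trajectories
            and p[1] in ds.trajectories
        }

    if pair_weights is None:
        pair_weights, _ = colocation_pair_weights(ds, window)

    networks: Dict[str, EgoNetwork] = {}
    neighbor: Dict[str, set] = defaultdict(set)
    for a, b in pairs:
        neighbor[a].add(b)
        neighbor[b].add(a)
    for ego in ds.users:
        weights = {alt: float(pair_weights.get((ego, alt), 0)) for alt in neighbor.get(ego, ())}
        networks[ego] = EgoNetwork(ego=ego, flavor="social", alters=_rank_ties(weights))
    return networks


def build_colocation_networks(
    ds: CheckinDataset,
    window: Optional[LagWindow] = None,
    drop_single_hotspot: bool = False,
    pair_weights: Optional[Counter] = None,
    pair_locations: Optional[Dict[Tuple[str, str], set]] = None,
) -> Dict[str, EgoNetwork]:
    """Non-social colocation ego-networks for a (possibly lagged) window.

    Every other user whose events colocate with the ego inside the window
    becomes an alter weighted by the colocation count, excluding declared
    social ties (check-in data) and any pair that exchanged calls
    (call-record data). ``drop_single_hotspot`` enables an optional
    spurious-colocator hook: alters whose colocations with the ego all
    happen at the ego's single most-visited location are removed (a
    synthetic stand-in for popularity-driven false ties; off by default).
    """
    window = window or LagWindow()
    if pair_weights is None or pair_locations is None:
        pair_weights, pair_locations = colocation_pair_weights(ds, window)

    excluded_pairs: set = set()
    if ds.social_edges is not None:
        excluded_pairs |= set(ds.social_edges)
    if ds.call_log is not None:
        excluded_pairs |= _called_pairs(ds.call_log)

    per_ego: Dict[str, Dict[str, float]] = defaultdict(dict)
    for (ego, alt), w in pair_weights.items():
        key = (ego, alt) if ego < alt else (alt, ego)
        if key in excluded_pairs:
            continue
        per_ego[ego][alt] = float(w)

    if window.contiguous:
        flavor = "colocation"
    else:
        flavor = f"lagged-colocation(T={window.T:g})"

    networks: Dict[str, EgoNetwork] = {}
    for ego in ds.users:
        weights = per_ego.get(ego, {})
        if drop_single_hotspot and weights:
            traj = ds.trajectories[ego]
            top_loc = Counter(traj.locations).most_common(1)[0][0]
            weights = {
                alt: w
                for alt, w in weights.items()
                if pair_locations.get((ego, alt), set()) != {top_loc}
            }
        networks[ego] = EgoNetwork(ego=ego, flavor=flavor, alters=_rank_ties(weights))
    return networks


def filter_better_than_random(
    ego: Trajectory, net: EgoNetwork, trajectories: Dict[str, Trajectory]
) -> EgoNetwork:
    """Retain alters whose history beats random guessing about the ego.

    An alter survives when its cross-entropy about the ego is strictly
    below ``log2(n_A)`` — i.e., its cross-predictability exceeds the
    random-guessing bound ``1/n_A``. Ranks are recomputed among survivors,
    preserving the weight ordering.
    """
    threshold = math.log2(ego.n) if ego.n > 1 else 0.0
    survivors = []
    for tie in net.alters:
        B = trajectories.get(tie.alter)
        if B is None or B.N < 2:
            continue
        if cross_entropy(ego, B).value < threshold:
            survivors.append(tie)
    reranked = [replace(t, rank=i + 1, retained=True) for i, t in enumerate(survivors)]
    return EgoNetwork(ego=net.ego, flavor=net.flavor, alters=reranked)


def select_eligible_egos(
    social: Dict[str, EgoNetwork],
    coloc: Dict[str, EgoNetwork],
    min_alters: int = 10,
) -> set:
    """Egos with at least ``min_alters`` retained alters in *both* flavors."""
    eligible = {
        ego
        for ego in social
        if len(social[ego]) >= min_alters and len(coloc.get(ego, EgoNetwork(ego, "colocation"))) >= min_alters
    }
    if not eligible:
        logger.warning("no egos have >= %d alters in both networks", min_alters)
    return eligible


def common_egos_across_lags(
    networks: Dict[float, Dict[str, EgoNetwork]], min_alters: int = 10
) -> set:
    """Egos eligible (>= ``min_alters`` alters) in every lagged network."""
    common: Optional[set] = None
    for lag in sorted(networks):
        eligible = {ego for ego, net in networks[lag].items() if len(net) >= min_alters}
        common = eligible if common is None else common & eligible
    common = common or set()
    if not common:
        logger.warning("no common eligible egos across the lag grid")
    return common


def serialize_networks(networks: Dict[str, EgoNetwork], lag_hours: Optional[float] = None):
    """Flatten ego networks to rows: ego, alter, flavor, lag, weight, rank, retained."""
    rows = []
    for ego in sorted(networks):
        for tie in networks[ego].alters:
            rows.append(
                {
                    "ego": ego,
                    "alter": tie.alter,
                    "flavor": networks[ego].flavor,
                    "lag_hours": lag_hours if lag_hours is not None else "",
                    "weight": tie.weight,
                    "rank": tie.rank,
                    "retained": tie.retained,
                }
            )
    return rows
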