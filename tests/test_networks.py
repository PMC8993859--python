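"""Ego-network construction: social ranking, colocation windows, retention."""

import numpy as np
import pandas as pd
import pytest

from mobinfo import (
    CheckinDataset,
    LagWindow,
    Trajectory,
    build_colocation_networks,
    build_social_networks,
    colocation_pair_weights,
    common_egos_across_lags,
    filter_better_than_random,
    select_eligible_egos,
)
from mobinfo.networks import AlterTie, EgoNetwork

from conftest import make_traj

H = 3600.0


def _dataset(trajs, edges=None, call_log=None):
    return CheckinDataset(
        trajectories={t.user_id: t for t in trajs},
        social_edges=edges,
        call_log=call_log,
    )


class TestLagWindow:
    def test_contiguous_default(self):
        w = LagWindow()
        assert w.contiguous
        assert w.intervals_seconds() == [(-1800.0, 1800.0)]

    def test_lagged_intervals(self):
        w = LagWindow(T=2.5)
        assert w.intervals_seconds() == [(-9000.0, -7200.0), (7200.0, 9000.0)]

    def test_invalid_lag(self):
        with pytest.raises(ValueError):
            LagWindow(T=0.25)


class TestSocialNetworks:
    def test_friends_ranked_by_colocation_frequency(self):
        ego = make_traj(["p"] * 14, np.arange(14) * H, user="ego")
        # b colocates 5 times, c colocates 9 times
        b = make_traj(["p"] * 5, np.arange(5) * H + 60, user="b")
        c = make_traj(["p"] * 9, np.arange(5, 14) * H + 60, user="c")
        ds = _dataset([ego, b, c], edges={("b", "ego"), ("c", "ego")})
        nets = build_social_networks(ds)
        assert nets["ego"].alter_ids == ["c", "b"]
        assert [t.weight for t in nets["ego"].alters] == [9.0, 5.0]

    def test_friend_without_trajectory_excluded(self):
        ego = make_traj("pp", [0, H], user="ego")
        ds = _dataset([ego], edges={("ego", "ghost")})
        assert build_social_networks(ds)["ego"].alter_ids == []

    @pytest.mark.parametrize("n_calls, expected", [(14, []), (15, ["b"])])
    def test_cdr_reciprocal_threshold_inclusive(self, n_calls, expected):
        # 2 * min(a->b, b->a) >= 30 requires 15 calls each way
        ego = make_traj("pp", [0, H], user="a")
        alt = make_traj("qq", [0, H], user="b")
        rows = [("a", "b", i) for i in range(n_calls)] + [
            ("b", "a", 1000 + i) for i in range(n_calls)
        ]
        log = pd.DataFrame(rows, columns=["caller", "callee", "timestamp"])
        ds = _dataset([ego, alt], call_log=log)
        assert build_social_networks(ds)["a"].alter_ids == expected

    def test_requires_edge_or_call_information(self):
        ds = _dataset([make_traj("pp", [0, H], user="a")])
        with pytest.raises(ValueError):
            build_social_networks(ds)


class TestColocationNetworks:
    def test_same_place_twenty_minutes_apart(self):
        ego = make_traj(["p"], [12 * H], user="ego")
        other = make_traj(["p"], [12 * H + 20 * 60], user="s")
        nets = build_colocation_networks(_dataset([ego, other]))
        assert nets["ego"].alter_ids == ["s"]
        assert nets["ego"].alters[0].weight == 1.0

    def test_declared_friend_excluded(self):
        ego = make_traj(["p"], [12 * H], user="ego")
        friend = make_traj(["p"], [12 * H + 20 * 60], user="f")
        ds = _dataset([ego, friend], edges={("ego", "f")})
        assert build_colocation_networks(ds)["ego"].alter_ids == []

    def test_called_pair_excluded_on_cdr(self):
        ego = make_traj(["p"], [12 * H], user="a")
        other = make_traj(["p"], [12 * H + 600], user="b")
        log = pd.DataFrame([("a", "b", 0.0)], columns=["caller", "callee", "timestamp"])
        ds = _dataset([ego, other], call_log=log)
        assert build_colocation_networks(ds)["a"].alter_ids == []

    def test_lagged_window_catches_displaced_visit(self):
        # stranger visits the same place 2 h 20 min later: inside [T-1/2, T] for T=2.5
        ego = make_traj(["p"], [12 * H], user="ego")
        other = make_traj(["p"], [12 * H + 2 * H + 20 * 60], user="s")
        ds = _dataset([ego, other])
        assert build_colocation_networks(ds, LagWindow(T=2.5))["ego"].alter_ids == ["s"]
        # but not inside the contiguous default window
        assert build_colocation_networks(ds)["ego"].alter_ids == []

    def test_pair_weights_symmetric(self):
        rng = np.random.default_rng(3)
        trajs = []
        for uid in "abc":
            times = np.sort(rng.uniform(0, 40 * H, size=30))
            locs = [f"l{i}" for i in rng.integers(0, 3, size=30)]
            trajs.append(make_traj(locs, times, user=uid))
        for window in (LagWindow(), LagWindow(T=2.0)):
            weights, _ = colocation_pair_weights(_dataset(trajs), window)
            for (a, b), w in weights.items():
                assert weights[(b, a)] == w

    def test_wider_half_width_never_loses_weight(self):
        rng = np.random.default_rng(4)
        trajs = []
        for uid in "ab":
            times = np.sort(rng.uniform(0, 20 * H, size=25))
            locs = [f"l{i}" for i in rng.integers(0, 2, size=25)]
            trajs.append(make_traj(locs, times, user=uid))
        narrow, _ = colocation_pair_weights(_dataset(trajs), LagWindow(0.5, 0.5))
        wide, _ = colocation_pair_weights(_dataset(trajs), LagWindow(1.0, 1.0))
        for pair, w in narrow.items():
            assert wide[pair] >= w

    def test_ranks_are_a_permutation(self):
        ego = make_traj(["p"] * 6, np.arange(6) * H, user="ego")
        a = make_traj(["p"] * 2, [60.0, H + 60], user="a")
        b = make_traj(["p"] * 4, [60.0, H + 60, 2 * H + 60, 3 * H + 60], user="b")
        net = build_colocation_networks(_dataset([ego, a, b]))["ego"]
        assert [t.rank for t in net.alters] == [1, 2]
        assert net.alter_ids == ["b", "a"]


class TestRetention:
    def test_better_than_random_filter(self):
        rng = np.random.default_rng(5)
        seq = [f"l{i % 4}" for i in range(200)]  # predictable periodic ego
        ego = make_traj(seq, np.arange(200) * H + 1e6, user="ego")
        # a time-shifted copy of the ego: maximally informative, retained
        copy = make_traj(seq, np.arange(200) * H, user="copy")
        # a partial copy (half the visits replaced): weaker but informative
        half_seq = [s if rng.random() < 0.5 else "z" for s in seq]
        half = make_traj(half_seq, np.arange(200) * H, user="half")
        # an alter sharing no locations: no information, removed
        disjoint = make_traj(["z"] * 200, np.arange(200) * H, user="disjoint")
        trajs = {t.user_id: t for t in (ego, copy, disjoint, half)}
        net = EgoNetwork(
            "ego",
            "colocation",
            [AlterTie("copy", 3.0, 1), AlterTie("disjoint", 2.0, 2), AlterTie("half", 1.0, 3)],
        )
        out = filter_better_than_random(ego, net, trajs)
        assert out.alter_ids == ["copy", "half"]
        assert [t.rank for t in out.alters] == [1, 2]


class TestEligibility:
    def _net(self, ego, n):
        return EgoNetwork(ego, "x", [AlterTie(f"a{i}", 1.0, i + 1) for i in range(n)])

    def test_both_flavors_required(self):
        social = {"e1": self._net("e1", 10), "e2": self._net("e2", 10)}
        coloc = {"e1": self._net("e1", 9), "e2": self._net("e2", 10)}
        assert select_eligible_egos(social, coloc) == {"e2"}

    def test_common_egos_intersection(self):
        nets = {
            0.5: {"a": self._net("a", 10), "b": self._net("b", 10), "c": self._net("c", 10)},
            1.0: {"b": self._net("b", 10), "c": self._net("c", 10), "d": self._net("d", 10)},
        }
        assert common_egos_across_lags(nets) == {"b", "c"}

    def test_empty_lag_gives_empty_intersection(self):
        nets = {0.5: {"a": self._net("a", 10)}, 1.0: {"a": self._net("a", 2)}}
        assert common_egos_across_lags(nets) == set()
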