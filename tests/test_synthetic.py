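"""Ground-truth structure and determinism of the synthetic generator."""

import math

import numpy as np
import pytest

from mobinfo import (
    SyntheticConfig,
    build_colocation_networks,
    build_social_networks,
    entropy_rate,
    filter_better_than_random,
    generate_population,
    odlr,
)


def test_seed_determinism():
    cfg = SyntheticConfig(n_egos=2, n_background=2, n_events=100, seed=9)
    ds1, _ = generate_population(cfg)
    ds2, _ = generate_population(cfg)
    assert ds1.users == ds2.users
    for uid in ds1.users:
        assert ds1.trajectories[uid].locations == ds2.trajectories[uid].locations
        assert np.array_equal(
            ds1.trajectories[uid].timestamps, ds2.trajectories[uid].timestamps
        )


def test_labels_partition_the_population():
    cfg = SyntheticConfig(n_egos=2, n_background=3, n_events=60, seed=1)
    ds, truth = generate_population(cfg)
    assert set(truth.labels) == set(ds.trajectories)
    counts = {lab: 0 for lab in ("ego", "social", "colocator", "background")}
    for lab in truth.labels.values():
        counts[lab] += 1
    assert counts == {
        "ego": 2,
        "social": 2 * cfg.n_social_per_ego,
        "colocator": 2 * cfg.n_coloc_per_ego,
        "background": 3,
    }


def test_declared_edges_connect_egos_to_their_social_alters():
    cfg = SyntheticConfig(n_egos=2, n_background=0, n_events=60, seed=2)
    ds, truth = generate_population(cfg)
    assert len(ds.social_edges) == 2 * cfg.n_social_per_ego
    for a, b in ds.social_edges:
        ego, alter = (a, b) if truth.labels[a] == "ego" else (b, a)
        assert truth.ego_of[alter] == ego


def test_iid_uniform_entropy_approaches_closed_form():
    cfg = SyntheticConfig(
        n_egos=1,
        n_social_per_ego=0,
        n_coloc_per_ego=0,
        n_background=0,
        n_locations=8,
        n_events=20000,
        ego_process="iid-uniform",
        seed=3,
    )
    ds, truth = generate_population(cfg)
    assert truth.theoretical_entropy["ego00"] == 3.0
    est = entropy_rate(ds.trajectories["ego00"]).value
    assert est == pytest.approx(3.0, rel=0.15)


def test_zipf_theoretical_entropy_is_shannon_of_weights():
    cfg = SyntheticConfig(
        n_egos=1,
        n_social_per_ego=0,
        n_coloc_per_ego=0,
        n_background=0,
        n_locations=16,
        n_events=50,
        ego_process="iid-zipf",
        zipf_s=1.5,
        seed=4,
    )
    _, truth = generate_population(cfg)
    w = 1.0 / np.arange(1, 17) ** 1.5
    p = w / w.sum()
    assert truth.theoretical_entropy["ego00"] == pytest.approx(
        float(-(p * np.log2(p)).sum())
    )


def test_zero_social_rate_leaves_no_information():
    cfg = SyntheticConfig(
        n_egos=1,
        n_social_per_ego=3,
        n_coloc_per_ego=0,
        n_background=0,
        n_events=200,
        rho_s=0.0,
        seed=5,
    )
    ds, truth = generate_population(cfg)
    ego = ds.trajectories["ego00"]
    social = build_social_networks(ds)
    # social alters share no events, so none survives the retention filter
    filtered = filter_better_than_random(ego, social["ego00"], ds.trajectories)
    assert filtered.alter_ids == []


def test_full_covisit_rate_gives_total_overlap_and_retention():
    cfg = SyntheticConfig(
        n_egos=1,
        n_social_per_ego=0,
        n_coloc_per_ego=3,
        n_background=0,
        n_events=300,
        rho_c=1.0,
        lag_offset_hours=0.0,
        seed=6,
    )
    ds, truth = generate_population(cfg)
    ego = ds.trajectories["ego00"]
    nets = build_colocation_networks(ds)
    planted = {u for u, lab in truth.labels.items() if lab == "colocator"}
    assert planted <= set(nets["ego00"].alter_ids)
    for uid in planted:
        assert odlr(ego, ds.trajectories[uid]).eta == pytest.approx(1.0)
    filtered = filter_better_than_random(ego, nets["ego00"], ds.trajectories)
    assert planted <= set(filtered.alter_ids)


def test_lagged_colocators_found_at_matching_lag_only():
    from mobinfo import LagWindow

    cfg = SyntheticConfig(
        n_egos=1,
        n_social_per_ego=0,
        n_coloc_per_ego=2,
        n_background=0,
        n_events=150,
        rho_c=1.0,
        lag_offset_hours=2.5,
        seed=7,
    )
    ds, truth = generate_population(cfg)
    planted = {u for u, lab in truth.labels.items() if lab == "colocator"}
    matched = build_colocation_networks(ds, LagWindow(T=2.5))["ego00"]
    contiguous = build_colocation_networks(ds)["ego00"]
    assert planted <= set(matched.alter_ids)
    matched_w = {t.alter: t.weight for t in matched.alters}
    contig_w = {t.alter: t.weight for t in contiguous.alters}
    for uid in planted:
        assert matched_w[uid] > 10 * contig_w.get(uid, 0.0)


def test_infeasible_config_rejected():
    with pytest.raises(ValueError):
        generate_population(SyntheticConfig(n_locations=0))
    with pytest.raises(ValueError):
        generate_population(SyntheticConfig(rho_s=1.5))


def test_call_log_plants_reciprocal_ties():
    cfg = SyntheticConfig(
        n_egos=1,
        n_social_per_ego=2,
        n_coloc_per_ego=0,
        n_background=0,
        n_events=50,
        emit_call_log=True,
        seed=8,
    )
    ds, truth = generate_population(cfg)
    from mobinfo.networks import _reciprocal_call_counts

    counts = _reciprocal_call_counts(ds.call_log)
    assert all(total >= 30 for total in counts.values())
    assert len(counts) == 2
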