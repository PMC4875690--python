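"""The synthetic cohort generator: determinism, truth geometry, depth model."""

import numpy as np
import pytest

from cnvpop.genome import ConfigurationError, GenomeLayout
from cnvpop.simulate import (
    SimConfig,
    generate_genome,
    plant_truth,
    simulate_cn_matrix,
    simulate_sample_depth,
)


def test_bin_counts_follow_ceil_arithmetic():
    cfg = SimConfig(scaffolds=[("s1", 1_000_000)], bin_size=500)
    layout = generate_genome(cfg)
    assert layout.n_bins("s1") == 2000
    cfg3 = SimConfig(scaffolds=[(f"s{i}", 2_000_000) for i in range(3)], bin_size=500)
    layout3 = generate_genome(cfg3)
    assert layout3.total_bins == 12_000
    for s in layout3.scaffold_names:
        gc = layout3.gc[s]
        assert gc.size == 4000
        assert np.all((gc >= 0) & (gc <= 1))
    # uneven length rounds up
    assert GenomeLayout(scaffolds=[("x", 1001)], bin_size=500).n_bins("x") == 3


def test_generate_genome_deterministic_under_seed():
    cfg = SimConfig(seed=7)
    a = generate_genome(cfg)
    b = generate_genome(cfg)
    for s in a.scaffold_names:
        np.testing.assert_array_equal(a.gc[s], b.gc[s])


def test_invalid_genome_config_rejected():
    with pytest.raises(ConfigurationError):
        SimConfig(scaffolds=[("s1", 0)])
    with pytest.raises(ConfigurationError):
        SimConfig(bin_size=0)
    with pytest.raises(ConfigurationError):
        SimConfig(n_neutral_events=-1)


def test_empty_truth_means_diploid_everywhere():
    cfg = SimConfig(n_neutral_events=0, n_differentiated_events=0, seed=1)
    layout = generate_genome(cfg)
    truth, table = plant_truth(layout, cfg)
    assert truth == []
    assert set(table["population"]) == {"wild", "domestic"}


def test_fixed_frequencies_force_carrier_status():
    cfg = SimConfig(
        n_samples={"wild": 6, "domestic": 6},
        n_neutral_events=0,
        n_differentiated_events=1,
        diff_freq_high=1.0,
        diff_freq_low=0.0,
        seed=3,
    )
    layout = generate_genome(cfg)
    truth, table = plant_truth(layout, cfg)
    (event,) = truth
    wild = table.loc[table["population"] == "wild", "sample"]
    domestic = table.loc[table["population"] == "domestic", "sample"]
    assert all(event.cn_by_sample[s] != 2 for s in wild)
    assert all(event.cn_by_sample[s] == 2 for s in domestic)
    if event.kind == "loss":
        assert all(event.cn_by_sample[s] < 2 for s in wild)
    else:
        assert all(event.cn_by_sample[s] > 2 for s in wild)


def test_planted_events_are_pairwise_disjoint_and_inside_scaffolds():
    cfg = SimConfig(
        scaffolds=[(f"s{i}", 2_000_000) for i in range(5)],
        n_neutral_events=40,
        n_differentiated_events=10,
        seed=9,
    )
    layout = generate_genome(cfg)
    truth, _ = plant_truth(layout, cfg)
    assert len(truth) == 50
    by_scaffold: dict = {}
    for e in truth:
        assert 0 <= e.start < e.end <= layout.length(e.scaffold)
        assert e.end - e.start >= layout.bin_size
        by_scaffold.setdefault(e.scaffold, []).append((e.start, e.end))
    # sweep over sorted starts: no interval may start before the previous ends
    for ivs in by_scaffold.values():
        ivs.sort()
        for (a1, b1), (a2, _b2) in zip(ivs, ivs[1:]):
            assert a2 >= b1


def test_homozygous_deletion_bins_have_zero_depth():
    cfg = SimConfig(
        n_samples={"wild": 2, "domestic": 0},
        scaffolds=[("s1", 500_000)],
        n_neutral_events=3,
        neutral_freq=1.0,
        seed=5,
    )
    layout = generate_genome(cfg)
    truth, _ = plant_truth(layout, cfg)
    # force a homozygous deletion into the first event for the first sample
    truth[0].kind = "loss"
    truth[0].cn_by_sample["wild_01"] = 0
    track = simulate_sample_depth(layout, truth, "wild_01", cfg)
    lo, hi = layout.bin_range(truth[0].scaffold, truth[0].start, truth[0].end)
    assert np.all(track.raw_depth[truth[0].scaffold][lo:hi] == 0)
    for scaffold in track.scaffolds:
        q0 = track.q0_frac[scaffold]
        assert np.all((q0 >= 0) & (q0 <= 1))


def test_diploid_flat_gc_depth_matches_poisson_mean():
    cfg = SimConfig(
        n_samples={"wild": 1, "domestic": 0},
        scaffolds=[("s1", 2_000_000)],
        gc_bias_amplitude=0.0,  # flat response
        seed=8,
    )
    layout = generate_genome(cfg)
    track = simulate_sample_depth(layout, [], "wild_01", cfg)
    depth = track.raw_depth["s1"]
    se = np.sqrt(cfg.mean_depth / depth.size)
    assert abs(depth.mean() - cfg.mean_depth) < 3 * se


def test_simulated_tracks_deterministic_under_seed():
    cfg = SimConfig(n_neutral_events=4, seed=12)
    layout = generate_genome(cfg)
    truth, _ = plant_truth(layout, cfg)
    a = simulate_sample_depth(layout, truth, "wild_01", cfg)
    b = simulate_sample_depth(layout, truth, "wild_01", cfg)
    for s in a.scaffolds:
        np.testing.assert_array_equal(a.raw_depth[s], b.raw_depth[s])
        np.testing.assert_array_equal(a.q0_frac[s], b.q0_frac[s])


def test_unknown_sample_rejected():
    cfg = SimConfig(seed=1)
    layout = generate_genome(cfg)
    with pytest.raises(KeyError):
        simulate_sample_depth(layout, [], "nobody", cfg)


def test_repeat_regions_elevate_q0():
    cfg = SimConfig(
        n_samples={"wild": 1, "domestic": 0},
        scaffolds=[("s1", 1_000_000)],
        repeat_regions=[("s1", 100_000, 110_000)],
        seed=2,
    )
    layout = generate_genome(cfg)
    track = simulate_sample_depth(layout, [], "wild_01", cfg)
    lo, hi = layout.bin_range("s1", 100_000, 110_000)
    assert track.q0_frac["s1"][lo:hi].mean() > 0.5
    outside = np.r_[track.q0_frac["s1"][:lo], track.q0_frac["s1"][hi:]]
    assert outside.mean() < 0.1


def test_cn_matrix_generator_plants_group_contrast():
    matrix, groups, diff_ids = simulate_cn_matrix(
        n_neutral=20, n_differentiated=3, n_per_group=(10, 10), seed=4
    )
    assert matrix.shape == (23, 20)
    assert (matrix.values >= 0).all()
    a = groups[groups == "A"].index
    b = groups[groups == "B"].index
    for rid in diff_ids:
        assert matrix.loc[rid, a].mean() > matrix.loc[rid, b].mean() + 1.0
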