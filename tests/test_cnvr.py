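"""CNVR merging: connected components, support counting, the CN matrix."""

import networkx as nx
import numpy as np
import pytest

from cnvpop.caller import CNVCall
from cnvpop.cnvr import build_cn_matrix, classify_type, merge_calls
from cnvpop.depth import BinnedDepthTrack, GenomeStats
from cnvpop.genome import GenomeLayout


def call(sample, scaffold, start, end, kind="loss", cn=None):
    if cn is None:
        cn = 1.0 if kind == "loss" else 4.0
    return CNVCall(sample_id=sample, scaffold=scaffold, start=start, end=end,
                   kind=kind, cn=cn, p_value=0.01, q0_frac=0.0)


def oracle_components(calls):
    """Connected components of the >=1bp-overlap graph, via networkx."""
    g = nx.Graph()
    g.add_nodes_from(range(len(calls)))
    for i, a in enumerate(calls):
        for j in range(i + 1, len(calls)):
            b = calls[j]
            if a.scaffold == b.scaffold and a.start < b.end and b.start < a.end:
                g.add_edge(i, j)
    out = set()
    for comp in nx.connected_components(g):
        members = [calls[i] for i in comp]
        out.add(
            (
                members[0].scaffold,
                min(c.start for c in members),
                max(c.end for c in members),
                len({c.sample_id for c in members}),
            )
        )
    return out


def test_single_call_removed_at_default_support():
    assert merge_calls([call("s1", "c", 1000, 5000)]) == []
    (r,) = merge_calls([call("s1", "c", 1000, 5000)], min_support=1)
    assert (r.start, r.end, r.support) == (1000, 5000, 1)


def test_chained_overlaps_merge_into_one_region():
    calls = [
        call("s1", "c", 1000, 5000),
        call("s2", "c", 4000, 9000),
        call("s3", "c", 8500, 12000),
        call("s4", "c", 2000, 3000),
    ]
    (r,) = merge_calls(calls, min_support=4)
    assert (r.start, r.end) == (1000, 12000)
    assert r.support == 4 and r.type == "loss"


def test_abutting_half_open_intervals_do_not_merge():
    calls = [call("s1", "c", 0, 500), call("s2", "c", 500, 900)]
    regions = merge_calls(calls, min_support=1)
    assert [(r.start, r.end) for r in regions] == [(0, 500), (500, 900)]


def test_support_counts_distinct_samples_not_calls():
    calls = [
        call("s1", "c", 0, 5000),
        call("s1", "c", 4000, 9000),  # same sample twice
        call("s2", "c", 3000, 6000),
    ]
    (r,) = merge_calls(calls, min_support=1)
    assert r.support == 2


def test_invalid_interval_rejected():
    with pytest.raises(ValueError):
        merge_calls([call("s1", "c", 500, 500)])


@pytest.mark.parametrize("kinds,expected", [
    (["gain", "gain"], "gain"),
    (["loss"], "loss"),
    (["gain", "loss"], "both"),
])
def test_classify_type(kinds, expected):
    calls = [call(f"s{i}", "c", 0, 1000, kind=k) for i, k in enumerate(kinds)]
    assert classify_type(calls) == expected


def test_merge_matches_connected_component_oracle_on_random_sets():
    rng = np.random.default_rng(123)
    for _ in range(50):
        n = int(rng.integers(1, 60))
        calls = []
        for i in range(n):
            scaffold = f"c{rng.integers(1, 4)}"
            start = int(rng.integers(0, 100_000))
            length = int(rng.integers(500, 20_000))
            calls.append(call(f"s{rng.integers(1, 8)}", scaffold, start, start + length))
        regions = merge_calls(calls, min_support=1)
        got = {(r.scaffold, r.start, r.end, r.support) for r in regions}
        assert got == oracle_components(calls)


def test_merge_is_idempotent():
    rng = np.random.default_rng(7)
    calls = []
    for i in range(40):
        start = int(rng.integers(0, 200_000))
        calls.append(call(f"s{i % 6}", "c", start, start + int(rng.integers(1000, 9000))))
    regions = merge_calls(calls, min_support=1)
    again = merge_calls(
        [call(f"s{i}", r.scaffold, r.start, r.end) for i, r in enumerate(regions)],
        min_support=1,
    )
    assert [(r.scaffold, r.start, r.end) for r in regions] == [
        (r.scaffold, r.start, r.end) for r in again
    ]
    # no two CNVRs on one scaffold overlap; calls lie inside their region
    for a, b in zip(regions, regions[1:]):
        if a.scaffold == b.scaffold:
            assert a.end <= b.start
    for r in regions:
        for c in r.contributing_calls:
            assert r.start <= c.start and c.end <= r.end


class TestCnMatrix:
    def setup_method(self):
        self.layout = GenomeLayout(scaffolds=[("c", 100_000)], bin_size=500)

    def track(self, sample, depth_value, region=None, region_value=0.0):
        depth = np.full(200, float(depth_value))
        if region:
            lo, hi = self.layout.bin_range("c", *region)
            depth[lo:hi] = region_value
        return BinnedDepthTrack(sample_id=sample, bin_size=500,
                                raw_depth={"c": depth}, q0_frac={"c": np.zeros(200)},
                                corrected_depth={"c": depth})

    def region(self, start, end):
        from cnvpop.cnvr import CNVR
        return CNVR(id="r1", scaffold="c", start=start, end=end, type="loss", support=4)

    def test_diploid_noiseless_sample_scores_exactly_two(self):
        tracks = {"a": self.track("a", 30.0)}
        stats = {"a": GenomeStats("a", 30.0, 200)}
        m = build_cn_matrix([self.region(10_000, 20_000)], tracks, stats, self.layout)
        assert m.loc["r1", "a"] == pytest.approx(2.0)

    def test_homozygous_deletion_scores_zero(self):
        tracks = {"a": self.track("a", 30.0, region=(10_000, 20_000), region_value=0.0)}
        stats = {"a": GenomeStats("a", 30.0, 200)}
        m = build_cn_matrix([self.region(10_000, 20_000)], tracks, stats, self.layout)
        assert m.loc["r1", "a"] == 0.0

    def test_poisson_cn4_carrier_recovers_dosage(self):
        rng = np.random.default_rng(11)
        depth = rng.poisson(33.5, 200).astype(float)
        lo, hi = self.layout.bin_range("c", 10_000, 20_000)
        depth[lo:hi] = rng.poisson(67.0, hi - lo)
        t = BinnedDepthTrack(sample_id="a", bin_size=500, raw_depth={"c": depth},
                             q0_frac={"c": np.zeros(200)}, corrected_depth={"c": depth})
        stats = {"a": GenomeStats("a", 33.5, 200)}
        m = build_cn_matrix([self.region(10_000, 20_000)], {"a": t}, stats, self.layout)
        assert m.loc["r1", "a"] == pytest.approx(4.0, abs=0.5)

    def test_uncovered_region_names_sample(self):
        tracks = {"a": self.track("a", 30.0)}
        stats = {"a": GenomeStats("a", 30.0, 200)}
        from cnvpop.cnvr import CNVR
        bad = CNVR(id="r9", scaffold="zz", start=0, end=1000, type="loss", support=4)
        with pytest.raises(KeyError, match="a"):
            build_cn_matrix([bad], tracks, stats, self.layout)
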