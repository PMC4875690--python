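"""Simulate a two-population resequencing cohort with planted CNVs.

Builds a 10-sample cohort over a 6 Mb genome at ~6.7x coverage: per-bin
read counts with GC bias, repeat regions with elevated multi-mapping (q0)
fractions, and 20 planted CNV events whose per-sample copy numbers are
known exactly. The printed summary shows the genome size in bins, the
planted events (coordinates, kind, carrier count) and the mean depth of
the first sample — the raw material every later stage consumes.
"""

from cnvpop import SimConfig, simulate_cohort

config = SimConfig(
    n_samples={"wild": 5, "domestic": 5},
    scaffolds=[("scaffold1", 2_000_000), ("scaffold2", 2_000_000),
               ("scaffold3", 2_000_000)],
    n_neutral_events=15,
    n_differentiated_events=5,
    n_repeat_regions=3,
    seed=1,
)
layout, truth, table, tracks = simulate_cohort(config)

print(f"genome: {layout.total_length / 1e6:.0f} Mb in {layout.total_bins} bins "
      f"of {layout.bin_size} bp")
print(f"samples: {', '.join(table['sample'])}")
print(f"planted events ({len(truth)}):")
for e in truth[:8]:
    print(f"  {e.scaffold}:{e.start}-{e.end} {e.kind:4s} "
          f"{len(e.carriers())} carriers, freq {e.pop_freq}")
print("  ...")
track = tracks["wild_01"]
mean_depth = sum(d.sum() for d in track.raw_depth.values()) / layout.total_bins
print(f"wild_01 mean depth: {mean_depth:.1f} reads/bin "
      f"(expected ~{config.mean_depth} x mean GC bias)")
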