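"""Synthetic multi-sample cohorts with planted copy-number truth.

Emulates the study design this package targets: tens of resequenced
individuals from two populations at ~6.7x mean coverage, summarised as
per-bin read counts over a multi-scaffold genome. CNV events are planted on
the bin grid with known integer copy number per carrier; carrier status is
Bernoulli per sample at a population-specific frequency, so "neutral"
events have equal frequency in both populations while "differentiated"
events differ by a configurable margin (the wild-vs-domestic contrast).

Per-bin depth is Poisson with rate
``mean_depth * (CN / 2) * gc_bias(GC_bin)``; bins inside designated repeat
regions carry an elevated multi-mapping fraction (q0). Everything is
deterministic under the configured seed.

The generator works at bin resolution by design: reads are never
synthesised, and truth breakpoints coincide with bin boundaries.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .depth import BinnedDepthTrack
from .genome import ConfigurationError, GenomeLayout

#: gains span the CN range detectable at ~6.7x; losses are hemi/homozygous
LOSS_CN = (0, 1)
GAIN_CN = (3, 4, 5, 6)


class PlacementError(RuntimeError):
    """Raised when events cannot be placed without overlap."""


def child_rng(seed: int, *keys: str | int) -> np.random.Generator:
    """Deterministic per-purpose generator derived from one global seed.

    Each key (stage name, sample id, ...) is CRC32-hashed into the seed
    sequence, so stages and samples are reproducible standalone.
    """
    entropy = [seed & 0x7FFFFFFF]
    for key in keys:
        if isinstance(key, str):
            entropy.append(zlib.crc32(key.encode()))
        else:
            entropy.append(int(key) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    ``mean_depth`` is expected reads per full bin for a diploid region;
    the default 33.5 corresponds to 6.7x base coverage with 100-bp reads
    over 500-bp bins. ``gc_bias`` is a quadratic bump peaking at GC 0.45
    with floor 0.6 (qualitatively the coverage response that motivates GC
    correction); set ``gc_bias_amplitude=0`` for a flat response.
    """

    n_samples: dict[str, int] = field(default_factory=lambda: {"wild": 5, "domestic": 5})
    scaffolds: list[tuple[str, int]] = field(
        default_factory=lambda: [(f"scaffold{i + 1}", 2_000_000) for i in range(5)]
    )
    bin_size: int = 500
    mean_depth: float = 33.5
    # GC model: smooth spatial GC track + unimodal bias response
    gc_mean: float = 0.42
    gc_sd: float = 0.07
    gc_smooth_bins: int = 50
    gc_bias_peak: float = 0.45
    gc_bias_floor: float = 0.6
    gc_bias_amplitude: float = 1.0
    # q0 model
    repeat_regions: list[tuple[str, int, int]] | None = None
    n_repeat_regions: int = 0
    repeat_region_bins: int = 20
    repeat_q0: float = 0.8
    background_q0: float = 0.02
    # truth events
    n_neutral_events: int = 0
    n_differentiated_events: int = 0
    neutral_freq: float = 0.5
    diff_freq_high: float = 0.95
    diff_freq_low: float = 0.05
    event_len_bins: tuple[int, int] = (6, 40)
    event_gap_bins: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_samples.values()):
            raise ConfigurationError("negative sample count")
        if self.n_neutral_events < 0 or self.n_differentiated_events < 0:
            raise ConfigurationError("negative event count")
        if self.mean_depth < 0:
            raise ConfigurationError("negative mean_depth")
        if self.bin_size <= 0:
            raise ConfigurationError("bin_size must be positive")
        for _, length in self.scaffolds:
            if length <= 0:
                raise ConfigurationError("non-positive scaffold length")

    def gc_bias(self, gc: np.ndarray | float) -> np.ndarray | float:
        """Relative coverage response as a function of GC fraction."""
        if self.gc_bias_amplitude == 0:
            return np.ones_like(np.asarray(gc, dtype=float)) if np.ndim(gc) else 1.0
        # quadratic bump hitting the floor at |gc - peak| = 0.35
        a = self.gc_bias_amplitude * (1.0 - self.gc_bias_floor) / 0.35**2
        return np.clip(1.0 - a * (np.asarray(gc, dtype=float) - self.gc_bias_peak) ** 2,
                       self.gc_bias_floor, 1.0)

    def sample_ids(self) -> list[tuple[str, str]]:
        """Ordered (sample_id, population) pairs, e.g. ('wild_01', 'wild')."""
        out = []
        for pop in self.n_samples:
            for i in range(self.n_samples[pop]):
                out.append((f"{pop}_{i + 1:02d}", pop))
        return out


@dataclass
class TruthEvent:
    """A planted CNV with per-sample integer copy number.

    Coordinates are 0-based half-open bp, aligned to the bin grid.
    ``cn_by_sample`` covers every sample; non-carriers are 2.
    """

    scaffold: str
    start: int
    end: int
    kind: str  # "gain" | "loss"
    cn_by_sample: dict[str, int]
    pop_freq: dict[str, float]

    @property
    def length(self) -> int:
        return self.end - self.start

    def carriers(self) -> list[str]:
        return [s for s, cn in self.cn_by_sample.items() if cn != 2]


def generate_genome(config: SimConfig) -> GenomeLayout:
    """Genome layout with a smooth per-bin GC track.

    GC is a moving-average-smoothed Gaussian process around ``gc_mean``,
    clipped to [0, 1] — spatially autocorrelated like real isochore
    structure, without modelling actual sequence.
    """
    rng = child_rng(config.seed, "genome")
    gc: dict[str, np.ndarray] = {}
    layout = GenomeLayout(scaffolds=list(config.scaffolds), bin_size=config.bin_size)
    for name, _length in config.scaffolds:
        n = layout.n_bins(name)
        white = rng.standard_normal(n + config.gc_smooth_bins)
        kernel = np.ones(config.gc_smooth_bins + 1)
        smooth = np.convolve(white, kernel, mode="valid")
        smooth /= np.sqrt(config.gc_smooth_bins + 1)
        gc[name] = np.clip(config.gc_mean + config.gc_sd * smooth, 0.0, 1.0)
    return GenomeLayout(scaffolds=list(config.scaffolds), bin_size=config.bin_size, gc=gc)


def _place_events(
    layout: GenomeLayout, config: SimConfig, n_events: int, rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    """Non-overlapping bin-aligned intervals, separated by a guard gap."""
    occupied: dict[str, list[tuple[int, int]]] = {s: [] for s in layout.scaffold_names}
    weights = np.array([layout.n_bins(s) for s in layout.scaffold_names], dtype=float)
    weights /= weights.sum()
    placed: list[tuple[str, int, int]] = []
    max_tries = 1000 * max(n_events, 1)
    tries = 0
    lo, hi = config.event_len_bins
    gap = config.event_gap_bins
    while len(placed) < n_events:
        if tries >= max_tries:
            raise PlacementError(
                f"placed only {len(placed)}/{n_events} events after {tries} tries"
            )
        tries += 1
        scaffold = rng.choice(layout.scaffold_names, p=weights)
        n_bins = layout.n_bins(scaffold)
        len_bins = int(rng.integers(lo, hi + 1))
        if len_bins + 2 * gap >= n_bins:
            continue
        start_bin = int(rng.integers(gap, n_bins - len_bins - gap))
        lo_b, hi_b = start_bin - gap, start_bin + len_bins + gap
        if any(a < hi_b and lo_b < b for a, b in occupied[scaffold]):
            continue
        occupied[scaffold].append((lo_b, hi_b))
        placed.append(
            (scaffold, start_bin * layout.bin_size, (start_bin + len_bins) * layout.bin_size)
        )
    return placed


def plant_truth(
    layout: GenomeLayout, config: SimConfig
) -> tuple[list[TruthEvent], pd.DataFrame]:
    """Plant neutral and population-differentiated truth events.

    Returns the events plus a sample table (sample, population,
    altitude_class). Differentiated events get carrier frequency
    ``diff_freq_high`` in the first population and ``diff_freq_low`` in the
    others; neutral events get ``neutral_freq`` everywhere. Carrier copy
    number is drawn uniformly from {0,1} for losses and {3,4,5,6} for
    gains.
    """
    rng = child_rng(config.seed, "truth")
    samples = config.sample_ids()
    pops = list(config.n_samples)
    # altitude classes split the second population (domestic) for the
    # high/low-altitude contrast; wild samples get their own class
    altitude = {}
    for pop in pops:
        members = [s for s, p in samples if p == pop]
        for i, s in enumerate(members):
            if pop == pops[0]:
                altitude[s] = "wild_range"
            else:
                altitude[s] = "high" if i % 2 == 0 else "low"
    table = pd.DataFrame(
        {
            "sample": [s for s, _ in samples],
            "population": [p for _, p in samples],
            "altitude_class": [altitude[s] for s, _ in samples],
        }
    )
    n_total = config.n_neutral_events + config.n_differentiated_events
    intervals = _place_events(layout, config, n_total, rng)
    events: list[TruthEvent] = []
    for i, (scaffold, start, end) in enumerate(intervals):
        differentiated = i >= config.n_neutral_events
        if differentiated:
            pop_freq = {
                pop: (config.diff_freq_high if pop == pops[0] else config.diff_freq_low)
                for pop in pops
            }
        else:
            pop_freq = {pop: config.neutral_freq for pop in pops}
        kind = "loss" if rng.random() < 0.5 else "gain"
        cn_pool = LOSS_CN if kind == "loss" else GAIN_CN
        cn_by_sample = {}
        for sample, pop in samples:
            if rng.random() < pop_freq[pop]:
                cn_by_sample[sample] = int(rng.choice(cn_pool))
            else:
                cn_by_sample[sample] = 2
        events.append(
            TruthEvent(
                scaffold=scaffold,
                start=start,
                end=end,
                kind=kind,
                cn_by_sample=cn_by_sample,
                pop_freq=pop_freq,
            )
        )
    events.sort(key=lambda e: (e.scaffold, e.start))
    return events, table


def _resolve_repeats(
    layout: GenomeLayout, config: SimConfig, truth: list[TruthEvent]
) -> list[tuple[str, int, int]]:
    """Repeat regions: explicit from config, or placed clear of truth events."""
    if config.repeat_regions is not None:
        return list(config.repeat_regions)
    if config.n_repeat_regions == 0:
        return []
    rng = child_rng(config.seed, "repeats")
    length = config.repeat_region_bins * layout.bin_size
    names = layout.scaffold_names
    weights = np.array([layout.n_bins(s) for s in names], dtype=float)
    weights /= weights.sum()
    avoid = [(e.scaffold, e.start, e.end) for e in truth]
    placed: list[tuple[str, int, int]] = []
    tries = 0
    while len(placed) < config.n_repeat_regions:
        if tries >= 1000 * config.n_repeat_regions:
            raise PlacementError("cannot place repeat regions clear of truth events")
        tries += 1
        scaffold = rng.choice(names, p=weights)
        n_bins = layout.n_bins(scaffold)
        if config.repeat_region_bins >= n_bins:
            continue
        start = int(rng.integers(0, n_bins - config.repeat_region_bins)) * layout.bin_size
        end = start + length
        if any(sc == scaffold and start < b and a < end for sc, a, b in avoid + placed):
            continue
        placed.append((scaffold, start, end))
    return placed


def cn_profile_for_sample(
    layout: GenomeLayout, truth: list[TruthEvent], sample_id: str
) -> dict[str, np.ndarray]:
    """Per-bin true copy number for one sample (background CN 2)."""
    cn: dict[str, np.ndarray] = {
        s: np.full(layout.n_bins(s), 2.0) for s in layout.scaffold_names
    }
    for event in truth:
        value = event.cn_by_sample.get(sample_id, 2)
        if value == 2:
            continue
        lo, hi = layout.bin_range(event.scaffold, event.start, event.end)
        cn[event.scaffold][lo:hi] = value
    return cn


def simulate_sample_depth(
    layout: GenomeLayout,
    truth: list[TruthEvent],
    sample_id: str,
    config: SimConfig,
    repeat_regions: list[tuple[str, int, int]] | None = None,
) -> BinnedDepthTrack:
    """Poisson per-bin depth for one sample given its planted CN profile."""
    known = {s for s, _ in config.sample_ids()}
    if sample_id not in known:
        raise KeyError(f"unknown sample {sample_id!r}")
    if repeat_regions is None:
        repeat_regions = _resolve_repeats(layout, config, truth)
    rng = child_rng(config.seed, "depth", sample_id)
    cn = cn_profile_for_sample(layout, truth, sample_id)
    raw: dict[str, np.ndarray] = {}
    q0: dict[str, np.ndarray] = {}
    for scaffold in layout.scaffold_names:
        n = layout.n_bins(scaffold)
        gc = layout.gc.get(scaffold)
        bias = config.gc_bias(gc) if gc is not None else 1.0
        # partial terminal bin contributes proportionally to its width
        width = np.full(n, 1.0)
        tail = layout.length(scaffold) - (n - 1) * layout.bin_size
        width[-1] = tail / layout.bin_size
        rate = config.mean_depth * (cn[scaffold] / 2.0) * bias * width
        raw[scaffold] = rng.poisson(rate).astype(float)
        q = config.background_q0 + np.abs(rng.normal(0.0, 0.01, size=n))
        q0[scaffold] = q
    for scaffold, start, end in repeat_regions:
        lo, hi = layout.bin_range(scaffold, start, end)
        n = hi - lo
        q0[scaffold][lo:hi] = config.repeat_q0 + rng.normal(0.0, 0.03, size=n)
    for scaffold in q0:
        q0[scaffold] = np.clip(q0[scaffold], 0.0, 1.0)
    return BinnedDepthTrack(
        sample_id=sample_id, bin_size=layout.bin_size, raw_depth=raw, q0_frac=q0
    )


def simulate_cohort(
    config: SimConfig,
) -> tuple[GenomeLayout, list[TruthEvent], pd.DataFrame, dict[str, BinnedDepthTrack]]:
    """Full cohort: layout, truth, sample table and one track per sample."""
    layout = generate_genome(config)
    truth, table = plant_truth(layout, config)
    repeats = _resolve_repeats(layout, config, truth)
    tracks = {
        sample: simulate_sample_depth(layout, truth, sample, config, repeat_regions=repeats)
        for sample, _pop in config.sample_ids()
    }
    return layout, truth, table, tracks


def simulate_cn_matrix(
    n_neutral: int,
    n_differentiated: int,
    n_per_group: tuple[int, int],
    diff_cn: int = 4,
    diff_freq: tuple[float, float] = (0.95, 0.05),
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """CNVR-by-sample copy-number matrix with planted differentiated rows.

    A lightweight stand-in for the full depth pipeline when only the
    population-differentiation stage is under study: neutral rows share one
    carrier frequency across both groups; differentiated rows place CN
    ``diff_cn`` carriers at ``diff_freq[0]`` in group A and ``diff_freq[1]``
    in group B. Gaussian noise emulates depth-estimation error.

    Returns (matrix, group assignment series, planted differentiated ids).
    """
    rng = np.random.default_rng(seed)
    n_a, n_b = n_per_group
    samples = [f"A_{i + 1:02d}" for i in range(n_a)] + [f"B_{i + 1:02d}" for i in range(n_b)]
    groups = pd.Series(["A"] * n_a + ["B"] * n_b, index=samples, name="population")
    rows = {}
    diff_ids = []
    for r in range(n_neutral):
        freq = rng.uniform(0.1, 0.9)
        base_cn = rng.choice([0, 1, 3, 4])
        carrier = rng.random(n_a + n_b) < freq
        cn = np.where(carrier, base_cn, 2).astype(float)
        rows[f"neutral_{r + 1:03d}"] = cn
    for r in range(n_differentiated):
        rid = f"diff_{r + 1:03d}"
        diff_ids.append(rid)
        carrier = np.concatenate(
            [rng.random(n_a) < diff_freq[0], rng.random(n_b) < diff_freq[1]]
        )
        rows[rid] = np.where(carrier, float(diff_cn), 2.0)
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    matrix += rng.normal(0.0, noise_sd, size=matrix.shape)
    return matrix.clip(lower=0.0), groups, diff_ids


def synthesize_gene_models(
    layout: GenomeLayout,
    n_genes: int,
    term_pool: list[str] | None = None,
    terms_per_gene: tuple[int, int] = (0, 3),
    length_range: tuple[int, int] = (1_000, 10_000),
    seed: int = 0,
) -> pd.DataFrame:
    """Random gene models (synthetic fixture for annotation tests).

    Columns: gene_id, scaffold, start, end, terms (comma-joined). Genes may
    overlap each other, as real gene models do.
    """
    rng = np.random.default_rng(seed)
    names = layout.scaffold_names
    weights = np.array([layout.length(s) for s in names], dtype=float)
    weights /= weights.sum()
    records = []
    for i in range(n_genes):
        scaffold = rng.choice(names, p=weights)
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        max_start = max(layout.length(scaffold) - length, 1)
        start = int(rng.integers(0, max_start))
        if term_pool:
            k = int(rng.integers(terms_per_gene[0], terms_per_gene[1] + 1))
            terms = ",".join(sorted(rng.choice(term_pool, size=k, replace=False))) if k else ""
        else:
            terms = ""
        records.append((f"gene_{i + 1:04d}", scaffold, start, start + length, terms))
    df = pd.DataFrame(records, columns=["gene_id", "scaffold", "start", "end", "terms"])
    return df.sort_values(["scaffold", "start"], ignore_index=True)


def synthesize_sd_intervals(
    layout: GenomeLayout,
    n_intervals: int,
    length_range: tuple[int, int] = (1_000, 50_000),
    near: list[tuple[str, int, int]] | None = None,
    near_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Random segmental-duplication intervals (synthetic fixture).

    With ``near_fraction > 0``, that fraction of intervals is placed
    adjacent to the provided ``near`` intervals, emulating the CNV-SD
    colocation the association test is meant to detect.
    """
    rng = np.random.default_rng(seed)
    names = layout.scaffold_names
    weights = np.array([layout.length(s) for s in names], dtype=float)
    weights /= weights.sum()
    records = []
    for i in range(n_intervals):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        if near and rng.random() < near_fraction:
            scaffold, a, b = near[int(rng.integers(len(near)))]
            anchor = a if rng.random() < 0.5 else b
            start = int(np.clip(anchor + int(rng.integers(-length, 1)), 0,
                                max(layout.length(scaffold) - length, 0)))
        else:
            scaffold = rng.choice(names, p=weights)
            start = int(rng.integers(0, max(layout.length(scaffold) - length, 1)))
        records.append((scaffold, start, start + length))
    df = pd.DataFrame(records, columns=["scaffold", "start", "end"])
    return df.sort_values(["scaffold", "start"], ignore_index=True)
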