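"""Per-sample CNV calling from segmented read depth.

A segment becomes a CNV call when its bin depths differ significantly
from the genome-wide mean depth (one-sample t-test, Benjamini-Hochberg
adjusted p < alpha across all segments of the sample), it is at least
``min_length`` bp long, and its mean multi-mapping fraction (q0) does not
exceed ``max_q0``. Copy number is normalised to the diploid baseline:
``cn = 2 * segment_mean / genome_mean``. Boundaries are reported on bin
edges — the resolution of the underlying signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .depth import BinnedDepthTrack, DegenerateInputError, GenomeStats, gc_correct, genome_stats
from .genome import GenomeLayout
from .segment import DEFAULT_BANDWIDTHS, Segment, segment_track


@dataclass
class CNVCall:
    """One sample's gain or loss interval with diploid-normalised CN."""

    sample_id: str
    scaffold: str
    start: int  # bp, bin-aligned, half-open
    end: int
    kind: str  # "gain" | "loss"
    cn: float
    p_value: float  # BH-adjusted significance vs genome mean RD
    q0_frac: float  # mean multi-mapping fraction over the call's bins

    @property
    def length(self) -> int:
        return self.end - self.start


def _segment_p_values(segments: list[Segment], track: BinnedDepthTrack, genome_mean: float):
    """One-sample t-test of each segment's bin depths against the genome mean."""
    pvals = np.ones(len(segments))
    for i, seg in enumerate(segments):
        rd = track.depth(seg.scaffold)[seg.start_bin : seg.end_bin]
        if rd.size < 2:
            # single-bin segment: no within-segment variance to test against
            pvals[i] = 1.0
            continue
        if np.ptp(rd) == 0.0:
            pvals[i] = 1.0 if rd[0] == genome_mean else 0.0
            continue
        pvals[i] = stats.ttest_1samp(rd, genome_mean).pvalue
    return pvals


def call_cnvs(
    segments: list[Segment],
    track: BinnedDepthTrack,
    stats_: GenomeStats,
    min_length: int = 1500,
    max_q0: float = 0.5,
    alpha: float = 0.05,
    min_cn_dev: float = 0.5,
) -> list[CNVCall]:
    """Turn segments into filtered CNV calls.

    Filters applied, mirroring read-depth practice: significance vs the
    genome mean (BH-adjusted one-sample t-test p < ``alpha``), length
    >= ``min_length`` bp, mean q0 <= ``max_q0``, and a copy-number
    deviation gate ``|cn - 2| >= min_cn_dev``. The default 0.5 is the
    classic deletion/duplication cutoff at 0.75x / 1.25x of the mean RD:
    with enough bins even a 2% drift of a long diploid stretch is
    statistically significant, so significance alone cannot separate
    biology from baseline wobble.
    """
    if stats_.mean_rd <= 0:
        raise DegenerateInputError("zero genome mean depth")
    if not segments:
        return []
    pvals = _segment_p_values(segments, track, stats_.mean_rd)
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    bin_size = track.bin_size
    calls: list[CNVCall] = []
    for seg, p in zip(segments, p_adj):
        cn = 2.0 * seg.mean_rd / stats_.mean_rd
        if abs(cn - 2.0) < min_cn_dev:
            continue
        start = seg.start_bin * bin_size
        end = seg.end_bin * bin_size
        if p >= alpha:
            continue
        if end - start < min_length:
            continue
        q0 = float(track.q0_frac[seg.scaffold][seg.start_bin : seg.end_bin].mean())
        if q0 > max_q0:
            continue
        calls.append(
            CNVCall(
                sample_id=track.sample_id,
                scaffold=seg.scaffold,
                start=start,
                end=end,
                kind="gain" if cn > 2.0 else "loss",
                cn=cn,
                p_value=float(p),
                q0_frac=q0,
            )
        )
    calls.sort(key=lambda c: (c.scaffold, c.start))
    return calls


def call_sample(
    track: BinnedDepthTrack,
    layout: GenomeLayout,
    bandwidths=DEFAULT_BANDWIDTHS,
    min_length: int = 1500,
    max_q0: float = 0.5,
    alpha: float = 0.05,
    min_cn_dev: float = 0.5,
    merge_alpha: float = 0.01,
    sex_scaffolds: set[str] | frozenset[str] = frozenset(),
) -> tuple[list[CNVCall], GenomeStats]:
    """GC-correct, segment and call one sample end to end."""
    corrected = gc_correct(track, layout)
    gstats = genome_stats(corrected, exclude_scaffolds=sex_scaffolds)
    segments = segment_track(corrected, bandwidths=bandwidths, merge_alpha=merge_alpha)
    calls = call_cnvs(
        segments, corrected, gstats, min_length=min_length, max_q0=max_q0, alpha=alpha,
        min_cn_dev=min_cn_dev,
    )
    return calls, gstats
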