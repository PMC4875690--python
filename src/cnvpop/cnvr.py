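"""Cross-sample CNV regions (CNVRs) and the CNVR-by-sample CN matrix.

A CNVR is a connected component of the overlap graph of per-sample CNV
calls: any amount of overlap (>= 1 bp, half-open — abutment does not
merge) chains calls together, and the region's boundaries are the extremes
of its component. Regions supported by fewer than ``min_support`` distinct
samples are dropped, the usual guard against coverage artefacts private to
one or two genomes.

The CN matrix assigns every sample a depth-derived copy number in every
CNVR — including samples with no call there — so downstream
differentiation statistics see real dosage rather than an imputed 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .caller import CNVCall
from .depth import BinnedDepthTrack, GenomeStats
from .genome import GenomeLayout


@dataclass
class CNVR:
    """A merged cross-sample copy-number-variable region."""

    id: str
    scaffold: str
    start: int
    end: int
    type: str  # "gain" | "loss" | "both"
    support: int  # distinct samples with an overlapping call
    contributing_calls: list[CNVCall] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def classify_type(calls: list[CNVCall]) -> str:
    """gain / loss / both from the kinds of the contributing calls."""
    kinds = {c.kind for c in calls}
    if not kinds:
        raise ValueError("CNVR with no contributing calls")
    if kinds == {"gain"}:
        return "gain"
    if kinds == {"loss"}:
        return "loss"
    return "both"


def merge_calls(calls: list[CNVCall], min_support: int = 4) -> list[CNVR]:
    """Merge all samples' calls into CNVRs and apply the support filter.

    Single sorted sweep per scaffold: because components of interval
    overlap are contiguous in start order, a call starting before the
    running maximum end extends the open component; otherwise it opens a
    new one.
    """
    for c in calls:
        if c.end <= c.start:
            raise ValueError(f"call with end <= start: {c}")
    regions: list[CNVR] = []
    by_scaffold: dict[str, list[CNVCall]] = {}
    for c in sorted(calls, key=lambda c: (c.scaffold, c.start, c.end)):
        by_scaffold.setdefault(c.scaffold, []).append(c)
    for scaffold in sorted(by_scaffold):
        component: list[CNVCall] = []
        comp_end = -1
        for c in by_scaffold[scaffold] + [None]:
            if c is not None and component and c.start < comp_end:
                component.append(c)
                comp_end = max(comp_end, c.end)
                continue
            if component:
                support = len({x.sample_id for x in component})
                regions.append(
                    CNVR(
                        id="",
                        scaffold=scaffold,
                        start=min(x.start for x in component),
                        end=comp_end,
                        type=classify_type(component),
                        support=support,
                        contributing_calls=component,
                    )
                )
            if c is not None:
                component = [c]
                comp_end = c.end
    regions = [r for r in regions if r.support >= min_support]
    regions.sort(key=lambda r: (r.scaffold, r.start))
    for i, r in enumerate(regions):
        r.id = f"cnvr_{i + 1:05d}"
    return regions


def build_cn_matrix(
    cnvrs: list[CNVR],
    tracks: dict[str, BinnedDepthTrack],
    stats: dict[str, GenomeStats],
    layout: GenomeLayout,
) -> pd.DataFrame:
    """CNVR-by-sample matrix of depth-derived copy number.

    ``value(r, s) = 2 * mean corrected depth of s over r / effective depth
    of s``. Complete by construction: every sample gets a value in every
    region, from depth, whether or not it contributed a call.
    """
    samples = list(tracks)
    values = np.zeros((len(cnvrs), len(samples)))
    for j, sample in enumerate(samples):
        track = tracks[sample]
        eff = stats[sample].mean_rd
        for i, r in enumerate(cnvrs):
            if r.scaffold not in track.raw_depth:
                raise KeyError(
                    f"sample {sample!r} has no depth on {r.scaffold!r} covering {r.id}"
                )
            lo, hi = layout.bin_range(r.scaffold, r.start, r.end)
            rd = track.depth(r.scaffold)[lo:hi]
            if rd.size == 0:
                raise KeyError(f"sample {sample!r}: region {r.id} covers no bins")
            values[i, j] = 2.0 * float(rd.mean()) / eff
    return pd.DataFrame(values, index=[r.id for r in cnvrs], columns=samples)
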