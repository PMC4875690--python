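"""Binned read-depth tracks and GC-bias correction.

The read-depth (RD) signal is a single scalar per fixed-width bin: the
number of reads overlapping the bin. ``q0`` is the fraction of those reads
that map to two or more genomic locations; bins dominated by multi-mapping
reads are unreliable for copy-number inference and calls over them are
filtered downstream.

GC correction rescales each bin by the ratio of the genome-wide mean RD to
the mean RD of all bins in the same integer-percent GC class, the standard
normalisation for the GC-dependent coverage bias of Illumina libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeLayout


class DegenerateInputError(ValueError):
    """Raised when an operation receives an all-zero or empty signal."""


@dataclass
class BinnedDepthTrack:
    """One sample's per-bin depth signal over a genome layout.

    Per scaffold: ``raw_depth`` (reads overlapping each bin), optional
    ``corrected_depth`` (after GC correction) and ``q0_frac`` (multi-mapping
    read fraction, in [0, 1]). Bin starts are implicit from the layout's
    uniform grid.
    """

    sample_id: str
    bin_size: int
    raw_depth: dict[str, np.ndarray]
    q0_frac: dict[str, np.ndarray]
    corrected_depth: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.raw_depth.items():
            self.raw_depth[name] = np.asarray(arr, dtype=float)
        for name, arr in self.q0_frac.items():
            arr = np.asarray(arr, dtype=float)
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError(f"q0 fractions outside [0, 1] on {name!r}")
            self.q0_frac[name] = arr

    @property
    def scaffolds(self) -> list[str]:
        return list(self.raw_depth)

    def depth(self, scaffold: str) -> np.ndarray:
        """Corrected depth if present, else raw."""
        if self.corrected_depth:
            return self.corrected_depth[scaffold]
        return self.raw_depth[scaffold]


def gc_correct(
    track: BinnedDepthTrack,
    layout: GenomeLayout,
    min_class_bins: int = 100,
) -> BinnedDepthTrack:
    """Rescale bin depth by integer-percent GC class.

    ``corrected[b] = raw[b] * global_mean / class_mean(GC%[b])``. GC classes
    with fewer than ``min_class_bins`` bins (or zero mean) fall back to the
    global mean, i.e. are left uncorrected. The genome-wide mean depth is
    preserved exactly whenever no fallback triggers.
    """
    scaffolds = [s for s in track.scaffolds if s in layout.gc]
    if set(track.scaffolds) - set(scaffolds):
        missing = sorted(set(track.scaffolds) - set(scaffolds))
        raise KeyError(f"no GC track for scaffolds {missing}")
    raw_all = np.concatenate([track.raw_depth[s] for s in scaffolds])
    if raw_all.size == 0 or not np.any(raw_all > 0):
        raise DegenerateInputError(f"sample {track.sample_id!r}: all-zero depth track")
    gc_all = np.concatenate([layout.gc[s] for s in scaffolds])
    gc_class = np.rint(gc_all * 100).astype(int)

    global_mean = raw_all.mean()
    # per-class scaling factor, identity where the class is too sparse
    factor = np.ones(101)
    counts = np.bincount(gc_class, minlength=101)
    sums = np.bincount(gc_class, weights=raw_all, minlength=101)
    ok = (counts >= min_class_bins) & (sums > 0)
    factor[ok] = global_mean / (sums[ok] / counts[ok])

    corrected: dict[str, np.ndarray] = {}
    offset = 0
    for s in scaffolds:
        n = track.raw_depth[s].size
        cls = gc_class[offset : offset + n]
        corrected[s] = track.raw_depth[s] * factor[cls]
        offset += n
    return BinnedDepthTrack(
        sample_id=track.sample_id,
        bin_size=track.bin_size,
        raw_depth=track.raw_depth,
        q0_frac=track.q0_frac,
        corrected_depth=corrected,
    )


@dataclass
class GenomeStats:
    """Per-sample genome-wide depth summary used for CN normalisation.

    ``mean_rd`` is the effective depth: the mean corrected autosomal bin
    depth, the denominator turning depth ratios into copy number (a diploid
    region has ratio 1, CN 2).
    """

    sample_id: str
    mean_rd: float
    n_bins: int


def genome_stats(
    track: BinnedDepthTrack,
    exclude_scaffolds: set[str] | frozenset[str] = frozenset(),
) -> GenomeStats:
    """Mean corrected depth over autosomal bins.

    ``exclude_scaffolds`` removes sex scaffolds, whose hemizygosity would
    bias the diploid baseline.
    """
    arrays = [track.depth(s) for s in track.scaffolds if s not in exclude_scaffolds]
    if not arrays:
        raise DegenerateInputError("no scaffolds left after exclusion")
    allbins = np.concatenate(arrays)
    mean = float(allbins.mean())
    if mean <= 0:
        raise DegenerateInputError(f"sample {track.sample_id!r}: zero genome mean depth")
    return GenomeStats(sample_id=track.sample_id, mean_rd=mean, n_bins=int(allbins.size))
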