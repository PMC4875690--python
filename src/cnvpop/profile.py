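"""Windowed copy-number profiles and heatmaps over a genomic region.

For every sample and every fixed-width window tiling a region, the
profile holds the ratio of the window's mean corrected depth to the
sample's effective depth (genome-wide mean corrected autosomal depth);
the CN scale is twice that ratio. This is the matrix behind per-locus
population heatmaps: carriers of a loss sit below the diploid band,
carriers of a gain above it.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .depth import BinnedDepthTrack, GenomeStats  # noqa: E402
from .genome import ConfigurationError, GenomeLayout  # noqa: E402


@dataclass
class WindowedCnProfile:
    scaffold: str
    start: int
    end: int
    window_size: int
    samples: list[str]
    ratios: np.ndarray  # samples x windows, depth / effective depth
    window_starts: np.ndarray

    @property
    def cn(self) -> np.ndarray:
        return 2.0 * self.ratios

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with both the ratio and the CN scale."""
        records = []
        for i, sample in enumerate(self.samples):
            for j, w in enumerate(self.window_starts):
                records.append(
                    (
                        sample,
                        self.scaffold,
                        int(w),
                        int(min(w + self.window_size, self.end)),
                        self.ratios[i, j],
                        2.0 * self.ratios[i, j],
                    )
                )
        return pd.DataFrame(
            records, columns=["sample", "scaffold", "start", "end", "ratio", "cn"]
        )


def profile_region(
    tracks: dict[str, BinnedDepthTrack],
    stats: dict[str, GenomeStats],
    layout: GenomeLayout,
    scaffold: str,
    start: int,
    end: int,
    window_size: int = 5000,
) -> WindowedCnProfile:
    """Per-sample windowed depth ratios over ``scaffold:[start, end)``."""
    if window_size % layout.bin_size != 0:
        raise ConfigurationError(
            f"window size {window_size} is not a multiple of bin size {layout.bin_size}"
        )
    window_starts = np.arange(start, end, window_size, dtype=np.int64)
    samples = list(tracks)
    ratios = np.zeros((len(samples), window_starts.size))
    for i, sample in enumerate(samples):
        track = tracks[sample]
        if scaffold not in track.raw_depth:
            raise KeyError(f"sample {sample!r} has no depth on {scaffold!r}")
        depth = track.depth(scaffold)
        eff = stats[sample].mean_rd
        for j, w in enumerate(window_starts):
            lo, hi = layout.bin_range(scaffold, int(w), int(min(w + window_size, end)))
            if hi <= lo:
                raise KeyError(f"window at {w} covers no bins for sample {sample!r}")
            ratios[i, j] = float(depth[lo:hi].mean()) / eff
    return WindowedCnProfile(
        scaffold=scaffold,
        start=start,
        end=end,
        window_size=window_size,
        samples=samples,
        ratios=ratios,
        window_starts=window_starts,
    )


def render_heatmap(
    profile: WindowedCnProfile,
    out_path: str,
    groups: pd.Series | dict | None = None,
    cmap: str = "RdYlGn_r",
) -> list[str]:
    """Write a heatmap image; rows are samples, columns windows.

    With ``groups``, rows are ordered by group label (then sample id) and
    the label is appended to the row name. Returns the row order used.
    """
    if profile.ratios.size == 0:
        raise ValueError("empty profile")
    samples = list(profile.samples)
    if groups is not None:
        groups = pd.Series(groups)
        samples = sorted(samples, key=lambda s: (str(groups.get(s, "")), s))
        labels = [f"{s} ({groups.get(s, '?')})" for s in samples]
    else:
        labels = samples
    order = [profile.samples.index(s) for s in samples]
    data = profile.cn[order, :]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * data.shape[1]), max(2, 0.25 * data.shape[0]))
    )
    im = ax.imshow(data, aspect="auto", cmap=cmap, interpolation="nearest")
    ax.set_yticks(range(len(labels)), labels=labels, fontsize=6)
    ax.set_xlabel(
        f"{profile.scaffold}:{profile.start}-{profile.end} "
        f"({profile.window_size // 1000} kb windows)"
    )
    fig.colorbar(im, ax=ax, label="copy number (2 x depth ratio)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return samples
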