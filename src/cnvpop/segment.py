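"""Mean-shift segmentation of a binned read-depth signal.

The segmentation follows the mean-shift idea used by read-depth CNV
callers: each bin is assigned the direction of a kernel-weighted gradient
of the depth signal, with a Gaussian positional kernel (bandwidth ``h``
bins) and a Gaussian signal kernel whose width follows the Poisson
variance of the local depth. A candidate boundary falls between two bins
that point away from each other (left bin attracted left, right bin
attracted right).

Partitioning is multi-bandwidth, smallest first. At each bandwidth the
candidate cuts are first coalesced by a greedy bottom-up merge (adjacent
pieces whose bin-depth distributions do not differ by a pooled two-sample
t-test at ``merge_alpha`` are joined, most-similar pair first), which
dissolves the spurious fragmentation of homogeneous stretches while
keeping genuine level shifts. A coalesced segment is then *frozen* when it
differs from both of its neighbours at a genome-size-aware threshold
(``merge_alpha / n_bins`` by default — a Bonferroni-style guard, since
every bin is a potential boundary). Frozen bins are masked to the
background mean before the next, coarser bandwidth so they no longer
attract their surroundings. After the last bandwidth the tiling defined by
the frozen boundaries gets a final ``merge_alpha`` re-merge pass.

The procedure is fully deterministic for a fixed input and bandwidth list.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import special

DEFAULT_BANDWIDTHS = (2, 4, 8, 16, 32)


@dataclass
class Segment:
    """A maximal run of bins with homogeneous read depth."""

    scaffold: str
    start_bin: int  # half-open bin indices
    end_bin: int
    mean_rd: float

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin


def mean_shift_gradient(rd: np.ndarray, h: int) -> np.ndarray:
    """Kernel-weighted depth gradient at positional bandwidth ``h`` bins.

    ``g[i] = sum_d d * exp(-d^2 / 2h^2) * exp(-(rd[i+d]-rd[i])^2 /
    (2*(s_i^2+s_{i+d}^2)))`` over offsets ``|d| <= 3h``, with Poisson
    signal variance ``s_i^2 = max(rd[i], 1)``. Positive values point
    right.
    """
    n = rd.size
    g = np.zeros(n)
    var = np.maximum(rd, 1.0)
    w_max = 3 * h
    for d in range(1, min(w_max, n - 1) + 1):
        k = np.exp(-(d * d) / (2.0 * h * h))
        # pairs (i, i+d): contribute +d at i and -d at i+d
        diff = rd[d:] - rd[:-d]
        s = np.exp(-(diff * diff) / (2.0 * (var[d:] + var[:-d])))
        w = k * s * d
        g[:-d] += w
        g[d:] -= w
    return g


def _sign_change_cuts(g: np.ndarray) -> np.ndarray:
    """Boundary positions b where g[b-1] < 0 < g[b] (bins point apart)."""
    return np.flatnonzero((g[:-1] < 0) & (g[1:] > 0)) + 1


def _pooled_t_p(n1: int, s1: float, q1: float, n2: int, s2: float, q2: float) -> float:
    """Two-sided pooled-variance t-test p from segment sufficient stats.

    (n, sum, sum-of-squares) per segment. Degenerate branches: zero pooled
    variance gives p=1 for equal means and p=0 otherwise; undefined tests
    (fewer than 3 bins total) give p=1 so tiny fragments merge.
    """
    if n1 + n2 < 3:
        return 1.0
    m1, m2 = s1 / n1, s2 / n2
    ss = (q1 - n1 * m1 * m1) + (q2 - n2 * m2 * m2)
    df = n1 + n2 - 2
    sp2 = max(ss / df, 0.0)
    if sp2 == 0.0:
        return 1.0 if m1 == m2 else 0.0
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(2.0 * special.stdtr(df, -abs(t)))


def _segment_p(rd: np.ndarray, a1: int, b1: int, a2: int, b2: int) -> float:
    x = rd[a1:b1]
    y = rd[a2:b2]
    return _pooled_t_p(
        x.size, float(x.sum()), float((x * x).sum()),
        y.size, float(y.sum()), float((y * y).sum()),
    )


def merge_partition(rd: np.ndarray, bounds, merge_alpha: float = 0.01) -> list[int]:
    """Greedy bottom-up merge of a partition given interior cut positions.

    Repeatedly merges the adjacent pair with the largest pooled-t p until
    every remaining pair differs at ``p < merge_alpha``. Returns the
    surviving interior cuts. Linked-list + lazy heap, O(S log S).
    """
    n = rd.size
    edges = [0, *sorted({int(b) for b in bounds} - {0, n}), n]
    m = len(edges) - 1
    if m <= 1:
        return []
    starts = edges[:-1]
    ends = edges[1:]
    sums = [float(rd[a:b].sum()) for a, b in zip(starts, ends)]
    sqs = [float((rd[a:b] ** 2).sum()) for a, b in zip(starts, ends)]
    prev = list(range(-1, m - 1))
    nxt = list(range(1, m + 1))
    alive = [True] * m
    version = [0] * m

    def pair_p(i: int, j: int) -> float:
        return _pooled_t_p(
            ends[i] - starts[i], sums[i], sqs[i], ends[j] - starts[j], sums[j], sqs[j]
        )

    heap: list[tuple[float, int, int, int]] = []
    for i in range(m - 1):
        heapq.heappush(heap, (-pair_p(i, i + 1), i, 0, 0))
    while heap:
        negp, i, vi, vj = heapq.heappop(heap)
        if not alive[i] or nxt[i] >= m:
            continue
        j = nxt[i]
        if version[i] != vi or version[j] != vj:
            continue
        if -negp < merge_alpha:
            break
        ends[i] = ends[j]
        sums[i] += sums[j]
        sqs[i] += sqs[j]
        alive[j] = False
        nxt[i] = nxt[j]
        if nxt[i] < m:
            prev[nxt[i]] = i
        version[i] += 1
        if prev[i] >= 0:
            heapq.heappush(
                heap, (-pair_p(prev[i], i), prev[i], version[prev[i]], version[i])
            )
        if nxt[i] < m:
            heapq.heappush(heap, (-pair_p(i, nxt[i]), i, version[i], version[nxt[i]]))
    return [starts[k] for k in range(1, m) if alive[k]]


def segment_signal(
    rd: np.ndarray,
    scaffold: str = "",
    bandwidths=DEFAULT_BANDWIDTHS,
    merge_alpha: float = 0.01,
    freeze_alpha: float | None = None,
) -> list[Segment]:
    """Segment one scaffold's depth signal into a gap-free tiling."""
    rd = np.asarray(rd, dtype=float)
    n = rd.size
    if n == 0:
        return []
    if freeze_alpha is None:
        freeze_alpha = merge_alpha / max(n, 1)
    frozen: list[tuple[int, int]] = []  # disjoint (start, end) runs of bins
    work = rd.copy()
    for h in sorted(bandwidths):
        frozen_cuts = {a for a, _ in frozen} | {b for _, b in frozen}
        g = mean_shift_gradient(work, h)
        cuts = set(map(int, _sign_change_cuts(g))) | frozen_cuts
        kept = merge_partition(rd, cuts, merge_alpha)
        edges = [0, *kept, n]
        newly: list[tuple[int, int]] = []
        for i in range(len(edges) - 1):
            a, b = edges[i], edges[i + 1]
            if any(fa <= a and b <= fb for fa, fb in frozen):
                continue
            ok = (a, b) != (0, n)  # the whole-scaffold segment never freezes
            if i > 0:
                ok = ok and _segment_p(rd, edges[i - 1], a, a, b) < freeze_alpha
            if i < len(edges) - 2:
                ok = ok and _segment_p(rd, a, b, b, edges[i + 2]) < freeze_alpha
            if ok:
                newly.append((a, b))
        if newly:
            frozen = sorted(set(frozen) | set(newly))
            # mask frozen bins to the background mean so they stop
            # attracting their surroundings at coarser bandwidths
            mask = np.zeros(n, dtype=bool)
            for a, b in frozen:
                mask[a:b] = True
            background = rd[~mask].mean() if np.any(~mask) else rd.mean()
            work = rd.copy()
            work[mask] = background
    final_cuts = ({a for a, _ in frozen} | {b for _, b in frozen}) - {0, n}
    kept = merge_partition(rd, final_cuts, merge_alpha)
    edges = [0, *kept, n]
    return [
        Segment(scaffold=scaffold, start_bin=a, end_bin=b, mean_rd=float(rd[a:b].mean()))
        for a, b in zip(edges[:-1], edges[1:])
    ]


def segment_track(track, bandwidths=DEFAULT_BANDWIDTHS, merge_alpha: float = 0.01,
                  freeze_alpha: float | None = None):
    """Segment every scaffold of a depth track (corrected depth if present).

    Returns a flat list of :class:`Segment` tiling each scaffold.
    """
    segments: list[Segment] = []
    for scaffold in track.scaffolds:
        segments.extend(
            segment_signal(
                track.depth(scaffold), scaffold, bandwidths, merge_alpha, freeze_alpha
            )
        )
    return segments
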