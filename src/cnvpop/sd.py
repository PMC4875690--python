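"""CNVR-segmental duplication association.

Direct statistic: the fraction of large CNVRs (length > ``min_len``,
default 15 kb) whose interval — optionally extended by a flank on both
sides, clipped to scaffold bounds — intersects at least one SD interval.
Significance comes from a random-placement permutation test: each
permutation re-places every CNVR uniformly at random on its own scaffold
(length preserved, placements independent, mutual overlap allowed) and
recomputes the statistic; the empirical p carries the +1 correction so it
is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeLayout


class UndefinedStatisticError(ValueError):
    """Raised when the overlap fraction has an empty denominator."""


class IntervalSet:
    """Per-scaffold sorted, disjoint half-open intervals.

    Overlapping or abutting input intervals are unioned on construction,
    so membership and intersection queries are well defined.
    """

    def __init__(self, intervals: list[tuple[str, int, int]]):
        by_scaffold: dict[str, list[tuple[int, int]]] = {}
        for scaffold, start, end in intervals:
            if end <= start:
                raise ValueError(f"interval with end <= start on {scaffold}")
            by_scaffold.setdefault(scaffold, []).append((start, end))
        self.starts: dict[str, np.ndarray] = {}
        self.ends: dict[str, np.ndarray] = {}
        for scaffold, ivs in by_scaffold.items():
            ivs.sort()
            merged = [list(ivs[0])]
            for a, b in ivs[1:]:
                if a <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], b)
                else:
                    merged.append([a, b])
            self.starts[scaffold] = np.array([a for a, _ in merged], dtype=np.int64)
            self.ends[scaffold] = np.array([b for _, b in merged], dtype=np.int64)

    @property
    def scaffolds(self) -> list[str]:
        return list(self.starts)

    def __len__(self) -> int:
        return sum(s.size for s in self.starts.values())

    def to_list(self) -> list[tuple[str, int, int]]:
        out = []
        for scaffold in self.starts:
            out.extend(
                (scaffold, int(a), int(b))
                for a, b in zip(self.starts[scaffold], self.ends[scaffold])
            )
        return out

    def intersects(self, scaffold: str, start: int, end: int) -> bool:
        """True iff [start, end) overlaps any interval by >= 1 bp."""
        if scaffold not in self.starts:
            return False
        s, e = self.starts[scaffold], self.ends[scaffold]
        i = int(np.searchsorted(s, end))  # intervals starting before `end`
        return i > 0 and bool(e[i - 1] > start)

    def intersects_many(self, scaffold: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`intersects` over parallel start/end arrays."""
        if scaffold not in self.starts:
            return np.zeros(starts.size, dtype=bool)
        s, e = self.starts[scaffold], self.ends[scaffold]
        idx = np.searchsorted(s, ends)
        hit = idx > 0
        hit[hit] = e[idx[hit] - 1] > starts[hit]
        return hit


@dataclass
class PermutationResult:
    observed: float
    null_mean: float
    null_sd: float
    n_perm: int
    p_value: float
    seed: int


def overlap_fraction(
    cnvrs: IntervalSet,
    sds: IntervalSet,
    min_len: int = 15_000,
    flank: int = 0,
    layout: GenomeLayout | None = None,
) -> float:
    """Fraction of CNVRs longer than ``min_len`` touching an SD.

    With ``flank > 0`` each CNVR is extended by the flank on both sides
    before testing intersection (clipped to scaffold bounds when a layout
    is given).
    """
    total = 0
    hits = 0
    for scaffold in cnvrs.scaffolds:
        starts = cnvrs.starts[scaffold]
        ends = cnvrs.ends[scaffold]
        keep = (ends - starts) > min_len
        if not np.any(keep):
            continue
        a = starts[keep] - flank
        b = ends[keep] + flank
        a = np.maximum(a, 0)
        if layout is not None:
            b = np.minimum(b, layout.length(scaffold))
        total += int(keep.sum())
        hits += int(sds.intersects_many(scaffold, a, b).sum())
    if total == 0:
        raise UndefinedStatisticError(f"no CNVR longer than {min_len} bp")
    return hits / total


def bp_overlap(cnvrs: IntervalSet, sds: IntervalSet) -> int:
    """Total base pairs shared between the two interval sets."""
    total = 0
    for scaffold in cnvrs.scaffolds:
        if scaffold not in sds.starts:
            continue
        sa, se = sds.starts[scaffold], sds.ends[scaffold]
        for a, b in zip(cnvrs.starts[scaffold], cnvrs.ends[scaffold]):
            lo = int(np.searchsorted(se, a, side="right"))
            hi = int(np.searchsorted(sa, b, side="left"))
            for k in range(lo, hi):
                total += max(0, min(b, se[k]) - max(a, sa[k]))
    return int(total)


def permutation_test(
    cnvrs: IntervalSet,
    sds: IntervalSet,
    layout: GenomeLayout,
    n_perm: int = 1000,
    seed: int = 0,
    min_len: int = 15_000,
    flank: int = 0,
    alternative: str = "greater",
    statistic: str = "fraction",
) -> PermutationResult:
    """Random-placement null for CNVR-SD association.

    One-sided by default (enrichment): ``p = (1 + #{null >= observed}) /
    (n_perm + 1)``; ``alternative='less'`` tests depletion. The default
    statistic is the overlap *fraction* of CNVRs longer than ``min_len``;
    ``statistic='bp'`` uses total shared base pairs over all CNVRs
    instead (a near-continuous statistic with far fewer permutation
    ties).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    for scaffold in cnvrs.scaffolds:
        scaffold_len = layout.length(scaffold)
        too_long = (cnvrs.ends[scaffold] - cnvrs.starts[scaffold]) > scaffold_len
        if np.any(too_long):
            raise ValueError(f"CNVR longer than scaffold {scaffold} ({scaffold_len} bp)")
    rng = np.random.default_rng(seed)
    if statistic == "fraction":
        observed = overlap_fraction(cnvrs, sds, min_len=min_len, flank=flank, layout=layout)
        null = np.zeros(n_perm)
        total = 0
        for scaffold in cnvrs.scaffolds:
            scaffold_len = layout.length(scaffold)
            lens = cnvrs.ends[scaffold] - cnvrs.starts[scaffold]
            lens = lens[lens > min_len]
            if lens.size == 0:
                continue
            total += lens.size
            starts = rng.integers(0, scaffold_len - lens + 1, size=(n_perm, lens.size))
            a = np.maximum(starts - flank, 0)
            b = np.minimum(starts + lens + flank, scaffold_len)
            hits = sds.intersects_many(scaffold, a.ravel(), b.ravel())
            null += hits.reshape(n_perm, lens.size).sum(axis=1)
        if total == 0:
            raise UndefinedStatisticError(f"no CNVR longer than {min_len} bp")
        null /= total
    elif statistic == "bp":
        observed = float(bp_overlap(cnvrs, sds))
        null = np.empty(n_perm)
        spec = [
            (s, (cnvrs.ends[s] - cnvrs.starts[s]).astype(int))
            for s in cnvrs.scaffolds
        ]
        for i in range(n_perm):
            placed = []
            for scaffold, lens in spec:
                scaffold_len = layout.length(scaffold)
                starts = rng.integers(0, scaffold_len - lens + 1)
                placed.extend(
                    (scaffold, int(st), int(st + ln)) for st, ln in zip(starts, lens)
                )
            null[i] = bp_overlap(IntervalSet(placed), sds)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    if alternative == "greater":
        exceed = int(np.sum(null >= observed))
    elif alternative == "less":
        exceed = int(np.sum(null <= observed))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return PermutationResult(
        observed=float(observed),
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=0)),
        n_perm=n_perm,
        p_value=(1 + exceed) / (n_perm + 1),
        seed=seed,
    )
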