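"""Genome layout: scaffold table, bin grid and per-bin GC content.

All coordinates in the package are 0-based, half-open (BED convention).
Depth and copy number are handled at the resolution of fixed-width bins
(default 500 bp); the last bin of a scaffold may be shorter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


class ConfigurationError(ValueError):
    """Raised for invalid genome / simulation configuration."""


@dataclass
class GenomeLayout:
    """Scaffold lengths, bin size and per-bin GC fraction.

    Parameters
    ----------
    scaffolds
        Ordered ``(name, length_bp)`` pairs; lengths must be positive.
    bin_size
        Width of the depth bins in bp.
    gc
        Per-scaffold arrays of per-bin GC fraction in ``[0, 1]``. Each
        array has ``ceil(length / bin_size)`` entries.
    """

    scaffolds: list[tuple[str, int]]
    bin_size: int = 500
    gc: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ConfigurationError(f"bin_size must be positive, got {self.bin_size}")
        for name, length in self.scaffolds:
            if length <= 0:
                raise ConfigurationError(f"scaffold {name!r} has non-positive length {length}")
        names = [n for n, _ in self.scaffolds]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate scaffold names")
        for name, arr in self.gc.items():
            arr = np.asarray(arr, dtype=float)
            self.gc[name] = arr
            expect = self.n_bins(name)
            if arr.shape != (expect,):
                raise ConfigurationError(
                    f"scaffold {name!r}: expected {expect} GC bins, got {arr.shape}"
                )
            if np.any((arr < 0) | (arr > 1)):
                raise ConfigurationError(f"scaffold {name!r}: GC values outside [0, 1]")

    @property
    def scaffold_names(self) -> list[str]:
        return [n for n, _ in self.scaffolds]

    def length(self, scaffold: str) -> int:
        for name, length in self.scaffolds:
            if name == scaffold:
                return length
        raise KeyError(f"unknown scaffold {scaffold!r}")

    def n_bins(self, scaffold: str) -> int:
        return math.ceil(self.length(scaffold) / self.bin_size)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.scaffolds)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(n) for n in self.scaffold_names)

    def bin_starts(self, scaffold: str) -> np.ndarray:
        """Start coordinate (bp) of every bin on a scaffold."""
        return np.arange(self.n_bins(scaffold), dtype=np.int64) * self.bin_size

    def bin_range(self, scaffold: str, start: int, end: int) -> tuple[int, int]:
        """Half-open bin-index range covering bp interval ``[start, end)``."""
        lo = start // self.bin_size
        hi = math.ceil(end / self.bin_size)
        return lo, min(hi, self.n_bins(scaffold))
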