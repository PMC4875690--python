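import numpy as np
import pytest

from cnvpop.genome import GenomeLayout
from cnvpop.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_layout():
    """1 Mb single-scaffold layout with flat GC (no bias to correct)."""
    return GenomeLayout(
        scaffolds=[("s1", 1_000_000)],
        bin_size=500,
        gc={"s1": np.full(2000, 0.45)},
    )


@pytest.fixture(scope="session")
def small_cohort():
    """4+4 samples, 2x1 Mb scaffolds, a handful of planted events."""
    cfg = SimConfig(
        n_samples={"wild": 4, "domestic": 4},
        scaffolds=[("s1", 1_000_000), ("s2", 1_000_000)],
        n_neutral_events=6,
        n_differentiated_events=2,
        n_repeat_regions=2,
        seed=42,
    )
    layout, truth, table, tracks = simulate_cohort(cfg)
    return cfg, layout, truth, table, tracks
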