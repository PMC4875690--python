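"""Scoring CNV calls and differentiation scans against planted truth.

Used by the test suite and the reproduction script; the definitions are
carrier-aware: a call is a true positive only if the *calling sample* is a
carrier of the overlapped truth event, which is stricter than plain
interval overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

from .caller import CNVCall
from .genome import GenomeLayout
from .simulate import TruthEvent


@dataclass
class RecoveryReport:
    n_pairs: int  # planted (event, carrier) pairs
    n_recovered: int  # pairs matched within breakpoint and CN tolerance
    n_calls: int  # emitted calls over all samples
    n_false_calls: int  # calls overlapping no truth event of their sample

    @property
    def recovered_fraction(self) -> float:
        return self.n_recovered / self.n_pairs if self.n_pairs else float("nan")

    @property
    def false_call_fraction(self) -> float:
        return self.n_false_calls / self.n_calls if self.n_calls else 0.0


def evaluate_calls(
    truth: list[TruthEvent],
    calls: list[CNVCall],
    layout: GenomeLayout,
    breakpoint_tol_bins: int = 2,
    cn_tol: float = 0.5,
) -> RecoveryReport:
    """Score emitted calls against the planted truth.

    A planted (event, carrier) pair is recovered when the carrier has a
    call on the event's scaffold with both breakpoints within
    ``breakpoint_tol_bins`` bins of the true ones and whose estimated CN is
    within ``cn_tol`` of the planted integer CN. A call is false when it
    overlaps (by >= 1 bp) no truth event carried by its own sample.
    """
    tol = breakpoint_tol_bins * layout.bin_size
    by_sample: dict[str, list[CNVCall]] = {}
    for c in calls:
        by_sample.setdefault(c.sample_id, []).append(c)

    n_pairs = 0
    n_recovered = 0
    for event in truth:
        for sample in event.carriers():
            n_pairs += 1
            true_cn = event.cn_by_sample[sample]
            for c in by_sample.get(sample, []):
                if (
                    c.scaffold == event.scaffold
                    and abs(c.start - event.start) <= tol
                    and abs(c.end - event.end) <= tol
                    and abs(c.cn - true_cn) <= cn_tol
                ):
                    n_recovered += 1
                    break

    n_false = 0
    for c in calls:
        hit = any(
            e.scaffold == c.scaffold
            and e.start < c.end
            and c.start < e.end
            and e.cn_by_sample.get(c.sample_id, 2) != 2
            for e in truth
        )
        n_false += not hit
    return RecoveryReport(
        n_pairs=n_pairs,
        n_recovered=n_recovered,
        n_calls=len(calls),
        n_false_calls=n_false,
    )
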