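"""Validation math: qPCR ΔΔCt copy number and cv%-based concordance.

qPCR copy number is estimated relative to a diploid single-copy reference
locus (a BTF3-like control): ΔΔCt = (Ct_target - Ct_reference)_sample -
(Ct_target - Ct_reference)_calibrator, and CN = 2 * 2^(-ΔΔCt) — one cycle
of advantage doubles dosage, and the calibrator (a known-diploid sample)
pins CN = 2.

Two copy-number predictions for the same locus are concordant when the
coefficient of variation of the pair — sample (n-1) standard deviation
over the mean, i.e. |a - b| / (sqrt(2) * mean) — is below 0.25.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass
class QpcrMeasurement:
    """Ct values for one sample/target, with calibrator Cts for the same assay."""

    sample_id: str
    target_id: str
    ct_target: float
    ct_reference: float
    calibrator_ct_target: float
    calibrator_ct_reference: float

    def __post_init__(self) -> None:
        for name in (
            "ct_target",
            "ct_reference",
            "calibrator_ct_target",
            "calibrator_ct_reference",
        ):
            value = getattr(self, name)
            if value is None or not math.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {value!r}")


@dataclass
class ConcordanceResult:
    cn_primary: float
    cn_highdepth: float
    cv: float
    acceptable: bool


def ddct(m: QpcrMeasurement) -> float:
    """ΔΔCt of a measurement against its calibrator."""
    return (m.ct_target - m.ct_reference) - (
        m.calibrator_ct_target - m.calibrator_ct_reference
    )


def ddct_copy_number(m: QpcrMeasurement) -> float:
    """Copy number from ΔΔCt against a diploid reference locus."""
    return 2.0 * 2.0 ** (-ddct(m))


def cv_concordance(
    cn_primary: float, cn_highdepth: float, threshold: float = 0.25, ddof: int = 1
) -> ConcordanceResult:
    """cv of a pair of CN estimates and the <0.25 acceptance gate.

    ``ddof=1`` (default) uses the sample standard deviation of the pair,
    |a - b| / sqrt(2); ``ddof=0`` the population form |a - b| / 2.
    """
    if cn_primary < 0 or cn_highdepth < 0:
        raise ValueError("copy numbers must be >= 0")
    mean = (cn_primary + cn_highdepth) / 2.0
    if mean == 0:
        raise ValueError("cv undefined: both copy numbers are 0")
    diff = abs(cn_primary - cn_highdepth)
    sd = diff / math.sqrt(2.0) if ddof == 1 else diff / 2.0
    cv = sd / mean
    return ConcordanceResult(
        cn_primary=cn_primary,
        cn_highdepth=cn_highdepth,
        cv=cv,
        acceptable=cv < threshold,
    )


def concordance_report(
    calls_primary,
    calls_highdepth,
    threshold: float = 0.25,
    require_overlap: bool = True,
    ddof: int = 1,
) -> dict:
    """Fraction of primary calls supported by a high-depth call.

    A primary call is supported when at least one high-depth call on the
    same scaffold overlaps it by >= 1 bp (unless ``require_overlap`` is
    off, in which case any same-scaffold call qualifies) and the cv of the
    two CN estimates is below ``threshold``.
    """
    calls_primary = list(calls_primary)
    calls_highdepth = list(calls_highdepth)
    if not calls_primary:
        raise ValueError("empty primary call set: supported fraction undefined")
    supported = 0
    for c in calls_primary:
        ok = False
        for h in calls_highdepth:
            if h.scaffold != c.scaffold:
                continue
            if require_overlap and not (h.start < c.end and c.start < h.end):
                continue
            if (c.cn + h.cn) == 0:
                ok = True  # both homozygous deletions agree exactly
                break
            if cv_concordance(c.cn, h.cn, threshold=threshold, ddof=ddof).acceptable:
                ok = True
                break
        supported += ok
    return {
        "n_primary": len(calls_primary),
        "n_supported": supported,
        "supported_fraction": supported / len(calls_primary),
    }
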