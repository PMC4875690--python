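"""FASTQ quality filtering, trimming and duplicate removal.

Rules, applied in a fixed order per read:

1. discard when the fraction of undetermined bases (N) is >= 10%;
2. discard when more than 65% of bases have Phred quality <= 7;
3. discard on an adapter match: any ungapped alignment offset giving an
   overlap of more than 10 bases with at most 2 mismatches;
4. trim at the first run of 3 consecutive bases with Phred <= 13, keeping
   the 5' prefix before the run (3'-quality decay is the usual failure
   mode);
5. discard when the read (after trimming) is shorter than 45 bp.

Duplicates are removed pair-wise: only the first occurrence of each exact
(mate-1 sequence, mate-2 sequence) pair is kept — the pre-alignment notion
of a PCR duplicate.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

N_FRACTION_MAX = 0.10
LOW_Q_PHRED = 7
LOW_Q_FRACTION = 0.65
ADAPTER_MIN_OVERLAP = 11  # "more than 10 bp aligned"
ADAPTER_MAX_MISMATCH = 2
TRIM_PHRED = 13
TRIM_RUN = 3
MIN_LENGTH = 45


class FormatError(ValueError):
    pass


class PairingError(ValueError):
    pass


@dataclass
class ReadRecord:
    id: str
    sequence: str
    qualities: list[int]
    mate: int = 1

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise FormatError(
                f"read {self.id}: {len(self.sequence)} bases but "
                f"{len(self.qualities)} quality values"
            )


@dataclass
class QcReport:
    """Per-rule attrition counts; kept + discarded == input."""

    n_input: int = 0
    n_kept: int = 0
    discarded: dict[str, int] = field(
        default_factory=lambda: {
            "N fraction": 0,
            "low quality": 0,
            "adapter": 0,
            "short after trim": 0,
            "duplicate": 0,
            "mate discarded": 0,
        }
    )
    n_trimmed: int = 0
    bases_trimmed: int = 0

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "discarded": dict(self.discarded),
            "n_trimmed": self.n_trimmed,
            "bases_trimmed": self.bases_trimmed,
        }


def adapter_match(sequence: str, adapter: str) -> bool:
    """Ungapped scan of every alignment offset of adapter vs read.

    A hit is any overlap of >= 11 aligned bases with <= 2 mismatches.
    """
    n, m = len(sequence), len(adapter)
    for offset in range(-m + 1, n):
        lo = max(0, offset)
        hi = min(n, offset + m)
        if hi - lo < ADAPTER_MIN_OVERLAP:
            continue
        mismatches = 0
        for i in range(lo, hi):
            if sequence[i] != adapter[i - offset]:
                mismatches += 1
                if mismatches > ADAPTER_MAX_MISMATCH:
                    break
        else:
            return True
    return False


def trim_low_quality(read: ReadRecord) -> ReadRecord:
    """Cut at the first run of TRIM_RUN consecutive bases with Phred <= 13."""
    q = read.qualities
    run = 0
    for i, value in enumerate(q):
        run = run + 1 if value <= TRIM_PHRED else 0
        if run == TRIM_RUN:
            cut = i - TRIM_RUN + 1
            return ReadRecord(
                id=read.id,
                sequence=read.sequence[:cut],
                qualities=q[:cut],
                mate=read.mate,
            )
    return read


def qc_read(read: ReadRecord, adapters: list[str] | None = None):
    """Apply rules 1-5 to one read.

    Returns ``("keep", trimmed_read)`` or ``("discard", reason)``.
    """
    seq = read.sequence.upper()
    n = len(seq)
    if n == 0:
        return ("discard", "short after trim")
    if seq.count("N") / n >= N_FRACTION_MAX:
        return ("discard", "N fraction")
    low = sum(1 for q in read.qualities if q <= LOW_Q_PHRED)
    if low / n > LOW_Q_FRACTION:
        return ("discard", "low quality")
    for adapter in adapters or []:
        if adapter_match(seq, adapter.upper()):
            return ("discard", "adapter")
    trimmed = trim_low_quality(read)
    if len(trimmed.sequence) < MIN_LENGTH:
        return ("discard", "short after trim")
    return ("keep", trimmed)


def qc_pairs(pairs, adapters: list[str] | None = None, deduplicate_pairs: bool = True):
    """QC a stream of (mate1, mate2) ReadRecord pairs.

    A pair survives only if both mates pass; duplicate removal (exact
    sequence match on both mates, first occurrence kept) runs after the
    per-read rules. Returns (kept pairs, QcReport); the report counts
    reads, not pairs.
    """
    report = QcReport()
    kept: list[tuple[ReadRecord, ReadRecord]] = []
    seen: set[tuple[str, str]] = set()
    for r1, r2 in pairs:
        if r1.id.split("/")[0] != r2.id.split("/")[0]:
            raise PairingError(f"mates {r1.id!r} and {r2.id!r} do not pair")
        report.n_input += 2
        d1 = qc_read(r1, adapters)
        d2 = qc_read(r2, adapters)
        if d1[0] == "discard" or d2[0] == "discard":
            for d in (d1, d2):
                # the surviving mate of a broken pair is dropped with it
                report.discarded[d[1] if d[0] == "discard" else "mate discarded"] += 1
            continue
        t1, t2 = d1[1], d2[1]
        for original, trimmed in ((r1, t1), (r2, t2)):
            cut = len(original.sequence) - len(trimmed.sequence)
            if cut:
                report.n_trimmed += 1
                report.bases_trimmed += cut
        if deduplicate_pairs:
            key = (t1.sequence, t2.sequence)
            if key in seen:
                report.discarded["duplicate"] += 2
                continue
            seen.add(key)
        kept.append((t1, t2))
        report.n_kept += 2
    return kept, report


def deduplicate(pairs):
    """Drop later exact duplicates of (mate1 sequence, mate2 sequence) pairs."""
    kept = []
    seen: set[tuple[str, str]] = set()
    dropped = 0
    for r1, r2 in pairs:
        key = (r1.sequence, r2.sequence)
        if key in seen:
            dropped += 1
            continue
        seen.add(key)
        kept.append((r1, r2))
    return kept, dropped


def _open_maybe_gz(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path, mate: int = 1) -> list[ReadRecord]:
    with _open_maybe_gz(Path(path)) as handle:
        return [
            ReadRecord(
                id=rec.id,
                sequence=str(rec.seq),
                qualities=list(rec.letter_annotations["phred_quality"]),
                mate=mate,
            )
            for rec in SeqIO.parse(handle, "fastq")
        ]


def write_fastq(reads: list[ReadRecord], path: str | Path) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    with _open_maybe_gz(Path(path), "wt") as handle:
        SeqIO.write(records, handle, "fastq")
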