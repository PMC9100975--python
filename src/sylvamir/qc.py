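"""Small-RNA read QC: 3' adapter inference, trimming, six-way filtering.

Single-end 1x50 bp small-RNA reads carry the sequenced insert (an 18-30 nt
small RNA) followed by the 3' sequencing adapter. QC proceeds by inferring
(or accepting) the adapter, trimming each read at its first adapter
occurrence, and assigning every read to exactly one of six discard
categories or to the clean set. Because each read lands in exactly one
bucket, the report satisfies an exact integer conservation identity:

    raw == clean + low_quality + high_n + five_prime_adapter
               + no_three_prime_adapter + poly_nt + length_out_of_range

Filter test order is fixed (low_quality -> high_n -> five_prime_adapter ->
no_three_prime_adapter -> poly_nt -> length_out_of_range -> clean) so that
per-category counts are additive.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, fields
from typing import Iterable

from .seq import gc_fraction, revcomp

ADAPTER_SEED_LEN = 10


@dataclass
class ReadRecord:
    """A sequencing read with per-base Phred quality scores."""

    id: str
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: sequence/quality length mismatch "
                f"({len(self.sequence)} vs {len(self.qualities)})"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FilterParams:
    """Thresholds of the six-way filter.

    low_quality_frac: discard if the fraction of bases with Q < q_min
        exceeds this value.
    high_n_frac: discard if the N fraction exceeds this value.
    poly_frac: discard if a single base makes up at least this fraction of
        the trimmed read (poly A/T/C/G).
    min_len / max_len: allowed trimmed-insert length window (inclusive).
    adapter5: explicit 5'-adapter detection string; by default the last
        10 nt of the reverse complement of the 3' adapter.
    """

    q_min: int = 20
    low_quality_frac: float = 0.30
    high_n_frac: float = 0.10
    poly_frac: float = 0.80
    min_len: int = 18
    max_len: int = 30
    adapter5: str | None = None
    max_seed_mismatch: int = 1


@dataclass
class FilterReport:
    """Per-category discard ledger plus library-level base statistics."""

    raw: int = 0
    clean: int = 0
    low_quality: int = 0
    high_n: int = 0
    five_prime_adapter: int = 0
    no_three_prime_adapter: int = 0
    poly_nt: int = 0
    length_out_of_range: int = 0
    q20_fraction: float = 0.0
    q30_fraction: float = 0.0
    gc_fraction: float = 0.0

    CATEGORIES = (
        "low_quality",
        "high_n",
        "five_prime_adapter",
        "no_three_prime_adapter",
        "poly_nt",
        "length_out_of_range",
    )

    def discarded(self) -> int:
        return sum(getattr(self, c) for c in self.CATEGORIES)

    def balanced(self) -> bool:
        """Exact integer conservation identity over all categories."""
        return self.raw == self.clean + self.discarded()

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _seed_match(seq: str, pos: int, seed: str, max_mismatch: int) -> bool:
    window = seq[pos : pos + len(seed)]
    if len(window) < len(seed):
        return False
    mm = 0
    for a, b in zip(window, seed):
        if a != b:
            mm += 1
            if mm > max_mismatch:
                return False
    return True


def find_adapter(sequence: str, adapter3: str, max_mismatch: int = 1) -> int:
    """Leftmost start of the adapter's first 10 nt (<= max_mismatch in the
    seed), or -1 if absent."""
    seed = adapter3[:ADAPTER_SEED_LEN]
    for pos in range(0, len(sequence) - ADAPTER_SEED_LEN + 1):
        if _seed_match(sequence, pos, seed, max_mismatch):
            return pos
    return -1


def infer_adapter3(
    reads: Iterable[ReadRecord],
    k: int = ADAPTER_SEED_LEN,
    min_reads: int = 100,
    min_support: float = 0.25,
    adapter: str | None = None,
) -> str:
    """Infer the 3' adapter prefix as a k-mer consensus over read 3' ends.

    Every k-mer occurring in a read (counted once per read, with its
    leftmost offset) votes; among k-mers supported by at least
    ``min_support`` of the reads, the one with the smallest median start
    offset is returned — insert lengths vary, so of the chained adapter
    k-mers (all equally supported) the leftmost-on-average is the adapter's
    5' end. A user-supplied ``adapter`` bypasses inference entirely.
    """
    if adapter is not None:
        return adapter
    support: Counter[str] = Counter()
    offsets: dict[str, list[int]] = {}
    n_reads = 0
    for read in reads:
        n_reads += 1
        seen: dict[str, int] = {}
        seq = read.sequence
        for pos in range(0, len(seq) - k + 1):
            kmer = seq[pos : pos + k]
            if "N" not in kmer and kmer not in seen:
                seen[kmer] = pos
        for kmer, pos in seen.items():
            support[kmer] += 1
            offsets.setdefault(kmer, []).append(pos)
    if n_reads < min_reads:
        raise ValueError(
            f"adapter inference needs >= {min_reads} reads, got {n_reads}"
        )
    candidates = [km for km, c in support.items() if c / n_reads >= min_support]
    if not candidates:
        raise ValueError("no adapter consensus")

    def median_offset(km: str) -> float:
        offs = sorted(offsets[km])
        n = len(offs)
        return (offs[(n - 1) // 2] + offs[n // 2]) / 2

    # Highest support first, then leftmost median offset, then lexicographic.
    best = min(candidates, key=lambda km: (-support[km], median_offset(km), km))
    return best


@dataclass
class TrimResult:
    """Outcome of adapter trimming: the insert (possibly empty) and where
    the adapter seed started."""

    id: str
    insert: str
    qualities: list[int]
    adapter_pos: int


def trim_read(
    read: ReadRecord, adapter3: str, max_mismatch: int = 1
) -> TrimResult | None:
    """Trim at the leftmost adapter-seed occurrence; None if no adapter.

    The absence of a 3' adapter is a discard category for the caller, not
    an error. An adapter at position 0 yields an empty insert, which the
    length filter flags downstream.
    """
    if len(adapter3) < ADAPTER_SEED_LEN:
        raise ValueError("adapter must be at least 10 nt")
    pos = find_adapter(read.sequence, adapter3, max_mismatch)
    if pos < 0:
        return None
    return TrimResult(
        id=read.id,
        insert=read.sequence[:pos],
        qualities=read.qualities[:pos],
        adapter_pos=pos,
    )


def _categorize(
    read: ReadRecord, adapter3: str, params: FilterParams
) -> tuple[str, ReadRecord | None]:
    """Assign a read to its (single) filter category, in the fixed order."""
    seq = read.sequence
    n_bases = len(seq)
    low_q = sum(1 for q in read.qualities if q < params.q_min)
    if low_q / n_bases > params.low_quality_frac:
        return "low_quality", None
    if seq.count("N") / n_bases > params.high_n_frac:
        return "high_n", None
    adapter5 = params.adapter5 or revcomp(adapter3)[-ADAPTER_SEED_LEN:]
    if _seed_match(seq, 0, adapter5[:ADAPTER_SEED_LEN], params.max_seed_mismatch):
        return "five_prime_adapter", None
    pos = find_adapter(seq, adapter3, params.max_seed_mismatch)
    if pos < 0:
        return "no_three_prime_adapter", None
    insert = seq[:pos]
    if insert:
        top = max(insert.count(b) for b in "ACGT")
        if top / len(insert) >= params.poly_frac:
            return "poly_nt", None
    if not (params.min_len <= len(insert) <= params.max_len):
        return "length_out_of_range", None
    return "clean", ReadRecord(
        id=read.id, sequence=insert, qualities=read.qualities[:pos]
    )


def categorize_read(
    read: ReadRecord, adapter3: str, params: FilterParams | None = None
) -> str:
    """Category a single read would be assigned ('clean' or a discard
    category), using the same fixed test order as :func:`filter_reads`."""
    category, _ = _categorize(read, adapter3, params or FilterParams())
    return category


def filter_reads(
    reads: Iterable[ReadRecord],
    adapter3: str,
    params: FilterParams | None = None,
) -> tuple[list[ReadRecord], FilterReport]:
    """Apply the six-way filter; returns (clean trimmed reads, report).

    Q20/Q30/GC statistics are computed over all raw bases.
    """
    if len(adapter3) < ADAPTER_SEED_LEN:
        raise ValueError("adapter must be at least 10 nt")
    params = params or FilterParams()
    report = FilterReport()
    clean: list[ReadRecord] = []
    total_bases = q20 = q30 = gc = 0
    for read in reads:
        report.raw += 1
        total_bases += len(read)
        q20 += sum(1 for q in read.qualities if q >= 20)
        q30 += sum(1 for q in read.qualities if q >= 30)
        gc += read.sequence.count("G") + read.sequence.count("C")
        category, trimmed = _categorize(read, adapter3, params)
        if category == "clean":
            report.clean += 1
            clean.append(trimmed)
        else:
            setattr(report, category, getattr(report, category) + 1)
    if total_bases:
        report.q20_fraction = q20 / total_bases
        report.q30_fraction = q30 / total_bases
        report.gc_fraction = gc / total_bases
    assert report.balanced(), "filter ledger must balance"
    return clean, report
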