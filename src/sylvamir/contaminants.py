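"""Contaminant removal: drop reads matching rRNA/tRNA/organelle references.

A clean small-RNA read is discarded if it aligns end-to-end, on either
strand, to any window of any contaminant reference with at most
``max_mismatch`` substitutions (ungapped Hamming matching — the convention
for 18-30 nt reads against contaminant databases).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .mapping import ReferenceIndex
from .qc import ReadRecord

REFERENCE_KINDS = (
    "rRNA",
    "tRNA",
    "organelle",
    "genome",
    "transcriptome",
    "known_miRNA",
)


@dataclass
class ReferenceSet:
    """A named reference collection (e.g. an rRNA database)."""

    name: str
    sequences: dict[str, str]
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in REFERENCE_KINDS:
            raise ValueError(f"unknown reference kind {self.kind!r}")
        for rid, seq in self.sequences.items():
            if set(seq.upper()) - set("ACGTN"):
                raise ValueError(f"{self.name}/{rid}: non-ACGTN characters")


def filter_contaminants(
    reads: Sequence[ReadRecord],
    refs: Sequence[ReferenceSet],
    max_mismatch: int = 1,
) -> tuple[list[ReadRecord], list[ReadRecord], dict[str, int]]:
    """Partition reads into (kept, removed) with per-kind removal counts.

    A read is removed if it matches ANY reference set; it is tallied under
    the kind of the first set (in the given order) that matches it, so the
    per-kind counts sum to ``len(removed)``.
    """
    if not refs:
        raise ValueError("empty reference set: refusing silent pass-through")
    indexes = [(ref.kind, ReferenceIndex(ref.sequences)) for ref in refs]
    kept: list[ReadRecord] = []
    removed: list[ReadRecord] = []
    counts: dict[str, int] = {kind: 0 for kind, _ in indexes}
    # Memoise per unique sequence: small-RNA libraries are highly redundant.
    verdict: dict[str, str | None] = {}
    for read in reads:
        seq = read.sequence
        if seq not in verdict:
            hit_kind = None
            for kind, index in indexes:
                if index.matches_anywhere(seq, max_mismatch):
                    hit_kind = kind
                    break
            verdict[seq] = hit_kind
        kind = verdict[seq]
        if kind is None:
            kept.append(read)
        else:
            removed.append(read)
            counts[kind] += 1
    return kept, removed, counts
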