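"""Exhaustive short-read matching against desk-scale references.

Implements ungapped end-to-end placement of 18-30 nt reads on reference
sequences with a bounded number of substitutions, on either strand, via a
pigeonhole seed-and-verify scheme: a read with at most m mismatches must
contain at least one of m+1 non-overlapping exact seed segments, so seed
lookups in a k-mer position index followed by full-length Hamming
verification find every hit. This is exact (no heuristics), which is what
lets it be property-tested against a brute-force all-windows scan.
"""

from __future__ import annotations

from collections import defaultdict

from .seq import revcomp


class ReferenceIndex:
    """K-mer position index over a set of reference sequences (plus strand).

    Minus-strand hits are found by querying the reverse complement of the
    read, so only the forward reference text is indexed.
    """

    def __init__(self, sequences: dict[str, str]):
        if not sequences or all(len(s) == 0 for s in sequences.values()):
            raise ValueError("empty reference")
        self.sequences = {k: v.upper() for k, v in sequences.items()}
        self._indexes: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def _index_for(self, k: int) -> dict[str, list[tuple[str, int]]]:
        if k not in self._indexes:
            idx: dict[str, list[tuple[str, int]]] = defaultdict(list)
            for name, seq in self.sequences.items():
                for pos in range(0, len(seq) - k + 1):
                    idx[seq[pos : pos + k]].append((name, pos))
            self._indexes[k] = dict(idx)
        return self._indexes[k]

    def _seed_candidates(self, read: str, max_mismatch: int):
        """Candidate (ref, start) placements from pigeonhole seeds."""
        length = len(read)
        n_seeds = max_mismatch + 1
        k = length // n_seeds
        if k < 4:
            # Degenerate: fall back to scanning every start position.
            for name, seq in self.sequences.items():
                for start in range(0, len(seq) - length + 1):
                    yield name, start
            return
        idx = self._index_for(k)
        seen: set[tuple[str, int]] = set()
        for i in range(n_seeds):
            off = i * k
            for name, pos in idx.get(read[off : off + k], ()):
                cand = (name, pos - off)
                if cand not in seen:
                    seen.add(cand)
                    yield cand

    def find_hits(
        self, read: str, max_mismatch: int = 0, both_strands: bool = True
    ) -> list[tuple[str, int, str, int]]:
        """All end-to-end placements: (ref id, start, strand, mismatches)."""
        read = read.upper()
        hits: list[tuple[str, int, str, int]] = []
        queries = [(read, "+")]
        if both_strands:
            queries.append((revcomp(read), "-"))
        for query, strand in queries:
            length = len(query)
            for name, start in self._seed_candidates(query, max_mismatch):
                if start < 0 or start + length > len(self.sequences[name]):
                    continue
                window = self.sequences[name][start : start + length]
                mm = 0
                ok = True
                for a, b in zip(query, window):
                    if a != b:
                        mm += 1
                        if mm > max_mismatch:
                            ok = False
                            break
                if ok:
                    hits.append((name, start, strand, mm))
        hits.sort()
        return hits

    def matches_anywhere(self, read: str, max_mismatch: int = 0) -> bool:
        read = read.upper()
        for query in (read, revcomp(read)):
            length = len(query)
            for name, start in self._seed_candidates(query, max_mismatch):
                if start < 0 or start + length > len(self.sequences[name]):
                    continue
                window = self.sequences[name][start : start + length]
                mm = 0
                ok = True
                for a, b in zip(query, window):
                    if a != b:
                        mm += 1
                        if mm > max_mismatch:
                            ok = False
                            break
                if ok:
                    return True
        return False


def brute_force_hits(
    read: str,
    sequences: dict[str, str],
    max_mismatch: int = 0,
    both_strands: bool = True,
) -> list[tuple[str, int, str, int]]:
    """Reference oracle: scan every window of every reference sequence."""
    read = read.upper()
    hits = []
    queries = [(read, "+")]
    if both_strands:
        queries.append((revcomp(read), "-"))
    for query, strand in queries:
        length = len(query)
        for name, seq in sequences.items():
            seq = seq.upper()
            for start in range(0, len(seq) - length + 1):
                mm = sum(a != b for a, b in zip(query, seq[start : start + length]))
                if mm <= max_mismatch:
                    hits.append((name, start, strand, mm))
    hits.sort()
    return hits
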