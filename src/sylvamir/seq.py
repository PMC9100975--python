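"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

DNA = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement (DNA alphabet; U treated as T, N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def is_wobble_rc(q: str, r: str) -> bool:
    """True if query base ``q`` forms a G:U wobble with the base whose
    reverse complement is ``r``.

    When a strand is compared against the reverse complement of its pairing
    partner, a G:U pair shows up as (G, A) and a U:G pair as (T, C).
    """
    return (q == "G" and r == "A") or (q == "T" and r == "C")
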