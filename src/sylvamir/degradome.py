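"""Degradome (PARE) tag mapping, cleavage-site categorisation, target calls.

AGO-guided cleavage leaves an uncapped 5' end on the downstream mRNA
fragment at the nucleotide opposite miRNA positions 10-11 (counted from
the miRNA 5' end); degradome tags pile up there. Target calling is
degradome-led: each tag-supported transcript position is tested against
each miRNA by complementarity, the site is categorised 0-4 by the tag
profile, and a permutation p-value (shuffled miRNA sequence, same
transcript, same rules) guards against chance complementarity.

Complementarity uses an Allen-style penalty scheme: mismatch 1.0, G:U
wobble 0.5, gap 1.0 per position, doubled at miRNA positions 2-13, with a
default score cutoff of 7.0. Categories follow the standard degradome
tiers: 0 unique profile maximum, 1 tied maximum, 2 above the mean of
tag-bearing positions, 3 below it, 4 single read.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .qc import ReadRecord
from .seq import is_wobble_rc, revcomp

SCORE_CUTOFF = 7.0
CORE_RANGE = (2, 13)  # miRNA positions (1-based) with doubled penalties
ANCHOR_LEN = 20


@dataclass
class DegradomeProfile:
    """Per-transcript 5'-tag coverage (1-based positions)."""

    transcript_id: str
    length: int
    tag5_counts: np.ndarray

    def __post_init__(self) -> None:
        self.tag5_counts = np.asarray(self.tag5_counts, dtype=np.int64)
        if self.tag5_counts.shape != (self.length,):
            raise ValueError("tag5_counts length must equal transcript length")
        if np.any(self.tag5_counts < 0):
            raise ValueError("negative tag counts")

    @property
    def total_tags(self) -> int:
        return int(self.tag5_counts.sum())


@dataclass
class TargetSite:
    """A called miRNA cleavage site on a transcript."""

    mirna_id: str
    transcript_id: str
    alignment: list[tuple[int, int]]  # (miRNA pos 1-based, transcript pos 1-based)
    complementarity_score: float
    cleavage_pos: int
    site_count: int
    category: int
    p_value: float = 1.0


# ---------------------------------------------------------------------------
# Tag mapping
# ---------------------------------------------------------------------------

def map_tags(
    tags: Iterable[ReadRecord],
    transcripts: Mapping[str, str],
    min_len: int = 18,
) -> tuple[dict[str, DegradomeProfile], int]:
    """Place tags by exact match of their first 20 nt on the sense strand.

    Multi-placed tags contribute to every placement. Returns the profiles
    and the number of unplaced (or too-short) tags.
    """
    if not transcripts:
        raise ValueError("empty transcriptome")
    index: dict[str, list[tuple[str, int]]] = {}
    for tx_id, seq in transcripts.items():
        seq = seq.upper()
        for pos in range(0, len(seq) - ANCHOR_LEN + 1):
            index.setdefault(seq[pos : pos + ANCHOR_LEN], []).append((tx_id, pos))
    profiles = {
        tx_id: DegradomeProfile(tx_id, len(seq), np.zeros(len(seq), dtype=np.int64))
        for tx_id, seq in transcripts.items()
    }
    unplaced = 0
    for tag in tags:
        seq = tag.sequence.upper()
        if len(seq) < max(min_len, ANCHOR_LEN):
            unplaced += 1
            continue
        placements = index.get(seq[:ANCHOR_LEN])
        if not placements:
            unplaced += 1
            continue
        for tx_id, pos in placements:
            profiles[tx_id].tag5_counts[pos] += 1  # pos is 0-based; store shifted
    return profiles, unplaced


# ---------------------------------------------------------------------------
# Complementarity scoring
# ---------------------------------------------------------------------------

def _position_weight(pos_1based: int) -> float:
    lo, hi = CORE_RANGE
    return 2.0 if lo <= pos_1based <= hi else 1.0


def score_complementarity(
    mirna: str, site: str
) -> tuple[float, list[tuple[int, int]]]:
    """Best ungapped-or-single-gap alignment of the miRNA against the
    site's reverse complement.

    The site window is the transcript subsequence (5'->3') the miRNA pairs
    with antiparallel; its length may differ from the miRNA's by up to 4.
    Penalties per miRNA position: mismatch 1.0, G:U 0.5, gap 1.0, doubled
    at positions 2-13. Returns (score, alignment) where the alignment
    lists (miRNA position, site-window position), both 1-based; gapped
    positions are omitted from the list. Ambiguous bases score as
    mismatches.
    """
    mirna = mirna.upper().replace("U", "T")
    site = site.upper().replace("U", "T")
    L, W = len(mirna), len(site)
    if abs(W - L) > 4:
        raise ValueError("site window length outside +/-4 of miRNA length")
    rc = revcomp(site)

    def column_penalty(pos_1based: int, q: str, t: str) -> float:
        if q == t and q in "ACGT":
            return 0.0
        if is_wobble_rc(q, t):
            return 0.5 * _position_weight(pos_1based)
        return 1.0 * _position_weight(pos_1based)

    d = W - L
    best: tuple[float, list[tuple[int, int]]] | None = None

    def try_alignment(gap_at: int) -> None:
        """Align with one gap run of length |d| starting at miRNA position
        ``gap_at`` (0-based, in whichever sequence is shorter)."""
        nonlocal best
        score = 0.0
        pairs: list[tuple[int, int]] = []
        if d >= 0:
            # rc longer: gap in miRNA; rc positions gap_at..gap_at+d-1 bulged.
            r = 0
            for i in range(L):
                if r == gap_at:
                    # charge the bulged target positions at this miRNA position
                    score += d * 1.0 * _position_weight(i + 1)
                    r += d
                score += column_penalty(i + 1, mirna[i], rc[r])
                pairs.append((i + 1, W - r))  # rc index r -> site pos W - r
                r += 1
            if r < W:  # trailing bulge: charge at the miRNA 3'-end weight
                score += (W - r) * 1.0 * _position_weight(L)
        else:
            # miRNA longer: gap in rc; miRNA positions gap_at..gap_at-d-1 gapped.
            g = -d
            r = 0
            for i in range(L):
                if gap_at <= i < gap_at + g:
                    score += 1.0 * _position_weight(i + 1)
                    continue
                score += column_penalty(i + 1, mirna[i], rc[r])
                pairs.append((i + 1, W - r))
                r += 1
        if best is None or score < best[0]:
            best = (score, pairs)

    if d == 0:
        try_alignment(gap_at=-1)  # never triggers: ungapped
    elif d > 0:
        for g in range(0, L + 1):
            try_alignment(g)
    else:
        for g in range(0, L + d + 1):
            try_alignment(g)
    assert best is not None
    return best


def locate_cleavage(alignment: Sequence[tuple[int, int]]) -> int:
    """Transcript coordinate opposite miRNA position 10 (the 5' end of the
    downstream cleavage fragment). Raises if positions 10-11 are gapped."""
    pos_map = dict(alignment)
    if 10 not in pos_map or 11 not in pos_map:
        raise ValueError("alignment gap at miRNA positions 10-11; site rejected")
    return pos_map[10]


# ---------------------------------------------------------------------------
# Site categorisation
# ---------------------------------------------------------------------------

def categorize_site(profile: DegradomeProfile, pos: int) -> int:
    """Degradome category 0-4 of a 1-based transcript position.

    c = counts[pos]; c == 1 -> 4; c == unique max -> 0; c == tied max -> 1;
    c above the mean of tag-bearing positions -> 2; else 3. A position with
    no tags cannot be categorised (ValueError).
    """
    if profile.total_tags < 1:
        raise ValueError("profile has no tags")
    if not 1 <= pos <= profile.length:
        raise ValueError(f"position {pos} outside transcript {profile.transcript_id}")
    counts = profile.tag5_counts
    c = int(counts[pos - 1])
    if c == 0:
        raise ValueError("no tag support at position; site not called")
    if c == 1:
        return 4
    maximum = int(counts.max())
    if c == maximum:
        return 0 if int((counts == maximum).sum()) == 1 else 1
    nonzero = counts[counts > 0]
    return 2 if c > nonzero.mean() else 3


def categorize_site_bruteforce(profile: DegradomeProfile, pos: int) -> int:
    """Independent enumeration-style re-statement of the category rule
    (kept deliberately separate from :func:`categorize_site`)."""
    counts = [int(x) for x in profile.tag5_counts]
    c = counts[pos - 1]
    if sum(counts) < 1 or c == 0:
        raise ValueError("uncategorisable position")
    if c == 1:
        return 4
    mx = max(counts)
    if c == mx and counts.count(mx) == 1:
        return 0
    if c == mx:
        return 1
    bearing = [x for x in counts if x > 0]
    return 2 if c > sum(bearing) / len(bearing) else 3


# ---------------------------------------------------------------------------
# Permutation p-value and target calling
# ---------------------------------------------------------------------------

def _candidate_positions(profile: DegradomeProfile, min_count: int) -> np.ndarray:
    return np.nonzero(profile.tag5_counts >= min_count)[0] + 1


def _site_window(
    transcript: str, pos: int, mirna_len: int
) -> str | None:
    """Transcript window (1-based [pos+10-L, pos+9]) paired with a miRNA
    whose position 10 is opposite ``pos``; None if out of bounds."""
    start = pos + 10 - mirna_len  # 1-based
    end = pos + 9
    if start < 1 or end > len(transcript):
        return None
    return transcript[start - 1 : end]


def _best_site_at(
    mirna: str, transcript: str, pos: int
) -> tuple[float, list[tuple[int, int]]] | None:
    window = _site_window(transcript, pos, len(mirna))
    if window is None:
        return None
    score, pairs = score_complementarity(mirna, window)
    # Translate window coordinates to transcript coordinates.
    offset = pos + 10 - len(mirna) - 1
    pairs = [(q, offset + w) for q, w in pairs]
    return score, pairs


def permutation_pvalue(
    mirna: str,
    transcript: str,
    profile: DegradomeProfile,
    observed_score: float,
    observed_category: int,
    R: int = 1000,
    seed: int = 0,
    max_score: float = SCORE_CUTOFF,
) -> float:
    """Permutation null: shuffle the miRNA sequence R times; count shuffles
    achieving a site on the same transcript at least as good as observed
    (category <= observed and score <= observed). p = (1 + hits) / (R + 1).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng(seed)
    letters = list(mirna.upper().replace("U", "T"))
    candidates = [
        int(p)
        for p in _candidate_positions(profile, min_count=1)
        if _site_window(transcript, int(p), len(letters)) is not None
    ]
    cat_cache = {p: categorize_site(profile, p) for p in candidates}
    hits = 0
    for _ in range(R):
        perm = rng.permutation(len(letters))
        shuffled = "".join(letters[i] for i in perm)
        for p in candidates:
            if cat_cache[p] > observed_category:
                continue
            score, _ = score_complementarity(
                shuffled, _site_window(transcript, p, len(letters))
            )
            if score <= observed_score and score <= max_score:
                hits += 1
                break
    return (1 + hits) / (R + 1)


def call_targets(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    profiles: Mapping[str, DegradomeProfile],
    max_score: float = SCORE_CUTOFF,
    max_category: int = 2,
    alpha: float = 0.05,
    R: int = 1000,
    seed: int = 0,
) -> list[TargetSite]:
    """Degradome-led target calling.

    For every tag-supported position (count >= 2 unless category 4 is
    allowed) on every transcript and every miRNA, a site is called when
    the complementarity score is <= max_score, the cleavage position has
    tag support, the category is <= max_category and the permutation
    p-value is <= alpha. Sorted by (category, p, score).
    """
    min_count = 1 if max_category >= 4 else 2
    sites: list[TargetSite] = []
    for tx_id, profile in profiles.items():
        if profile.total_tags == 0:
            continue
        transcript = transcripts[tx_id].upper()
        positions = _candidate_positions(profile, min_count)
        for mirna_id, mirna_seq in mirnas.items():
            mirna_seq = mirna_seq.upper().replace("U", "T")
            for pos in positions:
                pos = int(pos)
                found = _best_site_at(mirna_seq, transcript, pos)
                if found is None:
                    continue
                score, pairs = found
                if score > max_score:
                    continue
                try:
                    cleavage = locate_cleavage(pairs)
                except ValueError:
                    continue
                if cleavage != pos:  # pragma: no cover - anchored by design
                    continue
                category = categorize_site(profile, pos)
                if category > max_category:
                    continue
                site_key = zlib.crc32(f"{mirna_id}|{tx_id}|{pos}".encode())
                p = permutation_pvalue(
                    mirna_seq,
                    transcript,
                    profile,
                    observed_score=score,
                    observed_category=category,
                    R=R,
                    seed=(seed + site_key) % (2**31),
                    max_score=max_score,
                )
                if p > alpha:
                    continue
                sites.append(
                    TargetSite(
                        mirna_id=mirna_id,
                        transcript_id=tx_id,
                        alignment=pairs,
                        complementarity_score=score,
                        cleavage_pos=pos,
                        site_count=int(profile.tag5_counts[pos - 1]),
                        category=category,
                        p_value=p,
                    )
                )
    sites.sort(key=lambda s: (s.category, s.p_value, s.complementarity_score))
    return sites
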