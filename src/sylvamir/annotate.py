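"""miRNA locus annotation from mapped small-RNA reads.

The annotation path mirrors current plant miRNA criteria: map 18-30 nt
reads to the genome, merge near-identical placements into read stacks,
extend each stack by 150 nt on both sides to form a candidate precursor
window, and test whether the stack's representative read (the candidate
mature miRNA) forms a proper miRNA/miRNA* duplex with the opposite arm of
a hairpin in that window. A candidate passes when

* the mature is 20-24 nt and the trimmed precursor is at most 300 nt,
* the duplex has at most 5 mismatches, of which at most 3 are
  bulge/internal-loop (gap) positions,
* the hairpin has no large loop (no single internal loop longer than 5 nt
  on one strand, and the opposite arm pairs at all),
* the miRNA* can be inferred with the canonical 2-nt 3' overhangs.

G:U wobbles count as paired. Secondary structure is assessed by aligning
the mature against the reverse complement of the opposite arm (global over
the mature, free end gaps on the arm) rather than by thermodynamic
folding: every criterion above is a statement about that duplex alignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .contaminants import ReferenceSet
from .mapping import ReferenceIndex
from .seq import is_wobble_rc, revcomp

PRECURSOR_FLANK = 150
MAX_PRECURSOR_LEN = 300
MATURE_LEN_RANGE = (20, 24)
MAX_DUPLEX_MISMATCHES = 5
MAX_LOOP_MISMATCHES = 3
MAX_INTERNAL_LOOP = 5
MIN_TERMINAL_LOOP = 3
STAR_OVERHANG = 2
# Minimum local pairing score below which the window is deemed to have no
# complementary arm at all ("terminal loop pairing fails entirely").
MIN_ARM_SCORE = 8.0

_FAMILY_RE = re.compile(r"(miR[A-Za-z]?\d+)", re.IGNORECASE)


@dataclass
class AlignmentHit:
    """An end-to-end placement of one (unique) read sequence."""

    read_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    copies: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("invalid hit interval")


@dataclass
class ReadStack:
    seq_id: str
    strand: str
    start: int
    end: int
    representative_sequence: str
    counts_per_sample: np.ndarray


@dataclass
class PrecursorWindow:
    """A candidate precursor window in mature-sense orientation."""

    sequence: str
    seq_id: str
    start: int
    end: int
    strand: str

    def to_genome(self, w_start: int, w_end: int) -> tuple[int, int]:
        """Map a window-coordinate half-open interval to genome coordinates."""
        if self.strand == "+":
            return self.start + w_start, self.start + w_end
        return self.end - w_end, self.end - w_start


@dataclass
class DuplexEvaluation:
    """Audit of the miRNA/miRNA* duplex criteria for one candidate."""

    mature: str
    star: str
    total_mismatches: int
    loop_region_mismatches: int
    overhang_5p: int
    overhang_3p: int
    large_loop: bool
    passed: bool
    fail_reasons: list[str] = field(default_factory=list)
    # Window-coordinate intervals (half-open) for downstream mapping.
    mature_interval: tuple[int, int] | None = None
    star_interval: tuple[int, int] | None = None
    precursor_interval: tuple[int, int] | None = None


@dataclass
class MiRNALocus:
    """An annotated miRNA locus: mature, star, and trimmed precursor."""

    name: str
    family: str | None
    mature: str
    star: str
    precursor: str
    coordinates: tuple[str, int, int, str]
    status: str
    evaluation: DuplexEvaluation
    counts_per_sample: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    mature_coordinates: tuple[int, int] | None = None
    star_coordinates: tuple[int, int] | None = None

    def arm_coordinates(self, role: str) -> tuple[int, int] | None:
        return self.mature_coordinates if role == "mature" else self.star_coordinates

    def validate(self) -> None:
        if len(self.precursor) > MAX_PRECURSOR_LEN:
            raise ValueError(f"{self.name}: precursor exceeds {MAX_PRECURSOR_LEN} nt")
        lo, hi = MATURE_LEN_RANGE
        if not lo <= len(self.mature) <= hi:
            raise ValueError(f"{self.name}: mature length outside [{lo},{hi}]")
        if self.mature not in self.precursor or self.star not in self.precursor:
            raise ValueError(f"{self.name}: arms not contained in precursor")
        if not self.evaluation.passed:
            raise ValueError(f"{self.name}: duplex evaluation did not pass")


# ---------------------------------------------------------------------------
# Mapping and stacking
# ---------------------------------------------------------------------------

def collapse_reads(
    samples: Mapping[str, Iterable],
) -> tuple[dict[str, np.ndarray], list[str]]:
    """Collapse per-sample reads to unique sequences with count vectors."""
    sample_ids = list(samples)
    unique: dict[str, np.ndarray] = {}
    for j, sid in enumerate(sample_ids):
        for read in samples[sid]:
            seq = read.sequence if hasattr(read, "sequence") else str(read)
            if seq not in unique:
                unique[seq] = np.zeros(len(sample_ids), dtype=np.int64)
            unique[seq][j] += 1
    return unique, sample_ids


def map_reads(
    reads: Mapping[str, np.ndarray] | Sequence[str],
    genome: Mapping[str, str],
    max_mismatch: int = 0,
    max_hits: int = 20,
) -> tuple[list[AlignmentHit], int]:
    """Place unique read sequences end-to-end on the genome (both strands).

    Reads with more than ``max_hits`` placements are discarded and counted
    (second return value). ``reads`` maps sequence -> per-sample counts, or
    is a plain sequence collection (counts default to 1).
    """
    index = ReferenceIndex(dict(genome))
    if isinstance(reads, Mapping):
        items = [(seq, int(np.sum(cnt))) for seq, cnt in reads.items()]
    else:
        items = [(seq, 1) for seq in reads]
    hits: list[AlignmentHit] = []
    n_discarded = 0
    for seq, copies in items:
        placements = index.find_hits(seq, max_mismatch=max_mismatch)
        if len(placements) > max_hits:
            n_discarded += 1
            continue
        for name, start, strand, mm in placements:
            hits.append(
                AlignmentHit(
                    read_id=seq,
                    seq_id=name,
                    start=start,
                    end=start + len(seq),
                    strand=strand,
                    mismatches=mm,
                    copies=copies,
                )
            )
    return hits, n_discarded


def build_stacks(
    hits: Sequence[AlignmentHit],
    counts: Mapping[str, np.ndarray] | None = None,
    n_samples: int = 1,
    merge_gap: int = 2,
) -> list[ReadStack]:
    """Merge overlapping/abutting (within ``merge_gap`` nt) same-strand hits.

    Multi-mapped reads contribute their full counts to every stack they
    fall in (family members share sequences; total expression is used).
    Representative = most abundant member sequence, ties broken
    lexicographically.
    """

    def count_vec(read_id: str) -> np.ndarray:
        if counts is not None and read_id in counts:
            return np.asarray(counts[read_id], dtype=np.int64)
        return np.full(n_samples, 1, dtype=np.int64)

    ordered = sorted(hits, key=lambda h: (h.seq_id, h.strand, h.start, h.end))
    stacks: list[ReadStack] = []
    group: list[AlignmentHit] = []

    def flush() -> None:
        if not group:
            return
        total = sum(count_vec(h.read_id) for h in group)
        rep = min(
            {h.read_id for h in group},
            key=lambda s: (-int(np.sum(count_vec(s))), s),
        )
        stacks.append(
            ReadStack(
                seq_id=group[0].seq_id,
                strand=group[0].strand,
                start=min(h.start for h in group),
                end=max(h.end for h in group),
                representative_sequence=rep,
                counts_per_sample=total,
            )
        )

    cur_end = None
    for h in ordered:
        if (
            group
            and h.seq_id == group[0].seq_id
            and h.strand == group[0].strand
            and h.start <= cur_end + merge_gap
        ):
            group.append(h)
            cur_end = max(cur_end, h.end)
        else:
            flush()
            group = [h]
            cur_end = h.end
    flush()
    return stacks


def extract_precursor_window(
    stack: ReadStack, genome: Mapping[str, str], flank: int = PRECURSOR_FLANK
) -> PrecursorWindow:
    """Stack interval extended by ``flank`` nt both sides, clipped to the
    contig; minus-strand windows are reverse-complemented so the mature
    reads in sense orientation."""
    contig = genome[stack.seq_id]
    w_start = max(0, stack.start - flank)
    w_end = min(len(contig), stack.end + flank)
    seq = contig[w_start:w_end]
    if stack.strand == "-":
        seq = revcomp(seq)
    return PrecursorWindow(
        sequence=seq,
        seq_id=stack.seq_id,
        start=w_start,
        end=w_end,
        strand=stack.strand,
    )


# ---------------------------------------------------------------------------
# Duplex evaluation
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    alphabet = "ACGTN"
    matrix = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if a == "N" or b == "N":
                matrix[a, b] = -1.5
            elif a == b:
                matrix[a, b] = 2.0
            elif (a, b) in (("G", "A"), ("T", "C")):  # G:U wobble in rc space
                matrix[a, b] = 1.0
            else:
                matrix[a, b] = -1.5
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -1.5
    return aligner


_ALIGNER = _make_aligner()


def _fail(mature: str, reasons: list[str], large_loop: bool = False) -> DuplexEvaluation:
    return DuplexEvaluation(
        mature=mature,
        star="",
        total_mismatches=len(mature),
        loop_region_mismatches=0,
        overhang_5p=0,
        overhang_3p=0,
        large_loop=large_loop,
        passed=False,
        fail_reasons=reasons,
    )


def evaluate_duplex(mature: str, window: str) -> DuplexEvaluation:
    """Evaluate the miRNA/miRNA* duplex criteria for ``mature`` inside a
    precursor window (mature in sense orientation).

    Raises ValueError if the mature does not occur in the window.
    """
    mature = mature.upper()
    window = window.upper()
    if len(window) > 2 * PRECURSOR_FLANK + MAX_PRECURSOR_LEN + 21:
        raise ValueError("window longer than a precursor search window")
    m_start = window.find(mature)
    if m_start < 0:
        raise ValueError("mature not found in window")
    L = len(mature)
    m_end = m_start + L

    reasons: list[str] = []
    lo, hi = MATURE_LEN_RANGE
    if not lo <= L <= hi:
        reasons.append(f"mature_length_not_in_[{lo},{hi}]")

    # Locate the complementary arm on either side of the mature.
    best = None  # (score, alignment, side, side_offset_fn)
    for side_name, side in (("up", window[:m_start]), ("down", window[m_end:])):
        if len(side) < L // 2:
            continue
        rc_side = revcomp(side)
        alignments = _ALIGNER.align(mature, rc_side)
        if len(alignments) == 0:
            continue
        aln = alignments[0]
        if best is None or aln.score > best[0]:
            base = m_start if side_name == "up" else len(window)
            # rc index r <-> window coordinate base - 1 - r
            best = (aln.score, aln, side_name, base)
    if best is None or best[0] < MIN_ARM_SCORE:
        reasons.append("no_complementary_arm")
        return _fail(mature, reasons, large_loop=True)

    score, aln, side_name, base = best
    q_blocks, t_blocks = aln.aligned  # query=mature, target=rc_side
    q_blocks = [tuple(map(int, b)) for b in q_blocks]
    t_blocks = [tuple(map(int, b)) for b in t_blocks]

    substitutions = 0
    gap_positions = 0
    large_loop = False
    mature_seq = mature
    rc_side_seq = str(aln.query)
    for (qs, qe), (ts, te) in zip(q_blocks, t_blocks):
        for q, t in zip(mature_seq[qs:qe], rc_side_seq[ts:te]):
            if q != t and not is_wobble_rc(q, t):
                substitutions += 1
    for k in range(1, len(q_blocks)):
        gap_q = q_blocks[k][0] - q_blocks[k - 1][1]
        gap_t = t_blocks[k][0] - t_blocks[k - 1][1]
        gap_positions += gap_q + gap_t
        if max(gap_q, gap_t) > MAX_INTERNAL_LOOP:
            large_loop = True

    cov_start = q_blocks[0][0]
    cov_end = q_blocks[-1][1]
    uncovered = cov_start + (L - cov_end)
    total_mismatches = substitutions + gap_positions + uncovered
    loop_mismatches = gap_positions

    # Project the aligned arm to window coordinates (full mature extent).
    t_lo, t_hi = t_blocks[0][0], t_blocks[-1][1]  # rc-space, half-open
    # rc index r corresponds to window coordinate base - 1 - r.
    arm_hi = base - t_lo  # exclusive  (pairs mature[cov_start])
    arm_lo = base - t_hi  # inclusive  (pairs mature[cov_end - 1])
    arm_hi_full = arm_hi + cov_start
    arm_lo_full = arm_lo - (L - cov_end)

    # Terminal loop geometry.
    if side_name == "up":
        loop_len = m_start - arm_hi_full
    else:
        loop_len = arm_lo_full - m_end
    if loop_len < MIN_TERMINAL_LOOP:
        reasons.append("arms_overlap_or_loop_too_short")

    # Canonical miRNA* with 2-nt 3' overhangs: shift the arm interval by
    # +2 toward higher window coordinates (see antiparallel pairing).
    star_lo = arm_lo_full + STAR_OVERHANG
    star_hi = arm_hi_full + STAR_OVERHANG
    star_ok = 0 <= star_lo and star_hi <= len(window)
    if not star_ok:
        reasons.append("star_out_of_window")
        star = ""
    else:
        star = window[star_lo:star_hi]

    if total_mismatches > MAX_DUPLEX_MISMATCHES:
        reasons.append(f"mismatches>{MAX_DUPLEX_MISMATCHES}")
    if loop_mismatches > MAX_LOOP_MISMATCHES:
        reasons.append(f"loop_mismatches>{MAX_LOOP_MISMATCHES}")
    if large_loop:
        reasons.append("large_loop")

    passed = not reasons

    # Trimmed precursor: mature start <-> star end plus <= 15 nt flanks,
    # capped at MAX_PRECURSOR_LEN.
    if star_ok:
        core_lo = min(m_start, star_lo)
        core_hi = max(m_end, star_hi)
        pre_lo = max(0, core_lo - 15)
        pre_hi = min(len(window), core_hi + 15)
        while pre_hi - pre_lo > MAX_PRECURSOR_LEN:
            if pre_lo < core_lo:
                pre_lo += 1
            elif pre_hi > core_hi:
                pre_hi -= 1
            else:  # pragma: no cover - core itself exceeds the cap
                reasons.append("precursor_too_long")
                passed = False
                break
        precursor_interval = (pre_lo, pre_hi)
    else:
        precursor_interval = None

    return DuplexEvaluation(
        mature=mature,
        star=star,
        total_mismatches=total_mismatches,
        loop_region_mismatches=loop_mismatches,
        overhang_5p=STAR_OVERHANG if star_ok else 0,
        overhang_3p=STAR_OVERHANG if star_ok else 0,
        large_loop=large_loop,
        passed=passed,
        fail_reasons=reasons,
        mature_interval=(m_start, m_end),
        star_interval=(star_lo, star_hi) if star_ok else None,
        precursor_interval=precursor_interval,
    )


# ---------------------------------------------------------------------------
# Locus assembly
# ---------------------------------------------------------------------------

def annotate_loci(
    stacks: Sequence[ReadStack],
    genome: Mapping[str, str],
    min_count: int = 10,
    known_reference: ReferenceSet | None = None,
) -> list[MiRNALocus]:
    """Turn read stacks into annotated miRNA loci.

    A stack becomes a locus when its representative read passes the duplex
    evaluation in its precursor window. Loci whose maximum per-sample count
    is below ``min_count`` in every sample are removed; overlapping
    same-strand loci are deduplicated keeping the higher-count one.
    """
    candidates: list[MiRNALocus] = []
    for stack in stacks:
        rep = stack.representative_sequence
        if stack.strand == "-" and stack.seq_id in genome:
            pass  # window extraction handles orientation
        window = extract_precursor_window(stack, genome)
        if rep not in window.sequence:
            continue
        try:
            ev = evaluate_duplex(rep, window.sequence)
        except ValueError:
            continue
        if not ev.passed:
            continue
        pre_lo, pre_hi = ev.precursor_interval
        g_pre = window.to_genome(pre_lo, pre_hi)
        g_mat = window.to_genome(*ev.mature_interval)
        g_star = window.to_genome(*ev.star_interval)
        locus = MiRNALocus(
            name="",
            family=None,
            mature=rep,
            star=ev.star,
            precursor=window.sequence[pre_lo:pre_hi],
            coordinates=(stack.seq_id, g_pre[0], g_pre[1], stack.strand),
            status="novel",
            evaluation=ev,
            counts_per_sample=np.asarray(stack.counts_per_sample, dtype=np.int64),
            mature_coordinates=g_mat,
            star_coordinates=g_star,
        )
        candidates.append(locus)

    # Low-expression removal: below min_count in every sample.
    candidates = [
        loc
        for loc in candidates
        if loc.counts_per_sample.size and int(loc.counts_per_sample.max()) >= min_count
    ]

    # Deduplicate overlapping same-strand loci, keeping the higher count.
    candidates.sort(
        key=lambda l: (-int(l.counts_per_sample.sum()), l.coordinates[:3])
    )
    selected: list[MiRNALocus] = []
    for loc in candidates:
        sid, s, e, strand = loc.coordinates
        clash = any(
            sid == k.coordinates[0]
            and strand == k.coordinates[3]
            and s < k.coordinates[2]
            and k.coordinates[1] < e
            for k in selected
        )
        if not clash:
            selected.append(loc)
    selected.sort(key=lambda l: (l.coordinates[0], l.coordinates[1]))

    # Naming and known/novel classification in genomic order.
    novel_counter = 0
    for loc in selected:
        status, family, name = classify_known_novel(loc, known_reference)
        if status == "novel":
            novel_counter += 1
            name = f"miRN{novel_counter}"
        loc.status = status
        loc.family = family
        loc.name = name
        loc.validate()
    return selected


def _best_ungapped(a: str, b: str) -> int:
    """Minimum mismatches over all offsets of the shorter inside the longer."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    best = len(short)
    for off in range(0, len(long_) - len(short) + 1):
        mm = sum(x != y for x, y in zip(short, long_[off : off + len(short)]))
        best = min(best, mm)
    return best


def classify_known_novel(
    locus: MiRNALocus, reference: ReferenceSet | None
) -> tuple[str, str | None, str]:
    """Classify a locus against a known-miRNA reference.

    Known iff some reference mature matches with <= 2 substitutions at the
    best ungapped offset and a length difference <= 2; the family label is
    parsed from the best-matching reference id.
    """
    if reference is None or not reference.sequences:
        return "novel", None, ""
    best_id, best_mm = None, None
    for rid, rseq in sorted(reference.sequences.items()):
        rseq = rseq.upper().replace("U", "T")
        if abs(len(rseq) - len(locus.mature)) > 2:
            continue
        mm = _best_ungapped(locus.mature, rseq)
        if best_mm is None or mm < best_mm:
            best_id, best_mm = rid, mm
    if best_mm is not None and best_mm <= 2:
        match = _FAMILY_RE.search(best_id)
        family = match.group(1) if match else best_id
        return "known", family, best_id
    return "novel", None, ""
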