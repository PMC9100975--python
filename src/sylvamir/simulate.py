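"""Synthetic small-RNA / degradome data with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, at desk scale:

* a random (i.i.d. uniform A/C/G/T) genome with planted hairpin loci whose
  mature/star duplexes satisfy the annotation criteria — verified with the
  annotation module's own duplex evaluator at generation time — plus decoy
  read stacks verified NOT to satisfy them;
* per-sample 1x50 bp small-RNA reads (insert + 3' adapter + random pad)
  with negative-binomially distributed per-locus counts, planted fold
  changes between the two tissue groups, and mutually exclusive defect
  classes mirroring the QC filter categories;
* contaminant references (rRNA/tRNA/organelle) and reads drawn from them;
* a transcript set with planted miRNA cleavage sites and a pooled
  degradome 5'-tag library concentrated at those sites.

Everything is driven by one integer seed: identical config + seed gives
byte-identical artifacts. Sub-streams per stage are derived with fixed
offsets so stages are individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, asdict
from typing import Iterable, Mapping

import numpy as np

from . import annotate
from .contaminants import ReferenceSet
from .qc import FilterParams, ReadRecord, categorize_read, find_adapter
from .seq import DNA, revcomp

# Widely used small-RNA kit 3' adapter (any >= 10 nt string is accepted).
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"

_STAGE = {"genome": 1, "reads": 2, "counts": 3, "degradome": 4, "refs": 5}

_FAMILY_NAMES = [
    "miR166", "miR319", "miR396", "miR160", "miR167", "miR164",
    "miR172", "miR394", "miR171", "miR477", "miR482", "miR530",
    "miR475", "miR476", "miR6427", "miR6434",
]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Per-stage RNG derived from the global seed by a fixed offset."""
    return np.random.default_rng([int(seed), _STAGE[stage]])


@dataclass
class SimulationConfig:
    """Study-condition knobs of the synthetic dataset.

    Defaults follow the emulated study design: two tissue groups (developing
    xylem X and phloem P) with three replicates each, 1x50 bp single-end
    reads, 18-30 nt small-RNA inserts, and discard-category fractions on
    the order of the library breakdown the QC filter is meant to reproduce
    (no-3'-adapter the largest category).
    """

    seed: int = 0
    n_planted_loci: int = 12
    n_decoy_stacks: int = 25
    genome_length: int = 60_000
    read_length: int = 50
    adapter3: str = DEFAULT_ADAPTER3
    n_samples_per_group: int = 3
    depth_per_sample: int = 20_000
    nb_dispersion: float = 0.05
    base_mean: float = 200.0
    planted_fold_changes: list[float] = dc_field(
        default_factory=lambda: [1.0, 8.0, 0.125, 4.0, 0.25, 1.0]
    )
    defect_fractions: dict[str, float] = dc_field(
        default_factory=lambda: {
            "low_quality": 0.004,
            "high_n": 0.004,
            "five_prime_adapter": 0.002,
            "no_three_prime_adapter": 0.017,
            "poly_nt": 0.001,
            "length_out_of_range": 0.004,
        }
    )
    contaminant_fraction: float = 0.05
    degradome_signal_fraction: float = 0.8
    n_transcripts: int = 40
    transcript_length: int = 400
    degradome_depth: int = 15_000
    n_target_sites: int = 8
    n_novel: int = 2
    mature_length: int = 21

    def __post_init__(self) -> None:
        for name, frac in self.defect_fractions.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"defect fraction {name} outside [0,1]")
        if sum(self.defect_fractions.values()) >= 1.0:
            raise ValueError("defect fractions must sum to < 1")
        if not 0.0 <= self.contaminant_fraction <= 1.0:
            raise ValueError("contaminant_fraction outside [0,1]")
        if not 0.0 <= self.degradome_signal_fraction <= 1.0:
            raise ValueError("degradome_signal_fraction outside [0,1]")
        if self.depth_per_sample < 0:
            raise ValueError("depth must be >= 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if any(fc <= 0 for fc in self.planted_fold_changes):
            raise ValueError("fold changes must be positive")

    @property
    def sample_ids(self) -> list[str]:
        n = self.n_samples_per_group
        return [f"X{i+1}" for i in range(n)] + [f"P{i+1}" for i in range(n)]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PlantedLocus:
    """Ground-truth record of one planted hairpin."""

    name: str
    seq_id: str
    strand: str
    mature: str
    star: str
    precursor: str
    mature_start: int  # genome coordinates, 0-based half-open
    mature_end: int
    hairpin_start: int
    hairpin_end: int
    known_name: str | None = None  # id in the known-miRNA reference, if any


@dataclass
class DecoyStack:
    """A planted non-hairpin read stack (annotation must reject it)."""

    name: str
    seq_id: str
    strand: str
    sequence: str
    start: int
    end: int


@dataclass
class SimulationTruth:
    """Everything downstream stages are expected to recover."""

    planted_loci: list[PlantedLocus]
    decoys: list[DecoyStack]
    true_counts: np.ndarray  # planted locus x sample
    decoy_counts: np.ndarray
    true_log2fc: np.ndarray
    sample_ids: list[str]
    planted_sites: list[tuple[str, str, int, float]] = dc_field(default_factory=list)
    # (mirna locus name, transcript id, 1-based cleavage position, signal frac)


# ---------------------------------------------------------------------------
# Genome with planted hairpins
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(DNA), size=n)) if n else ""


_SUBST = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


def _clean_insert(rng: np.random.Generator, length: int, adapter3: str) -> str:
    """A random insert that survives QC: no internal adapter seed, not a
    near-homopolymer."""
    while True:
        s = _random_seq(rng, length)
        if max(s.count(b) for b in DNA) / length >= 0.8:
            continue
        if find_adapter(s + "A" * 10, adapter3) >= 0:
            continue
        return s


def _plant_hairpin(
    rng: np.random.Generator, config: SimulationConfig
) -> tuple[str, str, str, int]:
    """Build a hairpin (mature + loop + edited rc arm); returns
    (hairpin, mature, star_arm, mature_offset_in_hairpin)."""
    for _ in range(100):
        mature = _clean_insert(rng, config.mature_length, config.adapter3)
        loop = _random_seq(rng, int(rng.integers(8, 41)))
        arm = list(revcomp(mature))
        # 1-4 substitutions keep the duplex valid while ensuring the star
        # arm is never an exact reverse complement (a perfectly palindromic
        # hairpin would be annotatable from either arm).
        n_edits = int(rng.integers(1, 5))
        for pos in rng.choice(len(arm), size=n_edits, replace=False):
            arm[pos] = _SUBST[arm[pos]][rng.integers(0, 3)]
        hairpin = mature + loop + "".join(arm) + _random_seq(rng, 2)
        # Generation-time assertion: the planted duplex must pass the
        # annotation criteria in a realistic window.
        window = _random_seq(rng, 150) + hairpin + _random_seq(rng, 150)
        try:
            ev = annotate.evaluate_duplex(mature, window)
        except ValueError:
            continue
        if ev.passed:
            return hairpin, mature, ev.star, 0
    raise RuntimeError("failed to generate a valid hairpin")  # pragma: no cover


def simulate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], SimulationTruth]:
    """Generate the genome with planted hairpin loci and decoy stacks.

    The genome is i.i.d. uniform background with ``n_planted_loci``
    hairpins and ``n_decoy_stacks`` decoy read positions embedded at
    well-separated positions. Planted duplex validity and decoy
    non-validity are asserted at generation time using the annotation
    module's evaluator, so locus recovery is a clean oracle.
    """
    rng = stage_rng(config.seed, "genome")
    slot = 450  # max hairpin (~90) + 2x150 flank margin
    needed = (config.n_planted_loci + config.n_decoy_stacks) * slot
    if config.n_planted_loci * 400 > config.genome_length or needed > config.genome_length:
        raise ValueError("genome too small")

    genome_chars = list(_random_seq(rng, config.genome_length))
    n_slots = config.genome_length // slot
    slots = rng.permutation(n_slots)
    planted: list[PlantedLocus] = []
    decoys: list[DecoyStack] = []

    for i in range(config.n_planted_loci):
        hairpin, mature, star, _ = _plant_hairpin(rng, config)
        strand = "+" if rng.random() < 0.5 else "-"
        pos = int(slots[i]) * slot + int(rng.integers(0, slot - len(hairpin)))
        embed = hairpin if strand == "+" else revcomp(hairpin)
        genome_chars[pos : pos + len(hairpin)] = list(embed)
        if strand == "+":
            m_start = pos
        else:
            m_start = pos + len(hairpin) - config.mature_length
        planted.append(
            PlantedLocus(
                name=f"planted_{i+1}",
                seq_id="chr1",
                strand=strand,
                mature=mature,
                star=star,
                precursor=hairpin,
                mature_start=m_start,
                mature_end=m_start + config.mature_length,
                hairpin_start=pos,
                hairpin_end=pos + len(hairpin),
            )
        )

    genome = {"chr1": "".join(genome_chars)}

    j = config.n_planted_loci
    made = 0
    while made < config.n_decoy_stacks and j < n_slots:
        pos = int(slots[j]) * slot + int(rng.integers(0, slot - config.mature_length))
        j += 1
        seq = genome["chr1"][pos : pos + config.mature_length]
        if max(seq.count(b) for b in DNA) / len(seq) >= 0.8:
            continue
        if find_adapter(seq + "A" * 10, config.adapter3) >= 0:
            continue
        window = genome["chr1"][max(0, pos - 150) : pos + config.mature_length + 150]
        try:
            ev = annotate.evaluate_duplex(seq, window)
            if ev.passed:  # accidental hairpin: reject this decoy position
                continue
        except ValueError:
            pass
        made += 1
        decoys.append(
            DecoyStack(
                name=f"decoy_{made}",
                seq_id="chr1",
                strand="+",
                sequence=seq,
                start=pos,
                end=pos + config.mature_length,
            )
        )
    if made < config.n_decoy_stacks:
        raise ValueError("genome too small")

    # In-situ generation-time assertion: every planted duplex must pass the
    # annotation criteria in its actual genomic context.
    for locus in planted:
        w_lo = max(0, locus.mature_start - 150)
        w_hi = min(config.genome_length, locus.mature_end + 150)
        window = genome["chr1"][w_lo:w_hi]
        if locus.strand == "-":
            window = revcomp(window)
        ev = annotate.evaluate_duplex(locus.mature, window)
        if not ev.passed:  # pragma: no cover - guarded by construction
            raise RuntimeError(f"planted locus {locus.name} fails in situ")
        locus.star = ev.star

    counts, log2fc = simulate_counts(config, n_loci=config.n_planted_loci)
    decoy_counts, _ = simulate_counts(
        config,
        n_loci=len(decoys),
        fold_changes=[1.0],
        rng=np.random.default_rng([int(config.seed), _STAGE["counts"], 7]),
    )
    truth = SimulationTruth(
        planted_loci=planted,
        decoys=decoys,
        true_counts=counts,
        decoy_counts=decoy_counts,
        true_log2fc=log2fc,
        sample_ids=config.sample_ids,
    )
    return genome, truth


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB draws with Var = mu + dispersion * mu^2 (Poisson if dispersion 0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(
    config: SimulationConfig,
    n_loci: int | None = None,
    base_means: np.ndarray | None = None,
    fold_changes: Iterable[float] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the locus x sample count matrix under the NB model.

    Group X means are ``base_mean * fold_change``; group P means are the
    base means; dispersion is ``config.nb_dispersion`` throughout. Returns
    (counts, true log2 fold changes).
    """
    if config.n_samples_per_group < 2:
        raise ValueError("need >= 2 samples per group")
    rng = rng if rng is not None else stage_rng(config.seed, "counts")
    n_loci = n_loci if n_loci is not None else config.n_planted_loci
    fcs = list(fold_changes) if fold_changes is not None else list(
        config.planted_fold_changes
    )
    if any(fc <= 0 for fc in fcs):
        raise ValueError("fold changes must be positive")
    if base_means is None:
        base_means = np.exp(
            rng.normal(np.log(config.base_mean), 0.5, size=n_loci)
        )
    base_means = np.asarray(base_means, dtype=float)
    fc = np.array([fcs[i % len(fcs)] for i in range(n_loci)]) if fcs else np.ones(n_loci)
    n = config.n_samples_per_group
    counts = np.zeros((n_loci, 2 * n), dtype=np.int64)
    for j in range(n):  # X group
        counts[:, j] = _nb_draw(rng, base_means * fc, config.nb_dispersion)
    for j in range(n):  # P group
        counts[:, n + j] = _nb_draw(rng, base_means, config.nb_dispersion)
    return counts, np.log2(fc)


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def _qualities(rng: np.random.Generator, n: int, low: bool = False) -> list[int]:
    if low:
        q = rng.integers(30, 41, size=n)
        n_low = max(int(0.4 * n), int(np.ceil(0.31 * n)))
        idx = rng.choice(n, size=n_low, replace=False)
        q[idx] = rng.integers(5, 15, size=n_low)
        return [int(x) for x in q]
    return [int(x) for x in rng.integers(32, 41, size=n)]


def _assemble(
    rng: np.random.Generator, insert: str, adapter3: str, read_length: int
) -> str:
    seq = insert + adapter3
    if len(seq) < read_length:
        seq += _random_seq(rng, read_length - len(seq))
    return seq[:read_length]


def _defect_read(
    rng: np.random.Generator,
    kind: str,
    config: SimulationConfig,
    params: FilterParams,
) -> ReadRecord:
    """One read guaranteed to land in filter category ``kind``."""
    rl = config.read_length
    adapter3 = config.adapter3
    for _ in range(100):
        if kind == "low_quality":
            insert = _clean_insert(rng, 21, adapter3)
            seq = _assemble(rng, insert, adapter3, rl)
            rec = ReadRecord("d", seq, _qualities(rng, rl, low=True))
        elif kind == "high_n":
            insert = _clean_insert(rng, 21, adapter3)
            seq = list(_assemble(rng, insert, adapter3, rl))
            n_n = int(np.ceil(0.11 * rl)) + 2
            for pos in rng.choice(rl, size=n_n, replace=False):
                seq[pos] = "N"
            rec = ReadRecord("d", "".join(seq), _qualities(rng, rl))
        elif kind == "five_prime_adapter":
            adapter5 = params.adapter5 or revcomp(adapter3)[-10:]
            insert = _clean_insert(rng, 21, adapter3)
            seq = (adapter5 + insert + adapter3)[:rl]
            seq += _random_seq(rng, rl - len(seq))
            rec = ReadRecord("d", seq, _qualities(rng, rl))
        elif kind == "no_three_prime_adapter":
            seq = _random_seq(rng, rl)
            if find_adapter(seq, adapter3) >= 0:
                continue
            rec = ReadRecord("d", seq, _qualities(rng, rl))
        elif kind == "poly_nt":
            base = DNA[rng.integers(0, 4)]
            seq = _assemble(rng, base * 21, adapter3, rl)
            rec = ReadRecord("d", seq, _qualities(rng, rl))
        elif kind == "length_out_of_range":
            length = 12 if rng.random() < 0.5 else 32
            insert = _clean_insert(rng, length, adapter3)
            seq = _assemble(rng, insert, adapter3, rl)
            rec = ReadRecord("d", seq, _qualities(rng, rl))
        else:  # pragma: no cover
            raise ValueError(f"unknown defect kind {kind}")
        if categorize_read(rec, adapter3, params) == kind:
            return rec
    raise RuntimeError(f"could not construct a {kind} defect read")  # pragma: no cover


def simulate_reads(
    truth: SimulationTruth,
    config: SimulationConfig,
    contaminant_refs: Mapping[str, ReferenceSet] | None = None,
) -> dict[str, list[ReadRecord]]:
    """Per-sample read lists: planted + decoy + defect + contaminant +
    unmappable filler reads, each read = insert + 3' adapter + random pad.

    Planted and decoy read counts are exactly the NB counts recorded in the
    truth (no resampling), so post-QC mapped stack counts are recoverable
    end-to-end. Defect reads are mutually exclusive per category; filler
    reads are clean random inserts that do not map to the genome,
    emulating the unmapped fraction of a real library.
    """
    if len(config.adapter3) < 10:
        raise ValueError("adapter too short for inference fixture")
    params = FilterParams()
    out: dict[str, list[ReadRecord]] = {}
    contam_pool: list[str] = []
    if contaminant_refs:
        for ref in contaminant_refs.values():
            contam_pool.extend(ref.sequences.values())
    for j, sample in enumerate(truth.sample_ids):
        rng = np.random.default_rng([int(config.seed), _STAGE["reads"], j])
        reads: list[ReadRecord] = []
        serial = 0

        def emit(insert: str, tag: str) -> None:
            nonlocal serial
            serial += 1
            seq = _assemble(rng, insert, config.adapter3, config.read_length)
            reads.append(
                ReadRecord(f"{sample}.{serial}.{tag}", seq, _qualities(rng, config.read_length))
            )

        for i, locus in enumerate(truth.planted_loci):
            for _ in range(int(truth.true_counts[i, j])):
                emit(locus.mature, f"L{i+1}")
        for i, decoy in enumerate(truth.decoys):
            for _ in range(int(truth.decoy_counts[i, j])):
                emit(decoy.sequence, f"D{i+1}")

        depth = config.depth_per_sample
        for kind, frac in config.defect_fractions.items():
            for _ in range(int(round(frac * depth))):
                serial += 1
                rec = _defect_read(rng, kind, config, params)
                rec.id = f"{sample}.{serial}.def"
                reads.append(rec)
        if contam_pool:
            for _ in range(int(round(config.contaminant_fraction * depth))):
                src = contam_pool[rng.integers(0, len(contam_pool))]
                length = int(rng.integers(20, 25))
                start = int(rng.integers(0, max(1, len(src) - length)))
                emit(src[start : start + length], "C")
        n_filler = depth - len(reads)
        for _ in range(max(0, n_filler)):
            emit(_clean_insert(rng, int(rng.integers(20, 25)), config.adapter3), "F")
        if depth == 0:
            reads = []
        out[sample] = reads
    return out


# ---------------------------------------------------------------------------
# References, transcripts, degradome
# ---------------------------------------------------------------------------

def simulate_references(
    config: SimulationConfig, truth: SimulationTruth
) -> dict[str, ReferenceSet]:
    """Contaminant references and the known-miRNA reference.

    All but ``n_novel`` planted matures are entered into the known-miRNA
    reference under miRBase-style ids (pde-miR166a, ...), so annotation
    should classify exactly ``n_novel`` loci as novel.
    """
    rng = stage_rng(config.seed, "refs")
    refs = {
        "rRNA": ReferenceSet(
            "rRNA",
            {f"rRNA_{i+1}": _random_seq(rng, 1500) for i in range(2)},
            "rRNA",
        ),
        "tRNA": ReferenceSet(
            "tRNA",
            {f"tRNA_{i+1}": _random_seq(rng, 80) for i in range(5)},
            "tRNA",
        ),
        "organelle": ReferenceSet(
            "organelle", {"chloroplast_1": _random_seq(rng, 3000)}, "organelle"
        ),
    }
    known: dict[str, str] = {}
    n_known = max(0, len(truth.planted_loci) - config.n_novel)
    for i, locus in enumerate(truth.planted_loci[:n_known]):
        family = _FAMILY_NAMES[i % len(_FAMILY_NAMES)]
        letter = "abcdefgh"[i // len(_FAMILY_NAMES)]
        name = f"pde-{family}{letter}"
        known[name] = locus.mature
        locus.known_name = name
    refs["known_miRNA"] = ReferenceSet("known_miRNA", known, "known_miRNA")
    return refs


def simulate_transcripts(
    config: SimulationConfig, truth: SimulationTruth
) -> dict[str, str]:
    """Random transcripts with reverse-complement miRNA target sites planted
    in the first ``n_target_sites`` transcripts; records truth.planted_sites
    with 1-based cleavage positions opposite miRNA position 10."""
    rng = stage_rng(config.seed, "degradome")
    tx: dict[str, str] = {}
    for t in range(config.n_transcripts):
        tx[f"tx{t+1:03d}"] = _random_seq(rng, config.transcript_length)
    truth.planted_sites = []
    n_sites = min(config.n_target_sites, len(truth.planted_loci))
    for k in range(n_sites):
        locus = truth.planted_loci[k]
        tx_id = f"tx{k+1:03d}"
        L = len(locus.mature)
        site = revcomp(locus.mature)
        t0 = int(rng.integers(50, config.transcript_length - L - 60))  # 0-based
        seq = tx[tx_id]
        tx[tx_id] = seq[:t0] + site + seq[t0 + L :]
        cleavage = (t0 + 1) + L - 10  # 1-based position opposite miRNA pos 10
        truth.planted_sites.append(
            (locus.name, tx_id, cleavage, config.degradome_signal_fraction)
        )
    return tx


def simulate_degradome(
    truth: SimulationTruth,
    transcripts: Mapping[str, str],
    config: SimulationConfig,
    tag_length: int = 25,
) -> list[ReadRecord]:
    """One pooled degradome 5'-tag library (already adapter-trimmed).

    For each transcript with a planted site, a ``degradome_signal_fraction``
    of its tags start exactly at the cleavage position; the rest (and all
    tags of site-free transcripts) start uniformly. Tag allocation is even
    across transcripts.
    """
    rng = np.random.default_rng([int(config.seed), _STAGE["degradome"], 99])
    sites_by_tx: dict[str, list[tuple[str, int, float]]] = {}
    for mirna, tx_id, pos, frac in truth.planted_sites:
        if tx_id not in transcripts:
            raise ValueError(f"planted site references unknown transcript {tx_id}")
        if not 1 <= pos <= len(transcripts[tx_id]) - tag_length + 1:
            raise ValueError(f"cleavage position {pos} outside transcript {tx_id}")
        sites_by_tx.setdefault(tx_id, []).append((mirna, pos, frac))
    tags: list[ReadRecord] = []
    tx_ids = list(transcripts)
    if not tx_ids:
        return tags
    per_tx = config.degradome_depth // len(tx_ids)
    serial = 0
    for tx_id in tx_ids:
        seq = transcripts[tx_id]
        max_start = len(seq) - tag_length + 1  # 1-based start positions
        if max_start < 1:
            continue
        n_signal = 0
        if tx_id in sites_by_tx:
            _, pos, frac = sites_by_tx[tx_id][0]
            n_signal = int(round(frac * per_tx))
            for _ in range(n_signal):
                serial += 1
                tags.append(
                    ReadRecord(
                        f"tag.{serial}",
                        seq[pos - 1 : pos - 1 + tag_length],
                        [38] * tag_length,
                    )
                )
        for _ in range(per_tx - n_signal):
            serial += 1
            start = int(rng.integers(1, max_start + 1))
            tags.append(
                ReadRecord(
                    f"tag.{serial}",
                    seq[start - 1 : start - 1 + tag_length],
                    [38] * tag_length,
                )
            )
    return tags


def simulate_term_map(
    config: SimulationConfig,
    truth: SimulationTruth,
    transcripts: Mapping[str, str],
    n_terms: int = 6,
) -> dict[str, set[str]]:
    """Toy GO/KEGG-style term -> gene map over the transcript universe.

    Term 1 is enriched for planted target transcripts; remaining terms are
    random subsets, so the enrichment stage has one true positive.
    """
    rng = np.random.default_rng([int(config.seed), _STAGE["refs"], 13])
    universe = sorted(transcripts)
    target_tx = sorted({tx for _, tx, _, _ in truth.planted_sites})
    terms: dict[str, set[str]] = {}
    extra = [t for t in universe if t not in target_tx]
    pad = [extra[i] for i in rng.choice(len(extra), size=min(2, len(extra)), replace=False)]
    terms["TERM:0001"] = set(target_tx) | set(pad)
    for t in range(1, n_terms):
        size = int(rng.integers(4, max(5, len(universe) // 3)))
        members = rng.choice(len(universe), size=min(size, len(universe)), replace=False)
        terms[f"TERM:{t+1:04d}"] = {universe[i] for i in members}
    return terms
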