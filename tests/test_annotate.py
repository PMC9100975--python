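"""Read mapping, stacking, precursor windows, duplex criteria, loci."""

import numpy as np
import pytest

from sylvamir.annotate import (
    AlignmentHit,
    ReadStack,
    annotate_loci,
    build_stacks,
    classify_known_novel,
    evaluate_duplex,
    extract_precursor_window,
    map_reads,
)
from sylvamir.contaminants import ReferenceSet
from sylvamir.mapping import brute_force_hits
from sylvamir.seq import revcomp


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestMapReads:
    def test_planted_read_found_once(self, small_genome):
        genome, truth = small_genome
        locus = truth.planted_loci[0]
        hits, _ = map_reads([locus.mature], genome)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (
            locus.mature_start,
            locus.mature_end,
            locus.strand,
        )

    def test_absent_read_no_hits(self, small_genome):
        genome, _ = small_genome
        hits, _ = map_reads(["A" * 21], genome)
        assert hits == []

    def test_duplicated_read_two_hits_vs_bruteforce(self):
        rng = np.random.default_rng(31)
        read = _rand(rng, 21)
        genome = {"c": _rand(rng, 900) + read + _rand(rng, 500) + read + _rand(rng, 600)}
        hits, _ = map_reads([read], genome)
        assert len(hits) == 2
        oracle = brute_force_hits(read, genome)
        assert [(h.seq_id, h.start, h.strand, h.mismatches) for h in hits] == oracle

    def test_max_hits_discards_repeats(self):
        rng = np.random.default_rng(32)
        read = _rand(rng, 20)
        genome = {"c": (read + _rand(rng, 30)) * 5}
        hits, discarded = map_reads([read], genome, max_hits=3)
        assert hits == [] and discarded == 1

    def test_empty_genome_error(self):
        with pytest.raises(ValueError, match="empty reference"):
            map_reads(["ACGT" * 5], {})

    def test_agrees_with_bruteforce_on_random_genome(self):
        rng = np.random.default_rng(33)
        genome = {"a": _rand(rng, 3000), "b": _rand(rng, 2000)}
        for m in (0, 1):
            for _ in range(25):
                if rng.random() < 0.6:
                    src = genome["a" if rng.random() < 0.5 else "b"]
                    start = int(rng.integers(0, len(src) - 25))
                    read = src[start : start + 22]
                    if rng.random() < 0.5:
                        read = revcomp(read)
                else:
                    read = _rand(rng, 22)
                hits, _ = map_reads([read], genome, max_mismatch=m, max_hits=10**6)
                assert [
                    (h.seq_id, h.start, h.strand, h.mismatches) for h in hits
                ] == brute_force_hits(read, genome, max_mismatch=m)


def _hit(read_id, start, end, strand="+", seq_id="c"):
    return AlignmentHit(read_id, seq_id, start, end, strand, 0, 1)


class TestBuildStacks:
    def test_identical_coordinates_merge(self):
        hits = [_hit("AAACCC", 100, 121), _hit("AAACCC", 100, 121)]
        counts = {"AAACCC": np.array([2, 3])}
        stacks = build_stacks(hits, counts=counts, n_samples=2)
        assert len(stacks) == 1
        # the same unique sequence placed twice keeps its per-sample counts
        assert stacks[0].counts_per_sample.tolist() == [4, 6]

    def test_distant_reads_separate(self):
        stacks = build_stacks([_hit("A", 0, 21), _hit("B", 121, 142)])
        assert len(stacks) == 2

    def test_two_nt_offsets_merge_into_expected_boundaries(self):
        # hand enumeration: starts 0,2,4 chain (end 25); a 3-nt gap breaks
        # the chain at 28; 80 stands alone
        hits = [
            _hit("a", 0, 21), _hit("b", 2, 23), _hit("c", 4, 25),
            _hit("d", 28, 49), _hit("e", 30, 51), _hit("f", 80, 101),
        ]
        stacks = build_stacks(hits)
        spans = [(s.start, s.end) for s in stacks]
        assert spans == [(0, 25), (28, 51), (80, 101)]
        # abutting within 2 nt does merge
        merged = build_stacks([_hit("a", 0, 21), _hit("b", 23, 44)])
        assert [(s.start, s.end) for s in merged] == [(0, 44)]

    def test_strands_do_not_merge(self):
        hits = [_hit("a", 0, 21, "+"), _hit("b", 0, 21, "-")]
        assert len(build_stacks(hits)) == 2

    def test_representative_most_abundant_then_lexicographic(self):
        hits = [_hit("TTT", 0, 21), _hit("AAA", 1, 22), _hit("CCC", 2, 23)]
        counts = {"TTT": np.array([5]), "AAA": np.array([5]), "CCC": np.array([1])}
        stacks = build_stacks(hits, counts=counts, n_samples=1)
        assert stacks[0].representative_sequence == "AAA"


class TestPrecursorWindow:
    def test_plus_strand_extension(self):
        genome = {"c": "".join(np.random.default_rng(34).choice(list("ACGT"), 10_000))}
        stack = ReadStack("c", "+", 500, 521, genome["c"][500:521], np.array([1]))
        win = extract_precursor_window(stack, genome)
        assert (win.start, win.end) == (350, 671)
        assert len(win.sequence) == 321
        assert win.sequence == genome["c"][350:671]

    def test_clipped_at_contig_start(self):
        genome = {"c": "ACGT" * 200}
        stack = ReadStack("c", "+", 10, 31, genome["c"][10:31], np.array([1]))
        win = extract_precursor_window(stack, genome)
        assert win.start == 0 and win.end == 181

    def test_minus_strand_reverse_complement(self):
        rng = np.random.default_rng(35)
        genome = {"c": _rand(rng, 2000)}
        stack = ReadStack("c", "-", 800, 821, "x", np.array([1]))
        win = extract_precursor_window(stack, genome)
        assert win.sequence == revcomp(genome["c"][650:971])
        # coordinate round-trip
        assert win.to_genome(0, 5) == (966, 971)


def _complement_sub(c):
    return {"A": "C", "C": "A", "G": "T", "T": "G"}[c]


class TestEvaluateDuplex:
    def _window(self, rng, mature, arm, loop_len=8, flank=120):
        return _rand(rng, flank) + mature + _rand(rng, loop_len) + arm + _rand(rng, flank)

    def test_perfect_inverted_repeat(self):
        rng = np.random.default_rng(36)
        m = _rand(rng, 21)
        win = self._window(rng, m, revcomp(m))
        ev = evaluate_duplex(m, win)
        assert ev.passed
        assert ev.total_mismatches == 0 and ev.loop_region_mismatches == 0
        # star = rc arm shifted by the canonical 2-nt 3' overhang
        i = win.find(m)
        arm_start = i + 21 + 8
        assert ev.star == win[arm_start + 2 : arm_start + 23]
        assert ev.overhang_5p == ev.overhang_3p == 2

    def test_six_substitutions_fail(self):
        rng = np.random.default_rng(37)
        m = _rand(rng, 21)
        arm = list(revcomp(m))
        for pos in (1, 4, 8, 12, 16, 19):
            arm[pos] = _complement_sub(arm[pos])
        ev = evaluate_duplex(m, self._window(rng, m, "".join(arm)))
        assert not ev.passed
        assert ev.total_mismatches >= 6
        assert "mismatches>5" in ev.fail_reasons

    def test_five_mismatches_three_bulges_boundary_passes(self):
        rng = np.random.default_rng(38)
        m = _rand(rng, 21)
        rc = revcomp(m)
        # two substitutions plus a 3-nt bulge inserted in the star arm
        arm = list(rc)
        arm[2] = _complement_sub(arm[2])
        arm[18] = _complement_sub(arm[18])
        arm = "".join(arm[:10]) + "TAG" + "".join(arm[10:])
        ev = evaluate_duplex(m, self._window(rng, m, arm))
        assert ev.total_mismatches == 5
        assert ev.loop_region_mismatches == 3
        assert ev.passed

    def test_large_internal_loop_fails(self):
        rng = np.random.default_rng(39)
        m = _rand(rng, 21)
        rc = revcomp(m)
        arm = rc[:10] + "TTAGGCA" + rc[10:]  # 7-nt bulge > 5
        ev = evaluate_duplex(m, self._window(rng, m, arm))
        assert not ev.passed

    def test_mature_on_downstream_arm(self):
        """Hairpin with the mature on the 3' arm is found symmetrically."""
        rng = np.random.default_rng(40)
        m = _rand(rng, 21)
        win = _rand(rng, 120) + revcomp(m) + _rand(rng, 10) + m + _rand(rng, 120)
        ev = evaluate_duplex(m, win)
        assert ev.passed and ev.total_mismatches == 0

    def test_no_arm_is_large_loop_failure(self):
        # poly-A flanks cannot pair a T-free mature (no matches, no G:U),
        # so arm detection must fail entirely
        m = "ACGGCAGCCAGACGACCGAGA"
        ev = evaluate_duplex(m, "A" * 150 + m + "A" * 150)
        assert not ev.passed
        assert ev.large_loop
        assert "no_complementary_arm" in ev.fail_reasons

    def test_mature_absent_raises(self):
        with pytest.raises(ValueError, match="mature not found"):
            evaluate_duplex("ACGTACGTACGTACGTACGTA", "GGGG" * 40)

    def test_mature_length_bounds(self):
        rng = np.random.default_rng(42)
        m = _rand(rng, 19)  # below the 20-24 window
        ev = evaluate_duplex(m, self._window(rng, m, revcomp(m)))
        assert not ev.passed
        assert any("mature_length" in r for r in ev.fail_reasons)

    def test_precursor_capped_at_300(self, small_genome):
        genome, truth = small_genome
        for locus in truth.planted_loci:
            assert len(locus.precursor) <= 300


class TestAnnotateLoci:
    def test_planted_recovery_with_decoys(self, small_config, small_genome):
        genome, truth = small_genome
        unique = {}
        for i, locus in enumerate(truth.planted_loci):
            unique[locus.mature] = truth.true_counts[i]
        for i, decoy in enumerate(truth.decoys):
            unique[decoy.sequence] = truth.decoy_counts[i]
        hits, _ = map_reads(unique, genome)
        stacks = build_stacks(hits, counts=unique, n_samples=truth.true_counts.shape[1])
        loci = annotate_loci(stacks, genome)
        found = {l.mature for l in loci}
        planted = {p.mature for p in truth.planted_loci}
        assert found == planted  # sensitivity 1 and precision 1

    def test_low_count_locus_removed(self, small_genome):
        genome, truth = small_genome
        locus = truth.planted_loci[0]
        unique = {locus.mature: np.array([9, 9, 9, 9, 9, 9])}
        hits, _ = map_reads(unique, genome)
        stacks = build_stacks(hits, counts=unique, n_samples=6)
        assert annotate_loci(stacks, genome) == []
        unique = {locus.mature: np.array([9, 9, 10, 9, 9, 9])}
        stacks = build_stacks(hits, counts=unique, n_samples=6)
        assert len(annotate_loci(stacks, genome)) == 1

    def test_empty_stacks(self, small_genome):
        genome, _ = small_genome
        assert annotate_loci([], genome) == []

    def test_emitted_loci_satisfy_invariants(self, small_genome):
        genome, truth = small_genome
        unique = {p.mature: truth.true_counts[i] for i, p in enumerate(truth.planted_loci)}
        hits, _ = map_reads(unique, genome)
        stacks = build_stacks(hits, counts=unique, n_samples=6)
        for locus in annotate_loci(stacks, genome):
            locus.validate()  # raises on any invariant violation
            sid, s, e, strand = locus.coordinates
            contig = genome[sid]
            pre = contig[s:e] if strand == "+" else revcomp(contig[s:e])
            assert pre == locus.precursor

    def test_strand_symmetry(self, small_genome):
        """Reverse-complementing the genome mirrors the locus set."""
        genome, truth = small_genome
        unique = {p.mature: truth.true_counts[i] for i, p in enumerate(truth.planted_loci)}
        hits, _ = map_reads(unique, genome)
        stacks = build_stacks(hits, counts=unique, n_samples=6)
        loci = annotate_loci(stacks, genome)

        flipped = {k: revcomp(v) for k, v in genome.items()}
        hits2, _ = map_reads(unique, flipped)
        stacks2 = build_stacks(hits2, counts=unique, n_samples=6)
        loci2 = annotate_loci(stacks2, flipped)
        n = len(genome["chr1"])
        orig = {
            (l.mature, l.coordinates[1], l.coordinates[2], l.coordinates[3])
            for l in loci
        }
        mirrored = {
            (l.mature, n - l.coordinates[2], n - l.coordinates[1],
             "+" if l.coordinates[3] == "-" else "-")
            for l in loci2
        }
        assert orig == mirrored


class TestClassifyKnownNovel:
    def _locus(self, mature):
        from sylvamir.annotate import DuplexEvaluation, MiRNALocus

        ev = DuplexEvaluation(mature, "", 0, 0, 2, 2, False, True)
        return MiRNALocus(
            name="", family=None, mature=mature, star="", precursor=mature,
            coordinates=("c", 0, len(mature), "+"), status="novel", evaluation=ev,
        )

    def test_exact_match_known(self):
        rng = np.random.default_rng(43)
        m = _rand(rng, 21)
        ref = ReferenceSet("known_miRNA", {"pde-miR166a": m}, "known_miRNA")
        status, family, name = classify_known_novel(self._locus(m), ref)
        assert (status, family, name) == ("known", "miR166", "pde-miR166a")

    def test_three_substitutions_novel(self):
        rng = np.random.default_rng(44)
        m = _rand(rng, 21)
        mutated = list(m)
        for pos in (2, 9, 17):
            mutated[pos] = _complement_sub(mutated[pos])
        ref = ReferenceSet("known_miRNA", {"pde-miR396b": "".join(mutated)}, "known_miRNA")
        # oracle: exhaustive offset comparison says distance 3 > 2
        assert sum(a != b for a, b in zip(m, "".join(mutated))) == 3
        status, _, _ = classify_known_novel(self._locus(m), ref)
        assert status == "novel"

    def test_two_substitutions_known(self):
        rng = np.random.default_rng(45)
        m = _rand(rng, 21)
        mutated = list(m)
        for pos in (2, 9):
            mutated[pos] = _complement_sub(mutated[pos])
        ref = ReferenceSet("known_miRNA", {"ptc-miR319e": "".join(mutated)}, "known_miRNA")
        status, family, _ = classify_known_novel(self._locus(m), ref)
        assert (status, family) == ("known", "miR319")

    def test_empty_reference_all_novel(self):
        status, family, _ = classify_known_novel(
            self._locus("ACGTACGTACGTACGTACGTA"), None
        )
        assert status == "novel" and family is None
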