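"""Degradome tag mapping, scoring, categories, permutation p, target calls."""

import itertools

import numpy as np
import pytest

from sylvamir.degradome import (
    DegradomeProfile,
    call_targets,
    categorize_site,
    categorize_site_bruteforce,
    locate_cleavage,
    map_tags,
    permutation_pvalue,
    score_complementarity,
)
from sylvamir.seq import revcomp
from sylvamir.simulate import (
    SimulationConfig,
    simulate_degradome,
    simulate_genome,
    simulate_transcripts,
)

from conftest import make_read


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestMapTags:
    def test_exact_placement(self):
        rng = np.random.default_rng(60)
        tx = {"t1": _rand(rng, 300)}
        tag = make_read(tx["t1"][100:125])
        profiles, unplaced = map_tags([tag], tx)
        assert unplaced == 0
        assert profiles["t1"].tag5_counts[100] == 1  # 0-based index = pos 101
        assert profiles["t1"].total_tags == 1

    def test_absent_tag_counted_unplaced(self):
        rng = np.random.default_rng(61)
        tx = {"t1": _rand(rng, 300)}
        _, unplaced = map_tags([make_read("ACGT" * 7)], tx)
        assert unplaced == 1

    def test_multi_placement_counts_everywhere(self):
        rng = np.random.default_rng(62)
        core = _rand(rng, 40)
        tx = {"t1": _rand(rng, 50) + core + _rand(rng, 50) + core + _rand(rng, 30)}
        tag = make_read(core[:25])
        profiles, _ = map_tags([tag], tx)
        assert profiles["t1"].tag5_counts.sum() == 2

    def test_empty_transcriptome_error(self):
        with pytest.raises(ValueError, match="empty transcriptome"):
            map_tags([], {})


class TestScoreComplementarity:
    def test_perfect_complement_zero(self):
        rng = np.random.default_rng(63)
        m = _rand(rng, 21)
        score, pairs = score_complementarity(m, revcomp(m))
        assert score == 0.0
        assert len(pairs) == 21
        assert pairs[0] == (1, 21) and pairs[-1] == (21, 1)

    def test_gu_wobble_at_position5_scores_one(self):
        # G:U inside the doubled 2-13 core: 0.5 x 2 = 1.0
        m = "AACCG" + "ACCAACCAACCAACCA"  # position 5 is G
        rc = list(m)
        rc[4] = "A"  # (G, A) in rc space is the G:U wobble
        site = revcomp("".join(rc))
        score, _ = score_complementarity(m, site)
        assert score == 1.0

    def test_mismatch_at_position20_scores_one(self):
        m = "CCAACCAACCAACCAACCAAC"  # 21 nt, position 20 is A
        assert m[19] == "A"
        rc = list(m)
        rc[19] = "G"  # (A, G) is a plain mismatch, outside the core
        score, _ = score_complementarity(m, revcomp("".join(rc)))
        assert score == 1.0

    def test_mismatch_inside_core_doubled(self):
        m = "CCAACCAACCAACCAACCAAC"
        rc = list(m)
        rc[6] = "G"  # position 7, inside 2-13
        score, _ = score_complementarity(m, revcomp("".join(rc)))
        assert score == 2.0

    def test_single_gap_absorbs_length_difference(self):
        rng = np.random.default_rng(64)
        m = _rand(rng, 21)
        # site one nt longer: a bulged target base must cost >= 1.0
        site = revcomp(m[:10]) + "A" + revcomp(m[10:])
        site = revcomp(m[10:]) + "A" + revcomp(m[:10])
        score, _ = score_complementarity(m, site)
        assert 1.0 <= score <= 2.0

    def test_window_length_bound(self):
        with pytest.raises(ValueError, match="4 of miRNA length"):
            score_complementarity("ACGTACGTACGTACGTACGTA", "ACGT" * 10)


class TestLocateCleavage:
    def test_pairs_position10(self):
        rng = np.random.default_rng(65)
        m = _rand(rng, 21)
        _, pairs = score_complementarity(m, revcomp(m))
        # miRNA pos 10 pairs window pos L - 9 = 12
        assert locate_cleavage(pairs) == 12

    def test_shifted_alignment_shifts_antiparallel(self):
        rng = np.random.default_rng(66)
        m = _rand(rng, 21)
        _, pairs = score_complementarity(m, revcomp(m))
        shifted = [(q, w + 1) for q, w in pairs]
        assert locate_cleavage(shifted) == locate_cleavage(pairs) + 1

    def test_gap_at_core_rejected(self):
        rng = np.random.default_rng(67)
        m = _rand(rng, 21)
        _, pairs = score_complementarity(m, revcomp(m))
        gapped = [(q, w) for q, w in pairs if q != 10]
        with pytest.raises(ValueError, match="positions 10-11"):
            locate_cleavage(gapped)


class TestCategorizeSite:
    @pytest.mark.parametrize(
        "counts,pos,expected",
        [
            ([9, 2, 1, 1], 1, 0),   # unique maximum
            ([5, 5, 1], 1, 1),      # tied maximum
            ([5, 3, 3, 2, 1], 2, 2),  # 3 > mean(nonzero)=2.8
            ([5, 3, 3, 2, 1], 4, 3),  # 2 < 2.8
            ([5, 3, 3, 2, 1], 5, 4),  # single read
        ],
    )
    def test_stated_examples(self, counts, pos, expected):
        prof = DegradomeProfile("t", len(counts), np.array(counts))
        assert categorize_site(prof, pos) == expected

    def test_zero_count_position_not_called(self):
        prof = DegradomeProfile("t", 3, np.array([5, 0, 1]))
        with pytest.raises(ValueError, match="no tag support"):
            categorize_site(prof, 2)

    def test_out_of_range_position(self):
        prof = DegradomeProfile("t", 3, np.array([1, 1, 1]))
        with pytest.raises(ValueError, match="outside"):
            categorize_site(prof, 4)

    def test_agrees_with_bruteforce_on_all_small_profiles(self):
        """Complete enumeration: all profiles of length <= 6, counts 0-3."""
        for length in range(1, 7):
            for counts in itertools.product(range(4), repeat=length):
                if sum(counts) == 0:
                    continue
                prof = DegradomeProfile("t", length, np.array(counts))
                for pos in range(1, length + 1):
                    if counts[pos - 1] == 0:
                        continue
                    assert categorize_site(prof, pos) == categorize_site_bruteforce(
                        prof, pos
                    ), (counts, pos)

    def test_category_monotone_in_site_count(self):
        """Raising counts[pos] (others fixed) never worsens the category."""
        for length in range(2, 5):
            for counts in itertools.product(range(4), repeat=length):
                for pos in range(1, length + 1):
                    if counts[pos - 1] == 0:
                        continue
                    prof = DegradomeProfile("t", length, np.array(counts))
                    cat = categorize_site(prof, pos)
                    bumped = list(counts)
                    bumped[pos - 1] += 1
                    prof2 = DegradomeProfile("t", length, np.array(bumped))
                    assert categorize_site(prof2, pos) <= cat


class TestPermutationPvalue:
    def _planted(self, seed=68):
        rng = np.random.default_rng(seed)
        m = _rand(rng, 21)
        tx = _rand(rng, 150) + revcomp(m) + _rand(rng, 150)
        pos = 150 + 21 - 9  # 1-based position opposite miRNA position 10
        counts = np.zeros(len(tx), dtype=int)
        counts[pos - 1] = 50
        rest = rng.integers(0, len(tx), size=30)
        for r in rest:
            counts[r] += 1
        return m, tx, DegradomeProfile("t", len(tx), counts), pos

    def test_planted_site_small_p(self):
        m, tx, prof, pos = self._planted()
        score, pairs = score_complementarity(m, tx[pos + 9 - 21 : pos + 9])
        assert score == 0.0
        cat = categorize_site(prof, pos)
        p = permutation_pvalue(m, tx, prof, score, cat, R=100, seed=3)
        assert p <= 0.02

    def test_weak_site_p_near_one(self):
        m, tx, prof, pos = self._planted(seed=69)
        # observed far worse than anything: score above every achievable one
        p = permutation_pvalue(m, tx, prof, observed_score=50.0,
                               observed_category=4, R=50, seed=1, max_score=100.0)
        assert p == 1.0

    def test_determinism(self):
        m, tx, prof, pos = self._planted(seed=70)
        args = dict(observed_score=3.0, observed_category=2, R=60, seed=9)
        assert permutation_pvalue(m, tx, prof, **args) == permutation_pvalue(
            m, tx, prof, **args
        )

    def test_r_zero_rejected(self):
        m, tx, prof, _ = self._planted(seed=71)
        with pytest.raises(ValueError, match="R must be"):
            permutation_pvalue(m, tx, prof, 0.0, 0, R=0)

    def test_null_pvalues_super_uniform(self):
        """Random miRNA vs random transcript: P(p <= a) <= a + 0.03."""
        rng = np.random.default_rng(72)
        hits = 0
        n_rep = 60
        alpha = 0.2
        for _ in range(n_rep):
            m = _rand(rng, 21)
            tx = _rand(rng, 120)
            counts = np.zeros(120, dtype=int)
            for r in rng.integers(0, 100, size=25):
                counts[r] += 1
            prof = DegradomeProfile("t", 120, counts)
            positions = np.nonzero(counts)[0] + 1
            cand = [p for p in positions if 21 - 9 <= p <= 120 - 9]
            if not cand:
                continue
            pos = int(cand[0])
            window = tx[pos + 9 - 21 : pos + 9]
            score, _ = score_complementarity(m, window)
            cat = categorize_site(prof, pos)
            p = permutation_pvalue(m, tx, prof, score, cat, R=39,
                                   seed=int(rng.integers(0, 2**31)), max_score=1e9)
            hits += p <= alpha
        assert hits / n_rep <= alpha + 0.1


class TestCallTargets:
    def _synthetic(self):
        cfg = SimulationConfig(seed=73, n_planted_loci=6, n_decoy_stacks=0,
                               genome_length=14_000, n_transcripts=15,
                               n_target_sites=3, degradome_depth=3_000,
                               degradome_signal_fraction=0.9)
        genome, truth = simulate_genome(cfg)
        tx = simulate_transcripts(cfg, truth)
        tags = simulate_degradome(truth, tx, cfg)
        profiles, _ = map_tags(tags, tx)
        mirnas = {p.name: p.mature for p in truth.planted_loci}
        return cfg, truth, tx, profiles, mirnas

    def test_planted_sites_recovered_exactly(self):
        cfg, truth, tx, profiles, mirnas = self._synthetic()
        sites = call_targets(mirnas, tx, profiles, R=100, seed=1)
        called = {(s.mirna_id, s.transcript_id, s.cleavage_pos) for s in sites}
        planted = {(m, t, p) for m, t, p, _ in truth.planted_sites}
        assert called == planted
        assert all(s.category == 0 for s in sites)

    def test_max_category_relaxation_is_superset(self):
        cfg, truth, tx, profiles, mirnas = self._synthetic()
        strict = call_targets(mirnas, tx, profiles, R=50, seed=2, max_category=2)
        loose = call_targets(mirnas, tx, profiles, R=50, seed=2, max_category=4)
        strict_keys = {(s.mirna_id, s.transcript_id, s.cleavage_pos) for s in strict}
        loose_keys = {(s.mirna_id, s.transcript_id, s.cleavage_pos) for s in loose}
        assert strict_keys <= loose_keys

    def test_empty_degradome_empty_calls(self):
        cfg, truth, tx, _, mirnas = self._synthetic()
        empty = {
            t: DegradomeProfile(t, len(seq), np.zeros(len(seq), dtype=int))
            for t, seq in tx.items()
        }
        assert call_targets(mirnas, tx, empty, R=50, seed=3) == []
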