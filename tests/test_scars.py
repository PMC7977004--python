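"""Scar scores: rule examples, invariances, and brute-force oracle checks.

Unit tests use a toy genome with the same rule structure at unit scale
(thresholds 15 / 10 / 3 on chromosomes a few hundred bases long), which the
base-resolution oracle in ``_oracles`` can scan exhaustively.
"""

import numpy as np
import pytest

from drdscore.io import AllelicSegment, ChromosomeAnnotation
from drdscore.scars import ScarConfig, hrd_score, loh_count, lst_count, tai_count

from _oracles import brute_force_scars

TOY = ScarConfig(loh_min_length=15, lst_min_segment=10, lst_smooth_below=3,
                 tai_min_length=0)


def toy_ann(length=100, cen=(45, 55), chrom="chr1"):
    return {chrom: ChromosomeAnnotation(chrom, length, *cen)}


def seg(start, end, major, minor, chrom="chr1"):
    return AllelicSegment(chrom, start, end, major, minor)


class TestLoh:
    def test_balanced_genome_has_none(self):
        assert loh_count([seg(1, 100, 1, 1)], toy_ann(), TOY) == 0

    def test_long_interstitial_loh_counts_once(self):
        segs = [seg(1, 30, 1, 1), seg(31, 50, 2, 0), seg(51, 100, 1, 1)]
        assert loh_count(segs, toy_ann(), TOY) == 1

    def test_whole_chromosome_loh_excluded(self):
        assert loh_count([seg(1, 100, 1, 0)], toy_ann(), TOY) == 0

    def test_adjacent_loh_segments_merge_before_length_test(self):
        # two 10-unit LOH segments, each below the cutoff, merged above it
        segs = [seg(1, 30, 1, 1), seg(31, 40, 2, 0), seg(41, 50, 1, 0),
                seg(51, 100, 1, 1)]
        assert loh_count(segs, toy_ann(), TOY) == 1

    def test_homozygous_deletion_is_not_loh(self):
        segs = [seg(1, 30, 1, 1), seg(31, 50, 0, 0), seg(51, 100, 1, 1)]
        assert loh_count(segs, toy_ann(), TOY) == 0

    def test_unknown_chromosome_errors(self):
        with pytest.raises(KeyError, match="chr9"):
            loh_count([seg(1, 10, 1, 1, chrom="chr9")], toy_ann(), TOY)


class TestTai:
    def test_balanced_genome_has_none(self):
        assert tai_count([seg(1, 100, 2, 2)], toy_ann(), TOY) == 0

    def test_terminal_imbalance_counts(self):
        segs = [seg(1, 88, 1, 1), seg(89, 100, 2, 1)]
        assert tai_count(segs, toy_ann(), TOY) == 1

    def test_whole_chromosome_imbalance_excluded(self):
        assert tai_count([seg(1, 100, 2, 1)], toy_ann(), TOY) == 0

    def test_centromere_crossing_excluded(self):
        segs = [seg(1, 60, 2, 1), seg(61, 100, 1, 1)]  # covers cen 45-55
        assert tai_count(segs, toy_ann(), TOY) == 0

    def test_interstitial_imbalance_not_telomeric(self):
        segs = [seg(1, 20, 1, 1), seg(21, 40, 2, 1), seg(41, 100, 1, 1)]
        assert tai_count(segs, toy_ann(), TOY) == 0


class TestLst:
    def test_single_segment_has_no_transition(self):
        assert lst_count([seg(1, 100, 1, 1)], toy_ann(), TOY) == 0

    def test_two_large_arm_segments_give_one(self):
        # q arm 56..100: 20 + 25 units, both >= 10
        segs = [seg(1, 55, 1, 1), seg(56, 75, 1, 1), seg(76, 100, 2, 1)]
        assert lst_count(segs, toy_ann(), TOY) == 1

    def test_small_segment_smoothed_away(self):
        # 2-unit blip between equal large flanks: flanks merge, no transition
        segs = [seg(1, 44, 1, 1), seg(56, 75, 1, 1), seg(76, 77, 2, 2),
                seg(78, 100, 1, 1)]
        assert lst_count(segs, toy_ann(), TOY) == 0

    def test_centromere_breakpoint_not_counted(self):
        segs = [seg(1, 50, 1, 1), seg(51, 100, 2, 2)]
        assert lst_count(segs, toy_ann(), TOY) == 0


class TestHrdScore:
    def test_balanced_diploid_all_zero(self):
        r = hrd_score([seg(1, 100, 1, 1)], toy_ann(), TOY)
        assert (r.loh, r.tai, r.lst, r.hrd_score, r.hrd_high) == \
            (0, 0, 0, 0, False)

    def test_threshold_at_42_inclusive(self):
        assert ScarConfig().hrd_high_threshold == 42

    def test_sex_chromosomes_excluded_by_default(self):
        ann = {"chrX": ChromosomeAnnotation("chrX", 100, 45, 55)}
        segs = [seg(1, 30, 1, 1, "chrX"), seg(31, 50, 2, 0, "chrX"),
                seg(51, 100, 1, 1, "chrX")]
        assert loh_count(segs, ann, TOY) == 0
        inc = ScarConfig(loh_min_length=15, lst_min_segment=10,
                         lst_smooth_below=3, include_sex_chromosomes=True)
        assert loh_count(segs, ann, inc) == 1


def random_genome(rng):
    """2-3 chromosomes, <= 12 segments, random states and gaps."""
    ann = {}
    segments = []
    n_chrom = int(rng.integers(2, 4))
    states = [(1, 1), (1, 1), (2, 1), (1, 0), (2, 0), (2, 2), (0, 0), (3, 1)]
    for i in range(n_chrom):
        chrom = f"chr{i + 1}"
        length = int(rng.integers(80, 300))
        cen_start = int(rng.integers(2, length - 2))
        cen_end = int(rng.integers(cen_start + 1, length))
        ann[chrom] = ChromosomeAnnotation(chrom, length, cen_start, cen_end)
        pos = 1
        for _ in range(int(rng.integers(0, 5))):
            if pos > length:
                break
            if rng.random() < 0.25:  # leave a gap
                pos += int(rng.integers(1, 20))
                continue
            end = min(length, pos + int(rng.integers(1, 60)))
            st = states[int(rng.integers(0, len(states)))]
            segments.append(AllelicSegment(chrom, pos, end, *st))
            pos = end + 1
    return segments, ann


class TestOracleEquivalence:
    def test_randomized_genomes_match_brute_force(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            segments, ann = random_genome(rng)
            expected = brute_force_scars(segments, ann, TOY)
            got = (loh_count(segments, ann, TOY),
                   tai_count(segments, ann, TOY),
                   lst_count(segments, ann, TOY))
            assert got == expected, (segments, ann)

    def test_segment_bisection_invariance(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            segments, ann = random_genome(rng)
            base = (loh_count(segments, ann, TOY),
                    tai_count(segments, ann, TOY),
                    lst_count(segments, ann, TOY))
            # bisect every segment of length >= 2 into equal-state halves
            split = []
            for s in segments:
                if s.length >= 2:
                    mid = (s.start + s.end) // 2
                    split.append(AllelicSegment(s.chrom, s.start, mid,
                                                s.major_cn, s.minor_cn))
                    split.append(AllelicSegment(s.chrom, mid + 1, s.end,
                                                s.major_cn, s.minor_cn))
                else:
                    split.append(s)
            assert (loh_count(split, ann, TOY), tai_count(split, ann, TOY),
                    lst_count(split, ann, TOY)) == base

    def test_added_loh_region_is_monotone(self):
        ann = toy_ann(length=200, cen=(90, 110))
        segs = [seg(1, 200, 1, 1)]
        base = hrd_score(segs, ann, TOY)
        # carve an isolated interstitial 20-unit LOH into the q arm
        carved = [seg(1, 150, 1, 1), seg(151, 170, 1, 0), seg(171, 200, 1, 1)]
        after = hrd_score(carved, ann, TOY)
        assert after.loh == base.loh + 1
        assert after.tai == base.tai
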