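"""SBS-96 catalogs, indel/microhomology classification, catalog correction."""

import numpy as np
import pytest

from drdscore.catalog import (MutationalCatalog, ReferenceMismatchError,
                              SBS96_LABELS, PYRIMIDINE_TRIPLETS,
                              TripletFrequencyTable, classify_indel,
                              correct_catalog, mhid_count, revcomp,
                              sbs96_catalog, triplet_frequencies)
from drdscore.io import Variant, ValidationError


def snv(pos, ref, alt, chrom="chr1"):
    return Variant(chrom, pos, ref, alt, "SNV")


def deletion(pos, ref, alt, chrom="chr1"):
    return Variant(chrom, pos, ref, alt, "deletion")


class TestSbs96:
    def test_no_snvs_gives_zero_vector(self):
        cat = sbs96_catalog([], {"chr1": "ACGT"})
        assert cat.total == 0

    def test_pyrimidine_snv_bins_directly(self):
        cat = sbs96_catalog([snv(2, "C", "T")], {"chr1": "ACAG"})
        assert cat["A[C>T]A"] == 1
        assert cat.total == 1

    def test_purine_snv_reverse_complements(self):
        # G>A at reference context TGT maps to the A[C>T]A channel
        cat = sbs96_catalog([snv(2, "G", "A")], {"chr1": "TGTC"})
        assert cat["A[C>T]A"] == 1

    def test_reference_mismatch_names_variant(self):
        with pytest.raises(ReferenceMismatchError, match="chr1:2"):
            sbs96_catalog([snv(2, "C", "T")], {"chr1": "AAAA"})

    def test_non_snvs_ignored(self):
        cat = sbs96_catalog([deletion(1, "AC", "A")], {"chr1": "ACGT"})
        assert cat.total == 0

    def test_order_invariance_and_additivity(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=500))
        ref = {"chr1": seq}
        variants = []
        for pos in range(2, 400, 7):
            base = seq[pos - 1]
            alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[base]
            variants.append(snv(pos, base, alt))
        full = sbs96_catalog(variants, ref)
        shuffled = list(variants)
        rng.shuffle(shuffled)
        assert np.array_equal(sbs96_catalog(shuffled, ref).counts, full.counts)
        half = len(variants) // 2
        a = sbs96_catalog(variants[:half], ref)
        b = sbs96_catalog(variants[half:], ref)
        assert np.array_equal(a.counts + b.counts, full.counts)

    def test_strand_symmetry_under_genome_flip(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        variants = []
        for pos in range(2, 290, 11):
            base = seq[pos - 1]
            alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[base]
            variants.append(snv(pos, base, alt))
        cat = sbs96_catalog(variants, {"chr1": seq})
        flipped_seq = revcomp(seq)
        flipped = [snv(len(seq) - v.pos + 1, revcomp(v.ref), revcomp(v.alt))
                   for v in variants]
        cat2 = sbs96_catalog(flipped, {"chr1": flipped_seq})
        assert np.array_equal(cat.counts, cat2.counts)

    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        cat = MutationalCatalog(rng.integers(0, 30, size=96).astype(float))
        p = tmp_path / "cat.tsv"
        cat.to_tsv(p)
        assert np.array_equal(MutationalCatalog.from_tsv(p).counts, cat.counts)


class TestClassifyIndel:
    def test_microhomology_deletion(self):
        #              1234567890123
        seq = "GGGGA" + "CTG" + "CTTTTTTTT"  # delete CTG; 3' flank starts CT
        call = classify_indel(deletion(5, "ACTG", "A"), {"chr1": seq})
        assert call.category == "microhomology deletion"
        assert call.mh_length == 2

    def test_single_base_deletion_never_microhomology(self):
        seq = "GGGGACTTTTTT"
        call = classify_indel(deletion(5, "AC", "A"), {"chr1": seq})
        assert call.mh_length == 0
        assert call.category != "microhomology deletion"

    def test_tandem_repeat_takes_precedence(self):
        seq = "GGGGT" + "AG" + "AGAG" + "TTTT"  # AG deleted inside (AG)x3
        call = classify_indel(deletion(5, "TAG", "T"), {"chr1": seq})
        assert call.category == "repeat-unit deletion"
        assert call.repeat_count >= 2
        assert call.mh_length == 0

    def test_repeat_unit_insertion(self):
        seq = "GGGGT" + "AGAG" + "TTTT"
        v = Variant("chr1", 5, "T", "TAG", "insertion")
        call = classify_indel(v, {"chr1": seq})
        assert call.category == "repeat-unit insertion"

    def test_long_indel_logged_as_complex(self):
        seq = "G" + "A" * 150 + "CCCC"
        v = deletion(1, "G" + "A" * 120, "G")
        call = classify_indel(v, {"chr1": seq}, max_length=100)
        assert call.category == "complex"

    def test_oracle_equivalence_on_random_deletions(self):
        from _oracles import brute_force_mh
        rng = np.random.default_rng(77)
        seq = "".join(rng.choice(list("ACGT"), size=6000))
        checked = 0
        for _ in range(400):
            L = int(rng.integers(2, 13))
            start0 = int(rng.integers(30, len(seq) - 60))
            anchor = seq[start0 - 1]
            v = deletion(start0, anchor + seq[start0:start0 + L], anchor)
            call = classify_indel(v, {"chr1": seq})
            mh, is_repeat = brute_force_mh(seq, start0, L)
            if is_repeat:
                assert call.category == "repeat-unit deletion"
            else:
                assert call.mh_length == mh
                expected = ("microhomology deletion" if mh >= 1 else "complex")
                assert call.category == expected
            checked += 1
        assert checked == 400


class TestMhid:
    def test_no_indels_gives_zero(self):
        assert mhid_count([snv(2, "C", "T")], {"chr1": "ACAG"}) == 0

    def test_mixed_example_counts_only_microhomology(self):
        seq = "GGGGA" + "CTG" + "CTTTTT" + "AGAGAGTTTT"
        variants = [
            deletion(5, "ACTG", "A"),          # microhomology
            deletion(14, "TAG", "T"),          # repeat unit (AGAGAG)
        ]
        assert mhid_count(variants, {"chr1": seq}) == 1

    def test_planted_sites_recovered(self, mini_reference):
        """Deletions at engineered reference sites all classify as MH."""
        fasta = mini_reference.fasta()
        variants = [
            Variant(s.chrom, s.pos, s.ref, s.alt, "deletion")
            for s in mini_reference.mh_sites[:50]
        ]
        assert mhid_count(variants, fasta) == 50


class TestCatalogCorrection:
    def triplet_table(self, counts):
        return TripletFrequencyTable(np.asarray(counts, dtype=float))

    def test_identity_when_tables_equal(self):
        rng = np.random.default_rng(1)
        cat = MutationalCatalog(rng.integers(0, 20, 96).astype(float))
        freq = self.triplet_table(rng.integers(1, 100, 32))
        out = correct_catalog(cat, freq, freq)
        assert np.allclose(out.counts, cat.counts)

    def test_scaling_by_share_ratio(self):
        cat = MutationalCatalog(np.zeros(96))
        cat.counts[SBS96_LABELS.index("A[C>T]A")] = 10.0
        genome = np.ones(32)
        target = np.ones(32)
        aca = PYRIMIDINE_TRIPLETS.index("ACA")
        # genome share of ACA is half the target share -> counts halve...
        # keep other 31 triplets' shares equal by construction
        genome[aca] = 1.0
        target[aca] = 2.0
        genome_t = self.triplet_table(genome)     # share 1/32
        target_t = self.triplet_table(target)     # share 2/33
        out = correct_catalog(cat, genome_t, target_t)
        expected = 10.0 * (1 / 32) / (2 / 33)
        assert out.counts[SBS96_LABELS.index("A[C>T]A")] == pytest.approx(expected)

    def test_correction_inverts(self):
        rng = np.random.default_rng(2)
        cat = MutationalCatalog(rng.integers(0, 50, 96).astype(float))
        g = self.triplet_table(rng.integers(1, 200, 32))
        t = self.triplet_table(rng.integers(1, 200, 32))
        back = correct_catalog(correct_catalog(cat, g, t), t, g)
        assert np.allclose(back.counts, cat.counts, atol=1e-9)

    def test_zero_target_share_with_counts_errors(self):
        cat = MutationalCatalog(np.ones(96))
        g = self.triplet_table(np.ones(32))
        target = np.ones(32)
        target[0] = 0.0
        with pytest.raises(ValidationError, match="zero target"):
            correct_catalog(cat, g, self.triplet_table(target))


class TestTripletFrequencies:
    def test_whole_sequence_counts(self):
        # ACAC: windows ACA (-> ACA) and CAC (center A -> revcomp GTG... )
        table = triplet_frequencies({"chr1": "ACAC"})
        assert table["ACA"] == 1
        # CAC center A (purine): revcomp(CAC) = GTG, center T -> GTG
        assert table["GTG"] == 1
        assert table.counts.sum() == 2

    def test_bed_restriction(self, tmp_path, mini_reference):
        fasta = mini_reference.fasta()
        full = triplet_frequencies(fasta)
        sub = triplet_frequencies(fasta, mini_reference.exome_bed_path)
        assert sub.counts.sum() < full.counts.sum()
        assert (sub.counts > 0).all()  # exome windows cover all 32 contexts
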