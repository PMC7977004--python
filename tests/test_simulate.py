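"""Synthetic-cohort generator: determinism, planted truth, distributions."""

import numpy as np
import pytest

from drdscore.catalog import sbs96_catalog
from drdscore.io import read_segments, read_vcf
from drdscore.scars import hrd_score
from drdscore.signatures import SIGNATURE_NAMES, fit_exposures, load_signatures
from drdscore.simulate import (DESK_SCALE_SCARS, GeneratorConfig,
                               make_reference, simulate_cohort,
                               simulate_patient)


class TestMakeReference:
    def test_same_seed_identical_fasta_bytes(self, tmp_path):
        r1 = make_reference(tmp_path / "a", n_chrom=2, chrom_length=120_000,
                            seed=5, n_mh_sites=20)
        r2 = make_reference(tmp_path / "b", n_chrom=2, chrom_length=120_000,
                            seed=5, n_mh_sites=20)
        assert r1.fasta_path.read_bytes() == r2.fasta_path.read_bytes()

    def test_centromere_inside_chromosome(self, mini_reference):
        for a in mini_reference.ann.values():
            assert 0 < a.centromere_start < a.centromere_end < a.length

    def test_gc_fraction_near_half(self, mini_reference):
        fasta = mini_reference.fasta()
        seq = str(fasta["chr1"][:])
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.45 <= gc <= 0.55


class TestSimulatePatient:
    def test_same_seed_byte_identical_vcf(self, mini_reference, tmp_path):
        cfg = GeneratorConfig()
        kw = dict(scar_targets=(2, 2, 2), mhid_target=5, seed=99)
        p1 = simulate_patient(mini_reference, "sensitive", cfg.sensitive,
                              tmp_path / "a", "P1", **kw)
        p2 = simulate_patient(mini_reference, "sensitive", cfg.sensitive,
                              tmp_path / "b", "P1", **kw)
        assert p1.vcf_path.read_bytes() == p2.vcf_path.read_bytes()
        assert p1.segments_path.read_bytes() == p2.segments_path.read_bytes()

    def test_infeasible_tai_target_errors(self, mini_reference, tmp_path):
        cfg = GeneratorConfig()
        with pytest.raises(ValueError, match="larger genome"):
            simulate_patient(mini_reference, "sensitive", cfg.sensitive,
                             tmp_path, "P1", seed=1,
                             scar_targets=(0, 99, 0))

    def test_vcf_read_back_recovers_planted_variants(
            self, mini_reference, tmp_path):
        cfg = GeneratorConfig()
        p = simulate_patient(mini_reference, "resistant", cfg.resistant,
                             tmp_path, "P1", seed=123,
                             scar_targets=(3, 1, 2), mhid_target=8)
        got = {(v.chrom, v.pos, v.ref, v.alt) for v in read_vcf(p.vcf_path)}
        planted = {(r.chrom, r.pos, r.ref, r.alt) for r in p.planted}
        assert got == planted
        assert len(read_vcf(p.vcf_path)) == len(p.planted)

    def test_planted_scar_targets_recomputed_exactly(self, discovery_run,
                                                     tmp_path):
        """A genome engineered for (loh=20, tai=12, lst=10) scores exactly 42."""
        config, cohort, _ = discovery_run
        ref = cohort.reference
        p = simulate_patient(ref, "sensitive", config.sensitive,
                             tmp_path, "P1", seed=777,
                             scar_targets=(20, 12, 10), mhid_target=16)
        result = hrd_score(read_segments(p.segments_path), ref.ann,
                           config.scars)
        assert (result.loh, result.tai, result.lst) == (20, 12, 10)
        assert result.hrd_score == 42 and result.hrd_high

    def test_score_41_is_not_high(self, discovery_run, tmp_path):
        config, cohort, _ = discovery_run
        p = simulate_patient(cohort.reference, "sensitive", config.sensitive,
                             tmp_path, "P1", seed=778,
                             scar_targets=(20, 11, 10))
        result = hrd_score(read_segments(p.segments_path),
                           cohort.reference.ann, config.scars)
        assert result.hrd_score == 41 and not result.hrd_high


class TestSimulateCohort:
    def test_discovery_preset_size(self, discovery_run):
        _, cohort, _ = discovery_run
        assert len(cohort.patients) == 57
        groups = [p.group for p in cohort.patients]
        assert groups.count("sensitive") == 38
        assert groups.count("resistant") == 19

    def test_validation_preset_size(self, tmp_path):
        cohort = simulate_cohort(GeneratorConfig.validation(seed=2), tmp_path)
        assert len(cohort.patients) == 42
        groups = [p.group for p in cohort.patients]
        assert (groups.count("sensitive"), groups.count("resistant")) == (31, 11)

    def test_empty_cohort_writes_nothing(self, tmp_path):
        out = tmp_path / "empty"
        cohort = simulate_cohort(
            GeneratorConfig(n_sensitive=0, n_resistant=0, seed=1), out)
        assert cohort.patients == []
        assert not out.exists()

    def test_truth_and_manifest_written(self, discovery_run):
        _, cohort, _ = discovery_run
        assert cohort.truth_path.exists()
        assert cohort.manifest_path.exists()
        table = cohort.truth_table
        assert len(table) == 57
        assert set(["HRD", "MHID", "loh", "tai", "lst"]) <= set(table.columns)

    def test_group_medians_near_configured_targets(self, cohort_200):
        """At n=100 per group the planted medians track the configured ones.

        The resistant HRD target is the documented least-squares compromise
        between the published median and HRD-high prevalence, so its sample
        median sits a few points below the nominal 47 but within 10%.
        """
        config, cohort = cohort_200
        t = cohort.truth_table
        for group, params in (("sensitive", config.sensitive),
                              ("resistant", config.resistant)):
            sub = t[t.group == group]
            assert abs(sub["MHID"].median() - params.mhid_mean) \
                <= 0.10 * params.mhid_mean
            assert abs(sub["HRD"].median() - params.hrd_median) \
                <= 0.10 * params.hrd_median

    def test_pooled_catalogs_recover_group_mixture(self, discovery_run):
        """Pooled per-group catalogs NNLS-decompose close to the configured
        signature mixture (cosine >= 0.90)."""
        config, cohort, _ = discovery_run
        signatures = load_signatures()
        fasta = cohort.reference.fasta()
        for group in ("sensitive", "resistant"):
            pooled = np.zeros(96)
            n_mut = 0
            for p in cohort.patients:
                if p.group != group:
                    continue
                variants = read_vcf(p.vcf_path)
                cat = sbs96_catalog(variants, fasta)
                pooled += cat.counts
                n_mut += int(cat.total)
            assert n_mut >= 2_000
            from drdscore.catalog import MutationalCatalog
            exp = fit_exposures(MutationalCatalog(pooled), signatures)
            fitted = exp.values / exp.values.sum()
            weights = config.group(group).signature_weights
            truth = np.zeros(30)
            for name, w in weights.items():
                truth[SIGNATURE_NAMES.index(name)] = w
            truth = truth / truth.sum()
            cos = fitted @ truth / (np.linalg.norm(fitted)
                                    * np.linalg.norm(truth))
            assert cos >= 0.90


class TestEndToEndRecovery:
    INTEGER_FEATURES = ["HRD", "MHID", "CN_load", "DUP_1_100KB", "SNV_load",
                        "NEOANTIGENS"]

    def test_integer_features_equal_truth_exactly(self, discovery_run):
        _, cohort, computed = discovery_run
        truth = cohort.truth_table.set_index("patient_id")
        comp = computed.features
        for col in self.INTEGER_FEATURES:
            assert (comp[col] == truth[col]).all(), col

    def test_scar_components_recomputed_exactly(self, discovery_run):
        config, cohort, _ = discovery_run
        truth = cohort.truth_table.set_index("patient_id")
        for p in cohort.patients[:10]:
            r = hrd_score(read_segments(p.segments_path),
                          cohort.reference.ann, config.scars)
            row = truth.loc[p.patient_id]
            assert (r.loh, r.tai, r.lst) == \
                (row["loh"], row["tai"], row["lst"])
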