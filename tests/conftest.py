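"""Shared fixtures: mini reference, simulated cohorts, recomputed features.

Session-scoped because cohort simulation and per-patient feature
recomputation are the expensive steps; every test that needs the discovery
cohort shares one instance.
"""

from __future__ import annotations

import json

import pytest

from drdscore.pipeline import features_from_manifest
from drdscore.simulate import GeneratorConfig, make_reference, simulate_cohort


@pytest.fixture(scope="session")
def mini_reference(tmp_path_factory):
    """Small 3-chromosome reference for catalog/indel unit tests."""
    out = tmp_path_factory.mktemp("ref")
    return make_reference(out, n_chrom=3, chrom_length=500_000, seed=11,
                          n_mh_sites=120)


@pytest.fixture(scope="session")
def discovery_run(tmp_path_factory):
    """Discovery-preset cohort (38 sensitive / 19 resistant, seed 1) plus the
    feature table recomputed from the emitted files."""
    out = tmp_path_factory.mktemp("discovery")
    config = GeneratorConfig.discovery(seed=1)
    cohort = simulate_cohort(config, out)
    manifest = json.loads(cohort.manifest_path.read_text())
    computed = features_from_manifest(manifest, cohort.reference.ann,
                                      config.scars)
    return config, cohort, computed


@pytest.fixture(scope="session")
def cohort_200(tmp_path_factory):
    """Larger balanced cohort (100 + 100) for distributional checks."""
    out = tmp_path_factory.mktemp("cohort200")
    config = GeneratorConfig(n_sensitive=100, n_resistant=100, seed=7)
    return config, simulate_cohort(config, out)
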