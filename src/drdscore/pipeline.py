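"""End-to-end per-patient feature computation from files.

Glue over the individual modules: read a patient's VCF, segment table and
SV table, compute the scar scores, catalog, exposures and burden features,
and assemble the 14-entry feature vector.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd

from .catalog import mhid_count, sbs96_catalog
from .features import (FeatureVector, assemble_features, cn_load,
                       dup_events_from_segments, dup_load_1_100kb, snv_load)
from .io import (ChromosomeAnnotation, CohortTable, read_segments,
                 read_sv_table, read_vcf, FEATURE_COLUMNS)
from .scars import HG19_SCALE, ScarConfig, hrd_score
from .signatures import SignatureMatrix, fit_exposures, load_signatures

__all__ = ["compute_patient_features", "features_from_manifest"]


def compute_patient_features(
    vcf_path: str | Path,
    segments_path: str | Path,
    reference,
    ann: dict[str, ChromosomeAnnotation],
    sv_path: str | Path | None = None,
    signatures: SignatureMatrix | None = None,
    scars: ScarConfig = HG19_SCALE,
    neoantigens: Optional[float] = None,
) -> FeatureVector:
    """Compute one patient's feature vector from their input files.

    ``reference`` is an indexed sequence (``pyfaidx.Fasta``).  Without an
    SV table, duplication events are derived from copy-number gains in the
    segment table.  The neoantigen count is an external input.
    """
    if signatures is None:
        signatures = load_signatures()
    variants = read_vcf(vcf_path)
    segments = read_segments(segments_path)
    if sv_path is not None:
        events = read_sv_table(sv_path)
    else:
        events = dup_events_from_segments(segments)
    hrd = hrd_score(segments, ann, scars)
    catalog = sbs96_catalog(variants, reference)
    exposures = fit_exposures(catalog, signatures)
    return assemble_features(
        hrd=hrd,
        mhid=mhid_count(variants, reference),
        cn_load_count=cn_load(
            segments, include_sex_chromosomes=scars.include_sex_chromosomes),
        dup_count=dup_load_1_100kb(events),
        snv_count=snv_load(variants),
        exposures=exposures,
        neoantigens=neoantigens,
    )


def features_from_manifest(
    manifest: dict,
    ann: dict[str, ChromosomeAnnotation],
    scars: ScarConfig,
    signatures: SignatureMatrix | None = None,
) -> CohortTable:
    """Recompute every patient's features from a simulated-cohort manifest."""
    from pyfaidx import Fasta

    reference = Fasta(manifest["reference"]["fasta"])
    if signatures is None:
        signatures = load_signatures()
    rows = []
    for entry in manifest["patients"]:
        fv = compute_patient_features(
            entry["vcf"], entry["segments"], reference, ann,
            sv_path=entry["sv"], signatures=signatures, scars=scars,
            neoantigens=entry.get("neoantigens"),
        )
        rows.append({"patient_id": entry["patient_id"],
                     "group": entry["group"],
                     **dict(zip(FEATURE_COLUMNS, fv.as_array()))})
    return CohortTable(pd.DataFrame(rows))
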