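"""Scalar burden features and assembly of the 14-entry feature vector.

The risk score consumes, per patient: the HRD scar score, the
microhomology-deletion count (MHID), the copy-number change load, the
duplication load in 1-100 kb, the SNV load, the neoantigen count (an input,
never computed here) and eight signature exposures (AC1, AC4, AC7, AC10,
AC12, AC18, AC20, AC24).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, fields
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io import (AllelicSegment, StructuralEvent, Variant, ValidationError,
                 FEATURE_COLUMNS, is_autosome)
from .scars import HRDResult
from .signatures import ExposureVector

__all__ = ["FeatureVector", "tmb", "snv_load", "cn_load", "dup_load_1_100kb",
           "assemble_features", "CODING_EFFECTS"]

logger = logging.getLogger(__name__)

# Effect labels treated as coding for mutation-burden counting.  Both
# nonsynonymous and synonymous coding variants count (Chalmers-style TMB).
CODING_EFFECTS = frozenset({
    "missense", "nonsense", "synonymous", "stop_gained", "stop_lost",
    "start_lost", "frameshift", "inframe_insertion", "inframe_deletion",
    "splice_site", "coding",
})

# internal (lower-case) field name -> canonical feature-CSV column
FIELD_TO_COLUMN = {
    "hrd": "HRD",
    "mhid": "MHID",
    "cn_load": "CN_load",
    "dup_1_100kb": "DUP_1_100KB",
    "snv_load": "SNV_load",
    "neoantigens": "NEOANTIGENS",
    "ac1": "AC1",
    "ac4": "AC4",
    "ac7": "AC7",
    "ac10": "AC10",
    "ac12": "AC12",
    "ac18": "AC18",
    "ac20": "AC20",
    "ac24": "AC24",
}
COLUMN_TO_FIELD = {v: k for k, v in FIELD_TO_COLUMN.items()}
FEATURE_FIELDS = list(FIELD_TO_COLUMN)


@dataclass(frozen=True)
class FeatureVector:
    """The 14 per-patient inputs of the risk score."""

    hrd: float = 0.0
    mhid: float = 0.0
    cn_load: float = 0.0
    dup_1_100kb: float = 0.0
    snv_load: float = 0.0
    neoantigens: float = 0.0
    ac1: float = 0.0
    ac4: float = 0.0
    ac7: float = 0.0
    ac10: float = 0.0
    ac12: float = 0.0
    ac18: float = 0.0
    ac20: float = 0.0
    ac24: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            val = getattr(self, f.name)
            if not np.isfinite(val):
                raise ValidationError(f"feature {f.name} is not finite: {val!r}")
            if val < 0:
                raise ValidationError(f"feature {f.name} is negative: {val!r}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURE_FIELDS], dtype=float)

    def as_series(self) -> pd.Series:
        return pd.Series(self.as_array(), index=FEATURE_COLUMNS)

    @classmethod
    def from_series(cls, row: pd.Series) -> "FeatureVector":
        return cls(**{COLUMN_TO_FIELD[c]: float(row[c]) for c in FEATURE_COLUMNS})


def tmb(variants: Sequence[Variant], target_size_mb: float = 33.0) -> float:
    """Tumor mutation burden: qualifying variants per megabase of target.

    When effect annotations are present, coding variants (synonymous
    included) are counted; without annotations every variant counts, and the
    choice is logged.  The default target size is the 33 Mb exome capture.
    """
    if target_size_mb <= 0:
        raise ValidationError(f"target_size_mb must be > 0, got {target_size_mb}")
    annotated = any(v.effect is not None for v in variants)
    if annotated:
        n = sum(1 for v in variants
                if v.effect is not None and v.effect.lower() in CODING_EFFECTS)
        logger.info("TMB: counting %d coding variants (effect-annotated input)", n)
    else:
        n = len(variants)
        logger.info("TMB: no effect annotations; counting all %d variants", n)
    return n / target_size_mb


def snv_load(variants: Iterable[Variant]) -> int:
    """Number of single-nucleotide variants."""
    return sum(1 for v in variants if v.vclass == "SNV")


def cn_load(segments: Sequence[AllelicSegment],
            include_sex_chromosomes: bool = False,
            merge: bool = True) -> int:
    """Copy-number change load: merged autosomal regions with total CN != 2.

    Adjacent aberrant segments (next starts one base after the previous
    ends) merge into a single region regardless of their exact allelic
    state; ``merge=False`` counts raw aberrant segments instead.
    """
    segs = sorted(
        (s for s in segments
         if include_sex_chromosomes or is_autosome(s.chrom)),
        key=lambda s: (s.chrom, s.start),
    )
    n = 0
    prev: Optional[AllelicSegment] = None
    in_run = False
    for seg in segs:
        aberrant = seg.total_cn != 2
        contiguous = (prev is not None and prev.chrom == seg.chrom
                      and seg.start == prev.end + 1)
        if aberrant and not (merge and in_run and contiguous):
            n += 1
        in_run = aberrant
        prev = seg
    return n


def dup_load_1_100kb(events: Iterable[StructuralEvent],
                     min_length: int = 1_000,
                     max_length: int = 100_000) -> int:
    """Number of duplications with length in [1 kb, 100 kb], bounds inclusive."""
    return sum(1 for e in events
               if e.svtype == "DUP" and min_length <= e.length <= max_length)


def dup_events_from_segments(
    segments: Iterable[AllelicSegment],
    min_total_cn: int = 3,
) -> list[StructuralEvent]:
    """Fallback: derive DUP events from gained copy-number segments.

    For cohorts without an SV table, segments with total copy number >=
    ``min_total_cn`` are treated as duplication events.
    """
    return [
        StructuralEvent(s.chrom, s.start, s.end, "DUP")
        for s in segments if s.total_cn >= min_total_cn and s.start < s.end
    ]


def assemble_features(
    hrd: HRDResult,
    mhid: int,
    cn_load_count: int,
    dup_count: int,
    snv_count: int,
    exposures: ExposureVector,
    neoantigens: Optional[float] = None,
) -> FeatureVector:
    """Assemble the 14-entry feature vector from per-module outputs.

    The neoantigen count is an external input (no prediction is performed);
    when missing it defaults to 0 with a warning.
    """
    if neoantigens is None:
        warnings.warn("neoantigen count missing; defaulting to 0", stacklevel=2)
        neoantigens = 0.0
    return FeatureVector(
        hrd=float(hrd.hrd_score),
        mhid=float(mhid),
        cn_load=float(cn_load_count),
        dup_1_100kb=float(dup_count),
        snv_load=float(snv_count),
        neoantigens=float(neoantigens),
        ac1=exposures["AC1"],
        ac4=exposures["AC4"],
        ac7=exposures["AC7"],
        ac10=exposures["AC10"],
        ac12=exposures["AC12"],
        ac18=exposures["AC18"],
        ac20=exposures["AC20"],
        ac24=exposures["AC24"],
    )
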