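"""Readers and writers for the external formats the pipeline consumes.

Everything upstream of the feature computations enters through this module:
somatic variant calls (VCF v4.x), allele-specific copy-number segment tables
(SEG-like TSV), structural-variant tables (TSV), per-patient feature tables
(CSV) and the chromosome/centromere annotation (TSV, hg19 bundled).  The
module parses and validates; it never computes features.

Coordinate conventions
----------------------
VCF positions are 1-based (standard).  Segment and SV tables are 1-based and
inclusive on both ends, matching the SEG-style output of allele-specific
copy-number callers.  All internal arithmetic keeps this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional

import pandas as pd

__all__ = [
    "Variant",
    "AllelicSegment",
    "StructuralEvent",
    "ChromosomeAnnotation",
    "CohortTable",
    "ParseError",
    "ValidationError",
    "FEATURE_COLUMNS",
    "read_vcf",
    "read_segments",
    "write_segments",
    "read_sv_table",
    "write_sv_table",
    "read_feature_table",
    "write_feature_table",
    "load_chromosome_annotation",
    "write_chromosome_annotation",
    "normalize_chrom",
    "is_autosome",
]


class ParseError(ValueError):
    """A file could not be parsed as its declared format."""


class ValidationError(ValueError):
    """A parsed record violates a domain invariant."""


VariantClass = Literal["SNV", "insertion", "deletion", "MNV"]


@dataclass(frozen=True)
class Variant:
    """One somatic variant call (one record/alt pair of a VCF)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    vclass: VariantClass
    vaf: Optional[float] = None
    gene: Optional[str] = None
    effect: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        expected = classify_alleles(self.ref, self.alt)
        if self.vclass != expected:
            raise ValidationError(
                f"vclass {self.vclass!r} inconsistent with alleles "
                f"{self.ref}>{self.alt} (expected {expected!r})"
            )


def classify_alleles(ref: str, alt: str) -> VariantClass:
    """Variant class implied by allele lengths (VCF left-anchored alleles)."""
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(ref) < len(alt):
        return "insertion"
    if len(ref) > len(alt):
        return "deletion"
    return "MNV"


@dataclass(frozen=True)
class AllelicSegment:
    """One allele-specific copy-number segment, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    major_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"segment start > end: {self.chrom}:{self.start}-{self.end}"
            )
        if self.minor_cn < 0 or self.major_cn < self.minor_cn:
            raise ValidationError(
                f"require major_cn >= minor_cn >= 0, got "
                f"({self.major_cn}, {self.minor_cn}) at {self.chrom}:{self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn

    @property
    def state(self) -> tuple[int, int]:
        return (self.major_cn, self.minor_cn)


@dataclass(frozen=True)
class StructuralEvent:
    """One structural variant (duplication, deletion, inversion, translocation)."""

    chrom: str
    start: int
    end: int
    svtype: Literal["DUP", "DEL", "INV", "TRA"]

    def __post_init__(self) -> None:
        if self.svtype != "TRA" and self.start >= self.end:
            raise ValidationError(
                f"non-TRA event needs start < end: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ChromosomeAnnotation:
    """Chromosome length and centromere interval (1-based, inclusive)."""

    chrom: str
    length: int
    centromere_start: int
    centromere_end: int

    def __post_init__(self) -> None:
        if not (0 < self.centromere_start < self.centromere_end < self.length):
            raise ValidationError(
                f"centromere must lie strictly inside {self.chrom} "
                f"(length {self.length})"
            )


# The 14 predictor inputs, in the canonical column order of the feature CSV.
FEATURE_COLUMNS = [
    "HRD",
    "MHID",
    "CN_load",
    "DUP_1_100KB",
    "SNV_load",
    "NEOANTIGENS",
    "AC1",
    "AC4",
    "AC7",
    "AC10",
    "AC12",
    "AC18",
    "AC20",
    "AC24",
]

GROUP_LABELS = ("sensitive", "resistant")


@dataclass
class CohortTable:
    """Per-patient feature vectors with the platinum-response label.

    ``data`` holds one row per patient with columns ``patient_id``, ``group``
    (``sensitive``/``resistant`` per the GCIG 6-month criterion, lower-case)
    and the 14 feature columns of :data:`FEATURE_COLUMNS`.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in ["patient_id", "group", *FEATURE_COLUMNS]
                   if c not in self.data.columns]
        if missing:
            raise ValidationError("missing: " + ", ".join(missing))
        ids = self.data["patient_id"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique().tolist())
            raise ValidationError(f"duplicate patient_id: {dups}")
        groups = self.data["group"]
        bad = groups.dropna()[~groups.dropna().str.lower().isin(GROUP_LABELS)]
        if len(bad):
            raise ValidationError(
                f"unrecognized group labels: {sorted(bad.unique().tolist())}"
            )
        self.data = self.data.copy()
        self.data["group"] = groups.str.lower()

    def __len__(self) -> int:
        return len(self.data)

    @property
    def features(self) -> pd.DataFrame:
        return self.data.set_index("patient_id")[FEATURE_COLUMNS]

    @property
    def groups(self) -> pd.Series:
        return self.data.set_index("patient_id")["group"]


def normalize_chrom(chrom: str, use_prefix: bool = True) -> str:
    """Normalize a chromosome name to the requested ``chr`` dialect."""
    base = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return f"chr{base}" if use_prefix else base


def is_autosome(chrom: str) -> bool:
    return normalize_chrom(chrom, use_prefix=False).isdigit()


# ---------------------------------------------------------------------------
# VCF


def _prescan_vcf(path: Path) -> None:
    """Cheap line-level structure check so parse errors can name a line."""
    with open(path) as fh:
        saw_header = False
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                continue
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 8 tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                int(fields[1])
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: POS is not an integer: {fields[1]!r}"
                ) from None
        if not saw_header:
            raise ParseError(f"{path}: missing #CHROM header line")


def read_vcf(path: str | Path, pass_only: bool = True,
             max_vaf: float | None = None) -> list[Variant]:
    """Read a VCF into :class:`Variant` records, one per (record, alt) pair.

    Multi-allelic records are split per alternate allele.  Records whose
    FILTER is set (anything but PASS/``.``) are excluded unless
    ``pass_only=False``.  ``max_vaf``, if given, drops variants with a
    recorded allele fraction above the cutoff (off by default: the somatic
    filtering policy upstream of this pipeline is caller-specific).
    """
    from cyvcf2 import VCF

    path = Path(path)
    _prescan_vcf(path)
    try:
        reader = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 raises various types
        raise ParseError(f"{path}: not a readable VCF: {exc}") from exc
    variants: list[Variant] = []
    for rec in reader:
        if pass_only and rec.FILTER is not None:
            continue
        vaf = rec.INFO.get("VAF")
        if vaf is None:
            vaf = rec.INFO.get("AF")
        gene = rec.INFO.get("GENE")
        effect = rec.INFO.get("EFFECT")
        for alt in rec.ALT:
            if alt == rec.REF or alt.startswith("<"):
                continue
            v = Variant(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=alt,
                vclass=classify_alleles(rec.REF, alt),
                vaf=float(vaf) if vaf is not None else None,
                gene=gene,
                effect=effect,
            )
            if max_vaf is not None and v.vaf is not None and v.vaf > max_vaf:
                continue
            variants.append(v)
    reader.close()
    return variants


# ---------------------------------------------------------------------------
# Segment / SV tables

_SEG_COLUMNS = ["chrom", "start", "end", "major_cn", "minor_cn"]
_SV_COLUMNS = ["chrom", "start", "end", "svtype"]


def _read_tsv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns: {', '.join(missing)}")
    return df


def read_segments(path: str | Path) -> list[AllelicSegment]:
    """Read an allele-specific segment TSV; sort and validate.

    Rows are validated individually (integer copy numbers, start <= end,
    major >= minor) and jointly: segments of one chromosome must not overlap.
    Errors name the offending 0-based data row index.
    """
    df = _read_tsv(path, _SEG_COLUMNS)
    segments: list[tuple[int, AllelicSegment]] = []
    for idx, row in df.iterrows():
        for col in ("start", "end", "major_cn", "minor_cn"):
            val = row[col]
            if not float(val).is_integer():
                raise ValidationError(
                    f"{path}: row {idx}: non-integer {col}: {val!r}"
                )
        try:
            seg = AllelicSegment(
                chrom=str(row["chrom"]),
                start=int(row["start"]),
                end=int(row["end"]),
                major_cn=int(row["major_cn"]),
                minor_cn=int(row["minor_cn"]),
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from None
        segments.append((idx, seg))
    segments.sort(key=lambda t: (t[1].chrom, t[1].start, t[1].end))
    for (i_prev, prev), (i_cur, cur) in zip(segments, segments[1:]):
        if prev.chrom == cur.chrom and cur.start <= prev.end:
            raise ValidationError(
                f"{path}: rows {i_prev} and {i_cur} overlap on {cur.chrom} "
                f"({prev.start}-{prev.end} vs {cur.start}-{cur.end})"
            )
    return [seg for _, seg in segments]


def write_segments(segments: Iterable[AllelicSegment], path: str | Path) -> None:
    df = pd.DataFrame(
        [(s.chrom, s.start, s.end, s.major_cn, s.minor_cn) for s in segments],
        columns=_SEG_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_sv_table(path: str | Path) -> list[StructuralEvent]:
    """Read a structural-variant table (chrom, start, end, svtype)."""
    df = _read_tsv(path, _SV_COLUMNS)
    events = []
    for idx, row in df.iterrows():
        svtype = str(row["svtype"]).upper()
        if svtype not in ("DUP", "DEL", "INV", "TRA"):
            raise ValidationError(f"{path}: row {idx}: unknown svtype {svtype!r}")
        try:
            events.append(
                StructuralEvent(str(row["chrom"]), int(row["start"]),
                                int(row["end"]), svtype)
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from None
    return events


def write_sv_table(events: Iterable[StructuralEvent], path: str | Path) -> None:
    df = pd.DataFrame(
        [(e.chrom, e.start, e.end, e.svtype) for e in events],
        columns=_SV_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Feature / cohort tables


def read_feature_table(path: str | Path) -> CohortTable:
    """Read a cohort feature CSV (patient_id, group, 14 feature columns).

    Group labels are case-insensitive on read and normalized to lower case.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "group": str})
    missing = [c for c in ["patient_id", "group", *FEATURE_COLUMNS]
               if c not in df.columns]
    if missing:
        raise ValidationError("missing: " + ", ".join(missing))
    return CohortTable(df[["patient_id", "group", *FEATURE_COLUMNS]])


def write_feature_table(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort to CSV at full float precision (round-trip safe)."""
    cohort.data.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Chromosome annotation

_ANN_COLUMNS = ["chrom", "length", "centromere_start", "centromere_end"]


def load_chromosome_annotation(
    path: str | Path | None = None,
) -> dict[str, ChromosomeAnnotation]:
    """Load a chromosome/centromere table; bundled hg19 when ``path`` is None."""
    if path is None:
        ref = resources.files("drdscore.data") / "hg19_chromosomes.tsv"
        with resources.as_file(ref) as p:
            df = _read_tsv(p, _ANN_COLUMNS)
    else:
        df = _read_tsv(path, _ANN_COLUMNS)
    ann = {}
    for _, row in df.iterrows():
        a = ChromosomeAnnotation(
            chrom=str(row["chrom"]),
            length=int(row["length"]),
            centromere_start=int(row["centromere_start"]),
            centromere_end=int(row["centromere_end"]),
        )
        ann[a.chrom] = a
    return ann


def write_chromosome_annotation(
    ann: dict[str, ChromosomeAnnotation], path: str | Path
) -> None:
    df = pd.DataFrame(
        [(a.chrom, a.length, a.centromere_start, a.centromere_end)
         for a in ann.values()],
        columns=_ANN_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)
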