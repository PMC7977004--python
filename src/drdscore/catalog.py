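"""SBS-96 mutational catalogs, indel classification and catalog correction.

Single-base substitutions are binned into the canonical 96 trinucleotide
context channels (pyrimidine-centric: purine-reference substitutions are
reverse-complemented), in COSMIC ordering: substitution class C>A, C>G,
C>T, T>A, T>C, T>G (major), then 5' base A,C,G,T, then 3' base A,C,G,T.

Indels are classified into repeat-unit events, microhomology deletions and
complex events.  The microhomology length of a deletion is the longest
exact match between the deleted sequence and either immediate flank
(prefix of the deleted sequence against the 3' flank, suffix against the
5' flank), capped at one below the deletion length; a deletion embedded in
a tandem repeat of its own unit is a repeat-unit deletion, never a
microhomology one.  The MHID feature is the count of microhomology
deletions.

Catalog correction rescales each channel by the ratio of its triplet's
share of the whole genome to its share of the exome capture region, so
exome catalogs can be fitted against genome-normalized signature matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .io import ParseError, ValidationError, Variant

__all__ = [
    "SUBSTITUTION_TYPES",
    "SBS96_LABELS",
    "MutationalCatalog",
    "IndelCall",
    "TripletFrequencyTable",
    "PYRIMIDINE_TRIPLETS",
    "sbs96_catalog",
    "classify_indel",
    "mhid_count",
    "correct_catalog",
    "triplet_frequencies",
    "ReferenceMismatchError",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
BASES = "ACGT"

SUBSTITUTION_TYPES = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]

SBS96_LABELS = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_TYPES
    for five in BASES
    for three in BASES
]
_LABEL_INDEX = {lab: i for i, lab in enumerate(SBS96_LABELS)}

# 32 pyrimidine-centric triplets, 5' major then center (C before T) then 3'.
PYRIMIDINE_TRIPLETS = [
    f"{five}{center}{three}"
    for center in "CT"
    for five in BASES
    for three in BASES
]
_TRIPLET_INDEX = {t: i for i, t in enumerate(PYRIMIDINE_TRIPLETS)}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class ReferenceMismatchError(ValidationError):
    """A variant's REF allele disagrees with the reference sequence."""


@dataclass
class MutationalCatalog:
    """96-channel substitution counts in canonical COSMIC ordering.

    Uncorrected catalogs hold integer counts summing to the number of SNVs
    consumed; corrected catalogs may hold non-integral values.
    """

    counts: np.ndarray = field(default_factory=lambda: np.zeros(96))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValidationError(f"expected 96 channels, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValidationError("catalog counts must be non-negative")

    @property
    def labels(self) -> list[str]:
        return SBS96_LABELS

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def __getitem__(self, label: str) -> float:
        return float(self.counts[_LABEL_INDEX[label]])

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("context\tcount\n")
            for lab, c in zip(SBS96_LABELS, self.counts):
                fh.write(f"{lab}\t{c:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MutationalCatalog":
        counts = np.zeros(96)
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("context"):
                raise ParseError(f"{path}: expected 'context\\tcount' header")
            for lineno, line in enumerate(fh, start=2):
                lab, val = line.rstrip("\n").split("\t")
                if lab not in _LABEL_INDEX:
                    raise ParseError(f"{path}: line {lineno}: unknown context {lab!r}")
                counts[_LABEL_INDEX[lab]] = float(val)
        return cls(counts)


def _fetch(reference, chrom: str, start: int, end: int) -> str:
    """Fetch reference sequence [start, end], 1-based inclusive, upper-case."""
    keys = getattr(reference, "keys", None)
    name = chrom
    if keys is not None:
        available = list(reference.keys())
        if chrom not in available:
            alt = chrom[3:] if chrom.startswith("chr") else f"chr{chrom}"
            if alt in available:
                name = alt
            else:
                raise KeyError(f"chromosome {chrom!r} not in reference")
    return str(reference[name][start - 1:end]).upper()


def sbs96_catalog(variants: Iterable[Variant], reference) -> MutationalCatalog:
    """Build the SBS-96 catalog of the SNVs in ``variants``.

    ``reference`` is an indexed sequence (e.g. ``pyfaidx.Fasta``).  Non-SNVs
    are ignored; each SNV contributes exactly one count.  A REF allele that
    disagrees with the reference sequence raises
    :class:`ReferenceMismatchError`.
    """
    counts = np.zeros(96)
    for v in variants:
        if v.vclass != "SNV":
            continue
        triplet = _fetch(reference, v.chrom, v.pos - 1, v.pos + 1)
        if len(triplet) != 3 or "N" in triplet:
            raise ValidationError(
                f"no 1 bp flank available at {v.chrom}:{v.pos} (got {triplet!r})"
            )
        if triplet[1] != v.ref:
            raise ReferenceMismatchError(
                f"variant {v.chrom}:{v.pos} {v.ref}>{v.alt}: reference has "
                f"{triplet[1]!r} at that position"
            )
        ref, alt = v.ref, v.alt
        if ref in "GA":  # purine reference: map to the pyrimidine strand
            triplet, ref, alt = revcomp(triplet), revcomp(ref), revcomp(alt)
        label = f"{triplet[0]}[{ref}>{alt}]{triplet[2]}"
        counts[_LABEL_INDEX[label]] += 1
    return MutationalCatalog(counts)


IndelCategory = Literal[
    "repeat-unit deletion", "repeat-unit insertion",
    "microhomology deletion", "complex",
]


@dataclass(frozen=True)
class IndelCall:
    variant: Variant
    length: int
    category: IndelCategory
    mh_length: int
    repeat_count: int


def _count_unit_copies(seq: str, unit: str, start: int, direction: int) -> int:
    """Copies of ``unit`` tiling ``seq`` from index ``start`` (0-based)."""
    L = len(unit)
    n = 0
    i = start
    while True:
        if direction > 0:
            chunk = seq[i:i + L]
            i += L
        else:
            if i - L < 0:
                break
            chunk = seq[i - L:i]
            i -= L
        if chunk != unit:
            break
        n += 1
    return n


def classify_indel(
    variant: Variant,
    reference,
    max_length: int = 100,
    flanks: Literal["both", "three_prime", "five_prime"] = "both",
) -> IndelCall:
    """Classify an insertion or deletion (repeat / microhomology / complex).

    Deletions embedded in a tandem repeat of their own unit (two or more
    copies including the deleted one) are repeat-unit deletions.  Otherwise
    a deletion of length >= 2 with microhomology length >= 1 is a
    microhomology deletion.  ``flanks`` selects which flank(s) the
    microhomology search examines (default: both, taking the maximum).
    """
    if variant.vclass not in ("insertion", "deletion"):
        raise ValidationError(f"not an indel: {variant.vclass}")
    is_del = variant.vclass == "deletion"
    long_allele, short_allele = (
        (variant.ref, variant.alt) if is_del else (variant.alt, variant.ref)
    )
    if not long_allele.startswith(short_allele):
        raise ValidationError(
            f"unsupported indel representation at {variant.chrom}:{variant.pos} "
            f"({variant.ref}>{variant.alt}); expected left-anchored alleles"
        )
    unit = long_allele[len(short_allele):]
    L = len(unit)
    if L > max_length:
        logger.warning(
            "indel of %d bp at %s:%d exceeds max_length=%d; classified complex",
            L, variant.chrom, variant.pos, max_length,
        )
        return IndelCall(variant, L, "complex", 0, 0)

    anchor_end = variant.pos + len(short_allele) - 1  # last anchored ref base
    window = max(2 * L + 2, 2)
    left = _fetch(reference, variant.chrom, max(1, anchor_end - window + 1),
                  anchor_end)
    if is_del:
        ref_unit = _fetch(reference, variant.chrom, anchor_end + 1, anchor_end + L)
        if ref_unit != unit:
            raise ReferenceMismatchError(
                f"deletion at {variant.chrom}:{variant.pos}: reference has "
                f"{ref_unit!r} where {unit!r} should be deleted"
            )
        right = _fetch(reference, variant.chrom, anchor_end + L + 1,
                       anchor_end + L + window)
    else:
        right = _fetch(reference, variant.chrom, anchor_end + 1,
                       anchor_end + window)

    fwd = _count_unit_copies(right, unit, 0, +1)
    rev = _count_unit_copies(left, unit, len(left), -1)
    repeat_count = (1 if is_del else 0) + fwd + rev

    in_repeat = repeat_count >= 2 if is_del else repeat_count >= 1
    if in_repeat:
        category: IndelCategory = (
            "repeat-unit deletion" if is_del else "repeat-unit insertion"
        )
        return IndelCall(variant, L, category, 0, repeat_count)

    mh = 0
    if is_del and L >= 2:
        if flanks in ("both", "three_prime"):
            m = 0
            while m < L - 1 and m < len(right) and unit[m] == right[m]:
                m += 1
            mh = max(mh, m)
        if flanks in ("both", "five_prime"):
            m = 0
            while (m < L - 1 and m < len(left)
                   and unit[L - 1 - m] == left[len(left) - 1 - m]):
                m += 1
            mh = max(mh, m)
    if is_del and L >= 2 and mh >= 1:
        return IndelCall(variant, L, "microhomology deletion", mh, repeat_count)
    return IndelCall(variant, L, "complex", 0, repeat_count)


def mhid_count(
    variants: Iterable[Variant],
    reference,
    max_length: int = 100,
    flanks: Literal["both", "three_prime", "five_prime"] = "both",
) -> int:
    """Number of indels classified as microhomology deletions."""
    n = 0
    for v in variants:
        if v.vclass not in ("insertion", "deletion"):
            continue
        call = classify_indel(v, reference, max_length=max_length, flanks=flanks)
        if call.category == "microhomology deletion":
            n += 1
    return n


@dataclass
class TripletFrequencyTable:
    """Occurrence counts of the 32 pyrimidine-centric triplets in a region set."""

    counts: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (32,):
            raise ValidationError(f"expected 32 triplets, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValidationError("triplet counts must be non-negative")

    @property
    def shares(self) -> np.ndarray:
        total = self.counts.sum()
        if total <= 0:
            raise ValidationError(f"triplet table {self.name!r} is empty")
        return self.counts / total

    def __getitem__(self, triplet: str) -> float:
        return float(self.counts[_TRIPLET_INDEX[triplet]])


_BASE_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate(BASES):
    _BASE_CODE[ord(b)] = i
    _BASE_CODE[ord(b.lower())] = i


def _triplet_counts_for_seq(seq: str) -> np.ndarray:
    """Count pyrimidine-centric triplets over one sequence (vectorized)."""
    code = _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    counts = np.zeros(32)
    if len(code) < 3:
        return counts
    five, center, three = code[:-2], code[1:-1], code[2:]
    valid = (five >= 0) & (center >= 0) & (three >= 0)
    # pyrimidine-centric: A=0 C=1 G=2 T=3; complement base = 3 - base
    pyr = (center == 1) | (center == 3)
    c_idx = np.where(center == 1, 0, 1)  # C -> 0, T -> 1 on pyrimidine strand
    idx_pyr = c_idx * 16 + five * 4 + three
    cc = 3 - center
    c_idx_pur = np.where(cc == 1, 0, 1)
    idx_pur = c_idx_pur * 16 + (3 - three) * 4 + (3 - five)
    idx = np.where(pyr, idx_pyr, idx_pur)
    np.add.at(counts, idx[valid], 1)
    return counts


def triplet_frequencies(
    reference,
    bed_path: str | Path | None = None,
    name: str = "",
) -> TripletFrequencyTable:
    """Count pyrimidine-centric triplets in a reference, optionally BED-masked.

    With ``bed_path`` (0-based half-open intervals) only the covered regions
    are counted, each extended by 1 bp on both sides so substitutions at
    region edges still have a context.  Without it the whole reference is
    counted.
    """
    counts = np.zeros(32)
    if bed_path is None:
        for chrom in reference.keys():
            counts += _triplet_counts_for_seq(str(reference[chrom][:]))
    else:
        with open(bed_path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                start, end = int(start), int(end)
                lo = max(1, start)  # 0-based start - 1 flank, floor at 1-based 1
                seq = _fetch(reference, chrom, lo, end + 1)
                counts += _triplet_counts_for_seq(seq)
    return TripletFrequencyTable(counts, name=name)


def correct_catalog(
    catalog: MutationalCatalog,
    genome_freq: TripletFrequencyTable,
    target_freq: TripletFrequencyTable,
) -> MutationalCatalog:
    """Rescale an exome catalog to whole-genome triplet composition.

    Each channel is multiplied by (genome share of its triplet) / (target
    share of its triplet), with both tables normalized to sum to one.  A
    channel with observed counts but zero target share is an error.
    """
    genome_shares = genome_freq.shares
    target_shares = target_freq.shares
    out = np.array(catalog.counts, dtype=float)
    for i, label in enumerate(SBS96_LABELS):
        triplet = label[0] + label[2] + label[6]  # X[R>A]Y -> XRY
        t = _TRIPLET_INDEX[triplet]
        if out[i] == 0:
            continue
        if target_shares[t] == 0:
            raise ValidationError(
                f"channel {label}: zero target frequency for triplet {triplet} "
                f"with nonzero count"
            )
        out[i] *= genome_shares[t] / target_shares[t]
    return MutationalCatalog(out)
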