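"""Desk-scale synthetic cohorts with known ground truth.

The generator emits everything the pipeline consumes — a mini reference
genome (FASTA + exome BED + chromosome annotation), per-patient VCFs,
allele-specific segment tables and SV tables — together with a truth table
of the planted feature values, so every stage of the pipeline can be
verified end-to-end without any external data.

Design
------
* The mini genome defaults to 8 chromosomes of 1.5 Mb with a declared
  centromere; scar-rule size thresholds are used at 1/1000 scale (kb for
  Mb), so the same rule structure applies on a genome a thousandth the
  size.  The telomeric-imbalance count is capped at two per chromosome,
  which is why the cohort genome uses 8 chromosomes rather than the 2-3 of
  a standalone :func:`make_reference` call.
* Scar counts are *planted*: segment layouts are engineered so each LOH /
  TAI / LST target is realised exactly under the scoring rules, using
  small (5 kb) imbalanced spacer segments that survive smoothing but stay
  below the large-segment threshold to keep the components independent.
* Microhomology-deletion sites are engineered into the reference itself
  (the bases after each designated deletion repeat a proper prefix of the
  deleted unit, with tandem repeats excluded), so the planted MHID count
  is exact by construction.
* SNVs are drawn from a group-specific mixture of the bundled signature
  set and placed at genomic positions whose trinucleotide context matches
  the sampled channel.
* Group-conditional distributions follow the study conditions: HRD scores
  from a scaled-beta on the published range whose shapes jointly match the
  published median and HRD-high prevalence (sensitive: median 56, range
  23-122, 78.95% at 42 or more — exactly solvable; resistant: median 47,
  range 19-119, 47.37% — mutually inconsistent, since a median above 42
  forces at least half the genomes to 42 or more, so the fitted shape is
  the least-squares compromise: median ~44, prevalence ~0.53).  MHID
  medians 16 vs 13 and exome variant-count medians 497 vs 443 are drawn
  as overdispersed (negative-binomial) counts; duplication load is higher
  in the sensitive group.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from functools import lru_cache

from scipy import stats
from scipy.optimize import minimize

from .catalog import SBS96_LABELS
from .io import (AllelicSegment, ChromosomeAnnotation, CohortTable,
                 StructuralEvent, write_chromosome_annotation, write_segments,
                 write_sv_table, FEATURE_COLUMNS)
from .scars import ScarConfig
from .signatures import SignatureMatrix, load_signatures

__all__ = ["GroupParams", "GeneratorConfig", "SyntheticReference", "MHSite",
           "SyntheticPatient", "SyntheticCohort", "make_reference",
           "simulate_patient", "simulate_cohort", "DESK_SCALE_SCARS"]

# Scar rules at 1/1000 of genome scale: kb where the genome rules say Mb.
DESK_SCALE_SCARS = ScarConfig().scaled(1 / 1000)

_SPACER = 5_000          # survives smoothing (>=3 kb), below LST size (<10 kb)
_STOPPER = 4_000
_FILLER_MIN = 12_000
_CODE_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GroupParams:
    """Group-conditional generator distributions (one per response group)."""

    hrd_median: int
    hrd_min: int
    hrd_max: int
    mhid_mean: float
    mhid_dispersion: float  # negative-binomial size parameter
    nvar_mean: float
    nvar_dispersion: float
    dup_in_mean: float      # expected duplications in 1-100 kb
    dup_dispersion: float   # negative-binomial size for the in-window count
    dup_out_mean: float     # expected duplications outside the window
    neoantigen_mean: float  # unanchored: no published summary exists
    signature_weights: dict[str, float]
    hrd_high_target: float  # documented target of record (see module docstring)
    # per-patient mixtures are Dirichlet draws centred on signature_weights;
    # smaller concentration = more between-patient signature variability
    signature_concentration: float = 10.0
    # scar-neutral copy-number aberrations (small balanced gains) per genome;
    # equal across groups: the study found CN load uninformative on its own,
    # so the load must not be a proxy for the planted scar score
    cnv_extra_mean: float = 30.0


def _default_sensitive() -> GroupParams:
    return GroupParams(
        hrd_median=56, hrd_min=23, hrd_max=122,
        mhid_mean=16.0, mhid_dispersion=8.0,
        nvar_mean=497.0, nvar_dispersion=10.0,
        dup_in_mean=8.0, dup_dispersion=6.0, dup_out_mean=3.0,
        neoantigen_mean=20.0,
        signature_weights={"AC1": 0.42, "AC3": 0.25, "AC4": 0.13,
                           "AC6": 0.08, "AC10": 0.12},
        hrd_high_target=0.7895,
    )


def _default_resistant() -> GroupParams:
    return GroupParams(
        hrd_median=47, hrd_min=19, hrd_max=119,
        mhid_mean=13.0, mhid_dispersion=8.0,
        nvar_mean=443.0, nvar_dispersion=10.0,
        dup_in_mean=5.0, dup_dispersion=6.0, dup_out_mean=3.0,
        neoantigen_mean=20.0,
        signature_weights={"AC1": 0.58, "AC3": 0.12, "AC4": 0.06,
                           "AC6": 0.14, "AC10": 0.10},
        hrd_high_target=0.4737,
    )


@dataclass
class GeneratorConfig:
    """Cohort-level generator settings; defaults are the discovery preset."""

    n_sensitive: int = 38
    n_resistant: int = 19
    seed: int = 1
    n_chrom: int = 8
    chrom_length: int = 1_500_000
    exome_fraction: float = 0.30
    n_mh_sites: int = 400
    scars: ScarConfig = field(default_factory=lambda: DESK_SCALE_SCARS)
    sensitive: GroupParams = field(default_factory=_default_sensitive)
    resistant: GroupParams = field(default_factory=_default_resistant)

    @classmethod
    def discovery(cls, seed: int = 1, **kw) -> "GeneratorConfig":
        return cls(n_sensitive=38, n_resistant=19, seed=seed, **kw)

    @classmethod
    def validation(cls, seed: int = 1, **kw) -> "GeneratorConfig":
        return cls(n_sensitive=31, n_resistant=11, seed=seed, **kw)

    def group(self, name: str) -> GroupParams:
        if name == "sensitive":
            return self.sensitive
        if name == "resistant":
            return self.resistant
        raise ValueError(f"unknown group {name!r}")


@dataclass(frozen=True)
class MHSite:
    """A designated microhomology deletion engineered into the reference."""

    chrom: str
    pos: int        # anchor base (1-based); deletion removes pos+1 .. pos+length
    ref: str        # anchor base + deleted unit
    alt: str        # anchor base
    mh_length: int


@dataclass
class SyntheticReference:
    """Mini reference genome plus the artefacts derived from it."""

    fasta_path: Path
    annotation_path: Path
    exome_bed_path: Path
    ann: dict[str, ChromosomeAnnotation]
    mh_sites: list[MHSite]
    codes: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    _context_index: Optional[tuple] = field(default=None, repr=False)

    @property
    def chroms(self) -> list[str]:
        return list(self.ann)

    def fasta(self):
        from pyfaidx import Fasta
        return Fasta(str(self.fasta_path))

    def context_index(self):
        """Positions grouped by pyrimidine-centric triplet id (built lazily)."""
        if self._context_index is None:
            self._context_index = _build_context_index(self.codes, self.chroms)
        return self._context_index


def _write_fasta(codes: dict[str, np.ndarray], path: Path) -> None:
    with open(path, "w") as fh:
        for chrom, arr in codes.items():
            fh.write(f">{chrom}\n")
            seq = _CODE_TO_BASE[arr].tobytes().decode()
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def _engineer_mh_sites(
    codes: dict[str, np.ndarray],
    ann: dict[str, ChromosomeAnnotation],
    n_sites: int,
    rng: np.random.Generator,
) -> list[MHSite]:
    """Engineer deletion sites whose 3' flank repeats a prefix of the unit."""
    sites: list[MHSite] = []
    chroms = list(codes)
    per_chrom = int(np.ceil(n_sites / len(chroms)))
    margin = 30_000
    for chrom in chroms:
        arr = codes[chrom]
        a = ann[chrom]
        spans = [(margin, a.centromere_start - margin),
                 (a.centromere_end + margin, a.length - margin)]
        placed = 0
        for lo, hi in spans:
            if placed >= per_chrom or len(sites) >= n_sites:
                break
            step = max(2_000, (hi - lo) // max(1, per_chrom // 2 + 1))
            for anchor0 in range(lo, hi - 50, step):  # 0-based anchor
                if placed >= per_chrom or len(sites) >= n_sites:
                    break
                L = int(rng.integers(3, 7))       # deleted-unit length
                m = int(rng.integers(1, L))       # microhomology length
                unit = rng.integers(0, 4, size=L)
                arr[anchor0 + 1:anchor0 + 1 + L] = unit
                arr[anchor0 + 1 + L:anchor0 + 1 + L + m] = unit[:m]
                # break forward tiling: base after the copied prefix != unit[m]
                if m < L:
                    nxt = anchor0 + 1 + L + m
                    if arr[nxt] == unit[m]:
                        arr[nxt] = (unit[m] + 1 + rng.integers(0, 3)) % 4
                # break backward tiling: the L bases before the unit != unit
                back = arr[anchor0 + 1 - L:anchor0 + 1]
                if len(back) == L and np.array_equal(back, unit):
                    arr[anchor0] = (arr[anchor0] + 1 + int(rng.integers(0, 3))) % 4
                anchor = chr(_CODE_TO_BASE[arr[anchor0]])
                deleted = _CODE_TO_BASE[unit].tobytes().decode()
                sites.append(MHSite(
                    chrom=chrom, pos=anchor0 + 1,
                    ref=anchor + deleted, alt=anchor, mh_length=m,
                ))
                placed += 1
    return sites


def make_reference(
    out_dir: str | Path,
    n_chrom: int = 3,
    chrom_length: int = 1_500_000,
    seed: int = 0,
    n_mh_sites: int = 400,
    exome_fraction: float = 0.30,
) -> SyntheticReference:
    """Generate a deterministic mini reference genome.

    Writes ``reference.fa`` (uniform random sequence, GC ~0.5),
    ``chromosomes.tsv`` (lengths and mid-chromosome centromeres) and
    ``exome.bed`` (regular 2 kb capture windows covering roughly
    ``exome_fraction`` of the genome), and engineers ``n_mh_sites``
    microhomology deletion sites into the sequence.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(7,)))
    ann: dict[str, ChromosomeAnnotation] = {}
    codes: dict[str, np.ndarray] = {}
    for i in range(n_chrom):
        chrom = f"chr{i + 1}"
        codes[chrom] = rng.integers(0, 4, size=chrom_length, dtype=np.int8)
        ann[chrom] = ChromosomeAnnotation(
            chrom=chrom, length=chrom_length,
            centromere_start=int(chrom_length * 0.45),
            centromere_end=int(chrom_length * 0.55),
        )
    mh_sites = _engineer_mh_sites(codes, ann, n_mh_sites, rng)

    fasta_path = out_dir / "reference.fa"
    _write_fasta(codes, fasta_path)
    ann_path = out_dir / "chromosomes.tsv"
    write_chromosome_annotation(ann, ann_path)

    bed_path = out_dir / "exome.bed"
    window, stride = 2_000, int(round(2_000 / max(exome_fraction, 1e-6)))
    with open(bed_path, "w") as fh:
        for chrom in codes:
            for start in range(1_000, chrom_length - window - 1_000, stride):
                fh.write(f"{chrom}\t{start}\t{start + window}\n")
    return SyntheticReference(
        fasta_path=fasta_path, annotation_path=ann_path,
        exome_bed_path=bed_path, ann=ann, mh_sites=mh_sites, codes=codes,
    )


# ---------------------------------------------------------------------------
# scar planting


def _plant_scar_segments(
    ann: dict[str, ChromosomeAnnotation],
    loh: int,
    tai: int,
    lst: int,
    rng: np.random.Generator,
    scars: ScarConfig,
    n_cnv_extra: int = 0,
) -> tuple[list[AllelicSegment], int]:
    """Segment layout realising exactly (loh, tai, lst) under the scar rules.

    Returns the segments plus the copy-number change load implied by the
    layout (count of contiguous runs of total CN != 2).  Raises ValueError
    when the targets do not fit the genome.
    """
    chroms = list(ann)
    arms = [(c, side) for c in chroms for side in ("p", "q")]
    if tai > len(arms):
        raise ValueError(
            f"tai target {tai} exceeds {len(arms)} teloming arms; "
            f"use a larger genome (more chromosomes)"
        )
    quota = {arm: {"tai": False, "loh": 0, "lst": 0, "cnv": 0} for arm in arms}
    for i in range(tai):
        quota[arms[i]]["tai"] = True
    for i in range(loh):
        quota[arms[i % len(arms)]]["loh"] += 1
    for i in range(lst):
        quota[arms[i % len(arms)]]["lst"] += 1
    for i in range(n_cnv_extra):
        quota[arms[i % len(arms)]]["cnv"] += 1

    loh_lo = scars.loh_min_length + 1_000
    loh_hi = scars.loh_min_length + 7_000
    big_lo = scars.lst_min_segment + 500
    big_hi = scars.lst_min_segment + 3_000

    segments: list[AllelicSegment] = []
    cn_runs = 0
    for chrom in chroms:
        a = ann[chrom]
        chrom_blocks: list[tuple[int, int, int]] = []  # (length, major, minor)
        for side in ("p", "q"):
            q = quota[(chrom, side)]
            arm_len = (a.centromere_start - 1 if side == "p"
                       else a.length - a.centromere_end)
            blocks: list[tuple[int, int, int]] = []  # built telomere->centromere
            if q["tai"]:
                blocks.append((_SPACER, 2, 1))
            for _ in range(q["loh"]):
                blocks.append((int(rng.integers(_FILLER_MIN, _FILLER_MIN + 9_000)),
                               1, 1))
                blocks.append((_SPACER, 2, 1))
                blocks.append((int(rng.integers(loh_lo, loh_hi)), 1, 0))
                blocks.append((_SPACER, 2, 1))
            k = q["lst"]
            if k:
                blocks.append((int(rng.integers(_FILLER_MIN, _FILLER_MIN + 9_000)),
                               1, 1))
                for j in range(k):
                    state = (2, 2) if j % 2 == 0 else (1, 1)
                    blocks.append((int(rng.integers(big_lo, big_hi)), *state))
                if k % 2 == 1:  # chain ends imbalanced: shield it from the filler
                    blocks.append((_STOPPER, 3, 3))
            for _ in range(q["cnv"]):
                # scar-neutral copy-number change: balanced gain, small enough
                # to stay below the LST size rule; the short leading filler
                # only has to break the aberrant run
                blocks.append((int(rng.integers(4_000, 8_000)), 1, 1))
                blocks.append((_SPACER, 2, 2))
            used = sum(b[0] for b in blocks)
            if used + 1_000 > arm_len:
                raise ValueError(
                    f"scar targets do not fit {chrom}{side} arm "
                    f"({used} bp needed, {arm_len} bp available); "
                    f"use a larger genome"
                )
            tail = arm_len - used
            if side == "p":
                arm_blocks = blocks + [(tail, 1, 1)]
            else:
                # mirror: filler toward the centromere, features at the telomere
                arm_blocks = [(tail, 1, 1)] + _mirror_arm(blocks)
            chrom_blocks.extend(arm_blocks
                                if side == "p" else [("CEN",)] + arm_blocks)
        # realise coordinates; the centromere interval itself stays uncovered
        pos = 1
        prev_aberrant = False
        for blk in chrom_blocks:
            if blk == ("CEN",):
                pos = a.centromere_end + 1
                prev_aberrant = False
                continue
            length, major, minor = blk
            if length <= 0:
                continue
            seg = AllelicSegment(chrom, pos, pos + length - 1, major, minor)
            segments.append(seg)
            aberrant = major + minor != 2
            if aberrant and not prev_aberrant:
                cn_runs += 1
            prev_aberrant = aberrant
            pos += length
    return segments, cn_runs


def _mirror_arm(blocks: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Reverse a telomere-first arm layout for the q arm.

    Every planted unit (TAI spacer, spacer/LOH/spacer sandwich, LST chain
    plus stopper) is insensitive to orientation: small spacers shield every
    large imbalanced block, so reversing the block order preserves all
    planted counts.
    """
    return list(reversed(blocks))


# ---------------------------------------------------------------------------
# variant planting


def _build_context_index(codes: dict[str, np.ndarray], chroms: list[str]):
    """Group every interior genome position by pyrimidine-centric triplet id."""
    all_tid, all_chrom, all_pos, all_pyr = [], [], [], []
    for ci, chrom in enumerate(chroms):
        c = codes[chrom].astype(np.int8)
        five, center, three = c[:-2], c[1:-1], c[2:]
        pyr = (center == 1) | (center == 3)
        tid_pyr = np.where(center == 1, 0, 1) * 16 + five * 4 + three
        cc = 3 - center
        tid_pur = np.where(cc == 1, 0, 1) * 16 + (3 - three) * 4 + (3 - five)
        tid = np.where(pyr, tid_pyr, tid_pur).astype(np.int8)
        pos = np.arange(2, len(c), dtype=np.int32)  # 1-based center positions
        all_tid.append(tid)
        all_chrom.append(np.full(len(tid), ci, dtype=np.int16))
        all_pos.append(pos)
        all_pyr.append(pyr)
    tid = np.concatenate(all_tid)
    order = np.argsort(tid, kind="stable")
    tid_sorted = tid[order]
    offsets = np.searchsorted(tid_sorted, np.arange(33))
    return (np.concatenate(all_chrom)[order], np.concatenate(all_pos)[order],
            np.concatenate(all_pyr)[order], offsets)


_CHANNEL_TRIPLET_ID = np.array(
    [(0 if sub < 3 else 1) * 16 + five * 4 + three
     for sub in range(6) for five in range(4) for three in range(4)]
)
# alternate allele (pyrimidine strand) for each of the 96 channels
_SUB_ALTS = ["A", "G", "T", "A", "C", "G"]  # C>A C>G C>T T>A T>C T>G
_CHANNEL_ALT = [alt for alt in _SUB_ALTS for _ in range(16)]
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class _PlannedVariant:
    chrom: str
    pos: int
    ref: str
    alt: str


def _sample_snvs(
    reference: SyntheticReference,
    n_snv: int,
    weights: dict[str, float],
    signatures: SignatureMatrix,
    rng: np.random.Generator,
) -> list[_PlannedVariant]:
    """Place ``n_snv`` substitutions drawn from a signature mixture."""
    w = np.zeros(len(signatures.names))
    for name, val in weights.items():
        w[signatures.names.index(name)] = val
    w = w / w.sum()
    p_channel = signatures.matrix @ w
    p_channel = p_channel / p_channel.sum()
    channel_counts = rng.multinomial(n_snv, p_channel)
    chrom_idx, pos_arr, pyr_arr, offsets = reference.context_index()
    chroms = reference.chroms
    out: list[_PlannedVariant] = []
    for ch, count in enumerate(channel_counts):
        if count == 0:
            continue
        t = _CHANNEL_TRIPLET_ID[ch]
        lo, hi = offsets[t], offsets[t + 1]
        if hi - lo < count:
            raise ValueError(
                f"not enough genomic positions with context for channel "
                f"{SBS96_LABELS[ch]}; use a larger genome"
            )
        picks = rng.choice(hi - lo, size=count, replace=False) + lo
        alt_pyr = _CHANNEL_ALT[ch]
        for j in picks:
            chrom = chroms[chrom_idx[j]]
            pos = int(pos_arr[j])
            base = chr(_CODE_TO_BASE[reference.codes[chrom][pos - 1]])
            alt = alt_pyr if pyr_arr[j] else _COMP[alt_pyr]
            out.append(_PlannedVariant(chrom, pos, base, alt))
    return out


def _write_vcf(records: list[_PlannedVariant],
               ann: dict[str, ChromosomeAnnotation], path: Path) -> None:
    order = {c: i for i, c in enumerate(ann)}
    records = sorted(records, key=lambda r: (order[r.chrom], r.pos, r.ref, r.alt))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=drdscore-simulate\n")
        for a in ann.values():
            fh.write(f"##contig=<ID={a.chrom},length={a.length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\n")


@dataclass
class SyntheticPatient:
    patient_id: str
    group: str
    vcf_path: Path
    segments_path: Path
    sv_path: Path
    truth: dict[str, float]
    planted: list[_PlannedVariant] = field(default_factory=list, repr=False)


@lru_cache(maxsize=None)
def _beta_shapes(median_unit: float, threshold_unit: float,
                 target_prev: float) -> tuple[float, float]:
    """Beta shapes jointly matching a median and an exceedance probability.

    Solved in least squares with both shapes constrained >= 1 (unimodal).
    When the two targets are jointly infeasible — a median above the
    threshold forces exceedance >= 1/2 — the result is the closest
    compromise, which is the intended behaviour for the resistant group's
    mutually inconsistent published summary statistics.
    """
    def objective(x: np.ndarray) -> float:
        a, b = 1.0 + np.exp(x[0]), 1.0 + np.exp(x[1])
        return ((stats.beta.cdf(median_unit, a, b) - 0.5) ** 2
                + (stats.beta.sf(threshold_unit, a, b) - target_prev) ** 2)

    res = minimize(objective, x0=[0.0, np.log(3.0)], method="Nelder-Mead",
                   options=dict(xatol=1e-10, fatol=1e-14, maxiter=4000))
    return 1.0 + float(np.exp(res.x[0])), 1.0 + float(np.exp(res.x[1]))


def _sample_hrd_score(params: GroupParams, rng: np.random.Generator,
                      hrd_high_threshold: int = 42) -> int:
    span = params.hrd_max - params.hrd_min
    a, b = _beta_shapes(
        (params.hrd_median - params.hrd_min) / span,
        (hrd_high_threshold - params.hrd_min) / span,
        params.hrd_high_target,
    )
    x = rng.beta(a, b)
    score = int(round(params.hrd_min + span * x))
    return int(np.clip(score, params.hrd_min, params.hrd_max))


def _negbin(mean: float, size: float, rng: np.random.Generator) -> int:
    p = size / (size + mean)
    return int(rng.negative_binomial(size, p))


def simulate_patient(
    reference: SyntheticReference,
    group: str,
    params: GroupParams,
    out_dir: str | Path,
    patient_id: str,
    seed: int | np.random.SeedSequence,
    signatures: SignatureMatrix | None = None,
    scars: ScarConfig = DESK_SCALE_SCARS,
    scar_targets: Optional[tuple[int, int, int]] = None,
    mhid_target: Optional[int] = None,
) -> SyntheticPatient:
    """Emit one patient's VCF, segment and SV tables plus planted truth.

    ``scar_targets`` (loh, tai, lst) and ``mhid_target`` override the
    sampled values for targeted tests; by default both are drawn from the
    group-conditional distributions.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if signatures is None:
        signatures = load_signatures()
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rng = np.random.default_rng(ss)

    # scar layout ---------------------------------------------------------
    if scar_targets is None:
        score = _sample_hrd_score(params, rng, scars.hrd_high_threshold)
        n_arms = 2 * len(reference.ann)
        tai = min(int(round(0.20 * score)), n_arms)
        loh = int(round(0.5 * (score - tai)))
        lst = score - tai - loh
    else:
        loh, tai, lst = scar_targets
        score = loh + tai + lst
    n_cnv_extra = int(rng.poisson(params.cnv_extra_mean))
    segments, cn_runs = _plant_scar_segments(
        reference.ann, loh, tai, lst, rng, scars, n_cnv_extra=n_cnv_extra)

    # variants ------------------------------------------------------------
    n_mh = (int(mhid_target) if mhid_target is not None
            else _negbin(params.mhid_mean, params.mhid_dispersion, rng))
    if n_mh > len(reference.mh_sites):
        raise ValueError(
            f"mhid target {n_mh} exceeds the {len(reference.mh_sites)} "
            f"engineered sites; regenerate the reference with more"
        )
    n_var = _negbin(params.nvar_mean, params.nvar_dispersion, rng)
    n_plain_indel = int(rng.poisson(5.0))
    n_snv = max(0, n_var - n_mh - n_plain_indel)

    records: list[_PlannedVariant] = []
    site_ids = rng.choice(len(reference.mh_sites), size=n_mh, replace=False)
    for i in site_ids:
        s = reference.mh_sites[int(i)]
        records.append(_PlannedVariant(s.chrom, s.pos, s.ref, s.alt))
    # 1 bp deletions: never microhomology by definition
    chroms = reference.chroms
    for _ in range(n_plain_indel):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = int(rng.integers(40_000, reference.ann[chrom].length - 40_000))
        arr = reference.codes[chrom]
        ref = chr(_CODE_TO_BASE[arr[pos - 1]]) + chr(_CODE_TO_BASE[arr[pos]])
        records.append(_PlannedVariant(chrom, pos, ref, ref[0]))
    # patient-specific signature mixture around the group centre
    sig_names = list(params.signature_weights)
    centre = np.array([params.signature_weights[s] for s in sig_names])
    centre = centre / centre.sum()
    w_pat = rng.dirichlet(params.signature_concentration * centre)
    patient_weights = dict(zip(sig_names, w_pat))
    records.extend(_sample_snvs(reference, n_snv, patient_weights,
                                signatures, rng))
    vcf_path = out_dir / f"{patient_id}.vcf"
    _write_vcf(records, reference.ann, vcf_path)

    seg_path = out_dir / f"{patient_id}.segments.tsv"
    write_segments(segments, seg_path)

    # structural variants -------------------------------------------------
    events: list[StructuralEvent] = []
    n_in = _negbin(params.dup_in_mean, params.dup_dispersion, rng)
    n_out = int(rng.poisson(params.dup_out_mean))
    for length_range, count in (((1_000, 100_000), n_in),
                                ((150_000, 400_000), n_out)):
        for _ in range(count):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            start = int(rng.integers(1, reference.ann[chrom].length - length))
            events.append(StructuralEvent(chrom, start, start + length - 1, "DUP"))
    for _ in range(int(rng.poisson(2.0))):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(5_000, 80_000))
        start = int(rng.integers(1, reference.ann[chrom].length - length))
        events.append(StructuralEvent(chrom, start, start + length - 1, "DEL"))
    sv_path = out_dir / f"{patient_id}.sv.tsv"
    write_sv_table(events, sv_path)

    neo = int(rng.poisson(params.neoantigen_mean))
    w = patient_weights
    wsum = sum(w.values())
    truth = {
        "HRD": float(score), "loh": float(loh), "tai": float(tai),
        "lst": float(lst), "MHID": float(n_mh), "CN_load": float(cn_runs),
        "DUP_1_100KB": float(n_in), "SNV_load": float(n_snv),
        "NEOANTIGENS": float(neo),
    }
    for name in ("AC1", "AC4", "AC7", "AC10", "AC12", "AC18", "AC20", "AC24"):
        # expected exposures; the NNLS estimates carry sampling noise
        truth[name] = n_snv * w.get(name, 0.0) / wsum
    return SyntheticPatient(patient_id, group, vcf_path, seg_path, sv_path,
                            truth, planted=records)


@dataclass
class SyntheticCohort:
    reference: Optional[SyntheticReference]
    patients: list[SyntheticPatient]
    truth_path: Optional[Path]
    manifest_path: Optional[Path]

    @property
    def truth_table(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            rows.append({"patient_id": p.patient_id, "group": p.group, **p.truth})
        return pd.DataFrame(rows)

    def cohort_table(self) -> CohortTable:
        """Truth features as a cohort table (for model fitting against truth)."""
        df = self.truth_table[["patient_id", "group", *FEATURE_COLUMNS]]
        return CohortTable(df)


def simulate_cohort(
    config: GeneratorConfig, out_dir: str | Path
) -> SyntheticCohort:
    """Generate a full synthetic cohort under ``config`` into ``out_dir``.

    Creates one subdirectory per patient plus ``reference/``, ``truth.csv``
    and ``manifest.json``.  An empty configuration (both group sizes zero)
    returns an empty cohort and writes nothing.
    """
    out_dir = Path(out_dir)
    n_total = config.n_sensitive + config.n_resistant
    if n_total == 0:
        return SyntheticCohort(None, [], None, None)
    out_dir.mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(config.seed)
    ref_seed, *patient_seeds = root_ss.spawn(n_total + 1)
    reference = make_reference(
        out_dir / "reference",
        n_chrom=config.n_chrom,
        chrom_length=config.chrom_length,
        seed=config.seed,
        n_mh_sites=config.n_mh_sites,
        exome_fraction=config.exome_fraction,
    )
    signatures = load_signatures()
    patients: list[SyntheticPatient] = []
    labels = (["sensitive"] * config.n_sensitive
              + ["resistant"] * config.n_resistant)
    for i, group in enumerate(labels):
        pid = f"P{i + 1:03d}"
        patients.append(simulate_patient(
            reference, group, config.group(group), out_dir / pid, pid,
            seed=patient_seeds[i], signatures=signatures, scars=config.scars,
        ))
    cohort = SyntheticCohort(reference, patients, None, None)
    truth_path = out_dir / "truth.csv"
    cohort.truth_table.to_csv(truth_path, index=False, float_format="%.17g")
    manifest = {
        "seed": config.seed,
        "n_sensitive": config.n_sensitive,
        "n_resistant": config.n_resistant,
        "reference": {
            "fasta": str(reference.fasta_path),
            "annotation": str(reference.annotation_path),
            "exome_bed": str(reference.exome_bed_path),
        },
        "patients": [
            {"patient_id": p.patient_id, "group": p.group,
             "vcf": str(p.vcf_path), "segments": str(p.segments_path),
             "sv": str(p.sv_path),
             "neoantigens": p.truth["NEOANTIGENS"]}
            for p in patients
        ],
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    cohort.truth_path = truth_path
    cohort.manifest_path = manifest_path
    return cohort
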