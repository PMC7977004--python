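"""Genomic-scar scoring: LOH, TAI, LST and the summed HRD score.

The HRD score is the sum of three counts computed from allele-specific
copy-number segments:

* **LOH** — loss-of-heterozygosity regions: merged runs of segments with
  minor copy number 0 and total copy number > 0, longer than 15 Mb, that do
  not span the whole chromosome.
* **TAI** — telomeric allelic imbalance: merged regions of unequal parental
  copy number that reach a chromosome end, do not cross the centromere and
  do not span the whole chromosome.
* **LST** — large-scale state transitions: after smoothing (segments
  shorter than 3 Mb removed, equal-state flanks merged), breakpoints between
  adjacent segments that are each at least 10 Mb long, counted per
  chromosome arm.

A score of 42 or more flags the genome as HRD-high.  The size rules follow
the established scar-score lineage and are configurable through
:class:`ScarConfig` (the synthetic mini-genome uses the same rules with kb
in place of Mb).

Merging conventions, stated once and shared with the documentation:
segments are *adjacent* when the next segment starts exactly one base after
the previous one ends; a merged region *spans the whole chromosome* when it
covers the full extent of that chromosome's segments (first covered base to
last covered base); a region *crosses the centromere* when it overlaps the
annotated centromere interval; merged lengths are spans (end - start + 1),
so bases smoothed out inside a merged region still count toward its length.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .io import AllelicSegment, ChromosomeAnnotation, is_autosome

__all__ = ["ScarConfig", "HRDResult", "loh_count", "tai_count", "lst_count",
           "hrd_score", "HG19_SCALE"]


@dataclass(frozen=True)
class ScarConfig:
    """Size rules for the scar components (lengths in bp).

    Defaults are the genome-scale rules: LOH regions strictly longer than
    15 Mb; LST flanks at least 10 Mb with segments under 3 Mb smoothed away;
    TAI with no minimum size; sex chromosomes excluded; HRD-high at 42.
    """

    loh_min_length: int = 15_000_000  # strict >
    lst_min_segment: int = 10_000_000  # inclusive >=
    lst_smooth_below: int = 3_000_000  # strict < removed
    tai_min_length: int = 0  # strict >
    hrd_high_threshold: int = 42  # inclusive >=
    include_sex_chromosomes: bool = False

    def scaled(self, factor: float) -> "ScarConfig":
        """Same rules with all length thresholds multiplied by ``factor``."""
        return replace(
            self,
            loh_min_length=int(self.loh_min_length * factor),
            lst_min_segment=int(self.lst_min_segment * factor),
            lst_smooth_below=int(self.lst_smooth_below * factor),
            tai_min_length=int(self.tai_min_length * factor),
        )


HG19_SCALE = ScarConfig()


@dataclass(frozen=True)
class HRDResult:
    loh: int
    tai: int
    lst: int
    hrd_score: int
    hrd_high: bool


def _by_chromosome(
    segments: list[AllelicSegment],
    ann: dict[str, ChromosomeAnnotation],
    config: ScarConfig,
) -> dict[str, list[AllelicSegment]]:
    out: dict[str, list[AllelicSegment]] = {}
    for seg in segments:
        if not config.include_sex_chromosomes and not is_autosome(seg.chrom):
            continue
        if seg.chrom not in ann:
            raise KeyError(
                f"chromosome {seg.chrom!r} absent from annotation "
                f"(known: {sorted(ann)})"
            )
        out.setdefault(seg.chrom, []).append(seg)
    for chrom in out:
        out[chrom].sort(key=lambda s: s.start)
    return out


def _adjacent(prev: AllelicSegment, cur: AllelicSegment) -> bool:
    return cur.start == prev.end + 1


def _merge_equal_state(segs: list[AllelicSegment]) -> list[AllelicSegment]:
    """Merge runs of adjacent segments sharing the same (major, minor) state."""
    merged: list[AllelicSegment] = []
    for seg in segs:
        if merged and _adjacent(merged[-1], seg) and merged[-1].state == seg.state:
            merged[-1] = replace(merged[-1], end=seg.end)
        else:
            merged.append(seg)
    return merged


def _covered_extent(segs: list[AllelicSegment]) -> tuple[int, int]:
    return segs[0].start, max(s.end for s in segs)


def loh_count(
    segments: list[AllelicSegment],
    ann: dict[str, ChromosomeAnnotation],
    config: ScarConfig = HG19_SCALE,
) -> int:
    """Number of long loss-of-heterozygosity regions.

    Runs of adjacent segments with ``minor_cn == 0`` and ``total_cn > 0``
    are merged into regions; a region counts when its span exceeds
    ``config.loh_min_length`` and it does not span the whole chromosome.
    """
    n = 0
    for chrom, segs in _by_chromosome(segments, ann, config).items():
        lo, hi = _covered_extent(segs)
        run_start = run_end = None
        runs: list[tuple[int, int]] = []
        prev = None
        for seg in segs:
            if seg.minor_cn == 0 and seg.total_cn > 0:
                if run_start is not None and prev is not None and _adjacent(prev, seg):
                    run_end = seg.end
                else:
                    if run_start is not None:
                        runs.append((run_start, run_end))
                    run_start, run_end = seg.start, seg.end
            else:
                if run_start is not None:
                    runs.append((run_start, run_end))
                    run_start = run_end = None
            prev = seg
        if run_start is not None:
            runs.append((run_start, run_end))
        for start, end in runs:
            if (start, end) == (lo, hi):
                continue  # whole-chromosome LOH is not scored
            if end - start + 1 > config.loh_min_length:
                n += 1
    return n


def tai_count(
    segments: list[AllelicSegment],
    ann: dict[str, ChromosomeAnnotation],
    config: ScarConfig = HG19_SCALE,
) -> int:
    """Number of telomeric allelic-imbalance regions."""
    n = 0
    for chrom, segs in _by_chromosome(segments, ann, config).items():
        a = ann[chrom]
        for seg in _merge_equal_state(segs):
            if seg.major_cn == seg.minor_cn:
                continue
            telomeric = seg.start == 1 or seg.end == a.length
            if not telomeric:
                continue
            if seg.start == 1 and seg.end == a.length:
                continue  # whole chromosome
            crosses_cen = (seg.start <= a.centromere_end
                           and seg.end >= a.centromere_start)
            if crosses_cen:
                continue
            if seg.length > config.tai_min_length:
                n += 1
    return n


def _clip(seg: AllelicSegment, lo: int, hi: int) -> AllelicSegment | None:
    start, end = max(seg.start, lo), min(seg.end, hi)
    if start > end:
        return None
    return replace(seg, start=start, end=end)


def lst_count(
    segments: list[AllelicSegment],
    ann: dict[str, ChromosomeAnnotation],
    config: ScarConfig = HG19_SCALE,
) -> int:
    """Number of large-scale state transitions, per chromosome arm.

    Segments are clipped to each arm (the centromere interval itself belongs
    to neither arm, so breakpoints across it are never counted), segments
    shorter than the smoothing threshold are removed, equal-state neighbours
    are merged (spans, gaps included), and every boundary between
    consecutive remaining segments with both spans >= ``lst_min_segment``
    counts as one transition.
    """
    n = 0
    for chrom, segs in _by_chromosome(segments, ann, config).items():
        a = ann[chrom]
        # normalize the representation first: adjacent equal-state segments
        # are one segment (makes the count invariant to segment bisection)
        segs = _merge_equal_state(segs)
        arms = [(1, a.centromere_start - 1), (a.centromere_end + 1, a.length)]
        for lo, hi in arms:
            clipped = [c for s in segs if (c := _clip(s, lo, hi)) is not None]
            kept = [s for s in clipped if s.length >= config.lst_smooth_below]
            smoothed: list[AllelicSegment] = []
            for seg in kept:
                if smoothed and smoothed[-1].state == seg.state:
                    smoothed[-1] = replace(smoothed[-1], end=seg.end)
                else:
                    smoothed.append(seg)
            for prev, cur in zip(smoothed, smoothed[1:]):
                if (prev.length >= config.lst_min_segment
                        and cur.length >= config.lst_min_segment):
                    n += 1
    return n


def hrd_score(
    segments: list[AllelicSegment],
    ann: dict[str, ChromosomeAnnotation],
    config: ScarConfig = HG19_SCALE,
) -> HRDResult:
    """All three scar components plus the summed HRD score and high/low flag."""
    loh = loh_count(segments, ann, config)
    tai = tai_count(segments, ann, config)
    lst = lst_count(segments, ann, config)
    total = loh + tai + lst
    return HRDResult(
        loh=loh,
        tai=tai,
        lst=lst,
        hrd_score=total,
        hrd_high=total >= config.hrd_high_threshold,
    )
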