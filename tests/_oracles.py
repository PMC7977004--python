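"""Independent brute-force oracles used by the test suite.

These deliberately re-derive the scar counts and indel classification from
first principles (base-resolution scans and plain string matching) so they
share no code path with the package implementation.
"""

from __future__ import annotations

from drdscore.io import AllelicSegment, ChromosomeAnnotation
from drdscore.scars import ScarConfig


def _base_states(segments, length):
    """Per-base (major, minor) state, None where uncovered (1-based)."""
    states = [None] * (length + 1)
    for seg in segments:
        for p in range(seg.start, seg.end + 1):
            states[p] = (seg.major_cn, seg.minor_cn)
    return states


def _runs(states, lo, hi, key=lambda s: s):
    """Maximal runs of identical key over contiguous covered bases in [lo, hi]."""
    runs = []
    start = None
    prev_key = None
    for p in range(lo, hi + 1):
        s = states[p] if 0 < p < len(states) else None
        k = None if s is None else key(s)
        if k is not None and k == prev_key and start is not None:
            continue
        if start is not None and prev_key is not None:
            runs.append((start, p - 1, prev_key))
        start = p if k is not None else None
        prev_key = k
    if start is not None and prev_key is not None:
        runs.append((start, hi, prev_key))
    return runs


def brute_force_scars(
    segments: list[AllelicSegment],
    ann: dict[str, ChromosomeAnnotation],
    config: ScarConfig,
) -> tuple[int, int, int]:
    """(loh, tai, lst) by exhaustive base-level scanning."""
    loh = tai = lst = 0
    by_chrom: dict[str, list[AllelicSegment]] = {}
    for seg in segments:
        name = seg.chrom[3:] if seg.chrom.lower().startswith("chr") else seg.chrom
        if not config.include_sex_chromosomes and not name.isdigit():
            continue
        by_chrom.setdefault(seg.chrom, []).append(seg)

    for chrom, segs in by_chrom.items():
        a = ann[chrom]
        states = _base_states(segs, a.length)
        covered = [p for p in range(1, a.length + 1) if states[p] is not None]
        lo_cov, hi_cov = covered[0], covered[-1]

        # LOH: runs of minor == 0 and total > 0
        for start, end, _ in _runs(
                states, 1, a.length,
                key=lambda s: "loh" if s[1] == 0 and s[0] + s[1] > 0 else None):
            if (start, end) == (lo_cov, hi_cov):
                continue
            if end - start + 1 > config.loh_min_length:
                loh += 1

        # TAI: equal-state runs, imbalanced, touching an end, off-centromere
        for start, end, state in _runs(states, 1, a.length):
            if state[0] == state[1]:
                continue
            if not (start == 1 or end == a.length):
                continue
            if start == 1 and end == a.length:
                continue
            if start <= a.centromere_end and end >= a.centromere_start:
                continue
            if end - start + 1 > config.tai_min_length:
                tai += 1

        # LST: per arm, smooth, merge equal states (spans), count big pairs
        for arm_lo, arm_hi in ((1, a.centromere_start - 1),
                               (a.centromere_end + 1, a.length)):
            kept = [r for r in _runs(states, arm_lo, arm_hi)
                    if r[1] - r[0] + 1 >= config.lst_smooth_below]
            merged = []
            for start, end, state in kept:
                if merged and merged[-1][2] == state:
                    merged[-1] = (merged[-1][0], end, state)
                else:
                    merged.append((start, end, state))
            for (s1, e1, _), (s2, e2, _) in zip(merged, merged[1:]):
                if (e1 - s1 + 1 >= config.lst_min_segment
                        and e2 - s2 + 1 >= config.lst_min_segment):
                    lst += 1
    return loh, tai, lst


def brute_force_mh(sequence: str, del_start0: int, del_len: int):
    """(mh_length, is_repeat) for deleting sequence[del_start0:del_start0+L].

    Plain string matching: microhomology is the longest shared prefix with
    the 3' flank or shared suffix with the 5' flank, capped at L - 1; the
    deletion sits in a tandem repeat when at least one further whole copy of
    the deleted unit tiles either flank.
    """
    L = del_len
    unit = sequence[del_start0:del_start0 + L]
    right = sequence[del_start0 + L:]
    left = sequence[:del_start0]

    copies = 1
    i = 0
    while right[i * L:(i + 1) * L] == unit and len(right[i * L:(i + 1) * L]) == L:
        copies += 1
        i += 1
    i = 1
    while len(left) >= i * L and left[len(left) - i * L:len(left) - (i - 1) * L] == unit:
        copies += 1
        i += 1

    mh = 0
    for m in range(1, L):
        if right[:m] == unit[:m] and len(right) >= m:
            mh = max(mh, m)
        else:
            break
    back = 0
    for m in range(1, L):
        if len(left) >= m and left[-m:] == unit[L - m:]:
            back = m
        else:
            break
    mh = max(mh, back)
    return mh, copies >= 2
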