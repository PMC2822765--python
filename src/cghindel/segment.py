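"""Bottom-up t-test segmentation and indel calling.

Each chromosome starts as one segment per probe.  A heap prioritizes all
possible mergers of adjacent segments by the two-sample t-test P-value
that their log2 ratios share a mean; the most likely merger (largest P)
is made, the merged segment's statistics and neighbor P-values are
recomputed, and the process repeats until the best remaining merger
falls below a critical value (default 0.05).  Remaining segments are
tested against 0 with a one-sample t-test and labeled deletion
(mean log2 ≤ −2), amplification (mean log2 ≥ +1) or normal at P ≤ 0.01;
adjacent same-label segments are merged with statistics recomputed.
Aberrant segments spanning fewer than 3 probes are dropped, except
2-probe deletions whose probes both sit at or below the deletion cutoff.

For singleton segments the t-test variance is undefined; a per-chromosome
noise variance estimated from the scaled median absolute successive
difference stands in, and such terms contribute no degrees of freedom
(the test degenerates to a z-test when no segment supplies any).
P-values are raw, with no multiple-testing correction.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import ndtr, stdtr

from .probes import ProbeMap, RatioProfile

__all__ = [
    "CallingParameters",
    "Segment",
    "IndelCall",
    "robust_noise_variance",
    "segment_profile",
    "classify_and_filter",
    "find_flanking_probes",
    "call_indels",
    "review_table",
]

DELETION = "deletion"
AMPLIFICATION = "amplification"
NORMAL = "normal"


@dataclass(frozen=True)
class CallingParameters:
    """Thresholds for merging, classification and flank determination."""

    merge_alpha: float = 0.05
    segment_p_cutoff: float = 0.01
    deletion_cutoff: float = -2.0
    amplification_cutoff: float = 1.0
    min_probes: int = 3
    two_probe_deletion_cutoff: float = -2.0
    deletion_flank_threshold: float = -0.8
    amplification_flank_threshold: float = 0.5

    def __post_init__(self):
        if not (
            self.deletion_cutoff
            < self.deletion_flank_threshold
            < 0
            < self.amplification_flank_threshold
            < self.amplification_cutoff
        ):
            raise ValueError("inconsistent classification/flank thresholds")
        if not (0 < self.merge_alpha < 1 and 0 < self.segment_p_cutoff < 1):
            raise ValueError("merge_alpha and segment_p_cutoff must be in (0, 1)")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")


@dataclass
class Segment:
    """A contiguous run of probes on one chromosome.

    ``first_probe``/``last_probe`` index into the chromosome's ordered
    probes (0-based, inclusive).
    """

    chromosome: str
    first_probe: int
    last_probe: int
    mean_log2: float
    p_value: float | None = None
    label: str = "unlabeled"

    @property
    def n_probes(self) -> int:
        return self.last_probe - self.first_probe + 1


@dataclass
class IndelCall:
    """A called deletion or amplification.

    Breakpoint probes are the leftmost and rightmost affected probes;
    flanking probes mark where more normal ratios consistently resume
    outside them (absent at chromosome ends).  ``length_bp`` is measured
    midpoint-to-midpoint between the breakpoint probes; ``start``/``end``
    span the breakpoint probes (1-based inclusive).
    """

    strain: str
    chromosome: str
    kind: str
    start: int
    end: int
    left_bp_probe: str
    right_bp_probe: str
    left_flank_probe: str | None
    right_flank_probe: str | None
    mean_log2: float
    p_value: float
    n_probes: int
    length_bp: float


# ---------------------------------------------------------------------------
# noise and t-tests

# median |N(0,s) - N(0,s)| = s * sqrt(2) * Phi^-1(0.75) / ... : the median
# absolute successive difference of iid N(0, s) values is s * 0.95387
_MASD_TO_SD = 1.0 / 0.9538725524
_ZERO_GUARD = 1e-300


def robust_noise_variance(x: np.ndarray) -> float:
    """Per-chromosome noise variance from the scaled median absolute
    successive difference, insensitive to sparse copy-number steps."""
    if len(x) < 2:
        return 0.0
    masd = float(np.median(np.abs(np.diff(x))))
    return (masd * _MASD_TO_SD) ** 2


def _two_sided_p(t: float, df: float | None) -> float:
    if df is None:
        p = 2.0 * float(ndtr(-abs(t)))
    else:
        p = 2.0 * float(stdtr(df, -abs(t)))
    return min(max(p, 0.0), 1.0)


def _welch_p(n1, m1, v1, n2, m2, v2, var_g) -> float:
    """Welch two-sample P; singleton variances fall back to var_g and
    contribute no degrees of freedom."""
    u1 = v1 if n1 >= 2 else var_g
    u2 = v2 if n2 >= 2 else var_g
    se2 = u1 / n1 + u2 / n2
    if se2 <= _ZERO_GUARD:
        return 1.0 if m1 == m2 else 0.0
    t = (m1 - m2) / math.sqrt(se2)
    den = 0.0
    if n1 >= 2:
        den += (u1 / n1) ** 2 / (n1 - 1)
    if n2 >= 2:
        den += (u2 / n2) ** 2 / (n2 - 1)
    df = se2 * se2 / den if den > 0 else None
    return _two_sided_p(t, df)


def one_sample_p(n: int, mean: float, var: float, var_g: float) -> float:
    """One-sample t-test P of mean vs 0.

    Below 3 probes the sample variance has at most 1 degree of freedom
    and carries essentially no information, so the chromosome noise
    estimate ``var_g`` is used instead and the test degenerates to a
    z-test."""
    v = var if n >= 3 else var_g
    if v <= _ZERO_GUARD:
        return 1.0 if mean == 0.0 else 0.0
    t = mean / math.sqrt(v / n)
    return _two_sided_p(t, n - 1 if n >= 3 else None)


# ---------------------------------------------------------------------------
# bottom-up merging

def _segment_chromosome(x: np.ndarray, merge_alpha: float) -> list[tuple[int, int]]:
    """Greedy bottom-up merge of one chromosome's ratios.

    Returns (first, last) probe index pairs partitioning the chromosome.
    The heap is lazily invalidated: each segment carries a version bumped
    on every merge, and popped entries citing stale versions are skipped,
    which is behaviorally identical to eager updating.  Equal P-values
    break toward the leftmost pair.
    """
    n = len(x)
    if n <= 1:
        return [(0, n - 1)] if n else []
    var_g = robust_noise_variance(x)
    cnt = np.ones(n, dtype=np.int64)
    s = x.astype(float).copy()
    ss = x.astype(float) ** 2
    nxt = np.arange(1, n + 1)
    prv = np.arange(-1, n - 1)
    ver = np.zeros(n, dtype=np.int64)

    def var_of(i: int) -> float:
        if cnt[i] < 2:
            return 0.0
        v = (ss[i] - s[i] * s[i] / cnt[i]) / (cnt[i] - 1)
        return max(v, 0.0)

    def pair_p(i: int, j: int) -> float:
        return _welch_p(
            cnt[i], s[i] / cnt[i], var_of(i),
            cnt[j], s[j] / cnt[j], var_of(j),
            var_g,
        )

    heap: list[tuple] = []
    for i in range(n - 1):
        heap.append((-pair_p(i, i + 1), i, i, i + 1, 0, 0))
    heapq.heapify(heap)

    while heap:
        neg_p, _, i, j, vi, vj = heapq.heappop(heap)
        if ver[i] != vi or ver[j] != vj or nxt[i] != j:
            continue  # stale entry
        if -neg_p < merge_alpha:
            break
        cnt[i] += cnt[j]
        s[i] += s[j]
        ss[i] += ss[j]
        ver[i] += 1
        ver[j] += 1
        k = nxt[j]
        nxt[i] = k
        if k < n:
            prv[k] = i
            heapq.heappush(heap, (-pair_p(i, k), i, i, k, ver[i], ver[k]))
        h = prv[i]
        if h >= 0:
            heapq.heappush(heap, (-pair_p(h, i), h, h, i, ver[h], ver[i]))

    out = []
    i = 0
    while i < n:
        out.append((i, int(nxt[i]) - 1))
        i = int(nxt[i])
    return out


def segment_profile(profile: RatioProfile, merge_alpha: float = 0.05) -> list[Segment]:
    """Partition every chromosome of a (normalized) profile into segments
    by bottom-up t-test merging.  Chromosomes are processed independently;
    segments never span chromosomes."""
    pm = profile.probe_map
    segments: list[Segment] = []
    for chrom in pm.chromosomes:
        x = profile.chromosome_ratios(chrom)
        for first, last in _segment_chromosome(x, merge_alpha):
            member = x[first : last + 1]
            segments.append(
                Segment(chrom, first, last, mean_log2=float(member.mean()))
            )
    return segments


# ---------------------------------------------------------------------------
# classification

def _segment_stats(x: np.ndarray, first: int, last: int, var_g: float):
    member = x[first : last + 1]
    n = len(member)
    mean = float(member.mean())
    var = float(member.var(ddof=1)) if n >= 2 else 0.0
    return mean, one_sample_p(n, mean, var, var_g)


def classify_and_filter(
    profile: RatioProfile,
    segments: list[Segment],
    params: CallingParameters = CallingParameters(),
) -> list[Segment]:
    """Label segments, merge same-label neighbors, apply size filters.

    Each segment is tested against 0 (one-sample t); deletion requires
    mean ≤ deletion_cutoff, amplification mean ≥ amplification_cutoff,
    both at P ≤ segment_p_cutoff.  Adjacent segments sharing a label are
    merged and their statistics recomputed.  Aberrant segments with fewer
    than min_probes probes revert to normal, except 2-probe deletions
    whose two ratios are both ≤ two_probe_deletion_cutoff.
    """
    out: list[Segment] = []
    by_chrom: dict[str, list[Segment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chromosome, []).append(seg)
    for chrom in profile.probe_map.chromosomes:
        chrom_segs = sorted(by_chrom.get(chrom, []), key=lambda s: s.first_probe)
        if not chrom_segs:
            continue
        x = profile.chromosome_ratios(chrom)
        var_g = robust_noise_variance(x)

        labeled = []
        for seg in chrom_segs:
            mean, p = _segment_stats(x, seg.first_probe, seg.last_probe, var_g)
            # 2-probe deletion evidence: both ratios at/below the cutoff
            # stands in for the t-test, which has no power at df=1
            two_probe_del = seg.n_probes == 2 and bool(
                np.all(x[seg.first_probe : seg.last_probe + 1] <= params.two_probe_deletion_cutoff)
            )
            if two_probe_del or (p <= params.segment_p_cutoff and mean <= params.deletion_cutoff):
                label = DELETION
            elif p <= params.segment_p_cutoff and mean >= params.amplification_cutoff:
                label = AMPLIFICATION
            else:
                label = NORMAL
            labeled.append(replace(seg, mean_log2=mean, p_value=p, label=label))

        merged: list[Segment] = []
        for seg in labeled:
            if merged and merged[-1].label == seg.label:
                prev = merged.pop()
                mean, p = _segment_stats(x, prev.first_probe, seg.last_probe, var_g)
                seg = Segment(chrom, prev.first_probe, seg.last_probe, mean, p, seg.label)
            merged.append(seg)

        for seg in merged:
            if seg.label != NORMAL and seg.n_probes < params.min_probes:
                two_probe_rescue = (
                    seg.label == DELETION
                    and seg.n_probes == 2
                    and bool(
                        np.all(
                            x[seg.first_probe : seg.last_probe + 1]
                            <= params.two_probe_deletion_cutoff
                        )
                    )
                )
                if not two_probe_rescue:
                    seg = replace(seg, label=NORMAL)
            out.append(seg)
    return out


# ---------------------------------------------------------------------------
# flanks and calls

def _scan_flank(x: np.ndarray, start: int, step: int, ok) -> int | None:
    """First index from ``start`` in direction ``step`` where the ratio
    satisfies ``ok`` and at least 2 of the 3 probes beyond it (or all that
    remain near a chromosome end) do too."""
    n = len(x)
    i = start
    while 0 <= i < n:
        if ok(x[i]):
            follow = [x[i + step * k] for k in (1, 2, 3) if 0 <= i + step * k < n]
            need = min(2, len(follow))
            if sum(ok(v) for v in follow) >= need:
                return i
        i += step
    return None


def find_flanking_probes(
    profile: RatioProfile, call: IndelCall, params: CallingParameters = CallingParameters()
) -> IndelCall:
    """Attach flanking probes: scanning outward from each breakpoint, the
    flank is the first probe whose ratio is back past the threshold
    (> −0.8 for deletions, < +0.5 for amplifications) with at least 2 of
    the following 3 probes agreeing; absent if the chromosome ends first."""
    pm = profile.probe_map
    lo, hi = pm.span(call.chromosome)
    x = profile.log2_ratio[lo:hi]
    ids = pm.probe_ids[lo:hi]
    left = pm.index_of(call.left_bp_probe) - lo
    right = pm.index_of(call.right_bp_probe) - lo
    if call.kind == DELETION:
        ok = lambda v: v > params.deletion_flank_threshold  # noqa: E731
    else:
        ok = lambda v: v < params.amplification_flank_threshold  # noqa: E731
    lf = _scan_flank(x, left - 1, -1, ok)
    rf = _scan_flank(x, right + 1, +1, ok)
    call.left_flank_probe = str(ids[lf]) if lf is not None else None
    call.right_flank_probe = str(ids[rf]) if rf is not None else None
    return call


def call_indels(
    profile: RatioProfile,
    probe_map: ProbeMap | None = None,
    params: CallingParameters = CallingParameters(),
) -> list[IndelCall]:
    """Full calling chain: segment, classify, and build indel calls with
    breakpoint probes, flanking probes and midpoint-to-midpoint lengths.
    Calls are returned sorted by (chromosome, start)."""
    pm = probe_map if probe_map is not None else profile.probe_map
    if pm is not profile.probe_map and not (pm == profile.probe_map):
        raise ValueError("probe_map does not match profile")
    segments = segment_profile(profile, merge_alpha=params.merge_alpha)
    labeled = classify_and_filter(profile, segments, params)
    calls: list[IndelCall] = []
    for seg in labeled:
        if seg.label == NORMAL:
            continue
        lo, _ = pm.span(seg.chromosome)
        li = lo + seg.first_probe
        ri = lo + seg.last_probe
        mid_l = (pm.starts[li] + pm.ends[li]) / 2.0
        mid_r = (pm.starts[ri] + pm.ends[ri]) / 2.0
        call = IndelCall(
            strain=profile.strain,
            chromosome=seg.chromosome,
            kind=seg.label,
            start=int(pm.starts[li]),
            end=int(pm.ends[ri]),
            left_bp_probe=str(pm.probe_ids[li]),
            right_bp_probe=str(pm.probe_ids[ri]),
            left_flank_probe=None,
            right_flank_probe=None,
            mean_log2=seg.mean_log2,
            p_value=seg.p_value,
            n_probes=seg.n_probes,
            length_bp=mid_r - mid_l,
        )
        calls.append(find_flanking_probes(profile, call, params))
    order = {c: i for i, c in enumerate(pm.chromosomes)}
    calls.sort(key=lambda c: (order[c.chromosome], c.start))
    return calls


def review_table(profile: RatioProfile, calls: list[IndelCall], width: int = 10):
    """Audit table: each call with the log2 ratios of its probes and up to
    ``width`` probes of context on each side, for manual breakpoint review."""
    import pandas as pd

    pm = profile.probe_map
    rows = []
    for k, call in enumerate(calls):
        lo, hi = pm.span(call.chromosome)
        li = pm.index_of(call.left_bp_probe)
        ri = pm.index_of(call.right_bp_probe)
        for i in range(max(lo, li - width), min(hi, ri + width + 1)):
            rows.append(
                {
                    "call_index": k,
                    "strain": call.strain,
                    "kind": call.kind,
                    "chromosome": call.chromosome,
                    "probe_id": pm.probe_ids[i],
                    "start": int(pm.starts[i]),
                    "end": int(pm.ends[i]),
                    "log2_ratio": float(profile.log2_ratio[i]),
                    "in_call": bool(li <= i <= ri),
                }
            )
    return pd.DataFrame(rows)
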