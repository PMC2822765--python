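"""Synthetic aCGH study generator with a known truth set.

Emulates the statistical structure the calling pipeline assumes: an
exon-centric oligo array of roughly 380,000 probes across six chromosomes
(mean spacing 260 bp), a set of natural-isolate strains related by a
clonal genealogy, deletions and amplifications planted once on genealogy
branches and inherited by all descendant strains, Gaussian per-probe
noise, and a smooth intensity-dependent dye-bias trend for the
normalization stage to remove.

What it does **not** emulate: probe sequence/hybridization effects,
SNP-level divergence masquerading as deletions, or spatial slide
artifacts; see the methods note for the implications.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .probes import ProbeMap, RatioProfile
from .trees import Tree

__all__ = [
    "LayoutConfig",
    "NoiseConfig",
    "TruthIndel",
    "default_layout",
    "generate_probe_map",
    "simulate_genealogy_truth",
    "simulate_ratio_profile",
    "truth_recovery_metrics",
    "truth_presence_absence",
    "simulate_study",
    "child_seed",
]


@dataclass(frozen=True)
class LayoutConfig:
    """Array layout: chromosomes, probe spacing and arm geometry."""

    chromosome_names: tuple[str, ...]
    chromosome_lengths: tuple[int, ...]
    probe_spacing_mean: float = 260.0
    probe_length: int = 50
    arm_fraction: float = 0.23
    x_chromosome: str | None = "X"

    def __post_init__(self):
        if len(self.chromosome_names) != len(self.chromosome_lengths):
            raise ValueError("chromosome names/lengths length mismatch")
        if not self.probe_spacing_mean > self.probe_length > 0:
            raise ValueError("require probe_spacing_mean > probe_length > 0")
        if not 0 < 2 * self.arm_fraction < 1:
            raise ValueError("require 0 < 2*arm_fraction < 1")
        if any(length <= 0 for length in self.chromosome_lengths):
            raise ValueError("chromosome lengths must be positive")


def default_layout() -> LayoutConfig:
    """C. elegans-like layout: 6 chromosomes, ~100 Mb, ~380k probes at
    260 bp mean spacing; arms sized so they hold ~38% of all probes."""
    return LayoutConfig(
        chromosome_names=("I", "II", "III", "IV", "V", "X"),
        chromosome_lengths=(
            15_072_000,
            15_279_000,
            13_784_000,
            17_494_000,
            20_924_000,
            17_719_000,
        ),
    )


@dataclass(frozen=True)
class NoiseConfig:
    """Per-probe Gaussian log2 noise and intensity-dependent bias."""

    probe_sd: float = 0.25
    trend_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.probe_sd < 0:
            raise ValueError("probe_sd must be >= 0")


@dataclass(frozen=True)
class TruthIndel:
    """A planted indel allele carried by one strain (1-based inclusive)."""

    strain: str
    chromosome: str
    start: int
    end: int
    kind: str
    signal_log2: float
    locus_id: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("start > end")
        if self.kind == "deletion" and not self.signal_log2 <= -2:
            raise ValueError("deletion signal_log2 must be <= -2")
        if self.kind == "amplification" and not self.signal_log2 >= 1:
            raise ValueError("amplification signal_log2 must be >= 1")
        if self.kind not in ("deletion", "amplification"):
            raise ValueError(f"unknown kind {self.kind!r}")


def child_seed(root_seed: int, label: str) -> int:
    """Deterministic per-label child seed: first 4 bytes of
    sha256(f"{root_seed}:{label}"), masked to 31 bits."""
    digest = hashlib.sha256(f"{root_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF


def generate_probe_map(layout: LayoutConfig, seed: int = 0) -> ProbeMap:
    """Ordered non-overlapping probes with exponential spacing jitter.

    Successive probe starts differ by probe_length plus an exponential
    gap with mean (spacing_mean − probe_length), so probes never overlap
    and the mean start-to-start spacing is the configured mean.  Autosome
    probes in the outer ``arm_fraction`` of the chromosome (by position)
    are labeled ``arm``, the middle ``center``; the X chromosome is
    labeled ``X`` throughout.
    """
    rng = np.random.default_rng(seed)
    frames = []
    extra_mean = layout.probe_spacing_mean - layout.probe_length
    for chrom, length in zip(layout.chromosome_names, layout.chromosome_lengths):
        if length < layout.probe_length:
            raise ValueError(f"chromosome {chrom} shorter than one probe")
        # enough draws that truncation at the chromosome end is the binding
        # constraint (mean count + ~6 sd cushion)
        mean_n = length / layout.probe_spacing_mean
        n_max = int(mean_n + 6 * math.sqrt(mean_n + 1)) + 64
        gaps = rng.exponential(extra_mean, size=n_max).astype(np.int64)
        starts = 1 + np.cumsum(layout.probe_length + gaps) - (layout.probe_length + gaps[0])
        ends = starts + layout.probe_length - 1
        keep = ends <= length
        starts, ends = starts[keep], ends[keep]
        if chrom == layout.x_chromosome:
            region = np.full(len(starts), "X")
        else:
            mid = (starts + ends) / 2
            left = layout.arm_fraction * length
            right = (1 - layout.arm_fraction) * length
            region = np.where((mid < left) | (mid > right), "arm", "center")
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": [f"{chrom}_p{i:06d}" for i in range(len(starts))],
                    "chromosome": chrom,
                    "start": starts,
                    "end": ends,
                    "region": region,
                }
            )
        )
    return ProbeMap(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# genealogy truth

def _branches(tree: Tree) -> list[tuple[frozenset, int]]:
    """Every branch of the rooted genealogy as (descendant leafset, depth),
    in deterministic preorder."""
    out = []

    def rec(node, depth):
        leafset = frozenset(
            n.label for n in Tree(node).leaves()
        ) if node.children else frozenset([node.label])
        if depth > 0:  # the root has no branch above it
            out.append((leafset, depth))
        for c in node.children:
            rec(c, depth + 1)

    rec(tree.root, 0)
    return out


def simulate_genealogy_truth(
    probe_map: ProbeMap,
    tree_spec: str | Tree,
    rates,
    length_dist: tuple[float, float] = (math.log(2700.0), 1.15),
    arm_bias: float = 0.85,
    deletion_fraction: float = 8.0 / 9.0,
    deletion_signal: float = -3.0,
    amplification_signal: float = 1.5,
    recomb_swaps=(),
    min_probes: int = 3,
    min_gap_probes: int = 5,
    seed: int = 0,
) -> list[TruthIndel]:
    """Plant indels on genealogy branches and expand to per-strain truth.

    Each locus originates once on a branch and is inherited by every
    descendant strain (shared ``locus_id``).  ``rates`` is either an int
    (indels per branch), or a mapping from descendant leafsets (any
    iterable of strain labels) to an int count or an exact
    ``(n_deletions, n_amplifications)`` pair.  Lengths are log-normal
    (``length_dist`` = (mu, sigma) of log bp); placement is on an arm
    probe with probability ``arm_bias``, elsewhere otherwise.  Loci are
    kept mutually non-overlapping with at least ``min_gap_probes`` probes
    between them and each covers at least ``min_probes`` probes.
    ``recomb_swaps`` entries ((strain_a, strain_b), chromosome, start,
    end) exchange carrier status of the two strains at every locus whose
    start lies in the interval.
    """
    if not 0 <= arm_bias <= 1:
        raise ValueError("arm_bias must be in [0, 1]")
    tree = Tree.from_newick(tree_spec) if isinstance(tree_spec, str) else tree_spec
    strains = tree.leaf_labels()
    if len(strains) != len(set(strains)):
        raise ValueError("duplicate strains in tree_spec")
    branches = _branches(tree)
    if isinstance(rates, int):
        plan = [(leafset, rates, None) for leafset, _ in branches]
    elif isinstance(rates, tuple):
        plan = [(leafset, rates[0] + rates[1], rates) for leafset, _ in branches]
    else:
        norm = {frozenset(k): v for k, v in rates.items()}
        plan = []
        for leafset, _ in branches:
            v = norm.get(leafset, 0)
            if isinstance(v, tuple):
                plan.append((leafset, v[0] + v[1], v))
            else:
                plan.append((leafset, v, None))

    rng = np.random.default_rng(seed)
    table = probe_map.table
    regions = probe_map.regions
    arm_idx = np.flatnonzero(regions == "arm")
    other_idx = np.flatnonzero(regions != "arm")
    chrom_len = {
        c: int(table["end"].iloc[probe_map.span(c)[1] - 1])
        for c in probe_map.chromosomes
    }
    mu, sigma = length_dist
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in probe_map.chromosomes}

    loci = []  # (locus_id, carriers, chrom, start, end, kind, signal)
    counter = 0
    for leafset, total, exact in plan:
        kinds = []
        if exact is not None:
            kinds = ["deletion"] * exact[0] + ["amplification"] * exact[1]
        else:
            kinds = [
                "deletion" if rng.random() < deletion_fraction else "amplification"
                for _ in range(total)
            ]
        for kind in kinds:
            for _attempt in range(1000):
                pool = arm_idx if (rng.random() < arm_bias and len(arm_idx)) else other_idx
                anchor = int(pool[rng.integers(len(pool))])
                chrom = table["chromosome"].iloc[anchor]
                start = int(table["start"].iloc[anchor])
                length = max(1, int(round(float(rng.lognormal(mu, sigma)))))
                end = start + length - 1
                if end > chrom_len[chrom]:
                    continue
                probes = probe_map.overlapping(chrom, start, end)
                if len(probes) < min_probes:
                    continue
                lo, hi = int(probes[0]), int(probes[-1])
                clash = any(
                    lo - min_gap_probes <= h and hi + min_gap_probes >= l
                    for l, h in occupied[chrom]
                )
                if clash:
                    continue
                occupied[chrom].append((lo, hi))
                counter += 1
                signal = deletion_signal if kind == "deletion" else amplification_signal
                loci.append((f"L{counter:05d}", set(leafset), chrom, start, end, kind, signal))
                break
            else:
                raise RuntimeError("could not place indel; layout too crowded")

    for (a, b), chrom, lo_bp, hi_bp in recomb_swaps:
        if chrom not in probe_map.chromosomes:
            raise ValueError(f"recomb interval on unknown chromosome {chrom!r}")
        if hi_bp < 1 or lo_bp > chrom_len[chrom]:
            raise ValueError("recomb interval outside probe map")
        for _, carriers, c, start, _, _, _ in loci:
            if c == chrom and lo_bp <= start <= hi_bp:
                a_in, b_in = a in carriers, b in carriers
                if a_in != b_in:
                    if a_in:
                        carriers.discard(a)
                        carriers.add(b)
                    else:
                        carriers.discard(b)
                        carriers.add(a)

    truth = [
        TruthIndel(strain, chrom, start, end, kind, signal, locus_id)
        for locus_id, carriers, chrom, start, end, kind, signal in loci
        for strain in sorted(carriers)
    ]
    truth.sort(key=lambda t: (t.strain, probe_map.chromosomes.index(t.chromosome), t.start))
    return truth


def simulate_ratio_profile(
    probe_map: ProbeMap, truth: list[TruthIndel], noise: NoiseConfig, strain: str | None = None
) -> RatioProfile:
    """Forward model: signal + Gaussian noise + smooth intensity bias.

    Probes overlapping a truth indel take its full ``signal_log2``
    (breakpoint probes are not attenuated); everything else is 0.  A
    per-probe mean log-intensity covariate A ~ U(8, 16) is drawn and a
    cubic bias ``trend_amplitude * ((A-12)/4)**3`` is added to the log2
    ratios, giving LOWESS a smooth nonlinear target.  Test/reference
    intensities are reconstructed as 2**(A ± ratio/2).
    """
    if strain is None:
        strains = {t.strain for t in truth}
        if len(strains) > 1:
            raise ValueError("truth spans multiple strains; pass strain=")
        strain = strains.pop() if strains else "sim"
    rng = np.random.default_rng(noise.seed)
    r = np.zeros(len(probe_map))
    for t in truth:
        if t.strain != strain:
            continue
        if t.chromosome not in probe_map.chromosomes:
            raise ValueError(f"truth indel on unknown chromosome {t.chromosome!r}")
        r[probe_map.overlapping(t.chromosome, t.start, t.end)] = t.signal_log2
    if noise.probe_sd > 0:
        r = r + rng.normal(0.0, noise.probe_sd, size=len(r))
    else:
        rng.normal(0.0, 1.0, size=len(r))  # keep stream alignment across configs
    a = rng.uniform(8.0, 16.0, size=len(r))
    r = r + noise.trend_amplitude * ((a - 12.0) / 4.0) ** 3
    ref = np.exp2(a - r / 2.0)
    test = np.exp2(a + r / 2.0)
    return RatioProfile(
        strain=strain,
        probe_map=probe_map,
        log2_ratio=r,
        test_intensity=test,
        ref_intensity=ref,
        normalized=False,
    )


# ---------------------------------------------------------------------------
# recovery metrics

@dataclass
class RecoveryReport:
    """Truth-vs-call comparison at reciprocal probe-overlap >= 50%."""

    n_truth: int
    n_calls: int
    n_matched: int
    sensitivity: float
    fdr: float
    left_errors: list[int] = field(default_factory=list)
    right_errors: list[int] = field(default_factory=list)

    @property
    def breakpoint_errors(self) -> list[int]:
        return self.left_errors + self.right_errors


def truth_recovery_metrics(calls, truth, probe_map: ProbeMap) -> RecoveryReport:
    """Match calls to planted truth and report sensitivity, FDR and
    signed breakpoint offsets (in probes).

    A call matches a truth indel of the same strain and kind when their
    probe index ranges overlap reciprocally by at least 50%.  With empty
    truth and non-empty calls, FDR is 1 and sensitivity NaN.
    """
    truth_items = []
    for t in truth:
        probes = probe_map.overlapping(t.chromosome, t.start, t.end)
        if len(probes) == 0:
            continue
        truth_items.append((t, int(probes[0]), int(probes[-1])))
    matched_truth = set()
    matched_calls = 0
    left_err, right_err = [], []
    for call in calls:
        lo = probe_map.index_of(call.left_bp_probe)
        hi = probe_map.index_of(call.right_bp_probe)
        n_call = hi - lo + 1
        best = None
        for j, (t, tlo, thi) in enumerate(truth_items):
            if j in matched_truth or t.strain != call.strain or t.kind != call.kind:
                continue
            ov = min(hi, thi) - max(lo, tlo) + 1
            if ov <= 0:
                continue
            n_truth = thi - tlo + 1
            if ov >= 0.5 * n_call and ov >= 0.5 * n_truth:
                if best is None or ov > best[0]:
                    best = (ov, j, tlo, thi)
        if best is not None:
            _, j, tlo, thi = best
            matched_truth.add(j)
            matched_calls += 1
            left_err.append(lo - tlo)
            right_err.append(hi - thi)
    n_truth = len(truth_items)
    n_calls = len(list(calls))
    sensitivity = len(matched_truth) / n_truth if n_truth else float("nan")
    fdr = (n_calls - matched_calls) / n_calls if n_calls else 0.0
    return RecoveryReport(
        n_truth=n_truth,
        n_calls=n_calls,
        n_matched=len(matched_truth),
        sensitivity=sensitivity,
        fdr=fdr,
        left_errors=left_err,
        right_errors=right_err,
    )


def truth_presence_absence(truth: list[TruthIndel], strains: list[str], kinds=("deletion",)):
    """Ground-truth strain × locus presence/absence matrix (loci in
    locus_id order), for marker-level analyses that bypass calling."""
    from .popgen import PresenceAbsenceMatrix

    carriers: dict[str, set] = {}
    kind_of: dict[str, str] = {}
    for t in truth:
        carriers.setdefault(t.locus_id, set()).add(t.strain)
        kind_of[t.locus_id] = t.kind
    loci = sorted(l for l in carriers if kind_of[l] in kinds)
    values = np.array(
        [[1 if s in carriers[l] else 0 for l in loci] for s in strains], dtype=np.int8
    )
    return PresenceAbsenceMatrix.from_arrays(values, strains, loci)


def simulate_study(
    tree_spec: str | Tree,
    layout: LayoutConfig | None = None,
    rates=45,
    probe_sd: float = 0.25,
    trend_amplitude: float = 0.0,
    seed: int = 0,
    **truth_kwargs,
):
    """Convenience wrapper: probe map + genealogy truth + one raw profile
    per strain, with per-strain noise seeds derived from ``seed``.

    Returns (probe_map, truth, {strain: RatioProfile}).
    """
    layout = layout or default_layout()
    probe_map = generate_probe_map(layout, seed=child_seed(seed, "probe-map"))
    truth = simulate_genealogy_truth(
        probe_map, tree_spec, rates, seed=child_seed(seed, "truth"), **truth_kwargs
    )
    tree = Tree.from_newick(tree_spec) if isinstance(tree_spec, str) else tree_spec
    profiles = {}
    for strain in tree.leaf_labels():
        noise = NoiseConfig(
            probe_sd=probe_sd,
            trend_amplitude=trend_amplitude,
            seed=child_seed(seed, f"profile:{strain}"),
        )
        mine = [t for t in truth if t.strain == strain]
        profiles[strain] = simulate_ratio_profile(probe_map, mine, noise, strain=strain)
    return probe_map, truth, profiles
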