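"""Cross-strain indel catalog: loci, markers, genes, and summary statistics.

Indel calls from different strains are matched into loci (alleles shared
by descent): two same-kind calls on the same chromosome match when they
overlap and both breakpoint probes lie within 3 probes of each other
(probe-index distance), or when one call's breakpoint probes both fall
inside the span of the other's flanking probes.  Locus identity is the
transitive closure of this pairwise relation (union-find), so it
partitions the calls even when chained matches exceed the pairwise
tolerance (such chains are logged).

Deletion loci become binary presence/absence markers for the population
analyses; amplifications are matched too but flagged position-unknown,
since the genomic location of the extra copies is not observable on the
array.  Gene annotation intersects the span of the breakpoint probes
with gene intervals: a gene entirely inside the span is wholly affected,
otherwise partially.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .popgen import PresenceAbsenceMatrix
from .probes import ProbeMap
from .segment import AMPLIFICATION, DELETION, IndelCall

logger = logging.getLogger(__name__)

__all__ = [
    "GeneAnnotation",
    "IndelLocus",
    "match_indel_alleles",
    "build_presence_absence",
    "annotate_genes",
    "assign_region",
    "summarize_catalog",
    "CatalogSummary",
    "run_length_and_count_tests",
    "StatsReport",
]


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval (1-based inclusive), biotype gene or pseudogene."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    biotype: str = "gene"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("gene start > end")


@dataclass
class IndelLocus:
    """An equivalence class of matched indel alleles across strains."""

    locus_id: str
    kind: str
    chromosome: str
    left_bp_probe: str
    right_bp_probe: str
    left_index: int
    right_index: int
    carrier_strains: set[str]
    member_calls: list[IndelCall]
    position_unknown: bool = False


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _call_indices(call: IndelCall, pm: ProbeMap):
    li = pm.index_of(call.left_bp_probe)
    ri = pm.index_of(call.right_bp_probe)
    lo, hi = pm.span(call.chromosome)
    # flanks are normal-ratio probes strictly outside the indel; a missing
    # flank (chromosome end) acts as a virtual probe just past the end
    lf = pm.index_of(call.left_flank_probe) if call.left_flank_probe else lo - 1
    rf = pm.index_of(call.right_flank_probe) if call.right_flank_probe else hi
    return li, ri, lf, rf


def _calls_match(a, b, tol: int) -> bool:
    (ali, ari, alf, arf), (bli, bri, blf, brf) = a, b
    overlap = ali <= bri and bli <= ari
    if overlap and abs(ali - bli) <= tol and abs(ari - bri) <= tol:
        return True
    # containment is strictly between the flanking probes (the flanks
    # themselves carry normal ratios)
    if blf < ali and ari < brf:
        return True
    if alf < bli and bri < arf:
        return True
    return False


def match_indel_alleles(
    calls: list[IndelCall], probe_map: ProbeMap, tolerance_probes: int = 3
) -> list[IndelLocus]:
    """Group all strains' calls into loci by transitive closure of the
    breakpoint-matching rule.  Canonical breakpoints are the modal left
    and right breakpoint probes among members (ties toward the leftmost).
    Loci are returned in genomic order."""
    for call in calls:
        if call.left_bp_probe not in probe_map.table["probe_id"].values:
            raise ValueError(f"call references probe {call.left_bp_probe!r} not in probe map")
    idx = [_call_indices(c, probe_map) for c in calls]
    uf = _UnionFind(len(calls))
    groups: dict[tuple, list[int]] = {}
    for i, c in enumerate(calls):
        groups.setdefault((c.kind, c.chromosome), []).append(i)
    for members in groups.values():
        members.sort(key=lambda i: idx[i][0])
        for a_pos, i in enumerate(members):
            for j in members[a_pos + 1 :]:
                if _calls_match(idx[i], idx[j], tolerance_probes):
                    uf.union(i, j)

    components: dict[int, list[int]] = {}
    for i in range(len(calls)):
        components.setdefault(uf.find(i), []).append(i)

    loci = []
    for members in components.values():
        lefts = [idx[i][0] for i in members]
        rights = [idx[i][1] for i in members]
        spread = max(lefts) - min(lefts)
        if spread > tolerance_probes:
            logger.info(
                "locus chain joins calls %d probes apart (beyond tolerance %d)",
                spread,
                tolerance_probes,
            )
        modal_left = sorted(Counter(lefts).items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        modal_right = sorted(Counter(rights).items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        first = calls[members[0]]
        loci.append(
            IndelLocus(
                locus_id="",
                kind=first.kind,
                chromosome=first.chromosome,
                left_bp_probe=str(probe_map.probe_ids[modal_left]),
                right_bp_probe=str(probe_map.probe_ids[modal_right]),
                left_index=modal_left,
                right_index=modal_right,
                carrier_strains={calls[i].strain for i in members},
                member_calls=[calls[i] for i in members],
                position_unknown=first.kind == AMPLIFICATION,
            )
        )
    loci.sort(key=lambda loc: loc.left_index)
    n_del = n_amp = 0
    for loc in loci:
        if loc.kind == DELETION:
            n_del += 1
            loc.locus_id = f"DL{n_del:04d}"
        else:
            n_amp += 1
            loc.locus_id = f"AM{n_amp:04d}"
    return loci


def build_presence_absence(
    loci: list[IndelLocus],
    strains: list[str],
    kinds: frozenset = frozenset({DELETION}),
) -> PresenceAbsenceMatrix:
    """Binary strain × locus matrix over the selected kinds (deletions by
    default, mirroring the exclusion of amplifications from the
    relatedness analysis).  Columns follow genomic order, rows the input
    strain order."""
    selected = [loc for loc in loci if loc.kind in kinds]
    if not selected:
        raise ValueError("no loci of the requested kinds")
    values = np.zeros((len(strains), len(selected)), dtype=np.int8)
    for j, loc in enumerate(selected):
        for i, s in enumerate(strains):
            if s in loc.carrier_strains:
                values[i, j] = 1
    return PresenceAbsenceMatrix.from_arrays(values, strains, [loc.locus_id for loc in selected])


def _span_of(item, probe_map: ProbeMap) -> tuple[str, int, int]:
    if isinstance(item, IndelLocus):
        return (
            item.chromosome,
            int(probe_map.starts[item.left_index]),
            int(probe_map.ends[item.right_index]),
        )
    return item.chromosome, item.start, item.end


def annotate_genes(
    locus_or_call, genes: list[GeneAnnotation], probe_map: ProbeMap
) -> list[tuple[str, str]]:
    """Genes overlapping the span of the breakpoint probes, each tagged
    ``wholly`` (gene interval contained in the span) or ``partially``."""
    chrom, start, end = _span_of(locus_or_call, probe_map)
    hits = []
    for g in genes:
        if g.chromosome != chrom or g.end < start or g.start > end:
            continue
        mode = "wholly" if (start <= g.start and g.end <= end) else "partially"
        hits.append((g.gene_id, mode, g))
    hits.sort(key=lambda h: h[2].start)
    return [(gid, mode) for gid, mode, _ in hits]


def assign_region(
    call, boundaries, probe_map: ProbeMap, x_chromosome: str = "X"
) -> str:
    """Arm/center/X label of a call or locus.

    ``boundaries`` is an iterable of (chromosome, start, end) arm
    intervals (1-based inclusive).  The region is decided by the midpoint
    of the left breakpoint probe; the X chromosome is always ``X`` and
    autosome positions outside every arm interval default to ``center``.
    """
    if isinstance(call, IndelLocus):
        li = call.left_index
    else:
        li = probe_map.index_of(call.left_bp_probe)
    chrom = probe_map.table["chromosome"].iloc[li]
    if chrom == x_chromosome:
        return "X"
    mid = (probe_map.starts[li] + probe_map.ends[li]) / 2.0
    for c, s, e in boundaries:
        if c == chrom and s <= mid <= e:
            return "arm"
    return "center"


# ---------------------------------------------------------------------------
# summaries

@dataclass
class CatalogSummary:
    """Per-strain counts and lengths, pairwise sharing, and totals."""

    per_strain: pd.DataFrame
    shared_deletions: pd.DataFrame
    sharing_spectrum: pd.DataFrame
    n_deletion_calls: int
    n_amplification_calls: int
    n_deletion_loci: int
    n_amplification_loci: int


def summarize_catalog(
    calls: list[IndelCall],
    loci: list[IndelLocus],
    strains: list[str],
    genes: list[GeneAnnotation] | None = None,
    probe_map: ProbeMap | None = None,
) -> CatalogSummary:
    """Study-level summary tables.

    ``per_strain`` counts each strain's deletion and amplification calls
    and its indel length median/mean/max (an indel present in several
    strains counts once in each).  ``shared_deletions`` is the symmetric
    strain × strain matrix of deletion loci carried by both (diagonal:
    loci per strain).  ``sharing_spectrum`` counts, per strain, deletion
    loci by the number of other strains carrying them.  Deleted gene and
    pseudogene counts are included when annotations are supplied.
    """
    rows = []
    for s in strains:
        mine = [c for c in calls if c.strain == s]
        lengths = [c.length_bp for c in mine]
        row = {
            "strain": s,
            "deletions": sum(c.kind == DELETION for c in mine),
            "amplifications": sum(c.kind == AMPLIFICATION for c in mine),
            "median_length": float(np.median(lengths)) if lengths else np.nan,
            "mean_length": float(np.mean(lengths)) if lengths else np.nan,
            "max_length": float(np.max(lengths)) if lengths else np.nan,
        }
        if genes is not None and probe_map is not None:
            hit: dict[str, str] = {}
            for loc in loci:
                if loc.kind == DELETION and s in loc.carrier_strains:
                    for gid, _mode in annotate_genes(loc, genes, probe_map):
                        hit[gid] = next(g.biotype for g in genes if g.gene_id == gid)
            row["deleted_genes"] = sum(b == "gene" for b in hit.values())
            row["deleted_pseudogenes"] = sum(b == "pseudogene" for b in hit.values())
        rows.append(row)
    per_strain = pd.DataFrame(rows).set_index("strain")

    del_loci = [loc for loc in loci if loc.kind == DELETION]
    shared = pd.DataFrame(0, index=strains, columns=strains, dtype=int)
    for loc in del_loci:
        carriers = [s for s in strains if s in loc.carrier_strains]
        for a in carriers:
            for b in carriers:
                shared.loc[a, b] += 1
    spectrum = pd.DataFrame(
        0, index=strains, columns=range(len(strains)), dtype=int
    )
    for loc in del_loci:
        carriers = [s for s in strains if s in loc.carrier_strains]
        k = len(carriers) - 1
        for s in carriers:
            spectrum.loc[s, k] += 1
    return CatalogSummary(
        per_strain=per_strain,
        shared_deletions=shared,
        sharing_spectrum=spectrum,
        n_deletion_calls=sum(c.kind == DELETION for c in calls),
        n_amplification_calls=sum(c.kind == AMPLIFICATION for c in calls),
        n_deletion_loci=len(del_loci),
        n_amplification_loci=sum(loc.kind == AMPLIFICATION for loc in loci),
    )


@dataclass
class StatsReport:
    """Chi-square, ANOVA and Welch t-test results over the catalog."""

    deletion_count_chi2: dict = field(default_factory=dict)
    amplification_count_chi2: dict = field(default_factory=dict)
    length_anova_by_strain: dict = field(default_factory=dict)
    length_anova_by_chromosome: dict = field(default_factory=dict)
    length_arm_vs_center_ttest: dict = field(default_factory=dict)


def _chi2_vs_probe_share(calls, probe_map: ProbeMap, kind: str) -> dict:
    chroms = probe_map.chromosomes
    observed = np.array(
        [sum(c.chromosome == ch and c.kind == kind for c in calls) for ch in chroms],
        dtype=float,
    )
    shares = np.array([probe_map.span(ch)[1] - probe_map.span(ch)[0] for ch in chroms], float)
    shares /= shares.sum()
    total = observed.sum()
    if total == 0:
        return {"chi2": np.nan, "df": len(chroms) - 1, "p": np.nan, "n": 0}
    expected = total * shares
    chi2, p = sps.chisquare(observed, expected)
    return {"chi2": float(chi2), "df": len(chroms) - 1, "p": float(p), "n": int(total)}


def _anova_by(calls, key) -> dict:
    groups: dict[str, list[float]] = {}
    for c in calls:
        groups.setdefault(key(c), []).append(c.length_bp)
    kept = {k: v for k, v in groups.items() if len(v) >= 2}
    dropped = sorted(set(groups) - set(kept))
    if dropped:
        warnings.warn(f"groups with < 2 indels dropped from ANOVA: {dropped}", stacklevel=3)
    if len(kept) < 2:
        return {"F": np.nan, "p": np.nan, "groups": len(kept)}
    f, p = sps.f_oneway(*kept.values())
    return {"F": float(f), "p": float(p), "groups": len(kept)}


def run_length_and_count_tests(
    calls: list[IndelCall],
    probe_map: ProbeMap,
    boundaries,
    x_chromosome: str = "X",
) -> StatsReport:
    """Distribution tests on the call catalog.

    (a) chi-square goodness-of-fit of per-chromosome deletion and
    amplification counts against probe-proportional expectations;
    (b) one-way ANOVA of raw midpoint-to-midpoint indel lengths by strain
    and by chromosome (indels in several strains count once per strain);
    (c) Welch's two-sample t-test of lengths on autosome arms vs
    centers plus the X chromosome.
    """
    report = StatsReport()
    report.deletion_count_chi2 = _chi2_vs_probe_share(calls, probe_map, DELETION)
    report.amplification_count_chi2 = _chi2_vs_probe_share(calls, probe_map, AMPLIFICATION)
    report.length_anova_by_strain = _anova_by(calls, lambda c: c.strain)
    report.length_anova_by_chromosome = _anova_by(calls, lambda c: c.chromosome)
    arm, other = [], []
    for c in calls:
        region = assign_region(c, boundaries, probe_map, x_chromosome)
        (arm if region == "arm" else other).append(c.length_bp)
    if len(arm) >= 2 and len(other) >= 2:
        t, p = sps.ttest_ind(arm, other, equal_var=False)
        report.length_arm_vs_center_ttest = {
            "t": float(t),
            "p": float(p),
            "mean_arm": float(np.mean(arm)),
            "mean_other": float(np.mean(other)),
            "n_arm": len(arm),
            "n_other": len(other),
        }
    else:
        report.length_arm_vs_center_ttest = {"t": np.nan, "p": np.nan}
    return report
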