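"""Readers and writers for every on-disk format the pipeline touches.

Coordinate dialects: GFF3 and the ratio/probe TSVs are 1-based inclusive;
BED is 0-based half-open; the in-memory representation is 1-based
inclusive.  Writers are deterministic given identical inputs (no
timestamps inside data files), and each reader rejects, with a
line-numbered message, files its paired writer would not produce.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catalog import GeneAnnotation
from .popgen import PresenceAbsenceMatrix
from .probes import ProbeMap, RatioProfile
from .segment import CallingParameters, IndelCall
from .synthetic import TruthIndel
from .trees import Tree

__all__ = [
    "read_probe_map",
    "write_probe_map",
    "read_ratio_table",
    "write_ratio_table",
    "write_calls_gff3",
    "read_calls_gff3",
    "write_calls_bed",
    "write_truth_gff3",
    "read_genes_gff3",
    "write_genes_gff3",
    "read_arm_bed",
    "write_arm_bed",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "write_newick",
    "read_newick",
    "read_config",
    "write_config",
]

_RATIO_COLUMNS = ["probe_id", "chromosome", "start", "end", "test_intensity", "ref_intensity"]


def _atomic_write(path, text: str):
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    tmp.replace(path)


# ---------------------------------------------------------------------------
# probe map (BED-like TSV: 0-based half-open on disk)

def write_probe_map(probe_map: ProbeMap, path):
    lines = ["# cghindel probe map; BED-like: 0-based half-open coordinates"]
    lines.append("chromosome\tstart\tend\tprobe_id\tregion")
    t = probe_map.table
    for row in t.itertuples(index=False):
        lines.append(f"{row.chromosome}\t{row.start - 1}\t{row.end}\t{row.probe_id}\t{row.region}")
    _atomic_write(path, "\n".join(lines) + "\n")


def read_probe_map(path) -> ProbeMap:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chromosome", "start", "end", "probe_id", "region"}
    if not required <= set(df.columns):
        raise ValueError(f"probe map missing columns: {sorted(required - set(df.columns))}")
    df = df.rename(columns={"start": "start0"})
    df["start"] = df["start0"] + 1  # back to 1-based inclusive
    return ProbeMap(df[["probe_id", "chromosome", "start", "end", "region"]])


# ---------------------------------------------------------------------------
# ratio tables (1-based inclusive TSV)

def write_ratio_table(profile: RatioProfile, path):
    pm = profile.probe_map
    lines = [
        "# cghindel ratio table; 1-based inclusive coordinates",
        f"# strain={profile.strain} normalized={int(profile.normalized)}",
        "\t".join(_RATIO_COLUMNS + ["log2_ratio"]),
    ]
    test = profile.test_intensity
    ref = profile.ref_intensity
    for i in range(len(pm)):
        ti = f"{test[i]:.6g}" if test is not None else "NA"
        ri = f"{ref[i]:.6g}" if ref is not None else "NA"
        lines.append(
            f"{pm.probe_ids[i]}\t{pm.table['chromosome'].iloc[i]}\t{pm.starts[i]}\t"
            f"{pm.ends[i]}\t{ti}\t{ri}\t{float(profile.log2_ratio[i])!r}"
        )
    _atomic_write(path, "\n".join(lines) + "\n")


def read_ratio_table(path, strain: str | None = None) -> tuple[RatioProfile, ProbeMap]:
    """Read a ratio TSV; returns the profile and its probe-map fragment.

    A missing ``log2_ratio`` column is computed from the intensities.
    Unsorted input is sorted with a warning; a duplicate probe id or a
    non-numeric intensity is a hard error naming the offender.
    """
    path = Path(path)
    meta = {}
    n_header_comments = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header_comments += 1
            for token in line[1:].split():
                if "=" in token:
                    k, v = token.split("=", 1)
                    meta[k] = v
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"probe_id": str, "chromosome": str})
    missing = [c for c in _RATIO_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"ratio table missing columns: {missing}")
    dup = df["probe_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate probe id {df.loc[dup, 'probe_id'].iloc[0]!r}")
    have_intensities = {"test_intensity", "ref_intensity"} <= set(df.columns) and not (
        df["test_intensity"].astype(str).str.upper().eq("NA").all()
    )
    for col in ("test_intensity", "ref_intensity"):
        if col in df.columns and have_intensities:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                line_no = int(bad.idxmax()) + n_header_comments + 2  # +header +1-based
                raise ValueError(f"non-numeric {col} at line {line_no}: {df[col][bad].iloc[0]!r}")
            df[col] = coerced
    if "log2_ratio" not in df.columns:
        if not have_intensities:
            raise ValueError("ratio table has neither log2_ratio nor intensities")
        df["log2_ratio"] = np.log2(df["test_intensity"] / df["ref_intensity"])
    sorted_df = df.sort_values(
        ["chromosome", "start"],
        kind="mergesort",
        key=lambda s: s.map({c: i for i, c in enumerate(pd.unique(df["chromosome"]))})
        if s.name == "chromosome"
        else s,
    )
    if not sorted_df.index.equals(df.index):
        warnings.warn(f"{path.name}: probes were not sorted; sorting", stacklevel=2)
        df = sorted_df.reset_index(drop=True)
    if (df["start"] < 1).any():
        raise ValueError("coordinates must be 1-based (start >= 1)")
    pm = ProbeMap(df[["probe_id", "chromosome", "start", "end"]].assign(region="center"))
    profile = RatioProfile(
        strain=strain or meta.get("strain", path.stem),
        probe_map=pm,
        log2_ratio=df["log2_ratio"].to_numpy(),
        test_intensity=df["test_intensity"].to_numpy() if have_intensities else None,
        ref_intensity=df["ref_intensity"].to_numpy() if have_intensities else None,
        normalized=bool(int(meta.get("normalized", "0"))),
    )
    return profile, pm


# ---------------------------------------------------------------------------
# calls as GFF3 / BED

_CALL_ATTRS = [
    ("strain", str),
    ("mean_log2", float),
    ("p_value", float),
    ("n_probes", int),
    ("left_bp_probe", str),
    ("right_bp_probe", str),
    ("left_flank_probe", str),
    ("right_flank_probe", str),
    ("length_bp", float),
]


def write_calls_gff3(calls: list[IndelCall], path):
    lines = [
        "##gff-version 3",
        "# cghindel indel calls; 1-based inclusive coordinates",
    ]
    for k, call in enumerate(calls):
        attrs = [f"ID=call{k:05d}"]
        for name, _ in _CALL_ATTRS:
            v = getattr(call, name)
            if v is None:
                v = "NA"
            elif isinstance(v, float):
                v = repr(float(v))
            attrs.append(f"{name}={v}")
        lines.append(
            f"{call.chromosome}\tcgh-indel\t{call.kind}\t{call.start}\t{call.end}"
            f"\t.\t.\t.\t{';'.join(attrs)}"
        )
    _atomic_write(path, "\n".join(lines) + "\n")


def read_calls_gff3(path) -> list[IndelCall]:
    calls = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"line {line_no}: expected 9 GFF3 columns, got {len(fields)}")
            chrom, _source, kind, start, end, _score, _strand, _phase, attr_s = fields
            attrs = {}
            for item in attr_s.split(";"):
                if "=" not in item:
                    raise ValueError(f"line {line_no}: malformed attribute {item!r}")
                k, v = item.split("=", 1)
                attrs[k] = v
            try:
                kwargs = {}
                for name, typ in _CALL_ATTRS:
                    raw = attrs[name]
                    kwargs[name] = None if raw == "NA" else typ(raw)
            except KeyError as e:
                raise ValueError(f"line {line_no}: missing attribute {e}") from None
            calls.append(
                IndelCall(
                    chromosome=chrom,
                    kind=kind,
                    start=int(start),
                    end=int(end),
                    **kwargs,
                )
            )
    return calls


def write_calls_bed(calls: list[IndelCall], path):
    lines = ["# cghindel indel calls; BED: 0-based half-open coordinates"]
    for k, call in enumerate(calls):
        score = min(1000, int(round(-10 * math.log10(max(call.p_value, 1e-100)))))
        lines.append(
            f"{call.chromosome}\t{call.start - 1}\t{call.end}\t"
            f"{call.strain}.{call.kind}.{k:05d}\t{score}"
        )
    _atomic_write(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# truth set

def write_truth_gff3(truth: list[TruthIndel], path):
    lines = ["##gff-version 3", "# cghindel simulated truth; 1-based inclusive"]
    for t in truth:
        attrs = (
            f"strain={t.strain};locus_id={t.locus_id};kind={t.kind};signal={float(t.signal_log2)!r}"
        )
        lines.append(f"{t.chromosome}\tcgh-sim\t{t.kind}\t{t.start}\t{t.end}\t.\t.\t.\t{attrs}")
    _atomic_write(path, "\n".join(lines) + "\n")


def read_truth_gff3(path) -> list[TruthIndel]:
    truth = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"line {line_no}: expected 9 GFF3 columns")
            attrs = dict(item.split("=", 1) for item in fields[8].split(";"))
            truth.append(
                TruthIndel(
                    strain=attrs["strain"],
                    chromosome=fields[0],
                    start=int(fields[3]),
                    end=int(fields[4]),
                    kind=attrs["kind"],
                    signal_log2=float(attrs["signal"]),
                    locus_id=attrs["locus_id"],
                )
            )
    return truth


# ---------------------------------------------------------------------------
# genes

def read_genes_gff3(path) -> list[GeneAnnotation]:
    """Genes and pseudogenes from GFF3 (feature types gene/pseudogene, or
    a biotype attribute)."""
    genes = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"line {line_no}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, _strand, _phase, attr_s = fields
            if ftype not in ("gene", "pseudogene"):
                continue
            attrs = dict(item.split("=", 1) for item in attr_s.split(";") if "=" in item)
            gid = attrs.get("ID") or attrs.get("gene_id")
            if gid is None:
                raise ValueError(f"line {line_no}: gene feature without ID")
            biotype = attrs.get("biotype", ftype)
            genes.append(GeneAnnotation(gid, chrom, int(start), int(end), biotype))
    return genes


def write_genes_gff3(genes: list[GeneAnnotation], path):
    lines = ["##gff-version 3"]
    for g in genes:
        lines.append(
            f"{g.chromosome}\tcghindel\t{g.biotype}\t{g.start}\t{g.end}\t.\t.\t.\t"
            f"ID={g.gene_id};biotype={g.biotype}"
        )
    _atomic_write(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# arm boundaries

def read_arm_bed(path) -> list[tuple[str, int, int]]:
    """Arm intervals from BED (0-based half-open on disk → 1-based incl.)."""
    out = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {line_no}: BED needs at least 3 columns")
            out.append((fields[0], int(fields[1]) + 1, int(fields[2])))
    return out


def write_arm_bed(boundaries, path):
    lines = ["# arm intervals; BED: 0-based half-open"]
    for chrom, start, end in boundaries:
        lines.append(f"{chrom}\t{start - 1}\t{end}\tarm")
    _atomic_write(path, "\n".join(lines) + "\n")


def arm_bed_from_probe_map(probe_map: ProbeMap) -> list[tuple[str, int, int]]:
    """Arm intervals implied by a probe map's region labels (contiguous
    runs of 'arm' probes, extended to the chromosome ends)."""
    out = []
    t = probe_map.table
    for chrom in probe_map.chromosomes:
        lo, hi = probe_map.span(chrom)
        regions = probe_map.regions[lo:hi]
        starts = probe_map.starts[lo:hi]
        ends = probe_map.ends[lo:hi]
        run_start = None
        for i in range(len(regions)):
            if regions[i] == "arm" and run_start is None:
                run_start = int(starts[i])
            if regions[i] != "arm" and run_start is not None:
                out.append((chrom, run_start, int(ends[i - 1])))
                run_start = None
        if run_start is not None:
            out.append((chrom, run_start, int(ends[-1])))
    return out


# ---------------------------------------------------------------------------
# presence/absence matrix

def write_matrix_tsv(matrix: PresenceAbsenceMatrix, path):
    text = "strain\t" + "\t".join(matrix.loci) + "\n"
    for s in matrix.strains:
        row = matrix.data.loc[s]
        text += s + "\t" + "\t".join(str(int(v)) for v in row) + "\n"
    _atomic_write(path, text)


def read_matrix_tsv(path) -> PresenceAbsenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PresenceAbsenceMatrix(df)


# ---------------------------------------------------------------------------
# loci

def write_loci_tsv(loci, path):
    from .catalog import IndelLocus  # noqa: F401  (documented shape)

    lines = [
        "locus_id\tkind\tchromosome\tleft_bp_probe\tright_bp_probe\t"
        "carriers\tn_members\tposition_unknown"
    ]
    for loc in loci:
        carriers = ",".join(sorted(loc.carrier_strains))
        lines.append(
            f"{loc.locus_id}\t{loc.kind}\t{loc.chromosome}\t{loc.left_bp_probe}\t"
            f"{loc.right_bp_probe}\t{carriers}\t{len(loc.member_calls)}\t"
            f"{int(loc.position_unknown)}"
        )
    _atomic_write(path, "\n".join(lines) + "\n")


def read_loci_tsv(path, probe_map: ProbeMap):
    from .catalog import IndelLocus

    df = pd.read_csv(path, sep="\t", dtype={"carriers": str})
    loci = []
    for row in df.itertuples(index=False):
        loci.append(
            IndelLocus(
                locus_id=row.locus_id,
                kind=row.kind,
                chromosome=row.chromosome,
                left_bp_probe=row.left_bp_probe,
                right_bp_probe=row.right_bp_probe,
                left_index=probe_map.index_of(row.left_bp_probe),
                right_index=probe_map.index_of(row.right_bp_probe),
                carrier_strains=set(str(row.carriers).split(",")),
                member_calls=[],
                position_unknown=bool(row.position_unknown),
            )
        )
    return loci


# ---------------------------------------------------------------------------
# trees

def write_newick(tree: Tree, path):
    _atomic_write(path, tree.to_newick() + "\n")


def read_newick(path) -> Tree:
    return Tree.from_newick(Path(path).read_text())


# ---------------------------------------------------------------------------
# pipeline config

def calling_parameters_from_config(cfg: dict) -> CallingParameters:
    kwargs = {}
    for name in CallingParameters.__dataclass_fields__:
        if name in cfg:
            kwargs[name] = cfg[name]
    return CallingParameters(**kwargs)


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def write_config(cfg: dict, path):
    _atomic_write(path, yaml.safe_dump(cfg, sort_keys=True))
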