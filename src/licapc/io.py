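"""Readers, writers and the end-to-end pipeline driver.

All genomic coordinates are 0-based half-open internally; BED and bedGraph
are read/written as-is, SAM positions are converted from 1-based on ingest
(via pysam). Tabular dialects (read slices, truth, classified reads, qPCR,
count tables) are plain TSV handled with pandas. bedGraph values are written
with at most 6 significant decimals.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .classify import (
    ClassifiedRead,
    Slice,
    classify_reads,
    default_exclusion,
    DEFAULT_EXCLUSION_BP,
)
from .dedup import filter_duplicates
from .profile import (
    DEFAULT_SCALE,
    DEFAULT_WINDOW,
    InteractionProfile,
    build_profile,
    normalize_profile,
    window_profile,
)
from .qc_stats import cis_fraction, fragments_per_read
from .restriction_map import FragmentMap, digest_reference
from .sim3c import READ_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "read_fasta",
    "write_fasta",
    "write_fragment_map_bed",
    "read_fragment_map_bed",
    "read_targets_bed",
    "read_exclusion_bed",
    "read_reads_tsv",
    "write_reads_tsv",
    "read_sam",
    "write_bedgraph",
    "read_bedgraph",
    "write_profile_tsv",
    "write_classified_tsv",
    "read_classified_tsv",
    "read_qpcr_tsv",
    "read_count_table",
    "write_count_table",
    "write_fastq",
    "PipelineConfig",
    "load_pipeline_config",
    "run_pipeline",
]


class FormatError(ValueError):
    """Malformed input line, with file and line context."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path) -> dict[str, str]:
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not genome:
        raise FormatError(path, 0, "no FASTA records found")
    return genome


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads: pd.DataFrame, genome: Mapping[str, str], path) -> None:
    """Interoperability-only FASTQ writer: the sequence of each read is the
    concatenation of its slice sequences; qualities are constant."""
    with open(path, "w") as fh:
        for read_id, grp in reads.sort_values(["read_id", "slice_index"]).groupby(
            "read_id", sort=False
        ):
            seq = "".join(
                str(genome[r.chrom])[int(r.start) : int(r.end)]
                for r in grp.itertuples()
            )
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# BED

def write_fragment_map_bed(fmap: FragmentMap, path) -> None:
    """Fragment map as sorted BED4 (chrom, start, end, fragment id)."""
    with open(path, "w") as fh:
        for f in fmap:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.id}\n")


def _parse_bed_line(path, lineno: int, line: str, min_fields: int) -> list[str]:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < min_fields:
        raise FormatError(path, lineno, f"expected >= {min_fields} BED fields")
    try:
        int(fields[1]), int(fields[2])
    except ValueError:
        raise FormatError(path, lineno, "non-integer BED coordinates") from None
    return fields


def read_fragment_map_bed(path) -> FragmentMap:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    ids: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            fields = _parse_bed_line(path, lineno, line, 4)
            by_chrom.setdefault(fields[0], []).append(
                (int(fields[1]), int(fields[2]))
            )
            ids.append(int(fields[3]))
    fmap = FragmentMap(by_chrom)
    if ids != [f.id for f in fmap]:
        raise FormatError(path, 0, "fragment ids are not sequential in map order")
    return fmap


def read_targets_bed(path, fmap: FragmentMap) -> dict[str, set[int]]:
    """Targets BED with name column ``group:member``; each interval is
    located on the fragment map and the fragment joins the group's target
    set."""
    targets: dict[str, set[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            fields = _parse_bed_line(path, lineno, line, 4)
            group = fields[3].split(":", 1)[0]
            fid = fmap.locate(fields[0], int(fields[1]), int(fields[2]))
            if fid is None:
                raise FormatError(
                    path, lineno, f"target interval not on fragment map: {line.strip()}"
                )
            targets.setdefault(group, set()).add(fid)
    if not targets:
        raise FormatError(path, 0, "no target intervals found")
    return targets


def read_exclusion_bed(path) -> dict[str, list[tuple[str, int, int]]]:
    """Exclusion BED with name column = viewpoint group."""
    exclusion: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            fields = _parse_bed_line(path, lineno, line, 4)
            exclusion.setdefault(fields[3], []).append(
                (fields[0], int(fields[1]), int(fields[2]))
            )
    return exclusion


# ---------------------------------------------------------------------------
# read-slice tables (sim3c TSV dialect) and SAM

def write_reads_tsv(reads: pd.DataFrame, path) -> None:
    reads.to_csv(path, sep="\t", index=False)


def read_reads_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(READ_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(path, 1, f"missing columns: {sorted(missing)}")
    return df


def read_sam(path, min_mapq: int = 0) -> pd.DataFrame:
    """SAM ingest: each aligned record is one slice, grouped by query name
    in file order; 1-based positions become 0-based half-open."""
    rows = []
    slice_counters: dict[str, int] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.mapping_quality < min_mapq:
                continue
            idx = slice_counters.get(rec.query_name, 0)
            slice_counters[rec.query_name] = idx + 1
            rows.append(
                (
                    rec.query_name,
                    idx,
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                )
            )
    return pd.DataFrame(rows, columns=READ_COLUMNS)


# ---------------------------------------------------------------------------
# classified reads

_CLASSIFIED_COLUMNS = [
    "read_id",
    "slice_index",
    "chrom",
    "start",
    "end",
    "strand",
    "fragment_id",
    "viewpoint",
    "status",
    "role",
]


def write_classified_tsv(reads: Sequence[ClassifiedRead], path) -> None:
    rows = []
    for r in reads:
        capture_set, reporter_set = set(r.capture_ids), set(r.reporter_ids)
        for i, s in enumerate(r.slices):
            if r.viewpoint is None:
                role = "none"
            elif s.fragment_id in capture_set:
                role = "capture"
            elif s.fragment_id in reporter_set:
                role = "reporter"
            else:
                role = "excluded"
            rows.append(
                (
                    r.read_id,
                    i,
                    s.chrom,
                    s.start,
                    s.end,
                    s.strand,
                    s.fragment_id,
                    r.viewpoint or ".",
                    r.status,
                    role,
                )
            )
    pd.DataFrame(rows, columns=_CLASSIFIED_COLUMNS).to_csv(path, sep="\t", index=False)


def read_classified_tsv(path) -> list[ClassifiedRead]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_CLASSIFIED_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(path, 1, f"missing columns: {sorted(missing)}")
    out: list[ClassifiedRead] = []
    for read_id, grp in df.sort_values(["read_id", "slice_index"]).groupby(
        "read_id", sort=False
    ):
        grp = grp.reset_index(drop=True)
        slices = [
            Slice(r.chrom, int(r.start), int(r.end), str(r.strand), int(r.fragment_id))
            for r in grp.itertuples()
        ]
        viewpoint = None if grp["viewpoint"].iloc[0] == "." else str(
            grp["viewpoint"].iloc[0]
        )
        reporters = tuple(
            dict.fromkeys(
                int(r.fragment_id) for r in grp.itertuples() if r.role == "reporter"
            )
        )
        captures = tuple(
            dict.fromkeys(
                int(r.fragment_id) for r in grp.itertuples() if r.role == "capture"
            )
        )
        out.append(
            ClassifiedRead(
                read_id=str(read_id),
                slices=slices,
                viewpoint=viewpoint,
                n_capture=int((grp["role"] == "capture").sum()),
                reporter_ids=reporters,
                n_excluded=int((grp["role"] == "excluded").sum()),
                status=str(grp["status"].iloc[0]),
                capture_ids=captures,
            )
        )
    return out


# ---------------------------------------------------------------------------
# bedGraph / profile TSV

def _fmt(v: float) -> str:
    return f"{v:.6g}"


def write_bedgraph(profile: InteractionProfile, path) -> None:
    """One bedGraph track per profile; the track line records the viewpoint
    group and profile kind."""
    with open(path, "w") as fh:
        fh.write(
            f'track type=bedGraph name="{profile.group}" '
            f'description="kind={profile.kind}"\n'
        )
        for f in profile.fmap:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{_fmt(profile.values[f.id])}\n")


def read_bedgraph(path, fmap: FragmentMap) -> InteractionProfile:
    values = np.zeros(fmap.n_fragments)
    group, kind = "unknown", "raw"
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("track"):
                if 'name="' in line:
                    group = line.split('name="')[1].split('"')[0]
                if "kind=" in line:
                    kind = line.split("kind=")[1].split('"')[0]
                continue
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise FormatError(path, lineno, "expected 4 bedGraph fields")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError:
                raise FormatError(path, lineno, "malformed bedGraph values") from None
            fid = fmap.locate(fields[0], start, end)
            if fid is None:
                raise FormatError(path, lineno, "interval not on fragment map")
            values[fid] = value
    return InteractionProfile(group, values, kind, fmap)


def write_profile_tsv(profile: InteractionProfile, path) -> None:
    rows = []
    se = profile.se if profile.se is not None else np.zeros(len(profile.values))
    for f in profile.fmap:
        rows.append(
            (f.id, f.chrom, f.start, f.end, profile.values[f.id], se[f.id])
        )
    pd.DataFrame(
        rows, columns=["fragment_id", "chrom", "start", "end", "value", "se"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# qPCR and count tables

def read_qpcr_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "assay", "template", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(path, 1, f"missing columns: {sorted(missing)}")
    if (df["ct"] <= 0).any():
        raise FormatError(path, 0, "Ct values must be > 0")
    return df


def read_count_table(counts_path, samples_path):
    from .cstring import CountTable

    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    if "input_mass_ug" not in samples.columns:
        raise FormatError(samples_path, 1, "missing column: input_mass_ug")
    return CountTable(counts, samples)


def write_count_table(table, counts_path, samples_path) -> None:
    table.counts.to_csv(counts_path, sep="\t")
    table.samples.to_csv(samples_path, sep="\t")


# ---------------------------------------------------------------------------
# pipeline driver

@dataclass
class PipelineConfig:
    """Configuration of an end-to-end run: digest -> classify -> dedup ->
    profile -> QC."""

    genome_fasta: str
    targets_bed: str
    reads: str  # read-slice TSV or SAM
    out_dir: str
    exclusion_bed: str | None = None
    motif: str = "GATC"
    max_wobble: int = 2
    scale: float = DEFAULT_SCALE
    window: int = DEFAULT_WINDOW
    exclusion_bp: int = DEFAULT_EXCLUSION_BP
    min_mapq: int = 0
    seed: int = 0

    def validate(self) -> None:
        for label, p in [
            ("genome_fasta", self.genome_fasta),
            ("targets_bed", self.targets_bed),
            ("reads", self.reads),
        ]:
            if not Path(p).exists():
                raise ValueError(f"{label} path does not exist: {p}")
        if self.exclusion_bed and not Path(self.exclusion_bed).exists():
            raise ValueError(f"exclusion_bed path does not exist: {self.exclusion_bed}")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be an odd fragment count >= 1")
        if self.max_wobble < 0:
            raise ValueError("max_wobble must be >= 0")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.exclusion_bp < 0:
            raise ValueError("exclusion_bp must be >= 0")


def load_pipeline_config(path, **overrides) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run digest -> classify -> dedup -> profile -> QC and write all outputs
    plus a machine-readable run manifest. Deterministic given the config.

    Returns the manifest dict. On stage failure the manifest (with the failed
    stage marked) is still written and the exception re-raised; outputs of
    completed stages are left intact.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "manifest_schema": 1,
        "config": dataclasses.asdict(config),
        "stages": [],
    }
    manifest_path = out / "manifest.json"

    def record(stage: str, **info) -> None:
        manifest["stages"].append({"stage": stage, "status": "ok", **info})

    try:
        genome = read_fasta(config.genome_fasta)
        fmap = digest_reference(genome, config.motif)
        write_fragment_map_bed(fmap, out / "fragments.bed")
        record("digest", n_fragments=fmap.n_fragments, output="fragments.bed")

        if str(config.reads).endswith(".sam"):
            reads_df = read_sam(config.reads, config.min_mapq)
        else:
            reads_df = read_reads_tsv(config.reads)
        targets = read_targets_bed(config.targets_bed, fmap)
        if config.exclusion_bed:
            exclusion = read_exclusion_bed(config.exclusion_bed)
        else:
            exclusion = default_exclusion(fmap, targets, config.exclusion_bp)
        classified, n_dropped = classify_reads(reads_df, targets, exclusion, fmap)
        write_classified_tsv(classified, out / "classified.tsv")
        status_counts = (
            pd.Series([r.status for r in classified]).value_counts().to_dict()
        )
        record(
            "classify",
            n_reads=len(classified),
            n_dropped=n_dropped,
            status_counts=status_counts,
            output="classified.tsv",
        )

        qc: dict = {"viewpoints": {}}
        mean_fpr, fpr_hist = fragments_per_read(classified)
        qc["fragments_per_read_mean"] = mean_fpr
        qc["fragments_per_read_hist"] = {str(k): v for k, v in fpr_hist.items()}

        dedup_reports = {}
        for group in sorted(targets):
            group_reads = [
                r for r in classified if r.viewpoint == group and r.informative
            ]
            unique_reads, report = filter_duplicates(group_reads, config.max_wobble)
            dedup_reports[group] = report.to_dict()

            raw = build_profile(unique_reads, fmap, group)
            vp_chrom = fmap.chrom_of(next(iter(targets[group])))
            group_qc: dict = {"unique_interactions": raw.total}
            if raw.total > 0:
                norm = normalize_profile(raw, config.scale)
                win = window_profile(norm, config.window)
                write_bedgraph(raw, out / f"{group}.raw.bedgraph")
                write_bedgraph(norm, out / f"{group}.normalized.bedgraph")
                write_bedgraph(win, out / f"{group}.windowed.bedgraph")
                write_profile_tsv(norm, out / f"{group}.normalized.tsv")
                group_qc["cis_percent"] = cis_fraction(unique_reads, fmap, vp_chrom)
            qc["viewpoints"][group] = group_qc
            record(
                "profile",
                group=group,
                unique_interactions=raw.total,
                outputs=[f"{group}.{k}.bedgraph" for k in ("raw", "normalized", "windowed")],
            )

        qc["dedup"] = dedup_reports
        with open(out / "qc.json", "w") as fh:
            json.dump(qc, fh, indent=2, sort_keys=True)
        record("qc", output="qc.json")
    except Exception as e:
        manifest["stages"].append({"stage": "failed", "status": "error", "error": str(e)})
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise

    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
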