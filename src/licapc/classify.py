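"""Classification of aligned read slices into Capture-C interactions.

A sequenced molecule maps as an ordered list of slices, one per restriction
fragment it traverses. Slices landing on a targeted viewpoint fragment are
*capture* slices; slices inside the viewpoint's proximity-exclusion zone are
*excluded*; everything else is a *reporter* — one reporter fragment equals
one interaction.

Duplicated-gene promoters (e.g. the two alpha-globin genes) cannot be
distinguished, so viewpoints are declared as groups: a hit to any member of a
group is a capture slice of that group and never triggers double-capture.
Reads hitting targets of two distinct groups are flagged double-capture and
not counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .restriction_map import FragmentMap
from .sim3c import READ_COLUMNS

logger = logging.getLogger(__name__)

__all__ = [
    "Slice",
    "ClassifiedRead",
    "classify_read",
    "classify_reads",
    "default_exclusion",
    "reads_from_table",
]

DEFAULT_EXCLUSION_BP = 1000


@dataclass(frozen=True)
class Slice:
    chrom: str
    start: int
    end: int
    strand: str = "+"
    fragment_id: int | None = None


@dataclass
class ClassifiedRead:
    """One classified sequenced molecule."""

    read_id: str
    slices: list[Slice]
    viewpoint: str | None
    n_capture: int
    reporter_ids: tuple[int, ...]
    n_excluded: int
    status: str  # informative | no-reporter | no-capture | double-capture
    capture_ids: tuple[int, ...] = ()

    @property
    def informative(self) -> bool:
        return self.status == "informative"

    @property
    def n_slices(self) -> int:
        return len(self.slices)


def default_exclusion(
    fmap: FragmentMap,
    targets: Mapping[str, set[int]],
    pad: int = DEFAULT_EXCLUSION_BP,
) -> dict[str, list[tuple[str, int, int]]]:
    """Per-group exclusion intervals: each viewpoint fragment +/- ``pad`` bp.

    The size of the proximity-exclusion zone is a tunable convention, not a
    measured quantity; 1 kb is the default and is configurable per viewpoint.
    """
    exclusion: dict[str, list[tuple[str, int, int]]] = {}
    for group, fids in targets.items():
        ivals = []
        for fid in sorted(fids):
            f = fmap.fragment(fid)
            ivals.append(
                (f.chrom, max(0, f.start - pad), min(fmap.chrom_size(f.chrom), f.end + pad))
            )
        exclusion[group] = ivals
    return exclusion


def _overlaps(s: Slice, intervals: Sequence[tuple[str, int, int]]) -> bool:
    return any(
        s.chrom == chrom and s.start < end and s.end > start
        for chrom, start, end in intervals
    )


def classify_read(
    read_id: str,
    slices: Sequence[Slice],
    targets: Mapping[str, set[int]],
    exclusion: Mapping[str, Sequence[tuple[str, int, int]]],
    fmap: FragmentMap,
) -> ClassifiedRead:
    """Classify the ordered slices of one read.

    Raises ``ValueError`` if any slice cannot be located on the fragment map
    (callers batch-classifying should drop and log such reads).
    """
    located: list[Slice] = []
    for s in slices:
        fid = fmap.locate(s.chrom, s.start, s.end)
        if fid is None:
            raise ValueError(
                f"read {read_id}: slice {s.chrom}:{s.start}-{s.end} not on fragment map"
            )
        located.append(Slice(s.chrom, s.start, s.end, s.strand, fid))

    hit_groups = sorted(
        {g for g, fids in targets.items() for s in located if s.fragment_id in fids}
    )
    if len(hit_groups) >= 2:
        return ClassifiedRead(read_id, located, None, 0, (), 0, "double-capture")
    if not hit_groups:
        return ClassifiedRead(read_id, located, None, 0, (), 0, "no-capture")

    group = hit_groups[0]
    target_fids = targets[group]
    excl = exclusion.get(group, ())
    n_capture = 0
    n_excluded = 0
    reporters: list[int] = []
    captures: list[int] = []
    for s in located:
        if s.fragment_id in target_fids:
            n_capture += 1
            if s.fragment_id not in captures:
                captures.append(s.fragment_id)
        elif _overlaps(s, excl):
            n_excluded += 1
        elif s.fragment_id not in reporters:
            reporters.append(s.fragment_id)
    status = "informative" if reporters else "no-reporter"
    return ClassifiedRead(
        read_id,
        located,
        group,
        n_capture,
        tuple(reporters),
        n_excluded,
        status,
        tuple(captures),
    )


def reads_from_table(reads: pd.DataFrame) -> Iterable[tuple[str, list[Slice]]]:
    """Group a read-fragment slice table (``sim3c`` dialect) into per-read
    ordered slice lists."""
    missing = set(READ_COLUMNS) - set(reads.columns)
    if missing:
        raise ValueError(f"read table missing columns: {sorted(missing)}")
    for read_id, grp in reads.sort_values(["read_id", "slice_index"]).groupby(
        "read_id", sort=False
    ):
        yield str(read_id), [
            Slice(r.chrom, int(r.start), int(r.end), str(r.strand))
            for r in grp.itertuples()
        ]


def classify_reads(
    reads: pd.DataFrame | Iterable[tuple[str, list[Slice]]],
    targets: Mapping[str, set[int]],
    exclusion: Mapping[str, Sequence[tuple[str, int, int]]],
    fmap: FragmentMap,
) -> tuple[list[ClassifiedRead], int]:
    """Classify a batch of reads; returns (classified reads, n dropped).

    Reads with unlocatable slices are dropped with a logged reason.
    """
    if isinstance(reads, pd.DataFrame):
        reads = reads_from_table(reads)
    out: list[ClassifiedRead] = []
    n_dropped = 0
    for read_id, slices in reads:
        try:
            out.append(classify_read(read_id, slices, targets, exclusion, fmap))
        except ValueError as e:
            logger.warning("dropped read: %s", e)
            n_dropped += 1
    return out, n_dropped
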