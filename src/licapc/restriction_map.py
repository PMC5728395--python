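"""In-silico restriction digestion of a reference genome.

The genome is partitioned into restriction fragments at every occurrence of
the enzyme recognition motif (DpnII/GATC by default). The resulting
:class:`FragmentMap` is the coordinate system used by every downstream
interaction profile: interactions are counted per restriction fragment, not
per base pair.

Conventions
-----------
* Coordinates are 0-based, half-open throughout.
* The cut is placed at the *first* base of each motif occurrence, so every
  fragment (except the first of a chromosome) starts with the motif.
* Motif scanning is case-insensitive; ``N`` bases in the genome never match,
  so masked regions produce no cuts.
* Zero-length fragments (a cut at position 0, or overlapping motifs) are
  suppressed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Fragment",
    "FragmentMap",
    "digest_reference",
    "digest_read",
    "find_cut_sites",
]

_VALID_MOTIF = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class Fragment:
    """One restriction fragment: ``[start, end)`` on ``chrom``.

    ``id`` is unique genome-wide; ``index`` is the ordinal of the fragment
    within its chromosome (0-based).
    """

    chrom: str
    start: int
    end: int
    id: int
    index: int

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class FragmentMap:
    """The genome partitioned into restriction fragments.

    Fragments within a chromosome are sorted, non-overlapping and tile the
    chromosome exactly. Fragment ids are assigned sequentially in chromosome
    order, so they are stable for a given genome + motif and can index dense
    per-fragment vectors.
    """

    def __init__(self, fragments_by_chrom: Mapping[str, Sequence[tuple[int, int]]]):
        self._chroms: list[str] = []
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._ids: dict[str, np.ndarray] = {}
        self._fragments: list[Fragment] = []
        next_id = 0
        for chrom, intervals in fragments_by_chrom.items():
            if not intervals:
                raise ValueError(f"chromosome {chrom!r} has no fragments")
            starts = np.asarray([s for s, _ in intervals], dtype=np.int64)
            ends = np.asarray([e for _, e in intervals], dtype=np.int64)
            if starts[0] != 0:
                raise ValueError(f"{chrom}: first fragment must start at 0")
            if np.any(ends <= starts):
                raise ValueError(f"{chrom}: zero or negative length fragment")
            if np.any(starts[1:] != ends[:-1]):
                raise ValueError(f"{chrom}: fragments do not tile the chromosome")
            ids = np.arange(next_id, next_id + len(starts), dtype=np.int64)
            for i in range(len(starts)):
                self._fragments.append(
                    Fragment(chrom, int(starts[i]), int(ends[i]), int(ids[i]), i)
                )
            self._chroms.append(chrom)
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._ids[chrom] = ids
            next_id += len(starts)

    # -- basic queries -----------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return list(self._chroms)

    @property
    def n_fragments(self) -> int:
        return len(self._fragments)

    def __len__(self) -> int:
        return len(self._fragments)

    def __iter__(self):
        return iter(self._fragments)

    def chrom_size(self, chrom: str) -> int:
        return int(self._ends[chrom][-1])

    def fragments(self, chrom: str) -> list[Fragment]:
        ids = self._ids[chrom]
        return [self._fragments[i] for i in ids]

    def fragment(self, fragment_id: int) -> Fragment:
        return self._fragments[fragment_id]

    def chrom_of(self, fragment_id: int) -> str:
        return self._fragments[fragment_id].chrom

    def fragment_ids(self, chrom: str) -> np.ndarray:
        return self._ids[chrom].copy()

    def locate(self, chrom: str, start: int, end: int) -> int | None:
        """Return the id of the fragment containing the midpoint of
        ``[start, end)``, or None if ``chrom`` is absent or the midpoint
        falls beyond the chromosome end."""
        if start >= end:
            raise ValueError(f"inverted interval [{start}, {end})")
        if chrom not in self._starts:
            return None
        mid = (start + end) // 2
        if mid < 0 or mid >= self.chrom_size(chrom):
            return None
        idx = int(np.searchsorted(self._starts[chrom], mid, side="right")) - 1
        return int(self._ids[chrom][idx])

    def fragment_sequence(self, genome: Mapping[str, str], fragment_id: int) -> str:
        f = self._fragments[fragment_id]
        return str(genome[f.chrom])[f.start : f.end]

    # -- equality (same partition) ----------------------------------------

    def same_partition(self, other: "FragmentMap") -> bool:
        if self._chroms != other._chroms:
            return False
        return all(
            np.array_equal(self._starts[c], other._starts[c])
            and np.array_equal(self._ends[c], other._ends[c])
            for c in self._chroms
        )


def _clean_motif(motif: str) -> str:
    motif = motif.upper()
    if not motif or not _VALID_MOTIF.match(motif):
        raise ValueError(f"motif must be a non-empty string over ACGT, got {motif!r}")
    return motif


def find_cut_sites(sequence: str, motif: str = "GATC") -> list[int]:
    """Start positions of every (possibly overlapping) motif occurrence.

    Case-insensitive; occurrences containing N in the sequence do not match.
    """
    motif = _clean_motif(motif)
    # lookahead regex yields overlapping occurrences
    pattern = re.compile(f"(?={re.escape(motif)})")
    return [m.start() for m in pattern.finditer(sequence.upper())]


def _boundaries(length: int, cuts: Iterable[int]) -> list[int]:
    bounds = [0]
    for c in cuts:
        if c > bounds[-1]:
            bounds.append(c)
    if length > bounds[-1]:
        bounds.append(length)
    return bounds


def digest_reference(genome: Mapping[str, str], motif: str = "GATC") -> FragmentMap:
    """Digest a genome into a :class:`FragmentMap` at every motif occurrence.

    Parameters
    ----------
    genome
        Mapping of chromosome name to sequence (strings over A/C/G/T/N,
        case-insensitive).
    motif
        Enzyme recognition sequence; default GATC (DpnII).
    """
    motif = _clean_motif(motif)
    if not genome:
        raise ValueError("empty genome")
    fragments: dict[str, list[tuple[int, int]]] = {}
    for chrom, seq in genome.items():
        seq = str(seq)
        if len(seq) == 0:
            raise ValueError(f"chromosome {chrom!r} is empty")
        cuts = find_cut_sites(seq, motif)
        bounds = _boundaries(len(seq), cuts)
        fragments[chrom] = list(zip(bounds[:-1], bounds[1:]))
    return FragmentMap(fragments)


def digest_read(sequence: str, motif: str = "GATC") -> list[str]:
    """Split a read sequence at the same cut convention as the reference.

    The concatenation of the returned slices equals the input; no slice is
    empty (a motif at position 0 yields no leading empty slice).
    """
    if not sequence:
        raise ValueError("empty sequence")
    motif = _clean_motif(motif)
    cuts = find_cut_sites(sequence, motif)
    bounds = _boundaries(len(sequence), cuts)
    return [sequence[a:b] for a, b in zip(bounds[:-1], bounds[1:])]


def locate_fragment(
    fmap: FragmentMap, chrom: str, interval: tuple[int, int]
) -> int | None:
    """Functional wrapper around :meth:`FragmentMap.locate`."""
    return fmap.locate(chrom, interval[0], interval[1])
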