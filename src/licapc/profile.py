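"""Per-restriction-fragment interaction profiles.

A profile is a dense vector over the fragment map: the number of unique
(post-deduplication) interactions reported at each restriction fragment for
one viewpoint group. Profiles can be pooled across duplicated-gene viewpoint
members, normalized to a fixed genome-wide total (100 000 by convention),
smoothed by a fragment-count sliding window as in 4C analysis, and compared
between conditions as differential profiles with replicate standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classify import ClassifiedRead
from .restriction_map import FragmentMap

__all__ = [
    "InteractionProfile",
    "build_profile",
    "pool_viewpoints",
    "normalize_profile",
    "window_profile",
    "differential_profile",
    "DEFAULT_SCALE",
    "DEFAULT_WINDOW",
]

DEFAULT_SCALE = 100_000
DEFAULT_WINDOW = 5


@dataclass
class InteractionProfile:
    """Interaction counts (or derived values) indexed by fragment id.

    ``kind`` is one of raw / normalized / windowed / differential. ``se`` is
    the per-fragment standard error (differential profiles only).
    """

    group: str
    values: np.ndarray
    kind: str
    fmap: FragmentMap
    metadata: dict = field(default_factory=dict)
    se: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.fmap.n_fragments:
            raise ValueError("profile length does not match fragment map")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def cis_values(self, chrom: str) -> np.ndarray:
        return self.values[self.fmap.fragment_ids(chrom)]


def build_profile(
    reads: Sequence[ClassifiedRead], fmap: FragmentMap, group: str
) -> InteractionProfile:
    """Raw profile: value at fragment f = number of retained informative
    reads reporting f. A read with reporters in k distinct fragments adds 1
    to each of the k fragments."""
    values = np.zeros(fmap.n_fragments, dtype=float)
    n_reads = 0
    for read in reads:
        if not read.informative:
            continue
        if read.viewpoint != group:
            raise ValueError(
                f"read {read.read_id} belongs to viewpoint {read.viewpoint!r}, "
                f"not {group!r}"
            )
        for fid in read.reporter_ids:
            values[fid] += 1
        n_reads += 1
    return InteractionProfile(
        group,
        values,
        "raw",
        fmap,
        metadata={"total_raw": float(values.sum()), "n_reads": n_reads},
    )


def pool_viewpoints(profiles: Sequence[InteractionProfile]) -> InteractionProfile:
    """Composite profile for duplicated-gene viewpoints: element-wise sum of
    raw member profiles; totals add."""
    if not profiles:
        raise ValueError("no profiles to pool")
    first = profiles[0]
    for p in profiles[1:]:
        if not p.fmap.same_partition(first.fmap):
            raise ValueError("profiles are on different fragment maps")
        if p.kind != first.kind or p.kind != "raw":
            raise ValueError("only raw profiles of the same kind can be pooled")
    values = np.sum([p.values for p in profiles], axis=0)
    return InteractionProfile(
        first.group,
        values,
        "raw",
        first.fmap,
        metadata={
            "total_raw": float(values.sum()),
            "pooled_from": [p.group for p in profiles],
        },
    )


def normalize_profile(
    profile: InteractionProfile,
    scale: float = DEFAULT_SCALE,
    cis_only_chrom: str | None = None,
) -> InteractionProfile:
    """Scale a profile so its genome-wide total equals ``scale``.

    The denominator includes trans interactions (genome-wide convention).
    Pass ``cis_only_chrom`` to normalize over one chromosome's fragments
    instead (sensitivity analysis); values on other chromosomes are kept,
    scaled by the same constant.
    """
    if cis_only_chrom is not None:
        denom = float(profile.cis_values(cis_only_chrom).sum())
    else:
        denom = profile.total
    if denom <= 0:
        raise ValueError("cannot normalize a profile with zero total")
    factor = scale / denom
    meta = dict(profile.metadata)
    meta.update({"normalization_scale": scale, "normalization_factor": factor})
    return InteractionProfile(
        profile.group, profile.values * factor, "normalized", profile.fmap, meta
    )


def _sliding_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered sliding mean with truncated windows at the edges."""
    n = len(values)
    h = (window - 1) // 2
    cs = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(n)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h + 1, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def window_profile(
    profile: InteractionProfile, window: int = DEFAULT_WINDOW
) -> InteractionProfile:
    """Sliding-mean smoothing over ``window`` fragments (odd), per
    chromosome; windows never span chromosomes and shrink at chromosome
    edges."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd fragment count >= 1")
    out = np.empty_like(profile.values)
    for chrom in profile.fmap.chroms:
        ids = profile.fmap.fragment_ids(chrom)
        out[ids] = _sliding_mean(profile.values[ids], window)
    meta = dict(profile.metadata)
    meta["window"] = window
    return InteractionProfile(profile.group, out, "windowed", profile.fmap, meta)


def _group_mean_se(profiles: Sequence[InteractionProfile]) -> tuple[np.ndarray, np.ndarray]:
    stack = np.vstack([p.values for p in profiles])
    mean = stack.mean(axis=0)
    n = stack.shape[0]
    if n == 1:
        return mean, np.zeros_like(mean)
    se = stack.std(axis=0, ddof=1) / np.sqrt(n)
    return mean, se


def differential_profile(
    group_a: Sequence[InteractionProfile],
    group_b: Sequence[InteractionProfile],
) -> InteractionProfile:
    """Per-fragment mean(A) - mean(B) over normalized replicate profiles,
    with SE = sqrt(SE_A^2 + SE_B^2); SE of a single-replicate group is 0."""
    if not group_a or not group_b:
        raise ValueError("each group needs at least one replicate profile")
    fmap = group_a[0].fmap
    for p in list(group_a) + list(group_b):
        if not p.fmap.same_partition(fmap):
            raise ValueError("profiles are on different fragment maps")
    mean_a, se_a = _group_mean_se(group_a)
    mean_b, se_b = _group_mean_se(group_b)
    return InteractionProfile(
        f"{group_a[0].group}-{group_b[0].group}",
        mean_a - mean_b,
        "differential",
        fmap,
        metadata={"n_a": len(group_a), "n_b": len(group_b)},
        se=np.sqrt(se_a**2 + se_b**2),
    )
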