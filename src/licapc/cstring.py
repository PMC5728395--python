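"""C-String probe design and count analysis.

C-String quantifies 3C ligation junctions without PCR or sequencing: capture
probes anneal to the viewpoint fragment and reporter probes to ~120
restriction fragments across the locus; barcoded single-molecule counting
then yields one count per probed fragment per sample.

Probes target the two ends of each restriction fragment: the top strand of
the left end and the bottom strand (reverse complement) of the right end, so
a junction is detected regardless of the reporter fragment's ligation
orientation.

Counts are normalized per sample to a fixed total over the probed fragments
(1000 by convention), checked for linearity against input mass, and compared
to Capture-C profiles restricted and renormalized over the same fragments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .profile import InteractionProfile
from .restriction_map import FragmentMap

__all__ = [
    "Probe",
    "ProbeDesign",
    "CountTable",
    "design_probes",
    "normalize_counts",
    "linearity_check",
    "compare_to_capture",
    "differential_counts",
    "DEFAULT_PROBE_LENGTH",
    "DEFAULT_COUNT_SCALE",
]

DEFAULT_PROBE_LENGTH = 50
DEFAULT_COUNT_SCALE = 1000


@dataclass(frozen=True)
class Probe:
    fragment_id: int
    chrom: str
    start: int
    end: int
    strand: str  # "+" top strand (left end), "-" bottom strand (right end)
    sequence: str


@dataclass
class ProbeDesign:
    """Left/right-end probes per targeted fragment, plus fragments skipped
    because they are shorter than the probe length."""

    probes: list[Probe]
    skipped: list[int]
    probe_length: int

    def by_fragment(self) -> dict[int, tuple[Probe, Probe]]:
        out: dict[int, list[Probe]] = {}
        for p in self.probes:
            out.setdefault(p.fragment_id, []).append(p)
        return {fid: (ps[0], ps[1]) for fid, ps in out.items()}


@dataclass
class CountTable:
    """Probe-by-sample count matrix with per-sample metadata.

    ``counts``: DataFrame indexed by fragment/probe id, one column per
    sample. ``samples``: DataFrame indexed by sample name with at least
    ``tissue`` and ``input_mass_ug`` columns.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    normalized: bool = False

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)}")
        if self.samples["input_mass_ug"].isna().any():
            raise ValueError("every sample needs an input mass")


def design_probes(
    fmap: FragmentMap,
    genome: Mapping[str, str],
    targets: Sequence[int],
    probe_length: int = DEFAULT_PROBE_LENGTH,
) -> ProbeDesign:
    """Design left- and right-end probes for each target fragment.

    Left probe: top-strand sequence of the first ``probe_length`` bp of the
    fragment. Right probe: reverse complement of the last ``probe_length``
    bp. Fragments shorter than the probe length are skipped and reported.
    """
    if probe_length < 1:
        raise ValueError("probe_length must be >= 1")
    probes: list[Probe] = []
    skipped: list[int] = []
    for fid in targets:
        if fid < 0 or fid >= fmap.n_fragments:
            raise ValueError(f"target fragment id {fid} not in map")
        f = fmap.fragment(fid)
        if len(f) < probe_length:
            skipped.append(fid)
            continue
        seq = str(genome[f.chrom])
        left_seq = seq[f.start : f.start + probe_length].upper()
        right_top = seq[f.end - probe_length : f.end].upper()
        probes.append(
            Probe(fid, f.chrom, f.start, f.start + probe_length, "+", left_seq)
        )
        probes.append(
            Probe(
                fid,
                f.chrom,
                f.end - probe_length,
                f.end,
                "-",
                str(Seq(right_top).reverse_complement()),
            )
        )
    return ProbeDesign(probes, skipped, probe_length)


def normalize_counts(
    table: CountTable, scale: float = DEFAULT_COUNT_SCALE
) -> CountTable:
    """Scale each sample column so its total over the probed fragments equals
    ``scale`` (the instrument only sees probed fragments, so normalization is
    over the probed set)."""
    totals = table.counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero-total sample(s): {bad}")
    return CountTable(
        table.counts * (scale / totals), table.samples.copy(), normalized=True
    )


def linearity_check(table: CountTable) -> pd.DataFrame:
    """Ordinary least squares of raw counts on input mass, per tissue group.

    Returns one row per (tissue, probe) plus a ``__total__`` row per tissue
    for the summed counts, with slope, intercept and Pearson r. Requires >= 3
    samples spanning >= 2 distinct input masses in each group.
    """
    results = []
    for tissue, meta in table.samples.groupby("tissue"):
        cols = [c for c in table.counts.columns if c in meta.index]
        masses = table.samples.loc[cols, "input_mass_ug"].to_numpy(dtype=float)
        if len(cols) < 3:
            raise ValueError(f"tissue {tissue!r}: need >= 3 samples")
        if len(np.unique(masses)) < 2:
            raise ValueError(f"tissue {tissue!r}: need >= 2 distinct input masses")
        sub = table.counts[cols]
        rows = [("__total__", sub.sum(axis=0).to_numpy(dtype=float))]
        rows += [(pid, sub.loc[pid].to_numpy(dtype=float)) for pid in sub.index]
        for pid, y in rows:
            if np.ptp(y) == 0:
                slope, intercept, r = 0.0, float(y[0]), np.nan
                stderr = 0.0
            else:
                fit = stats.linregress(masses, y)
                slope, intercept, r, stderr = (
                    fit.slope,
                    fit.intercept,
                    fit.rvalue,
                    fit.stderr,
                )
            results.append(
                {
                    "tissue": tissue,
                    "probe": pid,
                    "slope": slope,
                    "intercept": intercept,
                    "pearson_r": r,
                    "slope_se": stderr,
                }
            )
    return pd.DataFrame(results)


def compare_to_capture(
    cstring_column: pd.Series,
    capture_profile: InteractionProfile,
    probed_fragments: Sequence[int],
    scale: float = DEFAULT_COUNT_SCALE,
) -> tuple[float, pd.DataFrame]:
    """Pearson r between a normalized C-String sample and a Capture-C profile
    over the probed fragment set.

    Both vectors are renormalized to ``scale`` over the probed set so they
    are commensurable. Returns (r, aligned value pairs).
    """
    fids = [f for f in probed_fragments if f in cstring_column.index]
    if len(fids) < 2:
        raise ValueError("need >= 2 overlapping probed fragments")
    cs = cstring_column.loc[fids].to_numpy(dtype=float)
    cap = capture_profile.values[np.asarray(fids, dtype=int)]
    if cs.sum() <= 0 or cap.sum() <= 0:
        raise ValueError("zero total over probed fragments")
    cs = cs * (scale / cs.sum())
    cap = cap * (scale / cap.sum())
    if np.ptp(cs) == 0 or np.ptp(cap) == 0:
        raise ValueError("zero variance over probed fragments")
    r = float(stats.pearsonr(cs, cap).statistic)
    paired = pd.DataFrame(
        {"fragment_id": fids, "cstring": cs, "capture": cap}
    ).set_index("fragment_id")
    return r, paired


def differential_counts(
    table: CountTable, group_a: Sequence[str], group_b: Sequence[str]
) -> pd.DataFrame:
    """Per-fragment mean(A) - mean(B) of normalized counts with SE =
    sqrt(SE_A^2 + SE_B^2); single-sample groups contribute SE 0."""
    if not group_a or not group_b:
        raise ValueError("each group needs at least one sample")
    if not table.normalized:
        raise ValueError("normalize counts before computing differentials")

    def mean_se(cols: Sequence[str]) -> tuple[pd.Series, pd.Series]:
        sub = table.counts[list(cols)]
        mean = sub.mean(axis=1)
        if sub.shape[1] == 1:
            return mean, pd.Series(0.0, index=sub.index)
        return mean, sub.std(axis=1, ddof=1) / np.sqrt(sub.shape[1])

    mean_a, se_a = mean_se(group_a)
    mean_b, se_b = mean_se(group_b)
    return pd.DataFrame(
        {"difference": mean_a - mean_b, "se": np.sqrt(se_a**2 + se_b**2)}
    )
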