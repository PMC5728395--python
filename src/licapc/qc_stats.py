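"""Library-quality statistics for Capture-C experiments.

Covers the composition and reproducibility metrics used to judge a 3C
library: the cis fraction of unique interactions (sensitive to fixation
strength), Pearson correlation between replicate profiles, the distribution
of restriction-fragment slices per read, and the two qPCR-derived wet-lab
numbers — digestion efficiency from a ligation-junction vs genomic-control
Ct comparison, and library mass from a genomic-DNA standard curve.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import ClassifiedRead
from .profile import InteractionProfile
from .restriction_map import FragmentMap

__all__ = [
    "cis_fraction",
    "replicate_correlation",
    "fragments_per_read",
    "digestion_efficiency",
    "quantify_mass",
    "QPCR_COLUMNS",
]

# qPCR table dialect: assay in {junction, control}; template in {3C, genomic}
QPCR_COLUMNS = ["sample", "assay", "template", "ct", "mass_ng"]


def cis_fraction(
    reads: Sequence[ClassifiedRead],
    fmap: FragmentMap,
    viewpoint_chrom: str,
) -> float:
    """Percentage of unique interactions whose reporter fragment lies on the
    viewpoint chromosome, counted per reporter-fragment event.

    Computed on post-deduplication informative reads.
    """
    n_cis = 0
    n_total = 0
    for read in reads:
        if not read.informative:
            continue
        for fid in read.reporter_ids:
            n_total += 1
            if fmap.chrom_of(fid) == viewpoint_chrom:
                n_cis += 1
    if n_total == 0:
        raise ValueError("no unique interactions")
    return 100.0 * n_cis / n_total


def replicate_correlation(
    profile_a: InteractionProfile,
    profile_b: InteractionProfile,
    restriction: Sequence[int] | None = None,
) -> float:
    """Pearson correlation coefficient between two profiles, optionally
    restricted to a fragment id set."""
    if not profile_a.fmap.same_partition(profile_b.fmap):
        raise ValueError("profiles are on different fragment maps")
    a, b = profile_a.values, profile_b.values
    if restriction is not None:
        idx = np.asarray(sorted(restriction), dtype=int)
        a, b = a[idx], b[idx]
    if len(a) < 2:
        raise ValueError("need >= 2 fragments after restriction")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in a profile vector")
    return float(stats.pearsonr(a, b).statistic)


def fragments_per_read(
    reads: Sequence[ClassifiedRead],
) -> tuple[float, dict[int, int]]:
    """Mean number of restriction-fragment slices per read, plus the full
    slice-count histogram."""
    if not reads:
        raise ValueError("no reads")
    counts = [r.n_slices for r in reads]
    hist = dict(sorted(Counter(counts).items()))
    return float(np.mean(counts)), hist


def _get_ct(table: pd.DataFrame, sample: str, assay: str, template: str) -> float:
    rows = table[
        (table["sample"] == sample)
        & (table["assay"] == assay)
        & (table["template"] == template)
    ]
    if rows.empty:
        raise ValueError(
            f"sample {sample!r}: missing Ct for assay={assay!r}, template={template!r}"
        )
    return float(rows["ct"].mean())


def digestion_efficiency(
    table: pd.DataFrame, sample: str, primer_efficiency: float = 2.0
) -> float:
    """Digestion efficiency (percent) from ligation-junction qPCR.

    The junction-site assay amplifies only undigested (or religated-intact)
    template; the genomic-control assay measures total template. With
    delta-Ct = Ct(junction) - Ct(control) measured on both the 3C library and
    undigested genomic DNA::

        efficiency = 100 * (1 - E^-(dCt_3C - dCt_genomic))

    where E is the per-cycle amplification factor (2 for perfect doubling;
    expose ``primer_efficiency`` for non-ideal assays). The result is clipped
    to [0, 100]. The genomic template calibrates out primer-pair differences.
    """
    if primer_efficiency <= 1.0:
        raise ValueError("primer_efficiency must be > 1")
    d_3c = _get_ct(table, sample, "junction", "3C") - _get_ct(
        table, sample, "control", "3C"
    )
    d_g = _get_ct(table, sample, "junction", "genomic") - _get_ct(
        table, sample, "control", "genomic"
    )
    eff = 100.0 * (1.0 - primer_efficiency ** -(d_3c - d_g))
    return float(np.clip(eff, 0.0, 100.0))


def quantify_mass(
    standards: Sequence[tuple[float, float]], sample_ct: float
) -> tuple[float, float, float]:
    """Library mass (ng) from a genomic-DNA qPCR standard curve.

    Fits Ct = a + b * log2(mass) by least squares over the standards (slope
    b = -1 for a perfectly efficient assay) and inverts the line at the
    sample's Ct. Returns (mass ng, slope, r-squared).
    """
    if len(standards) < 2:
        raise ValueError("need >= 2 standards")
    masses = np.array([m for m, _ in standards], dtype=float)
    cts = np.array([c for _, c in standards], dtype=float)
    if np.ptp(masses) == 0:
        raise ValueError("standards must span distinct masses")
    x = np.log2(masses)
    fit = stats.linregress(x, cts)
    if fit.slope == 0:
        raise ValueError("degenerate standard curve (zero slope)")
    log2_mass = (sample_ct - fit.intercept) / fit.slope
    return float(2.0**log2_mass), float(fit.slope), float(fit.rvalue**2)
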