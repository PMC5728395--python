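"""Synthetic Capture-C library generator with exhaustive ground truth.

Emulates the generative process behind a Capture-C experiment far enough to
exercise every downstream analysis stage: a viewpoint restriction fragment
ligates to a reporter fragment drawn from a proximity-decay-plus-peaks
interaction distribution; the junction molecule is sheared (sonication, or
GC-biased tagmentation as produced by Tn5 transposase); the sheared insert is
PCR-amplified, occasionally with 1-2 bp "wobble" errors on the mapped end
coordinates that make duplicates look unique.

Every emitted read carries a ground-truth record (:data:`SimTruth` columns),
so duplicate filtering and profile reconstruction can be scored exactly.

Only two-fragment junction molecules are simulated (viewpoint + one
reporter); higher-order concatemers are out of scope. Reads are emitted
pre-aligned as genomic slice coordinates — there is no sequencing-error model
on the read body and no alignment step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .restriction_map import FragmentMap

__all__ = [
    "SimConfig",
    "TRUTH_COLUMNS",
    "READ_COLUMNS",
    "random_genome",
    "build_interaction_distribution",
    "sample_breakpoints",
    "apply_pcr_duplication",
    "simulate_library",
]

READ_COLUMNS = ["read_id", "slice_index", "chrom", "start", "end", "strand"]
TRUTH_COLUMNS = [
    "read_id",
    "molecule_id",
    "reporter_fragment",
    "is_cis",
    "is_duplicate",
    "was_wobbled",
    "umi_left_chrom",
    "umi_left",
    "umi_right_chrom",
    "umi_right",
]

# inserts smaller than this on either side of the junction are not placeable
_MIN_SIDE = 3


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated Capture-C library.

    Attributes
    ----------
    viewpoint_ids
        Fragment id(s) of the captured viewpoint; multiple members model
        duplicated-gene viewpoints whose reads are pooled downstream.
    peaks
        ``(fragment id, enrichment weight >= 0)`` pairs; a peak fragment's
        cis weight is multiplied by ``1 + weight``.
    alpha
        Cis distance-decay exponent (> 0); weight ~ distance^-alpha.
    trans_fraction
        Fraction ``t`` of unique molecules with a trans reporter.
    n_molecules
        Number of unique ligation molecules to simulate.
    dup_rate
        Mean number of PCR duplicates per molecule (geometric law).
    wobble_prob
        Per-duplicate probability of a 1-2 bp shift on one UMI coordinate.
        No quantitative wobble rate is anchored to data; the default 0.05 is
        a free parameter.
    breakpoint_model
        ``"sonication"`` (uniform breakpoints) or ``"tagmentation"``
        (G/C-preferring breakpoints with weight ``gc_weight``).
    exclusion_bp
        Half-width of the proximity-exclusion zone around the viewpoint;
        fragments inside it get zero reporter probability so the simulated
        truth matches what the pipeline can see.
    insert_mean, insert_sd, insert_min, insert_max
        Sheared-insert size model: normal, truncated to [min, max]. The
        defaults (200 +/- 30 bp on [50, 500]) follow sonication to ~200 bp.
    """

    viewpoint_ids: tuple[int, ...]
    peaks: tuple[tuple[int, float], ...] = ()
    alpha: float = 1.0
    trans_fraction: float = 0.0
    n_molecules: int = 1000
    dup_rate: float = 0.0
    wobble_prob: float = 0.05
    breakpoint_model: str = "sonication"
    gc_weight: float = 1.0
    exclusion_bp: int = 1000
    insert_mean: float = 200.0
    insert_sd: float = 30.0
    insert_min: int = 50
    insert_max: int = 500
    seed: int = 0

    def __post_init__(self):
        if not self.viewpoint_ids:
            raise ValueError("at least one viewpoint fragment id required")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not 0.0 <= self.trans_fraction <= 1.0:
            raise ValueError("trans_fraction must be in [0, 1]")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.dup_rate < 0:
            raise ValueError("dup_rate must be >= 0")
        if not 0.0 <= self.wobble_prob <= 1.0:
            raise ValueError("wobble_prob must be in [0, 1]")
        if self.breakpoint_model not in ("sonication", "tagmentation"):
            raise ValueError(f"unknown breakpoint model {self.breakpoint_model!r}")
        if self.gc_weight < 1:
            raise ValueError("gc_weight must be >= 1")
        if any(w < 0 for _, w in self.peaks):
            raise ValueError("peak weights must be >= 0")


def random_genome(
    chrom_sizes: Mapping[str, int],
    gc: float = 0.42,
    seed: int | np.random.Generator = 0,
) -> dict[str, str]:
    """Random genome with the given chromosome sizes and GC content.

    Mouse-like default GC of 0.42. Used to build toy fragment maps for
    simulation and tests.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    return {
        chrom: "".join(bases[rng.choice(4, size=size, p=p)])
        for chrom, size in chrom_sizes.items()
    }


def excluded_fragments(
    fmap: FragmentMap, viewpoint_ids: Sequence[int], exclusion_bp: int
) -> set[int]:
    """Fragment ids overlapping any viewpoint fragment +/- exclusion_bp
    (viewpoint fragments themselves included)."""
    out: set[int] = set(int(v) for v in viewpoint_ids)
    for vid in viewpoint_ids:
        vp = fmap.fragment(vid)
        lo = max(0, vp.start - exclusion_bp)
        hi = min(fmap.chrom_size(vp.chrom), vp.end + exclusion_bp)
        for f in fmap.fragments(vp.chrom):
            if f.start < hi and f.end > lo:
                out.add(f.id)
    return out


def build_interaction_distribution(
    fmap: FragmentMap, config: SimConfig
) -> np.ndarray:
    """True reporter distribution: probability per fragment id.

    Cis fragments (same chromosome as the viewpoint) get unnormalized weight
    ``(1 + peak_weight) * d^-alpha`` with d the midpoint distance to the
    viewpoint midpoint, floored at one viewpoint-fragment length to avoid the
    singularity; cis weights are scaled to total mass ``1 - t``. Trans
    fragments share mass ``t`` uniformly. Viewpoint and exclusion-zone
    fragments get probability 0. The vector sums to 1.
    """
    vp0 = fmap.fragment(config.viewpoint_ids[0])
    vp_chrom = vp0.chrom
    for vid in config.viewpoint_ids:
        if fmap.fragment(vid).chrom != vp_chrom:
            raise ValueError("viewpoint group members must share a chromosome")
    vp_mid = float(np.mean([fmap.fragment(v).midpoint for v in config.viewpoint_ids]))
    d_floor = max(1, len(vp0))

    peak_w = dict(config.peaks)
    for pid in peak_w:
        if pid >= fmap.n_fragments:
            raise ValueError(f"peak fragment id {pid} not in map")

    excluded = excluded_fragments(fmap, config.viewpoint_ids, config.exclusion_bp)

    weights = np.zeros(fmap.n_fragments, dtype=float)
    t = config.trans_fraction
    cis_total = 0.0
    n_trans = 0
    for f in fmap:
        if f.id in excluded:
            continue
        if f.chrom == vp_chrom:
            d = max(abs(f.midpoint - vp_mid), d_floor)
            weights[f.id] = (1.0 + peak_w.get(f.id, 0.0)) * d ** (-config.alpha)
            cis_total += weights[f.id]
        else:
            n_trans += 1

    probs = np.zeros(fmap.n_fragments, dtype=float)
    if cis_total > 0:
        cis_mask = weights > 0
        probs[cis_mask] = weights[cis_mask] / cis_total * (1.0 - t)
    elif t < 1.0:
        raise ValueError("no cis fragments available outside the exclusion zone")
    if t > 0:
        if n_trans == 0:
            raise ValueError("trans_fraction > 0 but map has no trans fragments")
        for f in fmap:
            if f.chrom != vp_chrom:
                probs[f.id] = t / n_trans
    if probs.sum() <= 0:
        raise ValueError("interaction distribution is all zero")
    return probs / probs.sum()


def _position_weights(sequence: str, model: str, w: float) -> np.ndarray:
    """Per-internal-position breakpoint weights for a sequence (positions
    1..L-1; weight w when the base at the position is G or C)."""
    L = len(sequence)
    if model == "sonication" or w == 1.0:
        return np.ones(L - 1, dtype=float)
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)[1:]
    weights = np.ones(L - 1, dtype=float)
    weights[(arr == ord("G")) | (arr == ord("C"))] = w
    return weights


def sample_breakpoints(
    sequence: str, model: str, w: float, rng: np.random.Generator
) -> int:
    """Draw one breakpoint position over the internal positions 1..L-1.

    Sonication: uniform. Tagmentation: position weighted ``w`` when the base
    at the position is G or C, else 1 (Tn5 base-composition preference).
    """
    if len(sequence) < 2:
        raise ValueError("sequence must have length >= 2")
    weights = _position_weights(sequence, model, w)
    probs = weights / weights.sum()
    return int(rng.choice(len(probs), p=probs)) + 1


@dataclass
class _Molecule:
    molecule_id: int
    slices: list[tuple[str, int, int, str]]
    reporter_fragment: int
    is_cis: bool
    umi: tuple[str, int, str, int]  # (lchrom, lpos, rchrom, rpos)


def apply_pcr_duplication(
    molecules: Sequence[_Molecule],
    dup_rate: float,
    wobble_prob: float,
    rng: np.random.Generator,
) -> list[dict]:
    """Amplify molecules into reads.

    Each molecule is emitted ``1 + G`` times with G geometric (mean
    ``dup_rate``). Each duplicate independently wobbles with probability
    ``wobble_prob``: exactly one UMI coordinate shifts by +/-1 or +/-2 bp
    (uniform over the 8 end/shift combinations), moving the corresponding
    slice boundary. Originals are never wobbled.
    """
    if dup_rate < 0:
        raise ValueError("dup_rate must be >= 0")
    if not 0.0 <= wobble_prob <= 1.0:
        raise ValueError("wobble_prob must be in [0, 1]")
    reads: list[dict] = []
    p = 1.0 / (1.0 + dup_rate)
    for mol in molecules:
        n_copies = 1 if dup_rate == 0 else int(rng.geometric(p))
        for copy_idx in range(n_copies):
            slices = [list(s) for s in mol.slices]
            wobbled = False
            if copy_idx > 0 and rng.random() < wobble_prob:
                wobbled = True
                combo = int(rng.integers(8))
                end_side = combo // 4  # 0 = left UMI, 1 = right UMI
                shift = (-2, -1, 1, 2)[combo % 4]
                if end_side == 0:
                    new_start = slices[0][1] + shift
                    if new_start < 0 or new_start >= slices[0][2]:
                        new_start = slices[0][1] - shift
                    slices[0][1] = new_start
                else:
                    new_end = slices[-1][2] + shift
                    if new_end <= slices[-1][1]:
                        new_end = slices[-1][2] - shift
                    slices[-1][2] = new_end
            reads.append(
                {
                    "molecule_id": mol.molecule_id,
                    "slices": [tuple(s) for s in slices],
                    "reporter_fragment": mol.reporter_fragment,
                    "is_cis": mol.is_cis,
                    "is_duplicate": copy_idx > 0,
                    "was_wobbled": wobbled,
                    "true_umi": mol.umi,
                }
            )
    return reads


def simulate_library(
    config: SimConfig,
    fmap: FragmentMap,
    genome: Mapping[str, str] | None = None,
    max_retries: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a Capture-C library; returns (read slices, truth) tables.

    For each unique molecule: draw a reporter fragment from the interaction
    distribution, form the viewpoint+reporter junction molecule, place a
    sheared insert spanning the junction with ends from the breakpoint model,
    and emit the two aligned slices (viewpoint-side then reporter-side). PCR
    duplication and wobble are then applied, and reads are emitted in
    shuffled order.

    ``genome`` is required for the tagmentation model (breakpoint weights
    depend on base composition); sonication runs without sequence.

    Returns
    -------
    reads : DataFrame with columns ``READ_COLUMNS`` (one row per slice)
    truth : DataFrame with columns ``TRUTH_COLUMNS`` (one row per read)
    """
    if config.breakpoint_model == "tagmentation" and genome is None:
        raise ValueError("tagmentation breakpoints require the genome sequence")
    rng = np.random.default_rng(config.seed)
    probs = build_interaction_distribution(fmap, config)

    reporter_draws = rng.choice(fmap.n_fragments, size=config.n_molecules, p=probs)
    vp_draws = rng.choice(
        np.asarray(config.viewpoint_ids), size=config.n_molecules
    )

    seq_cache: dict[int, str] = {}

    def frag_seq(fid: int) -> str:
        if fid not in seq_cache:
            seq_cache[fid] = fmap.fragment_sequence(genome, fid)
        return seq_cache[fid]

    molecules: list[_Molecule] = []
    n_skipped = 0
    for mol_id in range(config.n_molecules):
        vp = fmap.fragment(int(vp_draws[mol_id]))
        rep = fmap.fragment(int(reporter_draws[mol_id]))
        Lv, Lr = len(vp), len(rep)
        total = Lv + Lr
        placed = False
        for _ in range(max_retries):
            size = int(round(rng.normal(config.insert_mean, config.insert_sd)))
            size = min(max(size, config.insert_min), config.insert_max)
            lo = max(0, Lv - size + _MIN_SIDE)
            hi = min(Lv - _MIN_SIDE, total - size)
            if lo > hi:
                continue
            if config.breakpoint_model == "tagmentation" and config.gc_weight != 1.0:
                mol_seq = frag_seq(vp.id) + frag_seq(rep.id)
                # both insert ends are biased: weight = product of per-end
                # base weights at the left cut and the right cut
                w = config.gc_weight
                cand = np.arange(lo, hi + 1)
                left_w = np.array(
                    [w if mol_seq[a] in "GCgc" else 1.0 for a in cand]
                )
                right_w = np.array(
                    [
                        w if mol_seq[min(a + size, total - 1)] in "GCgc" else 1.0
                        for a in cand
                    ]
                )
                pw = left_w * right_w
                a = int(rng.choice(cand, p=pw / pw.sum()))
            else:
                a = int(rng.integers(lo, hi + 1))
            placed = True
            break
        if not placed:
            n_skipped += 1
            continue
        b = a + size  # molecule-coordinate insert [a, b), junction at Lv
        vp_slice = (vp.chrom, vp.start + a, vp.end, "+")
        rep_slice = (rep.chrom, rep.start, rep.start + (b - Lv), "+")
        umi = (vp.chrom, vp.start + a, rep.chrom, rep.start + (b - Lv))
        molecules.append(
            _Molecule(
                molecule_id=mol_id,
                slices=[vp_slice, rep_slice],
                reporter_fragment=rep.id,
                is_cis=rep.chrom == vp.chrom,
                umi=umi,
            )
        )

    reads = apply_pcr_duplication(molecules, config.dup_rate, config.wobble_prob, rng)
    order = rng.permutation(len(reads))

    slice_rows = []
    truth_rows = []
    for out_idx, read_idx in enumerate(order):
        read = reads[int(read_idx)]
        read_id = f"r{out_idx:08d}"
        for si, (chrom, start, end, strand) in enumerate(read["slices"]):
            slice_rows.append((read_id, si, chrom, int(start), int(end), strand))
        lc, lp, rc, rp = read["true_umi"]
        truth_rows.append(
            (
                read_id,
                read["molecule_id"],
                read["reporter_fragment"],
                read["is_cis"],
                read["is_duplicate"],
                read["was_wobbled"],
                lc,
                lp,
                rc,
                rp,
            )
        )
    reads_df = pd.DataFrame(slice_rows, columns=READ_COLUMNS)
    truth_df = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    truth_df.attrs["n_skipped"] = n_skipped
    return reads_df, truth_df
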