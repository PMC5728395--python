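"""Reusable toy-locus constructions for simulations, examples and tests.

These builders produce small random genomes with controlled features: a long
motif-free viewpoint fragment (so coordinate-UMI space on the viewpoint side
is wide and genuine-molecule collisions are rare — a "sparse locus"), planted
enhancer-like peak fragments at chosen fragment offsets from the viewpoint,
and an optional trans chromosome.
"""

from __future__ import annotations

import numpy as np

from .restriction_map import FragmentMap, digest_reference, find_cut_sites
from .sim3c import random_genome

__all__ = ["scrub_motif", "toy_locus", "peaks_at_offsets"]


def scrub_motif(sequence: str, motif: str = "GATC") -> str:
    """Remove every motif occurrence from a sequence by mutating its first
    base (G -> T for GATC-like motifs), repeating until none remain."""
    seq = list(sequence.upper())
    while True:
        cuts = find_cut_sites("".join(seq), motif)
        if not cuts:
            return "".join(seq)
        for c in cuts:
            seq[c] = "T" if seq[c] != "T" else "A"


def toy_locus(
    cis_bp: int = 200_000,
    trans_bp: int = 100_000,
    vp_fragment_bp: int = 2_000,
    gc: float = 0.42,
    motif: str = "GATC",
    seed: int = 0,
) -> tuple[dict[str, str], FragmentMap, int]:
    """Random two-chromosome locus with a long viewpoint fragment at the
    centre of chr1.

    The viewpoint fragment is made motif-free over ``vp_fragment_bp`` bases
    and delimited by explicit motif occurrences, so its identity and length
    are known by construction. Returns (genome, fragment map, viewpoint
    fragment id).
    """
    rng = np.random.default_rng(seed)
    half = (cis_bp - vp_fragment_bp - 2 * len(motif)) // 2
    raw = random_genome(
        {"left": half, "vp": vp_fragment_bp, "right": half}, gc=gc, seed=rng
    )
    chr1 = raw["left"] + motif + scrub_motif(raw["vp"], motif) + motif + raw["right"]
    genome = {"chr1": chr1}
    if trans_bp > 0:
        genome["chr2"] = random_genome({"chr2": trans_bp}, gc=gc, seed=rng)["chr2"]
    fmap = digest_reference(genome, motif)
    vp_id = fmap.locate("chr1", half + len(motif), half + len(motif) + vp_fragment_bp)
    assert vp_id is not None
    return genome, fmap, vp_id


def peaks_at_offsets(
    fmap: FragmentMap,
    viewpoint_id: int,
    offsets: tuple[int, ...] = (-40, 20, 60),
    weight: float = 30.0,
) -> tuple[tuple[int, float], ...]:
    """Enhancer-like peaks at fragment-index offsets from the viewpoint."""
    vp = fmap.fragment(viewpoint_id)
    chrom_ids = fmap.fragment_ids(vp.chrom)
    peaks = []
    for off in offsets:
        idx = vp.index + off
        if not 0 <= idx < len(chrom_ids):
            raise ValueError(f"peak offset {off} outside chromosome")
        peaks.append((int(chrom_ids[idx]), float(weight)))
    return tuple(peaks)
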