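# Methods

This note documents the models, conventions and numerical choices behind
`licapc`, and what the synthetic-data checks do and do not demonstrate.

## Coordinate system and digestion

All coordinates are 0-based, half-open internally; BED and bedGraph files
are written in the same convention and SAM positions are converted from
1-based on ingest. The genome is partitioned at the first base of every
recognition-motif occurrence (GATC for DpnII), scanned case-insensitively
with overlapping occurrences allowed; `N` bases never match, so masked
references simply produce longer fragments. A cut at position 0 and
overlapping motifs would create zero-length fragments; these are suppressed
because they can hold no sequence. The same cut convention is applied when
digesting read sequences in silico, so read-slice boundaries coincide with
fragment boundaries by construction. The overhang chemistry of the enzyme is
irrelevant to this bookkeeping; a single unambiguous convention shared
between genome and reads is what matters. Degenerate recognition sequences
and multi-enzyme digests are out of scope.

Interval-to-fragment assignment uses the interval midpoint (floor of
(start+end)/2) and binary search over fragment starts. Midpoint assignment
is robust to slices that slightly overhang a fragment boundary through
soft-clipped or wobbled ends.

## Read classification

Viewpoints are declared as *groups* of target fragments because duplicated
gene promoters (the two α-globin and two β-globin genes) cannot be
distinguished by mapping; a hit to any member is a capture slice of the
group. Reads hitting targets of two distinct groups are double-capture
artefacts and dropped. Slices overlapping the group's proximity-exclusion
zone — each viewpoint fragment ± 1 kb by default, configurable per
viewpoint, since proximity ligation just around the viewpoint is
uninformative — are excluded. Remaining slices are reporters; multiple
slices in one fragment count once per read (one molecule = one interaction
event). The 1 kb default is a declared convention, not a measured value.

## Stringent duplicate filter

The two sheared ends of a molecule act as a coordinate-UMI pair: the 5′-most
mapped base of the first slice and the 3′-most mapped base of the last
slice, in slice order (not genomic order). Distance between UMI pairs is the
summed L1 coordinate distance with chromosomes required equal on both ends —
this treats the two ends symmetrically, and "one or two differences"
corresponds to 1–2 bp shifts from sequencing/mapping error. Reads are
clustered by single linkage at radius `max_wobble` (default 2; 0 reduces
exactly to hash-based exact deduplication) and one representative is kept
per cluster: the read whose exact UMI key has the most copies, ties broken
by the lexicographically smallest (chrom, left, right) key and then read id,
so results are deterministic. Keeping a representative dampens rather than
erases genuine signal; the stricter alternative of deleting every cluster
that contains more than one distinct key is available behind
`drop_wobble_clusters` / `--drop-wobble-clusters`.

Clustering buckets distinct keys by (left chromosome, right chromosome,
⌊left/w⌋, ⌊right/w⌋) and scans the 3×3 neighbouring bins, so any pair within
distance `w` is found without an all-pairs pass; the brute-force all-pairs +
connected-components oracle exists only in the tests, where the bucketed
implementation is checked against it exactly on hundreds of random key sets.

The filter is intentionally conservative: genuinely distinct molecules whose
UMI pairs fall within the wobble radius are merged. On simulated sparse-locus
libraries (below) this costs roughly 1% of unique molecules at n = 5000;
the retained count is a lower bound on true complexity, which is exactly the
trade-off the stringent filter makes to keep low-complexity profiles free of
spurious peaks. Deduplication is performed per viewpoint group over all its
reads, cis and trans together, since a molecule is unique irrespective of
where its reporter maps. Sequence-based UMI correction and read-count-
weighted directional networks are out of scope.

## Interaction profiles

A raw profile counts retained informative reads per reporter fragment; a
read with reporters in k distinct fragments contributes one to each.
Profiles of duplicated-promoter group members are pooled by element-wise
sum. Normalization scales to a fixed genome-wide total (default 100 000
interactions; the denominator includes trans fragments, with a cis-only
denominator available for sensitivity analysis). Windowed profiles take the
mean over a centred window of `w` fragments (odd, default 5 — a declared
choice in the usual 4C range) per chromosome; windows never span
chromosomes, and edge windows shrink to the available fragments, so the
profile total is not conserved under windowing (asserted in tests via a
constant-profile fixed point and an interior sliding-mean oracle instead).
The window unit is fragments, not bp, because the method's resolution unit
is the restriction fragment. Differential profiles subtract group means of
per-replicate normalized profiles and carry per-fragment standard errors
SE = √(SE_A² + SE_B²), where SE of a single-replicate group is 0.
Replicate means are always computed after per-replicate normalization.

## QC statistics

- **cis fraction**: percentage of post-deduplication reporter events on the
  viewpoint chromosome; cis% + trans% = 100 exactly.
- **replicate correlation**: standard Pearson product-moment over the
  (optionally restricted) fragment vectors; zero-variance input is an error
  rather than a NaN.
- **fragments per read**: mean slices per read plus the full histogram,
  used to compare shearing protocols.
- **digestion efficiency** from qPCR: with ΔCt = Ct(junction assay) −
  Ct(genomic control assay) measured on both the 3C library and undigested
  genomic DNA, efficiency = 100 × (1 − E^−(ΔCt_3C − ΔCt_genomic)), clipped
  to [0, 100]. The genomic template calibrates out primer-pair differences.
  E is the per-cycle amplification factor, default 2 (perfect doubling);
  this arithmetic is a declared convention for the junction-vs-control Ct
  comparison, and E is exposed for non-ideal assays.
- **mass quantification**: least-squares fit of Ct against log₂(mass) over
  the genomic-DNA standards (ideal slope −1), inverted at the sample Ct;
  slope and r² are reported so poor curves are visible.

## C-String analysis

Probes target the two ends of each probed restriction fragment: the left
probe is the top-strand sequence of the first L bases, the right probe the
reverse complement of the last L bases (default L = 50 nt, configurable;
fragments shorter than L are skipped and reported). Counts are normalized
per sample to a fixed total over the probed fragments only (default 1000) —
the instrument sees nothing else — and the Capture-C profile is restricted
and renormalized over the same fragment set before correlation, making the
two vectors commensurable. Linearity of counts against input mass is checked
by ordinary least squares per tissue group, per probe and on the total.
Differential count profiles use the same mean-difference ± SE arithmetic as
differential interaction profiles. No background or spike-in correction is
modelled: raw counts in.

## Simulator

Each unique molecule is a two-fragment junction: the viewpoint fragment
ligated to a reporter drawn from the interaction distribution. Higher-order
concatemers, body sequencing errors, optical duplicates and chimeric
mis-ligations are not modelled — two-fragment molecules are sufficient to
exercise classification, deduplication and profile recovery, and reads are
emitted pre-aligned so no external aligner is needed (a FASTQ writer exists
for interoperability only).

- **Interaction distribution**: cis fragment i gets unnormalized weight
  (1 + peak_weight_i) × d_i^−α, with d_i the midpoint distance to the
  viewpoint midpoint, floored at one viewpoint-fragment length to avoid the
  singularity (the floor must be some fragment-scale length; the viewpoint's
  own length is used). α defaults to 1, a generic proximity-decay exponent.
  Cis weights are scaled to total mass 1 − t and trans fragments share mass
  t uniformly. Viewpoint and exclusion-zone fragments get probability 0 so
  simulated truth matches what the pipeline can observe.
- **Shearing**: insert size is normal (200 ± 30 bp, truncated to
  [50, 500] — sonication to ~200 bp), placed to span the ligation junction
  with at least 3 bp on each side. Under sonication the placement is
  uniform; under tagmentation each candidate end position is weighted `w`
  (≥ 1, default from config) when the base at that position is G or C, and
  the two insert ends are weighted jointly (product of per-end weights),
  reflecting that both breakpoints of a transposase-fragmented molecule are
  base-composition biased. This biased co-location of breakpoints across
  cells is the mechanism by which independent molecules acquire identical
  coordinate UMIs and are lost as apparent duplicates.
- **PCR duplication**: each molecule is emitted 1 + G times with G geometric
  (mean ρ) — the simplest over-dispersed duplication law. Each duplicate
  independently wobbles with probability ε: exactly one UMI coordinate
  shifts by ±1 or ±2 bp (uniform over the 8 end/shift combinations), moving
  the corresponding slice boundary; originals are never wobbled. No
  quantitative wobble rate is anchored to data; ε defaults to 0.05 and is a
  free parameter.
- Output order is shuffled; identical config + seed gives byte-identical
  output; every emitted read has a ground-truth record (molecule id,
  reporter, cis flag, duplicate/wobble flags, true UMI pair).

## Study conditions used by the checks

Problem sizes were chosen once as realistic for the regime the method
targets and then frozen:

- **Sparse locus** (duplicate-recovery and cis-fraction checks): 400 kb cis
  chromosome + 100 kb trans chromosome, 2 kb motif-free viewpoint fragment,
  GC 0.42 (mouse-like), n = 5000 molecules, ρ = 1 — a low-input library of a
  few thousand interactions over a globin-locus-scale region.
- **Planted-peak locus** (profile recovery): ~514-fragment map (120 kb cis +
  12 kb trans), three peaks of weight 30 at fragment offsets −40, +20, +60,
  n = 10⁵, t = 0.05. Recovery is measured on classified informative reads
  without duplicate filtering because this library is simulated without PCR
  duplication and the locus is deliberately saturated.
- **Collision fixture** (tagmentation vs sonication): 40 kb cis-only locus,
  600 bp viewpoint fragment, GC 0.55 (GC-rich relative to the 0.42 default),
  w = 5, n ∈ {4000, 16000}; small UMI space so the collision mechanism is
  measurable.

What passing these checks shows: the arithmetic of every stage is correct
against independent oracles, the dedup filter is exactly the declared
single-linkage clustering, and the pipeline recovers the generating
distribution when its assumptions hold. What they do not show: behaviour
under real mapping error beyond ±2 bp wobble, chimeric reads, concatemers,
reference bias, or real chromatin contact structure — the simulator's decay-
plus-peaks profile is a stand-in, not a biological model.

## Numerical and degenerate-input conventions

- Normalized profile totals are exact to 10⁻⁶ relative tolerance; bedGraph
  values are written with ≤ 6 significant decimals (round-tripped in tests).
- Zero-total profiles/columns, zero-variance correlation inputs, inverted
  intervals, even windows, missing Ct combinations and singular standard
  curves raise `ValueError` rather than returning NaN.
- Malformed input lines raise a `FormatError` carrying file and line number.
- Wobble shifts that would invert a slice or cross zero flip sign, so a
  wobbled UMI always differs from the original by exactly 1 or 2.
- Molecules whose fragments cannot accommodate any insert of the configured
  size range are resampled up to 20 times, then skipped and counted
  (`truth.attrs["n_skipped"]`).
- CLI exit codes: 0 success, 2 validation error, 3 data error.
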