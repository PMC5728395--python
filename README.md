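# licapc — low-input Capture-C analysis

`licapc` is a Python library and command-line toolkit for analysing
low-input Capture-C experiments: chromosome conformation capture (3C)
libraries enriched for chosen *viewpoint* restriction fragments (typically
gene promoters), sequenced at depths where PCR-duplicate artefacts dominate
unless they are filtered aggressively. It is aimed at regulatory-genomics
groups profiling chromatin interactions from small or rare cell populations
(tens of thousands of cells), where library complexity is low and every
spurious duplicate shows up as a fake peak.

The package covers the complete desk side of the workflow:

- **restriction_map** — in-silico digestion of a reference genome into the
  restriction-fragment coordinate system (DpnII/GATC by default).
- **classify** — assignment of aligned read slices to capture, reporter or
  excluded roles per viewpoint group (duplicated-gene promoters such as
  *Hba-a1*/*Hba-a2* are handled as one group).
- **dedup** — the stringent wobble-tolerant coordinate-UMI duplicate filter
  (see below).
- **profile** — per-fragment interaction profiles: pooling, normalization to
  100 000 interactions genome-wide, fragment-window smoothing, differential
  profiles with replicate standard errors.
- **qc_stats** — cis/trans composition, replicate Pearson correlation,
  fragments-per-read, qPCR-derived digestion efficiency and library mass.
- **cstring** — C-String analysis: probe design against fragment ends and
  normalization/linearity/comparison of PCR-free hybridization-counting
  (NanoString-style) tables.
- **sim3c** — a 3C library simulator with exhaustive ground truth, so every
  stage above is testable without sequencing data.

## The stringent duplicate filter

Each sequenced molecule carries two coordinate UMIs: the mapped 5′ end of
its first slice and the mapped 3′ end of its last slice, the random products
of sonication or tagmentation. Exact-coordinate deduplication misses PCR
duplicates whose ends were shifted 1–2 bp by sequencing or mapping error
("wobbly" ends). The stringent filter clusters reads by single linkage —
reads *i*, *j* link iff

```
d(i, j) = |Δleft| + |Δright| ≤ w        (chromosomes equal on both ends)
```

with wobble radius `w = 2` by default — and retains one representative per
cluster (the read whose exact key has the most copies). The filter is
deliberately conservative: genuinely distinct molecules within the wobble
radius are merged too, so retained counts are a lower bound on true library
complexity. Neighbour search is bucketed by chromosome pair and coarse
coordinate bins, so it runs in near-linear time; the all-pairs oracle exists
only in the test suite.

## Worked example

```python
from licapc import (SimConfig, simulate_library, build_profile, normalize_profile,
                    window_profile, filter_duplicates, cis_fraction, fragments_per_read)
from licapc.classify import classify_reads, default_exclusion
from licapc.toydata import toy_locus, peaks_at_offsets

# toy locus: 200 kb cis chromosome + 100 kb trans chromosome,
# 2 kb viewpoint fragment at the centre
genome, fmap, vp = toy_locus(cis_bp=200_000, trans_bp=100_000,
                             vp_fragment_bp=2000, seed=11)

# simulate a low-input library: 3000 molecules, two enhancer-like peaks,
# 20% trans, one PCR duplicate per molecule on average, 10% wobble
peaks = peaks_at_offsets(fmap, vp, offsets=(-30, 25), weight=40.0)
config = SimConfig(viewpoint_ids=(vp,), peaks=peaks, trans_fraction=0.2,
                   n_molecules=3000, dup_rate=1.0, wobble_prob=0.1, seed=7)
reads, truth = simulate_library(config, fmap, genome)

targets = {"Hba": {vp}}
classified, _ = classify_reads(reads, targets, default_exclusion(fmap, targets), fmap)
informative = [r for r in classified if r.informative]
unique, report = filter_duplicates(informative, max_wobble=2)

profile = normalize_profile(build_profile(unique, fmap, "Hba"))
windowed = window_profile(profile, window=5)
print(f"retained after stringent filter: {report.n_retained}")
print(f"normalized profile total: {profile.total:.1f}")
print(f"cis interactions: {cis_fraction(unique, fmap, 'chr1'):.1f}%")
```

prints

```
retained after stringent filter: 2863
normalized profile total: 100000.0
cis interactions: 78.6%
```

The simulator emitted 6075 reads from 3000 unique molecules; the stringent
filter keeps 2863 — below the true 3000 because wobble-radius clustering
also merges a small number of genuinely distinct molecules (the filter's
documented conservatism). The normalized profile sums to 100 000
genome-wide, the measured cis percentage tracks the simulated 80%, and the
two planted peak fragments are the two strongest values in the recovered
profile (10 443.6 and 8 208.2 normalized interactions versus 943.1 for the
next fragment).

## Command line

Everything is also available as one umbrella CLI:

```sh
licapc digest   --fasta genome.fa --motif GATC --out fragments.bed
licapc simulate --config sim.yaml --out-prefix sim --seed 7
licapc classify --reads sim.reads.tsv --map fragments.bed --targets targets.bed --out classified.tsv
licapc dedup    --classified classified.tsv --max-wobble 2 --report dedup.json --out unique.tsv
licapc profile  build|pool|normalize|window|diff ...
licapc qc       cis|correlate|fpr|digestion|mass ...
licapc cstring  design|normalize|linearity|compare|diff ...
licapc run      --config pipeline.yaml   # digest → classify → dedup → profile → QC
```

`licapc run` writes bedGraph tracks, a JSON QC report and a machine-readable
run manifest; reruns with the same config are byte-identical.

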