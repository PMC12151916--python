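# Methods

## Scope and model

TPE-OLD (telomere position effect over long distances) is the modulation of
genes and methylation states far from chromosome ends — up to ~10 Mb — by
telomere length, mediated by chromatin loops between the telomere and
interior loci. The package implements the discovery-side computations of a
TPE-OLD screen: mining telomere-anchored chromatin contacts from Hi-C read
pairs, calling methylation regions that track telomere length
monotonically, testing whether responsive features concentrate in
subtelomeres, scanning for the shared 35-bp WE consensus, and clustering
chromosome ends by their telomere-associated feature profiles. Wet-lab
stages (TRF, ddTRAP, ChIP, EMSA, FISH), read alignment, differential
expression estimation, array preprocessing/batch correction, de novo motif
discovery and GO analysis are out of scope; their outputs (DE tables,
per-end protein signals, a given consensus) are inputs here.

## Coordinate and format conventions

All in-memory intervals are 0-based half-open; BED shares that convention
on disk. Hi-C pairs files use a 7-column 4DN-style dialect (readID, chr1,
pos1, chr2, pos2, strand1, strand2) with **1-based** positions, converted
on read. Because a telomeric mate is typically unalignable, classification
operates on raw sequence: each pairs file has a TSV side-file keyed by
readID carrying both mate sequences and their mapping qualities (the
7-column dialect has no mapq field). SAM input with both mates carrying
sequence is also accepted (via pysam).

## Telomeric read classification

`count_tandem_units` reports the longest run of consecutive repeat units
evaluated in both orientations (TTAGGG and CCCTAA) over all six phase
offsets; the orientation with the longer run wins, forward on ties. With
zero mismatch tolerance (the default — the repeat is short and exact) a
regex fast path finds maximal exact runs; with tolerance, each unit copy
may carry up to `max_mismatch_per_unit` Hamming mismatches and all phases
are scanned explicitly. `total_units` counts copies across all maximal
tandem runs, so `max_tandem_units <= total_units <= len(seq)//6` always
holds. A read is telomeric iff its longest run reaches `min_units`
(default 7); runs of 1–6 units resemble short interstitial telomeric
sequences (ITS) and are discarded from the telomeric class.

The ITS discard is interpreted as two separately switchable rules:
(a) sub-threshold reads are not telomeric (above), and (b) anchors falling
inside *annotated* ITS arrays of ≥ 7 units are excluded, because such loci
are internal telomere look-alikes and the interaction cannot be attributed
to a chromosome end. Defaults: `min_mapq` 30 on the anchor mate (no
mapping-quality filter is externally prescribed; 30 is a conventional
uniqueness threshold), anchor padding ±100 bp, `merge_gap_bp` 0 (the
padding itself creates 200 bp of merge slack), recurrence threshold
`min_runs` 2 — the weakest reading of "found across datasets", exposed as
a flag. Pairs with two telomeric mates are tallied and dropped; every
discard reason is counted in an audit table because only survivors appear
in results.

## DMR calling and the directional filter

The caller is deliberately minimal and fully specified rather than a
re-implementation of a packaged array pipeline; the analytic content
carried here is the threshold set and the directional filter. Probe-level
delta is mean beta of the shorter-telomere condition minus the longer, so
**hyper = methylation gained as telomeres shorten** (matching the overall
hypermethylation trend upon shortening). Consecutive probes (inter-probe
gap ≤ 1000 bp, a default chosen near array probe spacing; configurable)
with a common delta sign and |delta| ≥ 0.05 form candidate regions; each
region's p-value is a two-sample t-test on replicate-level region means.
Regions must hold ≥ 7 probes, span > 50 bp (last minus first probe
position, strict) and reach p < 0.05. No multiple-testing correction is
applied by default (the cutoff is a plain 0.05); Benjamini–Hochberg is
available as an option. The directional filter keeps a first-comparison
region iff every later comparison (in telomere-length order 12v10, 10v8,
8v6; order is validated) contains an overlapping region (≥ 1 bp by
default) with the same direction.

Bisulfite amplicon matrices use the 1/0/X convention (methylated /
unmethylated / misaligned). Per-CpG mean = #1 / #non-X; the smoothed
series is a centered moving average (window 3) using available neighbors
at the edges — the exact smoother behind published per-CpG curves is not
prescribed, and a moving average is the transparent choice. All-X columns
are flagged and excluded.

## Subtelomere windows and enrichment

Each chromosome contributes a p-side and a q-side window of `span_bp`
(default 10 Mb), clipped at the midpoint on chromosomes shorter than twice
the span so windows never overlap; a 46-chromosome diploid karyotype gives
92 ends. Features count at most once: a feature qualifying for both
windows of a short chromosome goes to the nearer end, ties to p.
Membership defaults to any-overlap of the full feature interval (gene
bodies, not TSS). The "geometric" enrichment test is implemented as the
exact hypergeometric upper tail — the standard exact test for
observed-versus-expected membership in a region class — alongside a 1-df
chi-square of in/out counts against the universe proportion (flagged, but
still computed, when an expected cell is below 5). Both choices are
exposed as flags.

## WE motif scanning

Matching is plain Hamming distance (no indels), default 0 mismatches, on
both strands; every qualifying position is reported, including overlaps.
IUPAC ambiguity codes are rejected — the consensus is a literal 35-mer.
Gene association uses the locus ± 2 kb; DMR association uses direct
overlap. Proximity enrichment is a 2×2 chi-square (set membership ×
WE-association) without continuity correction, with the odds ratio
reported and degenerate margins returning p = 1 with a flag.

## Chromosome-end clustering

Non-timing feature columns are divided by their mean (exact mean 1 after
normalization; zero-mean columns cannot be normalized and are dropped with
a warning; missing data must be dropped as a column, never imputed). The
replication-timing column is affinely mapped so its minimum is −1
(earliest) and maximum +1 (latest). The DEG ratio is DEG count / gene
count per end, 0 (flagged) where an end has no genes.

Agglomeration is Ward.D2 on a supplied Manhattan dissimilarity matrix: the
Lance–Williams update applied to squared dissimilarities, with merge
heights reported on the unsquared scale and ties broken by the lowest
cluster-index pair for cross-platform determinism. Pairing the Ward
update with non-Euclidean dissimilarities is a *formal* application — the
variance-minimization argument behind Ward's method holds only for squared
Euclidean distances — but it is exactly what mainstream statistical
software computes under this name, and the tests pin it three ways:
a from-scratch greedy Ward-criterion oracle on Euclidean points, scipy's
`linkage(..., "ward")`, and R's `hclust(method = "ward.D2")` on Manhattan
distances.

## The synthetic-data generator

The generator emulates the statistical structure each stage assumes, not
the biophysics of the assays:

- **Genome**: 4 chromosomes × 100 kb, terminal (TTAGGG)×500 arrays at both
  ends (reverse-complement array at the q end), ITS arrays above and below
  the 7-unit threshold, 10 WE copies with random strand, 40 non-overlapping
  2-kb genes. All placements are collision-checked; infeasible packing
  raises rather than truncates.
- **Hi-C**: 16 runs. Planted contacts pair a read sampled from a terminal
  array with a read overlapping a planted WE site; each planted site
  appears in exactly `planted_recurrence` (default 16) runs. Noise pairs
  join random non-telomeric loci (500 per run by default). A
  `noise_telomeric_fraction` knob adds sporadic one-off telomere-anchored
  contacts; its default is 0 because the realistic per-run rate of such
  contacts scaled from a 3-Gb genome down to this 0.4-Mb one is far below
  one, and the knob exists precisely to study precision degradation. No
  distance-decay or restriction-fragment model is attempted.
- **Methylation**: five conditions (12/10/8/6/4 kb) × 4 replicates. Beta
  values are Beta(mean·c, (1−mean)·c) with concentration c = 50 (a noise
  scale giving per-probe SD ≈ 0.05–0.07, typical of array replicates).
  Planted regions shift their mean by per-step deltas (default ±0.15)
  along the series; monotone regions keep one sign, decoys flip sign, fall
  below 7 probes, or span ≤ 50 bp. Planted regions are mutually isolated
  by ≥ 3 kb and background probes keep ≥ 2 kb clear of them, so every
  emitted DMR is attributable to exactly one truth row and the probe-count
  and width filters act on exactly the planted probe sets.
- **Expression**: planted DEGs draw FDR < 0.05 and |log2FC| > 2; all other
  genes fail at least one threshold. DEGs are uniform over genes by
  default (subtelomeric proportion = background, the null of the
  enrichment test); a knob forces other proportions.

Determinism: a configuration seed fully determines every output byte; each
generator consumes an independent seeded stream so stages can be
regenerated in isolation.

What passing tests on this generator do **not** show: robustness to
alignment artifacts, copy-number variation, array batch effects, probe
cross-reactivity, subtelomeric segmental duplications, or realistic Hi-C
contact-frequency backgrounds — none of which are modeled.

## Verification conditions and problem sizes

The test and acceptance workloads use desk-scale sizes chosen to estimate
each property with useful precision: 16 runs × ~500 pairs for mining
recovery; 50 methylation seeds (≈ 600 region-comparison checks) for DMR
recall/precision; 2000 null draws (universe 5000, 20% in-window, sets of
200 — large enough that the discrete exact test is near-continuous) for
type-I calibration; 500 × 100 uniform features for window-rate checks; 100
seeds for two-group clustering recovery; brute-force oracles at n ≤ 8
(clustering) and universes ≤ 30 (hypergeometric). Measured at these
conditions: planted-interaction recall and precision 1.0; DMR recall ≈
0.91 and precision 1.0 (recall is bounded by probe runs occasionally split
by a single sub-threshold probe, a direct consequence of the specified
candidate-merge rule); decoy emission 0; sign-flip removal 100%; both
enrichment tests' empirical type-I error within [0.03, 0.07] at α = 0.05.

## Known limitations

- The recurrence threshold (`min_runs` 2) and anchor mapq filter are
  conventions, not externally fixed values; both are flags.
- The caller's splitting behavior slightly lowers recall for regions whose
  per-probe effect is near the delta cutoff; a smoothing pre-step would
  trade this against boundary precision and is deliberately not applied.
- Enrichment ignores covariates (gene density, replication timing);
  permutation-based tests respecting them are out of scope.
- The WE scan is exact-length Hamming matching; indel-tolerant or
  PWM-based scoring is out of scope.
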