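# telomir

Computational discovery of **telomere position effect over long distances
(TPE-OLD)**: telomere-length-dependent chromatin loops that modulate genes
and methylation up to ~10 Mb from human chromosome ends.

The package is a library (plus a thin `telomir` CLI) for the five
computations that drive a TPE-OLD screen:

1. **Hi-C telomere-contact mining** — classify each mate of a read pair by
   its longest tandem run of telomeric repeat units (TTAGGG / CCCTAA, all
   six phase offsets, both orientations), keep pairs with exactly one
   telomeric mate (≥ 7 units; shorter runs are interstitial-telomere-like
   and discarded), pad the genomic anchor by ±100 bp and emit only windows
   supported by ≥ 2 independent Hi-C runs.
2. **Telomere-length DMR filtering** — call differentially methylated
   regions between adjacent telomere-length conditions (12/10/8/6/4 kb) with
   the thresholds ≥ 7 probes, width > 50 bp and p < 0.05, then keep only
   regions with a *constant* hyper- or hypomethylation direction across
   12v10, 10v8 and 8v6.
3. **Subtelomeric enrichment** — two 10-Mb windows per chromosome (92 ends
   for a diploid karyotype); exact hypergeometric upper-tail or 1-df
   chi-square tests of a feature set against its universe.
4. **WE motif scanning** — Hamming scanning of the 35-bp "Wide Effect"
   consensus `CCTCCCAAAGTGCTGGGATTACAGGCGTGAGCCAC` on both strands, plus
   gene/DMR association within ±2 kb and proximity chi-square tests.
5. **Chromosome-end clustering** — per-end feature tables (WE occurrences,
   DEG counts, DEG ratio corrected for gene density, ITS, replication
   timing) normalized to column mean 1 (timing mapped to [−1, 1]), clustered
   by Ward.D2 agglomeration on Manhattan distances.

A seeded synthetic-data generator (`telomir.synth`) produces genomes with
terminal (TTAGGG)n arrays, interstitial telomeric sequences above and below
the 7-unit threshold, planted WE copies, replicate Hi-C runs with planted
recurrent telomere contacts, beta-value series with planted monotone and
decoy DMRs, and DE tables — each with truth tables, so every stage is
testable without any download.

Auxiliary computations: population doublings `PD = ln(N_final/N_initial)/ln 2`,
DEG thresholding (FDR < 0.05 and |log2FC| > 2, strict), and gene-list
overlap percentages.

## Worked example

```python
from telomir import SimulationConfig, generate_genome, generate_hic_runs
from telomir.hicmine import read_pairs, extract_telomeric_contacts, aggregate_recurrent

config = SimulationConfig(seed=1, n_hic_runs=16, contacts_per_run=500)
genome = generate_genome(config)
truth = generate_hic_runs(genome, config, "example_out/hic")

contacts = []
for run in range(config.n_hic_runs):
    run_id = f"run_{run:02d}"
    records = read_pairs(f"example_out/hic/{run_id}.pairs",
                         f"example_out/hic/{run_id}.seqs.tsv")
    run_contacts, _ = extract_telomeric_contacts(
        records, run_id, genome.telomere_intervals, genome.its_intervals)
    contacts.extend(run_contacts)

interactions = aggregate_recurrent(contacts, genome.chrom_sizes,
                                   pad_bp=100, min_runs=2)
```

This prints (via `examples/02_mine_hic_contacts.py`):

```
96 telomere-anchored contacts across 16 runs
6 recurrent interactions (>= 2 runs):
  chr1:34275-34599  runs=16  nearest_end=chr1_p
  chr2:14081-14397  runs=16  nearest_end=chr2_p
  ...
truth table planted 6 sites; every one should appear above
```

96 = 6 planted sites × 16 runs: every informative pair was classified and
anchored, and the six merged windows are exactly the planted WE sites —
recall and precision 1.0 against the truth table. The `examples/` directory
holds one short script per capability (simulation, mining, DMR calling,
enrichment, motif scanning, clustering, full pipeline); each prints its
results and a line on what they mean.

## Command line

```bash
telomir simulate --out sim --seed 1
telomir hic-mine --pairs 'sim/run_*.pairs' --telomere-bed sim/telomeres.bed \
    --its-bed sim/its.bed --chrom-sizes sim/chrom.sizes --out interactions.bed
telomir dmr call --beta sim/beta.tsv --manifest sim/manifest.tsv \
    --condition-a 12kb --condition-b 10kb --out dmrs_12v10.tsv
telomir enrich --features degs.bed --universe genes.bed \
    --chrom-sizes sizes.tsv --span 10000000 --test hypergeometric
telomir run-all --out full_run --seed 1
```

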