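"""Build a seeded synthetic genome with telomeres, ITS arrays, WE sites and
genes, and show what was planted where."""

from telomir import SimulationConfig, generate_genome

config = SimulationConfig(seed=1)
genome = generate_genome(config, out_dir="example_out/genome")

print(f"chromosomes: {genome.chrom_names} ({config.chrom_length_bp:,} bp each)")
print(f"terminal arrays: (TTAGGG) x {genome.telomere_array_units} at both ends")
print(f"planted WE consensus copies: {len(genome.we_intervals)}")
for chrom, start, end, strand in genome.we_intervals[:3]:
    print(f"  {chrom}:{start}-{end} ({strand})")
print("interstitial telomeric arrays (unit counts):",
      [u for *_i, u in genome.its_intervals])
print(f"genes: {len(genome.gene_intervals)}")
# Arrays of >= 7 units mimic telomere-like interior loci that the Hi-C
# miner must not mistake for true chromosome ends; the shorter ones
# exercise the sub-threshold discard rule.
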