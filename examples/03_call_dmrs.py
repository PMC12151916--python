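"""Call DMRs between adjacent telomere-length conditions and keep only the
regions whose direction is constant along 12 -> 10 -> 8 -> 6 kb.

A region must hold >= 7 probes, span > 50 bp and pass p < 0.05; "hyper"
means methylation gained as telomeres shorten. The planted sign-flipping
decoy is called in single comparisons but removed by the directional
filter.
"""

from telomir import SimulationConfig, generate_genome, generate_methylation_series
from telomir.methylation import call_dmrs, dmrs_to_frame, filter_directional

config = SimulationConfig(seed=4)
genome = generate_genome(config)
manifest, beta, truth = generate_methylation_series(
    genome, config, "example_out/meth"
)

conditions = config.conditions  # ("12kb", "10kb", "8kb", "6kb", "4kb")
dmr_sets = []
for a, b in zip(conditions, conditions[1:3 + 1]):
    dmrs = call_dmrs(beta, manifest, a, b)
    dmr_sets.append(dmrs)
    print(f"{a} vs {b}: {len(dmrs)} DMRs "
          f"({sum(d.direction == 'hyper' for d in dmrs)} hyper)")

directional = filter_directional(dmr_sets)
print(f"\ndirectionally consistent across all three comparisons: {len(directional)}")
print(dmrs_to_frame(directional).to_string(index=False))
# monotone planted regions survive unless beta noise splits their probe
# run in one comparison; decoys never survive
print("\nplanted truth:")
print(truth[["region", "chrom", "n_probes", "width_bp", "monotone"]].to_string(index=False))
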