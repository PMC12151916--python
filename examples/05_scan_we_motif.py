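"""Scan a genome for the 35-bp WE consensus and associate hits with genes.

Hits on the minus strand are reverse-complement matches. Association uses
the gene locus +/- 2 kb, the window within which the motif co-occurs with
telomere-responsive genes.
"""

import pandas as pd

from telomir import SimulationConfig, WE_CONSENSUS, generate_genome, scan_motif
from telomir.motif import associate_hits

print(f"WE consensus ({len(WE_CONSENSUS)} nt): {WE_CONSENSUS}")

genome = generate_genome(SimulationConfig(seed=1))
hits = scan_motif(genome.sequences, max_mismatch=0, both_strands=True)
print(f"{len(hits)} exact occurrences "
      f"({sum(h.strand == '-' for h in hits)} on the minus strand)")

genes = pd.DataFrame(
    [(c, s, e, n) for c, s, e, n in genome.gene_intervals],
    columns=["chrom", "start", "end", "name"],
)
assoc = associate_hits(hits, genes=genes, flank_bp=2000)
if assoc.empty:
    print("no hit falls within 2 kb of a gene in this simulation")
else:
    print("gene associations (hit within gene locus +/- 2 kb):")
    print(assoc.to_string(index=False))
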