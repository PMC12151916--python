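"""Scanning for the 35-bp Wide Effect (WE) consensus and proximity tests.

The WE motif is an Alu-derived 35-mer shared by telomere-length-responsive
genes and methylation regions. Scanning is plain Hamming matching (no
indels) of the consensus and, optionally, its reverse complement at every
position of the target windows; association links hits to gene loci within a
flank (default +/-2 kb) and to overlapping DMRs; enrichment contrasts
WE-association rates between a gene set and its background with a 1-df
chi-square test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hicmine import revcomp
from .io import overlaps
from .subtelomere import EnrichmentResult

WE_CONSENSUS = "CCTCCCAAAGTGCTGGGATTACAGGCGTGAGCCAC"


@dataclass(frozen=True)
class MotifHit:
    chrom: str
    start: int
    end: int
    strand: str
    mismatches: int
    source_region: str


def _seq_to_codes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _hamming_positions(seq: str, pattern: str, max_mismatch: int) -> tuple:
    """Start positions and mismatch counts of approximate pattern matches."""
    n, k = len(seq), len(pattern)
    if n < k:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    codes = _seq_to_codes(seq)
    pat = _seq_to_codes(pattern)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    mism = (windows != pat).sum(axis=1)
    idx = np.flatnonzero(mism <= max_mismatch)
    return idx, mism[idx]


def scan_motif(
    sequences: Mapping[str, str],
    consensus: str = WE_CONSENSUS,
    intervals: Sequence[tuple] | None = None,
    max_mismatch: int = 0,
    both_strands: bool = True,
) -> list[MotifHit]:
    """All approximate occurrences of a consensus in the given windows.

    sequences maps chromosome name to sequence (a pyfaidx.Fasta works once
    wrapped with str()); intervals restricts the scan to
    (chrom, start, end[, name]) windows, defaulting to whole chromosomes.
    Every window position whose Hamming distance to the consensus (or its
    reverse complement when both_strands) is <= max_mismatch yields one hit;
    overlapping hits are all reported, ordered by (chrom, start, strand).
    """
    consensus = consensus.upper()
    if set(consensus) - set("ACGT"):
        raise ValueError("consensus must be plain ACGT (no ambiguity codes)")
    if intervals is None:
        intervals = [
            (chrom, 0, len(str(sequences[chrom])), "genome") for chrom in sequences
        ]
    rc = revcomp(consensus)
    hits: list[MotifHit] = []
    for iv in intervals:
        chrom, start, end = iv[0], int(iv[1]), int(iv[2])
        name = str(iv[3]) if len(iv) > 3 else f"{chrom}:{start}-{end}"
        window = str(sequences[chrom])[start:end]
        for pattern, strand in ((consensus, "+"), (rc, "-")):
            if strand == "-" and not both_strands:
                continue
            pos, mism = _hamming_positions(window, pattern, max_mismatch)
            for p, m in zip(pos, mism):
                hits.append(
                    MotifHit(
                        chrom,
                        start + int(p),
                        start + int(p) + len(consensus),
                        strand,
                        int(m),
                        name,
                    )
                )
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def associate_hits(
    hits: Sequence[MotifHit],
    genes: pd.DataFrame | None = None,
    dmrs: pd.DataFrame | None = None,
    flank_bp: int = 2000,
) -> pd.DataFrame:
    """Label each hit with nearby genes (locus +/- flank_bp) and overlapping DMRs.

    genes/dmrs are BED-like frames (chrom, start, end, name). Returns one
    row per (hit, feature) association with a feature_type column; genes and
    DMRs with at least one hit are the "WE-associated" features downstream.
    """
    rows = []
    for i, h in enumerate(hits):
        if genes is not None:
            for _, g in genes[genes["chrom"] == h.chrom].iterrows():
                if overlaps(h.start, h.end, g["start"] - flank_bp, g["end"] + flank_bp):
                    rows.append((i, h.chrom, h.start, h.end, "gene", g["name"]))
        if dmrs is not None:
            for _, d in dmrs[dmrs["chrom"] == h.chrom].iterrows():
                if overlaps(h.start, h.end, d["start"], d["end"]):
                    rows.append((i, h.chrom, h.start, h.end, "dmr", d["name"]))
    return pd.DataFrame(
        rows,
        columns=["hit_index", "chrom", "start", "end", "feature_type", "feature"],
    )


def we_associated_genes(
    hits: Sequence[MotifHit], genes: pd.DataFrame, flank_bp: int = 2000
) -> set[str]:
    assoc = associate_hits(hits, genes=genes, flank_bp=flank_bp)
    if assoc.empty:
        return set()
    return set(assoc.loc[assoc["feature_type"] == "gene", "feature"])


def proximity_enrichment(
    set_genes: set[str],
    background_genes: set[str],
    associated_genes: set[str],
) -> EnrichmentResult:
    """2x2 chi-square: gene-set membership vs WE-association, 1 df.

    set_genes must be a subset of background_genes (the universe).
    Degenerate margins (all or no genes associated, or an empty set) return
    p=1 with a "degenerate" flag. The statistic field carries chi-square;
    an infinite odds ratio is flagged "or-infinite".
    """
    if not set_genes <= background_genes:
        raise ValueError("gene set must be a subset of the background")
    a = len(set_genes & associated_genes)
    b = len(set_genes) - a
    rest = background_genes - set_genes
    c = len(rest & associated_genes)
    d = len(rest) - c
    n = a + b + c + d
    flags: list[str] = []
    assoc_rate_set = a / (a + b) if (a + b) else 0.0
    assoc_rate_bg = (a + c) / n if n else 0.0
    if n == 0 or (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        flags.append("degenerate")
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=False)
    if b * c == 0 and a * d > 0:
        flags.append("or-infinite")
        odds = float("inf")
    elif b * c == 0:
        odds = float("nan")
    else:
        odds = (a * d) / (b * c)
    res = EnrichmentResult(
        n_universe=n,
        n_in_windows_universe=a + c,
        n_set=a + b,
        n_set_in_windows=a,
        expected_proportion=assoc_rate_bg,
        observed_proportion=assoc_rate_set,
        test_name="chisq-2x2",
        statistic=float(chi2),
        p_value=float(p),
        flags=flags,
        odds_ratio=odds,
    )
    return res
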