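"""Seeded synthetic data with the statistical structure the analysis assumes.

The generator builds a small genome whose chromosomes carry terminal
(TTAGGG)n arrays at both ends, interstitial telomeric sequences (ITS) above
and below the 7-unit threshold, planted copies of the 35-bp WE consensus,
and gene loci; on top of it, replicate Hi-C runs with planted recurrent
telomere-locus contacts plus configurable noise, a methylation beta matrix
across five telomere-length conditions (12/10/8/6/4 kb) with planted
monotone and decoy DMRs, and a differential-expression table. Every output
is a plain-text interchange format (FASTA, BED6, pairs + TSV side-file,
TSV) accompanied by truth tables sufficient to score recall and precision
of each downstream stage, and the seed fully determines every byte.

Default parameter values mirror the study conditions the pipeline was built
for: 16 Hi-C runs, a 7-unit telomeric classification threshold, five
telomere-length conditions with four replicates each, planted DMRs of at
least seven probes spanning more than 50 bp with a per-step beta shift of
0.15, and a Beta noise model with concentration 50.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .hicmine import TELOMERE_UNIT, revcomp
from .io import ensure_dir, write_bed, write_chrom_sizes, write_fasta
from .motif import WE_CONSENSUS


class PlacementError(ValueError):
    """Planted features cannot be packed into the chromosomes without overlap."""


@dataclass(frozen=True)
class PlantedDMR:
    """A methylation region planted into the synthetic beta matrix.

    deltas gives the per-step change of the region's mean beta along the
    telomere-length series (12->10->8->6->4 kb, so four steps for five
    conditions). A monotone region keeps one sign throughout; a decoy
    flips sign at least once and must be rejected by the directional
    filter downstream.
    """

    name: str
    n_probes: int
    width_bp: int
    deltas: tuple[float, ...]
    baseline: float = 0.3
    subtelomeric: bool = False

    @property
    def monotone(self) -> bool:
        signs = {np.sign(d) for d in self.deltas if d != 0}
        return len(signs) == 1


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    # genome
    n_chroms: int = 4
    chrom_length_bp: int = 100_000
    telomere_units: int = 500
    n_its_below_threshold: int = 4
    n_its_at_or_above_threshold: int = 3
    its_mismatch_rate: float = 0.0
    n_we_sites: int = 10
    n_genes: int = 40
    gene_length_bp: int = 2_000
    subtel_span_bp: int = 20_000
    # Hi-C
    n_hic_runs: int = 16
    n_planted_contact_sites: int = 6
    planted_recurrence: int = 16
    contacts_per_run: int = 500
    noise_contact_rate: float = 1.0
    noise_telomeric_fraction: float = 0.0
    read_length_bp: int = 80
    # methylation
    conditions: tuple[str, ...] = ("12kb", "10kb", "8kb", "6kb", "4kb")
    n_replicates: int = 4
    n_background_probes: int = 1500
    beta_concentration: float = 50.0
    planted_dmrs: tuple[PlantedDMR, ...] = (
        PlantedDMR("hyper_subtel_1", 10, 400, (0.15, 0.15, 0.15, 0.15), 0.2, True),
        PlantedDMR("hyper_interior_1", 8, 300, (0.15, 0.15, 0.15, 0.15), 0.2, False),
        PlantedDMR("hypo_subtel_1", 9, 350, (-0.15, -0.15, -0.15, -0.15), 0.8, True),
        PlantedDMR("decoy_signflip_1", 10, 400, (0.15, -0.15, 0.15, -0.15), 0.4, False),
        PlantedDMR("decoy_fewprobes_1", 6, 300, (0.3, 0.3, 0.0, 0.0), 0.2, False),
        PlantedDMR("decoy_narrow_1", 8, 40, (0.3, 0.3, 0.0, 0.0), 0.2, False),
    )
    # expression
    n_planted_degs: int = 8
    subtelomeric_deg_proportion: float | None = None

    def validate(self) -> None:
        if self.planted_recurrence > self.n_hic_runs:
            raise ValueError("planted_recurrence cannot exceed n_hic_runs")
        if self.read_length_bp < 7 * len(TELOMERE_UNIT):
            raise ValueError(
                "read_length_bp too short to hold 7 telomeric units; "
                "telomeric reads would be unconstructible"
            )
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per condition")
        if any(d.n_probes < 1 for d in self.planted_dmrs):
            raise ValueError("planted DMR probe counts must be >= 1")
        for d in self.planted_dmrs:
            if len(d.deltas) != len(self.conditions) - 1:
                raise ValueError(
                    f"planted DMR {d.name}: deltas must have n_conditions-1 steps"
                )
            means = d.baseline + np.concatenate([[0], np.cumsum(d.deltas)])
            if (means < 0).any() or (means > 1).any():
                raise ValueError(
                    f"planted DMR {d.name}: condition means leave [0, 1]"
                )


@dataclass
class GenomeModel:
    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    telomere_array_units: int
    telomere_intervals: list[tuple]  # (chrom, start, end, side)
    its_intervals: list[tuple]  # (chrom, start, end, units)
    we_intervals: list[tuple]  # (chrom, start, end, strand)
    gene_intervals: list[tuple]  # (chrom, start, end, name)
    sequences: dict[str, str] = field(default_factory=dict)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.chrom_lengths)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _mutate_unit(rng: np.random.Generator, unit: str, rate: float) -> str:
    if rate <= 0:
        return unit
    out = list(unit)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def _place_features(
    rng: np.random.Generator,
    lengths: Sequence[int],
    interior: tuple[int, int],
    n_feats: int,
    feat_len,
    occupied: dict[int, list[tuple[int, int]]] | None = None,
    max_tries: int = 20_000,
) -> list[tuple[int, int, int]]:
    """Greedy non-overlapping placement of features on chromosomes.

    `occupied` is shared across calls so features of different categories
    never collide. Returns (chrom index, start, end) triples; raises
    PlacementError when packing fails.
    """
    placed: list[tuple[int, int, int]] = []
    if occupied is None:
        occupied = {i: [] for i in range(len(lengths))}
    else:
        for i in range(len(lengths)):
            occupied.setdefault(i, [])
    for f in range(n_feats):
        flen = feat_len(f) if callable(feat_len) else feat_len
        for _ in range(max_tries):
            ci = int(rng.integers(0, len(lengths)))
            lo, hi = interior[0], lengths[ci] - interior[1] - flen
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            end = start + flen
            if all(e <= start or s >= end for s, e in occupied[ci]):
                occupied[ci].append((start, end))
                placed.append((ci, start, end))
                break
        else:
            raise PlacementError(
                f"could not place feature {f} of length {flen} without overlap"
            )
    return placed


def generate_genome(
    config: SimulationConfig, out_dir: str | None = None
) -> GenomeModel:
    """Build the synthetic genome and write FASTA + BED annotations.

    Each chromosome starts with (TTAGGG) x telomere_units and ends with the
    reverse-complement array (CCCTAA repeats on the plus strand). Genes,
    ITS arrays and WE consensus copies are packed without overlap into the
    interior, at least 1 kb away from the terminal arrays. Re-running with
    the same seed reproduces every output byte.
    """
    config.validate()
    rng = _rng(config, 1)
    unit = TELOMERE_UNIT
    tel_len = config.telomere_units * len(unit)
    margin = tel_len + 1000
    names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    lengths = [config.chrom_length_bp] * config.n_chroms
    if config.chrom_length_bp < 2 * margin + 5000:
        raise PlacementError("chromosomes too short for the requested telomeres")

    seqs = [list(_random_seq(rng, L)) for L in lengths]
    telomere_intervals = []
    for ci, name in enumerate(names):
        seqs[ci][:tel_len] = list(unit * config.telomere_units)
        seqs[ci][-tel_len:] = list(revcomp(unit) * config.telomere_units)
        telomere_intervals.append((name, 0, tel_len, "p"))
        telomere_intervals.append((name, lengths[ci] - tel_len, lengths[ci], "q"))

    interior = (margin, margin)
    occupied: dict[int, list[tuple[int, int]]] = {}
    its_units = [
        int(rng.integers(2, 7)) for _ in range(config.n_its_below_threshold)
    ] + [
        int(rng.integers(7, 13)) for _ in range(config.n_its_at_or_above_threshold)
    ]
    its_sites = _place_features(
        rng, lengths, interior, len(its_units),
        lambda i: its_units[i] * len(unit), occupied,
    )
    its_intervals = []
    for (ci, start, end), units in zip(its_sites, its_units):
        array = "".join(
            _mutate_unit(rng, unit, config.its_mismatch_rate) for _ in range(units)
        )
        seqs[ci][start:end] = list(array)
        its_intervals.append((names[ci], start, end, units))

    we_sites = _place_features(
        rng, lengths, interior, config.n_we_sites, len(WE_CONSENSUS), occupied
    )
    we_intervals = []
    for ci, start, end in we_sites:
        strand = "+" if rng.random() < 0.5 else "-"
        copy = WE_CONSENSUS if strand == "+" else revcomp(WE_CONSENSUS)
        seqs[ci][start:end] = list(copy)
        we_intervals.append((names[ci], start, end, strand))

    gene_sites = _place_features(
        rng, lengths, interior, config.n_genes, config.gene_length_bp, occupied
    )
    gene_intervals = [
        (names[ci], start, end, f"GENE{gi + 1:03d}")
        for gi, (ci, start, end) in enumerate(gene_sites)
    ]
    gene_intervals.sort(key=lambda g: (g[0], g[1]))

    # planted features must not collide with each other; the placement
    # helper guarantees that per category but not across categories, so we
    # re-check globally and fail loudly rather than truncate.
    all_iv = (
        [(names[ci], s, e) for ci, s, e in its_sites]
        + [(names[ci], s, e) for ci, s, e in we_sites]
        + [(names[ci], s, e) for ci, s, e in gene_sites]
    )
    all_iv.sort()
    for a, b in zip(all_iv, all_iv[1:]):
        if a[0] == b[0] and b[1] < a[2]:
            raise PlacementError(f"planted features overlap at {a} / {b}")

    genome = GenomeModel(
        chrom_names=names,
        chrom_lengths=dict(zip(names, lengths)),
        telomere_array_units=config.telomere_units,
        telomere_intervals=telomere_intervals,
        its_intervals=sorted(its_intervals),
        we_intervals=sorted(we_intervals),
        gene_intervals=gene_intervals,
        sequences={name: "".join(s) for name, s in zip(names, seqs)},
    )
    if out_dir is not None:
        write_genome(genome, out_dir)
    return genome


def write_genome(genome: GenomeModel, out_dir: str) -> None:
    ensure_dir(out_dir)
    write_fasta(
        ((n, genome.sequences[n]) for n in genome.chrom_names),
        os.path.join(out_dir, "genome.fa"),
    )
    write_chrom_sizes(genome.chrom_lengths, os.path.join(out_dir, "chrom.sizes"))
    write_bed(
        pd.DataFrame(
            [(c, s, e, f"tel_{c}_{side}", 0, "+") for c, s, e, side in genome.telomere_intervals],
            columns=["chrom", "start", "end", "name", "score", "strand"],
        ),
        os.path.join(out_dir, "telomeres.bed"),
    )
    write_bed(
        pd.DataFrame(
            [(c, s, e, f"its_{i}", units, "+") for i, (c, s, e, units) in enumerate(genome.its_intervals)],
            columns=["chrom", "start", "end", "name", "score", "strand"],
        ),
        os.path.join(out_dir, "its.bed"),
    )
    write_bed(
        pd.DataFrame(
            [(c, s, e, f"we_{i}", 0, strand) for i, (c, s, e, strand) in enumerate(genome.we_intervals)],
            columns=["chrom", "start", "end", "name", "score", "strand"],
        ),
        os.path.join(out_dir, "we_sites.bed"),
    )
    write_bed(
        pd.DataFrame(
            [(c, s, e, name, 0, "+") for c, s, e, name in genome.gene_intervals],
            columns=["chrom", "start", "end", "name", "score", "strand"],
        ),
        os.path.join(out_dir, "genes.bed"),
    )


def _telomeric_read(
    rng: np.random.Generator, genome: GenomeModel, read_len: int
) -> tuple[str, int, str]:
    """A read drawn from a random terminal array: (chrom, pos, seq)."""
    chrom, start, end, _side = genome.telomere_intervals[
        int(rng.integers(0, len(genome.telomere_intervals)))
    ]
    pos = int(rng.integers(start, end - read_len))
    return chrom, pos, genome.sequences[chrom][pos : pos + read_len]


def _nontelomeric_read(
    rng: np.random.Generator, genome: GenomeModel, read_len: int
) -> tuple[str, int, str]:
    tel_len = genome.telomere_array_units * 6
    while True:
        chrom = genome.chrom_names[int(rng.integers(0, len(genome.chrom_names)))]
        L = genome.chrom_lengths[chrom]
        pos = int(rng.integers(tel_len, L - tel_len - read_len))
        seq = genome.sequences[chrom][pos : pos + read_len]
        # reject reads that happen to look telomeric (planted ITS overlap)
        if TELOMERE_UNIT * 7 not in seq and revcomp(TELOMERE_UNIT) * 7 not in seq:
            return chrom, pos, seq


def generate_hic_runs(
    genome: GenomeModel, config: SimulationConfig, out_dir: str
) -> pd.DataFrame:
    """Write n_hic_runs pairs files with planted recurrent telomere contacts.

    Planted contacts pair a read from a terminal telomere array with a read
    overlapping a planted WE site; each planted site appears in exactly
    `planted_recurrence` runs (chosen deterministically from the seed).
    Noise contacts (round(noise_contact_rate * contacts_per_run) per run)
    pair random non-telomeric loci, except that a `noise_telomeric_fraction`
    of them pair a telomeric read with a random locus, emulating sporadic
    one-off telomere contacts that recurrence filtering must suppress.

    Writes run_XX.pairs / run_XX.seqs.tsv and hic_truth.tsv; returns the
    truth table (site, chrom, start, end, runs).
    """
    config.validate()
    ensure_dir(out_dir)
    rng = _rng(config, 2)
    read_len = config.read_length_bp
    n_sites = min(config.n_planted_contact_sites, len(genome.we_intervals))
    site_idx = sorted(
        rng.choice(len(genome.we_intervals), size=n_sites, replace=False).tolist()
    )
    truth_rows = []
    runs_for_site: list[list[int]] = []
    for rank, si in enumerate(site_idx):
        chosen = sorted(
            rng.choice(
                config.n_hic_runs, size=config.planted_recurrence, replace=False
            ).tolist()
        )
        runs_for_site.append(chosen)
        chrom, start, end, strand = genome.we_intervals[si]
        truth_rows.append(
            {
                "site": f"we_{si}",
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": strand,
                "runs": ",".join(f"run_{r:02d}" for r in chosen),
            }
        )
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(os.path.join(out_dir, "hic_truth.tsv"), sep="\t", index=False)

    n_noise = int(round(config.noise_contact_rate * config.contacts_per_run))
    for run in range(config.n_hic_runs):
        run_id = f"run_{run:02d}"
        pairs_lines = []
        seq_lines = ["readID\tseq1\tseq2\tmapq1\tmapq2"]
        counter = 0

        def emit(c1, p1, s1, c2, p2, s2, q1, q2):
            nonlocal counter
            rid = f"{run_id}_r{counter:06d}"
            counter += 1
            strand1 = "+" if rng.random() < 0.5 else "-"
            strand2 = "+" if rng.random() < 0.5 else "-"
            pairs_lines.append(
                f"{rid}\t{c1}\t{p1 + 1}\t{c2}\t{p2 + 1}\t{strand1}\t{strand2}"
            )
            seq_lines.append(f"{rid}\t{s1}\t{s2}\t{q1}\t{q2}")

        for rank, si in enumerate(site_idx):
            if run not in runs_for_site[rank]:
                continue
            chrom, start, end, _ = genome.we_intervals[si]
            tc, tp, tseq = _telomeric_read(rng, genome, read_len)
            offset = int(rng.integers(0, max(1, read_len - (end - start))))
            astart = max(0, start - offset)
            aseq = genome.sequences[chrom][astart : astart + read_len]
            emit(tc, tp, tseq, chrom, astart, aseq, 0, 60)
        for _ in range(n_noise):
            if rng.random() < config.noise_telomeric_fraction:
                tc, tp, tseq = _telomeric_read(rng, genome, read_len)
                nc, npos, nseq = _nontelomeric_read(rng, genome, read_len)
                emit(tc, tp, tseq, nc, npos, nseq, 0, 60)
            else:
                c1, p1, s1 = _nontelomeric_read(rng, genome, read_len)
                c2, p2, s2 = _nontelomeric_read(rng, genome, read_len)
                emit(c1, p1, s1, c2, p2, s2, 60, 60)
        with open(os.path.join(out_dir, f"{run_id}.pairs"), "w") as fh:
            fh.write("## pairs format v1.0\n")
            fh.write("#columns: readID chr1 pos1 chr2 pos2 strand1 strand2\n")
            fh.write("\n".join(pairs_lines) + ("\n" if pairs_lines else ""))
        with open(os.path.join(out_dir, f"{run_id}.seqs.tsv"), "w") as fh:
            fh.write("\n".join(seq_lines) + "\n")
    return truth


def _probe_positions_for_region(
    rng: np.random.Generator,
    genome: GenomeModel,
    dmr: PlantedDMR,
    span: int,
    taken: list[tuple[str, int, int]],
    isolation_bp: int = 3000,
) -> tuple[str, np.ndarray]:
    """Pick a genomic window for a planted region, isolated from the others.

    Regions keep `isolation_bp` clear of previously placed regions so probe
    runs from different planted regions can never interleave or merge and
    every emitted DMR is attributable to exactly one truth row.
    """
    tel_len = genome.telomere_array_units * 6
    for _ in range(10_000):
        chrom = genome.chrom_names[int(rng.integers(0, len(genome.chrom_names)))]
        L = genome.chrom_lengths[chrom]
        if dmr.subtelomeric:
            lo = tel_len
            hi = min(span, L // 2) - dmr.width_bp
            if rng.random() < 0.5:
                start = int(rng.integers(lo, max(lo + 1, hi)))
            else:
                qlo = max(L - span, L // 2)
                start = int(rng.integers(qlo, L - tel_len - dmr.width_bp))
        else:
            start = int(rng.integers(span, L - span - dmr.width_bp))
        end = start + dmr.width_bp
        if any(
            c == chrom and start - isolation_bp < e and s < end + isolation_bp
            for c, s, e in taken
        ):
            continue
        taken.append((chrom, start, end))
        break
    else:
        raise PlacementError(f"could not isolate planted region {dmr.name}")
    if dmr.n_probes == 1:
        pos = np.array([start])
    else:
        pos = start + np.round(
            np.linspace(0, dmr.width_bp, dmr.n_probes)
        ).astype(int)
    return chrom, np.unique(pos)


def generate_methylation_series(
    genome: GenomeModel, config: SimulationConfig, out_dir: str
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Probe manifest + beta matrix across the telomere-length conditions.

    Background probes have a constant mean per probe across conditions;
    planted regions shift their mean by the configured per-step deltas along
    the condition series. Beta noise is Beta(mean * c, (1 - mean) * c) with
    concentration c. Returns (manifest, beta matrix, truth table) and
    writes manifest.tsv, beta.tsv and meth_truth.tsv.
    """
    config.validate()
    ensure_dir(out_dir)
    rng = _rng(config, 3)
    conds = list(config.conditions)
    samples = [f"{c}_rep{r + 1}" for c in conds for r in range(config.n_replicates)]

    rows = []  # (probe, chrom, pos, means per condition)
    truth_rows = []
    tel_len = genome.telomere_array_units * 6
    taken: list[tuple[str, int, int]] = []
    for dmr in config.planted_dmrs:
        chrom, positions = _probe_positions_for_region(
            rng, genome, dmr, config.subtel_span_bp, taken
        )
        means = dmr.baseline + np.concatenate([[0.0], np.cumsum(dmr.deltas)])
        for pi, pos in enumerate(positions):
            rows.append((f"{dmr.name}_p{pi:02d}", chrom, int(pos), means))
        truth_rows.append(
            {
                "region": dmr.name,
                "chrom": chrom,
                "start": int(positions.min()),
                "end": int(positions.max()) + 1,
                "n_probes": len(positions),
                "width_bp": int(positions.max() - positions.min()),
                "deltas": ",".join(f"{d:+.3f}" for d in dmr.deltas),
                "monotone": dmr.monotone,
                "subtelomeric": dmr.subtelomeric,
            }
        )
    # keep background probes clear of planted regions so probe-count and
    # width filters act on exactly the planted probe sets
    exclusion = [
        (t["chrom"], t["start"] - 2000, t["end"] + 2000) for t in truth_rows
    ]
    bi = 0
    while bi < config.n_background_probes:
        chrom = genome.chrom_names[int(rng.integers(0, len(genome.chrom_names)))]
        L = genome.chrom_lengths[chrom]
        pos = int(rng.integers(tel_len, L - tel_len))
        if any(c == chrom and s <= pos < e for c, s, e in exclusion):
            continue
        mean = float(rng.uniform(0.2, 0.8))
        rows.append((f"bg_{bi:05d}", chrom, pos, np.full(len(conds), mean)))
        bi += 1

    rows.sort(key=lambda r: (r[1], r[2]))
    manifest = pd.DataFrame(
        {"probe": [r[0] for r in rows], "chrom": [r[1] for r in rows], "pos": [r[2] for r in rows]}
    )
    c = config.beta_concentration
    data = np.empty((len(rows), len(samples)))
    for i, (_probe, _chrom, _pos, means) in enumerate(rows):
        for ci, cond in enumerate(conds):
            m = float(np.clip(means[ci], 1e-3, 1 - 1e-3))
            a, b = m * c, (1 - m) * c
            vals = rng.beta(a, b, size=config.n_replicates)
            data[i, ci * config.n_replicates : (ci + 1) * config.n_replicates] = vals
    beta = pd.DataFrame(data, index=manifest["probe"], columns=samples)
    truth = pd.DataFrame(truth_rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False)
    beta.to_csv(os.path.join(out_dir, "beta.tsv"), sep="\t")
    truth.to_csv(os.path.join(out_dir, "meth_truth.tsv"), sep="\t", index=False)
    return manifest, beta, truth


def generate_deg_table(
    genome: GenomeModel, config: SimulationConfig, out_dir: str | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differential-expression table with planted DEGs.

    Planted DEGs satisfy FDR < 0.05 and |log2FC| > 2; all other genes fail
    at least one threshold. With subtelomeric_deg_proportion None the DEGs
    are drawn uniformly from all genes, so their subtelomeric fraction
    matches the background gene density (the study's non-enrichment
    finding); a float forces the expected subtelomeric proportion.
    Returns (table, truth) and optionally writes deg_table.tsv / deg_truth.tsv.
    """
    config.validate()
    rng = _rng(config, 4)
    genes = genome.gene_intervals
    if config.n_planted_degs > len(genes):
        raise ValueError("requested more DEGs than genes exist")
    span = config.subtel_span_bp

    def is_subtel(g) -> bool:
        chrom, start, end, _ = g
        L = genome.chrom_lengths[chrom]
        return start < span or end > L - span

    if config.subtelomeric_deg_proportion is None:
        idx = rng.choice(len(genes), size=config.n_planted_degs, replace=False)
    else:
        p = config.subtelomeric_deg_proportion
        sub = [i for i, g in enumerate(genes) if is_subtel(g)]
        out_i = [i for i, g in enumerate(genes) if not is_subtel(g)]
        n_sub = min(len(sub), int(round(p * config.n_planted_degs)))
        idx = np.concatenate(
            [
                rng.choice(sub, size=n_sub, replace=False),
                rng.choice(out_i, size=config.n_planted_degs - n_sub, replace=False),
            ]
        ).astype(int)
    deg_set = set(int(i) for i in idx)
    rows = []
    for gi, g in enumerate(genes):
        name = g[3]
        if gi in deg_set:
            fdr = float(rng.uniform(1e-6, 0.049))
            lfc = float(rng.uniform(2.1, 6.0)) * (1 if rng.random() < 0.5 else -1)
        else:
            if rng.random() < 0.8:
                fdr = float(rng.uniform(0.05, 1.0))
                lfc = float(rng.normal(0, 1.5))
            else:
                fdr = float(rng.uniform(1e-4, 0.049))
                lfc = float(rng.uniform(-2.0, 2.0))
        rows.append({"gene": name, "log2FC": round(lfc, 4), "FDR": round(fdr, 6)})
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {
            "gene": [genes[i][3] for i in sorted(deg_set)],
            "subtelomeric": [is_subtel(genes[i]) for i in sorted(deg_set)],
        }
    )
    if out_dir is not None:
        ensure_dir(out_dir)
        table.to_csv(os.path.join(out_dir, "deg_table.tsv"), sep="\t", index=False)
        truth.to_csv(os.path.join(out_dir, "deg_truth.tsv"), sep="\t", index=False)
    return table, truth


def simulate_all(config: SimulationConfig, out_dir: str) -> GenomeModel:
    """Run every generator into one output directory."""
    genome = generate_genome(config, out_dir)
    generate_hic_runs(genome, config, out_dir)
    generate_methylation_series(genome, config, out_dir)
    generate_deg_table(genome, config, out_dir)
    return genome
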