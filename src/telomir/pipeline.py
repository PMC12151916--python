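"""End-to-end orchestration: simulate -> mine -> call -> filter -> scan ->
enrich -> cluster, with every intermediate written to disk and a
machine-readable summary of the counts at each stage."""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from . import endcluster, hicmine, methylation, motif, stats_util, subtelomere, synth
from .io import ensure_dir, overlaps, write_bed

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "telomir_out"
    seed: int = 0
    # simulation
    sim: synth.SimulationConfig = field(default_factory=synth.SimulationConfig)
    # mining
    min_units: int = 7
    pad_bp: int = 100
    min_runs: int = 2
    min_mapq: int = 30
    merge_gap_bp: int = 0
    # methylation
    min_probes: int = 7
    min_width_bp: int = 50
    p_cutoff: float = 0.05
    delta_cutoff: float = 0.05
    max_probe_gap_bp: int = 1000
    # motif / enrichment / clustering
    flank_bp: int = 2000
    span_bp: int | None = None  # subtelomere span; default sim.subtel_span_bp
    k_clusters: int = 3

    def __post_init__(self) -> None:
        self.sim = dataclasses.replace(self.sim, seed=self.seed)
        if self.span_bp is None:
            self.span_bp = self.sim.subtel_span_bp

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a fresh simulation; returns the summary dict.

    Writes all intermediates plus summary.json and the effective
    configuration under config.out_dir.
    """
    out = ensure_dir(config.out_dir)
    with open(os.path.join(out, "effective_config.json"), "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, default=str)
    summary: dict = {"seed": config.seed}

    # --- simulate ---------------------------------------------------------
    genome = synth.generate_genome(config.sim, out)
    hic_truth = synth.generate_hic_runs(genome, config.sim, out)
    manifest, beta, meth_truth = synth.generate_methylation_series(
        genome, config.sim, out
    )
    deg_table, deg_truth = synth.generate_deg_table(genome, config.sim, out)
    summary["genome"] = {
        "n_chroms": len(genome.chrom_names),
        "n_genes": len(genome.gene_intervals),
        "n_we_sites": len(genome.we_intervals),
        "n_its": len(genome.its_intervals),
    }

    # --- mine Hi-C --------------------------------------------------------
    all_contacts: list[hicmine.ContactRecord] = []
    tallies = []
    for run in range(config.sim.n_hic_runs):
        run_id = f"run_{run:02d}"
        records = hicmine.read_pairs(
            os.path.join(out, f"{run_id}.pairs"),
            os.path.join(out, f"{run_id}.seqs.tsv"),
        )
        contacts, tally = hicmine.extract_telomeric_contacts(
            records,
            run_id,
            genome.telomere_intervals,
            genome.its_intervals,
            min_units=config.min_units,
            min_mapq=config.min_mapq,
        )
        all_contacts.extend(contacts)
        tally["run_id"] = run_id
        tallies.append(tally)
    pd.DataFrame(tallies).to_csv(
        os.path.join(out, "mining_tallies.tsv"), sep="\t", index=False
    )
    interactions = hicmine.aggregate_recurrent(
        all_contacts,
        genome.chrom_sizes,
        pad_bp=config.pad_bp,
        merge_gap_bp=config.merge_gap_bp,
        min_runs=config.min_runs,
    )
    inter_bed = hicmine.interactions_to_bed(interactions)
    write_bed(inter_bed, os.path.join(out, "interactions.bed"))
    recall, precision = score_interactions(interactions, hic_truth, config.min_runs)
    summary["hic"] = {
        "n_contacts": len(all_contacts),
        "n_interactions": len(interactions),
        "recall": recall,
        "precision": precision,
    }

    # --- methylation ------------------------------------------------------
    conds = list(config.sim.conditions)
    comparisons = [(conds[i], conds[i + 1]) for i in range(3)]  # 12v10,10v8,8v6
    dmr_sets = []
    for a, b in comparisons:
        dmrs = methylation.call_dmrs(
            beta,
            manifest,
            a,
            b,
            min_probes=config.min_probes,
            min_width_bp=config.min_width_bp,
            p_cutoff=config.p_cutoff,
            delta_cutoff=config.delta_cutoff,
            max_probe_gap_bp=config.max_probe_gap_bp,
        )
        dmr_sets.append(dmrs)
    directional = methylation.filter_directional(dmr_sets)
    for (a, b), dmrs in zip(comparisons, dmr_sets):
        methylation.dmrs_to_frame(dmrs).to_csv(
            os.path.join(out, f"dmrs_{a}_{b}.tsv"), sep="\t", index=False
        )
    dir_frame = methylation.dmrs_to_frame(directional)
    dir_frame.to_csv(os.path.join(out, "dmrs_directional.tsv"), sep="\t", index=False)
    summary["methylation"] = {
        "n_dmrs_per_comparison": [len(s) for s in dmr_sets],
        "n_directional": len(directional),
        "directional_recall": score_directional(directional, meth_truth),
    }

    # --- DEGs + enrichment ------------------------------------------------
    degs = stats_util.deg_filter(deg_table)
    windows = subtelomere.make_subtelomere_windows(genome.chrom_sizes, config.span_bp)
    gene_frame = pd.DataFrame(
        [(c, s, e, n) for c, s, e, n in genome.gene_intervals],
        columns=["chrom", "start", "end", "name"],
    )
    _, n_genes_sub, _ = subtelomere.count_in_windows(gene_frame, windows)
    deg_frame = gene_frame[gene_frame["name"].isin(degs)]
    _, n_degs_sub, _ = subtelomere.count_in_windows(deg_frame, windows)
    deg_enrich = subtelomere.enrichment_test(
        n_degs_sub, len(deg_frame), n_genes_sub, len(gene_frame), "hypergeometric"
    )
    dmr_frame = dir_frame.assign(name=[f"dmr{i}" for i in range(len(dir_frame))])
    _, n_dmrs_sub, _ = (
        subtelomere.count_in_windows(dmr_frame, windows)
        if len(dmr_frame)
        else ({}, 0, 0)
    )
    summary["enrichment"] = {
        "n_degs": len(degs),
        "deg_subtel_fraction": (n_degs_sub / len(deg_frame)) if len(deg_frame) else 0.0,
        "gene_subtel_fraction": n_genes_sub / len(gene_frame),
        "deg_hypergeom_p": deg_enrich.p_value,
        "dmr_subtel_fraction": (n_dmrs_sub / len(dmr_frame)) if len(dmr_frame) else 0.0,
    }
    if len(dmr_frame):
        # expected DMR proportion comes from the probe universe
        probe_frame = manifest.assign(start=manifest["pos"], end=manifest["pos"] + 1)
        _, n_probes_sub, _ = subtelomere.count_in_windows(probe_frame, windows)
        dmr_enrich = subtelomere.enrichment_test(
            n_dmrs_sub,
            len(dmr_frame),
            n_probes_sub,
            len(manifest),
            "chisq",
        )
        summary["enrichment"]["dmr_chisq_p"] = dmr_enrich.p_value
        summary["enrichment"]["probe_subtel_fraction"] = n_probes_sub / len(manifest)

    # --- motif scan over interaction windows ------------------------------
    scan_windows = [
        (r.chrom, r.start, r.end, r["name"]) for _, r in inter_bed.iterrows()
    ]
    hits = motif.scan_motif(genome.sequences, intervals=scan_windows)
    genome_hits = motif.scan_motif(genome.sequences)
    hit_bed = pd.DataFrame(
        [(h.chrom, h.start, h.end, h.source_region, h.mismatches, h.strand) for h in genome_hits],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
    write_bed(hit_bed, os.path.join(out, "we_hits.bed"))
    summary["motif"] = {
        "n_hits_in_interactions": len(hits),
        "n_interactions_with_hit": len({h.source_region for h in hits}),
        "n_hits_genome": len(genome_hits),
    }

    # --- chromosome-end feature table + clustering ------------------------
    table = build_feature_table(genome, genome_hits, degs, windows)
    table.to_csv(os.path.join(out, "end_features_raw.tsv"), sep="\t")
    gene_counts = table.pop("gene_count")
    norm, meta = endcluster.build_end_table(table, gene_counts=gene_counts)
    norm.to_csv(os.path.join(out, "end_features_normalized.tsv"), sep="\t")
    k = min(config.k_clusters, norm.shape[0])
    Z, labels = endcluster.cluster_ends(norm, k=k)
    labels.to_csv(os.path.join(out, "end_clusters.tsv"), sep="\t")
    with open(os.path.join(out, "end_dendrogram.nwk"), "w") as fh:
        fh.write(endcluster.linkage_to_newick(Z, list(norm.index)) + "\n")
    summary["clustering"] = {
        "n_ends": int(norm.shape[0]),
        "k": int(k),
        "cluster_sizes": labels.value_counts().sort_index().tolist(),
    }

    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def score_interactions(
    interactions, truth: pd.DataFrame, min_runs: int
) -> tuple[float, float]:
    """Recall/precision of emitted interactions against the planted truth.

    A truth site is expected only when planted in >= min_runs runs; an
    emitted interaction is correct when it overlaps an expected site.
    """
    expected = [
        (t["chrom"], int(t["start"]), int(t["end"]))
        for _, t in truth.iterrows()
        if len(t["runs"].split(",")) >= min_runs
    ]
    if not expected:
        return (1.0 if not interactions else 0.0, 1.0 if not interactions else 0.0)
    hit = [
        any(
            m.chrom == c and overlaps(m.start, m.end, s, e)
            for m in interactions
        )
        for c, s, e in expected
    ]
    recall = sum(hit) / len(expected)
    if not interactions:
        return recall, 1.0
    correct = sum(
        any(m.chrom == c and overlaps(m.start, m.end, s, e) for c, s, e in expected)
        for m in interactions
    )
    return recall, correct / len(interactions)


def score_directional(directional, meth_truth: pd.DataFrame) -> float:
    """Fraction of planted monotone DMRs recovered by the directional set."""
    monotone = meth_truth[meth_truth["monotone"] & (meth_truth["n_probes"] >= 7) & (meth_truth["width_bp"] > 50)]
    if monotone.empty:
        return 1.0
    hit = [
        any(
            d.chrom == t["chrom"] and overlaps(d.start, d.end, int(t["start"]), int(t["end"]))
            for d in directional
        )
        for _, t in monotone.iterrows()
    ]
    return sum(hit) / len(hit)


def build_feature_table(
    genome, hits, degs: set[str], windows
) -> pd.DataFrame:
    """Per-chromosome-end raw features for clustering."""
    import numpy as np

    rows = {}
    for w in windows:
        in_w = lambda c, s, e: c == w.chrom and overlaps(s, e, w.start, w.end)
        genes_here = [g for g in genome.gene_intervals if in_w(g[0], g[1], g[2])]
        rows[w.end_id] = {
            "we_count": sum(1 for h in hits if in_w(h.chrom, h.start, h.end)),
            "deg_count": sum(1 for g in genes_here if g[3] in degs),
            "gene_count": len(genes_here),
            "its_count": sum(
                1 for it in genome.its_intervals if in_w(it[0], it[1], it[2])
            ),
            "replication_timing": np.nan,
        }
    table = pd.DataFrame(rows).T
    # synthetic timing: a deterministic gradient across ends so the column
    # exercises the [-1, 1] affine map without an external timing input
    table["replication_timing"] = np.linspace(10.0, 30.0, len(table))
    return table
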