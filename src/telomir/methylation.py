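"""DMR calling across telomere-length conditions, the directional-consistency
filter, and bisulfite amplicon summarization.

The caller is deliberately minimal and fully specified: probe-level beta
deltas between two conditions are merged into candidate regions (consecutive
probes with a common delta sign and |delta| above a cutoff, within a maximum
genomic gap), each region is tested with a two-sample t-test on
replicate-level region means, and regions must contain at least `min_probes`
probes, exceed `min_width_bp` in width and pass the p-value cutoff. The
analytic contribution carried here is the threshold set (7 probes, 50 bp,
p 0.05) and the directional filter across the telomere-length series, not
the caller machinery itself.

Direction convention: delta = shorter-telomere condition minus longer, so
"hyper" means methylation gained as telomeres shorten.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import overlaps


@dataclass
class DMR:
    """A differentially methylated region between two conditions."""

    chrom: str
    start: int
    end: int
    n_probes: int
    width_bp: int
    mean_delta_beta: float
    direction: str  # "hyper" | "hypo"
    p_value: float
    comparison: str  # e.g. "12v10" (longer condition first)
    probes: tuple[str, ...] = ()
    supporting_comparisons: tuple[str, ...] = ()


def condition_of(sample: str) -> str:
    """Condition label of a sample column named '<condition>_rep<i>'."""
    return sample.rsplit("_rep", 1)[0]


def call_dmrs(
    beta: pd.DataFrame,
    manifest: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    min_probes: int = 7,
    min_width_bp: int = 50,
    p_cutoff: float = 0.05,
    delta_cutoff: float = 0.05,
    max_probe_gap_bp: int = 1000,
    bh_correct: bool = False,
) -> list[DMR]:
    """Call DMRs of condition_b relative to condition_a.

    condition_a is the longer-telomere condition; probe delta is
    mean beta(b) - mean beta(a). `beta` has probes as rows and
    '<condition>_rep<i>' columns; `manifest` has columns probe, chrom, pos,
    sorted by position within each chromosome.

    Regions are kept when they hold at least `min_probes` probes, their
    width (last minus first probe position) strictly exceeds `min_width_bp`,
    and the region t-test p-value is below `p_cutoff` (after optional
    Benjamini-Hochberg correction across candidate regions).
    """
    cols_a = [c for c in beta.columns if condition_of(c) == condition_a]
    cols_b = [c for c in beta.columns if condition_of(c) == condition_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            f"conditions {condition_a!r}/{condition_b!r} need >=2 replicates each"
        )
    for chrom, grp in manifest.groupby("chrom", sort=False):
        if not grp["pos"].is_monotonic_increasing:
            raise ValueError(f"manifest positions not sorted on {chrom}")
    mani = manifest.set_index("probe")
    common = [p for p in manifest["probe"] if p in beta.index]
    delta = beta.loc[common, cols_b].mean(axis=1) - beta.loc[common, cols_a].mean(axis=1)

    candidates: list[list[str]] = []
    current: list[str] = []
    prev_chrom, prev_pos, prev_sign = None, None, 0
    for probe in common:
        chrom, pos = mani.at[probe, "chrom"], int(mani.at[probe, "pos"])
        d = delta[probe]
        sign = 0 if abs(d) < delta_cutoff else (1 if d > 0 else -1)
        extend = (
            sign != 0
            and sign == prev_sign
            and chrom == prev_chrom
            and pos - prev_pos <= max_probe_gap_bp
        )
        if extend:
            current.append(probe)
        else:
            if current:
                candidates.append(current)
            current = [probe] if sign != 0 else []
        prev_chrom, prev_pos, prev_sign = chrom, pos, sign
    if current:
        candidates.append(current)

    comparison = _comparison_label(condition_a, condition_b)
    dmrs: list[DMR] = []
    pvals: list[float] = []
    for probes in candidates:
        if len(probes) < min_probes:
            continue
        positions = mani.loc[probes, "pos"].astype(int)
        width = int(positions.max() - positions.min())
        if width <= min_width_bp:
            continue
        region_a = beta.loc[probes, cols_a].mean(axis=0)
        region_b = beta.loc[probes, cols_b].mean(axis=0)
        t, p = stats.ttest_ind(region_b, region_a, equal_var=True)
        mean_d = float(delta[probes].mean())
        dmrs.append(
            DMR(
                chrom=str(mani.at[probes[0], "chrom"]),
                start=int(positions.min()),
                end=int(positions.max()) + 1,
                n_probes=len(probes),
                width_bp=width,
                mean_delta_beta=mean_d,
                direction="hyper" if mean_d > 0 else "hypo",
                p_value=float(p),
                comparison=comparison,
                probes=tuple(probes),
            )
        )
        pvals.append(float(p))
    if bh_correct and pvals:
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, pvals[i] * m / (rank_idx + 1))
            adj[i] = running
        for d, q in zip(dmrs, adj):
            d.p_value = float(q)
    out = [d for d in dmrs if d.p_value < p_cutoff]
    out.sort(key=lambda d: (d.chrom, d.start))
    return out


def _comparison_label(condition_a: str, condition_b: str) -> str:
    def stem(c: str) -> str:
        m = re.match(r"(\d+)", c)
        return m.group(1) if m else c

    return f"{stem(condition_a)}v{stem(condition_b)}"


def filter_directional(
    dmr_sets: Sequence[Sequence[DMR]],
    min_overlap_bp: int = 1,
) -> list[DMR]:
    """Keep first-comparison DMRs consistently hyper- or hypomethylated.

    dmr_sets lists DMR calls for adjacent condition pairs in
    telomere-length order (e.g. 12v10, 10v8, 8v6). A DMR from the first
    comparison survives iff every subsequent comparison contains an
    overlapping DMR (>= min_overlap_bp shared bases) with the same
    direction. Survivors record the chain of supporting comparisons.
    """
    if len(dmr_sets) < 2:
        raise ValueError("need at least two comparisons")
    _check_comparison_order(dmr_sets)
    kept: list[DMR] = []
    for dmr in dmr_sets[0]:
        chain = [dmr.comparison]
        ok = True
        for later in dmr_sets[1:]:
            match = next(
                (
                    o
                    for o in later
                    if o.chrom == dmr.chrom
                    and o.direction == dmr.direction
                    and _overlap_len(dmr, o) >= min_overlap_bp
                ),
                None,
            )
            if match is None:
                ok = False
                break
            chain.append(match.comparison)
        if ok:
            kept.append(
                DMR(
                    **{
                        **dmr.__dict__,
                        "supporting_comparisons": tuple(chain),
                    }
                )
            )
    return kept


def _overlap_len(a: DMR, b: DMR) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _check_comparison_order(dmr_sets: Sequence[Sequence[DMR]]) -> None:
    labels = []
    for s in dmr_sets:
        labs = {d.comparison for d in s}
        if len(labs) > 1:
            raise ValueError(f"mixed comparison labels in one set: {labs}")
        labels.append(next(iter(labs)) if labs else None)
    prev_short = None
    for lab in labels:
        if lab is None or "v" not in lab:
            continue
        longer, shorter = lab.split("v", 1)
        if prev_short is not None and longer != prev_short:
            raise ValueError(
                f"comparisons out of telomere-length order near {lab!r}"
            )
        prev_short = shorter


def dmrs_to_frame(dmrs: Sequence[DMR]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end,
                "n_probes": d.n_probes,
                "width_bp": d.width_bp,
                "mean_delta_beta": d.mean_delta_beta,
                "direction": d.direction,
                "p_value": d.p_value,
                "comparison": d.comparison,
            }
            for d in dmrs
        ],
        columns=[
            "chrom",
            "start",
            "end",
            "n_probes",
            "width_bp",
            "mean_delta_beta",
            "direction",
            "p_value",
            "comparison",
        ],
    )


def summarize_bisulfite(
    matrix: pd.DataFrame, smooth_window: int = 3
) -> pd.DataFrame:
    """Per-CpG mean methylation and a smoothed series from 1/0/X calls.

    Rows are sequenced clones/reads, columns CpG positions; entries are
    '1' (methylated), '0' (unmethylated) or 'X' (misaligned, ignored).
    The per-CpG mean is (# of 1) / (# of non-X); the smoothed value is a
    centered moving average over `smooth_window` CpGs using whatever
    neighbors exist at the edges. Columns that are entirely X have no
    defined mean: they are flagged and excluded from smoothing.
    """
    if matrix.empty:
        raise ValueError("empty bisulfite matrix")
    vals = matrix.astype(str)
    means: dict[str, float] = {}
    flagged: list[str] = []
    for col in vals.columns:
        entries = vals[col]
        bad = ~entries.isin(["0", "1", "X"])
        if bad.any():
            raise ValueError(f"column {col}: entries must be 1, 0 or X")
        informative = entries[entries != "X"]
        if informative.empty:
            flagged.append(col)
            continue
        means[col] = (informative == "1").mean()
    cols = list(means)
    series = np.array([means[c] for c in cols])
    half = smooth_window // 2
    smoothed = np.array(
        [
            series[max(0, i - half) : i + half + 1].mean()
            for i in range(len(series))
        ]
    )
    out = pd.DataFrame(
        {
            "cpg": list(vals.columns),
            "mean_methylation": [means.get(c, np.nan) for c in vals.columns],
            "smoothed": [
                smoothed[cols.index(c)] if c in means else np.nan
                for c in vals.columns
            ],
            "all_x": [c in flagged for c in vals.columns],
        }
    )
    return out
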