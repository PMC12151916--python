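"""Subtelomeric windows and enrichment tests.

A subtelomere is operationalized as a fixed-span window (default 10 Mb) from
each chromosome end, so every chromosome contributes exactly two windows: a
p-side window anchored at position 0 and a q-side window anchored at the
chromosome's last base. On chromosomes shorter than twice the span the two
windows are truncated at the midpoint so they never overlap.

Enrichment of a feature set within the windows is tested either with the
exact hypergeometric upper tail (observed-or-more in-window members when
drawing the set from the universe without replacement) or with a 1-df
chi-square test of the observed in/out counts against the universe
proportion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .io import overlaps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubtelomereWindow:
    """One chromosome-end window, 0-based half-open."""

    end_id: str  # e.g. "chr1_p"
    chrom: str
    side: str  # "p" or "q"
    start: int
    end: int
    chrom_length: int

    @property
    def span_bp(self) -> int:
        return self.end - self.start


@dataclass
class EnrichmentResult:
    n_universe: int
    n_in_windows_universe: int
    n_set: int
    n_set_in_windows: int
    expected_proportion: float
    observed_proportion: float
    test_name: str
    statistic: float
    p_value: float
    flags: list[str] = field(default_factory=list)
    odds_ratio: float = float("nan")


def make_subtelomere_windows(
    chrom_sizes: Mapping[str, int], span_bp: int = 10_000_000
) -> list[SubtelomereWindow]:
    """Two windows per chromosome, in chromosome order with p before q."""
    if span_bp <= 0:
        raise ValueError("span_bp must be positive")
    windows: list[SubtelomereWindow] = []
    for chrom, size in chrom_sizes.items():
        if size <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive size {size}")
        if size < 2 * span_bp:
            mid = size // 2
            p_end, q_start = mid, mid
        else:
            p_end, q_start = span_bp, size - span_bp
        windows.append(SubtelomereWindow(f"{chrom}_p", chrom, "p", 0, p_end, size))
        windows.append(SubtelomereWindow(f"{chrom}_q", chrom, "q", q_start, size, size))
    return windows


def _member(start: int, end: int, win: SubtelomereWindow, rule: str) -> bool:
    if rule == "any-overlap":
        return overlaps(start, end, win.start, win.end)
    if rule == "fully-contained":
        return start >= win.start and end <= win.end
    raise ValueError("rule must be 'any-overlap' or 'fully-contained'")


def count_in_windows(
    features: pd.DataFrame | Sequence[tuple],
    windows: Iterable[SubtelomereWindow],
    rule: str = "any-overlap",
) -> tuple[dict[str, int], int, int]:
    """Count features falling in subtelomeric windows.

    Each feature is counted at most once overall. A feature qualifying for
    both windows of a short chromosome is assigned to the nearer end
    (midpoint distance); an exact tie goes to the p side. Features on
    chromosomes absent from the window set are skipped with a warning.

    Returns (per-end counts, total in windows, number skipped).
    """
    if isinstance(features, pd.DataFrame):
        rows = list(zip(features["chrom"], features["start"], features["end"]))
    else:
        rows = [(r[0], int(r[1]), int(r[2])) for r in features]
    by_chrom: dict[str, list[SubtelomereWindow]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    counts = {w.end_id: 0 for chrom in by_chrom for w in by_chrom[chrom]}
    skipped = 0
    for chrom, start, end in rows:
        wins = by_chrom.get(chrom)
        if wins is None:
            skipped += 1
            continue
        hits = [w for w in wins if _member(int(start), int(end), w, rule)]
        if not hits:
            continue
        if len(hits) == 1:
            counts[hits[0].end_id] += 1
            continue
        mid = (int(start) + int(end)) / 2
        length = hits[0].chrom_length
        # nearer end; ties to p
        chosen = min(
            hits,
            key=lambda w: (mid if w.side == "p" else length - mid, w.side != "p"),
        )
        counts[chosen.end_id] += 1
    if skipped:
        msg = f"skipped {skipped} features on chromosomes without windows"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return counts, sum(counts.values()), skipped


def enrichment_test(
    n_set_in_windows: int,
    n_set: int,
    n_in_windows_universe: int,
    n_universe: int,
    test: str = "hypergeometric",
) -> EnrichmentResult:
    """Test whether a feature set is enriched in subtelomeric windows.

    hypergeometric: exact upper-tail P(X >= n_set_in_windows) for X the
    number of in-window members when n_set items are drawn without
    replacement from a universe with n_in_windows_universe in-window members.

    chisq: 1-df goodness-of-fit of the observed (in, out) counts against the
    expected split n_set * (p, 1-p) with p the universe in-window proportion.
    Expected cells below 5 flag the result "low-count" but the statistic is
    still returned.
    """
    if n_universe <= 0:
        raise ValueError("empty universe")
    if not (0 <= n_set_in_windows <= n_set <= n_universe):
        raise ValueError("inconsistent counts")
    if n_set_in_windows > n_in_windows_universe:
        raise ValueError("more in-window set members than the universe holds")
    expected_p = n_in_windows_universe / n_universe
    observed_p = n_set_in_windows / n_set if n_set else 0.0
    flags: list[str] = []
    if test == "hypergeometric":
        p = float(
            stats.hypergeom.sf(
                n_set_in_windows - 1, n_universe, n_in_windows_universe, n_set
            )
        )
        statistic = float(n_set_in_windows)
        name = "hypergeometric"
    elif test == "chisq":
        exp_in = n_set * expected_p
        exp_out = n_set * (1 - expected_p)
        if min(exp_in, exp_out) < 5:
            flags.append("low-count")
        chi2, p = stats.chisquare(
            [n_set_in_windows, n_set - n_set_in_windows], [exp_in, exp_out]
        )
        statistic, p = float(chi2), float(p)
        name = "chisq"
    else:
        raise ValueError("test must be 'hypergeometric' or 'chisq'")
    return EnrichmentResult(
        n_universe=n_universe,
        n_in_windows_universe=n_in_windows_universe,
        n_set=n_set,
        n_set_in_windows=n_set_in_windows,
        expected_proportion=expected_p,
        observed_proportion=observed_p,
        test_name=name,
        statistic=statistic,
        p_value=p,
        flags=flags,
    )
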