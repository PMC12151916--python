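"""Mining recurrent telomere-anchored interactions from Hi-C read pairs.

The pipeline classifies each mate of a read pair by its longest run of
tandem telomeric repeat units (TTAGGG, or CCCTAA on the opposite strand),
keeps pairs where exactly one mate is telomeric (>= 7 tandem units by
default; shorter runs are interstitial-telomere-like and discarded), anchors
the interaction at the non-telomeric mate, expands the anchor by +/-100 bp,
and aggregates anchors across independent Hi-C runs, emitting only
interactions supported by a minimum number of distinct runs.

Two distinct interstitial-telomeric-sequence (ITS) rules apply and are
separately switchable: (a) a read with fewer than `min_units` tandem units
never counts as telomeric; (b) an anchor falling inside an annotated ITS
array of `min_units` or more units is discarded, because such loci are
internal telomere look-alikes rather than chromosome ends.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from .io import overlaps

logger = logging.getLogger(__name__)

TELOMERE_UNIT = "TTAGGG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RepeatCall:
    """Tandem telomeric repeat content of one read."""

    read_id: str
    max_tandem_units: int
    unit_orientation: str  # "forward" (TTAGGG) or "reverse" (CCCTAA)
    total_units: int


@dataclass(frozen=True)
class ContactRecord:
    """One informative Hi-C pair: a telomeric mate anchored at a locus."""

    run_id: str
    telomeric_mate: RepeatCall
    anchor_chrom: str
    anchor_start: int
    anchor_end: int
    anchor_mapq: int


@dataclass
class TelomereInteraction:
    """A recurrent telomere-anchored genomic window merged across runs."""

    chrom: str
    start: int
    end: int
    supporting_runs: set[str]
    n_reads_total: int
    nearest_end: str = ""
    distance_to_nearest_end_bp: int = -1


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _count_one_orientation(seq: str, unit: str, max_mm: int) -> tuple[int, int]:
    """(longest tandem run, matching-unit count) over all phase offsets."""
    k = len(unit)
    best_run = 0
    best_total = 0
    for phase in range(k):
        run = total = longest = 0
        for i in range(phase, len(seq) - k + 1, k):
            if _hamming(seq[i : i + k], unit) <= max_mm:
                total += 1
                run += 1
                longest = max(longest, run)
            else:
                run = 0
        best_run = max(best_run, longest)
        best_total = max(best_total, total)
    return best_run, best_total


_EXACT_RE: dict[str, re.Pattern] = {}


def _count_exact(seq: str, unit: str) -> tuple[int, int]:
    """Fast path for zero-mismatch counting via regex runs.

    total counts unit copies across all maximal (non-overlapping) tandem
    runs, so max_run <= total <= len(seq) // len(unit) always holds.
    """
    pat = _EXACT_RE.get(unit)
    if pat is None:
        pat = _EXACT_RE.setdefault(unit, re.compile(f"(?:{unit})+"))
    best_run = 0
    total = 0
    for m in pat.finditer(seq):
        n = (m.end() - m.start()) // len(unit)
        best_run = max(best_run, n)
        total += n
    return best_run, total


def count_tandem_units(
    seq: str,
    unit: str = TELOMERE_UNIT,
    max_mismatch_per_unit: int = 0,
    read_id: str = "",
) -> RepeatCall:
    """Longest run of consecutive telomeric repeat units in a read.

    Both orientations (the unit and its reverse complement) and all phase
    offsets are evaluated; the orientation with the longer tandem run wins
    (forward on ties). Each unit copy may carry up to
    `max_mismatch_per_unit` Hamming mismatches. An empty sequence yields a
    zero call; symbols outside ACGTN are an error (N never matches).
    """
    if len(unit) < 2:
        raise ValueError("unit length must be >= 2")
    seq = seq.upper()
    if re.search("[^ACGTN]", seq):
        raise ValueError("sequence contains symbols outside ACGTN")
    if not seq:
        return RepeatCall(read_id, 0, "forward", 0)
    rc_unit = revcomp(unit)
    if max_mismatch_per_unit == 0:
        fwd = _count_exact(seq, unit)
        rev = _count_exact(seq, rc_unit)
    else:
        fwd = _count_one_orientation(seq, unit, max_mismatch_per_unit)
        rev = _count_one_orientation(seq, rc_unit, max_mismatch_per_unit)
    if rev[0] > fwd[0]:
        return RepeatCall(read_id, rev[0], "reverse", rev[1])
    return RepeatCall(read_id, fwd[0], "forward", fwd[1])


def classify_read(call: RepeatCall, min_units: int = 7) -> str:
    """'telomeric' iff the longest tandem run reaches min_units.

    Reads with 1-6 tandem units under the default threshold resemble short
    interstitial telomeric arrays and are treated as non-telomeric.
    """
    if min_units < 1:
        raise ValueError("min_units must be >= 1")
    return "telomeric" if call.max_tandem_units >= min_units else "non_telomeric"


def expand_anchor(
    interval: tuple[str, int, int],
    pad_bp: int = 100,
    chrom_sizes: Mapping[str, int] | None = None,
) -> tuple[str, int, int]:
    """Pad an anchor window upstream and downstream, clipped to the chromosome."""
    chrom, start, end = interval
    start = max(0, start - pad_bp)
    end = end + pad_bp
    if chrom_sizes is not None:
        end = min(end, chrom_sizes[chrom])
    return chrom, start, end


@dataclass
class PairRecord:
    """One parsed mate pair with sequences and mapping qualities."""

    read_id: str
    chrom1: str
    pos1: int  # 0-based leftmost
    chrom2: str
    pos2: int
    strand1: str
    strand2: str
    seq1: str
    seq2: str
    mapq1: int
    mapq2: int


def read_pairs(pairs_path: str, seqs_path: str) -> Iterator[PairRecord]:
    """Parse a 7-column pairs file plus its sequence side-file.

    The pairs dialect stores 1-based leftmost positions; they are converted
    to 0-based here. The side-file is TSV with columns
    readID, seq1, seq2, mapq1, mapq2; pairs whose readID is absent from the
    side-file are skipped with a logged count.
    """
    seqs: dict[str, tuple[str, str, int, int]] = {}
    with open(seqs_path) as fh:
        header = fh.readline()
        if not header.startswith("readID"):
            raise ValueError(f"{seqs_path}: expected a readID header line")
        for line in fh:
            rid, s1, s2, q1, q2 = line.rstrip("\n").split("\t")
            seqs[rid] = (s1, s2, int(q1), int(q2))
    n_missing = 0
    with open(pairs_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 7:
                raise ValueError(f"{pairs_path}:{lineno}: malformed pairs line")
            rid, c1, p1, c2, p2, s1, s2 = fields[:7]
            rec = seqs.get(rid)
            if rec is None:
                n_missing += 1
                continue
            yield PairRecord(
                rid, c1, int(p1) - 1, c2, int(p2) - 1, s1, s2, *rec
            )
    if n_missing:
        logger.warning("%s: %d pairs lacked side-file sequence", pairs_path, n_missing)


def read_pairs_from_sam(sam_path: str) -> Iterator[PairRecord]:
    """Read mate pairs from a SAM file where both mates carry sequence."""
    import pysam

    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        pending: dict[str, object] = {}
        for aln in sam:
            if aln.is_secondary or aln.is_supplementary:
                continue
            mate = pending.pop(aln.query_name, None)
            if mate is None:
                pending[aln.query_name] = aln
                continue
            first, second = (mate, aln) if mate.is_read1 else (aln, mate)
            yield PairRecord(
                read_id=first.query_name,
                chrom1=first.reference_name or "*",
                pos1=first.reference_start if first.reference_start >= 0 else 0,
                chrom2=second.reference_name or "*",
                pos2=second.reference_start if second.reference_start >= 0 else 0,
                strand1="-" if first.is_reverse else "+",
                strand2="-" if second.is_reverse else "+",
                seq1=first.query_sequence or "",
                seq2=second.query_sequence or "",
                mapq1=first.mapping_quality,
                mapq2=second.mapping_quality,
            )
    if pending:
        logger.warning("%s: %d unpaired records dropped", sam_path, len(pending))


def _overlaps_any(
    chrom: str, start: int, end: int, intervals: Sequence[tuple]
) -> bool:
    return any(
        c == chrom and overlaps(start, end, s, e) for c, s, e, *_ in intervals
    )


def extract_telomeric_contacts(
    records: Iterable[PairRecord],
    run_id: str,
    telomere_intervals: Sequence[tuple],
    its_intervals: Sequence[tuple] = (),
    min_units: int = 7,
    min_mapq: int = 30,
    max_mismatch_per_unit: int = 0,
    discard_its_anchors: bool = True,
) -> tuple[list[ContactRecord], dict[str, int]]:
    """Keep pairs with exactly one telomeric mate anchored at a mappable locus.

    telomere_intervals: annotated terminal arrays (chrom, start, end, ...);
    anchors overlapping them are dropped (the "contact" would be
    telomere-telomere). its_intervals: annotated interstitial arrays with a
    unit count as the 4th element; anchors inside arrays of >= min_units
    units are dropped when discard_its_anchors is set.

    Returns the contact list and a tally of discards by reason.
    """
    tally = {
        "pairs_seen": 0,
        "telo_telo": 0,
        "no_telomeric_mate": 0,
        "low_mapq": 0,
        "anchor_in_telomere": 0,
        "anchor_in_its": 0,
        "kept": 0,
    }
    big_its = [iv for iv in its_intervals if len(iv) > 3 and int(iv[3]) >= min_units]
    contacts: list[ContactRecord] = []
    for rec in records:
        tally["pairs_seen"] += 1
        call1 = count_tandem_units(rec.seq1, max_mismatch_per_unit=max_mismatch_per_unit, read_id=rec.read_id)
        call2 = count_tandem_units(rec.seq2, max_mismatch_per_unit=max_mismatch_per_unit, read_id=rec.read_id)
        telo1 = classify_read(call1, min_units) == "telomeric"
        telo2 = classify_read(call2, min_units) == "telomeric"
        if telo1 and telo2:
            tally["telo_telo"] += 1
            continue
        if not (telo1 or telo2):
            tally["no_telomeric_mate"] += 1
            continue
        if telo1:
            telo_call = call1
            chrom, start, mapq, seq = rec.chrom2, rec.pos2, rec.mapq2, rec.seq2
        else:
            telo_call = call2
            chrom, start, mapq, seq = rec.chrom1, rec.pos1, rec.mapq1, rec.seq1
        end = start + len(seq)
        if mapq < min_mapq:
            tally["low_mapq"] += 1
            continue
        if _overlaps_any(chrom, start, end, telomere_intervals):
            tally["anchor_in_telomere"] += 1
            continue
        if discard_its_anchors and _overlaps_any(chrom, start, end, big_its):
            tally["anchor_in_its"] += 1
            continue
        tally["kept"] += 1
        contacts.append(
            ContactRecord(run_id, telo_call, chrom, start, end, mapq)
        )
    return contacts, tally


def aggregate_recurrent(
    contacts: Iterable[ContactRecord],
    chrom_sizes: Mapping[str, int],
    pad_bp: int = 100,
    merge_gap_bp: int = 0,
    min_runs: int = 2,
) -> list[TelomereInteraction]:
    """Merge padded anchors across runs and keep recurrent interactions.

    Anchors are expanded by pad_bp, sorted, and merged whenever they overlap
    or lie within merge_gap_bp of each other; each merged interaction
    records its distinct supporting runs and is emitted only when supported
    by at least min_runs runs, sorted by genomic position.
    """
    contacts = list(contacts)
    run_ids = {c.run_id for c in contacts}
    if contacts and min_runs > len(run_ids):
        warnings.warn(
            f"min_runs={min_runs} exceeds the {len(run_ids)} runs provided; "
            "result will be empty",
            stacklevel=2,
        )
    expanded = []
    for c in contacts:
        chrom, start, end = expand_anchor(
            (c.anchor_chrom, c.anchor_start, c.anchor_end), pad_bp, chrom_sizes
        )
        expanded.append((chrom, start, end, c.run_id))
    expanded.sort(key=lambda t: (t[0], t[1], t[2]))
    merged: list[TelomereInteraction] = []
    for chrom, start, end, run_id in expanded:
        last = merged[-1] if merged else None
        if last is not None and last.chrom == chrom and start <= last.end + merge_gap_bp:
            last.end = max(last.end, end)
            last.supporting_runs.add(run_id)
            last.n_reads_total += 1
        else:
            merged.append(
                TelomereInteraction(chrom, start, end, {run_id}, 1)
            )
    out = [m for m in merged if len(m.supporting_runs) >= min_runs]
    for m in out:
        size = chrom_sizes[m.chrom]
        mid = (m.start + m.end) / 2
        dist_p, dist_q = mid, size - mid
        if dist_p <= dist_q:
            m.nearest_end, m.distance_to_nearest_end_bp = f"{m.chrom}_p", int(dist_p)
        else:
            m.nearest_end, m.distance_to_nearest_end_bp = f"{m.chrom}_q", int(dist_q)
    out.sort(key=lambda m: (m.chrom, m.start, m.end))
    return out


def interactions_to_bed(interactions: Sequence[TelomereInteraction]):
    """BED6 frame: name = interaction id, score = supporting-run count."""
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": [m.chrom for m in interactions],
            "start": [m.start for m in interactions],
            "end": [m.end for m in interactions],
            "name": [f"TI_{i:04d}" for i in range(len(interactions))],
            "score": [len(m.supporting_runs) for m in interactions],
            "strand": ["." for _ in interactions],
        }
    )
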