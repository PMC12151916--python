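"""Plain-text genomic interchange: BED6, chrom-sizes TSV, FASTA writing.

All in-memory coordinates are 0-based half-open; BED shares that convention
on disk, so no shifting happens here.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str) -> pd.DataFrame:
    """Read a BED file with up to 6 columns into a DataFrame.

    Missing optional columns are filled (name ".", score 0, strand ".").
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    df = df.iloc[:, : min(6, df.shape[1])]
    df.columns = BED_COLUMNS[: df.shape[1]]
    for col, default in (("name", "."), ("score", "0"), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df[BED_COLUMNS]


def write_bed(df: pd.DataFrame, path: str) -> None:
    out = df.copy()
    for col, default in (("name", "."), ("score", 0), ("strand", ".")):
        if col not in out.columns:
            out[col] = default
    out[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path: str) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"], df["size"].astype(int)))


def write_chrom_sizes(sizes: Mapping[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def write_fasta(records: Iterable[tuple[str, str]], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def overlaps(start1: int, end1: int, start2: int, end2: int) -> bool:
    """True when two 0-based half-open intervals share at least one base."""
    return start1 < end2 and start2 < end1


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
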