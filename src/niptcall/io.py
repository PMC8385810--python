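"""Readers and writers for the pipeline's plain-text formats.

Bin counts travel as BED-like TSV (columns ``chrom  start  end  gc
count``, header required, one row per bin); reference panels as JSON.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import BinCounts, GenomeBins, normalize_chrom

logger = logging.getLogger("niptcall")

_COLUMNS = ["chrom", "start", "end", "gc", "count"]


def setup_logging(level: int = logging.INFO) -> None:
    """Timestamped logging to stderr (idempotent)."""
    root = logging.getLogger("niptcall")
    if root.handlers:
        return
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root.addHandler(h)
    root.setLevel(level)


def write_bin_counts(
    bc: BinCounts, bins: GenomeBins, path: str | Path
) -> None:
    """Write one sample's counts as a BED-like TSV with a comment header."""
    if len(bc.counts) != len(bins):
        raise ValueError("counts length does not match bin model")
    df = bins.df[["chrom", "start", "end", "gc"]].copy()
    df["count"] = bc.counts
    with open(path, "w") as fh:
        fh.write(f"# sample_id={bc.sample_id}\trun_id={bc.run_id}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_bin_counts(path: str | Path) -> tuple[BinCounts, pd.DataFrame]:
    """Read a bin-count TSV.

    Returns the :class:`BinCounts` and the bin table (chrom/start/end/gc)
    it was written against.  Malformed rows are rejected with the line
    number named.
    """
    path = Path(path)
    sample_id, run_id = path.stem, "run0"
    header_offset = 1
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            header_offset = 2
            for token in first[1:].strip().split("\t"):
                key, _, val = token.partition("=")
                if key.strip() == "sample_id":
                    sample_id = val.strip()
                elif key.strip() == "run_id":
                    run_id = val.strip()
            header_line = fh.readline()
        else:
            header_line = first
        cols = header_line.rstrip("\n").split("\t")
        if cols != _COLUMNS:
            raise ValueError(f"{path}: expected header {_COLUMNS}, got {cols}")
        df = pd.read_csv(fh, sep="\t", names=_COLUMNS, header=None)
    if len(df) == 0:
        raise ValueError(f"{path}: no bins")
    for i, row in enumerate(df.itertuples(index=False)):
        lineno = i + header_offset + 1
        try:
            normalize_chrom(row.chrom)
        except ValueError as e:
            raise ValueError(f"{path}:{lineno}: {e}") from None
        if not (0 <= row.gc <= 1):
            raise ValueError(f"{path}:{lineno}: gc {row.gc} out of [0, 1]")
        if row.end <= row.start:
            raise ValueError(f"{path}:{lineno}: empty interval")
        if row.count < 0 or row.count != int(row.count):
            raise ValueError(f"{path}:{lineno}: bad count {row.count}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    # overlap check within each chromosome
    for chrom, sub in df.groupby("chrom", sort=False):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        if (s[1:] < e[:-1]).any():
            bad = int(np.argmax(s[1:] < e[:-1]))
            lineno = sub.index[bad + 1] + header_offset + 1
            raise ValueError(f"{path}:{lineno}: overlapping bins on chromosome {chrom}")
    counts = df["count"].to_numpy(dtype=np.int64)
    return BinCounts(sample_id=sample_id, counts=counts, run_id=run_id), df[
        ["chrom", "start", "end", "gc"]
    ]
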