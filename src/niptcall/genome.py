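"""Genome bin model for shallow-WGS cfDNA screening.

The whole pipeline operates on fixed-width windows ("bins", 1 Mb by
default) tiling each chromosome.  Coordinates are 0-based half-open
(BED convention).  Chromosome labels are stored without a ``chr``
prefix; readers accept both dialects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHROMOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 23)) + ("X", "Y")
AUTOSOMES: tuple[str, ...] = CHROMOSOMES[:22]

#: hg19-scale chromosome lengths (bases).  Shipping a length table avoids
#: any reference download; actual alignment is upstream of this package.
HG19_CHROM_LENGTHS: dict[str, int] = {
    "1": 249250621, "2": 243199373, "3": 198022430, "4": 191154276,
    "5": 180915260, "6": 171115067, "7": 159138663, "8": 146364022,
    "9": 141213431, "10": 135534747, "11": 135006516, "12": 133851895,
    "13": 115169878, "14": 107349540, "15": 102531392, "16": 90354753,
    "17": 81195210, "18": 78077248, "19": 59128983, "20": 63025520,
    "21": 48129895, "22": 51304566, "X": 155270560, "Y": 59373566,
}

#: Approximate per-chromosome mean GC fraction of the human genome.
#: Chromosome-level GC structure is what couples library GC bias to
#: chromosome representation, so the bundled bin model reproduces it.
CHROM_MEAN_GC: dict[str, float] = {
    "1": 0.417, "2": 0.402, "3": 0.397, "4": 0.382, "5": 0.395,
    "6": 0.396, "7": 0.407, "8": 0.401, "9": 0.413, "10": 0.415,
    "11": 0.415, "12": 0.408, "13": 0.385, "14": 0.408, "15": 0.422,
    "16": 0.447, "17": 0.455, "18": 0.398, "19": 0.483, "20": 0.441,
    "21": 0.408, "22": 0.479, "X": 0.395, "Y": 0.397,
}

# GC band outside which bins are excluded from proportions (count-level
# analogue of alignment-level read filtering, which is out of scope).
GC_USABLE_BAND: tuple[float, float] = (0.30, 0.60)

# Internal seed fixing the bundled synthetic GC track; part of the bin
# model definition, independent of any analysis seed.
_GC_TRACK_SEED = 20130419


def normalize_chrom(label: str) -> str:
    """Strip an optional ``chr`` prefix and validate the label."""
    c = str(label).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    if c == "23":
        c = "X"
    elif c == "24":
        c = "Y"
    if c not in CHROMOSOMES:
        raise ValueError(f"unknown chromosome label: {label!r}")
    return c


@dataclass
class GenomeBins:
    """Fixed-width windows tiling a genome.

    ``df`` columns: chrom (str, no prefix), start, end (0-based half-open),
    gc (fraction in [0, 1]), usable (bool).  Bins of one chromosome are
    sorted, disjoint and cover ``[0, length)``.
    """

    df: pd.DataFrame
    bin_size: int

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        d = self.df
        required = {"chrom", "start", "end", "gc", "usable"}
        missing = required - set(d.columns)
        if missing:
            raise ValueError(f"GenomeBins missing columns: {sorted(missing)}")
        if len(d) == 0:
            raise ValueError("no bins")
        if ((d["gc"] < 0) | (d["gc"] > 1)).any():
            raise ValueError("gc out of [0, 1]")
        if (d["end"] <= d["start"]).any():
            raise ValueError("empty or inverted bin interval")
        if ((d["end"] - d["start"]) > self.bin_size).any():
            raise ValueError("bin longer than bin_size")
        for chrom, sub in d.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if starts[0] != 0 or not np.array_equal(starts[1:], ends[:-1]):
                raise ValueError(f"bins of chromosome {chrom} do not tile from 0")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_usable(self) -> int:
        return int(self.df["usable"].sum())

    @property
    def usable_mask(self) -> np.ndarray:
        return self.df["usable"].to_numpy(dtype=bool)

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy()

    @property
    def gc(self) -> np.ndarray:
        return self.df["gc"].to_numpy(dtype=float)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return self.df["chrom"].to_numpy() == normalize_chrom(chrom)


def make_genome_bins(
    chrom_lengths: dict[str, int],
    bin_size: int = 1_000_000,
    gc: np.ndarray | None = None,
    gc_band: tuple[float, float] = GC_USABLE_BAND,
) -> GenomeBins:
    """Tile each chromosome with ``bin_size`` windows (last bin may be short).

    ``gc`` supplies the per-bin GC fraction; when omitted a synthetic
    autocorrelated GC track around each chromosome's characteristic mean
    is generated (deterministic — the track is part of the bundled bin
    model, not of any analysis).  Bins with GC outside ``gc_band`` are
    flagged unusable.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    rows: list[tuple[str, int, int]] = []
    for label, length in chrom_lengths.items():
        c = normalize_chrom(label)
        length = int(length)
        if length <= 0:
            raise ValueError(f"non-positive length for chromosome {label}")
        n = -(-length // bin_size)  # ceil division
        for i in range(n):
            rows.append((c, i * bin_size, min((i + 1) * bin_size, length)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if gc is None:
        gc = _synthetic_gc_track(df)
    gc = np.asarray(gc, dtype=float)
    if gc.shape != (len(df),):
        raise ValueError("gc vector length does not match bin count")
    df["gc"] = gc
    lo, hi = gc_band
    df["usable"] = (gc >= lo) & (gc <= hi)
    return GenomeBins(df, bin_size=bin_size)


def _synthetic_gc_track(df: pd.DataFrame) -> np.ndarray:
    """AR(1) GC fluctuation around each chromosome's mean GC, clipped to [0.2, 0.7]."""
    rng = np.random.default_rng(_GC_TRACK_SEED)
    out = np.empty(len(df))
    pos = 0
    for chrom, sub in df.groupby("chrom", sort=False):
        n = len(sub)
        mu = CHROM_MEAN_GC.get(str(chrom), 0.41)
        eps = rng.normal(0.0, 1.0, n)
        ar = np.empty(n)
        ar[0] = eps[0]
        for i in range(1, n):  # rho=0.6 local autocorrelation, like isochores
            ar[i] = 0.6 * ar[i - 1] + np.sqrt(1 - 0.6**2) * eps[i]
        out[pos : pos + n] = np.clip(mu + 0.045 * ar, 0.20, 0.70)
        pos += n
    # re-order to the dataframe's row order (groupby preserved input order)
    return out


_DEFAULT_BINS_CACHE: dict[int, GenomeBins] = {}


def default_genome_bins(bin_size: int = 1_000_000) -> GenomeBins:
    """The bundled hg19-scale bin model at ``bin_size`` (cached)."""
    if bin_size not in _DEFAULT_BINS_CACHE:
        _DEFAULT_BINS_CACHE[bin_size] = make_genome_bins(HG19_CHROM_LENGTHS, bin_size)
    return _DEFAULT_BINS_CACHE[bin_size]


@dataclass
class BinCounts:
    """Raw read counts of one sample over a bin model."""

    sample_id: str
    counts: np.ndarray
    run_id: str = "run0"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if np.issubdtype(self.counts.dtype, np.floating):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("negative count")

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinCounts):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.run_id == other.run_id
            and np.array_equal(self.counts, other.counts)
        )
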