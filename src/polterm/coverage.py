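"""Stranded base-resolution coverage and the normalisation arithmetic.

Signal is held densely as one float array per ``(chrom, strand)``.  All
normalisation steps of the occupancy pipeline are implemented explicitly:
spike-in factor computation from experimental/spike-in read counts, the
depth-normalise-then-reverse step (algebraically the identity, exposed and
logged as such), input subtraction with clamping at zero, replicate
averaging, and the Pol II-ratio occupancy adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


class CoverageError(ValueError):
    pass


class StrandedCoverage:
    """Per-chromosome, per-strand nonnegative base-resolution signal."""

    def __init__(self, chrom_lengths: dict):
        self.chrom_lengths = dict(chrom_lengths)
        self._data: dict[tuple, np.ndarray] = {}

    # -- access ------------------------------------------------------------
    def get(self, chrom: str, strand: str) -> np.ndarray:
        key = (chrom, strand)
        if key not in self._data:
            self._data[key] = np.zeros(self.chrom_lengths[chrom], dtype=float)
        return self._data[key]

    def set(self, chrom: str, strand: str, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.shape != (self.chrom_lengths[chrom],):
            raise CoverageError(
                f"array length {values.shape} does not match chromosome "
                f"{chrom} length {self.chrom_lengths[chrom]}"
            )
        self._data[(chrom, strand)] = values

    def keys(self):
        return list(self._data)

    def total(self) -> float:
        return float(sum(arr.sum() for arr in self._data.values()))

    def copy(self) -> "StrandedCoverage":
        out = StrandedCoverage(self.chrom_lengths)
        for key, arr in self._data.items():
            out._data[key] = arr.copy()
        return out

    def _map(self, fn) -> "StrandedCoverage":
        out = StrandedCoverage(self.chrom_lengths)
        for (chrom, strand), arr in self._data.items():
            out._data[(chrom, strand)] = fn(arr)
        return out

    def same_genome(self, other: "StrandedCoverage") -> bool:
        return self.chrom_lengths == other.chrom_lengths

    def __eq__(self, other) -> bool:
        if not isinstance(other, StrandedCoverage):
            return NotImplemented
        if self.chrom_lengths != other.chrom_lengths:
            return False
        keys = set(self._data) | set(other._data)
        return all(
            np.array_equal(self.get(*k), other.get(*k)) for k in keys
        )


@dataclass(frozen=True)
class LibraryCounts:
    """Uniquely mapped read counts of one library, split by species."""

    sample_id: str
    experimental_reads: int
    spikein_reads: int

    def __post_init__(self):
        if self.experimental_reads < 0 or self.spikein_reads < 0:
            raise ValueError("read counts must be >= 0")


# ---------------------------------------------------------------------------
# track I/O
# ---------------------------------------------------------------------------

def read_track(
    path: str,
    fmt: str,
    strand: str,
    chrom_lengths: dict | None = None,
) -> StrandedCoverage:
    """Read one strand of coverage from bedGraph or bigWig.

    bedGraph is 4-column, 0-based half-open; intervals must be sorted and
    non-overlapping per chromosome.  For bedGraph, ``chrom_lengths`` may be
    omitted, in which case each chromosome length is the largest interval
    end seen.
    """
    if strand not in STRANDS:
        raise ValueError("strand must be '+' or '-'")
    if fmt == "bedgraph":
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        if chrom_lengths is None:
            chrom_lengths = df.groupby("chrom")["end"].max().to_dict()
        cov = StrandedCoverage(chrom_lengths)
        for chrom, sub in df.groupby("chrom", sort=False):
            starts = sub["start"].to_numpy(dtype=int)
            ends = sub["end"].to_numpy(dtype=int)
            if np.any(ends[:-1] > starts[1:]) or np.any(starts >= ends):
                raise CoverageError(
                    f"{path}: unsorted or overlapping intervals on {chrom}"
                )
            arr = cov.get(str(chrom), strand)
            for s, e, v in zip(starts, ends, sub["value"].to_numpy(dtype=float)):
                arr[s:e] = v
        return cov
    if fmt == "bigwig":
        import pyBigWig

        bw = pyBigWig.open(path)
        try:
            lengths = dict(bw.chroms())
            cov = StrandedCoverage(chrom_lengths or lengths)
            for chrom, n in lengths.items():
                vals = np.nan_to_num(
                    np.asarray(bw.values(chrom, 0, n), dtype=float), nan=0.0
                )
                cov.set(chrom, strand, vals)
        finally:
            bw.close()
        return cov
    raise ValueError(f"unknown track format {fmt!r}")


def _runs(arr: np.ndarray):
    """Run-length encode an array into (start, end, value) with zero runs
    retained (caller may drop them)."""
    if arr.size == 0:
        return
    change = np.flatnonzero(np.diff(arr) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [arr.size]))
    for s, e in zip(starts, ends):
        yield int(s), int(e), float(arr[s])


def write_track(cov: StrandedCoverage, path: str, fmt: str, strand: str) -> None:
    """Write one strand as bedGraph or bigWig; zero runs are omitted."""
    chroms = sorted(c for c, s in cov.keys() if s == strand) or sorted(
        cov.chrom_lengths
    )
    if fmt == "bedgraph":
        with open(path, "w") as fh:
            for chrom in chroms:
                for s, e, v in _runs(cov.get(chrom, strand)):
                    if v != 0.0:
                        fh.write(f"{chrom}\t{s}\t{e}\t{v:.10g}\n")
        return
    if fmt == "bigwig":
        import pyBigWig

        bw = pyBigWig.open(path, "w")
        try:
            header = [(c, int(cov.chrom_lengths[c])) for c in sorted(cov.chrom_lengths)]
            bw.addHeader(header)
            for chrom, _n in header:
                starts, ends, vals = [], [], []
                for s, e, v in _runs(cov.get(chrom, strand)):
                    if v != 0.0:
                        starts.append(s)
                        ends.append(e)
                        vals.append(v)
                if starts:
                    bw.addEntries(
                        [chrom] * len(starts), starts, ends=ends, values=vals
                    )
        finally:
            bw.close()
        return
    raise ValueError(f"unknown track format {fmt!r}")


# ---------------------------------------------------------------------------
# windowed statistics and normalisation
# ---------------------------------------------------------------------------

def window_density(
    cov: StrandedCoverage, chrom: str, start: int, end: int, strand: str
) -> float:
    """Mean per-base signal over ``[start, end)``."""
    n = cov.chrom_lengths[chrom]
    if not (0 <= start < end <= n):
        raise ValueError(
            f"invalid window [{start}, {end}) on {chrom} (length {n})"
        )
    arr = cov.get(chrom, strand)
    return float(arr[start:end].mean())


def spikein_factors(counts, reference: str) -> dict:
    """Spike-in normalisation factors relative to a reference sample.

    factor(s) = spikein_reads(reference) / spikein_reads(s); the reference
    maps to exactly 1.  Invariant to uniform rescaling of all spike counts.
    """
    by_id = {c.sample_id: c for c in counts}
    if reference not in by_id:
        raise ValueError(f"reference sample {reference!r} not in counts")
    for c in counts:
        if c.spikein_reads <= 0:
            raise ValueError(
                f"sample {c.sample_id!r} has no spike-in reads; library unusable"
            )
    ref = by_id[reference].spikein_reads
    factors = {c.sample_id: ref / c.spikein_reads for c in counts}
    factors[reference] = 1.0
    return factors


def apply_normalization(
    cov: StrandedCoverage, depth_factor: float = 1.0, spike_factor: float = 1.0
) -> StrandedCoverage:
    """Scale a track by its spike-in factor.

    The published pipeline first normalises to sequencing depth, then
    reverses that normalisation before applying spike-in factors; the
    depth step is algebraically the identity, so only the spike factor is
    applied here.  Both factors are logged for the manifest.
    """
    if depth_factor <= 0 or spike_factor <= 0:
        raise ValueError("normalisation factors must be > 0")
    logger.info(
        "apply_normalization: depth_factor=%g (normalised then reversed; net "
        "identity), spike_factor=%g",
        depth_factor,
        spike_factor,
    )
    return cov._map(lambda a: a * spike_factor)


def chip_input_subtract(
    ip: StrandedCoverage, input_cov: StrandedCoverage
) -> StrandedCoverage:
    """Per-base ``max(ip - input, 0)``; only positive values are retained."""
    if not ip.same_genome(input_cov):
        raise CoverageError("IP and input tracks cover different genomes")
    out = StrandedCoverage(ip.chrom_lengths)
    for key in set(ip.keys()) | set(input_cov.keys()):
        out._data[key] = np.maximum(ip.get(*key) - input_cov.get(*key), 0.0)
    return out


def average_replicates(tracks) -> StrandedCoverage:
    """Per-base arithmetic mean of replicate tracks."""
    tracks = list(tracks)
    if not tracks:
        raise ValueError("need at least one track to average")
    first = tracks[0]
    for t in tracks[1:]:
        if not first.same_genome(t):
            raise CoverageError("replicate tracks cover different genomes")
    out = StrandedCoverage(first.chrom_lengths)
    keys = set()
    for t in tracks:
        keys.update(t.keys())
    for key in keys:
        out._data[key] = sum(t.get(*key) for t in tracks) / len(tracks)
    return out


def occupancy_adjust(
    target: StrandedCoverage,
    polII_treated_mean: float,
    polII_control_mean: float,
) -> StrandedCoverage:
    """Rescale an occupancy track by the Pol II signal change between
    conditions (control mean / treated mean), so that a treatment-induced
    global Pol II loss does not masquerade as a loss of the target factor."""
    if polII_treated_mean <= 0 or polII_control_mean <= 0:
        raise ValueError("Pol II means must be > 0")
    ratio = polII_control_mean / polII_treated_mean
    return target._map(lambda a: a * ratio)


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "condition",
    "plus_track",
    "minus_track",
    "experimental_reads",
    "spikein_reads",
]


def read_sample_sheet(path: str) -> pd.DataFrame:
    """Read the TSV sample sheet (sample_id, condition, per-strand track
    paths, experimental and spike-in read counts)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SAMPLE_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return df
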