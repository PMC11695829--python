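"""Scaled and anchored signal matrices, log2-ratio heatmaps, metagene curves.

``scaled_matrix`` rescales every gene body to a common number of bins by
exact integration of the per-base signal over fractional bin spans (the
signal is treated as piecewise constant per base), so two genes whose
signal is the same function of relative position produce identical rows
regardless of their lengths.  ``anchored_matrix`` bins fixed windows around
an anchor without scaling.  Confidence bands on metagene curves are
percentile bootstraps over genes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from polterm.coverage import StrandedCoverage

logger = logging.getLogger(__name__)


@dataclass
class SignalMatrix:
    """Genes x positional bins, with segment labels per column.

    ``segments`` labels each column "upstream", "body" or "downstream" (or
    "anchor" bins for anchored matrices); ``bin_labels`` carries a
    human-readable position for plotting and serialisation.
    """

    values: np.ndarray
    row_ids: list
    segments: list
    bin_labels: list
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.values.shape

    def same_scheme(self, other: "SignalMatrix") -> bool:
        return (
            self.segments == other.segments
            and self.bin_labels == other.bin_labels
            and self.row_ids == other.row_ids
        )

    def to_frame(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_arrays(
            [self.segments, self.bin_labels], names=["segment", "bin"]
        )
        return pd.DataFrame(self.values, index=self.row_ids, columns=cols)

    def to_tsv(self, path: str) -> None:
        df = self.to_frame()
        df.columns = [f"{seg}:{lab}" for seg, lab in df.columns]
        df.to_csv(path, sep="\t", index_label="unit_id")

    def sort_rows(self, order) -> "SignalMatrix":
        idx = {rid: i for i, rid in enumerate(self.row_ids)}
        sel = [idx[r] for r in order]
        return SignalMatrix(
            self.values[sel], list(order), self.segments, self.bin_labels,
            dict(self.meta),
        )


def _interp_cumsum(arr: np.ndarray) -> np.ndarray:
    """Cumulative integral of a piecewise-constant per-base signal; value at
    fractional x obtained by linear interpolation of this array."""
    return np.concatenate(([0.0], np.cumsum(arr)))


def _fractional_bin_means(arr: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Exact means of a per-base signal over bins with fractional edges
    (relative to the start of ``arr``)."""
    csum = _interp_cumsum(arr)
    x = np.arange(csum.size)
    integrals = np.interp(edges, x, csum)
    widths = np.diff(edges)
    return np.diff(integrals) / widths


def _oriented_dense(cov: StrandedCoverage, chrom: str, strand: str,
                    start: int, end: int, pad_nan: bool = True) -> np.ndarray:
    """Per-base signal over genomic ``[start, end)``, flipped to
    transcription orientation for minus-strand requests; positions outside
    the chromosome are NaN-padded (or zero if ``pad_nan`` is False)."""
    n = cov.chrom_lengths[chrom]
    fill = np.nan if pad_nan else 0.0
    out = np.full(end - start, fill, dtype=float)
    clo, chi = max(0, start), min(n, end)
    if clo < chi:
        out[clo - start:chi - start] = cov.get(chrom, strand)[clo:chi]
    if strand == "-":
        out = out[::-1]
    return out


def scaled_matrix(
    cov: StrandedCoverage,
    units,
    n_body_bins: int = 100,
    upstream: int = 500,
    downstream: int = 500,
    trim: int = 250,
    up_binsize: int = 50,
    down_binsize: int = 50,
) -> SignalMatrix:
    """Gene-body-scaled signal matrix.

    Fixed-size unscaled flanks (binned at ``up_binsize``/``down_binsize``)
    surround a body segment ``[TSS + trim, PAS - trim)`` divided into
    ``n_body_bins`` equal-length strand-oriented bins.  Units whose trimmed
    body is shorter than one base per bin boundary are skipped (recorded in
    ``meta['skipped']``).
    """
    if upstream % up_binsize or downstream % down_binsize:
        raise ValueError("flank sizes must be multiples of their bin sizes")
    n_up = upstream // up_binsize
    n_down = downstream // down_binsize
    rows, row_ids = [], []
    skipped = []
    for u in units:
        body_len = u.length - 2 * trim
        if body_len < n_body_bins or body_len <= 0:
            skipped.append((u.id, f"trimmed body {body_len} bp < {n_body_bins} bins"))
            continue
        if u.strand == "+":
            gstart, gend = u.start - upstream, u.end + downstream
        else:
            gstart, gend = u.start - downstream, u.end + upstream
        dense = _oriented_dense(cov, u.chrom, u.strand, gstart, gend)
        # oriented layout: [upstream | trim | body | trim | downstream]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN flank bins
            up = np.nanmean(dense[:upstream].reshape(n_up, up_binsize), axis=1)
            down = np.nanmean(
                dense[upstream + u.length:].reshape(n_down, down_binsize), axis=1
            )
        body = dense[upstream + trim: upstream + trim + body_len]
        edges = np.linspace(0, body_len, n_body_bins + 1)
        body_bins = _fractional_bin_means(body, edges)
        rows.append(np.concatenate([up, body_bins, down]))
        row_ids.append(u.id)
    if skipped:
        logger.info("scaled_matrix: skipped %d short units", len(skipped))
    segments = ["upstream"] * n_up + ["body"] * n_body_bins + ["downstream"] * n_down
    bin_labels = (
        [f"{-upstream + i * up_binsize}" for i in range(n_up)]
        + [f"body{i}" for i in range(n_body_bins)]
        + [f"+{i * down_binsize}" for i in range(n_down)]
    )
    values = np.vstack(rows) if rows else np.empty((0, len(segments)))
    return SignalMatrix(values, row_ids, segments, bin_labels,
                        {"skipped": skipped, "trim": trim})


def anchored_matrix(
    cov: StrandedCoverage,
    anchors,
    upstream: int = 500,
    downstream: int = 500,
    binsize: int = 10,
) -> SignalMatrix:
    """Fixed-window matrix around anchors, position 0 at the anchor.

    ``anchors`` is an iterable of ``(id, chrom, position, strand)``; bins of
    ``binsize`` bp run from ``-upstream`` to ``+downstream`` in
    transcription orientation.  Out-of-chromosome positions contribute NaN
    and bins average over their in-range bases.
    """
    if upstream % binsize or downstream % binsize:
        raise ValueError("window sizes must be multiples of binsize")
    n_bins = (upstream + downstream) // binsize
    rows, row_ids = [], []
    for aid, chrom, pos, strand in anchors:
        if strand == "+":
            gstart, gend = pos - upstream, pos + downstream
        else:
            # +1 shift keeps the anchor base itself at oriented offset 0
            gstart, gend = pos - downstream + 1, pos + upstream + 1
        dense = _oriented_dense(cov, chrom, strand, gstart, gend)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
            rows.append(np.nanmean(dense.reshape(n_bins, binsize), axis=1))
        row_ids.append(aid)
    segments = ["anchor"] * n_bins
    bin_labels = [f"{-upstream + i * binsize}" for i in range(n_bins)]
    values = np.vstack(rows) if rows else np.empty((0, n_bins))
    return SignalMatrix(values, row_ids, segments, bin_labels,
                        {"binsize": binsize})


def log2_ratio(a: SignalMatrix, b: SignalMatrix, pseudocount: float = 0.01) -> SignalMatrix:
    """Elementwise ``log2((a + p) / (b + p))`` of two same-scheme matrices."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if not a.same_scheme(b):
        raise ValueError("matrices have different row/column schemes")
    vals = np.log2((a.values + pseudocount) / (b.values + pseudocount))
    return SignalMatrix(vals, a.row_ids, a.segments, a.bin_labels,
                        {"pseudocount": pseudocount})


def profile_with_ci(
    m: SignalMatrix,
    level: float = 0.95,
    n_boot: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Columnwise mean with a percentile-bootstrap confidence band over rows.

    Returns a DataFrame with columns ``mean``, ``lo``, ``hi`` (``lo``/``hi``
    NaN for a single-row matrix, where a band is undefined).
    """
    n_rows = m.values.shape[0]
    if n_rows < 1:
        raise ValueError("matrix has no rows")
    mean = np.nanmean(m.values, axis=0)
    if n_rows < 2:
        lo = hi = np.full_like(mean, np.nan)
    else:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n_rows, size=(n_boot, n_rows))
        boots = np.nanmean(m.values[idx], axis=1)
        alpha = (1.0 - level) / 2.0
        lo = np.nanquantile(boots, alpha, axis=0)
        hi = np.nanquantile(boots, 1.0 - alpha, axis=0)
    return pd.DataFrame(
        {"mean": mean, "lo": lo, "hi": hi},
        index=pd.Index(m.bin_labels, name="bin"),
    )


# ---------------------------------------------------------------------------
# plotting (convenience layer)
# ---------------------------------------------------------------------------

def plot_heatmap(m: SignalMatrix, ax=None, cmap: str = "RdBu_r",
                 vmin=None, vmax=None, sort_by_mean: bool = True):
    """Heatmap of a signal matrix (rows = genes)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 8))
    vals = m.values
    if sort_by_mean and vals.shape[0] > 1:
        order = np.argsort(-np.nanmean(vals, axis=1))
        vals = vals[order]
    im = ax.imshow(vals, aspect="auto", interpolation="nearest",
                   cmap=cmap, vmin=vmin, vmax=vmax)
    ax.set_xlabel("position bin")
    ax.set_ylabel("genes")
    ax.figure.colorbar(im, ax=ax, shrink=0.6)
    return ax


def plot_metagene(profile: pd.DataFrame, ax=None, label=None, color=None):
    """Metagene curve with its confidence band (output of profile_with_ci)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(len(profile))
    ax.plot(x, profile["mean"].to_numpy(), label=label, color=color)
    if profile["lo"].notna().any():
        ax.fill_between(x, profile["lo"], profile["hi"], alpha=0.25,
                        color=color, linewidth=0)
    ax.set_xlabel("position bin")
    ax.set_ylabel("mean signal")
    if label:
        ax.legend()
    return ax
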