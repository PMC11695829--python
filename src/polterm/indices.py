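"""Per-gene indices of attenuation, readthrough, cleavage and retention.

Each index is a ratio of windowed mean densities and is therefore invariant
to multiplying the coverage track by any positive constant.  Windows are
constructed strand-oriented; a ratio whose denominator window carries zero
signal is *undefined* and propagates as NaN, never as an infinity, and
selection operations require defined values.  All threshold comparisons are
boundary-inclusive.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from polterm.annotation import (
    PasSite,
    TranscriptionUnit,
    fetch_sequence,
    reverse_complement,
)
from polterm.config import AnalysisConfig
from polterm.coverage import StrandedCoverage, window_density


def _clipped_density(
    cov: StrandedCoverage, chrom: str, start: int, end: int, strand: str,
    warn_label: str | None = None,
) -> float:
    """Window density with truncation at chromosome bounds (warning once per
    call when clipping was needed)."""
    n = cov.chrom_lengths[chrom]
    cstart, cend = max(0, start), min(n, end)
    if cstart >= cend:
        return float("nan")
    if (cstart, cend) != (start, end) and warn_label:
        warnings.warn(
            f"{warn_label}: window [{start}, {end}) truncated to "
            f"[{cstart}, {cend}) on {chrom}",
            stacklevel=3,
        )
    return window_density(cov, chrom, cstart, cend, strand)


def _ratio(num: float, den: float) -> float:
    if not np.isfinite(num) or not np.isfinite(den) or den == 0.0:
        return float("nan")
    return num / den


# ---------------------------------------------------------------------------
# indices
# ---------------------------------------------------------------------------

def attenuation_index(
    cov: StrandedCoverage, unit: TranscriptionUnit, cfg: AnalysisConfig
) -> float:
    """Promoter-proximal attenuation index.

    Mean density over the first ``cfg.tss_window`` bp downstream of the TSS
    divided by mean density over the remainder of the gene.  NaN for genes
    not longer than the window, or when the gene body carries no signal.
    """
    if unit.length <= cfg.tss_window:
        return float("nan")
    if unit.strand == "+":
        w5 = (unit.start, unit.start + cfg.tss_window)
        body = (unit.start + cfg.tss_window, unit.end)
    else:
        w5 = (unit.end - cfg.tss_window, unit.end)
        body = (unit.start, unit.end - cfg.tss_window)
    num = window_density(cov, unit.chrom, *w5, unit.strand)
    den = window_density(cov, unit.chrom, *body, unit.strand)
    return _ratio(num, den)


def select_attenuated(
    table: pd.DataFrame,
    cfg: AnalysisConfig,
    treated: str,
    control: str,
) -> set:
    """Units whose attenuation index rose at least ``cfg.attenuation_fold``
    in the treated sample relative to control.

    ``table`` is a long-format metric table with columns ``unit_id``,
    ``sample``, ``attenuation_index`` and ``length``.  Only units longer
    than ``cfg.min_len_attenuation`` with defined indices in both samples
    are considered; the threshold is inclusive.
    """
    present = set(table["sample"].unique())
    missing = {treated, control} - present
    if missing:
        raise ValueError(f"samples missing from table: {sorted(missing)}")
    sub = table[table["length"] > cfg.min_len_attenuation]
    if sub.empty:
        return set()
    piv = (
        sub.groupby(["unit_id", "sample"])["attenuation_index"]
        .first()
        .unstack("sample")
    )
    for col in (treated, control):
        if col not in piv.columns:
            return set()
    ratio = piv[treated] / piv[control]
    ok = ratio.notna() & (ratio >= cfg.attenuation_fold)
    return set(piv.index[ok])


def readthrough_index(
    cov: StrandedCoverage, unit: TranscriptionUnit, cfg: AnalysisConfig
) -> float:
    """Signal persisting downstream of the PAS, normalised to the gene body.

    Mean density over ``cfg.readthrough_window`` bp downstream of the PAS
    divided by mean density over the body (TSS + ``cfg.metagene_trim`` to
    the PAS).  Windows reaching past the chromosome end are truncated with a
    warning.  NaN when the body is empty or carries no signal.
    """
    if unit.length <= cfg.metagene_trim:
        return float("nan")
    if unit.strand == "+":
        down = (unit.end, unit.end + cfg.readthrough_window)
        body = (unit.start + cfg.metagene_trim, unit.end)
    else:
        down = (unit.start - cfg.readthrough_window, unit.start)
        body = (unit.start, unit.end - cfg.metagene_trim)
    num = _clipped_density(cov, unit.chrom, *down, unit.strand,
                           warn_label=f"readthrough_index({unit.id})")
    den = window_density(cov, unit.chrom, *body, unit.strand)
    return _ratio(num, den)


def cleavage_index(
    cov: StrandedCoverage, pas: PasSite, cfg: AnalysisConfig
) -> float:
    """Cleavage-site usage index.

    Mean density over the 2 x ``cfg.pas_half_window`` nt window centred on
    the PAS, divided by mean density over a ``cfg.body_window`` bp gene-body
    window ending ``cfg.body_offset`` bp upstream of the PAS (inside the
    gene).  Efficient cleavage removes the RNA 3' of the site from the
    nascent pool, so the index drops as cleavage improves at a fixed body
    signal -- in depletion experiments the comparison of interest is the
    shift of the index distribution between conditions.
    """
    h = cfg.pas_half_window
    if pas.strand == "+":
        num_w = (pas.position - h, pas.position + h)
        den_w = (
            pas.position - cfg.body_offset - cfg.body_window,
            pas.position - cfg.body_offset,
        )
    else:
        num_w = (pas.position - h + 1, pas.position + h + 1)
        den_w = (
            pas.position + 1 + cfg.body_offset,
            pas.position + 1 + cfg.body_offset + cfg.body_window,
        )
    num = _clipped_density(cov, pas.chrom, *num_w, pas.strand,
                           warn_label=f"cleavage_index({pas.unit_id})")
    den = _clipped_density(cov, pas.chrom, *den_w, pas.strand,
                           warn_label=f"cleavage_index({pas.unit_id})")
    return _ratio(num, den)


def intron_retention_index(
    cov: StrandedCoverage, unit: TranscriptionUnit
) -> tuple[list, float]:
    """Intron retention: intronic density over flanking exonic density.

    Per intron: density(intron) / mean(density(upstream exon),
    density(downstream exon)), flanks taken in genomic order (the mean is
    orientation-symmetric).  Returns ``(per_intron, aggregate)`` where the
    aggregate is the mean of the defined per-intron ratios; ``([], nan)``
    for intronless units.
    """
    introns = unit.introns
    if not introns:
        return [], float("nan")
    per_intron = []
    exons = unit.exons
    for i, (istart, iend) in enumerate(introns):
        up = exons[i]
        down = exons[i + 1]
        d_int = window_density(cov, unit.chrom, istart, iend, unit.strand)
        d_up = window_density(cov, unit.chrom, up[0], up[1], unit.strand)
        d_down = window_density(cov, unit.chrom, down[0], down[1], unit.strand)
        per_intron.append(_ratio(d_int, (d_up + d_down) / 2.0))
    defined = [r for r in per_intron if np.isfinite(r)]
    agg = float(np.mean(defined)) if defined else float("nan")
    return per_intron, agg


def chip_target_set(table: pd.DataFrame, cfg: AnalysisConfig) -> set:
    """Occupancy targets: coding genes longer than ``cfg.chip_min_len`` whose
    mean occupancy is at least ``cfg.chip_enrichment`` times the mean over
    that universe (inclusive)."""
    uni = table[
        (table["biotype"] == "coding") & (table["length"] > cfg.chip_min_len)
    ].drop_duplicates("unit_id")
    if uni.empty:
        return set()
    mean = uni["chip_mean"].mean()
    ok = uni["chip_mean"] >= cfg.chip_enrichment * mean
    return set(uni.loc[ok, "unit_id"])


# ---------------------------------------------------------------------------
# sequence bias
# ---------------------------------------------------------------------------

def _anchor_base(unit: TranscriptionUnit, anchor: str) -> int:
    """First-base genomic coordinate of the anchor in transcription
    orientation (TSS: first transcribed base; PAS: last transcribed base)."""
    if anchor == "TSS":
        return unit.start if unit.strand == "+" else unit.end - 1
    if anchor == "PAS":
        return unit.end - 1 if unit.strand == "+" else unit.start
    raise ValueError("anchor must be 'TSS' or 'PAS'")


def _sense_window(genome, unit: TranscriptionUnit, anchor: str,
                  upstream: int, downstream: int) -> tuple[str, int]:
    """Sense-strand sequence covering oriented offsets
    ``[-upstream, downstream)`` around the anchor, clipped at chromosome
    bounds.  Returns ``(sequence, n_clipped_left)`` where the clip count
    refers to positions removed at the upstream edge."""
    c = _anchor_base(unit, anchor)
    n = len(genome[unit.chrom])
    if unit.strand == "+":
        lo, hi = c - upstream, c + downstream
        clo, chi = max(0, lo), min(n, hi)
        seq = fetch_sequence(genome, unit.chrom, clo, chi)
        return seq, clo - lo
    lo, hi = c - downstream + 1, c + upstream + 1
    clo, chi = max(0, lo), min(n, hi)
    seq = reverse_complement(fetch_sequence(genome, unit.chrom, clo, chi))
    return seq, hi - chi


def base_composition_profile(
    genome,
    units,
    anchor: str = "TSS",
    upstream: int = 100,
    downstream: int = 100,
) -> pd.DataFrame:
    """Per-position A/C/G/T frequencies on the sense strand around an anchor.

    Returns a DataFrame indexed by oriented position (0 = anchor base) with
    columns A, C, G, T; each row sums to 1 over the bases counted at that
    position (genes whose window leaves the chromosome contribute only
    in-range positions; N bases are not counted).
    """
    units = list(units)
    if not units:
        raise ValueError("empty gene set")
    width = upstream + downstream
    counts = np.zeros((width, 4), dtype=float)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for u in units:
        seq, clip_left = _sense_window(genome, u, anchor, upstream, downstream)
        for j, ch in enumerate(seq):
            k = base_idx.get(ch)
            if k is not None:
                counts[clip_left + j, k] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = counts / totals
    return pd.DataFrame(
        freqs, index=np.arange(-upstream, downstream), columns=list("ACGT")
    )


def _has_t_run(seq: str, min_run: int) -> bool:
    run = 0
    for ch in seq:
        if ch == "T":
            run += 1
            if run >= min_run:
                return True
        else:
            run = 0
    return False


def polyt_run_enrichment(
    genome,
    set_a,
    set_b,
    anchor: str = "TSS",
    upstream: int = 100,
    downstream: int = 100,
    min_run: int = 5,
) -> dict:
    """Poly-T run content of two gene sets around an anchor.

    For each set, the fraction of genes whose sense-strand window contains
    at least one run of ``min_run`` or more consecutive T, plus per-position
    run-coverage profiles and the a/b ratio of the fractions.
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    set_a, set_b = list(set_a), list(set_b)
    ids_a = {u.id for u in set_a}
    if any(u.id in ids_a for u in set_b):
        warnings.warn("gene sets overlap; enrichment ratio may be diluted")

    def _profile(units):
        width = upstream + downstream
        cov = np.zeros(width)
        n_at = np.zeros(width)
        hits = 0
        for u in units:
            seq, clip_left = _sense_window(genome, u, anchor, upstream, downstream)
            if _has_t_run(seq, min_run):
                hits += 1
            in_run = np.zeros(len(seq), dtype=bool)
            run_start = None
            for j, ch in enumerate(seq + "$"):
                if ch == "T":
                    if run_start is None:
                        run_start = j
                else:
                    if run_start is not None and j - run_start >= min_run:
                        in_run[run_start:j] = True
                    run_start = None
            cov[clip_left:clip_left + len(seq)] += in_run
            n_at[clip_left:clip_left + len(seq)] += 1
        frac = hits / len(units) if units else float("nan")
        with np.errstate(invalid="ignore", divide="ignore"):
            per_pos = cov / n_at
        return frac, per_pos

    frac_a, prof_a = _profile(set_a)
    frac_b, prof_b = _profile(set_b)
    ratio = frac_a / frac_b if frac_b else float("inf") if frac_a else float("nan")
    return {
        "fraction_a": frac_a,
        "fraction_b": frac_b,
        "ratio": ratio,
        "per_position_a": prof_a,
        "per_position_b": prof_b,
        "positions": np.arange(-upstream, downstream),
    }
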