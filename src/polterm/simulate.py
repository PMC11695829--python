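"""Synthetic genomes, annotations, coverage and kinetics with known truth.

The generator emulates the design of a nascent-RNA depletion experiment in a
small eukaryote: two chromosomes of random sequence, a few hundred
non-overlapping stranded transcription units, and strand-specific per-base
coverage for a control and a depleted condition.  Planted effects mirror the
phenotypes the downstream indices are built to detect:

* **attenuation** -- in the depleted condition a chosen subset of genes keeps
  full promoter-proximal signal over the first ``attenuation_window`` bp but
  loses body signal by a planted factor (premature termination);
* **readthrough / cleavage loss** -- signal continues past the PAS as an
  exponential tail whose initial amplitude is ``expression * (1 - cleavage
  efficiency)``; planted-readthrough genes get a low efficiency and a long
  tail length-scale in the depleted condition;
* **intron retention** -- intronic signal sits at a planted fraction of the
  flanking exonic signal;
* **global elongation loss** -- an optional scalar multiplying all depleted
  signal, recoverable only through spike-in normalisation;
* **spike-in admixture** -- library counts mix experimental and spike-in
  reads at a planted fraction (default 1/101, a 100:1 ratio).

Per-base counts are Poisson around the expected signal; expectation mode
(``noise="none"``) returns the expectation exactly so every downstream index
is analytically predictable from the recorded truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from polterm.annotation import TranscriptionUnit, write_gff3
from polterm.coverage import LibraryCounts, StrandedCoverage, write_track
from polterm.kinetics import DecayTrace, Titration, fraction_bound, _exp_model

DEFAULT_CHROM_LENGTHS = {"chrI": 500_000, "chrII": 500_000}
DEFAULT_SPIKE_FRACTION = 1.0 / 101.0  # 100:1 experimental:spike-in mixture


@dataclass
class UnitTruth:
    """Planted ground truth for one transcription unit."""

    expression: float
    attenuated: bool = False
    attenuation_ratio: float = 1.0
    readthrough: bool = False
    tail_scale: float = 25.0
    cleavage_efficiency: dict = field(
        default_factory=lambda: {"control": 0.9, "depleted": 0.9}
    )
    retention: tuple = ()
    t_tract_offset: int | None = None


@dataclass
class SimulationTruth:
    """Full ground truth of a synthetic experiment."""

    units: dict
    spike_fraction: float
    seed: int
    global_elongation_loss: float = 1.0
    attenuation_window: int = 300
    params: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        payload = {
            "units": {uid: asdict(t) for uid, t in self.units.items()},
            "spike_fraction": self.spike_fraction,
            "seed": self.seed,
            "global_elongation_loss": self.global_elongation_loss,
            "attenuation_window": self.attenuation_window,
            "params": self.params,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "SimulationTruth":
        with open(path) as fh:
            payload = json.load(fh)
        units = {
            uid: UnitTruth(
                **{**d, "retention": tuple(d.get("retention", ()))}
            )
            for uid, d in payload["units"].items()
        }
        return cls(
            units=units,
            spike_fraction=payload["spike_fraction"],
            seed=payload["seed"],
            global_elongation_loss=payload.get("global_elongation_loss", 1.0),
            attenuation_window=payload.get("attenuation_window", 300),
            params=payload.get("params", {}),
        )


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------

def make_genome_annotation(
    n_genes: int = 200,
    chrom_lengths: dict | None = None,
    gene_length_range: tuple = (800, 4000),
    min_spacing: int = 800,
    mean_extra_spacing: float = 1200.0,
    intron_fraction: float = 0.2,
    introns_per_gene: tuple = (1, 3),
    intron_length_range: tuple = (60, 200),
    retention_range: tuple = (0.1, 0.9),
    attenuated_fraction: float = 0.1,
    attenuation_ratio: float = 3.0,
    readthrough_fraction: float = 0.3,
    readthrough_tail_scale: float = 400.0,
    base_tail_scale: float = 25.0,
    cleavage_efficiency_control: float = 0.9,
    cleavage_efficiency_depleted_readthrough: float = 0.2,
    t_tract_offset: int = 20,
    t_tract_length: int = 8,
    plant_t_tracts: bool = True,
    expression_mean: float = 20.0,
    n_crowded_pairs: int = 0,
    crowded_gap: int = 100,
    global_elongation_loss: float = 1.0,
    spike_fraction: float = DEFAULT_SPIKE_FRACTION,
    seed: int = 0,
):
    """Generate a random genome, a stranded annotation, and planted truth.

    Returns ``(genome, units, truth)`` where ``genome`` is a dict of
    chromosome name to sequence string.  Genes are packed sequentially with
    same-strand gaps of at least ``min_spacing`` bp (plus an exponential
    surplus); ``n_crowded_pairs`` extra close same-strand pairs (gap
    ``crowded_gap``) can be requested to exercise the isolation filter.
    Expression levels are per-base expected coverage of the gene body, drawn
    lognormally around ``expression_mean``.
    """
    rng = np.random.default_rng(seed)
    chrom_lengths = dict(chrom_lengths or DEFAULT_CHROM_LENGTHS)
    chroms = list(chrom_lengths)

    # -- place genes -------------------------------------------------------
    placements = []  # (chrom, strand, start, end, crowded_partner_of)
    cursors = {c: 1000 for c in chroms}
    ci = 0
    n_normal = n_genes - 2 * n_crowded_pairs
    if n_normal <= 0:
        raise ValueError("n_crowded_pairs too large for n_genes")
    i = 0
    while i < n_normal:
        chrom = chroms[ci % len(chroms)]
        length = int(rng.integers(*gene_length_range))
        gap = int(min_spacing + rng.exponential(mean_extra_spacing))
        start = cursors[chrom] + gap
        end = start + length
        if end + 1000 > chrom_lengths[chrom]:
            ci += 1
            if all(
                cursors[c] + min_spacing + max(gene_length_range) + 2000
                > chrom_lengths[c]
                for c in chroms
            ):
                raise ValueError("genes do not fit in the genome; enlarge it")
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        placements.append((chrom, strand, start, end))
        cursors[chrom] = end
        ci += 1
        i += 1
    for _ in range(n_crowded_pairs):
        chrom = chroms[ci % len(chroms)]
        length = int(rng.integers(*gene_length_range))
        gap = int(min_spacing + rng.exponential(mean_extra_spacing))
        start = cursors[chrom] + gap
        strand = "+" if rng.random() < 0.5 else "-"
        end = start + length
        start2 = end + crowded_gap
        end2 = start2 + int(rng.integers(*gene_length_range))
        if end2 + 1000 > chrom_lengths[chrom]:
            raise ValueError("genes do not fit in the genome; enlarge it")
        placements.append((chrom, strand, start, end))
        placements.append((chrom, strand, start2, end2))
        cursors[chrom] = end2
        ci += 1

    # -- exon structure, truth --------------------------------------------
    units, truth_units = [], {}
    n_placed = len(placements)
    attenuated = rng.random(n_placed) < attenuated_fraction
    readthrough = rng.random(n_placed) < readthrough_fraction
    has_introns = rng.random(n_placed) < intron_fraction
    for idx, (chrom, strand, start, end) in enumerate(placements):
        uid = f"gene{idx + 1:04d}"
        length = end - start
        exons = [(start, end)]
        retention: tuple = ()
        if has_introns[idx] and length > 2 * intron_length_range[1] + 600:
            k = int(rng.integers(introns_per_gene[0], introns_per_gene[1] + 1))
            # carve introns out of the middle half of the gene
            lo, hi = start + length // 4, end - length // 4
            pos = sorted(
                rng.choice(
                    np.arange(lo, hi - intron_length_range[1], 50),
                    size=min(k, max(1, (hi - lo) // 500)),
                    replace=False,
                )
            )
            introns = []
            prev_end = None
            for p in pos:
                ilen = int(rng.integers(*intron_length_range))
                if prev_end is not None and p < prev_end + 50:
                    continue
                introns.append((int(p), int(p) + ilen))
                prev_end = int(p) + ilen
            if introns:
                exons = []
                cursor = start
                for istart, iend in introns:
                    exons.append((cursor, istart))
                    cursor = iend
                exons.append((cursor, end))
                retention = tuple(
                    float(rng.uniform(*retention_range)) for _ in introns
                )
        unit = TranscriptionUnit(
            id=uid, chrom=chrom, strand=strand, start=start, end=end,
            biotype="coding", exons=tuple(exons),
        )
        units.append(unit)
        eff = {
            "control": cleavage_efficiency_control,
            "depleted": (
                cleavage_efficiency_depleted_readthrough
                if readthrough[idx]
                else cleavage_efficiency_control
            ),
        }
        truth_units[uid] = UnitTruth(
            expression=float(
                rng.lognormal(mean=np.log(expression_mean), sigma=0.4)
            ),
            attenuated=bool(attenuated[idx]),
            attenuation_ratio=attenuation_ratio if attenuated[idx] else 1.0,
            readthrough=bool(readthrough[idx]),
            tail_scale=(
                readthrough_tail_scale if readthrough[idx] else base_tail_scale
            ),
            cleavage_efficiency=eff,
            retention=retention,
            t_tract_offset=(
                t_tract_offset if (plant_t_tracts and attenuated[idx]) else None
            ),
        )

    # -- genome sequence ---------------------------------------------------
    genome = {}
    for chrom, n in chrom_lengths.items():
        genome[chrom] = "".join(
            np.array(list("ACGT"))[rng.integers(0, 4, size=n)]
        )
    # plant sense-strand T-tracts downstream of the TSS of attenuated genes
    for u in units:
        t = truth_units[u.id]
        if t.t_tract_offset is None:
            continue
        seq = genome[u.chrom]
        tract = "T" * t_tract_length
        if u.strand == "+":
            p = u.start + t.t_tract_offset
            genome[u.chrom] = seq[:p] + tract + seq[p + t_tract_length:]
        else:
            p = u.end - 1 - t.t_tract_offset - (t_tract_length - 1)
            genome[u.chrom] = seq[:p] + "A" * t_tract_length + seq[p + t_tract_length:]

    truth = SimulationTruth(
        units=truth_units,
        spike_fraction=spike_fraction,
        seed=seed,
        global_elongation_loss=global_elongation_loss,
        params={
            "n_genes": n_placed,
            "attenuation_ratio": attenuation_ratio,
            "readthrough_tail_scale": readthrough_tail_scale,
            "base_tail_scale": base_tail_scale,
            "t_tract_length": t_tract_length,
            "expression_mean": expression_mean,
        },
    )
    return genome, units, truth


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def expected_signal(
    units, truth: SimulationTruth, chrom_lengths: dict, condition: str
) -> StrandedCoverage:
    """Noise-free expected coverage implied by the truth (expectation mode)."""
    if condition not in ("control", "depleted"):
        raise ValueError("condition must be 'control' or 'depleted'")
    cov = StrandedCoverage(chrom_lengths)
    win = truth.attenuation_window
    scale = truth.global_elongation_loss if condition == "depleted" else 1.0
    for u in units:
        t = truth.units[u.id]
        arr = cov.get(u.chrom, u.strand)
        expr = t.expression * scale
        body_level = expr
        if condition == "depleted" and t.attenuated:
            body_level = expr / t.attenuation_ratio
        # local gene profile: 5' window at full expression, remainder at
        # body level, intron slices reduced to the retention fraction
        profile = np.full(u.length, body_level)
        if u.strand == "+":
            profile[:min(u.length, win)] = expr
        else:
            profile[max(0, u.length - win):] = expr
        for (istart, iend), ret in zip(u.introns, t.retention):
            profile[istart - u.start:iend - u.start] *= ret
        arr[u.start:u.end] += profile
        # readthrough tail beyond the PAS
        eff = t.cleavage_efficiency[condition]
        amp = body_level * (1.0 - eff)
        if amp > 0:
            tail_len = int(min(6 * t.tail_scale, 5000))
            d = np.arange(tail_len, dtype=float)
            tail = amp * np.exp(-d / t.tail_scale)
            n = chrom_lengths[u.chrom]
            if u.strand == "+":
                lo = u.end
                hi = min(n, u.end + tail_len)
                arr[lo:hi] += tail[: hi - lo]
            else:
                hi = u.start
                lo = max(0, u.start - tail_len)
                arr[lo:hi] += tail[: hi - lo][::-1]
    return cov


def simulate_coverage(
    units,
    truth: SimulationTruth,
    condition: str = "control",
    chrom_lengths: dict | None = None,
    noise: str = "poisson",
    seed: int = 0,
    sample_id: str | None = None,
):
    """Simulate one library: stranded coverage plus its read counts.

    ``noise="poisson"`` draws independent per-base Poisson counts around the
    expected signal; ``noise="none"`` returns the expectation exactly.
    Spike-in reads are drawn to match the planted mixing fraction
    (spike = experimental * f / (1 - f), Poisson-perturbed under noise).
    """
    chrom_lengths = dict(chrom_lengths or DEFAULT_CHROM_LENGTHS)
    expected = expected_signal(units, truth, chrom_lengths, condition)
    rng = np.random.default_rng(seed)
    if noise == "poisson":
        cov = StrandedCoverage(chrom_lengths)
        for chrom, strand in expected.keys():
            lam = expected.get(chrom, strand)
            cov.set(chrom, strand, rng.poisson(lam).astype(float))
    elif noise == "none":
        cov = expected
    else:
        raise ValueError("noise must be 'poisson' or 'none'")
    total = cov.total()
    experimental = int(round(total))
    f = truth.spike_fraction
    spike_mean = total * f / (1.0 - f)
    if noise == "poisson":
        spike = int(rng.poisson(spike_mean))
    else:
        spike = int(round(spike_mean))
    counts = LibraryCounts(
        sample_id=sample_id or condition,
        experimental_reads=experimental,
        spikein_reads=max(spike, 1),
    )
    return cov, counts


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def simulate_decay(
    k: float,
    plateau: float,
    times,
    sigma: float = 0.0,
    seed: int = 0,
    label: str = "",
) -> DecayTrace:
    """Plateau-exponential decay values with seeded Gaussian noise."""
    if k <= 0:
        raise ValueError("rate k must be > 0")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    t = np.asarray(times, dtype=float)
    y = _exp_model(t, k, plateau)
    if sigma > 0:
        y = y + np.random.default_rng(seed).normal(0.0, sigma, size=t.size)
    return DecayTrace(t, y, label=label)


def simulate_titration(
    Kd: float,
    probe_conc: float,
    conc_grid,
    a_free: float = 0.05,
    a_bound: float = 0.25,
    sigma: float = 0.0,
    seed: int = 0,
) -> Titration:
    """Binding-isotherm anisotropy values with seeded Gaussian noise."""
    if Kd <= 0 or probe_conc <= 0:
        raise ValueError("Kd and probe_conc must be > 0")
    P = np.asarray(conc_grid, dtype=float)
    y = a_free + (a_bound - a_free) * fraction_bound(P, probe_conc, Kd)
    if sigma > 0:
        y = y + np.random.default_rng(seed).normal(0.0, sigma, size=P.size)
    return Titration(P, y, probe_conc=probe_conc)


# ---------------------------------------------------------------------------
# fixture on disk
# ---------------------------------------------------------------------------

def write_fixture(outdir: str, seed: int = 0, noise: str = "poisson", **kwargs):
    """Write a complete synthetic experiment to ``outdir``.

    Produces genome FASTA, GFF3 annotation, per-strand bedGraph tracks for a
    control and a depleted sample, a sample sheet TSV, and the truth JSON.
    Returns ``(genome, units, truth)``.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    chrom_lengths = dict(kwargs.pop("chrom_lengths", DEFAULT_CHROM_LENGTHS))
    genome, units, truth = make_genome_annotation(
        chrom_lengths=chrom_lengths, seed=seed, **kwargs
    )
    with open(os.path.join(outdir, "genome.fa"), "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    write_gff3(units, os.path.join(outdir, "annotation.gff3"))
    truth.to_json(os.path.join(outdir, "truth.json"))
    rows = []
    for i, condition in enumerate(("control", "depleted")):
        cov, counts = simulate_coverage(
            units, truth, condition=condition, chrom_lengths=chrom_lengths,
            noise=noise, seed=seed + 1 + i, sample_id=condition,
        )
        paths = {}
        for strand, tag in (("+", "plus"), ("-", "minus")):
            p = os.path.join(outdir, f"{condition}.{tag}.bedgraph")
            write_track(cov, p, "bedgraph", strand)
            paths[tag] = p
        rows.append(
            dict(
                sample_id=condition,
                condition=condition,
                plus_track=paths["plus"],
                minus_track=paths["minus"],
                experimental_reads=counts.experimental_reads,
                spikein_reads=counts.spikein_reads,
            )
        )
    import pandas as pd

    pd.DataFrame(rows).to_csv(
        os.path.join(outdir, "samples.tsv"), sep="\t", index=False
    )
    return genome, units, truth
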