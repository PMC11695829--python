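# polterm

Quantification of RNA polymerase II transcription termination and its
failure modes from strand-specific, base-resolution sequencing coverage —
plus the curve fits used alongside such experiments in vitro.

## The problem

When termination factors such as the 5'→3' exonuclease Xrn2 or the
elongation factor Spt5 (DSIF) are depleted in fission yeast, nascent-RNA
sequencing (TT-seq) and occupancy profiling (ChIP-seq) show characteristic
genome-wide signatures: signal persisting downstream of the polyadenylation
site (readthrough), promoter-proximal signal with a depleted gene body
(premature termination / attenuation), reads spanning the cleavage site
(3'-end processing defects), and intron retention.  Because depletion can
change transcription globally, per-sample signal must be placed on a common
scale with a spike-in before any of these quantities are comparable.

`polterm` implements that analysis as a tested, reusable library for
computational biologists working with stranded coverage tracks (bedGraph or
bigWig), a genome FASTA and a transcription-unit annotation (GFF3/BED12).

## What it computes

For isolated coding transcription units (no same-strand neighbour within
250 bp of the TSS or PAS), per gene and per sample:

- **attenuation index** = density(TSS → TSS+300 bp) / density(rest of gene);
  genes > 600 bp with a ≥ 1.5-fold treated/control increase are called
  attenuated;
- **readthrough index** = density(PAS → PAS+500 bp) / density(gene body);
- **cleavage index** = density(PAS ± 5 nt) / density(400 bp of gene body
  ending 100 bp upstream of the PAS), at the most prominent experimentally
  supported PAS carrying a poly(A) motif (any of AATAAA, AATGAA, AATAAT,
  TAATAA, AAATAA, ATAATA) within 50 bp upstream;
- **intron retention** = density(intron) / mean density(flanking exons);
- **occupancy targets**: coding genes > 500 nt whose mean occupancy is
  ≥ 2× the universe average, after spike-in normalisation, input
  subtraction (clamped at zero) and replicate averaging.

Metagene machinery builds gene-body-scaled and PAS-anchored matrices,
log2-ratio heatmaps and bootstrap confidence bands; sequence-bias tools
profile base composition and poly-T runs around TSS/PAS anchors.  The
kinetics module fits anisotropy decays y(t) = (1−c)·e^(−kt) + c (half-life
= ln 2 / k) and probe-depletion 1:1 binding isotherms, and normalises
phosphatase-reporter readings.  A synthetic-data generator plants all of
these effects with known truth so the full pipeline runs without any
downloads.

## Worked example

```python
import numpy as np
from polterm.simulate import make_genome_annotation, simulate_coverage
from polterm.model import TerminationAnalysis

genome, units, truth = make_genome_annotation(n_genes=60, seed=42)
chroms = {"chrI": 500_000, "chrII": 500_000}
control, _ = simulate_coverage(units, truth, "control", chroms, seed=43)
depleted, _ = simulate_coverage(units, truth, "depleted", chroms, seed=44)

model = TerminationAnalysis({"control": control, "depleted": depleted},
                            units, genome=genome)
results = model.fit()
attenuated = results.select_attenuated("depleted", "control")
print(results.summary())
```

```
Termination analysis
========================================================
units: 60   samples: ['control', 'depleted']
[control] median attenuation 1.001 | median readthrough 0.005 | median cleavage 0.626 | median intron retention 0.557
[depleted] median attenuation 1.008 | median readthrough 0.006 | median cleavage 0.674 | median intron retention 0.531
attenuated genes (>= 1.5-fold index change): 4
```

The four selected genes are exactly the four the generator planted with a
3-fold promoter-proximal index change; median indices near 1 (attenuation)
and near 0 (readthrough) describe the unperturbed background.  Kinetics
fits follow the same model/results pattern:

```python
from polterm.kinetics import ExponentialDecay
from polterm.simulate import simulate_decay

trace = simulate_decay(k=0.009, plateau=0.05, times=np.arange(0, 1201, 15.0),
                       sigma=0.02, seed=7, label="Xrn2 + Kow5-sCTR")
print(ExponentialDecay(trace).fit().summary())
```

```
Exponential decay fit: Xrn2 + Kow5-sCTR
==============================================
model: y(t) = (1 - c) exp(-k t) + c   n = 81
converged: True  converged
k          0.0092045  (se 0.000145)  1/s
plateau c  0.0381724  (se 0.00244)
half-life  75.3052  s  (ln 2 / k)
residual norm  0.1582
```

The fitted rate (0.0092 s⁻¹) recovers the simulated 0.009 s⁻¹ within its
standard error; the half-life of 75 s is what the decay constant implies.

A command-line pipeline wraps the same stages:

```bash
polterm all --out run/ --seed 7        # simulate → normalize → indices → metagene
polterm kinetics --config kin.yaml --out fits/
```

## Layout

- `polterm.annotation` — transcription units, PAS sites, isolation filter,
  motif scanning, GFF3/BED12/BED6/FASTA I/O
- `polterm.coverage` — stranded coverage, bedGraph/bigWig I/O, spike-in
  factors, input subtraction, replicate averaging, occupancy adjustment
- `polterm.indices` — the per-gene indices and selection rules
- `polterm.metagene` — scaled/anchored matrices, log2 ratios, bootstrap CIs
- `polterm.kinetics` — decay, binding and reporter fits (model/results)
- `polterm.model` — `TerminationAnalysis` / `TerminationResults`
- `polterm.simulate` — synthetic genomes, coverage and kinetics with truth
- `polterm.validation` — planted-effect recovery benchmarks
- `polterm.cli` — the `polterm` command

See `docs/methods.md` for the underlying models, parameter defaults and
limitations.
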