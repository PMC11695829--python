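# Methods

This note documents the quantitative procedures `polterm` implements, the
choices made where the underlying analysis conventions were open, and what
the synthetic benchmarks do and do not demonstrate.

## Coordinates and orientation

All internal coordinates are 0-based half-open.  A transcription unit's TSS
is its `start` boundary on the plus strand and its `end` boundary on the
minus strand; the PAS is the opposite boundary.  Every window (promoter
window, readthrough window, cleavage windows, metagene flanks) is
constructed in transcription orientation at the moment it is evaluated;
windows themselves never carry strand state.  Windows that would leave the
chromosome are truncated with a warning (indices) or NaN-padded (matrices).

## Normalisation

Spike-in factors are `spike_reads(reference) / spike_reads(sample)`, so the
reference maps to exactly 1 and the factors are invariant to any uniform
rescaling of the spike counts.  The occupancy pipeline's
depth-normalise-then-reverse step is algebraically the identity and is
implemented as such; both factors are logged so the manifest records what
was nominally applied.  Input subtraction clamps at zero per base
(`max(IP − input, 0)`), replicates are averaged per base, and occupancy
tracks can additionally be rescaled by the control/treated ratio of mean
Pol II signal so that a treatment-induced global polymerase loss is not
misread as loss of the profiled factor.  That Pol II ratio is computed over
the analysis gene set — the region over which the original ratio was taken
is not specified anywhere, so the gene-set mean is this package's choice.
Because some treatments (auxin) perturb the spike-in organism itself, the
normalisation mode is explicit: `spike` (default) or `depth_only`.

## Per-gene indices

All indices are ratios of windowed mean densities, hence invariant to
multiplying a track by any positive constant, and all threshold
comparisons are boundary-inclusive.  A ratio whose denominator window has
zero signal is undefined and propagates as NaN — never as an infinity —
and selection rules require defined values.

- *Attenuation*: density over the first 300 bp downstream of the TSS
  divided by density over the remainder of the gene; only genes longer
  than 600 bp enter selection, and a gene is called attenuated when the
  treated/control ratio of its index is ≥ 1.5.  The selection is defined on
  the *change* between conditions rather than on the treated index alone;
  a single-sample criterion cannot distinguish intrinsically 5'-biased
  genes from genes that became 5'-biased upon depletion.
- *Readthrough*: density over 500 bp downstream of the PAS divided by
  gene-body density (TSS+250 → PAS).  The 500 bp window width is a
  configurable default; the PAS-anchored heatmap is the primary
  readthrough display and does not depend on it.
- *Cleavage*: density over [PAS−5, PAS+5) divided by density over the
  400 bp body window ending 100 bp upstream of the PAS ([PAS−500,
  PAS−100) on the plus strand).  The body window is placed upstream,
  inside the gene; "5 nt around" and "10 bp window" descriptions are
  reconciled as the half-open 10-base window above.  Reads spanning the
  cleavage site persist when 3'-end cleavage is impaired, so the index
  *rises* as cleavage efficiency falls; only the monotone relationship is
  meaningful, not the absolute value, which depends on window geometry.
- *Intron retention*: per intron, intronic density divided by the mean of
  the two flanking exonic densities (genomic order; the mean is
  orientation-symmetric), aggregated per gene as the mean over defined
  introns.
- *Occupancy targets*: among coding genes longer than 500 nt, those whose
  gene-body mean is at least twice the mean over that universe.

PAS sites for the cleavage index come from an experimental atlas (BED6,
score = prominence).  A candidate passes if any configured hexamer — the
published list deduplicates to {AATAAA, AATGAA, AATAAT, TAATAA, AAATAA,
ATAATA} — occurs within the 50 bp strand-oriented window immediately
upstream of the site, excluding the site base itself (whether the original
window included the site base is unstated; exclusive was chosen and the
motif window width is configurable for sensitivity analysis).  Among
passing candidates the most prominent wins; exact prominence ties go to
the candidate closest to the annotated end, then to the smaller genomic
coordinate — the last tie-break is purely for determinism.  Prominence is
an input column (read support in the source atlas), never recomputed.
Without an atlas the annotated terminal base is used.

## Metagenes

Gene bodies are rescaled by exact integration: the per-base signal is
treated as piecewise constant, its cumulative integral is interpolated at
fractional bin edges, and each of the `n_body_bins` equal-length bins gets
its true mean.  Two genes whose signal is the same function of relative
position therefore produce identical rows regardless of length.  Flanks
are unscaled fixed-size bins; 250 bp after the TSS and before the PAS are
trimmed from the body by default.  Log2 ratios use a pseudocount of 0.01
(in units of mean per-base density; no published value exists).
Confidence bands are percentile bootstraps over genes (1000 resamples,
seeded); on Gaussian rows the band converges to the CLT interval, which
the tests verify at 400 rows.

## Kinetics

Anisotropy decays are affine-rescaled to [0, 1] and fitted with
y(t) = (1−c)·exp(−kt) + c by bounded least squares (`scipy`'s trust-region
reflective, relative parameter tolerance 1e-8, ≤ 10⁴ evaluations), with the
initial rate from a log-linear regression on the upper half of the decay.
The half-life is parametric, ln 2 / k, not the time to cross 0.5.  The
plateau accounts for incomplete decays and residual anisotropy; its lower
bound is −10, not 0, because a trace truncated before its plateau and then
rescaled to [0, 1] is exactly a decay with c = −m/(1−m) < 0 (m the model
value at the last time point) — clamping at zero would bias the rate on
every truncated trace.  Data whose overall trend is non-decreasing yield a
fit-failure result, not an exception.

Binding titrations are fitted with the probe-depletion (quadratic) 1:1
isotherm, f = ((P+L+K_d) − sqrt((P+L+K_d)² − 4PL)) / (2L), because the
probe (50 nM default) need not be far below K_d; when it is, the fit
agrees with the hyperbola P/(P+K_d) (verified to 2%).  Standard errors for
both fits come from the covariance of the least-squares estimate.

Reporter readings are blank-corrected, normalised to culture OD and
optionally scaled to the mean control activity (control → exactly 1);
negative blank-corrected absorbances are clipped to zero with a warning.

## Synthetic data

The generator emulates a two-condition depletion experiment: two 500 kb
chromosomes, 200 stranded, non-overlapping genes (lengths 800–4000 bp,
same-chromosome gaps ≥ 800 bp plus an exponential surplus), 10% attenuated
genes (3-fold planted index change, active only in the depleted
condition), 30% readthrough genes (cleavage efficiency dropping from 0.9
to 0.2 and tail length-scale growing from 25 to 400 bp when depleted), 20%
intron-bearing genes with planted retention fractions drawn from
[0.1, 0.9], mean body coverage 20, per-base Poisson counts, and library
counts mixed with a spike-in at 1/101 (a 100:1 ratio).  Post-PAS signal is
an exponential tail with initial amplitude expression × (1 − cleavage
efficiency) — a single interpretable parameter per effect.  Attenuated
genes optionally carry a sense-strand T₈ tract 20 bp into the gene so the
sequence-bias tools have a planted signal.  Expectation mode (`noise=
"none"`) returns the expected signal exactly, making every index
analytically predictable from the recorded truth; those predictions are
asserted in the tests.

Decay benchmarks use a 0–1200 s time course sampled every 15 s (a typical
plate-reader kinetics setting that covers several half-lives of the slower
species), rates 0.003 and 0.009 s⁻¹ for the 3-fold pair, Gaussian noise
σ = 0.02 on the unit-interval scale, and triplicate traces per condition
whose half-lives are averaged before the fold is taken, mirroring
standard n = 3 assay design.

What the generator does **not** emulate: mappability and GC bias,
fragment-length autocorrelation of read coverage (bases are independent
Poisson draws, so real tracks are noisier at a given mean), overlapping
and nested transcription units beyond the optional crowded pairs,
antisense transcription, and condition-dependent expression changes other
than the planted effects.  Passing the recovery benchmarks therefore
demonstrates correctness of the arithmetic and robustness to counting
noise at realistic coverage — not performance on the full complexity of
real libraries.

## Benchmarks and problem sizes

`polterm.validation` re-runs each pipeline stage on freshly generated
data: brute-force oracle comparisons (~4000 random instances across
windowed densities, motif scans, input subtraction, isolation filtering
and poly-T detection), attenuation selection and readthrough separation on
the 200-gene fixture, retention recovery over ≥ 100 intron-bearing genes
at coverage 50, cleavage monotonicity over efficiencies 0.95→0.2, decay
recovery over 200 noisy replicates, and K_d recovery over 10 nM–1 µM.
These sizes give each benchmark comfortable statistical resolution while
the whole set completes in a few seconds.

## Known limitations

- Headline gene counts from the original depletion study (3190 isolated
  units, 465 attenuated, 961 occupancy targets) depend on a specific
  genome annotation and deposited libraries; the package reproduces the
  *procedures* and verifies them on planted truth instead.
- The isolation filter treats any same-strand overlap of the flanked
  interval as disqualifying (containment included); annotations with
  transcript isoforms should be reduced to one unit per gene first.
- Densities are computed from coverage, not read counts; results are
  identical up to a constant only when fragment lengths are uniform.
- The cleavage index at annotation-derived PAS positions (no atlas) is
  systematically offset by the half-window geometry; compare conditions,
  not absolute values.
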