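"""Planted-effect recovery and oracle-equivalence benchmarks.

Every function here re-runs a piece of the pipeline on freshly generated
synthetic data with known ground truth and returns quantitative recovery
metrics.  They serve two purposes: the acceptance checks of the package's
own test suite, and a quick self-diagnostic for users who want to confirm
the installation reproduces the expected detection performance.

The default problem sizes are the package's reference study conditions:
a 200-gene, two-chromosome (2 x 500 kb) genome with mean body coverage 20,
10% attenuated genes (planted 3-fold promoter-proximal index change), 30%
readthrough genes, Poisson counting noise and a 100:1 spike-in mixture.
"""

from __future__ import annotations

import numpy as np

from polterm.annotation import filter_isolated_coding, scan_motifs
from polterm.config import DEFAULT_PAS_MOTIFS, AnalysisConfig
from polterm.coverage import (
    StrandedCoverage,
    chip_input_subtract,
    window_density,
)
from polterm.indices import cleavage_index, readthrough_index
from polterm.kinetics import fit_binding, fit_exponential, fraction_bound
from polterm.model import TerminationAnalysis
from polterm.simulate import (
    make_genome_annotation,
    simulate_coverage,
    simulate_decay,
    simulate_titration,
)

CFG = AnalysisConfig()


# ---------------------------------------------------------------------------
# oracle equivalence
# ---------------------------------------------------------------------------

def oracle_equivalence(seed: int = 0,
                       n_windows: int = 1000,
                       n_motif_seqs: int = 1000,
                       n_subtract: int = 200,
                       n_annotations: int = 20,
                       n_polyt: int = 500) -> dict:
    """Fraction of random instances where the fast implementations agree
    with naive per-base / all-pairs re-computation."""
    rng = np.random.default_rng(seed)
    checked = agreed = 0

    # windowed densities vs per-base loop
    vals = rng.gamma(2.0, 1.0, 20_000)
    cov = StrandedCoverage({"chrI": vals.size})
    cov.set("chrI", "+", vals)
    for _ in range(n_windows):
        a = int(rng.integers(0, vals.size - 1))
        b = int(rng.integers(a + 1, min(a + 400, vals.size) + 1))
        loop = sum(float(vals[i]) for i in range(a, b)) / (b - a)
        got = window_density(cov, "chrI", a, b, "+")
        checked += 1
        agreed += abs(got - loop) <= 1e-9 * max(abs(loop), 1.0)

    # motif scan vs naive sliding window
    motifs = sorted(DEFAULT_PAS_MOTIFS)
    for _ in range(n_motif_seqs):
        seq = "".join(rng.choice(list("ACGTN"), size=200,
                                 p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        naive = sorted(
            (i, m)
            for i in range(len(seq) - 5)
            for m in motifs
            if seq[i:i + 6] == m
        )
        checked += 1
        agreed += scan_motifs(seq, motifs) == naive

    # input subtraction vs per-base max(., 0)
    for _ in range(n_subtract):
        n = int(rng.integers(10, 200))
        a = rng.gamma(1.5, 2.0, n)
        b = rng.gamma(1.5, 2.0, n)
        ca = StrandedCoverage({"c": n}); ca.set("c", "+", a)
        cb = StrandedCoverage({"c": n}); cb.set("c", "+", b)
        out = chip_input_subtract(ca, cb).get("c", "+")
        expected = np.array([max(x - y, 0.0) for x, y in zip(a, b)])
        checked += 1
        agreed += bool(np.allclose(out, expected) and np.all(out >= 0))

    # isolation filter vs all-pairs oracle
    from polterm.annotation import TranscriptionUnit

    for _ in range(n_annotations):
        n = int(rng.integers(5, 120))
        units = []
        for i in range(n):
            start = int(rng.integers(0, 80_000))
            units.append(TranscriptionUnit(
                id=f"u{i}",
                chrom=str(rng.choice(["chrI", "chrII"])),
                strand=str(rng.choice(["+", "-"])),
                start=start,
                end=start + int(rng.integers(200, 3000)),
                biotype=str(rng.choice(["coding", "noncoding"], p=[0.8, 0.2])),
            ))
        flank = int(rng.integers(0, 500))
        got = {u.id for u in filter_isolated_coding(units, flank)}
        expected = set()
        for u in units:
            if u.biotype != "coding":
                continue
            lo, hi = u.start - flank, u.end + flank
            if not any(
                v.id != u.id and v.chrom == u.chrom and v.strand == u.strand
                and v.start < hi and v.end > lo
                for v in units
            ):
                expected.add(u.id)
        checked += n
        agreed += n if got == expected else 0

    # poly-T run detection vs substring search
    from polterm.indices import _has_t_run

    for _ in range(n_polyt):
        seq = "".join(rng.choice(list("ACGT"), size=150,
                                 p=[0.2, 0.2, 0.2, 0.4]))
        min_run = int(rng.integers(2, 8))
        checked += 1
        agreed += _has_t_run(seq, min_run) == ("T" * min_run in seq)

    return {"agreement_rate": agreed / checked, "n": checked}


# ---------------------------------------------------------------------------
# planted-effect recovery
# ---------------------------------------------------------------------------

def attenuation_recovery(seed: int = 0, n_genes: int = 200) -> dict:
    """Sensitivity/specificity of attenuated-gene selection on the default
    Poisson fixture (mean body coverage 20, planted 3-fold change)."""
    _, units, truth = make_genome_annotation(n_genes=n_genes, seed=seed)
    control, _ = simulate_coverage(units, truth, "control",
                                   noise="poisson", seed=seed + 1)
    depleted, _ = simulate_coverage(units, truth, "depleted",
                                    noise="poisson", seed=seed + 2)
    res = TerminationAnalysis(
        {"control": control, "depleted": depleted}, units
    ).fit()
    selected = res.select_attenuated("depleted", "control")
    planted = {uid for uid, t in truth.units.items() if t.attenuated}
    universe = {u.id for u in units if u.length > CFG.min_len_attenuation}
    tp = len(selected & planted)
    fp = len(selected - planted)
    fn = len((planted & universe) - selected)
    tn = len(universe - planted - selected)
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "n": len(universe),
    }


def retention_recovery(seed: int = 0, n_genes: int = 150,
                       coverage: float = 50.0) -> dict:
    """Mean error of the intron-retention estimate against planted
    fractions over at least 100 intron-bearing genes."""
    from polterm.indices import intron_retention_index

    _, units, truth = make_genome_annotation(
        n_genes=n_genes, intron_fraction=1.0, expression_mean=coverage,
        seed=seed,
    )
    cov, _ = simulate_coverage(units, truth, "control", noise="poisson",
                               seed=seed + 1)
    errors = []
    for u in units:
        t = truth.units[u.id]
        if not u.introns:
            continue
        est_per_intron, _ = intron_retention_index(cov, u)
        for est, planted in zip(est_per_intron, t.retention):
            if np.isfinite(est):
                errors.append(est - planted)
    return {
        "mean_error": float(np.mean(errors)),
        "mean_abs_error": float(np.mean(np.abs(errors))),
        "n": len(errors),
    }


def readthrough_separation(seed: int = 0, n_genes: int = 200) -> dict:
    """Pairwise exceedance (AUC) of readthrough indices: planted-readthrough
    vs clean genes in the depleted sample."""
    _, units, truth = make_genome_annotation(n_genes=n_genes, seed=seed)
    depleted, _ = simulate_coverage(units, truth, "depleted",
                                    noise="poisson", seed=seed + 1)
    rt, clean = [], []
    for u in units:
        idx = readthrough_index(depleted, u, CFG)
        if not np.isfinite(idx):
            continue
        (rt if truth.units[u.id].readthrough else clean).append(idx)
    rt_a, cl_a = np.asarray(rt), np.asarray(clean)
    wins = (rt_a[:, None] > cl_a[None, :]).mean()
    return {"auc": float(wins), "n": len(rt) + len(clean)}


def cleavage_monotonicity(seed: int = 0, n_genes: int = 100,
                          efficiencies=(0.95, 0.8, 0.6, 0.4, 0.2)) -> dict:
    """Median cleavage index across a grid of simulated cleavage
    efficiencies; the index must fall as efficiency rises (more complete
    cleavage leaves fewer reads spanning the PAS)."""
    from polterm.model import _annotated_pas_site

    medians = []
    for eff in efficiencies:
        _, units, truth = make_genome_annotation(
            n_genes=n_genes, seed=seed,
            cleavage_efficiency_control=eff, readthrough_fraction=0.0,
        )
        cov, _ = simulate_coverage(units, truth, "control",
                                   noise="poisson", seed=seed + 1)
        idx = [
            cleavage_index(cov, _annotated_pas_site(u), CFG) for u in units
        ]
        medians.append(float(np.nanmedian(idx)))
    pairs = list(zip(medians, medians[1:]))
    # efficiencies are listed falling, so medians must rise along the list
    ordered = sum(b > a for a, b in pairs)
    return {
        "efficiencies": list(efficiencies),
        "median_indices": medians,
        "fraction_ordered": ordered / len(pairs),
        "n": n_genes * len(efficiencies),
    }


# ---------------------------------------------------------------------------
# kinetics recovery
# ---------------------------------------------------------------------------

DECAY_TIMES = np.arange(0, 1201, 15.0)


def decay_recovery(seed: int = 0, n_replicates: int = 200,
                   k_true: float = 0.00693, sigma: float = 0.02) -> dict:
    """Exponential-rate recovery: noiseless relative error, plus mean
    relative error and bias across seeded noisy replicates."""
    res0 = fit_exponential(simulate_decay(k_true, 0.05, DECAY_TIMES, 0.0))
    noiseless_err = abs(res0.k - k_true) / k_true
    ks = []
    base = seed * n_replicates
    for i in range(n_replicates):
        res = fit_exponential(
            simulate_decay(k_true, 0.05, DECAY_TIMES, sigma, seed=base + i)
        )
        if res.success:
            ks.append(res.k)
    ks = np.asarray(ks)
    return {
        "noiseless_rel_error": float(noiseless_err),
        "mean_rel_error": float(np.mean(np.abs(ks - k_true)) / k_true),
        "bias": float((ks.mean() - k_true) / k_true),
        "n": int(ks.size),
    }


def halflife_fold_recovery(seed: int = 0, fold: float = 3.0,
                           sigma: float = 0.02) -> dict:
    """Planted ``fold``-change in decay rate, triplicate traces per
    condition, half-lives averaged per condition before the ratio."""
    k_slow, k_fast = 0.003, 0.003 * fold
    slow = np.mean([
        fit_exponential(
            simulate_decay(k_slow, 0.05, DECAY_TIMES, sigma, seed=seed * 10 + i)
        ).half_life
        for i in range(3)
    ])
    fast = np.mean([
        fit_exponential(
            simulate_decay(k_fast, 0.05, DECAY_TIMES, sigma,
                           seed=seed * 10 + 5 + i)
        ).half_life
        for i in range(3)
    ])
    recovered = slow / fast
    return {
        "recovered_fold": float(recovered),
        "rel_error": float(abs(recovered - fold) / fold),
        "n": 6,
    }


def binding_recovery(seed: int = 0) -> dict:
    """Kd recovery on noiseless titrations and the hyperbolic limit."""
    errs = {}
    for kd in (10e-9, 100e-9, 1e-6):
        grid = np.geomspace(kd / 50, kd * 50, 12)
        res = fit_binding(simulate_titration(kd, 50e-9, grid))
        errs[kd] = abs(res.Kd - kd) / kd
    # probe << Kd: quadratic fit must agree with the hyperbola
    kd, probe = 1e-6, 1e-9
    grid = np.geomspace(kd / 30, kd * 30, 12)
    res = fit_binding(simulate_titration(kd, probe, grid,
                                         a_free=0.05, a_bound=0.25))
    hyper = 0.05 + 0.20 * grid / (grid + kd)
    dev = np.max(np.abs(res.predict(grid) - hyper) / hyper)
    return {
        "max_kd_rel_error": float(max(errs.values())),
        "kd_rel_errors": {f"{k:g}": float(v) for k, v in errs.items()},
        "hyperbolic_max_rel_dev": float(dev),
        "n": 4 * 12,
    }


# ---------------------------------------------------------------------------
# normalisation contracts
# ---------------------------------------------------------------------------

def normalization_contracts(seed: int = 0, n_trials: int = 50) -> dict:
    """Spike-factor rescaling invariance, input-subtraction nonnegativity
    and the depth-normalise-then-reverse identity, on random inputs."""
    from polterm.coverage import LibraryCounts, apply_normalization, spikein_factors

    rng = np.random.default_rng(seed)
    ok = total = 0
    for _ in range(n_trials):
        spikes = rng.integers(100, 100_000, size=4)
        counts = [LibraryCounts(f"s{i}", 10**6, int(s))
                  for i, s in enumerate(spikes)]
        f1 = spikein_factors(counts, "s0")
        scale = int(rng.integers(2, 1000))
        scaled = [LibraryCounts(c.sample_id, c.experimental_reads,
                                c.spikein_reads * scale) for c in counts]
        f2 = spikein_factors(scaled, "s0")
        total += 1
        ok += all(abs(f1[k] - f2[k]) <= 1e-12 * abs(f1[k]) for k in f1) \
            and f1["s0"] == 1.0
    for _ in range(n_trials):
        n = int(rng.integers(10, 500))
        a = rng.gamma(1.5, 2.0, n)
        b = rng.gamma(1.5, 2.0, n)
        ca = StrandedCoverage({"c": n}); ca.set("c", "+", a)
        cb = StrandedCoverage({"c": n}); cb.set("c", "+", b)
        out = chip_input_subtract(ca, cb).get("c", "+")
        total += 1
        ok += bool(np.all(out >= 0))
        depth = float(rng.uniform(0.1, 10.0))
        same = apply_normalization(ca, depth_factor=depth, spike_factor=1.0)
        total += 1
        ok += bool(np.array_equal(same.get("c", "+"), a))
    return {"pass_rate": ok / total, "n": total}
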