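import numpy as np
import pytest

from polterm.annotation import TranscriptionUnit
from polterm.coverage import StrandedCoverage
from polterm.simulate import make_genome_annotation, simulate_coverage

SMALL_CHROMS = {"chrI": 200_000, "chrII": 200_000}


def constant_coverage(chrom_lengths, value, strands=("+", "-")):
    cov = StrandedCoverage(chrom_lengths)
    for chrom, n in chrom_lengths.items():
        for strand in strands:
            cov.set(chrom, strand, np.full(n, float(value)))
    return cov


def unit(id="g1", chrom="chrI", strand="+", start=1000, end=3000,
         biotype="coding", exons=None):
    return TranscriptionUnit(id=id, chrom=chrom, strand=strand, start=start,
                             end=end, biotype=biotype,
                             exons=exons or ((start, end),))


@pytest.fixture(scope="session")
def small_experiment():
    """40-gene synthetic experiment with control/depleted Poisson coverage."""
    genome, units, truth = make_genome_annotation(
        n_genes=40, chrom_lengths=SMALL_CHROMS, seed=11
    )
    control, counts_c = simulate_coverage(
        units, truth, "control", SMALL_CHROMS, noise="poisson", seed=12
    )
    depleted, counts_d = simulate_coverage(
        units, truth, "depleted", SMALL_CHROMS, noise="poisson", seed=13
    )
    return {
        "genome": genome,
        "units": units,
        "truth": truth,
        "chrom_lengths": SMALL_CHROMS,
        "control": control,
        "depleted": depleted,
        "counts": {"control": counts_c, "depleted": counts_d},
    }


@pytest.fixture(scope="session")
def expectation_experiment():
    """Noise-free (expectation-mode) version for analytic predictions."""
    genome, units, truth = make_genome_annotation(
        n_genes=30, chrom_lengths=SMALL_CHROMS, seed=21
    )
    control, _ = simulate_coverage(
        units, truth, "control", SMALL_CHROMS, noise="none"
    )
    depleted, _ = simulate_coverage(
        units, truth, "depleted", SMALL_CHROMS, noise="none"
    )
    return {
        "genome": genome,
        "units": units,
        "truth": truth,
        "chrom_lengths": SMALL_CHROMS,
        "control": control,
        "depleted": depleted,
    }
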