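"""Per-gene index arithmetic, selection rules and sequence-bias profiling."""

import numpy as np
import pandas as pd
import pytest

from polterm.annotation import PasSite, TranscriptionUnit
from polterm.config import AnalysisConfig
from polterm.coverage import StrandedCoverage
from polterm.indices import (
    attenuation_index,
    base_composition_profile,
    chip_target_set,
    cleavage_index,
    intron_retention_index,
    polyt_run_enrichment,
    readthrough_index,
    select_attenuated,
)

from conftest import constant_coverage, unit

CFG = AnalysisConfig()
LENGTHS = {"chrI": 20_000}


def cov_from(values, strand="+", chrom="chrI"):
    cov = StrandedCoverage({chrom: len(values)})
    cov.set(chrom, strand, np.asarray(values, dtype=float))
    return cov


class TestAttenuationIndex:
    def test_uniform_coverage_gives_one(self):
        cov = constant_coverage(LENGTHS, 2.0)
        assert attenuation_index(cov, unit(start=1000, end=3000), CFG) == 1.0

    def test_direct_ratio(self):
        vals = np.zeros(20_000)
        vals[1000:1300] = 3.0   # 5' window
        vals[1300:3000] = 1.0   # remainder of the gene
        assert attenuation_index(cov_from(vals), unit(start=1000, end=3000),
                                 CFG) == pytest.approx(3.0)

    def test_minus_strand_windows_are_mirrored(self):
        vals = np.zeros(20_000)
        vals[2700:3000] = 3.0   # 5' window of a '-' gene is at the high end
        vals[1000:2700] = 1.0
        u = unit(strand="-", start=1000, end=3000)
        assert attenuation_index(cov_from(vals, strand="-"), u, CFG) \
            == pytest.approx(3.0)

    def test_gene_not_longer_than_window_is_undefined(self):
        cov = constant_coverage(LENGTHS, 1.0)
        assert np.isnan(attenuation_index(cov, unit(start=0, end=300), CFG))

    def test_zero_body_is_undefined_not_infinite(self):
        vals = np.zeros(20_000)
        vals[1000:1300] = 5.0
        idx = attenuation_index(cov_from(vals), unit(start=1000, end=3000), CFG)
        assert np.isnan(idx)


class TestSelectAttenuated:
    def table(self, rows):
        return pd.DataFrame(
            rows, columns=["unit_id", "sample", "attenuation_index", "length"]
        )

    def test_boundary_ratio_is_inclusive(self):
        t = self.table([
            ("g1", "treated", 3.0, 1000), ("g1", "control", 2.0, 1000),
            ("g2", "treated", 1.4, 1000), ("g2", "control", 1.0, 1000),
        ])
        assert select_attenuated(t, CFG, "treated", "control") == {"g1"}

    def test_short_genes_outside_selection_universe(self):
        t = self.table([
            ("g1", "treated", 9.0, 600), ("g1", "control", 1.0, 600),
        ])
        # length must strictly exceed 600 bp
        assert select_attenuated(t, CFG, "treated", "control") == set()

    def test_undefined_indices_never_selected(self):
        t = self.table([
            ("g1", "treated", np.nan, 1000), ("g1", "control", 1.0, 1000),
        ])
        assert select_attenuated(t, CFG, "treated", "control") == set()

    def test_identical_conditions_select_nothing(self, small_experiment):
        from polterm.model import TerminationAnalysis

        cov = small_experiment["control"]
        res = TerminationAnalysis(
            {"a": cov, "b": cov}, small_experiment["units"]
        ).fit()
        assert res.select_attenuated("a", "b") == set()


class TestReadthroughIndex:
    def test_uniform_coverage_through_pas_gives_one(self):
        cov = constant_coverage(LENGTHS, 3.0)
        assert readthrough_index(cov, unit(start=1000, end=3000), CFG) == 1.0

    def test_clean_termination_gives_zero(self):
        vals = np.zeros(20_000)
        vals[1000:3000] = 2.0
        assert readthrough_index(cov_from(vals), unit(start=1000, end=3000),
                                 CFG) == 0.0

    def test_direct_ratio(self):
        vals = np.zeros(20_000)
        vals[1000:3000] = 2.0
        vals[3000:3500] = 1.0
        assert readthrough_index(cov_from(vals), unit(start=1000, end=3000),
                                 CFG) == pytest.approx(0.5)

    def test_window_truncated_at_chromosome_end_with_warning(self):
        vals = np.full(3200, 2.0)
        u = unit(start=1000, end=3000)
        with pytest.warns(UserWarning, match="truncated"):
            idx = readthrough_index(cov_from(vals), u, CFG)
        assert idx == pytest.approx(1.0)


class TestCleavageIndex:
    def test_uniform_coverage_gives_one(self):
        cov = constant_coverage(LENGTHS, 2.0)
        pas = PasSite("chrI", "+", 3000, 1.0, "g1")
        assert cleavage_index(cov, pas, CFG) == 1.0

    def test_direct_ratio(self):
        vals = np.zeros(20_000)
        vals[2500:2900] = 2.0            # body window [PAS-500, PAS-100)
        vals[2995:3005] = 0.2            # 10 nt around the PAS
        pas = PasSite("chrI", "+", 3000, 1.0, "g1")
        assert cleavage_index(cov_from(vals), pas, CFG) == pytest.approx(0.1)

    def test_strand_mirror(self):
        rng = np.random.default_rng(5)
        vals = rng.gamma(2.0, 1.0, 20_000)
        pas_plus = PasSite("chrI", "+", 3000, 1.0, "g1")
        idx_plus = cleavage_index(cov_from(vals), pas_plus, CFG)
        n = 20_000
        mirrored = vals[::-1].copy()
        pas_minus = PasSite("chrI", "-", n - 1 - 3000, 1.0, "g1")
        idx_minus = cleavage_index(cov_from(mirrored, strand="-"), pas_minus, CFG)
        assert idx_minus == pytest.approx(idx_plus, rel=1e-12)


class TestIntronRetention:
    def three_exon_unit(self):
        return unit(start=1000, end=4000,
                    exons=((1000, 2000), (2500, 3000), (3500, 4000)))

    def test_uniform_coverage_gives_one_per_intron(self):
        cov = constant_coverage(LENGTHS, 5.0)
        per_intron, agg = intron_retention_index(cov, self.three_exon_unit())
        assert per_intron == [1.0, 1.0]
        assert agg == 1.0

    def test_fully_spliced_gives_zero(self):
        vals = np.zeros(20_000)
        for s, e in ((1000, 2000), (2500, 3000), (3500, 4000)):
            vals[s:e] = 2.0
        per_intron, agg = intron_retention_index(cov_from(vals),
                                                 self.three_exon_unit())
        assert per_intron == [0.0, 0.0] and agg == 0.0

    def test_hand_arithmetic(self):
        vals = np.zeros(20_000)
        vals[1000:2000] = 2.0   # upstream exon
        vals[2000:2500] = 1.0   # intron
        vals[2500:3000] = 4.0   # downstream exon
        u = unit(start=1000, end=3000, exons=((1000, 2000), (2500, 3000)))
        per_intron, agg = intron_retention_index(cov_from(vals), u)
        assert per_intron[0] == pytest.approx(1 / 3)
        assert agg == pytest.approx(1 / 3)

    def test_intronless_gene_skipped(self):
        cov = constant_coverage(LENGTHS, 1.0)
        per_intron, agg = intron_retention_index(cov, unit())
        assert per_intron == [] and np.isnan(agg)


class TestChipTargetSet:
    def table(self, means, lengths=None, biotype="coding"):
        n = len(means)
        return pd.DataFrame({
            "unit_id": [f"g{i}" for i in range(n)],
            "biotype": [biotype] * n,
            "length": lengths or [1000] * n,
            "chip_mean": means,
        })

    def test_equal_signal_selects_nothing(self):
        assert chip_target_set(self.table([3.0] * 10), CFG) == set()

    def test_single_outlier_selected(self):
        means = [1.0] * 99 + [10.0]
        sel = chip_target_set(self.table(means), CFG)
        assert sel == {"g99"}

    def test_short_gene_excluded_despite_signal(self):
        t = self.table([1.0, 1.0, 50.0], lengths=[1000, 1000, 400])
        assert chip_target_set(t, CFG) == set()

    def test_matches_brute_force_on_random_table(self):
        rng = np.random.default_rng(9)
        n = 200
        t = pd.DataFrame({
            "unit_id": [f"g{i}" for i in range(n)],
            "biotype": rng.choice(["coding", "noncoding"], n, p=[0.9, 0.1]),
            "length": rng.integers(100, 4000, n),
            "chip_mean": rng.gamma(2.0, 2.0, n),
        })
        uni = t[(t.biotype == "coding") & (t.length > 500)]
        mean = uni.chip_mean.mean()
        expected = set(uni[uni.chip_mean >= 2.0 * mean].unit_id)
        assert chip_target_set(t, CFG) == expected


class TestScalingAndMirrorInvariance:
    """Every ratio index is invariant to track scaling and strand mirroring."""

    @pytest.mark.parametrize("c", [0.01, 3.7, 1000.0])
    def test_indices_invariant_under_track_scaling(self, small_experiment, c):
        cov = small_experiment["depleted"]
        scaled = StrandedCoverage(cov.chrom_lengths)
        for chrom, strand in cov.keys():
            scaled.set(chrom, strand, cov.get(chrom, strand) * c)
        for u in small_experiment["units"][:10]:
            a1 = attenuation_index(cov, u, CFG)
            a2 = attenuation_index(scaled, u, CFG)
            r1 = readthrough_index(cov, u, CFG)
            r2 = readthrough_index(scaled, u, CFG)
            np.testing.assert_allclose(a2, a1, rtol=1e-12)
            np.testing.assert_allclose(r2, r1, rtol=1e-12)
            _, ir1 = intron_retention_index(cov, u)
            _, ir2 = intron_retention_index(scaled, u)
            np.testing.assert_allclose(ir2, ir1, rtol=1e-12)

    def test_indices_invariant_under_strand_mirror(self, small_experiment):
        cov = small_experiment["depleted"]
        n_by_chrom = cov.chrom_lengths
        mirrored = StrandedCoverage(n_by_chrom)
        for chrom, strand in cov.keys():
            flip = "-" if strand == "+" else "+"
            mirrored.set(chrom, flip, cov.get(chrom, strand)[::-1].copy())
        for u in small_experiment["units"][:10]:
            n = n_by_chrom[u.chrom]
            mu = TranscriptionUnit(
                id=u.id, chrom=u.chrom,
                strand="-" if u.strand == "+" else "+",
                start=n - u.end, end=n - u.start, biotype=u.biotype,
                exons=tuple(sorted((n - e, n - s) for s, e in u.exons)),
            )
            np.testing.assert_allclose(
                attenuation_index(mirrored, mu, CFG),
                attenuation_index(cov, u, CFG), rtol=1e-12,
            )
            np.testing.assert_allclose(
                readthrough_index(mirrored, mu, CFG),
                readthrough_index(cov, u, CFG), rtol=1e-12,
            )
            np.testing.assert_allclose(
                intron_retention_index(mirrored, mu)[1],
                intron_retention_index(cov, u)[1], rtol=1e-12,
            )


class TestSequenceBias:
    def test_all_t_genome_gives_frequency_one(self):
        genome = {"chrI": "T" * 5000}
        units = [unit(start=1000, end=2000), unit(id="g2", start=3000, end=4000)]
        prof = base_composition_profile(genome, units, "TSS", 50, 50)
        assert np.allclose(prof["T"].to_numpy(), 1.0)

    def test_planted_tract_shows_mixture_frequency(self):
        # half the genes carry a T at +20; background is all C
        rng = np.random.default_rng(4)
        seq = list("C" * 100_000)
        units = []
        for i in range(1000):
            start = 100 * i
            units.append(unit(id=f"g{i}", start=start, end=start + 90))
            if i % 2 == 0:
                seq[start + 20] = "T"
            else:
                seq[start + 20] = "A" if rng.random() < 0.5 else "G"
        genome = {"chrI": "".join(seq)}
        prof = base_composition_profile(genome, units, "TSS", 0, 40)
        assert prof.loc[20, "T"] == pytest.approx(0.5)
        assert prof.loc[19, "C"] == 1.0

    def test_random_genome_near_uniform(self):
        rng = np.random.default_rng(8)
        genome = {"chrI": "".join(rng.choice(list("ACGT"), 200_000))}
        units = [unit(id=f"g{i}", start=150 * i + 10, end=150 * i + 120)
                 for i in range(1000)]
        prof = base_composition_profile(genome, units, "TSS", 20, 20)
        # binomial: p=0.25, n=1000 -> 5 sigma ~ 0.068
        assert np.all(np.abs(prof.to_numpy() - 0.25) < 0.07)

    def test_rows_sum_to_one(self, small_experiment):
        prof = base_composition_profile(
            small_experiment["genome"], small_experiment["units"], "PAS", 50, 50
        )
        assert np.allclose(prof.sum(axis=1).to_numpy(), 1.0)

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            base_composition_profile({"chrI": "ACGT"}, [], "TSS", 5, 5)


class TestPolyTRuns:
    def test_clean_separation(self):
        genome = {"chrI": "C" * 2000 + "TTTTT" + "C" * 2000}
        a = [unit(id="a", start=1990, end=2100)]   # window contains the run
        b = [unit(id="b", start=100, end=300)]
        out = polyt_run_enrichment(genome, a, b, "TSS", 0, 50, min_run=5)
        assert out["fraction_a"] == 1.0 and out["fraction_b"] == 0.0

    def test_identical_sets_ratio_one(self):
        genome = {"chrI": "CTTTTTC" * 1000}
        a = [unit(id="a", start=100, end=300)]
        with pytest.warns(UserWarning, match="overlap"):
            out = polyt_run_enrichment(genome, a, a, "TSS", 0, 50, min_run=5)
        assert out["ratio"] == 1.0

    def test_fraction_matches_naive_run_scan(self):
        rng = np.random.default_rng(12)
        genome = {"chrI": "".join(rng.choice(list("ACGT"), 100_000,
                                             p=[0.2, 0.2, 0.2, 0.4]))}
        units = [unit(id=f"g{i}", start=200 * i + 50, end=200 * i + 160)
                 for i in range(400)]
        min_run = 4
        out = polyt_run_enrichment(genome, units, units[:1], "TSS", 10, 60,
                                   min_run=min_run)
        seq = genome["chrI"]
        hits = 0
        for u in units:
            w = seq[u.start - 10:u.start + 60]
            if "T" * min_run in w:
                hits += 1
        assert out["fraction_a"] == pytest.approx(hits / len(units))

    def test_min_run_validated(self):
        with pytest.raises(ValueError):
            polyt_run_enrichment({"chrI": "ACGT"}, [], [], min_run=1)
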