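"""Transcription-unit parsing, isolation filtering and PAS selection."""

import numpy as np
import pytest

from polterm.annotation import (
    AnnotationError,
    PasSite,
    TranscriptionUnit,
    filter_isolated_coding,
    load_annotation,
    read_pas_bed,
    reverse_complement,
    scan_motifs,
    select_pas_site,
    write_gff3,
    write_pas_bed,
)
from polterm.config import DEFAULT_PAS_MOTIFS, AnalysisConfig
from polterm.simulate import make_genome_annotation

from conftest import unit


class TestTranscriptionUnit:
    def test_tss_pas_orientation(self):
        plus = unit(strand="+", start=100, end=500)
        minus = unit(strand="-", start=100, end=500)
        assert (plus.tss, plus.pas) == (100, 500)
        assert (minus.tss, minus.pas) == (500, 100)
        assert plus.length == minus.length == 400

    def test_introns_between_exons(self):
        u = unit(start=0, end=300, exons=((0, 100), (150, 200), (250, 300)))
        assert u.introns == ((100, 150), (200, 250))

    def test_exon_outside_bounds_rejected(self):
        with pytest.raises(AnnotationError):
            unit(start=100, end=200, exons=((50, 150),))

    def test_overlapping_exons_rejected(self):
        with pytest.raises(AnnotationError):
            unit(start=0, end=300, exons=((0, 120), (100, 200)))


class TestLoadAnnotation:
    def test_gff3_coordinate_convention(self, tmp_path):
        # 1-based inclusive 1..100 becomes 0-based half-open [0, 100)
        p = tmp_path / "one.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chrI\tx\tgene\t1\t100\t.\t+\t.\tID=g1;biotype=protein_coding\n"
        )
        (u,) = load_annotation(str(p))
        assert (u.start, u.end, u.strand, u.biotype) == (0, 100, "+", "coding")
        assert u.exons == ((0, 100),)

    def test_bed12_blocks_to_exons(self, tmp_path):
        p = tmp_path / "two.bed"
        p.write_text(
            "chrI\t100\t500\tg1\t0\t+\t100\t500\t0\t2\t100,100\t0,300\n"
        )
        (u,) = load_annotation(str(p))
        assert u.exons == ((100, 200), (400, 500))
        assert u.introns == ((200, 400),)
        assert u.biotype == "coding"

    def test_synthetic_annotation_round_trips(self, tmp_path):
        _, units, _ = make_genome_annotation(
            n_genes=50, chrom_lengths={"chrI": 300_000, "chrII": 300_000},
            seed=5,
        )
        path = tmp_path / "ann.gff3"
        write_gff3(units, str(path))
        back = load_annotation(str(path))
        assert back == units

    def test_malformed_gff_raises(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("chrI\tgene\tnot-enough-fields\n")
        with pytest.raises(AnnotationError):
            load_annotation(str(p))


class TestIsolationFilter:
    def make_pair(self, gap, strand_b="+"):
        a = unit(id="a", start=1000, end=2000)
        b = unit(id="b", strand=strand_b, start=2000 + gap, end=3000 + gap)
        return [a, b]

    def test_gap_above_flank_keeps_both(self):
        kept = filter_isolated_coding(self.make_pair(300), flank=250)
        assert {u.id for u in kept} == {"a", "b"}

    def test_gap_below_flank_removes_both(self):
        kept = filter_isolated_coding(self.make_pair(200), flank=250)
        assert kept == []

    def test_opposite_strand_neighbour_never_disqualifies(self):
        # adjacent genes on opposite strands: both remain isolated
        kept = filter_isolated_coding(self.make_pair(0, strand_b="-"), flank=250)
        assert {u.id for u in kept} == {"a", "b"}

    def test_noncoding_units_disqualify_but_are_not_returned(self):
        a = unit(id="a", start=1000, end=2000)
        nc = unit(id="nc", start=2100, end=2400, biotype="noncoding")
        kept = filter_isolated_coding([a, nc], flank=250)
        assert kept == []

    def test_matches_all_pairs_oracle_on_random_annotations(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            n = int(rng.integers(2, 60))
            units = []
            for i in range(n):
                start = int(rng.integers(0, 50_000))
                units.append(
                    unit(
                        id=f"u{trial}_{i}",
                        chrom=rng.choice(["chrI", "chrII"]),
                        strand=rng.choice(["+", "-"]),
                        start=start,
                        end=start + int(rng.integers(200, 3000)),
                        biotype=rng.choice(["coding", "noncoding"], p=[0.8, 0.2]),
                    )
                )
            flank = int(rng.integers(0, 500))
            got = {u.id for u in filter_isolated_coding(units, flank)}
            expected = set()
            for u in units:
                if u.biotype != "coding":
                    continue
                lo, hi = u.start - flank, u.end + flank
                clash = any(
                    v.id != u.id
                    and v.chrom == u.chrom
                    and v.strand == u.strand
                    and v.start < hi
                    and v.end > lo
                    for v in units
                )
                if not clash:
                    expected.add(u.id)
            assert got == expected


class TestMotifScan:
    def test_exact_identity(self):
        assert scan_motifs("AATAAA", {"AATAAA"}) == [(0, "AATAAA")]

    def test_overlapping_occurrences_reported(self):
        assert scan_motifs("AATAATAAT", {"AATAAT"}) == [(0, "AATAAT"), (3, "AATAAT")]

    def test_n_never_matches(self):
        assert scan_motifs("AATANA", {"AATAAA"}) == []

    def test_empty_motif_set_rejected(self):
        with pytest.raises(ValueError):
            scan_motifs("ACGT", set())

    def test_agrees_with_naive_scan_on_random_sequences(self):
        rng = np.random.default_rng(3)
        motifs = sorted(DEFAULT_PAS_MOTIFS)
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGTN"), size=200,
                                     p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            naive = sorted(
                (i, m)
                for i in range(len(seq) - 5)
                for m in motifs
                if seq[i:i + 6] == m
            )
            assert scan_motifs(seq, motifs) == naive

    def test_default_motif_set_has_six_members(self):
        assert len(DEFAULT_PAS_MOTIFS) == 6
        assert all(len(m) == 6 for m in DEFAULT_PAS_MOTIFS)


def _genome_with(seq_at, length=2000, fill="C"):
    seq = list(fill * length)
    for pos, s in seq_at.items():
        seq[pos:pos + len(s)] = list(s)
    return {"chrI": "".join(seq)}


class TestSelectPasSite:
    cfg = AnalysisConfig()

    def test_motif_in_upstream_window_retained(self):
        # site at 1000; AATAAA at 980 (20 bp upstream)
        genome = _genome_with({980: "AATAAA"})
        u = unit(start=200, end=1000)
        site = PasSite("chrI", "+", 1000, 10.0, "g1")
        assert select_pas_site([site], u, genome, self.cfg) == site

    def test_no_motif_in_window_rejected(self):
        genome = _genome_with({})  # poly-C: no motif anywhere
        u = unit(start=200, end=1000)
        site = PasSite("chrI", "+", 1000, 10.0, "g1")
        assert select_pas_site([site], u, genome, self.cfg) is None

    def test_upstream_window_excludes_site_base(self):
        # motif would need to start at the site base itself
        genome = _genome_with({1000: "AATAAA"})
        u = unit(start=200, end=1000)
        site = PasSite("chrI", "+", 1000, 10.0, "g1")
        assert select_pas_site([site], u, genome, self.cfg) is None

    def test_prominence_then_distance_tie_break(self):
        genome = _genome_with({980: "AATAAA", 1030: "AATAAA"})
        u = unit(start=200, end=1000)
        near = PasSite("chrI", "+", 1005, 10.0, "g1")   # 5 bp from end
        far = PasSite("chrI", "+", 1050, 10.0, "g1")    # 50 bp from end
        assert select_pas_site([far, near], u, genome, self.cfg) == near
        stronger_far = PasSite("chrI", "+", 1050, 20.0, "g1")
        assert select_pas_site([stronger_far, near], u, genome, self.cfg) \
            == stronger_far

    def test_minus_strand_upstream_is_higher_coordinates(self):
        # '-' site at 1000: upstream 50 bp are genomic [1001, 1051);
        # plant reverse-complement of AATAAA (TTTATT) there
        genome = _genome_with({1020: reverse_complement("AATAAA")})
        u = unit(strand="-", start=1000, end=1800)
        site = PasSite("chrI", "-", 1000, 5.0, "g1")
        assert select_pas_site([site], u, genome, self.cfg) == site

    def test_out_of_bounds_site_raises(self):
        genome = _genome_with({})
        u = unit(start=200, end=1000)
        site = PasSite("chrI", "+", 5000, 1.0, "g1")
        with pytest.raises(ValueError):
            select_pas_site([site], u, genome, self.cfg)


class TestPasBedRoundTrip:
    def test_bed6_round_trip(self, tmp_path):
        sites = [
            PasSite("chrI", "+", 123, 7.0, "g1"),
            PasSite("chrII", "-", 456, 2.5, "g2"),
        ]
        p = tmp_path / "pas.bed"
        write_pas_bed(sites, str(p))
        assert read_pas_bed(str(p)) == sites


class TestMirrorInvariance:
    """Reverse-complementing the genome and flipping coordinates/strands
    must leave the isolated-gene set and the selected PAS sites (after
    back-mapping) unchanged."""

    @staticmethod
    def _flip_unit(u, n):
        return TranscriptionUnit(
            id=u.id, chrom=u.chrom,
            strand="-" if u.strand == "+" else "+",
            start=n - u.end, end=n - u.start, biotype=u.biotype,
            exons=tuple(sorted((n - e, n - s) for s, e in u.exons)),
        )

    def test_isolated_set_mirror_invariant(self):
        _, units, _ = make_genome_annotation(
            n_genes=40, chrom_lengths={"chrI": 300_000, "chrII": 300_000},
            seed=7, n_crowded_pairs=3,
        )
        lengths = {"chrI": 300_000, "chrII": 300_000}
        flipped = [self._flip_unit(u, lengths[u.chrom]) for u in units]
        a = {u.id for u in filter_isolated_coding(units, 250)}
        b = {u.id for u in filter_isolated_coding(flipped, 250)}
        assert a == b

    def test_pas_selection_mirror_invariant(self):
        genome = _genome_with({980: "AATAAA", 1030: "AATAAA"}, length=2000)
        u = unit(start=200, end=1000)
        sites = [
            PasSite("chrI", "+", 1005, 10.0, "g1"),
            PasSite("chrI", "+", 1050, 10.0, "g1"),
            PasSite("chrI", "+", 990, 3.0, "g1"),
        ]
        cfg = AnalysisConfig()
        picked = select_pas_site(sites, u, genome, cfg)

        n = 2000
        genome_rc = {"chrI": reverse_complement(genome["chrI"])}
        u_rc = self._flip_unit(u, n)
        sites_rc = [
            PasSite("chrI", "-", n - 1 - s.position, s.prominence, s.unit_id)
            for s in sites
        ]
        picked_rc = select_pas_site(sites_rc, u_rc, genome_rc, cfg)
        assert picked_rc is not None and picked is not None
        assert n - 1 - picked_rc.position == picked.position
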