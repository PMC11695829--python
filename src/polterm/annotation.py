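"""Transcription units, PAS sites, and the gene-set / PAS-site filters.

Coordinates are 0-based half-open throughout.  On the plus strand the TSS is
``start`` and the PAS is ``end``; on the minus strand the TSS is ``end`` and
the PAS is ``start`` (both are interval boundaries, so the first transcribed
base of a minus-strand unit is ``end - 1``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Extract ``[start, end)`` from a genome (pyfaidx Fasta or dict of str).

    Raises ``ValueError`` for out-of-bounds coordinates.
    """
    if hasattr(genome, "keys") and not isinstance(genome, dict):
        # pyfaidx.Fasta: sequences support slicing, str() yields the bases
        record = genome[chrom]
        n = len(record)
    else:
        record = genome[chrom]
        n = len(record)
    if start < 0 or end > n or start > end:
        raise ValueError(
            f"coordinates [{start}, {end}) outside {chrom} (length {n})"
        )
    return str(record[start:end]).upper()


def chromosome_length(genome, chrom: str) -> int:
    return len(genome[chrom])


class AnnotationError(ValueError):
    """Malformed annotation record."""


@dataclass(frozen=True)
class TranscriptionUnit:
    """A stranded transcription unit with optional exon structure."""

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str = "coding"
    exons: tuple = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.id}: strand must be '+' or '-'")
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"{self.id}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.biotype not in ("coding", "noncoding"):
            raise AnnotationError(f"{self.id}: unknown biotype {self.biotype!r}")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if s < self.start or e > self.end or s >= e:
                raise AnnotationError(
                    f"{self.id}: exon [{s}, {e}) outside unit bounds "
                    f"[{self.start}, {self.end})"
                )
            if prev_end is not None and s < prev_end:
                raise AnnotationError(f"{self.id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """TSS boundary coordinate (start on +, end on -)."""
        return self.start if self.strand == "+" else self.end

    @property
    def pas(self) -> int:
        """PAS boundary coordinate (end on +, start on -)."""
        return self.end if self.strand == "+" else self.start

    @property
    def introns(self) -> tuple:
        """Genomic intervals between consecutive exons."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return tuple(out)

    def oriented_window(self, anchor: int, up: int, down: int) -> tuple:
        """Genomic interval covering oriented offsets ``[-up, down)`` around
        a boundary coordinate, where offsets increase in the direction of
        transcription."""
        if self.strand == "+":
            return (anchor - up, anchor + down)
        return (anchor - down, anchor + up)


@dataclass(frozen=True)
class PasSite:
    """A candidate polyadenylation/cleavage site from an experimental atlas.

    ``prominence`` is the read support of the site in its source atlas; it is
    an input column, never recomputed here.
    """

    chrom: str
    strand: str
    position: int
    prominence: float
    unit_id: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise AnnotationError("PasSite strand must be '+' or '-'")
        if self.prominence < 0:
            raise AnnotationError("PasSite prominence must be >= 0")
        if self.position < 0:
            raise AnnotationError("PasSite position must be >= 0")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_GFF_BIOTYPE_CODING = {"protein_coding", "coding", "mRNA", "protein coding gene"}
_GFF_GENE_TYPES = ("gene", "ncRNA_gene")


def _load_gff3(path: str) -> list:
    """Parse gene + exon features from a GFF3 file via gffutils.

    GFF3 is 1-based inclusive; converted to 0-based half-open here.
    """
    import gffutils

    # gffutils silently tolerates some malformed rows; validate field counts
    # up front so errors name the offending line.
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or line.startswith(">") or not line.strip():
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 9 tab-separated fields"
                )
    try:
        db = gffutils.create_db(
            path,
            dbfn=":memory:",
            keep_order=True,
            merge_strategy="error",
        )
    except Exception as exc:  # sqlite/gffutils raise various parse errors
        raise AnnotationError(f"{path}: failed to parse GFF3: {exc}") from exc
    units = []
    for ftype in _GFF_GENE_TYPES:
        for gene in db.features_of_type(ftype):
            biotype_raw = (
                gene.attributes.get("biotype", gene.attributes.get("gene_biotype", [""]))
            )[0]
            if ftype == "ncRNA_gene" or (
                biotype_raw and biotype_raw not in _GFF_BIOTYPE_CODING
            ):
                biotype = "noncoding"
            else:
                biotype = "coding"
            start, end = gene.start - 1, gene.end  # to 0-based half-open
            exons = sorted(
                (ex.start - 1, ex.end)
                for ex in db.children(gene, featuretype="exon")
            )
            if not exons:
                exons = [(start, end)]
            units.append(
                TranscriptionUnit(
                    id=gene.id,
                    chrom=gene.seqid,
                    strand=gene.strand,
                    start=start,
                    end=end,
                    biotype=biotype,
                    exons=tuple(exons),
                )
            )
    # restore file order (gffutils returns per-featuretype)
    order = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) == 9 and fields[2] in _GFF_GENE_TYPES:
                for token in fields[8].strip().split(";"):
                    if token.startswith("ID="):
                        order.setdefault(token[3:].strip(), len(order))
    units.sort(key=lambda u: order.get(u.id, len(order)))
    return units


_BED12_COLS = [
    "chrom", "start", "end", "name", "score", "strand",
    "thick_start", "thick_end", "rgb", "block_count", "block_sizes",
    "block_starts",
]


def _load_bed12(path: str) -> list:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 12:
        raise AnnotationError(
            f"{path}: BED12 requires 12 columns, found {df.shape[1]}"
        )
    df = df.iloc[:, :12]
    df.columns = _BED12_COLS
    units = []
    for i, row in df.iterrows():
        try:
            start, end = int(row.start), int(row.end)
            nblocks = int(row.block_count)
            sizes = [int(x) for x in str(row.block_sizes).rstrip(",").split(",")]
            offsets = [int(x) for x in str(row.block_starts).rstrip(",").split(",")]
            thick_start, thick_end = int(row.thick_start), int(row.thick_end)
        except ValueError as exc:
            raise AnnotationError(f"{path}: line {i + 1}: malformed record") from exc
        if len(sizes) != nblocks or len(offsets) != nblocks:
            raise AnnotationError(
                f"{path}: line {i + 1}: blockCount disagrees with block lists"
            )
        exons = tuple(
            (start + off, start + off + size) for off, size in zip(offsets, sizes)
        )
        biotype = "coding" if thick_end > thick_start else "noncoding"
        units.append(
            TranscriptionUnit(
                id=str(row["name"]),
                chrom=str(row.chrom),
                strand=str(row.strand),
                start=start,
                end=end,
                biotype=biotype,
                exons=exons,
            )
        )
    return units


def load_annotation(path: str, fmt: str | None = None) -> list:
    """Load transcription units from GFF3 or BED12.

    Parameters
    ----------
    path : str
        Annotation file path.
    fmt : {"gff3", "bed12"}, optional
        Inferred from the file extension when omitted.
    """
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = {"gff3": "gff3", "gff": "gff3", "bed": "bed12", "bed12": "bed12"}.get(
            ext.lstrip(".")
        )
        if fmt is None:
            raise ValueError(f"cannot infer annotation format from {path!r}")
    if fmt == "gff3":
        return _load_gff3(path)
    if fmt == "bed12":
        return _load_bed12(path)
    raise ValueError(f"unknown annotation format {fmt!r}")


def write_gff3(units, path: str) -> None:
    """Write units (and their exons) as GFF3, converting back to 1-based."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for u in units:
            biotype = "protein_coding" if u.biotype == "coding" else "ncRNA"
            fh.write(
                f"{u.chrom}\tpolterm\tgene\t{u.start + 1}\t{u.end}\t.\t"
                f"{u.strand}\t.\tID={u.id};biotype={biotype}\n"
            )
            for j, (s, e) in enumerate(u.exons, 1):
                fh.write(
                    f"{u.chrom}\tpolterm\texon\t{s + 1}\t{e}\t.\t{u.strand}\t.\t"
                    f"ID={u.id}.exon{j};Parent={u.id}\n"
                )


def read_pas_bed(path: str) -> list:
    """Read PAS candidate sites from BED6 (score column = prominence).

    The site position is the BED start coordinate; the ``name`` column is the
    identifier of the transcription unit the site is a candidate for.
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 6:
        raise AnnotationError(f"{path}: BED6 requires 6 columns")
    sites = []
    for _, row in df.iterrows():
        sites.append(
            PasSite(
                chrom=str(row[0]),
                strand=str(row[5]),
                position=int(row[1]),
                prominence=float(row[4]),
                unit_id=str(row[3]),
            )
        )
    return sites


def write_pas_bed(sites, path: str) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.position}\t{s.position + 1}\t{s.unit_id}\t"
                f"{s.prominence:g}\t{s.strand}\n"
            )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_isolated_coding(units, flank: int = 250):
    """Coding units with no same-strand neighbour within ``flank`` bp of the
    TSS (upstream) or the PAS (downstream).

    Isolation is evaluated in transcription orientation; because the flank is
    applied on both the TSS and PAS sides, the tested genomic interval is
    ``[start - flank, end + flank)`` on either strand.  Any same-strand unit
    (coding or not) overlapping that interval disqualifies; opposite-strand
    neighbours never do.  Containment counts as overlap.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    trees: dict[tuple, IntervalTree] = {}
    for u in units:
        trees.setdefault((u.chrom, u.strand), IntervalTree()).addi(u.start, u.end, u.id)
    kept = []
    for u in units:
        if u.biotype != "coding":
            continue
        tree = trees[(u.chrom, u.strand)]
        lo, hi = u.start - flank, u.end + flank
        hits = {iv.data for iv in tree.overlap(lo, hi)}
        hits.discard(u.id)
        if not hits:
            kept.append(u)
    return kept


def scan_motifs(sequence: str, motifs) -> list:
    """All exact occurrences of any motif in ``sequence`` (overlaps included).

    Returns a sorted list of ``(offset, motif)``.  ``N`` never matches.
    """
    if not motifs:
        raise ValueError("motif set must be non-empty")
    sequence = sequence.upper()
    hits = []
    for motif in motifs:
        m = motif.upper()
        pos = sequence.find(m)
        while pos != -1:
            hits.append((pos, m))
            pos = sequence.find(m, pos + 1)
    hits.sort()
    return hits


def _upstream_window(site: PasSite, width: int, genome) -> str:
    """Strand-oriented upstream sequence of a PAS site, excluding the site
    base itself, clipped at the chromosome boundary."""
    n = chromosome_length(genome, site.chrom)
    if not (0 <= site.position < n):
        raise ValueError(
            f"PAS position {site.position} outside {site.chrom} (length {n})"
        )
    if site.strand == "+":
        lo, hi = max(0, site.position - width), site.position
        return fetch_sequence(genome, site.chrom, lo, hi)
    lo, hi = site.position + 1, min(n, site.position + 1 + width)
    return reverse_complement(fetch_sequence(genome, site.chrom, lo, hi))


def select_pas_site(candidates, unit: TranscriptionUnit, genome, cfg) -> PasSite | None:
    """Pick the PAS for ``unit`` from candidate atlas sites.

    A candidate passes if any configured hexamer occurs in its
    ``cfg.motif_upstream`` bp upstream window (strand-oriented, excluding the
    site base).  Among passing candidates the most prominent wins; exact
    prominence ties go to the site closest to the annotated unit end, then to
    the smaller genomic coordinate.  Returns ``None`` if nothing passes.
    """
    passing = []
    for c in candidates:
        if c.chrom != unit.chrom or c.strand != unit.strand:
            continue
        window = _upstream_window(c, cfg.motif_upstream, genome)
        if window and scan_motifs(window, cfg.pas_motifs):
            passing.append(c)
    if not passing:
        return None
    # PAS boundary: on + the annotated end is `end`; a site at base `end-1`
    # is 1 away from the boundary in either convention, so plain distance to
    # the boundary coordinate orders ties consistently on both strands.
    ref = unit.end if unit.strand == "+" else unit.start
    passing.sort(key=lambda c: (-c.prominence, abs(c.position - ref), c.position))
    return passing[0]
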