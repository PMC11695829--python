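"""Analysis configuration: every window, threshold and motif used downstream.

Defaults follow the published fission-yeast termination analysis this package
implements: 250 bp isolation flanks around transcription units, a 300 bp
promoter-proximal window for the attenuation index on genes longer than
600 bp with a 1.5-fold selection threshold, a +/-5 nt cleavage window around
the PAS normalised to a 400 bp gene-body window offset 100 bp from the PAS,
a 50 bp upstream window for PAS-motif scanning, and a 2-fold-above-average
enrichment rule on protein-coding genes longer than 500 nt for occupancy
target selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

#: Hexamer polyadenylation-signal motifs scanned upstream of candidate PAS
#: sites.  The published list contains duplicate tokens; stored deduplicated.
DEFAULT_PAS_MOTIFS: frozenset[str] = frozenset(
    {"AATAAA", "AATGAA", "AATAAT", "TAATAA", "AAATAA", "ATAATA"}
)


@dataclass
class AnalysisConfig:
    """All numeric thresholds and windows of the termination analysis.

    Attributes
    ----------
    flank_isolation : int
        bp before the TSS and after the PAS that must be free of same-strand
        neighbours for a gene to count as "isolated" (default 250).
    tss_window : int
        Promoter-proximal window downstream of the TSS used as the
        attenuation-index numerator (default 300 bp).
    attenuation_fold : float
        Minimum treated/control fold change of the attenuation index for a
        gene to be called attenuated (default 1.5, boundary inclusive).
    min_len_attenuation : int
        Only genes strictly longer than this take part in attenuation
        selection (default 600 bp).
    pas_half_window : int
        Half-width of the cleavage-index window around the PAS (default 5 nt,
        i.e. a 10 nt window).
    body_window : int
        Length of the gene-body window used as the cleavage-index denominator
        (default 400 bp).
    body_offset : int
        Gap between the PAS and the start of the cleavage body window
        (default 100 bp); the body window sits upstream, inside the gene.
    motif_upstream : int
        Length of the strand-oriented upstream window scanned for PAS motifs
        (default 50 bp; excludes the PAS base itself).
    pas_motifs : frozenset of str
        Hexamer motif set for PAS filtering.
    chip_min_len : int
        Minimum protein-coding gene length for occupancy target selection
        (default 500 nt).
    chip_enrichment : float
        Occupancy must reach this multiple of the universe mean to be a
        target (default 2.0).
    metagene_trim : int
        bp trimmed after the TSS / before the PAS when scaling gene bodies
        and when defining the readthrough-index body (default 250).
    readthrough_window : int
        Window downstream of the PAS for the readthrough index (default 500).
    normalization_mode : str
        "spike" applies spike-in factors; "depth_only" normalises to
        sequencing depth alone (used when a treatment perturbs the spike-in).
    log2_pseudocount : float
        Pseudocount added to both matrices in log2-ratio heatmaps.
    n_boot : int
        Bootstrap resamples for metagene confidence bands.
    """

    flank_isolation: int = 250
    tss_window: int = 300
    attenuation_fold: float = 1.5
    min_len_attenuation: int = 600
    pas_half_window: int = 5
    body_window: int = 400
    body_offset: int = 100
    motif_upstream: int = 50
    pas_motifs: frozenset = field(default_factory=lambda: DEFAULT_PAS_MOTIFS)
    chip_min_len: int = 500
    chip_enrichment: float = 2.0
    metagene_trim: int = 250
    readthrough_window: int = 500
    normalization_mode: str = "spike"
    log2_pseudocount: float = 0.01
    n_boot: int = 1000

    def __post_init__(self) -> None:
        for name in (
            "flank_isolation",
            "tss_window",
            "min_len_attenuation",
            "pas_half_window",
            "body_window",
            "body_offset",
            "motif_upstream",
            "chip_min_len",
            "metagene_trim",
            "readthrough_window",
        ):
            if getattr(self, name) <= 0 and name != "flank_isolation":
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.flank_isolation < 0:
            raise ValueError("flank_isolation must be >= 0")
        if self.attenuation_fold <= 0 or self.chip_enrichment <= 0:
            raise ValueError("fold thresholds must be > 0")
        if not self.pas_motifs:
            raise ValueError("pas_motifs must be non-empty")
        for m in self.pas_motifs:
            if len(m) != 6 or set(m) - set("ACGT"):
                raise ValueError(f"PAS motif must be a 6-mer over ACGT: {m!r}")
        if self.normalization_mode not in ("spike", "depth_only"):
            raise ValueError(
                "normalization_mode must be 'spike' or 'depth_only', "
                f"got {self.normalization_mode!r}"
            )
        if self.log2_pseudocount <= 0:
            raise ValueError("log2_pseudocount must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pas_motifs"] = sorted(self.pas_motifs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "pas_motifs" in d:
            d["pas_motifs"] = frozenset(d["pas_motifs"])
        return cls(**d)
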