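"""Model/Results interface over the termination analysis.

``TerminationAnalysis`` bundles coverage tracks, the annotation and the
analysis configuration; ``fit()`` computes every per-gene index and returns
a ``TerminationResults`` carrying the gene metric table, the selection
operations and metagene builders.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from polterm.annotation import PasSite, select_pas_site
from polterm.config import AnalysisConfig
from polterm.coverage import StrandedCoverage, window_density
from polterm import indices as _ix
from polterm import metagene as _mg


def _annotated_pas_site(unit) -> PasSite:
    """Fallback PAS at the unit's terminal transcribed base."""
    pos = unit.end - 1 if unit.strand == "+" else unit.start
    return PasSite(chrom=unit.chrom, strand=unit.strand, position=pos,
                   prominence=0.0, unit_id=unit.id)


class TerminationAnalysis:
    """Per-gene termination analysis of one or more coverage samples.

    Parameters
    ----------
    coverage : dict of sample_id -> StrandedCoverage
        Normalised nascent-RNA (or occupancy) signal per sample.
    units : list of TranscriptionUnit
        The transcription-unit universe (typically pre-filtered to isolated
        coding units).
    config : AnalysisConfig, optional
    pas_candidates : list of PasSite, optional
        Experimental PAS atlas; when given together with ``genome`` the PAS
        used for the cleavage index is selected per gene by prominence and
        motif content, otherwise the annotated gene end is used.
    genome : dict or pyfaidx.Fasta, optional
    chip : dict of sample_id -> StrandedCoverage, optional
        Occupancy tracks for target-set selection (gene-body mean signal).
    """

    def __init__(self, coverage: dict, units, config: AnalysisConfig | None = None,
                 pas_candidates=None, genome=None, chip: dict | None = None):
        self.coverage = dict(coverage)
        self.units = list(units)
        self.config = config or AnalysisConfig()
        self.pas_candidates = list(pas_candidates) if pas_candidates else None
        self.genome = genome
        self.chip = dict(chip) if chip else {}

    def _pas_for(self, unit) -> PasSite | None:
        if self.pas_candidates is not None and self.genome is not None:
            cands = [c for c in self.pas_candidates if c.unit_id == unit.id]
            return select_pas_site(cands, unit, self.genome, self.config)
        return _annotated_pas_site(unit)

    def fit(self) -> "TerminationResults":
        cfg = self.config
        rows = []
        pas_by_unit = {}
        for u in self.units:
            pas = self._pas_for(u)
            pas_by_unit[u.id] = pas
            for sample, cov in self.coverage.items():
                per_intron, ir = _ix.intron_retention_index(cov, u)
                rows.append({
                    "unit_id": u.id,
                    "sample": sample,
                    "length": u.length,
                    "biotype": u.biotype,
                    "strand": u.strand,
                    "attenuation_index": _ix.attenuation_index(cov, u, cfg),
                    "readthrough_index": _ix.readthrough_index(cov, u, cfg),
                    "cleavage_index": (
                        _ix.cleavage_index(cov, pas, cfg) if pas else np.nan
                    ),
                    "intron_retention": ir,
                    "n_introns": len(per_intron),
                })
        metrics = pd.DataFrame(rows)
        chip_rows = []
        for sample, cov in self.chip.items():
            for u in self.units:
                chip_rows.append({
                    "unit_id": u.id,
                    "sample": sample,
                    "length": u.length,
                    "biotype": u.biotype,
                    "chip_mean": window_density(
                        cov, u.chrom, u.start, u.end, u.strand
                    ),
                })
        chip_table = pd.DataFrame(chip_rows)
        return TerminationResults(self, metrics, chip_table, pas_by_unit)


class TerminationResults:
    """Fitted per-gene indices plus selections and metagene builders."""

    def __init__(self, model: TerminationAnalysis, metrics: pd.DataFrame,
                 chip_table: pd.DataFrame, pas_by_unit: dict):
        self.model = model
        self.metrics = metrics
        self.chip_table = chip_table
        self.pas_by_unit = pas_by_unit

    @property
    def config(self) -> AnalysisConfig:
        return self.model.config

    # -- selections --------------------------------------------------------
    def select_attenuated(self, treated: str, control: str) -> set:
        sel = _ix.select_attenuated(self.metrics, self.config, treated, control)
        self.metrics["attenuated"] = self.metrics["unit_id"].isin(sel)
        return sel

    def chip_targets(self, sample: str) -> set:
        sub = self.chip_table[self.chip_table["sample"] == sample]
        if sub.empty:
            raise ValueError(f"no occupancy data for sample {sample!r}")
        sel = _ix.chip_target_set(sub, self.config)
        self.metrics["chip_target"] = self.metrics["unit_id"].isin(sel)
        return sel

    # -- metagenes ---------------------------------------------------------
    def scaled_matrix(self, sample: str, **kwargs) -> _mg.SignalMatrix:
        kwargs.setdefault("trim", self.config.metagene_trim)
        return _mg.scaled_matrix(
            self.model.coverage[sample], self.model.units, **kwargs
        )

    def pas_anchored_matrix(self, sample: str, **kwargs) -> _mg.SignalMatrix:
        anchors = []
        for u in self.model.units:
            pas = self.pas_by_unit.get(u.id)
            if pas is not None:
                anchors.append((u.id, pas.chrom, pas.position, pas.strand))
        return _mg.anchored_matrix(self.model.coverage[sample], anchors, **kwargs)

    def log2_ratio_matrix(self, treated: str, control: str,
                          anchored: bool = False, **kwargs) -> _mg.SignalMatrix:
        build = self.pas_anchored_matrix if anchored else self.scaled_matrix
        a = build(treated, **kwargs)
        b = build(control, **kwargs)
        # rows can differ if a track is missing a unit; align on intersection
        common = [r for r in a.row_ids if r in set(b.row_ids)]
        a, b = a.sort_rows(common), b.sort_rows(common)
        return _mg.log2_ratio(a, b, pseudocount=self.config.log2_pseudocount)

    # -- reporting ---------------------------------------------------------
    def to_tsv(self, path: str) -> None:
        self.metrics.to_csv(path, sep="\t", index=False, na_rep="NA")

    def summary(self) -> str:
        lines = [
            "Termination analysis",
            "=" * 56,
            f"units: {len(self.model.units)}   samples: "
            f"{sorted(self.model.coverage)}",
        ]
        for sample, sub in self.metrics.groupby("sample"):
            lines.append(
                f"[{sample}] median attenuation "
                f"{sub['attenuation_index'].median():.3f} | "
                f"median readthrough {sub['readthrough_index'].median():.3f} | "
                f"median cleavage {sub['cleavage_index'].median():.3f} | "
                f"median intron retention {sub['intron_retention'].median():.3f}"
            )
        if "attenuated" in self.metrics:
            n = self.metrics.loc[self.metrics["attenuated"], "unit_id"].nunique()
            lines.append(f"attenuated genes (>= {self.config.attenuation_fold}"
                         f"-fold index change): {n}")
        if "chip_target" in self.metrics:
            n = self.metrics.loc[self.metrics["chip_target"], "unit_id"].nunique()
            lines.append(
                f"occupancy targets (>= {self.config.chip_enrichment}x mean): {n}"
            )
        return "\n".join(lines)
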