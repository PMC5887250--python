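"""End-to-end run: scan -> STR specificity -> transcript specificity -> stats.

The report carries, per unit length (3 and 4):

* the per-locus table with per-species presence evidence,
* the per-transcript identity/specificity table,
* a motif frequency table split by compartment,
* Levene's test comparing the two compartments' per-motif relative
  frequency vectors (the skewing statistic), and
* the mid-p enrichment of human-specific transcripts in the human-specific
  STR compartment versus round(1.5 n) sampled controls.

A compartment is a set of *transcripts*: a transcript belongs to the
human-specific compartment of a unit length when at least one of its
detected loci of that unit length is called human-specific, and to the
control (non-human-specific) compartment when it has loci of that length
but none human-specific.  Stages that cannot run on a given input (an empty
control pool, a single-motif frequency table) are reported as ``None`` with
a warning rather than failing the run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .io_model import PromoterSet, SpeciesPanel, UtrSet, ValidationError
from .ortholog_compare import MatchPolicy, StrSpecificityCall, classify_str_specificity
from .stats import (
    EnrichmentResult,
    LeveneResult,
    MotifFrequencyTable,
    enrichment_test,
    levene_test,
    motif_frequency_table,
    round_half_up,
)
from .str_scan import ScanConfig, StrLocus, find_str_loci
from .utr_identity import AlignmentScoreScheme, TranscriptCall, classify_transcript

__all__ = ["PipelineReport", "CompartmentSummary", "run_pipeline"]


class StageError(Exception):
    """A pipeline stage failed; carries the stage name and offending record."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r}: {detail}")
        self.stage = stage


@dataclass
class CompartmentSummary:
    """Headline numbers for one unit length."""

    unit_length: int
    n_hs_transcripts_compartment: int          # n: transcripts with >=1 hs locus
    n_control_transcripts: int
    hs_transcript_count: int                   # human-specific transcripts within n
    hs_transcript_genes: tuple[str, ...]
    percent_hs_transcripts: float              # 1 dp
    percent_hs_transcripts_int: int            # nearest integer, as printed
    frequency_table: MotifFrequencyTable | None
    levene: LeveneResult | None
    enrichment: EnrichmentResult | None


@dataclass
class PipelineReport:
    loci: list[StrLocus]
    str_calls: list[StrSpecificityCall]
    transcript_calls: dict[str, TranscriptCall]
    compartments: dict[int, CompartmentSummary]
    warnings: list[str]
    manifest: dict

    def loci_frame(self) -> pd.DataFrame:
        rows = []
        for locus, call in zip(self.loci, self.str_calls):
            row = {
                "gene": locus.gene, "transcript_id": locus.transcript_id,
                "species": locus.species, "motif": locus.motif,
                "unit_length": locus.unit_length, "copies": locus.copies,
                "start_offset": locus.start_offset, "end_offset": locus.end_offset,
                "formula": locus.formula, "human_specific": call.human_specific,
            }
            for sp, v in call.presence.items():
                row[f"presence_{sp}"] = v
            rows.append(row)
        return pd.DataFrame(rows)

    def transcript_frame(self) -> pd.DataFrame:
        rows = []
        for call in self.transcript_calls.values():
            row = {
                "gene": call.gene, "transcript_id": call.transcript_id,
                "min_identity": call.min_identity, "max_identity": call.max_identity,
                "threshold": call.threshold,
                "composition_divergent": call.composition_divergent,
                "human_specific": call.human_specific,
            }
            for sp, v in call.pairwise_identity.items():
                row[f"identity_{sp}"] = round(v, 2)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        out = {"manifest": self.manifest, "warnings": self.warnings,
               "compartments": {}}
        for u, comp in self.compartments.items():
            d = {
                "unit_length": comp.unit_length,
                "n": comp.n_hs_transcripts_compartment,
                "n_control": comp.n_control_transcripts,
                "hs_transcript_count": comp.hs_transcript_count,
                "hs_transcript_genes": list(comp.hs_transcript_genes),
                "percent_hs_transcripts": comp.percent_hs_transcripts,
                "percent_hs_transcripts_int": comp.percent_hs_transcripts_int,
                "levene": asdict(comp.levene) if comp.levene else None,
                "enrichment": asdict(comp.enrichment) if comp.enrichment else None,
                "top_motif_human_specific": (
                    comp.frequency_table.top_motif("human_specific")
                    if comp.frequency_table else None),
                "top_motif_non_human_specific": (
                    comp.frequency_table.top_motif("non_human_specific")
                    if comp.frequency_table else None),
            }
            out["compartments"][str(u)] = d
        return out

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.loci_frame().to_csv(outdir / "loci.tsv", sep="\t", index=False)
        self.transcript_frame().to_csv(outdir / "transcripts.tsv", sep="\t",
                                       index=False)
        for u, comp in self.compartments.items():
            if comp.frequency_table is not None:
                rows = [
                    {"motif": m, "total": v[0], "human_specific": v[1],
                     "non_human_specific": v[2]}
                    for m, v in comp.frequency_table.rows.items()
                ]
                pd.DataFrame(rows).to_csv(
                    outdir / f"motif_frequencies_{u}.tsv", sep="\t", index=False)
        (outdir / "report.json").write_text(
            json.dumps(self.to_json_dict(), indent=2) + "\n")


def run_pipeline(
    promoters: PromoterSet,
    utrs: UtrSet,
    panel: SpeciesPanel | None = None,
    scan_config: ScanConfig = ScanConfig(),
    policy: MatchPolicy = MatchPolicy(),
    threshold: float = 50.0,
    scheme: AlignmentScoreScheme = AlignmentScoreScheme(),
    ratio: float = 1.5,
    seed: int = 0,
    resamples: int = 1,
    outdir: str | Path | None = None,
) -> PipelineReport:
    """Run the full analysis over an in-memory dataset.

    Genes without a reference-species promoter are skipped with a warning
    (they cannot anchor a scan); any malformed record aborts with the stage
    name.
    """
    panel = panel or promoters.panel
    warnings: list[str] = []

    # stage 1: scan reference promoters
    loci: list[StrLocus] = []
    genes = sorted(promoters.by_gene)
    for gene in promoters.missing_reference:
        warnings.append(f"scan: gene {gene} has no reference-species promoter")
    try:
        for gene in genes:
            ref = promoters.reference_record(gene)
            if ref is None:
                continue
            loci.extend(find_str_loci(ref, scan_config))
    except ValidationError as exc:
        raise StageError("scan", str(exc)) from exc

    # stage 2: per-locus specificity against the panel
    str_calls: list[StrSpecificityCall] = []
    try:
        ortho_cache = {g: promoters.ortholog_records(g) for g in genes}
        for locus in loci:
            str_calls.append(classify_str_specificity(
                locus, ortho_cache[locus.gene], panel, policy, scan_config))
    except ValidationError as exc:
        raise StageError("classify-str", str(exc)) from exc

    # stage 3: transcript specificity from 5'UTR identity
    transcript_calls: dict[str, TranscriptCall] = {}
    try:
        for gene in sorted(utrs.by_gene):
            transcript_calls[gene] = classify_transcript(
                utrs.by_gene[gene], panel, threshold, scheme)
    except ValidationError as exc:
        raise StageError("classify-transcript", str(exc)) from exc

    # stage 4: compartments and statistics per unit length
    compartments: dict[int, CompartmentSummary] = {}
    for u in scan_config.unit_lengths:
        hs_genes: set[str] = set()
        ctrl_genes: set[str] = set()
        for locus, call in zip(loci, str_calls):
            if locus.unit_length != u:
                continue
            if call.human_specific:
                hs_genes.add(locus.gene)
            else:
                ctrl_genes.add(locus.gene)
        ctrl_genes -= hs_genes

        u_loci = [l for l in loci if l.unit_length == u]
        u_calls = [c for l, c in zip(loci, str_calls) if l.unit_length == u]
        freq = motif_frequency_table(u_loci, u_calls, u) if u_loci else None

        levene: LeveneResult | None = None
        if freq is not None:
            hs_prop = freq.proportions("human_specific")
            ctrl_prop = freq.proportions("non_human_specific")
            motifs = sorted(set(hs_prop) | set(ctrl_prop))
            if hs_prop and ctrl_prop and len(motifs) >= 2:
                levene = levene_test([
                    [hs_prop.get(m, 0.0) for m in motifs],
                    [ctrl_prop.get(m, 0.0) for m in motifs],
                ])
            else:
                warnings.append(
                    f"skew: unit length {u}: need both compartments populated "
                    "and >=2 motifs for Levene's test")

        hs_tx_calls = [transcript_calls[g] for g in sorted(hs_genes)
                       if g in transcript_calls]
        ctrl_tx_calls = [transcript_calls[g] for g in sorted(ctrl_genes)
                         if g in transcript_calls]
        n = len(hs_tx_calls)
        hs_count = sum(c.human_specific for c in hs_tx_calls)
        enrich: EnrichmentResult | None = None
        if n:
            need = round_half_up(ratio * n)
            if len(ctrl_tx_calls) >= need:
                try:
                    enrich = enrichment_test(hs_tx_calls, ctrl_tx_calls,
                                             ratio=ratio, seed=seed,
                                             resamples=resamples)
                except ValidationError as exc:
                    warnings.append(f"enrich: unit length {u}: {exc}")
            else:
                warnings.append(
                    f"enrich: unit length {u}: control pool has "
                    f"{len(ctrl_tx_calls)} transcripts, {need} required; "
                    "mid-p not computed")
        pct = 100.0 * hs_count / n if n else 0.0
        compartments[u] = CompartmentSummary(
            unit_length=u,
            n_hs_transcripts_compartment=n,
            n_control_transcripts=len(ctrl_tx_calls),
            hs_transcript_count=hs_count,
            hs_transcript_genes=tuple(
                c.gene for c in hs_tx_calls if c.human_specific),
            percent_hs_transcripts=round(pct, 1),
            percent_hs_transcripts_int=round_half_up(pct) if n else 0,
            frequency_table=freq,
            levene=levene,
            enrichment=enrich,
        )

    manifest = {
        "artifact_version": __version__,
        "n_genes": len(genes),
        "n_promoter_records": promoters.n_records,
        "n_loci": len(loci),
        "n_transcripts": len(transcript_calls),
        "scan_config": asdict(scan_config),
        "match_policy": asdict(policy),
        "identity_threshold": threshold,
        "control_ratio": ratio,
        "seed": seed,
        "resamples": resamples,
    }
    report = PipelineReport(
        loci=loci, str_calls=str_calls, transcript_calls=transcript_calls,
        compartments=compartments, warnings=warnings, manifest=manifest,
    )
    if outdir is not None:
        report.write(outdir)
    return report
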