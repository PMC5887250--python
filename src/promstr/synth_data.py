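"""Synthetic multi-species promoter/5'UTR datasets with known planted truth.

Two generators:

* :func:`generate_dataset` builds an N-gene, 25-species ortholog panel in
  which a configurable fraction of genes receives a human-only core-promoter
  STR (the rest share the STR with a species subset), and transcript 5'UTRs
  are either conserved copies of the human UTR (substitution-mutated to a
  target identity, ~70% by default) or independent draws resampled into the
  unrelated-identity band (37-48%).  Every planted fact is recorded in a
  truth table so pipeline recovery is exactly checkable.

* :func:`build_table_replica` turns the packaged human-specific STR tables
  into a dataset: one gene per table row, the human promoter synthesized
  from the printed repeat formula(s), non-human promoters free of any
  tri/tetra repeat (human-specific by construction), and UTR divergence
  planted according to each row's human-specific-transcript flag.

Divergence is substitutions only (no indels), so conserved identity is
controllable in closed form; flanks and clean windows are rejection-sampled
until they contain no accidental >=3-copy tri/tetra repeat, keeping truth
tables exact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_model import (
    PromoterSet,
    SpeciesPanel,
    UtrRecord,
    UtrSet,
    ValidationError,
    default_panel,
    load_paper_fixture,
    offset_to_index,
    write_promoter_set,
    write_utr_set,
)
from .str_scan import ScanConfig, parse_formula, synthesize_window
from .stats import round_half_up
from .utr_identity import AlignmentScoreScheme, pairwise_identity

__all__ = [
    "SimConfig",
    "TruthRow",
    "SyntheticDataset",
    "generate_dataset",
    "build_table_replica",
    "DEFAULT_TRI_WEIGHTS",
    "DEFAULT_TETRA_WEIGHTS",
]

# Qualitative genome-wide motif weights: GC-rich motifs dominate, with GGC
# and GGGC the most common tri/tetra units.
DEFAULT_TRI_WEIGHTS: dict[str, float] = {
    "GGC": 5.0, "GCC": 3.0, "CCG": 1.5, "GGA": 2.0, "CCT": 2.0,
    "GCA": 1.0, "GAA": 1.0, "TGC": 1.0, "GGT": 0.5, "ATT": 0.5,
}
DEFAULT_TETRA_WEIGHTS: dict[str, float] = {
    "GGGC": 5.0, "CTCC": 2.5, "TCCC": 2.0, "GAAA": 1.5, "GTTT": 1.0,
    "GATA": 1.0, "GGCT": 1.0, "CCGG": 0.5, "GCCC": 1.0, "TTTA": 0.5,
}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic panel generator."""

    n_genes: int = 100
    window_length: int = 151          # core window (121) + upstream buffer (30)
    gc_content: float = 0.5
    frac_hs_str: float = 0.3
    frac_hs_transcript_in_hs: float = 0.26
    frac_hs_transcript_in_control: float = 0.0
    tri_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRI_WEIGHTS))
    tetra_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TETRA_WEIGHTS))
    copy_number_range: tuple[int, int] = (3, 13)
    conserved_utr_identity_target: float = 70.0
    unrelated_utr_identity_band: tuple[float, float] = (37.0, 48.0)
    utr_length: int = 150
    core_window: tuple[int, int] = (-120, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.frac_hs_str, self.frac_hs_transcript_in_hs,
                  self.frac_hs_transcript_in_control):
            if not 0.0 <= f <= 1.0:
                raise ValidationError("fractions must lie in [0, 1]")
        lo, hi = self.copy_number_range
        if not (3 <= lo <= hi <= 13):
            raise ValidationError("copy_number_range must lie within [3, 13]")
        if not 0.0 < self.gc_content < 1.0:
            raise ValidationError("gc_content must lie in (0, 1)")
        # the longest jittered run (hi+1 tetra copies) must fit in the window
        if 4 * (hi + 1) >= self.window_length:
            raise ValidationError("window too short for the maximum repeat run")
        lo_off, hi_off = self.core_window
        if lo_off >= hi_off or lo_off == 0 or hi_off == 0:
            raise ValidationError("core window must be well-ordered with zero-free bounds")
        span = hi_off - lo_off + 1 - (1 if lo_off < 0 < hi_off else 0)  # closed, no position 0
        if span > self.window_length:
            raise ValidationError("window shorter than the core window")
        if self.n_genes < 1:
            raise ValidationError("n_genes must be positive")


@dataclass(frozen=True)
class TruthRow:
    """Planted facts for one synthetic gene."""

    gene: str
    transcript_id: str
    unit_length: int
    motif: str
    copies: int
    start_offset: int
    formula: str
    str_human_specific: bool
    shared_species: tuple[str, ...]
    transcript_human_specific: bool


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset plus the truth table that generated it."""

    panel: SpeciesPanel
    promoters: PromoterSet
    utrs: UtrSet
    truth: list[TruthRow]
    scan_config: ScanConfig
    label: str = "synthetic"

    def truth_by_gene(self) -> dict[str, TruthRow]:
        return {t.gene: t for t in self.truth}

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Write FASTA/TSV files plus a JSON manifest; returns content hashes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_promoter_set(self.promoters, outdir / "promoters.fasta",
                           outdir / "promoters.tsv")
        write_utr_set(self.utrs, outdir / "utrs.fasta", outdir / "utrs.tsv")
        truth_lines = ["\t".join([
            "gene", "transcript_id", "unit_length", "motif", "copies",
            "start_offset", "formula", "str_human_specific", "shared_species",
            "transcript_human_specific"])]
        for t in self.truth:
            truth_lines.append("\t".join([
                t.gene, t.transcript_id, str(t.unit_length), t.motif,
                str(t.copies), str(t.start_offset), t.formula,
                str(int(t.str_human_specific)), ",".join(t.shared_species),
                str(int(t.transcript_human_specific))]))
        (outdir / "truth.tsv").write_text("\n".join(truth_lines) + "\n")
        hashes = {}
        for name in ("promoters.fasta", "promoters.tsv", "utrs.fasta",
                     "utrs.tsv", "truth.tsv"):
            hashes[name] = hashlib.sha256((outdir / name).read_bytes()).hexdigest()
        (outdir / "manifest.json").write_text(json.dumps(
            {"label": self.label, "hashes": hashes}, indent=2) + "\n")
        return hashes


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _mutate_to_identity(rng: np.random.Generator, seq: str, target_pct: float) -> str:
    """Substitute an exact fraction of positions so ungapped identity equals
    the target (alignment identity lands within a point or two; valid for
    high targets where realignment gain is negligible)."""
    k = round_half_up(len(seq) * (1.0 - target_pct / 100.0))
    return _mutate_exact(rng, seq, k)


def tuned_copy(
    rng: np.random.Generator,
    seq: str,
    target_pct: float,
    tol: float = 5.0,
    scheme: AlignmentScoreScheme | None = None,
    max_tries: int = 200,
) -> str:
    """Substitution-mutated copy whose *alignment* identity to ``seq`` lands
    within ``tol`` points of the target.

    The closed-form substitution count is only exact while realignment gain
    is negligible (high identity); at lower targets gapped realignment
    inflates identity towards the unrelated baseline, so the substitution
    count is searched against the measured pairwise identity.
    """
    scheme = scheme or AlignmentScoreScheme()
    n = len(seq)
    k = int(np.clip(round_half_up(n * (1.0 - target_pct / 100.0)), 0, n))
    for _ in range(max_tries):
        cand = seq if k == 0 else _mutate_exact(rng, seq, k)
        d = pairwise_identity(seq, cand, scheme) - target_pct
        if abs(d) <= tol:
            return cand
        step = round_half_up(abs(d) * n / 200.0) or 1
        k = int(np.clip(k + (step if d > 0 else -step), 0, n))
    raise ValidationError(
        f"could not tune a copy to {target_pct}% +- {tol} identity"
    )


def _mutate_exact(rng: np.random.Generator, seq: str, k: int) -> str:
    pos = rng.choice(len(seq), size=k, replace=False)
    arr = list(seq)
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _unrelated_seq(
    rng: np.random.Generator, human: str, band: tuple[float, float],
    gc: float, scheme: AlignmentScoreScheme, max_tries: int = 500,
) -> str:
    """Independent random draw, resampled until its pairwise identity to the
    human sequence falls inside the unrelated band."""
    lo, hi = band
    for _ in range(max_tries):
        cand = _random_seq(rng, len(human), gc)
        if lo <= pairwise_identity(human, cand, scheme) <= hi:
            return cand
    raise ValidationError(
        f"could not draw an unrelated sequence with identity in [{lo}, {hi}]"
    )


def _exact_subset(rng: np.random.Generator, items: Sequence[str], frac: float) -> set[str]:
    k = round_half_up(frac * len(items))
    if k == 0:
        return set()
    return set(rng.choice(np.array(items), size=k, replace=False).tolist())


def _weighted_choice(rng: np.random.Generator, weights: Mapping[str, float]) -> str:
    keys = sorted(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=w / w.sum())]


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def generate_dataset(
    config: SimConfig,
    panel: SpeciesPanel | None = None,
    outdir: str | Path | None = None,
) -> SyntheticDataset:
    """Generate a planted-truth multi-species dataset.

    Exactly ``round(frac_hs_str * n_genes)`` genes receive a human-only STR;
    the remainder share theirs (copy-number jitter of +/-1, floor 3) with a
    random non-empty species subset.  Transcript human-specificity is
    likewise planted in exact counts within each compartment.  All
    randomness flows from ``config.seed``; the same config reproduces
    byte-identical files.
    """
    panel = panel or default_panel()
    rng = np.random.default_rng(config.seed)
    scheme = AlignmentScoreScheme()
    W = config.window_length
    tss = W - 1
    win_lo_idx = offset_to_index(config.core_window[0], tss)
    win_hi_idx = offset_to_index(config.core_window[1], tss)

    genes = [f"GENE{i + 1:04d}" for i in range(config.n_genes)]
    hs_genes = _exact_subset(rng, genes, config.frac_hs_str)
    ctrl_genes = [g for g in genes if g not in hs_genes]
    hs_tx = _exact_subset(rng, sorted(hs_genes), config.frac_hs_transcript_in_hs)
    hs_tx |= _exact_subset(rng, ctrl_genes, config.frac_hs_transcript_in_control)

    promoters = PromoterSet(panel=panel)
    utrs = UtrSet(panel=panel)
    truth: list[TruthRow] = []
    nonref = list(panel.non_reference)

    for gene in genes:
        tid = f"{gene}.t1"
        u = int(rng.choice([3, 4]))
        weights = config.tri_weights if u == 3 else config.tetra_weights
        motif = _weighted_choice(rng, weights)
        k = int(rng.integers(config.copy_number_range[0],
                             config.copy_number_range[1] + 1))
        # jitter-safe placement: the run still fits and still overlaps the
        # core window at k-1 and k+1 copies
        start_min = max(0, win_lo_idx - u * (k - 1) + 1)
        start_max = min(win_hi_idx, tss - u * (k + 1) + 1)
        if start_max < start_min:
            raise ValidationError(
                f"window too short to place {motif}x{k} overlapping the core window"
            )
        start = int(rng.integers(start_min, start_max + 1))
        offset = start - tss if start < tss else start - tss + 1
        formula = format_formula_parts(offset, motif, k)

        is_hs = gene in hs_genes
        if is_hs:
            shared: tuple[str, ...] = ()
        else:
            m = int(rng.integers(1, len(nonref) + 1))
            shared = tuple(sorted(
                rng.choice(np.array(nonref), size=m, replace=False).tolist()))

        human_prom = synthesize_window(
            [formula], window_length=W, gc=config.gc_content, rng=rng,
            gene=gene, transcript_id=tid, species=panel.reference_species,
        )
        recs = [human_prom]
        for sp in nonref:
            if sp in shared:
                k_o = int(np.clip(k + rng.integers(-1, 2), 3, None))
                recs.append(synthesize_window(
                    [format_formula_parts(offset, motif, k_o)],
                    window_length=W, gc=config.gc_content, rng=rng,
                    gene=gene, transcript_id=tid, species=sp,
                ))
            else:
                recs.append(synthesize_window(
                    [], window_length=W, gc=config.gc_content, rng=rng,
                    gene=gene, transcript_id=tid, species=sp,
                ))
        promoters.by_gene[gene] = recs

        tx_hs = gene in hs_tx
        utrs.by_gene[gene] = _make_utrs(
            rng, gene, tid, panel, tx_hs, config, scheme)
        truth.append(TruthRow(
            gene=gene, transcript_id=tid, unit_length=u, motif=motif,
            copies=k, start_offset=offset, formula=formula,
            str_human_specific=is_hs, shared_species=shared,
            transcript_human_specific=tx_hs,
        ))

    ds = SyntheticDataset(
        panel=panel, promoters=promoters, utrs=utrs, truth=truth,
        scan_config=ScanConfig(core_window=config.core_window),
        label=f"synthetic(n={config.n_genes},seed={config.seed})",
    )
    if outdir is not None:
        ds.write(outdir)
    return ds


def format_formula_parts(offset: int, motif: str, copies: int) -> str:
    sign = "-" if offset < 0 else "+"
    return f"{sign} {abs(offset)} ({motif}){copies}"


def _make_utrs(
    rng: np.random.Generator,
    gene: str,
    tid: str,
    panel: SpeciesPanel,
    tx_hs: bool,
    config: SimConfig,
    scheme: AlignmentScoreScheme,
) -> list[UtrRecord]:
    human_seq = _random_seq(rng, config.utr_length, config.gc_content)
    tl = int(rng.integers(800, 3001))
    ex = int(rng.integers(2, 13))
    aa = int(rng.integers(100, 801))
    recs = [UtrRecord(gene=gene, transcript_id=tid, species=panel.reference_species,
                      sequence=human_seq, transcript_length=tl, exon_count=ex,
                      aa_count=aa)]
    for sp in panel.non_reference:
        if tx_hs:
            seq = _unrelated_seq(rng, human_seq,
                                 config.unrelated_utr_identity_band,
                                 config.gc_content, scheme)
            comp = (int(tl * 1.5) + int(rng.integers(0, 200)), ex + 1,
                    aa + int(rng.integers(50, 200)))
        else:
            seq = _mutate_to_identity(rng, human_seq,
                                      config.conserved_utr_identity_target)
            comp = (tl, ex, aa)
        recs.append(UtrRecord(
            gene=gene, transcript_id=tid, species=sp, sequence=seq,
            transcript_length=comp[0], exon_count=comp[1], aa_count=comp[2]))
    return recs


# ---------------------------------------------------------------------------
# table replicas
# ---------------------------------------------------------------------------

#: Scan window used for the table replicas.  One printed tetranucleotide row
#: (a (GGCT)6 run at -144..-121) lies wholly upstream of the -120 window
#: edge; the replicas scan an extended core window (-150..+1) so that every
#: printed formula is recoverable.
REPLICA_SCAN_CONFIG = ScanConfig(core_window=(-150, 1))
REPLICA_WINDOW_LENGTH = 181


def build_table_replica(
    which: str,
    seed: int = 1,
    panel: SpeciesPanel | None = None,
    outdir: str | Path | None = None,
) -> SyntheticDataset:
    """Dataset replicating the packaged human-specific STR tables.

    One gene per fixture row; the human promoter carries exactly the
    printed repeat run(s), every non-human promoter is repeat-free (so each
    printed STR is human-specific by construction), and 5'UTR divergence is
    planted to match the row's human-specific-transcript flag.
    """
    rows = load_paper_fixture(which)
    panel = panel or default_panel()
    rng = np.random.default_rng(seed)
    scheme = AlignmentScoreScheme()
    config = SimConfig(seed=seed)  # UTR/identity conditions shared with the simulator

    promoters = PromoterSet(panel=panel)
    utrs = UtrSet(panel=panel)
    truth: list[TruthRow] = []
    for row in rows:
        human_prom = synthesize_window(
            list(row.formulas), window_length=REPLICA_WINDOW_LENGTH,
            gc=config.gc_content, rng=rng, gene=row.gene,
            transcript_id=row.transcript_id, variant_no=row.variant_no,
            species=panel.reference_species,
        )
        recs = [human_prom]
        for sp in panel.non_reference:
            recs.append(synthesize_window(
                [], window_length=REPLICA_WINDOW_LENGTH, gc=config.gc_content,
                rng=rng, gene=row.gene, transcript_id=row.transcript_id,
                variant_no=row.variant_no, species=sp,
            ))
        promoters.by_gene[row.gene] = recs
        utrs.by_gene[row.gene] = _make_utrs(
            rng, row.gene, row.transcript_id, panel,
            row.human_specific_transcript, config, scheme)
        for f in row.formulas:
            offset, motif, copies = parse_formula(f)
            truth.append(TruthRow(
                gene=row.gene, transcript_id=row.transcript_id,
                unit_length=len(motif), motif=motif, copies=copies,
                start_offset=offset, formula=f, str_human_specific=True,
                shared_species=(), transcript_human_specific=row.human_specific_transcript,
            ))

    ds = SyntheticDataset(
        panel=panel, promoters=promoters, utrs=utrs, truth=truth,
        scan_config=REPLICA_SCAN_CONFIG,
        label=f"table_replica({which},seed={seed})",
    )
    if outdir is not None:
        ds.write(outdir)
    return ds
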