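"""Perfect tri-/tetranucleotide tandem-repeat detection in TSS-anchored windows.

The scanner reports every *phase* of a perfect repeat run separately: a
locus is emitted for a unit ``u`` starting at position ``i`` when (a) the
unit repeats at least ``min_copies`` times, (b) the unit is primitive (not a
power of a shorter string), (c) the run is not left-extendable in its own
phase (the ``|u|`` bases upstream are not the unit again), and (d) the run
overlaps the closed core window.  Distinct rotations of one physical run
(e.g. a GCC-phase and a CCG-phase of one G/C-rich stretch) are therefore
reported as separate loci with their own start offsets, each maximal for its
phase.  Only perfect runs count: any mismatch, including ``N``, terminates a
run.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .io_model import (
    CoordinateRangeError,
    PromoterRecord,
    ValidationError,
    index_to_offset,
    offset_to_index,
)

__all__ = [
    "StrLocus",
    "ScanConfig",
    "is_primitive_unit",
    "find_str_loci",
    "format_formula",
    "parse_formula",
    "synthesize_from_formula",
    "synthesize_window",
    "rotations",
]


@dataclass(frozen=True)
class StrLocus:
    """A detected perfect tandem repeat, e.g. ``- 48 (CCA)3``."""

    gene: str
    transcript_id: str
    species: str
    motif: str
    unit_length: int
    copies: int
    start_offset: int  # signed, zero-free; 5'-most base of the run
    end_offset: int    # 3'-most base of the run

    def __post_init__(self) -> None:
        if self.unit_length != len(self.motif):
            raise ValidationError("unit_length must equal len(motif)")
        if self.copies < 2:
            raise ValidationError("copies must be >= 2")
        if not is_primitive_unit(self.motif):
            raise ValidationError(f"motif {self.motif!r} is not primitive")

    @property
    def formula(self) -> str:
        return format_formula(self)


@dataclass(frozen=True)
class ScanConfig:
    """Scanning parameters.

    ``core_window`` is a closed offset interval, default (-120, +1); a run
    is reported when it *overlaps* the window.  Scanning starts
    ``scan_buffer_upstream`` nt upstream of the window edge so runs
    straddling it are found with their true upstream start offsets.
    """

    core_window: tuple[int, int] = (-120, 1)
    scan_buffer_upstream: int = 30
    unit_lengths: tuple[int, ...] = (3, 4)
    min_copies: int = 3

    def __post_init__(self) -> None:
        lo, hi = self.core_window
        if lo == 0 or hi == 0:
            raise ValidationError("core window bounds use zero-free offsets")
        if lo >= hi:
            raise ValidationError("core window must be well-ordered (lo < hi)")
        if self.min_copies < 2:
            raise ValidationError("min_copies must be >= 2")
        if self.scan_buffer_upstream < 0:
            raise ValidationError("scan_buffer_upstream must be >= 0")
        for u in self.unit_lengths:
            if u < 1:
                raise ValidationError("unit lengths must be positive")


def is_primitive_unit(unit: str) -> bool:
    """True iff ``unit`` is not a whole-number power of a shorter string.

    Excludes homopolymer units ("CCC") and even rotations of dinucleotide
    runs ("ATAT"), which would otherwise masquerade as tri-/tetranucleotide
    motifs.
    """
    if not unit:
        raise ValidationError("empty repeat unit")
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def rotations(motif: str) -> set[str]:
    return {motif[i:] + motif[:i] for i in range(len(motif))}


def find_str_loci(record: PromoterRecord, config: ScanConfig = ScanConfig()) -> list[StrLocus]:
    """All perfect tandem-repeat loci overlapping the core window.

    Output is sorted by (start offset, unit length, motif).  A window too
    short to hold any run yields an empty list.
    """
    seq = record.sequence
    tss = record.tss_index
    n = len(seq)
    lo_off, hi_off = config.core_window
    win_lo = tss + lo_off if lo_off < 0 else tss + lo_off - 1  # may lie outside seq
    win_hi = tss + hi_off if hi_off < 0 else tss + hi_off - 1
    scan_lo = max(0, win_lo - config.scan_buffer_upstream)
    scan_hi = min(win_hi, n - 1)

    loci: list[StrLocus] = []
    for u in config.unit_lengths:
        for i in range(scan_lo, scan_hi + 1):
            if i + u > n:
                break
            unit = seq[i:i + u]
            if "N" in unit or not is_primitive_unit(unit):
                continue
            if i >= u and seq[i - u:i] == unit:
                continue  # left-extendable: reported at its own phase start
            k = 1
            while seq[i + k * u:i + (k + 1) * u] == unit:
                k += 1
            if k < config.min_copies:
                continue
            end = i + k * u - 1
            if end < win_lo or i > win_hi:
                continue
            loci.append(
                StrLocus(
                    gene=record.gene,
                    transcript_id=record.transcript_id,
                    species=record.species,
                    motif=unit,
                    unit_length=u,
                    copies=k,
                    start_offset=index_to_offset(i, tss),
                    end_offset=index_to_offset(end, tss),
                )
            )
    loci.sort(key=lambda l: (l.start_offset, l.unit_length, l.motif))
    return loci


# ---------------------------------------------------------------------------
# formula grammar:  "- 48 (CCA)3"  /  "+ 1 (GATA)3"
# ---------------------------------------------------------------------------

_FORMULA_RE = re.compile(
    r"^\s*([+−-]?)\s*(\d+)\s+\((?P<motif>[ACGT]+)\)(?P<copies>\d+)\s*$"
)


def format_formula(locus: StrLocus) -> str:
    """Render a locus in the table grammar, e.g. ``"- 48 (CCA)3"``."""
    sign = "-" if locus.start_offset < 0 else "+"
    return f"{sign} {abs(locus.start_offset)} ({locus.motif}){locus.copies}"


def parse_formula(formula: str) -> tuple[int, str, int]:
    """Parse ``"- 48 (CCA)3"`` to ``(-48, "CCA", 3)``.

    Accepts ASCII hyphen and the typographic minus sign; inverse of
    :func:`format_formula`.
    """
    m = _FORMULA_RE.match(formula)
    if not m:
        raise ValidationError(f"unparseable STR formula {formula!r}")
    sign, number = m.group(1), int(m.group(2))
    offset = -number if sign in ("-", "−") else number
    if offset == 0:
        raise ValidationError("formula offset 0 does not exist")
    motif, copies = m.group("motif"), int(m.group("copies"))
    if not is_primitive_unit(motif):
        raise ValidationError(f"formula motif {motif!r} is not primitive")
    if copies < 2:
        raise ValidationError("formula copy number must be >= 2")
    return offset, motif, copies


# ---------------------------------------------------------------------------
# sequence synthesis (formula -> promoter window)
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    spans = sorted(spans)
    merged = [spans[0]]
    for s, e in spans[1:]:
        ps, pe = merged[-1]
        if s <= pe + 1:
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def synthesize_window(
    formulas: list[str],
    *,
    window_length: int = 181,
    gc: float = 0.5,
    seed: int = 0,
    gene: str = "SYNTH",
    transcript_id: str = "SYNTH.1",
    variant_no: str = "",
    species: str = "human",
    max_tries: int = 1000,
    rng: np.random.Generator | None = None,
) -> PromoterRecord:
    """Build a promoter window carrying exactly the given repeat runs.

    The TSS (+1) is the window's last base, so a window of length L spans
    offsets -(L-1)..+1.  Flanks are drawn from a seeded background model and
    rejected until a whole-window scan finds each planted formula exactly
    and no locus outside the planted runs.  Phase rotations *inside* a
    planted run are inherent to the run (a (CCG)4 necessarily carries a GCC
    and a CGC phase) and are accepted.
    """
    tss = window_length - 1
    planted = [parse_formula(f) for f in formulas]
    spans: list[tuple[int, int]] = []
    template: dict[int, str] = {}
    for offset, motif, copies in planted:
        start = offset_to_index(offset, tss)
        run = motif * copies
        end = start + len(run) - 1
        if start < 0 or end >= window_length:
            raise CoordinateRangeError(
                f"run {motif}x{copies} at {offset} does not fit in a "
                f"{window_length}-nt window"
            )
        for j, base in enumerate(run):
            prev = template.get(start + j)
            if prev is not None and prev != base:
                raise ValidationError(
                    f"formulas conflict at offset {index_to_offset(start + j, tss)}"
                )
            template[start + j] = base
        spans.append((start, end))
    merged = _merge_spans(spans) if spans else []
    want = {(motif, offset, copies) for offset, motif, copies in planted}

    # accept iff every planted phase is recovered exactly and every scanned
    # locus lies inside one planted block (no accidental or extended runs)
    check_cfg = ScanConfig(core_window=(-(window_length - 1), 1), scan_buffer_upstream=0)
    if rng is None:
        rng = np.random.default_rng(seed)
    free = [i for i in range(window_length) if i not in template]
    for _ in range(max_tries):
        arr = [""] * window_length
        fill = _random_seq(rng, len(free), gc)
        for pos, base in zip(free, fill):
            arr[pos] = base
        for pos, base in template.items():
            arr[pos] = base
        rec = PromoterRecord(
            gene=gene, transcript_id=transcript_id, variant_no=variant_no,
            species=species, sequence="".join(arr), tss_index=tss,
        )
        found = find_str_loci(rec, check_cfg)
        got = {(l.motif, l.start_offset, l.copies) for l in found}
        if not want <= got:
            continue
        ok = True
        for l in found:
            s = offset_to_index(l.start_offset, tss)
            e = offset_to_index(l.end_offset, tss)
            if not any(bs <= s and e <= be for bs, be in merged):
                ok = False
                break
        if ok:
            return rec
    raise ValidationError(
        f"could not synthesize a clean window for {formulas!r} in {max_tries} tries"
    )


def synthesize_from_formula(
    formula: str,
    *,
    gc: float = 0.5,
    seed: int = 0,
    window_length: int = 181,
    gene: str = "SYNTH",
    transcript_id: str = "SYNTH.1",
    species: str = "human",
) -> PromoterRecord:
    """Deterministically embed one repeat formula in a synthetic window."""
    return synthesize_window(
        [formula], window_length=window_length, gc=gc, seed=seed,
        gene=gene, transcript_id=transcript_id, species=species,
    )
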