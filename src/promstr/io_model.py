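"""Domain types, coordinate conventions and file I/O for promoter STR analysis.

Coordinates follow standard promoter numbering: the transcription start site
(TSS) is +1, the base immediately upstream is -1, and there is **no position
0**.  Internally every sequence carries a 0-based ``tss_index`` locating the
+1 base; :func:`offset_to_index` / :func:`index_to_offset` convert between
the two systems and are exact inverses on legal (non-zero) offsets.

Sequences are stored on the transcribed (sense) strand, 5'->3', uppercase
over ``{A, C, G, T, N}``.  Extraction of windows from genome assemblies is
the data producer's job; this package consumes promoter-window FASTA plus a
plain TSV annotation mapping each FASTA record to (gene, transcript,
species, TSS position).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PromstrError",
    "ValidationError",
    "InvalidCoordinateError",
    "CoordinateRangeError",
    "PanelMismatchError",
    "MissingSequenceError",
    "FixtureParseError",
    "SpeciesPanel",
    "PromoterRecord",
    "UtrRecord",
    "PromoterSet",
    "UtrSet",
    "FixtureRow",
    "GROUPS",
    "default_panel",
    "offset_to_index",
    "index_to_offset",
    "offset_to_linear",
    "read_promoter_set",
    "write_promoter_set",
    "read_utr_set",
    "write_utr_set",
    "load_paper_fixture",
    "read_panel_config",
    "write_panel_config",
]


class PromstrError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(PromstrError):
    """Input failed a domain invariant."""


class InvalidCoordinateError(ValidationError):
    """A TSS offset of 0 (no such position exists)."""


class CoordinateRangeError(ValidationError):
    """A coordinate fell outside the sequence."""


class PanelMismatchError(ValidationError):
    """A species identifier not present in the species panel."""


class MissingSequenceError(ValidationError):
    """An annotation row referenced a FASTA entry that does not exist."""


class FixtureParseError(ValidationError):
    """A packaged table fixture row could not be parsed."""


GROUPS = ("primate", "non_primate_mammal", "bird_reptile", "amphibian", "fish")

_ALPHABET = set("ACGTN")


# ---------------------------------------------------------------------------
# coordinate conversion
# ---------------------------------------------------------------------------

def offset_to_index(offset: int, tss_index: int, seq_len: int | None = None) -> int:
    """Convert a signed, zero-free TSS offset to a 0-based sequence index.

    ``+1`` maps to ``tss_index`` itself; ``-1`` to the base immediately
    upstream.  When ``seq_len`` is given the result is range-checked.
    """
    if offset == 0:
        raise InvalidCoordinateError("TSS offset 0 does not exist (+1 is the TSS base)")
    idx = tss_index + offset - 1 if offset > 0 else tss_index + offset
    if seq_len is not None and not (0 <= idx < seq_len):
        raise CoordinateRangeError(
            f"offset {offset} maps to index {idx}, outside sequence of length {seq_len}"
        )
    return idx


def index_to_offset(index: int, tss_index: int) -> int:
    """Inverse of :func:`offset_to_index`."""
    d = index - tss_index
    return d + 1 if d >= 0 else d


def offset_to_linear(offset: int) -> int:
    """Map a zero-free offset onto the integers (-1 -> -1, +1 -> 0).

    Useful for distances between offsets, where the missing position 0
    would otherwise inflate gaps spanning the TSS by one.
    """
    if offset == 0:
        raise InvalidCoordinateError("TSS offset 0 does not exist")
    return offset - 1 if offset > 0 else offset


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesPanel:
    """An ordered panel of species with coarse taxonomic group labels.

    The default panel holds 25 species: 5 primates (including the human
    reference), 12 non-primate mammals, 5 birds/reptiles, 1 amphibian and
    2 fish.
    """

    species: tuple[str, ...]
    group_of: Mapping[str, str]
    reference_species: str = "human"

    def __post_init__(self) -> None:
        if self.reference_species not in self.species:
            raise ValidationError(
                f"reference species {self.reference_species!r} not in panel"
            )
        for sp in self.species:
            g = self.group_of.get(sp)
            if g is None:
                raise ValidationError(f"species {sp!r} has no group label")
            if g not in GROUPS:
                raise ValidationError(f"unknown group {g!r} for species {sp!r}")
        if len(set(self.species)) != len(self.species):
            raise ValidationError("duplicate species in panel")

    @property
    def non_reference(self) -> tuple[str, ...]:
        return tuple(s for s in self.species if s != self.reference_species)

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {g: 0 for g in GROUPS}
        for sp in self.species:
            sizes[self.group_of[sp]] += 1
        return sizes

    def require(self, species: str) -> None:
        if species not in self.group_of:
            raise PanelMismatchError(f"species {species!r} not in panel")


_DEFAULT_PANEL_SPEC: tuple[tuple[str, str], ...] = (
    ("human", "primate"),
    ("chimpanzee", "primate"),
    ("gorilla", "primate"),
    ("orangutan", "primate"),
    ("macaque", "primate"),
    ("mouse", "non_primate_mammal"),
    ("rat", "non_primate_mammal"),
    ("rabbit", "non_primate_mammal"),
    ("dog", "non_primate_mammal"),
    ("cat", "non_primate_mammal"),
    ("horse", "non_primate_mammal"),
    ("cow", "non_primate_mammal"),
    ("pig", "non_primate_mammal"),
    ("sheep", "non_primate_mammal"),
    ("elephant", "non_primate_mammal"),
    ("opossum", "non_primate_mammal"),
    ("platypus", "non_primate_mammal"),
    ("chicken", "bird_reptile"),
    ("turkey", "bird_reptile"),
    ("zebra_finch", "bird_reptile"),
    ("anole_lizard", "bird_reptile"),
    ("painted_turtle", "bird_reptile"),
    ("xenopus", "amphibian"),
    ("zebrafish", "fish"),
    ("fugu", "fish"),
)


def default_panel() -> SpeciesPanel:
    """The 25-species comparison panel (groups 5/12/5/1/2, human reference)."""
    return SpeciesPanel(
        species=tuple(s for s, _ in _DEFAULT_PANEL_SPEC),
        group_of={s: g for s, g in _DEFAULT_PANEL_SPEC},
        reference_species="human",
    )


@dataclass(frozen=True)
class PromoterRecord:
    """One species' promoter window, anchored at a TSS."""

    gene: str
    transcript_id: str
    variant_no: str
    species: str
    sequence: str
    tss_index: int

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"{self.gene}/{self.species}: empty sequence")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValidationError(
                f"{self.gene}/{self.species}: illegal characters {sorted(bad)!r} "
                "(sequences must be uppercase A/C/G/T/N)"
            )
        if not (0 <= self.tss_index < len(self.sequence)):
            raise ValidationError(
                f"{self.gene}/{self.species}: tss_index {self.tss_index} outside "
                f"sequence of length {len(self.sequence)}"
            )

    @property
    def seq_id(self) -> str:
        return f"{self.gene}|{self.species}"


@dataclass(frozen=True)
class UtrRecord:
    """A TSS-flanking 5'UTR sequence plus coarse transcript composition."""

    gene: str
    transcript_id: str
    species: str
    sequence: str
    transcript_length: int = 0
    exon_count: int = 0
    aa_count: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"{self.gene}/{self.species}: empty UTR sequence")
        if min(self.transcript_length, self.exon_count, self.aa_count) < 0:
            raise ValidationError("composition counts must be non-negative")

    @property
    def seq_id(self) -> str:
        return f"{self.gene}|{self.species}"


@dataclass
class PromoterSet:
    """Promoter records grouped by gene, with reference-coverage bookkeeping."""

    panel: SpeciesPanel
    by_gene: dict[str, list[PromoterRecord]] = field(default_factory=dict)
    missing_reference: list[str] = field(default_factory=list)

    def reference_record(self, gene: str) -> PromoterRecord | None:
        for rec in self.by_gene.get(gene, ()):
            if rec.species == self.panel.reference_species:
                return rec
        return None

    def ortholog_records(self, gene: str) -> list[PromoterRecord]:
        return [
            r for r in self.by_gene.get(gene, ())
            if r.species != self.panel.reference_species
        ]

    @property
    def n_records(self) -> int:
        return sum(len(v) for v in self.by_gene.values())


@dataclass
class UtrSet:
    panel: SpeciesPanel
    by_gene: dict[str, list[UtrRecord]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# FASTA + TSV readers / writers
# ---------------------------------------------------------------------------

_PROM_ANNOT_COLS = ["gene", "transcript_id", "variant_no", "species", "tss_index"]
_UTR_ANNOT_COLS = [
    "gene", "transcript_id", "species", "transcript_length", "exon_count", "aa_count",
]


def _read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _write_fasta(path: str | Path, entries: Iterable[tuple[str, str]]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in entries
    ]
    SeqIO.write(records, str(path), "fasta")


def read_promoter_set(
    fasta_path: str | Path, annotation_tsv_path: str | Path, panel: SpeciesPanel
) -> PromoterSet:
    """Load promoter windows described by an annotation TSV.

    The TSV has header ``gene, transcript_id, variant_no, species,
    tss_index`` with one row per (gene, species, transcript); each row's
    sequence is the FASTA entry named ``gene|species``.  Genes lacking a
    reference-species record are listed in ``missing_reference`` rather than
    silently dropped.
    """
    seqs = _read_fasta(fasta_path)
    out = PromoterSet(panel=panel)
    with open(annotation_tsv_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or [c for c in _PROM_ANNOT_COLS if c not in reader.fieldnames]:
            raise ValidationError(
                f"promoter annotation must have columns {_PROM_ANNOT_COLS}"
            )
        for row in reader:
            panel.require(row["species"])
            key = f"{row['gene']}|{row['species']}"
            if key not in seqs:
                raise MissingSequenceError(f"no FASTA entry {key!r}")
            rec = PromoterRecord(
                gene=row["gene"],
                transcript_id=row["transcript_id"],
                variant_no=row["variant_no"],
                species=row["species"],
                sequence=seqs[key],
                tss_index=int(row["tss_index"]),
            )
            out.by_gene.setdefault(rec.gene, []).append(rec)
    for gene, recs in out.by_gene.items():
        if not any(r.species == panel.reference_species for r in recs):
            out.missing_reference.append(gene)
    return out


def write_promoter_set(
    pset: PromoterSet, fasta_path: str | Path, annotation_tsv_path: str | Path
) -> None:
    entries = []
    rows = []
    for gene in pset.by_gene:
        for rec in pset.by_gene[gene]:
            entries.append((rec.seq_id, rec.sequence))
            rows.append(
                [rec.gene, rec.transcript_id, rec.variant_no, rec.species,
                 str(rec.tss_index)]
            )
    _write_fasta(fasta_path, entries)
    with open(annotation_tsv_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_PROM_ANNOT_COLS)
        w.writerows(rows)


def read_utr_set(
    fasta_path: str | Path, annotation_tsv_path: str | Path, panel: SpeciesPanel
) -> UtrSet:
    """Load 5'UTR sequences; annotation columns are ``gene, transcript_id,
    species, transcript_length, exon_count, aa_count``."""
    seqs = _read_fasta(fasta_path)
    out = UtrSet(panel=panel)
    with open(annotation_tsv_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or [c for c in _UTR_ANNOT_COLS if c not in reader.fieldnames]:
            raise ValidationError(f"UTR annotation must have columns {_UTR_ANNOT_COLS}")
        for row in reader:
            panel.require(row["species"])
            key = f"{row['gene']}|{row['species']}"
            if key not in seqs:
                raise MissingSequenceError(f"no FASTA entry {key!r}")
            rec = UtrRecord(
                gene=row["gene"],
                transcript_id=row["transcript_id"],
                species=row["species"],
                sequence=seqs[key],
                transcript_length=int(row["transcript_length"]),
                exon_count=int(row["exon_count"]),
                aa_count=int(row["aa_count"]),
            )
            out.by_gene.setdefault(rec.gene, []).append(rec)
    return out


def write_utr_set(
    uset: UtrSet, fasta_path: str | Path, annotation_tsv_path: str | Path
) -> None:
    entries = []
    rows = []
    for gene in uset.by_gene:
        for rec in uset.by_gene[gene]:
            entries.append((rec.seq_id, rec.sequence))
            rows.append(
                [rec.gene, rec.transcript_id, rec.species,
                 str(rec.transcript_length), str(rec.exon_count), str(rec.aa_count)]
            )
    _write_fasta(fasta_path, entries)
    with open(annotation_tsv_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_UTR_ANNOT_COLS)
        w.writerows(rows)


# ---------------------------------------------------------------------------
# packaged table fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureRow:
    """One transcript entry of the packaged human-specific STR tables."""

    gene: str
    transcript_id: str
    variant_no: str
    formulas: tuple[str, ...]
    human_specific_transcript: bool


def load_paper_fixture(which: str) -> list[FixtureRow]:
    """Load the packaged human-specific core-promoter STR table.

    ``which`` is ``"tri"`` (55 transcript entries) or ``"tetra"`` (19).
    Each row carries one or more repeat formula strings in the table grammar
    ``"- 48 (CCA)3"`` plus a flag marking transcripts whose 5'UTR is
    human-specific.
    """
    if which not in ("tri", "tetra"):
        raise ValueError("which must be 'tri' or 'tetra'")
    # imported here to avoid a cycle: str_scan needs types from this module
    from .str_scan import parse_formula

    name = f"table_{which}.tsv"
    rows: list[FixtureRow] = []
    with resources.files("promstr.data").joinpath(name).open() as fh:
        for i, row in enumerate(csv.DictReader(fh, delimiter="\t"), start=2):
            formulas = tuple(f.strip() for f in row["formulas"].split(";"))
            for f in formulas:
                try:
                    parse_formula(f)
                except PromstrError as exc:
                    raise FixtureParseError(
                        f"{name} line {i} ({row['gene']}): bad formula {f!r}: {exc}"
                    ) from exc
            rows.append(
                FixtureRow(
                    gene=row["gene"],
                    transcript_id=row["transcript_id"],
                    variant_no=row["variant_no"],
                    formulas=formulas,
                    human_specific_transcript=row["human_specific_transcript"] == "1",
                )
            )
    return rows


# ---------------------------------------------------------------------------
# panel config (key = value lines)
# ---------------------------------------------------------------------------

def read_panel_config(path: str | Path) -> SpeciesPanel:
    """Parse a key-value panel file: one ``species = group`` line per
    species (ordered) plus an optional ``reference = NAME`` line."""
    species: list[str] = []
    group_of: dict[str, str] = {}
    reference = "human"
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if not value:
            raise ValidationError(f"malformed panel line {raw!r}")
        if key == "reference":
            reference = value
        else:
            species.append(key)
            group_of[key] = value
    return SpeciesPanel(tuple(species), group_of, reference)


def write_panel_config(panel: SpeciesPanel, path: str | Path) -> None:
    lines = [f"reference = {panel.reference_species}"]
    lines += [f"{sp} = {panel.group_of[sp]}" for sp in panel.species]
    Path(path).write_text("\n".join(lines) + "\n")
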