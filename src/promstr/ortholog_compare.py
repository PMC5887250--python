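"""Cross-species human-specificity calls for promoter STR loci.

A human locus is *human-specific* when no non-human species of the panel
carries a matching STR in the orthologous core-promoter window.  Matching
re-uses the same scanner as detection, so the edge rules (window overlap,
phase maximality, perfect repeats only) are identical on both sides.

Species for which no orthologous promoter record is supplied are tracked as
``no_ortholog``: they cannot block human specificity, but reports keep them
distinct from a scanned-and-absent call so that genes which are themselves
human-specific (no ortholog exists at all) remain recognizable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

from .io_model import (
    PromoterRecord,
    SpeciesPanel,
    ValidationError,
    offset_to_linear,
)
from .str_scan import ScanConfig, StrLocus, find_str_loci, rotations

__all__ = ["MatchPolicy", "StrSpecificityCall", "match_str_in_ortholog",
           "classify_str_specificity"]

PRESENT = "present"
ABSENT = "absent"
NO_ORTHOLOG = "no_ortholog"


@dataclass(frozen=True)
class MatchPolicy:
    """What counts as "the same STR" in another species.

    ``motif_match`` is ``"exact"`` (literal string equality, the default) or
    ``"any_rotation"`` (any cyclic rotation of the human motif).
    ``offset_tolerance`` of ``None`` means any position in the core window
    qualifies (``window_only``); an integer k restricts matches to within k
    nt of the human start offset.
    """

    motif_match: str = "exact"
    min_copies_for_presence: int = 3
    offset_tolerance: int | None = None

    def __post_init__(self) -> None:
        if self.motif_match not in ("exact", "any_rotation"):
            raise ValidationError("motif_match must be 'exact' or 'any_rotation'")
        if self.min_copies_for_presence < 2:
            raise ValidationError("min_copies_for_presence must be >= 2")
        if self.offset_tolerance is not None and self.offset_tolerance < 0:
            raise ValidationError("offset_tolerance must be >= 0")


@dataclass(frozen=True)
class StrSpecificityCall:
    """Per-locus verdict with per-species presence/absence evidence."""

    locus: StrLocus
    presence: Mapping[str, str]  # species -> present|absent|no_ortholog
    human_specific: bool
    supporting_groups: frozenset[str]

    def key(self) -> tuple:
        l = self.locus
        return (l.gene, l.transcript_id, l.motif, l.start_offset, l.copies)


def match_str_in_ortholog(
    locus: StrLocus,
    ortholog: PromoterRecord,
    policy: MatchPolicy = MatchPolicy(),
    config: ScanConfig = ScanConfig(),
) -> bool:
    """True when the ortholog window carries a matching STR under the policy."""
    if ortholog.species == locus.species:
        raise ValidationError("ortholog record must be a non-reference species")
    scan_cfg = replace(config, min_copies=min(config.min_copies,
                                              policy.min_copies_for_presence))
    accepted = (
        {locus.motif} if policy.motif_match == "exact" else rotations(locus.motif)
    )
    for cand in find_str_loci(ortholog, scan_cfg):
        if cand.motif not in accepted:
            continue
        if cand.copies < policy.min_copies_for_presence:
            continue
        if policy.offset_tolerance is not None:
            d = abs(offset_to_linear(cand.start_offset)
                    - offset_to_linear(locus.start_offset))
            if d > policy.offset_tolerance:
                continue
        return True
    return False


def classify_str_specificity(
    locus: StrLocus,
    ortholog_set: Iterable[PromoterRecord],
    panel: SpeciesPanel,
    policy: MatchPolicy = MatchPolicy(),
    config: ScanConfig = ScanConfig(),
) -> StrSpecificityCall:
    """Fill presence for every non-reference panel species and call specificity.

    An empty ortholog set yields ``human_specific=True`` with all species
    ``no_ortholog`` (the gene-level human-specificity case).
    """
    by_species: dict[str, PromoterRecord] = {}
    for rec in ortholog_set:
        panel.require(rec.species)
        if rec.species == panel.reference_species:
            raise ValidationError("ortholog set must not contain the reference species")
        if rec.species in by_species:
            raise ValidationError(f"duplicate ortholog record for {rec.species!r}")
        by_species[rec.species] = rec

    presence: dict[str, str] = {}
    for sp in panel.non_reference:
        if sp not in by_species:
            presence[sp] = NO_ORTHOLOG
        elif match_str_in_ortholog(locus, by_species[sp], policy, config):
            presence[sp] = PRESENT
        else:
            presence[sp] = ABSENT
    supporting = frozenset(
        panel.group_of[sp] for sp, v in presence.items() if v == PRESENT
    )
    return StrSpecificityCall(
        locus=locus,
        presence=presence,
        human_specific=not supporting,
        supporting_groups=supporting,
    )
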