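"""Skewing and enrichment statistics for promoter STR compartments.

Three pieces: per-motif frequency tables split by specificity compartment,
Levene's equality-of-variances test (classic mean-centred form) applied to
the two compartments' relative-frequency vectors, and a one-sided Lancaster
mid-p 2x2 enrichment test in which the human-specific compartment (size n)
is compared against round(1.5 n) controls sampled without replacement from
the non-human-specific pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .io_model import ValidationError
from .ortholog_compare import StrSpecificityCall
from .str_scan import StrLocus

__all__ = [
    "MotifFrequencyTable",
    "LeveneResult",
    "EnrichmentResult",
    "motif_frequency_table",
    "levene_test",
    "hypergeom_midp",
    "enrichment_test",
    "round_half_up",
]

HUMAN_SPECIFIC = "human_specific"
NON_HUMAN_SPECIFIC = "non_human_specific"
TOTAL = "total"


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# motif frequency tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifFrequencyTable:
    """Counts of loci per literal motif, split by specificity compartment."""

    unit_length: int
    rows: Mapping[str, tuple[int, int, int]]  # motif -> (total, hs, non_hs)

    def counts(self, compartment: str) -> dict[str, int]:
        idx = {TOTAL: 0, HUMAN_SPECIFIC: 1, NON_HUMAN_SPECIFIC: 2}[compartment]
        return {m: v[idx] for m, v in self.rows.items()}

    def proportions(self, compartment: str) -> dict[str, float]:
        c = self.counts(compartment)
        tot = sum(c.values())
        if tot == 0:
            return {}
        return {m: v / tot for m, v in c.items()}

    def top_motif(self, compartment: str) -> str | None:
        """Modal motif of a compartment; ties broken lexicographically."""
        c = {m: v for m, v in self.counts(compartment).items() if v > 0}
        if not c:
            return None
        return min(c, key=lambda m: (-c[m], m))

    @property
    def n_loci(self) -> int:
        return sum(v[0] for v in self.rows.values())


def motif_frequency_table(
    loci: Sequence[StrLocus],
    calls: Iterable[StrSpecificityCall | bool],
    unit_length: int,
) -> MotifFrequencyTable:
    """Tabulate motif counts for one unit length.

    ``calls`` runs parallel to ``loci``; each element is a
    :class:`StrSpecificityCall` (or bare bool) giving the locus'
    human-specificity.  A missing call is an error.
    """
    calls = list(calls)
    if len(calls) != len(loci):
        raise ValidationError(
            f"{len(loci)} loci but {len(calls)} specificity calls"
        )
    counts: dict[str, list[int]] = {}
    for locus, call in zip(loci, calls):
        if locus.unit_length != unit_length:
            continue
        hs = call.human_specific if isinstance(call, StrSpecificityCall) else bool(call)
        row = counts.setdefault(locus.motif, [0, 0, 0])
        row[0] += 1
        row[1 if hs else 2] += 1
    return MotifFrequencyTable(
        unit_length=unit_length,
        rows={m: tuple(v) for m, v in sorted(counts.items())},
    )


# ---------------------------------------------------------------------------
# Levene's test (classic, mean-centred)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LeveneResult:
    W: float
    df1: int
    df2: int
    p: float
    centering: str = "mean"


def levene_test(groups: Sequence[Sequence[float]]) -> LeveneResult:
    """Classic Levene test with mean centering.

    With Z_ij = |Y_ij - mean_i|,
    W = ((N-k)/(k-1)) * sum_i n_i (Zbar_i - Zbar)^2 / sum_ij (Z_ij - Zbar_i)^2,
    referred to the upper tail of F(k-1, N-k).  Fully degenerate input
    (zero spread both between and within groups) yields W=0, p=1.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValidationError("Levene's test needs at least 2 groups")
    for g in gs:
        if g.size < 2:
            raise ValidationError("each group needs at least 2 observations")
    k = len(gs)
    N = sum(g.size for g in gs)
    Z = [np.abs(g - g.mean()) for g in gs]
    zbar_i = np.array([z.mean() for z in Z])
    zbar = sum(z.sum() for z in Z) / N
    num = sum(z.size * (zi - zbar) ** 2 for z, zi in zip(Z, zbar_i))
    den = sum(((z - zi) ** 2).sum() for z, zi in zip(Z, zbar_i))
    df1, df2 = k - 1, N - k
    if den == 0.0:
        if num == 0.0:
            return LeveneResult(W=0.0, df1=df1, df2=df2, p=1.0)
        return LeveneResult(W=float("inf"), df1=df1, df2=df2, p=0.0)
    W = (df2 / df1) * num / den
    p = float(sps.f.sf(W, df1, df2))
    return LeveneResult(W=float(W), df1=df1, df2=df2, p=p)


# ---------------------------------------------------------------------------
# Lancaster mid-p for 2x2 enrichment
# ---------------------------------------------------------------------------

def hypergeom_midp(a: int, b: int, c: int, d: int,
                   alternative: str = "greater") -> float:
    """One-sided Lancaster mid-p for the 2x2 table [[a, b], [c, d]].

    With X hypergeometric on the table's margins and ``a`` the observed
    top-left cell, returns P(X > a) + 0.5 * P(X = a) — the enrichment
    direction.  Zero margins are rejected.
    """
    if alternative != "greater":
        raise ValidationError("only the one-sided 'greater' alternative is defined")
    if min(a, b, c, d) < 0:
        raise ValidationError("table counts must be non-negative")
    n1, n2 = a + b, c + d
    k1, k2 = a + c, b + d
    if min(n1, n2, k1, k2) == 0:
        raise ValidationError("2x2 table has a zero margin")
    N = a + b + c + d
    dist = sps.hypergeom(N, k1, n1)
    return float(dist.sf(a) + 0.5 * dist.pmf(a))


@dataclass(frozen=True)
class EnrichmentResult:
    """2x2 mid-p enrichment of human-specific transcripts, with control
    sampling metadata."""

    n: int
    control_size: int
    table: tuple[tuple[int, int], tuple[int, int]]
    midp: float
    seed: int
    percent_hs_transcripts: float
    ratio: float = 1.5
    resamples: int = 1


def _is_hs(item) -> bool:
    if isinstance(item, bool) or isinstance(item, (int, np.bool_)):
        return bool(item)
    if isinstance(item, tuple):
        return _is_hs(item[-1])
    return bool(item.human_specific)


def enrichment_test(
    hs_calls: Sequence,
    non_hs_pool: Sequence,
    ratio: float = 1.5,
    seed: int = 0,
    resamples: int = 1,
) -> EnrichmentResult:
    """Mid-p enrichment of human-specific transcripts in the human-specific
    STR compartment versus sampled controls.

    ``hs_calls`` and ``non_hs_pool`` are transcript-specificity calls (or
    (locus, call) pairs, or bare booleans).  round(1.5 n) controls (round
    half-up) are drawn from the pool without replacement using ``seed``.
    With ``resamples`` > 1 the reported mid-p is the median over that many
    independent draws and the table comes from the first draw.
    """
    n = len(hs_calls)
    if n == 0:
        raise ValidationError("empty human-specific compartment")
    control_size = round_half_up(ratio * n)
    if len(non_hs_pool) < control_size:
        raise ValidationError(
            f"control pool has {len(non_hs_pool)} items; "
            f"round({ratio} x {n}) = {control_size} required"
        )
    a = sum(_is_hs(x) for x in hs_calls)
    pool_flags = np.array([_is_hs(x) for x in non_hs_pool])
    rng = np.random.default_rng(seed)
    midps: list[float] = []
    first_table = None
    for _ in range(max(1, resamples)):
        idx = rng.choice(len(pool_flags), size=control_size, replace=False)
        c = int(pool_flags[idx].sum())
        table = ((a, n - a), (c, control_size - c))
        if first_table is None:
            first_table = table
        midps.append(hypergeom_midp(a, n - a, c, control_size - c))
    return EnrichmentResult(
        n=n,
        control_size=control_size,
        table=first_table,
        midp=float(np.median(midps)),
        seed=seed,
        percent_hs_transcripts=100.0 * a / n,
        ratio=ratio,
        resamples=max(1, resamples),
    )
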