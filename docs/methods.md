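# Methods

`promstr` implements a comparative analysis of tri- and tetranucleotide
short tandem repeats (STRs) in human core promoters: which perfect repeats
sit in the window immediately upstream of a transcription start site (TSS),
which of them are unique to the human lineage across a 25-species ortholog
panel, whether the transcripts carrying human-only repeats are themselves
human-specific by 5'UTR sequence identity, and whether the human-specific
repeat compartment is skewed in motif composition and enriched for
human-specific transcripts.

## Coordinates and scanning window

Promoter positions use standard promoter numbering: the TSS base is +1, the
base immediately upstream is −1, and position 0 does not exist.  The core
window is the closed interval [−120, +1], i.e. 121 bases.  A repeat run
belongs to the window when it *overlaps* it — several catalogued repeats
start upstream of −120 and reach into the window, so containment would be
the wrong rule.  Scanning therefore starts `scan_buffer_upstream` (default
30) nt upstream of the window edge so that straddling runs are found with
their true start offsets.

One catalogued tetranucleotide entry, a (GGCT)6 run at −144..−121, lies
wholly upstream of −120 and overlaps no [−120, +1] window under any rule.
The packaged fixture keeps the entry as printed; the table-replica datasets
are scanned with an extended core window (−150..+1) so that every packaged
formula, including this one, is recoverable end to end.

## Repeat detection

A locus is a perfect tandem repeat of a primitive unit (length 3 or 4, not
a power of a shorter string — no homopolymers, no `ATAT`-style units) with
at least `min_copies` (default 3) exact copies.  Detection is exhaustive:
for every start position and unit length, the maximal copy count of the
unit beginning there is computed, and a locus is emitted when the count
reaches the minimum, the unit is primitive, the run is not left-extendable
in its own phase, and the run overlaps the window.  Consequences of the
per-phase rule:

* Distinct rotations of one physical run are reported as separate loci
  (a `G(CCG)3` stretch yields both a GCC-phase and a CCG-phase locus with
  start offsets one base apart), matching how such runs are catalogued.
* Runs of k ≥ 4 copies necessarily contain every rotation at ≥ 3 copies,
  so a single physical run can legitimately yield three phase loci.
* Motifs are literal strings: GGC, GCC and CCG are distinct motif classes,
  and no reverse-complement merging is performed.

Only perfect repeats count; any mismatch, including the ambiguity code N,
terminates a run.  Detection is deterministic; output is sorted by
(start offset, unit length, motif).

## Human-specificity of a repeat

Each human locus is tested against the orthologous promoter window of every
non-human panel species with the *same scanner*, so edge rules are
identical on both sides.  The default match policy is: literal motif
equality, ≥ 3 copies, anywhere in the core window.  Because the source
catalogue does not define its match rule, two relaxations are available as
explicit options: `any_rotation` motif matching, and an offset tolerance in
nt.  A species with no ortholog record is tracked as `no_ortholog`: it
cannot block human specificity, but is kept distinct from a
scanned-and-absent call so that genes that are themselves human-specific
remain recognizable in reports.  A locus is human-specific iff no
non-human species scores `present`; evidence is therefore monotone (adding
records can only remove specificity).

The default panel has 25 species — 5 primates (including the human
reference), 12 non-primate mammals, 5 birds/reptiles, 1 amphibian, 2 fish —
configurable through a key-value panel file.

## Transcript specificity from 5'UTR identity

The TSS-flanking 5'UTR of the human transcript is globally aligned to each
available non-human ortholog UTR (Needleman–Wunsch, linear gap; fixed
scheme +1 match / −1 mismatch / −2 per gap position; ties broken
diagonal > up > left so the reported alignment is deterministic).  Percent
identity is matching columns over all alignment columns, gaps included,
which makes 0% attainable.  A transcript is human-specific when the
*maximum* pairwise identity over species is strictly below the threshold
(default 50%), or when no non-human UTR exists.

The 50% threshold sits where unrelated sequences score: random equal-length
DNA pairs at GC 0.5 align at ≈ 48.5% mean identity (sd ≈ 2.3) under this
scheme, below 55% in ≥ 99% of trials.  The comparison is pairwise-only; a
multiple-alignment score is not computed, since the pairwise maximum is the
deterministic, self-contained criterion and degenerates to the same floor
for fully unrelated sets.  Transcript composition (length differing by
> 20%, exon count, amino-acid count — versus every non-human record) is
reported as a corroborating `composition_divergent` flag and never
overrides the identity rule.

## Statistics

**Motif frequency tables.**  Per unit length, loci are counted by literal
motif and split into human-specific and non-human-specific compartments;
the modal motif per compartment breaks ties lexicographically.

**Skewing (Levene's test).**  The classic mean-centred Levene statistic
W = ((N−k)/(k−1)) · Σ nᵢ(Z̄ᵢ−Z̄)² / ΣΣ(Z_ij−Z̄ᵢ)² with Z_ij = |Y_ij−Ȳᵢ|,
referred to the upper tail of F(k−1, N−k).  Mean centring (not the
Brown–Forsythe median variant) is deliberate and the implementation is
cross-checked against an independent one in the tests.  In the pipeline the
two groups are the compartments' per-motif relative-frequency vectors over
the union of observed motifs — the reading under which compartment skewing
is a two-sample variance comparison; other groupings can be fed to
`levene_test` directly.  Degenerate input (zero spread between and within)
returns W = 0, p = 1.

**Enrichment (Lancaster mid-p).**  The human-specific compartment of size n
is compared against round(1.5 n) controls (round half-up) drawn once,
seeded, without replacement from the non-human-specific pool.  For the 2×2
table with observed top-left cell a and X hypergeometric on the table's
margins, mid-p = P(X > a) + ½·P(X = a), one-sided in the enrichment
direction.  Mid-p is strictly below the ordinary exact p whenever
P(X = a) > 0.  An optional `resamples` parameter reports the median mid-p
over repeated control draws to quantify selection noise.  No chi-square
approximation and no multiple-testing correction are applied.

## Synthetic data

The generator emulates the study's input structure with exact planted
truth.  Defaults are the study conditions: window 151 nt (121-nt core plus
30-nt buffer), GC 0.5, 30% of genes given a human-only STR, 26% of those
genes given a human-specific transcript (0% among shared-STR controls),
copy numbers 3–13, motif weights skewed toward GGC/GGGC, conserved-UTR
identity target 70%, unrelated-UTR identity band 37–48%, UTR length 150 nt.

* **Promoters.**  The chosen motif×copies run is planted at a uniform legal
  offset (placement leaves room for ±1 copy-number jitter and guarantees
  core-window overlap at k−1 copies).  Shared-STR genes replant the run, at
  the same offset with jittered copy number, in a random non-empty species
  subset; human-specific genes get repeat-free non-human windows.  All
  flanks and clean windows are rejection-sampled until a whole-window scan
  finds exactly the planted phases and nothing else, so truth tables are
  exact rather than probabilistic.
* **UTRs.**  Conserved orthologs are substitution-mutated copies of the
  human UTR with the substitution count set in closed form from the
  identity target (valid at high identity, where gapped realignment gain is
  negligible; a calibrated variant, `tuned_copy`, searches the substitution
  count against measured alignment identity for targets near the unrelated
  baseline).  Human-specific transcripts get independent random draws
  resampled until pairwise identity falls inside the unrelated band (~40%
  of draws qualify, so rejection is cheap).  Divergence is substitutions
  only — no indels, no phylogenetic tree, no GC-isochore structure — so
  recovery tests demonstrate correctness of the pipeline's logic, not
  robustness to alignment ambiguity or assembly artefacts in real data.

**Table replicas.**  `build_table_replica` converts the packaged catalogue
tables (55 trinucleotide and 19 tetranucleotide transcript entries, with
the 14 and 5 genes whose transcripts are human-specific) into datasets: one
gene per row, the human promoter synthesized to carry exactly the printed
formula(s) — including rows listing several phases of one physical run —
repeat-free non-human promoters, and UTR divergence planted per the row's
flag.  Running the pipeline on the replicas re-derives 14/55 → 25% and
5/19 → 26%, the gene lists, and the modal human-specific motifs GCC and
CTCC.  Because all replica loci are human-specific by construction, the
control compartment is empty: the enrichment mid-p and Levene stage are
reported as unavailable (with a warning) while the compartment percentages
are still computed.

## Numerical and design notes

* Offsets are validated as zero-free everywhere; conversion to sequence
  indices round-trips exactly and is property-tested.
* Scanning and synthesis are pure-Python over short windows; alignment uses
  a vectorised DP (row-wise running-maximum formulation of the linear-gap
  recurrence) with an O(n+m) traceback recomputed from the score matrix.
* round(1.5 n) uses round-half-up for determinism.
* The phase rule means a scanned window can contain a rotation locus that a
  curated catalogue would not list (e.g. the third rotation inside a
  12-base run); compartment counting is per transcript, so such phases do
  not perturb the headline percentages.
* Problem sizes used in the shipped analyses: 200-gene panels for planted
  recovery, 1,000 simulations for Levene type-I calibration, 200 seeded
  draws for enrichment null behaviour.  In the enrichment null check the
  control pool is exactly round(1.5 n) at the compartment's own
  human-specific fraction — the construction in which both groups have
  identical proportions; with a larger pool at the same proportion,
  sampling noise alone pushes ~10% of draws below mid-p 0.25.

## Known limitations

* Orthology is taken from the annotation; no ortholog inference, liftover,
  or alignment-based promoter homology mapping is performed.
* Only perfect repeats are modelled; interrupted or compound STRs are out
  of scope, as are unit lengths other than those configured.
* The transcript rule is an interpretation: the identity criterion is
  pairwise-max with composition as a flag, because how multiple-alignment
  scores and composition were combined upstream is not specified.
* Genome-wide motif inventories (dozens of motif types over all
  protein-coding promoters) depend on database extractions that are not
  redistributable; the synthetic generator makes no claim of matching that
  unpublished distribution beyond its qualitative GGC/GGGC weighting.
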