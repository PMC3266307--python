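# Methods

## Problem and scope

3'-biased Affymetrix expression arrays report one value per *probe set*
(typically 11 probes of 25 bases). Manufacturer annotations predate current
transcript catalogs, so probe sets nominally querying the same gene can
differ in cross-hybridization, splice-isoform reach and distance from the
transcript 3' end. `probemap` re-annotates probe sets against a user-supplied
cDNA reference and selects one probe set per gene. It does not parse binary
chip files (CDF/CEL), fetch references over the network, or evaluate probe
sets against external expression data.

## Alignment model

Probes are aligned to every transcript by seeded, ungapped local alignment:

- **Scoring**: match +1, mismatch −3 (the BLASTN default pair). Gapped
  alignment is excluded by design: at the tier thresholds below, a gap
  inside a 25-mer cannot produce a competitive block.
- **Seeding**: a (probe, transcript) pair is searched only if the two share
  an exact 8-base word on either strand, mirroring a word size chosen for
  sensitivity. Seeding loses nothing at tier-relevant scores: any block
  scoring ≥ 16 within a 25-mer must contain ≥ 8 consecutive matches.
- **Search**: given a seed, the maximum-scoring block over *all* ungapped
  offsets of both strands is computed (a vectorized per-diagonal maximum
  block scan, followed by an exact prefix-sum pass on the winning
  diagonals). Ties resolve to the smallest transcript start coordinate,
  then the smallest end, then the plus strand; the tests verify exact
  agreement with a brute-force oracle that enumerates offsets and blocks
  independently.
- **Bit scores**: `bits = (λ·raw − ln K) / ln 2` with λ = 1.374 and
  K = 0.711 (Karlin–Altschul parameters for +1/−3 on uniform base
  composition). λ must be specified to three decimals: at 1.37 a perfect
  24-mer falls to 47.9 bits, below the strong threshold, breaking the
  calibration the tiers are defined by. `ScoringParams` refuses parameter
  sets that break the 24↔strong and 16↔moderate correspondences.
- **Tiers**: strong ≥ 48 bits, moderate [32, 48), weak < 32. The upper
  bounds sometimes quoted for 25-mers (51/47) are descriptive, not
  enforced. Weak hits are retained for diagnostics and ignored by scoring.

Both strands are searched because probe files vary in sense/antisense
convention; the matched strand is recorded on every hit. Coordinates are
1-based inclusive on the transcript, ascending regardless of strand.

## Scores

Let the probe set have *n* probes and targeted gene *g* (the gene
specifically detected by the largest number of probes; ties go to the
lexicographically smallest gene id and set `ambiguous_target`).

- **Specificity** `S_s` = (#probes whose specific-gene set is exactly
  {*g*}) / *n*. A probe's specific set is empty whenever any strong or
  moderate alignment touches a second gene — including the case of strong
  alignments to two genes, which disqualify each other. Moderate alignments
  to *other transcripts of g itself* are harmless.
- **Coverage** `S_c` = detected transcripts of *g* / all transcripts of
  *g*, where detection requires strong alignments from a *strict* majority
  of probes (≥ 6 of 11). Isoform abundance is deliberately ignored.
- **Robustness** `S_r = (1 − p)^N`. The processivity requirement of one
  strong hit is `L − t_start + 1`: the inclusive distance from the
  alignment's 5'-most transcript base to the 3' terminus, i.e. the length
  of labeled target IVT must synthesize to cover the probe. The inclusive
  convention changes `S_r` by < 0.2% versus the exclusive one and equals
  the synthesized length, so it is used throughout. `N` is the standard
  median over all strong (probe × transcript-of-*g*) hits — over hits, not
  over per-probe medians — and even-count medians give half-integral `N`,
  used as-is as a real exponent. `p` defaults to 1/600 (U95/U133-class
  design criterion; preset `x3p` uses 1/300). With no strong hit to *g*,
  `N` is undefined and `S_r = 0`.
- **Overall** `S_o = S_s · S_c · S_r`, computed before any rounding; the
  score CSV prints 4 decimals (2-decimal displays elsewhere are
  presentation only).

The survival-product reading of the robustness formula is the only one
consistent with `S_r ∈ [0, 1]` for all `N` and with published component
values (a robustness of 0.64 at p = 1/600 implies N ≈ 268, a plausible 3'
distance; reading it as `1 − p^N` would make every probe set score ≈ 1, and
as `1 − pN` would go negative beyond N = 600).

## Selection

Per gene, the targeting probe set with maximal `S_o` wins. Ties fall back
to higher `S_r` (the component that empirically dominates selection), then
higher `S_s`, then the smallest probe-set id, and are flagged `tie_broken`.
Genes whose best score is 0 are still mapped — no absolute score cutoff is
imposed — and carry the 0 so users can filter. The mapping is a function on
genes and injective on probe sets (a probe set targets one gene).

## Inputs and conventions

Transcript → gene assignment must be supplied explicitly (two-column
table); gene ids are opaque strings, since accession-to-gene conventions
vary. Transcripts missing from the table are dropped with a logged count
rather than treated as an anonymous "other gene": specificity is defined
only over genes, and unassigned accessions would silently destroy it.
Probe ids are synthesized as `probeset:ordinal` (or `probeset:x:y` when
probe-tab X/Y columns exist). BLAST tabular ingest keeps the maximum-bit
row per (probe, transcript) pair and assigns tiers from the file's bit
scores, so externally aligned hits reproduce internal tiers whenever the
bit scores agree to within half a bit.

## Synthetic data generator

`probemap.fixtures` builds toy platforms whose scores are known in closed
form from the construction. Defaults emulate U133-class conditions: 11
probes × 25 bases per set, tiling step 3, p = 1/600, 2–3 isoforms per gene
sharing a 3'-terminal block (a common 3' UTR with alternative 5' starts),
transcripts ~0.8–1.4 kb drawn with uniform base composition (matching the
aligner's Karlin–Altschul calibration), stretched where an archetype needs
room. The five archetypes plant: an ideal 3'-proximal set (probes 100 bases
from the 3' end); a cross-hybridizer whose 20-base sub-block, copied into a
decoy gene, gives exactly 5 of 11 probes a moderate off-target alignment; a
set on a region private to one isoform; a set 3000 bases from the 3' end;
and an orphan of random probes matching nothing.

Expected scores are derived from planted coordinates and the tier rules
alone — never by running the aligner or scorer — so the fixture-recovery
tests are a genuine dual-route check. Two devices make the expectations
exact rather than approximate: the three bases flanking a copied
cross-hybridization block are forced to mismatch every overlapping probe
(so the off-target score equals the planted overlap length exactly: a
blocked extension costs −9 before it can recover at most +6), and any
probe whose 16-mers occur in the transcriptome outside the planted loci
triggers deterministic regeneration. Occurrences *within* the probe's own
gene are allowed anywhere, since only the best hit per (probe, transcript)
pair enters scoring and the planted perfect match always dominates.

What the generator does not emulate: realistic (non-uniform) base
composition and repeat structure, partial-homology families, expression
levels, or sequencing/annotation error. Passing the planted-recovery tests
therefore demonstrates correctness of the scoring pipeline on unambiguous
ground truth, not annotation quality on a real transcriptome.

## Problem sizes and numerics

The default test and acceptance workloads are desk-scale by choice: seven
genes (~19 transcripts, ~30 kb) per fixture, 20 fixture seeds, and 1,000
randomized aligner-vs-oracle instances of 50–2,000 transcript bases (every
tenth instance drawn at the full 2 kb range). Score comparisons against
analytic expectations use an absolute tolerance of 1e−9; component scores
are exact rational arithmetic followed by one floating-point power and
product, so agreement is in practice bit-exact. Medians use the standard
mean-of-central-pair convention. Degenerate inputs are defined explicitly:
`S_r(N = 0) = 1`, empty hit lists give an untargeted probe set with all
scores 0, and a transcript exactly as long as a probe yields processivity
requirement 25.

## Known limitations

- The robustness model assumes one global per-base interruption rate; real
  clinical specimens vary, and whole-transcript (non-3'-biased) assay
  designs violate the model entirely.
- Coverage weights all isoforms equally regardless of abundance.
- The internal aligner reports one best block per (probe, transcript)
  pair; multiple distinct strong sites on the same transcript collapse to
  the best one, which matches how the scores are defined but discards
  positional multiplicity.
- Probe orientation conventions are absorbed by both-strand search; a
  strict single-strand mode would need the original platform convention,
  which is not recorded in probe-tab files.
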