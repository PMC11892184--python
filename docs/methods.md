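# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `invertonkit`. It is written for users who need to judge
what the package's validation on synthetic data does and does not
establish about real metagenomes.

## Coordinates and identifiers

All internal coordinates are 0-based half-open. An inverton is the tuple
`(contig, a, b, c, d)`: left IR `[a, b)`, invertible region `[b, c)`,
right IR `[c, d)`, printed as `<contig>:a-b-c-d`. Printed identifiers
reproduce the numbers given on input; parsing and formatting are exact
inverses. Contig keys are `<strain abbreviation>__<zero-based contig
index>`, with the strain mapping supplied by a manifest table —
`invertonkit` never infers taxonomy from sequence.

External one-based inclusive candidate tables (the convention of classical
IR finders) can be ingested through `read_candidates_tsv(one_based=True)`.

## Inverted-repeat search

`find_inverted_repeats` is a seed-and-extend search: every exact
`min_ir_len`-mer match between the sequence and its reverse complement
seeds an ungapped extension, outward and inward, to the longest prefix of
steps achieving the maximal cumulative score. Since every IR pair of
length ≥ `min_ir_len` whose alignment contains an exact seed word is
seeded, and extension is score-maximal, reported pairs are maximal: they
cannot be extended without score loss. Defaults follow the conventions of
classical IR finders: match +3, mismatch −4, score threshold 50, IR length
10–100 nt, total extent ≤ 750 nt, minimum loop 0. The `gap_penalty` field
exists for interface parity but the built-in extension is ungapped; a
mismatch-tolerant gapped search is out of scope.

Under *exact-match scoring* (a prohibitive mismatch penalty) the output
provably equals the set of maximal exact complementary runs, which is what
the test suite checks against an independent anti-diagonal enumeration
oracle. With the default scoring, candidates may extend a planted IR by
chance-matching flanking bases; the simulator deliberately breaks such
extensions so ground-truth coordinates are exact.

Overlapping candidates on one contig are resolved before indexing: highest
score wins, ties broken leftmost-then-shortest, deterministically.

## Augmented orientation reference

For each candidate the index contains a forward record over
`[a − flank, d + flank)` (default flank 500 nt, clipped at contig edges)
and a reverse record with `[b, c)` reverse-complemented in place, plus
*intervening* records tiling all genome outside candidate cores. Two
invariants are enforced by construction and asserted in tests: the reverse
record's interior is the reverse complement of the forward record's, and
concatenating intervening records with flank-stripped forward records
reconstructs every contig byte for byte. Including the intervening genome
is what lets an aligner see that a read has placements outside the
candidate loci, so that multi-mapping between near-identical strains is
reflected in MAPQ.

## Orientation classification and calling

Alignments with MAPQ < 30 are discarded. A properly oriented
(inward-facing, insert within bounds) pair on an orientation record whose
fragment overlaps the invertible interior *and* straddles an IR junction
votes `Pe` for that record's orientation; a single mate covering a
junction by ≥ 10 nt on both sides (the `junction_overhang`, a package
choice — the geometry is not standardized) votes `Span`. A pair
contributes at most one `Pe` event and its mates at most one `Span` event
each, capped so that total events never exceed the pair's retained
records.

Pooling is declarative over sample metadata: an inverton's pool contains
its own strain's isolate samples plus all community (mouse stool and mixed
in vitro) samples. Calling requires all four pooled counts ≥ 5. There is
deliberately no minor-orientation-frequency floor: an inverton supported
by (1000, 9, 1000, 9) is called, keeping rarely flipped elements; the
slightly stricter spanning threshold (5 rather than 3) compensates.

Only `Pe` counts feed the downstream ratio and contrast statistics;
spanning counts serve calling only.

## IR grouping

Distances are `1 − fractional identity` of a global pairwise alignment
(match 1, mismatch 0, gap open −5, extend −2), strand-aware for DNA by
taking the better of sequence vs reverse complement. Gaps are penalized
heavily on purpose: with mild gap costs the optimal alignment of unrelated
short sequences pads itself with gaps until identity is inflated and all
distances compress toward the middle of the scale. A guide tree is built
by neighbor joining (negative branch lengths clamped to zero) with
midpoint rooting, and cut into the minimal number of clades whose maximum
leaf-to-leaf path length is ≤ T (an average-linkage variant is available
as `mode="avg"`). This pairwise-distance pipeline replaces a full multiple
sequence alignment; it preserves the distance → tree → threshold semantics
while keeping the package free of external binaries, and an MSA-derived
tree can be substituted anywhere a tree is accepted.

The working threshold T = 0.60 groups invertons whose IRs a recombinase
would plausibly cross-recognize. The threshold scan over
T = 0.01…0.99 (step 0.01) reports, per T, the group count and the number
of multi-member groups in which a motif is discoverable, choosing the T
maximizing the latter (ties → larger T). The built-in discoverability
callback — some 6–12-mer or its reverse complement present in ≥ 80% of
members — is a permissive stand-in for zero-or-one-occurrence motif
discovery; because it rewards fine splittings more than an EM-based
discoverer would, its chosen T tends to be small on clean synthetic
families, and any external discovery tool can be swapped in through the
same callback signature. Invertase proteins are grouped by the identical
pipeline on protein identity distances (no strand awareness) at T = 0.8.

Group numbering follows the smallest input index in each group, so
permuting input order relabels but never re-partitions.

## Motif scanning and the promoter test

PWMs are probability matrices with pseudocounts over background base
frequencies (MEME minimal format is read directly). Scanning scores both
strands of every contig with integerized log-odds scores (step = score
range / 1000) and converts scores to exact p-values via dynamic
programming over the discretized score distribution; for short motifs the
DP is verified against enumeration of all 4^L words. The default cutoff
10⁻⁸ suits genome-scale databases. Windows containing N never match.

Each instance's nearest gene is the one at the smallest genomic gap
(0 when overlapping; ties → smaller gene start); placement is upstream or
downstream relative to the gene's 5′→3′ direction. The promoter statistic
is the count of instances upstream of and on the same strand as their
nearest gene (a symmetric downstream mode supports terminator-like
analyses). Three nulls, 10,000 samples each: instance loci re-drawn
uniformly on their own contig (length and strand kept); instance strands
flipped by fair coins; gene strands flipped by fair coins. Coin flips were
chosen over label permutation as the simplest reading of "permuted"
(label-permutation is a one-line change: for strand labels on a large set
the two are nearly indistinguishable). A motif is a putative promoter only
when the observed count strictly exceeds ≥ 99.9% of samples in *every*
null; both the motif and its reverse complement are evaluated and the
orientation aligned with the nearest genes is reported.

The vectorized nearest-gene path used inside the nulls assumes genes on a
contig do not overlap one another; the scalar path has no such
restriction.

## Gene neighborhoods and enrichment

Genes within ±5 kb of an inverton's outer IR bounds are classified
exactly once per (gene, inverton): `intersecting` when overlapping
`[a, d)`; otherwise `regulatable` when the gene's 5′ end faces the
inverton and every gene between it and the inverton faces it too (an
unbroken read-through chain that an inverton-embedded promoter could
drive); otherwise `non_regulatable`. The chain is evaluated outward on
each side and breaks permanently at the first opposed gene.

Enrichment builds one 2×2 table per (annotation, inverton group,
proximity type) — gene in family vs not, against proximal in that stratum
vs not, over the universe of all genes — with a gene near several group
members counted once (avoiding pseudo-replication). Fisher's exact test
(two-sided) is used throughout, with Bonferroni correction over all tables
evaluated in one analysis call; annotations are evaluated in a stratum
when they have at least one proximal member, which does not change any
p-value, only the reported family. Odds ratios use the sample estimate
`ad/bc` with `inf`/`0`/`NaN` conventions for empty margins.

Invertase candidates are genes whose annotation mentions "invertase",
"integrase" or "recombinase" (case-insensitive). Inverton-group ↔
invertase-group links count an inverton as proximal to an invertase group
when any member invertase intersects it or lies within ±5 kb; one Fisher
table per group pair over the inverton universe.

## Condition contrasts, time, and regulation predictions

A condition contrast pools `Pe_F`/`Pe_R` per inverton over each
condition's samples and tests `[[F_A, R_A], [F_B, R_B]]` with Fisher's
exact test, Bonferroni-corrected over the invertons tested (those with
nonzero totals in both conditions). The reported direction is the
orientation whose frequency is higher in condition 1.

Longitudinal analysis evaluates every early/late split of k ordered
timepoints (k − 1 splits) and flags an inverton as time-dependent when any
split is significant. Because the any-split rule multiplies opportunities
for a false flag, the Bonferroni family spans all (inverton × split)
tests in the call — more conservative than correcting each split
separately, and necessary for the family-wise error to stay at the nominal
5% when few invertons are tested. Carrier-attached and supernatant
cultures are analyzed independently via the `sample_types` filter, and
per-timepoint inversion ratios are emitted for trend inspection.

Regulation predictions require a directionally biased inverton, a
putative-promoter instance strictly inside `[b, c)` — only the interior
flips, so instances overlapping an IR are excluded — and a regulatable
gene. On the reference orientation the promoter strand either already
points at the gene (prediction: up in the forward-enriched condition) or
points away so flipping aims it (up in the reverse-enriched condition);
all genes of one read-through chain share the prediction. Family-level
enrichment of predictions is per (annotation, predicted-up condition), so
a family can be enriched for up- and downregulation simultaneously.

## Synthetic data: what it emulates and what it does not

The simulator manufactures the study's input regime at desk scale: random
genomes (≥ 1 kb, configurable GC) with invertons planted as
`IR · payload · revcomp(IR)` at exact coordinates; related strains derived
by independent per-site substitution (e.g. 1% divergence ≈ 99% ANI), with
the option of preserving an inverton neighborhood bitwise — the hard case
for read assignment; and paired-end fragments whose orientation is drawn
reverse with probability ρ whenever the fragment overlaps a planted
invertible region, logged to a truth table. Read length 100 nt, insert
300 ± 30 nt, error-free by default (uniform substitutions up to 5%
available).

The bundled mapper places mates at every exact-match position, enumerates
concordant placements, and assigns MAPQ 42 to uniquely placed pairs and 0
otherwise, reporting one placement drawn from the seeded generator (as
aligners break ties). It is test-scoped by design: transparent MAPQ
semantics, no tolerance for sequencing error. Production data must be
aligned with a real short-read aligner against the index FASTA and fed in
as SAM/BAM.

Consequently, passing tests demonstrate correctness of the counting,
calling and statistical machinery and the *logic* of MAPQ-based mismap
suppression — not robustness to indels, structural variation, coverage
bias, chimeric fragments, or aligner-specific MAPQ calibration, none of
which the generator models.

## Problem sizes and numerical choices

Validation runs use genomes of 15–30 kb per strain, planted IRs of
10–40 nt with payloads around 300 nt, read depths of a few hundred to a
few thousand pairs per locus (≥ 2,000 informative pairs where ratio
recovery is asserted within the 99% binomial interval), 10–20 replicate
seeds for benchmark rates, and 10,000-sample permutation nulls. These
sizes make the whole suite run in well under a minute per module while
leaving every statistical check properly powered.

Numerical conventions collected in one place: undefined ratios are NaN,
never 0; the PWM score discretization is 1/1000 of the score range;
Fisher two-sided p sums hypergeometric probabilities ≤ the observed
table's; Bonferroni is `min(1, p·m)` at α = 0.05; NJ branch lengths are
clamped at 0; zero-diameter trees skip midpoint rooting; all RNG flows
through `numpy.random.Generator` seeds, and every simulation entry point
is reproducible given its seed.

## Known limitations

* Discarding MAPQ < 30 is conservative: invertons inside genuinely
  homologous regions shared by community members are undetectable, and
  this worsens as the database grows. Probabilistic read reassignment is
  the natural extension.
* The exact mapper cannot tolerate sequencing errors; error-bearing
  simulations require an external aligner.
* Pairwise-distance NJ approximates an MSA guide tree; for IR families
  with heavy indel structure the distances coarsen.
* The shared-kmer motif callback overstates discoverability on
  low-divergence groups relative to EM-based discovery, biasing the
  threshold scan toward small T on clean synthetic input.
* Annotation strings are opaque labels; no ontology mapping is attempted.
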