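# Methods

## Problem setting

A market sample of processed root material carries no morphological
characters, so identification rests entirely on matching one or more
barcode sequences (*rpoC1*, *psbA-trnH*, ITS) against a regional
reference database keyed to a taxonomy table (species, genus, family,
major clade, regional occurrence, endemism). Three features of real
surveys shape every design choice here: the reference material is
sequenced from different populations than the queries, so conspecific
reference–query pairs differ by a nonzero intraspecific offset; not
every candidate species has a reference sequence; and the putative name
attached to a sample (derived from its vernacular name via a
pharmacopoeia) may simply be wrong (adulteration).

## Alignment layer

All methods consume semi-global pairwise alignments (Needleman–Wunsch
with free terminal gaps), scored +1/−1 with affine gaps (−2 first
residue, −1 per additional). Terminal gaps are free because trimmed
amplicons of one locus legitimately differ in length; penalizing
overhangs would conflate length with divergence.

* **identity** = 100 × matches / aligned columns, excluding columns under
  a terminal gap in either row; internal gap columns count as mismatches
  (conservative, BLAST-like).
* **coverage** = aligned span of the *shorter* sequence / its length.
  One-sided coverage avoids double-penalizing short queries against
  full-length references.
* **p-distance** = 1 − identity/100; it feeds neighbor joining directly,
  uncorrected, because only tree *shape* near the tips matters for the
  clade rules, not clock-consistent depths.

Dynamic programming is delegated to Biopython's `PairwiseAligner`; the
test suite checks its scores against an independent quadratic Gotoh
implementation. Traceback ties are resolved by the aligner's
deterministic first-alignment order (a deliberate simplification over
prescribing a custom tie-break: scores and therefore identities of
co-optimal tracebacks differ only in rare gap-placement cases, and
determinism is what matters downstream). Each unordered pair is aligned
once, in lexicographic order, making identity exactly symmetric.

## Similarity method

Parameters: `min_identity_species` (default 99%), `min_identity_genus`
(95%), `min_coverage` (0.9), `tie_margin` (0.5 points of identity),
`apply_region_filter` (on). The thresholds are *configuration, not
measurements*: the original manual workflow made these calls by eye, and
the defaults are chosen to separate the generator's intraspecific
(0.002) and interspecific (0.02) divergence scales. E-values are not
emulated — they are database-size dependent, and the decisive quantities
are maximum identity and the composition of the near-tied candidate set.
If the region filter would empty the candidate set entirely, the
distribution datum is treated as uninformative and ignored rather than
returning no identification.

## Clustering method

Single-linkage clustering at marker-specific identity thresholds
(*rpoC1* 100%, non-coding 98%, both inclusive) with 90% coverage,
implemented as connected components (networkx) of the neighbor graph.
"Similarity" is this package's percent identity, not Blastclust's
bit-score density — a declared divergence. The slow coding locus needs
exact matching because congeners are frequently identical there; the
threshold choice survey from the original workflow is replaced by a
histogram utility (`identity_histogram`) with no decision logic.
Threshold comparisons being inclusive is a choice the source material
leaves open. Lowering a threshold can only merge clusters; the suite
tests this refinement monotonicity and order-independence.

## Tree method

Neighbor joining (scikit-bio) over p-distance matrices; negative
estimated branch lengths are clamped to zero (scikit-bio's behavior —
without transferring the deficit to the adjacent branch, which would be
an alternative convention; no downstream rule is sensitive to this).
Midpoint rooting by default — deterministic and outgroup-free;
outgroup rooting is available when outgroup tips are supplied, and
externally built phylograms can be imported as newick (branch lengths
required). Bootstrap is omitted because support values play no role in
the assignment rules.

Assignment rules, evaluated in order for each query tip (other query
tips carry no taxonomy and are ignored in uniformity checks):

1. *Identical-sequence exception*: a reference at patristic distance
   ≤ 1e−8 whose smallest shared clade with the query contains references
   of only that species → species. Identity is judged on the tree, not
   the sequences (the rule is about clade structure); a warning is
   logged if the sequences actually differ. If the query is
   tree-identical to references of several species (possible at
   *rpoC1*), the exception does not fire and the walk falls through to
   the clade rules — a declared choice where the source rule is silent.
2. *Species rule*: some ancestor of the query subtends references of
   exactly one species, at least two of them, and the query's parent is
   a strict descendant of that ancestor (one node in — being sister to a
   species clade is not enough). Requiring ≥2 reference tips makes a
   single-reference cherry the excluded "sister" case.
3. *Genus, then family rule*: same structural condition with ≥1
   reference tip; the weaker tip requirement reflects that the one-node-in
   wording imposes no minimum.

The rules are verified against an enumeration oracle that evaluates them
on clades-as-tip-sets over every rooted binary topology of {query + 3
references} × 3 taxonomy scenarios × unit/zero branch lengths.

## Consensus and concordance

Verdicts are combined by a deterministic cascade: drop empty verdicts;
optionally drop verdicts that contradict a species-level verdict when
the contradicting marker's reference database lacks that species (it
never had a chance to find it; if two species verdicts each fail the
other's presence check, method precedence — similarity, tree, cluster —
decides which survives); resolve nested lineages to the most specific
rank; otherwise fall upward to the lowest shared rank (genus, family);
otherwise report a conflict. The cascade is idempotent.

Concordance classes compare the final identification to the putative
name list at the final call's rank; multi-candidate putative lists match
if any candidate matches; subspecies compare equal to their species
(names are canonicalized case-insensitively with author strings and
infraspecific epithets dropped). The misidentification percentage counts
different-genus plus different-family samples over all analyzed samples,
rounded to the nearest integer.

The packaged 83-row market table stores the printed concordance label of
each sample as authoritative: tallies never re-derive labels. A shipped
skip-list names the rows whose printed label cannot be re-derived
mechanically (genus-rank putatives labeled species-confirmed,
two-candidate finals, epithet changes absorbed as subspecies, and two
internally inconsistent rows); the classifier cross-check runs only on
the remaining rows.

## Synthetic data generator

The generator emulates the survey situation, not any particular dataset:

* **Species tree** — fixed family/genus backbone with a random
  coalescent-style crown per genus, rescaled so the mean congeneric
  tip-pair divergence equals `interspecific_depth` (0.02 subs/site at
  reference rate). Genus splits sit at 4× and family splits at 8× that
  divergence; a "fungal" outgroup lineage for ITS contamination sits at
  1.5 subs/site total. These backbone factors are generator constants
  chosen to keep the rank levels cleanly separated.
* **Substitutions** — Jukes–Cantor only; the identification rules
  consume distances, so model richness buys nothing here. Marker rates
  default to 0.3 (*rpoC1*), 1.0 (*psbA-trnH*), 2.0 (ITS), reproducing
  the slow-coding/fast-ITS ordering. Marker lengths are drawn once per
  marker from the empirical amplicon ranges (409–545, 141–658, 194–748
  bp).
* **Populations** — each species gets two population variants separated
  by `intraspecific_depth` (default 0.002); the reference database takes
  population 0, queries population 1, so conspecific reference–query
  pairs are never identical unless the offset is zero.
* **Indels and homopolymers** — non-coding markers receive geometric
  (mean 2) indels at rate 0.001/site plus one A/T homopolymer (length
  10), never within 20 bp of an end. Both are applied at the species
  level, before the population split: applied per individual sequence
  they would be non-homologous between reference and query and would
  swamp the intraspecific signal with alignment-gap mismatches, which is
  not what locus-specific indel difficulty looks like in real data.
* **Degradation** — per-marker dropout, ITS polymorphism discards and
  fungal-contamination swaps are off by default (the clean baseline
  scenario); `market_scenario()` provides magnitudes typical of dried
  root material (12/25/30% dropout, 35% polymorphism, 11%
  contamination). Adulteration (10% of samples get a putative name from
  a different genus) affects only the name comparison, never the
  sequences.
* **Determinism** — every sub-stage derives its RNG from `seed`; writers
  emit records in fixed order, so identical seeds give byte-identical
  files.

What passing tests on this generator do *not* show: robustness to
alignment error in genuinely hard-to-align loci (indels here are mild),
to chimeric or low-quality reads, to paralogy within the plant genome,
or to rate variation across lineages — the generator's clock is strict
and its families are exchangeable. Real surveys will sit below the
simulated recovery rates.

## Problem sizes and tolerances

Default study: 30 species (5 families × 2 genera × 3 species), 60
queries, three markers — small enough that all-pairs exact alignment
replaces heuristic search (a few thousand cached alignments per marker).
The parameter-recovery check demands ≥90% species-correct consensus on
the clean scenario and non-increasing accuracy as the population offset
rises 0 → 0.002 → 0.02; observed values are 97–100% and a collapse to
roughly 45–80% at the congeneric offset, across seeds. Numerical
comparisons in tests use exact equality where the computation is exact
(filters, tallies, partitions, additive-matrix recovery) and
Monte-Carlo-derived bounds (3–4 standard errors) for simulated
divergences.

## Known limitations

* Identity-based clustering inherits Blastclust's fragility: no single
  threshold fits lineages with heterogeneous rates, and query-only or
  mixed clusters yield no identification. This is faithful to the
  method, not a defect to fix.
* The tree method with singleton reference sampling can only reach
  species rank through the identical-sequence exception; with two
  populations per reference species it recovers species directly (tested).
* The consensus cascade is a codification of a genuinely manual
  procedure; it reproduces the mechanism (rank resolution plus
  reference-presence discounting), not any particular study's
  case-by-case judgments.
* `matK` is out of scope entirely, mirroring its exclusion for
  amplification failure in the motivating survey.
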