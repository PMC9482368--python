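# Methods

## Problem setting

Teleost visual opsins fall into five classes — RH1 (rod), and the cone
classes RH2, SWS1, SWS2 and LWS — and within a class a genome may carry
several paralogs of ~1.0–1.1 kb coding sequence at 80–99% pairwise
identity. With 150 bp paired-end reads, a read from one paralog often
aligns to its siblings within ordinary mapper tolerances; expression
estimates then leak between copies, and de novo assembly of the family is
prone to chimeras. The pipeline treats this as a *competitive assignment*
problem: derive, per gene, the largest read divergence that is still
unambiguous given the family's similarity structure, and discard any pair
that satisfies more than one gene.

## Pairwise identity and mismatch thresholds

Identity is computed from a global (end-to-end) alignment under a fixed
scheme: match +1, mismatch −1, gap open/extend −2/−2 (Bio.Align
PairwiseAligner). Identity = matched columns / all aligned columns × 100;
gap columns count as non-matches, and `N` never matches. Fixing the scheme
makes identity values — and everything derived from them — reproducible.

For gene *g* with at least one paralog,

    threshold(g) = min over p≠g of (100 − identity(g, p)) − 1   [pp, clamped at 0]

A read pair whose divergence from *g* is at or below `threshold(g)` cannot
have come error-free from any other family member, because every other
member is at least one point more divergent. A solo gene has no competitor;
it receives a configurable default (10%), sized to tolerate intra-species
polymorphism plus sequencing error.

Two related choices deserve note:

* **Threshold comparisons use alignment divergence** (mismatch *plus* gap
  columns), not the mismatch share alone. Edit-distance aligners will
  otherwise trade a run of substitutions for a short gap and slip a
  paralog read under the ceiling; divergence is also exactly the quantity
  the thresholds were derived from, so the comparison is like-for-like.
* **The counting unit is the read pair**: both mates must individually
  satisfy a gene's threshold before the pair is credited, and a pair
  satisfying two or more genes is discarded outright (counted in
  `discarded_multi`) rather than fractionally split.

## Tolerant mapping

Read recruitment for extraction runs at deliberately permissive ceilings:
maximum mismatches per read 40%, maximum gapped columns 15%, maximum
single gap 50 bp, seeds found as exact 12-mers verified out to 14 bp, and
both mates of a pair must map. These settings are meant to capture reads
from *every* paralog of a family against a single published reference;
specificity is restored later by SNP partitioning and by the competitive
thresholds. Alignment extension is semi-global via edlib (the read
contained in the reference); coordinates are 0-based half-open and FASTQ
is assumed Phred+33 throughout.

## SNP-consistent partitioning

Mapping a whole family's reads onto one reference produces a pile-up in
which paralogs appear as ladders of linked SNPs. The pipeline formalises
the manual practice of following those linked variants: a variant site is
*called* where a non-reference allele is supported by at least
max(2, 5% of coverage) reads; a read pair stays in the reference gene's
pile only if it carries the reference allele at every called site it
covers. Sporadic sequencing errors sit below the calling floor and do not
eject a pair. If no pair is fully consistent (e.g. the sample's allele of
the gene is uniformly diverged from the published reference), all pairs
are kept and the majority consensus absorbs the divergence. An earlier
design linked pairs into connected components by shared alleles; it was
abandoned because a single spurious link (an alignment-slip allele) merges
entire piles transitively.

## Consensus and cyclic extension

The consensus is per-column majority over covering reads; zero-coverage
columns emit `N` (uncovered runs at the ends are trimmed); count ties
resolve deterministically to the highest base under the fixed order
A<C<G<T. No coverage floor beyond ≥1 read is imposed.

Extension then cycles: reads matching the current consensus exactly over
≥20 bp of overlap (consensus `N` matches anything) are placed; mates of
placed reads are recruited at a relaxed ≥10 bp overlap to bridge interior
gaps — a mate lying wholly beyond the current contig has no sequence
anchor and is picked up on a later cycle once the contig has grown.
Overhangs extend both ends by column majority; an extension column whose
top count is tied between two bases is treated as ambiguous and extension
halts there (flagged on the result). The cycle terminates when the
consensus contains an in-frame ATG→stop ORF within ±9 bp (three codons of
indel polymorphism) of the reference model's length, when an iteration
adds nothing, or after `max_iterations` (default 30 — a 1.1 kb gene grows
~130 bp per end per cycle, so convergence takes far fewer). Reads placed
directly in an extension cycle have, by construction, zero mismatches to
the consensus; consensus length never decreases across cycles.

## Classification

Tree-based confirmation is replaced by a deterministic nearest-reference
rule: the query takes the class of its highest-identity reference, with
the identity gap to the best reference of any other class reported as a
margin. Queries below a 60% identity floor (teleost opsins within a class
typically exceed this) are flagged unclassified. Ties resolve by panel
order.

## Proportional expression

Counts are length-normalised to per-base rates, r(g) = pairs(g)/length(g),
the minimal reading of gene-length adjustment (any constant rescaling,
TPM-style, cancels in the ratios). Reported quantities: rod share
r(rh1-class genes)/Σr; per-gene shares within the single-cone set
(SWS1+SWS2) and the double-cone set (RH2+LWS). A cone category with zero
total is reported as absent rather than divided by zero. Tabular output
rounds to one decimal; full precision is kept internally.

## DEG stage

Significance is adjusted P ≤ 0.05 *inclusive*; rows with missing adjusted
P are dropped. Direction uses the strict sign of the log fold change —
exact zeros belong to neither direction and are excluded with a warning.
Summaries report per-direction counts, percentages of all DEGs (one
decimal), and the top N (default 15) by absolute log fold change with ties
broken by transcript id.

Overrepresentation: for each term, a one-sided Fisher's exact test
(alternative "greater") on the 2×2 study/term table; Benjamini–Hochberg
FDR across tested terms; results filtered to FDR strictly < 0.05 and fold
enrichment ≥ 6 inclusive, fold enrichment being
(study_count/study_size)/(pop_count/pop_size). The test universe defaults
to terms with at least one study gene (configurable to all annotated
terms); terms absent from the population are skipped (undefined ratio).
Terms are flat labels — no ontology-graph propagation. Genes lacking
annotation count toward the population size only.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the targeted setting: one random valid CDS (ATG
start, no internal in-frame stop, terminal stop) of 1,065 bp by default;
paralogs derived by substitutions at a rate set by the target identity;
150 bp paired reads with ~350±30 bp inserts at multinomial per-gene
proportions; independent per-base substitution errors (default 0.1%);
constant Q37 qualities (no stage consumes qualities).

Three deliberate modelling choices:

* **Stratified substitution placement.** Paralog substitutions are drawn
  one per equal-width stratum along the gene, so every read-length window
  diverges at close to the family-wide rate. Thresholds are derived from
  *global* identity; they separate paralogs only where local divergence
  tracks it. Real paralogs are patchier — conserved blocks can locally
  fall under any global threshold, which is precisely why reads there are
  discarded as multi-mapping rather than guessed.
* **Boundary-clipped fragments.** Fragment windows are sampled from a
  range extending one insert-minus-read beyond each CDS end and clipped at
  the boundaries, giving uniform coverage across the whole gene including
  its terminal bases (real cDNA fragments run into the UTRs and achieve
  the same). Sampling strictly inside the CDS would cover the first and
  last base only with probability ~1/700 per fragment, making exact
  end-recovery a coin flip at realistic depth.
* **Substitution-only errors.** Keeps read mismatch percentages directly
  comparable to the divergence thresholds; indels are not simulated.

Consequently, passing tests demonstrate correctness of the *assignment and
reconstruction logic* under idealised Illumina-like conditions; they do
not establish robustness to indel errors, coverage bias, patchy paralog
divergence, splice variants or UTR sequence, all of which real data
contain.

The DE-table generator plants an exact number of significant rows
(adjusted P drawn in (0, 0.05]) with a set up-regulated fraction (rounded
half-away-from-zero) and leaves the rest above 0.05, providing exact truth
for the filter/split/summarise stage. It does not model count
distributions or P-value/effect-size correlation.

## Problem sizes and numerical notes

Default validation runs use families of 2–3 genes of 1,065 bp, 2,000–20,000
read pairs, and exhaustive Fisher checks over all 2×2 tables with totals
up to 50 (~315,000 tables) — sizes chosen so the full suite and the
acceptance script each complete in about a minute on one CPU while leaving
every statistical check well-powered. All randomness flows from explicit
integer seeds through `numpy.random.default_rng`; reruns are byte-identical.

## Known limitations

* Extraction assumes the target's true sequence is reachable from the
  panel reference by substitution-dominated divergence; structurally
  rearranged or heavily indel-diverged genes may stall as partial contigs.
* Competitive assignment discards reads from regions where paralogs are
  locally near-identical; strongly conserved blocks therefore reduce
  effective depth rather than bias proportions.
* The classifier is nucleotide-level and margin-based; it does not replace
  phylogenetic analysis when reference panels are sparse or classes are
  close.
* Enrichment treats annotation as flat labels; parent-term effects that
  ontology propagation would surface are invisible.
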