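# Methods

## Problem setting

A somatic mutation near an exon/intron boundary can create or strengthen a
cryptic splice donor or acceptor. The evidence for such a splice-site-
creating mutation (SCM) is transcriptomic: spliced RNA-seq reads whose
`N` CIGAR operation delineates an intron that is not in the annotation,
appearing in the mutated sample but not in comparable samples without the
mutation. `scmfinder` formalizes that evidence chain as a per-mutation
pipeline; this note records the model, the conventions, and the design
choices that were genuinely open.

## Coordinates and distances

Internally all intervals are 0-based half-open; MAF-style 1-based positions
are converted at the I/O boundary. An intron is `(chrom, start, end)` with
`start` the first intronic base — a CIGAR `N` span maps onto it directly.

The ±20 bp discovery window is anchored on the mutation and measured to the
**nearer** junction boundary. A junction has two ends and the convention for
"distance" to a boundary point is not unique; we measure from the mutation
base to the reference base immediately 5′ of each splice point (the last
exonic base for the start boundary, the last intronic base for the end
boundary) and take the minimum. The 20 bp cutoff is the farthest position
from a splice junction that is conventionally counted as splice region, and
the boundary is exact: distance 20 is in, 21 is out.

## Discovery and counting rules

- Support is counted in **distinct fragments**: mate pairs share a query
  name and are counted once even when both mates span the junction.
  "Unique reads" is thereby interpreted at the fragment level.
- Secondary, supplementary, unmapped and (by default, configurable)
  duplicate-marked records never count; mapping quality must be ≥ 20.
- A candidate needs ≥ 5 supporting fragments. Both thresholds are exact
  boundaries (5 in, 4 out; Q20 in, Q19 out).
- Candidates equal to an annotated intron (exact `(chrom, start, end)`
  match, strand ignored) are canonical and removed. Candidates overlapping
  HLA loci are removed; HLA loci are identified by the `HLA-` gene-symbol
  prefix in the annotation, a deliberate convention since no locus list is
  prescribed — it is visible in `io.HLA_GENE_PREFIX`.
- Each survivor is annotated with its nearest canonical intron, preferring
  a same-gene intron sharing one boundary (the cryptic donor/acceptor
  geometry where only one end moved), else nearest by boundary distance.

## Junction allele fraction

JAF = junction-spanning fragments / fragments at "the locus". The locus
needs a concrete definition; we anchor at the exonic base immediately
adjacent to the created boundary (the boundary nearer the mutation) and
count deduplicated fragments with an aligned base *or* an `N` skip across
that anchor. This makes JAF a local exon-inclusion fraction: contiguous
reads, canonical-junction reads, and alternative-junction reads all
contribute to the denominator. Events with JAF < 0.05 are filtered
(exact boundary; threshold configurable).

The spliced-in JAF — among junction fragments, the fraction carrying the
mutant allele — is computed for splice-in SNVs by reading the aligned base
at the mutation position. When no junction fragment reaches the mutation
(distance beyond the fragment span) the quantity is reported as undefined
rather than zero, because the fragment geometry, not biology, forbids the
observation. Non-SNV alleles are not read off single bases and are likewise
reported undefined.

Splice-in vs splice-out is a half-open containment test: a mutation at the
first intronic base of the new intron is splice-out, at the last exonic base
or the first base after the intron is splice-in.

## Control cohort

For each junction, supporting fragments are counted in every control sample
with the same dedup/mapping-quality rules as the case. Controls are cohort
samples lacking a mutation in the gene of interest (gene-level exclusion;
site-level exclusion is available via `control_scope="site"` since the
eligibility wording admits both readings — gene level is the stricter
default).

Thresholds are **nearest-rank empirical quantiles without interpolation**:
the order statistic at 0-based index `floor(q·n)`, clamped to the last
element (the smallest value whose rank exceeds `q·n`). Control counts are
small integers; interpolation would fabricate thresholds no sample shows.
For `[0×18, 3, 9]` this gives q05 = 0 and q95 = 9.

The case must **strictly exceed** q95. With heavily zero-inflated control
distributions a ≥ test would admit cases indistinguishable from controls.
When every control count is zero the percentile is degenerate and the test
reduces to case support ≥ the discovery minimum (5): a junction never seen
in any control and well-supported in the case is the strongest pattern the
filter can produce. The same thresholds give the per-sample expression
verdict: `no_expression` when q05 = q95 = 0 and the count is 0, `high`
above q95, `low` below q05, else `average`.

## Splice-site scoring

Donor sites are scored on 9-mers (3 exonic + 6 intronic bases), acceptors
on 23-mers (20 intronic + 3 exonic). A model factorizes the k-mer
probability into the intronic consensus dinucleotide (donor +1/+2, acceptor
−2/−1), scored by consensus frequencies, and a signed product of
probability tables over sub-windows of the remaining positions; the score is
`log2(P_model / P_background)` in bits. This factorized-table form covers
both a single full joint table and overlapping sub-model ratios, which is
the shape of the established maximum-entropy splice models; the model file
format is plain text (one block per table) so miniature models can be built
programmatically and published tables converted offline. Which published
sub-model variant to mirror is left to the model file — the scoring engine
is agnostic.

Numerical choices: a pseudocount (default 1e−6) is added to both the model
and background side of every ratio, so all scores are finite and a model
identical to its background scores exactly 0.0 bits. Each table's
distribution must sum to 1 within 1e−9 and every non-consensus position must
be covered with net multiplicity one; `SpliceModel.validate()` enforces
both. k-mers containing non-ACGT bases are unscoreable.

Mutant k-mers are built by substituting the alternate allele into the
footprint; an indel overlapping a footprint marks the site unscoreable
rather than scoring shifted sequence, because the k-mer model is defined
for single-base events. A mutation outside a site's footprint leaves that
site's mutant score equal to its reference score.

Comparison of the created site against its nearest canonical site yields a
trichotomy on post-mutation scores: `alt_stronger` (mutant alternative >
mutant canonical), `gap_narrowed` (not stronger, but the alternative−
canonical margin increased after mutation), else `no_evidence`. Acceptor
−3 events with AG at −2/−1 are additionally classified by the reference
repeat context around the mutated base (`aGag`, `agGag`, other) and the
substitution is labeled as transition or transversion.

## Review and aggregation

Junction-level evidence review is rule-based: `Complex` when more than one
alternative product survives all filters for a mutation, `Pass` when
exactly one does, `NoSupport` otherwise. Visual IGV-style review cannot be
automated faithfully; the rules capture its published categories, and every
filtered candidate keeps its first-failing-filter reason in the audit
trail, so each input mutation appears exactly once in calls ∪ audit.
An optional homology flag marks junctions whose supporting fragments are
dominated by sub-Q50 mapping qualities (off by default; such regions
warrant inspection rather than silent exclusion).

Aggregation reports per-gene Pass counts, the conventional-annotation
breakdown, clusters of mutations within ±5 bp creating the identical
alternative intron, and an optional gene × cancer-type matrix taken from a
sample-metadata table (never inferred).

## Neoepitopes

The alternative intron supersedes whatever canonical splicing covered its
span in the transcript model (handled symmetrically, so both intron-
lengthening and intron-shortening events work), the CDS is re-spliced, the
mutation substituted when exonic, and translation runs from the CDS start
to the first stop — no readthrough, frameshifts yield novel C-termini,
frame-preserving donor shifts yield in-frame deletions. Candidate
neoepitopes are all 8–11-mer windows of the mutant protein that are not
substrings of the wild-type protein *of the same transcript* (proteome-wide
exclusion is out of scope). Binding affinity is consumed from a
precomputed table keyed by (peptide, HLA allele); a peptide is kept when
its best affinity is ≤ 500 nM, and peptides absent from the table are kept
with unknown affinity so an incomplete prediction run never silently drops
candidates.

## Synthetic worlds

The simulator is first-class code and defines the study conditions the
tests measure under. A world is a plus-strand mini-genome of three-exon
genes (exons 300/240/300 bp, introns 120/130 bp, canonical GT/AG forced at
every junction) carrying four event geometries:

- `donor_exonic` — a pre-existing exonic GT 12 bp upstream of the canonical
  donor; the mutation strengthens the exonic donor context (CTG→CAG two
  bases before the splice point). Splice-in.
- `acceptor_minus3` — reference `a,G,a,g` across alternative-acceptor
  −4..−1 with a G>C at −3 that destroys the canonical AG and activates the
  acceptor exactly 2 nt downstream. Splice-out.
- `donor_intronic` — a cryptic GT 9 bp upstream of the canonical donor with
  the mutation at the new intron's +3 position. Splice-out.
- `inframe_del` — a cryptic donor 30 bp upstream in a coding gene whose CDS
  is laid out in frame with the shift; the mutation is a genuinely silent
  third-codon-position change (CTG→CTA), and the event deletes exactly 10
  amino acids with intact flanks. Splice-in.

Defaults are the conditions the pipeline is specified for: junction-locus
depth 100, JAF 0.5, 10 mutation-free controls at half depth, and zero
control contamination; decoy genes carry mutations with no splicing effect,
including one per gene placed 10 bp before a canonical donor to exercise
the annotation filter. Reads are 100 bp paired-end (fragment 250 bp),
error-free by default — discovery is CIGAR-driven, so base noise only
matters for allele-aware quantities, and an optional substitution-error
rate exposes those. Read 1 of every fragment covers the locus anchor, and
alternative fragments span the junction with ≥ 8 matched bases on each
side; the alternative-fragment count is binomial in the declared JAF (an
exact-count mode exists for boundary fixtures). SAM text is the canonical
output for diffability; the alignment layer sorts and indexes into a
process-local cache on demand.

What the simulator does **not** emulate — expression gradients, GC and
positional bias, alignment artifacts, multi-isoform genes, minus-strand
event geometries (the scoring engine handles minus strands; the embedded
events are plus-strand) — bounds what passing tests show about real data:
they demonstrate the decision rules, counting conventions and arithmetic
are implemented exactly, not that the thresholds are optimal for any
particular cohort.

## Problem sizes used in the checks

The end-to-end benchmark uses 5 case + 20 control samples, 20 injected
events (JAF ∈ {0.2, 0.3, 0.5, 0.75}, locus depth 100) and 200 decoy
mutations; JAF recovery uses a {0.05, 0.1, 0.25, 0.5, 0.75} grid at depth
200 with 20 replicates; discovery is cross-checked against a brute-force
CIGAR re-parse over dozens of seeded worlds, the percentile thresholds
against a rank-search oracle on 1,000 random multisets, and the scorer
against direct table arithmetic over all 4⁹ donor 9-mers. These sizes make
the checks exact or tightly bounded while keeping a full run in seconds.

## Known limitations

- Intron retention, exitrons and fusion junctions are out of scope (no `N`
  span, or spans crossing contigs).
- No multiple-testing correction is applied across junctions, mirroring the
  filter-cascade design rather than a hypothesis-testing framing.
- The JAF denominator convention (anchor-base fragments) is one of several
  defensible choices; alternatives (e.g. junction-window averages) would
  shift absolute JAF values slightly.
- Epitope novelty is transcript-level; a peptide novel to this transcript
  may exist elsewhere in the proteome.
- Review is rule-based; complex loci a human reviewer would rescue or
  reject on read-level appearance are decided purely by the filter cascade.
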