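# Methods

## Scope and units of analysis

The pipeline starts after base calling, vector clipping and clustering: its
inputs are the post-assembly *unique sequences* (contig consensi from
clusters of ≥ 2 ESTs, plus singleton reads), the cluster membership table,
per-contig multiple alignments, tabular similarity-search results, a
reference-genome annotation, and GO annotation tables. Producing those inputs
(assembler, aligner, annotation engine) is deliberately out of scope; the
package either consumes their tabular outputs or, for the synthetic data,
fabricates them from known provenance.

All coordinates are 0-based half-open internally. The 1-based inclusive
conventions of hit tables and GFF3 are converted exactly once, at the I/O
boundary, and converted back on output; `sstart > send` in a hit row encodes
a minus-strand subject match and is normalised to a forward interval before
any interval arithmetic.

## Statistics and conventions

**GC content** is pooled: all unique sequences are amalgamated and
(G+C)/(A+C+G+T) computed with ambiguity codes excluded from both numerator
and denominator. This differs from the mean of per-sequence fractions when
lengths vary.

**Best hits.** Per query passing the e-value cutoff, the hit with minimal
e-value wins; ties are broken by maximal bitscore, then lexicographically
smallest subject id. The tie-break makes output deterministic across runs
and platforms, which matters because downstream tallies are exact counts.

**Taxonomic tallies** use ordered first-match category rules, because
taxonomic categories nest (a genus-level rule must precede the family-level
rule containing it). Counts plus the no-hit count always sum to the number
of queries; this conservation is asserted, not assumed.

**Redundancy.** With `h` hit-bearing queries matching `u` distinct subjects
in one reference proteome, the ratio `u/h` estimates the fraction of unique
sequences deriving from distinct genes; `round(u/h · N)` extrapolates to the
whole set. Percentages are reported round-half-even. Published summaries of
the mean-ESTs-per-contig statistic are sometimes truncated rather than
rounded; the implementation reports the exact ratio (4.44 at 2 decimals for
the reference inputs) and does not chase any particular printed rounding.

**Positional classification.** A genome hit is `inside` when its interval is
contained in some CDS, `spanning` when the minimal gap to a CDS is zero
without containment (overlap or abutment both qualify — UTRs begin exactly at
the CDS boundary, so an abutting hit is evidence of flanking transcript, not
of distance), `utr_range` when the gap is positive but ≤ `utr_max`
(default 4,375 bases; the boundary is inclusive), and `distal` beyond that.
Distance is strand-agnostic because UTRs flank both CDS ends. The full hit
interval is used by default; a `start_only` flag reproduces the variant that
classifies only the alignment's 5'-most subject coordinate. A sequence with
no CDS at all yields `distal` with a `None` distance sentinel. Ties between
equally near CDS features go to the smallest feature id.

**ORFs** are maximal ATG→stop runs under the standard genetic code (stops
TAA/TAG/TGA), up to six frames, length counted inclusive of the stop codon,
minimum 100 nt by default (consistent with common ORF-finder defaults).
Within a frame only the leftmost ATG before each stop is reported; ORFs
truncated by the sequence end carry an `incomplete_3prime` flag and are
excluded from summary statistics by default, since ESTs are partial by
nature but the summary statistic should describe complete frames. The
per-sequence longest-ORF median uses the lower-middle value for even counts.

**Pseudogene screen.** A genomic region matched by a reference protein is
translated in the frame given by the hit table (column 13); stop symbols
strictly inside the aligned codon span are counted, except a stop at the
span's final codon, which is read as a legitimate terminator. Any premature
stop yields the `stop_codon` verdict; positions are reported for human
review because a stop adjacent to an alignment gap may deserve manual
judgement.

**SSRs.** A reportable microsatellite is a maximal tandem run of a primitive
2–6 nt motif with ≥ 6 complete units (period 2) or ≥ 5 (periods 3–6). Only
complete units count; runs break at ambiguous bases; mononucleotide runs are
out of scope; motifs are reported as found (no rotation/strand
canonicalisation, matching the common reporting convention) with an
additional canonical-class column for convenience. Maximal runs are found as
maximal stretches of the self-match relation `s[j] == s[j−p]`, truncated to
whole units — this anchors each run at its leftmost phase automatically.
Runs of *different* periods can genuinely overlap by a few bases at their
junction (period arithmetic forbids long overlaps but not short ones);
because downstream compound grouping needs disjoint spans, candidates are
accepted greedily left-to-right, smallest period first. The exhaustive
oracle in the test suite enumerates every (position, period) pair
independently and applies the same published resolution rule, so the
run-finding itself is dual-checked. Compound SSRs are transitive chains of
runs separated by ≤ 100 bases; both the number of SSR records in compounds
and the number of compound groups are reported, since either reading of "in
compound formation" is defensible.

**SNPs.** Per alignment column: gap-containing columns are skipped entirely
(a gap means the aligner was unsure; the column is unreliable), `N` counts
neither as allele nor depth, and a candidate SNP requires unambiguous depth
≥ 4, minor count ≥ 2 and minor frequency ≥ 0.1 (the MAF comparison uses a
1e-9 float tolerance so a count sitting exactly on the threshold is
accepted). Columns where a third allele also meets the minor criteria are
reported once, top two alleles, with a multi-allelic flag. The published
tool this emulates had additional unspecified read-quality filtering; rather
than guess it, the caller states its own rule set and accepts an optional
per-column quality mask as a hook. Contig eligibility for SNP mining is ≥ 4
members; covered bases are the ungapped consensus lengths of eligible
contigs.

**Fisher exact tests** (GO-slim comparison) are two-sided: the sum of
hypergeometric probabilities of all same-margin tables no likelier than the
observed one. The computation delegates to scipy; the test suite checks it
against full exact-integer enumeration for every table with N ≤ 30 at 1e-12.
A zero margin returns p = 1.0 with a warning. Published slim-distribution
comparisons rarely state their significance convention, so both raw (p < α) and
Bonferroni-corrected (p < α/m within namespace, α = 0.05) flags are emitted.
A sequence reaching one slim term through two GO ids counts once per
(sequence, term) pair; the GO→slim mapping is a flat table, no ontology
traversal.

## The synthetic-data generator

The generator emulates a normalised 5'-read EST project at desk scale:
120 genes (UTR5 10–80 nt, CDS 60–300 codons, UTR3 20–300 nt, random strand)
placed round-robin on 3 chromosomes with 1–3 kb intergenic spacers at 36%
GC, and 480 ESTs drawn as 5' prefixes (300–600 nt, start jitter ≤ 10 nt) of
transcripts chosen by Dirichlet-weighted expression (concentration 5 —
normalisation is modelled only as this flattening, since it matters
downstream only through redundancy). That yields a mean of ~4–5 ESTs per
contig with a contig/singleton mix, the regime the method is meant for.
Reads of one gene form one contig (or a singleton); alignments are gapless
by construction (5' reads are exact substrings, padded with leading/trailing
gaps), which is intentional: the SNP caller skips gapped columns, so planted
columns must be gap-free to be callable.

Planted features and their guarantees:

* **SSRs** are written into 3' UTRs or a gene-free "desert" chromosome with
  guard bases chosen so the run can extend in neither direction; background
  sequence is actively *scrubbed* — any chance run meeting the reporting
  thresholds is broken by one mid-run substitution (chosen stop-codon-aware
  inside coding frames) — so planted-marker precision, not just recall, is
  measurable and equals 1.0 at error rate 0.
* **SNP columns** are planted at the nearest achievable minor count for the
  requested MAF (capped so the planted allele stays the minor one), in
  contigs whose read depth is reserved ≥ 12; realised counts are recorded.
  Requested MAFs that violate the calling contract (minor count < 2 or
  frequency < 0.1) are rejected at configuration time.
* **Pseudogenes** are copies of real CDSs with k interior sense codons
  replaced by stops (first and last codon never touched), placed on the
  desert chromosome and described by a 13-column protein-vs-genome hit row;
  the screen recovers exactly k premature stops.
* **Proteome deletions** remove chosen genes from individual reference-hit
  tables; the cross-proteome candidate set then equals those genes'
  unique sequences exactly.

Oracle hit tables replace running any aligner: a hit exists iff the source
gene is present in the target database, with e-values drawn log-uniform
below the cutoff. E-value *statistics* are therefore not realistic, and the
simulator also does not model chromatogram quality, chimeric clones,
paralogy (each transcript has exactly one true source), splicing, or
assembly error (one contig per gene, perfect membership). Passing the
planted-recovery suite consequently demonstrates correctness of the
detectors' logic under clean conditions, not robustness to misassembly or
cross-hybridising gene families; the oracle-equivalence property suites on
random sequences are what cover the detectors' behaviour on arbitrary input.

Determinism: one integer-seeded numpy generator drives every choice in fixed
order; the same seed reproduces the output tree byte for byte.

## Problem sizes in the verification suite

The oracle-equivalence suites run at sizes chosen to finish quickly while
exhausting the interesting boundary structure: the SSR scanner against
exhaustive enumeration of *every* 2-letter sequence to length 14–16 (which
crosses the 12-base di-nucleotide threshold in all phase/period
combinations) plus 1,000 random sequences to length 50; the SNP caller on
500 random alignments; the classifier on 1,000 random instances plus the
inclusive 4,375 boundary; the ORF finder on 500 random sequences; Fisher
against exact enumeration of all ~46k tables with N ≤ 30.

## Known limitations

* The positional classifier assumes unspliced alignments (one interval per
  hit); spliced hits should be classified per exon-block by the caller.
* Only the standard genetic code is supported.
* GC, SSR and SNP logic treat every IUPAC ambiguity code other than
  A/C/G/T as ambiguous; ambiguity is never evidence.
* `compare_distributions` offers Bonferroni or no correction; finer FDR
  control was not needed for slim-sized vocabularies.
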