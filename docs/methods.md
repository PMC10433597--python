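# Methods

## Scope and data model

The package measures RNA editomes from reads aligned directly to coding
sequences (CDS), the natural reference for organellar C-to-U editing where
essentially all sites of interest are inside chloroplast/mitochondrial
genes. All coordinates are 1-based on the CDS, codon frame starting at
position 1; every TSV written states this in a header comment. Read mapping
itself is out of scope — inputs are SAM/BAM plus the CDS FASTA.

Each alignment record is treated as one independent molecule observation:
overlapping mate pairs are not merged, and secondary, supplementary and
duplicate-flagged records are ignored. Replicate runs of a tissue can be
pooled by summing pileup counts (`pool_pileups`) before levels or DES are
computed; pooling is a caller decision, not automatic.

## Pileup and quality filtering

Bases below Phred 30 are discarded by default (`min_base_quality=30`),
leaving bases with error rates below 1e-3; deletions, reference skips and N
calls contribute nothing. There is deliberately *no* minimum depth or
minimum alternative-read-count cutoff at the pileup stage: site reliability
comes from the enrichment standard below, not from per-site count
thresholds. Mapping-quality filtering defaults to 0 (off) and is
configurable.

## Editome anchoring

The 12-type mismatch spectrum counts, per sample, the number of sites
(positions) showing each ref→alt change with at least `min_alt_reads`
supporting reads; a read-level counting mode exists behind a flag.
Candidate editing sites are anchored only in samples whose spectrum is
dominated by the target change: each anchor sample must have
fraction(target) ≥ `min_target_fraction` (default 0.5) or anchoring fails
loudly, naming the sample. The 0.5 default operationalises "the desired
mutation type is the clear majority"; there is no canonical numeric bar, so
the value is a logged, overridable choice. The anchored set is the union
over anchor samples of target-ref positions with ≥ `min_alt_reads` edited
reads; in the remaining samples editing is quantified directly at those
positions.

Editing level is alt/(ref+alt) — e.g. T/(T+C) for C-to-U. Bases other than
the site's ref/alt are excluded from both numerator and denominator. A site
uncovered in a sample is reported with depth 0 and level NaN, never
silently dropped. A-to-I analyses use the identical machinery with target
(A,G); a known-site mode skips anchoring, quantifies a supplied site list,
and keeps sites with ≥ 1 edited read in ≥ 1 sample (`keep_detected_sites`).

## Annotation and the adaptation test

Sites are classified by mutating their codon position and translating
before/after (Biopython codon tables; standard code by default — angiosperm
organelles follow it — with the NCBI table id configurable and recorded).
Stop-gains and stop-losses are retained as effect subtypes but count as
nonsynonymous in the two-way Nonsyn/Syn tally. A site whose stated
reference base disagrees with the FASTA is a hard error, since it almost
always indicates a coordinate bug.

The neutral expectation comes from exhaustive in-silico mutagenesis: every
occurrence of the target base in every CDS is mutated singly and
classified; codons containing non-ACGT bases are skipped with a logged
count. The adaptation test is a two-sided Fisher exact test on
[[obs_nonsyn, obs_syn], [exp_nonsyn, exp_syn]] (scipy); an
observed/expected ratio above 1 indicates positive selection on
nonsynonymous editing.

## Haplotype diversity

For a site pair, each read co-covering both sites with a quality-passing
ref-or-alt base at each contributes to exactly one of the four haplotype
cells; reads covering one site, or carrying a third base at either site,
are excluded entirely (a third base is almost always a sequencing error and
would otherwise inflate the observed haplotype count n). n counts cells
with count > 0, literally — no pseudocounts. HD and θπ are undefined (NaN)
below 2 co-covering reads, and pairs need N ≥ 5 reads (`min_reads`) to
enter summaries, suppressing the upward noise bias of tiny N. Pairs are
unordered (emitted with pos1 < pos2), never formed across sequences. Values
are kept at full float precision; rounding to 2 d.p. happens only in
display. The statistic is deliberately limited to pairs: an X-site
generalisation (m = 2^X) produces HD values that are not comparable across
X, so the API reserves the extension without implementing it.

Both statistics are verified in the test suite against brute-force
enumeration over all C(N,2) read pairs for every count vector with N ≤ 30
(≈46k vectors, 1e-12 agreement), together with the defining contrast:
vectors sharing marginal allele counts always share θπ while HD
distinguishes linkage.

## Differential editing sites

For each site and sample pair the 2×2 table [[ref_a, alt_a], [ref_b,
alt_b]] is tested with a two-sided Fisher exact test; p-values are
Benjamini-Hochberg adjusted *within one sample pair and one annotation
class* (nonsynonymous and synonymous sites form separate families), and
FDR < 0.05 (strict) calls a DES. The BH step-up is implemented directly
(and cross-checked in tests against statsmodels and a from-scratch
procedure) so the family scoping is explicit. Sites uncovered in either
sample receive p = 1 and stay in the family, keeping family sizes equal
across sample pairs; `drop_uncovered=True` removes them instead. Tissue
specificity is summarised by the average pairwise DES fraction
total_des / C(k,2) / n_sites.

## Simulator

`simulate_editome` writes a CDS FASTA, a truth table and an already-aligned
SAM (correct POS, all-match CIGAR), so no mapper is needed. Per CDS,
`site_levels` sites are placed on target-ref bases clustered within one
read length (auto-placement avoids third codon positions so the simulated
pairs are predominantly recoding sites); reads are uniformly positioned
windows of independent molecules.

Linkage is a two-component mixture, the simplest mechanism that reproduces
both observed regimes: with probability λ a molecule is fully linked — all
its sites edited together with probability p̄, the mean site level — and
with probability 1−λ each site is edited independently at its own level.
λ→1 gives plant-like suppression of single-edited haplotypes; λ→0 gives
fly-like near-product haplotype frequencies. For the two-site-per-CDS
configurations used throughout, the molecule-level mixture coincides with a
per-pair definition. This is a modelling choice for test substrate, not an
empirical claim about mechanism.

Sequencing errors are uniform substitutions at `error_rate` per base
(applied to edited bases too); a configurable fraction of bases is emitted
at Phred 20 to exercise the quality filter, the rest at Phred 40. Reads are
single-end. Identical configuration (including seed) yields byte-identical
FASTA/SAM output. `expected_hd` gives E[HD] under the generative model for
N sampled reads — exact enumeration over multinomial haplotype outcomes for
N ≤ 30, seeded Monte Carlo beyond — and anchors the parameter-recovery
tests (observed mean HD tracks E[HD]; E[HD] non-increasing in λ).

What the simulator does *not* emulate: fragment-length and positional
coverage bias, splicing, PCR duplicates, mapping artefacts, strand-specific
(antisense) editing, or quality-dependent error profiles. Passing tests
therefore demonstrate correctness of the statistics and pipeline plumbing
under idealised coverage, not robustness to mapping error.

## Problem sizes and numerical choices

Default test and validation runs use small configurations — tens of CDS of
50 codons, coverage 25–200×, 30–50 editing sites, 200-site DES null panels
at depth 50 — chosen so the full validation suite replays in seconds while
leaving binomial/multinomial sampling noise well inside the asserted
tolerances (e.g. 3σ level-recovery bounds, ±0.05 haplotype-frequency
bands). Fisher tests use scipy's exact implementation; ratios with zero
denominators are reported as NaN rather than raising; ties in BH are
handled by the standard step-up minimum. The Fig-style pooled haplotype
frequency is a cellwise sum before normalisation, so deep pairs weigh more
than shallow ones — matching pooling of reads, not averaging of pairs.

## Known limitations

HD for more than two sites is intentionally unimplemented (values would not
be comparable across site counts). Editing calls are sense-strand only
(reads are mapped to CDS). DES uses count-based Fisher tests, which at very
high depth can flag biologically tiny level differences; continuous-level
models (beta-binomial) are out of scope. The adaptation expectation depends
on the supplied CDS set; with non-ACGT bases present, skipped codons make
the expectation slightly conservative.
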