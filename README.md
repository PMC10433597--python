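# edhap

Quantify RNA editomes from CDS-mapped RNA-seq and measure the proteomic
diversity that recoding (amino-acid-changing) editing creates, using a
read-backed **haplotype diversity (HD)** statistic for pairs of editing
sites.

## The problem

RNA editing (plant organellar C-to-U, read as C→T mismatches; animal
A-to-I, read as A→G) can serve two opposite purposes. Under the
*diversifying* hypothesis editing flexibly multiplies protein isoforms, so
editing should be tissue-specific and the edited/unedited states should mix
freely on individual molecules. Under the *restorative* hypothesis editing
mimics a DNA mutation that reverts an unfavorable genomic allele, so
editing should be high-level, uniform across tissues, and "all or none" on
each molecule. Distinguishing the two requires statistics that see
*linkage between editing events on the same read* — which classical
per-site summaries cannot.

## The statistics

For two editing sites covered by the same reads, each read carries one of
m = 4 haplotypes (for a C-to-U pair: CC, CT, TC, TT), with read counts
N_CC, N_CT, N_TC, N_TT and N their sum. With n the number of observed
haplotypes (nonzero counts):

    HD = (n/m) · (N_CC·N_CT + N_CC·N_TC + N_CC·N_TT
                  + N_CT·N_TC + N_CT·N_TT + N_TC·N_TT) / C(N,2)

i.e. (n/m) times the probability that two random reads differ in
haplotype. The classical nucleotide diversity over the same two sites,

    θπ = (N_CC·N_CT + N_CC·N_TC + 2·N_CC·N_TT + 2·N_CT·N_TC
          + N_CT·N_TT + N_TC·N_TT) / (2·C(N,2)),

depends only on the per-site allele frequencies and is blind to linkage:
four reads {CC, CC, TT, TT} (complete linkage) and {CC, CT, TC, TT} (free
mixing) both give θπ = 0.67, but HD = 0.33 vs HD = 1. When both sites are
nonsynonymous, each haplotype is a distinct protein isoform, so HD directly
proxies proteomic diversity.

Around HD the package implements the full measurement stack:

* **align_io** — quality-filtered pileups (default Phred ≥ 30) and per-read
  base calls from SAM/BAM against CDS references;
* **editome** — 12-type mismatch spectrum, editing-site anchoring in
  enrichment-passing samples, editing levels alt/(ref+alt);
* **annotate** — codon-aware Nonsyn/Syn classification, exhaustive
  in-silico C→T (or A→G) mutagenesis expectation, and the observed/expected
  Fisher adaptation test;
* **hapdiv** — haplotype counting, HD, θπ, pair scans, pooled haplotype
  frequencies;
* **diffedit** — differential editing sites (DES) between samples by
  two-sided Fisher exact test with Benjamini-Hochberg FDR < 0.05, DES
  matrices, and the average pairwise DES fraction total/C(k,2)/n_sites;
* **synth** — a seeded editome simulator (reference FASTA + aligned SAM +
  truth tables) with per-site editing levels and a tunable inter-site
  linkage parameter λ, used to validate every stage against known truth.

## Worked example

```python
from edhap import (EditingSite, HaplotypeCounts, haplotype_diversity,
                   nucleotide_diversity_pair)

s1 = EditingSite("rps4", 10, "C", "T", "Nonsyn")
s2 = EditingSite("rps4", 25, "C", "T", "Nonsyn")
case1 = HaplotypeCounts(s1, s2, n_rr=2, n_ra=0, n_ar=0, n_aa=2)  # CC,CC,TT,TT
case2 = HaplotypeCounts(s1, s2, n_rr=1, n_ra=1, n_ar=1, n_aa=1)  # CC,CT,TC,TT
for name, c in [("case1", case1), ("case2", case2)]:
    print(f"{name}: HD = {haplotype_diversity(c):.2f}, "
          f"theta_pi = {nucleotide_diversity_pair(c):.2f}")
```

```
case1: HD = 0.33, theta_pi = 0.67
case2: HD = 1.00, theta_pi = 0.67
```

θπ cannot tell the two cases apart; HD separates complete linkage (0.33)
from free mixing (1.00).

A full simulated pipeline — plant-like strongly linked editing (λ = 0.9,
editing level 0.5, 80× coverage, 0.1% base errors):

```python
from edhap import (SimConfig, simulate_editome, ReferenceSet, load_pileup,
                   anchor_sites, annotate_sites, per_read_bases, pair_scan,
                   pooled_haplotype_frequency)

cfg = SimConfig(n_cds=20, site_levels=(0.5, 0.5), linkage=0.9,
                coverage=80, error_rate=0.001, seed=42)
truth = simulate_editome(cfg, "ref.fa", "reads.sam")
ref = ReferenceSet.from_fasta("ref.fa")
pileup = load_pileup("reads.sam", ref, min_base_quality=30)
sites = anchor_sites({"anther": pileup}, ["anther"], target=("C", "T"),
                     min_alt_reads=2)
sites = annotate_sites(ref, sites)
calls = per_read_bases("reads.sam", [(s.seq_id, s.pos) for s in sites])
records = [r for r in pair_scan(sites, calls, min_reads=5)
           if r.passes_min_reads]
mean_hd = sum(r.hd for r in records) / len(records)
freqs = pooled_haplotype_frequency([r.counts for r in records])
print(f"{len(sites)} sites anchored, {len(records)} passing pairs")
print(f"mean HD = {mean_hd:.3f}")
print("pooled haplotype freqs (CC, CT, TC, TT):",
      " ".join(f"{f:.3f}" for f in freqs))
```

```
40 sites anchored, 17 passing pairs
mean HD = 0.538
pooled haplotype freqs (CC, CT, TC, TT): 0.472 0.021 0.026 0.481
```

The single-edited haplotypes CT and TC are strongly suppressed (4.7%
combined) and HD sits far below 1 — the signature of "all or none" editing.
With `linkage=0` the same configuration gives near-even haplotype
frequencies and much higher HD.

The same steps are available from the shell: `edhap simulate`, `edhap
pileup`, `edhap spectrum`, `edhap anchor`, `edhap levels`, `edhap hd`,
`edhap des` (see `edhap --help`).

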