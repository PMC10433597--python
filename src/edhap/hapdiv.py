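"""Read-backed haplotype diversity (HD) for pairs of editing sites.

A single read spanning two editing sites carries one of four haplotypes —
for a C-to-U pair: CC, CT, TC, TT. HD treats each haplotype as a distinct
element and measures the pairwise difference between reads:

    HD = (n/m) × Σ_{i<j} N_i N_j / C(N,2)

where the N_i are the four haplotype read counts, N their sum, n the number
of observed haplotypes (nonzero cells), and m = 4 the possible haplotypes
for a pair. When the two sites are nonsynonymous, each haplotype encodes a
different protein isoform, so HD is a direct proxy for proteomic diversity.

The classical nucleotide diversity over the same two sites,

    θπ = (N_CC·N_CT + N_CC·N_TC + 2·N_CC·N_TT + 2·N_CT·N_TC
          + N_CT·N_TT + N_TC·N_TT) / (2·C(N,2)),

is the mean per-site pairwise difference and is blind to linkage: it
depends only on the marginal allele counts at each site, so fully linked
("all or none") editing and independent editing with the same levels are
indistinguishable to θπ but not to HD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

from .align_io import ReadBaseCall
from .editome import EditingSite

#: Possible haplotypes for a site pair.
M_PAIR = 4

#: Minimum co-covering reads for a pair to enter summaries.
DEFAULT_MIN_READS = 5


@dataclass(frozen=True)
class HaplotypeCounts:
    """Read counts of the four haplotypes at one ordered site pair.

    Cells are (ref,ref), (ref,alt), (alt,ref), (alt,alt) — N_CC, N_CT,
    N_TC, N_TT for a C-to-U pair. Reads missing either site, or carrying a
    base that is neither ref nor alt at either site, are excluded from all
    cells.
    """

    site1: EditingSite
    site2: EditingSite
    n_rr: int = 0
    n_ra: int = 0
    n_ar: int = 0
    n_aa: int = 0

    def __post_init__(self) -> None:
        if self.site1.seq_id != self.site2.seq_id:
            raise ValueError("haplotype counts require sites on the same sequence")
        if self.site1.pos >= self.site2.pos:
            raise ValueError("site1.pos must be < site2.pos")
        if min(self.n_rr, self.n_ra, self.n_ar, self.n_aa) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.n_rr, self.n_ra, self.n_ar, self.n_aa)

    @property
    def total(self) -> int:
        return self.n_rr + self.n_ra + self.n_ar + self.n_aa

    @property
    def n_observed(self) -> int:
        """Observed number of haplotypes (cells with count > 0)."""
        return sum(1 for c in self.cells if c > 0)


def _pair_diversity(cells: Sequence[int], weights: Optional[dict] = None) -> float:
    """Σ weighted cross-products over C(N,2); helper for HD and θπ."""
    n_total = sum(cells)
    pairs = n_total * (n_total - 1) / 2
    s = 0.0
    for (i, ci), (j, cj) in combinations(enumerate(cells), 2):
        w = weights[(i, j)] if weights is not None else 1
        s += w * ci * cj
    return s / pairs


def hd_from_cells(cells: Sequence[int]) -> float:
    """HD from a bare (N_RR, N_RA, N_AR, N_AA) count vector."""
    if sum(cells) < 2:
        return math.nan
    n_obs = sum(1 for c in cells if c > 0)
    return (n_obs / M_PAIR) * _pair_diversity(cells)


def haplotype_diversity(counts: HaplotypeCounts) -> float:
    """HD of one site pair; NaN when fewer than 2 co-covering reads.

    Equals (n/m) × P(two random reads carry different haplotypes). Ranges
    over [0,1]; 0 iff a single haplotype is observed; 1 only when all four
    haplotypes occur in equal numbers.
    """
    return hd_from_cells(counts.cells)


# Hamming distance between haplotypes i,j in cell order (RR, RA, AR, AA).
_HAMMING = {
    (0, 1): 1, (0, 2): 1, (0, 3): 2,
    (1, 2): 2, (1, 3): 1,
    (2, 3): 1,
}


def theta_pi_from_cells(cells: Sequence[int]) -> float:
    """θπ from a bare (N_RR, N_RA, N_AR, N_AA) count vector."""
    if sum(cells) < 2:
        return math.nan
    return _pair_diversity(cells, _HAMMING) / 2


def nucleotide_diversity_pair(counts: HaplotypeCounts) -> float:
    """θπ over the two sites: mean pairwise per-site difference of reads.

    NaN when fewer than 2 co-covering reads. Depends only on the marginal
    allele counts at each site (linkage-blind).
    """
    return theta_pi_from_cells(counts.cells)


@dataclass
class PairDiversityRecord:
    """HD and θπ of one site pair in one sample."""

    sample_id: str
    counts: HaplotypeCounts
    min_reads: int = DEFAULT_MIN_READS

    @property
    def n(self) -> int:
        return self.counts.n_observed

    @property
    def m(self) -> int:
        return M_PAIR

    @property
    def total_reads(self) -> int:
        return self.counts.total

    @property
    def hd(self) -> float:
        return haplotype_diversity(self.counts)

    @property
    def theta_pi(self) -> float:
        return nucleotide_diversity_pair(self.counts)

    @property
    def passes_min_reads(self) -> bool:
        return self.counts.total >= self.min_reads


def pair_haplotype_counts(
    read_calls: Iterable[ReadBaseCall],
    site1: EditingSite,
    site2: EditingSite,
) -> HaplotypeCounts:
    """Tally the four haplotypes from per-read base calls at two sites.

    A read enters exactly one cell iff it has a quality-passing ref-or-alt
    base at both positions; everything else (one-site coverage, third
    bases) contributes nothing — third bases are sequencing noise and would
    otherwise inflate the observed haplotype count.
    """
    if site1.seq_id != site2.seq_id:
        raise ValueError("sites must be on the same sequence")
    if site1.pos == site2.pos:
        raise ValueError("sites must be at distinct positions")
    if site1.pos > site2.pos:
        site1, site2 = site2, site1
    by_read: dict[str, dict[int, str]] = {}
    for call in read_calls:
        if call.seq_id != site1.seq_id:
            continue
        if call.pos in (site1.pos, site2.pos):
            by_read.setdefault(call.read_id, {})[call.pos] = call.base
    cells = [0, 0, 0, 0]
    for bases in by_read.values():
        b1 = bases.get(site1.pos)
        b2 = bases.get(site2.pos)
        if b1 is None or b2 is None:
            continue
        if b1 not in (site1.ref_base, site1.alt_base):
            continue
        if b2 not in (site2.ref_base, site2.alt_base):
            continue
        idx = 2 * (b1 == site1.alt_base) + (b2 == site2.alt_base)
        cells[idx] += 1
    return HaplotypeCounts(site1, site2, *cells)


def pair_scan(
    sites: Sequence[EditingSite],
    read_calls: Sequence[ReadBaseCall],
    sample_id: str = "",
    min_reads: int = DEFAULT_MIN_READS,
    anno_class: Optional[str] = "Nonsyn",
) -> list[PairDiversityRecord]:
    """HD/θπ for every same-sequence pair of (by default nonsynonymous) sites.

    All pairs are enumerated with pos1 < pos2; pairs with fewer than
    ``min_reads`` co-covering reads are returned with
    ``passes_min_reads=False`` and should be excluded from summaries.
    Cross-sequence pairs are never formed.
    """
    if anno_class is not None:
        sites = [s for s in sites if s.anno == anno_class]
    records = []
    for s1, s2 in combinations(sorted(sites), 2):
        if s1.seq_id != s2.seq_id:
            continue
        counts = pair_haplotype_counts(read_calls, s1, s2)
        records.append(PairDiversityRecord(sample_id, counts, min_reads))
    return records


def pooled_haplotype_frequency(
    records: Iterable[HaplotypeCounts],
) -> tuple[float, float, float, float]:
    """Cellwise pooled haplotype frequencies across pairs and samples.

    Sums the (RR, RA, AR, AA) cells over all records and normalises to 1.
    Returns NaNs when the pooled total is zero.
    """
    totals = [0, 0, 0, 0]
    seen = False
    for rec in records:
        seen = True
        for i, c in enumerate(rec.cells):
            totals[i] += c
    if not seen:
        raise ValueError("need at least one record")
    grand = sum(totals)
    if grand == 0:
        return (math.nan,) * 4
    return tuple(c / grand for c in totals)  # type: ignore[return-value]


def write_pairs_tsv(records: Iterable[PairDiversityRecord], path: str) -> None:
    """Pair table TSV: sample, seq_id, pos1, pos2, cells, N, n, HD, θπ, pass."""
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based, inclusive\n")
        fh.write(
            "sample\tseq_id\tpos1\tpos2\tN_RR\tN_RA\tN_AR\tN_AA\tN\tn\tHD\ttheta_pi\tpass\n"
        )
        for r in records:
            c = r.counts
            hd = "NA" if math.isnan(r.hd) else f"{r.hd:.6g}"
            tp = "NA" if math.isnan(r.theta_pi) else f"{r.theta_pi:.6g}"
            fh.write(
                f"{r.sample_id}\t{c.site1.seq_id}\t{c.site1.pos}\t{c.site2.pos}\t"
                f"{c.n_rr}\t{c.n_ra}\t{c.n_ar}\t{c.n_aa}\t{c.total}\t{r.n}\t"
                f"{hd}\t{tp}\t{str(r.passes_min_reads).lower()}\n"
            )
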