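"""Editome profiling: mutation spectrum, site anchoring, editing levels.

RNA editing appears in CDS-mapped RNA-seq as a reference→alternative
mismatch: C→T for plant C-to-U editing, A→G for animal A-to-I editing.
Reliable editomes are anchored in samples whose 12-type mismatch spectrum
is dominated by the target change (the enrichment "golden standard"); in
all other samples editing is then quantified directly at the anchored
positions as level = alt/(ref+alt).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .align_io import NUCLEOTIDES, PileupSite

logger = logging.getLogger("edhap")

#: The 12 ordered substitution types over {A,C,G,T}.
SUBSTITUTION_TYPES: tuple[tuple[str, str], ...] = tuple(
    (r, a) for r in NUCLEOTIDES for a in NUCLEOTIDES if r != a
)


@dataclass
class SpectrumTable:
    """Site counts for each of the 12 substitution types in one sample."""

    sample_id: str
    counts: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        if set(self.counts) != set(SUBSTITUTION_TYPES):
            raise ValueError("spectrum must have exactly the 12 substitution types")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[tuple[str, str], float]:
        total = self.total
        if total == 0:
            logger.warning("sample %s: empty spectrum, fractions reported as 0", self.sample_id)
            return {k: 0.0 for k in self.counts}
        return {k: v / total for k, v in self.counts.items()}

    def fraction(self, target: tuple[str, str]) -> float:
        return self.fractions[target]


@dataclass(frozen=True, order=True)
class EditingSite:
    """An anchored candidate editing site.

    ``ref_base`` is the unedited base (C for C-to-U, A for A-to-I);
    ``alt_base`` the base edited reads carry (T or G). ``anno`` is
    Nonsyn/Syn/NA from codon-aware classification.
    """

    seq_id: str
    pos: int  # 1-based
    ref_base: str
    alt_base: str
    anno: str = "NA"

    def __post_init__(self) -> None:
        if (self.ref_base, self.alt_base) not in {("C", "T"), ("A", "G")}:
            raise ValueError(
                f"unsupported editing type {self.ref_base}->{self.alt_base}; "
                "expected C->T (C-to-U) or A->G (A-to-I)"
            )
        if self.pos < 1:
            raise ValueError("pos must be >= 1")


@dataclass
class SiteLevelRecord:
    """Editing quantification of one site in one sample.

    level = alt/(ref+alt); bases other than ref/alt are ignored, so depth
    here is ref_count + alt_count, not total pileup depth. level is NaN
    when depth is 0.
    """

    sample_id: str
    site: EditingSite
    ref_count: int
    alt_count: int

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def level(self) -> float:
        if self.depth == 0:
            return math.nan
        return self.alt_count / self.depth


def mutation_spectrum(
    pileup: Iterable[PileupSite],
    sample_id: str = "",
    min_alt_reads: int = 1,
    read_level: bool = False,
) -> SpectrumTable:
    """12-type mismatch spectrum of one sample's pileup.

    Site-level counting (default): each position contributes at most 1 to a
    ref→alt cell, for every non-reference base with at least
    ``min_alt_reads`` supporting reads. ``read_level=True`` counts mismatch
    observations (reads) instead.
    """
    counts = {t: 0 for t in SUBSTITUTION_TYPES}
    for site in pileup:
        if site.ref_base not in NUCLEOTIDES:
            continue
        for alt in NUCLEOTIDES:
            if alt == site.ref_base:
                continue
            n = site.counts.get(alt, 0)
            if n >= min_alt_reads:
                counts[(site.ref_base, alt)] += n if read_level else 1
    return SpectrumTable(sample_id=sample_id, counts=counts)


def anchor_sites(
    pileups_by_sample: Mapping[str, Sequence[PileupSite]],
    anchor_samples: Sequence[str],
    target: tuple[str, str] = ("C", "T"),
    min_alt_reads: int = 1,
    min_target_fraction: float = 0.5,
) -> list[EditingSite]:
    """Anchor candidate editing sites in enrichment-passing samples.

    Each anchor sample must show fraction(target) >= ``min_target_fraction``
    in its mutation spectrum — the enrichment standard that substitutes for
    depth/alt-count cutoffs. The returned sites are the union over anchor
    samples of positions with reference base target[0] and at least
    ``min_alt_reads`` reads carrying target[1]; deduplicated, sorted.
    """
    missing = [s for s in anchor_samples if s not in pileups_by_sample]
    if missing:
        raise ValueError(f"anchor samples not in pileups: {missing}")
    found: set[tuple[str, int]] = set()
    ref_base, alt_base = target
    for sample in anchor_samples:
        pileup = pileups_by_sample[sample]
        spec = mutation_spectrum(pileup, sample_id=sample, min_alt_reads=min_alt_reads)
        frac = spec.fraction(target)
        if frac < min_target_fraction:
            raise ValueError(
                f"anchor sample {sample!r} fails the {ref_base}->{alt_base} enrichment "
                f"standard: fraction {frac:.3f} < {min_target_fraction} "
                "(lower min_target_fraction explicitly to override)"
            )
        for site in pileup:
            if site.ref_base == ref_base and site.counts.get(alt_base, 0) >= min_alt_reads:
                found.add((site.seq_id, site.pos))
    return [
        EditingSite(seq_id, pos, ref_base, alt_base)
        for seq_id, pos in sorted(found)
    ]


def editing_levels(
    pileup: Iterable[PileupSite],
    sites: Sequence[EditingSite],
    sample_id: str = "",
) -> list[SiteLevelRecord]:
    """Editing level of every site in one sample, level = alt/(ref+alt).

    Every site yields a record even when uncovered (depth 0, level NaN);
    reads carrying bases other than the site's ref/alt are ignored.
    """
    by_pos = {(s.seq_id, s.pos): s for s in pileup}
    records = []
    for site in sites:
        p = by_pos.get((site.seq_id, site.pos))
        ref_n = p.counts.get(site.ref_base, 0) if p is not None else 0
        alt_n = p.counts.get(site.alt_base, 0) if p is not None else 0
        records.append(SiteLevelRecord(sample_id, site, ref_n, alt_n))
    return records


def pool_pileups(pileups: Sequence[Sequence[PileupSite]]) -> list[PileupSite]:
    """Pool replicate runs of one tissue by summing base counts per position."""
    merged: dict[tuple[str, int], PileupSite] = {}
    for pileup in pileups:
        for s in pileup:
            key = (s.seq_id, s.pos)
            tgt = merged.get(key)
            if tgt is None:
                merged[key] = PileupSite(s.seq_id, s.pos, s.ref_base, dict(s.counts))
            else:
                for b, n in s.counts.items():
                    tgt.counts[b] += n
    return [merged[k] for k in sorted(merged)]


def keep_detected_sites(
    levels_by_sample: Mapping[str, Sequence[SiteLevelRecord]],
    min_alt_reads: int = 1,
) -> list[EditingSite]:
    """Keep sites with editing detected in at least one sample.

    Post-filter used in known-site mode (e.g. externally supplied A-to-I
    lists): a site survives if alt_count >= min_alt_reads in >= 1 sample.
    """
    detected: set[EditingSite] = set()
    for recs in levels_by_sample.values():
        for r in recs:
            if r.alt_count >= min_alt_reads:
                detected.add(r.site)
    return sorted(detected)


def write_sites_tsv(sites: Iterable[EditingSite], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based, inclusive\n")
        fh.write("seq_id\tpos\tref\talt\tanno\n")
        for s in sites:
            fh.write(f"{s.seq_id}\t{s.pos}\t{s.ref_base}\t{s.alt_base}\t{s.anno}\n")


def read_sites_tsv(path: str) -> list[EditingSite]:
    sites = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("seq_id"):
                continue
            parts = line.rstrip("\n").split("\t")
            anno = parts[4] if len(parts) > 4 else "NA"
            sites.append(EditingSite(parts[0], int(parts[1]), parts[2], parts[3], anno))
    return sites


def write_levels_tsv(records: Iterable[SiteLevelRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based, inclusive; level = alt/(ref+alt)\n")
        fh.write("sample\tseq_id\tpos\tref\talt\tanno\tref_count\talt_count\tdepth\tlevel\n")
        for r in records:
            lvl = "NA" if math.isnan(r.level) else f"{r.level:.6g}"
            fh.write(
                f"{r.sample_id}\t{r.site.seq_id}\t{r.site.pos}\t"
                f"{r.site.ref_base}\t{r.site.alt_base}\t{r.site.anno}\t"
                f"{r.ref_count}\t{r.alt_count}\t{r.depth}\t{lvl}\n"
            )


def read_levels_tsv(path: str) -> list[SiteLevelRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("sample\t"):
                continue
            f = line.rstrip("\n").split("\t")
            site = EditingSite(f[1], int(f[2]), f[3], f[4], f[5])
            records.append(SiteLevelRecord(f[0], site, int(f[6]), int(f[7])))
    return records
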