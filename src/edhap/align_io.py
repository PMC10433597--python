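"""Alignment and reference I/O.

Reads CDS references (FASTA) and aligned reads (SAM/BAM), and turns them
into the two substrates every downstream analysis uses:

* a quality-filtered per-position base-count pileup (:func:`load_pileup`),
* per-read base calls at requested positions (:func:`per_read_bases`),
  the raw material for read-backed haplotype counting.

All coordinates are 1-based and inclusive on the CDS reference; every TSV
written by this package states that convention in its header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO

logger = logging.getLogger("edhap")

NUCLEOTIDES = ("A", "C", "G", "T")
VALID_BASES = frozenset("ACGTN")

#: Phred cut used throughout; bases below it carry error rates above 1e-3.
DEFAULT_MIN_BASE_QUALITY = 30


@dataclass(frozen=True)
class ReferenceSet:
    """A set of coding sequences, keyed by id, codon frame starting at 1.

    Sequences are uppercase A/C/G/T/N strings. For codon-aware annotation
    the lengths are expected to be multiples of 3.
    """

    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        for seq_id, seq in self.sequences.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"reference {seq_id!r} contains non-nucleotide characters: {sorted(bad)}"
                )

    @classmethod
    def from_fasta(cls, path: str) -> "ReferenceSet":
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(path, "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate reference id {rec.id!r} in {path}")
            seqs[rec.id] = str(rec.seq).upper()
        return cls(seqs)

    def base_at(self, seq_id: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.sequences[seq_id][pos - 1]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.sequences

    def __getitem__(self, seq_id: str) -> str:
        return self.sequences[seq_id]


@dataclass
class PileupSite:
    """Quality-filtered base counts for one reference position."""

    seq_id: str
    pos: int  # 1-based
    ref_base: str
    counts: dict[str, int] = field(default_factory=lambda: dict.fromkeys(NUCLEOTIDES, 0))

    @property
    def depth_used(self) -> int:
        return sum(self.counts.values())

    def alt_count(self, base: str) -> int:
        return self.counts.get(base, 0)


@dataclass(frozen=True)
class ReadBaseCall:
    """The base one read carries at one reference position."""

    read_id: str
    seq_id: str
    pos: int  # 1-based
    base: str
    base_quality: int


def _usable_alignments(
    af: pysam.AlignmentFile, min_mapping_quality: int
) -> Iterable[pysam.AlignedSegment]:
    """Primary, non-duplicate, mapped records above the MAPQ cut.

    Each record is one independent molecule observation; overlapping mates
    are not merged.
    """
    for aln in af.fetch(until_eof=True):
        if aln.is_unmapped or aln.is_secondary or aln.is_supplementary or aln.is_duplicate:
            continue
        if aln.mapping_quality < min_mapping_quality:
            continue
        yield aln


def load_pileup(
    alignments: str,
    reference: ReferenceSet,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
    min_mapping_quality: int = 0,
) -> list[PileupSite]:
    """Per-position base counts from a SAM/BAM file, quality-filtered.

    Bases with Phred quality below ``min_base_quality`` and N calls are
    discarded; deletions and reference skips contribute nothing. One
    :class:`PileupSite` is returned per covered reference position, sorted
    by (seq_id, pos).

    Raises ``ValueError`` if an alignment targets a sequence id absent from
    ``reference``.
    """
    if min_base_quality < 0:
        raise ValueError("min_base_quality must be >= 0")
    sites: dict[tuple[str, int], PileupSite] = {}
    with pysam.AlignmentFile(alignments, check_sq=False) as af:
        for aln in _usable_alignments(af, min_mapping_quality):
            seq_id = aln.reference_name
            if seq_id not in reference:
                raise ValueError(f"alignment references unknown sequence id {seq_id!r}")
            seq = aln.query_sequence
            quals = aln.query_qualities
            if seq is None:
                continue
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                base = seq[qpos].upper()
                if base == "N" or base not in NUCLEOTIDES:
                    continue
                if quals is not None and quals[qpos] < min_base_quality:
                    continue
                pos1 = rpos + 1
                key = (seq_id, pos1)
                site = sites.get(key)
                if site is None:
                    site = PileupSite(seq_id, pos1, reference.base_at(seq_id, pos1))
                    sites[key] = site
                site.counts[base] += 1
    return [sites[k] for k in sorted(sites)]


def per_read_bases(
    alignments: str,
    positions: Sequence[tuple[str, int]],
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
    min_mapping_quality: int = 0,
) -> list[ReadBaseCall]:
    """Per-read base calls at requested 1-based positions.

    A read contributes one record per requested position where it has an
    aligned, non-N, quality-passing base; deletions, skips and low-quality
    bases yield no record for that position.
    """
    if not positions:
        raise ValueError("positions must be non-empty")
    wanted: dict[str, set[int]] = {}
    for seq_id, pos in positions:
        wanted.setdefault(seq_id, set()).add(pos)
    calls: list[ReadBaseCall] = []
    with pysam.AlignmentFile(alignments, check_sq=False) as af:
        for aln in _usable_alignments(af, min_mapping_quality):
            pos_set = wanted.get(aln.reference_name)
            if not pos_set:
                continue
            seq = aln.query_sequence
            quals = aln.query_qualities
            if seq is None:
                continue
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                pos1 = rpos + 1
                if pos1 not in pos_set:
                    continue
                base = seq[qpos].upper()
                if base == "N":
                    continue
                qual = quals[qpos] if quals is not None else 255
                if qual < min_base_quality:
                    continue
                calls.append(ReadBaseCall(aln.query_name, aln.reference_name, pos1, base, qual))
    return calls


def write_pileup_tsv(pileup: Iterable[PileupSite], path: str) -> None:
    """Export a pileup as TSV: seq_id, pos (1-based), ref, A, C, G, T, depth."""
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based, inclusive\n")
        fh.write("seq_id\tpos\tref\tA\tC\tG\tT\tdepth\n")
        for s in pileup:
            fh.write(
                f"{s.seq_id}\t{s.pos}\t{s.ref_base}\t"
                f"{s.counts['A']}\t{s.counts['C']}\t{s.counts['G']}\t{s.counts['T']}\t"
                f"{s.depth_used}\n"
            )
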