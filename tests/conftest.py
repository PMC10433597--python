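"""Shared fixtures: tiny hand-written SAM/FASTA fixtures built at test time."""

from __future__ import annotations

from pathlib import Path

import pytest

from edhap import ReferenceSet

#: 30 bp toy CDS (10 codons) used by the alignment fixtures.
TOY_CDS = "ATGCCAGTACCTGGATCCAAGCTTGACTAA"
TOY_ID = "gene1"


def sam_text(records: list[str], seq_lens: dict[str, int]) -> str:
    header = ["@HD\tVN:1.6\tSO:unsorted"]
    header += [f"@SQ\tSN:{sid}\tLN:{ln}" for sid, ln in seq_lens.items()]
    return "\n".join(header + records) + "\n"


def sam_record(
    qname: str,
    rname: str,
    pos: int,
    seq: str,
    qual: str | None = None,
    cigar: str | None = None,
    flag: int = 0,
    mapq: int = 60,
) -> str:
    qual = qual or "I" * len(seq)  # 'I' = Phred 40
    cigar = cigar or f"{len(seq)}M"
    return f"{qname}\t{flag}\t{rname}\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t{qual}"


def write_sam(path: Path, records: list[str], seq_lens: dict[str, int] | None = None) -> str:
    seq_lens = seq_lens or {TOY_ID: len(TOY_CDS)}
    path.write_text(sam_text(records, seq_lens))
    return str(path)


@pytest.fixture
def toy_reference() -> ReferenceSet:
    return ReferenceSet({TOY_ID: TOY_CDS})


@pytest.fixture
def toy_fasta(tmp_path: Path) -> str:
    p = tmp_path / "ref.fa"
    p.write_text(f">{TOY_ID}\n{TOY_CDS}\n")
    return str(p)
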