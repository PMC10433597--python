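"""Synthetic editome simulator.

Generates a reference CDS set, an editing-site truth table, and aligned
single-end reads (SAM, no mapper needed) with controllable per-site
editing levels, inter-site linkage, coverage and base-quality noise. The
simulator is the test substrate for every other module: anchoring, level
quantification, haplotype diversity and differential-editing calls can all
be checked against the generative truth.

Linkage model
-------------
Each read comes from its own RNA molecule. With probability ``linkage``
(λ) the molecule is fully linked: every editing site on it is edited
together, with probability p̄ = mean of the site levels — the "all edited
or none edited" regime of plant C-to-U editing. With probability 1−λ each
site is edited independently at its own level — the regime of fly A-to-I
editing. λ=1 suppresses the single-edited haplotypes entirely; λ=0 makes
the four haplotype frequencies the products of the marginals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pysam
from scipy import stats

from .editome import EditingSite
from .hapdiv import hd_from_cells

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one simulated editome.

    ``site_levels`` are the per-site true editing levels, replicated on
    every CDS; positions are auto-placed on target-ref bases clustered
    within one read length (so site pairs are co-covered), or given
    explicitly via ``site_positions`` (1-based). ``low_quality_fraction``
    of bases are emitted at ``quality_low`` (< 30) to exercise the base
    quality filter.
    """

    n_cds: int = 1
    cds_length: int = 50  # codons
    gc_bias: float = 0.5
    site_levels: tuple[float, ...] = (0.5, 0.5)
    site_positions: Optional[tuple[int, ...]] = None
    linkage: float = 0.0  # λ ∈ [0,1]
    target: tuple[str, str] = ("C", "T")
    coverage: float = 50.0  # mean reads per base
    read_length: int = 80
    error_rate: float = 0.0  # per-base substitution rate
    quality_high: int = 40
    quality_low: int = 20
    low_quality_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (*self.site_levels, self.linkage, self.gc_bias,
                 self.error_rate, self.low_quality_fraction)
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.read_length > 3 * self.cds_length:
            raise ValueError("read_length exceeds CDS length")
        if self.target not in {("C", "T"), ("A", "G")}:
            raise ValueError("target must be ('C','T') or ('A','G')")


@dataclass
class SimTruth:
    """Generative truth emitted alongside the simulated files."""

    config: SimConfig
    fasta_path: str
    sam_path: str
    #: seq_id -> list of (pos, true level), positions 1-based.
    sites: dict[str, list[tuple[int, float]]]
    #: seq_id -> per-read edited-flags array (n_reads × n_sites).
    haplotypes: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def editing_sites(self) -> list[EditingSite]:
        ref, alt = self.config.target
        return [
            EditingSite(seq_id, pos, ref, alt)
            for seq_id, sl in sorted(self.sites.items())
            for pos, _ in sl
        ]

    def true_level(self, seq_id: str, pos: int) -> float:
        for p, level in self.sites[seq_id]:
            if p == pos:
                return level
        raise KeyError(f"no simulated site at {seq_id}:{pos}")

    def expected_hd(self, seq_id: str, pair: tuple[int, int], n_reads: int,
                    seed: int = 0) -> float:
        p1 = self.true_level(seq_id, pair[0])
        p2 = self.true_level(seq_id, pair[1])
        return expected_hd(p1, p2, self.config.linkage, n_reads, seed=seed)

    def write_tables(self, tsv_path: str, json_path: str) -> None:
        with open(tsv_path, "w") as fh:
            fh.write("# coordinates: 1-based, inclusive\n")
            fh.write("seq_id\tpos\tref\talt\ttrue_level\tlinkage\n")
            ref, alt = self.config.target
            for seq_id, sl in sorted(self.sites.items()):
                for pos, level in sl:
                    fh.write(f"{seq_id}\t{pos}\t{ref}\t{alt}\t{level}\t{self.config.linkage}\n")
        with open(json_path, "w") as fh:
            cfg = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(self.config).items()}
            json.dump({"config": cfg, "sites": self.sites,
                       "fasta": self.fasta_path, "sam": self.sam_path}, fh, indent=1)


def haplotype_probabilities(
    p1: float, p2: float, linkage: float
) -> tuple[float, float, float, float]:
    """(RR, RA, AR, AA) haplotype probabilities under the mixture model."""
    pbar = (p1 + p2) / 2
    linked = (1 - pbar, 0.0, 0.0, pbar)
    indep = ((1 - p1) * (1 - p2), (1 - p1) * p2, p1 * (1 - p2), p1 * p2)
    return tuple(linkage * a + (1 - linkage) * b for a, b in zip(linked, indep))  # type: ignore[return-value]


def expected_hd(
    p1: float,
    p2: float,
    linkage: float,
    n_reads: int,
    max_exact_n: int = 30,
    n_mc: int = 200_000,
    seed: int = 0,
) -> float:
    """E[HD] for a sample of ``n_reads`` reads from the generative model.

    Exact enumeration over multinomial haplotype-count outcomes for
    n_reads <= ``max_exact_n``; seeded Monte Carlo beyond.
    """
    if n_reads < 2:
        raise ValueError("need at least 2 reads")
    probs = haplotype_probabilities(p1, p2, linkage)
    if n_reads <= max_exact_n:
        total = 0.0
        # compositions of n_reads into 4 cells
        for a in range(n_reads + 1):
            for b in range(n_reads - a + 1):
                for c in range(n_reads - a - b + 1):
                    d = n_reads - a - b - c
                    cells = (a, b, c, d)
                    pm = stats.multinomial.pmf(cells, n_reads, probs)
                    if pm > 0:
                        total += pm * hd_from_cells(cells)
        return total
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n_reads, probs, size=n_mc)
    return float(np.mean([hd_from_cells(tuple(row)) for row in draws]))


def _place_sites(cfg: SimConfig, length: int) -> list[int]:
    """Deterministic site placement, clustered within one read length."""
    if cfg.site_positions is not None:
        positions = list(cfg.site_positions)
        if any(not 1 <= p <= length for p in positions):
            raise ValueError("site positions outside CDS")
        if len(set(positions)) != len(positions):
            raise ValueError("duplicate site positions")
        return sorted(positions)
    k = len(cfg.site_levels)
    window = min(cfg.read_length, length)
    start = max(1, (length - window) // 2)
    # spread k sites evenly inside the window, avoiding third codon
    # positions (wobble sites are mostly synonymous; the simulated pairs
    # are meant to exercise recoding-pair analyses)
    step = max(1, window // (k + 1))
    positions = []
    for i in range(k):
        pos = start + step * (i + 1)
        if (pos - 1) % 3 == 2:
            pos += 1 if pos < length else -1
        positions.append(pos)
    if len(set(positions)) != k or positions[-1] > length:
        raise ValueError("cannot place sites: CDS/read length too small for k sites")
    return positions


def simulate_editome(
    config: SimConfig,
    fasta_path: str,
    sam_path: str,
    fastq_path: Optional[str] = None,
) -> SimTruth:
    """Simulate references, editing truth, and aligned reads.

    Writes a FASTA of CDS references and a SAM of already-aligned,
    error-perturbed single-end reads (correct POS, all-match CIGAR).
    Identical config (including seed) gives byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    length = 3 * config.cds_length
    ref, alt = config.target
    base_p = np.array([(1 - config.gc_bias) / 2, config.gc_bias / 2,
                       config.gc_bias / 2, (1 - config.gc_bias) / 2])
    levels = np.asarray(config.site_levels)
    pbar = float(levels.mean()) if levels.size else 0.0

    sequences: dict[str, str] = {}
    sites: dict[str, list[tuple[int, float]]] = {}
    reads: list[tuple[str, str, int, str, np.ndarray]] = []  # (seq_id, name, pos, seq, quals)
    haplotypes: dict[str, np.ndarray] = {}
    n_reads = max(1, round(config.coverage * length / config.read_length))

    for i in range(config.n_cds):
        seq_id = f"cds{i:04d}"
        seq = rng.choice(BASES, size=length, p=base_p)
        positions = _place_sites(config, length)
        for pos in positions:
            seq[pos - 1] = ref
        sequences[seq_id] = "".join(seq)
        sites[seq_id] = [(pos, float(p)) for pos, p in zip(positions, levels)]

        # molecule haplotypes: one molecule per read
        k = len(positions)
        linked = rng.random(n_reads) < config.linkage
        all_edit = rng.random(n_reads) < pbar
        indep = rng.random((n_reads, k)) < levels[None, :]
        edited = np.where(linked[:, None], all_edit[:, None], indep)
        haplotypes[seq_id] = edited

        starts = rng.integers(1, length - config.read_length + 2, size=n_reads)
        for r in range(n_reads):
            start = int(starts[r])
            window = list(sequences[seq_id][start - 1 : start - 1 + config.read_length])
            for s_idx, pos in enumerate(positions):
                if edited[r, s_idx] and start <= pos < start + config.read_length:
                    window[pos - start] = alt
            # sequencing errors: uniform substitution to one of the other 3 bases
            if config.error_rate > 0:
                err = rng.random(config.read_length) < config.error_rate
                for j in np.flatnonzero(err):
                    choices = [b for b in "ACGT" if b != window[j]]
                    window[j] = choices[rng.integers(0, 3)]
            if config.low_quality_fraction > 0:
                low = rng.random(config.read_length) < config.low_quality_fraction
                quals = np.where(low, config.quality_low, config.quality_high)
            else:
                quals = np.full(config.read_length, config.quality_high)
            reads.append((seq_id, f"{seq_id}_read{r:06d}", start, "".join(window), quals))

    with open(fasta_path, "w") as fh:
        for seq_id, seq in sequences.items():
            fh.write(f">{seq_id}\n{seq}\n")

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": sid, "LN": length} for sid in sequences],
    }
    with pysam.AlignmentFile(sam_path, "wh", header=header) as out:
        for seq_id, name, start, seq, quals in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.query_sequence = seq
            a.flag = 0
            a.reference_id = out.header.get_tid(seq_id)
            a.reference_start = start - 1
            a.mapping_quality = 60
            a.cigartuples = [(0, config.read_length)]
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in quals)
            )
            out.write(a)

    if fastq_path is not None:
        with open(fastq_path, "w") as fh:
            for _, name, _, seq, quals in reads:
                fh.write(f"@{name}\n{seq}\n+\n{''.join(chr(q + 33) for q in quals)}\n")

    return SimTruth(config, fasta_path, sam_path, sites, haplotypes)
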