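"""Codon-aware annotation and the nonsyn/syn adaptation test.

Each editing site inside a CDS either changes the encoded amino acid
(nonsynonymous, "recoding") or not (synonymous). The expected nonsyn/syn
ratio under no selection comes from exhaustive in-silico mutagenesis:
change every occurrence of the target base in every CDS singly, classify
each mutant codon, and tally. Observed/expected (O/E) ratios above 1,
tested by a two-sided Fisher exact test, signal positive selection on
editing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

from Bio.Data import CodonTable
from scipy import stats

from .align_io import ReferenceSet
from .editome import EditingSite

logger = logging.getLogger("edhap")

NONSYN = "Nonsyn"
SYN = "Syn"


@dataclass(frozen=True)
class CodonChange:
    """A single-base codon substitution and its protein-level effect."""

    codon_before: str
    codon_after: str
    aa_before: str  # '*' for stop
    aa_after: str
    effect: str  # Syn | Nonsyn | Stop-gain | Stop-loss

    @property
    def is_synonymous(self) -> bool:
        return self.effect == SYN

    @property
    def anno(self) -> str:
        """Two-way Nonsyn/Syn label; stop changes count as nonsynonymous."""
        return SYN if self.is_synonymous else NONSYN


@dataclass
class AdaptationTestResult:
    """Observed vs expected nonsyn/syn contingency and Fisher test."""

    obs_nonsyn: int
    obs_syn: int
    exp_nonsyn: int
    exp_syn: int
    obs_ratio: float  # NaN when obs_syn == 0
    exp_ratio: float
    oe_ratio: float
    p_value: float


def _translate(codon: str, table: CodonTable.CodonTable) -> str:
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


def _effect(aa_before: str, aa_after: str) -> str:
    if aa_before == aa_after:
        return SYN
    if aa_after == "*":
        return "Stop-gain"
    if aa_before == "*":
        return "Stop-loss"
    return NONSYN


def _codon_table(genetic_code: int) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[genetic_code]


def classify_site(
    reference: ReferenceSet,
    site: EditingSite,
    genetic_code: int = 1,
) -> CodonChange:
    """Classify one editing site by its codon change.

    The CDS frame starts at position 1. A mismatch between the site's
    stated reference base and the FASTA, or a site in a trailing partial
    codon, is a hard error (guards coordinate bugs).
    """
    cds = reference[site.seq_id]
    if not 1 <= site.pos <= len(cds):
        raise ValueError(f"position {site.pos} outside {site.seq_id} (len {len(cds)})")
    if cds[site.pos - 1] != site.ref_base:
        raise ValueError(
            f"{site.seq_id}:{site.pos}: reference base is {cds[site.pos - 1]}, "
            f"site claims {site.ref_base}"
        )
    codon_start = (site.pos - 1) // 3 * 3
    codon = cds[codon_start : codon_start + 3]
    if len(codon) < 3:
        raise ValueError(f"{site.seq_id}:{site.pos} falls in a trailing partial codon")
    offset = (site.pos - 1) % 3
    mutant = codon[:offset] + site.alt_base + codon[offset + 1 :]
    table = _codon_table(genetic_code)
    aa_before = _translate(codon, table)
    aa_after = _translate(mutant, table)
    return CodonChange(codon, mutant, aa_before, aa_after, _effect(aa_before, aa_after))


def annotate_sites(
    reference: ReferenceSet,
    sites: list[EditingSite],
    genetic_code: int = 1,
) -> list[EditingSite]:
    """Return sites with the two-way Nonsyn/Syn annotation filled in."""
    return [
        EditingSite(
            s.seq_id, s.pos, s.ref_base, s.alt_base,
            classify_site(reference, s, genetic_code).anno,
        )
        for s in sites
    ]


def expected_counts(
    reference: ReferenceSet,
    target: tuple[str, str] = ("C", "T"),
    genetic_code: int = 1,
) -> tuple[int, int]:
    """Exhaustive in-silico mutagenesis expectation (nonsyn, syn).

    Every occurrence of target[0] in every CDS is mutated singly to
    target[1] and classified; stop-gain/loss tally as nonsynonymous.
    Codons containing non-ACGT bases are skipped with a logged count.
    CDS lengths must be multiples of 3.
    """
    ref_base, alt_base = target
    table = _codon_table(genetic_code)
    nonsyn = syn = skipped = 0
    for seq_id, cds in reference.sequences.items():
        if len(cds) % 3 != 0:
            raise ValueError(f"CDS {seq_id!r} length {len(cds)} not divisible by 3")
        for codon_start in range(0, len(cds), 3):
            codon = cds[codon_start : codon_start + 3]
            if ref_base not in codon:
                continue
            if any(b not in "ACGT" for b in codon):
                skipped += 1
                continue
            aa_before = _translate(codon, table)
            for offset in range(3):
                if codon[offset] != ref_base:
                    continue
                mutant = codon[:offset] + alt_base + codon[offset + 1 :]
                if _effect(aa_before, _translate(mutant, table)) == SYN:
                    syn += 1
                else:
                    nonsyn += 1
    if skipped:
        logger.warning("expected_counts: skipped %d codons with non-ACGT bases", skipped)
    return nonsyn, syn


def adaptation_test(
    obs_nonsyn: int,
    obs_syn: int,
    exp_nonsyn: int,
    exp_syn: int,
) -> AdaptationTestResult:
    """Two-sided Fisher exact test of observed vs expected nonsyn/syn.

    Contingency table [[obs_nonsyn, obs_syn], [exp_nonsyn, exp_syn]];
    O/E ratio > 1 suggests positive selection. Ratios with a zero
    denominator are NaN; the test itself is still computed.
    """
    if min(obs_nonsyn, obs_syn, exp_nonsyn, exp_syn) < 0:
        raise ValueError("counts must be non-negative")
    obs_ratio = obs_nonsyn / obs_syn if obs_syn > 0 else math.nan
    exp_ratio = exp_nonsyn / exp_syn if exp_syn > 0 else math.nan
    oe = obs_ratio / exp_ratio if exp_ratio and not math.isnan(obs_ratio) and not math.isnan(exp_ratio) else math.nan
    _, p = stats.fisher_exact(
        [[obs_nonsyn, obs_syn], [exp_nonsyn, exp_syn]], alternative="two-sided"
    )
    return AdaptationTestResult(
        obs_nonsyn, obs_syn, exp_nonsyn, exp_syn, obs_ratio, exp_ratio, oe, float(p)
    )
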