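"""Haplotype counting, HD and θπ — checked against brute-force pair enumeration."""

from __future__ import annotations

import math
from itertools import combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from edhap import (
    EditingSite,
    HaplotypeCounts,
    ReadBaseCall,
    haplotype_diversity,
    hd_from_cells,
    nucleotide_diversity_pair,
    pair_haplotype_counts,
    pair_scan,
    per_read_bases,
    pooled_haplotype_frequency,
    theta_pi_from_cells,
)

from conftest import TOY_CDS, TOY_ID, sam_record, write_sam

S1 = EditingSite("g", 5, "C", "T", "Nonsyn")
S2 = EditingSite("g", 12, "C", "T", "Nonsyn")


def _counts(rr, ra, ar, aa):
    return HaplotypeCounts(S1, S2, rr, ra, ar, aa)


def _calls(read_bases):
    """read_bases: {read_id: (base_at_5, base_at_12)}, None = not covered."""
    calls = []
    for rid, (b1, b2) in read_bases.items():
        if b1 is not None:
            calls.append(ReadBaseCall(rid, "g", 5, b1, 40))
        if b2 is not None:
            calls.append(ReadBaseCall(rid, "g", 12, b2, 40))
    return calls


# ---- brute-force oracles: explicit enumeration over read pairs ----

def _expand(cells):
    reads = []
    for hap, n in enumerate(cells):
        reads.extend([hap] * n)
    return reads


HAMMING = [[0, 1, 1, 2], [1, 0, 2, 1], [1, 2, 0, 1], [2, 1, 1, 0]]


def hd_oracle(cells):
    reads = _expand(cells)
    pairs = list(combinations(reads, 2))
    unequal = sum(1 for a, b in pairs if a != b)
    n_obs = sum(1 for c in cells if c > 0)
    return (n_obs / 4) * unequal / len(pairs)


def theta_pi_oracle(cells):
    reads = _expand(cells)
    pairs = list(combinations(reads, 2))
    return sum(HAMMING[a][b] for a, b in pairs) / (2 * len(pairs))


# ---- haplotype counting ----

def test_fig1_case1_genotypes_tally_to_diagonal_cells():
    calls = _calls({"r1": ("C", "C"), "r2": ("C", "C"), "r3": ("T", "T"), "r4": ("T", "T")})
    c = pair_haplotype_counts(calls, S1, S2)
    assert c.cells == (2, 0, 0, 2)


def test_read_covering_one_site_is_excluded():
    calls = _calls({"r1": ("C", "C"), "r2": ("C", None)})
    assert pair_haplotype_counts(calls, S1, S2).cells == (1, 0, 0, 0)


def test_third_base_read_excluded_entirely(tmp_path):
    """6-read SAM fixture; the G-at-site2 read drops from all four cells."""
    sites = (EditingSite(TOY_ID, 5, "C", "T"), EditingSite(TOY_ID, 10, "C", "T"))
    window = TOY_CDS[:15]  # pos 5 and 10 are both C

    def variant(b5, b10):
        return window[:4] + b5 + window[5:9] + b10 + window[10:]

    recs = [
        sam_record("r1", TOY_ID, 1, variant("C", "C")),
        sam_record("r2", TOY_ID, 1, variant("C", "T")),
        sam_record("r3", TOY_ID, 1, variant("T", "C")),
        sam_record("r4", TOY_ID, 1, variant("T", "T")),
        sam_record("r5", TOY_ID, 1, variant("T", "T")),
        sam_record("r6", TOY_ID, 1, variant("C", "G")),  # third base at site2
    ]
    calls = per_read_bases(
        write_sam(tmp_path / "a.sam", recs), [(TOY_ID, 5), (TOY_ID, 10)]
    )
    c = pair_haplotype_counts(calls, *sites)
    assert c.cells == (1, 1, 1, 2)
    assert c.total == 5


def test_sites_on_different_sequences_is_error():
    other = EditingSite("h", 12, "C", "T")
    with pytest.raises(ValueError, match="same sequence"):
        pair_haplotype_counts([], S1, other)


def test_site_order_is_normalised():
    calls = _calls({"r1": ("T", "C")})
    assert pair_haplotype_counts(calls, S2, S1).cells == (0, 0, 1, 0)


# ---- HD and θπ ----

@pytest.mark.parametrize(
    "cells, expected",
    [
        ((2, 0, 0, 2), 1 / 3),
        ((1, 1, 1, 1), 1.0),
        ((5, 0, 0, 0), 0.0),
        ((2, 1, 1, 1), 0.9),
    ],
)
def test_haplotype_diversity_worked_examples(cells, expected):
    assert haplotype_diversity(_counts(*cells)) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "cells, expected",
    [
        ((2, 0, 0, 2), 2 / 3),
        ((1, 1, 1, 1), 2 / 3),
        ((2, 1, 1, 1), 0.6),
    ],
)
def test_nucleotide_diversity_worked_examples(cells, expected):
    assert nucleotide_diversity_pair(_counts(*cells)) == pytest.approx(expected, abs=1e-12)


def test_undefined_below_two_reads():
    assert math.isnan(hd_from_cells((1, 0, 0, 0)))
    assert math.isnan(theta_pi_from_cells((0, 0, 0, 0)))


cell_vectors = st.tuples(*[st.integers(0, 12)] * 4).filter(lambda c: sum(c) >= 2)


@settings(max_examples=300, derandomize=True, deadline=None)
@given(cells=cell_vectors)
def test_formulas_match_pair_enumeration_oracle(cells):
    assert hd_from_cells(cells) == pytest.approx(hd_oracle(cells), abs=1e-12)
    assert theta_pi_from_cells(cells) == pytest.approx(theta_pi_oracle(cells), abs=1e-12)


@settings(max_examples=300, derandomize=True, deadline=None)
@given(cells=cell_vectors)
def test_hd_bounds_and_single_haplotype_zero(cells):
    hd = hd_from_cells(cells)
    assert 0 <= hd <= 1
    n_obs = sum(1 for c in cells if c > 0)
    assert (hd == 0) == (n_obs == 1)


@settings(max_examples=300, derandomize=True, deadline=None)
@given(cells=cell_vectors)
def test_label_symmetry(cells):
    rr, ra, ar, aa = cells
    transposed = (rr, ar, ra, aa)  # swap site1/site2
    flipped = (aa, ar, ra, rr)     # swap ref<->alt at both sites jointly
    for variant in (transposed, flipped):
        assert hd_from_cells(variant) == pytest.approx(hd_from_cells(cells), abs=1e-12)
        assert theta_pi_from_cells(variant) == pytest.approx(
            theta_pi_from_cells(cells), abs=1e-12
        )


def test_theta_pi_depends_only_on_marginals_hd_does_not():
    # (2,0,0,2) and (1,1,1,1): same marginal allele counts at both sites
    assert theta_pi_from_cells((2, 0, 0, 2)) == pytest.approx(
        theta_pi_from_cells((1, 1, 1, 1)), abs=1e-12
    )
    assert hd_from_cells((2, 0, 0, 2)) != pytest.approx(hd_from_cells((1, 1, 1, 1)))


def test_complete_linkage_bounds_hd_below_030():
    """Two-haplotype (RR/AA only) vectors with N >= 5 never exceed HD 0.3."""
    for n in range(5, 31):
        for rr in range(1, n):
            hd = hd_from_cells((rr, 0, 0, n - rr))
            assert hd <= 0.3 + 1e-12


# ---- pair scan and pooling ----

def test_pair_scan_enumerates_all_same_sequence_pairs():
    sites = [EditingSite("g", p, "C", "T", "Nonsyn") for p in (5, 12, 20)]
    records = pair_scan(sites, [], min_reads=5)
    assert len(records) == 3
    assert all(not r.passes_min_reads for r in records)


def test_pair_scan_filters_to_nonsynonymous_sites():
    sites = [
        EditingSite("g", 5, "C", "T", "Nonsyn"),
        EditingSite("g", 12, "C", "T", "Syn"),
        EditingSite("g", 20, "C", "T", "Nonsyn"),
    ]
    records = pair_scan(sites, [], anno_class="Nonsyn")
    assert len(records) == 1
    assert (records[0].counts.site1.pos, records[0].counts.site2.pos) == (5, 20)


def test_pair_scan_never_pairs_across_sequences():
    sites = [
        EditingSite("g", 5, "C", "T", "Nonsyn"),
        EditingSite("h", 12, "C", "T", "Nonsyn"),
    ]
    assert pair_scan(sites, []) == []


@pytest.mark.parametrize(
    "cell_sets, expected",
    [
        ([(2, 0, 0, 2)], (0.5, 0, 0, 0.5)),
        ([(1, 1, 1, 1), (1, 1, 1, 1)], (0.25, 0.25, 0.25, 0.25)),
    ],
)
def test_pooled_haplotype_frequency(cell_sets, expected):
    records = [_counts(*c) for c in cell_sets]
    assert pooled_haplotype_frequency(records) == pytest.approx(expected)


def test_pooled_frequency_requires_records():
    with pytest.raises(ValueError):
        pooled_haplotype_frequency([])
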