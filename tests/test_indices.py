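"""Editing indices: AEI, CEI, per-site levels, UTR-Alu selection, centralization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aluedit.annotations import EditingSite, GenomicInterval
from aluedit.indices import (
    centralization,
    compute_aei,
    compute_cei,
    edited_transcript_counts,
    select_utr3_alus,
    site_levels,
)
from aluedit.pileup import PileupTable


def make_pile(entries):
    """Build a PileupTable directly: entries = {(chrom,pos): (ref, strand, (A,C,G,T))}."""
    table = PileupTable()
    by_chrom = {}
    for (chrom, pos), (ref, strand, counts) in entries.items():
        by_chrom.setdefault(chrom, []).append((pos, ref, strand, counts))
    for chrom, rows in by_chrom.items():
        rows.sort()
        table._add_chrom(
            chrom,
            np.array([r[0] for r in rows], dtype=np.int64),
            np.array([r[1] for r in rows], dtype="<U1"),
            np.array([r[2] for r in rows], dtype="<U1"),
        )
        table._chroms[chrom]["counts"][:] = [r[3] for r in rows]
    return table


class TestAEI:
    def test_three_positions_pooled(self):
        # three reference-A positions, each A=8 G=2 -> 100*6/30 = 20%
        pile = make_pile(
            {("chr1", p): ("A", "+", (8, 0, 2, 0)) for p in (10, 11, 12)}
        )
        res = compute_aei(pile, [GenomicInterval("chr1", 9, 12, "+")])
        assert (res.numerator, res.denominator) == (6, 30)
        assert res.index_pct == pytest.approx(20.0)

    @pytest.mark.parametrize(
        "counts,expected", [((10, 0, 0, 0), 0.0), ((0, 0, 10, 0), 100.0)]
    )
    def test_extremes(self, counts, expected):
        pile = make_pile({("chr1", 10): ("A", "+", counts)})
        res = compute_aei(pile, [GenomicInterval("chr1", 9, 10, "+")])
        assert res.index_pct == pytest.approx(expected)

    def test_minus_strand_uses_t_and_c(self):
        # antisense editing shows as T->C on the reference strand
        pile = make_pile({("chr1", 10): ("T", "-", (0, 1, 0, 3))})
        res = compute_aei(pile, [GenomicInterval("chr1", 9, 10, "-")])
        assert (res.numerator, res.denominator) == (1, 4)

    def test_non_a_positions_ignored(self):
        pile = make_pile(
            {
                ("chr1", 10): ("A", "+", (8, 0, 2, 0)),
                ("chr1", 11): ("C", "+", (0, 10, 0, 0)),
                ("chr1", 12): ("G", "+", (0, 0, 10, 0)),
            }
        )
        res = compute_aei(pile, [GenomicInterval("chr1", 9, 12, "+")])
        assert (res.numerator, res.denominator) == (2, 10)

    def test_counts_add_over_partition(self, rng):
        entries = {}
        for p in range(1, 61):
            counts = tuple(int(c) for c in rng.integers(0, 20, size=4))
            entries[("chr1", p)] = (str(rng.choice(list("ACGT"))), "+", counts)
        pile = make_pile(entries)
        whole = compute_aei(pile, [GenomicInterval("chr1", 0, 60, "+")])
        left = compute_aei(pile, [GenomicInterval("chr1", 0, 30, "+")])
        right = compute_aei(pile, [GenomicInterval("chr1", 30, 60, "+")])
        assert whole.numerator == left.numerator + right.numerator
        assert whole.denominator == left.denominator + right.denominator

    def test_zero_denominator_is_nan_with_warning(self):
        pile = make_pile({("chr1", 10): ("C", "+", (0, 5, 0, 0))})
        with pytest.warns(UserWarning, match="zero"):
            res = compute_aei(pile, [GenomicInterval("chr1", 9, 10, "+")])
        assert np.isnan(res.index_pct)


class TestSiteLevels:
    def test_plus_strand_level_and_inclusion(self):
        pile = make_pile({("chr1", 100): ("A", "+", (74, 0, 26, 0))})
        table = site_levels(pile, [EditingSite("chr1", 100, "+", "IGFBP7")])
        row = table.iloc[0]
        assert row["level_pct"] == pytest.approx(26.0)
        assert row["coverage"] == 100 and bool(row["included"])

    def test_below_ten_reads_excluded_but_level_computed(self):
        pile = make_pile({("chr1", 100): ("A", "+", (6, 0, 3, 0))})
        row = site_levels(pile, [EditingSite("chr1", 100, "+", "G")]).iloc[0]
        assert row["level_pct"] == pytest.approx(100 * 3 / 9)
        assert not row["included"]

    def test_minus_strand_complement_arithmetic(self):
        pile = make_pile({("chr1", 100): ("T", "-", (0, 1, 0, 3))})
        row = site_levels(pile, [EditingSite("chr1", 100, "-", "G")]).iloc[0]
        assert row["level_pct"] == pytest.approx(25.0)

    def test_zero_edited_is_representable_not_detected(self):
        pile = make_pile({("chr1", 100): ("A", "+", (50, 0, 0, 0))})
        row = site_levels(pile, [EditingSite("chr1", 100, "+", "G")]).iloc[0]
        assert row["level_pct"] == 0.0 and not row["detected"]


class TestCEI:
    def test_two_site_example(self):
        table = pd.DataFrame({"edited": [5, 0], "coverage": [50, 50]})
        assert compute_cei(table).index_pct == pytest.approx(5.0)

    def test_fully_edited(self):
        table = pd.DataFrame({"edited": [10, 20], "coverage": [10, 20]})
        assert compute_cei(table).index_pct == pytest.approx(100.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_equals_coverage_weighted_mean_of_levels(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(1, 40))
        cov = r.integers(1, 500, size=n)
        edited = r.integers(0, cov + 1)
        table = pd.DataFrame({"edited": edited, "coverage": cov})
        cei = compute_cei(table).index_pct
        levels = 100.0 * edited / cov
        weighted = float((levels * cov).sum() / cov.sum())
        assert cei == pytest.approx(weighted, abs=1e-12)


class TestUtr3AluSelection:
    UTR = GenomicInterval("chr1", 0, 2000, "+", "utr")

    def a(self, start, length, strand):
        return GenomicInterval("chr1", start, start + length, strand)

    def test_mutual_opposite_partners_both_returned(self):
        plus, minus = self.a(100, 300, "+"), self.a(600, 280, "-")
        assert select_utr3_alus([plus, minus], [self.UTR]) == [plus, minus]

    def test_single_alu_has_no_partner(self):
        assert select_utr3_alus([self.a(100, 300, "+")], [self.UTR]) == []

    def test_short_partner_qualifies_only_the_long_alu(self):
        long_plus, short_minus = self.a(100, 300, "+"), self.a(600, 100, "-")
        assert select_utr3_alus([long_plus, short_minus], [self.UTR]) == [long_plus]
        # strict mode additionally requires the partner itself to pass min_len
        assert select_utr3_alus(
            [long_plus, short_minus], [self.UTR], strict_partner=True
        ) == []

    def test_same_strand_pair_excluded(self):
        pair = [self.a(100, 300, "+"), self.a(600, 300, "+")]
        assert select_utr3_alus(pair, [self.UTR]) == []

    def test_partial_overlap_not_contained(self):
        inside, hanging = self.a(100, 300, "+"), self.a(1900, 300, "-")
        assert select_utr3_alus([inside, hanging], [self.UTR]) == []

    def test_order_invariance_and_global_strand_swap(self):
        alus = [self.a(100, 300, "+"), self.a(600, 280, "-"), self.a(950, 120, "+")]
        fwd = select_utr3_alus(alus, [self.UTR])
        rev = select_utr3_alus(alus[::-1], [self.UTR])
        assert fwd == rev
        flip = {"+": "-", "-": "+"}
        flipped = [
            GenomicInterval(a.chrom, a.start, a.end, flip[a.strand]) for a in alus
        ]
        swapped = select_utr3_alus(flipped, [self.UTR])
        assert {(a.start, a.end) for a in swapped} == {(a.start, a.end) for a in fwd}


class TestActivity:
    def test_gene_aggregation(self):
        table = pd.DataFrame(
            {"site": ["s1", "s2", "s3"], "gene": ["G1", "G1", "G2"],
             "edited": [3, 4, 7], "coverage": [10, 10, 10]}
        )
        counts = edited_transcript_counts(table, by="gene")
        assert counts["G1"] == 7 and counts["G2"] == 7

    def test_empty_table(self):
        assert edited_transcript_counts(pd.DataFrame(), by="gene").sum() == 0

    def test_sample_totals_conserve(self):
        table = pd.DataFrame(
            {"sample": ["a", "a", "b"], "site": ["s1", "s2", "s1"],
             "gene": ["G", "G", "G"], "edited": [1, 2, 5], "coverage": [9, 9, 9]}
        )
        by_sample = edited_transcript_counts(table, by="sample")
        assert by_sample["a"] == 3 and by_sample["b"] == 5
        assert by_sample.sum() == table["edited"].sum()

    @pytest.mark.parametrize(
        "activity,k,expected",
        [
            ([90, 5, 3, 1, 1], 5, 1.0),
            ([50, 30, 10, 5, 3, 2], 5, 0.98),
            ([1] * 10, 5, 0.5),
        ],
    )
    def test_centralization(self, activity, k, expected):
        assert centralization(pd.Series(activity), k) == pytest.approx(expected)

    def test_centralization_all_zero_is_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(centralization(pd.Series([0, 0, 0])))
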