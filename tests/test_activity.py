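import math

import numpy as np
import pandas as pd
import pytest

from actampl.activity import (
    DNA_ENRICHED,
    PROPORTIONAL,
    RNA_ENRICHED,
    UNDEFINED,
    bulk_expression_ratio,
    classify_proportionality,
    efficiency_from_slope,
    expression_ratio_table,
    expression_summary,
    group_expression_ratio,
    group_frequencies,
    proportionality_table,
    rank_abundant_otus,
)
from actampl.tables import (
    QpcrRecord,
    QpcrTable,
    TaxonomyMap,
    ValidationError,
)
from conftest import make_table


def _paired(counts_dna, counts_rna, otu_ids=None):
    n = len(counts_dna)
    dna = make_table(
        np.array(counts_dna).reshape(n, -1),
        otu_ids=otu_ids,
        sample_ids=["A_DNA"],
        stations=["A"],
        libraries=["DNA"],
    )
    rna = make_table(
        np.array(counts_rna).reshape(n, -1),
        otu_ids=otu_ids,
        sample_ids=["A_RNA"],
        stations=["A"],
        libraries=["RNA"],
    )
    return dna, rna


class TestRanking:
    def test_hand_aggregation(self):
        dna, rna = _paired([60, 5, 1], [40, 5, 0], otu_ids=["a", "b", "c"])
        rk = rank_abundant_otus(dna, rna, n=2)
        assert list(rk.index) == ["a", "b"]
        assert rk["aggregated_reads"].tolist() == [100, 10]
        assert rk["cumulative_fraction"].iloc[-1] == pytest.approx(110 / 111)

    def test_ties_break_lexicographically(self):
        dna, rna = _paired([5, 5, 5], [5, 5, 5], otu_ids=["z", "m", "a"])
        rk = rank_abundant_otus(dna, rna, n=3)
        assert list(rk.index) == ["a", "m", "z"]

    def test_full_ranking_conserves_mass(self):
        dna, rna = _paired([3, 2, 1], [1, 2, 3])
        rk = rank_abundant_otus(dna, rna, n=3)
        assert rk["cumulative_fraction"].iloc[-1] == pytest.approx(1.0)

    def test_n_larger_than_universe_truncates(self):
        dna, rna = _paired([3, 2], [1, 2])
        rk = rank_abundant_otus(dna, rna, n=10)
        assert len(rk) == 2


class TestGroupFrequencies:
    def test_dominant_group_frequency(self):
        table = make_table(
            [[98], [2]], sample_ids=["A_DNA"], stations=["A"], libraries=["DNA"]
        )
        tax = TaxonomyMap({"OTU1": "Trichodesmium", "OTU2": "other"})
        freqs = group_frequencies(table, tax)
        assert freqs.frequency("Trichodesmium", "A", "DNA") == pytest.approx(0.98)

    def test_frequencies_sum_to_one_per_sample(self, paired_station_table):
        tax = TaxonomyMap({"OTU1": "g1", "OTU2": "g2", "OTU3": "other"})
        freqs = group_frequencies(paired_station_table, tax)
        per = freqs.per_station
        for (col, lib) in (("f_dna", "DNA"), ("f_rna", "RNA")):
            sums = per[col].groupby(level="station").sum()
            for v in sums:
                assert v == pytest.approx(1.0, abs=1e-9) or v == pytest.approx(0.0)


class TestProportionality:
    def test_on_the_line_is_proportional(self):
        assert classify_proportionality(0.5, 0.5) == PROPORTIONAL

    def test_cluster_iii_like_is_dna_enriched(self):
        # present at ~1.1% of DNA reads, negligible in RNA
        assert classify_proportionality(0.011, 0.0) == DNA_ENRICHED
        assert classify_proportionality(0.011, 0.0001) == DNA_ENRICHED

    def test_unicellular_like_is_rna_enriched(self):
        # 0.01% of DNA reads vs 0.5% of RNA reads
        assert classify_proportionality(0.0001, 0.005) == RNA_ENRICHED

    def test_both_zero_undefined(self):
        assert classify_proportionality(0.0, 0.0) == UNDEFINED

    def test_threshold_boundary_inclusive(self):
        assert classify_proportionality(0.1, 0.2, threshold=2) == PROPORTIONAL
        assert classify_proportionality(0.1, 0.201, threshold=2) == RNA_ENRICHED

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValidationError):
            classify_proportionality(0.1, 0.1, threshold=1.0)

    def test_table_output(self):
        dna, rna = _paired([90, 10, 0], [50, 10, 40], otu_ids=["a", "b", "c"])
        tab = proportionality_table(dna, rna)
        assert tab.loc["c", "class"] == RNA_ENRICHED
        assert set(tab.columns) == {"f_dna", "f_rna", "log2_rna_dna", "class"}


class TestEfficiency:
    def test_perfect_doubling_slope(self):
        assert efficiency_from_slope(-1 / math.log10(2)) == pytest.approx(2.0, abs=1e-4)

    def test_typical_slope(self):
        assert efficiency_from_slope(-3.5) == pytest.approx(1.9307, abs=1e-4)

    def test_positive_slope_rejected(self):
        with pytest.raises(ValidationError):
            efficiency_from_slope(1.0)


def _qpcr(ct_dna, ct_cdna, station="A"):
    return QpcrTable(
        [
            QpcrRecord("d", station, "DNA", list(np.atleast_1d(ct_dna))),
            QpcrRecord("c", station, "cDNA", list(np.atleast_1d(ct_cdna))),
        ]
    )


class TestExpressionRatios:
    def test_equal_ct_gives_unity(self):
        for e in (1.5, 1.9, 2.0):
            assert bulk_expression_ratio(_qpcr(21.0, 21.0), e, "A") == pytest.approx(1.0)

    def test_lower_cdna_ct_means_more_transcript(self):
        # Ct(DNA)=20, Ct(cDNA)=22 -> dCt=-2 -> R=0.25 at E=2
        assert bulk_expression_ratio(_qpcr(20.0, 22.0), 2.0, "A") == pytest.approx(0.25)

    def test_replicates_averaged_on_ct_scale(self):
        q = _qpcr([20.0, 21.0, 22.0], [20.0, 20.0, 20.0])
        # mean Ct(DNA)=21, dCt=1 -> R=1.9 at E=1.9
        assert bulk_expression_ratio(q, 1.9, "A") == pytest.approx(1.9)

    def test_missing_template_raises_keyerror(self):
        q = QpcrTable([QpcrRecord("d", "A", "DNA", [20.0])])
        with pytest.raises(KeyError):
            bulk_expression_ratio(q, 2.0, "A")

    def test_group_ratio_worked_example(self):
        # bulk 0.17, dominant genus at 87% of RNA and 98% of DNA reads
        assert round(group_expression_ratio(0.17, 0.87, 0.98), 2) == 0.15

    def test_group_ratio_identity_when_frequencies_equal(self):
        assert group_expression_ratio(0.42, 0.3, 0.3) == pytest.approx(0.42)

    def test_absent_from_dna_library_is_undefined(self):
        assert np.isnan(group_expression_ratio(0.5, 0.2, 0.0))

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValidationError):
            group_expression_ratio(0.5, -0.1, 0.2)

    def test_monotonicity(self):
        base = group_expression_ratio(0.5, 0.4, 0.2)
        assert group_expression_ratio(0.5, 0.5, 0.2) > base
        assert group_expression_ratio(0.5, 0.4, 0.3) < base


class TestExpressionTable:
    def _freqs(self, table, tax):
        return group_frequencies(table, tax)

    def test_weighted_consistency_identity(self):
        """sum_g f_DNA,g * R_group,g == R_bulk when every group is defined."""
        counts = np.array([[70, 50, 60, 30], [20, 30, 30, 50], [10, 20, 10, 20]])
        table = make_table(
            counts,
            sample_ids=["A_DNA", "A_RNA", "B_DNA", "B_RNA"],
            stations=["A", "A", "B", "B"],
            libraries=["DNA", "RNA", "DNA", "RNA"],
        )
        tax = TaxonomyMap({"OTU1": "g1", "OTU2": "g2", "OTU3": "g3"})
        freqs = group_frequencies(table, tax)
        qpcr = QpcrTable(
            [
                QpcrRecord("ad", "A", "DNA", [20.0]),
                QpcrRecord("ac", "A", "cDNA", [21.5]),
                QpcrRecord("bd", "B", "DNA", [19.0]),
                QpcrRecord("bc", "B", "cDNA", [18.0]),
            ]
        )
        expr = expression_ratio_table(qpcr, freqs, efficiency=2.0)
        for station, sub in expr.groupby(level="station"):
            r_bulk = sub["r_bulk"].iloc[0]
            assert (sub["f_dna"] * sub["r_group"]).sum() == pytest.approx(r_bulk)

    def test_missing_station_skipped_with_notice(self):
        table = make_table(
            [[70, 50], [30, 50]],
            sample_ids=["A_DNA", "A_RNA"],
            stations=["A", "A"],
            libraries=["DNA", "RNA"],
        )
        tax = TaxonomyMap({"OTU1": "g1", "OTU2": "g2"})
        freqs = group_frequencies(table, tax)
        qpcr = QpcrTable([QpcrRecord("ad", "A", "DNA", [20.0])])
        expr = expression_ratio_table(qpcr, freqs, efficiency=2.0)
        assert expr.attrs["skipped_stations"] == ["A"]
        assert len(expr) == 0 or expr.empty

    def test_summary_shape(self):
        table = make_table(
            [[70, 50], [30, 50]],
            sample_ids=["A_DNA", "A_RNA"],
            stations=["A", "A"],
            libraries=["DNA", "RNA"],
        )
        tax = TaxonomyMap({"OTU1": "g1", "OTU2": "g2"})
        freqs = group_frequencies(table, tax)
        qpcr = _qpcr(20.0, 21.0)
        expr = expression_ratio_table(qpcr, freqs, efficiency=2.0)
        s = expression_summary(expr)
        assert s["r_bulk_mean"] == pytest.approx(0.5)
        assert set(s["groups"]) == {"g1", "g2"}
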