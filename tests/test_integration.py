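"""Contingency statistics, mark-matrix assembly, groups, tallies, burden."""

import math

import numpy as np
import pandas as pd
import pytest

from oracles import fisher_two_sided_enum, randomization_mid_p

from epiweave.chromatin import ActiveEnhancer, DiffFeature
from epiweave.expression import DERecord, classify_de
from epiweave.integration import (
    MARK_COLUMNS,
    assign_groups,
    association_report,
    build_mark_matrix,
    chi_square_2x2,
    epigenetic_group,
    fisher_2x2,
    mark_weight_tally,
    modification_burden,
)
from epiweave.intervals import GenomicInterval
from epiweave.methylome import DMR


def _dmr(chrom, start, end, direction, location, genes):
    return DMR(
        region=GenomicInterval(chrom, start, end),
        n_cpg=6, level_control=0.4, level_treated=0.1, fold_change=4.0,
        direction=direction, p_value=1e-6, q_value=1e-5,
        location=location, linked_genes=tuple(genes),
    )


class TestChiSquare:
    @pytest.mark.parametrize(
        "table, printed_one_sided",
        [
            ([[10, 152], [0, 76]], 0.0135),   # promoter hypo-methylation vs up/down
            ([[4, 9], [3, 30]], 0.0327),      # panel promoters
            ([[5, 8], [0, 3]], 0.0976),       # panel H3K4me3 gains
            ([[24, 138], [1, 75]], 0.0008),   # hypo-methylated enhancers
            ([[33, 129], [5, 71]], 0.0034),   # intergenic hypo-methylation
            ([[12, 1], [11, 22]], 0.0002),    # panel gene bodies
        ],
    )
    def test_one_sided_reproduces_published_values(self, table, printed_one_sided):
        res = chi_square_2x2(table)
        assert res.p_one_sided == pytest.approx(printed_one_sided, abs=5e-5)
        assert res.direction_positive

    def test_no_association_gives_chi2_zero(self):
        res = chi_square_2x2([[5, 5], [5, 5]])
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_two_sided == pytest.approx(1.0)

    def test_negative_direction_one_sided_complement(self):
        res = chi_square_2x2([[1, 20], [10, 11]])
        assert not res.direction_positive
        assert res.p_one_sided == pytest.approx(1 - res.p_two_sided / 2)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2([[0, 0], [5, 5]])

    def test_yates_correction_flag_shrinks_statistic(self):
        plain = chi_square_2x2([[10, 152], [0, 76]])
        yates = chi_square_2x2([[10, 152], [0, 76]], correction=True)
        assert yates.chi2 < plain.chi2

    def test_one_sided_agrees_with_randomization_mid_p(self):
        # validity regime (all expected cells well above 5): the asymptotic
        # one-sided P tracks the fixed-margins randomization mid-P
        rng = np.random.default_rng(99)
        table = [[100, 50], [80, 70]]
        res = chi_square_2x2(table)
        mc = randomization_mid_p(table, 50_000, rng)
        se = math.sqrt(mc * (1 - mc) / 50_000)
        assert abs(res.p_one_sided - mc) < 3 * se + 5e-4


class TestFisher:
    def test_fully_crossed_table(self):
        res = fisher_2x2([[0, 5], [5, 0]])
        assert res.p_two_sided == pytest.approx(2 / 252, abs=1e-12)

    def test_uniform_table_p_one(self):
        assert fisher_2x2([[1, 1], [1, 1]]).p_two_sided == pytest.approx(1.0)

    def test_matches_enumeration_oracle_randomized(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            cells = rng.multinomial(int(rng.integers(4, 61)), [0.25] * 4)
            table = [[int(cells[0]), int(cells[1])], [int(cells[2]), int(cells[3])]]
            res = fisher_2x2(table)
            assert res.p_two_sided == pytest.approx(
                fisher_two_sided_enum(table), abs=1e-10
            )

    def test_odds_ratio_infinite_with_haldane_fallback(self):
        res = fisher_2x2([[5, 0], [2, 7]])
        assert math.isinf(res.odds_ratio)
        assert res.odds_ratio_haldane == pytest.approx((5.5 * 7.5) / (0.5 * 2.5))


class ToyStudy:
    """A tiny fully-enumerable study for matrix-assembly oracles."""

    genes = ["g1", "g2", "g3", "g4", "g5"]
    dmrs = [
        _dmr("chr1", 0, 100, "hypo", "gene_body", ["g1"]),
        _dmr("chr1", 200, 300, "hypo", "promoter", ["g2"]),
        _dmr("chr1", 400, 500, "hyper", "intergenic", ["g2", "g3"]),
    ]
    diff_features = [
        DiffFeature(GenomicInterval("chr1", 0, 50), "OCR", "gain", 0.001, ("g1",)),
        DiffFeature(GenomicInterval("chr1", 60, 90), "H3K27ac", "gain", 0.001, ("g1",)),
        DiffFeature(GenomicInterval("chr1", 100, 130), "H3K4me3", "loss", 0.001, ("g4",)),
        DiffFeature(GenomicInterval("chr1", 150, 180), "H3K27ac", "gain", 0.5, ("g5",)),  # fails FDR
    ]
    enhancers_pre = [ActiveEnhancer(GenomicInterval("chr1", 0, 10), "gene_body", ("g1",))]
    enhancers_post = [ActiveEnhancer(GenomicInterval("chr1", 0, 10), "gene_body", ("g1", "g3"))]
    links50 = {"g1": enhancers_post}
    de = classify_de(
        [
            DERecord("g1", 8.0, 0.001),
            DERecord("g2", 6.0, 0.001),
            DERecord("g3", 0.3, 0.001),
            DERecord("g4", 0.2, 0.001),
            DERecord("g5", 1.1, 0.8),
        ]
    )


class TestBuildMarkMatrix:
    def matrix(self):
        s = ToyStudy
        return build_mark_matrix(
            s.genes, s.dmrs, s.diff_features, s.enhancers_pre, s.enhancers_post,
            s.links50, s.de,
        )

    def test_matches_hand_derived_join(self):
        m = self.matrix()
        expected_true = {
            "g1": {"hypo_gene_body", "diff_ocr_gain", "k27ac_gain",
                   "enhancer_pre", "enhancer_post", "hypo_enhancer_50kb"},
            "g2": {"hypo_promoter", "hyper_intergenic"},
            "g3": {"hyper_intergenic", "enhancer_post"},
            "g4": {"k4me3_loss"},
            "g5": set(),
        }
        for gene, marks in expected_true.items():
            for col in MARK_COLUMNS:
                assert bool(m.loc[gene, col]) == (col in marks), (gene, col)
        assert m["de_class"].tolist() == ["up", "up", "down", "down", "unchanged"]

    def test_unknown_gene_rejected(self):
        s = ToyStudy
        with pytest.raises(KeyError):
            build_mark_matrix(["g1"], s.dmrs, [], [], [], {}, [])

    def test_gene_with_no_features_is_all_false(self):
        m = self.matrix()
        assert not m.loc["g5", list(MARK_COLUMNS)].any()


class TestAssociationReport:
    def matrix_with_counts(self, n_up, up_marked, n_down, down_marked):
        genes = [f"u{i}" for i in range(n_up)] + [f"d{i}" for i in range(n_down)]
        m = pd.DataFrame(False, index=pd.Index(genes, name="gene_id"),
                         columns=list(MARK_COLUMNS))
        m.loc[[f"u{i}" for i in range(up_marked)], "hypo_gene_body"] = True
        m.loc[[f"d{i}" for i in range(down_marked)], "hypo_gene_body"] = True
        m["de_class"] = ["up"] * n_up + ["down"] * n_down
        return m

    def test_published_gene_body_proportions(self):
        m = self.matrix_with_counts(162, 55, 76, 6)
        rep = association_report(m, "hypo_gene_body")
        assert (rep["up_pct"], rep["down_pct"]) == (33.95, 7.89)
        assert rep["table"] == [[55, 107], [6, 70]]
        assert rep["p_one_sided"] < 1e-4

    def test_zero_margin_reported_as_nan(self):
        m = self.matrix_with_counts(10, 0, 10, 0)
        rep = association_report(m, "hypo_gene_body")
        assert math.isnan(rep["p_one_sided"]) and rep["result"] is None

    def test_counts_match_hand_fractions(self):
        m = self.matrix_with_counts(20, 5, 10, 2)
        rep = association_report(m, "hypo_gene_body")
        assert rep["up_pct"] == pytest.approx(25.0)
        assert rep["down_pct"] == pytest.approx(20.0)


class TestGroups:
    def row(self, hypo=False, ocr=False, k27=False):
        r = {c: False for c in MARK_COLUMNS}
        r["hypo_gene_body"] = hypo
        r["diff_ocr_gain"] = ocr
        r["k27ac_gain"] = k27
        return r

    @pytest.mark.parametrize(
        "hypo, ocr, k27, expected",
        [
            (True, True, True, "Group1"),
            (True, False, True, "Group2"),
            (True, True, False, "Group3"),
            (True, False, False, "Group4"),
            (False, True, True, "ungrouped"),
            (False, False, False, "ungrouped"),
        ],
    )
    def test_group_rules(self, hypo, ocr, k27, expected):
        assert epigenetic_group(self.row(hypo, ocr, k27)) == expected

    def test_any_hypo_compartment_counts(self):
        r = self.row()
        r["hypo_intergenic"] = True
        assert epigenetic_group(r) == "Group4"

    def test_labels_partition_random_matrices(self):
        rng = np.random.default_rng(17)
        m = pd.DataFrame(
            rng.random((200, len(MARK_COLUMNS))) < 0.3,
            columns=list(MARK_COLUMNS),
            index=pd.Index([f"g{i}" for i in range(200)], name="gene_id"),
        )
        m["de_class"] = "up"
        labels = assign_groups(m)
        assert labels.isin(["Group1", "Group2", "Group3", "Group4", "ungrouped"]).all()
        assert labels.value_counts().sum() == 200


class TestTallyAndBurden:
    def test_single_gene_tally(self):
        m = pd.DataFrame(False, index=pd.Index(["g1"], name="gene_id"),
                         columns=list(MARK_COLUMNS))
        m.loc["g1", "hypo_gene_body"] = True
        m["de_class"] = "up"
        tally = mark_weight_tally(m)
        hypo_row = tally[tally["mark"] == "hypo_gene_body"].iloc[0]
        assert (hypo_row["up_count"], hypo_row["down_count"]) == (1, 0)
        assert tally["up_count"].sum() == 1 and tally["down_count"].sum() == 0

    def test_tally_equals_column_sums_by_class(self):
        rng = np.random.default_rng(23)
        m = pd.DataFrame(
            rng.random((50, len(MARK_COLUMNS))) < 0.4,
            columns=list(MARK_COLUMNS),
            index=pd.Index([f"g{i}" for i in range(50)], name="gene_id"),
        )
        m["de_class"] = rng.choice(["up", "down", "unchanged"], size=50)
        tally = mark_weight_tally(m)
        for _, row in tally.iterrows():
            assert row["up_count"] == int(m.loc[m.de_class == "up", row["mark"]].sum())
            assert row["down_count"] == int(m.loc[m.de_class == "down", row["mark"]].sum())

    def test_burden_counts_types_not_marks(self):
        m = pd.DataFrame(False, index=pd.Index(["g1", "g2"], name="gene_id"),
                         columns=list(MARK_COLUMNS))
        # g1 carries all four types (one of them via two marks)
        for col in ("hypo_gene_body", "hyper_promoter", "diff_ocr_gain",
                    "k27ac_gain", "k4me3_gain"):
            m.loc["g1", col] = True
        m["de_class"] = ["up", "down"]
        counts, hist = modification_burden(m)
        assert counts["g1"] == 4  # 5 marks collapse to 4 types
        assert counts["g2"] == 0
        for _, grp in hist.groupby("de_class"):
            assert grp["pct"].sum() == pytest.approx(100.0)

    def test_empty_class_histogram(self):
        m = pd.DataFrame(False, index=pd.Index([], name="gene_id"),
                         columns=list(MARK_COLUMNS))
        m["de_class"] = pd.Series(dtype=str)
        counts, hist = modification_burden(m)
        assert len(counts) == 0 and len(hist) == 0
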