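"""CpG report parsing, segmentation, DMR calling and merging."""

import math
import random

import numpy as np
import pytest

from oracles import fisher_two_sided_enum

from epiweave.intervals import GeneModel, GenomicInterval
from epiweave.methylome import (
    CpGSiteCounts,
    DmrParams,
    annotate_dmrs,
    call_dmrs,
    merge_adjacent_dmrs,
    methylation_level,
    read_cpg_report,
    segment_candidates,
    write_cpg_report,
)


def sites(spec, chrom="chr1"):
    """Build sites from (pos, meth, total) triples."""
    return [CpGSiteCounts(chrom, p, "+", m, t) for p, m, t in spec]


class TestReadCpgReport:
    def test_position_conversion_and_total(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("chr1\t101\t+\t5\t5\n")
        (s,) = read_cpg_report(p)
        assert (s.pos, s.meth_count, s.total_count) == (100, 5, 10)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("")
        assert read_cpg_report(p) == []

    def test_negative_count_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("chr1\t101\t+\t-1\t5\n")
        with pytest.raises(ValueError):
            read_cpg_report(p)

    def test_non_cpg_context_filtered(self, tmp_path):
        p = tmp_path / "ctx.tsv"
        p.write_text("chr1\t101\t+\t5\t5\tCpG\nchr1\t151\t+\t5\t5\tCHH\n")
        assert len(read_cpg_report(p)) == 1
        assert len(read_cpg_report(p, contexts=("CpG", "CHH"))) == 2

    def test_round_trip(self, tmp_path):
        original = sites([(100, 5, 10), (150, 0, 7), (200, 7, 7)])
        p = tmp_path / "rt.tsv"
        write_cpg_report(original, p)
        assert read_cpg_report(p) == original


@pytest.mark.parametrize(
    "meth, total, expected",
    [(5, 10, 0.5), (0, 10, 0.0), (7, 7, 1.0), (0, 0, None)],
)
def test_methylation_level(meth, total, expected):
    lv = methylation_level(CpGSiteCounts("chr1", 0, "+", meth, total))
    assert lv == expected


class TestSegmentation:
    def test_contiguous_run_is_one_candidate(self):
        s = sites([(i * 50, 5, 10) for i in range(6)])
        cands = segment_candidates(s, s)
        assert len(cands) == 1 and len(cands[0]) == 6

    def test_below_min_cpg_discarded(self):
        s = sites([(i * 50, 5, 10) for i in range(4)])
        assert segment_candidates(s, s) == []

    def test_large_gap_splits_runs(self):
        spec = [(i * 50, 5, 10) for i in range(5)]
        spec += [(5_000 + i * 50, 5, 10) for i in range(5)]
        s = sites(spec)
        assert len(segment_candidates(s, s)) == 2

    def test_site_must_be_covered_in_both_groups(self):
        ctrl = sites([(i * 50, 5, 10) for i in range(6)])
        trt = sites([(i * 50, 5, 10) for i in range(5)])  # last site missing
        cands = segment_candidates(ctrl, trt)
        assert len(cands) == 1 and len(cands[0]) == 5


class TestCallDmrs:
    def test_pooled_fisher_against_enumeration_oracle(self):
        # 6 CpGs, 20/100 in control vs 5/100 in treated: pooled table
        # (120, 480 | 30, 570); P from exhaustive hypergeometric enumeration
        ctrl = sites([(i * 50, 20, 100) for i in range(6)])
        trt = sites([(i * 50, 5, 100) for i in range(6)])
        (dmr,) = call_dmrs(ctrl, trt)
        assert dmr.direction == "hypo"
        assert dmr.n_cpg == 6
        assert dmr.fold_change == pytest.approx(4.0)
        assert dmr.pooled_control == (120, 480)
        assert dmr.pooled_treated == (30, 570)
        p_oracle = fisher_two_sided_enum([[120, 480], [30, 570]])
        assert dmr.p_value == pytest.approx(p_oracle, abs=1e-10)
        assert dmr.p_value < 0.05
        assert (dmr.region.start, dmr.region.end) == (0, 251)

    def test_identical_levels_not_called(self):
        s = sites([(i * 50, 50, 100) for i in range(6)])
        assert call_dmrs(s, s) == []

    def test_sub_twofold_change_not_called(self):
        ctrl = sites([(i * 50, 30, 100) for i in range(6)])
        trt = sites([(i * 50, 16, 100) for i in range(6)])  # fold 1.875
        assert call_dmrs(ctrl, trt) == []

    def test_hyper_direction(self):
        ctrl = sites([(i * 50, 10, 100) for i in range(6)])
        trt = sites([(i * 50, 60, 100) for i in range(6)])
        (dmr,) = call_dmrs(ctrl, trt)
        assert dmr.direction == "hyper"

    def test_zero_level_one_group_passes_as_infinite_fold(self):
        ctrl = sites([(i * 50, 40, 100) for i in range(6)])
        trt = sites([(i * 50, 0, 100) for i in range(6)])
        (dmr,) = call_dmrs(ctrl, trt)
        assert math.isinf(dmr.fold_change) and dmr.direction == "hypo"

    def test_empty_input(self):
        assert call_dmrs([], []) == []

    def test_site_order_invariance(self):
        spec_c = [(i * 50, 20, 100) for i in range(8)]
        spec_t = [(i * 50, 5, 100) for i in range(8)]
        ctrl, trt = sites(spec_c), sites(spec_t)
        shuffled_c, shuffled_t = list(ctrl), list(trt)
        random.Random(7).shuffle(shuffled_c)
        random.Random(8).shuffle(shuffled_t)
        assert call_dmrs(ctrl, trt) == call_dmrs(shuffled_c, shuffled_t)

    def test_q_values_bh_monotone_and_at_least_p(self):
        rng = np.random.default_rng(5)
        spec_c, spec_t = [], []
        pos = 0
        for block in range(40):
            lv_c = rng.uniform(0.2, 0.9)
            lv_t = lv_c / rng.choice([1.0, 2.5, 4.0])
            for i in range(6):
                cov_c, cov_t = rng.poisson(60), rng.poisson(60)
                spec_c.append((pos, int(rng.binomial(cov_c, lv_c)), int(cov_c)))
                spec_t.append((pos, int(rng.binomial(cov_t, lv_t)), int(cov_t)))
                pos += 50
            pos += 1_000
        dmrs = call_dmrs(sites(spec_c), sites(spec_t))
        assert dmrs, "expected some calls"
        for d in dmrs:
            assert d.q_value >= d.p_value - 1e-12
        ordered = sorted(dmrs, key=lambda d: d.p_value)
        qs = [d.q_value for d in ordered]
        assert all(q2 >= q1 - 1e-12 for q1, q2 in zip(qs, qs[1:]))


class TestNullCalibration:
    def test_fisher_fpr_at_most_nominal_under_null(self):
        # both groups from one per-site probability; Fisher is conservative
        rng = np.random.default_rng(11)
        n_cand = 2_000
        spec_c, spec_t = [], []
        pos = 0
        for _ in range(n_cand):
            lv = rng.uniform(0.2, 0.8)
            for _ in range(6):
                cov_c, cov_t = rng.poisson(80), rng.poisson(80)
                spec_c.append((pos, int(rng.binomial(cov_c, lv)), int(cov_c)))
                spec_t.append((pos, int(rng.binomial(cov_t, lv)), int(cov_t)))
                pos += 50
            pos += 1_000
        ctrl, trt = sites(spec_c), sites(spec_t)
        cands = segment_candidates(ctrl, trt)
        assert len(cands) >= 2_000
        from scipy.stats import fisher_exact

        n_sig = 0
        for cand in cands:
            cm = sum(c.meth_count for c, _ in cand)
            cu = sum(c.total_count - c.meth_count for c, _ in cand)
            tm = sum(t.meth_count for _, t in cand)
            tu = sum(t.total_count - t.meth_count for _, t in cand)
            if fisher_exact([[cm, cu], [tm, tu]])[1] <= 0.05:
                n_sig += 1
        bound = 0.05 + 3 * math.sqrt(0.05 * 0.95 / len(cands))
        assert n_sig / len(cands) <= bound


class TestMerge:
    def _two_called_neighbours(self, direction="both_hypo", second_at=700):
        lv_t2 = 5 if direction == "both_hypo" else 80
        ctrl = sites([(i * 50, 40, 100) for i in range(6)])
        trt = sites([(i * 50, 10, 100) for i in range(6)])
        # second candidate separated by > max_gap so candidates split
        ctrl += sites([(second_at + i * 50, 40, 100) for i in range(6)])
        trt += sites([(second_at + i * 50, lv_t2, 100) for i in range(6)])
        return ctrl, trt

    def test_adjacent_same_direction_merge_conserves_cpgs(self):
        ctrl, trt = self._two_called_neighbours()
        dmrs = call_dmrs(ctrl, trt)
        assert len(dmrs) == 2
        merged = merge_adjacent_dmrs(dmrs, ctrl, trt)
        assert len(merged) == 1
        assert merged[0].n_cpg == 12
        assert merged[0].direction == "hypo"
        assert merged[0].region.start == 0 and merged[0].region.end == 951

    def test_direction_mismatch_not_merged(self):
        ctrl, trt = self._two_called_neighbours(direction="mixed")
        dmrs = call_dmrs(ctrl, trt)
        assert {d.direction for d in dmrs} == {"hypo", "hyper"}
        assert len(merge_adjacent_dmrs(dmrs, ctrl, trt)) == 2

    def test_intervening_failed_candidate_blocks_merge(self):
        # called islands at 0-250 and 1400-1650; a null candidate at 700-950
        # sits between them (all gaps > max_gap, so three candidates)
        ctrl, trt = self._two_called_neighbours(second_at=1_400)
        ctrl += sites([(700 + i * 50, 40, 100) for i in range(6)])
        trt += sites([(700 + i * 50, 40, 100) for i in range(6)])
        ctrl.sort(key=lambda s: s.pos)
        trt.sort(key=lambda s: s.pos)
        dmrs = call_dmrs(ctrl, trt)
        assert len(dmrs) == 2  # the null middle candidate fails
        merged = merge_adjacent_dmrs(dmrs, ctrl, trt)
        assert len(merged) == 2

    def test_idempotent(self):
        ctrl, trt = self._two_called_neighbours()
        dmrs = call_dmrs(ctrl, trt)
        once = merge_adjacent_dmrs(dmrs, ctrl, trt)
        twice = merge_adjacent_dmrs(once, ctrl, trt)
        assert once == twice


class TestAnnotate:
    def test_compartment_assignment(self, two_gene_models):
        def dmr_at(start, end):
            ctrl = sites([(start + i * 50, 40, 100) for i in range(6)])
            trt = sites([(start + i * 50, 10, 100) for i in range(6)])
            (d,) = call_dmrs(ctrl, trt)
            assert (d.region.start, d.region.end) == (start, end)
            return d

        inside = dmr_at(11_000, 11_251)  # in geneA's body
        promoter = dmr_at(8_500, 8_751)  # in geneA's 2 kb promoter
        distal = dmr_at(90_000, 90_251)  # 80 kb from geneA's TSS
        annotated = annotate_dmrs([inside, promoter, distal], two_gene_models)
        assert [d.location for d in annotated] == ["gene_body", "promoter", "intergenic"]
        assert annotated[2].linked_genes == ("geneA",)


def test_merge_with_single_candidate_inputs_noop():
    ctrl = sites([(i * 50, 40, 100) for i in range(6)])
    trt = sites([(i * 50, 10, 100) for i in range(6)])
    dmrs = call_dmrs(ctrl, trt)
    assert merge_adjacent_dmrs(dmrs, ctrl, trt) == dmrs
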