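"""Regulatory-landscape pipeline: a hand-built 20-loop fixture through the
three filters, quantile-oracle gap cutoffs, trimming idempotence, anchor
fusion and the loop enrichment statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from finsynt import landscapes as lsm
from finsynt.landscapes import GapCutoff, RegulatoryLandscape

BS = 10_000  # anchor width used by the fixtures


def loop(chrom, a1, a2, count=5, q=0.01):
    return dict(chrom1=chrom, start1=a1, end1=a1 + BS,
                chrom2=chrom, start2=a2, end2=a2 + BS, count=count, q=q)


def build_fixture20():
    """Hand-built 20-loop fixture with known classification.

    Genes gA (TSS 100,000) and gB (TSS 500,000) carry H3K4me3 peaks; a
    third peak at 900,000 has no TSS within 2 kb, so anchors there stay
    distal.
    """
    peaks = pd.DataFrame({"chrom": "c1",
                          "start": [99_000, 499_000, 899_000],
                          "end": [101_500, 501_500, 901_500]})
    tss = pd.DataFrame({"chrom": "c1", "pos": [100_000, 500_000],
                        "gene_id": ["gA", "gB"]})
    loops = pd.DataFrame([
        # gA promoter-distal loops (anchors clustered then one far)
        loop("c1", 95_000, 150_000),
        loop("c1", 95_000, 170_000),
        loop("c1", 95_000, 190_000),
        loop("c1", 95_000, 240_000),
        loop("c1", 95_000, 360_000),   # far anchor beyond a big gap
        # gB promoter-distal loops
        loop("c1", 495_000, 560_000),
        loop("c1", 495_000, 580_000),
        loop("c1", 495_000, 640_000),
        # promoter-promoter (both overlap K4 peaks near TSSs) -> removed
        loop("c1", 95_000, 495_000),
        loop("c1", 95_000, 497_000),
        # distal-distal -> removed
        loop("c1", 700_000, 760_000),
        loop("c1", 760_000, 820_000),
        loop("c1", 895_000, 940_000),  # peak at 900k but no TSS: distal-distal
        # below-significance loops -> removed up front
        loop("c1", 95_000, 210_000, q=0.2),
        loop("c1", 495_000, 620_000, q=0.5),
        loop("c1", 95_000, 470_000, q=0.11),
        # a second promoter anchor bin for gB (overlaps the same peak)
        loop("c1", 493_000, 660_000),
        # singleton promoter gC-like: distal-distal since no peak/TSS
        loop("c1", 1_100_000, 1_160_000),
        loop("c1", 1_200_000, 1_260_000),
        loop("c1", 1_300_000, 1_360_000),
    ])
    return loops, peaks, tss


@pytest.fixture()
def fixture20():
    return build_fixture20()


class TestFilters(object):
    def test_fixture_classification_matches_hand_table(self, fixture20):
        loops, peaks, tss = fixture20
        retained = lsm.retain_significant(loops)
        assert len(retained) == 17  # three q >= 0.1 loops removed
        typed = lsm.classify_anchors(retained, peaks, tss)
        # hand-derived anchor-1 typing for the retained loops, in order
        expected_t1 = (["promoter"] * 5 + ["promoter"] * 3
                       + ["promoter"] * 2 + ["distal"] * 3
                       + ["promoter"] + ["distal"] * 3)
        assert list(typed["type1"]) == expected_t1
        assert set(typed[typed["type1"] == "promoter"]["gene1_assigned"]) \
            == {"gA", "gB"}

    def test_promoter_promoter_and_distal_distal_removed(self, fixture20):
        loops, peaks, tss = fixture20
        typed = lsm.classify_anchors(lsm.retain_significant(loops), peaks, tss)
        pdl = lsm.filter_promoter_distal(typed)
        assert len(pdl) == 9
        assert (pdl["type1"] == "promoter").all()
        assert (pdl["type2"] == "distal").all()
        # the removed set is exactly the PP + DD classes
        removed = len(typed) - len(pdl)
        pp = ((typed["type1"] == "promoter") & (typed["type2"] == "promoter")).sum()
        dd = ((typed["type1"] == "distal") & (typed["type2"] == "distal")).sum()
        assert removed == pp + dd

    def test_landscapes_match_precomputed_set(self, fixture20):
        loops, peaks, tss = fixture20
        typed = lsm.classify_anchors(lsm.retain_significant(loops), peaks, tss)
        ls = lsm.build_landscapes(lsm.filter_promoter_distal(typed))
        got = {l.gene_id: l.anchors for l in ls}
        assert got == {
            "gA": [(150_000, 160_000), (170_000, 180_000), (190_000, 200_000),
                   (240_000, 250_000), (360_000, 370_000)],
            "gB": [(560_000, 570_000), (580_000, 590_000), (640_000, 650_000),
                   (660_000, 670_000)],
        }

    def test_single_distal_anchor_landscape_dropped(self):
        filtered = pd.DataFrame([
            dict(chrom1="c1", start1=0, end1=BS, chrom2="c1",
                 start2=100_000, end2=100_000 + BS, count=1, q=0.01,
                 type1="promoter", type2="distal", gene1_assigned="g1",
                 gene2_assigned=None)])
        assert lsm.build_landscapes(filtered) == []

    def test_empty_input_empty_output(self):
        empty = pd.DataFrame(columns=["chrom1", "start1", "end1", "chrom2",
                                      "start2", "end2", "type1", "type2",
                                      "gene1_assigned", "gene2_assigned"])
        assert lsm.build_landscapes(empty) == []


class TestGapCutoff:
    def test_quantile_oracle(self):
        # max gaps 10/20/30/40 kb under the linear-interpolation convention:
        # Q3 = 30k + 0.25*10k = 32,500; Q1 = 10k + 0.75*10k = 17,500;
        # IQR = 15,000 -> cutoff = 32,500 + 30,000 = 62,500
        mk = [10_000, 20_000, 30_000, 40_000]
        landscapes = [
            RegulatoryLandscape("g%d" % i, "c1", (0, 1_000),
                                [(2_000, 3_000), (3_000 + g, 4_000 + g)])
            for i, g in enumerate(mk)]
        cut = lsm.gap_cutoff(landscapes)
        assert cut.q3 == pytest.approx(np.quantile(mk, 0.75))
        assert cut.q3 == pytest.approx(32_500)
        assert cut.iqr == pytest.approx(15_000)
        assert cut.cutoff == pytest.approx(62_500)

    def test_all_equal_gaps(self):
        landscapes = [RegulatoryLandscape(f"g{i}", "c1", (0, 1_000),
                                          [(2_000, 3_000), (8_000, 9_000)])
                      for i in range(4)]
        cut = lsm.gap_cutoff(landscapes)
        assert cut.iqr == 0
        assert cut.cutoff == cut.q3 == 5_000

    def test_single_landscape_degenerate_quantiles(self):
        ls = [RegulatoryLandscape("g", "c1", (0, 1_000),
                                  [(2_000, 3_000), (10_000, 11_000)])]
        cut = lsm.gap_cutoff(ls)
        assert cut.cutoff == ls[0].max_gap() == 7_000

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            lsm.gap_cutoff([])


def random_landscape(rng) -> RegulatoryLandscape:
    chrom = "c1"
    p = int(rng.integers(1_000_000, 2_000_000))
    n_left = int(rng.integers(0, 5))
    n_right = int(rng.integers(0, 5))
    anchors = []
    pos = p
    for _ in range(n_left):
        pos -= int(rng.integers(30_000, 300_000))
        anchors.append((pos, pos + BS))
    pos = p + BS
    for _ in range(n_right):
        pos += int(rng.integers(30_000, 300_000))
        anchors.append((pos, pos + BS))
    return RegulatoryLandscape("g", chrom, (p, p + BS), sorted(anchors))


class TestTrim:
    def test_no_gap_exceeding_cutoff_is_identity(self):
        ls = RegulatoryLandscape("g", "c1", (100_000, 110_000),
                                 [(150_000, 160_000), (200_000, 210_000)])
        out = lsm.trim_landscapes([ls], GapCutoff("s", 1e6, 0.0))
        assert out[0].anchors == ls.anchors
        assert not out[0].trimmed

    def test_anchors_beyond_big_gap_discarded(self):
        # promoter at left; gap > cutoff between anchors 2 and 3
        ls = RegulatoryLandscape("g", "c1", (100_000, 110_000),
                                 [(150_000, 160_000), (200_000, 210_000),
                                  (800_000, 810_000), (850_000, 860_000)])
        out = lsm.trim_landscapes([ls], 300_000)
        assert out[0].anchors == [(150_000, 160_000), (200_000, 210_000)]
        assert out[0].trimmed

    def test_sides_trimmed_independently(self):
        ls = RegulatoryLandscape("g", "c1", (500_000, 510_000),
                                 [(100_000, 110_000), (450_000, 460_000),
                                  (550_000, 560_000), (900_000, 910_000)])
        out = lsm.trim_landscapes([ls], 100_000)
        assert out[0].anchors == [(450_000, 460_000), (550_000, 560_000)]

    def test_below_two_anchors_dropped(self):
        ls = RegulatoryLandscape("g", "c1", (0, 10_000),
                                 [(50_000, 60_000), (900_000, 910_000)])
        assert lsm.trim_landscapes([ls], 100_000) == []

    def test_idempotent_on_random_landscapes(self, rng):
        landscapes = [random_landscape(rng) for _ in range(100)]
        cut = lsm.gap_cutoff(landscapes)
        once = lsm.trim_landscapes(landscapes, cut)
        twice = lsm.trim_landscapes(once, cut)
        assert [(l.gene_id, l.anchors) for l in once] == \
            [(l.gene_id, l.anchors) for l in twice]

    def test_no_anchor_created_by_pipeline(self, rng):
        landscapes = [random_landscape(rng) for _ in range(50)]
        inputs = {a for l in landscapes for a in l.anchors}
        for l in lsm.trim_landscapes(landscapes, lsm.gap_cutoff(landscapes)):
            assert set(l.anchors) <= inputs


class TestMergeAndCount:
    @staticmethod
    def _landscape(gene, anchors):
        return RegulatoryLandscape(gene, "c1", (0, BS), anchors)

    def test_fusion_distance_rule(self):
        # 25 kb apart: kept separate; 15 kb apart: fused into one interval
        far = self._landscape("g", [(100_000, 110_000), (135_000, 145_000)])
        near = self._landscape("g", [(100_000, 110_000), (125_000, 135_000)])
        reps = {"r1": _typed_loops("g", [(100_000, 3)]),
                "r2": _typed_loops("g", [(100_000, 4)])}
        tab_far = lsm.merge_distal_and_count({"a": [far]}, reps)
        tab_near = lsm.merge_distal_and_count({"a": [near]}, reps)
        assert len(tab_far) == 2
        assert len(tab_near) == 1
        assert (tab_near.iloc[0]["a_start"], tab_near.iloc[0]["a_end"]) \
            == (100_000, 135_000)

    def test_identical_replicates_identical_columns(self):
        ls = self._landscape("g", [(100_000, 110_000), (200_000, 210_000)])
        rep = _typed_loops("g", [(100_000, 3), (200_000, 7)])
        tab = lsm.merge_distal_and_count({"a": [ls]}, {"r1": rep, "r2": rep.copy()})
        assert (tab["r1"] == tab["r2"]).all()
        assert np.corrcoef(tab["r1"], tab["r2"])[0, 1] == pytest.approx(1.0)

    def test_counts_match_hand_aggregation(self):
        ls = self._landscape("g", [(100_000, 110_000), (120_000, 130_000)])
        rep = _typed_loops("g", [(100_000, 3), (122_000, 7), (500_000, 99)])
        tab = lsm.merge_distal_and_count({"a": [ls]}, {"r1": rep, "r2": rep})
        # anchors fused (gap 10 kb < 20 kb): one union loop, counts 3 + 7
        assert len(tab) == 1
        assert tab.iloc[0]["r1"] == 10

    def test_column_sums_conserve_supporting_reads(self):
        ls = self._landscape("g", [(100_000, 110_000), (200_000, 210_000)])
        rep = _typed_loops("g", [(100_000, 3), (200_000, 7)])
        tab = lsm.merge_distal_and_count({"a": [ls]}, {"r1": rep, "r2": rep})
        assert tab["r1"].sum() == rep["count"].sum()


def _typed_loops(gene, pos_counts):
    rows = []
    for pos, count in pos_counts:
        rows.append(dict(chrom1="c1", start1=0, end1=BS, chrom2="c1",
                         start2=pos, end2=pos + BS, count=count, q=0.01,
                         type1="promoter", type2="distal",
                         gene1_assigned=gene, gene2_assigned=None))
    return pd.DataFrame(rows)


class TestLoopStats:
    TADS = pd.DataFrame({"chrom": "c1",
                         "start": np.arange(10) * 1_000_000,
                         "end": (np.arange(10) + 1) * 1_000_000})

    def test_nested_loop_is_intra_and_straddling_is_inter(self):
        loops = pd.DataFrame([
            loop("c1", 100_000, 400_000),       # inside TAD 0
            loop("c1", 900_000, 1_200_000)])    # straddles boundary at 1 Mb
        res = lsm.intertad_loop_stats(loops, self.TADS, n_shuffles=100, seed=0)
        assert res["intra"] == 1 and res["inter"] == 1

    def test_tad_respecting_loops_reach_minimum_p(self):
        # TADs of 800 kb spaced every 1 Mb leave room for the shuffle to move
        tads = pd.DataFrame({"chrom": "c1",
                             "start": np.arange(10) * 1_000_000,
                             "end": np.arange(10) * 1_000_000 + 800_000})
        rng = np.random.default_rng(1)
        rows = []
        for _ in range(60):
            t = rng.integers(10)
            a = t * 1_000_000 + rng.integers(0, 300_000)
            rows.append(loop("c1", a, a + 350_000))
        loops = pd.DataFrame(rows)
        res = lsm.intertad_loop_stats(loops, tads, n_shuffles=999, seed=0,
                                      chrom_sizes={"c1": 12_000_000})
        assert res["frac_intra"] == 1.0
        assert res["p"] == pytest.approx(1 / 1000)

    def test_atac_extreme_enrichment(self):
        anchors = np.arange(20) * 500_000 + 100_000
        loops = pd.DataFrame([loop("c1", 0, a) for a in anchors])
        peaks = pd.DataFrame({"chrom": "c1", "start": anchors + 2_000,
                              "end": anchors + 4_000})
        res = lsm.atac_overlap_test(loops, peaks, {"c1": 100_000_000}, seed=0)
        assert res["frac_anchor_on_peak"] == 1.0
        assert res["p"] < 1e-4

    def test_atac_chi2_equals_closed_form(self):
        rng = np.random.default_rng(0)
        anchors = rng.integers(0, 10_000_000, 50)
        loops = pd.DataFrame([loop("c1", 0, int(a)) for a in anchors])
        pk = rng.integers(0, 10_000_000, 30)
        peaks = pd.DataFrame({"chrom": "c1", "start": pk, "end": pk + 20_000})
        res = lsm.atac_overlap_test(loops, peaks, {"c1": 10_000_000}, seed=3)
        t = res["table"]
        n = t.sum()
        E = np.outer(t.sum(1), t.sum(0)) / n
        chi2 = ((t - E) ** 2 / E).sum()
        assert res["chi2"] == pytest.approx(chi2, abs=1e-10)

    def test_no_peaks_raises(self):
        with pytest.raises(ValueError):
            lsm.atac_overlap_test(pd.DataFrame([loop("c1", 0, 100_000)]),
                                  pd.DataFrame(columns=["chrom", "start", "end"]),
                                  {"c1": 1_000_000})
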