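"""Karyotype module: RBH against a brute-force scan, Fisher enrichment
against exact hypergeometric enumeration, segment-label recovery and
retention-rate estimation on simulated genomes."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from finsynt import SimConfig, karyotype as kt, simgenome as sg


def hyper_tail(shared, a_only, b_only, neither):
    """Independent oracle: one-sided enrichment tail of the hypergeometric,
    enumerated directly from binomial coefficients."""
    N = shared + a_only + b_only + neither
    R, C = shared + a_only, shared + b_only
    return sum(comb(C, k) * comb(N - C, R - k)
               for k in range(shared, min(R, C) + 1)) / comb(N, R)


def brute_force_rbh(scores: np.ndarray):
    """Mutual argmax scan over a dense score matrix (rows = A, cols = B)."""
    pairs = []
    for i in range(scores.shape[0]):
        j = int(np.argmax(scores[i]))
        if int(np.argmax(scores[:, j])) == i:
            pairs.append((i, j))
    return pairs


def hits_from_matrix(scores: np.ndarray) -> pd.DataFrame:
    rows = []
    for i in range(scores.shape[0]):
        for j in range(scores.shape[1]):
            rows.append(("A", f"a{i}", "B", f"b{j}", scores[i, j]))
            rows.append(("B", f"b{j}", "A", f"a{i}", scores[i, j]))
    return pd.DataFrame(rows, columns=["species_a", "gene_a", "species_b",
                                       "gene_b", "score"])


class TestRBH:
    def test_identity_matrix_gives_diagonal(self):
        out = kt.reciprocal_best_hits(hits_from_matrix(np.eye(4)))
        assert list(out["gene_a"]) == [f"a{i}" for i in range(4)]
        assert list(out["gene_b"]) == [f"b{i}" for i in range(4)]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random((4, 4))
        out = kt.reciprocal_best_hits(hits_from_matrix(scores))
        expected = {(f"a{i}", f"b{j}") for i, j in brute_force_rbh(scores)}
        assert set(zip(out["gene_a"], out["gene_b"])) == expected

    def test_tie_broken_lexicographically(self):
        scores = np.array([[1.0, 1.0], [0.0, 0.0]])
        out = kt.reciprocal_best_hits(hits_from_matrix(scores))
        assert ("a0", "b0") in set(zip(out["gene_a"], out["gene_b"]))

    def test_symmetric_under_species_swap(self):
        rng = np.random.default_rng(3)
        hits = hits_from_matrix(rng.random((5, 5)))
        fwd = kt.reciprocal_best_hits(hits)
        swapped = hits.rename(columns={
            "species_a": "species_b", "species_b": "species_a",
            "gene_a": "gene_b", "gene_b": "gene_a"})
        rev = kt.reciprocal_best_hits(swapped)
        # output orientation is canonical (species sorted), so a swap of the
        # input direction leaves the pair set unchanged
        assert set(zip(fwd["gene_a"], fwd["gene_b"])) == \
            set(zip(rev["gene_a"], rev["gene_b"]))

    def test_missing_direction_raises(self):
        hits = hits_from_matrix(np.eye(2))
        with pytest.raises(ValueError, match="direction"):
            kt.reciprocal_best_hits(hits[hits["species_a"] == "A"])


def _ann(assign: dict[str, str]) -> pd.DataFrame:
    """gene -> chrom mapping as a minimal annotation frame."""
    return pd.DataFrame({
        "gene_id": list(assign), "chrom": list(assign.values()),
        "start": np.arange(len(assign)) * 10_000,
        "end": np.arange(len(assign)) * 10_000 + 5_000, "strand": "+"})


class TestEnrichment:
    def test_fisher_p_equals_enumeration(self):
        # the table (8, 2, 2, 8) has enumerated tail 0.011507068782610578
        genes_a = {f"g{i}": ("A1" if i < 10 else "A2") for i in range(20)}
        genes_b = {f"g{i}": ("B1" if (i < 8 or 10 <= i < 12) else "B2")
                   for i in range(20)}
        orth = pd.DataFrame({"species_a": "qa", "gene_a": list(genes_a),
                             "species_b": "qb", "gene_b": list(genes_b),
                             "score": 1.0, "unique": True})
        ann_a = _ann(genes_a)
        ann_b = _ann(genes_b)
        out = kt.chrom_pair_enrichment(orth, ann_a, ann_b)
        row = out[(out["chrom_a"] == "A1") & (out["chrom_b"] == "B1")].iloc[0]
        assert (row["shared"], row["a_only"], row["b_only"], row["neither"]) \
            == (8, 2, 2, 8)
        assert row["p"] == pytest.approx(0.011507068782610578, rel=1e-12)
        assert row["p"] == pytest.approx(hyper_tail(8, 2, 2, 8), rel=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_fisher_matches_enumeration_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        ca = rng.choice(["A1", "A2", "A3"], size=n)
        cb = rng.choice(["B1", "B2"], size=n)
        orth = pd.DataFrame({"species_a": "x", "gene_a": [f"g{i}" for i in range(n)],
                             "species_b": "y", "gene_b": [f"g{i}" for i in range(n)],
                             "score": 1.0, "unique": True})
        out = kt.chrom_pair_enrichment(orth, _ann(dict(zip(orth["gene_a"], ca))),
                                       _ann(dict(zip(orth["gene_b"], cb))))
        for _, r in out.iterrows():
            assert r["p"] == pytest.approx(
                hyper_tail(r["shared"], r["a_only"], r["b_only"], r["neither"]),
                rel=1e-9)

    def test_uniform_orthologs_rarely_significant(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 200
            ca = rng.choice([f"A{k}" for k in range(4)], size=n)
            cb = rng.choice([f"B{k}" for k in range(4)], size=n)
            orth = pd.DataFrame({"species_a": "x",
                                 "gene_a": [f"g{i}" for i in range(n)],
                                 "species_b": "y",
                                 "gene_b": [f"g{i}" for i in range(n)],
                                 "score": 1.0, "unique": True})
            out = kt.chrom_pair_enrichment(
                orth, _ann(dict(zip(orth["gene_a"], ca))),
                _ann(dict(zip(orth["gene_b"], cb))))
            hits += int(out["significant"].any())
        assert hits <= 3  # BH at q<0.05 over 16 pairs, 20 null datasets

    def test_extreme_enrichment_flagged(self):
        genes_a = {f"g{i}": ("A1" if i < 10 else "A2") for i in range(30)}
        genes_b = {f"g{i}": ("B1" if i < 10 else "B2") for i in range(30)}
        orth = pd.DataFrame({"species_a": "x", "gene_a": list(genes_a),
                             "species_b": "y", "gene_b": list(genes_b),
                             "score": 1.0, "unique": True})
        out = kt.chrom_pair_enrichment(orth, _ann(genes_a), _ann(genes_b))
        row = out[(out["chrom_a"] == "A1") & (out["chrom_b"] == "B1")].iloc[0]
        assert row["significant"]
        assert row["p"] == out[out["chrom_a"] == "A1"]["p"].min()

    def test_bh_q_monotone_in_p_rank(self):
        rng = np.random.default_rng(1)
        n = 100
        ca = rng.choice(["A1", "A2"], size=n)
        cb = rng.choice(["B1", "B2"], size=n)
        orth = pd.DataFrame({"species_a": "x", "gene_a": [f"g{i}" for i in range(n)],
                             "species_b": "y", "gene_b": [f"g{i}" for i in range(n)],
                             "score": 1.0, "unique": True})
        out = kt.chrom_pair_enrichment(orth, _ann(dict(zip(orth["gene_a"], ca))),
                                       _ann(dict(zip(orth["gene_b"], cb))))
        s = out.sort_values("p")
        assert (np.diff(s["q"].to_numpy()) >= -1e-12).all()

    def test_empty_orthologs_give_empty_result(self):
        empty = pd.DataFrame(columns=["species_a", "gene_a", "species_b",
                                      "gene_b", "score", "unique"])
        out = kt.chrom_pair_enrichment(empty, _ann({}), _ann({}))
        assert out.empty


def _query_to_ref(ds_orth: pd.DataFrame) -> pd.DataFrame:
    """Reorient a reference->query table as query->reference."""
    return ds_orth.rename(columns={
        "species_a": "species_b", "species_b": "species_a",
        "gene_a": "gene_b", "gene_b": "gene_a"})


class TestSegments:
    @staticmethod
    def _setup(seed, **cfg_kw):
        cfg = SimConfig(seed=seed, n_clg=6, genes_per_clg=40, **cfg_kw)
        anc = sg.simulate_ancestor(cfg)
        sp, _ = sg.apply_wgd(anc, cfg)
        ref = sg.split_lineage(sp, cfg, "ref", extra_loss=0.05)
        orth = _query_to_ref(sg.make_ortholog_table(ref, sp, np.random.default_rng(0)))
        ref_seg = sg.segments_from_genes(ref, cfg.gene_spacing)
        ref_labels = (ref_seg.groupby("chrom").first().reset_index()
                      [["chrom", "clg", "r1", "r2"]])
        return cfg, sp, ref, orth, ref_labels

    def test_recovery_on_simulated_genomes(self):
        cfg, sp, ref, orth, ref_labels = self._setup(3)
        enrich = kt.chrom_pair_enrichment(orth, sp.genes, ref.genes)
        seg = kt.assign_segments(enrich, ref_labels, orth=orth,
                                 ann_query=sp.genes, ann_ref=ref.genes)
        truth = sg.segments_from_genes(sp, cfg.gene_spacing)
        merged = seg.merge(truth, on="chrom", suffixes=("_est", "_true"))
        correct = ((merged["clg_est"] == merged["clg_true"])
                   & (merged["r1_est"] == merged["r1_true"])
                   & (merged["r2_est"] == merged["r2_true"])).mean()
        assert correct >= 0.95

    def test_no_significant_pairs_all_unassigned(self):
        enrich = pd.DataFrame({
            "chrom_a": ["q1", "q2"], "chrom_b": ["r1", "r2"],
            "shared": [1, 1], "a_only": [5, 5], "b_only": [5, 5],
            "neither": [50, 50], "odds_ratio": [1.0, 1.0],
            "p": [0.5, 0.6], "q": [0.6, 0.6], "significant": [False, False]})
        labels = pd.DataFrame({"chrom": ["r1", "r2"], "clg": ["A1", "B"],
                               "r1": ["1", "1"], "r2": ["a", "a"]})
        seg = kt.assign_segments(enrich, labels)
        assert (seg["clg"] == "unassigned").all()

    def test_fused_chromosome_resolved_into_runs(self):
        cfg, sp, ref, orth, ref_labels = self._setup(11)
        cfg2 = sg.SimConfig(**{**cfg.__dict__, "n_fusions": 1})
        fused, _ = sg.apply_rearrangements(sp, sg.simulate_tads(sp, cfg), cfg2)
        orth2 = _query_to_ref(sg.make_ortholog_table(ref, fused,
                                                     np.random.default_rng(0)))
        enrich = kt.chrom_pair_enrichment(orth2, fused.genes, ref.genes)
        seg = kt.assign_segments(enrich, ref_labels, orth=orth2,
                                 ann_query=fused.genes, ann_ref=ref.genes)
        fused_chrom = [c for c in fused.genes["chrom"].unique() if "+" in c]
        assert fused_chrom
        runs = seg[seg["chrom"] == fused_chrom[0]]
        truth_runs = sg.segments_from_genes(fused, cfg.gene_spacing)
        truth_runs = truth_runs[truth_runs["chrom"] == fused_chrom[0]]
        assert len(runs) == len(truth_runs)
        for (_, est), (_, tru) in zip(runs.iterrows(), truth_runs.iterrows()):
            assert (est["clg"], est["r1"], est["r2"]) == \
                (tru["clg"], tru["r1"], tru["r2"])


class TestRetention:
    def test_no_loss_gives_rate_one(self):
        cfg = SimConfig(seed=2, n_clg=3, genes_per_clg=30,
                        loss_rate_alpha=0.0, loss_rate_beta=0.0)
        anc = sg.simulate_ancestor(cfg)
        sp, truth = sg.apply_wgd(anc, cfg)
        orth = sg.make_ortholog_table(anc, sp, np.random.default_rng(0))
        rates = kt.retention_rates(orth, truth.segments, anc, sp.genes)
        assert (rates["rate"] == 1.0).all()

    def test_recovery_and_alpha_beta_sign(self):
        cfg = SimConfig(seed=8, n_clg=5, genes_per_clg=300,
                        loss_rate_alpha=0.45, loss_rate_beta=0.75)
        anc = sg.simulate_ancestor(cfg)
        sp, truth = sg.apply_wgd(anc, cfg)
        orth = sg.make_ortholog_table(anc, sp, np.random.default_rng(0))
        rates = kt.retention_rates(orth, truth.segments, anc, sp.genes)
        a = rates[rates["r2_copy"] == "a"].set_index("clg")["rate"]
        b = rates[rates["r2_copy"] == "b"].set_index("clg")["rate"]
        assert (a - 0.55).abs().max() < 0.05
        assert (b - 0.25).abs().max() < 0.05
        assert (a > b.reindex(a.index)).all()  # beta loses more in every CLG


class TestCLGTrack:
    def test_monochromatic_windows(self):
        ann = _ann({f"g{i}": "c1" for i in range(40)})
        track = kt.clg_fraction_track(ann, {f"g{i}": "A1" for i in range(40)})
        assert (track["fraction"] == 1.0).all()
        assert (track["clg"] == "A1").all()

    def test_alternating_clgs_give_half_half(self):
        ann = _ann({f"g{i}": "c1" for i in range(40)})
        clg = {f"g{i}": ("A1" if i % 2 == 0 else "B") for i in range(40)}
        track = kt.clg_fraction_track(ann, clg)
        assert np.allclose(track["fraction"], 0.5)

    def test_window_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        ann = _ann({f"g{i}": "c1" for i in range(55)})
        clg = {f"g{i}": rng.choice(["A1", "B", "C"]) for i in range(55)}
        track = kt.clg_fraction_track(ann, clg)
        sums = track.groupby("window_index")["fraction"].sum()
        assert np.allclose(sums, 1.0)
        assert track[track["window_index"] == 2]["partial"].all()  # 15-gene tail

    def test_fusion_point_localised(self):
        genes = {f"g{i}": "c1" for i in range(80)}
        clg = {f"g{i}": ("A1" if i < 43 else "B") for i in range(80)}
        track = kt.clg_fraction_track(_ann(genes), clg)
        a1 = track[track["clg"] == "A1"].set_index("window_index")["fraction"]
        # switchover between windows 1 and 3 (true point inside window 2)
        assert a1.loc[1] == 1.0
        assert a1.get(3, 0.0) == 0.0
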