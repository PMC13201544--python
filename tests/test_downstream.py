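import numpy as np
import pandas as pd
import pytest

from spotfuse.ccc import build_weights
from spotfuse.downstream import (
    cell_abundance_per_pattern,
    colocalization,
    extract_lr_tf_tg,
    pathway_enrichment,
)
from helpers import hypergeom_upper_tail


class TestPathwayEnrichment:
    def _inputs(self, n_universe=20, n_pathway=5, n_query=10):
        universe = [f"p{i}" for i in range(n_universe)]
        pathways = {
            p: ("A" if i < n_pathway else "B") for i, p in enumerate(universe)
        }
        return universe[:n_query], universe, pathways

    def test_worked_hypergeometric_example(self):
        query, universe, pathways = self._inputs()
        table = pathway_enrichment(query, universe, pathways)
        row = table[table["pathway"] == "A"].iloc[0]
        assert row["p"] == pytest.approx(3003 / 184756, abs=1e-12)
        assert row["pairs_in_query"] == 5 and row["fraction"] == 1.0

    def test_query_equals_pathway_equals_universe(self):
        universe = ["a", "b", "c"]
        table = pathway_enrichment(universe, universe, {p: "X" for p in universe})
        assert table.iloc[0]["p"] == pytest.approx(1.0)

    def test_disjoint_query_and_pathway(self):
        universe = [f"p{i}" for i in range(10)]
        pathways = {p: ("A" if i < 5 else "B") for i, p in enumerate(universe)}
        table = pathway_enrichment(universe[5:], universe, pathways)
        assert table[table["pathway"] == "A"].iloc[0]["p"] == pytest.approx(1.0)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pathway_enrichment([], ["a"], {"a": "A"})

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            pathway_enrichment(["zzz"], ["a"], {"a": "A"})

    def test_matches_exact_closed_form_sweep(self):
        # sweep of 2x2 tables against the exact binomial-coefficient tail
        for N in range(2, 51, 7):
            universe = [f"p{i}" for i in range(N)]
            for K in range(1, N + 1, 5):
                pathways = {
                    p: ("A" if i < K else "B") for i, p in enumerate(universe)
                }
                for n in range(1, N + 1, 5):
                    table = pathway_enrichment(universe[:n], universe, pathways)
                    row = table[table["pathway"] == "A"]
                    if row.empty:
                        continue
                    a = int(row.iloc[0]["pairs_in_query"])
                    exact = hypergeom_upper_tail(a, N, K, n)
                    assert row.iloc[0]["p"] == pytest.approx(exact, abs=1e-12)

    def test_monotone_in_query_overlap(self):
        universe = [f"p{i}" for i in range(30)]
        pathways = {p: ("A" if i < 10 else "B") for i, p in enumerate(universe)}
        # queries of fixed size with increasing pathway overlap
        prev = 1.1
        for overlap in range(0, 11):
            query = universe[:overlap] + universe[10 : 10 + (10 - overlap)]
            p = pathway_enrichment(query, universe, pathways)
            p_a = p[p["pathway"] == "A"].iloc[0]["p"]
            assert p_a <= prev + 1e-12
            prev = p_a

    def test_bh_flag_adds_q_column(self):
        query, universe, pathways = self._inputs()
        table = pathway_enrichment(query, universe, pathways, bh_correct=True)
        assert "q" in table.columns
        assert (table["q"] >= table["p"] - 1e-15).all()


class TestNetworkExtraction:
    def _tables(self):
        rtf = pd.DataFrame(
            {
                "receptor": ["R1", "R1", "R2", "R9"],
                "tf": ["TF1", "TF2", "TF1", "TF9"],
                "score": [0.9, 0.4, 0.8, 0.7],
            }
        )
        tftg = pd.DataFrame(
            {"tf": ["TF1", "TF1", "TF2", "TF9"], "target": ["G1", "G2", "G3", "G9"]}
        )
        return rtf, tftg

    def test_minimal_chain(self):
        rtf, tftg = self._tables()
        mod = extract_lr_tf_tg([("L1", "R1")], rtf, tftg)
        assert len(mod.lr_edges) == 1
        assert set(mod.rtf_edges["tf"]) == {"TF1", "TF2"}
        assert set(mod.tftg_edges["target"]) == {"G1", "G2", "G3"}

    def test_receptor_without_tf_keeps_lr_layer(self):
        rtf, tftg = self._tables()
        mod = extract_lr_tf_tg([("L5", "R5")], rtf, tftg)
        assert len(mod.lr_edges) == 1
        assert mod.rtf_edges.empty and mod.tftg_edges.empty

    def test_shared_receptor_deduplicated(self):
        rtf, tftg = self._tables()
        mod = extract_lr_tf_tg([("L1", "R1"), ("L2", "R1"), ("L3", "R2")], rtf, tftg)
        # receptors {R1, R2}; TF edges: R1->TF1, R1->TF2, R2->TF1
        assert len(mod.rtf_edges) == 3
        assert set(mod.tftg_edges["tf"]) == {"TF1", "TF2"}
        assert len(mod.tftg_edges) == 3

    def test_order_independent(self):
        rtf, tftg = self._tables()
        pairs = [("L1", "R1"), ("L3", "R2"), ("L2", "R1")]
        a = extract_lr_tf_tg(pairs, rtf, tftg)
        b = extract_lr_tf_tg(
            list(reversed(pairs)),
            rtf.sample(frac=1, random_state=0),
            tftg.sample(frac=1, random_state=1),
        )
        pd.testing.assert_frame_equal(a.lr_edges, b.lr_edges)
        pd.testing.assert_frame_equal(
            a.rtf_edges.reset_index(drop=True), b.rtf_edges.reset_index(drop=True)
        )

    def test_score_threshold(self):
        rtf, tftg = self._tables()
        mod = extract_lr_tf_tg([("L1", "R1")], rtf, tftg, min_rtf_score=0.5)
        assert set(mod.rtf_edges["tf"]) == {"TF1"}

    def test_malformed_table_names_column(self):
        rtf, tftg = self._tables()
        with pytest.raises(ValueError, match="tf"):
            extract_lr_tf_tg([("L1", "R1")], rtf.rename(columns={"tf": "TF"}), tftg)


class TestColocalization:
    def test_duplicated_type_matches_self_pair(self):
        rng = np.random.default_rng(0)
        coords = rng.uniform(0, 20, (80, 2))
        w = build_weights(coords, cutoff=5)
        a = rng.uniform(0, 1, 80)
        ab = np.column_stack([a, a])
        out = colocalization(ab, ["A", "B"], w)
        r_ab = out[(out.type_a == "A") & (out.type_b == "B")].iloc[0]["R_global"]
        r_aa = out[(out.type_a == "A") & (out.type_b == "A")].iloc[0]["R_global"]
        assert r_ab == pytest.approx(r_aa)

    def test_disjoint_halves_negative(self):
        xx, yy = np.meshgrid(np.arange(10), np.arange(10))
        coords = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        w = build_weights(coords, cutoff=4)
        left = (coords[:, 0] < 5).astype(float)
        out = colocalization(np.column_stack([left, 1 - left]), ["L", "R"], w)
        r = out[(out.type_a == "L") & (out.type_b == "R")].iloc[0]["R_global"]
        assert r < 0

    def test_independent_abundances_rarely_significant(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 30, (200, 2))
        w = build_weights(coords, cutoff=6)
        nonsig = 0
        n_rep = 20
        for _ in range(n_rep):
            ab = rng.uniform(0, 1, (200, 2))
            out = colocalization(ab, ["A", "B"], w)
            row = out[(out.type_a == "A") & (out.type_b == "B")].iloc[0]
            nonsig += row["p"] > 0.05
        assert nonsig >= 0.9 * n_rep

    def test_zero_variance_type_excluded(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 10, (40, 2))
        w = build_weights(coords, cutoff=4)
        ab = np.column_stack([np.ones(40), rng.uniform(0, 1, 40), rng.uniform(0, 1, 40)])
        out = colocalization(ab, ["C", "A", "B"], w)
        assert "C" not in set(out.type_a) | set(out.type_b)

    def test_single_type_rejected(self):
        w = build_weights(np.random.default_rng(0).uniform(0, 5, (10, 2)), cutoff=3)
        with pytest.raises(ValueError, match="2 cell types"):
            colocalization(np.ones((10, 1)), ["A"], w)


class TestCellAbundance:
    def test_uniform_pattern_recovers_global_proportions(self):
        rng = np.random.default_rng(0)
        types = rng.uniform(0, 1, (50, 3))
        mu = np.ones((50, 1))
        out = cell_abundance_per_pattern(mu, types, ["a", "b", "c"])
        expected = types.sum(axis=0) / types.sum()
        np.testing.assert_allclose(out["pattern0"].to_numpy(), expected)

    def test_mass_on_pure_type_location(self):
        types = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
        mu = np.array([[1.0], [0.0], [0.0]])
        out = cell_abundance_per_pattern(mu, types, ["A", "B"])
        np.testing.assert_allclose(out["pattern0"].to_numpy(), [1.0, 0.0])

    def test_four_location_worked_example(self):
        types = np.array([[2.0, 0.0], [1.0, 1.0], [0.0, 2.0], [1.0, 0.0]])
        mu = np.column_stack([[1.0, 1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 1.0]])
        out = cell_abundance_per_pattern(mu, types, ["A", "B"])
        # pattern0 weights (.5,.5,0,0): mass A=1.5, B=.5 -> (0.75, 0.25)
        np.testing.assert_allclose(out["pattern0"], [0.75, 0.25])
        # pattern1 weights (0,0,.5,.5): mass A=.5, B=1 -> (1/3, 2/3)
        np.testing.assert_allclose(out["pattern1"], [1 / 3, 2 / 3])

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            cell_abundance_per_pattern(np.ones((2, 1)), np.array([[1.0], [-1.0]]))

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(1)
        out = cell_abundance_per_pattern(
            rng.uniform(0, 1, (30, 4)), rng.uniform(0, 1, (30, 5))
        )
        np.testing.assert_allclose(out.sum(axis=0), 1.0)
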