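import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from letharank.io import GeneMatrix
from letharank.integration import (
    Embedding,
    aggregate_score,
    anchor_neighbors,
    build_predictor_matrix,
    embed,
    embedding_fidelity,
    filter_candidates,
    stability_analysis,
)


def random_predictors(rng, n=60, n_sim=7):
    genes = [f"G{i:03d}" for i in range(n)]
    corr = pd.DataFrame(
        rng.uniform(-1, 1, (n, 6)), index=genes,
        columns=[f"expr_d{j}" for j in range(3)] + [f"dep_d{j}" for j in range(3)],
    )
    sim = pd.DataFrame(rng.standard_normal((n, n_sim)) * 50, index=genes,
                       columns=[f"P{j}" for j in range(n_sim)])
    return corr, sim


class TestBuildPredictorMatrix:
    def test_thirteen_columns(self, rng):
        corr, sim = random_predictors(rng, n_sim=7)
        matrix = build_predictor_matrix(corr, sim)
        assert matrix.shape[1] == 13

    def test_column_range(self, rng):
        corr, sim = random_predictors(rng)
        matrix = build_predictor_matrix(corr, sim)
        assert matrix.min().min() == pytest.approx(0.0)
        assert matrix.max().max() == pytest.approx(1.0)
        assert (matrix.min() == 0).all() and (matrix.max() == 1).all()

    def test_matches_fractional_rank_oracle(self, rng):
        corr, sim = random_predictors(rng, n=40)
        matrix = build_predictor_matrix(corr, sim)
        for col in matrix.columns:
            raw = (corr[col] if col in corr else sim[col]).loc[matrix.index]
            r = sps.rankdata(raw)
            expected = (r - r.min()) / (r.max() - r.min())
            np.testing.assert_allclose(matrix[col].to_numpy(), expected)

    def test_missing_predictor_drops_gene(self, rng):
        corr, sim = random_predictors(rng, n=20)
        corr.loc["G000", "expr_d0"] = np.nan
        matrix = build_predictor_matrix(corr, sim)
        assert "G000" not in matrix.index

    def test_monotone_transform_invariance(self, rng):
        corr, sim = random_predictors(rng, n=30)
        m1 = build_predictor_matrix(corr, sim)
        m2 = build_predictor_matrix(corr, np.exp(sim / 30.0))  # strictly monotone
        pd.testing.assert_frame_equal(m1, m2)

    def test_empty_intersection_error(self, rng):
        corr, sim = random_predictors(rng, n=10)
        sim.index = [f"X{i}" for i in range(10)]
        with pytest.raises(ValueError, match="shared"):
            build_predictor_matrix(corr, sim)


class TestEmbed:
    def test_deterministic(self, rng):
        corr, sim = random_predictors(rng, n=40)
        matrix = build_predictor_matrix(corr, sim)
        e1 = embed(matrix, seed=5)
        e2 = embed(matrix, seed=5)
        np.testing.assert_array_equal(e1.coords.to_numpy(), e2.coords.to_numpy())

    def test_shape(self, rng):
        corr, sim = random_predictors(rng, n=40)
        matrix = build_predictor_matrix(corr, sim)
        assert embed(matrix, seed=0).coords.shape == (40, 2)

    def test_too_few_genes(self, rng):
        corr, sim = random_predictors(rng, n=10)
        matrix = build_predictor_matrix(corr, sim)
        with pytest.raises(ValueError, match="n_neighbors"):
            embed(matrix, n_neighbors=15, seed=0)

    def test_duplicate_rows_land_close(self, rng):
        corr, sim = random_predictors(rng, n=50)
        corr.loc["G001"] = corr.loc["G000"]
        sim.loc["G001"] = sim.loc["G000"]
        matrix = build_predictor_matrix(corr, sim)
        emb = embed(matrix, seed=3)
        xy = emb.coords
        d_dup = np.linalg.norm(xy.loc["G000"] - xy.loc["G001"])
        pts = xy.to_numpy()
        diffs = pts[:, None, :] - pts[None, :, :]
        all_d = np.linalg.norm(diffs, axis=-1)[np.triu_indices(len(pts), 1)]
        assert d_dup <= np.percentile(all_d, 1)


class TestAnchorNeighbors:
    def _embedding(self, coords, genes):
        df = pd.DataFrame(coords, index=genes, columns=["x", "y"])
        return Embedding(coords=df, seed=0, min_dist=0.05, n_neighbors=15)

    def test_anchor_excluded(self, rng):
        emb = self._embedding(rng.standard_normal((10, 2)),
                              [f"G{i}" for i in range(10)])
        ranking, top = anchor_neighbors(emb, "G0", 3)
        assert "G0" not in ranking.index and "G0" not in top.members
        assert sorted(ranking["rank"]) == list(range(1, 10))

    def test_matches_brute_force_sort(self, rng):
        genes = [f"G{i}" for i in range(10)]
        coords = rng.standard_normal((10, 2))
        emb = self._embedding(coords, genes)
        ranking, _ = anchor_neighbors(emb, "G0", 5)
        d = np.linalg.norm(coords - coords[0], axis=1)
        expected = sorted(
            ((d[i], genes[i]) for i in range(1, 10)))
        assert ranking.index.tolist() == [g for _, g in expected]

    def test_missing_anchor_named(self, rng):
        emb = self._embedding(rng.standard_normal((5, 2)),
                              [f"G{i}" for i in range(5)])
        with pytest.raises(ValueError, match="NOPE"):
            anchor_neighbors(emb, "NOPE", 3)

    def test_top_k_size(self, rng):
        emb = self._embedding(rng.standard_normal((100, 2)),
                              [f"G{i}" for i in range(100)])
        _, top = anchor_neighbors(emb, "G0", 75)
        assert len(top) == 75

    def test_isometry_invariance(self, rng):
        genes = [f"G{i}" for i in range(20)]
        coords = rng.standard_normal((20, 2))
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = coords @ rot.T + np.array([5.0, -3.0])
        r1, _ = anchor_neighbors(self._embedding(coords, genes), "G0", 5)
        r2, _ = anchor_neighbors(self._embedding(moved, genes), "G0", 5)
        assert r1.index.tolist() == r2.index.tolist()


class TestAggregateScore:
    def test_top_in_both_scores_n(self):
        genes = list("ABCDE")
        corr = pd.DataFrame(0.0, index=genes,
                            columns=["expr_1", "expr_2", "expr_3",
                                     "dep_1", "dep_2", "dep_3"])
        corr.loc["A", ["expr_1", "expr_2", "expr_3"]] = 0.9
        corr.loc["B":"E", "expr_1"] = [0.1, 0.2, 0.3, 0.4]
        sim = pd.DataFrame({"P0": [50.0, 1.0, 2.0, 3.0, 4.0]}, index=genes)
        scores = aggregate_score(corr, sim)
        assert scores["A"] == pytest.approx(5.0)

    def test_five_gene_hand_oracle(self):
        # spreadsheet-style hand computation (frozen):
        # m = max(mean expr, mean dep): A .9, B .6, C .3, D .85, E .1
        # r1 (asc): E1 C2 B3 D4 A5; mean sim: A10 B40 C20 D50 E30
        # r2 (asc): A1 C2 E3 B4 D5; score = (r1 + r2) / 2
        genes = list("ABCDE")
        a = [0.9, 0.5, 0.2, 0.8, 0.1]
        b = [0.1, 0.6, 0.3, 0.85, 0.0]
        corr = pd.DataFrame(
            {f"expr_{j}": a for j in range(3)} | {f"dep_{j}": b for j in range(3)},
            index=genes)
        sim = pd.DataFrame({"P0": [10.0, 40.0, 20.0, 50.0, 30.0]}, index=genes)
        scores = aggregate_score(corr, sim)
        expected = {"A": 3.0, "B": 3.5, "C": 2.0, "D": 4.5, "E": 2.0}
        for g, v in expected.items():
            assert scores[g] == pytest.approx(v)

    def test_max_symmetry(self):
        genes = ["A", "B", "C"]
        expr = {f"expr_{j}": [0.2, 0.5, 0.1] for j in range(3)}
        dep = {f"dep_{j}": [0.4, 0.1, 0.3] for j in range(3)}
        corr1 = pd.DataFrame(expr | dep, index=genes)
        # swap a and b for every gene: m = max(a, b) unchanged
        corr2 = pd.DataFrame(
            {f"expr_{j}": dep[f"dep_{j}"] for j in range(3)}
            | {f"dep_{j}": expr[f"expr_{j}"] for j in range(3)}, index=genes)
        sim = pd.DataFrame({"P0": [1.0, 2.0, 3.0]}, index=genes)
        pd.testing.assert_series_equal(aggregate_score(corr1, sim),
                                       aggregate_score(corr2, sim))


class TestStability:
    def test_duplicate_of_anchor_always_retained(self, rng):
        corr, sim = random_predictors(rng, n=40)
        corr.loc["G001"] = corr.loc["G000"]
        sim.loc["G001"] = sim.loc["G000"]
        matrix = build_predictor_matrix(corr, sim)
        retention = stability_analysis(matrix, "G000", k=5, n_seeds=10,
                                       master_seed=0)
        assert retention["G001"] >= 0.95

    def test_fractions_in_range_anchor_excluded(self, rng):
        corr, sim = random_predictors(rng, n=30)
        matrix = build_predictor_matrix(corr, sim)
        retention = stability_analysis(matrix, "G000", k=5, n_seeds=2,
                                       n_neighbors=10, master_seed=1)
        assert "G000" not in retention.index
        assert retention.between(0, 1).all()

    def test_single_seed_binary(self, rng):
        corr, sim = random_predictors(rng, n=30)
        matrix = build_predictor_matrix(corr, sim)
        retention = stability_analysis(matrix, "G000", k=5, n_seeds=1,
                                       n_neighbors=10, master_seed=2)
        assert set(retention.unique()) <= {0.0, 1.0}


class TestEmbeddingFidelity:
    def test_identity_embedding_perfect(self, rng):
        genes = [f"G{i}" for i in range(50)]
        matrix = pd.DataFrame(rng.random((50, 2)), index=genes, columns=["a", "b"])
        emb = Embedding(coords=matrix.rename(columns={"a": "x", "b": "y"}),
                        seed=0, min_dist=0.05, n_neighbors=15)
        assert embedding_fidelity(matrix, emb, n_pairs=2000, seed=0) == pytest.approx(1.0)

    def test_random_embedding_uncorrelated(self, rng):
        genes = [f"G{i}" for i in range(200)]
        matrix = pd.DataFrame(rng.random((200, 5)), index=genes)
        emb = Embedding(coords=pd.DataFrame(rng.standard_normal((200, 2)),
                                            index=genes, columns=["x", "y"]),
                        seed=0, min_dist=0.05, n_neighbors=15)
        assert abs(embedding_fidelity(matrix, emb, n_pairs=10000, seed=0)) < 0.1

    def test_stable_across_sampling_seeds(self, rng):
        corr, sim = random_predictors(rng, n=80)
        matrix = build_predictor_matrix(corr, sim)
        emb = embed(matrix, seed=0)
        f1 = embedding_fidelity(matrix, emb, n_pairs=10000, seed=1)
        f2 = embedding_fidelity(matrix, emb, n_pairs=10000, seed=2)
        assert abs(f1 - f2) < 0.05


class TestFilterCandidates:
    def _neighbors(self, genes):
        return pd.DataFrame({"distance": np.linspace(0.1, 1.0, len(genes)),
                             "rank": range(1, len(genes) + 1)},
                            index=pd.Index(genes, name="gene"))

    def test_pan_essential_flag(self):
        genes = ["ESS", "OK"]
        dep = GeneMatrix(pd.DataFrame(
            [[-1.0] * 19 + [0.0], [0.0] * 20], index=genes,
            columns=[f"L{i}" for i in range(20)]))
        out = filter_candidates(self._neighbors(genes), dep,
                                essentiality_threshold=-0.5,
                                essential_fraction=0.9)
        assert bool(out.loc["ESS", "pan_essential"])
        assert not bool(out.loc["OK", "pan_essential"])

    def test_uncited_gene(self):
        genes = ["A", "B"]
        dep = GeneMatrix(pd.DataFrame(np.zeros((2, 5)), index=genes,
                                      columns=[f"L{i}" for i in range(5)]))
        cites = pd.DataFrame({"term1": [3, 0]}, index=genes)
        out = filter_candidates(self._neighbors(genes), dep, citations=cites)
        assert bool(out.loc["A", "previously_cited"])
        assert not bool(out.loc["B", "previously_cited"])

    def test_nothing_removed_and_matches_scan_oracle(self, small_world):
        genes = small_world.expression.row_ids[:50]
        out = filter_candidates(self._neighbors(genes), small_world.dependency,
                                citations=small_world.citations,
                                druggable={"SUP01", "G00001"},
                                essentiality_threshold=-0.5,
                                essential_fraction=0.9)
        assert len(out) == 50
        dep = small_world.dependency.df
        for g in genes:
            frac = (dep.loc[g] < -0.5).sum() / dep.loc[g].notna().sum()
            assert bool(out.loc[g, "pan_essential"]) == (frac >= 0.9)
            assert bool(out.loc[g, "previously_cited"]) == (
                small_world.citations.loc[g].sum() > 0)
        assert bool(out.loc["SUP01", "druggable"])
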