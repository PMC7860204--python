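"""Nei/Bruvo/genotypic distances, MSN construction, Mantel tests."""

import numpy as np
import pytest

from ssrpop.distances import (
    DistanceMatrix,
    bruvo_distance,
    bruvo_matrix,
    genotypic_sq_matrix,
    genotypic_squared_distance,
    geographic_distance,
    haversine_km,
    mantel_test,
    minimum_spanning_network,
    nei_distance,
    trait_distance,
)
from ssrpop.io import MISSING, AccessionMetadata, LocusInfo

from conftest import make_genotypes


class TestNei:
    def test_identical_tables_zero(self):
        f = {"L1": {200: 0.5, 204: 0.5}, "L2": {150: 1.0}}
        assert nei_distance(f, f) == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_example(self):
        # one locus, p=(1,0) vs (0.5,0.5): I = 0.5/sqrt(0.5) = 0.70711,
        # D = -ln I = 0.34657
        fa = {"L1": {200: 1.0}}
        fb = {"L1": {200: 0.5, 204: 0.5}}
        d = nei_distance(fa, fb)
        assert d == pytest.approx(-np.log(0.5 / np.sqrt(0.5)), abs=1e-9)
        assert d == pytest.approx(0.34657, abs=1e-5)

    def test_symmetry(self):
        fa = {"L1": {200: 0.7, 204: 0.3}, "L2": {150: 0.2, 152: 0.8}}
        fb = {"L1": {200: 0.4, 206: 0.6}, "L2": {150: 1.0}}
        assert nei_distance(fa, fb) == pytest.approx(nei_distance(fb, fa), abs=1e-12)

    def test_disjoint_supports_infinite(self):
        fa = {"L1": {200: 1.0}}
        fb = {"L1": {204: 1.0}}
        with pytest.warns(UserWarning, match="zero genetic identity"):
            assert np.isinf(nei_distance(fa, fb))


class TestBruvo:
    LOCI = [LocusInfo("L1", repeat_unit=4)]

    def test_identical_zero(self):
        a = np.array([[200, 204]])
        assert bruvo_distance(a, a, self.LOCI) == 0.0

    def test_single_repeat_step(self):
        a = np.array([[200, 200]])
        b = np.array([[204, 204]])
        assert bruvo_distance(a, b, self.LOCI) == pytest.approx(0.5, abs=1e-12)

    def test_hand_worked_matching_minimum(self):
        # (200,204) vs (200,208), repeat 4: straight matching mean
        # (0 + 0.5)/2 = 0.25; crossed ((1-2^-1)+(1-2^-2))/2 = 0.625
        a = np.array([[200, 204]])
        b = np.array([[200, 208]])
        assert bruvo_distance(a, b, self.LOCI) == pytest.approx(0.25, abs=1e-12)

    def test_matrix_agrees_with_brute_force_matchings(self, small_panel):
        g = small_panel.genotypes.subset(np.arange(12))
        mat = bruvo_matrix(g)
        rng = np.random.default_rng(3)
        for _ in range(20):
            i, j = rng.choice(12, 2, replace=False)
            expected = bruvo_distance(g.calls[i], g.calls[j], g.loci)
            assert mat.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_bounded_unit_interval(self, small_panel):
        mat = bruvo_matrix(small_panel.genotypes)
        assert mat.values.min() >= 0.0 and mat.values.max() <= 1.0


class TestGenotypicSquared:
    @pytest.mark.parametrize(
        "ga,gb,expected",
        [
            ([(200, 200)], [(200, 204)], 1.0),   # AA vs AB
            ([(200, 200)], [(204, 204)], 4.0),   # AA vs BB
            ([(200, 204)], [(208, 212)], 2.0),   # AB vs CD
            ([(200, 204)], [(200, 204)], 0.0),
        ],
    )
    def test_genotype_pair_values(self, ga, gb, expected):
        d = genotypic_squared_distance(np.array(ga), np.array(gb))
        assert d == pytest.approx(expected, abs=1e-12)

    def test_missing_rescaled_to_full_locus_count(self):
        ga = np.array([(200, 200), (MISSING, MISSING)])
        gb = np.array([(204, 204), (150, 150)])
        # only 1 of 2 loci comparable: 4 * 2/1
        assert genotypic_squared_distance(ga, gb) == pytest.approx(8.0)

    def test_matrix_matches_pairwise_function(self, small_panel):
        g = small_panel.genotypes.subset(np.arange(10))
        mat = genotypic_sq_matrix(g)
        for i in range(10):
            for j in range(i + 1, 10):
                assert mat.values[i, j] == pytest.approx(
                    genotypic_squared_distance(g.calls[i], g.calls[j]), abs=1e-9
                )

    def test_sqrt_triangle_inequality(self):
        # on complete data the distance is half a squared Euclidean norm, so
        # its square root is a metric (per-pair missing-locus rescaling
        # would break this, hence a missing-free panel)
        from ssrpop.simulate import SimulationConfig, simulate_panel

        panel = simulate_panel(
            SimulationConfig.small(n_pops=3, n_per_pop=10, missing_rate=0.0, seed=9)
        )
        g = panel.genotypes.subset(np.arange(20))
        d = np.sqrt(genotypic_sq_matrix(g).values)
        rng = np.random.default_rng(1)
        for _ in range(1000):
            i, j, k = rng.choice(20, 3, replace=False)
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestMSN:
    def test_three_equidistant_nodes_keep_all_edges(self):
        d = DistanceMatrix(["a", "b", "c"], np.array(
            [[0, 1, 1], [1, 0, 1], [1, 1, 0]], float), "bruvo")
        msn = minimum_spanning_network(d)
        assert msn.number_of_edges() == 3
        assert sum(1 for *_, e in msn.edges(data=True) if e["tie"]) == 1

    def test_distinct_weights_give_unique_mst(self):
        vals = np.array([[0, 1, 4], [1, 0, 2], [4, 2, 0]], float)
        d = DistanceMatrix(["a", "b", "c"], vals, "bruvo")
        msn = minimum_spanning_network(d)
        assert msn.number_of_edges() == 2
        assert not msn.has_edge("a", "c")

    def test_contains_mst_of_equal_weight(self, small_panel):
        import networkx as nx

        g = small_panel.genotypes.subset(np.arange(15))
        d = bruvo_matrix(g)
        msn = minimum_spanning_network(d)
        full = nx.Graph()
        for i in range(15):
            for j in range(i + 1, 15):
                full.add_edge(d.labels[i], d.labels[j], weight=d.values[i, j])
        mst_weight = nx.minimum_spanning_tree(full).size(weight="weight")
        mst_edges = [(u, v) for u, v, e in msn.edges(data=True) if e["in_mst"]]
        assert len(mst_edges) == 14
        sub_weight = sum(msn[u][v]["weight"] for u, v in mst_edges)
        assert sub_weight == pytest.approx(mst_weight, abs=1e-12)


class TestTraitGeo:
    def test_trait_distance_single_difference(self, small_panel):
        t = small_panel.traits
        d = trait_distance(t)
        # brute force a handful of pairs
        rng = np.random.default_rng(2)
        for _ in range(10):
            i, j = rng.choice(t.n_accessions, 2, replace=False)
            expected = np.sqrt(((t.codes[i] - t.codes[j]) ** 2).sum())
            assert d.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_antipodal_haversine(self):
        assert haversine_km(0.0, 0.0, 0.0, 180.0) == pytest.approx(20015.1, abs=0.5)

    def test_identical_coordinates_zero(self):
        meta = [
            AccessionMetadata("a", lat=35.0, lon=10.0),
            AccessionMetadata("b", lat=35.0, lon=10.0),
        ]
        d = geographic_distance(meta)
        assert d.values[0, 1] == 0.0

    def test_log_transform_monotone_and_missing_excluded(self):
        meta = [
            AccessionMetadata("a", lat=35.0, lon=10.0),
            AccessionMetadata("b", lat=35.5, lon=10.0),
            AccessionMetadata("c", lat=36.5, lon=10.0),
            AccessionMetadata("d"),
        ]
        with pytest.warns(UserWarning, match="without coordinates"):
            d = geographic_distance(meta)
        assert d.labels == ["a", "b", "c"]
        raw = geographic_distance(meta[:3], log_transform=False)
        assert raw.values[0, 2] > raw.values[0, 1]
        assert d.values[0, 2] > d.values[0, 1]
        assert d.values[0, 1] == pytest.approx(np.log1p(raw.values[0, 1]), abs=1e-12)


class TestMantel:
    def _random_dm(self, n, seed, labels=None):
        rng = np.random.default_rng(seed)
        x = rng.random((n, 3))
        d = np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(axis=2))
        return DistanceMatrix(labels or [f"a{i}" for i in range(n)], d, "trait")

    def test_self_correlation(self):
        d = self._random_dm(15, 0)
        r, p = mantel_test(d, d, n_perm=99, seed=1)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p == pytest.approx(1 / 100)

    def test_positive_affine_transform_preserves_r(self):
        d = self._random_dm(15, 2)
        d2 = DistanceMatrix(d.labels, 3.0 * d.values, d.kind)
        r, _ = mantel_test(d, d2, n_perm=49, seed=3)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_independent_matrices_rarely_significant(self):
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            da = self._random_dm(30, 100 + seed)
            db = self._random_dm(30, 500 + seed)
            r, p = mantel_test(da, db, n_perm=199, seed=seed)
            if abs(r) < 0.2 and p > 0.05:
                hits += 1
        assert hits >= 0.85 * n_seeds

    def test_constant_matrix_rejected(self):
        d = DistanceMatrix(["a", "b", "c"], np.ones((3, 3)) - np.eye(3), "trait")
        with pytest.raises(ValueError, match="constant"):
            mantel_test(d, d, n_perm=9, seed=0)


def test_distance_matrix_invariants(small_panel):
    for dm in (
        bruvo_matrix(small_panel.genotypes),
        trait_distance(small_panel.traits),
    ):
        assert np.allclose(dm.values, dm.values.T, atol=1e-12)
        assert (np.diag(dm.values) == 0).all()
        assert dm.values.min() >= 0
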