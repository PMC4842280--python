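import math

import numpy as np
import pytest

from kdrscape import (
    Alignment,
    DistanceMatrix,
    PopulationSet,
    great_circle,
    ibd_inputs,
    landscape_surface,
    mantel,
    samova,
)
from kdrscape.spatial import linearize_fst, samova_exhaustive


class TestGreatCircle:
    def test_identical_points(self):
        assert great_circle((10.0, 20.0), (10.0, 20.0)) == 0.0

    def test_quarter_circumference(self):
        assert great_circle((0.0, 0.0), (0.0, 90.0)) == pytest.approx(
            math.pi * 6371 / 2, rel=1e-6
        )

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = (rng.uniform(-90, 90), rng.uniform(-180, 180))
            b = (rng.uniform(-90, 90), rng.uniform(-180, 180))
            assert great_circle(a, b) == pytest.approx(great_circle(b, a))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            great_circle((95.0, 0.0), (0.0, 0.0))


class TestMantel:
    def _random_dm(self, rng, n):
        m = rng.uniform(1, 10, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        return DistanceMatrix([f"p{i}" for i in range(n)], m)

    def test_identical_matrices_perfect_correlation(self):
        rng = np.random.default_rng(1)
        dx = self._random_dm(rng, 8)
        res = mantel(dx, dx, perms=200, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p <= 2 / 201

    def test_constant_matrix_flagged_undefined(self):
        n = 5
        c = np.ones((n, n)) - np.eye(n)
        dx = DistanceMatrix([f"p{i}" for i in range(n)], c)
        dy = self._random_dm(np.random.default_rng(2), n)
        assert not mantel(dx, dy, perms=100).defined

    def test_correlation_decreases_with_noise(self):
        rng = np.random.default_rng(3)
        dx = self._random_dm(rng, 10)
        rs = []
        for scale in (0.1, 2.0, 20.0):
            noise = rng.normal(0, scale, size=dx.d.shape)
            noise = (noise + noise.T) / 2
            y = 2 * dx.d + noise
            np.fill_diagonal(y, 0)
            res = mantel(dx, DistanceMatrix(dx.labels, y), perms=100, seed=0)
            rs.append(res.r)
        assert rs[0] > rs[1] > rs[2]

    def test_matches_scikit_bio_statistic(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(4)
        dx = self._random_dm(rng, 9)
        dy = self._random_dm(rng, 9)
        r_ref, _, _ = skbio_mantel(
            SkbioDM(dx.d, dx.labels), SkbioDM(dy.d, dy.labels),
            permutations=0, alternative="greater",
        )
        res = mantel(dx, dy, perms=100, seed=0)
        assert res.r == pytest.approx(float(r_ref), abs=1e-9)


class TestIbd:
    def test_linearisation(self):
        assert linearize_fst(np.array([0.0]))[0] == 0.0
        assert linearize_fst(np.array([0.5]))[0] == pytest.approx(1.0)
        assert np.isfinite(linearize_fst(np.array([1.0]))[0])

    def test_stepping_stone_shows_isolation_by_distance(self):
        from kdrscape.synth import Demography, SimConfig, neutral_layout, simulate_dataset

        # a single non-recombining locus carries one genealogy, so short
        # chains give little Mantel power; a 12-deme chain detects reliably
        hits = 0
        reps = 10
        for rep in range(reps):
            cfg = SimConfig(
                n_demes=12, samples_per_deme=10, migration_rate=2.0,
                theta_per_site=0.02, layout=neutral_layout(300),
                migration_model="stepping_stone",
                deme_coords=[(20.0, 100.0 + 2 * i) for i in range(12)],
                seed=100 + rep,
            )
            aln, pops, _ = simulate_dataset(cfg)
            geo, gen = ibd_inputs(aln, pops, mode="phist")
            res = mantel(geo, gen, perms=199, seed=rep)
            if res.p < 0.05:
                hits += 1
        assert hits >= 8  # IBD detected in most replicates


class TestSamova:
    def _two_cluster_bundle(self):
        seqs = {"p1": "AAAA", "p2": "AAAT", "p3": "TTTA", "p4": "TTTT"}
        ids, sequences, assign = [], [], {}
        for p, s in seqs.items():
            for k in range(4):
                sid = f"{p}_{k}"
                ids.append(sid)
                sequences.append(s)
                assign[sid] = p
        aln = Alignment(ids, sequences)
        pops = PopulationSet(assign)
        return aln, pops

    def test_recovers_known_bipartition(self):
        aln, pops = self._two_cluster_bundle()
        res = samova(aln, pops, K_range=[2], runs=5, iters=300, seed=0)[0]
        g = res.best_grouping
        assert g["p1"] == g["p2"] and g["p3"] == g["p4"] and g["p1"] != g["p3"]
        # exhaustive oracle over the 7 bipartitions agrees
        _, best_f = samova_exhaustive(aln, pops, K=2)
        assert res.fct == pytest.approx(best_f)

    def test_k_equal_to_pops_degenerate(self):
        aln, pops = self._two_cluster_bundle()
        res = samova(aln, pops, K_range=[4], runs=2, iters=100, seed=0)[0]
        assert res.degenerate and math.isnan(res.fsc)

    def test_k_larger_than_pops_rejected(self):
        aln, pops = self._two_cluster_bundle()
        with pytest.raises(ValueError):
            samova(aln, pops, K_range=[5], runs=1, iters=10)

    def test_matches_exhaustive_on_structured_data(self, small_neutral_bundle):
        aln, pops, _ = small_neutral_bundle
        for K in (2, 3):
            res = samova(aln, pops, K_range=[K], runs=8, iters=800, seed=2)[0]
            _, best_f = samova_exhaustive(aln, pops, K=K)
            assert res.fct == pytest.approx(best_f, abs=1e-9)

    def test_isolated_deme_assigned_own_group(self, mimic_bundle):
        aln, pops, _ = mimic_bundle
        # southwest demes are nearly isolated: K=2 best split separates at
        # least one of them from the connected south/central demes
        keep = ["SW1", "SW2", "SO1", "SO2", "SO3", "CE1"]
        ids = [s for s in aln.ids if pops.sample_to_pop[s] in keep]
        sub = aln.subset(ids)
        sub_pops = PopulationSet({s: pops.sample_to_pop[s] for s in ids})
        grouping, _ = samova_exhaustive(sub, sub_pops, K=2)
        sw = {grouping["SW1"], grouping["SW2"]}
        rest = {grouping[p] for p in ("SO1", "SO2", "SO3", "CE1")}
        assert sw != rest  # the isolated pair does not dissolve into the rest


class TestLandscape:
    def _pops(self, coords):
        return PopulationSet(
            {f"s{i}": f"p{i}" for i in range(len(coords))},
            {f"p{i}": c for i, c in enumerate(coords)},
        )

    def test_constant_distances_flat_surface(self):
        coords = [(20.0, 100.0), (21.0, 103.0), (23.0, 101.0), (24.0, 104.0)]
        pops = self._pops(coords)
        labels = [f"p{i}" for i in range(4)]
        d = np.full((4, 4), 3.0)
        np.fill_diagonal(d, 0)
        gen = DistanceMatrix(labels, d)
        surf = landscape_surface(pops, gen, grid=(12, 12), alpha=1.0)
        assert np.allclose(surf.grid, 3.0)

    def test_ridge_between_divergent_clusters(self):
        # two tight clusters, high between-cluster distances: the surface
        # peaks between them
        coords = [(20.0, 100.0), (20.5, 100.4), (20.0, 108.0), (20.5, 108.4)]
        pops = self._pops(coords)
        labels = [f"p{i}" for i in range(4)]
        d = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                same = (i < 2) == (j < 2)
                d[i, j] = 0.0 if i == j else (0.1 if same else 5.0)
        surf = landscape_surface(pops, self._popsafe(labels, d), grid=(40, 8))
        mid_col = surf.grid[:, surf.grid.shape[1] // 2]
        edge_col = surf.grid[:, 0]
        assert mid_col.max() > edge_col.mean()

    def _popsafe(self, labels, d):
        return DistanceMatrix(labels, d)

    def test_surface_within_input_range(self):
        rng = np.random.default_rng(5)
        coords = [(20 + rng.uniform(0, 5), 100 + rng.uniform(0, 5)) for _ in range(6)]
        pops = self._pops(coords)
        labels = [f"p{i}" for i in range(6)]
        d = rng.uniform(1, 4, size=(6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        gen = DistanceMatrix(labels, d)
        surf = landscape_surface(pops, gen, grid=(10, 10), alpha=1.0)
        vals = [gen.d[a, b] for a, b in
                [(labels.index(x), labels.index(y)) for x, y in surf.edges]]
        assert surf.grid.min() >= min(vals) - 1e-9
        assert surf.grid.max() <= max(vals) + 1e-9

    def test_large_alpha_approaches_nearest_midpoint(self):
        coords = [(20.0, 100.0), (20.0, 104.0), (23.0, 102.0)]
        pops = self._pops(coords)
        labels = ["p0", "p1", "p2"]
        d = np.array([[0, 1.0, 2.0], [1.0, 0, 3.0], [2.0, 3.0, 0]])
        gen = DistanceMatrix(labels, d)
        surf = landscape_surface(pops, gen, grid=(15, 15), alpha=40.0)
        # away from midpoint boundaries the surface collapses to the
        # nearest midpoint's value
        flat = surf.grid.ravel()
        dist_to_vals = np.min(
            np.abs(flat[:, None] - np.array([1.0, 2.0, 3.0])[None, :]), axis=1
        )
        assert np.quantile(dist_to_vals, 0.75) < 0.05

    def test_collinear_points_fall_back_to_complete_graph(self):
        coords = [(20.0, 100.0 + i) for i in range(4)]
        pops = self._pops(coords)
        labels = [f"p{i}" for i in range(4)]
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0)
        surf = landscape_surface(pops, DistanceMatrix(labels, d), grid=(8, 8))
        assert not surf.used_delaunay
        assert len(surf.edges) == 6
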