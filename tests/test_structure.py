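import itertools

import numpy as np
import pytest

from kdrscape import (
    Alignment,
    DistanceMatrix,
    HaplotypeTable,
    PopulationSet,
    amova,
    collapse_haplotypes,
    nei_distance,
    pairwise_differentiation,
    upgma,
)
from kdrscape.structure import sequence_distances, significant_pair_count

from conftest import random_alignment


def _make_pops(assignment: dict[str, str]) -> PopulationSet:
    return PopulationSet(assignment)


def brute_force_amova(d2, pop_of, group_of_pop):
    """Independent oracle: sums of squares written directly from their
    definitions as double loops over individuals."""
    N = len(pop_of)
    pops = sorted(set(pop_of))
    def ss(members):
        total = 0.0
        for i, j in itertools.combinations(members, 2):
            total += d2[i][j]
        return total / len(members)
    ss_total = ss(range(N))
    ss_wp = sum(ss([i for i in range(N) if pop_of[i] == p]) for p in pops)
    groups = sorted(set(group_of_pop.values()))
    ss_wg = sum(
        ss([i for i in range(N) if group_of_pop[pop_of[i]] == g])
        for g in groups
    )
    G, P = len(groups), len(pops)
    df_a, df_b, df_c = G - 1, P - G, N - P
    ms_a = (ss_total - ss_wg) / df_a
    ms_b = (ss_wg - ss_wp) / df_b if df_b else 0.0
    ms_c = ss_wp / df_c if df_c else 0.0
    n_p = {p: sum(1 for x in pop_of if x == p) for p in pops}
    n_g = {g: sum(n_p[p] for p in pops if group_of_pop[p] == g) for g in groups}
    sum_npg = sum(
        sum(n_p[p] ** 2 for p in pops if group_of_pop[p] == g) / n_g[g]
        for g in groups
    )
    n1 = (N - sum_npg) / df_b if df_b else 0.0
    n2 = (sum_npg - sum(v**2 for v in n_p.values()) / N) / df_a
    n3 = (N - sum(v**2 for v in n_g.values()) / N) / df_a
    sc = ms_c
    sb = (ms_b - sc) / n1 if n1 else 0.0
    sa = (ms_a - sc - n2 * sb) / n3
    return sa, sb, sc


class TestPairwiseDifferentiation:
    def test_fixed_difference_gives_fst_one(self):
        ids = [f"x{i}" for i in range(16)]
        aln = Alignment(ids, ["AAA"] * 8 + ["TTT"] * 8)
        pops = _make_pops(
            {s: ("p1" if i < 8 else "p2") for i, s in enumerate(ids)}
        )
        dm, pmat = pairwise_differentiation(
            aln, pops, mode="phist", perms=200, seed=0
        )
        assert dm.d[0, 1] == pytest.approx(1.0)
        # only a permutation reproducing the exact split can tie F_ST = 1
        assert pmat[0, 1] <= 2 / 201

    def test_identical_compositions_give_fst_zero(self):
        aln = Alignment(
            ["a", "b", "c", "d"], ["AAA", "TTT", "AAA", "TTT"]
        )
        pops = _make_pops({"a": "p1", "b": "p1", "c": "p2", "d": "p2"})
        dm, pmat = pairwise_differentiation(aln, pops, mode="fst_freq", perms=100)
        assert dm.d[0, 1] <= 0.0 + 1e-12  # unbiased estimator goes negative
        assert pmat[0, 1] > 0.5

    def test_hand_amova_on_four_sequences(self):
        # 2 pops × 2 seqs, one fixed difference between, none within:
        # all variance among populations → F_ST = 1
        aln = Alignment(["a", "b", "c", "d"], ["A", "A", "T", "T"])
        pops = _make_pops({"a": "p1", "b": "p1", "c": "p2", "d": "p2"})
        dm, _ = pairwise_differentiation(aln, pops, mode="phist", perms=0)
        assert dm.d[0, 1] == pytest.approx(1.0)

    def test_small_population_excluded(self):
        aln = Alignment(["a", "b", "c"], ["A", "T", "T"])
        pops = _make_pops({"a": "p1", "b": "p2", "c": "p2"})
        dm, _ = pairwise_differentiation(aln, pops, perms=0)
        assert dm.labels == ["p2"]


class TestAmova:
    def test_one_population_per_group_all_variance_among_groups(self):
        aln = Alignment(["a", "b", "c", "d"], ["AA", "AA", "TT", "TT"])
        pops = _make_pops({"a": "p1", "b": "p1", "c": "p2", "d": "p2"})
        res = amova(aln, pops, grouping={"p1": "g1", "p2": "g2"}, perms=0)
        assert res.percentages[0] == pytest.approx(100.0)
        assert res.phi["F_CT"] == pytest.approx(1.0)

    def test_homogeneous_populations_only_within_variance(self):
        aln = Alignment(
            ["a", "b", "c", "d", "e", "f"],
            ["AA", "TT", "AA", "TT", "AA", "TT"],
        )
        pops = _make_pops(
            {"a": "p1", "b": "p1", "c": "p2", "d": "p2", "e": "p3", "f": "p3"}
        )
        res = amova(aln, pops, grouping={"p1": "g1", "p2": "g1", "p3": "g2"}, perms=0)
        assert res.percentages[2] > 99.0 or res.percentages[2] == pytest.approx(100.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            n_per = rng.integers(2, 5, size=3)
            ids, assign = [], {}
            for pi, np_ in enumerate(n_per):
                for k in range(np_):
                    sid = f"p{pi}_{k}"
                    ids.append(sid)
                    assign[sid] = f"p{pi}"
            aln = random_alignment(rng, len(ids), 8)
            aln = Alignment(ids, aln.seqs)
            pops = _make_pops(assign)
            grouping = {"p0": "g1", "p1": "g1", "p2": "g2"}
            res = amova(aln, pops, grouping=grouping, mode="phist", perms=0)
            d2 = sequence_distances(aln, "phist")
            oracle = brute_force_amova(
                d2, [assign[s] for s in ids], grouping
            )
            assert res.variance_components == pytest.approx(oracle, abs=1e-9)
            assert sum(res.percentages) == pytest.approx(100.0)
            # F_ST identity on the variance components
            sa, sb, sc = oracle
            tot = sa + sb + sc
            if tot != 0:
                assert res.phi["F_ST"] == pytest.approx((sa + sb) / tot)

    def test_single_group_falls_back_to_one_level(self):
        aln = Alignment(["a", "b", "c", "d"], ["AA", "AT", "TT", "TA"])
        pops = _make_pops({"a": "p1", "b": "p1", "c": "p2", "d": "p2"})
        res = amova(aln, pops, grouping={"p1": "g", "p2": "g"}, perms=0)
        assert not res.two_level
        assert "F_CT" not in res.phi

    def test_permutation_pvalues_in_valid_range(self, mimic_bundle):
        aln, pops, _ = mimic_bundle
        sub_ids = [s for s in aln.ids if pops.sample_to_pop[s] in
                   ("SW1", "SO1", "CE1", "CE2")]
        sub = aln.subset(sub_ids)
        res = amova(
            sub, PopulationSet(
                {s: pops.sample_to_pop[s] for s in sub_ids}),
            grouping={"SW1": "a", "SO1": "a", "CE1": "b", "CE2": "b"},
            perms=100, seed=1,
        )
        for p in res.pvals.values():
            assert 1 / 101 <= p <= 1.0


class TestNeiDistance:
    def test_identical_frequencies_near_zero(self):
        tab = HaplotypeTable(
            ["H1", "H2"], np.array([[50, 50], [50, 50]]), ["p1", "p2"]
        )
        assert nei_distance(tab).d[0, 1] == pytest.approx(0.0, abs=0.05)

    def test_disjoint_sets_capped(self):
        tab = HaplotypeTable(
            ["H1", "H2"], np.array([[10, 0], [0, 10]]), ["p1", "p2"]
        )
        assert nei_distance(tab, cap=10.0).d[0, 1] == 10.0

    def test_hand_computed_shared_haplotype(self):
        # both pops n=10; p1: H1/H2 at 5/5, p2: H1/H3 at 5/5
        tab = HaplotypeTable(
            ["H1", "H2", "H3"],
            np.array([[5, 5], [5, 0], [0, 5]]),
            ["p1", "p2"],
        )
        jx = (10 * 0.5 - 1) / 9  # unbiased within-identity
        d_expected = -np.log(0.25 / jx)
        assert nei_distance(tab).d[0, 1] == pytest.approx(d_expected)

    def test_small_sample_rejected(self):
        tab = HaplotypeTable(["H1"], np.array([[1, 5]]), ["p1", "p2"])
        with pytest.raises(ValueError):
            nei_distance(tab)


class TestUpgma:
    def test_hand_agglomeration(self):
        dm = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        )
        assert upgma(dm) == "((A:1,B:1):1,C:2);"

    def test_two_taxa(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 2], [2, 0]], float))
        assert upgma(dm) == "(A:1,B:1);"

    def test_reproduces_ultrametric_hierarchy(self):
        # cophenetic matrix of an average-linkage dendrogram is ultrametric;
        # UPGMA on it must reproduce the generating heights exactly
        import dendropy
        from scipy.cluster.hierarchy import average, cophenet
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(1)
        for _ in range(5):
            pts = rng.normal(size=(6, 3))
            Z = average(pdist(pts))
            coph = squareform(cophenet(Z))
            labels = [f"t{i}" for i in range(6)]
            nwk = upgma(DistanceMatrix(labels, coph))
            tree = dendropy.Tree.get(data=nwk, schema="newick")
            pdm = tree.phylogenetic_distance_matrix()
            taxa = {t.label: t for t in tree.taxon_namespace}
            for i in range(6):
                for j in range(i + 1, 6):
                    got = pdm.patristic_distance(taxa[f"t{i}"], taxa[f"t{j}"])
                    assert got == pytest.approx(coph[i, j], abs=1e-6)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], np.array([[0, np.nan], [np.nan, 0]]))


class TestSignificantPairCount:
    def test_counting_with_corrections(self):
        pmat = np.array(
            [[1.0, 0.001, 0.5], [0.001, 1.0, 0.04], [0.5, 0.04, 1.0]]
        )
        assert significant_pair_count(pmat, correction="none") == 2
        assert significant_pair_count(pmat, correction="bonferroni") == 1
        assert significant_pair_count(pmat, correction="fdr") >= 1
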