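import itertools

import networkx as nx
import numpy as np
import pytest
from Bio.Seq import Seq

from kdrscape import (
    Alignment,
    HaplotypeTable,
    PopulationSet,
    build_network,
    classify_kdr_codon,
    count_origin_events,
    informative_sites,
    kdr_fragment_layout,
    network_states,
)
from kdrscape.kdrnet import classify_codon, network_edge_table
from kdrscape.seqdata import FragmentLayout
from kdrscape.synth import WILD_CODON


LAYOUT = FragmentLayout(
    [("exon", 1, 3), ("intron", 4, 9)], codon_span=(1, 3)
)


def _aln_with_codons(codons_backgrounds, pops=None):
    """Alignment of codon + 6-bp intron; entries (codon, background, count)."""
    ids, seqs, assign = [], [], {}
    k = 0
    for codon, background, count, pop in codons_backgrounds:
        for _ in range(count):
            sid = f"s{k}"
            ids.append(sid)
            seqs.append(codon + background)
            assign[sid] = pop
            k += 1
    return Alignment(ids, seqs), PopulationSet(assign)


class TestCodonClassification:
    def test_reference_codons(self):
        assert classify_codon("TTG").allele_class == "wild_L"
        assert classify_codon("TTT").allele_class == "F"
        assert classify_codon("TGT").allele_class == "C"
        assert classify_codon("TCG").allele_class == "S"
        assert classify_codon("TGG").allele_class == "W"
        assert classify_codon("GGG").allele_class == "other"

    def test_all_64_codons_agree_with_translation_oracle(self):
        classes = {"L": "wild_L", "F": "F", "C": "C", "S": "S", "W": "W"}
        for codon in ("".join(c) for c in itertools.product("ACGT", repeat=3)):
            aa = str(Seq(codon).translate())
            expected = classes.get(aa, "other")
            got = classify_codon(codon)
            assert got.amino_acid == aa
            assert got.allele_class == expected

    def test_ambiguous_codon_flagged_unresolved(self):
        assert classify_codon("TNG").allele_class == "unresolved"

    def test_per_sequence_classification_with_layout(self):
        aln, _ = _aln_with_codons(
            [("TTG", "AAAAAA", 1, "p"), ("TTT", "AAAAAA", 1, "p")]
        )
        alleles = classify_kdr_codon(aln, LAYOUT)
        assert [a.allele_class for a in alleles] == ["wild_L", "F"]


class TestAlleleFrequencies:
    def test_frequencies_sum_to_one_and_match_counts(self):
        from kdrscape import allele_frequencies

        aln, pops = _aln_with_codons(
            [("TTT", "AAAAAA", 8, "d1"), ("TTG", "AAAAAA", 2, "d1"),
             ("TTG", "CCCCCC", 5, "d2")]
        )
        alleles = classify_kdr_codon(aln, LAYOUT)
        fr = allele_frequencies(alleles, aln.ids, pops)
        assert fr.loc["d1", "F"] == pytest.approx(0.8)
        assert fr.loc["d1", "wild_L"] == pytest.approx(0.2)
        assert fr.loc["d2", "wild_L"] == pytest.approx(1.0)
        assert fr.sum(axis=1).tolist() == pytest.approx([1.0, 1.0])


class TestInformativeSites:
    def test_maf_threshold(self):
        # intron col 4: 50/50 split (selected); col 5: 1/99 (excluded)
        seqs = []
        for i in range(100):
            c4 = "A" if i < 50 else "T"
            c5 = "G" if i > 0 else "C"
            seqs.append("TTG" + c4 + c5 + "AAAA")
        aln = Alignment([f"s{i}" for i in range(100)], seqs)
        sel = informative_sites(aln, LAYOUT, maf=0.10)
        assert 4 in sel and 5 not in sel

    def test_codon_variable_positions_appended(self):
        aln, _ = _aln_with_codons(
            [("TTG", "AAAAAA", 5, "p"), ("TTT", "AAAAAA", 5, "p")]
        )
        sel = informative_sites(aln, LAYOUT, maf=0.10)
        assert sel[-1] == 3  # third codon base varies

    def test_invalid_maf(self):
        aln, _ = _aln_with_codons([("TTG", "AAAAAA", 2, "p")])
        with pytest.raises(ValueError):
            informative_sites(aln, LAYOUT, maf=0.6)


def brute_force_msn(haps, limit):
    """Independent oracle: an edge (a, b, w) belongs to the minimum-spanning
    network iff its endpoints are not connected using all candidate edges of
    weight strictly smaller than w."""
    def ham(a, b):
        return sum(x != y for x, y in zip(a, b))

    candidates = [
        (ham(a, b), a, b)
        for a, b in itertools.combinations(haps, 2)
        if ham(a, b) <= limit
    ]
    edges = set()
    for w, a, b in candidates:
        G = nx.Graph()
        G.add_nodes_from(haps)
        G.add_edges_from(
            (x, y) for ww, x, y in candidates if ww < w
        )
        if not nx.has_path(G, a, b):
            edges.add(frozenset((a, b)))
    return edges


class TestBuildNetwork:
    def test_chain_with_frequency_root_probabilities(self):
        tab = HaplotypeTable(
            ["AA", "AT", "TT"], np.array([[5], [3], [1]]), ["p"]
        )
        net = build_network(tab, connection_limit=2)
        assert set(map(frozenset, net.graph.edges)) == {
            frozenset(("AA", "AT")), frozenset(("AT", "TT"))
        }
        rp = nx.get_node_attributes(net.graph, "root_probability")
        assert max(rp, key=rp.get) == "AA"
        assert sum(rp.values()) == pytest.approx(1.0)

    def test_single_haplotype(self):
        tab = HaplotypeTable(["ACGT"], np.array([[4]]), ["p"])
        net = build_network(tab)
        assert net.graph.number_of_nodes() == 1
        assert net.graph.number_of_edges() == 0

    def test_connection_limit_splits_components(self):
        tab = HaplotypeTable(["AAA", "TTT"], np.array([[2], [2]]), ["p"])
        net = build_network(tab, connection_limit=2)
        assert len(net.components()) == 2

    def test_matches_brute_force_msn_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n_h = rng.integers(2, 7)
            haps = set()
            while len(haps) < n_h:
                haps.add("".join(rng.choice(list("AT"), size=4)))
            haps = sorted(haps)
            tab = HaplotypeTable(
                haps, rng.integers(1, 9, size=(len(haps), 1)), ["p"]
            )
            net = build_network(tab, connection_limit=2)
            got = set(map(frozenset, net.graph.edges))
            assert got == brute_force_msn(haps, 2)

    def test_edge_table_mutation_labels(self):
        tab = HaplotypeTable(["GA", "TA"], np.array([[3], [1]]), ["p"])
        net = build_network(tab)
        df = network_edge_table(net)
        assert df.loc[0, "mutations"] == "G-1-T"


class TestOriginCounting:
    def _net(self, entries, maf=0.10):
        aln, pops = _aln_with_codons(entries)
        states, sites, cidx = network_states(aln, pops, LAYOUT, maf)
        return build_network(states, codon_site_idx=cidx, sites=sites)

    def test_single_origin_on_shared_background(self):
        net = self._net(
            [("TTG", "AAATAA", 5, "p"), ("TTT", "AAATAA", 5, "p"),
             ("TTG", "CCCTCC", 4, "p")]
        )
        rep = count_origin_events(net, LAYOUT)
        assert rep.n_events == 1
        assert rep.events[0].allele == "F"
        assert rep.n_backgrounds == 1

    def test_two_origins_on_distinct_backgrounds(self):
        # wild centre, two F derivatives on different intron backgrounds
        net = self._net(
            [("TTG", "AAAAAA", 6, "p"), ("TTG", "TTTTTT", 6, "p"),
             ("TTT", "AAAAAA", 3, "p"), ("TTT", "TTTTTT", 3, "p")],
            maf=0.2,
        )
        rep = count_origin_events(net, LAYOUT)
        assert rep.n_events == 2
        assert rep.n_backgrounds == 2
        assert rep.n_resistant_haplotypes == 2

    def test_secondary_mutation_counts_as_new_origin(self):
        # wild → F (TTG→TTT) → C (TTT→TGT): C is a further origin event
        net = self._net(
            [("TTG", "AAAAAA", 8, "p"), ("TTT", "AAAAAA", 4, "p"),
             ("TGT", "AAAAAA", 1, "p")]
        )
        rep = count_origin_events(net, LAYOUT)
        alleles = sorted(e.allele for e in rep.events)
        assert alleles == ["C", "F"]

    def test_component_without_wild_counts_founder(self):
        # resistant-only component far from the wild node
        net = self._net(
            [("TTG", "AAAAAA", 5, "p"), ("TTT", "GGGTTT", 5, "p")],
            maf=0.2,
        )
        rep = count_origin_events(net, LAYOUT)
        assert rep.n_events >= 1
        assert rep.lower_bound

    def test_invariant_under_relabeling(self):
        entries = [
            ("TTG", "AAAAAA", 6, "p"), ("TTT", "AAAAAA", 3, "p"),
            ("TTG", "TTTTTT", 5, "p"), ("TCG", "TTTTTT", 2, "p"),
        ]
        rep1 = count_origin_events(self._net(entries, maf=0.2), LAYOUT)
        rep2 = count_origin_events(
            self._net(list(reversed(entries)), maf=0.2), LAYOUT
        )
        assert rep1.n_events == rep2.n_events
        assert sorted(e.allele for e in rep1.events) == sorted(
            e.allele for e in rep2.events
        )


class TestEndToEndSweepRecovery:
    def test_two_implanted_backgrounds_detected(self):
        from kdrscape.synth import (
            Demography, SimConfig, SweepConfig, simulate_dataset,
        )

        cfg = SimConfig(
            n_demes=3, samples_per_deme=25, migration_rate=2.0,
            theta_per_site=0.01, demography=Demography(),
            sweep=SweepConfig(
                target_demes=["D01", "D02"], allele="F",
                final_frequency=0.9, background_count=2,
            ),
            seed=21,
        )
        aln, pops, layout = simulate_dataset(cfg)
        states, sites, cidx = network_states(aln, pops, layout, maf=0.10)
        net = build_network(states, codon_site_idx=cidx, sites=sites)
        rep = count_origin_events(net, layout)
        assert rep.n_events >= 2
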