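"""kdr-specific analyses: codon classification, allele frequencies,
informative-site selection, statistical-parsimony (minimum-spanning)
haplotype networks, and counting of independent resistance-mutation origins.

The focal codon is the leucine codon of the voltage-gated sodium channel
(position L1014 in the house-fly numbering); replacement by phenylalanine,
cysteine, serine or tryptophan confers knockdown resistance (kdr) to
pyrethroids. The network connects haplotype states over a small set of
informative sites by mutational steps up to a fixed connection limit (two
steps, carried with the conventional 0.95 parsimony probability as
metadata); an origin event is an edge along which the codon class changes
away from the ancestral (higher root-probability) side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .diversity import base_counts
from .seqdata import (
    Alignment,
    FragmentLayout,
    HaplotypeTable,
    PopulationSet,
    collapse_haplotypes,
    extract_columns,
)

AA_TO_CLASS = {"L": "wild_L", "F": "F", "C": "C", "S": "S", "W": "W"}
RESISTANT_CLASSES = ("F", "C", "S", "W")


@dataclass
class KdrAllele:
    codon: str
    amino_acid: str
    allele_class: str


def classify_codon(codon: str) -> KdrAllele:
    """Translate one 3-base codon and assign its resistance class."""
    codon = codon.upper()
    if len(codon) != 3:
        raise ValueError(f"codon must have 3 bases, got {codon!r}")
    if set(codon) - set("ACGT"):
        return KdrAllele(codon, "X", "unresolved")
    aa = str(Seq(codon).translate())
    return KdrAllele(codon, aa, AA_TO_CLASS.get(aa, "other"))


def classify_kdr_codon(
    aln: Alignment, layout: FragmentLayout
) -> list[KdrAllele]:
    """Per-sequence codon classification at the layout's focal codon."""
    cols = layout.codon_columns()
    sub = extract_columns(aln, cols)
    return [classify_codon(s) for s in sub.seqs]


def allele_frequencies(
    alleles: list[KdrAllele], sample_ids: list[str], pops: PopulationSet
) -> pd.DataFrame:
    """Per-population frequency of each allele class (rows sum to 1)."""
    if len(alleles) != len(sample_ids):
        raise ValueError("alleles and sample ids differ in length")
    missing = [s for s in sample_ids if s not in pops.sample_to_pop]
    if missing:
        raise KeyError(f"samples without population: {missing}")
    classes = ["wild_L", *RESISTANT_CLASSES, "other", "unresolved"]
    rows: dict[str, dict[str, int]] = {}
    for a, s in zip(alleles, sample_ids):
        pop = pops.sample_to_pop[s]
        rows.setdefault(pop, {c: 0 for c in classes})[a.allele_class] += 1
    out = pd.DataFrame.from_dict(rows, orient="index")[classes]
    return out.div(out.sum(axis=1), axis=0)


def informative_sites(
    aln: Alignment, layout: FragmentLayout, maf: float = 0.10
) -> list[int]:
    """Intron columns with minor-allele frequency above *maf* (over all
    chromosomes, gaps/N excluded from the frequency), in original
    1-based fragment coordinates, followed by the codon's variable
    positions as designated sites."""
    if not 0.0 < maf < 0.5:
        raise ValueError("maf must lie in (0, 0.5)")
    arr = aln.to_array()
    counts = base_counts(arr)
    totals = counts.sum(axis=0).astype(float)
    intron_cols = set(layout.columns({"intron"}))
    selected: list[int] = []
    for col in sorted(intron_cols):
        tot = totals[col - 1]
        if tot == 0:
            continue
        c = np.sort(counts[:, col - 1])[::-1]
        minor = tot - c[0]
        if minor / tot > maf:
            selected.append(col)
    codon_sites = []
    for col in layout.codon_columns():
        col_counts = counts[:, col - 1]
        if (col_counts > 0).sum() >= 2:
            codon_sites.append(col)
    return selected + codon_sites


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------

@dataclass
class HaploNetwork:
    """Haplotype states over the selected sites, joined by mutational steps.

    graph: networkx Graph; node keys are state strings; node attributes
    carry frequency, per-population counts, codon state, intron background
    and root probability; edge attributes carry the step count and per-site
    mutation labels ("from-siteindex-to"). Components may be disconnected.
    """

    graph: nx.Graph
    sites: list[int]  # original coordinates of the selected sites
    codon_site_idx: list[int]  # indices into `sites` that are codon positions
    connection_limit: int = 2
    prob_threshold: float = 0.95

    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]


def _mutation_labels(a: str, b: str) -> list[str]:
    return [
        f"{x}-{i + 1}-{y}" for i, (x, y) in enumerate(zip(a, b)) if x != y
    ]


def build_network(
    states: HaplotypeTable,
    connection_limit: int = 2,
    codon_site_idx: list[int] | None = None,
    sites: list[int] | None = None,
    prob_threshold: float = 0.95,
) -> HaploNetwork:
    """Minimum-spanning network over haplotype states.

    Candidate edges (pairs at Hamming distance <= connection_limit) are added
    in increasing step order; an edge is skipped when its endpoints are
    already connected at a smaller or equal path cost, but all co-minimal
    edges of the same step count are retained. Root probability of a node is
    its frequency share within its connected component.
    """
    haps = states.haplotypes
    if len(haps) == 0:
        raise ValueError("no haplotypes")
    totals = states.counts.sum(axis=1)
    G = nx.Graph()
    for h, tot, row in zip(haps, totals, states.counts):
        G.add_node(
            h,
            frequency=int(tot),
            pop_counts={p: int(c) for p, c in zip(states.populations, row)},
        )
    candidates: dict[int, list[tuple[str, str]]] = {}
    for i in range(len(haps)):
        for j in range(i + 1, len(haps)):
            steps = sum(a != b for a, b in zip(haps[i], haps[j]))
            if steps <= connection_limit:
                candidates.setdefault(steps, []).append((haps[i], haps[j]))
    for steps in sorted(candidates):
        # connectivity as of the start of this step class
        comp_of: dict[str, int] = {}
        for ci, comp in enumerate(nx.connected_components(G)):
            for node in comp:
                comp_of[node] = ci
        for a, b in candidates[steps]:
            if comp_of[a] != comp_of[b]:
                G.add_edge(a, b, steps=steps, mutations=_mutation_labels(a, b))
    for comp in nx.connected_components(G):
        total = sum(G.nodes[h]["frequency"] for h in comp)
        for h in comp:
            G.nodes[h]["root_probability"] = G.nodes[h]["frequency"] / total
    net = HaploNetwork(
        graph=G,
        sites=sites or list(range(1, len(haps[0]) + 1)),
        codon_site_idx=codon_site_idx or [],
        connection_limit=connection_limit,
        prob_threshold=prob_threshold,
    )
    if codon_site_idx:
        for h in G.nodes:
            codon_state = "".join(h[i] for i in codon_site_idx)
            background = "".join(
                c for i, c in enumerate(h) if i not in codon_site_idx
            )
            G.nodes[h]["codon_state"] = codon_state
            G.nodes[h]["background"] = background
    return net


def network_states(
    aln: Alignment,
    pops: PopulationSet,
    layout: FragmentLayout,
    maf: float = 0.10,
) -> tuple[HaplotypeTable, list[int], list[int]]:
    """Collapse the alignment to informative-site states.

    Returns the state table, the selected site coordinates, and the indices
    (within the selected set) of the codon's 2nd/3rd-base positions used to
    read the codon class off a state string.
    """
    sel = informative_sites(aln, layout, maf)
    sub = extract_columns(aln, sel)
    table = collapse_haplotypes(sub, pops)
    codon_cols = set(layout.codon_columns())
    codon_idx = [i for i, c in enumerate(sel) if c in codon_cols]
    return table, sel, codon_idx


# ---------------------------------------------------------------------------
# Origin counting
# ---------------------------------------------------------------------------

@dataclass
class OriginEvent:
    allele: str  # resistant class created
    background: str  # intron background (non-codon selected-site state)
    parent: str
    child: str
    founder: bool = False  # component without wild-type: lower-bound event


@dataclass
class OriginReport:
    events: list[OriginEvent]
    n_events: int
    n_backgrounds: int
    n_resistant_haplotypes: int
    lower_bound: bool  # True when any founder event was counted


def _node_class(
    net: HaploNetwork, layout: FragmentLayout, wild_codon: str = "TTG"
) -> dict[str, str]:
    """Map each network node to its codon allele class, reconstructing the
    full codon from the wild-type template at unselected codon positions."""
    codon_cols = layout.codon_columns()
    sel_codon_pos = [net.sites[i] for i in net.codon_site_idx]
    out = {}
    for node in net.graph.nodes:
        codon = list(wild_codon)
        for idx, site in zip(net.codon_site_idx, sel_codon_pos):
            codon[codon_cols.index(site)] = node[idx]
        out[node] = classify_codon("".join(codon)).allele_class
    return out


def count_origin_events(
    net: HaploNetwork,
    layout: FragmentLayout,
    wild_codon: str = "TTG",
) -> OriginReport:
    """Count independent mutational origins of resistant codon classes.

    An origin event is an edge whose endpoints differ at a codon position
    such that the allele class changes from the ancestral side (the
    higher-root-probability endpoint) to a resistant class; changes between
    resistant classes count as new origins of the derived class. In a
    component with no wild-type member, the resistant node of highest root
    probability is counted as one founding event (lower-bound semantics).
    """
    if not net.codon_site_idx:
        raise ValueError("network nodes carry no codon state")
    classes = _node_class(net, layout, wild_codon)
    G = net.graph
    events: list[OriginEvent] = []
    lower_bound = False
    for a, b in G.edges:
        ca, cb = classes[a], classes[b]
        if ca == cb:
            continue
        resistant_a = ca in RESISTANT_CLASSES
        resistant_b = cb in RESISTANT_CLASSES
        if ca == "wild_L" and resistant_b:
            # resistance arises from the susceptible codon, whatever the
            # frequencies: a sweep leaves the derived allele more common
            # than its wild ancestor
            parent, child = a, b
        elif cb == "wild_L" and resistant_a:
            parent, child = b, a
        elif resistant_a and resistant_b:
            # between resistant classes: ancestral side is the higher
            # root-probability endpoint (frequency correlates with age)
            ra = G.nodes[a]["root_probability"]
            rb = G.nodes[b]["root_probability"]
            parent, child = (a, b) if (ra, a) >= (rb, b) else (b, a)
        else:
            continue
        events.append(
            OriginEvent(
                allele=classes[child],
                background=G.nodes[child].get("background", ""),
                parent=parent,
                child=child,
            )
        )
    for comp in net.components():
        if any(classes[h] == "wild_L" for h in comp):
            continue
        resistant = [h for h in comp if classes[h] in RESISTANT_CLASSES]
        if not resistant:
            continue
        founder = max(
            resistant, key=lambda h: (G.nodes[h]["root_probability"], h)
        )
        covered = {e.child for e in events}
        if founder not in covered:
            events.append(
                OriginEvent(
                    allele=classes[founder],
                    background=G.nodes[founder].get("background", ""),
                    parent="",
                    child=founder,
                    founder=True,
                )
            )
            lower_bound = True
    resistant_haps = {
        h for h in G.nodes if classes[h] in RESISTANT_CLASSES
    }
    backgrounds = {e.background for e in events}
    return OriginReport(
        events=events,
        n_events=len(events),
        n_backgrounds=len(backgrounds),
        n_resistant_haplotypes=len(resistant_haps),
        lower_bound=lower_bound,
    )


def network_edge_table(net: HaploNetwork) -> pd.DataFrame:
    """Edge list with states, frequencies and mutation labels."""
    rows = []
    for a, b, data in net.graph.edges(data=True):
        rows.append(
            {
                "state_a": a,
                "state_b": b,
                "freq_a": net.graph.nodes[a]["frequency"],
                "freq_b": net.graph.nodes[b]["frequency"],
                "steps": data["steps"],
                "mutations": ";".join(data["mutations"]),
            }
        )
    return pd.DataFrame(rows)


def accession_report(
    aln: Alignment, layout: FragmentLayout, maf: float = 0.10
) -> dict[str, int]:
    """Summary counts over a deposited-haplotype alignment: fragment length,
    segregating sites overall and in the introns, distinct intron
    haplotypes, informative-site haplotypes (with and without the codon),
    and network origin-event counts. Intended for checking a downloaded
    haplotype set against published figures."""
    from .diversity import diversity_stats
    from .seqdata import extract_region

    full = diversity_stats(aln)
    introns, _ = extract_region(aln, layout, {"intron"})
    intron_stats = diversity_stats(introns)
    intron_haps = collapse_haplotypes(introns)
    table, sites, codon_idx = network_states(
        aln, {s: "all" for s in aln.ids}, layout, maf
    )
    intron_only_sites = [s for i, s in enumerate(sites) if i not in codon_idx]
    sub = extract_columns(aln, intron_only_sites)
    intron_site_haps = collapse_haplotypes(sub)
    net = build_network(table, codon_site_idx=codon_idx, sites=sites)
    origins = count_origin_events(net, layout)
    return {
        "alignment_length": aln.length,
        "n_sequences": aln.n,
        "segregating_sites": full.S,
        "intron_segregating_sites": intron_stats.S,
        "intron_haplotypes": intron_haps.n_haplotypes,
        "informative_sites": len(sites),
        "informative_intron_sites": len(intron_only_sites),
        "state_haplotypes_with_codon": table.n_haplotypes,
        "state_haplotypes_intron_only": intron_site_haps.n_haplotypes,
        "origin_events": origins.n_events,
        "resistant_state_haplotypes": origins.n_resistant_haplotypes,
    }
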