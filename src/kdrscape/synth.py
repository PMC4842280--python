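"""Synthetic data generator: structured coalescent with infinite-sites mutation.

The generator emulates the data regimes the analyses assume: multi-deme
haploid samples under a migration-structured coalescent, per-deme sudden
demographic expansion (unimodal mismatch distributions with recoverable tau),
a focal resistance codon embedded in an exon between two introns, and a
phenomenological selective sweep that near-fixes resistant codon states on a
small number of intron backgrounds in designated demes.

Time is measured in coalescent units (one unit = the expected pairwise
coalescence time in a deme of relative size 1); mutations fall on branches as
a Poisson process of rate theta_locus/2 per unit length, so tau mutational
units correspond to tau/theta_locus coalescent units.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .seqdata import (
    Alignment,
    FragmentLayout,
    PopulationSet,
    kdr_fragment_layout,
)

WILD_CODON = "TTG"  # leucine at the focal position
RESISTANT_CODONS = {"F": "TTT", "C": "TGT", "S": "TCG", "W": "TGG"}


@dataclass
class Demography:
    """Per-deme size history: constant, or a sudden (stepwise) expansion of
    age *tau* (mutational units) from relative size *size × ratio* to *size*.

    ``size`` is the present-day relative deme size (sets within-deme
    diversity, K ≈ theta_locus × size at equilibrium); expansion regimes
    normally keep size=1 so pairwise differences pile up at ~tau.
    """

    model: str = "constant"  # "constant" | "sudden_expansion"
    tau: float = 0.0
    ratio: float = 1.0
    size: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in ("constant", "sudden_expansion"):
            raise ValueError(f"unknown demography model {self.model!r}")
        if self.tau < 0 or self.ratio < 0 or self.size <= 0:
            raise ValueError("invalid demography parameters")


@dataclass
class SweepConfig:
    """Phenomenological sweep: in *target_demes*, resistant codon states reach
    *final_frequency* on *background_count* intron backgrounds."""

    target_demes: list[str]
    allele: str = "F"
    final_frequency: float = 0.95
    background_count: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.final_frequency <= 1.0:
            raise ValueError("final_frequency must be in [0, 1]")
        if self.allele not in RESISTANT_CODONS:
            raise ValueError(f"unknown resistant allele class {self.allele!r}")
        if self.background_count < 1:
            raise ValueError("background_count must be >= 1")


@dataclass
class SimConfig:
    """Full description of one synthetic dataset."""

    n_demes: int = 15
    samples_per_deme: int | list[int] = 20
    migration_rate: float = 2.0  # per-lineage emigration rate, coalescent units
    theta_per_site: float = 0.005
    layout: FragmentLayout = field(default_factory=kdr_fragment_layout)
    demography: Demography | list[Demography] = field(default_factory=Demography)
    sweep: SweepConfig | None = None
    migration_model: str = "island"  # "island" | "stepping_stone" | "region"
    cross_region_scale: float = 1.0  # migration multiplier across regions
    deme_names: list[str] | None = None
    deme_regions: list[str] | None = None
    deme_coords: list[tuple[float, float]] | None = None
    seed: int = 0

    def sample_sizes(self) -> list[int]:
        if isinstance(self.samples_per_deme, int):
            return [self.samples_per_deme] * self.n_demes
        if len(self.samples_per_deme) != self.n_demes:
            raise ValueError("samples_per_deme length != n_demes")
        return list(self.samples_per_deme)

    def demographies(self) -> list[Demography]:
        if isinstance(self.demography, Demography):
            return [self.demography] * self.n_demes
        if len(self.demography) != self.n_demes:
            raise ValueError("demography list length != n_demes")
        return list(self.demography)

    def names(self) -> list[str]:
        if self.deme_names is not None:
            return list(self.deme_names)
        return [f"D{i + 1:02d}" for i in range(self.n_demes)]

    @property
    def eligible_columns(self) -> list[int]:
        return self.layout.columns({"intron"})

    @property
    def theta_locus(self) -> float:
        return self.theta_per_site * len(self.eligible_columns)


def neutral_layout(length: int) -> FragmentLayout:
    """A minimal layout for a neutral (mtDNA-like) locus: a 3-base exon stub
    holding the formal codon slot, then one intron carrying all variation."""
    if length < 4:
        raise ValueError("length must be at least 4")
    return FragmentLayout(
        segments=[("exon", 1, 3), ("intron", 4, length)], codon_span=(1, 3)
    )


# ---------------------------------------------------------------------------
# Genealogies
# ---------------------------------------------------------------------------

@dataclass
class Genealogy:
    """A coalescent tree over n tips.

    Nodes 0..n-1 are tips (in sample order), internal nodes are appended in
    coalescence order so every parent id exceeds its children's ids. ``blen``
    is the branch length from each node to its parent (0 at the root).
    """

    n: int
    parent: np.ndarray
    blen: np.ndarray
    tip_deme: np.ndarray

    def tip_masks(self) -> list[int]:
        """Per-node bitmask of the tips below it (tip i → bit i)."""
        masks = [0] * len(self.parent)
        for i in range(self.n):
            masks[i] = 1 << i
        for child in range(len(self.parent) - 1):
            p = self.parent[child]
            masks[p] |= masks[child]
        return masks

    def tip_counts(self) -> np.ndarray:
        return np.array([m.bit_count() for m in self.tip_masks()])

    def total_length(self) -> float:
        return float(self.blen.sum())


def _migration_weights(cfg: SimConfig) -> np.ndarray | None:
    """Row-stochastic target-deme weights for a migrating lineage."""
    D = cfg.n_demes
    if D == 1:
        return None
    W = np.ones((D, D))
    np.fill_diagonal(W, 0.0)
    if cfg.migration_model == "stepping_stone":
        W[:] = 0.0
        for i in range(D - 1):
            W[i, i + 1] = W[i + 1, i] = 1.0
    elif cfg.migration_model == "region":
        regions = cfg.deme_regions
        if regions is None or len(regions) != D:
            raise ValueError("region migration model needs deme_regions")
        for i in range(D):
            for j in range(D):
                if i != j and regions[i] != regions[j]:
                    W[i, j] = cfg.cross_region_scale
    elif cfg.migration_model != "island":
        raise ValueError(f"unknown migration model {cfg.migration_model!r}")
    rowsum = W.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    return W / rowsum


def simulate_genealogy(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> Genealogy:
    """Sample one genealogy of the full multi-deme sample under *cfg*.

    Event-driven structured coalescent: within-deme pair coalescence at rate
    1/size_d(t), per-lineage migration at rate ``migration_rate`` with targets
    drawn from the model's weight matrix; deme sizes are piecewise constant
    (sudden expansion: relative size ``ratio`` before time tau/theta_locus).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    sizes = cfg.sample_sizes()
    if min(sizes) < 1 or sum(sizes) < 1:
        raise ValueError("each deme needs at least one sample")
    n = sum(sizes)
    D = cfg.n_demes
    demos = cfg.demographies()
    theta = cfg.theta_locus
    # size breakpoints in coalescent units (backwards in time)
    breaks = np.full(D, np.inf)
    present = np.array([dem.size for dem in demos])
    ancient = present.copy()
    for d, dem in enumerate(demos):
        if dem.model == "sudden_expansion" and dem.tau > 0:
            if theta <= 0:
                raise ValueError("expansion demography requires theta > 0")
            breaks[d] = dem.tau / theta
            ancient[d] = max(dem.size * dem.ratio, 1e-6)
    W = _migration_weights(cfg)

    tip_deme = np.repeat(np.arange(D), sizes)
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=int)
    blen = np.zeros(n_nodes)
    node_time = np.zeros(n_nodes)
    lineage_deme = list(tip_deme)
    lineage_node = list(range(n))
    next_node = n
    t = 0.0
    future_breaks = sorted(b for b in set(breaks.tolist()) if np.isfinite(b))

    while len(lineage_node) > 1:
        k_d = np.bincount(lineage_deme, minlength=D)
        cur_size = np.where(t >= breaks, ancient, present)
        coal_d = k_d * (k_d - 1) / 2.0 / cur_size
        total_coal = coal_d.sum()
        mig = cfg.migration_rate * len(lineage_node) if D > 1 else 0.0
        R = total_coal + mig
        if R <= 0:
            raise RuntimeError(
                "no possible event: isolated lineages with zero migration"
            )
        dt = rng.exponential(1.0 / R)
        nb = next((b for b in future_breaks if b > t), None)
        if nb is not None and t + dt > nb:
            t = nb
            continue
        t += dt
        if rng.uniform(0.0, R) < total_coal:
            d = rng.choice(D, p=coal_d / total_coal)
            members = [i for i, dd in enumerate(lineage_deme) if dd == d]
            i, j = rng.choice(len(members), size=2, replace=False)
            a, b = members[i], members[j]
            na, nb_ = lineage_node[a], lineage_node[b]
            parent[na] = parent[nb_] = next_node
            blen[na] = t - node_time[na]
            blen[nb_] = t - node_time[nb_]
            node_time[next_node] = t
            for idx in sorted((a, b), reverse=True):
                del lineage_node[idx], lineage_deme[idx]
            lineage_node.append(next_node)
            lineage_deme.append(d)
            next_node += 1
        else:
            i = rng.integers(len(lineage_node))
            src = lineage_deme[i]
            lineage_deme[i] = int(rng.choice(D, p=W[src]))
    return Genealogy(n, parent, blen, tip_deme)


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------

def mutations_poisson(
    gen: Genealogy, theta_locus: float, rng: np.random.Generator
) -> np.ndarray:
    """Branch id of each mutation under Poisson(theta/2 × branch length)."""
    if theta_locus < 0:
        raise ValueError("theta must be non-negative")
    counts = rng.poisson(theta_locus / 2.0 * gen.blen)
    return np.repeat(np.arange(len(gen.blen)), counts)


def mutations_fixed_s(
    gen: Genealogy, S: int, rng: np.random.Generator
) -> np.ndarray:
    """Place exactly S mutations, branch chosen proportionally to length."""
    total = gen.blen.sum()
    p = gen.blen / total
    counts = rng.multinomial(S, p)
    return np.repeat(np.arange(len(gen.blen)), counts)


def genotype_matrix(gen: Genealogy, branch_ids: np.ndarray) -> np.ndarray:
    """(n, n_mutations) 0/1 derived-state matrix (one column per mutation)."""
    masks = gen.tip_masks()
    M = len(branch_ids)
    out = np.zeros((gen.n, M), dtype=np.uint8)
    for k, b in enumerate(branch_ids):
        m = masks[b]
        for i in range(gen.n):
            if m >> i & 1:
                out[i, k] = 1
    return out


def pairwise_differences(gen: Genealogy, branch_ids: np.ndarray) -> np.ndarray:
    """(n, n) pairwise difference counts implied by the placed mutations."""
    g = genotype_matrix(gen, branch_ids).astype(np.int32)
    # Hamming distance over mutation columns
    same = g @ g.T
    ones = g.sum(axis=1)
    return ones[:, None] + ones[None, :] - 2 * same


_OTHER = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


def drop_mutations(
    gen: Genealogy, cfg: SimConfig, rng: np.random.Generator
) -> tuple[Alignment, bool]:
    """Materialise sequences: infinite-sites mutations on the eligible
    (intron) columns of the layout.

    Returns the alignment and a flag that is True when more mutations arose
    than eligible columns, forcing positions to be reused (finite-sites
    fallback).
    """
    branch_ids = mutations_poisson(gen, cfg.theta_locus, rng)
    eligible = np.array(cfg.eligible_columns, dtype=int)
    M = len(branch_ids)
    recycled = M > len(eligible)
    if recycled:
        pos = np.concatenate(
            [
                rng.permutation(eligible),
                rng.choice(eligible, size=M - len(eligible), replace=True),
            ]
        )
    else:
        pos = rng.choice(eligible, size=M, replace=False)
    L = cfg.layout.length
    ref = rng.choice(list("ACGT"), size=L)
    c0, _ = cfg.layout.codon_span
    ref[c0 - 1 : c0 + 2] = list(WILD_CODON)
    geno = genotype_matrix(gen, branch_ids)
    rows = np.tile(ref, (gen.n, 1))
    for k in range(M):
        col = pos[k] - 1
        derived = rng.choice(list(_OTHER[str(ref[col])]))
        rows[geno[:, k] == 1, col] = derived
    seqs = ["".join(r) for r in rows]
    ids = [f"s{i + 1:03d}" for i in range(gen.n)]
    return Alignment(ids, seqs), recycled


# ---------------------------------------------------------------------------
# Sweep implantation
# ---------------------------------------------------------------------------

def implant_sweep(
    aln: Alignment,
    deme_of: dict[str, str],
    layout: FragmentLayout,
    sweep: SweepConfig,
    rng: np.random.Generator,
) -> Alignment:
    """Write resistant codon states onto a few intron backgrounds in the
    target demes and resample chromosomes so the resistant classes reach the
    configured final frequency (hitchhiking signature: reduced intron
    diversity in swept demes)."""
    codon_cols = [c - 1 for c in layout.codon_columns()]
    res_codon = RESISTANT_CODONS[sweep.allele]
    seqs = list(aln.seqs)
    index_of = {s: k for k, s in enumerate(aln.ids)}
    for deme in sweep.target_demes:
        rows = [index_of[s] for s in aln.ids if deme_of.get(s) == deme]
        if not rows:
            raise ValueError(f"sweep target deme {deme!r} has no samples")
        n_res = int(round(sweep.final_frequency * len(rows)))
        if n_res == 0:
            continue
        # choose donor backgrounds: most frequent haplotypes in the deme
        hap_count: dict[str, int] = {}
        for r in rows:
            hap_count[seqs[r]] = hap_count.get(seqs[r], 0) + 1
        donors = sorted(hap_count, key=lambda h: (-hap_count[h], h))
        donors = donors[: sweep.background_count]
        carriers: list[str] = []
        for d_idx, donor in enumerate(donors):
            chars = list(donor)
            for c, b in zip(codon_cols, res_codon):
                chars[c] = b
            carriers.append("".join(chars))
        chosen = rng.choice(len(rows), size=n_res, replace=False)
        for j, ri in enumerate(chosen):
            seqs[rows[ri]] = carriers[j % len(carriers)]
    return Alignment(list(aln.ids), seqs)


# ---------------------------------------------------------------------------
# Full datasets
# ---------------------------------------------------------------------------

def _default_coords(cfg: SimConfig, rng: np.random.Generator):
    """Deme coordinates: supplied, or a jittered grid (lat, lon)."""
    if cfg.deme_coords is not None:
        return [tuple(c) for c in cfg.deme_coords]
    side = int(np.ceil(np.sqrt(cfg.n_demes)))
    coords = []
    for i in range(cfg.n_demes):
        lat = 20.0 + 3.0 * (i // side) + rng.uniform(-0.5, 0.5)
        lon = 100.0 + 3.0 * (i % side) + rng.uniform(-0.5, 0.5)
        coords.append((lat, lon))
    return coords


def simulate_dataset(
    cfg: SimConfig,
) -> tuple[Alignment, PopulationSet, FragmentLayout]:
    """Simulate a complete pipeline input bundle, deterministic under seed."""
    rng = np.random.default_rng(cfg.seed)
    gen = simulate_genealogy(cfg, rng)
    aln, _ = drop_mutations(gen, cfg, rng)
    names = cfg.names()
    sizes = cfg.sample_sizes()
    deme_of: dict[str, str] = {}
    k = 0
    new_ids = []
    for d, nd in enumerate(sizes):
        for j in range(nd):
            sid = f"{names[d]}_{j + 1:03d}"
            new_ids.append(sid)
            deme_of[sid] = names[d]
            k += 1
    aln = Alignment(new_ids, aln.seqs)
    if cfg.sweep is not None:
        aln = implant_sweep(aln, deme_of, cfg.layout, cfg.sweep, rng)
    coords = _default_coords(cfg, rng)
    regions = cfg.deme_regions or ["all"] * cfg.n_demes
    pops = PopulationSet(
        sample_to_pop=deme_of,
        pop_coords={names[d]: coords[d] for d in range(cfg.n_demes)},
        pop_region={names[d]: regions[d] for d in range(cfg.n_demes)},
    )
    return aln, pops, cfg.layout


def paper_mimic_config(
    seed: int = 0,
    samples_per_deme: int = 20,
    seq_length: int | None = None,
) -> SimConfig:
    """The study-conditions configuration: 15 demes in 3 regions; the two
    southwest demes are demographically constant and nearly isolated, the
    south and central demes expanded (tau = 6), and the five central demes
    carry a near-fixed L1014F sweep on one intron background."""
    regions = ["southwest"] * 3 + ["south"] * 7 + ["central"] * 5
    names = (
        [f"SW{i}" for i in range(1, 4)]
        + [f"SO{i}" for i in range(1, 8)]
        + [f"CE{i}" for i in range(1, 6)]
    )
    # post-expansion theta_locus ≈ 19 well above tau=6, and within-region
    # migration fast relative to the expansion age: star-like genealogies
    # whose mismatch mode sits near tau, with demes inside a region nearly
    # homogeneous (low F_SC) while regions stay strongly isolated; the two
    # constant southwest demes are small so their equilibrium diversity
    # stays moderate
    expansion = Demography("sudden_expansion", tau=6.0, ratio=0.01)
    constant = Demography("constant", size=0.05)
    sw3 = Demography("sudden_expansion", tau=6.0, ratio=0.01, size=0.15)
    demos = [constant, constant, sw3] + [expansion] * 12
    coords = [
        (24.8, 98.3), (23.1, 101.0), (29.7, 105.0),      # southwest
        (23.4, 105.8), (25.4, 106.8), (25.7, 108.9), (25.8, 109.6),
        (18.6, 109.8), (23.7, 113.1), (24.4, 118.4),      # south
        (29.8, 115.6), (32.1, 114.0), (33.9, 118.0), (33.2, 117.9),
        (34.8, 116.1),                                     # central
    ]
    layout = kdr_fragment_layout() if seq_length is None else neutral_layout(seq_length)
    return SimConfig(
        n_demes=15,
        samples_per_deme=samples_per_deme,
        migration_rate=100.0,
        theta_per_site=0.02,
        layout=layout,
        demography=demos,
        sweep=SweepConfig(
            target_demes=[n for n, r in zip(names, regions) if r == "central"],
            allele="F",
            final_frequency=0.95,
            background_count=1,
        ),
        migration_model="region",
        cross_region_scale=0.001,
        deme_names=names,
        deme_regions=regions,
        deme_coords=coords,
        seed=seed,
    )


def config_to_json(cfg: SimConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["layout"] = {
        "segments": [
            {"label": lab, "start": s, "end": e} for lab, s, e in cfg.layout.segments
        ],
        "codon": list(cfg.layout.codon_span),
    }
    return d
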