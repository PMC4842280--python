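"""Population differentiation: hierarchical AMOVA, pairwise F_ST / Phi_ST
with permutation tests, Nei's unbiased genetic distance, and UPGMA trees.

AMOVA follows the Excoffier sums-of-squares formulation on a matrix of
squared inter-individual distances: haplotype identity (0/1) for the
frequency-based F-statistics, pairwise nucleotide difference counts for the
Phi-statistics. The analysis is haploid throughout (sequences, not
genotypes), so there is no within-individual level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import pairwise_diff_matrix
from .seqdata import Alignment, HaplotypeTable, PopulationSet, collapse_haplotypes


@dataclass
class AmovaResult:
    variance_components: tuple[float, float, float]  # (AG, AP/WG, WP)
    percentages: tuple[float, float, float]
    phi: dict[str, float]  # F_CT, F_SC, F_ST
    pvals: dict[str, float] = field(default_factory=dict)
    df: tuple[int, int, int] = (0, 0, 0)
    two_level: bool = True  # False: single-level AMOVA, F_CT undefined


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if np.isnan(self.d).any():
            raise ValueError("NaN in distance matrix")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.d[iu]


# ---------------------------------------------------------------------------
# Distance matrices between sequences
# ---------------------------------------------------------------------------

def sequence_distances(aln: Alignment, mode: str) -> np.ndarray:
    """Squared inter-individual distances: 0/1 haplotype identity
    (mode='fst_freq') or nucleotide difference counts (mode='phist')."""
    if mode == "fst_freq":
        arr = aln.seqs
        n = len(arr)
        d = np.fromiter(
            (0.0 if arr[i] == arr[j] else 1.0 for i in range(n) for j in range(n)),
            dtype=float,
            count=n * n,
        ).reshape(n, n)
        return d
    if mode == "phist":
        return pairwise_diff_matrix(aln).astype(float)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# AMOVA core
# ---------------------------------------------------------------------------

def _ss_within(d2: np.ndarray, idx: np.ndarray) -> float:
    """Sum of squares within one set: (1/n) * sum over unordered pairs."""
    sub = d2[np.ix_(idx, idx)]
    return float(sub.sum() / (2.0 * len(idx)))


def _amova_components(
    d2: np.ndarray, pop_of: np.ndarray, group_of_pop: np.ndarray | None
) -> tuple[tuple[float, float, float], tuple[int, int, int]]:
    """Variance components (sigma_a AG, sigma_b AP/WG, sigma_c WP) and df.

    With group_of_pop None, a one-level AMOVA is computed and sigma_a = 0
    with df_a = 0.
    """
    N = len(pop_of)
    pops = np.unique(pop_of)
    P = len(pops)
    all_idx = np.arange(N)
    ss_total = _ss_within(d2, all_idx)
    pop_idx = {p: np.where(pop_of == p)[0] for p in pops}
    n_p = {p: len(pop_idx[p]) for p in pops}
    ss_wp = sum(_ss_within(d2, pop_idx[p]) for p in pops)

    if group_of_pop is None:
        df_b, df_c = P - 1, N - P
        ms_b = (ss_total - ss_wp) / df_b
        ms_c = ss_wp / df_c if df_c > 0 else 0.0
        n0 = (N - sum(v**2 for v in n_p.values()) / N) / (P - 1)
        sigma_c = ms_c
        sigma_b = (ms_b - sigma_c) / n0
        return (0.0, sigma_b, sigma_c), (0, df_b, df_c)

    groups = np.unique(group_of_pop)
    G = len(groups)
    if G < 2:
        raise ValueError("two-level AMOVA needs at least two groups")
    grp_idx = {
        g: np.concatenate([pop_idx[p] for p in pops[group_of_pop == g]])
        for g in groups
    }
    n_g = {g: len(grp_idx[g]) for g in groups}
    ss_wg = sum(_ss_within(d2, grp_idx[g]) for g in groups)
    ss_ag = ss_total - ss_wg
    ss_ap = ss_wg - ss_wp
    df_a, df_b, df_c = G - 1, P - G, N - P
    ms_a = ss_ag / df_a
    ms_b = ss_ap / df_b if df_b > 0 else 0.0
    ms_c = ss_wp / df_c if df_c > 0 else 0.0
    # unequal-size coefficients
    sum_npg = {
        g: sum(n_p[p] ** 2 for p in pops[group_of_pop == g]) / n_g[g] for g in groups
    }
    n1 = (N - sum(sum_npg.values())) / df_b if df_b > 0 else 0.0
    n2 = (sum(sum_npg.values()) - sum(v**2 for v in n_p.values()) / N) / df_a
    n3 = (N - sum(v**2 for v in n_g.values()) / N) / df_a
    sigma_c = ms_c
    sigma_b = (ms_b - sigma_c) / n1 if n1 > 0 else 0.0
    sigma_a = (ms_a - sigma_c - n2 * sigma_b) / n3
    return (sigma_a, sigma_b, sigma_c), (df_a, df_b, df_c)


def _phi_from_components(sig: tuple[float, float, float], two_level: bool):
    sa, sb, sc = sig
    tot = sa + sb + sc
    phi: dict[str, float] = {}
    if two_level:
        phi["F_CT"] = sa / tot if tot != 0 else float("nan")
        phi["F_SC"] = sb / (sb + sc) if (sb + sc) != 0 else float("nan")
        phi["F_ST"] = (sa + sb) / tot if tot != 0 else float("nan")
    else:
        phi["F_ST"] = sb / tot if tot != 0 else float("nan")
    return phi


def _expand_grouping(
    table_pops: list[str], grouping: dict[str, str] | None
) -> np.ndarray | None:
    if grouping is None:
        return None
    missing = [p for p in table_pops if p not in grouping]
    if missing:
        raise KeyError(f"populations without group: {missing}")
    groups = sorted(set(grouping[p] for p in table_pops))
    gid = {g: i for i, g in enumerate(groups)}
    return np.array([gid[grouping[p]] for p in table_pops])


def amova(
    aln: Alignment,
    pops: PopulationSet,
    grouping: dict[str, str] | None = None,
    mode: str = "phist",
    perms: int = 1000,
    seed: int = 0,
) -> AmovaResult:
    """Hierarchical (or one-level) AMOVA with permutation p-values.

    Permutation schemes: individuals among all populations for F_ST,
    individuals among populations within their group for F_SC, whole
    populations among groups for F_CT.
    """
    order = [s for s in aln.ids if s in pops.sample_to_pop]
    if len(order) != aln.n:
        missing = [s for s in aln.ids if s not in pops.sample_to_pop]
        raise KeyError(f"samples without population: {missing}")
    d2 = sequence_distances(aln, mode)
    pop_names = pops.populations
    pop_id = {p: i for i, p in enumerate(pop_names)}
    pop_of = np.array([pop_id[pops.sample_to_pop[s]] for s in aln.ids])
    # populations in integer-code order
    pops_sorted = [p for p, _ in sorted(pop_id.items(), key=lambda kv: kv[1])]
    group_codes = None
    two_level = grouping is not None
    if two_level:
        group_codes = _expand_grouping(pops_sorted, grouping)
        if len(np.unique(group_codes)) < 2:
            two_level = False
            group_codes = None
    sig, df = _amova_components(d2, pop_of, group_codes)
    phi = _phi_from_components(sig, two_level)
    tot = sum(sig)
    if two_level:
        pct = tuple(100.0 * s / tot for s in sig) if tot != 0 else (0.0, 0.0, 0.0)
        comps = sig
    else:
        comps = (0.0, sig[1], sig[2])
        pct = (
            (0.0, 100.0 * sig[1] / tot, 100.0 * sig[2] / tot)
            if tot != 0
            else (0.0, 0.0, 0.0)
        )

    rng = np.random.default_rng(seed)
    pvals: dict[str, float] = {}
    if perms > 0:
        # F_ST: permute individuals among all populations
        b = 0
        for _ in range(perms):
            perm = rng.permutation(pop_of)
            s_p, _ = _amova_components(d2, perm, group_codes)
            ph = _phi_from_components(s_p, two_level)
            if ph["F_ST"] >= phi["F_ST"] - 1e-12:
                b += 1
        pvals["F_ST"] = (b + 1) / (perms + 1)
        if two_level:
            # F_SC: permute individuals among populations within groups
            grp_of_ind = group_codes[pop_of]
            b = 0
            for _ in range(perms):
                perm = pop_of.copy()
                for g in np.unique(group_codes):
                    sel = np.where(grp_of_ind == g)[0]
                    perm[sel] = perm[sel][rng.permutation(len(sel))]
                s_p, _ = _amova_components(d2, perm, group_codes)
                ph = _phi_from_components(s_p, True)
                if ph["F_SC"] >= phi["F_SC"] - 1e-12:
                    b += 1
            pvals["F_SC"] = (b + 1) / (perms + 1)
            # F_CT: permute whole populations among groups
            b = 0
            for _ in range(perms):
                perm_groups = group_codes[rng.permutation(len(group_codes))]
                s_p, _ = _amova_components(d2, pop_of, perm_groups)
                ph = _phi_from_components(s_p, True)
                if ph["F_CT"] >= phi["F_CT"] - 1e-12:
                    b += 1
            pvals["F_CT"] = (b + 1) / (perms + 1)
    return AmovaResult(comps, pct, phi, pvals, df, two_level)


# ---------------------------------------------------------------------------
# Pairwise differentiation
# ---------------------------------------------------------------------------

def _fst_two_pops(d2: np.ndarray, pop_of: np.ndarray) -> float:
    sig, _ = _amova_components(d2, pop_of, None)
    phi = _phi_from_components(sig, False)
    return phi["F_ST"]


def pairwise_differentiation(
    aln: Alignment,
    pops: PopulationSet,
    mode: str = "fst_freq",
    perms: int = 1000,
    seed: int = 0,
    clamp_negative: bool = False,
) -> tuple[DistanceMatrix, np.ndarray]:
    """Pairwise F_ST (haplotype identity) or Phi_ST (nucleotide distances)
    between all population pairs, with permutation p-values.

    Populations with fewer than 2 samples are excluded. Negative estimates
    are reported as computed unless clamp_negative is set.
    """
    rng = np.random.default_rng(seed)
    usable = [p for p in pops.populations if len(pops.samples_of(p)) >= 2]
    samples = [s for s in aln.ids if pops.sample_to_pop.get(s) in usable]
    sub = aln.subset(samples)
    d2_all = sequence_distances(sub, mode)
    pop_arr = np.array([usable.index(pops.sample_to_pop[s]) for s in sub.ids])
    P = len(usable)
    fst = np.zeros((P, P))
    pmat = np.ones((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            sel = np.where((pop_arr == i) | (pop_arr == j))[0]
            d2 = d2_all[np.ix_(sel, sel)]
            labels = (pop_arr[sel] == j).astype(int)
            obs = _fst_two_pops(d2, labels)
            b = 0
            for _ in range(perms):
                perm = labels[rng.permutation(len(labels))]
                if _fst_two_pops(d2, perm) >= obs - 1e-12:
                    b += 1
            p = (b + 1) / (perms + 1)
            val = max(obs, 0.0) if clamp_negative else obs
            fst[i, j] = fst[j, i] = val
            pmat[i, j] = pmat[j, i] = p
    return DistanceMatrix(usable, fst), pmat


# ---------------------------------------------------------------------------
# Nei's unbiased genetic distance and UPGMA
# ---------------------------------------------------------------------------

def nei_distance(
    table: HaplotypeTable, cap: float = 10.0
) -> DistanceMatrix:
    """Nei (1978) unbiased standard genetic distance between populations,
    treating the locus's haplotypes as alleles. Pairs with zero shared
    identity get the (logged) cap instead of +inf."""
    sizes = table.pop_sizes()
    if (sizes < 2).any():
        small = [p for p, s in zip(table.populations, sizes) if s < 2]
        raise ValueError(f"populations with n < 2: {small}")
    freqs = table.frequencies()
    P = len(table.populations)
    d = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            x, y = freqs[:, i], freqs[:, j]
            ni, nj = sizes[i], sizes[j]
            jx = (ni * (x**2).sum() - 1.0) / (ni - 1.0)
            jy = (nj * (y**2).sum() - 1.0) / (nj - 1.0)
            jxy = float((x * y).sum())
            if jxy <= 0 or jx <= 0 or jy <= 0:
                val = cap
            else:
                val = -math.log(jxy / math.sqrt(jx * jy))
                val = min(val, cap)
            d[i, j] = d[j, i] = max(val, 0.0)
    return DistanceMatrix(list(table.populations), d)


def upgma(dm: DistanceMatrix) -> str:
    """Average-linkage agglomeration; deterministic tie-break on the
    lexicographically smallest (sorted) label pair. Returns Newick with
    branch lengths (ultrametric heights = half the join distance)."""
    labels = list(dm.labels)
    if len(labels) < 2:
        raise ValueError("UPGMA needs at least 2 labels")
    d = dm.d.astype(float).copy()
    clusters = {i: ([i], labels[i], labels[i], 0.0, 1) for i in range(len(labels))}
    # value: (member idx, newick, min label, height, size)
    active = list(clusters)
    dist = {
        frozenset((i, j)): d[i, j]
        for i in active
        for j in active
        if i < j
    }
    nxt = len(labels)
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                dd = dist[frozenset((i, j))]
                li, lj = clusters[i][2], clusters[j][2]
                key = (dd, min(li, lj), max(li, lj))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dd = dist[frozenset((i, j))]
        height = dd / 2.0
        mi, ni_, li, hi, si = clusters[i]
        mj, nj_, lj, hj, sj = clusters[j]
        # deterministic child order: smaller min-label first
        if lj < li:
            (mi, ni_, li, hi, si), (mj, nj_, lj, hj, sj) = (
                (mj, nj_, lj, hj, sj),
                (mi, ni_, li, hi, si),
            )
        newick = f"({ni_}:{height - hi:.10g},{nj_}:{height - hj:.10g})"
        clusters[nxt] = (mi + mj, newick, min(li, lj), height, si + sj)
        for k in active:
            if k in (i, j):
                continue
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((nxt, k))] = (si * dik + sj * djk) / (si + sj)
        dist.pop(frozenset((i, j)))
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1
    return clusters[active[0]][1] + ";"


def significant_pair_count(
    pmat: np.ndarray, alpha: float = 0.05, correction: str = "fdr"
) -> int:
    """Count significant population pairs after multiple-testing correction
    (FDR by default; Bonferroni selectable)."""
    iu = np.triu_indices(pmat.shape[0], k=1)
    p = pmat[iu]
    if len(p) == 0:
        return 0
    if correction == "fdr":
        from .neutrality import fdr_adjust

        q = np.asarray(fdr_adjust(list(p)))
        return int((q < alpha).sum())
    if correction == "bonferroni":
        return int((p * len(p) < alpha).sum())
    if correction == "none":
        return int((p < alpha).sum())
    raise ValueError(f"unknown correction {correction!r}")
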