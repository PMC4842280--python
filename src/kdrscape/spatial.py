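"""Spatial analyses: great-circle distances, Mantel isolation-by-distance,
SAMOVA group search by simulated annealing, and genetic-landscape-shape
inverse-distance-weighted interpolation over a Delaunay network.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .seqdata import Alignment, PopulationSet
from .structure import (
    DistanceMatrix,
    _phi_from_components,
    pairwise_differentiation,
    sequence_distances,
)

EARTH_RADIUS_KM = 6371.0


def great_circle(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine distance in kilometres between (lat, lon) points."""
    for lat, lon in (a, b):
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            raise ValueError(f"coordinate out of range: {(lat, lon)}")
    la1, lo1, la2, lo2 = map(math.radians, (*a, *b))
    h = (
        math.sin((la2 - la1) / 2) ** 2
        + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def geographic_distances(pops: PopulationSet) -> DistanceMatrix:
    pops.require_coords()
    labels = pops.populations
    P = len(labels)
    d = np.zeros((P, P))
    for i in range(P):
        for j in range(i + 1, P):
            d[i, j] = d[j, i] = great_circle(
                pops.pop_coords[labels[i]], pops.pop_coords[labels[j]]
            )
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    R2: float
    p: float
    n_pairs: int
    defined: bool = True


def mantel(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    perms: int = 10000,
    seed: int = 0,
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    Pearson r over the upper-triangle pairs; one-tailed p from joint
    row/column permutations of the second matrix.
    """
    if dx.labels != dy.labels:
        raise ValueError("matrices must carry identical labels")
    if perms < 100:
        raise ValueError("perms must be >= 100")
    n = len(dx.labels)
    iu = np.triu_indices(n, k=1)
    x = dx.d[iu]
    y = dy.d[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        return MantelResult(float("nan"), float("nan"), float("nan"), len(x), False)
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    b = 0
    xc = (x - x.mean()) / x.std()
    for _ in range(perms):
        perm = rng.permutation(n)
        yp = dy.d[np.ix_(perm, perm)][iu]
        r_p = float(np.mean(xc * (yp - yp.mean()) / yp.std()))
        if r_p >= r_obs - 1e-12:
            b += 1
    p = (b + 1) / (perms + 1)
    return MantelResult(r_obs, r_obs**2, p, len(x))


def linearize_fst(fst: np.ndarray, clip: float = 0.999) -> np.ndarray:
    """F_ST / (1 - F_ST); values at/above 1 are clipped to a large finite
    linearized distance (clip controls the ceiling)."""
    f = np.minimum(fst, clip)
    return f / (1.0 - f)


def ibd_inputs(
    aln: Alignment,
    pops: PopulationSet,
    mode: str = "phist",
    seed: int = 0,
) -> tuple[DistanceMatrix, DistanceMatrix]:
    """(geographic, linearized-F_ST) matrices for isolation-by-distance."""
    pops.require_coords()
    fst_dm, _ = pairwise_differentiation(aln, pops, mode=mode, perms=0, seed=seed)
    gen = DistanceMatrix(fst_dm.labels, linearize_fst(fst_dm.d))
    geo_all = geographic_distances(pops)
    keep = [geo_all.labels.index(p) for p in fst_dm.labels]
    geo = DistanceMatrix(fst_dm.labels, geo_all.d[np.ix_(keep, keep)])
    return geo, gen


# ---------------------------------------------------------------------------
# SAMOVA
# ---------------------------------------------------------------------------

class _PopAggregates:
    """Population-level aggregates of squared inter-individual distances,
    letting the AMOVA sums of squares be recomputed in O(P^2) per grouping."""

    def __init__(self, aln: Alignment, pops: PopulationSet, mode: str):
        self.labels = [p for p in pops.populations]
        pid = {p: i for i, p in enumerate(self.labels)}
        d2 = sequence_distances(aln, mode)
        pop_of = np.array([pid[pops.sample_to_pop[s]] for s in aln.ids])
        P = len(self.labels)
        self.n_p = np.bincount(pop_of, minlength=P).astype(float)
        onehot = np.eye(P)[pop_of]
        self.W = onehot.T @ d2 @ onehot  # full double-sum per pop pair
        self.N = float(len(aln.ids))
        self.ss_total = self.W.sum() / (2.0 * self.N)
        self.ss_wp = float(
            sum(self.W[p, p] / (2.0 * self.n_p[p]) for p in range(P))
        )

    def components(self, group_of_pop: np.ndarray):
        """(sigma_a, sigma_b, sigma_c), df for a pop→group assignment."""
        P = len(self.labels)
        groups = np.unique(group_of_pop)
        G = len(groups)
        N = self.N
        ss_wg = 0.0
        n_g = np.zeros(G)
        sum_npg = 0.0
        for gi, g in enumerate(groups):
            sel = group_of_pop == g
            n_g[gi] = self.n_p[sel].sum()
            ss_wg += self.W[np.ix_(sel, sel)].sum() / (2.0 * n_g[gi])
            sum_npg += (self.n_p[sel] ** 2).sum() / n_g[gi]
        ss_ag = self.ss_total - ss_wg
        ss_ap = ss_wg - self.ss_wp
        df_a, df_b, df_c = G - 1, P - G, int(N) - P
        ms_a = ss_ag / df_a if df_a > 0 else 0.0
        ms_b = ss_ap / df_b if df_b > 0 else 0.0
        ms_c = self.ss_wp / df_c if df_c > 0 else 0.0
        n1 = (N - sum_npg) / df_b if df_b > 0 else 0.0
        n2 = (sum_npg - (self.n_p**2).sum() / N) / df_a if df_a > 0 else 0.0
        n3 = (N - (n_g**2).sum() / N) / df_a if df_a > 0 else 0.0
        sigma_c = ms_c
        sigma_b = (ms_b - sigma_c) / n1 if n1 > 0 else 0.0
        sigma_a = (ms_a - sigma_c - n2 * sigma_b) / n3 if n3 > 0 else 0.0
        return (sigma_a, sigma_b, sigma_c), (df_a, df_b, df_c)

    def fct(self, group_of_pop: np.ndarray) -> float:
        sig, _ = self.components(group_of_pop)
        tot = sum(sig)
        return sig[0] / tot if tot != 0 else float("-inf")


@dataclass
class SamovaResult:
    K: int
    best_grouping: dict[str, int]
    fct: float
    fsc: float
    fst: float
    run_best: list[float] = field(default_factory=list)
    rng_seed: int = 0
    degenerate: bool = False  # K == #pops: F_SC undefined


def _random_grouping(P: int, K: int, rng: np.random.Generator) -> np.ndarray:
    g = np.concatenate([np.arange(K), rng.integers(0, K, P - K)])
    return g[rng.permutation(P)]


def samova(
    aln: Alignment,
    pops: PopulationSet,
    K_range=range(2, 11),
    runs: int = 100,
    iters: int = 10000,
    seed: int = 0,
    mode: str = "phist",
    t0: float = 0.05,
    cooling: float = 0.999,
) -> list[SamovaResult]:
    """Search, for each K, the population grouping maximising F_CT.

    `runs` independent simulated-annealing chains per K, each `iters`
    proposals (move one population to another group, rejecting moves that
    empty a group), Metropolis acceptance with geometric cooling; the
    best-of-runs grouping is retained together with its F_SC / F_ST.
    """
    agg = _PopAggregates(aln, pops, mode)
    P = len(agg.labels)
    results: list[SamovaResult] = []
    for K in K_range:
        if K > P:
            raise ValueError(f"K={K} exceeds number of populations ({P})")
        rng = np.random.default_rng((seed, K))
        best_g, best_f = None, -np.inf
        run_best: list[float] = []
        for _ in range(runs):
            g = _random_grouping(P, K, rng)
            f = agg.fct(g)
            gb, fb = g.copy(), f
            T = t0
            for _ in range(iters):
                p = rng.integers(P)
                sizes = np.bincount(g, minlength=K)
                if sizes[g[p]] <= 1:
                    T *= cooling
                    continue
                new = rng.integers(K - 1)
                if new >= g[p]:
                    new += 1
                old = g[p]
                g[p] = new
                f_new = agg.fct(g)
                if f_new >= f or rng.random() < math.exp((f_new - f) / max(T, 1e-12)):
                    f = f_new
                    if f > fb:
                        fb, gb = f, g.copy()
                else:
                    g[p] = old
                T *= cooling
            run_best.append(fb)
            if fb > best_f:
                best_f, best_g = fb, gb
        sig, df = agg.components(best_g)
        phi = _phi_from_components(sig, True)
        degenerate = K == P
        results.append(
            SamovaResult(
                K=K,
                best_grouping={agg.labels[i]: int(best_g[i]) for i in range(P)},
                fct=phi["F_CT"],
                fsc=phi["F_SC"] if not degenerate else float("nan"),
                fst=phi["F_ST"],
                run_best=run_best,
                rng_seed=seed,
                degenerate=degenerate,
            )
        )
    return results


def samova_exhaustive(
    aln: Alignment, pops: PopulationSet, K: int, mode: str = "phist"
) -> tuple[dict[str, int], float]:
    """Exact best-F_CT grouping by enumerating all partitions into K
    non-empty groups (oracle for small numbers of populations)."""
    agg = _PopAggregates(aln, pops, mode)
    P = len(agg.labels)
    best, best_f = None, -np.inf
    for assign in itertools.product(range(K), repeat=P):
        arr = np.asarray(assign)
        if len(np.unique(arr)) != K:
            continue
        if arr[0] != 0:  # canonical labelling to skip relabelled duplicates
            continue
        f = agg.fct(arr)
        if f > best_f:
            best_f, best = f, arr
    return {agg.labels[i]: int(best[i]) for i in range(P)}, float(best_f)


# ---------------------------------------------------------------------------
# Genetic landscape shape (IDW surface)
# ---------------------------------------------------------------------------

@dataclass
class LandscapeSurface:
    grid: np.ndarray  # (ny, nx) surface heights
    x_coords: np.ndarray
    y_coords: np.ndarray
    alpha: float
    edges: list[tuple[str, str]]
    used_delaunay: bool = True


def _project(pops: PopulationSet, labels: list[str]) -> np.ndarray:
    """Equirectangular planar projection (km) about the mean latitude."""
    lats = np.array([pops.pop_coords[p][0] for p in labels])
    lons = np.array([pops.pop_coords[p][1] for p in labels])
    lat0 = math.radians(lats.mean())
    x = np.radians(lons) * EARTH_RADIUS_KM * math.cos(lat0)
    y = np.radians(lats) * EARTH_RADIUS_KM
    return np.column_stack([x, y])


def landscape_surface(
    pops: PopulationSet,
    gen: DistanceMatrix,
    grid: tuple[int, int] = (80, 80),
    alpha: float = 1.0,
) -> LandscapeSurface:
    """Genetic-landscape-shape surface: Delaunay edge midpoints carry the
    pairwise genetic distance of their endpoints; surface height at each
    node of a uniform grid over the bounding box is the inverse-distance
    (exponent alpha) weighted mean of the midpoint values."""
    labels = gen.labels
    if len(labels) < 3:
        raise ValueError("landscape surface needs at least 3 populations")
    pops.require_coords()
    xy = _project(pops, labels)
    used_delaunay = True
    edges: set[tuple[int, int]] = set()
    try:
        tri = Delaunay(xy)
        for simplex in tri.simplices:
            for a, b in itertools.combinations(simplex, 2):
                edges.add((min(a, b), max(a, b)))
    except QhullError:
        used_delaunay = False
        for a in range(len(labels)):
            for b in range(a + 1, len(labels)):
                edges.add((a, b))
    mids = np.array([(xy[a] + xy[b]) / 2.0 for a, b in edges])
    vals = np.array([gen.d[a, b] for a, b in edges])
    nx, ny = grid
    xg = np.linspace(xy[:, 0].min(), xy[:, 0].max(), nx)
    yg = np.linspace(xy[:, 1].min(), xy[:, 1].max(), ny)
    gx, gy = np.meshgrid(xg, yg)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    d = np.sqrt(((pts[:, None, :] - mids[None, :, :]) ** 2).sum(axis=2))
    surface = np.empty(len(pts))
    exact = d < 1e-9
    with np.errstate(divide="ignore"):
        w = (1.0 / np.where(exact, np.inf, d)) ** alpha
    for k in range(len(pts)):
        if exact[k].any():
            surface[k] = vals[exact[k]][0]
        else:
            surface[k] = (w[k] * vals).sum() / w[k].sum()
    return LandscapeSurface(
        grid=surface.reshape(ny, nx),
        x_coords=xg,
        y_coords=yg,
        alpha=alpha,
        edges=[(labels[a], labels[b]) for a, b in edges],
        used_delaunay=used_delaunay,
    )
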