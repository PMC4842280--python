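"""Neutrality test statistics and their coalescent-null significance.

Implements Tajima's D, Fu & Li's outgroup-free D* and F* (with the corrected
variance coefficients of Simonsen, Churchill & Aquadro 1995), Fu's Fs via the
Ewens sampling distribution (log-space unsigned Stirling numbers of the first
kind, stable to samples of several hundred chromosomes), and Ramos-Onsins &
Rozas's R2. Significance comes from neutral constant-size coalescent
simulation conditioned on the observed number of segregating sites (fixed-S
convention), with Benjamini-Hochberg FDR adjustment across populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .diversity import DiversityStats, base_counts, diversity_stats, _analysed_columns
from .seqdata import Alignment
from .synth import Genealogy, genotype_matrix, mutations_fixed_s

STATISTICS = ("D", "Dstar", "Fstar", "Fs", "R2")


@dataclass
class NeutralityStats:
    """The five test statistics; NaN with a defined_flags=False entry marks a
    statistic that is undefined on the input (e.g. S=0)."""

    D: float
    Dstar: float
    Fstar: float
    Fs: float
    R2: float
    pvals: dict[str, float] = field(default_factory=dict)
    defined_flags: dict[str, bool] = field(default_factory=dict)

    def value(self, name: str) -> float:
        return getattr(self, name)


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def _harmonic(n: int, power: int = 1) -> float:
    return float(sum(1.0 / i**power for i in range(1, n)))


def tajima_d(stats: DiversityStats) -> float:
    """Tajima's D from (n, S, K); NaN when S = 0."""
    n, S, K = stats.n, stats.S, stats.K
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    if S == 0:
        return float("nan")
    a1 = _harmonic(n, 1)
    a2 = _harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (K - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


# ---------------------------------------------------------------------------
# Fu & Li's D* and F* (no outgroup)
# ---------------------------------------------------------------------------

def fu_li_star(stats: DiversityStats) -> tuple[float, float]:
    """Outgroup-free (D*, F*) from (n, K, eta, eta_s); NaN pair when eta=0."""
    n, K, eta, eta_s = stats.n, stats.K, stats.eta, stats.eta_s
    if n < 4:
        raise ValueError("Fu & Li's tests require n >= 4")
    if eta == 0:
        return float("nan"), float("nan")
    a1 = _harmonic(n, 1)
    a2 = _harmonic(n, 2)
    an1 = a1 + 1.0 / n  # harmonic number of n+1 terms
    cn = 2.0 * (n * a1 - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = (
        cn
        + (n - 2) / (n - 1) ** 2
        + (2.0 / (n - 1)) * (1.5 - (2 * an1 - 3) / (n - 2) - 1.0 / n)
    )
    nf = float(n)
    v_d = (
        (nf / (nf - 1)) ** 2 * a2
        + a1**2 * dn
        - 2 * nf * a1 * (a1 + 1) / (nf - 1) ** 2
    ) / (a1**2 + a2)
    u_d = (nf / (nf - 1)) * (a1 - nf / (nf - 1)) - v_d
    dstar = (nf / (nf - 1) * eta - a1 * eta_s) / math.sqrt(u_d * eta + v_d * eta**2)

    v_f = (
        dn
        + 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
        - (2.0 / (n - 1)) * (4 * a2 - 6 + 8.0 / n)
    ) / (a1**2 + a2)
    u_f = (
        nf / (nf - 1)
        + (n + 1) / (3.0 * (n - 1))
        - 4.0 / (n * (n - 1))
        + 2.0 * (n + 1) / (n - 1) ** 2 * (an1 - 2.0 * nf / (n + 1))
    ) / a1 - v_f
    fstar = (K - (nf - 1) / nf * eta_s) / math.sqrt(u_f * eta + v_f * eta**2)
    return dstar, fstar


# ---------------------------------------------------------------------------
# Fu's Fs
# ---------------------------------------------------------------------------

_LOG_STIRLING: list[np.ndarray] = [np.array([0.0])]  # row m: log|s(m, k)|, k=0..m


def _log_stirling_row(n: int) -> np.ndarray:
    """log of unsigned Stirling numbers of the first kind |s(n, k)|."""
    while len(_LOG_STIRLING) <= n:
        m = len(_LOG_STIRLING)
        prev = _LOG_STIRLING[m - 1]
        row = np.full(m + 1, -np.inf)
        row[1 : m + 1] = prev[0:m]  # s(m-1, k-1) term
        with np.errstate(divide="ignore"):
            shifted = np.log(m - 1) + prev if m > 1 else np.full(m, -np.inf)
        row[0:m] = np.logaddexp(row[0:m], shifted)
        row[0] = -np.inf if m >= 1 else 0.0
        _LOG_STIRLING.append(row)
    return _LOG_STIRLING[n]


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log Pr(k alleles | theta) for k = 0..n under the Ewens distribution."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    ls = _log_stirling_row(n)
    k = np.arange(n + 1)
    log_denom = float(np.log(theta + np.arange(n)).sum())
    return ls + k * math.log(theta) - log_denom


def fu_fs_from(n: int, theta: float, h_obs: int) -> float:
    """Fs = ln(S'/(1-S')) with S' = Pr(#alleles >= h_obs | theta)."""
    if theta <= 0:
        return float("nan")
    if h_obs <= 1:
        return float("inf")  # S' = 1: boundary flag
    logp = ewens_log_pmf(n, theta)
    log_upper = logsumexp(logp[h_obs:])
    log_lower = logsumexp(logp[1:h_obs])
    if not np.isfinite(log_lower):
        return float("inf")
    if not np.isfinite(log_upper):
        return float("-inf")
    return float(log_upper - log_lower)


def fu_fs(stats: DiversityStats) -> float:
    """Fu's Fs using theta = K (mean pairwise differences) and observed h."""
    return fu_fs_from(stats.n, stats.K, stats.h)


# ---------------------------------------------------------------------------
# Ramos-Onsins & Rozas's R2
# ---------------------------------------------------------------------------

def _singletons_per_sequence(aln: Alignment) -> tuple[np.ndarray, float, int]:
    """(U, K, S) over complete-deletion columns: U_i = number of singleton
    sites where sequence i carries the column's unique base."""
    arr = aln.to_array()
    mask = _analysed_columns(arr, True)
    sub = arr[:, mask]
    counts = base_counts(sub)
    n = aln.n
    k_alleles = (counts > 0).sum(axis=0)
    S = int((k_alleles >= 2).sum())
    U = np.zeros(n)
    bases = (b"A", b"C", b"G", b"T")
    for bi, b in enumerate(bases):
        cols = np.where((counts[bi] == 1) & (k_alleles >= 2))[0]
        for c in cols:
            U[sub[:, c] == b] += 1
    # mean pairwise differences over the same column set
    if n >= 2:
        npairs = n * (n - 1) / 2.0
        same = sum(
            counts[bi] * (counts[bi] - 1) / 2.0 for bi in range(4)
        )
        K = float((npairs - same).sum() / npairs)
    else:
        K = 0.0
    return U, K, S


def r2_from(U: np.ndarray, K: float, S: int, n: int) -> float:
    if S == 0:
        return float("nan")
    return float(math.sqrt(((U - K / 2.0) ** 2).sum() / n) / S)


def r2_stat(aln: Alignment) -> float:
    """Ramos-Onsins & Rozas's R2; NaN when there are no segregating sites."""
    if aln.n < 2:
        raise ValueError("R2 requires n >= 2")
    U, K, S = _singletons_per_sequence(aln)
    return r2_from(U, K, S, aln.n)


# ---------------------------------------------------------------------------
# Observed statistics bundle
# ---------------------------------------------------------------------------

def compute_neutrality(aln: Alignment) -> NeutralityStats:
    """All five statistics on one alignment, flagged where undefined."""
    st = diversity_stats(aln)
    if st.n >= 4 and st.S >= 1:
        D = tajima_d(st)
        Dstar, Fstar = fu_li_star(st)
    else:
        D = Dstar = Fstar = float("nan")
    Fs = fu_fs(st) if st.K > 0 else float("nan")
    R2 = r2_stat(aln) if st.n >= 2 else float("nan")
    out = NeutralityStats(D, Dstar, Fstar, Fs, R2)
    for name in STATISTICS:
        out.defined_flags[name] = bool(np.isfinite(out.value(name)))
    return out


# ---------------------------------------------------------------------------
# Null distributions (fixed-S coalescent) and p-values
# ---------------------------------------------------------------------------

def _kingman(n: int, rng: np.random.Generator) -> Genealogy:
    """Constant-size single-deme coalescent genealogy (fast path)."""
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=int)
    blen = np.zeros(n_nodes)
    node_time = np.zeros(n_nodes)
    active = list(range(n))
    t = 0.0
    nxt = n
    k = n
    while k > 1:
        t += rng.exponential(2.0 / (k * (k - 1)))
        i = rng.integers(k)
        j = rng.integers(k - 1)
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        blen[a] = t - node_time[a]
        blen[b] = t - node_time[b]
        node_time[nxt] = t
        for idx in sorted((i, j), reverse=True):
            del active[idx]
        active.append(nxt)
        nxt += 1
        k -= 1
    return Genealogy(n, parent, blen, np.zeros(n, dtype=int))


def null_statistics(
    n: int, S: int, reps: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Simulate `reps` neutral constant-size samples with exactly S mutations
    and return the joint null sample of all five statistics."""
    if S < 1:
        raise ValueError("fixed-S simulation needs S >= 1")
    out = {name: np.empty(reps) for name in STATISTICS}
    npairs = n * (n - 1) / 2.0
    for r in range(reps):
        gen = _kingman(n, rng)
        branch_ids = mutations_fixed_s(gen, S, rng)
        geno = genotype_matrix(gen, branch_ids)
        c = geno.sum(axis=0)
        K = float((c * (n - c)).sum() / npairs)
        eta_s = int(((c == 1) | (c == n - 1)).sum())
        U = (geno[:, c == 1] == 1).sum(axis=1) + (geno[:, c == n - 1] == 0).sum(
            axis=1
        )
        h = len({row.tobytes() for row in geno})
        st = DiversityStats(n, S, K, K, h, 0.0, S, eta_s, S)
        out["D"][r] = tajima_d(st)
        ds, fs_ = fu_li_star(st)
        out["Dstar"][r] = ds
        out["Fstar"][r] = fs_
        out["Fs"][r] = fu_fs_from(n, K, h) if K > 0 else np.nan
        out["R2"][r] = r2_from(U.astype(float), K, S, n)
    return out


def empirical_pvalue(
    null: np.ndarray, obs: float, tail: str = "lower"
) -> float:
    """Add-one-smoothed empirical p-value against a null sample."""
    null = null[np.isfinite(null)]
    m = len(null)
    if m == 0 or not np.isfinite(obs):
        return float("nan")
    lower = ((null <= obs).sum() + 1) / (m + 1)
    upper = ((null >= obs).sum() + 1) / (m + 1)
    if tail == "lower":
        return float(lower)
    if tail == "upper":
        return float(upper)
    if tail == "two":
        return float(min(1.0, 2.0 * min(lower, upper)))
    raise ValueError(f"unknown tail {tail!r}")


_TAILS = {"D": "two", "Dstar": "two", "Fstar": "two", "Fs": "lower", "R2": "lower"}


def neutrality_pvalues(
    stats_obs: NeutralityStats,
    n: int,
    S: int,
    reps: int = 1000,
    seed: int = 0,
    null: dict[str, np.ndarray] | None = None,
) -> NeutralityStats:
    """Attach empirical p-values from the fixed-S neutral null.

    Tails follow the usual conventions: two-tailed for D, D*, F*; lower-tail
    for Fs and R2 (small values signal expansion / hitchhiking). Both tails
    of Fs are reported (`Fs_upper`) so either convention can be applied.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    if null is None:
        rng = np.random.default_rng(seed)
        null = null_statistics(n, S, reps, rng)
    pv: dict[str, float] = {}
    for name in STATISTICS:
        obs = stats_obs.value(name)
        if not np.isfinite(obs):
            continue
        pv[name] = empirical_pvalue(null[name], obs, _TAILS[name])
    if np.isfinite(stats_obs.Fs):
        pv["Fs_upper"] = empirical_pvalue(null["Fs"], stats_obs.Fs, "upper")
    return NeutralityStats(
        stats_obs.D,
        stats_obs.Dstar,
        stats_obs.Fstar,
        stats_obs.Fs,
        stats_obs.R2,
        pvals=pv,
        defined_flags=dict(stats_obs.defined_flags),
    )


def fdr_adjust(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values."""
    if len(pvals) == 0:
        return []
    arr = np.asarray(pvals, dtype=float)
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(arr, method="fdr_bh")[1])
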