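"""Sudden (stepwise) demographic-expansion model for mismatch distributions.

The model: a population at equilibrium with scaled mutation rate theta0
instantaneously grows to theta1 at mutational time tau before the present
(tau = 2*t*mu per locus). The expected distribution of pairwise differences
is the equilibrium geometric law convolved with Poisson(tau) mutation
accumulation. Fits are by the method of moments (mean/variance of pairwise
differences) or by least squares on the mismatch relative frequencies;
goodness of fit (SSD and Harpending's raggedness index) is assessed by
parametric bootstrap under the fitted model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .diversity import MismatchDistribution
from .synth import Genealogy, mutations_poisson, pairwise_differences


@dataclass
class ExpansionFit:
    """Fitted sudden-expansion parameters and goodness-of-fit measures.

    SSD is computed on mismatch *relative frequencies* (documented scale).
    """

    tau: float
    theta0: float
    theta1: float
    SSD: float
    p_SSD: float = float("nan")
    r: float = float("nan")
    p_r: float = float("nan")
    method: str = "moments"
    degenerate: bool = False
    time_years: float = float("nan")


def _geometric(theta: float, max_i: int) -> np.ndarray:
    """Equilibrium law of pairwise differences: p_i = theta^i/(1+theta)^(i+1)."""
    i = np.arange(max_i + 1, dtype=float)
    if theta == 0:
        out = np.zeros(max_i + 1)
        out[0] = 1.0
        return out
    return np.exp(i * math.log(theta) - (i + 1) * math.log1p(theta))


def expected_mismatch(
    tau: float, theta0: float, theta1: float, max_i: int
) -> np.ndarray:
    """Probability of i pairwise differences (i = 0..max_i) under the sudden
    expansion model, truncated and renormalized to sum to 1."""
    if tau < 0 or theta0 < 0 or theta1 < 0:
        raise ValueError("expansion parameters must be non-negative")
    g1 = _geometric(theta1, max_i)
    if tau == 0:
        out = _geometric(theta0, max_i)
    elif theta1 == 0:
        out = g1
    else:
        g0 = _geometric(theta0, max_i)
        i = np.arange(max_i + 1, dtype=float)
        log_pois = i * math.log(tau) - gammaln(i + 1) if tau > 0 else None
        pois = np.exp(log_pois - tau * (theta1 + 1.0) / theta1)
        out = g1 + np.convolve(pois, g0 - g1)[: max_i + 1]
    out = np.clip(out, 0.0, None)
    s = out.sum()
    if s <= 0:
        raise FloatingPointError("degenerate expected mismatch distribution")
    return out / s


def raggedness(mm: MismatchDistribution) -> float:
    """Harpending's raggedness index r = sum of squared successive
    differences of the relative frequencies (with a trailing zero class)."""
    x = np.append(mm.relative(), 0.0)
    return float(np.sum(np.diff(x) ** 2))


def _ssd(obs_rel: np.ndarray, tau: float, th0: float, th1: float) -> float:
    exp_rel = expected_mismatch(tau, th0, th1, len(obs_rel) - 1)
    return float(((obs_rel - exp_rel) ** 2).sum())


def fit_expansion(
    mm: MismatchDistribution, method: str = "moments"
) -> ExpansionFit:
    """Estimate (tau, theta0, theta1) from a mismatch distribution.

    moments: Rogers' estimators theta0 = sqrt(max(v-m, 0)), tau = m - theta0
    from the mean m and variance v of pairwise differences (theta1 treated as
    effectively infinite, reported at the stabilising cap). least_squares:
    coarse grid then local refinement of the SSD between observed and
    expected relative frequencies, constrained to theta1 >= theta0 with
    theta1 capped at 10x the largest mismatch class.
    """
    if mm.n_pairs < 1:
        raise ValueError("empty mismatch distribution")
    obs = mm.relative()
    max_class = len(obs) - 1
    cap = max(10.0 * max_class, 10.0)
    if max_class == 0:
        return ExpansionFit(0.0, 0.0, 0.0, 0.0, method=method, degenerate=True)
    m = mm.mean()
    v = mm.variance()
    th0_m = math.sqrt(max(v - m, 0.0))
    tau_m = max(m - th0_m, 0.0)
    if method == "moments":
        ssd = _ssd(obs, tau_m, th0_m, cap)
        return ExpansionFit(tau_m, th0_m, cap, ssd, method="moments")
    if method != "least_squares":
        raise ValueError(f"unknown fit method {method!r}")
    best = (math.inf, 0.0, 0.0, cap)
    taus = np.linspace(0.0, 2.0 * max_class, 17)
    th0s = np.linspace(0.0, max(m, 0.5), 7)
    th1s = np.unique(np.concatenate([np.geomspace(max(m, 0.5), cap, 5), [cap]]))
    for tau in taus:
        for th0 in th0s:
            for th1 in th1s:
                if th1 < th0:
                    continue
                s = _ssd(obs, tau, th0, th1)
                if s < best[0]:
                    best = (s, tau, th0, th1)
    # local refinement; theta1 parameterised as theta0 + delta to keep order
    def objective(x):
        tau, th0, d1 = x
        th1 = min(th0 + d1, cap)
        return _ssd(obs, max(tau, 0.0), max(th0, 0.0), max(th1, 0.0))

    x0 = [best[1], best[2], max(best[3] - best[2], 0.0)]
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-12, "maxiter": 2000},
    )
    tau, th0, d1 = res.x
    tau, th0 = max(tau, 0.0), max(th0, 0.0)
    th1 = min(th0 + max(d1, 0.0), cap)
    ssd = _ssd(obs, tau, th0, th1)
    if ssd > best[0]:  # keep the grid optimum if refinement drifted
        ssd, tau, th0, th1 = best
    return ExpansionFit(tau, th0, th1, ssd, method="least_squares")


# ---------------------------------------------------------------------------
# Parametric bootstrap
# ---------------------------------------------------------------------------

def _expansion_genealogy(
    n: int, t_change: float, ratio: float, rng: np.random.Generator
) -> Genealogy:
    """Single-deme coalescent with relative size 1 now, `ratio` before
    `t_change` (coalescent units)."""
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=int)
    blen = np.zeros(n_nodes)
    node_time = np.zeros(n_nodes)
    active = list(range(n))
    t, nxt, k = 0.0, n, n
    while k > 1:
        size = ratio if t >= t_change else 1.0
        dt = rng.exponential(2.0 * size / (k * (k - 1)))
        if t < t_change and t + dt > t_change:
            t = t_change
            continue
        t += dt
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


def simulate_mismatch(
    n: int,
    tau: float,
    theta0: float,
    theta1: float,
    rng: np.random.Generator,
) -> MismatchDistribution:
    """One coalescent sample of size n under the fitted sudden-expansion
    demography, summarised as its mismatch distribution."""
    theta1 = max(theta1, 1e-9)
    ratio = min(max(theta0 / theta1, 1e-6), 1.0)
    t_change = tau / theta1
    gen = _expansion_genealogy(n, t_change, ratio, rng)
    branch_ids = mutations_poisson(gen, theta1, rng)
    d = pairwise_differences(gen, branch_ids)
    iu = np.triu_indices(n, k=1)
    return MismatchDistribution(np.bincount(d[iu]))


def gof_bootstrap(
    fit: ExpansionFit,
    n: int,
    reps: int = 1000,
    seed: int = 0,
    method: str | None = None,
) -> tuple[float, float]:
    """Parametric bootstrap p-values for SSD and raggedness.

    `reps` samples of size n are simulated under the fitted model and refit
    with the same method; p = (1 + #{sim >= observed}) / (reps + 1).
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    method = method or fit.method
    rng = np.random.default_rng(seed)
    obs_r = fit.r
    b_ssd = b_r = 0
    for _ in range(reps):
        mm = simulate_mismatch(n, fit.tau, fit.theta0, fit.theta1, rng)
        refit = fit_expansion(mm, method=method)
        if refit.SSD >= fit.SSD:
            b_ssd += 1
        if np.isfinite(obs_r) and raggedness(mm) >= obs_r:
            b_r += 1
    p_ssd = (b_ssd + 1) / (reps + 1)
    p_r = (b_r + 1) / (reps + 1) if np.isfinite(obs_r) else float("nan")
    return float(p_ssd), float(p_r)


def expansion_time(tau: float, mu_locus: float) -> float:
    """Convert tau to years: t = tau / (2 mu), mu per locus per year."""
    if mu_locus <= 0:
        raise ValueError("mutation rate must be positive")
    return tau / (2.0 * mu_locus)


def analyse_expansion(
    mm: MismatchDistribution,
    n: int,
    method: str = "moments",
    reps: int = 1000,
    seed: int = 0,
    mu_locus: float | None = None,
) -> ExpansionFit:
    """Fit, raggedness, bootstrap p-values, and optional time conversion."""
    fit = fit_expansion(mm, method=method)
    fit.r = raggedness(mm)
    fit.p_SSD, fit.p_r = gof_bootstrap(fit, n, reps=reps, seed=seed)
    if mu_locus is not None:
        fit.time_years = expansion_time(fit.tau, mu_locus)
    return fit
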