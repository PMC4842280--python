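"""Per-population sequence diversity summaries.

Site-based statistics (S, eta, eta_s) use complete deletion by default:
columns containing '-' or 'N' are dropped before counting. Pairwise
differences (K, the mismatch distribution) use pairwise deletion: each pair
is compared only at columns where both sequences carry a plain base. Both
behaviours are configurable for strict parity with complete-deletion outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqdata import Alignment, HaplotypeTable, PopulationSet, collapse_haplotypes

_BASES = (b"A", b"C", b"G", b"T")


@dataclass
class DiversityStats:
    """Summary statistics of one population sample.

    n: sequences; S: segregating sites; K: mean pairwise differences;
    Pi: nucleotide diversity per analysed site; h/Hd: haplotype count and
    diversity; eta: total mutations (sum of per-column allele count − 1);
    eta_s: singleton mutations; L: number of analysed columns.
    """

    n: int
    S: int
    K: float
    Pi: float
    h: int
    Hd: float
    eta: int
    eta_s: int
    L: int
    hd_defined: bool = True


@dataclass
class MismatchDistribution:
    """Histogram of pairwise difference counts; entry i = pairs at i diffs."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)

    @property
    def n_pairs(self) -> int:
        return int(self.counts.sum())

    def relative(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def mean(self) -> float:
        i = np.arange(len(self.counts))
        return float((i * self.counts).sum() / self.counts.sum())

    def variance(self) -> float:
        i = np.arange(len(self.counts))
        m = self.mean()
        return float(((i - m) ** 2 * self.counts).sum() / self.counts.sum())


def _analysed_columns(arr: np.ndarray, complete_deletion: bool = True) -> np.ndarray:
    """Boolean mask of columns used for site-based statistics."""
    if not complete_deletion:
        return np.ones(arr.shape[1], dtype=bool)
    missing = (arr == b"-") | (arr == b"N")
    return ~missing.any(axis=0)


def base_counts(arr: np.ndarray) -> np.ndarray:
    """(4, L) counts of A,C,G,T per column (missing states ignored)."""
    return np.stack([(arr == b).sum(axis=0) for b in _BASES])


def pairwise_diff_matrix(
    aln: Alignment, pairwise_deletion: bool = True
) -> np.ndarray:
    """Symmetric (n, n) matrix of per-pair difference counts.

    With pairwise deletion, positions where either sequence carries '-' or
    'N' are skipped for that pair only.
    """
    arr = aln.to_array()
    n = arr.shape[0]
    valid = ~((arr == b"-") | (arr == b"N"))
    if not pairwise_deletion:
        keep = valid.all(axis=0)
        arr = arr[:, keep]
        valid = valid[:, keep]
    d = np.zeros((n, n), dtype=int)
    for i in range(n):
        neq = arr[i] != arr[i + 1 :]
        both = valid[i] & valid[i + 1 :]
        row = (neq & both).sum(axis=1)
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return d


def diversity_stats(
    aln: Alignment,
    complete_deletion: bool = True,
    pairwise_deletion: bool = True,
) -> DiversityStats:
    """Compute S, K, Pi, h, Hd, eta, eta_s for one alignment."""
    if aln.n == 0:
        raise ValueError("empty alignment")
    arr = aln.to_array()
    mask = _analysed_columns(arr, complete_deletion)
    counts = base_counts(arr[:, mask])
    k_alleles = (counts > 0).sum(axis=0)
    S = int((k_alleles >= 2).sum())
    eta = int(np.maximum(k_alleles - 1, 0).sum())
    # singleton mutations: per column, alleles observed exactly once, capped
    # at the column's mutation count (multi-allelic all-singleton columns)
    singles = (counts == 1).sum(axis=0)
    eta_s = int(np.minimum(singles, np.maximum(k_alleles - 1, 0)).sum())
    L = int(mask.sum())

    if aln.n >= 2:
        d = pairwise_diff_matrix(aln, pairwise_deletion=pairwise_deletion)
        iu = np.triu_indices(aln.n, k=1)
        K = float(d[iu].mean())
    else:
        K = 0.0
    Pi = K / L if L else 0.0

    table = collapse_haplotypes(aln)
    h = table.n_haplotypes
    if aln.n >= 2:
        p = table.counts.sum(axis=1) / aln.n
        Hd = float(aln.n / (aln.n - 1) * (1.0 - (p**2).sum()))
        hd_defined = True
    else:
        Hd, hd_defined = float("nan"), False
    return DiversityStats(aln.n, S, K, Pi, h, Hd, eta, eta_s, L, hd_defined)


def mismatch_distribution(
    aln: Alignment, pairwise_deletion: bool = True
) -> MismatchDistribution:
    """Histogram of pairwise differences over all unordered sequence pairs."""
    if aln.n < 2:
        raise ValueError("mismatch distribution needs at least 2 sequences")
    d = pairwise_diff_matrix(aln, pairwise_deletion=pairwise_deletion)
    iu = np.triu_indices(aln.n, k=1)
    vals = d[iu]
    counts = np.bincount(vals)
    return MismatchDistribution(counts)


def per_population_stats(
    aln: Alignment, pops: PopulationSet, **kwargs
) -> pd.DataFrame:
    """Diversity summary table, one row per population (report shape of the
    per-population polymorphism tables: n, S, K, Pi, h, Hd, eta, eta_s)."""
    rows = []
    for pop in pops.populations:
        samples = [s for s in aln.ids if pops.sample_to_pop.get(s) == pop]
        sub = aln.subset(samples)
        st = diversity_stats(sub, **kwargs)
        rows.append(
            {
                "population": pop,
                "n": st.n,
                "S": st.S,
                "K": st.K,
                "Pi": st.Pi,
                "h": st.h,
                "Hd": st.Hd,
                "eta": st.eta,
                "eta_s": st.eta_s,
                "L": st.L,
            }
        )
    return pd.DataFrame(rows)
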