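"""Genome-wide distances and per-individual uniqueness weights.

Relatedness correction for haplotype-length statistics: each carrier of a
core allele is weighted by its "uniqueness" — its average squared
genome-wide Hamming distance to the other carriers, normalized so the
weights sum to the carrier count m.  Unit weights (all carriers equally
related) reproduce the classical unweighted statistic exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .haplodata import MISSING, HaplotypeDataset

__all__ = [
    "DistanceMatrix",
    "UniquenessWeights",
    "squared_hamming_matrix",
    "uniqueness",
    "write_distance_matrix",
    "read_distance_matrix",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over sequences.

    ``values[i, j]`` is the squared missing-normalized Hamming distance
    ``(h_ij / c_ij)^2 * L`` where ``h_ij`` counts differing non-missing
    sites, ``c_ij`` counts mutually non-missing sites and ``L`` is the total
    SNP count.  With no missing data this reduces to ``h_ij^2 / L``.
    ``sites_compared`` stores ``c_ij``.
    """

    values: np.ndarray
    sites_compared: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")
        self.sites_compared = np.asarray(self.sites_compared, dtype=np.int64)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @classmethod
    def constant(cls, n: int, value: float = 1.0) -> "DistanceMatrix":
        """All off-diagonal entries equal — the unweighted (U = 1) case."""
        v = np.full((n, n), float(value))
        np.fill_diagonal(v, 0.0)
        return cls(values=v, sites_compared=np.zeros((n, n), dtype=np.int64))


@dataclass
class UniquenessWeights:
    """Weights U(I) for the carrier set X of one core allele.

    ``sum(U) == len(carriers) == m`` by normalization, so U = 1 everywhere
    means equal relatedness and recovers the classical statistic.
    """

    carriers: np.ndarray       # indices into the sequence axis
    U: np.ndarray              # one weight per carrier, >= 0
    D_bar: np.ndarray          # mean pairwise distance to the other carriers

    @property
    def m(self) -> int:
        return len(self.carriers)

    @classmethod
    def unit(cls, carriers) -> "UniquenessWeights":
        carriers = np.asarray(carriers)
        m = len(carriers)
        return cls(carriers=carriers, U=np.ones(m), D_bar=np.full(m, np.nan))


def squared_hamming_matrix(
    dataset: HaplotypeDataset, diploid_pairs: bool = False
) -> DistanceMatrix:
    """Squared genome-wide Hamming distance between all sequence pairs.

    Missing calls are excluded pairwise: the Hamming count is normalized by
    the number of mutually non-missing sites before squaring, then rescaled
    by the total SNP count so that fully observed data give ``h^2 / L``.

    With ``diploid_pairs=True`` consecutive haplotype rows (2i, 2i+1) are
    collapsed to one individual's 0/1/2 dosage vector; the individual-level
    distance is assigned to all four haplotype pairs so that both haplotypes
    of an individual share one weight downstream.
    """
    X = dataset.alleles
    if diploid_pairs:
        if X.shape[0] % 2:
            raise ValueError("diploid_pairs requires an even number of haplotypes")
        a, b = X[0::2], X[1::2]
        miss = (a == MISSING) | (b == MISSING)
        dosage = np.where(miss, MISSING, a + b)
        dm_ind = _sq_hamming(dosage, n_levels=3)
        idx = np.repeat(np.arange(dosage.shape[0]), 2)
        values = dm_ind.values[np.ix_(idx, idx)].copy()
        np.fill_diagonal(values, 0.0)
        return DistanceMatrix(
            values=values,
            sites_compared=dm_ind.sites_compared[np.ix_(idx, idx)],
            labels=list(dataset.sequence_ids),
        )
    dm = _sq_hamming(X, n_levels=2)
    dm.labels = list(dataset.sequence_ids)
    return dm


def _sq_hamming(X: np.ndarray, n_levels: int) -> DistanceMatrix:
    n, L = X.shape
    valid = (X != MISSING).astype(np.float64)
    c = valid @ valid.T
    off = ~np.eye(n, dtype=bool)
    if np.any(c[off] == 0):
        raise ValueError("a sequence pair has no mutually non-missing sites")
    # matching non-missing sites, summed over allele levels
    match = np.zeros((n, n))
    for lev in range(n_levels):
        ind = ((X == lev) & (X != MISSING)).astype(np.float64)
        match += ind @ ind.T
    h = c - match
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(c > 0, (h / c) ** 2 * L, 0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # exact symmetry against float noise
    return DistanceMatrix(values=d, sites_compared=c.astype(np.int64))


def uniqueness(dm: DistanceMatrix, carrier_set) -> UniquenessWeights:
    """Uniqueness weights U(I) for the carriers of one core allele.

    ``D_bar(I)`` is the mean distance from carrier I to the other carriers;
    ``U(I) = m * D_bar(I) / sum_J D_bar(J)``, so ``sum(U) = m`` and only the
    relative weighting between carriers matters (the statistic is invariant
    to rescaling the whole distance matrix).  When every ``D_bar`` is equal
    — including the degenerate all-identical case, with a warning — unit
    weights are returned exactly.
    """
    carriers = np.asarray(sorted(carrier_set))
    m = len(carriers)
    if m < 2:
        raise ValueError("carrier set must contain at least 2 sequences")
    sub = dm.values[np.ix_(carriers, carriers)]
    d_bar = sub.sum(axis=1) / (m - 1)
    total = d_bar.sum()
    if total == 0:
        warnings.warn(
            "all carriers are at zero genome-wide distance; using unit weights",
            stacklevel=2,
        )
        return UniquenessWeights(carriers=carriers, U=np.ones(m), D_bar=d_bar)
    if d_bar.min() == d_bar.max():
        # exactly equidistant carriers: the normalized ratio is exactly 1
        return UniquenessWeights(carriers=carriers, U=np.ones(m), D_bar=d_bar)
    U = m * d_bar / total
    return UniquenessWeights(carriers=carriers, U=U, D_bar=d_bar)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    labels = dm.labels or [f"seq_{i}" for i in range(dm.n)]
    with open(path, "w") as fh:
        fh.write("\t".join(labels) + "\n")
        for row in dm.values:
            fh.write("\t".join(f"{x:.12g}" for x in row) + "\n")


def read_distance_matrix(path) -> DistanceMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    labels = lines[0].split("\t")
    values = np.array([[float(x) for x in ln.split("\t")] for ln in lines[1:]])
    return DistanceMatrix(
        values=values, sites_compared=np.zeros_like(values, dtype=np.int64), labels=labels
    )
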