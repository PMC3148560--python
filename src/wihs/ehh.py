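"""Weighted extended haplotype homozygosity (wEHH) decay and integration.

EHH(x, y) is the probability that two sequences carrying the same core
allele at SNP x are identical at every SNP between x and y.  The weighted
variant replaces each carrier's unit contribution with its uniqueness
weight U(I): with W_h = sum of U over the carriers sharing haplotype h on
[x, y],

    wEHH(x, y) = (sum_h W_h^2 - sum_I U(I)^2) / (m^2 - sum_I U(I)^2)

which at U = 1 reduces to the classical sample EHH
sum_h n_h (n_h - 1) / (m (m - 1)).  The decay is walked SNP by SNP in both
directions from the core, truncated after the first point below a cutoff
(default 0.05), and integrated over genetic distance (cM) by the
trapezoidal rule.  The log-ratio of the ancestral and derived integrals is
the raw (unstandardized) per-SNP score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .haplodata import MISSING, HaplotypeDataset
from .weights import UniquenessWeights

__all__ = [
    "EHHDecay",
    "IntegratedEHH",
    "ehh_decay",
    "integrate_ehh",
    "raw_score",
    "integrated_ehh",
    "write_decay_tsv",
]

TRUNCATION = 0.05

try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    def _njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not a or not callable(a[0]) else a[0]


@_njit(cache=True)
def _walk(alleles, core, direction, U, sum_u2, denom, truncation, phys, gap_limit):
    """Refine carrier identity classes one SNP at a time away from the core.

    Returns (ehh values including the core's 1.0, number of steps taken,
    stopped-by-truncation flag).  A missing call (-1) always splits its
    carrier into a singleton class.
    """
    m, S = alleles.shape
    last = S - 1 if direction > 0 else 0
    max_steps = abs(last - core)
    ehh = np.ones(max_steps + 1)
    group = np.zeros(m, dtype=np.int64)
    relabel = np.empty(4 * m, dtype=np.int64)
    n_groups = 1
    steps = 0
    truncated = False
    y = core
    while y != last:
        y += direction
        if gap_limit >= 0.0 and abs(phys[y] - phys[y - direction]) > gap_limit:
            break
        # key = 3*group + allele symbol; missing gets a unique key per carrier
        relabel[: 3 * n_groups + m] = -1
        new_n = 0
        for i in range(m):
            a = alleles[i, y]
            key = 3 * group[i] + (a + 1) if a >= 0 else 3 * n_groups + i
            if relabel[key] < 0:
                relabel[key] = new_n
                new_n += 1
            group[i] = relabel[key]
        n_groups = new_n
        sum_w2 = 0.0
        w = np.zeros(n_groups)
        for i in range(m):
            w[group[i]] += U[i]
        for h in range(n_groups):
            sum_w2 += w[h] * w[h]
        value = (sum_w2 - sum_u2) / denom if denom > 0 else 0.0
        if value < 0.0:
            value = 0.0
        elif value > 1.0:
            value = 1.0
        steps += 1
        ehh[steps] = value
        if value < truncation:
            truncated = True
            break
    return ehh, steps, truncated

COMPLETE = "complete"
BOUNDARY_TRUNCATED = "boundary_truncated"
UNDEFINED = "undefined"


@dataclass
class EHHDecay:
    """wEHH values walking outward from one core allele.

    Each direction starts at the core itself (ehh = 1) and lists
    (SNP index, genetic position, ehh); ehh is non-increasing outward.
    ``*_truncated`` records whether the walk stopped by crossing the cutoff
    (True) or by hitting the chromosome end (False).
    """

    core_index: int
    core_allele: int
    left_indices: np.ndarray
    left_cm: np.ndarray
    left_ehh: np.ndarray
    right_indices: np.ndarray
    right_cm: np.ndarray
    right_ehh: np.ndarray
    left_truncated: bool
    right_truncated: bool


@dataclass
class IntegratedEHH:
    """Trapezoidal areas under the decay for both core alleles."""

    iwehh_a: float
    iwehh_d: float
    status: str  # complete | boundary_truncated | undefined


def ehh_decay(
    dataset: HaplotypeDataset,
    core_index: int,
    core_allele: int,
    weights: UniquenessWeights | None = None,
    truncation: float = TRUNCATION,
    max_gap_bp: float | None = None,
    counters: dict | None = None,
) -> EHHDecay:
    """Walk the wEHH decay outward from one core allele.

    Carriers are partitioned into haplotype-identity classes over [x, y],
    refining the partition one SNP at a time; a missing call always splits
    its sequence into a singleton class (missing treated as mismatch).  The
    walk in each direction stops after the first point with wEHH below
    *truncation* (that point is kept, so the crossing trapezoid is
    integrated) or at the chromosome end.  ``weights=None`` means unit
    weights (classical EHH).
    """
    if dataset.genetic_positions is None:
        raise ValueError("dataset needs genetic positions (apply a genetic map first)")
    col = dataset.alleles[:, core_index]
    carriers = np.flatnonzero(col == core_allele)
    m = len(carriers)
    if m < 2:
        raise ValueError(
            f"core allele {core_allele} at SNP {core_index} has {m} carriers; need >= 2"
        )
    n_other = int(np.sum((col != core_allele) & (col != MISSING)))
    if n_other == 0:
        raise ValueError(f"SNP {core_index} is monomorphic; cannot be a core site")
    if weights is None:
        U = np.ones(m)
    else:
        if weights.m != m or not np.array_equal(np.sort(weights.carriers), carriers):
            raise ValueError("weights were computed for a different carrier set")
        order = np.argsort(weights.carriers)
        U = np.asarray(weights.U, dtype=np.float64)[order]
    if np.any(U < 0):
        raise ValueError("uniqueness weights must be non-negative")

    sum_u2 = float(np.sum(U * U))
    denom = m * m - sum_u2
    gmap = dataset.genetic_positions
    alleles = np.ascontiguousarray(dataset.alleles[carriers])
    gap_limit = -1.0 if max_gap_bp is None else float(max_gap_bp)
    phys = dataset.physical_positions.astype(np.float64)

    sides = {}
    for direction in (-1, +1):
        ehh_vals, n_steps, truncated = _walk(
            alleles, int(core_index), direction, U, sum_u2, denom,
            float(truncation), phys, gap_limit,
        )
        if counters is not None:
            counters["carrier_steps"] = counters.get("carrier_steps", 0) + m * n_steps
        idx = core_index + direction * np.arange(n_steps + 1)
        sides[direction] = (idx, gmap[idx], ehh_vals[: n_steps + 1], truncated)
    li, lc, le, lt = sides[-1]
    ri, rc, re_, rt = sides[+1]
    return EHHDecay(
        core_index=core_index,
        core_allele=core_allele,
        left_indices=li, left_cm=lc, left_ehh=le,
        right_indices=ri, right_cm=rc, right_ehh=re_,
        left_truncated=lt, right_truncated=rt,
    )


def integrate_ehh(decay: EHHDecay, truncation: float = TRUNCATION) -> float:
    """Sum of the two directional trapezoidal integrals over genetic distance.

    Points are integrated up to and including the first one below
    *truncation*; the x axis is |cM distance to the core|, so the result is
    in cM x (dimensionless EHH) units.  All points at one genetic position
    (zero-width map) integrate to 0.
    """
    total = 0.0
    for cm, ehh in ((decay.left_cm, decay.left_ehh), (decay.right_cm, decay.right_ehh)):
        stop = len(ehh)
        below = np.flatnonzero(ehh < truncation)
        if len(below):
            stop = below[0] + 1
        x = np.abs(cm[:stop] - cm[0])
        total += float(np.trapezoid(ehh[:stop], x))
    return total


def write_decay_tsv(decay: EHHDecay, path) -> None:
    """Export a decay as TSV (direction, snp_index, cM, ehh) for plotting."""
    with open(path, "w") as fh:
        fh.write(f"# core_index {decay.core_index} core_allele {decay.core_allele}\n")
        fh.write("direction\tsnp_index\tcm\tehh\n")
        for name, idx, cm, vals in (
            ("left", decay.left_indices, decay.left_cm, decay.left_ehh),
            ("right", decay.right_indices, decay.right_cm, decay.right_ehh),
        ):
            for i, c, v in zip(idx, cm, vals):
                fh.write(f"{name}\t{int(i)}\t{c:.8g}\t{v:.10g}\n")


def raw_score(iwehh_a: float, iwehh_d: float) -> float:
    """ln(iwEHH_A / iwEHH_D): positive when the ancestral haplotype is longer,
    negative when the derived haplotype is longer; NaN when either area is 0."""
    if iwehh_a < 0 or iwehh_d < 0:
        raise ValueError("integrated EHH values must be non-negative")
    if iwehh_a == 0 or iwehh_d == 0:
        return np.nan
    return float(np.log(iwehh_a / iwehh_d))


def integrated_ehh(
    dataset: HaplotypeDataset,
    core_index: int,
    weights_ancestral: UniquenessWeights | None = None,
    weights_derived: UniquenessWeights | None = None,
    truncation: float = TRUNCATION,
    boundary: str = "integrate",
    counters: dict | None = None,
) -> IntegratedEHH:
    """iwEHH for both alleles of one core SNP.

    *boundary* controls chromosome-end handling: ``"missing"`` marks the SNP
    boundary_truncated (score later treated as undefined); ``"integrate"``
    keeps the partial integral.
    """
    areas = {}
    hit_boundary = False
    for allele, w in ((0, weights_ancestral), (1, weights_derived)):
        d = ehh_decay(
            dataset, core_index, allele, weights=w, truncation=truncation,
            counters=counters,
        )
        if not (d.left_truncated and d.right_truncated):
            hit_boundary = True
        areas[allele] = integrate_ehh(d, truncation=truncation)
    status = COMPLETE
    if hit_boundary:
        status = BOUNDARY_TRUNCATED
        if boundary == "missing":
            return IntegratedEHH(iwehh_a=areas[0], iwehh_d=areas[1], status=status)
    if areas[0] == 0 or areas[1] == 0:
        status = UNDEFINED
    return IntegratedEHH(iwehh_a=areas[0], iwehh_d=areas[1], status=status)
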