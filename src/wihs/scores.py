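"""Genome scans (iHS, WiHS, PHS), standardization and window statistics.

All three statistics are computed per core SNP for every site passing the
minor-allele-frequency filter (both alleles at frequency >= 0.05 by
default) and then standardized within derived-allele-frequency classes, so
that the score is comparable across frequencies.  WiHS is iHS with each
carrier's contribution weighted by its genome-wide uniqueness; with a
constant distance matrix the two are identical.  PHS is the pairwise
haplotype sharing comparator: the carrier-pair excess of per-pair
genome-standardized shared-tract lengths, O(n^2) in sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import rankdata

from . import ehh as _ehh
from .haplodata import MISSING, HaplotypeDataset
from .weights import DistanceMatrix, uniqueness

__all__ = [
    "SNPScore",
    "WindowScore",
    "FrequencyReference",
    "ihs_scan",
    "wihs_scan",
    "phs_scan",
    "standardize",
    "window_average",
    "sliding_windows",
    "empirical_significance",
]

MAF_MIN = 0.05


@dataclass
class SNPScore:
    """Per-core-SNP scan record (raw and frequency-standardized)."""

    snp_index: int
    physical_position: int
    derived_freq: float
    derived_count: int
    iwehh_a: float = np.nan
    iwehh_d: float = np.nan
    raw: float = np.nan
    standardized: float = np.nan
    status: str = "ok"
    chromosome: str = "chr"

    @property
    def defined(self) -> bool:
        return np.isfinite(self.raw)


@dataclass
class WindowScore:
    """Mean |standardized score| over a SNP-index window."""

    start: int               # first SNP index (inclusive)
    stop: int                # last SNP index (exclusive)
    mean_abs_score: float
    n_defined: int
    rank: float = np.nan
    empirical_p: float = np.nan
    significant: bool | None = None

    @property
    def defined(self) -> bool:
        return np.isfinite(self.mean_abs_score)


def _core_sites(dataset: HaplotypeDataset, maf_min: float) -> np.ndarray:
    """Indices eligible as core sites: MAF >= maf_min, no missing calls, and
    at least two carriers of each allele (pairs must exist on both sides)."""
    ok = dataset.maf() >= maf_min
    ok &= ~dataset.has_missing()
    n_der = (dataset.alleles == 1).sum(axis=0)
    n_anc = (dataset.alleles == 0).sum(axis=0)
    ok &= (n_der >= 2) & (n_anc >= 2)
    return np.flatnonzero(ok)


def ihs_scan(
    dataset: HaplotypeDataset,
    maf_min: float = MAF_MIN,
    truncation: float = _ehh.TRUNCATION,
    boundary: str = "integrate",
    binning: str = "auto",
    min_bin_count: int = 20,
    counters: dict | None = None,
    diagnostics: dict | None = None,
) -> list[SNPScore]:
    """Classical integrated haplotype score scan (unit weights), standardized."""
    return _integrated_scan(
        dataset, dm=None, maf_min=maf_min, truncation=truncation, boundary=boundary,
        binning=binning, min_bin_count=min_bin_count, counters=counters,
        diagnostics=diagnostics,
    )


def wihs_scan(
    dataset: HaplotypeDataset,
    dm: DistanceMatrix,
    maf_min: float = MAF_MIN,
    truncation: float = _ehh.TRUNCATION,
    boundary: str = "integrate",
    binning: str = "auto",
    min_bin_count: int = 20,
    counters: dict | None = None,
    diagnostics: dict | None = None,
) -> list[SNPScore]:
    """Uniqueness-weighted iHS scan: each core allele's carriers are weighted
    by their genome-wide uniqueness within that carrier set."""
    if dm is None:
        raise ValueError("wihs_scan requires a distance matrix")
    if dm.n != dataset.n_haplotypes:
        raise ValueError(
            f"distance matrix is {dm.n}x{dm.n} but dataset has "
            f"{dataset.n_haplotypes} haplotypes"
        )
    return _integrated_scan(
        dataset, dm=dm, maf_min=maf_min, truncation=truncation, boundary=boundary,
        binning=binning, min_bin_count=min_bin_count, counters=counters,
        diagnostics=diagnostics,
    )


def _integrated_scan(
    dataset, dm, maf_min, truncation, boundary, binning, min_bin_count,
    counters, diagnostics,
) -> list[SNPScore]:
    if dataset.genetic_positions is None:
        raise ValueError("dataset needs genetic positions (apply a genetic map first)")
    freq = dataset.derived_freq()
    counts = (dataset.alleles == 1).sum(axis=0)
    cores = _core_sites(dataset, maf_min)
    scores: list[SNPScore] = []
    for x in cores:
        w_a = w_d = None
        if dm is not None:
            col = dataset.alleles[:, x]
            w_a = uniqueness(dm, np.flatnonzero(col == 0))
            w_d = uniqueness(dm, np.flatnonzero(col == 1))
        res = _ehh.integrated_ehh(
            dataset, int(x), weights_ancestral=w_a, weights_derived=w_d,
            truncation=truncation, boundary=boundary, counters=counters,
        )
        if res.status == _ehh.COMPLETE:
            raw, status = _ehh.raw_score(res.iwehh_a, res.iwehh_d), "ok"
            if not np.isfinite(raw):
                status = "zero_integral"
        elif res.status == _ehh.BOUNDARY_TRUNCATED and boundary == "integrate":
            raw = _ehh.raw_score(res.iwehh_a, res.iwehh_d)
            status = "boundary_integrated" if np.isfinite(raw) else "zero_integral"
        else:
            raw, status = np.nan, res.status
        scores.append(
            SNPScore(
                snp_index=int(x),
                physical_position=int(dataset.physical_positions[x]),
                derived_freq=float(freq[x]),
                derived_count=int(counts[x]),
                iwehh_a=res.iwehh_a,
                iwehh_d=res.iwehh_d,
                raw=raw,
                status=status,
                chromosome=dataset.chromosome_id,
            )
        )
    scores = standardize(scores, binning=binning, min_bin_count=min_bin_count)
    if diagnostics is not None:
        diagnostics.update(_diagnose(dataset, cores, scores))
    return scores


def _diagnose(dataset, cores, scores) -> dict:
    return {
        "n_snps": dataset.n_snps,
        "n_cores": len(cores),
        "n_maf_filtered": dataset.n_snps - len(cores),
        "n_undefined": sum(not s.defined for s in scores),
        "n_standardized": sum(np.isfinite(s.standardized) for s in scores),
    }


# ---------------------------------------------------------------------------
# PHS
# ---------------------------------------------------------------------------


def phs_scan(
    dataset: HaplotypeDataset,
    maf_min: float = MAF_MIN,
    binning: str = "auto",
    min_bin_count: int = 20,
    counters: dict | None = None,
    diagnostics: dict | None = None,
) -> list[SNPScore]:
    """Pairwise haplotype sharing scan, reported for the derived allele.

    For each sequence pair (i, j), d_xij is the genetic (cM) length of the
    maximal interval containing SNP x over which i and j are identical
    (0 when they differ at x; missing counts as a mismatch); Z_xij
    standardizes d_xij by that pair's genome-wide mean and SD.  The score at
    (x, derived) is the mean Z over derived-carrier pairs minus the mean Z
    over all pairs, afterwards frequency-standardized like the other scans.
    """
    if dataset.genetic_positions is None:
        raise ValueError("dataset needs genetic positions (apply a genetic map first)")
    X = dataset.alleles
    n, S = X.shape
    g = dataset.genetic_positions
    iu0, iu1 = np.triu_indices(n, k=1)
    n_pairs = len(iu0)
    Z = np.empty((n_pairs, S))
    zero_sd_pairs = 0
    snp_idx = np.arange(S)
    for p in range(n_pairs):
        a, b = X[iu0[p]], X[iu1[p]]
        mism = np.flatnonzero((a != b) | (a == MISSING) | (b == MISSING))
        d = np.empty(S)
        if len(mism) == 0:
            d[:] = g[-1] - g[0]
        else:
            # tract around SNP s spans (previous mismatch, next mismatch)
            nxt = np.searchsorted(mism, snp_idx, side="left")
            right = np.where(nxt < len(mism), mism[np.minimum(nxt, len(mism) - 1)] - 1, S - 1)
            prv = np.searchsorted(mism, snp_idx, side="right") - 1
            left = np.where(prv >= 0, mism[np.maximum(prv, 0)] + 1, 0)
            d = np.where(left <= right, g[np.maximum(right, 0)] - g[np.minimum(left, S - 1)], 0.0)
            d[mism] = 0.0
        if counters is not None:
            counters["pair_site_evals"] = counters.get("pair_site_evals", 0) + S
        mu = d.mean()
        sd = d.std(ddof=1)
        if sd == 0:
            zero_sd_pairs += 1
            Z[p] = 0.0
        else:
            Z[p] = (d - mu) / sd
    if zero_sd_pairs:
        warnings.warn(
            f"{zero_sd_pairs} sequence pair(s) have zero tract-length variance; "
            "their Z contributions were set to 0",
            stacklevel=2,
        )
    freq = dataset.derived_freq()
    counts = (X == 1).sum(axis=0)
    cores = _core_sites(dataset, maf_min)
    mean_all = Z.mean(axis=0)  # over C(n,2) pairs, per SNP
    scores: list[SNPScore] = []
    for x in cores:
        carrier = X[:, x] == 1
        pair_mask = carrier[iu0] & carrier[iu1]
        n_cpairs = int(pair_mask.sum())
        if n_cpairs == 0:
            raw, status = np.nan, "undefined"
        else:
            raw = float(Z[pair_mask, x].sum() / n_cpairs - mean_all[x])
            status = "ok"
        scores.append(
            SNPScore(
                snp_index=int(x),
                physical_position=int(dataset.physical_positions[x]),
                derived_freq=float(freq[x]),
                derived_count=int(counts[x]),
                raw=raw,
                status=status,
                chromosome=dataset.chromosome_id,
            )
        )
    scores = standardize(scores, binning=binning, min_bin_count=min_bin_count)
    if diagnostics is not None:
        diagnostics.update(_diagnose(dataset, cores, scores))
        diagnostics["zero_sd_pairs"] = zero_sd_pairs
    return scores


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


def standardize(
    scores: list[SNPScore], binning: str = "auto", min_bin_count: int = 20
) -> list[SNPScore]:
    """Standardize raw scores within derived-allele-frequency classes.

    ``binning="count"`` groups by exact derived-allele count (appropriate
    when every site shares one sample size, as in simulations);
    ``binning="freq"`` uses 2%-wide frequency bins; ``"auto"`` picks
    ``"count"`` when no score's frequency depends on missing data.  Bins
    with fewer than *min_bin_count* defined scores are merged with the
    nearest bin.  Each populated bin ends up with mean 0 and (sample) SD 1;
    a merged bin with zero SD gets its scores marked missing with a warning.
    """
    scores = [replace(s) for s in scores]
    defined = [s for s in scores if s.defined]
    if not defined:
        return scores
    if binning == "auto":
        ns = np.array([_implied_n(s) for s in defined])
        binning = "count" if np.nanmax(ns) - np.nanmin(ns) < 0.5 else "freq"
    if binning == "count":
        keys = np.array([s.derived_count for s in scores], dtype=float)
    elif binning == "freq":
        keys = np.floor(np.array([s.derived_freq for s in scores]) / 0.02)
    else:
        raise ValueError(f"unknown binning {binning!r}")
    def_mask = np.array([s.defined for s in scores])
    merged = _merge_bins(keys[def_mask], min_bin_count)
    # map every score (defined or not) to its merged bin for reporting
    raw = np.array([s.raw for s in scores])
    for bin_keys in merged:
        in_bin = np.isin(keys, list(bin_keys))
        vals = raw[in_bin & def_mask]
        if len(vals) < 2:
            for i in np.flatnonzero(in_bin & def_mask):
                scores[i].standardized = np.nan
                scores[i].status = "bin_too_small"
            continue
        mu = vals.mean()
        sd = vals.std(ddof=1)
        if sd == 0:
            warnings.warn("zero SD in a frequency bin; its scores set missing", stacklevel=2)
            for i in np.flatnonzero(in_bin & def_mask):
                scores[i].standardized = np.nan
                scores[i].status = "zero_sd_bin"
            continue
        for i in np.flatnonzero(in_bin & def_mask):
            scores[i].standardized = (scores[i].raw - mu) / sd
    return scores


def _implied_n(s: SNPScore) -> float:
    return s.derived_count / s.derived_freq if s.derived_freq > 0 else np.nan


def _merge_bins(def_keys: np.ndarray, min_bin_count: int) -> list[set]:
    """Greedily merge under-populated bins with their nearest neighbor bin."""
    uniq, counts = np.unique(def_keys, return_counts=True)
    bins = [{"keys": {k}, "count": int(c), "center": float(k)} for k, c in zip(uniq, counts)]
    while len(bins) > 1:
        small = min(range(len(bins)), key=lambda i: bins[i]["count"])
        if bins[small]["count"] >= min_bin_count:
            break
        dists = [
            (abs(bins[i]["center"] - bins[small]["center"]), i)
            for i in range(len(bins))
            if i != small
        ]
        _, nearest = min(dists)
        a, b = sorted((small, nearest))
        bins[a] = {
            "keys": bins[a]["keys"] | bins[b]["keys"],
            "count": bins[a]["count"] + bins[b]["count"],
            "center": (bins[a]["center"] * bins[a]["count"] + bins[b]["center"] * bins[b]["count"])
            / (bins[a]["count"] + bins[b]["count"]),
        }
        del bins[b]
    return [b["keys"] for b in bins]


class FrequencyReference:
    """Standardization moments per derived-allele count, estimated from
    reference scans (typically neutral replicates of a simulation study).

    Standardizing against an external neutral reference keeps the moments
    free of the focal dataset's own sweep signal, which matters when the
    scanned locus is short relative to the sweep footprint.  Sparse counts
    widen symmetrically to neighboring counts until at least
    ``min_bin_count`` reference scores are available.
    """

    def __init__(self, raws_by_count: dict[int, np.ndarray], min_bin_count: int = 20):
        self.raws_by_count = {int(k): np.asarray(v, float) for k, v in raws_by_count.items()}
        if not self.raws_by_count:
            raise ValueError("reference contains no defined raw scores")
        self.min_bin_count = int(min_bin_count)
        self._cache: dict[int, tuple[float, float]] = {}

    @classmethod
    def from_scans(cls, scans, min_bin_count: int = 20) -> "FrequencyReference":
        """Pool raw scores by derived-allele count over one or more scans."""
        if scans and isinstance(scans[0], SNPScore):
            scans = [scans]
        by: dict[int, list[float]] = {}
        for sc in scans:
            for s in sc:
                if s.defined:
                    by.setdefault(s.derived_count, []).append(s.raw)
        return cls(by, min_bin_count=min_bin_count)

    def moments(self, derived_count: int) -> tuple[float, float]:
        if derived_count in self._cache:
            return self._cache[derived_count]
        width = 0
        vals = self.raws_by_count.get(derived_count, np.empty(0))
        max_count = max(self.raws_by_count)
        while len(vals) < self.min_bin_count and width <= max_count:
            width += 1
            vals = np.concatenate(
                [
                    self.raws_by_count.get(derived_count + d, np.empty(0))
                    for d in range(-width, width + 1)
                ]
            )
        mu = float(vals.mean())
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        self._cache[derived_count] = (mu, sd)
        return mu, sd

    def apply(self, scores: list[SNPScore]) -> list[SNPScore]:
        """Return scores re-standardized against the reference moments."""
        out = [replace(s) for s in scores]
        for s in out:
            if not s.defined:
                s.standardized = np.nan
                continue
            mu, sd = self.moments(s.derived_count)
            s.standardized = (s.raw - mu) / sd if sd > 0 else np.nan
        return out


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def window_average(
    scores: list[SNPScore], center: int, half_width: int = 25, n_snps: int | None = None
) -> WindowScore:
    """Mean |standardized| over SNP indices [center - hw, center + hw],
    clipped at the chromosome ends; undefined scores are skipped."""
    if n_snps is None:
        n_snps = max(s.snp_index for s in scores) + 1
    start = max(0, center - half_width)
    stop = min(n_snps, center + half_width + 1)
    return _window(scores, start, stop)


def _window(scores, start, stop) -> WindowScore:
    vals = [
        abs(s.standardized)
        for s in scores
        if start <= s.snp_index < stop and np.isfinite(s.standardized)
    ]
    if not vals:
        return WindowScore(start=start, stop=stop, mean_abs_score=np.nan, n_defined=0)
    return WindowScore(
        start=start, stop=stop, mean_abs_score=float(np.mean(vals)), n_defined=len(vals)
    )


def sliding_windows(
    scores: list[SNPScore],
    window_size: int = 50,
    offset: int = 20,
    n_snps: int | None = None,
) -> list[WindowScore]:
    """Windows of *window_size* SNP indices every *offset* indices.

    A final partial window is kept if it covers at least half the window
    size, otherwise it is merged into the previous window.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if offset < 1:
        raise ValueError("offset must be >= 1")
    if n_snps is None:
        n_snps = max(s.snp_index for s in scores) + 1
    starts = list(range(0, max(n_snps - window_size, 0) + 1, offset))
    if not starts:
        starts = [0]
    windows = [(st, min(st + window_size, n_snps)) for st in starts]
    tail_start = windows[-1][1]
    if tail_start < n_snps:
        if n_snps - tail_start >= window_size / 2 or not windows:
            windows.append((tail_start, n_snps))
        else:
            windows[-1] = (windows[-1][0], n_snps)
    return [_window(scores, st, sp) for st, sp in windows]


def empirical_significance(
    windows: list[WindowScore], null_stats, alpha: float
) -> list[WindowScore]:
    """Attach empirical p-values, ranks and significance calls from a null
    distribution of window statistics (add-one estimator:
    p = (1 + #{null >= obs}) / (1 + #null))."""
    null_stats = np.asarray(null_stats, dtype=float)
    if len(null_stats) == 0:
        raise ValueError("null_stats must be non-empty")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    cutoff = float(np.quantile(null_stats, 1 - alpha))
    out = [replace(w) for w in windows]
    obs = np.array([w.mean_abs_score for w in out])
    def_mask = np.isfinite(obs)
    ranks = np.full(len(out), np.nan)
    if def_mask.any():
        ranks[def_mask] = rankdata(-obs[def_mask], method="average")
    for i, w in enumerate(out):
        if not np.isfinite(obs[i]):
            continue
        w.empirical_p = float((1 + np.sum(null_stats >= obs[i])) / (1 + len(null_stats)))
        w.significant = bool(obs[i] > cutoff)
        w.rank = float(ranks[i])
    return out
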