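"""Haplotype containers, file I/O and genetic-map handling.

The central object is :class:`HaplotypeDataset`: a phased, ancestral/derived
polarized 0/1 haplotype matrix together with physical (bp) and genetic (cM)
SNP coordinates.  Readers are provided for phased VCF (via cyvcf2), for the
ms simulator text format, and for a plain tab-separated dialect used
throughout the test suite.  Physical coordinates are 0-based half-open
internally; VCF I/O converts from/to the 1-based convention.

:class:`GeneticMap` converts physical to genetic coordinates.  Maps are
fitted as least-squares polynomials to (bp, cM) anchor markers; because the
downstream haplotype-length integrals require non-decreasing genetic
positions, a fit that is non-monotone anywhere on the anchored range is
replaced by monotone piecewise-linear interpolation of the anchors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

MISSING = -1

__all__ = [
    "MISSING",
    "HaplotypeDataset",
    "GeneticMap",
    "read_haplotypes",
    "read_ms_replicates",
    "write_haplotypes_tsv",
    "write_ms",
    "fit_genetic_map",
    "read_genetic_map",
    "assign_genetic_positions",
    "write_scores",
    "read_scores",
]


@dataclass
class HaplotypeDataset:
    """Phased polarized haplotypes.

    Parameters
    ----------
    alleles
        ``(n, S)`` integer matrix; rows are haplotypes, columns SNPs.
        0 = ancestral, 1 = derived, :data:`MISSING` (-1) = missing.
    physical_positions
        Strictly increasing bp coordinate per SNP (0-based).
    genetic_positions
        Non-decreasing cM coordinate per SNP, or ``None`` until a map is
        applied.
    sequence_ids
        One label per haplotype row.
    chromosome_id
        Chromosome / contig label.
    """

    alleles: np.ndarray
    physical_positions: np.ndarray
    genetic_positions: np.ndarray | None = None
    sequence_ids: list[str] | None = None
    chromosome_id: str = "chr"
    io_report: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        n, s = self.alleles.shape
        if n < 2 or s < 2:
            raise ValueError(f"need at least 2 haplotypes and 2 SNPs, got {n}x{s}")
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise ValueError("allele values must be 0, 1 or missing (-1)")
        self.physical_positions = np.asarray(self.physical_positions, dtype=np.int64)
        if self.physical_positions.shape != (s,):
            raise ValueError("physical_positions length must match SNP count")
        if np.any(np.diff(self.physical_positions) <= 0):
            raise ValueError("physical_positions must be strictly increasing")
        if self.genetic_positions is not None:
            self.genetic_positions = np.asarray(self.genetic_positions, dtype=np.float64)
            if self.genetic_positions.shape != (s,):
                raise ValueError("genetic_positions length must match SNP count")
            if np.any(np.diff(self.genetic_positions) < 0):
                raise ValueError("genetic_positions must be non-decreasing")
        if self.sequence_ids is None:
            self.sequence_ids = [f"hap_{i}" for i in range(n)]
        elif len(self.sequence_ids) != n:
            raise ValueError("sequence_ids length must match haplotype count")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    def derived_freq(self) -> np.ndarray:
        """Derived-allele frequency per SNP over non-missing calls."""
        valid = self.alleles != MISSING
        n_valid = valid.sum(axis=0)
        n_der = (self.alleles == 1).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_valid > 0, n_der / n_valid, np.nan)

    def maf(self) -> np.ndarray:
        f = self.derived_freq()
        return np.minimum(f, 1.0 - f)

    def has_missing(self) -> np.ndarray:
        """Boolean per SNP: any missing call at that site."""
        return (self.alleles == MISSING).any(axis=0)

    def subset_snps(self, index) -> "HaplotypeDataset":
        """New dataset restricted to the given SNP indices (order preserved)."""
        index = np.asarray(index)
        return HaplotypeDataset(
            alleles=self.alleles[:, index],
            physical_positions=self.physical_positions[index],
            genetic_positions=None
            if self.genetic_positions is None
            else self.genetic_positions[index],
            sequence_ids=list(self.sequence_ids),
            chromosome_id=self.chromosome_id,
        )

    def content_equal(self, other: "HaplotypeDataset") -> bool:
        """Equality on scientific content (alleles, coordinates, labels)."""
        if self.alleles.shape != other.alleles.shape:
            return False
        same_gen = (
            (self.genetic_positions is None) == (other.genetic_positions is None)
        ) and (
            self.genetic_positions is None
            or np.allclose(self.genetic_positions, other.genetic_positions)
        )
        return (
            bool(np.array_equal(self.alleles, other.alleles))
            and bool(np.array_equal(self.physical_positions, other.physical_positions))
            and same_gen
            and self.sequence_ids == other.sequence_ids
            and self.chromosome_id == other.chromosome_id
        )


class GeneticMap:
    """Physical (bp) to genetic (cM) coordinate conversion.

    Fitted as a least-squares polynomial to anchor markers.  If the fitted
    polynomial is non-monotone anywhere on the anchored bp range, evaluation
    falls back to monotone piecewise-linear interpolation of the anchors
    (``uses_fallback``).  Outside the anchored range the map extrapolates
    linearly with the boundary slope.
    """

    def __init__(self, anchor_bp, anchor_cm, degree=3, coefficients=None, uses_fallback=False):
        self.anchor_bp = np.asarray(anchor_bp, dtype=np.float64)
        self.anchor_cm = np.asarray(anchor_cm, dtype=np.float64)
        if np.any(np.diff(self.anchor_bp) <= 0):
            raise ValueError("anchor bp values must be strictly increasing")
        if np.any(np.diff(self.anchor_cm) < 0):
            raise ValueError("anchor cM values must be non-decreasing")
        self.degree = int(degree)
        self.coefficients = coefficients  # numpy Polynomial or None under fallback
        self.uses_fallback = bool(uses_fallback)

    def __call__(self, bp) -> np.ndarray:
        bp = np.atleast_1d(np.asarray(bp, dtype=np.float64))
        lo, hi = self.anchor_bp[0], self.anchor_bp[-1]
        inside = np.clip(bp, lo, hi)
        if self.uses_fallback:
            cm = np.interp(inside, self.anchor_bp, self.anchor_cm)
            slope_lo = self._anchor_slope(0)
            slope_hi = self._anchor_slope(-1)
            val_lo, val_hi = self.anchor_cm[0], self.anchor_cm[-1]
        else:
            p = self.coefficients
            cm = p(inside)
            dp = p.deriv()
            slope_lo, slope_hi = dp(lo), dp(hi)
            val_lo, val_hi = p(lo), p(hi)
        below = bp < lo
        above = bp > hi
        cm = np.where(below, val_lo + slope_lo * (bp - lo), cm)
        cm = np.where(above, val_hi + slope_hi * (bp - hi), cm)
        return cm

    def _anchor_slope(self, end: int) -> float:
        b, c = self.anchor_bp, self.anchor_cm
        if end == 0:
            db, dc = b[1] - b[0], c[1] - c[0]
        else:
            db, dc = b[-1] - b[-2], c[-1] - c[-2]
        return dc / db if db > 0 else 0.0

    @classmethod
    def uniform(cls, cm_per_bp: float, length_bp: float) -> "GeneticMap":
        """Constant-rate map over [0, length_bp] (used for simulated data)."""
        return fit_genetic_map([(0, 0.0), (length_bp, cm_per_bp * length_bp)], degree=1)


def fit_genetic_map(anchor_points, degree: int = 3) -> GeneticMap:
    """Least-squares polynomial fit of cM against bp at marker anchors.

    Falls back to monotone piecewise-linear interpolation whenever the
    polynomial's derivative goes negative on the anchored range, since
    downstream integration requires non-decreasing genetic positions.
    """
    pts = sorted((float(b), float(c)) for b, c in anchor_points)
    bp = np.array([p[0] for p in pts])
    cm = np.array([p[1] for p in pts])
    if len(bp) < degree + 1:
        raise ValueError(f"need at least degree+1={degree + 1} anchors, got {len(bp)}")
    if np.any(np.diff(bp) <= 0):
        raise ValueError("anchor bp values must be strictly increasing")
    if np.any(np.diff(cm) < 0):
        raise ValueError("anchor cM values must be non-decreasing in bp")
    poly = np.polynomial.Polynomial.fit(bp, cm, deg=degree)
    dense = np.linspace(bp[0], bp[-1], max(512, 8 * len(bp)))
    if np.any(poly.deriv()(dense) < 0):
        warnings.warn(
            "polynomial genetic-map fit is non-monotone on the anchored range; "
            "falling back to piecewise-linear interpolation of the anchors",
            stacklevel=2,
        )
        return GeneticMap(bp, cm, degree=degree, coefficients=None, uses_fallback=True)
    return GeneticMap(bp, cm, degree=degree, coefficients=poly.convert())


def read_genetic_map(path) -> GeneticMap:
    """Read a two-column (bp, cM) TSV and fit the default degree-3 map."""
    anchors = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            b, c = line.split("\t")[:2]
            try:
                anchors.append((float(b), float(c)))
            except ValueError:
                continue  # header line
    degree = min(3, len(anchors) - 1)
    return fit_genetic_map(anchors, degree=degree)


def assign_genetic_positions(dataset: HaplotypeDataset, gmap: GeneticMap) -> HaplotypeDataset:
    """Return a copy of *dataset* with genetic positions from the map."""
    cm = gmap(dataset.physical_positions)
    cm = np.maximum.accumulate(cm)  # guard against float noise at the boundary
    return replace(dataset, genetic_positions=cm)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_haplotypes(
    path,
    format: str,
    ancestral_source: str = "AA",
    sequence_length: float | None = None,
) -> HaplotypeDataset:
    """Read phased haplotypes from ``vcf``, ``ms`` or ``tsv`` files.

    For VCF the genotypes must be phased and sites biallelic; alleles are
    polarized against the INFO tag named by *ancestral_source* (sites whose
    ancestral state is unavailable or matches neither allele are dropped and
    counted in ``io_report``).  For ms format the unit-interval positions are
    scaled by *sequence_length* to integer bp.
    """
    if format == "tsv":
        return _read_tsv(path)
    if format == "ms":
        reps = list(read_ms_replicates(path, sequence_length=sequence_length))
        if not reps:
            raise ValueError(f"no ms replicate block found in {path}")
        return reps[0]
    if format == "vcf":
        return _read_vcf(path, ancestral_source)
    raise ValueError(f"unknown format {format!r}; expected vcf, ms or tsv")


def _read_tsv(path) -> HaplotypeDataset:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    has_ids = not _is_number(header[0])
    positions = [int(float(x)) for x in (header[1:] if has_ids else header)]
    rows, ids = [], []
    for i, ln in enumerate(lines[1:]):
        fields = ln.split("\t")
        if has_ids:
            ids.append(fields[0])
            fields = fields[1:]
        rows.append([MISSING if f in (".", "NA", "") else int(f) for f in fields])
    return HaplotypeDataset(
        alleles=np.array(rows, dtype=np.int8),
        physical_positions=np.array(positions, dtype=np.int64),
        sequence_ids=ids or None,
    )


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_ms_replicates(path, sequence_length: float | None = None):
    """Yield one :class:`HaplotypeDataset` per ``//`` block of an ms file.

    Unit-interval positions are scaled by *sequence_length* (required) and
    rounded to integer bp; positions colliding after rounding are shifted by
    +1 bp deterministically from left to right.
    """
    if sequence_length is None:
        raise ValueError("sequence_length is required to scale ms positions to bp")
    with open(path) as fh:
        text = fh.read()
    blocks = text.split("\n//")[1:]
    for bi, block in enumerate(blocks):
        lines = [ln.strip() for ln in block.strip().splitlines() if ln.strip()]
        positions = None
        haps = []
        for ln in lines:
            if ln.startswith("segsites:"):
                if int(ln.split()[1]) == 0:
                    break
            elif ln.startswith("positions:"):
                positions = np.array([float(x) for x in ln.split()[1:]])
            elif positions is not None and set(ln) <= set("01"):
                haps.append([int(ch) for ch in ln])
        if positions is None or not haps:
            continue
        bp = _dedupe_positions(np.floor(positions * sequence_length).astype(np.int64))
        yield HaplotypeDataset(
            alleles=np.array(haps, dtype=np.int8),
            physical_positions=bp,
            chromosome_id=f"ms_{bi}",
        )


def _dedupe_positions(bp: np.ndarray) -> np.ndarray:
    bp = bp.copy()
    collided = False
    for i in range(1, len(bp)):
        if bp[i] <= bp[i - 1]:
            bp[i] = bp[i - 1] + 1
            collided = True
    if collided:
        warnings.warn("duplicate bp positions after scaling; jittered +1 bp", stacklevel=3)
    return bp


def _read_vcf(path, ancestral_source: str) -> HaplotypeDataset:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = vcf.samples
    cols, positions = [], []
    report = {"n_records": 0, "dropped_no_ancestral": 0, "skipped_multiallelic": 0}
    chrom = None
    for var in vcf:
        report["n_records"] += 1
        if len(var.ALT) != 1:
            warnings.warn(f"skipping multiallelic site {var.CHROM}:{var.POS}", stacklevel=3)
            report["skipped_multiallelic"] += 1
            continue
        chrom = chrom or var.CHROM
        gts = var.genotypes  # [a, b, phased] per sample
        col = []
        for g in gts:
            if not g[-1] and len(g) > 2:
                raise ValueError(f"unphased genotype at {var.CHROM}:{var.POS}")
            for a in g[:-1]:
                col.append(MISSING if a < 0 else int(a))
        aa = var.INFO.get(ancestral_source)
        if aa is None:
            report["dropped_no_ancestral"] += 1
            continue
        aa = str(aa).upper()
        if aa == var.REF.upper():
            pass  # REF already ancestral: ALT index 1 = derived
        elif aa == var.ALT[0].upper():
            col = [MISSING if a == MISSING else 1 - a for a in col]
        else:
            report["dropped_no_ancestral"] += 1
            continue
        cols.append(col)
        positions.append(var.POS - 1)  # 1-based VCF -> 0-based internal
    if not cols:
        raise ValueError(f"no usable polarized biallelic sites in {path}")
    alleles = np.array(cols, dtype=np.int8).T
    ids = [f"{s}_{h}" for s in samples for h in (0, 1)][: alleles.shape[0]]
    ds = HaplotypeDataset(
        alleles=alleles,
        physical_positions=_dedupe_positions(np.array(positions, dtype=np.int64)),
        sequence_ids=ids,
        chromosome_id=chrom or "chr",
    )
    ds.io_report = report
    return ds


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_haplotypes_tsv(dataset: HaplotypeDataset, path) -> None:
    """Plain TSV dialect: header of bp positions, one 0/1 row per haplotype."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(str(p) for p in dataset.physical_positions) + "\n")
        for sid, row in zip(dataset.sequence_ids, dataset.alleles):
            toks = ["." if a == MISSING else str(int(a)) for a in row]
            fh.write(sid + "\t" + "\t".join(toks) + "\n")


def write_ms(datasets, path, sequence_length: float, header: str = "ms-like output") -> None:
    """Write datasets as consecutive ms-format replicate blocks."""
    if isinstance(datasets, HaplotypeDataset):
        datasets = [datasets]
    with open(path, "w") as fh:
        fh.write(header + "\n\n")
        for ds in datasets:
            fh.write("//\n")
            fh.write(f"segsites: {ds.n_snps}\n")
            rel = ds.physical_positions / float(sequence_length)
            fh.write("positions: " + " ".join(f"{p:.8f}" for p in rel) + "\n")
            for row in ds.alleles:
                fh.write("".join("?" if a == MISSING else str(int(a)) for a in row) + "\n")


_SNP_COLUMNS = [
    "chromosome", "position", "derived_freq", "iwEHH_A", "iwEHH_D", "raw",
    "standardized", "status",
]
_WINDOW_COLUMNS = [
    "window_start", "window_end", "mean_abs_score", "rank", "empirical_p",
]


def write_scores(scores, path, header_lines=()) -> None:
    """Write per-SNP or per-window scores as TSV (round-trips via read_scores)."""
    from . import scores as _sc  # local import to avoid a cycle

    with open(path, "w") as fh:
        for ln in header_lines:
            fh.write(f"# {ln}\n")
        if scores and isinstance(scores[0], _sc.WindowScore):
            fh.write("\t".join(_WINDOW_COLUMNS) + "\n")
            for w in scores:
                fh.write(
                    f"{w.start}\t{w.stop}\t{_fmt(w.mean_abs_score)}\t"
                    f"{_fmt(w.rank)}\t{_fmt(w.empirical_p)}\n"
                )
        else:
            fh.write("\t".join(_SNP_COLUMNS) + "\n")
            for s in scores:
                fh.write(
                    f"{s.chromosome}\t{s.physical_position}\t{s.derived_freq:.10g}\t"
                    f"{_fmt(s.iwehh_a)}\t{_fmt(s.iwehh_d)}\t{_fmt(s.raw)}\t"
                    f"{_fmt(s.standardized)}\t{s.status}\n"
                )


def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    return f"{x:.10g}"


def _parse(tok: str) -> float:
    return np.nan if tok == "NA" else float(tok)


def read_scores(path):
    """Read a score TSV written by :func:`write_scores`."""
    from . import scores as _sc

    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if not ln.startswith("#")]
    header = lines[0].split("\t")
    out = []
    if header[0] == "window_start":
        for ln in lines[1:]:
            f = ln.split("\t")
            out.append(
                _sc.WindowScore(
                    start=int(f[0]), stop=int(f[1]), mean_abs_score=_parse(f[2]),
                    n_defined=-1, rank=_parse(f[3]), empirical_p=_parse(f[4]),
                )
            )
    else:
        for i, ln in enumerate(lines[1:]):
            f = ln.split("\t")
            out.append(
                _sc.SNPScore(
                    snp_index=i, chromosome=f[0], physical_position=int(f[1]),
                    derived_freq=float(f[2]), derived_count=-1,
                    iwehh_a=_parse(f[3]), iwehh_d=_parse(f[4]),
                    raw=_parse(f[5]), standardized=_parse(f[6]),
                    status=f[7] if len(f) > 7 else "ok",
                )
            )
    return out
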