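"""Coalescent simulation study: sweep/neutral replicates, power and FDR.

Replicates are simulated with msprime under four demographic models
(panmictic, two-deme island, exponential growth, recent bottleneck), with
a structured-coalescent selective sweep at the sequence midpoint when the
scaled selection coefficient 2Ns is positive.  Defaults follow the study
conditions: 2 Mbp sequences, 100 sampled chromosomes, theta = 6e-3 and
rho = 8e-4 per site, Ne = 1000, 2Ns = 200, and a random subsample of 4000
SNPs with minor allele frequency >= 0.05.

The sweep is conditioned on a present-day derived allele frequency inside
``target_freq_range`` by rejection sampling.  msprime does not report which
samples carry the beneficial allele, so the selected site is proxied by the
segregating site nearest the sweep position whose sample frequency falls in
the target range; attempts with no such site within ``causal_max_dist_bp``
are rejected.  Island-model sweeps are not supported by the built-in
backend: simulate them externally with an msms-compatible simulator and
load the ms output via :func:`wihs.haplodata.read_haplotypes`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import scores as _sc
from .haplodata import HaplotypeDataset
from .weights import squared_hamming_matrix

__all__ = [
    "ScenarioSpec",
    "SimReplicate",
    "simulate_replicate",
    "downsample_snps",
    "causal_rank",
    "power_fdr_study",
    "make_fixture",
]

MODELS = ("panmictic", "island", "growth", "bottleneck")


@dataclass
class ScenarioSpec:
    """Demographic and selection parameters of one simulation scenario.

    Epoch times (``growth_onset``, ``bottleneck_start``, ``bottleneck_end``)
    are in units of 2*Ne generations before present.  ``sel_2ns = 0`` means
    neutral.  ``sweep_start_time`` is carried for ms-format interoperability
    only; the built-in backend derives the sweep duration from its internal
    allele-frequency trajectory.
    """

    model: str = "panmictic"
    sequence_length: float = 2_000_000
    sample_size: int = 100
    theta: float = 6e-3
    rho: float = 8e-4
    ne: float = 1000.0
    sel_2ns: float = 200.0
    migration_4nm: float | None = None
    growth_factor: float = 10.0
    growth_onset: float = 0.1
    bottleneck_depth: float = 0.2
    bottleneck_start: float = 0.15
    bottleneck_end: float = 0.05
    sweep_start_time: float | None = None
    target_freq_range: tuple[float, float] = (0.6, 0.8)
    n_sampled_snps: int = 4000
    maf_min: float = 0.05
    causal_max_dist_bp: float = 25_000
    max_rejects: int = 200

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        for name in ("sequence_length", "sample_size", "theta", "rho", "ne"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.target_freq_range
        if not (0 < lo < hi < 1):
            raise ValueError("target_freq_range must be inside (0, 1)")
        if self.model == "island" and self.migration_4nm is None:
            raise ValueError("island model requires migration_4nm")

    @property
    def mutation_rate(self) -> float:
        """Per-bp per-generation mutation rate implied by theta = 4*Ne*mu."""
        return self.theta / (4 * self.ne)

    @property
    def recombination_rate(self) -> float:
        """Per-bp per-generation crossover rate implied by rho = 4*Ne*r."""
        return self.rho / (4 * self.ne)

    @property
    def cm_per_bp(self) -> float:
        """Uniform genetic-map rate: 1 cM = 0.01 crossovers per generation."""
        return 100.0 * self.recombination_rate

    @property
    def neutral(self) -> bool:
        return self.sel_2ns == 0


@dataclass
class SimReplicate:
    """One simulated dataset plus its causal-site bookkeeping."""

    dataset: HaplotypeDataset
    scenario: ScenarioSpec
    seed: int
    causal_snp_index: int | None = None
    causal_derived_freq: float | None = None
    n_attempts: int = 1
    diagnostics: dict = field(default_factory=dict)


def _demography(spec: ScenarioSpec):
    """msprime demography on the haploid-lineage timescale.

    Samples are haploid chromosomes, so sizes are passed as 2*Ne lineages:
    two lineages then coalesce at rate 1/(2*Ne) per generation and the
    diploid scalings theta = 4*Ne*mu, rho = 4*Ne*r, alpha = 2*Ne*s hold.
    """
    import msprime

    n0 = 2 * spec.ne
    dem = msprime.Demography()
    if spec.model == "island":
        return msprime.Demography.island_model(
            [n0, n0], migration_rate=spec.migration_4nm / (4 * spec.ne)
        )
    if spec.model == "panmictic":
        dem.add_population(name="pop0", initial_size=n0)
    elif spec.model == "growth":
        t_on = spec.growth_onset * 2 * spec.ne
        rate = np.log(spec.growth_factor) / t_on
        dem.add_population(name="pop0", initial_size=n0, growth_rate=rate)
        dem.add_population_parameters_change(
            time=t_on, initial_size=n0 / spec.growth_factor, growth_rate=0.0,
            population="pop0",
        )
    elif spec.model == "bottleneck":
        dem.add_population(name="pop0", initial_size=n0)
        dem.add_population_parameters_change(
            time=spec.bottleneck_end * 2 * spec.ne,
            initial_size=n0 * spec.bottleneck_depth, population="pop0",
        )
        dem.add_population_parameters_change(
            time=spec.bottleneck_start * 2 * spec.ne,
            initial_size=n0, population="pop0",
        )
    return dem


def simulate_replicate(spec: ScenarioSpec, seed: int) -> SimReplicate:
    """Simulate one replicate; sweeps are rejection-conditioned on the
    present-day derived frequency of the causal site (see module docstring).

    Deterministic given (spec, seed).
    """
    import msprime

    if not spec.neutral and spec.model == "island":
        raise NotImplementedError(
            "the msprime backend does not support sweeps in multi-deme models; "
            "simulate island-model sweeps with an msms-compatible simulator and "
            "load the ms output via read_haplotypes(..., format='ms')"
        )
    L = spec.sequence_length
    dem = _demography(spec)
    samples = (
        {0: spec.sample_size // 2, 1: spec.sample_size - spec.sample_size // 2}
        if spec.model == "island"
        else spec.sample_size
    )
    for attempt in range(spec.max_rejects):
        ss = np.random.SeedSequence([int(seed), attempt])
        rng = np.random.default_rng(ss)
        anc_seed, mut_seed = (int(x) for x in rng.integers(1, 2**31 - 1, size=2))
        if spec.neutral:
            model = None
        else:
            f_end = rng.uniform(*spec.target_freq_range)
            # population_size is 2*Ne lineages, so alpha = 2*(2Ne)*s'
            # equals the diploid 2*Ne*s at s' = s/2
            sweep = msprime.SweepGenicSelection(
                position=L / 2,
                start_frequency=1.0 / (2 * spec.ne),
                end_frequency=f_end,
                s=spec.sel_2ns / (4 * spec.ne),
                dt=1e-6,
            )
            model = [sweep, msprime.StandardCoalescent()]
        try:
            ts = msprime.sim_ancestry(
                samples=samples, ploidy=1, demography=dem, sequence_length=L,
                recombination_rate=spec.recombination_rate, model=model,
                random_seed=anc_seed,
            )
        except Exception as err:  # pragma: no branch
            if spec.neutral or "LibraryError" not in type(err).__name__:
                raise
            # sweep trajectory collided with a demographic event epoch:
            # reject the attempt (conditions sweeps on completing within the
            # most recent epoch; see docs/methods.md)
            continue
        mts = msprime.sim_mutations(
            ts, rate=spec.mutation_rate, random_seed=mut_seed,
            model=msprime.BinaryMutationModel(),
        )
        G = mts.genotype_matrix()  # sites x samples, 0 ancestral / 1 derived
        pos = mts.sites_position.astype(np.int64)
        poly = (G.sum(axis=1) > 0) & (G.sum(axis=1) < G.shape[1])
        G, pos = G[poly], pos[poly]
        ds = HaplotypeDataset(
            alleles=G.T.astype(np.int8),
            physical_positions=pos,
            genetic_positions=pos * spec.cm_per_bp,
            chromosome_id=f"sim_{spec.model}",
        )
        if spec.neutral:
            return SimReplicate(dataset=ds, scenario=spec, seed=seed,
                                n_attempts=attempt + 1)
        freq = ds.derived_freq()
        lo, hi = spec.target_freq_range
        cand = np.flatnonzero((freq >= lo) & (freq <= hi))
        if len(cand):
            dist = np.abs(pos[cand] - L / 2)
            best = cand[np.argmin(dist)]
            if dist.min() <= spec.causal_max_dist_bp:
                return SimReplicate(
                    dataset=ds, scenario=spec, seed=seed,
                    causal_snp_index=int(best),
                    causal_derived_freq=float(freq[best]),
                    n_attempts=attempt + 1,
                )
    raise RuntimeError(
        f"no accepted sweep replicate in {spec.max_rejects} attempts "
        f"(acceptance conditioning on frequency {spec.target_freq_range})"
    )


def downsample_snps(
    rep: SimReplicate,
    n_snps: int | None = None,
    maf_min: float | None = None,
    seed: int = 0,
) -> SimReplicate:
    """Uniform random subsample of qualifying SNPs (MAF >= maf_min), order
    preserved; the causal SNP is force-included and its index re-mapped."""
    spec = rep.scenario
    n_snps = spec.n_sampled_snps if n_snps is None else n_snps
    maf_min = spec.maf_min if maf_min is None else maf_min
    qual = np.flatnonzero(rep.dataset.maf() >= maf_min)
    if len(qual) < n_snps:
        raise ValueError(
            f"only {len(qual)} SNPs with MAF >= {maf_min}; need {n_snps}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 951]))
    chosen = np.sort(rng.choice(qual, size=n_snps, replace=False))
    causal_new = None
    if rep.causal_snp_index is not None:
        causal = rep.causal_snp_index
        if causal not in chosen:
            drop = rng.integers(n_snps)
            chosen[drop] = causal
            chosen = np.sort(chosen)
        causal_new = int(np.searchsorted(chosen, causal))
    return replace(
        rep,
        dataset=rep.dataset.subset_snps(chosen),
        causal_snp_index=causal_new,
    )


def causal_rank(
    scores: list[_sc.SNPScore], causal_snp_index: int, n_snps: int | None = None
) -> float:
    """Rank of the causal SNP when all SNPs are sorted by |standardized score|
    descending (average ranks for ties).  An undefined or filtered causal
    score gets the midpoint convention (S + 1) / 2 over the full SNP grid."""
    from scipy.stats import rankdata

    if n_snps is None:
        n_snps = max(s.snp_index for s in scores) + 1
    if not 0 <= causal_snp_index < n_snps:
        raise IndexError(f"causal index {causal_snp_index} outside 0..{n_snps - 1}")
    by_index = {s.snp_index: s for s in scores}
    causal = by_index.get(causal_snp_index)
    if causal is None or not np.isfinite(causal.standardized):
        return (n_snps + 1) / 2
    defined = [s for s in scores if np.isfinite(s.standardized)]
    vals = np.array([abs(s.standardized) for s in defined])
    ranks = rankdata(-vals, method="average")
    pos = next(i for i, s in enumerate(defined) if s.snp_index == causal_snp_index)
    return float(ranks[pos])


def _scan(dataset: HaplotypeDataset, statistic, counters=None) -> list[_sc.SNPScore]:
    if callable(statistic):
        return statistic(dataset)
    if statistic == "ihs":
        return _sc.ihs_scan(dataset, counters=counters)
    if statistic == "wihs":
        dm = squared_hamming_matrix(dataset)
        return _sc.wihs_scan(dataset, dm, counters=counters)
    if statistic == "phs":
        return _sc.phs_scan(dataset, counters=counters)
    raise ValueError(f"unknown statistic {statistic!r}")


def _binom_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact binomial confidence interval."""
    from scipy.stats import beta

    a = (1 - conf) / 2
    lo = 0.0 if k == 0 else float(beta.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1 - a, k + 1, n - k))
    return lo, hi


def power_fdr_study(
    scenario: ScenarioSpec,
    n_sweep_reps: int,
    n_neutral_reps: int,
    null_spec: ScenarioSpec,
    n_null_reps: int,
    alpha: float,
    statistic="wihs",
    seed: int = 1,
    window_half_width: int = 25,
    standardization: str = "dataset",
    fdr_cutoff: str = "null",
) -> dict:
    """Detection power and false discovery rate of one or more statistics.

    1. Null distribution: for each neutral replicate of *null_spec*, the
       mean |standardized score| in a +/-``window_half_width``-SNP window at
       one uniformly random SNP is recorded; the detection cutoff is its
       (1 - alpha) quantile.
    2. Power: fraction of sweep replicates of *scenario* whose window
       statistic centred on the causal SNP exceeds the cutoff.  Causal
       ranks over the sampled SNP grid are recorded as well.
    3. FDR: fraction of non-overlapping windows exceeding the cutoff over
       neutral replicates of *scenario*'s demography.

    Each replicate is standardized against itself by default, mirroring a
    genome scan of a single dataset.  With ``standardization="reference"``
    the frequency-class moments are instead estimated once from the neutral
    null replicates and applied to every scan, so a sweep cannot contaminate
    its own standardization moments (sharper at small locus sizes, where the
    sweep spans much of the scanned region).

    The FDR detection threshold defaults to the power cutoff
    (``fdr_cutoff="null"``).  Because the power null samples one mid-locus
    window per replicate while the FDR tiles whole loci — including
    edge-attenuated windows — the tiled false-positive rate sits below the
    nominal level on short loci; ``fdr_cutoff="matched"`` instead takes the
    (1 - alpha) quantile of the *tiled* windows of the same null
    replicates, making the null-model FDR equal alpha by construction so
    demographic inflation is measured cleanly.

    *statistic* may be ``"ihs"``/``"wihs"``/``"phs"``, a callable
    ``dataset -> scores``, or a list of these; replicates are shared across
    statistics so comparisons are paired.  Deterministic given *seed*.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_null_reps < 1:
        raise ValueError("need at least one null replicate")
    if standardization not in ("reference", "dataset"):
        raise ValueError("standardization must be 'reference' or 'dataset'")
    if fdr_cutoff not in ("null", "matched"):
        raise ValueError("fdr_cutoff must be 'null' or 'matched'")
    stats = statistic if isinstance(statistic, (list, tuple)) else [statistic]
    names = [s if isinstance(s, str) else getattr(s, "__name__", "custom") for s in stats]
    root = np.random.SeedSequence(int(seed))
    null_ss, sweep_ss, fdr_ss = root.spawn(3)
    report = {
        "alpha": alpha, "seed": int(seed), "window_half_width": window_half_width,
        "scenario_model": scenario.model, "n_null": n_null_reps,
        "n_sweep": n_sweep_reps, "n_fdr_reps": n_neutral_reps,
        "standardization": standardization,
        "statistics": {nm: {} for nm in names},
    }

    # 1. panmictic null: one random window centre per neutral replicate
    null_neutral = replace(null_spec, sel_2ns=0.0)
    null_scans = {nm: [] for nm in names}
    null_centers = []
    null_ncols = []
    for child in null_ss.spawn(n_null_reps):
        rep_seed = int(child.generate_state(1)[0] % (2**31 - 1)) + 1
        rep = simulate_replicate(null_neutral, rep_seed)
        rep = downsample_snps(rep, seed=rep_seed)
        s_count = rep.dataset.n_snps
        null_ncols.append(s_count)
        null_centers.append(
            int(np.random.default_rng(child).integers(window_half_width,
                                                      s_count - window_half_width))
        )
        for st, nm in zip(stats, names):
            null_scans[nm].append(_scan(rep.dataset, st))
    refs = {nm: None for nm in names}
    if standardization == "reference":
        refs = {nm: _sc.FrequencyReference.from_scans(null_scans[nm]) for nm in names}

    def _std(nm, scores):
        return refs[nm].apply(scores) if refs[nm] is not None else scores

    win = 2 * window_half_width + 1
    cutoffs = {}
    fdr_cutoffs = {}
    for nm in names:
        vals, tiled = [], []
        for scores, center, s_count in zip(null_scans[nm], null_centers, null_ncols):
            std_scores = _std(nm, scores)
            w = _sc.window_average(std_scores, center, window_half_width,
                                   n_snps=s_count)
            if w.defined:
                vals.append(w.mean_abs_score)
            if fdr_cutoff == "matched" and n_neutral_reps > 0:
                tiled.extend(
                    t.mean_abs_score
                    for t in _sc.sliding_windows(std_scores, window_size=win,
                                                 offset=win, n_snps=s_count)
                    if t.defined
                )
        vals = np.array(vals)
        cutoffs[nm] = float(np.quantile(vals, 1 - alpha))
        fdr_cutoffs[nm] = (
            float(np.quantile(tiled, 1 - alpha)) if tiled else cutoffs[nm]
        )
        report["statistics"][nm]["null_stats"] = vals.tolist()
        report["statistics"][nm]["cutoff"] = cutoffs[nm]
        report["statistics"][nm]["fdr_cutoff"] = fdr_cutoffs[nm]
    del null_scans

    # 2. power on sweep replicates of the scenario
    if n_sweep_reps > 0:
        causal_scores = {nm: [] for nm in names}
        causal_ranks = {nm: [] for nm in names}
        for child in sweep_ss.spawn(n_sweep_reps):
            rep_seed = int(child.generate_state(1)[0] % (2**31 - 1)) + 1
            rep = simulate_replicate(scenario, rep_seed)
            rep = downsample_snps(rep, seed=rep_seed)
            s_count = rep.dataset.n_snps
            for st, nm in zip(stats, names):
                scores = _std(nm, _scan(rep.dataset, st))
                w = _sc.window_average(
                    scores, rep.causal_snp_index, window_half_width, n_snps=s_count
                )
                causal_scores[nm].append(w.mean_abs_score)
                causal_ranks[nm].append(
                    causal_rank(scores, rep.causal_snp_index, n_snps=s_count)
                )
        for nm in names:
            vals = np.array(causal_scores[nm])
            detected = int(np.sum(vals[np.isfinite(vals)] > cutoffs[nm]))
            r = report["statistics"][nm]
            r["causal_window_scores"] = vals.tolist()
            r["causal_ranks"] = causal_ranks[nm]
            r["mean_causal_rank"] = float(np.mean(causal_ranks[nm]))
            r["power"] = detected / n_sweep_reps
            r["power_ci"] = _binom_ci(detected, n_sweep_reps)

    # 3. FDR on neutral replicates of the scenario's demography
    if n_neutral_reps > 0:
        fdr_neutral = replace(scenario, sel_2ns=0.0)
        n_exceed = {nm: 0 for nm in names}
        n_windows = {nm: 0 for nm in names}
        for child in fdr_ss.spawn(n_neutral_reps):
            rep_seed = int(child.generate_state(1)[0] % (2**31 - 1)) + 1
            rep = simulate_replicate(fdr_neutral, rep_seed)
            rep = downsample_snps(rep, seed=rep_seed)
            for st, nm in zip(stats, names):
                scores = _std(nm, _scan(rep.dataset, st))
                for w in _sc.sliding_windows(
                    scores, window_size=win, offset=win, n_snps=rep.dataset.n_snps
                ):
                    if w.defined:
                        n_windows[nm] += 1
                        if w.mean_abs_score > fdr_cutoffs[nm]:
                            n_exceed[nm] += 1
        for nm in names:
            r = report["statistics"][nm]
            r["fdr"] = n_exceed[nm] / n_windows[nm] if n_windows[nm] else np.nan
            r["fdr_ci"] = _binom_ci(n_exceed[nm], n_windows[nm])
            r["n_windows"] = n_windows[nm]
    return report


# ---------------------------------------------------------------------------
# deterministic unit-test fixtures
# ---------------------------------------------------------------------------


def make_fixture(kind: str, params: dict | None = None, seed: int = 0) -> HaplotypeDataset:
    """Small deterministic datasets with analytically known properties.

    ``random``
        Seeded uniform 0/1 alleles (``n`` x ``s``); byte-identical on
        regeneration with the same seed.
    ``mirror``
        Derived and ancestral carriers of the centre SNP have identical
        haplotype structure on the flanks, so the unweighted raw score at
        the centre is exactly 0.
    ``identical-block``
        ``n_carriers`` sequences carry the derived centre allele and are
        identical over ``block`` flanking SNPs each side, so derived-allele
        EHH stays 1 across the block.
    ``duplicated-individual``
        A random dataset whose first row is duplicated (for
        uniqueness-monotonicity checks).
    """
    p = dict(params or {})
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7151]))
    cm_per_bp = p.pop("cm_per_bp", 1e-5)
    spacing = p.pop("spacing_bp", 1000)

    def _build(alleles):
        alleles = np.asarray(alleles, dtype=np.int8)
        pos = (np.arange(alleles.shape[1]) + 1) * spacing
        return HaplotypeDataset(
            alleles=alleles,
            physical_positions=pos,
            genetic_positions=pos * cm_per_bp,
            chromosome_id=f"fixture_{kind}",
        )

    if kind == "random":
        n, s = p.pop("n", 20), p.pop("s", 60)
        _check_no_extra(kind, p)
        return _build(rng.integers(0, 2, size=(n, s)))
    if kind == "mirror":
        half, s = p.pop("n_half", 10), p.pop("s", 41)
        _check_no_extra(kind, p)
        if s % 2 == 0:
            raise ValueError("mirror fixture needs an odd SNP count")
        flanks = rng.integers(0, 2, size=(half, s))
        alleles = np.vstack([flanks, flanks.copy()])
        alleles[:half, s // 2] = 1
        alleles[half:, s // 2] = 0
        return _build(alleles)
    if kind == "identical-block":
        n, s = p.pop("n", 20), p.pop("s", 61)
        n_carriers = p.pop("n_carriers", 8)
        block = p.pop("block", 10)
        _check_no_extra(kind, p)
        center = s // 2
        alleles = rng.integers(0, 2, size=(n, s))
        shared = rng.integers(0, 2, size=s)
        lo, hi = center - block, center + block + 1
        alleles[:n_carriers, lo:hi] = shared[lo:hi]
        alleles[:n_carriers, center] = 1
        alleles[n_carriers:, center] = 0
        return _build(alleles)
    if kind == "duplicated-individual":
        n, s = p.pop("n", 12), p.pop("s", 50)
        _check_no_extra(kind, p)
        base = rng.integers(0, 2, size=(n, s))
        return _build(np.vstack([base, base[:1]]))
    raise ValueError(f"unknown fixture kind {kind!r}")


def _check_no_extra(kind, p):
    if p:
        raise ValueError(f"unknown parameters for fixture {kind!r}: {sorted(p)}")
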