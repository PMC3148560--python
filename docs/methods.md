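# Methods

## The statistics

### EHH and its weighted form

For a biallelic core SNP at position *x* with ancestral/derived polarized
alleles, the extended haplotype homozygosity EHH(*x*, *y*) is the
probability that two sequences drawn from the carriers of the same core
allele are identical at every SNP between *x* and *y*.  With carriers
partitioned into haplotype-identity classes *h* over [*x*, *y*], the sample
version is Σ_h n_h(n_h−1) / (m(m−1)) for m carriers.

The weighted form corrects for unequal relatedness: each carrier *I* gets a
uniqueness weight U(*I*), and with W_h = Σ_{I∈h} U(I),

    wEHH(x, y) = (Σ_h W_h² − Σ_I U(I)²) / (m² − Σ_I U(I)²).

This is the weighted analogue of pair homozygosity: it equals the classical
sample EHH exactly at U ≡ 1, stays in [0, 1] for non-negative weights, and
is non-increasing as the interval grows (identity classes only refine).
That unit-weight identity is enforced by a brute-force pair-counting oracle
in the test suite and is the package's normative definition of wEHH.

### Uniqueness weights

Relatedness is summarized by a genome-wide squared Hamming distance matrix:
entry (i, j) is (h_ij / c_ij)² · L, with h_ij the count of differing
non-missing sites, c_ij the mutually non-missing site count and L the total
SNP count (so fully observed data give h²/L).  We normalize the Hamming
fraction before squaring; any other distance matrix can be supplied
instead.  For the carrier set X of one core allele, D̄(I) is carrier I's
mean distance to the other carriers and

    U(I) = m · D̄(I) / Σ_{J∈X} D̄(J),

so Σ U = m and only relative relatedness matters: the weights are invariant
to rescaling the distance matrix, equal weights reduce to the classical
statistic, and duplicating a sequence strictly lowers its weight.  Weights
are recomputed for each core allele's carrier set; the n×n matrix is
computed once.  If every carrier is genome-wide identical the weights fall
back to 1 with a warning.  A diploid mode collapses haplotype pairs to
0/1/2 dosages so both haplotypes of an individual share one weight.

### iHS / WiHS

The decay is walked SNP by SNP in both directions from the core, for the
ancestral and the derived allele separately, and truncated after the first
point below 0.05 (that crossing point is included in the last trapezoid; the
exact 0.05 crossing is not interpolated).  The decay is integrated over
genetic distance (cM) by the trapezoidal rule, directional integrals are
summed, and the raw score is ln(iwEHH_A / iwEHH_D) — negative when the
derived haplotype is longer (the sweep signature), positive when the
ancestral one is.  WiHS is identical except that both carrier sets use
their uniqueness weights; with a constant distance matrix WiHS and iHS are
bit-identical (tested).

Core sites require minor allele frequency ≥ 0.05, no missing calls, and at
least two carriers of each allele.  Within a decay walk, a missing call
splits its sequence into a singleton identity class (missing is never
identical to anything).

**Boundary handling.**  When a decay reaches the end of the scanned region
while still above 0.05, the scan integrates to the end and flags the score
`boundary_integrated` (a `missing` policy is selectable).  Integrate-to-end
is the default because small carrier sets have an EHH floor of 1/C(m,2),
which exceeds 0.05 for m ≤ 6 whenever one close haplotype pair survives: on
simulated 2-Mbp loci roughly half of all cores never cross the cutoff, and
discarding them would hollow out every windowed statistic.  Edge scores are
consequently attenuated; the frequency standardization absorbs most of the
shared attenuation.

No maximum-gap rule is applied by default (`max_gap_bp` exists but is off).

### Standardization

Raw log-ratios depend strongly on allele frequency (young, low-frequency
derived alleles sit on long haplotypes), so scores are standardized within
derived-allele-frequency classes: z = (raw − mean_f)/SD_f with the sample
(n−1) SD.  When all sites share one sample size (simulated data), classes
are exact derived-allele counts; otherwise 2%-frequency bins are used.
Classes with fewer than 20 defined scores merge with the nearest class.  A
zero-SD class marks its scores missing with a warning.  Undefined scores
(zero integrals) never enter the moments.

Two standardization scopes exist.  A single-dataset scan standardizes
against itself — appropriate for genome-wide empirical data and the
default everywhere.  The simulation harness can instead estimate the
moments once from its neutral null replicates (`standardization=
"reference"` / `FrequencyReference`): on short simulated loci the sweep
occupies a large fraction of the scanned SNPs and would otherwise shift its
own standardization moments.  The study defaults to per-dataset
standardization, which on full-size (2 Mbp, 4000 SNP) replicates matches
the behaviour described above.

### PHS

The pairwise haplotype sharing score is the O(n²) comparator.  For each
sequence pair (i, j), d_xij is the genetic length (cM) of the maximal
interval containing x over which the pair is identical on the SNP grid
(0 if they differ at x; missing counts as a mismatch), standardized per
pair by that pair's genome-wide mean and SD: Z_xij.  The score for allele
a at x is the mean Z over carrier pairs minus the mean Z over all pairs;
the derived-allele score is reported and then frequency-standardized like
the other statistics.  Pairs with zero tract-length variance (genome-wide
identical) contribute Z = 0 with a warning.  Operation counters record the
pair×site evaluations, which grow as C(n,2) — the quadratic cost that
motivates the linear-cost WiHS.

## Genetic maps

Physical→genetic conversion fits a least-squares polynomial (default
degree 3, configurable) to (bp, cM) anchor markers.  Downstream integration
requires non-decreasing genetic positions, so a fit whose derivative goes
negative anywhere on the anchored range is replaced by monotone
piecewise-linear interpolation of the anchors; outside the anchored range
the map extrapolates linearly from the boundary slope.  Simulated data use
a uniform map at 100·r cM/bp derived from ρ = 4Ne·r.

## The simulation study

### What is emulated

Replicates emulate a 2-Mbp locus sampled as 100 phased chromosomes with
θ = 6·10⁻³ and ρ = 8·10⁻⁴ per site (Ne = 1000) — rates in the range
reported for *A. thaliana* — with 4000 SNPs of MAF ≥ 0.05 drawn at random
from all segregating sites to mimic SNP-array density, and a single site
under positive selection (2Ns = 200 by default) at the locus midpoint whose
present-day derived frequency is conditioned into [0.6, 0.8] by rejection
sampling.  Four demographies are provided: panmictic; two islands with
4Nm ∈ {4, 40, 400} sampled 50/50; exponential growth (10× increase
beginning 0.1·2Ne generations ago, ancestral size Ne/10); and a bottleneck
to Ne/5 between 0.15 and 0.05·2Ne generations ago.  The growth and
bottleneck epoch parameters are approximate shapes, configurable in
`ScenarioSpec`, not calibrated to any external dataset.

The backend is msprime's structured-coalescent sweep model.  Samples are
haploid chromosomes; population sizes are passed as 2Ne lineages so that
the diploid scalings θ = 4Neμ, ρ = 4Ner and α = 2Ns hold exactly (neutral
diversity is verified against E[π] = θ in the tests).  Two backend-specific
choices follow from msprime's interface:

- the simulator does not report which samples carry the beneficial allele,
  so the causal site is proxied by the segregating site nearest the sweep
  position whose sample frequency lies in the target range (rejecting
  attempts with none within 25 kb) — a hitchhiker indistinguishable from
  the selected site for scan purposes;
- multi-deme sweeps are not supported, so island-model sweep replicates
  must be produced externally by an msms-compatible simulator and loaded
  through the ms-format reader; neutral island replicates run natively.

What this generator does *not* emulate: recombination-rate variation and
hotspots, recurrent mutation at the selected site, gene conversion,
genotyping error, ascertainment bias of real SNP arrays, and selfing.
Passing tests therefore demonstrate correctness of the statistics and
their documented behaviour under idealized coalescent conditions, not
performance on real data.

### Power, FDR, ranking

The windowed test statistic is the mean |standardized score| over ±25 SNPs
around a centre.  The null distribution takes one window at a uniformly
random SNP per neutral panmictic replicate; the detection cutoff is its
(1−α) empirical quantile.  Power is the fraction of sweep replicates whose
causal-centred window exceeds the cutoff.  FDR tiles each neutral
replicate of the focal demography with non-overlapping 51-SNP windows and
reports the fraction exceeding the panmictic cutoff — the two conventions
mirror the different denominators of the power and FDR summaries.
Causal ranks sort all scanned SNPs by |standardized score| (average ranks
on ties; an undefined causal score gets the midpoint convention (S+1)/2).
Empirical window p-values use the add-one estimator (1 + #{null ≥ obs}) /
(1 + #null).  All replication is driven by numpy `SeedSequence` spawning
from a single seed; every run is reproducible from (spec, seed).

### Problem sizes

Full-size replicates (2 Mbp / 4000 SNPs) cost seconds each, so the bundled
test suite and the acceptance script run the same pipeline at reduced
sizes chosen as the package's standard desk-scale configuration: 1-Mbp
loci with 2000 sampled SNPs for sweep-signal comparisons (ranks, paired
score differences, power in 2Ns, FDR), and 400-kbp loci with 800 SNPs for
neutral self-calibration, with tens to hundreds of replicates.  At these
sizes the sweep footprint occupies a larger fraction of the locus than at
full size, which attenuates rank contrasts; the tests assert directions,
orderings and calibration rather than the full-size point values.

Two further conventions matter at reduced sizes.  The FDR comparison in
the tests and the acceptance script uses the convention-matched cutoff
(`fdr_cutoff="matched"`; see `power_fdr_study`): the random-mid-locus
power null does not see edge-attenuated windows, and against it even the
panmictic tiled false-positive rate sits well below the nominal level,
hiding the small demographic inflation of interest.  And sweeps combined
with growth or bottleneck demographies are conditioned — via the rejection
loop, because the backend cannot process a demographic event during the
sweep phase — on the sweep completing within the most recent epoch; sweep
start time is reported elsewhere to have no measurable effect on
detection power, and the epoch times remain configurable.

## Numerical choices

- Trapezoidal integration on cM coordinates; a zero-width (constant) map
  integrates to 0 and yields undefined scores.
- wEHH values are clamped to [0, 1] against floating-point round-off.
- `uniqueness` returns exactly 1.0 for every carrier when all D̄ are equal,
  making the constant-matrix reduction to the unweighted statistic
  bit-exact rather than accurate to round-off.
- Rank ties use average ranks throughout.
- ms-format positions colliding after bp scaling are jittered +1 bp
  deterministically left to right.
- The identity-class walk is a numba-compiled kernel (O(m) per SNP step);
  PHS tract lengths use per-pair mismatch indices and binary search.

## Known limitations

- The PHS comparator implemented here follows the package's normative
  definition above; published PHS analyses differ in unprinted details
  (tract definition at array boundaries, standardization scope), and on
  these simulations this PHS ranks causal sites better than its reputation
  in parts of the literature suggests.  Comparisons across publications
  should treat PHS results as implementation-specific.
- Island-model sweeps require an external msms-compatible simulator.
- Ancestral polarization is annotation-based only (e.g. INFO/AA);
  alignment-based polarization against an outgroup genome is out of scope.
- Phasing, imputation and liftover are out of scope; input haplotypes must
  be phased.
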