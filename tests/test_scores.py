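import numpy as np
import pytest

from conftest import random_dataset
from tests_util_oracles import brute_force_phs
from wihs import scores as sc
from wihs.haplodata import HaplotypeDataset
from wihs.scores import SNPScore
from wihs.simstudy import make_fixture
from wihs.weights import DistanceMatrix, squared_hamming_matrix


def _snp(i, raw, count=50, freq=None, n=100):
    return SNPScore(
        snp_index=i, physical_position=(i + 1) * 100,
        derived_freq=count / n if freq is None else freq,
        derived_count=count, raw=raw,
        status="ok" if np.isfinite(raw) else "undefined",
    )


class TestIhsScan:
    def test_mirror_fixture_scores_zero_at_center(self):
        ds = make_fixture("mirror", {"n_half": 8, "s": 21}, seed=3)
        out = sc.ihs_scan(ds)
        center = next(s for s in out if s.snp_index == 10)
        assert center.raw == pytest.approx(0.0, abs=1e-12)

    def test_all_rare_snps_give_empty_scan(self, rng):
        alleles = np.zeros((25, 5), dtype=np.int8)
        alleles[0] = 1  # every SNP at derived frequency 1/25 < 0.05
        pos = (np.arange(5) + 1) * 100
        ds = HaplotypeDataset(alleles, pos, genetic_positions=pos * 1e-5)
        assert sc.ihs_scan(ds) == []

    def test_matches_straight_line_reimplementation(self, rng):
        from tests_util_oracles import brute_force_ehh

        ds = random_dataset(rng, n=14, s=30)
        out = sc.ihs_scan(ds, boundary="integrate")
        for s in out[:6]:
            # direct recomputation: walk both alleles with the pair-counting
            # oracle, trapezoid by hand, take the log-ratio
            areas = {}
            for allele in (0, 1):
                total = 0.0
                for direction in (-1, 1):
                    xs, ys = [0.0], [1.0]
                    y = s.snp_index
                    while 0 <= y + direction <= ds.n_snps - 1:
                        y += direction
                        val = brute_force_ehh(ds.alleles, s.snp_index, allele, y)
                        xs.append(abs(ds.genetic_positions[y]
                                      - ds.genetic_positions[s.snp_index]))
                        ys.append(val)
                        if val < 0.05:
                            break
                    below = [i for i, v in enumerate(ys) if v < 0.05]
                    stop = below[0] + 1 if below else len(ys)
                    total += np.trapezoid(ys[:stop], xs[:stop])
                areas[allele] = total
            if areas[0] > 0 and areas[1] > 0:
                assert s.raw == pytest.approx(np.log(areas[0] / areas[1]), abs=1e-10)

    def test_reversing_snp_order_preserves_scores(self, rng):
        ds = random_dataset(rng, n=12, s=40)
        rev = HaplotypeDataset(
            ds.alleles[:, ::-1],
            np.sort(ds.physical_positions.max() - ds.physical_positions + 1),
            genetic_positions=np.sort(
                ds.genetic_positions.max() - ds.genetic_positions
            ),
        )
        a = {s.snp_index: s.raw for s in sc.ihs_scan(ds)}
        b = {39 - s.snp_index: s.raw for s in sc.ihs_scan(rev)}
        assert set(a) == set(b)
        for k in a:
            assert (np.isnan(a[k]) and np.isnan(b[k])) or a[k] == pytest.approx(b[k], abs=1e-12)


class TestWihsScan:
    def test_constant_distance_matrix_is_bit_identical_to_ihs(self, rng):
        ds = random_dataset(rng, n=16, s=40)
        dm = DistanceMatrix.constant(16, value=2.5)
        a = sc.ihs_scan(ds)
        b = sc.wihs_scan(ds, dm)
        assert len(a) == len(b) > 0
        for x, y in zip(a, b):
            for f in ("raw", "standardized", "iwehh_a", "iwehh_d"):
                xa, ya = getattr(x, f), getattr(y, f)
                assert (np.isnan(xa) and np.isnan(ya)) or xa == ya

    def test_scaling_distance_matrix_changes_nothing(self, rng):
        ds = random_dataset(rng, n=12, s=35)
        dm = squared_hamming_matrix(ds)
        dm10 = DistanceMatrix(values=dm.values * 10, sites_compared=dm.sites_compared)
        a = sc.wihs_scan(ds, dm)
        b = sc.wihs_scan(ds, dm10)
        for x, y in zip(a, b):
            assert (np.isnan(x.raw) and np.isnan(y.raw)) or x.raw == pytest.approx(
                y.raw, rel=1e-12
            )

    def test_near_duplicate_clade_shifts_score_as_downweighting_predicts(self):
        # derived carriers: 5 copies of one haplotype + 1 recombinant;
        # the clade is genome-wide self-identical, the recombinant distant.
        # Down-weighting the clade lowers wEHH_D, shrinking iwEHH_D and
        # pushing the raw score upward relative to unweighted iHS.
        rng = np.random.default_rng(5)
        s_count = 41
        others = rng.integers(0, 2, size=(10, s_count)).astype(np.int8)
        clade = np.tile(rng.integers(0, 2, size=s_count).astype(np.int8), (5, 1))
        recomb = np.concatenate([others[0, :20], clade[0, 20:]]).astype(np.int8)
        alleles = np.vstack([clade, recomb, others])
        core = 20
        alleles[:6, core] = 1
        alleles[6:, core] = 0
        pos = (np.arange(s_count) + 1) * 1000
        ds = HaplotypeDataset(alleles, pos, genetic_positions=pos * 1e-5)
        dm = squared_hamming_matrix(ds)
        ihs_raw = {s.snp_index: s.raw for s in sc.ihs_scan(ds)}[core]
        wihs_raw = {s.snp_index: s.raw for s in sc.wihs_scan(ds, dm)}[core]
        assert wihs_raw > ihs_raw

    def test_dimension_mismatch_is_an_error(self, rng):
        ds = random_dataset(rng, n=10, s=20)
        with pytest.raises(ValueError, match="distance matrix"):
            sc.wihs_scan(ds, DistanceMatrix.constant(9))


class TestStandardize:
    def test_populated_bins_have_zero_mean_unit_sd(self, rng):
        import collections

        # counts drawn from a few well-populated classes: no merging occurs,
        # so each derived count is its own bin
        counts = rng.choice([10, 30, 50, 70, 90], size=300)
        scores = [
            _snp(i, rng.normal(loc=cnt / 10), count=int(cnt))
            for i, cnt in enumerate(counts)
        ]
        out = sc.standardize(scores, binning="count", min_bin_count=20)
        bins = collections.defaultdict(list)
        for s in out:
            assert np.isfinite(s.standardized)
            bins[s.derived_count].append(s.standardized)
        for z in bins.values():
            z = np.array(z)
            assert z.mean() == pytest.approx(0.0, abs=1e-9)
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_two_score_bin_sample_sd(self):
        scores = [_snp(0, 1.0, count=30), _snp(1, 3.0, count=30)]
        out = sc.standardize(scores, binning="count", min_bin_count=1)
        z = sorted(s.standardized for s in out)
        assert z == pytest.approx([-np.sqrt(0.5), np.sqrt(0.5)])

    def test_location_shift_invariance(self, rng):
        raws = rng.normal(size=100)
        counts = rng.integers(5, 95, size=100)
        a = sc.standardize([_snp(i, r, count=c) for i, (r, c) in enumerate(zip(raws, counts))])
        b = sc.standardize(
            [_snp(i, r + 7.5, count=c) for i, (r, c) in enumerate(zip(raws, counts))]
        )
        for x, y in zip(a, b):
            assert x.standardized == pytest.approx(y.standardized, abs=1e-9)

    def test_small_bins_merge_with_nearest(self, rng):
        # counts 10 and 11 individually below min_bin_count merge together
        scores = [_snp(i, rng.normal(), count=10) for i in range(12)]
        scores += [_snp(i + 12, rng.normal(), count=11) for i in range(12)]
        out = sc.standardize(scores, binning="count", min_bin_count=20)
        z = np.array([s.standardized for s in out])
        assert np.isfinite(z).all()
        assert z.mean() == pytest.approx(0.0, abs=1e-9)

    def test_zero_sd_bin_marked_missing(self):
        scores = [_snp(i, 2.0, count=40) for i in range(25)]
        with pytest.warns(UserWarning, match="zero SD"):
            out = sc.standardize(scores, binning="count")
        assert all(not np.isfinite(s.standardized) for s in out)
        assert all(s.status == "zero_sd_bin" for s in out)


class TestFrequencyReference:
    def test_reference_moments_reproduce_dataset_standardization(self, rng):
        scores = [_snp(i, rng.normal(), count=50) for i in range(40)]
        ref = sc.FrequencyReference.from_scans(scores)
        out = ref.apply(scores)
        raws = np.array([s.raw for s in scores])
        expect = (raws - raws.mean()) / raws.std(ddof=1)
        assert [s.standardized for s in out] == pytest.approx(expect)

    def test_sparse_counts_widen_neighbourhood(self, rng):
        scores = [_snp(i, rng.normal(), count=49 + (i % 3)) for i in range(60)]
        ref = sc.FrequencyReference.from_scans(scores, min_bin_count=100)
        mu, sd = ref.moments(50)
        raws = np.array([s.raw for s in scores])
        assert mu == pytest.approx(raws.mean())

    def test_undefined_raw_stays_undefined(self):
        scores = [_snp(i, float(i), count=50) for i in range(30)] + [
            _snp(30, np.nan, count=50)
        ]
        out = sc.FrequencyReference.from_scans(scores).apply(scores)
        assert np.isnan(out[-1].standardized)


class TestPhsScan:
    def test_all_identical_haplotypes_give_no_signal(self):
        # every pair identical genome-wide: all tract lengths equal, every
        # pair's Z is zeroed (with a warning) and no site is a valid core
        alleles = np.tile([0, 1, 0, 1, 1], (6, 1)).astype(np.int8)
        pos = (np.arange(5) + 1) * 100
        ds = HaplotypeDataset(alleles, pos, genetic_positions=pos * 1e-4)
        with pytest.warns(UserWarning, match="zero tract-length"):
            out = sc.phs_scan(ds)
        assert out == []

    def test_duplicated_pairs_zeroed_not_nan(self, rng):
        ds = random_dataset(rng, n=6, s=20)
        dup = HaplotypeDataset(
            np.vstack([ds.alleles, ds.alleles[:1]]), ds.physical_positions,
            genetic_positions=ds.genetic_positions,
        )
        with pytest.warns(UserWarning, match="zero tract-length"):
            out = sc.phs_scan(dup)
        assert all(np.isfinite(s.raw) for s in out)

    def test_matches_direct_summation_oracle(self, rng):
        ds = random_dataset(rng, n=8, s=25)
        out = sc.phs_scan(ds)
        for s in out[::3]:
            expect = brute_force_phs(
                ds.alleles, ds.genetic_positions, s.snp_index, 1
            )
            assert s.raw == pytest.approx(expect, abs=1e-10)

    def test_shared_segment_scores_positive(self):
        ds = make_fixture("identical-block", {"n": 20, "s": 41, "n_carriers": 8,
                                              "block": 12}, seed=9)
        out = sc.phs_scan(ds)
        center = next(s for s in out if s.snp_index == 20)
        assert center.raw > 0

    def test_pair_evaluations_grow_quadratically(self, rng):
        ds = random_dataset(rng, n=10, s=30)
        doubled = HaplotypeDataset(
            np.vstack([ds.alleles, ds.alleles]), ds.physical_positions,
            genetic_positions=ds.genetic_positions,
        )
        c1, c2 = {}, {}
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.phs_scan(ds, counters=c1)
            sc.phs_scan(doubled, counters=c2)
        ratio = c2["pair_site_evals"] / c1["pair_site_evals"]
        assert ratio == pytest.approx((20 * 19) / (10 * 9), rel=1e-9)


class TestWindows:
    def _scores(self, values):
        out = []
        for i, v in enumerate(values):
            s = _snp(i, v, count=50)
            s.standardized = v
            out.append(s)
        return out

    def test_constant_scores_give_constant_windows(self):
        scores = self._scores([1.0] * 100)
        w = sc.window_average(scores, 50, half_width=25, n_snps=100)
        assert w.mean_abs_score == 1.0

    def test_mid_chromosome_window_has_51_snps(self):
        scores = self._scores(np.arange(200.0))
        w = sc.window_average(scores, 100, half_width=25, n_snps=200)
        assert w.n_defined == 51
        assert w.stop - w.start == 51

    def test_window_clipped_at_edge(self):
        scores = self._scores(np.ones(200))
        w = sc.window_average(scores, 10, half_width=25, n_snps=200)
        assert w.stop - w.start == 36
        assert w.n_defined == 36

    def test_no_defined_scores_flagged(self):
        scores = self._scores([np.nan] * 60)
        for s in scores:
            s.standardized = np.nan
        w = sc.window_average(scores, 30, 25, n_snps=60)
        assert not w.defined and w.n_defined == 0

    def test_sliding_starts(self):
        scores = self._scores(np.ones(100))
        ws = sc.sliding_windows(scores, window_size=50, offset=20, n_snps=100)
        assert [w.start for w in ws] == [0, 20, 40]
        assert all(w.mean_abs_score == 1.0 for w in ws)

    def test_non_overlapping_tiling(self):
        scores = self._scores(np.ones(150))
        ws = sc.sliding_windows(scores, window_size=50, offset=50, n_snps=150)
        assert [(w.start, w.stop) for w in ws] == [(0, 50), (50, 100), (100, 150)]

    def test_short_tail_merges_into_previous(self):
        scores = self._scores(np.ones(120))
        ws = sc.sliding_windows(scores, window_size=50, offset=50, n_snps=120)
        # tail of 20 < 25 merges into the previous window
        assert [(w.start, w.stop) for w in ws] == [(0, 50), (50, 120)]


class TestEmpiricalSignificance:
    def _windows(self, values):
        return [
            sc.WindowScore(start=i, stop=i + 50, mean_abs_score=v, n_defined=50)
            for i, v in enumerate(values)
        ]

    def test_observation_below_all_nulls(self):
        ws = sc.empirical_significance(self._windows([0.1]), np.arange(1, 100), 0.05)
        assert ws[0].empirical_p == 1.0
        assert ws[0].significant is False

    def test_observation_above_1000_nulls(self):
        null = np.linspace(0, 1, 1000)
        ws = sc.empirical_significance(self._windows([2.0]), null, 0.01)
        assert ws[0].empirical_p == pytest.approx(1 / 1001)
        assert ws[0].significant is True

    def test_ranks_descending_with_average_ties(self):
        ws = sc.empirical_significance(
            self._windows([3.0, 1.0, 3.0, 0.5]), [0.1, 0.2], 0.05
        )
        assert [w.rank for w in ws] == [1.5, 3.0, 1.5, 4.0]

    def test_calibration_on_null_draws(self, rng):
        null = rng.normal(size=2000)
        obs = rng.normal(size=2000)
        ws = sc.empirical_significance(self._windows(obs), null, 0.05)
        rate = np.mean([w.significant for w in ws])
        # binomial(2000, 0.05) 99.9% interval
        assert 0.03 < rate < 0.07
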