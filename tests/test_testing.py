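import numpy as np
import pytest

from peakshape.errors import (
    InvalidInputError,
    NormalizationError,
    UntestableBinError,
)
from peakshape.testing import (
    TestParams,
    bh_adjust,
    bin_peaks_by_counts,
    compute_size_factors,
    empirical_pvalue,
    results_to_frame,
    run_shape_test,
)


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        c = np.array([[10, 10], [25, 25], [3, 3]])
        assert compute_size_factors(c) == pytest.approx([1.0, 1.0])

    def test_doubled_depth_splits_symmetrically(self):
        a = np.array([13, 40, 7, 100])
        c = np.column_stack([a, 2 * a])
        # ratios to the geometric mean sqrt(2)*a are 1/sqrt(2) and sqrt(2)
        assert compute_size_factors(c) == pytest.approx(
            [1 / np.sqrt(2), np.sqrt(2)]
        )

    def test_matches_naive_loop_oracle(self, rng):
        counts = rng.poisson(40, size=(50, 3)).astype(float)
        counts[rng.random((50, 3)) < 0.1] = 0  # some zeros
        expected = []
        rows = [r for r in counts if all(v > 0 for v in r)]
        for s in range(3):
            ratios = []
            for r in rows:
                geo = np.prod(r) ** (1.0 / len(r))
                ratios.append(r[s] / geo)
            expected.append(np.median(ratios))
        assert compute_size_factors(counts) == pytest.approx(expected)

    def test_no_common_peak_raises(self):
        with pytest.raises(NormalizationError):
            compute_size_factors(np.array([[0, 5], [5, 0]]))


class TestCountBinning:
    def test_equal_occupancy_quartiles(self, rng):
        x = rng.permutation(np.arange(100, dtype=float))
        bins = bin_peaks_by_counts(x, n_bins=4, min_per_bin=10)
        assert np.bincount(bins).tolist() == [25, 25, 25, 25]
        # bins ordered by count value
        assert (np.argsort([x[bins == b].mean() for b in range(4)]) == range(4)).all()

    def test_all_equal_counts_collapse_to_one_bin(self):
        assert (bin_peaks_by_counts(np.full(200, 7.0), 4, min_per_bin=10) == 0).all()

    def test_sparse_bins_merge_to_min_occupancy(self, rng):
        x = rng.lognormal(5, 1, 1000)
        bins = bin_peaks_by_counts(x, n_bins=20, min_per_bin=100)
        occ = np.bincount(bins)
        assert occ.size <= 10
        assert (occ >= 100).all()
        assert occ.sum() == 1000

    def test_fewer_peaks_than_min_per_bin_gives_single_bin(self):
        assert (bin_peaks_by_counts(np.arange(9.0), 4, min_per_bin=50) == 0).all()


class TestEmpiricalPvalue:
    def test_plain_fraction(self):
        null = [0.1, 0.2, 0.3]
        assert empirical_pvalue(0.25, null) == pytest.approx(1 / 3)
        assert empirical_pvalue(0.05, null) == 1.0
        assert empirical_pvalue(0.9, null) == 0.0  # exceeds every null

    def test_add_one_smoothing(self):
        null99 = np.linspace(0.01, 0.99, 99)
        assert empirical_pvalue(2.0, null99, smoothing="add_one") == pytest.approx(0.01)
        assert empirical_pvalue(0.0, null99, smoothing="add_one") == 1.0
        assert empirical_pvalue(
            0.25, [0.1, 0.2, 0.3], smoothing="add_one"
        ) == pytest.approx(0.5)

    def test_empty_null_raises(self):
        with pytest.raises(UntestableBinError):
            empirical_pvalue(0.5, [])


def reference_bh(p):
    """Independent step-up oracle: sort, cumulative minima from the top."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    best = np.inf
    for rank in range(m, 0, -1):
        best = min(best, m * p[order[rank - 1]] / rank)
        q[order[rank - 1]] = min(best, 1.0)
    return q


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.25], [0.25]),
            ([0.005, 0.1], [0.01, 0.1]),
        ],
    )
    def test_hand_computed_step_up(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_matches_independent_oracle_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.random(rng.integers(1, 40))
            assert np.array_equal(bh_adjust(p), reference_bh(p))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(25):
            p = rng.random(200)
            expected = multipletests(p, method="fdr_bh")[1]
            assert bh_adjust(p) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_p_ranking(self, rng):
        p = rng.random(500)
        q = bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()
        assert ((q > 0) & (q <= 1)).all()

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(InvalidInputError):
            bh_adjust([0.5, 1.5])


class TestRunShapeTest:
    def test_copied_conditions_yield_no_signal(self, small_experiment):
        """When treatment reads are literal copies of control reads, each
        matched between-group pair has MMD 0 and the cross pairs coincide
        with the replicate null, so nothing is ever called."""
        exp = small_experiment
        regions = exp.regions[:80]
        from peakshape.design import ExperimentDesign
        from peakshape.io import InMemoryReadSource

        c1 = exp.reads["control_rep1"]
        c2 = exp.reads["control_rep2"]
        sources = {
            "c_rep1": InMemoryReadSource(c1),
            "c_rep2": InMemoryReadSource(c2),
            "t_rep1": InMemoryReadSource(c1),  # verbatim copies
            "t_rep2": InMemoryReadSource(c2),
        }
        design = ExperimentDesign(
            samples=[("c_rep1", "ctl", None), ("c_rep2", "ctl", None),
                     ("t_rep1", "trt", None), ("t_rep2", "trt", None)],
            contrast=("ctl", "trt"),
            null_pairs=[("c_rep1", "c_rep2"), ("t_rep1", "t_rep2")],
        )
        results = run_shape_test(regions, sources, design, TestParams(seed=3))
        tested = [r for r in results if r.status == "tested"]
        assert tested
        # matched copies: the between statistic is half the replicate distance
        # it duplicates, so it can never exceed the peak's own null values
        assert all(r.stat_between <= r.stats_within.max() for r in tested)
        assert all(r.p_empirical > 0.0 for r in tested)
        assert all(r.q_bh > 0.5 for r in tested)

    def test_pipeline_is_deterministic(self, small_experiment):
        exp = small_experiment
        regions = exp.regions[:60]
        kwargs = dict(
            read_sources=exp.read_sources(), design=exp.design,
            params=TestParams(seed=11),
        )
        f1 = results_to_frame(run_shape_test(regions, **kwargs))
        f2 = results_to_frame(run_shape_test(regions, **kwargs))
        assert f1.equals(f2)

    def test_low_coverage_peaks_are_skipped_not_tested(self, small_experiment):
        exp = small_experiment
        regions = exp.regions[:60]
        params = TestParams(seed=1, min_reads=10_000)  # nothing passes
        results = run_shape_test(regions, exp.read_sources(), exp.design, params)
        assert all(r.status == "skipped_low_coverage" for r in results)
        assert all(np.isnan(r.q_bh) for r in results)

    def test_matched_statistic_is_calibrated_under_global_null(self):
        """With the disjoint-matching statistic and per-peak-mean nulls the
        between- and within-group means are exchangeable under the global
        null, so empirical p-values are near-uniform and few peaks reach
        q < 0.05."""
        from peakshape.simulate import SimConfig, simulate_experiment

        cfg = SimConfig(n_peaks=2000, n_affinity_changes=0, n_profile_changes=0)
        exp = simulate_experiment(cfg, repetition_seed=21)
        results = run_shape_test(
            exp.regions, exp.read_sources(), exp.design,
            TestParams(seed=21, statistic="matched_pairs"),
        )
        p = np.array([r.p_empirical for r in results if r.status == "tested"])
        q = np.array([r.q_bh for r in results if r.status == "tested"])
        grid = np.sort(p)
        n = p.size
        ks = max(
            np.max(np.arange(1, n + 1) / n - grid),
            np.max(grid - np.arange(0, n) / n),
        )
        assert ks < 0.05
        assert (q < 0.05).mean() <= 0.05

    def test_within_group_mmd_decreases_with_coverage(self, small_experiment):
        """Replicate (null) MMDs shrink with mean counts: the median of the
        within-group MMD over count deciles is non-increasing overall."""
        exp = small_experiment
        results = run_shape_test(
            exp.regions, exp.read_sources(), exp.design, TestParams(seed=2)
        )
        unchanged = set(exp.truth.peaks.index[exp.truth.labels == "unchanged"])
        tested = [
            r for r in results if r.status == "tested" and r.peak_id in unchanged
        ]
        counts = np.array([np.mean(list(r.counts.values())) for r in tested])
        within = np.array([r.stats_within.mean() for r in tested])
        edges = np.quantile(counts, np.linspace(0, 1, 6))
        idx = np.clip(np.searchsorted(edges, counts, side="right") - 1, 0, 4)
        medians = [np.median(within[idx == g]) for g in range(5) if (idx == g).any()]
        # per-quintile medians decline monotonically with coverage
        assert medians[-1] < 0.7 * medians[0]
        assert (np.diff(medians) <= 1e-12).all()
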