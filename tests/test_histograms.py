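import numpy as np
import pytest

from peakshape.errors import DegenerateSampleError, InvalidInputError
from peakshape.histograms import (
    PeakHistogram,
    gmd_distance,
    gmd_matrix,
    histogram_from_reads,
)


def lp_transport_oracle(mass_a, mass_b, centers):
    """Brute-force transportation LP: minimal cost moving mass_a to mass_b."""
    from scipy.optimize import linprog

    n = len(centers)
    cost = np.abs(np.subtract.outer(centers, centers)).ravel()
    a_eq = []
    for i in range(n):  # row sums = mass_a
        row = np.zeros((n, n))
        row[i, :] = 1
        a_eq.append(row.ravel())
    for j in range(n):  # column sums = mass_b
        col = np.zeros((n, n))
        col[:, j] = 1
        a_eq.append(col.ravel())
    res = linprog(cost, A_eq=np.array(a_eq), b_eq=np.r_[mass_a, mass_b],
                  bounds=(0, None), method="highs")
    assert res.success
    return res.fun


def random_histogram(rng, n_bins=12, bin_width=20.0):
    mass = rng.random(n_bins)
    mass /= mass.sum()
    edges = np.arange(n_bins + 1) * bin_width
    return PeakHistogram(bin_width, edges, mass)


class TestHistogramFromReads:
    def test_point_mass(self):
        h = histogram_from_reads(np.zeros(10), region_length=200, bin_width=20)
        assert h.n_bins == 10
        assert h.masses[0] == 1.0
        assert h.masses[1:].sum() == 0.0

    def test_uniform_over_bin_centers(self):
        reads = np.repeat([10.0, 30.0, 50.0, 70.0], 5)
        h = histogram_from_reads(reads, region_length=80, bin_width=20)
        assert h.masses == pytest.approx([0.25] * 4)

    def test_edge_positions_fall_in_left_closed_bin(self):
        h = histogram_from_reads([20.0], region_length=40, bin_width=20)
        assert h.masses.tolist() == [0.0, 1.0]

    def test_matches_per_read_loop_oracle(self, rng):
        reads = rng.uniform(0, 500, 137)
        h = histogram_from_reads(reads, region_length=500, bin_width=20)
        counts = [0] * h.n_bins
        for r in reads:
            counts[min(int(r // 20), h.n_bins - 1)] += 1
        assert h.masses == pytest.approx(np.array(counts) / len(reads))

    def test_empty_sample_rejected(self):
        with pytest.raises(DegenerateSampleError):
            histogram_from_reads([], region_length=100)


class TestGmdDistance:
    def test_identical_histograms_give_zero(self, rng):
        h = random_histogram(rng)
        assert gmd_distance(h, h) == 0.0

    def test_point_masses_transport_by_center_distance(self):
        edges = np.arange(6) * 20.0
        for i, j in [(0, 3), (1, 4), (2, 2)]:
            a = np.zeros(5); a[i] = 1.0
            b = np.zeros(5); b[j] = 1.0
            d = gmd_distance(PeakHistogram(20.0, edges, a), PeakHistogram(20.0, edges, b))
            assert d == pytest.approx(abs(i - j) * 20.0)

    def test_matches_transportation_lp_oracle(self, rng):
        for _ in range(10):
            h_a = random_histogram(rng)
            h_b = random_histogram(rng)
            expected = lp_transport_oracle(h_a.masses, h_b.masses, h_a.bin_centers)
            assert gmd_distance(h_a, h_b) == pytest.approx(expected, abs=1e-8)

    def test_matches_scipy_wasserstein(self, rng):
        from scipy.stats import wasserstein_distance

        h_a = random_histogram(rng)
        h_b = random_histogram(rng)
        expected = wasserstein_distance(
            h_a.bin_centers, h_b.bin_centers, h_a.masses, h_b.masses
        )
        assert gmd_distance(h_a, h_b) == pytest.approx(expected, abs=1e-10)

    def test_metric_properties_on_random_triples(self, rng):
        for _ in range(25):
            a, b, c = (random_histogram(rng) for _ in range(3))
            dab, dba = gmd_distance(a, b), gmd_distance(b, a)
            assert dab >= 0 and dab == pytest.approx(dba, abs=1e-12)
            assert gmd_distance(a, c) <= dab + gmd_distance(b, c) + 1e-8

    def test_shift_by_k_bins_moves_mass_by_k_bin_widths(self):
        edges = np.arange(13) * 20.0
        mass = np.zeros(12); mass[1] = 0.6; mass[2] = 0.4
        for k in (3, 5):
            shifted = np.roll(mass, k)
            d = gmd_distance(PeakHistogram(20.0, edges, mass),
                             PeakHistogram(20.0, edges, shifted))
            assert d == pytest.approx(k * 20.0)

    def test_mismatched_grids_rejected(self, rng):
        h_a = random_histogram(rng, n_bins=12)
        h_b = random_histogram(rng, n_bins=10)
        with pytest.raises(InvalidInputError):
            gmd_distance(h_a, h_b)

    def test_gmd_matrix_consistent_with_pairwise_calls(self, rng):
        arrays = [rng.uniform(0, 400, rng.integers(10, 80)) for _ in range(4)]
        M = gmd_matrix(arrays, region_length=400, bin_width=20)
        hists = [histogram_from_reads(a, 400, 20) for a in arrays]
        for i in range(4):
            for j in range(4):
                expected = gmd_distance(hists[i], hists[j]) if i != j else 0.0
                assert M[i, j] == pytest.approx(expected, abs=1e-12)


class TestGmdPipeline:
    def test_copied_conditions_never_called(self, small_experiment):
        from peakshape.design import ExperimentDesign
        from peakshape.histograms import run_gmd_test
        from peakshape.io import InMemoryReadSource
        from peakshape.testing import TestParams

        exp = small_experiment
        regions = exp.regions[:80]
        c1, c2 = exp.reads["control_rep1"], exp.reads["control_rep2"]
        sources = {"a1": InMemoryReadSource(c1), "a2": InMemoryReadSource(c2),
                   "b1": InMemoryReadSource(c1), "b2": InMemoryReadSource(c2)}
        design = ExperimentDesign(
            samples=[("a1", "A", None), ("a2", "A", None),
                     ("b1", "B", None), ("b2", "B", None)],
            contrast=("A", "B"),
            null_pairs=[("a1", "a2"), ("b1", "b2")],
        )
        results = run_gmd_test(regions, sources, design, TestParams(seed=3))
        tested = [r for r in results if r.status == "tested"]
        assert tested
        assert all(np.isnan(r.sigma) for r in tested)  # no kernel bandwidth used
        assert all(r.q_bh > 0.5 for r in tested)

    def test_detects_planted_profile_changes(self, small_experiment):
        from peakshape.histograms import run_gmd_test
        from peakshape.metrics import evaluate_calls
        from peakshape.testing import TestParams, results_to_frame

        exp = small_experiment
        results = run_gmd_test(exp.regions, exp.read_sources(), exp.design,
                               TestParams(seed=5))
        frame = results_to_frame(results, stat_name="gmd")
        m = evaluate_calls(frame["q"].to_numpy(), 0.05, exp.truth.labels, "profile",
                           p_values=frame["p"].to_numpy(),
                           statistics=frame["gmd"].to_numpy())
        assert m["auROC"] > 75.0
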