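import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bmecv import (
    ThetaScanRecord,
    ThetaScanResult,
    ValidationError,
    WeightVector,
    align_by_tags,
    default_theta_grid,
    lag1_autocorrelation,
    mean_distribution_distance,
    refit_full_ensemble,
    runs_test,
    select_theta,
    split_interleaved,
    theta_scan,
    uniform_weights,
    wasserstein_weighted,
)
from conftest import make_matrix, make_targets
from oracles import (
    cdf_integral_wasserstein,
    runs_distribution_enumeration,
    wasserstein_sorted_oracle,
)


class TestSplitInterleaved:
    def test_odd_even_rule(self):
        s = split_interleaved(6)
        assert list(s.train) == [1, 3, 5]
        assert list(s.validation) == [2, 4, 6]

    def test_odd_count(self):
        s = split_interleaved(5)
        assert list(s.train) == [1, 3, 5]
        assert list(s.validation) == [2, 4]

    def test_too_few_frames(self):
        with pytest.raises(ValidationError):
            split_interleaved(3)

    def test_zero_based_views(self):
        s = split_interleaved(4)
        assert list(s.train0) == [0, 2]
        assert list(s.validation0) == [1, 3]


class TestWassersteinWeighted:
    def test_identity(self):
        v = np.array([1.0, 2.0, 3.0])
        w = uniform_weights(3)
        assert wasserstein_weighted(v, w, v, w) == 0.0

    def test_point_mass_translation(self):
        a = np.array([0.0])
        b = np.array([3.0])
        w = uniform_weights(1)
        assert wasserstein_weighted(a, w, b, w) == pytest.approx(3.0)

    def test_cdf_hand_example(self):
        v = np.array([0.0, 1.0])
        wu = uniform_weights(2)
        wb = WeightVector(np.array([0.25, 0.75]))
        assert wasserstein_weighted(v, wu, v, wb) == pytest.approx(0.25, abs=1e-12)

    @given(st.integers(2, 30), st.randoms(use_true_random=False))
    @settings(max_examples=40, deadline=None)
    def test_equal_weight_sorted_oracle(self, n, pyrandom):
        rng = np.random.default_rng(pyrandom.randrange(2**32))
        a = rng.normal(0, 2, n)
        b = rng.normal(1, 1, n)
        w = uniform_weights(n)
        got = wasserstein_weighted(a, w, b, w)
        assert got == pytest.approx(wasserstein_sorted_oracle(a, b), abs=1e-10)

    @given(st.integers(2, 12), st.randoms(use_true_random=False))
    @settings(max_examples=30, deadline=None)
    def test_against_cdf_integral_oracle(self, n, pyrandom):
        rng = np.random.default_rng(pyrandom.randrange(2**32))
        a = rng.normal(0, 1, n)
        b = rng.normal(0, 1, n + 1)
        wa = rng.random(n) + 0.01
        wa /= wa.sum()
        wb = rng.random(n + 1) + 0.01
        wb /= wb.sum()
        got = wasserstein_weighted(a, WeightVector(wa), b, WeightVector(wb))
        want = cdf_integral_wasserstein(a, wa, b, wb)
        assert got == pytest.approx(want, abs=1e-10)

    def test_metric_axioms_random_triples(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            xs = [rng.normal(0, 1, rng.integers(2, 10)) for _ in range(3)]
            ws = [uniform_weights(len(x)) for x in xs]
            d01 = wasserstein_weighted(xs[0], ws[0], xs[1], ws[1])
            d10 = wasserstein_weighted(xs[1], ws[1], xs[0], ws[0])
            d02 = wasserstein_weighted(xs[0], ws[0], xs[2], ws[2])
            d12 = wasserstein_weighted(xs[1], ws[1], xs[2], ws[2])
            assert d01 == pytest.approx(d10, abs=1e-12)
            assert d02 <= d01 + d12 + 1e-10
            assert wasserstein_weighted(xs[0], ws[0], xs[0], ws[0]) == 0.0


class TestMeanDistributionDistance:
    def test_identical_sets(self):
        m = make_matrix([[1.0, 2.0], [3.0, 4.0]])
        w = uniform_weights(2)
        assert mean_distribution_distance(m, w, m, w) == 0.0

    def test_arithmetic_mean_of_columns(self):
        a = make_matrix([[0.0, 0.0]], tags=["x", "y"])
        a.values = np.vstack([a.values, a.values])
        a.frame_ids = [1, 2]
        b = make_matrix([[0.2, 0.4], [0.2, 0.4]], tags=["x", "y"])
        w = uniform_weights(2)
        assert mean_distribution_distance(a, w, b, w) == pytest.approx(0.3, abs=1e-12)

    def test_column_permutation_symmetry(self):
        rng = np.random.default_rng(4)
        va = rng.normal(0, 1, (6, 3))
        vb = rng.normal(0, 1, (6, 3))
        w = uniform_weights(6)
        base = mean_distribution_distance(
            make_matrix(va, tags=["a", "b", "c"]), w,
            make_matrix(vb, tags=["a", "b", "c"]), w)
        perm = [2, 0, 1]
        permuted = mean_distribution_distance(
            make_matrix(va[:, perm], tags=["c", "a", "b"]), w,
            make_matrix(vb[:, perm], tags=["c", "a", "b"]), w)
        assert permuted == pytest.approx(base, abs=1e-12)

    def test_tag_mismatch_rejected(self):
        a = make_matrix([[1.0], [2.0]], tags=["x"])
        b = make_matrix([[1.0], [2.0]], tags=["y"])
        w = uniform_weights(2)
        with pytest.raises(ValidationError):
            mean_distribution_distance(a, w, b, w)


class TestRunsTest:
    def test_two_blocks(self):
        n_runs, _, _ = runs_test(np.array([1.0, 2.0, 0.5, -1.0, -2.0, -0.5]))
        assert n_runs == 2

    def test_alternating(self):
        resid = np.array([1.0, -1.0] * 5)
        n_runs, z, _ = runs_test(resid)
        assert n_runs == 10
        mu = 2 * 5 * 5 / 10 + 1
        var = 2 * 5 * 5 * (2 * 5 * 5 - 10) / (10**2 * 9)
        assert z == pytest.approx((10 - mu) / np.sqrt(var), abs=1e-12)
        assert z > 0

    def test_enumeration_oracle_matches_formulas(self):
        _, _, mean, var = runs_distribution_enumeration(5, 5)
        n = 10
        mu = 2 * 5 * 5 / n + 1
        v = 2 * 5 * 5 * (2 * 5 * 5 - n) / (n**2 * (n - 1))
        assert mean == pytest.approx(mu, abs=1e-12)
        assert var == pytest.approx(v, abs=1e-12)

    def test_zeros_dropped(self):
        n_runs, _, _ = runs_test(np.array([1.0, 0.0, 1.0, -1.0]))
        assert n_runs == 2

    def test_single_sign_degenerate(self):
        n_runs, z, p = runs_test(np.array([1.0, 2.0, 3.0]))
        assert n_runs == 1
        assert p == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            runs_test(np.zeros(5))


def _scan_fixture_matrices(case):
    matrix = align_by_tags(case.prior_cs, case.targets)
    target_matrix = align_by_tags(case.target_cs, case.targets)
    return matrix, target_matrix


@pytest.fixture(scope="module")
def small_scan(small_benchmark):
    matrix, target_matrix = _scan_fixture_matrices(small_benchmark)
    return theta_scan(
        matrix,
        small_benchmark.targets,
        theta_grid=default_theta_grid(1e2, 1e-2, 12),
        target_matrix=target_matrix,
        target_weights=uniform_weights(target_matrix.n_frames),
    ), matrix


class TestThetaScan:

    def test_descending_and_converged(self, small_scan):
        scan, _ = small_scan
        thetas = [r.theta for r in scan.records]
        assert all(a > b for a, b in zip(thetas, thetas[1:]))
        assert all(r.converged for r in scan.records)

    def test_huge_theta_matches_unweighted(self, small_benchmark):
        from bmecv.solver import chi2_red

        matrix, _ = _scan_fixture_matrices(small_benchmark)
        scan = theta_scan(matrix, small_benchmark.targets, theta_grid=[1e8])
        rec = scan.records[0]
        split = scan.split
        train = matrix.take_frames(split.train0)
        val = matrix.take_frames(split.validation0)
        chi_t0 = chi2_red(train, uniform_weights(train.n_frames), small_benchmark.targets)
        chi_v0 = chi2_red(val, uniform_weights(val.n_frames), small_benchmark.targets)
        assert rec.chi2_t == pytest.approx(chi_t0, abs=1e-6)
        assert rec.chi2_v == pytest.approx(chi_v0, abs=1e-6)

    def test_chi2_t_monotone(self, small_scan):
        scan, _ = small_scan
        chi = [r.chi2_t for r in scan.records]
        assert np.all(np.diff(chi) <= 1e-8)

    def test_triangle_sanity(self, small_scan):
        scan, _ = small_scan
        for r in scan.records:
            assert r.d_tg <= r.d_tv + r.d_vg + 1e-10

    def test_benchmark_mode_switch(self, small_benchmark):
        matrix, _ = _scan_fixture_matrices(small_benchmark)
        scan = theta_scan(matrix, small_benchmark.targets, theta_grid=[10.0, 1.0])
        assert scan.records[0].d_tg is None
        assert not scan.benchmark_mode

    def test_nonpositive_grid_rejected(self, small_benchmark):
        matrix, _ = _scan_fixture_matrices(small_benchmark)
        with pytest.raises(ValidationError):
            theta_scan(matrix, small_benchmark.targets, theta_grid=[1.0, 0.0])

    def test_tsv_and_json_round(self, small_scan, tmp_path):
        scan, _ = small_scan
        scan.to_tsv(str(tmp_path / "scan.tsv"))
        scan.to_json(str(tmp_path / "scan.json"))
        header = (tmp_path / "scan.tsv").read_text().splitlines()[0].split("\t")
        assert header[:6] == ["theta", "chi2_t", "chi2_v", "neff_t", "lambda_rms", "d_tv"]
        assert "d_tg" in header and "d_vg" in header


class TestSelectTheta:
    def _scan_from(self, thetas, chi2_v, d_tv=None):
        d_tv = d_tv if d_tv is not None else np.linspace(0.1, 0.2, len(thetas))
        recs = [
            ThetaScanRecord(theta=t, chi2_t=0.0, chi2_v=c, neff_t=1.0,
                            lambda_rms=0.0, d_tv=d, converged=True)
            for t, c, d in zip(thetas, chi2_v, d_tv)
        ]
        return ThetaScanResult(records=recs, split=split_interleaved(4))

    def test_interior_argmin(self):
        scan = self._scan_from([100, 10, 3, 1, 0.1], [10, 5, 3, 4, 6])
        sel = select_theta(scan, "min_chi2_v")
        assert sel.theta_star == 3

    def test_monotone_decreasing_flags_no_overfitting(self):
        scan = self._scan_from([100, 10, 1], [3, 2, 1])
        sel = select_theta(scan, "min_chi2_v")
        assert sel.theta_star == 1
        assert "no overfitting" in sel.diagnostics

    def test_tie_prefers_larger_theta(self):
        scan = self._scan_from([100, 10, 3, 1], [5, 2, 2, 4])
        sel = select_theta(scan, "min_chi2_v")
        assert sel.theta_star == 10

    def test_elbow_rule(self):
        thetas = np.logspace(2, -2, 9)
        d_tv = np.array([0.1] * 4 + [0.1, 0.3, 0.7, 1.2, 1.8])
        scan = self._scan_from(thetas, np.ones(9), d_tv)
        sel = select_theta(scan, "d_tv_elbow")
        assert sel.theta_star in thetas[3:7]

    def test_too_few_points(self):
        scan = self._scan_from([10, 1], [1, 2])
        with pytest.raises(ValidationError):
            select_theta(scan)

    def test_unknown_rule(self):
        scan = self._scan_from([10, 1, 0.1], [1, 2, 3])
        with pytest.raises(ValidationError):
            select_theta(scan, "bogus")

    def test_nonconverged_excluded(self):
        recs = [
            ThetaScanRecord(theta=t, chi2_t=0.0, chi2_v=c, neff_t=1.0,
                            lambda_rms=0.0, d_tv=0.1, converged=conv)
            for t, c, conv in [(100, 5, True), (10, 1, False), (3, 3, True), (1, 4, True)]
        ]
        scan = ThetaScanResult(records=recs, split=split_interleaved(4))
        sel = select_theta(scan)
        assert sel.theta_star == 3  # theta=10 ignored despite lowest chi2_v


class TestRefitFullEnsemble:
    def test_huge_theta_uniform(self, small_benchmark):
        matrix, _ = _scan_fixture_matrices(small_benchmark)
        sol = refit_full_ensemble(matrix, small_benchmark.targets, 1e8)
        np.testing.assert_allclose(
            sol.weights.weights, np.full(matrix.n_frames, 1 / matrix.n_frames), atol=1e-8
        )

    def test_chi2_between_train_and_unweighted(self, small_benchmark):
        from bmecv.solver import chi2_red

        matrix, target_matrix = _scan_fixture_matrices(small_benchmark)
        scan = theta_scan(matrix, small_benchmark.targets,
                          theta_grid=default_theta_grid(1e2, 1e-1, 8))
        sel = select_theta(scan)
        sol = refit_full_ensemble(matrix, small_benchmark.targets, sel.theta_star)
        chi_full0 = chi2_red(matrix, uniform_weights(matrix.n_frames), small_benchmark.targets)
        rec = next(r for r in scan.records if r.theta == sel.theta_star)
        assert sol.chi2_red <= chi_full0 + 1e-12
        # comparable to the training fit at the same theta (the full refit
        # may land slightly above or below it)
        assert rec.chi2_t / 3 <= sol.chi2_red <= 3 * rec.chi2_t


class TestLag1Autocorrelation:
    def test_iid_frames_near_zero(self, small_benchmark):
        matrix = align_by_tags(small_benchmark.prior_cs, small_benchmark.targets)
        r = lag1_autocorrelation(matrix)
        assert np.max(np.abs(r)) < 0.35  # i.i.d. generator, modest n

    def test_alternating_signal(self):
        v = np.array([[1.0], [-1.0]] * 10)
        m = make_matrix(v)
        assert lag1_autocorrelation(m)[0] < -0.8
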