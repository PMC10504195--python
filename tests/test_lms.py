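import numpy as np
import pytest
from scipy.stats import kstest, norm

from bpref.lms import ConvergenceError, LMSModel, LMSResults, default_edf_grid


def simulate_constant(n, seed, L=1.0, M=90.0, S=0.09):
    rng = np.random.default_rng(seed)
    zht = rng.normal(0.0, 1.0, n)
    u = rng.standard_normal(n)
    y = M * (1.0 + L * S * u) ** (1.0 / L) if L != 0 else M * np.exp(S * u)
    return zht, y


class TestFitting:
    def test_constant_truth_recovery(self):
        # consistency check: at n = 20_000 a single draw sits well inside
        # the +/-0.5 / +/-0.01 band even at the sparse edges of [-2, 2]
        # (study-sized samples are covered by the 20-seed acceptance check)
        grid = np.linspace(-2, 2, 41)
        for seed in (101, 102, 103):
            zht, y = simulate_constant(20_000, seed=seed)
            res = LMSModel(zht, y, sex="boy", outcome="sbp").fit()
            L, M, S = res.curves(grid, allow_extrapolation=True)
            assert np.max(np.abs(M - 90.0)) < 0.5, seed
            assert np.max(np.abs(S - 0.09)) < 0.01, seed

    def test_singleton_grid(self):
        zht, y = simulate_constant(500, seed=7)
        res = LMSModel(zht, y).fit(edf_grid=[(1, 2, 1)])
        assert res.edf == (1.0, 2.0, 1.0)
        assert len(res.bic_trace) == 1

    def test_selected_bic_is_minimum(self):
        zht, y = simulate_constant(800, seed=13)
        res = LMSModel(zht, y).fit(edf_grid=[(1, 2, 1), (1, 3, 1), (2, 4, 2)])
        assert res.bic == pytest.approx(res.bic_trace["bic"].min())
        assert res.bic <= res.bic_trace["bic"].min() + 1e-9

    def test_bic_formula(self):
        zht, y = simulate_constant(500, seed=19)
        res = LMSModel(zht, y).fit(edf_grid=[(1, 2, 1)])
        assert res.bic == pytest.approx(
            -2.0 * res.loglik + np.log(res.n_fit) * sum(res.edf)
        )

    def test_linear_median_recovery(self):
        rng = np.random.default_rng(23)
        zht = rng.normal(0.0, 1.0, 5000)
        M = 90.0 + 3.0 * zht
        y = M * (1.0 + 0.08 * rng.standard_normal(5000))
        res = LMSModel(zht, y).fit(edf_grid=[(1, 2, 1)])
        grid = np.linspace(-2, 2, 21)
        _, Mv, _ = res.curves(grid, allow_extrapolation=True)
        assert np.max(np.abs(Mv - (90.0 + 3.0 * grid))) < 0.6

    def test_empty_grid_rejected(self):
        zht, y = simulate_constant(200, seed=5)
        with pytest.raises(ValueError):
            LMSModel(zht, y).fit(edf_grid=[])

    def test_input_validation(self):
        with pytest.raises(ValueError):
            LMSModel(np.zeros(10), np.ones(10))  # below min_n
        zht, y = simulate_constant(100, seed=1)
        y[0] = -1.0
        with pytest.raises(ValueError):
            LMSModel(zht, y)
        zht2, y2 = simulate_constant(100, seed=2)
        zht2[0] = np.inf
        with pytest.raises(ValueError):
            LMSModel(zht2, y2)

    def test_convergence_error_carries_diagnostics(self):
        zht, y = simulate_constant(200, seed=3)
        model = LMSModel(zht, y)
        with pytest.raises(ConvergenceError) as exc:
            model.fit(edf_grid=[(2, 5, 3)], maxiter=1)
        assert "grad_max" in exc.value.diagnostics


@pytest.fixture(scope="module")
def fitted():
    zht, y = simulate_constant(3000, seed=31)
    return LMSModel(zht, y, sex="boy", outcome="sbp").fit(
        edf_grid=[(1, 2, 1), (1, 3, 2)]
    ), zht, y


class TestResults:

    def test_centile_non_crossing(self, fitted):
        res, _, _ = fitted
        grid = np.linspace(*res.zht_range, 101)
        prev = None
        for p in (0.05, 0.5, 0.9, 0.95, 0.99):
            c = res.centile(p, grid)
            if prev is not None:
                assert np.all(c > prev)
            prev = c

    def test_scalar_centile(self, fitted):
        res, _, _ = fitted
        v = res.centile(0.5, 0.0)
        assert isinstance(v, float)
        assert 85 < v < 95

    def test_extrapolation_guard(self, fitted):
        res, _, _ = fitted
        lo, hi = res.zht_range
        with pytest.raises(ValueError):
            res.centile(0.5, hi + 1.0)
        flat_far = res.centile(0.5, hi + 1.0, allow_extrapolation=True)
        flat_edge = res.centile(0.5, hi, allow_extrapolation=True)
        assert flat_far == pytest.approx(flat_edge, abs=1e-9)

    def test_z_residuals_distribution(self, fitted):
        res, _, _ = fitted
        z, n_excl = res.z_residuals()
        assert n_excl == 0
        assert abs(float(np.mean(z))) < 0.05
        assert 0.95 < float(np.std(z)) < 1.05

    def test_z_residuals_single_point_at_median(self, fitted):
        res, _, _ = fitted
        m = res.centile(0.5, 0.1)
        z, _ = res.z_residuals(np.array([0.1]), np.array([m]))
        assert z[0] == pytest.approx(0.0, abs=1e-9)

    def test_z_residuals_ks_under_truth(self):
        rejections = 0
        n_rep = 20
        for seed in range(n_rep):
            zht, y = simulate_constant(5000, seed=1000 + seed)
            res = LMSModel(zht, y).fit(edf_grid=[(1, 2, 1)])
            z, _ = res.z_residuals()
            if kstest(z, "norm").pvalue < 0.05:
                rejections += 1
        assert rejections <= 0.1 * n_rep + 1

    def test_summary_text(self, fitted):
        res, _, _ = fitted
        s = res.summary()
        assert "BIC" in s and "boy" in s

    def test_export_round_trip_bit_identical(self, fitted, tmp_path):
        res, _, _ = fitted
        res.export(tmp_path / "coefs.csv", tmp_path / "model.json")
        back = LMSResults.from_export(tmp_path / "model.json")
        grid = np.linspace(*res.zht_range, 37)
        for p in (0.05, 0.5, 0.99):
            a = res.centile(p, grid)
            b = back.centile(p, grid)
            assert np.array_equal(a, b)


class TestNormalLimit:
    def test_matches_normal_quantiles(self):
        """L=1 + minimal edf reduces to mean + z(p)*SD on normal data."""
        rng = np.random.default_rng(41)
        n = 20_000
        zht = rng.normal(0.0, 1.0, n)
        y = 90.0 + 3.0 * zht + rng.normal(0.0, 7.0, n)
        res = LMSModel(zht, y).fit(edf_grid=[(1, 2, 1)])
        for z0 in (-1.0, 0.0, 1.0):
            for p in (0.05, 0.5, 0.95):
                expect = 90.0 + 3.0 * z0 + norm.ppf(p) * 7.0
                assert res.centile(p, z0) == pytest.approx(expect, abs=1.0)


def test_default_grid_shape():
    grid = default_edf_grid()
    assert len(grid) == 24
    assert (1, 2, 1) in grid and (2, 5, 3) in grid


def test_preset_truth_recovery_at_study_n(standard):
    """Fitted centiles at the seven knot Zhts within +/-1 mmHg of truth."""
    from bpref.cohort import apply_exclusions
    from bpref.simulate import SimulationConfig, generate_cohort

    cfg = SimulationConfig(n_children=3139, pct_boys=1.0, seed=2024)
    df = generate_cohort(cfg, standard)
    sbp_set, _, _ = apply_exclusions(df, standard)
    res = LMSModel(sbp_set["zht"].to_numpy(), sbp_set["bp"].to_numpy()).fit()
    ts = cfg.resolve_truth()[("boy", "sbp")]
    knots = norm.ppf([0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 0.95])
    for z0 in knots:
        for p in (0.5, 0.9, 0.95, 0.99):
            got = float(res.centile(p, z0, allow_extrapolation=True))
            assert got == pytest.approx(ts.centile(p, z0), abs=1.0), (z0, p)
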