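import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from bpref.bccg import (
    CalibrationError,
    bccg_centile,
    bccg_logpdf,
    bccg_zscore,
    calibrate_from_quantiles,
)


class TestZScore:
    def test_median_maps_to_zero(self):
        for L in (-0.5, 0.0, 1.0, 2.3):
            assert bccg_zscore(90.0, L, 90.0, 0.09) == pytest.approx(0.0, abs=1e-12)

    def test_normal_special_case(self):
        # L=1: z = (y - M) / (M*S), i.e. an ordinary z-score with SD = M*S
        assert bccg_zscore(98.1, 1.0, 90.0, 0.09) == pytest.approx(1.0, abs=1e-12)

    def test_direct_formula_negative_L(self):
        y, L, M, S = 80.0, -0.5, 90.0, 0.09
        expect = ((y / M) ** L - 1.0) / (L * S)
        assert bccg_zscore(y, L, M, S) == pytest.approx(expect, abs=1e-12)

    def test_log_branch(self):
        y, M, S = 95.0, 90.0, 0.08
        assert bccg_zscore(y, 0.0, M, S) == pytest.approx(np.log(y / M) / S, abs=1e-12)

    def test_L_to_zero_continuity(self):
        y = np.linspace(70, 120, 41)
        z_small = bccg_zscore(y, 1e-6, 90.0, 0.09)
        z_zero = bccg_zscore(y, 0.0, 90.0, 0.09)
        assert np.max(np.abs(z_small - z_zero)) < 1e-6

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            bccg_zscore(-1.0, 1.0, 90.0, 0.09)
        with pytest.raises(ValueError):
            bccg_zscore(90.0, 1.0, -90.0, 0.09)
        with pytest.raises(ValueError):
            bccg_zscore(90.0, 1.0, 90.0, 0.0)


class TestCentile:
    def test_median_property(self):
        for L in (-1.0, 0.0, 0.5, 1.0):
            assert bccg_centile(0.5, L, 91.0, 0.1) == pytest.approx(91.0, abs=1e-12)

    def test_normal_case(self):
        # L=1, p=0.8413: M*(1 + S*z), z(0.8413) ~ 1
        got = bccg_centile(norm.cdf(1.0), 1.0, 90.0, 0.09)
        assert got == pytest.approx(98.1, abs=1e-9)

    def test_round_trip(self):
        ps = np.array([0.01, 0.05, 0.25, 0.5, 0.75, 0.95, 0.99])
        for L in (-0.8, 0.0, 0.7, 1.5):
            y = bccg_centile(ps, L, 88.0, 0.11)
            z = bccg_zscore(y, L, 88.0, 0.11)
            assert np.max(np.abs(z - norm.ppf(ps))) < 1e-10

    def test_out_of_support(self):
        # large L*S pushes 1 + L*S*z(p) below 0 at small p
        with pytest.raises(ValueError):
            bccg_centile(1e-6, 4.0, 90.0, 0.5)

    def test_rejects_bad_p(self):
        with pytest.raises(ValueError):
            bccg_centile(0.0, 1.0, 90.0, 0.09)
        with pytest.raises(ValueError):
            bccg_centile(1.0, 1.0, 90.0, 0.09)


class TestLogPdf:
    def test_matches_normal_pdf_in_normal_case(self):
        # L=1: y ~ (approximately) Normal(M, M*S); densities agree where
        # the truncation correction is negligible
        y = np.linspace(70, 110, 9)
        M, S = 90.0, 0.09
        got = bccg_logpdf(y, 1.0, M, S)
        expect = norm.logpdf(y, loc=M, scale=M * S)
        assert np.max(np.abs(got - expect)) < 1e-9

    def test_integrates_to_one(self):
        from scipy.integrate import quad

        for L in (0.0, 0.5, 1.3):
            total, _ = quad(
                lambda y: np.exp(bccg_logpdf(y, L, 90.0, 0.09)), 1e-6, 400.0
            )
            assert total == pytest.approx(1.0, abs=1e-6)


class TestCalibration:
    def test_median_pins_M(self):
        L, M, S = calibrate_from_quantiles(
            (0.50, 0.90, 0.95, 0.99), (91.0, 102.0, 106.0, 112.0)
        )
        assert M == pytest.approx(91.0, abs=1e-12)
        assert S > 0

    def test_fixed_L_normal_case(self):
        # with L=1 the distribution is normal, mean 100, SD 10
        L, M, S = calibrate_from_quantiles(
            (0.50, norm.cdf(1.0)), (100.0, 110.0), fix_L=1.0
        )
        assert L == 1.0
        assert M == pytest.approx(100.0, abs=1e-9)
        assert S == pytest.approx(0.10, abs=1e-6)

    def test_exactly_determined_matches_grid_search_oracle(self):
        probs = (0.50, 0.90, 0.95)
        quants = (91.0, 102.0, 106.0)
        L, M, S = calibrate_from_quantiles(probs, quants)
        # independent grid-search oracle over (L, S), M pinned at 91
        zp = norm.ppf(probs)
        best = (np.inf, None, None)
        for Lg in np.arange(-3.0, 3.001, 1e-3):
            Ls = Lg if abs(Lg) > 1e-12 else 1e-12
            # solve S from the 90th quantile, check the 95th
            # q = M*(1+L*S*z)^(1/L) -> S = ((q/M)^L - 1)/(L*z)
            Sg = ((quants[1] / 91.0) ** Ls - 1.0) / (Ls * zp[1])
            if Sg <= 0:
                continue
            base = 1.0 + Ls * Sg * zp
            if np.any(base <= 0):
                continue
            q = 91.0 * base ** (1.0 / Ls)
            err = np.max(np.abs(q - quants))
            if err < best[0]:
                best = (err, Lg, Sg)
        assert L == pytest.approx(best[1], abs=1e-2)
        assert S == pytest.approx(best[2], abs=1e-2)
        # and the solution reproduces the quantiles
        q = bccg_centile(np.asarray(probs), L, M, S)
        assert np.max(np.abs(q - quants)) < 0.01

    def test_reproduces_quantiles_within_tolerance(self):
        probs = (0.50, 0.90, 0.95, 0.99)
        quants = (52.0, 62.0, 65.0, 71.0)
        L, M, S = calibrate_from_quantiles(probs, quants)
        q = bccg_centile(np.asarray(probs), L, M, S)
        assert np.max(np.abs(q - np.asarray(quants))) < 0.5

    def test_polish_never_worse(self):
        probs = (0.50, 0.90, 0.95, 0.99)
        quants = (90.0, 101.0, 103.0, 109.0)
        plain = calibrate_from_quantiles(probs, quants)
        polished = calibrate_from_quantiles(probs, quants, polish=True)
        worst = lambda lms: np.max(
            np.abs(bccg_centile(np.asarray(probs), *lms) - np.asarray(quants))
        )
        assert worst(polished) <= worst(plain) + 1e-9

    def test_rejects_non_monotone(self):
        with pytest.raises(CalibrationError):
            calibrate_from_quantiles((0.5, 0.9, 0.95), (91.0, 90.0, 106.0))

    def test_rejects_too_few(self):
        with pytest.raises(CalibrationError):
            calibrate_from_quantiles((0.5, 0.9), (91.0, 102.0))

    @given(
        L=st.floats(-1.5, 2.5),
        M=st.floats(40.0, 150.0),
        S=st.floats(0.03, 0.25),
    )
    def test_calibration_recovers_known_parameters(self, L, M, S):
        probs = np.array([0.5, 0.9, 0.95])
        try:
            q = bccg_centile(probs, L, M, S)
        except ValueError:
            return  # outside BCCG support: nothing to calibrate against
        if np.any(np.diff(q) <= 1e-9):
            return
        Lr, Mr, Sr = calibrate_from_quantiles(probs, q)
        qr = bccg_centile(probs, Lr, Mr, Sr)
        assert np.max(np.abs(qr - q)) < 0.01
        assert Mr == pytest.approx(M, abs=1e-9)


@given(
    y=st.floats(50.0, 200.0),
    L=st.floats(-2.0, 3.0),
    M=st.floats(50.0, 150.0),
    S=st.floats(0.02, 0.3),
)
def test_zscore_centile_inverse_pair(y, L, M, S):
    z = bccg_zscore(y, L, M, S)
    p = norm.cdf(z)
    if not 1e-12 < p < 1 - 1e-12:
        return
    back = bccg_centile(p, L, M, S)
    assert back == pytest.approx(y, rel=1e-7)
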