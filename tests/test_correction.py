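"""Correction methods: power-proportion, proportion, residual variants."""

import math

import numpy as np
import pytest
from sklearn.base import clone

from icvnorm import (
    ICVCorrector,
    VolumeTable,
    apply_ancova_quadratic,
    apply_ancova_residual,
    apply_loglog_residual,
    apply_power_proportion,
    apply_proportion,
    correct_table,
    fit_power_law,
    residual_slope,
)
from icvnorm.exceptions import IdentifiabilityError

from conftest import one_region_data

import pandas as pd


def _table(icv, voi, name="roi"):
    df = pd.DataFrame(
        {"icv": icv, name: voi},
        index=pd.Index([f"s{i}" for i in range(len(icv))], name="subject_id"),
    )
    return VolumeTable(df)


class TestPowerProportion:
    def test_b_one_is_bitwise_proportion(self):
        icv, voi, _ = one_region_data(0.8, seed=1)
        pp = apply_power_proportion(voi, icv, 1.0)
        prop = apply_proportion(voi, icv)
        assert np.array_equal(pp, prop)

    def test_b_zero_identity(self):
        icv, voi, _ = one_region_data(0.8, seed=2)
        assert np.array_equal(apply_power_proportion(voi, icv, 0.0), voi)

    def test_worked_example_independent_exponentiation(self):
        # 3.5 cc structure in a 1600 cc skull at b = 0.80
        got = apply_power_proportion([3.5], [1600.0], 0.80)[0]
        expected = 3.5 * math.exp(-0.80 * math.log(1600.0))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(9.566e-3, rel=1e-3)

    def test_rejects_nonfinite_exponent(self):
        with pytest.raises(ValueError):
            apply_power_proportion([3.5], [1600.0], np.inf)


class TestProportion:
    def test_arithmetic(self):
        assert apply_proportion([3.5], [1600.0])[0] == pytest.approx(2.1875e-3)

    def test_self_ratio_is_one(self):
        icv = np.linspace(1300, 1900, 9)
        assert np.allclose(apply_proportion(icv, icv), 1.0)


class TestAncovaResidual:
    def test_exact_linear_data(self):
        out = apply_ancova_residual([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert np.allclose(out, 4.0, atol=1e-12)

    def test_zero_slope_returns_input(self):
        # voi constructed orthogonal to centred icv -> fitted slope exactly 0
        icv = np.array([1.0, 2.0, 3.0, 4.0])
        voi = np.array([5.0, 4.0, 4.0, 5.0])
        out = apply_ancova_residual(voi, icv)
        assert np.allclose(out, voi, atol=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(21)
        icv = rng.uniform(1300, 1900, 60)
        voi = 1.0 + 0.002 * icv + rng.normal(0, 0.3, 60)
        out = apply_ancova_residual(voi, icv, recentre=False)
        # independent 2x2 normal-equations solve
        n = icv.size
        sx, sy = icv.sum(), voi.sum()
        sxx, sxy = (icv * icv).sum(), (icv * voi).sum()
        det = n * sxx - sx * sx
        b1 = (n * sxy - sx * sy) / det
        b0 = (sy - b1 * sx) / n
        oracle = voi - (b0 + b1 * icv)
        assert np.allclose(out, oracle, atol=1e-10)

    def test_constant_icv_rejected(self):
        with pytest.raises(IdentifiabilityError):
            apply_ancova_residual([3.0, 3.1, 3.2], [1500.0] * 3)


class TestAncovaQuadratic:
    def test_exact_parabola(self):
        icv = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        voi = 2.0 + 0.5 * icv + 0.25 * icv**2
        out = apply_ancova_quadratic(voi, icv, recentre=False)
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_linear_data_has_null_quadratic_term(self):
        icv = np.linspace(1300, 1900, 20)
        voi = 1.0 + 0.002 * icv
        _, diag = apply_ancova_quadratic(voi, icv, return_diagnostics=True)
        assert abs(diag["quadratic_coef"]) < 1e-8
        assert not diag["significant_05"]

    def test_nests_linear_sse(self):
        icv, voi, _ = one_region_data(0.6, target_se=0.06, typical_vol=4.0, seed=3)
        lin = apply_ancova_residual(voi, icv, recentre=False)
        quad = apply_ancova_quadratic(voi, icv, recentre=False)
        assert quad @ quad <= lin @ lin + 1e-9


class TestLogLogResidual:
    def test_noiseless_power_law_exact(self):
        rng = np.random.default_rng(4)
        icv = rng.uniform(1300, 1900, 30)
        alpha = 3.5 / 1600**0.8
        voi = alpha * icv**0.8
        out, params = apply_loglog_residual(voi, icv, return_params=True)
        assert params["b_log"] == pytest.approx(0.8, abs=1e-10)
        assert np.allclose(out, alpha, rtol=1e-10)

    def test_proportional_data_equals_proportion_method(self):
        icv = np.linspace(1300, 1900, 15)
        voi = 0.002 * icv
        out = apply_loglog_residual(voi, icv)
        assert np.allclose(out, apply_proportion(voi, icv), rtol=1e-9)

    def test_recovers_slope_under_multiplicative_noise(self):
        icv, voi, p = one_region_data(
            0.7, target_se=0.08, typical_vol=5.0, seed=5,
            n_male=170, n_female=330, noise_mode="multiplicative_lognormal",
        )
        _, params = apply_loglog_residual(voi, icv, return_params=True)
        # independent SE of the log-log OLS slope
        lx, ly = np.log(icv), np.log(voi)
        r = ly - np.polyval(np.polyfit(lx, ly, 1), lx)
        se = np.sqrt((r @ r / (lx.size - 2)) / ((lx - lx.mean()) ** 2).sum())
        assert abs(params["b_log"] - 0.7) < 2 * se


class TestDiagnosticsProperties:
    def test_residual_methods_leave_zero_slope(self):
        icv, voi, _ = one_region_data(0.7, seed=6)
        for corrected in (
            apply_ancova_residual(voi, icv),
            apply_ancova_quadratic(voi, icv),
        ):
            assert abs(residual_slope(corrected, icv).slope) < 1e-8

    def test_proportion_leaves_negative_trend_on_sublinear_data(self):
        icv, voi, _ = one_region_data(0.7, target_se=0.08, typical_vol=5.0, seed=0)
        d = residual_slope(apply_proportion(voi, icv), icv)
        assert d.slope < 0 and d.p_value < 0.05

    def test_power_proportion_decorrelates_large_n(self):
        icv, voi, _ = one_region_data(
            0.7, target_se=0.08, typical_vol=5.0, seed=1,
            n_male=695, n_female=1305,
        )
        f = fit_power_law(icv, voi)
        d = residual_slope(apply_power_proportion(voi, icv, f.beta), icv)
        assert abs(d.pearson_r) < 3 / np.sqrt(icv.size)


class TestICVCorrector:
    def _matrix(self, seed=0):
        icv, v1, _ = one_region_data(0.8, seed=seed)
        _, v2, _ = one_region_data(0.6, target_se=0.06, typical_vol=4.0, seed=seed + 1)
        return np.column_stack([icv, v1, v2]), icv, v1, v2

    @pytest.mark.parametrize("method, fn", [
        ("proportion", lambda v, x: apply_proportion(v, x)),
        ("ancova_residual", lambda v, x: apply_ancova_residual(v, x)),
        ("ancova_quadratic", lambda v, x: apply_ancova_quadratic(v, x)),
        ("loglog_residual", lambda v, x: apply_loglog_residual(v, x)),
    ])
    def test_transform_matches_functions(self, method, fn):
        X, icv, v1, v2 = self._matrix()
        out = ICVCorrector(method=method).fit(X).transform(X)
        assert np.allclose(out[:, 0], fn(v1, icv), rtol=1e-10)
        assert np.allclose(out[:, 1], fn(v2, icv), rtol=1e-10)

    def test_power_proportion_uses_fitted_exponent(self):
        X, icv, v1, _ = self._matrix()
        est = ICVCorrector(method="power_proportion").fit(X)
        b = est.params_[0]["b"]
        f = fit_power_law(icv, v1)
        assert b == pytest.approx(f.beta, abs=1e-10)
        out = est.transform(X)
        assert np.allclose(out[:, 0], apply_power_proportion(v1, icv, b))

    def test_supplied_exponent_scalar_and_clone(self):
        X, icv, v1, v2 = self._matrix()
        est = clone(ICVCorrector(method="power_proportion", exponent=1.0)).fit(X)
        out = est.transform(X)
        assert np.array_equal(out[:, 0], apply_proportion(v1, icv))
        assert est.params_[0]["b_source"] == "supplied"

    def test_transform_on_new_data_reuses_training_parameters(self):
        X, *_ = self._matrix(seed=3)
        Xnew, icv_new, v1_new, _ = self._matrix(seed=9)
        est = ICVCorrector(method="ancova_residual").fit(X)
        out = est.transform(Xnew)
        p = est.params_[0]
        expected = v1_new - (p["intercept"] + p["slope"] * icv_new) + p["mean_voi"]
        assert np.allclose(out[:, 0], expected)


class TestCorrectTable:
    def test_parameters_reproduce_correction(self):
        icv, voi, _ = one_region_data(0.8, seed=12)
        t = _table(icv, voi)
        ct = correct_table(t, "power_proportion")
        b = ct.parameters["roi"]["b"]
        redo = apply_power_proportion(voi, icv, b)
        got = ct.data.set_index("subject_id")["corrected_value"]
        assert np.allclose(got.to_numpy(), redo)

    def test_external_fits_take_precedence(self):
        icv, voi, _ = one_region_data(0.8, seed=13)
        t = _table(icv, voi)
        ct = correct_table(t, "power_proportion", exponent=0.5)
        assert ct.parameters["roi"] == {"b": 0.5, "b_source": "supplied"}

    def test_csv_roundtrip_with_provenance(self, tmp_path):
        icv, voi, _ = one_region_data(0.8, seed=14)
        ct = correct_table(_table(icv, voi), "loglog_residual")
        out = tmp_path / "corr.csv"
        ct.to_csv(out)
        df = pd.read_csv(out)
        assert set(df.columns) == {
            "subject_id", "region", "method", "corrected_value", "parameters"
        }
        import json

        params = json.loads(df["parameters"].iloc[0])
        assert "b_log" in params
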