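"""Round-trip and degeneracy behavior of the dual-energy calibration fits."""

import numpy as np
import pytest

from porospr.dect import (
    DectParams,
    InsertObservation,
    default_params,
    fit_all,
    fit_gamma_L,
    fit_i_calibration,
    fit_rho_e_params,
)
from porospr.physics import PhysicsConstants

CONSTANTS = PhysicsConstants()


def synthetic_observations(params: DectParams, hu_low, rho_e, constants=CONSTANTS):
    """Noiseless observations generated exactly from the conversion relations.

    Given rho_e and HU_L per insert, HU_H follows by inverting the
    electron-density relation; Z_eff and I follow from the EAN and
    ln(I/I_w) relations with the branch picked by the resulting EAN.
    """
    hu_low = np.asarray(hu_low, dtype=float)
    rho_e = np.asarray(rho_e, dtype=float)
    hu_high = (1000.0 * (rho_e - params.b) / params.a + params.alpha * hu_low) / (1.0 + params.alpha)
    mu_l = hu_low / 1000.0 + 1.0
    x = params.gamma_L * (mu_l / rho_e - 1.0)
    zeff = constants.zeff_water * (1.0 + x) ** (1.0 / params.m)
    obs = []
    for k in range(len(hu_low)):
        bone = zeff[k] >= params.ean_split
        c1 = params.c1_bone if bone else params.c1_soft
        c0 = params.c0_bone if bone else params.c0_soft
        i_ev = constants.i_water * np.exp(c1 * x[k] - c0)
        obs.append(
            InsertObservation(
                material=f"synthetic_{k}",
                hu_low=float(hu_low[k]),
                hu_high=float(hu_high[k]),
                rho_e=float(rho_e[k]),
                zeff=float(zeff[k]),
                i_ev=float(i_ev),
            )
        )
    return obs


# HU_L / rho_e pairs spanning lung to cortical bone, with EAN on both
# sides of the soft/bone split
HU_LOW = [-750.0, -480.0, -60.0, -10.0, 0.0, 40.0, 60.0, 500.0, 900.0, 1600.0]
RHO_E = [0.24, 0.50, 0.95, 0.99, 1.0, 1.04, 1.06, 1.25, 1.55, 1.90]


class TestRhoEFit:
    def test_round_trip_published_values(self):
        params = default_params()  # a=1.01, b=1.00, alpha=1.01
        obs = synthetic_observations(params, HU_LOW, RHO_E)
        a, b, alpha, r2 = fit_rho_e_params(obs)
        assert a == pytest.approx(params.a, rel=1e-9)
        assert b == pytest.approx(params.b, rel=1e-9)
        assert alpha == pytest.approx(params.alpha, rel=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_collinear_hu_is_degenerate(self):
        obs = [
            InsertObservation(f"m{k}", hu, hu, 1.0 + hu / 1000.0, 7.5, 75.0)
            for k, hu in enumerate([-500.0, 0.0, 500.0])
        ]
        with pytest.raises(ValueError, match="collinear"):
            fit_rho_e_params(obs)

    def test_noisy_recovery_within_three_standard_errors(self):
        params = default_params()
        rng = np.random.default_rng(1)
        obs = synthetic_observations(params, HU_LOW, RHO_E)
        noisy = [
            InsertObservation(
                o.material,
                o.hu_low + rng.normal(0, 5.0),
                o.hu_high + rng.normal(0, 5.0),
                o.rho_e,
                o.zeff,
                o.i_ev,
            )
            for o in obs
        ]
        a, b, alpha, _ = fit_rho_e_params(noisy)
        # OLS standard errors from the noisy design
        hu_h = np.array([o.hu_high for o in noisy])
        hu_l = np.array([o.hu_low for o in noisy])
        y = np.array([o.rho_e for o in noisy])
        X = np.column_stack([hu_h, hu_l, np.ones_like(hu_h)])
        coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        dof = len(y) - 3
        sigma2 = float(np.sum((y - X @ coef) ** 2)) / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se_a = 1000.0 * np.sqrt(cov[0, 0] + cov[1, 1] + 2 * cov[0, 1])
        assert abs(a - params.a) < 3 * se_a + 1e-12


class TestGammaLFit:
    def test_round_trip_published_value(self):
        params = default_params()  # gamma_L = 10.85
        obs = synthetic_observations(params, HU_LOW, RHO_E)
        gamma, r2 = fit_gamma_L(obs, CONSTANTS)
        assert gamma == pytest.approx(10.85, rel=1e-9)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_two_point_hand_least_squares(self):
        # x = {0.1, 0.2}, y = {1.085, 2.17} -> gamma = sum(xy)/sum(x^2) = 10.85
        m = CONSTANTS.mayneord_m
        obs = []
        for x, y in [(0.1, 1.085), (0.2, 2.17)]:
            rho_e = 1.2
            hu_low = 1000.0 * (rho_e * (1.0 + x) - 1.0)
            zeff = CONSTANTS.zeff_water * (1.0 + y) ** (1.0 / m)
            obs.append(InsertObservation("m", hu_low, 0.0, rho_e, zeff, 100.0))
        gamma, _ = fit_gamma_L(obs, CONSTANTS)
        assert gamma == pytest.approx(10.85, rel=1e-12)

    def test_water_only_is_degenerate(self):
        obs = [
            InsertObservation("water", 0.0, 0.0, 1.0, CONSTANTS.zeff_water, CONSTANTS.i_water)
            for _ in range(3)
        ]
        with pytest.raises(ValueError, match="contrast"):
            fit_gamma_L(obs, CONSTANTS)


class TestICalibrationFit:
    def test_round_trip_published_values(self):
        params = default_params()
        obs = synthetic_observations(params, HU_LOW, RHO_E)
        fit = fit_i_calibration(obs, CONSTANTS)
        assert fit["c1_soft"] == pytest.approx(0.3423, rel=1e-9)
        assert fit["c0_soft"] == pytest.approx(0.0206, rel=1e-9)
        assert fit["c1_bone"] == pytest.approx(0.0696, rel=1e-9)
        assert fit["c0_bone"] == pytest.approx(0.0444, rel=1e-9)

    def test_boundary_ean_goes_to_bone_group(self):
        params = default_params()
        obs = synthetic_observations(params, HU_LOW, RHO_E)
        boundary = InsertObservation("boundary", 100.0, 100.0, 1.1, 8.8, 90.0)
        fit = fit_i_calibration(obs + [boundary], CONSTANTS)
        assert "boundary" in fit["groups"]["bone"]

    def test_no_ean_contrast_flags_unidentifiable_slope(self):
        soft = [
            InsertObservation(f"w{k}", hu, hu, 1.0, CONSTANTS.zeff_water, CONSTANTS.i_water)
            for k, hu in enumerate([0.0, 10.0])
        ]
        bone = [
            InsertObservation(f"b{k}", 800.0 + 100 * k, 700.0 + 90 * k, 1.5 + 0.1 * k, 11.0 + k, 95.0 + k)
            for k in range(2)
        ]
        fit = fit_i_calibration(soft + bone, CONSTANTS)
        assert fit.get("soft_unidentifiable") is True
        assert fit["c0_soft"] == pytest.approx(0.0, abs=1e-12)

    def test_sign_convention_reproduces_high_i_bone(self):
        params = default_params()
        obs = synthetic_observations(params, HU_LOW, RHO_E)
        fit = fit_i_calibration(obs, CONSTANTS)
        bone_obs = [o for o in obs if o.zeff >= 8.8 and o.i_ev > CONSTANTS.i_water]
        assert bone_obs
        for o in bone_obs:
            x = (o.zeff / CONSTANTS.zeff_water) ** CONSTANTS.mayneord_m - 1.0
            ln_ratio = fit["c1_bone"] * x - fit["c0_bone"]
            assert ln_ratio > 0
            assert ln_ratio == pytest.approx(np.log(o.i_ev / CONSTANTS.i_water), rel=1e-9)


class TestFitAll:
    def test_full_round_trip_any_params(self):
        generating = DectParams(
            a=0.97, b=1.02, alpha=0.8, gamma_L=9.5,
            c1_soft=0.30, c0_soft=0.015, c1_bone=0.08, c0_bone=0.05,
        )
        obs = synthetic_observations(generating, HU_LOW, RHO_E)
        fitted = fit_all(obs, CONSTANTS)
        for name in ("a", "b", "alpha", "gamma_L", "c1_soft", "c0_soft", "c1_bone", "c0_bone"):
            assert getattr(fitted, name) == pytest.approx(getattr(generating, name), rel=1e-9)

    def test_unbiased_over_replicates(self):
        """With HU noise, the rho_e fit is unbiased: mean error within 3 SEM."""
        params = default_params()
        base = synthetic_observations(params, HU_LOW, RHO_E)
        rng = np.random.default_rng(12345)
        errors_a, errors_g = [], []
        for _ in range(200):
            noisy = [
                InsertObservation(
                    o.material,
                    o.hu_low + rng.normal(0, 3.0),
                    o.hu_high + rng.normal(0, 3.0),
                    o.rho_e, o.zeff, o.i_ev,
                )
                for o in base
            ]
            a, _, _, _ = fit_rho_e_params(noisy)
            g, _ = fit_gamma_L(noisy, CONSTANTS)
            errors_a.append(a - params.a)
            errors_g.append(g - params.gamma_L)
        for errs in (errors_a, errors_g):
            errs = np.array(errs)
            sem = errs.std(ddof=1) / np.sqrt(len(errs))
            assert abs(errs.mean()) < 3 * sem

    def test_published_i_params_passthrough(self):
        params = default_params()
        obs = synthetic_observations(params, HU_LOW, RHO_E)
        fitted = fit_all(obs, CONSTANTS, use_published_i_params=True)
        assert fitted.c1_soft == 0.3423 and fitted.c0_bone == 0.0444
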