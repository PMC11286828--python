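"""Dual-energy (DEEDZ-style) calibration of the HU-pair -> SPR conversion.

The conversion chain estimates, per voxel, relative electron density
from an energy-subtracted pair of CT numbers,

    rho_e = a [ (1 + alpha) HU_H - alpha HU_L ] / 1000 + b,

the effective-atomic-number term from the reduced low-kV CT number
mu_L = HU_L / 1000 + 1,

    (Z_eff / Z_eff,w)^m - 1 = gamma_L (mu_L / rho_e - 1),

and the mean excitation energy from a two-branch linear relation in the
EAN term with a soft/bone separation at EAN = 8.8,

    ln(I / I_w) = c1 [ (Z_eff / Z_eff,w)^m - 1 ] - c0.

This module fits those constants from calibration-insert observations
by ordinary least squares, and ships the published constant set
(a = 1.01, b = 1.00, alpha = 1.01, gamma_L = 10.85, c1/c0 soft
0.3423/0.0206, bone 0.0696/0.0444) as defaults so the conversion can
run without refitting.

Identifiability note: the (a, alpha) pair of the rho_e relation is
over-parameterized — only the two HU coefficients are identified.  The
decomposition used here sets a = 1000 (c_H + c_L), which is exactly the
sum of the fitted HU coefficients scaled by 1000, and
alpha = -1000 c_L / a.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .physics import (
    MaterialSpec,
    PhysicsConstants,
    effective_atomic_number,
    mean_excitation_energy,
    relative_electron_density,
)

__all__ = [
    "DectParams",
    "InsertObservation",
    "default_params",
    "fit_rho_e_params",
    "fit_gamma_L",
    "fit_i_calibration",
    "fit_all",
    "observations_from_materials",
    "read_observations_csv",
    "write_observations_csv",
]


@dataclass(frozen=True)
class DectParams:
    """Constant set of the dual-energy SPR conversion (defaults: published values)."""

    a: float = 1.01
    b: float = 1.00
    alpha: float = 1.01
    gamma_L: float = 10.85
    c1_soft: float = 0.3423
    c0_soft: float = 0.0206
    c1_bone: float = 0.0696
    c0_bone: float = 0.0444
    m: float = 3.3
    i_water: float = 75.3
    ean_split: float = 8.8
    r_squared: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"a = {self.a} must be > 0")
        if self.gamma_L <= 0:
            raise ValueError(f"gamma_L = {self.gamma_L} must be > 0")
        if self.ean_split <= 0:
            raise ValueError(f"ean_split = {self.ean_split} must be > 0")

    def rho_e(self, hu_l, hu_h):
        """Relative electron density from the energy-subtracted HU pair."""
        return self.a * ((1.0 + self.alpha) * np.asarray(hu_h) - self.alpha * np.asarray(hu_l)) / 1000.0 + self.b

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DectParams":
        return cls(**json.loads(Path(path).read_text()))


def default_params() -> DectParams:
    """The published constant set (m = 3.3, I_w = 75.3 eV, split at EAN 8.8)."""
    return DectParams()


@dataclass(frozen=True)
class InsertObservation:
    """Mean CT numbers of one calibration insert plus its reference quantities."""

    material: str
    hu_low: float
    hu_high: float
    rho_e: float
    zeff: float
    i_ev: float
    hu_120: float | None = None

    def __post_init__(self) -> None:
        for label, hu in (("hu_low", self.hu_low), ("hu_high", self.hu_high)):
            if hu < -1000:
                raise ValueError(f"{self.material}: {label} = {hu} < -1000")
        if not np.isfinite([self.rho_e, self.zeff, self.i_ev]).all():
            raise ValueError(f"{self.material}: non-finite reference values")


def observations_from_materials(
    materials: list[MaterialSpec],
    hu_low: np.ndarray,
    hu_high: np.ndarray,
    constants: PhysicsConstants | None = None,
    hu_120: np.ndarray | None = None,
) -> list[InsertObservation]:
    """Pair measured insert HU with physics-derived reference rho_e / Z_eff / I."""
    if constants is None:
        constants = PhysicsConstants()
    obs = []
    for k, mat in enumerate(materials):
        obs.append(
            InsertObservation(
                material=mat.name,
                hu_low=float(hu_low[k]),
                hu_high=float(hu_high[k]),
                rho_e=relative_electron_density(mat),
                zeff=effective_atomic_number(mat.composition, constants.mayneord_m),
                i_ev=mean_excitation_energy(mat.composition),
                hu_120=None if hu_120 is None else float(hu_120[k]),
            )
        )
    return obs


def write_observations_csv(observations: list[InsertObservation], path: str | Path) -> None:
    pd.DataFrame([asdict(o) for o in observations]).to_csv(path, index=False)


def read_observations_csv(path: str | Path) -> list[InsertObservation]:
    df = pd.read_csv(path)
    obs = []
    for row in df.itertuples(index=False):
        hu_120 = getattr(row, "hu_120", None)
        if hu_120 is not None and pd.isna(hu_120):
            hu_120 = None
        obs.append(
            InsertObservation(
                material=row.material,
                hu_low=row.hu_low,
                hu_high=row.hu_high,
                rho_e=row.rho_e,
                zeff=row.zeff,
                i_ev=row.i_ev,
                hu_120=hu_120,
            )
        )
    return obs


def generate_exact_observations(
    params: DectParams,
    hu_low,
    rho_e,
    constants: PhysicsConstants | None = None,
) -> list[InsertObservation]:
    """Noiseless observations generated exactly from the conversion relations.

    Given per-insert rho_e and HU_L, HU_H follows by inverting the
    electron-density relation, and Z_eff / I follow from the EAN and
    ln(I/I_w) relations with the branch picked by the resulting EAN.
    Useful for calibration round-trip validation: fitting these
    observations recovers ``params`` exactly.
    """
    if constants is None:
        constants = PhysicsConstants()
    hu_low = np.asarray(hu_low, dtype=float)
    rho_e = np.asarray(rho_e, dtype=float)
    hu_high = (1000.0 * (rho_e - params.b) / params.a + params.alpha * hu_low) / (
        1.0 + params.alpha
    )
    mu_l = hu_low / 1000.0 + 1.0
    x = params.gamma_L * (mu_l / rho_e - 1.0)
    zeff = constants.zeff_water * (1.0 + x) ** (1.0 / params.m)
    obs = []
    for k in range(len(hu_low)):
        bone = zeff[k] >= params.ean_split
        c1 = params.c1_bone if bone else params.c1_soft
        c0 = params.c0_bone if bone else params.c0_soft
        obs.append(
            InsertObservation(
                material=f"synthetic_{k}",
                hu_low=float(hu_low[k]),
                hu_high=float(hu_high[k]),
                rho_e=float(rho_e[k]),
                zeff=float(zeff[k]),
                i_ev=float(constants.i_water * np.exp(c1 * x[k] - c0)),
            )
        )
    return obs


def _r_squared(y: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_rho_e_params(observations: list[InsertObservation]) -> tuple[float, float, float, float]:
    """Fit (a, b, alpha) of the rho_e relation by OLS; returns (a, b, alpha, R^2).

    Regresses reference rho_e on (HU_H, HU_L, 1); the HU coefficients
    (c_H, c_L) map to a = 1000 (c_H + c_L), alpha = -1000 c_L / a.
    Raises if the design is rank-deficient (e.g. HU_H and HU_L collinear
    across inserts, which leaves alpha unidentified).
    """
    if len(observations) < 3:
        raise ValueError(f"need >= 3 inserts, got {len(observations)}")
    hu_h = np.array([o.hu_high for o in observations])
    hu_l = np.array([o.hu_low for o in observations])
    y = np.array([o.rho_e for o in observations])
    X = np.column_stack([hu_h, hu_l, np.ones_like(hu_h)])
    rank = np.linalg.matrix_rank(X, tol=1e-8 * max(1.0, float(np.abs(X).max())))
    if rank < 3:
        raise ValueError(
            "rank-deficient design: HU_H and HU_L are collinear across inserts "
            "(alpha unidentifiable); widen the insert range"
        )
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    c_h, c_l, b = (float(c) for c in coef)
    a = 1000.0 * (c_h + c_l)
    if a <= 0:
        raise ValueError(f"fitted a = {a} <= 0: insert set inconsistent with the model")
    alpha = -1000.0 * c_l / a
    r2 = _r_squared(y, X @ coef)
    return a, b, alpha, r2


def fit_gamma_L(
    observations: list[InsertObservation], constants: PhysicsConstants | None = None
) -> tuple[float, float]:
    """Fit gamma_L of the EAN relation (least squares through the origin).

    x = mu_L / rho_e - 1 with mu_L = HU_L / 1000 + 1;
    y = (Z_eff / Z_eff,w)^m - 1;  gamma_L = sum(xy) / sum(x^2).
    """
    if constants is None:
        constants = PhysicsConstants()
    mu_l = np.array([o.hu_low for o in observations]) / 1000.0 + 1.0
    rho_e = np.array([o.rho_e for o in observations])
    x = mu_l / rho_e - 1.0
    y = (np.array([o.zeff for o in observations]) / constants.zeff_water) ** constants.mayneord_m - 1.0
    sxx = float(np.sum(x * x))
    if sxx <= 1e-12:
        raise ValueError("no effective-atomic-number contrast: all reduced CT ratios equal 1")
    gamma = float(np.sum(x * y) / sxx)
    r2 = _r_squared(y, gamma * x)
    return gamma, r2


def fit_i_calibration(
    observations: list[InsertObservation],
    constants: PhysicsConstants | None = None,
    ean_split: float = 8.8,
) -> dict:
    """Fit the two-branch ln(I/I_w) relation; returns the c1/c0 pairs per branch.

    Inserts with reference Z_eff >= ``ean_split`` go to the bone branch
    (boundary values inclusive on the bone side; the assignment is
    reported in the result).  Per branch, OLS of ln(I/I_w) on
    x = (Z_eff/Z_eff,w)^m - 1 with slope c1 and intercept -c0.
    """
    if constants is None:
        constants = PhysicsConstants()
    zeff = np.array([o.zeff for o in observations])
    x = (zeff / constants.zeff_water) ** constants.mayneord_m - 1.0
    y = np.log(np.array([o.i_ev for o in observations]) / constants.i_water)
    bone_sel = zeff >= ean_split

    result: dict = {
        "ean_split": ean_split,
        "boundary_rule": "zeff >= split -> bone",
        "groups": {
            "soft": [o.material for o, b in zip(observations, bone_sel) if not b],
            "bone": [o.material for o, b in zip(observations, bone_sel) if b],
        },
    }
    for branch, sel in (("soft", ~bone_sel), ("bone", bone_sel)):
        if sel.sum() < 2:
            raise ValueError(
                f"{branch} group has {int(sel.sum())} insert(s); need >= 2 "
                f"(split at EAN {ean_split})"
            )
        xb, yb = x[sel], y[sel]
        if float(np.ptp(xb)) < 1e-12:
            # no EAN contrast in this group: slope unidentifiable
            result[f"c1_{branch}"] = float("nan")
            result[f"c0_{branch}"] = float(-np.mean(yb))
            result[f"r2_{branch}"] = float("nan")
            result[f"{branch}_unidentifiable"] = True
            continue
        X = np.column_stack([xb, np.ones_like(xb)])
        coef, *_ = np.linalg.lstsq(X, yb, rcond=None)
        result[f"c1_{branch}"] = float(coef[0])
        result[f"c0_{branch}"] = float(-coef[1])
        result[f"r2_{branch}"] = _r_squared(yb, X @ coef)
    return result


def fit_all(
    observations: list[InsertObservation],
    constants: PhysicsConstants | None = None,
    ean_split: float = 8.8,
    use_published_i_params: bool = False,
) -> DectParams:
    """Fit the full constant set from insert observations.

    With ``use_published_i_params`` the c1/c0 pairs keep their published
    values (the study's practice of reusing previously determined I
    calibration) while a, b, alpha and gamma_L are refit.
    """
    if constants is None:
        constants = PhysicsConstants()
    a, b, alpha, r2_rho = fit_rho_e_params(observations)
    gamma, r2_gamma = fit_gamma_L(observations, constants)
    published = DectParams()
    if use_published_i_params:
        c1s, c0s = published.c1_soft, published.c0_soft
        c1b, c0b = published.c1_bone, published.c0_bone
        r2_i = {}
    else:
        i_fit = fit_i_calibration(observations, constants, ean_split)
        c1s, c0s = i_fit["c1_soft"], i_fit["c0_soft"]
        c1b, c0b = i_fit["c1_bone"], i_fit["c0_bone"]
        r2_i = {"i_soft": i_fit["r2_soft"], "i_bone": i_fit["r2_bone"]}
    return DectParams(
        a=a,
        b=b,
        alpha=alpha,
        gamma_L=gamma,
        c1_soft=c1s,
        c0_soft=c0s,
        c1_bone=c1b,
        c0_bone=c0b,
        m=constants.mayneord_m,
        i_water=constants.i_water,
        ean_split=ean_split,
        r_squared={"rho_e": r2_rho, "gamma_L": r2_gamma, **r2_i},
    )
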