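"""Single-energy stoichiometric calibration and the HU -> SPR lookup table.

The stoichiometric method fits a two-term parameterized photon
cross-section model to measured insert CT numbers at 120 kV,

    mu/mu_w = rho_e (k1 Zt1 + k2 Zt2 + 1) / (k1 Zt1_w + k2 Zt2_w + 1),
    Ztj = sum_i lambda_i Z_i^{n_j} / sum_i lambda_i,

with a photoelectric-like exponent n1 = 3.62 and a coherent-like
exponent n2 = 1.86 (Rutherford-style parameterization; configurable).
The fitted model then predicts the CT numbers of reference human
tissues, whose Bethe SPR values populate a monotone piecewise-linear
HU -> SPR lookup table with air (-1000 HU, SPR 0) and water (0 HU,
SPR 1) anchor nodes.  The inverse of that table converts SPR maps into
hypothetical 120 kV CT images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from .dect import InsertObservation
from .materials import REFERENCE_TISSUES, load_material
from .physics import (
    BeamSpec,
    MaterialSpec,
    PhysicsConstants,
    mean_excitation_energy,
    relative_electron_density,
    spr_bethe,
)

__all__ = [
    "StoichiometricModel",
    "SectLut",
    "fit_stoichiometric_model",
    "build_hu_spr_lut",
    "invert_lut",
    "default_reference_tissues",
]


def _z_tilde(material: MaterialSpec, exponent: float) -> float:
    lam = material.composition.electron_fractions()
    Z = np.array([e[1] for e in material.composition.entries], dtype=float)
    return float(np.sum(lam * Z**exponent) / lam.sum())


@dataclass(frozen=True)
class StoichiometricModel:
    """Two-term cross-section model mapping a material to its 120 kV CT number."""

    k1: float
    k2: float
    n1: float = 3.62
    n2: float = 1.86
    tube: str = "120kV"
    zeff_identified: bool = True

    def mu_ratio(self, material: MaterialSpec) -> float:
        """Predicted mu/mu_water; exactly 1 for water (so HU(water) = 0)."""
        water = load_material("water")
        num = self.k1 * _z_tilde(material, self.n1) + self.k2 * _z_tilde(material, self.n2) + 1.0
        den = self.k1 * _z_tilde(water, self.n1) + self.k2 * _z_tilde(water, self.n2) + 1.0
        ratio = relative_electron_density(material) * num / den
        if ratio < 0:
            raise ValueError(f"model predicts negative attenuation for {material.name!r}")
        return ratio

    def predict_hu(self, material: MaterialSpec) -> float:
        return 1000.0 * (self.mu_ratio(material) - 1.0)


def fit_stoichiometric_model(
    observations: list[InsertObservation],
    materials: list[MaterialSpec],
    n1: float = 3.62,
    n2: float = 1.86,
) -> StoichiometricModel:
    """Fit (k1, k2) to measured 120 kV insert CT numbers by least squares.

    ``observations[k].hu_120`` must be present and correspond to
    ``materials[k]``.  The water point is constrained by construction
    (the model ratio is exactly rho_e at water).  If the insert set has
    no effective-atomic-number contrast (a pure-density series), any
    (k1, k2) fits equally well; the returned model is then flagged
    ``zeff_identified=False``.
    """
    if len(observations) != len(materials):
        raise ValueError("observations and materials must align")
    usable = [(o, m) for o, m in zip(observations, materials) if o.hu_120 is not None]
    if len(usable) < 3:
        raise ValueError(f"need >= 3 inserts with 120 kV HU, got {len(usable)}")
    measured = np.array([o.hu_120 / 1000.0 + 1.0 for o, _ in usable])
    mats = [m for _, m in usable]
    rho_e = np.array([relative_electron_density(m) for m in mats])
    zt1 = np.array([_z_tilde(m, n1) for m in mats])
    zt2 = np.array([_z_tilde(m, n2) for m in mats])
    water = load_material("water")
    zt1_w, zt2_w = _z_tilde(water, n1), _z_tilde(water, n2)

    contrast = float(np.ptp(zt1)) + float(np.ptp(zt2))
    if contrast < 1e-9:
        # pure-density series: mu/mu_w depends only on rho_e
        return StoichiometricModel(k1=0.0, k2=0.0, n1=n1, n2=n2, zeff_identified=False)

    def residuals(k):
        k1, k2 = k
        pred = rho_e * (k1 * zt1 + k2 * zt2 + 1.0) / (k1 * zt1_w + k2 * zt2_w + 1.0)
        return pred - measured

    fit = least_squares(residuals, x0=[1e-5, 1e-3], bounds=([0.0, 0.0], [np.inf, np.inf]))
    return StoichiometricModel(k1=float(fit.x[0]), k2=float(fit.x[1]), n1=n1, n2=n2)


@dataclass
class SectLut:
    """Monotone piecewise-linear HU -> SPR lookup table.

    Below the first node SPR clamps to 0; above the last node the final
    segment's slope continues.  ``adjusted_nodes`` records tissues whose
    SPR was pooled to enforce monotonicity.
    """

    hu: np.ndarray
    spr: np.ndarray
    labels: tuple[str, ...] = ()
    adjusted_nodes: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=float)
        self.spr = np.asarray(self.spr, dtype=float)
        if self.hu.size < 2:
            raise ValueError("lookup table needs at least 2 nodes")
        if np.any(np.diff(self.hu) <= 0):
            raise ValueError("HU nodes must be strictly increasing")
        if np.any(np.diff(self.spr) < 0):
            raise ValueError("SPR nodes must be non-decreasing")

    def lookup(self, hu):
        """Piecewise-linear SPR at ``hu`` (scalar or array)."""
        hu = np.asarray(hu, dtype=float)
        out = np.interp(hu, self.hu, self.spr)
        # linear extrapolation above the last node with the final slope
        top_slope = (self.spr[-1] - self.spr[-2]) / (self.hu[-1] - self.hu[-2])
        above = hu > self.hu[-1]
        if np.any(above):
            out = np.where(above, self.spr[-1] + (hu - self.hu[-1]) * top_slope, out)
        out = np.maximum(out, 0.0)
        if out.ndim == 0:
            return float(out)
        return out

    def to_csv(self, path: str | Path) -> None:
        lines = ["# HU -> SPR lookup table (piecewise linear)"]
        for k, v in self.meta.items():
            lines.append(f"# {k}: {v}")
        if self.labels:
            lines.append(f"# nodes: {','.join(self.labels)}")
        if self.adjusted_nodes:
            lines.append(f"# monotonicity_pooled: {','.join(self.adjusted_nodes)}")
        lines.append("hu,spr")
        lines += [f"{h:.6f},{s:.9f}" for h, s in zip(self.hu, self.spr)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SectLut":
        hu, spr, meta = [], [], {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if line.startswith("#"):
                if ":" in line:
                    k, v = line.lstrip("# ").split(":", 1)
                    meta[k.strip()] = v.strip()
                continue
            if not line or line.startswith("hu"):
                continue
            h, s = line.split(",")
            hu.append(float(h))
            spr.append(float(s))
        labels = tuple(meta.pop("nodes", "").split(",")) if "nodes" in meta else ()
        adjusted = tuple(meta.pop("monotonicity_pooled", "").split(",")) if "monotonicity_pooled" in meta else ()
        return cls(hu=np.array(hu), spr=np.array(spr), labels=labels,
                   adjusted_nodes=adjusted, meta=meta)


def _isotonic_pool(
    values: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, list[int], list[list[int]]]:
    """Weighted pool-adjacent-violators on an ordered sequence.

    Returns (pooled values, indices touched by pooling, block index lists).
    Heavily weighted entries (anchors) effectively pin their value.
    """
    vals = np.asarray(values, dtype=float)
    n = len(vals)
    if weights is None:
        weights = np.ones(n)
    blocks: list[list[float]] = []
    index_blocks: list[list[int]] = []
    touched: set[int] = set()
    for i, (v, w) in enumerate(zip(vals, weights)):
        blocks.append([float(v), float(w)])
        index_blocks.append([i])
        while len(blocks) > 1 and blocks[-2][0] > blocks[-1][0] + 1e-15:
            v2, w2 = blocks.pop()
            i2 = index_blocks.pop()
            v1, w1 = blocks.pop()
            i1 = index_blocks.pop()
            blocks.append([(v1 * w1 + v2 * w2) / (w1 + w2), w1 + w2])
            index_blocks.append(i1 + i2)
            touched.update(i1 + i2)
    out = np.empty(n)
    for (v, _), idxs in zip(blocks, index_blocks):
        for i in idxs:
            out[i] = v
    return out, sorted(touched), index_blocks


def default_reference_tissues() -> list[MaterialSpec]:
    """The packaged reference-tissue list used to populate the curve."""
    return [load_material(n) for n in REFERENCE_TISSUES]


def build_hu_spr_lut(
    model: StoichiometricModel,
    tissues: list[MaterialSpec] | None = None,
    beam: BeamSpec | None = None,
    constants: PhysicsConstants | None = None,
) -> SectLut:
    """Build the HU -> SPR table from model-predicted tissue CT numbers.

    One node per reference tissue (HU from the stoichiometric model, SPR
    from the Bethe ratio), plus (-1000, 0) air and (0, 1) water anchors;
    adjacent monotonicity violations are pooled (isotonic regression)
    and recorded.
    """
    if tissues is None:
        tissues = default_reference_tissues()
    if beam is None:
        beam = BeamSpec.from_energy(131.0)
    if constants is None:
        constants = PhysicsConstants()
    if len(tissues) < 2:
        raise ValueError("need at least 2 reference tissues")

    nodes: list[tuple[float, float, str]] = [(-1000.0, 0.0, "air_anchor"), (0.0, 1.0, "water_anchor")]
    for t in tissues:
        hu = model.predict_hu(t)
        spr = spr_bethe(
            relative_electron_density(t), mean_excitation_energy(t.composition), beam, constants
        )
        nodes.append((hu, float(spr), t.name))
    nodes.sort(key=lambda n: n[0])

    # merge nodes at (numerically) identical HU
    merged: list[list] = []
    for hu, spr, name in nodes:
        if merged and abs(hu - merged[-1][0]) < 1e-6:
            k = len(merged[-1][2].split("+")) if merged[-1][2] else 1
            merged[-1][1] = (merged[-1][1] * k + spr) / (k + 1)
            merged[-1][2] += f"+{name}"
        else:
            merged.append([hu, spr, name])
    hu_arr = np.array([m[0] for m in merged])
    if len(hu_arr) < 2:
        raise ValueError("fewer than 2 distinct HU values among reference tissues")
    spr_arr = np.array([m[1] for m in merged])
    labels = tuple(m[2] for m in merged)
    # anchors are pinned: violating tissue nodes pool toward them, not past them
    anchors = {i for i, lab in enumerate(labels) if "anchor" in lab}
    weights = np.array([1e12 if i in anchors else 1.0 for i in range(len(labels))])
    spr_mono, touched, blocks = _isotonic_pool(spr_arr, weights)
    for block in blocks:
        pinned = [i for i in block if i in anchors]
        if pinned:
            spr_mono[block] = spr_arr[pinned[0]]
    return SectLut(
        hu=hu_arr,
        spr=spr_mono,
        labels=labels,
        adjusted_nodes=tuple(labels[i] for i in touched),
        meta={
            "tube": model.tube,
            "k1": model.k1,
            "k2": model.k2,
            "n1": model.n1,
            "n2": model.n2,
            "beam_energy_MeV_u": beam.kinetic_energy,
        },
    )


class InverseLut:
    """SPR -> HU mapping: the inverse of a monotone piecewise-linear table.

    Plateaus (flat segments) invert to their left edge; SPR above the
    table's last node extrapolates with the inverse of the forward
    extrapolation slope.
    """

    def __init__(self, lut: SectLut):
        self.lut = lut
        spr, hu = lut.spr, lut.hu
        # distinct SPR values with the HU extent [left, right] of each plateau
        first = np.concatenate([[True], np.diff(spr) > 1e-15])
        self._v = spr[first]
        self._hu_left = hu[first]
        last = np.concatenate([np.diff(spr) > 1e-15, [True]])
        self._hu_right = hu[last]
        # exact plateau values invert to the anchor node (air/water) if the
        # plateau contains one, else to the left edge
        self._hu_exact = self._hu_left.copy()
        if lut.labels:
            group = np.cumsum(first) - 1
            for i, lab in enumerate(lut.labels):
                if "anchor" in lab:
                    self._hu_exact[group[i]] = hu[i]
        if self._v.size < 2:
            raise ValueError("lookup table is flat: not invertible")
        top = (lut.spr[-1] - lut.spr[-2]) / (lut.hu[-1] - lut.hu[-2])
        if top <= 0:  # flat top segment: continue the last rising segment
            top = (self._v[-1] - self._v[-2]) / (self._hu_left[-1] - self._hu_right[-2])
        self._top_slope = top

    def __call__(self, spr):
        s = np.atleast_1d(np.asarray(spr, dtype=float))
        if np.any(s < 0):
            raise ValueError("SPR must be >= 0")
        v, hl, hr = self._v, self._hu_left, self._hu_right
        idx = np.searchsorted(v, s, side="left")
        out = np.empty_like(s)

        above = idx == v.size
        exact = ~above & np.isclose(s, v[np.minimum(idx, v.size - 1)], rtol=0, atol=1e-12)
        below = ~above & ~exact & (idx == 0)
        interior = ~above & ~exact & ~below

        out[above] = hr[-1] + (s[above] - v[-1]) / self._top_slope
        out[exact] = self._hu_exact[idx[exact]]
        out[below] = hl[0]
        k = idx[interior]
        x0, x1 = v[k - 1], v[k]
        out[interior] = hr[k - 1] + (s[interior] - x0) * (hl[k] - hr[k - 1]) / (x1 - x0)
        if np.isscalar(spr) or np.asarray(spr).ndim == 0:
            return float(out[0])
        return out.reshape(np.asarray(spr).shape)


def invert_lut(lut: SectLut) -> InverseLut:
    """Return the SPR -> HU inverse mapping of ``lut``."""
    return InverseLut(lut)
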