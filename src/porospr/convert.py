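"""Voxelwise SPR map production and comparison statistics.

Implements both conversion routes on shared voxel grids:

* the dual-energy chain (HU_L, HU_H) -> rho_e -> EAN term -> ln(I/I_w)
  -> Bethe SPR, with a per-voxel soft/bone branch chosen by comparing
  the EAN term against the split value x* = (8.8 / Z_eff,w)^m - 1 and an
  air guard at very low electron density;
* the single-energy route via the piecewise-linear HU -> SPR table;

plus their difference map (Delta SPR = SPR_DECT - SPR_SECT), cylindrical
ROI means, masked histograms/medians, a soft-tissue SPR override, and
the SPR -> hypothetical-120 kV-CT transform through the inverse table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dect import DectParams
from .physics import BeamSpec, PhysicsConstants, stopping_number_denominator
from .sect import SectLut, invert_lut
from .volumes import SprVolume, VoxelVolume

__all__ = [
    "DectIntermediates",
    "RoiCylinder",
    "AIR_RHO_E_THRESHOLD",
    "deedz_spr_map",
    "sect_spr_map",
    "delta_spr_map",
    "roi_cylinder_mean",
    "mask_statistics",
    "scatter_samples",
    "override_spr_region",
    "spr_to_hypothetical_ct",
]

#: Voxels with estimated rho_e below this are treated as air (SPR 0); the
#: EAN relation divides by rho_e and is meaningless there.
AIR_RHO_E_THRESHOLD = 0.01

_X_FLOOR = -1.0 + 1e-9  # keeps (Zeff/Zeff_w)^m non-negative


@dataclass
class DectIntermediates:
    """Per-voxel intermediates of the dual-energy chain (diagnostics)."""

    rho_e: np.ndarray
    mu_l: np.ndarray
    x: np.ndarray  # (Zeff/Zeff_w)^m - 1
    ln_i_ratio: np.ndarray
    branch: np.ndarray  # "soft" | "bone" | "air"


@dataclass(frozen=True)
class RoiCylinder:
    """Cylindrical region of interest (default 4 mm diameter x 9 mm length)."""

    center: tuple[float, float, float]
    axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    diameter: float = 4.0
    length: float = 9.0

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.length <= 0:
            raise ValueError("ROI diameter and length must be > 0")
        norm = float(np.linalg.norm(self.axis))
        if norm == 0:
            raise ValueError("ROI axis must be a nonzero direction")
        object.__setattr__(self, "axis", tuple(a / norm for a in self.axis))


def _check_params(params: DectParams) -> None:
    for name in ("a", "b", "alpha", "gamma_L", "c1_soft", "c0_soft", "c1_bone", "c0_bone"):
        v = getattr(params, name)
        if v is None or not np.isfinite(v):
            raise ValueError(f"conversion constant {name!r} is missing or non-finite")


def deedz_spr_map(
    vol_low: VoxelVolume,
    vol_high: VoxelVolume,
    params: DectParams,
    beam: BeamSpec,
    constants: PhysicsConstants | None = None,
) -> tuple[SprVolume, DectIntermediates]:
    """Dual-energy SPR map from a paired low/high-kV volume.

    Per voxel: rho_e from the energy-subtracted HU pair; reduced CT
    number mu_L = HU_L/1000 + 1; EAN term x = gamma_L (mu_L/rho_e - 1)
    (floored at -1); branch soft if x < x* else bone with
    x* = (ean_split / Z_eff,w)^m - 1; ln(I/I_w) = c1 x - c0 with the
    branch's constants; SPR from the Bethe ratio.  Voxels with rho_e
    below the air threshold get SPR 0 and branch "air".
    """
    if vol_low.data.shape != vol_high.data.shape or not vol_low.same_grid(vol_high):
        raise ValueError(
            f"low/high volumes misaligned: {vol_low.shape}/{vol_low.spacing} vs "
            f"{vol_high.shape}/{vol_high.spacing}"
        )
    _check_params(params)
    if constants is None:
        constants = PhysicsConstants().with_m(params.m)
    hu_l = vol_low.data
    hu_h = vol_high.data

    rho_e = params.rho_e(hu_l, hu_h)
    air = rho_e < AIR_RHO_E_THRESHOLD
    mu_l = hu_l / 1000.0 + 1.0
    safe_rho = np.where(air, 1.0, rho_e)
    x = params.gamma_L * (mu_l / safe_rho - 1.0)
    x = np.maximum(x, _X_FLOOR)

    x_star = (params.ean_split / constants.zeff_water) ** params.m - 1.0
    bone = x >= x_star
    c1 = np.where(bone, params.c1_bone, params.c1_soft)
    c0 = np.where(bone, params.c0_bone, params.c0_soft)
    ln_i_ratio = c1 * x - c0

    denom = stopping_number_denominator(beam.beta, constants)
    spr = rho_e * (1.0 - ln_i_ratio / denom)
    spr = np.where(air, 0.0, np.maximum(spr, 0.0))

    branch = np.where(air, "air", np.where(bone, "bone", "soft"))
    spr_vol = SprVolume(
        data=spr,
        spacing=vol_low.spacing,
        origin=vol_low.origin,
        provenance="DECT",
        meta={"beam_energy_MeV_u": beam.kinetic_energy},
    )
    inter = DectIntermediates(rho_e=rho_e, mu_l=mu_l, x=x, ln_i_ratio=ln_i_ratio, branch=branch)
    return spr_vol, inter


def sect_spr_map(vol_120: VoxelVolume, lut: SectLut) -> SprVolume:
    """Single-energy SPR map by piecewise-linear table lookup."""
    spr = lut.lookup(vol_120.data)
    return SprVolume(
        data=spr, spacing=vol_120.spacing, origin=vol_120.origin, provenance="SECT"
    )


def delta_spr_map(spr_dect: SprVolume, spr_sect: SprVolume) -> np.ndarray:
    """Delta SPR = SPR_DECT - SPR_SECT, voxelwise (plain array: may be negative)."""
    if not spr_dect.same_grid(spr_sect):
        raise ValueError("SPR volumes are on different grids")
    return spr_dect.data - spr_sect.data


def _roi_mask(spr: SprVolume, roi: RoiCylinder) -> np.ndarray:
    X, Y, Z = np.meshgrid(
        spr.voxel_centers_axis(0),
        spr.voxel_centers_axis(1),
        spr.voxel_centers_axis(2),
        indexing="ij",
    )
    d = np.stack([X - roi.center[0], Y - roi.center[1], Z - roi.center[2]])
    axis = np.asarray(roi.axis)
    t = np.tensordot(axis, d, axes=(0, 0))
    radial2 = (d**2).sum(axis=0) - t**2
    return (np.abs(t) <= roi.length / 2.0) & (radial2 <= (roi.diameter / 2.0) ** 2)


def roi_cylinder_mean(spr: SprVolume, roi: RoiCylinder) -> tuple[float, int]:
    """Unweighted mean SPR over voxels whose centers lie inside the cylinder."""
    mask = _roi_mask(spr, roi)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(
            f"ROI (center {roi.center}, axis {roi.axis}, d={roi.diameter} mm, "
            f"L={roi.length} mm) contains no voxel centers"
        )
    return float(spr.data[mask].mean()), n


def mask_statistics(
    spr: SprVolume,
    mask: np.ndarray,
    bin_edges: np.ndarray | None = None,
) -> dict:
    """Histogram (default edges 0..2.5 step 0.05), median and mean over a mask."""
    if mask.shape != spr.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {spr.shape}")
    values = spr.data[mask]
    if values.size == 0:
        raise ValueError("mask selects no voxels")
    if bin_edges is None:
        bin_edges = np.arange(0.0, 2.5 + 0.05 / 2, 0.05)
    counts, edges = np.histogram(values, bins=bin_edges)
    return {
        "counts": counts,
        "bin_edges": edges,
        "median": float(np.median(values)),
        "mean": float(values.mean()),
        "n": int(values.size),
    }


def scatter_samples(spr_sect: SprVolume, spr_dect: SprVolume, mask: np.ndarray) -> pd.DataFrame:
    """Paired (SECT SPR, Delta SPR) samples over a mask, for scatter plots."""
    if not spr_dect.same_grid(spr_sect):
        raise ValueError("SPR volumes are on different grids")
    if mask.shape != spr_sect.shape:
        raise ValueError("mask shape mismatch")
    delta = spr_dect.data - spr_sect.data
    return pd.DataFrame({"spr_sect": spr_sect.data[mask], "delta_spr": delta[mask]})


def override_spr_region(spr: SprVolume, mask: np.ndarray, value: float) -> SprVolume:
    """Return a copy with masked voxels set to ``value`` (input unmodified)."""
    if value < 0:
        raise ValueError(f"override SPR {value} < 0")
    if mask.shape != spr.shape:
        raise ValueError("mask shape mismatch")
    data = spr.data.copy()
    data[mask] = value
    return SprVolume(
        data=data,
        spacing=spr.spacing,
        origin=spr.origin,
        provenance=spr.provenance,
        meta={**spr.meta, "override": value},
    )


def spr_to_hypothetical_ct(spr: SprVolume, lut: SectLut) -> VoxelVolume:
    """Transform an SPR map into a hypothetical 120 kV CT via the inverse table.

    A planning system holding the fixed forward table reproduces the
    original SPR map from the returned volume (round trip <= 1e-6).
    """
    inv = invert_lut(lut)
    hu = inv(spr.data)
    return VoxelVolume(
        data=hu,
        spacing=spr.spacing,
        origin=spr.origin,
        tube="120kV",
        meta={"hypothetical": True, "source_provenance": spr.provenance},
    )
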