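"""Water-equivalent path length, virtual range-pullback SPR, and range shifts.

A beam's water-equivalent path length (WEPL) is the line integral of
SPR along its path.  WEPL here is computed on a fixed sub-voxel step
grid with nearest-voxel sampling, which makes the cumulative WEPL a
piecewise-linear function of depth: segment integrals are exactly
additive and the depth at which a target WEPL is reached follows from
linear interpolation inside one step cell.

The virtual range measurement mirrors a range-pullback experiment: a
sample of physical length L placed in a water beamline pulls the range
back by its WEPL, and SPR = (R_water - R_insert) / L recovers the
path-mean SPR of the sample exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .physics import BeamSpec
from .volumes import SprVolume

__all__ = [
    "RayPath",
    "RangeMeasurement",
    "wepl_along_ray",
    "spr_from_range_pullback",
    "simulate_range_measurement",
    "range_shift",
]


@dataclass(frozen=True)
class RayPath:
    """A sampling ray: entry point (mm), unit direction, step (mm), total length (mm)."""

    entry: tuple[float, float, float]
    direction: tuple[float, float, float]
    step: float
    total_length: float

    def __post_init__(self) -> None:
        norm = float(np.linalg.norm(self.direction))
        if norm < 1e-12:
            raise ValueError("ray direction is degenerate (zero vector)")
        object.__setattr__(self, "direction", tuple(d / norm for d in self.direction))
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.total_length <= 0:
            raise ValueError("total length must be > 0")

    @classmethod
    def through(
        cls,
        spr: SprVolume,
        entry: tuple[float, float, float],
        direction: tuple[float, float, float],
        total_length: float | None = None,
        step: float | None = None,
    ) -> "RayPath":
        """Convenience constructor: default step = 0.25 x min voxel spacing."""
        if step is None:
            step = 0.25 * min(spr.spacing)
        if total_length is None:
            total_length = float(
                np.linalg.norm(np.array(spr.shape) * np.array(spr.spacing))
            )
        return cls(entry=entry, direction=direction, step=step, total_length=total_length)


@dataclass(frozen=True)
class RangeMeasurement:
    """A range-pullback triple: range in water, range with sample, sample length (mm)."""

    r_water: float
    r_insert: float
    l_insert: float

    def __post_init__(self) -> None:
        if self.r_water <= 0 or self.l_insert <= 0:
            raise ValueError("R_water and L_insert must be > 0")
        if self.r_insert < 0:
            raise ValueError("R_insert must be >= 0")


def _sample_profile(spr: SprVolume, ray: RayPath) -> np.ndarray:
    """Nearest-voxel SPR at the midpoint of each step cell along the ray.

    Points outside the grid contribute zero (vacuum).  Raises if no
    sample point falls inside the grid.
    """
    n = int(np.floor(ray.total_length / ray.step + 1e-9))
    if n == 0:
        raise ValueError("ray shorter than one step")
    t_mid = (np.arange(n) + 0.5) * ray.step
    pts = np.asarray(ray.entry) + t_mid[:, None] * np.asarray(ray.direction)
    idx = np.rint((pts - np.asarray(spr.origin)) / np.asarray(spr.spacing)).astype(int)
    inside = np.all((idx >= 0) & (idx < np.array(spr.shape)), axis=1)
    if not inside.any():
        raise ValueError("ray does not intersect the volume")
    values = np.zeros(n)
    ii = idx[inside]
    values[inside] = spr.data[ii[:, 0], ii[:, 1], ii[:, 2]]
    return values


def _cumulative_wepl(spr: SprVolume, ray: RayPath) -> tuple[np.ndarray, np.ndarray]:
    """Breakpoints t_k = k*step and cumulative WEPL at each breakpoint."""
    profile = _sample_profile(spr, ray)
    t = np.arange(profile.size + 1) * ray.step
    w = np.concatenate([[0.0], np.cumsum(profile) * ray.step])
    return t, w


def _wepl_at(t: np.ndarray, w: np.ndarray, profile_step: float, depth: float) -> float:
    if depth < 0:
        raise ValueError("depth must be >= 0")
    depth = min(depth, t[-1])
    return float(np.interp(depth, t, w))


def wepl_along_ray(spr: SprVolume, ray: RayPath, depth: float | None = None) -> float:
    """WEPL (mm) from the ray entry to ``depth`` (default: full ray length)."""
    t, w = _cumulative_wepl(spr, ray)
    if depth is None:
        depth = ray.total_length
    return _wepl_at(t, w, ray.step, depth)


def wepl_between(spr: SprVolume, ray: RayPath, start: float, end: float) -> float:
    """WEPL of the segment [start, end] along the ray (exactly additive)."""
    if end < start:
        raise ValueError("segment end before start")
    t, w = _cumulative_wepl(spr, ray)
    return _wepl_at(t, w, ray.step, end) - _wepl_at(t, w, ray.step, start)


def spr_from_range_pullback(meas: RangeMeasurement) -> float:
    """SPR = (R_water - R_insert) / L_insert."""
    return (meas.r_water - meas.r_insert) / meas.l_insert


def simulate_range_measurement(
    spr: SprVolume,
    ray: RayPath,
    sample_extent: tuple[float, float],
    beam: BeamSpec,
) -> RangeMeasurement:
    """Virtual range-pullback measurement of the sample segment along a ray.

    R_insert = R_water - WEPL(sample segment); the derived pullback SPR
    is therefore exactly the path-mean SPR over the segment.
    """
    start, end = sample_extent
    if end <= start:
        raise ValueError(f"zero- or negative-length sample extent {sample_extent}")
    if beam.water_range is None:
        raise ValueError("beam needs a reference water_range for a range measurement")
    wepl = wepl_between(spr, ray, start, end)
    if wepl > beam.water_range:
        raise ValueError(
            f"sample WEPL {wepl:.1f} mm exceeds the beam water range "
            f"{beam.water_range:.1f} mm (beam stops inside the sample)"
        )
    return RangeMeasurement(
        r_water=beam.water_range,
        r_insert=beam.water_range - wepl,
        l_insert=end - start,
    )


def _crossing_depth(t: np.ndarray, w: np.ndarray, target: float) -> float:
    if target > w[-1]:
        raise ValueError(
            f"target WEPL {target:.1f} mm unreachable along ray (max {w[-1]:.1f} mm)"
        )
    k = int(np.searchsorted(w, target))
    if k == 0:
        return float(t[0])
    slope = (w[k] - w[k - 1]) / (t[k] - t[k - 1])
    if slope <= 0:
        return float(t[k])
    return float(t[k - 1] + (target - w[k - 1]) / slope)


def range_shift(
    spr_a: SprVolume, spr_b: SprVolume, ray: RayPath, target_wepl: float
) -> float:
    """Depth difference (mm) at which the two maps reach ``target_wepl``.

    Positive when map ``a`` stops the beam deeper (lower SPR along the
    path) than map ``b``.
    """
    t_a, w_a = _cumulative_wepl(spr_a, ray)
    t_b, w_b = _cumulative_wepl(spr_b, ray)
    return _crossing_depth(t_a, w_a, target_wepl) - _crossing_depth(t_b, w_b, target_wepl)
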