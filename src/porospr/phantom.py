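"""Digital phantoms and the monoenergetic CT forward model.

This module replaces the scanner and the physical phantoms of a
CT-to-SPR study: it builds voxelized phantoms (a calibration phantom
with tissue-equivalent inserts, porous-bone samples, and a femur-like
bone-in-soft-tissue geometry), simulates CT numbers at the effective
energy of each tube, and computes the Bethe ground-truth SPR of every
voxel from its known material mixture.

The forward model is monoenergetic per tube (no spectra, scatter or
beam hardening): the linear attenuation of a voxel is the
volume-fraction-weighted sum of its component materials' attenuation at
the tube's effective energy, and HU = 1000 (mu / mu_water - 1) with
optional additive Gaussian noise, clamped at -1000 HU.  Water maps to
exactly 0 HU at every tube by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import attenuation as atten
from .materials import CALIBRATION_INSERTS, load_material
from .physics import BeamSpec, MaterialSpec, PhysicsConstants, mix_materials, spr_bethe
from .volumes import SprVolume, VoxelVolume

__all__ = [
    "ScanModel",
    "PhantomDefinition",
    "DEFAULT_SCANS",
    "default_scan",
    "build_calibration_phantom",
    "build_porosity_phantom",
    "build_femur_phantom",
    "simulate_ct",
    "ground_truth_spr_volume",
]

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class ScanModel:
    """A CT tube modeled by a single effective energy plus HU noise.

    ``mass_attenuation`` maps element symbol -> mu/rho (cm^2/g) at the
    effective energy; by default it is filled from the packaged
    synthetic cross-section model for all fixture elements.
    """

    tube: str
    effective_energy_kev: float
    noise_sigma_hu: float = 0.0
    mass_attenuation: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.effective_energy_kev <= 0:
            raise ValueError("effective energy must be > 0")
        if self.noise_sigma_hu < 0:
            raise ValueError("noise sigma must be >= 0")
        if not self.mass_attenuation:
            from .materials import load_elements

            table = {
                sym: atten.elemental_mass_attenuation(Z, A, self.effective_energy_kev)
                for sym, (Z, A, _) in load_elements().items()
            }
            object.__setattr__(self, "mass_attenuation", table)
        if any(v <= 0 for v in self.mass_attenuation.values()):
            raise ValueError("attenuation values must be > 0")

    def material_mu(self, material: MaterialSpec) -> float:
        """Linear attenuation (1/cm) of ``material`` at the effective energy."""
        mu_rho = 0.0
        for sym, _, _, w, _ in material.composition.entries:
            if sym not in self.mass_attenuation:
                raise KeyError(
                    f"element {sym!r} missing from attenuation table at "
                    f"{self.effective_energy_kev} keV"
                )
            mu_rho += w * self.mass_attenuation[sym]
        return material.density * mu_rho


# Effective energies typical for the scanner class at 80 / 120 / 135 kV;
# noise defaults emulate noise-matched reconstructions.
DEFAULT_SCANS: dict[str, tuple[float, float]] = {
    "80kV": (52.0, 7.0),
    "120kV": (63.0, 5.0),
    "135kV": (68.0, 7.0),
}


def default_scan(tube: str, noise_sigma_hu: float | None = None) -> ScanModel:
    """Default ScanModel for a tube label ("80kV" | "120kV" | "135kV")."""
    if tube not in DEFAULT_SCANS:
        raise KeyError(f"unknown tube {tube!r}; expected one of {sorted(DEFAULT_SCANS)}")
    energy, sigma = DEFAULT_SCANS[tube]
    return ScanModel(
        tube=tube,
        effective_energy_kev=energy,
        noise_sigma_hu=sigma if noise_sigma_hu is None else noise_sigma_hu,
    )


@dataclass
class PhantomDefinition:
    """A voxelized phantom: per-voxel volume-fraction mixtures of named materials.

    ``fractions`` has shape (n_materials, nx, ny, nz) and sums to one
    over the material axis at every voxel.  ``masks`` are named boolean
    regions on the same grid.
    """

    materials: tuple[MaterialSpec, ...]
    fractions: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=np.float64)
        if self.fractions.ndim != 4 or self.fractions.shape[0] != len(self.materials):
            raise ValueError(
                f"fractions shape {self.fractions.shape} does not match "
                f"{len(self.materials)} materials + 3-D grid"
            )
        if np.any(self.fractions < -_FRACTION_TOL) or np.any(self.fractions > 1 + _FRACTION_TOL):
            raise ValueError("volume fractions must lie in [0, 1]")
        total = self.fractions.sum(axis=0)
        if np.max(np.abs(total - 1.0)) > _FRACTION_TOL:
            raise ValueError("volume fractions must sum to 1 at every voxel")
        for name, mask in self.masks.items():
            if mask.shape != self.shape:
                raise ValueError(f"mask {name!r} shape {mask.shape} != grid {self.shape}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.fractions.shape[1:]

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Meshgrid (ij indexing) of voxel-center world coordinates, mm."""
        axes = [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)
        ]
        return np.meshgrid(*axes, indexing="ij")


def _grid_center(shape, spacing, origin) -> tuple[float, float, float]:
    return tuple(origin[a] + (shape[a] - 1) / 2.0 * spacing[a] for a in range(3))


def _cylinder_mask(shape, spacing, origin, center_xy, radius, z_range=None) -> np.ndarray:
    X, Y, Z = np.meshgrid(
        *(origin[a] + np.arange(shape[a]) * spacing[a] for a in range(3)), indexing="ij"
    )
    mask = (X - center_xy[0]) ** 2 + (Y - center_xy[1]) ** 2 <= radius**2
    if z_range is not None:
        mask &= (Z >= z_range[0]) & (Z <= z_range[1])
    return mask


def build_calibration_phantom(
    insert_names: tuple[str, ...] | None = None,
    arrangement: str = "head",
    shape: tuple[int, int, int] = (128, 128, 32),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    insert_radius_mm: float = 8.0,
) -> PhantomDefinition:
    """Calibration phantom: pure-material insert cylinders in a water background.

    The default insert set spans lung (inhale) through cortical bone,
    arranged on a ring around a central water insert, mirroring a
    commercial electron-density phantom.  ``arrangement`` chooses the
    ring radius ("head" or "body"); masks are ``insert_<name>`` per
    insert plus ``insert_water`` and ``background``.
    """
    if insert_names is None:
        insert_names = CALIBRATION_INSERTS
    ring_radius = {"head": 40.0, "body": 52.0}.get(arrangement)
    if ring_radius is None:
        raise ValueError(f"unknown arrangement {arrangement!r}; expected 'head' or 'body'")
    water = load_material("water")
    inserts = [load_material(n) for n in insert_names]
    materials = (water, *inserts)
    fractions = np.zeros((len(materials), *shape))
    fractions[0] = 1.0  # water everywhere, then carve inserts
    cx, cy, _ = _grid_center(shape, spacing, origin=(0.0, 0.0, 0.0))

    masks: dict[str, np.ndarray] = {}
    occupied = np.zeros(shape, dtype=bool)

    def _add(name: str, mask: np.ndarray) -> None:
        if np.any(mask & occupied):
            raise ValueError(f"insert {name!r} overlaps a previously placed insert")
        occupied[:] |= mask
        masks[name] = mask

    if insert_names:
        angles = 2 * math.pi * np.arange(len(inserts)) / len(inserts)
        for mat, theta in zip(inserts, angles):
            center = (cx + ring_radius * math.cos(theta), cy + ring_radius * math.sin(theta))
            mask = _cylinder_mask(shape, spacing, (0, 0, 0), center, insert_radius_mm)
            _add(f"insert_{mat.name.removeprefix('insert_')}", mask)
    # central water insert (reference), present even for an empty insert list
    _add("insert_water", _cylinder_mask(shape, spacing, (0, 0, 0), (cx, cy), insert_radius_mm))

    for mat_index, mat in enumerate(inserts, start=1):
        mask = masks[f"insert_{mat.name.removeprefix('insert_')}"]
        fractions[0][mask] = 0.0
        fractions[mat_index][mask] = 1.0

    masks["background"] = ~occupied
    return PhantomDefinition(
        materials=materials, fractions=fractions, spacing=spacing, masks=masks
    )


def build_porosity_phantom(
    base: MaterialSpec,
    filler: MaterialSpec,
    porosity: float,
    pore_model: str = "uniform",
    pore_diameter_mm: float = 0.15,
    seed: int = 0,
    shape: tuple[int, int, int] = (64, 64, 32),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    sample_radius_mm: float = 15.0,
    background: MaterialSpec | None = None,
) -> PhantomDefinition:
    """Porous sample: a cylinder of ``base`` material with ``porosity`` of ``filler``.

    ``pore_model="uniform"`` mixes every sample voxel as
    (1-porosity) base + porosity filler — the partial-volume regime of
    pores far below voxel size (e.g. a 150-um-pore ceramic imaged at
    1 mm).  ``pore_model="binary"`` assigns whole pore blocks to the
    filler with probability ``porosity`` (seeded); block edge is
    ``pore_diameter_mm`` rounded to whole voxels, so sub-voxel diameters
    collapse to voxel granularity.  The background is water unless given.
    Masks: ``sample`` and ``background``.
    """
    if not 0.0 <= porosity < 1.0:
        raise ValueError(f"porosity {porosity} outside [0, 1)")
    if background is None:
        background = load_material("water")
    materials = (background, base, filler)
    fractions = np.zeros((3, *shape))
    fractions[0] = 1.0
    cx, cy, _ = _grid_center(shape, spacing, (0.0, 0.0, 0.0))
    sample = _cylinder_mask(shape, spacing, (0, 0, 0), (cx, cy), sample_radius_mm)

    if pore_model == "uniform":
        base_frac = np.where(sample, 1.0 - porosity, 0.0)
        filler_frac = np.where(sample, porosity, 0.0)
    elif pore_model == "binary":
        rng = np.random.default_rng(seed)
        block = max(1, round(pore_diameter_mm / min(spacing)))
        coarse_shape = tuple(-(-n // block) for n in shape)
        coarse = rng.random(coarse_shape) < porosity
        pores = np.kron(coarse, np.ones((block,) * 3, dtype=bool))[
            : shape[0], : shape[1], : shape[2]
        ]
        filler_frac = np.where(sample & pores, 1.0, 0.0)
        base_frac = np.where(sample, 1.0, 0.0) - filler_frac
    else:
        raise ValueError(f"unknown pore_model {pore_model!r}")

    fractions[0] = np.where(sample, 0.0, 1.0)
    fractions[1] = base_frac
    fractions[2] = filler_frac
    return PhantomDefinition(
        materials=materials,
        fractions=fractions,
        spacing=spacing,
        masks={"sample": sample, "background": ~sample},
    )


def build_femur_phantom(
    shape: tuple[int, int, int] = (128, 128, 32),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    outer_radius_mm: float = 16.0,
    cortical_thickness_mm: float = 2.0,
    trabecular_fractions: tuple[float, float, float] = (0.20, 0.50, 0.30),
    soft_tissue: MaterialSpec | None = None,
) -> PhantomDefinition:
    """Femur-like geometry: cortical shell around a porous trabecular interior.

    The interior mixes (mineral, marrow, air) at ``trabecular_fractions``
    (hydroxyapatite / yellow marrow / air volume fractions) and the
    shell is cortical bone, embedded in a soft-tissue background
    (skeletal muscle by default).  Masks: ``cortical``, ``trabecular``,
    ``bone`` (their union) and ``soft_tissue``.
    """
    if abs(sum(trabecular_fractions) - 1.0) > _FRACTION_TOL:
        raise ValueError("trabecular fractions must sum to 1")
    if soft_tissue is None:
        soft_tissue = load_material("muscle")
    cortical = load_material("cortical_bone")
    mineral = load_material("hydroxyapatite")
    marrow = load_material("yellow_marrow")
    air = load_material("air")
    materials = (soft_tissue, cortical, mineral, marrow, air)

    cx, cy, _ = _grid_center(shape, spacing, (0.0, 0.0, 0.0))
    outer = _cylinder_mask(shape, spacing, (0, 0, 0), (cx, cy), outer_radius_mm)
    inner = _cylinder_mask(
        shape, spacing, (0, 0, 0), (cx, cy), outer_radius_mm - cortical_thickness_mm
    )
    shell = outer & ~inner

    fractions = np.zeros((5, *shape))
    fractions[0] = np.where(outer, 0.0, 1.0)
    fractions[1] = np.where(shell, 1.0, 0.0)
    fm, fma, fa = trabecular_fractions
    fractions[2] = np.where(inner, fm, 0.0)
    fractions[3] = np.where(inner, fma, 0.0)
    fractions[4] = np.where(inner, fa, 0.0)
    masks = {
        "cortical": shell,
        "trabecular": inner,
        "bone": outer,
        "soft_tissue": ~outer,
    }
    return PhantomDefinition(
        materials=materials, fractions=fractions, spacing=spacing, masks=masks
    )


def simulate_ct(phantom: PhantomDefinition, scan: ScanModel, seed: int = 0) -> VoxelVolume:
    """Simulate a CT volume: HU = 1000 (mu/mu_w - 1) + N(0, sigma), clamped at -1000.

    Linear attenuation is the volume-fraction-weighted sum of the
    component materials' monoenergetic attenuation; with
    ``noise_sigma_hu == 0`` the output is deterministic and
    seed-independent.
    """
    mu_water = scan.material_mu(load_material("water"))
    mu_materials = np.array([scan.material_mu(m) for m in phantom.materials])
    mu = np.tensordot(mu_materials, phantom.fractions, axes=(0, 0))
    hu = 1000.0 * (mu / mu_water - 1.0)
    if scan.noise_sigma_hu > 0:
        rng = np.random.default_rng(seed)
        hu = hu + rng.normal(0.0, scan.noise_sigma_hu, size=hu.shape)
    hu = np.maximum(hu, -1000.0)
    return VoxelVolume(
        data=hu,
        spacing=phantom.spacing,
        origin=phantom.origin,
        tube=scan.tube,
        meta={
            "effective_energy_keV": scan.effective_energy_kev,
            "noise_sigma_HU": scan.noise_sigma_hu,
            "seed": seed,
        },
    )


def ground_truth_spr_volume(
    phantom: PhantomDefinition,
    beam: BeamSpec,
    constants: PhysicsConstants | None = None,
) -> SprVolume:
    """Bethe ground-truth SPR of every voxel from its known mixture.

    Mixture composition is pooled by mass: rho_e is volume-fraction
    additive and ln I averages with electron-density weights, then SPR
    follows from the Bethe ratio at the beam's speed.
    """
    if constants is None:
        constants = PhysicsConstants()
    from .physics import mean_excitation_energy, relative_electron_density

    rho_e_mats = np.array([relative_electron_density(m) for m in phantom.materials])
    # electron density weight per material: rho * sum(w Z / A)
    lam_mats = np.array(
        [m.density * m.composition.electrons_per_gram_mol() for m in phantom.materials]
    )
    ln_i_mats = np.array([math.log(mean_excitation_energy(m.composition)) for m in phantom.materials])

    rho_e = np.tensordot(rho_e_mats, phantom.fractions, axes=(0, 0))
    lam = np.tensordot(lam_mats, phantom.fractions, axes=(0, 0))
    lam_ln_i = np.tensordot(lam_mats * ln_i_mats, phantom.fractions, axes=(0, 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        ln_i = np.where(lam > 0, lam_ln_i / np.maximum(lam, 1e-300), math.log(constants.i_water))
    spr = spr_bethe(rho_e, np.exp(ln_i), beam, constants)
    spr = np.maximum(spr, 0.0)
    return SprVolume(
        data=spr,
        spacing=phantom.spacing,
        origin=phantom.origin,
        provenance="truth",
        meta={"beam_energy_MeV_u": beam.kinetic_energy},
    )
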