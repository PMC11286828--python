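"""Packaged material fixtures: elements, tissues and phantom inserts.

Fixture CSVs live under ``porospr/data``:

* ``elements.csv`` — symbol, Z, A (g/mol), elemental mean excitation
  energy I (eV) for the elements appearing in the tissue fixtures.
* ``materials/<name>.csv`` — one file per material with a density
  metadata line and an element/mass-fraction table.

Tissue compositions follow the standard reference-tissue tables
(ICRU-44 style); the calibration-insert set mirrors a commercial
electron-density phantom (lung inhale/exhale through cortical bone) at
nominal densities.  Vendor insert formulations are proprietary, so the
insert fixtures are nominal tissue-equivalent stand-ins, which is all
the synthetic study needs.
"""

from __future__ import annotations

import functools
from importlib import resources

from .physics import ElementalComposition, MaterialSpec

__all__ = [
    "load_elements",
    "load_material",
    "available_materials",
    "make_material",
    "CALIBRATION_INSERTS",
    "REFERENCE_TISSUES",
]

#: Insert set of the synthetic calibration phantom (lung -> cortical bone).
CALIBRATION_INSERTS: tuple[str, ...] = (
    "insert_lung_inhale",
    "insert_lung_exhale",
    "insert_adipose",
    "insert_breast",
    "insert_muscle",
    "insert_liver",
    "insert_trabecular_bone",
    "insert_dense_bone",
    "insert_cortical_bone",
)

#: Reference human tissues used to populate the single-energy HU->SPR curve.
REFERENCE_TISSUES: tuple[str, ...] = (
    "lung_inflated",
    "adipose",
    "yellow_marrow",
    "breast",
    "water",
    "red_marrow",
    "brain",
    "muscle",
    "liver",
    "blood",
    "eye_lens",
    "skin",
    "cartilage",
    "spongiosa",
    "cortical_bone",
)


def _data_root():
    return resources.files("porospr").joinpath("data")


@functools.cache
def load_elements() -> dict[str, tuple[int, float, float]]:
    """Element table: symbol -> (Z, A g/mol, I eV)."""
    table: dict[str, tuple[int, float, float]] = {}
    text = _data_root().joinpath("elements.csv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("symbol"):
            continue
        sym, z, a, i_elem = line.split(",")
        table[sym] = (int(z), float(a), float(i_elem))
    return table


def make_material(name: str, density: float, mass_pct: dict[str, float]) -> MaterialSpec:
    """Build a MaterialSpec from percent mass fractions using the element table.

    Fractions must sum to 100 within 0.01%; they are renormalized exactly.
    """
    elements = load_elements()
    total = sum(mass_pct.values())
    if abs(total - 100.0) > 1e-2:
        raise ValueError(f"material {name!r}: mass fractions sum to {total}, expected 100")
    entries = []
    for sym, pct in sorted(mass_pct.items(), key=lambda kv: elements[kv[0]][0]):
        if sym not in elements:
            raise KeyError(f"material {name!r}: unknown element {sym!r}")
        Z, A, I_elem = elements[sym]
        entries.append((sym, Z, A, pct / total, I_elem))
    return MaterialSpec(name=name, density=density, composition=ElementalComposition(tuple(entries)))


@functools.cache
def available_materials() -> tuple[str, ...]:
    names = [
        p.name.removesuffix(".csv")
        for p in _data_root().joinpath("materials").iterdir()
        if p.name.endswith(".csv")
    ]
    return tuple(sorted(names))


@functools.cache
def load_material(name: str) -> MaterialSpec:
    """Load a packaged material fixture by name."""
    path = _data_root().joinpath("materials").joinpath(f"{name}.csv")
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"unknown material {name!r}; available: {', '.join(available_materials())}"
        ) from None
    density = None
    mass_pct: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("# density_g_cm3:"):
            density = float(line.split(":", 1)[1])
        elif not line or line.startswith("#") or line.startswith("element"):
            continue
        else:
            sym, pct = line.split(",")
            mass_pct[sym] = float(pct)
    if density is None:
        raise ValueError(f"material file for {name!r} lacks a density_g_cm3 line")
    return make_material(name, density, mass_pct)
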