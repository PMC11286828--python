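# porospr

Stopping-power-ratio (SPR) estimation from single- and dual-energy CT for
**porous bone**, on fully synthetic phantoms, with carbon-ion
water-equivalent range analysis.

## The problem

Particle-therapy treatment planning converts CT numbers (HU) to the
stopping-power ratio relative to water; the beam's water-equivalent depth is
the line integral of SPR along its path (WEPL). Single-energy CT (SECT) uses
one calibrated HU → SPR curve built from *solid* tissue-equivalent materials.
Porous bone — trabecular bone, mastoid air cells, or a 75%-porosity
hydroxyapatite ceramic — mixes mineral with air *below* the voxel scale: the
voxel's HU lands on a calibration curve that assumes a solid tissue of that
HU, and the SECT SPR is badly overestimated. Dual-energy CT (DECT) measures
two independent attenuation values per voxel and separates electron density
from effective atomic number, so the partial-volume mixture is handled
correctly.

`porospr` rebuilds this comparison end to end without a scanner: digital
phantoms with known material mixtures, a monoenergetic CT forward model per
tube (80 / 120 / 135 kV), both calibration chains, voxelwise conversion, and
WEPL-based range shifts.

## The model

SPR of a material with relative electron density ρe and mean excitation
energy *I* for a projectile of speed β (Bethe ratio, no shell/density terms):

    SPR = ρe · [ 1 − ln(I/I_w) / ( ln{ 2 m_e c² β² / (I_w (1−β²)) } − β² ) ]

with I_w = 75.3 eV and β = 0.481 at 131.0 MeV/u. The dual-energy
(energy-subtraction) chain estimates, per voxel,

    ρe   = a [ (1+α) HU_H − α HU_L ] / 1000 + b
    (Z_eff/Z_eff,w)^m − 1 = γ_L ( μ_L/ρe − 1 ),   μ_L = HU_L/1000 + 1
    ln(I/I_w) = c1 [ (Z_eff/Z_eff,w)^m − 1 ] − c0

with a two-branch (soft / bone) I-calibration split at Z_eff = 8.8 and
Mayneord exponent m = 3.3. The constants are fit from calibration-insert
scans by least squares, or taken from the published set
(a = 1.01, b = 1.00, α = 1.01, γ_L = 10.85, c1/c0 soft 0.3423/0.0206,
bone 0.0696/0.0444). The SECT route fits a two-term stoichiometric
cross-section model to insert CT numbers, predicts HU for ~15 reference
human tissues, and builds a monotone piecewise-linear HU → SPR lookup table
(with inverse, for "hypothetical 120 kV CT" generation).

## Worked example

```sh
porospr run --seed 1 --out run1
```

runs the full synthetic study (~2 s): calibration phantom scans at three
tubes, dual- and single-energy calibration, porous-bone samples
(hydroxyapatite + air at porosity 0 / 0.25 / 0.5 / 0.75), soft-tissue
samples, a femur-like phantom, and range analysis. With seed 1 it prints:

```
  porous_bone_p0.00: measured 2.602 DECT 2.596 (-0.2%) SECT 2.816 (+8.2%)
  porous_bone_p0.25: measured 1.952 DECT 1.947 (-0.3%) SECT 2.252 (+15.3%)
  porous_bone_p0.50: measured 1.302 DECT 1.297 (-0.3%) SECT 1.687 (+29.6%)
  porous_bone_p0.75: measured 0.651 DECT 0.648 (-0.6%) SECT 1.126 (+72.9%)
  soft_muscle:       measured 1.042 DECT 1.041 (-0.1%) SECT 1.044 (+0.2%)
  soft_adipose:      measured 0.969 DECT 0.964 (-0.5%) SECT 0.969 (+0.0%)
```

"measured" is the virtual range-pullback SPR,
SPR = (R_water − R_insert) / L_insert, evaluated on the ground-truth map —
it equals the path-mean true SPR exactly. SECT overestimates the porous
ceramic's SPR increasingly with porosity (up to ~+73% at 75% porosity, where
the true SPR is 0.65 but the tissue calibration curve reads ~1.13 at that
HU), while the dual-energy route stays within ~1%. On the femur-like
phantom the bone-mask SPR median from DECT is ~17% lower than from SECT,
and the DECT-vs-SECT range shift along a ray crossing the porous bone is
~+6 mm (the DECT map stops the beam deeper), while a soft-tissue-only ray
shifts by 0 because both maps are overridden to SPR 1.0 outside bone.

The report bundle (`report.json`, `sample_spr.csv`, `bone_spr_histogram.csv`,
`delta_spr_scatter.csv`, `range_shifts.csv`, SPR volumes and the
hypothetical 120 kV CT as NIfTI) lands in `run1/`.

## Library layout

| module | contents |
|---|---|
| `porospr.physics` | ρe, Z_eff (Mayneord), I (Bragg additivity), β(E), Bethe SPR |
| `porospr.attenuation` | synthetic elemental photon cross-section model |
| `porospr.materials` | packaged element/tissue/insert fixtures |
| `porospr.phantom` | calibration / porosity / femur phantoms, CT simulation, ground truth |
| `porospr.dect` | dual-energy calibration fits and the published constant set |
| `porospr.sect` | stoichiometric fit, monotone HU→SPR table and its inverse |
| `porospr.convert` | voxelwise SPR maps, ΔSPR, ROI/mask statistics, overrides, hypothetical CT |
| `porospr.raytrace` | WEPL, virtual range-pullback measurement, range shift |
| `porospr.pipeline` | the end-to-end experiment |
| `porospr.cli` | `porospr` command-line entry points |

See `docs/methods.md` for modeling assumptions and design choices.
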