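# Methods

## Scope and intent

`porospr` reproduces, on synthetic data, the comparison between
single-energy (SECT) and dual-energy (DECT) CT-to-SPR conversion for porous
bone, and the consequence for carbon-ion beam range. Everything a scanner
or a physical phantom provided in the original experimental setting is
replaced by code: phantoms are voxel grids of known material mixtures, CT
acquisition is a monoenergetic forward model, and range measurement is exact
WEPL integration. The package's claims are therefore *mechanistic and
directional*: it demonstrates and quantifies, under a self-consistent
forward model, why sub-voxel porosity defeats a single-energy calibration
curve and why an electron-density / effective-atomic-number decomposition
does not. Absolute error magnitudes on a real scanner depend on spectra,
beam hardening, reconstruction and vendor insert formulations, none of
which are modeled.

## Stopping-power physics

SPR is the Bethe stopping-power ratio relative to water without shell,
Barkas or density-effect corrections and without nuclear interactions:

SPR = ρe [1 − ln(I/I_w) / (ln{2 m_e c² β²/(I_w(1−β²))} − β²)].

* β from kinetic energy per nucleon via γ = 1 + E/u, u = 931.494 MeV
  (931.494 MeV and m_e c² = 510 998.95 eV are CODATA values; at
  131.0 MeV/u, β = 0.4810).
* Electron-fraction weights λ_i = w_i Z_i/A_i drive every compositional
  quantity: ρe (relative to water at 1 g/cm³), Z_eff as the Mayneord power
  mean with exponent m = 3.3, and ln I as the Bragg-additivity average.
* Elemental I values are ICRU-37-style recommendations for elements in
  condensed compounds (H 19.2, C 81, N 82, O 106 eV; elemental values for
  Z ≥ 11). Bragg additivity over the water composition then yields
  75.32 eV, i.e. the adopted water value 75.3 eV at its printed precision.
* `PhysicsConstants` defaults I_w and Z_eff,w to the values *computed from
  the packaged water composition* (75.32 eV, 7.478 at m = 3.3) rather than
  to rounded literals, so water maps to SPR exactly 1 and the EAN relation
  is exactly self-consistent at water. Passing `i_water=75.3` pins the
  rounded convention instead.

## Material fixtures

Tissue compositions follow the standard reference-tissue tables (ICRU-44
style; ~15 tissues from inflated lung to cortical bone). The calibration
inserts mimic a commercial electron-density phantom (lung inhale/exhale,
adipose, breast, muscle, liver, two hydroxyapatite-loaded bone inserts at
200 and 800 mg/cc, cortical bone) at nominal densities; vendor formulations
are proprietary, so these are explicitly nominal tissue-equivalent
stand-ins. Hydroxyapatite Ca₁₀(PO₄)₆(OH)₂ at 3.16 g/cm³ is the porous-bone
substrate. Fixtures are plain CSVs under `porospr/data` with provenance
notes in their headers.

## CT forward model

Each tube is a single effective energy — 52 keV (80 kV), 63 keV (120 kV),
68 keV (135 kV), typical for this scanner class — with elemental mass
attenuation from a **synthetic parameterized cross-section model**: exact
Klein–Nishina incoherent scattering plus power-law photoelectric
(∝ Z³·⁸ E⁻³·²) and coherent (∝ Z¹·⁹ E⁻¹·⁹) terms per electron, anchored to
the accepted partial coefficients of water at 60 keV. This is a stand-in
constructed for this package, not a tabulated dataset; it preserves the
Z/E structure that dual-energy decomposition exploits. The photoelectric
and coherent exponents deliberately differ from the exponents of the
stoichiometric SECT fit (3.62/1.86), so that fit remains a genuine
approximation rather than an identity.

Voxel attenuation is the volume-fraction-weighted sum of component
materials' linear attenuation (partial-volume mixing is exact);
HU = 1000(μ/μ_w − 1) with optional additive Gaussian noise (defaults
5 HU at 120 kV, 7 HU at 80/135 kV, emulating noise-matched
reconstructions), clamped at −1000 HU. Water is exactly 0 HU at every tube
by construction. No spectra, scatter, beam hardening, or reconstruction
effects are modeled — this is the main reason error *magnitudes* here are
not transferable to real scanners.

## Phantoms

* **Calibration phantom**: nine pure-material insert cylinders (16 mm
  diameter) on a ring (head 40 mm / body 52 mm radius) in a water
  background, plus a central water insert; default grid 128×128×32 at 1 mm.
* **Porosity phantom**: a 30 mm cylinder of base material (default
  hydroxyapatite) with void fraction p of filler (default air). The default
  `uniform` pore model mixes every voxel at (1−p)/p — the partial-volume
  regime of 150 µm pores imaged at 1 mm, which is exactly the regime that
  defeats SECT. A `binary` model assigns whole pore blocks (seeded) for
  resolved-pore studies.
* **Femur-like phantom**: a 2 mm cortical shell around a trabecular
  interior mixing mineral/marrow/air at (0.20/0.50/0.30) by volume,
  embedded in skeletal muscle.

Ground-truth SPR pools each voxel's mixture by mass (ρe is
volume-fraction additive; ln I averages with electron-density weights) and
applies the Bethe ratio.

## Calibration

**Dual-energy**: ρe is regressed on (HU_H, HU_L, 1) by ordinary least
squares. The (a, α) pair of the published parameterization is
over-determined (only the two HU coefficients are identified); the
decomposition a = 1000(c_H + c_L), α = −1000 c_L/a is used, which
reproduces the published convention exactly on round trips. γ_L is a
least-squares slope through the origin. The I-calibration fits
ln(I/I_w) on the EAN term per branch, with the boundary Z_eff = 8.8
assigned to the *bone* branch (recorded in the fit output). Degenerate
designs (collinear HU pairs, no EAN contrast, single-insert branches) raise
or are flagged rather than silently fit. All fits are unweighted OLS.
`default_params()` returns the published constant set so the conversion can
run without refitting.

**Single-energy**: the two-term stoichiometric model
μ/μ_w = ρe(k1·Z̃₁ + k2·Z̃₂ + 1)/(same at water), Z̃ⱼ the electron-weighted
Z^{n_j} mean with n₁ = 3.62, n₂ = 1.86, is fit to 120 kV insert CT numbers
(non-negative k, water exact by construction). The lookup table takes one
node per reference tissue plus pinned air (−1000, 0) and water (0, 1)
anchors. Monotonicity is enforced by weighted pool-adjacent-violators in
which anchors carry effectively infinite weight: violating tissue nodes
pool toward anchors, never past them; pooled nodes are recorded in the
table metadata. Real HU–SPR relations *do* cross near water (carbon-rich
tissues have SPR > 1 at slightly negative HU), so a short plateau at SPR 1
below 0 HU is expected, not a defect. Extrapolation continues the final
segment's slope above the last node and clamps to SPR 0 below −1000 HU.

**Inversion**: exact plateau values invert to the anchor node if the
plateau contains one (so SPR 1.0 → 0 HU), otherwise to the plateau's left
edge; values between plateaus interpolate between the right edge of the
lower plateau and the left edge of the upper one. This makes
forward(inverse(s)) = s to 1e-9 everywhere in range, which is the
correctness condition the hypothetical-CT transform relies on.

## Voxel conversion

The dual-energy chain is evaluated branch-per-voxel: the EAN term
x = γ_L(μ_L/ρe − 1) (floored at −1 + 1e-9) is compared against
x* = (8.8/Z_eff,w)^m − 1 ≈ 0.711; x ≥ x* selects the bone I-constants. The
published parameterization defines the branch split only for calibration
inserts; applying it per voxel through x is this package's choice. Voxels
with estimated ρe < 0.01 are air (SPR 0): the EAN relation divides by ρe
and the conversion is meaningless there. ROI extraction uses a cylinder
(default 4 mm diameter × 9 mm length) with voxel-center membership.
Histogram bins default to 0–2.5 SPR at 0.05 width.

## Range analysis

WEPL is integrated on a fixed sub-voxel step grid (default step =
0.25 × min spacing) with nearest-voxel sampling, making cumulative WEPL
piecewise linear in depth: segment additivity is exact and target-WEPL
crossing depths come from linear interpolation inside one cell. The virtual
range-pullback measurement sets R_insert = R_water − WEPL(sample), so the
derived SPR equals the path-mean SPR exactly — the virtual measurement is
unbiased by construction (physical dosimetry uncertainty does not apply).
Range comparison between two SPR maps is the difference of
target-WEPL-crossing depths: a dose-free surrogate for dose-profile range
shift; no dose engine, lateral scattering or RBE model is included.

## The experiment, and what passing it shows

`run_experiment` scans the calibration phantom (three tubes), fits both
calibrations, then evaluates porous samples at p = 0 / 0.25 / 0.5 / 0.75,
two soft-tissue samples, and the femur phantom, with the soft-tissue SPR
override to 1.0 applied before range analysis (isolating the bone effect,
as in the motivating experimental design). Problem sizes — 128×128×32
calibration/femur grids, 64×64×32 samples — were chosen so the whole study
runs in seconds while every mask holds 10³–10⁵ voxels.

Expected behavior under the default conditions: soft-tissue samples within
±1% for both routes; SECT error on porous bone positive and increasing with
porosity (≈ +15/+30/+73% at p = 0.25/0.5/0.75) while DECT stays within
~1%; bone-median SPR lower for DECT; range shift positive through porous
bone and zero along soft-tissue-only rays. At p = 0 the sample is *pure*
hydroxyapatite ceramic (ρe 2.83), outside the reference-tissue family, and
SECT retains a ≈ +8% extrapolation bias — a real limitation of a
tissue-calibrated curve, retained deliberately.

Because the same attenuation model generates both the calibration scans
and the test scans, these results validate the *conversion logic*, not
scanner accuracy: what the tests demonstrate is that, even with a perfectly
known forward model, the single-energy route cannot represent sub-voxel
porosity while the dual-energy route can.

## Numerical conventions

* Voxel centers at origin + index·spacing; volumes stored as NIfTI float32
  with JSON sidecars (tiny negative round-off clipped on load).
* All randomness flows from explicit integer seeds; noiseless simulation is
  seed-independent; a rerun of the pipeline with the same config is
  byte-identical.
* Fit degeneracies raise informative errors; unidentifiable slopes are
  flagged (`NaN` + flag), never silently zeroed.

## Known limitations

Monoenergetic tubes (no beam hardening → no size/SFOV dependence); nominal
insert compositions; no registration (all volumes share a grid); no dose
calculation; Bethe ratio without corrections beyond the logarithmic term;
the synthetic cross-section model is accurate in structure, not in
sub-percent elemental values.
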