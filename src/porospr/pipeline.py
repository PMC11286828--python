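"""One-command reproduction of the synthetic study design.

``run_experiment`` chains every stage on synthetic data: build the
calibration phantom and scan it at 80 / 120 / 135 kV; fit the
dual-energy conversion constants and the single-energy stoichiometric
table; build porous-bone and soft-tissue samples plus a femur-like
phantom; convert each scan to SPR by both routes; compare ROI means
against the virtual range-pullback measurement on the ground-truth map;
and compute bone-mask statistics, scatter samples, WEPL range shifts and
the hypothetical 120 kV CT.  All randomness derives from the single
config seed, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .convert import (
    RoiCylinder,
    deedz_spr_map,
    mask_statistics,
    override_spr_region,
    roi_cylinder_mean,
    scatter_samples,
    sect_spr_map,
    spr_to_hypothetical_ct,
)
from .dect import fit_all, observations_from_materials, write_observations_csv
from .materials import load_material
from .phantom import (
    build_calibration_phantom,
    build_femur_phantom,
    build_porosity_phantom,
    default_scan,
    ground_truth_spr_volume,
    simulate_ct,
)
from .physics import BeamSpec, PhysicsConstants
from .raytrace import RayPath, range_shift, simulate_range_measurement, spr_from_range_pullback
from .sect import build_hu_spr_lut, fit_stoichiometric_model
from .volumes import save_spr, save_volume

__all__ = ["ExperimentConfig", "run_experiment"]

log = logging.getLogger("porospr")


@dataclass
class ExperimentConfig:
    """Configuration of the end-to-end synthetic experiment."""

    seed: int = 1
    out_dir: str = "porospr_run"
    grid_shape: tuple[int, int, int] = (128, 128, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    arrangement: str = "head"
    porosity_levels: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75)
    pore_model: str = "uniform"
    noise_sigmas: dict = field(
        default_factory=lambda: {"80kV": 7.0, "120kV": 5.0, "135kV": 7.0}
    )
    beam_energy_mev_u: float = 131.0
    water_range_mm: float = 155.0
    soft_tissue_override: bool = True
    sample_grid_shape: tuple[int, int, int] = (64, 64, 32)

    @classmethod
    def from_toml(cls, path: str | Path) -> "ExperimentConfig":
        import tomllib

        raw = tomllib.loads(Path(path).read_text())
        kwargs = {}
        for f in cls.__dataclass_fields__:
            if f in raw:
                v = raw[f]
                kwargs[f] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


def _scan_set(config: ExperimentConfig) -> dict:
    return {
        tube: default_scan(tube, noise_sigma_hu=config.noise_sigmas.get(tube, 0.0))
        for tube in ("80kV", "120kV", "135kV")
    }


def _stage(name):
    log.info("stage: %s", name)


def _mask_mean(volume, mask) -> float:
    return float(volume.data[mask].mean())


def run_experiment(config: ExperimentConfig) -> dict:
    """Run the full synthetic study; writes a report bundle and returns a summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    beam = BeamSpec.from_energy(config.beam_energy_mev_u, water_range=config.water_range_mm)
    constants = PhysicsConstants()
    scans = _scan_set(config)
    seed = int(config.seed)

    summary: dict = {"seed": seed, "version": __version__}

    try:
        # ---- stage 1: calibration -------------------------------------------
        _stage("calibration")
        calib = build_calibration_phantom(
            arrangement=config.arrangement, shape=config.grid_shape, spacing=config.spacing
        )
        vols = {
            tube: simulate_ct(calib, scan, seed=seed * 100 + k)
            for k, (tube, scan) in enumerate(scans.items())
        }
        insert_masks = {n: m for n, m in calib.masks.items() if n.startswith("insert_")}
        insert_mats = []
        for name in insert_masks:
            short = name.removeprefix("insert_")
            insert_mats.append(load_material("water" if short == "water" else f"insert_{short}"))
        hu_l = [_mask_mean(vols["80kV"], m) for m in insert_masks.values()]
        hu_h = [_mask_mean(vols["135kV"], m) for m in insert_masks.values()]
        hu_120 = [_mask_mean(vols["120kV"], m) for m in insert_masks.values()]
        observations = observations_from_materials(
            insert_mats, hu_l, hu_h, constants, hu_120=hu_120
        )
        write_observations_csv(observations, out / "insert_observations.csv")

        params = fit_all(observations, constants)
        params.to_json(out / "dect_params.json")
        summary["dect_params"] = {
            k: getattr(params, k)
            for k in ("a", "b", "alpha", "gamma_L", "c1_soft", "c0_soft", "c1_bone", "c0_bone")
        }
        summary["dect_fit_r_squared"] = params.r_squared

        model = fit_stoichiometric_model(observations, insert_mats)
        lut = build_hu_spr_lut(model, beam=beam, constants=constants)
        lut.to_csv(out / "sect_lut.csv")
        summary["stoichiometric"] = {"k1": model.k1, "k2": model.k2}
    except Exception as exc:  # noqa: BLE001 - stage reporting contract
        raise RuntimeError(f"experiment failed in stage 'calibration': {exc}") from exc

    # ---- stage 2: sample SPR accuracy (porous + soft samples) ---------------
    try:
        _stage("samples")
        mineral = load_material("hydroxyapatite")
        air = load_material("air")
        rows = []
        sample_specs = [("porous_bone", p) for p in config.porosity_levels]
        sample_specs += [("muscle", None), ("adipose", None)]
        for kind, p in sample_specs:
            if kind == "porous_bone":
                phantom = build_porosity_phantom(
                    mineral, air, p, pore_model=config.pore_model,
                    seed=seed * 10 + int(p * 100),
                    shape=config.sample_grid_shape, spacing=config.spacing,
                )
                label = f"porous_bone_p{p:.2f}"
            else:
                phantom = build_porosity_phantom(
                    load_material(kind), air, 0.0,
                    shape=config.sample_grid_shape, spacing=config.spacing,
                )
                label = f"soft_{kind}"
            truth = ground_truth_spr_volume(phantom, beam, constants)
            svols = {
                tube: simulate_ct(phantom, scan, seed=seed * 100 + 7 + j)
                for j, (tube, scan) in enumerate(scans.items())
            }
            dect, _ = deedz_spr_map(svols["80kV"], svols["135kV"], params, beam, constants)
            sect = sect_spr_map(svols["120kV"], lut)

            shape, sp = phantom.shape, phantom.spacing
            center = tuple((shape[a] - 1) / 2.0 * sp[a] for a in range(3))
            roi = RoiCylinder(center=center)  # 4 mm x 9 mm, anterior-posterior axis
            ray = RayPath(
                entry=(center[0], -10.0, center[2]),
                direction=(0.0, 1.0, 0.0),
                step=0.25 * min(sp),
                total_length=shape[1] * sp[1] + 20.0,
            )
            extent = (10.0 + center[1] - 15.0, 10.0 + center[1] + 15.0)
            meas = simulate_range_measurement(truth, ray, extent, beam)
            measured_spr = spr_from_range_pullback(meas)

            truth_roi, _ = roi_cylinder_mean(truth, roi)
            dect_roi, _ = roi_cylinder_mean(dect, roi)
            sect_roi, n_vox = roi_cylinder_mean(sect, roi)
            rows.append(
                {
                    "sample": label,
                    "porosity": p if p is not None else 0.0,
                    "spr_truth_roi": truth_roi,
                    "spr_measured": measured_spr,
                    "spr_dect": dect_roi,
                    "spr_sect": sect_roi,
                    "pct_err_dect": 100.0 * (dect_roi - measured_spr) / measured_spr,
                    "pct_err_sect": 100.0 * (sect_roi - measured_spr) / measured_spr,
                    "roi_voxels": n_vox,
                }
            )
        samples = pd.DataFrame(rows)
        samples.to_csv(out / "sample_spr.csv", index=False, float_format="%.6f")
        summary["samples"] = samples.to_dict("records")
        porous = samples[samples["sample"].str.startswith("porous")]
        if len(porous) >= 2:
            errs = porous.sort_values("porosity")
            summary["sect_error_increases_with_porosity"] = bool(
                np.all(np.diff(errs["pct_err_sect"].to_numpy()) > 0)
            )
            summary["dect_abs_error_below_sect"] = bool(
                np.all(
                    np.abs(errs["pct_err_dect"].to_numpy()[1:])
                    < np.abs(errs["pct_err_sect"].to_numpy()[1:])
                )
            )
    except RuntimeError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"experiment failed in stage 'samples': {exc}") from exc

    # ---- stage 3: femur-like phantom, maps and bone statistics --------------
    try:
        _stage("femur")
        femur = build_femur_phantom(shape=config.grid_shape, spacing=config.spacing)
        fvols = {
            tube: simulate_ct(femur, scan, seed=seed * 100 + 17 + j)
            for j, (tube, scan) in enumerate(scans.items())
        }
        truth = ground_truth_spr_volume(femur, beam, constants)
        dect, _ = deedz_spr_map(fvols["80kV"], fvols["135kV"], params, beam, constants)
        sect = sect_spr_map(fvols["120kV"], lut)
        bone = femur.masks["bone"]
        soft = femur.masks["soft_tissue"]
        if config.soft_tissue_override:
            dect = override_spr_region(dect, soft, 1.0)
            sect = override_spr_region(sect, soft, 1.0)
            truth = override_spr_region(truth, soft, 1.0)

        save_volume(fvols["120kV"], out / "femur_ct120.nii.gz")
        save_spr(truth, out / "femur_spr_truth.nii.gz")
        save_spr(dect, out / "femur_spr_dect.nii.gz")
        save_spr(sect, out / "femur_spr_sect.nii.gz")

        stats_d = mask_statistics(dect, bone)
        stats_s = mask_statistics(sect, bone)
        hist = pd.DataFrame(
            {
                "bin_left": stats_d["bin_edges"][:-1],
                "bin_right": stats_d["bin_edges"][1:],
                "count_dect": stats_d["counts"],
                "count_sect": stats_s["counts"],
            }
        )
        hist.to_csv(out / "bone_spr_histogram.csv", index=False, float_format="%.6f")
        median_shift_pct = 100.0 * (stats_d["median"] - stats_s["median"]) / stats_s["median"]
        summary["bone_median_spr"] = {
            "dect": stats_d["median"],
            "sect": stats_s["median"],
            "median_shift_pct": median_shift_pct,
        }
        scatter_samples(sect, dect, bone).to_csv(
            out / "delta_spr_scatter.csv", index=False, float_format="%.6f"
        )

        # range shifts: one ray through the bone, one through soft tissue only
        shape, sp = femur.shape, femur.spacing
        center = tuple((shape[a] - 1) / 2.0 * sp[a] for a in range(3))
        step = 0.25 * min(sp)
        length = shape[0] * sp[0] + 20.0
        ray_bone = RayPath(
            entry=(-10.0, center[1], center[2]), direction=(1.0, 0.0, 0.0),
            step=step, total_length=length,
        )
        ray_soft = RayPath(
            entry=(-10.0, center[1] + 40.0, center[2]), direction=(1.0, 0.0, 0.0),
            step=step, total_length=length,
        )
        ray_rows = []
        from .raytrace import wepl_along_ray

        for name, ray in (("through_bone", ray_bone), ("soft_tissue_only", ray_soft)):
            w_d = wepl_along_ray(dect, ray)
            w_s = wepl_along_ray(sect, ray)
            target = 0.9 * min(w_d, w_s)
            shift = range_shift(dect, sect, ray, target)
            ray_rows.append(
                {
                    "ray": name,
                    "wepl_dect_mm": w_d,
                    "wepl_sect_mm": w_s,
                    "target_wepl_mm": target,
                    "range_shift_mm": shift,
                }
            )
        rays = pd.DataFrame(ray_rows)
        rays.to_csv(out / "range_shifts.csv", index=False, float_format="%.6f")
        summary["range_shifts"] = rays.to_dict("records")

        hypo = spr_to_hypothetical_ct(dect, lut)
        save_volume(hypo, out / "femur_hypothetical_ct120.nii.gz")
        rt = sect_spr_map(hypo, lut)
        summary["hypothetical_ct_roundtrip_max_err"] = float(
            np.max(np.abs(rt.data - dect.data))
        )
    except RuntimeError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"experiment failed in stage 'femur': {exc}") from exc

    summary["note"] = (
        "Range comparison is WEPL-based (dose-free surrogate); no dose engine is used."
    )
    (out / "report.json").write_text(json.dumps(summary, indent=1))
    (out / "run_log.json").write_text(
        json.dumps({"seed": seed, "version": __version__, "config": asdict(config)}, indent=1)
    )
    return summary
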