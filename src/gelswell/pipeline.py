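"""Stage orchestration: moduli -> pressure decomposition -> chi fits -> kinetics.

A config (dict, YAML or JSON) names inputs per stage; stages execute in
dependency order and later stages may consume earlier products (the chi
fit needs the mixing pressure, which needs measured moduli when the
osmotic table carries only Pi_tot).  Partial configs run partial
pipelines.  Every run writes a manifest with input checksums, the full
config echo, package version and seed, so identical inputs reproduce
identical outputs.
"""

from __future__ import annotations

import datetime
import importlib.metadata
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .elasticity import fit_power_law, fit_shear_modulus
from .front import FrontSimConfig, sigmoid_phi_map, simulate_reswell, simulate_shrink
from .kinetics import analyze_curve, master_curve
from .presets import divalent_bath, pa_gel_params
from .thermo import FloryHugginsParams, SolventSpec, fit_chi, mixing_from_total

__all__ = ["run_pipeline", "DependencyError"]

STAGE_ORDER = ("generate", "modulus", "chi", "kinetics", "transition", "front")


class DependencyError(RuntimeError):
    """A stage's upstream product is missing from the config."""


def _version() -> str:
    try:
        return importlib.metadata.version("gelswell")
    except importlib.metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def run_pipeline(config: dict, out_dir: str | Path, seed: int = 0) -> dict:
    """Execute the configured stages; returns the result bundle as a dict.

    Writes per-stage JSON/CSV products plus ``manifest.json`` under
    ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    inputs: dict[str, str] = {}

    def note_input(path):
        inputs[str(path)] = gio.file_sha256(path)

    solvent = _solvent_from(config)

    for stage in STAGE_ORDER:
        if stage not in config:
            continue
        cfg = config[stage] or {}
        if stage == "generate":
            results["generate"] = _stage_generate(cfg, out, seed)
        elif stage == "modulus":
            results["modulus"] = _stage_modulus(cfg, out, note_input)
        elif stage == "chi":
            results["chi"] = _stage_chi(cfg, out, solvent, results, note_input)
        elif stage == "kinetics":
            results["kinetics"] = _stage_kinetics(cfg, out, note_input)
        elif stage == "transition":
            results["transition"] = _stage_transition(cfg, out, note_input)
        elif stage == "front":
            results["front"] = _stage_front(cfg, out, seed)
    if not results:
        raise DependencyError(
            f"config names no runnable stage; expected one of {STAGE_ORDER[1:]}"
        )

    manifest = {
        "package_version": _version(),
        "seed": seed,
        "inputs": inputs,
        "config": gio.round_sig(config),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    gio.json_dump(manifest, out / "manifest.json")
    return results


def _solvent_from(config: dict) -> SolventSpec:
    s = config.get("solvent", {})
    return SolventSpec(
        molar_volume=float(s.get("molar_volume", SolventSpec().molar_volume)),
        temperature=float(s.get("temperature", SolventSpec().temperature)),
    )


def _stage_generate(cfg: dict, out: Path, seed: int) -> dict:
    from . import synthetic as syn
    from .presets import REFERENCE_CHI

    produced = {}
    noise = syn.NoiseSpec(
        kind=cfg.get("noise_kind", "gaussian-relative"),
        level=float(cfg.get("noise_level", 0.0)),
        seed=seed,
    )
    if "stress_strain" in cfg:
        g = float(cfg["stress_strain"].get("G_kPa", 10.0)) * 1e3
        rec, gt = syn.gen_stress_strain(g, noise=noise)
        df = pd.DataFrame({"lam": rec.lam, "sigma_kPa": rec.sigma / 1e3})
        gio.write_table(df, out / "compression.csv")
        (out / "ground_truth_stress_strain.json").write_text(gt.to_json(indent=2))
        produced["compression.csv"] = asdict_gt(gt)
    if "mixing" in cfg:
        c = cfg["mixing"]
        fh = FloryHugginsParams(float(c.get("chi0", REFERENCE_CHI.chi0)),
                                float(c.get("chi1", REFERENCE_CHI.chi1)))
        phi = np.linspace(float(c.get("phi_min", 0.01)), float(c.get("phi_max", 0.1)),
                          int(c.get("n", 25)))
        phi_arr, pi, gt = syn.gen_mixing_series(fh, phi, noise=noise)
        df = pd.DataFrame({"phi": phi_arr, "pi_mix_kPa": pi / 1e3})
        gio.write_table(df, out / "osmotic.csv")
        (out / "ground_truth_mixing.json").write_text(gt.to_json(indent=2))
        produced["osmotic.csv"] = asdict_gt(gt)
    if "kinetics" in cfg:
        c = cfg["kinetics"]
        radii = np.asarray(c.get("radii_mm", [0.25, 0.375, 0.5]), float) * 1e-3
        curves, gt = syn.gen_swelling_curves(
            dc=float(c.get("Dc", 3e-11)),
            r_ratio=float(c.get("R", 0.25)),
            radii=radii,
            d_ratio=float(c.get("d_ratio", 1.3)),
            noise=noise,
        )
        rows = []
        for cv in curves:
            for t, d in zip(cv.t, cv.d):
                rows.append({"bead_id": cv.bead_id, "t_s": t, "d_mm": d * 1e3})
        gio.write_table(pd.DataFrame(rows), out / "kinetics.csv")
        meta = pd.DataFrame(
            {"bead_id": [cv.bead_id for cv in curves],
             "a_mm": [cv.radius * 1e3 for cv in curves],
             "d0_mm": [cv.d0 * 1e3 for cv in curves],
             "d_inf_mm": [cv.d_inf * 1e3 for cv in curves]}
        )
        gio.write_table(meta, out / "beads.csv")
        (out / "ground_truth_kinetics.json").write_text(gt.to_json(indent=2))
        produced["kinetics.csv"] = asdict_gt(gt)
    return produced


def asdict_gt(gt) -> dict:
    import json

    return json.loads(gt.to_json())


def _stage_modulus(cfg: dict, out: Path, note_input) -> dict:
    res: dict = {}
    if "input" in cfg:
        note_input(cfg["input"])
        recs = gio.load_compression(cfg["input"])
        res["samples"] = [
            {"sample_id": r.sample_id, "G_kPa": (f := fit_shear_modulus(r)).g / 1e3,
             "stderr_kPa": f.stderr / 1e3, "n_used": f.n_used}
            for r in recs
        ]
    if "series" in cfg:
        note_input(cfg["series"])
        series = gio.load_modulus_series(cfg["series"])
        fixed = cfg.get("fixed_exponent")
        fit = fit_power_law(series, None if fixed is None else float(fixed))
        res["power_law"] = {
            "g0_kPa": fit.g0 / 1e3,
            "exponent": fit.exponent,
            "stderr_exponent": fit.stderr_exponent,
        }
    if not res:
        raise DependencyError("modulus stage needs 'input' and/or 'series'")
    gio.json_dump(res, out / "modulus.json")
    return res


def _stage_chi(cfg: dict, out: Path, solvent, results: dict, note_input) -> dict:
    if "osmotic" not in cfg:
        raise DependencyError("chi stage needs an 'osmotic' table")
    note_input(cfg["osmotic"])
    df = gio.load_osmotic(cfg["osmotic"])
    if "pi_mix" in df.columns:
        pi_mix = df["pi_mix"].to_numpy()
    elif "pi_tot" in df.columns:
        if "G" in df.columns:
            g = df["G"].to_numpy()
        elif "modulus" in results and "power_law" in results["modulus"]:
            pl = results["modulus"]["power_law"]
            g = pl["g0_kPa"] * 1e3 * df["phi"].to_numpy() ** pl["exponent"]
        else:
            raise DependencyError(
                "chi stage: osmotic table has Pi_tot but no G column and no "
                "upstream 'modulus' stage produced a power law"
            )
        pi_mix = mixing_from_total(df["pi_tot"].to_numpy(), g)
    else:
        raise DependencyError("osmotic table needs pi_mix_kPa or pi_tot_kPa")
    fix = cfg.get("fix_chi0")
    fit = fit_chi(df["phi"].to_numpy(), pi_mix, solvent,
                  fix_chi0=None if fix is None else float(fix))
    res = {
        "chi0": fit.params.chi0,
        "chi1": fit.params.chi1,
        "stderr_chi0": fit.stderr_chi0,
        "stderr_chi1": fit.stderr_chi1,
        "residual_norm_kPa": fit.residual_norm / 1e3,
        "n_points": fit.n_points,
    }
    gio.json_dump(res, out / "chi.json")
    return res


def _stage_kinetics(cfg: dict, out: Path, note_input) -> dict:
    if "input" not in cfg:
        raise DependencyError("kinetics stage needs an 'input' table")
    note_input(cfg["input"])
    meta = cfg.get("meta")
    if meta:
        note_input(meta)
    curves = gio.load_kinetics(cfg["input"], meta)
    fits = [analyze_curve(c) for c in curves]
    res = {
        "beads": [
            {
                "bead_id": f.bead_id,
                "B1": f.B1,
                "tau1_s": f.tau1,
                "beta1": f.beta1,
                "R": f.R,
                "Dc_m2_per_s": f.Dc,
                "d_inf_mm": f.d_inf * 1e3,
            }
            for f in fits
        ]
    }
    if len(curves) > 1:
        mc = master_curve(curves, fits)
        res["collapse_score"] = mc.collapse_score
        rows = []
        for cv, rt, rd in zip(curves, mc.reduced_time, mc.reduced_diameter):
            for a, b in zip(rt, rd):
                rows.append({"bead_id": cv.bead_id, "t_reduced": a, "d_reduced": b})
        gio.write_table(pd.DataFrame(rows), out / "master.csv")
    gio.json_dump(res, out / "kinetics.json")
    return res


def _stage_transition(cfg: dict, out: Path, note_input) -> dict:
    from .thermo import transition_scan

    if "chi_table" not in cfg:
        raise DependencyError("transition stage needs a 'chi_table' input")
    note_input(cfg["chi_table"])
    grid, chi_of_salt = gio.load_chi_table(cfg["chi_table"])
    params = pa_gel_params(
        g0=float(cfg.get("g0_kPa", 10.0)) * 1e3,
        fixed_charge_per_monomer=float(cfg.get("fixed_charge_per_monomer", 0.02)),
    )
    c_mono = float(cfg.get("c_monovalent_mM", 40.0))
    scan = transition_scan(
        params, chi_of_salt, lambda c: divalent_bath(c, c_mono), grid,
        jump_factor=float(cfg.get("jump_factor", 3.0)),
    )
    res = {
        "transition_salt_mM": scan.transition_salt,
        "has_transition": scan.has_transition,
        "c_salt_mM": scan.salt_grid,
        "phi": scan.phi_stable,
    }
    gio.json_dump(res, out / "transition.json")
    return res


def _stage_front(cfg: dict, out: Path, seed: int) -> dict:
    sim = FrontSimConfig(
        bead_radius=float(cfg.get("bead_radius_mm", 0.5)) * 1e-3,
        n_shells=int(cfg.get("n_shells", 100)),
        D_ion=float(cfg.get("D_ion", 1e-9)),
        exchange_rate=float(cfg.get("exchange_rate", 0.01)),
        phi_map=sigmoid_phi_map(),
        bath=divalent_bath(float(cfg.get("bath_ca_mM", 5.0))),
        t_end=float(cfg.get("t_end_s", 900.0)),
        seed=seed,
        safety=float(cfg.get("safety", 3.0)),
    )
    traj, state = simulate_shrink(sim, return_state=True)
    df = pd.DataFrame(
        {
            "t_s": traj.t,
            "d_mm": traj.diameter * 1e3,
            "front_r_mm": traj.front_radius * 1e3,
            "total_Ca_nmol": traj.total_ca * 1e9,
        }
    )
    gio.write_table(df, out / "trajectory.csv")
    res = {
        "final_diameter_mm": float(traj.diameter[-1]) * 1e3,
        "conservation_error": traj.conservation_error(),
        "n_records": len(traj.t),
    }
    if cfg.get("reswell", False):
        traj2 = simulate_reswell(sim, state)
        df2 = pd.DataFrame(
            {
                "t_s": traj2.t,
                "d_mm": traj2.diameter * 1e3,
                "front_r_mm": traj2.front_radius * 1e3,
                "total_Ca_nmol": traj2.total_ca * 1e9,
            }
        )
        gio.write_table(df2, out / "trajectory_reswell.csv")
        res["reswollen_diameter_mm"] = float(traj2.diameter[-1]) * 1e3
    gio.json_dump(res, out / "front.json")
    return res
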