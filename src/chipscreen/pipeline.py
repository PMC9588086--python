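"""End-to-end demo pipeline: simulate inputs, run every analysis stage.

A pipeline run is configured by a flat mapping (usually loaded from YAML)
with a global ``seed``, a ``stages`` list and one optional parameter block
per stage.  Stages are validated before any work happens, run in the order
given, and contribute a JSON-serializable block to the run report.  For a
fixed config (seed included) the run is deterministic, so rerunning
reproduces every output byte-for-byte.

Supported stages
----------------
``transport``        design table for the built-in molecule panel (or a CSV)
``ladder``           predicted dilution fractions of the width network
``mixing``           simulate mixing images across flow rates, extract AMI/slope
``dilution``         simulate end-of-mixer channel images, estimate dilution
``fcs``              simulate a noisy FCS curve, fit it, convert to diffusivity
``penetration``      erf penetration depth/time grid and time-to-threshold
``dose_response``    simulate a viability table, fit EC50
``cells``            simulate a live/dead field, count it, compute viability
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np

from chipscreen import doseresponse, fcs, io, mixer, network, penetration
from chipscreen import synthetic, transport
from chipscreen._version import __version__
from chipscreen.exceptions import ConfigError

STAGES = (
    "transport",
    "ladder",
    "mixing",
    "dilution",
    "fcs",
    "penetration",
    "dose_response",
    "cells",
)

# fixed per-stage seed offsets keep stages decoupled but fully determined
_SEED_OFFSET = {name: 1000 + 17 * i for i, name in enumerate(STAGES)}


def demo_config(seed: int = 0) -> dict:
    """A self-contained configuration exercising every stage."""
    return {
        "seed": int(seed),
        "stages": list(STAGES),
        "transport": {"distance_um": 150.0},
        "mixing": {"flow_rates_ul_min": [1.0, 1.5, 2.0, 5.0, 10.0], "noise_sd": 1.0},
        "dilution": {"fractions": [1.0, 0.51, 0.26, 0.0], "noise_sd": 1.0},
        "fcs": {
            "n_particles": 1.0,
            "tau_d_s": 2.35e-5,
            "p": 0.2,
            "triplet_amp": 0.15,
            "tau_t_s": 2e-6,
            "noise_frac": 0.02,
            "r0_m": 2.0e-7,
        },
        "penetration": {
            "c0_mm": 2.0,
            "diffusivity_m2_s": 2.55e-10,
            "depth_um": 250.0,
            "times_h": [1.0, 4.0, 24.0, 48.0],
            "threshold_mm": 1.9,
        },
        "dose_response": {
            "top": 90.0,
            "bottom": 10.0,
            "ec50": 0.61,
            "hill": 2.0,
            "doses": [0.0, 0.25, 0.5, 1.0, 2.0, 4.0],
            "noise_sd": 2.0,
        },
        "cells": {"n_live": 90, "n_dead": 10},
    }


def _stage_seed(config: Mapping, stage: str) -> int:
    return (int(config.get("seed", 0)) + _SEED_OFFSET[stage]) % (2**31 - 1)


def run_pipeline(config: Mapping, outdir: str | Path | None = None) -> dict:
    """Execute the configured stages; return (and optionally write) the report.

    Raises :class:`ConfigError` on an unknown stage before running anything;
    a failure inside a stage aborts the run with the failing stage recorded
    in the partial report under ``"failed_stage"``.
    """
    stages = list(config.get("stages", []))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stage(s) {unknown}; valid stages: {list(STAGES)}")
    report: dict = {"version": __version__, "seed": int(config.get("seed", 0)), "stages": {}}
    if outdir is not None and stages:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    for stage in stages:
        params = dict(config.get(stage, {}))
        runner = globals()[f"_run_{stage}"]
        try:
            report["stages"][stage] = runner(params, _stage_seed(config, stage), outdir)
        except Exception as exc:
            report["failed_stage"] = stage
            report["error"] = f"{type(exc).__name__}: {exc}"
            if outdir is not None:
                io.write_json(Path(outdir) / "report.json", report)
            raise
    if outdir is not None and stages:
        io.write_json(Path(outdir) / "report.json", report)
    return report


def _run_transport(params: dict, seed: int, outdir: Path | None) -> dict:
    conditions = transport.TransportConditions(
        temperature=params.get("temperature_k", transport.DEFAULT_TEMPERATURE),
        viscosity=params.get("viscosity_pa_s", transport.DEFAULT_VISCOSITY),
    )
    molecules = (
        io.read_molecules(params["molecules_csv"])
        if "molecules_csv" in params
        else list(transport.CHEMOTHERAPEUTICS)
    )
    table = transport.transport_table(
        molecules, conditions, params.get("distance_um", 150.0) * 1e-6
    )
    if outdir is not None:
        table.to_csv(outdir / "transport_table.csv", index=False)
    return {"n_molecules": len(molecules), "table": table.to_dict(orient="records")}


def _run_ladder(params: dict, seed: int, outdir: Path | None) -> dict:
    net = params.get("network", network.WIDTH_LADDER_NETWORK)
    fractions = network.ladder_fractions(net)
    return {"outputs": list(net["outputs"]), "fractions": fractions}


def _run_mixing(params: dict, seed: int, outdir: Path | None) -> dict:
    flow_rates = params.get("flow_rates_ul_min", [1.0, 1.5, 2.0, 5.0, 10.0])
    noise_sd = params.get("noise_sd", 1.0)
    rows = []
    for i, flow in enumerate(flow_rates):
        # velocity scales linearly with flow from the 1 uL/min = 1.11 mm/s point
        spec = synthetic.MixingImageSpec(
            velocity=1.11e-3 * flow, noise_sd=noise_sd, seed=seed + i
        )
        image, _truth = synthetic.make_mixing_image(spec)
        profile = mixer.extract_profile(image, "blue")
        profile = mixer.normalize_profile(profile, spec.background_level, spec.dye_level)
        rows.append(
            {
                "flow_ul_min": flow,
                "ami": mixer.absolute_mixing_index(profile),
                "slope_per_um": mixer.profile_slope(profile),
            }
        )
    slope, intercept, r2 = mixer.mixing_vs_flowrate(
        [(r["flow_ul_min"], r["ami"]) for r in rows]
    )
    if outdir is not None:
        import pandas as pd

        pd.DataFrame(rows).to_csv(outdir / "mixing_metrics.csv", index=False)
    return {"metrics": rows, "ami_vs_flow": {"slope": slope, "intercept": intercept, "r2": r2}}


def _run_dilution(params: dict, seed: int, outdir: Path | None) -> dict:
    fractions = params.get("fractions", [1.0, 0.5, 0.25, 0.0])
    noise_sd = params.get("noise_sd", 1.0)
    images = []
    for i, frac in enumerate(fractions):
        # fully mixed end-of-mixer channel: flat profile at the channel fraction
        spec = synthetic.MixingImageSpec(
            downstream_len=1.0, velocity=1e-6, noise_sd=noise_sd, seed=seed + i
        )
        image, _ = synthetic.make_mixing_image(spec)
        level = spec.background_level + frac * (spec.dye_level - spec.background_level)
        pixels = image.pixels.copy()
        pixels[..., 2] = np.clip(
            level
            + (noise_sd * np.random.default_rng(seed + i).standard_normal(pixels.shape[:2])),
            0,
            None,
        )
        images.append(mixer.ChannelImage(pixels=pixels, pixel_size=image.pixel_size))
    estimated = mixer.estimate_dilution(images)
    return {"true_percent": [100 * f for f in fractions], "estimated_percent": list(estimated)}


def _run_fcs(params: dict, seed: int, outdir: Path | None) -> dict:
    true_params = fcs.FcsParams(
        n_particles=params.get("n_particles", 1.0),
        tau_d=params.get("tau_d_s", 2.35e-5),
        p=params.get("p", 0.2),
        triplet_amp=params.get("triplet_amp", 0.15),
        tau_t=params.get("tau_t_s", 2e-6),
    )
    lags = np.logspace(-7, -3, 50)
    curve, _ = synthetic.make_fcs_curve(
        true_params, lags, noise_frac=params.get("noise_frac", 0.02), seed=seed
    )
    if outdir is not None:
        io.write_fcs_curve(outdir / "fcs_curve.csv", curve)
    results = fcs.fit_fcs(curve, true_params, fixed=("p",))
    out = results.to_dict()
    out["true_tau_d_s"] = true_params.tau_d
    if "r0_m" in params:
        instrument = fcs.FcsInstrument(
            r0=params["r0_m"], z0=params["r0_m"] / true_params.p
        )
        out["diffusivity_m2_s"] = results.diffusivity(instrument)
    return out


def _run_penetration(params: dict, seed: int, outdir: Path | None) -> dict:
    c0 = params.get("c0_mm", 2.0)
    d = params.get("diffusivity_m2_s", 2.55e-10)
    depth = params.get("depth_um", 250.0) * 1e-6
    times_h = params.get("times_h", [1.0, 4.0, 24.0, 48.0])
    concentrations = [
        penetration.concentration_at(penetration.PenetrationSpec(c0, d, depth, th * 3600.0))
        for th in times_h
    ]
    out = {
        "c0_mm": c0,
        "depth_um": depth * 1e6,
        "times_h": list(times_h),
        "concentration_mm": concentrations,
    }
    if "threshold_mm" in params:
        t = penetration.time_to_threshold(params["threshold_mm"], depth, d, c0)
        out["time_to_threshold_h"] = t / 3600.0
    return out


def _run_dose_response(params: dict, seed: int, outdir: Path | None) -> dict:
    data, truth = synthetic.make_dose_response(
        top=params.get("top", 90.0),
        bottom=params.get("bottom", 10.0),
        ec50=params.get("ec50", 0.61),
        hill=params.get("hill", 2.0),
        doses=params.get("doses", [0.0, 0.25, 0.5, 1.0, 2.0, 4.0]),
        noise_sd=params.get("noise_sd", 2.0),
        seed=seed,
    )
    if outdir is not None:
        io.write_dose_response(outdir / "dose_response.csv", data)
    results = doseresponse.fit_dose_response(data)
    out = results.to_dict()
    out["truth"] = truth
    return out


def _run_cells(params: dict, seed: int, outdir: Path | None) -> dict:
    spec = synthetic.CellImageSpec(
        n_live=params.get("n_live", 90), n_dead=params.get("n_dead", 10), seed=seed
    )
    image, true_counts = synthetic.make_cell_image(spec)
    if outdir is not None:
        io.write_image(outdir / "cells.tif", image.astype(np.float32))
    n_live, n_dead = synthetic.count_cells(image)
    return {
        "true_counts": list(true_counts),
        "counted": [n_live, n_dead],
        "viability_percent": doseresponse.viability(
            doseresponse.ViabilityCount(n_live, n_dead)
        ),
    }
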