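"""End-to-end pipeline driver: synth -> (clutter) -> piv -> hemo -> compare.

Configured by a single YAML/dict config validated against a small
schema; every run writes a manifest recording the config snapshot,
seeds, package versions and all thresholds actually used, so each
output can be traced back to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Dict, Optional, Union

import numpy as np
import yaml

from . import __version__
from . import clutter as clutter_mod
from . import compare as compare_mod
from . import hemo, io, piv, synth
from .types import BLOOD_MIMICKING_FLUID, VesselSpec

__all__ = ["RunManifest", "run_pipeline", "validate_config", "DEMO_CONFIG"]


_SCHEMA: Dict[str, Any] = {
    "seed": int,
    "out_dir": str,
    "synth": {
        "mode": str,  # "control" | "stenosed"
        "period_s": float,
        "forward_volume_ml": float,
        "backflow_volume_ml": float,
        "cfa_diameter_mm": float,
        "stenosis_area_reduction": float,
        "grid_spacing_mm": float,
        "n_time": int,
        "n_cycles": int,
        "render": {
            "pixel_size_mm": float,
            "frame_rate_fps": float,
            "noise_sd": float,
            "seeding_density_per_mm2": float,
        },
        "clutter": {
            "enabled": bool,
            "rank": int,
            "amplitude": float,
            "velocity_mm_s": float,
        },
    },
    "piv": {"schedule": object},
    "analyze": {"vc": bool, "tawss": bool},
    "compare": {"enabled": bool, "scope": str},
}


DEMO_CONFIG: Dict[str, Any] = {
    "seed": 1,
    "out_dir": "runs/demo",
    "synth": {
        "mode": "stenosed",
        # demo-scale fast cycle so a handful of frames span full cycles
        "period_s": 0.05,
        "forward_volume_ml": 0.48,
        "backflow_volume_ml": 0.115,
        "cfa_diameter_mm": 8.9,
        "stenosis_area_reduction": 0.75,
        "grid_spacing_mm": 0.4,
        "n_time": 25,
        "n_cycles": 2,
        "render": {
            "pixel_size_mm": 0.2,
            "frame_rate_fps": 500.0,
            "noise_sd": 1.0,
        },
        "clutter": {"enabled": False},
    },
    "piv": {"schedule": {"window_sizes": [32, 16], "overlap": 0.5,
                         "correlation_averaging_n": 1,
                         "pairing_mode": "sliding"}},
    "analyze": {"vc": True, "tawss": False},
    "compare": {"enabled": True, "scope": "all_timepoints"},
}


def validate_config(config: Dict[str, Any], schema: Optional[Dict] = None,
                    path: str = "") -> None:
    """Reject unknown keys before any compute."""
    if schema is None:
        schema = _SCHEMA
    for key, val in config.items():
        here = f"{path}.{key}" if path else key
        if key not in schema:
            raise ValueError(f"unknown config key: {here!r}")
        sub = schema[key]
        if isinstance(sub, dict):
            if not isinstance(val, dict):
                raise ValueError(f"config key {here!r} must be a mapping")
            validate_config(val, sub, here)


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    config: Dict[str, Any]
    seed: int
    versions: Dict[str, str]
    timestamp: str
    input_hashes: Dict[str, str] = dc_field(default_factory=dict)
    thresholds: Dict[str, Any] = dc_field(default_factory=dict)
    outputs: Dict[str, str] = dc_field(default_factory=dict)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str))


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: Union[Dict[str, Any], str, Path]) -> RunManifest:
    """Execute the configured pipeline; deterministic for fixed seeds.

    Stages: generate the phantom flow field and particle images,
    optionally contaminate and SVD-filter them, recover velocity
    fields with multipass PIV, compute vector complexity (and TAWSS if
    configured), and compare the PIV ensemble against the ground-truth
    field ensemble.  All outputs plus a manifest land in ``out_dir``.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    validate_config(config)

    seed = int(config.get("seed", 0))
    out_dir = Path(config.get("out_dir", "runs/run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config, seed=seed,
        versions={"hemoveloc": __version__, "numpy": np.__version__},
        timestamp=_time.strftime("%Y-%m-%dT%H:%M:%S"),
    )

    def stage(name):
        def wrap(exc):
            return RuntimeError(f"pipeline stage {name!r} failed: {exc}")
        return wrap

    # --- synth ---
    scfg = config.get("synth", {})
    try:
        period = float(scfg.get("period_s", 1.0))
        waveform = synth.make_triphasic_waveform(
            period=period,
            forward_volume=float(scfg.get("forward_volume_ml", 9.6)),
            backflow_volume=float(scfg.get("backflow_volume_ml", 2.3)),
        )
        vessel = VesselSpec(
            cfa_diameter=float(scfg.get("cfa_diameter_mm", 8.9)),
            stenosis_area_reduction=(
                float(scfg.get("stenosis_area_reduction", 0.75))
                if scfg.get("mode", "stenosed") == "stenosed" else 0.0
            ),
        )
        field = synth.stenotic_field(
            vessel, waveform,
            grid_spacing=float(scfg.get("grid_spacing_mm", 0.4)),
            n_time=int(scfg.get("n_time", 25)),
        )
        io.write_waveform_csv(waveform, out_dir / "waveform.csv")
        io.write_field_h5(field, out_dir / "ground_truth.h5")
        manifest.outputs["waveform"] = "waveform.csv"
        manifest.outputs["ground_truth"] = "ground_truth.h5"

        rcfg = scfg.get("render", {})
        n_cycles = int(scfg.get("n_cycles", 2))
        frame_rate = float(rcfg.get("frame_rate_fps", 500.0))
        n_frames = int(round(n_cycles * period * frame_rate)) + 1
        images = synth.render_particle_images(
            field,
            seeding_density=rcfg.get("seeding_density_per_mm2"),
            pixel_size=float(rcfg.get("pixel_size_mm", 0.2)),
            frame_rate=frame_rate,
            n_frames=n_frames,
            noise_sd=float(rcfg.get("noise_sd", 1.0)),
            seed=seed,
        )
        io.write_images_tiff(images, out_dir / "images.tif")
        manifest.outputs["images"] = "images.tif"
        manifest.input_hashes["images.tif"] = _hash_file(out_dir / "images.tif")
    except Exception as exc:  # noqa: BLE001
        raise stage("synth")(exc) from exc

    # --- clutter ---
    ccfg = scfg.get("clutter", {})
    if ccfg.get("enabled", False):
        try:
            images = synth.add_clutter(
                images,
                clutter_rank=int(ccfg.get("rank", 3)),
                clutter_amplitude=float(ccfg.get("amplitude", 40.0)),
                clutter_velocity=float(ccfg.get("velocity_mm_s", 1.0)),
                seed=seed + 1,
            )
            dec = clutter_mod.casorati_svd(images)
            low, high = clutter_mod.select_rank_thresholds(dec)
            images = clutter_mod.svd_filter(images, low, high)
            manifest.thresholds["svd_low"] = low
            manifest.thresholds["svd_high"] = high
        except Exception as exc:  # noqa: BLE001
            raise stage("clutter")(exc) from exc

    # --- piv ---
    pcfg = config.get("piv", {})
    try:
        sched_spec = pcfg.get("schedule", "opiv")
        if isinstance(sched_spec, str):
            schedule = piv.SCHEDULE_PRESETS[sched_spec]
        else:
            schedule = piv.PivSchedule(
                window_sizes=tuple(sched_spec["window_sizes"]),
                overlap=float(sched_spec.get("overlap", 0.5)),
                correlation_averaging_n=int(
                    sched_spec.get("correlation_averaging_n", 1)),
                pairing_mode=sched_spec.get("pairing_mode", "non_overlapping"),
            )
        fields = piv.multipass_piv(images, schedule)
        fields = piv.postprocess_fields(fields, spatial_gaussian=True)
        io.write_field_h5(fields, out_dir / "piv_fields.h5")
        manifest.outputs["piv_fields"] = "piv_fields.h5"
        manifest.thresholds["piv_schedule"] = {
            "window_sizes": list(schedule.window_sizes),
            "overlap": schedule.overlap,
            "correlation_averaging_n": schedule.correlation_averaging_n,
            "pairing_mode": schedule.pairing_mode,
        }
    except Exception as exc:  # noqa: BLE001
        raise stage("piv")(exc) from exc

    # --- analyze ---
    acfg = config.get("analyze", {})
    try:
        if acfg.get("vc", True):
            vc = hemo.vector_complexity(fields)
            np.savetxt(
                out_dir / "vc.csv",
                np.column_stack([vc.time, vc.vc, vc.n_vectors]),
                delimiter=",", header="time_s,vc,n_vectors", comments="",
            )
            manifest.outputs["vc"] = "vc.csv"
        if acfg.get("tawss", False):
            upper, lower = hemo.tube_walls(field)
            prof = hemo.tawss(field, upper, BLOOD_MIMICKING_FLUID)
            np.savetxt(
                out_dir / "tawss.csv",
                np.column_stack([prof.arc_length, prof.tawss]),
                delimiter=",", header="arc_length_cm,tawss_Pa", comments="",
            )
            manifest.outputs["tawss"] = "tawss.csv"
    except Exception as exc:  # noqa: BLE001
        raise stage("analyze")(exc) from exc

    # --- compare ---
    ocfg = config.get("compare", {})
    if ocfg.get("enabled", False):
        try:
            n_cycles_avail = max(1, int(fields.t[-1] // period))
            piv_ens = compare_mod.align_cycles(fields, period, n_cycles_avail)
            truth_ens = compare_mod.ensemble_from_periodic(field)
            truth_on_piv = compare_mod.resample_to_reference(truth_ens, piv_ens)
            report = compare_mod.limits_of_agreement(
                piv_ens, truth_on_piv, scope=ocfg.get("scope", "all_timepoints")
            )
            (out_dir / "agreement.json").write_text(json.dumps({
                "mean_difference_cm_s": report.mean_difference,
                "sd_difference_cm_s": report.sd_difference,
                "loa_low_cm_s": report.loa_low,
                "loa_high_cm_s": report.loa_high,
                "n": report.n,
            }, indent=2))
            manifest.outputs["agreement"] = "agreement.json"
        except Exception as exc:  # noqa: BLE001
            raise stage("compare")(exc) from exc

    manifest.to_json(out_dir / "manifest.json")
    return manifest
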