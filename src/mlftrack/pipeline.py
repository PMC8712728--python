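"""End-to-end comparison pipeline: phantom -> models -> three trackers -> metrics.

Runs tensor-based, FOD-peak and multi-level tracking on the same inputs and
computes the assessment metrics (radial extent per hemisphere per algorithm,
coverage of the tensor-based reconstruction by the other two, coverage of the
FOD baseline by the multi-level result). Fully deterministic given the
configuration and seed; two runs with the same config produce byte-identical
summary JSON.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fod_model import (
    SphericalHarmonicBasis,
    calibrate_response_recursive,
    csd_deconvolve,
)
from .formats_io import (
    BinaryMask,
    Tractogram,
    ValidationError,
    read_dwi,
    read_gradient_table,
    read_mask,
    write_tractogram,
)
from .metrics import coverage, radial_extent, visitation_mask
from .mlft import MultiLevelBundle, filter_interhemispheric, mlft_track
from .phantom import PhantomSpec, make_branching_phantom
from .tensor_model import fit_tensor
from .tracking import TrackingParams, track_bundle

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class RunConfig:
    """Inputs and parameters of one comparison run.

    Either ``phantom`` is set (synthetic run) or ``paths`` points at
    dwi/bval/bvec and mask files on one grid. All tracking defaults equal the
    emulated clinical protocol.
    """

    phantom: PhantomSpec | None = field(default_factory=PhantomSpec)
    paths: dict | None = None
    params: TrackingParams = field(default_factory=TrackingParams)
    l_max: int = 6
    output_dir: str = "results"
    log_level: str = "INFO"

    @staticmethod
    def default_yaml() -> str:
        spec = PhantomSpec()
        params = TrackingParams()
        cfg = {
            "phantom": {
                "dims": list(spec.dims),
                "voxel_size": list(spec.voxel_size),
                "branch_angles": list(spec.branch_angles),
                "branch_level_fraction": spec.branch_level_fraction,
                "lambda_parallel": spec.lambda_parallel,
                "lambda_perp": spec.lambda_perp,
                "S0": spec.S0,
                "snr": spec.snr,
                "rng_seed": spec.rng_seed,
            },
            "params": {
                "step_size": params.step_size,
                "angle_threshold": params.angle_threshold,
                "fa_threshold": params.fa_threshold,
                "peak_threshold": params.peak_threshold,
                "seeds_per_voxel": params.seeds_per_voxel,
                "max_levels": params.max_levels,
                "max_length": params.max_length,
                "rng_seed": params.rng_seed,
            },
            "l_max": 6,
            "output_dir": "results",
            "log_level": "INFO",
        }
        return yaml.safe_dump(cfg, sort_keys=False)

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        phantom = None
        if "paths" not in raw or raw.get("phantom") is not None:
            ph = dict(raw.get("phantom") or {})
            for key in ("dims", "voxel_size", "branch_angles", "volume_fractions"):
                if key in ph and ph[key] is not None:
                    ph[key] = tuple(ph[key])
            phantom = PhantomSpec(**ph)
        params = TrackingParams(**(raw.get("params") or {}))
        return RunConfig(
            phantom=phantom,
            paths=raw.get("paths"),
            params=params,
            l_max=int(raw.get("l_max", 6)),
            output_dir=str(raw.get("output_dir", "results")),
            log_level=str(raw.get("log_level", "INFO")),
        )


def _load_inputs(config: RunConfig):
    """Returns (dwi, masks dict, seed_plane, hemisphere masks or None)."""
    if config.paths is not None:
        p = config.paths
        gradients = read_gradient_table(p["bval"], p["bvec"])
        dwi = read_dwi(p["dwi"], gradients)
        grid = dwi.grid
        masks = {
            "seed": read_mask(p["seed"], grid),
            "tracking": read_mask(p["tracking"], grid),
            "motor_left": read_mask(p["motor_left"], grid),
            "motor_right": read_mask(p["motor_right"], grid),
        }
        hemi = None
        if "hemisphere_left" in p and "hemisphere_right" in p:
            hemi = (
                read_mask(p["hemisphere_left"], grid),
                read_mask(p["hemisphere_right"], grid),
            )
        seed_vox = np.argwhere(masks["seed"].values > 0)
        if len(seed_vox) == 0:
            raise ValidationError("empty seed mask")
        plane = float(grid.voxel_to_world(seed_vox.astype(float))[:, 2].mean())
        return dwi, masks, plane, hemi
    dwi, truth = make_branching_phantom(config.phantom)
    masks = {
        "seed": truth.seed_mask,
        "tracking": truth.tracking_mask,
        "motor_left": truth.motor_mask_left,
        "motor_right": truth.motor_mask_right,
    }
    hemi = (truth.hemisphere_mask_left, truth.hemisphere_mask_right)
    return dwi, masks, truth.seed_plane_world, hemi


def _as_bundle(tractogram: Tractogram) -> MultiLevelBundle:
    from .mlft import LevelStreamline

    return MultiLevelBundle(
        levels=[[LevelStreamline(streamline=s, level=1) for s in tractogram]],
        grid=tractogram.grid,
    )


def run_comparison(config: RunConfig, output_dir: str | Path | None = None) -> dict:
    """Run the three-way comparison; writes tractograms + summary, returns manifest."""
    outdir = Path(output_dir if output_dir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    stage = "load_inputs"
    try:
        t0 = time.perf_counter()
        dwi, masks, seed_plane, hemi = _load_inputs(config)
        grid = dwi.grid
        timings[stage] = time.perf_counter() - t0

        stage = "fit_models"
        t0 = time.perf_counter()
        basis = SphericalHarmonicBasis(config.l_max)
        tensors = fit_tensor(dwi, masks["tracking"])
        response = calibrate_response_recursive(dwi, masks["tracking"], basis)
        fods = csd_deconvolve(dwi, response, masks["tracking"], basis)
        timings[stage] = time.perf_counter() - t0

        stage = "tracking"
        t0 = time.perf_counter()
        bundles: dict[tuple[str, str], MultiLevelBundle] = {}
        diagnostics: dict[str, dict] = {}
        for hemi_name in ("left", "right"):
            motor = masks[f"motor_{hemi_name}"]
            dti = track_bundle(
                "dti", tensors, masks["seed"], masks["tracking"], motor, config.params
            )
            csd = track_bundle(
                "csd", fods, masks["seed"], masks["tracking"], motor, config.params
            )
            ml = mlft_track(
                fods, masks["seed"], motor, masks["tracking"], config.params
            )
            bundles[("dti", hemi_name)] = _as_bundle(dti.tractogram)
            bundles[("csd", hemi_name)] = _as_bundle(csd.tractogram)
            bundles[("mlft", hemi_name)] = ml
            diagnostics[f"dti_{hemi_name}"] = dti.termination_histogram
            diagnostics[f"csd_{hemi_name}"] = csd.termination_histogram
        if hemi is not None:
            left_mask, right_mask = hemi
            bundles = {
                key: filter_interhemispheric(b, left_mask, right_mask, seed_plane)
                for key, b in bundles.items()
            }
        timings[stage] = time.perf_counter() - t0

        stage = "metrics"
        t0 = time.perf_counter()
        rows = []
        extents: dict[str, float] = {}
        coverages: dict[str, float | None] = {}
        vis = {
            key: visitation_mask(b.merged, grid) for key, b in bundles.items()
        }
        for hemi_name in ("left", "right"):
            for algo in ("dti", "csd", "mlft"):
                ext = radial_extent(
                    vis[(algo, hemi_name)], masks[f"motor_{hemi_name}"], hemi_name
                ).degrees
                extents[f"{algo}_{hemi_name}"] = ext
                rows.append(
                    {
                        "hemisphere": hemi_name,
                        "algorithm": algo,
                        "n_streamlines": len(bundles[(algo, hemi_name)].merged),
                        "radial_extent_deg": ext,
                    }
                )
            for algo in ("csd", "mlft"):
                key = f"dti_by_{algo}_{hemi_name}"
                try:
                    coverages[key] = coverage(
                        vis[("dti", hemi_name)], vis[(algo, hemi_name)]
                    ).percent
                except ValidationError:
                    coverages[key] = None
            try:
                coverages[f"csd_by_mlft_{hemi_name}"] = coverage(
                    vis[("csd", hemi_name)], vis[("mlft", hemi_name)]
                ).percent
            except ValidationError:
                coverages[f"csd_by_mlft_{hemi_name}"] = None
        timings[stage] = time.perf_counter() - t0

        stage = "write_outputs"
        tract_files = {}
        for (algo, hemi_name), b in bundles.items():
            path = outdir / f"tracks_{algo}_{hemi_name}.tck"
            write_tractogram(b.merged, path)
            tract_files[f"{algo}_{hemi_name}"] = path.name
            if algo == "mlft":
                for lvl in range(1, b.n_levels + 1):
                    write_tractogram(
                        b.level_tractogram(lvl),
                        outdir / f"tracks_mlft_{hemi_name}_level{lvl}.tck",
                    )
        summary = {
            "schema_version": SCHEMA_VERSION,
            "rng_seed": config.params.rng_seed,
            "n_streamlines": {
                f"{algo}_{hemi_name}": len(bundles[(algo, hemi_name)].merged)
                for algo in ("dti", "csd", "mlft")
                for hemi_name in ("left", "right")
            },
            "mlft_level_counts": {
                hemi_name: [
                    len(lvl) for lvl in bundles[("mlft", hemi_name)].levels
                ]
                for hemi_name in ("left", "right")
            },
            "radial_extent_deg": extents,
            "coverage_percent": coverages,
            "tractograms": dict(sorted(tract_files.items())),
            "complete": True,
        }
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )
        pd.DataFrame(rows).to_csv(outdir / "results.csv", index=False)
        log = {
            "timings_sec": {k: round(v, 3) for k, v in timings.items()},
            "terminations": diagnostics,
        }
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
        logger.info("comparison complete: %s", outdir / "summary.json")
        return summary
    except Exception as exc:
        (outdir / "summary.json").write_text(
            json.dumps(
                {
                    "schema_version": SCHEMA_VERSION,
                    "complete": False,
                    "failed_stage": stage,
                    "error": str(exc),
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
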