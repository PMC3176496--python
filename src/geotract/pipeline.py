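"""The end-to-end pipeline: precompute -> track -> filter -> rank.

A single YAML/JSON config document drives a full run.  Schema sketch::

    input: tensors.nii.gz          # or  phantom: {kind: halfplane, ...}
    dialect: lower
    tracking: {h: 0.1, solver: rk2, max_steps: 4096,
               interpolation: trilinear, rng_seed: 0}
    seeds:  {region: [[10,10,10],[20,20,20]], n_seeds: 100,
             direction_mode: uniform_sphere, directions_per_seed: 8}
    filter: {roi: {box: [[30,0,0],[40,63,63]]}}   # optional
    rank: true                                    # optional
    output: {fibers: fibers.json, format: json, report: report.json}

Per-stage counts (seeds, fibers, terminations by reason) and the fully
resolved configuration are logged and returned, so any run can be
reproduced from its report alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import phantoms
from .connectivity import ROI, default_score, filter_through_region, rank_fibers
from .io import read_tensor_volume, write_fibers
from .providers import GridFieldProvider
from .tensors import TensorVolume, precompute
from .tracking import SeedSpec, TrackingConfig, generate_seeds, trace_batch

__all__ = ["PipelineError", "run_pipeline", "build_phantom"]

log = logging.getLogger("geotract")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def build_phantom(spec: dict):
    """Construct a phantom volume (and, for the benchmark, its seeds)."""
    kind = spec.get("kind")
    dims = tuple(spec.get("dims", (32, 32, 32)))
    if kind == "homogeneous":
        return (
            phantoms.make_homogeneous(
                dims,
                tuple(spec.get("eigenvalues", (9.0, 1.0, 1.0))),
                tuple(spec.get("principal_axis", (1.0, 0.0, 0.0))),
            ),
            None,
        )
    if kind == "halfplane":
        return phantoms.make_halfplane(dims, float(spec.get("y0", 4.0))), None
    if kind == "curved":
        return (
            phantoms.make_curved(
                dims,
                float(spec.get("radius", 20.0)),
                tuple(spec.get("eigenvalues", (9.0, 1.0, 1.0))),
            ),
            None,
        )
    if kind == "benchmark":
        vol, seeds = phantoms.make_benchmark(
            dims=tuple(spec.get("dims", (256, 32, 32))),
            n_seeds=int(spec.get("n_seeds", 128)),
            inset=float(spec.get("inset", 2.0)),
            rng_seed=int(spec.get("rng_seed", 0)),
            max_steps=int(spec.get("max_steps", 512)),
            h=float(spec.get("h", 0.1)),
            full=bool(spec.get("full", False)),
        )
        return vol, seeds
    raise ValueError(f"unknown phantom kind {kind!r}")


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    return wrap


def run_pipeline(config: dict, base_dir: Optional[Path] = None) -> dict:
    """Execute the configured stages; returns the run report dict."""
    base = Path(base_dir) if base_dir else Path.cwd()

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    tcfg = TrackingConfig(**config.get("tracking", {}))
    report: dict = {"tracking": asdict(tcfg)}

    # --- input -----------------------------------------------------------
    def load_input():
        if "phantom" in config:
            return build_phantom(config["phantom"])
        if "input" in config:
            return (
                read_tensor_volume(resolve(config["input"]), config.get("dialect", "lower")),
                None,
            )
        raise ValueError("config needs either 'input' or 'phantom'")

    vol, phantom_seeds = _stage("input")(load_input)
    report["dims"] = list(vol.dims)

    # --- precompute ------------------------------------------------------
    fields = _stage("precompute")(precompute, vol, config.get("det_tol"))
    provider = GridFieldProvider(fields, tcfg.interpolation)
    n_invalid = int(np.sum(~fields.diffusion.validity))
    report["invalid_voxels"] = n_invalid
    log.info("precompute: dims=%s invalid_voxels=%d", vol.dims, n_invalid)

    # --- seeds -----------------------------------------------------------
    def make_seeds():
        if "seeds" in config:
            spec_dict = dict(config["seeds"])
            if "region" in spec_dict:
                spec_dict["region"] = tuple(tuple(b) for b in spec_dict["region"])
            spec = SeedSpec(**spec_dict)
            return generate_seeds(spec, fields, tcfg.rng_seed)
        if phantom_seeds is not None:
            return phantom_seeds
        raise ValueError("config needs 'seeds' (or a benchmark phantom)")

    seeds = _stage("generate_seeds")(make_seeds)
    report["n_seeds"] = len(seeds)
    log.info("seeds: %d (rng_seed=%d)", len(seeds), tcfg.rng_seed)

    # --- track -----------------------------------------------------------
    fibers = _stage("track")(trace_batch, seeds, tcfg, provider)
    term_counts = {t: 0 for t in ("left_volume", "max_steps", "error")}
    for f in fibers:
        term_counts[f.termination] += 1
    report["n_fibers"] = len(fibers)
    report["terminations"] = term_counts
    log.info(
        "track: %d fibers (h=%g solver=%s max_steps=%d) terminations=%s",
        len(fibers), tcfg.h, tcfg.solver, tcfg.max_steps, term_counts,
    )

    # --- filter ----------------------------------------------------------
    if "filter" in config:
        roi_spec = config["filter"]["roi"]
        roi = _stage("filter")(
            lambda: ROI("box", (tuple(roi_spec["box"][0]), tuple(roi_spec["box"][1])))
        )
        fibers = _stage("filter")(filter_through_region, fibers, roi)
        report["n_filtered"] = len(fibers)
        log.info("filter: %d fibers pass the target region", len(fibers))

    # --- rank ------------------------------------------------------------
    if config.get("rank"):
        ranked = _stage("rank")(rank_fibers, fibers, default_score(fields))
        fibers = [f for f, _ in ranked]
        report["scores"] = [None if np.isnan(s) else float(s) for _, s in ranked]
        log.info("rank: top score %s", report["scores"][0] if ranked else None)

    # --- output ----------------------------------------------------------
    out = config.get("output", {})
    if "fibers" in out:
        _stage("write_fibers")(
            write_fibers,
            fibers,
            resolve(out["fibers"]),
            out.get("format", "json"),
            vol.affine(),
            vol.dims,
            vol.spacing,
        )
        report["fibers_path"] = str(resolve(out["fibers"]))
    if "report" in out:
        resolve(out["report"]).write_text(json.dumps(report, indent=1, sort_keys=True) + "\n")
    return report
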