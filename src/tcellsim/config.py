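"""Scenario configuration: structured-text (YAML) documents.

A scenario config fully determines a stochastic run: body rates, geometry,
transit mode, priming, infection layout (dLN count, ramp), cohort size,
horizon and the mandatory seed.  All rates and times carry unit suffixes in
their keys.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace
from pathlib import Path
from typing import Optional

import yaml

from tcellsim import geometry
from tcellsim.circulation import (
    N_SPHERES,
    BodyConfig,
    EntryRateRamp,
    TransitMode,
)
from tcellsim.priming import PrimingParams

__all__ = [
    "load_scenario",
    "dump_scenario",
    "validate_scenario",
    "build_body",
    "build_transit",
    "build_priming",
    "config_hash",
]


def load_scenario(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    validate_scenario(cfg)
    return cfg


def dump_scenario(cfg: dict, path) -> None:
    validate_scenario(cfg)
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def validate_scenario(cfg: dict, require_seed: bool = True) -> None:
    if not isinstance(cfg, dict):
        raise ValueError("scenario config must be a mapping")
    if require_seed and not isinstance(cfg.get("seed"), int):
        raise ValueError("scenario config requires an integer 'seed' (stochastic run)")
    body = cfg.get("body", {})
    if body:
        if body.get("spleen_entry_rate_per_h", 1.0) <= 0:
            raise ValueError("spleen entry rate must be > 0")
        if body.get("total_ln_entry_rate_per_h", 1.5) <= 0:
            raise ValueError("LN entry rate must be > 0")
        dln = body.get("dln_count", 0)
        if not 0 <= dln <= 23:
            raise ValueError("dln_count must be between 0 and 23 (single-sphere LNs)")
    transit = cfg.get("transit", {})
    if transit and transit.get("kind") == "deterministic":
        if not transit.get("t_det_hours"):
            raise ValueError("deterministic transit requires t_det_hours")


def build_body(cfg: dict) -> BodyConfig:
    body_cfg = cfg.get("body", {})
    geo_cfg = cfg.get("geometry", {})
    motility = float(geo_cfg.get("motility_um2_per_min", geometry.DEFAULT_MOTILITY))
    ln_mean = float(geo_cfg.get("ln_mean_transit_h", geometry.DEFAULT_LN_MEAN_HOURS))
    ln_geom = geometry.LNSphere(
        radius=float(
            geo_cfg.get("ln_radius_um", geometry.calibrate_ln_radius(ln_mean, motility))
        ),
        motility=motility,
    )
    spleen_geom = geometry.SpleenSection(
        radius=float(geo_cfg.get("spleen_radius_um", geometry.DEFAULT_SPLEEN_RADIUS)),
        aperture_angle=float(
            geo_cfg.get("spleen_aperture_rad", geometry.DEFAULT_SPLEEN_APERTURE)
        ),
        motility=motility,
    )
    total_ln = float(body_cfg.get("total_ln_entry_rate_per_h", 1.5))
    body = BodyConfig(
        spleen_entry_rate=float(body_cfg.get("spleen_entry_rate_per_h", 1.0)),
        ln_entry_rates=tuple([total_ln / N_SPHERES] * N_SPHERES),
        ln_geometry=ln_geom,
        spleen_geometry=spleen_geom,
    )
    ramp_cfg = body_cfg.get("ramp")
    ramp = None
    if ramp_cfg:
        ramp = EntryRateRamp(
            fold_increase=float(ramp_cfg.get("fold_increase", 9.0)),
            ramp_end_days=float(ramp_cfg.get("ramp_end_days", 4.5)),
            shape=str(ramp_cfg.get("shape", "linear")),
        )
    dln_count = int(body_cfg.get("dln_count", 0))
    if dln_count or ramp:
        body = body.with_dlns(dln_count, ramp=ramp)
    return body


def build_transit(cfg: dict) -> TransitMode:
    transit = cfg.get("transit", {})
    if transit.get("kind", "stochastic") == "deterministic":
        return TransitMode.deterministic(float(transit["t_det_hours"]))
    return TransitMode.stochastic()


def build_priming(cfg: dict) -> Optional[PrimingParams]:
    p = cfg.get("priming")
    return PrimingParams.from_dict(p) if p else None


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config document, for run logs."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
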