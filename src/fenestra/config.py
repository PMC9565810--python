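"""YAML configuration for geometry and generator settings.

Geometry schema (all lengths in Å)::

    z_ic: 0.0          # intracellular pore mouth plane
    z_ec: 40.0         # vestibule floor / pore top plane
    z_vest_top: 70.0   # vestibule ceiling plane
    axis_xy: [0.0, 0.0]
    r_vest: 15.0
    r_apical: 5.0
    fen_band: [45.0, 60.0]
    fen_width: 10.0
    hysteresis: 2.0

Generator schema adds ``n_ions, duration, dt, voltage, drift_gain, noise_sd,
seed, n_render, n_vest_init, box_z`` and a ``rates`` mapping with keys
``tm_inward, tm_outward, lat_inward, lat_outward, api_inward, api_outward``
(events/ns), plus an optional nested ``geometry`` block.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .geometry import RegionModel
from .synth import GeneratorConfig, PathwayRates

__all__ = ["load_region_model", "load_generator_config", "dump_region_model"]


def _as_tuple(v):
    return tuple(v) if isinstance(v, (list, tuple)) else v


def load_region_model(path: str | Path) -> RegionModel:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("axis_xy", "fen_band"):
        if key in raw:
            raw[key] = _as_tuple(raw[key])
    return RegionModel(**raw)


def dump_region_model(model: RegionModel, path: str | Path) -> None:
    data = {
        "z_ic": model.z_ic,
        "z_ec": model.z_ec,
        "z_vest_top": model.z_vest_top,
        "axis_xy": list(model.axis_xy),
        "r_vest": model.r_vest,
        "r_apical": model.r_apical,
        "fen_band": list(model.fen_band),
        "fen_width": model.fen_width,
        "hysteresis": model.hysteresis,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_generator_config(path: str | Path) -> GeneratorConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "geometry" in raw:
        geo = raw.pop("geometry")
        for key in ("axis_xy", "fen_band"):
            if key in geo:
                geo[key] = _as_tuple(geo[key])
        raw["geometry"] = RegionModel(**geo)
    if "rates" in raw:
        raw["rates"] = PathwayRates(**raw.pop("rates"))
    if "seed" not in raw:
        raise ValueError("generator config must set an explicit seed")
    return GeneratorConfig(**raw)
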