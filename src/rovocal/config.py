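"""YAML/JSON configuration loading and output provenance.

Config conventions: all angles in degrees, all physical distances in
cm, attenuation coefficients in m^-1, RGB in 0-255.
"""

from __future__ import annotations

import hashlib
import json
from importlib import metadata
from pathlib import Path

import yaml

from .camera import CameraModel
from .distortion import DistortionModel
from .synth import AttenuationModel, ColorPatch, TargetSpec, default_color_chart

__all__ = [
    "load_config",
    "camera_from_dict",
    "target_from_dict",
    "distortion_from_dict",
    "attenuation_from_dict",
    "provenance",
]


def load_config(path) -> dict:
    """Load a YAML or JSON config file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def camera_from_dict(cfg: dict) -> CameraModel:
    return CameraModel(
        width_px=int(cfg["width_px"]),
        height_px=int(cfg["height_px"]),
        fov_air_deg=float(cfg["fov_air_deg"]),
        n_water=float(cfg.get("n_water", 1.34)),
    )


def target_from_dict(cfg: dict) -> TargetSpec:
    patches_cfg = cfg.get("patches", "default")
    if patches_cfg == "default":
        patches = default_color_chart()
    elif patches_cfg in (None, "none"):
        patches = ()
    else:
        patches = tuple(
            ColorPatch(
                patch_id=str(p["patch_id"]),
                rgb=tuple(float(c) for c in p["rgb"]),
                x_cm=float(p["x_cm"]),
                y_cm=float(p["y_cm"]),
                size_cm=float(p["size_cm"]),
            )
            for p in patches_cfg
        )
    return TargetSpec(
        node_pitch_cm=float(cfg.get("node_pitch_cm", 8.0)),
        n_rows=int(cfg.get("n_rows", 9)),
        n_cols=int(cfg.get("n_cols", 9)),
        line_width_cm=float(cfg.get("line_width_cm", 1.0)),
        line_overhang_cm=(None if cfg.get("line_overhang_cm") is None
                          else float(cfg["line_overhang_cm"])),
        edge_span_cm=(None if cfg.get("edge_span_cm") is None
                      else float(cfg["edge_span_cm"])),
        patches=patches,
    )


def distortion_from_dict(cfg: dict) -> DistortionModel:
    return DistortionModel(
        d=float(cfg.get("d", 0.0)),
        form=cfg.get("form", "radial"),
        center_x=cfg.get("center_x"),
        center_y=cfg.get("center_y"),
    )


def attenuation_from_dict(cfg: dict) -> AttenuationModel:
    return AttenuationModel(
        k_r=float(cfg.get("k_r", 0.0)),
        k_g=float(cfg.get("k_g", 0.0)),
        k_b=float(cfg.get("k_b", 0.0)),
    )


def provenance(config: dict | None = None, seed: int | None = None) -> dict:
    """Version/config-hash/seed block attached to every CLI output."""
    try:
        version = metadata.version("rovocal")
    except metadata.PackageNotFoundError:
        version = "unknown"
    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    return {
        "package": "rovocal",
        "version": version,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "seed": seed,
    }
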