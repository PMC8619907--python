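"""Synthetic calibration-target scenes.

Emulates a pool calibration campaign: a flat target carrying a black
grid and a colour chart is imaged face-on at a known distance D by a
pinhole camera with configurable field of view, radial distortion,
per-channel water attenuation of the chart colours, and additive pixel
noise.  Every render comes with a ground-truth sidecar (node positions,
patch boxes, all generative parameters) so analysis code can be tested
by round trip without any field data.

Geometry: physical target coordinates are in cm with the origin on the
optical axis; the pinhole projection to centre-relative pixels is
``x_px = f * x_cm / D`` with ``f = width_px / (2*tan(FOV/2))``.  The
rendered image shows the *distorted* scene; rendering is done by inverse
mapping (each output pixel is carried back to ideal pattern space), so
lines are anti-aliased and node positions are exact to the model.

Colour attenuation follows a single-path Beer-Lambert law per channel:
``c(D) = c_ref * exp(-k_c * D)`` with D in metres.  This exponential
form is the generator's own declared model of water absorption.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .camera import CameraModel, focal_length_px
from .distortion import DistortionModel, NodeSet, apply_distortion, undistort_points

__all__ = [
    "ColorPatch",
    "TargetSpec",
    "AttenuationModel",
    "SceneSpec",
    "default_color_chart",
    "default_target",
    "attenuate_color",
    "project_target",
    "render_scene",
    "make_fixture_series",
    "SEAWATER_ATTENUATION",
]


@dataclass(frozen=True)
class ColorPatch:
    """One chart patch: id, reference RGB (0-255) and physical placement."""

    patch_id: str
    rgb: tuple[float, float, float]
    x_cm: float
    y_cm: float
    size_cm: float

    def __post_init__(self) -> None:
        if not all(0 <= c <= 255 for c in self.rgb):
            raise ValueError("reference RGB components must lie in [0, 255]")
        if self.size_cm <= 0:
            raise ValueError("patch size must be positive")


@dataclass(frozen=True)
class TargetSpec:
    """Physical geometry of the grid-plus-chart calibration target.

    The grid has ``n_rows x n_cols`` line intersections (nodes) at
    ``node_pitch_cm`` spacing, drawn as dark lines of ``line_width_cm``.
    ``edge_span_cm`` is the horizontal distance between the two
    reference edges used for FOV estimation; by default the outer grid
    columns, i.e. ``(n_cols - 1) * node_pitch_cm``.
    """

    node_pitch_cm: float = 8.0
    n_rows: int = 9
    n_cols: int = 9
    line_width_cm: float = 1.0
    #: grid lines extend this far beyond the outermost nodes, so the
    #: border nodes are full four-arm crossings; default half a pitch
    line_overhang_cm: float | None = None
    edge_span_cm: float | None = None
    patches: tuple[ColorPatch, ...] = ()

    def __post_init__(self) -> None:
        if self.node_pitch_cm <= 0:
            raise ValueError("node_pitch_cm must be positive")
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid needs at least 2x2 nodes")

    @property
    def overhang_cm(self) -> float:
        if self.line_overhang_cm is not None:
            return self.line_overhang_cm
        return self.node_pitch_cm / 2.0

    @property
    def span_cm(self) -> float:
        """Horizontal reference-edge separation (the dx_cm of the FOV formula)."""
        if self.edge_span_cm is not None:
            return self.edge_span_cm
        return (self.n_cols - 1) * self.node_pitch_cm

    def node_positions_cm(self) -> np.ndarray:
        """(N, 2) physical node coordinates, row-major, origin at centre."""
        xs = (np.arange(self.n_cols) - (self.n_cols - 1) / 2.0) * self.node_pitch_cm
        ys = (np.arange(self.n_rows) - (self.n_rows - 1) / 2.0) * self.node_pitch_cm
        gx, gy = np.meshgrid(xs, ys)
        return np.stack([gx.ravel(), gy.ravel()], axis=1)

    def grid_indices(self) -> np.ndarray:
        """(N, 2) integer (row, col) for each node, row-major order."""
        rr, cc = np.meshgrid(np.arange(self.n_rows), np.arange(self.n_cols),
                             indexing="ij")
        return np.stack([rr.ravel(), cc.ravel()], axis=1)

    def scaled(self, factor: float) -> "TargetSpec":
        """A geometrically similar target enlarged by ``factor``.

        Pool campaigns use larger panels at larger distances so the
        pattern keeps a workable pixel footprint.
        """
        return TargetSpec(
            node_pitch_cm=self.node_pitch_cm * factor,
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            line_width_cm=self.line_width_cm * factor,
            line_overhang_cm=None if self.line_overhang_cm is None
            else self.line_overhang_cm * factor,
            edge_span_cm=None if self.edge_span_cm is None
            else self.edge_span_cm * factor,
            patches=tuple(
                ColorPatch(p.patch_id, p.rgb, p.x_cm * factor,
                           p.y_cm * factor, p.size_cm * factor)
                for p in self.patches
            ),
        )


@dataclass(frozen=True)
class AttenuationModel:
    """Per-channel exponential attenuation coefficients, m^-1."""

    k_r: float = 0.0
    k_g: float = 0.0
    k_b: float = 0.0

    def __post_init__(self) -> None:
        if min(self.k_r, self.k_g, self.k_b) < 0:
            raise ValueError("attenuation coefficients must be non-negative")

    @property
    def k(self) -> np.ndarray:
        return np.array([self.k_r, self.k_g, self.k_b])


#: Seawater-like defaults: long wavelengths (red) absorb fastest,
#: blue least — the ordering seen in real chart measurements.
SEAWATER_ATTENUATION = AttenuationModel(k_r=0.6, k_g=0.15, k_b=0.08)


def default_color_chart(y_cm: float = 38.0, size_cm: float = 6.0,
                        spacing_cm: float = 10.0) -> tuple[ColorPatch, ...]:
    """Six-patch reference chart laid out in a row below the grid."""
    colors = [
        ("red", (220.0, 40.0, 40.0)),
        ("orange", (230.0, 140.0, 40.0)),
        ("green", (40.0, 180.0, 60.0)),
        ("blue", (40.0, 70.0, 200.0)),
        ("gray", (128.0, 128.0, 128.0)),
        ("white", (240.0, 240.0, 240.0)),
    ]
    n = len(colors)
    xs = (np.arange(n) - (n - 1) / 2.0) * spacing_cm
    return tuple(
        ColorPatch(name, rgb, float(x), y_cm, size_cm)
        for (name, rgb), x in zip(colors, xs)
    )


def default_target(with_chart: bool = True) -> TargetSpec:
    """The stock pool target: 9x9 grid at 8 cm pitch plus a 6-patch chart."""
    return TargetSpec(patches=default_color_chart() if with_chart else ())


@dataclass(frozen=True)
class SceneSpec:
    """Full generative description of one pool shot.

    ``fov_deg`` is the effective full horizontal FOV at the port in the
    scene medium (for an in-water shot, pass the water FOV); it defaults
    to the camera's nominal air FOV.  ``distance_cm`` is the
    camera-to-target distance D.
    """

    camera: CameraModel
    target: TargetSpec
    distance_cm: float
    distortion: DistortionModel = field(
        default_factory=lambda: DistortionModel(d=0.0))
    attenuation: AttenuationModel = field(default_factory=AttenuationModel)
    noise_sigma: float = 0.0
    seed: int | None = None
    fov_deg: float | None = None
    background: float = 235.0
    line_value: float = 20.0

    def __post_init__(self) -> None:
        if self.distance_cm <= 0:
            raise ValueError("distance_cm must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.noise_sigma > 0 and self.seed is None:
            raise ValueError("a seed is required when noise_sigma > 0")

    @property
    def effective_fov_deg(self) -> float:
        return self.camera.fov_air_deg if self.fov_deg is None else self.fov_deg

    @property
    def scale_px_per_cm(self) -> float:
        """Pinhole magnification at the target plane."""
        f = focal_length_px(self.camera, self.effective_fov_deg)
        return f / self.distance_cm

    @property
    def distance_m(self) -> float:
        return self.distance_cm / 100.0


def attenuate_color(reference_rgb, attenuation: AttenuationModel,
                    distance_m: float) -> np.ndarray:
    """Beer-Lambert attenuation of a reference RGB triplet over a path.

    ``c -> c * exp(-k_c * distance)`` per channel, clipped to [0, 255].
    """
    if distance_m < 0:
        raise ValueError("distance must be non-negative")
    rgb = np.asarray(reference_rgb, dtype=float)
    return np.clip(rgb * np.exp(-attenuation.k * distance_m), 0.0, 255.0)


def project_target(scene: SceneSpec) -> dict:
    """Project the target into the image: nodes, span and patch boxes.

    Returns a dict with the ideal (undistorted) and observed (distorted)
    node coordinates in centre-relative pixels, an in-frame mask, the
    grid (row, col) index of each node, the ground-truth span, and one
    raster-coordinate bounding box per chart patch.

    Raises
    ------
    ValueError
        If every node falls outside the image at this distance.
    """
    s = scene.scale_px_per_cm
    ideal = scene.target.node_positions_cm() * s
    observed = apply_distortion(ideal, scene.distortion)
    w, h = scene.camera.width_px, scene.camera.height_px
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    raster = observed + [cx, cy]
    in_frame = (
        (raster[:, 0] >= 0) & (raster[:, 0] <= w - 1)
        & (raster[:, 1] >= 0) & (raster[:, 1] <= h - 1)
    )
    if not in_frame.any():
        raise ValueError(
            f"target entirely outside the field of view at D={scene.distance_cm} cm")

    patch_boxes = []
    for p in scene.target.patches:
        half = p.size_cm / 2.0
        corners_cm = np.array([
            [p.x_cm - half, p.y_cm - half],
            [p.x_cm + half, p.y_cm - half],
            [p.x_cm + half, p.y_cm + half],
            [p.x_cm - half, p.y_cm + half],
        ])
        corners_px = apply_distortion(corners_cm * s, scene.distortion) + [cx, cy]
        x0, y0 = corners_px.min(axis=0)
        x1, y1 = corners_px.max(axis=0)
        patch_boxes.append({
            "patch_id": p.patch_id,
            "reference_rgb": list(p.rgb),
            "true_rgb": attenuate_color(p.rgb, scene.attenuation,
                                        scene.distance_m).tolist(),
            "box_xyxy": [float(x0), float(y0), float(x1), float(y1)],
        })

    return {
        "ideal": ideal,
        "observed": observed,
        "in_frame": in_frame,
        "grid_index": scene.target.grid_indices(),
        "span_cm": scene.target.span_cm,
        "span_px_ideal": scene.target.span_cm * s,
        "patch_boxes": patch_boxes,
    }


def _pattern_rgb(scene: SceneSpec, x_ideal: np.ndarray,
                 y_ideal: np.ndarray) -> np.ndarray:
    """Evaluate the ideal target pattern at ideal-space pixel coords.

    Returns an (..., 3) float array in [0, 255].  Grid lines are drawn
    with ~1 px of analytic anti-aliasing (coverage ramp); chart patches
    are flat fills of their attenuated colour.
    """
    s = scene.scale_px_per_cm
    t = scene.target
    out = np.full(x_ideal.shape + (3,), scene.background, dtype=float)

    xs = (np.arange(t.n_cols) - (t.n_cols - 1) / 2.0) * t.node_pitch_cm * s
    ys = (np.arange(t.n_rows) - (t.n_rows - 1) / 2.0) * t.node_pitch_cm * s
    hw = t.line_width_cm * s / 2.0
    over = t.overhang_cm * s
    ymin, ymax = ys[0] - over, ys[-1] + over
    xmin, xmax = xs[0] - over, xs[-1] + over

    # distance to nearest vertical / horizontal grid line, limited to the
    # grid extent so line ends terminate cleanly
    dv = np.min(np.abs(x_ideal[..., None] - xs), axis=-1)
    dv = np.where((y_ideal >= ymin) & (y_ideal <= ymax), dv, np.inf)
    dh = np.min(np.abs(y_ideal[..., None] - ys), axis=-1)
    dh = np.where((x_ideal >= xmin) & (x_ideal <= xmax), dh, np.inf)
    dist = np.minimum(dv, dh)
    cov = np.clip(hw + 0.5 - dist, 0.0, 1.0)
    out = out * (1.0 - cov[..., None]) + scene.line_value * cov[..., None]

    for p in t.patches:
        color = attenuate_color(p.rgb, scene.attenuation, scene.distance_m)
        half = p.size_cm / 2.0 * s
        px, py = p.x_cm * s, p.y_cm * s
        covx = np.clip(half + 0.5 - np.abs(x_ideal - px), 0.0, 1.0)
        covy = np.clip(half + 0.5 - np.abs(y_ideal - py), 0.0, 1.0)
        pc = covx * covy
        out = out * (1.0 - pc[..., None]) + color * pc[..., None]
    return out


def render_scene(scene: SceneSpec) -> tuple[np.ndarray, dict]:
    """Render one pool shot and its ground-truth sidecar.

    Returns ``(image, sidecar)`` where image is (H, W, 3) uint8.  The
    render is deterministic given the scene (same seed, same bytes).
    """
    proj = project_target(scene)
    w, h = scene.camera.width_px, scene.camera.height_px
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    pts = np.stack([(xx - cx).ravel(), (yy - cy).ravel()], axis=1)
    ideal_pts = undistort_points(pts, scene.distortion)
    img = _pattern_rgb(scene,
                       ideal_pts[:, 0].reshape(h, w),
                       ideal_pts[:, 1].reshape(h, w))
    if scene.noise_sigma > 0:
        rng = np.random.default_rng(scene.seed)
        img = img + rng.normal(0.0, scene.noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    sidecar = {
        "camera": {"width_px": w, "height_px": h,
                   "fov_air_deg": scene.camera.fov_air_deg,
                   "n_water": scene.camera.n_water},
        "fov_deg": scene.effective_fov_deg,
        "distance_cm": scene.distance_cm,
        "distortion": {"d": scene.distortion.d, "form": scene.distortion.form},
        "attenuation": {"k_r": scene.attenuation.k_r,
                        "k_g": scene.attenuation.k_g,
                        "k_b": scene.attenuation.k_b},
        "noise_sigma": scene.noise_sigma,
        "seed": scene.seed,
        "target": {
            "node_pitch_cm": scene.target.node_pitch_cm,
            "n_rows": scene.target.n_rows,
            "n_cols": scene.target.n_cols,
            "line_width_cm": scene.target.line_width_cm,
            "line_overhang_cm": scene.target.overhang_cm,
            "edge_span_cm": scene.target.span_cm,
        },
        "nodes_ideal": proj["ideal"].tolist(),
        "nodes_observed": proj["observed"].tolist(),
        "nodes_in_frame": proj["in_frame"].tolist(),
        "grid_index": proj["grid_index"].tolist(),
        "span_cm": proj["span_cm"],
        "span_px_ideal": proj["span_px_ideal"],
        "patch_boxes": proj["patch_boxes"],
    }
    return img, sidecar


def scene_nodeset(scene: SceneSpec) -> NodeSet:
    """Ground-truth NodeSet (ideal vs distorted) for a scene, no render."""
    proj = project_target(scene)
    return NodeSet(ideal=proj["ideal"], observed=proj["observed"],
                   grid_index=proj["grid_index"])


def make_fixture_series(
    outdir,
    camera: CameraModel | None = None,
    target: TargetSpec | None = None,
    distances_m=(1, 2, 3, 4, 5, 6),
    distortion: DistortionModel | None = None,
    attenuation: AttenuationModel | None = None,
    noise_sigma: float = 1.0,
    seed: int = 0,
    fov_deg: float | None = None,
    scale_with_distance: bool = True,
) -> list[dict]:
    """Write the full pool series (one PNG + JSON sidecar per distance).

    By default the target is scaled proportionally to distance, mirroring
    the use of larger grid panels further from the camera, so the pixel
    footprint of the pattern stays constant across the series.

    Returns a manifest: one dict per distance with paths and truth.
    """
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    camera = camera or CameraModel(width_px=1600, height_px=1200, fov_air_deg=82.0)
    target = target or default_target()
    distortion = distortion or DistortionModel(d=1.3e-4)
    attenuation = attenuation or SEAWATER_ATTENUATION

    manifest = []
    for i, dist_m in enumerate(distances_m):
        tgt = target.scaled(float(dist_m)) if scale_with_distance else target
        scene = SceneSpec(
            camera=camera, target=tgt, distance_cm=100.0 * float(dist_m),
            distortion=distortion, attenuation=attenuation,
            noise_sigma=noise_sigma,
            seed=None if noise_sigma == 0 else seed + i,
            fov_deg=fov_deg,
        )
        img, sidecar = render_scene(scene)
        stem = f"target_{float(dist_m):.0f}m"
        img_path = outdir / f"{stem}.png"
        side_path = outdir / f"{stem}.json"
        iio.imwrite(img_path, img)
        side_path.write_text(json.dumps(sidecar, indent=1))
        manifest.append({"distance_m": float(dist_m), "image": str(img_path),
                         "sidecar": str(side_path)})
    return manifest
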