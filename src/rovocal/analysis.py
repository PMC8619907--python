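"""Measurement extraction from calibration-target images.

Replaces the manual point-and-click workflow (node coordinates read off
in an image viewer, patch colours sampled with a pipette tool) with
reproducible operations:

* :func:`detect_nodes` — sub-pixel grid-intersection detection,
* :func:`match_nodes` — correspondence between detected and ideal nodes,
* :func:`measure_span` — the reference-edge span feeding the FOV formula,
* :func:`extract_patch_rgb` — mean chart-patch colours,
* :class:`ColorAttenuation` / :func:`fit_attenuation` — per-channel
  exponential attenuation coefficients vs distance,
* :func:`calibrate_image` — the full per-image pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

from .camera import CameraModel, SpanMeasurement, fov_from_span
from .distortion import (
    DistortionModel,
    GridDistortionResults,
    NodeSet,
    fit_distortion,
    undistort_points,
)
from .synth import SceneSpec, TargetSpec, project_target

__all__ = [
    "DetectionError",
    "MatchingError",
    "detect_nodes",
    "match_nodes",
    "measure_span",
    "extract_patch_rgb",
    "ColorAttenuation",
    "ColorAttenuationResults",
    "fit_attenuation",
    "calibrate_image",
    "CHANNEL_FLOOR",
]

#: Channel values at or below this level (out of 255) are excluded from
#: the log-domain attenuation fit: near-zero channels are dominated by
#: quantisation and noise and would blow up the log transform.
CHANNEL_FLOOR = 5.0


class DetectionError(RuntimeError):
    """Grid-node detection failed; carries the candidate count."""

    def __init__(self, message: str, n_found: int = 0):
        super().__init__(message)
        self.n_found = n_found


class MatchingError(RuntimeError):
    """Node correspondence failed (too few mutual matches)."""


def _to_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    return img


def _crossing_response(darkness: np.ndarray, size: int) -> np.ndarray:
    """Separable line-crossing response.

    ``A`` is high where the row neighbourhood of a pixel is dark (it
    lies on a horizontal line), ``B`` where the column neighbourhood is
    dark; their product peaks where a horizontal and a vertical line
    cross and stays low on isolated line segments.
    """
    A = uniform_filter1d(darkness, size=size, axis=1, mode="nearest")
    B = uniform_filter1d(darkness, size=size, axis=0, mode="nearest")
    return A * B


def _refine_crossing(darkness: np.ndarray, cx: float, cy: float,
                     half: int, _recenter: bool = True
                     ) -> tuple[float, float] | None:
    """Sub-pixel crossing position by intersecting the two line centrelines.

    Within a window around the coarse candidate, the y-centroid of
    darkness in each column traces the horizontal line and the
    x-centroid in each row traces the vertical line; a straight line is
    fitted to each trace (skipping the central band where the
    perpendicular line contaminates the centroid) and their
    intersection is returned.  None if either trace is too short.
    """
    h, w = darkness.shape
    x0, x1 = int(round(cx)) - half, int(round(cx)) + half + 1
    y0, y1 = int(round(cy)) - half, int(round(cy)) + half + 1
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        return None
    win = darkness[y0:y1, x0:x1]
    n = win.shape[0]
    idx = np.arange(n, dtype=float)

    if _recenter:
        # the coarse response peaks anywhere on a plateau about one
        # line-width wide, so first recentre the window on the marginal
        # darkness profiles (column sums peak at the vertical line, row
        # sums at the horizontal one)
        def line_pos(profile: np.ndarray) -> float:
            # centroid of the contiguous above-half-maximum run around
            # the peak; separate dark structure elsewhere in the window
            # (a chart patch, a neighbouring line) stays excluded
            j = int(np.argmax(profile))
            base = float(profile.min())
            level = base + 0.5 * (float(profile[j]) - base)
            lo = j
            while lo > 0 and profile[lo - 1] > level:
                lo -= 1
            hi = j
            while hi < n - 1 and profile[hi + 1] > level:
                hi += 1
            seg = profile[lo:hi + 1] - base
            s = seg.sum()
            if s <= 0:
                return float(j)
            return lo + float(seg @ np.arange(hi - lo + 1)) / s

        nx = x0 + line_pos(win.sum(axis=0))
        ny = y0 + line_pos(win.sum(axis=1))
        return _refine_crossing(darkness, nx, ny, half, _recenter=False)
    band = max(2, int(0.35 * half))
    center = half  # candidate sits at the window centre
    keep = np.abs(idx - center) > band
    floor = 0.35 * win.max()
    if float((win > floor).mean()) > 0.5:
        # mostly-dark window: a flat dark region (e.g. a chart patch
        # interior), not a crossing of two thin lines
        return None

    # after recentring, both lines pass within ~1 px of the window
    # centre, so the across-line centroid only needs a narrow band —
    # this keeps nearby structure (chart patches, neighbouring lines)
    # out of the weights
    c0, c1 = max(0, center - band), min(n, center + band + 1)

    def trace(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
        # mat rows = positions along the fitted line, columns = across it
        sub = mat[:, c0:c1]
        wts = np.where(sub > floor, sub, 0.0)
        tot = wts.sum(axis=1)
        ok = keep & (tot > 1e-9)
        if ok.sum() < 4:
            return None
        cent = (wts @ idx[c0:c1]) / np.where(tot > 0, tot, 1.0)
        return idx[ok], cent[ok]

    # trace(mat) returns, for each row of mat, the centroid across its
    # columns; win rows are y, so trace(win) follows the vertical line
    # (x-centroid per row) and trace(win.T) the horizontal one.
    th = trace(win.T)          # horizontal line: per-column y-centroid
    tv = trace(win)            # vertical line: per-row x-centroid
    if th is None or tv is None:
        return None
    # quadratic centrelines absorb the bowing that radial distortion
    # imposes on straight target lines across the window
    deg = 2 if min(len(th[0]), len(tv[0])) >= 6 else 1
    ph = np.polynomial.Polynomial.fit(th[0], th[1], deg)  # y = ph(x)
    pv = np.polynomial.Polynomial.fit(tv[0], tv[1], deg)  # x = pv(y)
    x_loc, y_loc = float(center), float(center)
    for _ in range(8):
        y_new = float(ph(x_loc))
        x_new = float(pv(y_new))
        if abs(x_new - x_loc) < 1e-9 and abs(y_new - y_loc) < 1e-9:
            x_loc, y_loc = x_new, y_new
            break
        x_loc, y_loc = x_new, y_new
    if not (0 <= x_loc < n and 0 <= y_loc < n):
        return None

    # a grid crossing has dark line arms in all four directions; patch
    # corners and isolated edges have only two and are rejected here
    def arm_dark(ts: np.ndarray, along_horizontal: bool) -> float:
        vals = []
        for t in ts:
            if along_horizontal:
                xi, yi = t, float(ph(t))
            else:
                xi, yi = float(pv(t)), t
            xi, yi = int(round(xi)), int(round(yi))
            if 0 <= xi < n and 0 <= yi < n:
                vals.append(win[yi, xi])
        return float(np.mean(vals)) if vals else 0.0

    lo = np.arange(max(0.0, x_loc - half), x_loc - band)
    hi = np.arange(x_loc + band, min(float(n), x_loc + half))
    lov = np.arange(max(0.0, y_loc - half), y_loc - band)
    hiv = np.arange(y_loc + band, min(float(n), y_loc + half))
    arm_floor = 0.5 * win.max()
    if (arm_dark(lo, True) < arm_floor or arm_dark(hi, True) < arm_floor
            or arm_dark(lov, False) < arm_floor or arm_dark(hiv, False) < arm_floor):
        return None
    return x0 + float(x_loc), y0 + float(y_loc)


def detect_nodes(image: np.ndarray, min_distance: int | None = None,
                 min_count: int = 9) -> np.ndarray:
    """Detect grid-line intersections at sub-pixel precision.

    Coarse candidates come from local maxima of a separable crossing
    response (dark along the row times dark along the column); each
    candidate is refined by fitting the centrelines of the two crossing
    lines in a local window and intersecting them.  Returns an (N, 2)
    array of (x, y) raster coordinates sorted row-major (top-to-bottom,
    left-to-right).

    Raises
    ------
    DetectionError
        If fewer than ``min_count`` intersections survive refinement;
        the exception carries the candidate count for diagnostics.
    """
    gray = _to_gray(image)
    if gray.size == 0:
        raise DetectionError("empty image", 0)
    contrast = float(gray.max() - gray.min())
    if contrast < 10.0:
        raise DetectionError("image has no usable contrast", 0)
    if min_distance is None:
        min_distance = max(5, min(gray.shape) // 60)

    bg = np.percentile(gray, 75)
    darkness = np.clip(bg - gray, 0.0, None)
    response = _crossing_response(darkness, size=2 * min_distance + 1)
    peaks = peak_local_max(response, min_distance=min_distance,
                           threshold_rel=0.4, exclude_border=2)
    if len(peaks) < min_count:
        raise DetectionError(
            f"found only {len(peaks)} crossing candidates "
            f"(minimum {min_count})", len(peaks))

    # refinement window: a bit under half the node pitch, so the
    # neighbouring grid lines stay outside
    if len(peaks) >= 2:
        nn = cKDTree(peaks).query(peaks, k=2)[0][:, 1]
        pitch_est = float(np.median(nn))
    else:
        pitch_est = 4.0 * min_distance
    half = max(4, int(0.38 * pitch_est))

    refined = []
    for py, px in peaks:
        loc = _refine_crossing(darkness, float(px), float(py), half)
        if loc is not None:
            refined.append(loc)
    if len(refined) < min_count:
        raise DetectionError(
            f"only {len(refined)} of {len(peaks)} candidates refined to a "
            f"line crossing (minimum {min_count})", len(refined))
    coords = np.asarray(refined, dtype=float)

    # merge duplicates closer than half the estimated pitch
    tree = cKDTree(coords)
    groups = tree.query_ball_point(coords, r=0.4 * pitch_est)
    seen: set[int] = set()
    unique = []
    for i, grp in enumerate(groups):
        if i in seen:
            continue
        seen.update(grp)
        unique.append(coords[sorted(grp)].mean(axis=0))
    return _sort_row_major(np.asarray(unique))


def _sort_row_major(coords: np.ndarray) -> np.ndarray:
    """Sort (x, y) points top-to-bottom, then left-to-right within rows.

    Rows are split where the y gap exceeds half the median nearest-
    neighbour spacing — robust to mild distortion bowing the rows.
    """
    order = np.argsort(coords[:, 1])
    pts = coords[order]
    if len(pts) < 2:
        return pts
    dys = np.diff(pts[:, 1])
    big = dys[dys > 1.0]
    row_gap = np.median(big) / 2.0 if len(big) else 1.0
    rows: list[list[int]] = [[0]]
    for i, dy in enumerate(dys, start=1):
        if dy > row_gap:
            rows.append([i])
        else:
            rows[-1].append(i)
    out = []
    for row in rows:
        seg = pts[row]
        out.append(seg[np.argsort(seg[:, 0])])
    return np.vstack(out)


def match_nodes(
    detected: np.ndarray,
    target: TargetSpec,
    camera: CameraModel,
    distance_cm: float,
    fov_deg: float | None = None,
    max_offset_frac: float = 0.55,
) -> NodeSet:
    """Pair detected nodes with their ideal projected counterparts.

    The ideal grid is projected for the given camera/target/distance,
    both point sets are centroid-aligned, and pairs are formed by mutual
    nearest neighbour with a gate of ``max_offset_frac`` times the node
    pitch.  Detected coordinates are raster (x, y); the returned NodeSet
    is centre-relative, with the (row, col) grid index of each match.

    Raises
    ------
    MatchingError
        If fewer than half of the projected in-frame nodes are matched.
    """
    detected = np.asarray(detected, dtype=float)
    if len(detected) < 3:
        raise MatchingError(f"need at least 3 detected nodes, got {len(detected)}")
    scene = SceneSpec(camera=camera, target=target, distance_cm=distance_cm,
                      fov_deg=fov_deg)
    proj = project_target(scene)
    ideal = proj["ideal"][proj["in_frame"]]
    gidx = proj["grid_index"][proj["in_frame"]]

    cx, cy = (camera.width_px - 1) / 2.0, (camera.height_px - 1) / 2.0
    det = detected - [cx, cy]
    det_aligned = det - det.mean(axis=0) + ideal.mean(axis=0)

    pitch_px = target.node_pitch_cm * scene.scale_px_per_cm
    gate = max_offset_frac * pitch_px
    tree_i = cKDTree(ideal)

    def mutual_pairs(det_pts):
        tree_d = cKDTree(det_pts)
        d_id, nn_of_det = tree_i.query(det_pts)
        _, nn_of_ideal = tree_d.query(ideal)
        return [
            (j, i) for j, (i, dist) in enumerate(zip(nn_of_det, d_id))
            if dist <= gate and nn_of_ideal[i] == j
        ]

    # first pass with centroid alignment (spurious detections bias the
    # centroid), then re-align on the median residual of the matches
    pairs = mutual_pairs(det_aligned)
    if pairs:
        shift = np.median(
            [ideal[i] - det_aligned[j] for j, i in pairs], axis=0)
        pairs = mutual_pairs(det_aligned + shift)
    if len(pairs) < max(3, len(ideal) // 2):
        raise MatchingError(
            f"matched only {len(pairs)} of {len(ideal)} projected nodes")
    det_idx = np.array([j for j, _ in pairs])
    ide_idx = np.array([i for _, i in pairs])
    return NodeSet(ideal=ideal[ide_idx], observed=det[det_idx],
                   grid_index=gidx[ide_idx])


def measure_span(
    nodes: NodeSet,
    target: TargetSpec,
    distance_cm: float,
    distortion: DistortionModel | GridDistortionResults | None = None,
) -> SpanMeasurement:
    """Reference-edge span from matched nodes, ready for the FOV formula.

    Uses the leftmost and rightmost grid columns present in the match:
    ``dx_pix`` is the difference of their mean observed x coordinates
    (after undistorting the observations when a distortion model is
    supplied — raw spans are biased by the lens distortion), and
    ``dx_cm`` the corresponding physical column separation.
    """
    if nodes.grid_index is None:
        raise ValueError("measure_span needs a NodeSet with grid indices")
    obs = nodes.observed
    if distortion is not None:
        if isinstance(distortion, GridDistortionResults):
            distortion = distortion.distortion_model
        obs = undistort_points(obs, distortion)
    cols = nodes.grid_index[:, 1]
    c_lo, c_hi = cols.min(), cols.max()
    if c_hi == c_lo:
        raise ValueError("span needs nodes from at least two grid columns")
    x_lo = obs[cols == c_lo, 0].mean()
    x_hi = obs[cols == c_hi, 0].mean()
    return SpanMeasurement(
        dx_cm=(c_hi - c_lo) * target.node_pitch_cm,
        dx_pix=float(x_hi - x_lo),
        distance_cm=distance_cm,
    )


def extract_patch_rgb(image: np.ndarray, patch_boxes,
                      central_area_frac: float = 0.5) -> dict[str, np.ndarray]:
    """Mean RGB of each chart patch over the centre of its box.

    ``patch_boxes`` is a list of dicts with ``patch_id`` and
    ``box_xyxy`` (raster pixel corners), as produced by the scene
    ground truth.  The mean is taken over the centred sub-box covering
    ``central_area_frac`` of the box area, avoiding edge anti-aliasing
    and any box/patch misregistration.

    Raises
    ------
    ValueError
        If a patch's sampling region is empty or outside the image.
    """
    img = np.asarray(image)
    if img.ndim != 3:
        raise ValueError("extract_patch_rgb expects an RGB image")
    h, w = img.shape[:2]
    shrink = np.sqrt(central_area_frac)
    out: dict[str, np.ndarray] = {}
    for box in patch_boxes:
        x0, y0, x1, y1 = box["box_xyxy"]
        mx, my = (x0 + x1) / 2.0, (y0 + y1) / 2.0
        hx, hy = (x1 - x0) / 2.0 * shrink, (y1 - y0) / 2.0 * shrink
        ix0, ix1 = int(np.ceil(mx - hx)), int(np.floor(mx + hx))
        iy0, iy1 = int(np.ceil(my - hy)), int(np.floor(my + hy))
        if ix0 < 0 or iy0 < 0 or ix1 > w - 1 or iy1 > h - 1 or ix1 < ix0 or iy1 < iy0:
            raise ValueError(
                f"patch {box['patch_id']!r} sampling region empty or out of frame")
        region = img[iy0:iy1 + 1, ix0:ix1 + 1].astype(float)
        out[box["patch_id"]] = region.reshape(-1, img.shape[-1]).mean(axis=0)
    return out


class ColorAttenuation:
    """Per-channel exponential attenuation model of chart colours.

    The water column attenuates each channel as
    ``measured = reference * exp(-k * D)``; taking logs,
    ``-log(measured/reference) = k * D``, a zero-intercept line in the
    distance D.  :meth:`fit` estimates k per channel by least squares
    over all patches and distances, excluding measurements at or below
    the channel floor (:data:`CHANNEL_FLOOR`).

    Parameters
    ----------
    data : pandas.DataFrame
        Long-format measurements with columns ``distance_m``,
        ``patch_id``, ``channel`` (one of r/g/b), ``value`` and
        ``reference`` (both 0-255).
    """

    CHANNELS = ("r", "g", "b")

    def __init__(self, data: pd.DataFrame, floor: float = CHANNEL_FLOOR):
        required = {"distance_m", "patch_id", "channel", "value", "reference"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if data["distance_m"].nunique() < 2:
            raise ValueError("attenuation fit needs at least 2 distinct distances")
        self.data = data.reset_index(drop=True)
        self.floor = floor

    @classmethod
    def from_measurements(cls, measurements: dict[float, dict[str, np.ndarray]],
                          reference: dict[str, np.ndarray],
                          floor: float = CHANNEL_FLOOR) -> "ColorAttenuation":
        """Build from {distance_m: {patch_id: mean RGB}} plus references."""
        rows = []
        for dist, patches in measurements.items():
            for pid, rgb in patches.items():
                ref = np.asarray(reference[pid], dtype=float)
                for ci, ch in enumerate(cls.CHANNELS):
                    rows.append({
                        "distance_m": float(dist), "patch_id": pid,
                        "channel": ch, "value": float(np.asarray(rgb)[ci]),
                        "reference": float(ref[ci]),
                    })
        return cls(pd.DataFrame(rows), floor=floor)

    def fit(self) -> "ColorAttenuationResults":
        ks, r2s, ns, flags = {}, {}, {}, {}
        for ch in self.CHANNELS:
            sub = self.data[(self.data["channel"] == ch)
                            & (self.data["value"] > self.floor)
                            & (self.data["reference"] > self.floor)]
            ns[ch] = len(sub)
            if len(sub) == 0:
                ks[ch], r2s[ch], flags[ch] = np.nan, np.nan, True
                continue
            D = sub["distance_m"].to_numpy(dtype=float)
            y = -np.log(sub["value"].to_numpy(dtype=float)
                        / sub["reference"].to_numpy(dtype=float))
            denom = float(D @ D)
            k = float(D @ y) / denom
            resid = y - k * D
            ss_tot = float(y @ y)
            r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
            ks[ch], r2s[ch], flags[ch] = k, r2, False
        return ColorAttenuationResults(model=self, k=ks, rsquared=r2s,
                                       nobs=ns, unfittable=flags)


@dataclass(frozen=True)
class ColorAttenuationResults:
    """Fitted attenuation coefficients (m^-1) and per-channel fit quality."""

    model: ColorAttenuation
    k: dict
    rsquared: dict
    nobs: dict
    unfittable: dict

    @property
    def params(self) -> dict:
        return {f"k_{ch}": self.k[ch] for ch in ColorAttenuation.CHANNELS}

    @property
    def attenuation_model(self):
        from .synth import AttenuationModel

        return AttenuationModel(
            k_r=max(self.k["r"], 0.0) if not self.unfittable["r"] else 0.0,
            k_g=max(self.k["g"], 0.0) if not self.unfittable["g"] else 0.0,
            k_b=max(self.k["b"], 0.0) if not self.unfittable["b"] else 0.0,
        )

    def summary(self) -> str:
        lines = ["Colour attenuation fit", "=" * 48,
                 f"{'channel':<9}{'k (1/m)':>12}{'R^2':>9}{'n':>6}{'  note'}"]
        for ch in ColorAttenuation.CHANNELS:
            note = "  unfittable (below floor)" if self.unfittable[ch] else ""
            k = self.k[ch]
            r2 = self.rsquared[ch]
            lines.append(f"{ch:<9}{k:>12.4f}{r2:>9.4f}{self.nobs[ch]:>6}{note}")
        return "\n".join(lines)


def fit_attenuation(measurements, reference=None,
                    floor: float = CHANNEL_FLOOR) -> ColorAttenuationResults:
    """Fit per-channel attenuation coefficients.

    Accepts either a long-format DataFrame (columns distance_m,
    patch_id, channel, value, reference) or a
    ``{distance_m: {patch_id: rgb}}`` mapping plus a
    ``{patch_id: reference rgb}`` dict.
    """
    if isinstance(measurements, pd.DataFrame):
        model = ColorAttenuation(measurements, floor=floor)
    else:
        if reference is None:
            raise ValueError("reference chart values required with dict input")
        model = ColorAttenuation.from_measurements(measurements, reference,
                                                   floor=floor)
    return model.fit()


def calibrate_image(
    image: np.ndarray,
    target: TargetSpec,
    camera: CameraModel,
    distance_cm: float,
    form: str = "radial",
    fov_deg: float | None = None,
) -> dict:
    """Full single-image geometric calibration.

    Pipeline: detect nodes -> match to the projected ideal grid -> fit
    the distortion coefficient -> undistort the node positions ->
    measure the reference span -> FOV.  Returns a report dict with the
    estimated FOV (degrees), distortion coefficient and its character,
    fit residual, and the span measurement.
    """
    detected = detect_nodes(image)
    nodes = match_nodes(detected, target, camera, distance_cm, fov_deg=fov_deg)
    dist_fit = fit_distortion(nodes, form=form)
    span = measure_span(nodes, target, distance_cm, distortion=dist_fit)
    fov = fov_from_span(camera, span)
    return {
        "n_nodes_detected": int(len(detected)),
        "n_nodes_matched": int(len(nodes)),
        "distortion": {
            "d": dist_fit.d,
            "form": form,
            "se": dist_fit.bse,
            "rms_residual_px": dist_fit.rms_residual,
            "character": dist_fit.character,
        },
        "span": {"dx_cm": span.dx_cm, "dx_pix": span.dx_pix,
                 "distance_cm": span.distance_cm},
        "fov_deg": fov,
    }
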