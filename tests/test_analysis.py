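import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

import rovocal as rv
from rovocal.analysis import (
    CHANNEL_FLOOR,
    ColorAttenuation,
    DetectionError,
    MatchingError,
    calibrate_image,
    detect_nodes,
    extract_patch_rgb,
    fit_attenuation,
    match_nodes,
    measure_span,
)
from rovocal.camera import fov_from_span
from rovocal.synth import AttenuationModel, SceneSpec, attenuate_color


class TestDetectNodes:
    def test_blank_image_fails_with_diagnostic(self):
        with pytest.raises(DetectionError) as err:
            detect_nodes(np.full((200, 200, 3), 240, dtype=np.uint8))
        assert err.value.n_found == 0

    def test_sparse_pattern_reports_candidate_count(self, camera):
        # a single crossing is below the 3x3 minimum
        img = np.full((200, 200), 240, dtype=np.uint8)
        img[95:105, :] = 20
        img[:, 95:105] = 20
        with pytest.raises(DetectionError):
            detect_nodes(img)

    def test_noisy_localization_under_half_pixel(self, camera, grid_target):
        """Mean node localization error stays below 0.5 px at pixel noise
        sigma = 2 across seeds."""
        scene0 = SceneSpec(camera=camera, target=grid_target,
                           distance_cm=100.0, fov_deg=60.0,
                           distortion=rv.DistortionModel(d=1.3e-4))
        _, sidecar = rv.render_scene(scene0)
        truth = np.asarray(sidecar["nodes_observed"]) + [
            (camera.width_px - 1) / 2, (camera.height_px - 1) / 2]
        tree = cKDTree(truth)
        errs = []
        for seed in range(20):
            scene = SceneSpec(camera=camera, target=grid_target,
                              distance_cm=100.0, fov_deg=60.0,
                              distortion=rv.DistortionModel(d=1.3e-4),
                              noise_sigma=2.0, seed=seed)
            img, _ = rv.render_scene(scene)
            det = detect_nodes(img)
            d, _ = tree.query(det)
            errs.append(d[d < 3].mean())
        assert np.mean(errs) < 0.5

    def test_row_major_ordering(self, camera, grid_target):
        scene = SceneSpec(camera=camera, target=grid_target,
                          distance_cm=100.0, fov_deg=60.0)
        img, _ = rv.render_scene(scene)
        det = detect_nodes(img)
        # reshaped row-major: y increases down the rows, x across columns
        rows = det.reshape(9, 9, 2)
        assert np.all(np.diff(rows[:, 4, 1]) > 0)
        assert np.all(np.diff(rows[4, :, 0]) > 0)


class TestMatchNodes:
    def test_identity_on_ground_truth(self, camera, grid_target,
                                      grid_nodeset):
        cx = (camera.width_px - 1) / 2
        cy = (camera.height_px - 1) / 2
        detected = grid_nodeset.observed + [cx, cy]
        nodes = match_nodes(detected, grid_target, camera, 100.0,
                            fov_deg=60.0)
        assert len(nodes) == len(grid_nodeset)
        np.testing.assert_allclose(
            np.sort(nodes.observed, axis=0),
            np.sort(grid_nodeset.observed, axis=0), atol=1e-9)

    @pytest.mark.parametrize("d0", [-1.5e-4, 1.5e-4])
    def test_pairing_correct_under_distortion(self, camera, grid_target, d0):
        from rovocal.synth import scene_nodeset

        scene = SceneSpec(camera=camera, target=grid_target,
                          distance_cm=100.0, fov_deg=60.0,
                          distortion=rv.DistortionModel(d=d0))
        truth = scene_nodeset(scene)
        cx = (camera.width_px - 1) / 2
        cy = (camera.height_px - 1) / 2
        nodes = match_nodes(truth.observed + [cx, cy], grid_target, camera,
                            100.0, fov_deg=60.0)
        assert len(nodes) == len(truth)
        # each observed node paired with its own ideal counterpart
        res = rv.fit_distortion(nodes)
        assert res.d == pytest.approx(d0, abs=1e-9)
        assert res.rms_residual < 1e-6

    def test_random_scatter_fails(self, camera, grid_target):
        rng = np.random.default_rng(3)
        scatter = rng.uniform(0, 400, (40, 2))
        with pytest.raises(MatchingError):
            match_nodes(scatter, grid_target, camera, 100.0, fov_deg=60.0)


class TestMeasureSpan:
    def test_span_yields_configured_fov(self, camera, grid_target,
                                        grid_nodeset):
        span = measure_span(grid_nodeset, grid_target, 100.0,
                            distortion=rv.DistortionModel(d=1.3e-4))
        assert fov_from_span(camera, span) == pytest.approx(60.0, abs=0.01)

    def test_single_column_rejected(self, grid_target, grid_nodeset):
        mask = grid_nodeset.grid_index[:, 1] == 4
        from rovocal.distortion import NodeSet

        column = NodeSet(ideal=grid_nodeset.ideal[mask],
                         observed=grid_nodeset.observed[mask],
                         grid_index=grid_nodeset.grid_index[mask])
        with pytest.raises(ValueError, match="two grid columns"):
            measure_span(column, grid_target, 100.0)

    def test_halving_distance_doubles_pixel_span(self, camera, grid_target):
        from rovocal.synth import scene_nodeset

        spans = []
        for D in (200.0, 100.0):
            scene = SceneSpec(camera=camera, target=grid_target,
                              distance_cm=D, fov_deg=60.0)
            nodes = scene_nodeset(scene)
            spans.append(measure_span(nodes, grid_target, D).dx_pix)
        assert spans[1] == pytest.approx(2 * spans[0], rel=1e-9)

    def test_raw_span_is_distortion_biased(self, camera, grid_target,
                                           grid_nodeset):
        """Without undistorting first, a pincushion coefficient inflates
        the measured span — the reason the pipeline fits d before the
        span measurement."""
        raw = measure_span(grid_nodeset, grid_target, 100.0)
        corrected = measure_span(grid_nodeset, grid_target, 100.0,
                                 distortion=rv.DistortionModel(d=1.3e-4))
        assert raw.dx_pix > corrected.dx_pix


class TestExtractPatchRGB:
    def test_uniform_patch_returns_fill_value(self):
        img = np.full((60, 60, 3), 17, dtype=np.uint8)
        boxes = [{"patch_id": "p", "box_xyxy": [10, 10, 50, 50]}]
        out = extract_patch_rgb(img, boxes)
        np.testing.assert_allclose(out["p"], [17, 17, 17])

    def test_out_of_frame_patch_rejected(self):
        img = np.full((60, 60, 3), 17, dtype=np.uint8)
        boxes = [{"patch_id": "p", "box_xyxy": [40, 40, 90, 90]}]
        with pytest.raises(ValueError, match="out of frame"):
            extract_patch_rgb(img, boxes)


class TestFitAttenuation:
    @staticmethod
    def synthetic_series(k=(0.6, 0.15, 0.08), distances=(1, 2, 3, 4, 5, 6)):
        reference = {"red": np.array([220.0, 40.0, 40.0]),
                     "gray": np.array([128.0, 128.0, 128.0])}
        model = AttenuationModel(*k)
        measurements = {
            float(D): {pid: attenuate_color(ref, model, float(D))
                       for pid, ref in reference.items()}
            for D in distances
        }
        return measurements, reference

    def test_noiseless_exact_recovery(self):
        measurements, reference = self.synthetic_series()
        res = fit_attenuation(measurements, reference)
        assert res.k["r"] == pytest.approx(0.6, abs=1e-6)
        assert res.k["g"] == pytest.approx(0.15, abs=1e-6)
        assert res.k["b"] == pytest.approx(0.08, abs=1e-6)
        assert all(r2 > 1 - 1e-9 for r2 in res.rsquared.values())

    def test_zero_attenuation_fits_zero(self):
        measurements, reference = self.synthetic_series(k=(0.0, 0.0, 0.0))
        res = fit_attenuation(measurements, reference)
        for ch in "rgb":
            assert res.k[ch] == pytest.approx(0.0, abs=1e-12)

    def test_seawater_ordering_red_most_absorbed(self):
        """Long wavelengths go first: the red coefficient dominates in a
        seawater-like series."""
        measurements, reference = self.synthetic_series()
        res = fit_attenuation(measurements, reference)
        assert res.k["r"] > res.k["g"]
        assert res.k["r"] > res.k["b"]

    def test_matches_brute_force_search(self):
        measurements, reference = self.synthetic_series()
        # perturb the red channel so the optimum is not the exact truth
        rng = np.random.default_rng(5)
        for D in measurements:
            for pid in measurements[D]:
                measurements[D][pid] = np.clip(
                    measurements[D][pid] + rng.normal(0, 1.5, 3), 0, 255)
        res = fit_attenuation(measurements, reference)

        step = 1e-4
        model = ColorAttenuation.from_measurements(measurements, reference)
        for ci, ch in enumerate("rgb"):
            sub = model.data[(model.data.channel == ch)
                             & (model.data.value > CHANNEL_FLOOR)]
            D = sub.distance_m.to_numpy()
            y = -np.log(sub.value.to_numpy() / sub.reference.to_numpy())
            grid = np.arange(0.0, 1.0, step)
            sse = [(np.sum((y - k * D) ** 2)) for k in grid]
            k_brute = grid[int(np.argmin(sse))]
            assert abs(res.k[ch] - k_brute) <= step

    def test_channel_below_floor_flagged_unfittable(self):
        reference = {"p": np.array([4.0, 200.0, 200.0])}  # red below floor
        measurements = {
            1.0: {"p": np.array([3.0, 150.0, 180.0])},
            2.0: {"p": np.array([2.0, 120.0, 160.0])},
        }
        res = fit_attenuation(measurements, reference)
        assert res.unfittable["r"]
        assert not res.unfittable["g"]
        assert np.isnan(res.k["r"])
        assert "unfittable" in res.summary()

    def test_single_distance_rejected(self):
        measurements, reference = self.synthetic_series(distances=(3,))
        with pytest.raises(ValueError, match="2 distinct distances"):
            fit_attenuation(measurements, reference)

    def test_dataframe_input_equivalent(self):
        measurements, reference = self.synthetic_series()
        res_dict = fit_attenuation(measurements, reference)
        df = ColorAttenuation.from_measurements(measurements, reference).data
        res_df = fit_attenuation(df)
        for ch in "rgb":
            assert res_df.k[ch] == pytest.approx(res_dict.k[ch], abs=1e-12)


class TestCalibrateImage:
    def test_full_pipeline_on_rendered_scene(self, pincushion_render,
                                             pincushion_scene, camera,
                                             chart_target):
        img, _ = pincushion_render
        report = calibrate_image(img, chart_target, camera, 100.0,
                                 fov_deg=60.0)
        assert report["fov_deg"] == pytest.approx(60.0, abs=0.5)
        assert report["distortion"]["d"] == pytest.approx(1.3e-4, abs=2e-5)
        assert report["distortion"]["character"] == "pincushion"
        assert report["n_nodes_matched"] >= 70
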