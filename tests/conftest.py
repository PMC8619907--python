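import numpy as np
import pytest

import rovocal as rv


@pytest.fixture(scope="session")
def camera():
    """Small-format camera keeps rendering fast without changing geometry."""
    return rv.CameraModel(width_px=640, height_px=480, fov_air_deg=82.0)


@pytest.fixture(scope="session")
def grid_target():
    return rv.default_target(with_chart=False)


@pytest.fixture(scope="session")
def chart_target():
    return rv.default_target(with_chart=True)


@pytest.fixture(scope="session")
def pincushion_scene(camera, chart_target):
    return rv.SceneSpec(
        camera=camera, target=chart_target, distance_cm=100.0,
        distortion=rv.DistortionModel(d=1.3e-4), fov_deg=60.0,
        attenuation=rv.AttenuationModel(k_r=0.6, k_g=0.15, k_b=0.08),
    )


@pytest.fixture(scope="session")
def pincushion_render(pincushion_scene):
    """Rendered scene plus sidecar, shared across tests (it is deterministic)."""
    return rv.render_scene(pincushion_scene)


@pytest.fixture(scope="session")
def grid_nodeset(camera, grid_target):
    """Analytic ground-truth node set (no rendering), d = 1.3e-4 radial."""
    from rovocal.synth import scene_nodeset

    scene = rv.SceneSpec(camera=camera, target=grid_target, distance_cm=100.0,
                         distortion=rv.DistortionModel(d=1.3e-4), fov_deg=60.0)
    return scene_nodeset(scene)
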