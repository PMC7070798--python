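import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vinescan as vs
from vinescan.scene import Batch, Segment, VineScene

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def cylinder_scene():
    """A single vertical cylinder (post) over flat ground, 5 m of row."""
    post = Segment(np.array([2.5, 1.0, 0.0]), np.array([2.5, 1.0, 1.8]),
                   0.05, 0.05, tag="post")
    return VineScene(segments=[post], markers=[], batches=[Batch("T", 1, 0.0, 5.0)],
                     wood_density=450.0, seed=0, row_y=1.0, ground_z=0.0)


@pytest.fixture(scope="session")
def quiet_sensor():
    """Noise-free sensor at the slow datasheet mode (25 Hz, 0.25 m/s pairing)."""
    return vs.SensorConfig(scan_rate_hz=25.0, range_noise_sd=0.0,
                           systematic_error_bound=0.0)


@pytest.fixture(scope="session")
def quiet_trajectory():
    return vs.TrajectorySpec(speed=0.25, row_length=5.0, start_x=0.0,
                             attitude_amp_rad=(0.0, 0.0, 0.0),
                             attitude_jitter_rad=0.0, lateral_wobble_amp=0.0,
                             gnss_noise_sd=0.0, seed=5)


@pytest.fixture(scope="session")
def quiet_run(cylinder_scene, quiet_sensor, quiet_trajectory):
    """Deterministic noise-free pass over the cylinder scene."""
    return vs.simulate_run(cylinder_scene, quiet_sensor, quiet_trajectory)


@pytest.fixture(scope="session")
def small_vineyard_run():
    """A short noisy two-vine batch with per-point provenance labels."""
    spec = vs.SceneSpec(n_treatments=1, n_plots_per_treatment=1,
                        n_vines_per_plot=2)
    scene = vs.build_scene(spec, 77)
    x0, x1 = scene.x_extent
    sensor = vs.SensorConfig()
    traj = vs.TrajectorySpec(row_length=(x1 - x0) + 1.0, start_x=x0 - 0.5, seed=78)
    run = vs.simulate_run(scene, sensor, traj)
    cloud = vs.georeference(run.frames, run.fixes, sensor,
                            frame_labels=run.hit_tags)
    return scene, run, cloud
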