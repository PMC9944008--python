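import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from grazetrack.scene import (
    BehaviourModel,
    SceneConfig,
    boundary_resolvable_behaviour,
    render_frames,
    simulate_trajectories,
)

settings.register_profile(
    "suite", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def desk_scene() -> SceneConfig:
    """Default desk-scale scene: 2 h at 15 s frames, 8 grazers, 5 px/cm."""
    return SceneConfig()


@pytest.fixture(scope="session")
def short_scene() -> SceneConfig:
    """A 15-minute variant for cheap rendering tests."""
    return SceneConfig(duration_s=900.0, n_grazers=3)


@pytest.fixture(scope="session")
def classification_profile():
    """Scene + behaviour where per-interval displacements at the category
    boundaries span multiple pixels (20 px/cm, 15-min frames) and speed
    supports keep a wide margin from the boundaries; headings are
    uncorrelated so grazers stay well separated."""
    scene = SceneConfig(px_per_cm=20.0, frame_interval_s=900.0, duration_s=900.0 * 120, n_grazers=4)
    base = boundary_resolvable_behaviour()
    behaviour = BehaviourModel(
        transition_matrix=base.transition_matrix,
        speed_ranges=base.speed_ranges,
        turning_kappa=0.0,
    )
    return scene, behaviour


@pytest.fixture(scope="session")
def rendered_short(short_scene):
    truth = simulate_trajectories(short_scene, seed=11)
    frames, masks = render_frames(truth, short_scene)
    return short_scene, truth, frames, masks


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def stationary_from_matrix(tm: np.ndarray) -> np.ndarray:
    """Independent oracle: stationary distribution via the eigenvector of
    the transposed transition matrix for eigenvalue 1."""
    w, v = np.linalg.eig(np.asarray(tm, dtype=float).T)
    pi = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    pi = np.abs(pi)
    return pi / pi.sum()
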