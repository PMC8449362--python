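import pytest

from pseudopodtomo.config import PipelineConfig, load_builtin_config
from pseudopodtomo.scene import (HelicalParams, ReceptorSpec, SceneSpec,
                                 TubeSpec, generate_scene)


@pytest.fixture(scope="session")
def fig3b_config() -> PipelineConfig:
    return load_builtin_config("fig3b")


@pytest.fixture(scope="session")
def receptor_config() -> PipelineConfig:
    return load_builtin_config("receptor")


@pytest.fixture(scope="session")
def small_scene_spec() -> SceneSpec:
    """A reduced scene for unit tests: quarter-size volume, few filaments."""
    return SceneSpec(
        volume_shape=(128, 128, 96),
        n_filaments=(6, 8),
        length_distribution=(50.0, 80.0),
        tube=TubeSpec(radius=34.0, length=90.0),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_scene(small_scene_spec):
    return generate_scene(small_scene_spec)


@pytest.fixture(scope="session")
def small_receptor_scene():
    spec = SceneSpec(
        volume_shape=(192, 192, 128),
        n_filaments=(3, 4),
        length_distribution=(50.0, 80.0),
        tube=TubeSpec(radius=60.0, length=100.0, clearance=2.0),
        receptor_spec=ReceptorSpec(count=20),
        seed=21,
    )
    return spec, generate_scene(spec)


@pytest.fixture(scope="session")
def helical_default() -> HelicalParams:
    return HelicalParams()
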