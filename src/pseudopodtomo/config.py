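"""Pipeline configuration: defaults, YAML round trip, shipped presets.

Two presets ship with the package:

* ``fig3b`` -- the 28-scene polarity-recovery study (74% tip-ward
  generator composition);
* ``receptor`` -- the 5-scene membrane-receptor recovery study (12-nm
  receptors placed 50-70 nm above the support).

Every run writes a frozen copy of the resolved configuration next to its
outputs, so any result can be traced to the exact parameters.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .scene import HelicalParams, ReceptorSpec, SceneSpec, TubeSpec


@dataclass
class PipelineConfig:
    scene: SceneSpec = field(default_factory=SceneSpec)
    n_scenes: int = 1
    # polarity side
    spacing: float = 8.0          # nm between segment centres
    box_edge: int = 32            # voxels
    slab_thickness: float = 11.0  # nm
    k_classes_2d: int = 20
    classify_iterations: int = 12
    margin: float = 0.05
    min_members: int = 10
    alpha: float = 0.05
    alpha_stringent: float = 0.01
    n_min_votes: int = 5
    # receptor side
    attach_band: tuple[float, float] = (2.0, 12.0)
    height_band: tuple[float, float] = (50.0, 70.0)
    tilt_max: float = 20.0
    min_separation: float = 8.0
    k_classes_3d: int = 2
    measure_level: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("spacing", "box_edge", "slab_thickness", "alpha",
                     "alpha_stringent", "tilt_max", "min_separation",
                     "measure_level"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    def scene_for(self, index: int) -> SceneSpec:
        """Scene spec of the index-th tomogram (seed offset per scene)."""
        return replace(self.scene, seed=self.scene.seed + index)


def _scene_from_dict(d: dict) -> SceneSpec:
    d = dict(d)
    tube = TubeSpec(**d.pop("tube", {}))
    if "receptor_spec" in d:           # canonical (frozen-config) form
        rd = dict(d.pop("receptor_spec"))
        if "placement_band" in rd:
            rd["placement_band"] = tuple(rd["placement_band"])
        rec = ReceptorSpec(**rd)
    else:                              # user-facing shorthand
        rec = ReceptorSpec(
            count=d.pop("receptor_count", 0),
            height=d.pop("receptor_height", 12.0),
            placement_band=tuple(d.pop("receptor_band", (50.0, 70.0))),
        )
    hel = HelicalParams(**d.pop("helical", {}))
    for key in ("volume_shape", "n_filaments", "length_distribution"):
        if key in d:
            d[key] = tuple(d[key])
    return SceneSpec(tube=tube, receptor_spec=rec, helical=hel, **d)


def config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    scene = _scene_from_dict(d.pop("scene", {}))
    for key in ("attach_band", "height_band"):
        if key in d:
            d[key] = tuple(d[key])
    return PipelineConfig(scene=scene, **d)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def load_builtin_config(name: str) -> PipelineConfig:
    """Load a shipped preset by name ('fig3b' or 'receptor')."""
    ref = importlib.resources.files("pseudopodtomo") / "configs" / f"{name}.yaml"
    return config_from_dict(yaml.safe_load(ref.read_text()))


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Freeze the resolved configuration as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(asdict(cfg)), fh, sort_keys=False)


def _to_plain(obj):
    import numpy as np
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
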