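"""Bundled configuration profiles.

``standard_profile`` mirrors the full-scale study protocol: 250 x 250
working resolution, sigma-3 Gaussian targets, full-width networks, 5-fold
cross-validation at 500 epochs.

``desk_profile`` is the scaled-down surrogate used by the test suite and
the worked examples: 128 x 128 scenes, targets with sigma 2 (papilla
radius scales with resolution), networks at 1/8 width, 50 epochs. It is
documented as a surrogate and never silently substituted for the standard
profile; every consumer names the profile it used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .heatmap import HeatmapConfig
from .models import ArchitectureSpec, scale_spec
from .synthetic import SceneConfig
from .training import TrainingConfig


@dataclass(frozen=True)
class Profile:
    name: str
    scene: SceneConfig
    heatmap: HeatmapConfig
    training: TrainingConfig
    width_scale: float
    match_radius: float

    def scaled(self, spec: ArchitectureSpec) -> ArchitectureSpec:
        if self.width_scale == 1.0:
            return spec
        return scale_spec(spec, self.width_scale)


def standard_profile(seed: int = 0) -> Profile:
    return Profile(
        name="standard",
        scene=SceneConfig(seed=seed),
        heatmap=HeatmapConfig(sigma=3.0, peak_min_distance=3),
        training=TrainingConfig(seed=seed),
        width_scale=1.0,
        match_radius=5.0,
    )


def desk_profile(seed: int = 0) -> Profile:
    return Profile(
        name="desk",
        scene=SceneConfig(
            image_size=(128, 128),
            spot_radius_px=(2.0, 4.0),
            min_separation=6.0,
            seed=seed,
        ),
        heatmap=HeatmapConfig(sigma=2.0, peak_min_distance=2),
        training=TrainingConfig(epochs=50, seed=seed),
        width_scale=0.125,
        match_radius=5.0,
    )
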