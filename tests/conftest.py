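"""Shared fixtures: small synthetic scenes classified once per session."""

from __future__ import annotations

import numpy as np
import pytest

from icehab.classify import classify_scene
from icehab.synthetic import SyntheticSceneSpec, generate_scene


@pytest.fixture(scope="session")
def moderate_scene():
    """A mid-fjord scene: 4 icebergs, 20% brash, easy contrast."""
    spec = SyntheticSceneSpec(
        height_px=250, width_px=375, n_icebergs=4, brash_coverage=0.2, seed=11
    )
    return generate_scene(spec)


@pytest.fixture(scope="session")
def classified_moderate(moderate_scene):
    """The moderate scene run through the full rule set (one run, reused)."""
    scene, truth = moderate_scene
    class_map, objects = classify_scene(scene)
    return scene, truth, class_map, objects


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
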