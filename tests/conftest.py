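"""Shared fixtures: hand-built scene databases and synthetic draws."""

from __future__ import annotations

import numpy as np
import pytest

from scenestats import (
    GeneratorConfig,
    ObjectAnnotation,
    Polygon,
    SceneAnnotation,
    SceneDatabase,
    default_profiles,
    generate_database,
    recovery_profiles,
)


def rect(x0: float, y0: float, w: float = 1.0, h: float = 1.0) -> Polygon:
    return Polygon(
        np.array([[x0, y0], [x0 + w, y0], [x0 + w, y0 + h], [x0, y0 + h]])
    )


def make_scene(
    scene_id: str,
    category: str,
    labels: list[str],
    width: float = 10.0,
    height: float = 10.0,
) -> SceneAnnotation:
    """Scene with one unit square per label on a deterministic grid."""
    objects = []
    for i, label in enumerate(labels):
        x0 = (i * 2) % 8
        y0 = ((i * 2) // 8) * 2
        objects.append(ObjectAnnotation(label, rect(x0, y0)))
    return SceneAnnotation(
        scene_id=scene_id,
        width=width,
        height=height,
        category=category,
        objects=tuple(objects),
    )


TAXONOMY3 = {"kitchen": "indoor", "street": "urban", "coast": "natural"}


@pytest.fixture
def three_cat_db() -> SceneDatabase:
    """Small hand-built database with known label statistics.

    kitchen scenes: k1 [sink, stove, wall], k2 [sink, wall, wall]
    street scenes:  s1 [car, road, wall],  s2 [car, road]
    coast scenes:   c1 [sky, ocean],       c2 [sky, ocean, rock]
    """
    scenes = [
        make_scene("k1", "kitchen", ["sink", "stove", "wall"]),
        make_scene("k2", "kitchen", ["sink", "wall", "wall"]),
        make_scene("s1", "street", ["car", "road", "wall"]),
        make_scene("s2", "street", ["car", "road"]),
        make_scene("c1", "coast", ["sky", "ocean"]),
        make_scene("c2", "coast", ["sky", "ocean", "rock"]),
    ]
    return SceneDatabase(scenes=tuple(scenes), taxonomy=dict(TAXONOMY3))


@pytest.fixture(scope="session")
def default_db() -> SceneDatabase:
    """Default 16-category synthetic database, 20 scenes per category."""
    return generate_database(
        GeneratorConfig(
            profiles=tuple(default_profiles()), scenes_per_category=20, seed=5
        )
    )


@pytest.fixture(scope="session")
def recovery_db_small() -> SceneDatabase:
    """Recovery-profile database at a size suited to fast unit tests."""
    return generate_database(
        GeneratorConfig(
            profiles=tuple(recovery_profiles()), scenes_per_category=10, seed=11
        )
    )
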