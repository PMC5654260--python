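import numpy as np
import pytest

from rbcmorph import synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """One 12-cell scene with touching clusters, shared across tests."""
    cfg = synthetic.SceneConfig(
        frame_width=512, frame_height=512, n_cells=12,
        touching_fraction=0.5, artifact_count=3, seed=7,
    )
    frame, truth = synthetic.render_scene(cfg)
    return cfg, frame, truth


@pytest.fixture(scope="session")
def scene_batch():
    """20 small seeded scenes for recall statistics."""
    scenes = []
    for seed in range(20):
        cfg = synthetic.SceneConfig(
            frame_width=320, frame_height=320, n_cells=5,
            touching_fraction=0.4, seed=seed,
        )
        scenes.append((cfg, *synthetic.render_scene(cfg)))
    return scenes


def disc_mask(radius: int, pad: int = 4) -> np.ndarray:
    n = radius + pad
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    return (xx**2 + yy**2) <= radius**2


def dumbbell_mask(radius: int = 10, gap: int = 16, neck: int = 3) -> np.ndarray:
    """Two discs joined by a thin neck, symmetric about the vertical axis."""
    h = 2 * radius + 9
    w = 2 * (radius + gap) + 9
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h // 2, w // 2
    left = (yy - cy) ** 2 + (xx - (cx - gap)) ** 2 <= radius**2
    right = (yy - cy) ** 2 + (xx - (cx + gap)) ** 2 <= radius**2
    bar = (np.abs(yy - cy) <= neck) & (np.abs(xx - cx) <= gap)
    return left | right | bar
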