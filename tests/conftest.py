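import dataclasses

import numpy as np
import pytest

import mnquant as m


@pytest.fixture(scope="session")
def default_scene():
    """One moderately dense scene used by many read-only tests."""
    return m.generate_scene(m.SceneConfig(seed=7))


@pytest.fixture(scope="session")
def small_scene():
    """A tiny fast scene (no decoys, no noise randomness surprises)."""
    cfg = m.SceneConfig(
        width=256, height=256, n_nuclei=12,
        apoptotic_fraction=0.0, mitotic_fraction=0.0, seed=3,
    )
    return m.generate_scene(cfg)


@pytest.fixture(scope="session")
def scene_grid():
    """Twenty small seeded scenes for oracle-equivalence sweeps."""
    base = m.SceneConfig(width=320, height=320, n_nuclei=24)
    return [
        m.generate_scene(dataclasses.replace(base, seed=100 + i)) for i in range(20)
    ]


@pytest.fixture(scope="session")
def desk_benchmark():
    """The full desk-scale benchmark (train + hold-out + scene sweep).

    Expensive (several minutes); shared by the acceptance tests.
    """
    from mnquant.benchmarks import run_benchmark

    return run_benchmark(seed=1)


def brute_force_bboxes(mask: np.ndarray):
    """Independent per-pixel oracle for tight label bounding boxes."""
    out = {}
    for y in range(mask.shape[0]):
        for x in range(mask.shape[1]):
            lbl = int(mask[y, x])
            if lbl == 0:
                continue
            y0, y1, x0, x1 = out.get(lbl, (y, y, x, x))
            out[lbl] = (min(y0, y), max(y1, y), min(x0, x), max(x1, x))
    return {
        lbl: (y0, y1 + 1, x0, x1 + 1) for lbl, (y0, y1, x0, x1) in out.items()
    }
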