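import numpy as np
import pytest

from spinelabel.canal import centerline_from_truth
from spinelabel.phantom import PhantomConfig, generate_phantom

THORACIC_PLAN = tuple(f"T{i}" for i in range(1, 13))


@pytest.fixture(scope="session")
def full_phantom():
    """Default 26-level phantom with truth (session-cached)."""
    cfg = PhantomConfig(seed=42)
    vol, truth = generate_phantom(cfg)
    return cfg, vol, truth


@pytest.fixture(scope="session")
def thoracic_phantom():
    """Smaller 12-level phantom for faster geometry tests."""
    cfg = PhantomConfig(seed=7, level_plan=THORACIC_PLAN)
    vol, truth = generate_phantom(cfg)
    return cfg, vol, truth


@pytest.fixture()
def truth_centerline(thoracic_phantom):
    _, vol, truth = thoracic_phantom
    return centerline_from_truth(truth.canal_centerline, vol.spacing)


def straight_centroids(names, start_mm=30.0, gap_mm=30.0, ap=50.0, lr=30.0):
    """Evenly spaced truth-like centroid sets for metric tests."""
    from spinelabel.levels import CentroidSet

    return CentroidSet.from_items(
        [(n, [start_mm + i * gap_mm, ap, lr]) for i, n in enumerate(names)]
    )
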