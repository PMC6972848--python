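import numpy as np
import pandas as pd
import pytest

from parklens.synth import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic study shared by read-only tests."""
    cfg = SynthConfig(n_users=120, photos_per_user_mean=10.0,
                      favs_per_user_mean=8.0, seed=42)
    return cfg, generate_dataset(cfg)


@pytest.fixture()
def photo_frame():
    """Tiny hand-written photo table with keyword sets."""
    def make(sets, channel="park"):
        return pd.DataFrame({
            "photo_id": [f"p{i}" for i in range(len(sets))],
            "user_id": [f"u{i}" for i in range(len(sets))],
            "channel": channel,
            "keywords": [sorted(s) for s in sets],
        })
    return make


def brute_jaccard(a: set, b: set) -> float:
    union = a | b
    return 1.0 - len(a & b) / len(union) if union else 0.0


def ray_cast(point, ring) -> bool:
    """Even-odd ray casting; independent point-in-polygon oracle."""
    x, y = point
    inside = False
    n = len(ring)
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xi = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xi:
                inside = not inside
    return inside


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
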