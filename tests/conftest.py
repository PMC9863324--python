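"""Shared fixtures: small phantom exams and simple geometric masks."""

import numpy as np
import pytest

from aortamech.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One phantom exam at the full study conditions (256 px, 30 frames)."""
    cfg = PhantomConfig()
    seq, masks, truth = generate_phantom(cfg)
    return cfg, seq, masks, truth


@pytest.fixture(scope="session")
def small_phantom():
    """A fast 64 px phantom for I/O and plumbing tests."""
    cfg = PhantomConfig(
        grid_size=64,
        n_frames=5,
        semi_axes_dia=(14.0, 12.0),
        center_offset_px=(-1.6, 1.3),
        seed=3,
    )
    seq, masks, truth = generate_phantom(cfg)
    return cfg, seq, masks, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_disk(n: int, center: tuple[float, float], radius: float) -> np.ndarray:
    """Rasterised disk mask: pixel centers within ``radius`` of ``center``."""
    rr, cc = np.mgrid[0:n, 0:n].astype(float)
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


@pytest.fixture()
def disk_mask():
    return make_disk(128, (63.5, 63.5), 40.0)
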