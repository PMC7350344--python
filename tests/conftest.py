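"""Shared fixtures: small synthetic scenes, rendered once per session."""

from __future__ import annotations

import numpy as np
import pytest

import rootmorph as rm


@pytest.fixture(scope="session")
def mini_scene():
    """One small tray scene (250 DPI, 6x8 cm) with its ground truth."""
    stack, truth = rm.generate_tray(rm.SceneParams.mini(), seed=1)
    return stack, truth


@pytest.fixture(scope="session")
def mini_result(mini_scene):
    stack, _ = mini_scene
    return rm.run_tray(stack, keep_intermediates=True)


@pytest.fixture(scope="session")
def blank_scene():
    stack, truth = rm.generate_tray(
        rm.SceneParams.mini(n_fibrous=0, n_storage=0, n_dirt=0), seed=2
    )
    return stack, truth


def full_frame_mask(result, shape):
    """Map a cropped-tray mask back into full-image coordinates."""
    out = np.zeros(shape, dtype=bool)
    r0, c0 = result.cropped.offset
    h, w = result.mask.shape
    out[r0 : r0 + h, c0 : c0 + w] = result.mask.pixels
    return out
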