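"""Shared fixtures: geometric helpers and the cached phantom battery."""

from __future__ import annotations

import numpy as np
import pytest

from mammoseg import fast_config, generate_phantom, run_pipeline
from mammoseg.synthetic import BATTERY_SEEDS, battery_specs


def make_disc(shape=(64, 64), center=(32, 32), radius=15):
    """Boolean disc mask."""
    r = np.arange(shape[0])[:, None]
    c = np.arange(shape[1])[None, :]
    return np.hypot(r - center[0], c - center[1]) <= radius


def disc_image(shape=(64, 64), center=(32, 32), radius=15, lo=80.0, hi=200.0):
    """Bright disc on a dark background (hard edge, no noise)."""
    return np.where(make_disc(shape, center, radius), hi, lo)


@pytest.fixture(scope="session")
def battery_phantoms():
    """The 20-seed standard phantom battery (images + exact ground truth)."""
    return [(spec, generate_phantom(spec)) for spec in battery_specs(BATTERY_SEEDS)]


@pytest.fixture(scope="session")
def battery_results(battery_phantoms):
    """Full pipeline runs over the battery at the fast operating point.

    Shared across the acceptance checks that score the unperturbed
    battery so the 20 runs happen once per session.
    """
    cfg = fast_config()
    return [
        (spec, phantom, run_pipeline(phantom[0], cfg))
        for spec, phantom in battery_phantoms
    ]
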