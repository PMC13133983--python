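"""Shared fixtures for the mtseam test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mtseam import ParticleTable


def make_table(n: int = 10, micrograph_id: str = "mic_0.mrc", filament_id: int = 0, seed: int = 0):
    """Small valid particle table with smoothly varying picks and angles."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) * 82.0
    df = pd.DataFrame(
        dict(
            micrograph_id=micrograph_id,
            filament_id=filament_id,
            particle_id=np.arange(n),
            x=100.0 + t * 0.8,
            y=200.0 + t * 0.6,
            pixel_size=1.0,
            rot=rng.uniform(-180, 180, n),
            tilt=90.0,
            psi=np.full(n, 36.87),
        )
    )
    return ParticleTable(df)


@pytest.fixture
def small_table():
    return make_table()
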