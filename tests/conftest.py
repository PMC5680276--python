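import numpy as np
import pytest

from flagbeat.synthetic import (DriftProfile, WaveformSpec, default_grid,
                                gen_curvature_wave)


@pytest.fixture
def spec():
    return WaveformSpec(C1=0.1, C2=0.02, phi=0.5, wavelength=40.0, L=45.0,
                        freq_hz=20.0)


@pytest.fixture
def short_grid():
    """2 s at 500 fps, 30 arclength points at Δs = 0.9 µm."""
    return default_grid(duration=2.0)


@pytest.fixture
def two_harmonic_field(spec, short_grid):
    s, t = short_grid
    field, record = gen_curvature_wave(spec, DriftProfile.none(spec), s=s, t=t,
                                       seed=0)
    return field, record
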