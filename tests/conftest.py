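import math

import numpy as np
import pytest

import fiberfield as ff
from fiberfield.synthetic_tissue import NeuronPopulation


@pytest.fixture(scope="session")
def cylinder_volume() -> ff.TissueVolume:
    """The traced control region: 300 µm-diameter × 300 µm cylinder."""
    return ff.TissueVolume(shape="cylinder", dimensions=(300.0, 300.0))


@pytest.fixture(scope="session")
def contralateral_population(cylinder_volume):
    cfg = ff.PopulationConfig.contralateral(seed=20240101)
    return ff.generate_contralateral_population(cylinder_volume, cfg)


@pytest.fixture(scope="session")
def implant_row():
    """16 tips in a row at the 80 µm design pitch, with an implant population."""
    volume = ff.TissueVolume(shape="box", dimensions=(1500.0, 300.0, 300.0))
    tips = [
        ff.FiberTip(f"f{i:02d}", (-600.0 + 80.0 * i, 0.0, 150.0))
        for i in range(16)
    ]
    cfg = ff.PopulationConfig.implant(seed=7, exclusion_radius=10.0)
    population = ff.generate_implant_population(volume, tips, cfg)
    return volume, tips, population


def make_ellipsoid_population(
    center=(30.0, 30.0, 150.0), radius=8.85, cssi=0.0, orientation=0.3
) -> NeuronPopulation:
    """One analytic ellipsoid soma of sphere-equivalent radius ``radius``."""
    k = (2.0 + cssi) / (2.0 - cssi)
    volume = 4.0 / 3.0 * math.pi * radius**3
    p = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    return NeuronPopulation(
        ids=["soma"],
        centroids=np.array([center], dtype=float),
        semi_axes=np.array([[p / math.sqrt(k), p * math.sqrt(k), p]]),
        orientations=np.array([orientation]),
        cssi=np.array([cssi]),
        volumes=np.array([volume]),
    )
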