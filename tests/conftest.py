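import numpy as np
import pandas as pd
import pytest

from nlossrisk.sources import MonthlySourceInputs
from nlossrisk.transport import ClimateSeries, SoilLayer, SoilProfile


def make_climate(rain, pet=None, start="2000-01-01"):
    """Build a ClimateSeries from bare rain (and optional PET) arrays."""
    rain = np.asarray(rain, dtype=float)
    pet = np.zeros_like(rain) if pet is None else np.asarray(pet, dtype=float)
    dates = pd.date_range(start, periods=len(rain), freq="D")
    return ClimateSeries(dates, rain, pet)


def single_layer_profile(k=0.5, curve=0.2, thickness=1000.0):
    """One 1000 mm layer: sat 0.4, fc 0.3, wp 0.1 -> 400/300/100 mm."""
    return SoilProfile(
        "toy", (SoilLayer(thickness, 0.4, 0.3, 0.1, k),), runoff_curve_parameter=curve
    )


def random_soil(rng):
    """A random valid soil profile reaching at least 1000 mm."""
    n_layers = int(rng.integers(2, 5))
    thicknesses = rng.uniform(250, 600, n_layers)
    thicknesses *= max(1.0, 1050.0 / thicknesses.sum())
    layers = []
    for t in thicknesses:
        wp = rng.uniform(0.03, 0.15)
        fc = wp + rng.uniform(0.05, 0.2)
        sat = fc + rng.uniform(0.03, 0.15)
        layers.append(SoilLayer(float(t), float(sat), float(fc), float(wp), float(rng.uniform(0.05, 1.0))))
    return SoilProfile(
        f"rand{rng.integers(1 << 30)}",
        tuple(layers),
        runoff_curve_parameter=float(rng.uniform(0.05, 1.0)),
        total_n_fraction=float(rng.uniform(0.001, 0.006)),
    )


def random_sources(rng):
    return MonthlySourceInputs(*rng.uniform(0, 30, 8))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
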