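import numpy as np
import pandas as pd
import pytest

from htfc.gating import GateConfig
from htfc.panel import Antibody, demo_plate_map
from htfc.presets import default_noise, default_populations
from htfc.simulate import PopulationSpec, TechnicalNoiseModel


@pytest.fixture(scope="session")
def demo_map():
    return demo_plate_map()


@pytest.fixture()
def populations():
    return default_populations()


@pytest.fixture()
def noise():
    return default_noise()


@pytest.fixture()
def gate_config():
    return GateConfig()


@pytest.fixture()
def clean_noise():
    """Noise-free acquisition: no dead cells, doublets, spillover or jitter."""
    return TechnicalNoiseModel(
        events_per_well=10_000,
        dead_fraction=0.0,
        doublet_fraction=0.0,
        spillover=None,
        intensity_jitter_sd=0.0,
    )


@pytest.fixture()
def sharp_population():
    """Single population with tightly separated negative/positive modes, for
    ideal-threshold percent-positive recovery tests."""
    return [
        PopulationSpec(
            "cells",
            1.0,
            positive_fraction={"CD99": 0.30},
            stain_intensity={"CD99": (3.5, 0.2)},
            autofluorescence=(2.0, 0.2),
        )
    ]


@pytest.fixture()
def cd99_pe():
    return Antibody("CD99", "PE")
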