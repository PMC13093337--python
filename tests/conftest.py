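import numpy as np
import pandas as pd
import pytest

from owh_screen import synthetic_data as sd


@pytest.fixture(scope="session")
def nuclei_field():
    cfg = sd.SimulationConfig(seed=11, n_nuclei=50, pyknotic_fraction=0.2,
                              min_separation=10.0)
    img, truth = sd.gen_nuclei_image(cfg)
    return cfg, img, truth


@pytest.fixture(scope="session")
def microglia_benchmark():
    cfg = sd.SimulationConfig(seed=5)
    masks, truth = sd.gen_microglia_images(cfg)
    return masks, truth


@pytest.fixture(scope="session")
def expression_panel():
    cfg = sd.SimulationConfig(seed=13, n_deg=20, n_emergent=14,
                              n_restored_combo=5, n_restored_az=3,
                              n_restored_epo=3)
    values, meta, truth = sd.gen_expression_panel(cfg)
    return cfg, values, meta, truth


def subthreshold_config(seed):
    return sd.SimulationConfig(seed=seed, group_effects={
        "control": {"fractional_effect": 1.0},
        "OGD": {"fractional_effect": 0.0},
        "Az": {"fractional_effect": 0.0},
        "Epo": {"fractional_effect": 0.0},
        "AzEpo": {"fractional_effect": 0.6},
    })
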