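import numpy as np
import pytest

from tkqsar.chemreg import ChemicalRecord, standardize_structure
from tkqsar.synthdata import GeneratorConfig, PlantedFragment, generate_library


@pytest.fixture(scope="session")
def small_library():
    """60 deterministic synthetic records, ~half carrying a CF3 group."""
    cfg = GeneratorConfig(
        n_chemicals=60, seed=42,
        planted_fragments=[PlantedFragment("C(F)(F)F", -40.0, 0.5)],
    )
    records, truth = generate_library(cfg)
    return records, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2026)


def record(smiles: str, rid: str = "") -> ChemicalRecord:
    return standardize_structure(smiles, record_id=rid or smiles)
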