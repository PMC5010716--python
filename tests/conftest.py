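"""Shared fixtures: small hand-built inputs and one seeded synthetic dataset."""

import pytest
from hypothesis import settings

import p53conv as pc

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture()
def toy_alignment() -> pc.Alignment:
    """Four species, 12 columns, with gaps and one ambiguity code."""
    return pc.Alignment(
        [
            ("human", "MEEPQ-SDPSVX"),
            ("mouse", "MEESQ-SDISLE"),
            ("whale", "MEE-QASDPSVE"),
            ("spalax", "MQEPQASDPSVE"),
        ]
    )


@pytest.fixture()
def toy_species() -> list[pc.SpeciesRecord]:
    return [
        pc.SpeciesRecord("spalax", "hypoxic", clade="Rodentia"),
        pc.SpeciesRecord("whale", "hypoxic", clade="Cetartiodactyla"),
        pc.SpeciesRecord("human", "non_stress", clade="Primates"),
        pc.SpeciesRecord("mouse", "non_stress", clade="Rodentia"),
    ]


@pytest.fixture(scope="session")
def mc_null_5_5() -> pc.MCNullSample:
    """Shared Monte-Carlo null for two groups of 5 species (n1 = n2 = 10)."""
    return pc.mc_null(5, 5, 20_000, dim=2, seed=7)


@pytest.fixture(scope="session")
def implanted_dataset() -> pc.SimulatedDataset:
    """One seeded dataset with full implantation in TAD2."""
    return pc.simulate_dataset(pc.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def null_dataset() -> pc.SimulatedDataset:
    """Same conditions, no implantation."""
    return pc.simulate_dataset(pc.SimulationConfig(seed=11, implant=None))
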