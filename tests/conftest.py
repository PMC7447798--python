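import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from twinmeth.core import ProbeManifest, SampleSheet
from twinmeth.simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_manifest,
    simulate_methylation,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A desk-sized cohort: 8 discordant / 6 concordant-negative / 3 concordant-positive."""
    return SimulationConfig(
        n_pairs_discordant=8,
        n_pairs_concneg=6,
        n_pairs_concpos=3,
        n_probes=400,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_manifest(small_cfg) -> ProbeManifest:
    return simulate_manifest(small_cfg)


@pytest.fixture(scope="session")
def small_sheet(small_cfg) -> SampleSheet:
    return simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_sim(small_cfg, small_manifest, small_sheet):
    return simulate_methylation(small_cfg, small_manifest, small_sheet)


@pytest.fixture(scope="session")
def paper_sheet() -> SampleSheet:
    """The published cohort composition: 27 discordant / 42 / 6 pairs."""
    return simulate_cohort(SimulationConfig(seed=7))


def make_sheet(rows: list[dict]) -> SampleSheet:
    return SampleSheet(pd.DataFrame(rows))


def discordant_sheet(n_pairs: int, seed: int = 0, nk_constant: float | None = None) -> SampleSheet:
    cfg = SimulationConfig(
        n_pairs_discordant=n_pairs,
        n_pairs_concneg=0,
        n_pairs_concpos=0,
        n_probes=10,
        seed=seed,
        nk_range=(nk_constant, nk_constant) if nk_constant is not None else (0.02, 0.12),
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
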