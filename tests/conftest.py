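"""Shared fixtures: dictionary/slice singletons and scaled-down synthetic runs."""
from __future__ import annotations

from pathlib import Path

import pytest

from neurovigil.drug_normalize import load_drug_dictionary
from neurovigil.meddra_map import load_meddra_slice
from neurovigil.synthetic_data import PlantedSignal, SynthConfig, generate


@pytest.fixture(scope="session")
def dictionary():
    return load_drug_dictionary()


@pytest.fixture(scope="session")
def meddra():
    return load_meddra_slice()


def small_synth_config(seed: int = 0, n: int = 8000, **overrides) -> SynthConfig:
    """Desk-scale study conditions: same structure as the defaults, smaller n."""
    kwargs = dict(
        n_reports=n,
        seed=seed,
        quarters=("2023Q1", "2023Q2", "2023Q3", "2023Q4"),
        planted_signals=(
            PlantedSignal("NIVOLUMAB", "Myasthenia gravis", 20.0, 300),
            PlantedSignal("PEMBROLIZUMAB", "Neuropathy peripheral", 5.0, 400),
            PlantedSignal(("CEMIPLIMAB", "PACLITAXEL"), "Hypoaesthesia", 8.0, 150),
        ),
    )
    kwargs.update(overrides)
    return SynthConfig(**kwargs)


@pytest.fixture(scope="session")
def small_package(tmp_path_factory) -> tuple[Path, object]:
    """One small generated package on disk, shared across pipeline tests."""
    root = tmp_path_factory.mktemp("faers_small")
    config = small_synth_config(seed=11)
    truth = generate(config, root)
    return root, truth
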