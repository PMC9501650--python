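"""Shared fixtures: synthetic datasets generated once per session."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pytest

from oohmenu import GeneratorConfig, generate_dataset, write_dataset
from oohmenu.pipeline import RunResult, run_all
from oohmenu.synthetic import SyntheticDataset


@dataclass
class PipelineRun:
    """A generated dataset together with its full pipeline run."""

    dataset: SyntheticDataset
    result: RunResult
    dataset_dir: str
    out_dir: str

    @property
    def truth(self) -> pd.DataFrame:
        return self.dataset.truth

    def analyzed_truth(self) -> pd.DataFrame:
        """Ground truth restricted to the chain-waves the pipeline analyzed."""
        truth = self.dataset.truth
        keep = [
            chain in set(self.result.analyzed_chains[wave])
            for chain, wave in zip(truth["chain"], truth["wave"])
        ]
        return truth[keep]


def _run(config: GeneratorConfig, seed: int, tmp_path_factory, label: str) -> PipelineRun:
    root = tmp_path_factory.mktemp(label)
    dataset = generate_dataset(config, seed=seed)
    data_dir = root / "data"
    out_dir = root / "out"
    write_dataset(dataset, data_dir)
    result = run_all(data_dir, out_dir, seed=seed)
    return PipelineRun(dataset, result, str(data_dir), str(out_dir))


@pytest.fixture(scope="session")
def mixed_run(tmp_path_factory) -> PipelineRun:
    """Two-wave dataset over all dialects, with pizza chains and one stale chain."""
    config = GeneratorConfig.small(
        n_chains=12,
        items_per_chain=(120, 200),
        pizza_chain_fraction=0.2,
        stale_chain_count=1,
        seed=11,
    )
    return _run(config, seed=11, tmp_path_factory=tmp_path_factory, label="mixed")


@pytest.fixture(scope="session")
def recovery_run(tmp_path_factory) -> PipelineRun:
    """~5000 fully-reported items per nutrient at a 25% per-meal target."""
    config = GeneratorConfig.small(
        n_chains=10,
        items_per_chain=(500, 500),
        waves=["2021-03-01"],
        target_exceedance={n: 0.25 for n in ("energy", "fat", "saturated_fat", "carbohydrate", "sugar", "salt")},
        target_daily_exceedance={n: 0.05 for n in ("energy", "fat", "saturated_fat", "carbohydrate", "sugar", "salt")},
        missingness={k: 0.0 for k in ("energy", "fat", "saturated_fat", "carbohydrate", "sugar", "protein", "salt", "fiber", "serving_weight")},
        pizza_chain_fraction=0.0,
        seed=7,
    )
    return _run(config, seed=7, tmp_path_factory=tmp_path_factory, label="recovery")
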