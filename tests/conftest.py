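"""Shared fixtures: one synthetic study and one full pipeline run per session."""

from __future__ import annotations

import numpy as np
import pytest

from lncstate import pipeline, synthio


@pytest.fixture(scope="session")
def sim_config() -> synthio.SimulationConfig:
    return synthio.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def study(tmp_path_factory, sim_config):
    """Default synthetic study written to disk, with its truth table."""
    outdir = tmp_path_factory.mktemp("study")
    paths, truth = synthio.generate_study(sim_config, outdir)
    return {"paths": paths, "truth": truth, "dir": outdir, "config": sim_config}


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default pipeline run (simulation included), seed 1."""
    base = tmp_path_factory.mktemp("pipeline")
    config = pipeline.PipelineConfig(
        outdir=str(base / "results"), datadir=str(base / "data"), seed=1
    )
    manifest = pipeline.run_all(config)
    return {"config": config, "manifest": manifest, "base": base}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)

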