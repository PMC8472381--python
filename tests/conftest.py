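from pathlib import Path

import pytest

from phagesip import RunConfig, SimulationConfig, simulate_experiment, worked_example_fixture


@pytest.fixture(scope="session")
def worked_example():
    """The published worked example, packaged as in-memory input tables."""
    return worked_example_fixture()


@pytest.fixture()
def worked_example_dir(worked_example, tmp_path) -> Path:
    """Worked-example tables written to disk as the pipeline reads them."""
    for name in ("qpcr", "counts", "taxonomy", "copy_numbers", "labeling", "pfu"):
        worked_example[name].to_csv(tmp_path / f"{name}.tsv", sep="\t", index=False)
    return tmp_path


@pytest.fixture()
def worked_example_config(worked_example, worked_example_dir) -> RunConfig:
    return RunConfig.from_dir(
        worked_example_dir,
        labeling_source="table",
        pfu_references=worked_example["pfu_references"],
    )


@pytest.fixture(scope="session")
def default_experiment():
    """One default synthetic experiment, shared across tests (read-only)."""
    return simulate_experiment(SimulationConfig(seed=1))


def run_on_experiment(experiment, tmp_path, **overrides):
    """Write a synthetic experiment and run the full pipeline on its tables."""
    from phagesip import run_pipeline

    outdir = tmp_path / "sim"
    experiment.write(outdir)
    constants = experiment.config.constants.with_pool(
        experiment.truth_totals["pool_13c_g"]
    )
    config = RunConfig.from_dir(outdir, constants=constants, **overrides)
    return run_pipeline(config)
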