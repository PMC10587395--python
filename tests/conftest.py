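import pytest

from emodecode import (
    DatasetConfig,
    ExperimentDesign,
    fit_trial_betas,
    generate_dataset,
)
from emodecode.patterns import RegionSpec, TruthConfig


@pytest.fixture(scope="session")
def tiny_design() -> ExperimentDesign:
    """A shrunken schedule: 2 sessions x 2 runs, 80 volumes, 9-trial halves
    (8 regular = 2 per emotion, 1 catch)."""
    return ExperimentDesign(
        runs_per_session=2,
        volumes_per_run=80,
        trials_per_run_half=9,
        regular_trials_per_run_half=8,
        catch_trials_per_run_half=1,
    )


@pytest.fixture(scope="session")
def null_dataset(tiny_design):
    cfg = DatasetConfig(
        design=tiny_design, truth=TruthConfig(grid_shape=(8, 8, 8)), n_subjects=3
    )
    return generate_dataset(cfg, seed=11)


@pytest.fixture(scope="session")
def null_betas(null_dataset):
    return [
        fit_trial_betas(s, null_dataset.truth.brain_mask, null_dataset.config.hrf)
        for s in null_dataset.subjects
    ]


@pytest.fixture(scope="session")
def signal_dataset(tiny_design):
    """Modality-specific signals only: a stimulus-category region and a
    voice-emotion region, no supramodal patterns."""
    truth = TruthConfig(
        grid_shape=(10, 10, 10),
        regions={
            "modality_region": RegionSpec((3, 3, 3), 2.0, 6.0),
            "emotion_voice_region": RegionSpec((7, 7, 7), 2.0, 6.0),
        },
    )
    cfg = DatasetConfig(design=tiny_design, truth=truth, n_subjects=4)
    return generate_dataset(cfg, seed=21)


@pytest.fixture(scope="session")
def signal_betas(signal_dataset):
    return [
        fit_trial_betas(s, signal_dataset.truth.brain_mask, signal_dataset.config.hrf)
        for s in signal_dataset.subjects
    ]
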