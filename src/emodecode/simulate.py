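"""BOLD time-series simulation and whole-dataset generation.

A run's voxel time series is the sum of HRF-convolved trial responses
(scaled by the ground-truth condition pattern at each voxel), an AR(1)
Gaussian noise process, random low-frequency cosine drift, and a
constant baseline.  All randomness is driven by
:class:`numpy.random.SeedSequence` spawning, so a dataset is fully
reproducible from its master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .design import ExperimentDesign, build_design
from .exceptions import ConfigurationError, InsufficientDataError
from .hrf import HRFSpec, event_regressor
from .patterns import GroundTruth, NoiseModel, TruthConfig, simulate_patterns


@dataclass
class BoldRun:
    """One run's 4D volume series plus grid geometry."""

    data: np.ndarray  # (x, y, z, t)
    tr: float
    affine: np.ndarray
    run: int
    session: int

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


def _cosine_basis(n_volumes: int, n_components: int) -> np.ndarray:
    n = np.arange(n_volumes)
    basis = np.stack(
        [
            np.sqrt(2.0 / n_volumes) * np.cos(np.pi * (2 * n + 1) * k / (2 * n_volumes))
            for k in range(1, n_components + 1)
        ],
        axis=1,
    )
    return basis


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float, ar1: float) -> np.ndarray:
    """(n_series, n_time) stationary AR(1) noise with marginal sd sigma."""
    n_series, n_time = shape
    if sigma == 0:
        return np.zeros(shape)
    innov_sd = sigma * np.sqrt(1.0 - ar1**2)
    w = rng.standard_normal(shape) * innov_sd
    # stationary start
    w[:, 0] = rng.standard_normal(n_series) * sigma
    if ar1 == 0:
        out = w
        out[:, 0] = w[:, 0]
        return out
    return lfilter([1.0], [1.0, -ar1], w, axis=1)


def simulate_run(
    events: pd.DataFrame,
    truth: GroundTruth,
    noise: NoiseModel,
    design: ExperimentDesign,
    seed: int,
    hrf: HRFSpec = HRFSpec(),
) -> BoldRun:
    """Simulate one run given its event table and the ground truth."""
    runs = events["run"].unique()
    if len(runs) != 1:
        raise ConfigurationError("simulate_run expects events of exactly one run")
    run = int(runs[0])
    session = int(events["session"].iloc[0])
    rng = np.random.default_rng(seed)
    n_vol = design.volumes_per_run
    mask = truth.brain_mask
    n_mask = int(mask.sum())

    signal = np.zeros((n_mask, n_vol))
    # group trials by condition: one regressor sum per shared pattern
    for (stim, emo, catch), grp in events.groupby(
        ["stimulus_type", "emotion", "is_catch"], sort=True
    ):
        amp = truth.trial_amplitudes(stim, emo, is_catch=bool(catch))
        if not np.any(amp):
            continue
        reg = event_regressor(
            grp["onset"].to_numpy(), grp["duration"].to_numpy(), n_vol, design.tr, hrf
        )
        signal += np.outer(amp, reg)

    series = signal + noise.baseline
    if noise.sigma > 0:
        series += _ar1_noise(rng, (n_mask, n_vol), noise.sigma, noise.ar1)
    if noise.drift_amplitude > 0 and noise.n_drift_components > 0:
        basis = _cosine_basis(n_vol, noise.n_drift_components)
        coeffs = rng.standard_normal((n_mask, noise.n_drift_components)) * noise.drift_amplitude
        series += coeffs @ basis.T
    data = np.zeros(truth.grid_shape + (n_vol,))
    data[mask] = series
    return BoldRun(data=data, tr=design.tr, affine=truth.affine, run=run, session=session)


@dataclass
class SubjectData:
    """One simulated participant: their runs and the shared event table."""

    subject: int
    runs: list[BoldRun]
    events: pd.DataFrame


@dataclass
class DatasetConfig:
    """Everything needed to generate a multi-subject dataset."""

    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    truth: TruthConfig = field(default_factory=TruthConfig)
    noise: NoiseModel = field(default_factory=NoiseModel)
    n_subjects: int = 8
    hrf: HRFSpec = field(default_factory=HRFSpec)


@dataclass
class Dataset:
    config: DatasetConfig
    truth: GroundTruth
    events: pd.DataFrame
    subjects: list[SubjectData]
    seed: int


def generate_dataset(config: DatasetConfig, seed: int, out_dir: str | Path | None = None) -> Dataset:
    """Generate a full multi-subject dataset.

    All subjects share the event schedule and ground-truth regions but
    receive independent noise realizations.  When ``out_dir`` is given,
    NIfTI volumes, event TSVs and a ground-truth JSON sidecar are
    written there.
    """
    if config.n_subjects < 2:
        raise InsufficientDataError("need at least 2 subjects for group stages")
    ss = np.random.SeedSequence(seed)
    design_seed, truth_seed, noise_seed = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    ]
    events = build_design(config.design, design_seed)
    truth = simulate_patterns(config.truth, truth_seed)
    noise_ss = np.random.SeedSequence(noise_seed)
    subjects = []
    for subj, subj_ss in enumerate(noise_ss.spawn(config.n_subjects), start=1):
        run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in subj_ss.spawn(config.design.n_runs)]
        runs = [
            simulate_run(
                events[events["run"] == run].reset_index(drop=True),
                truth,
                config.noise,
                config.design,
                run_seeds[run - 1],
                config.hrf,
            )
            for run in range(1, config.design.n_runs + 1)
        ]
        subjects.append(SubjectData(subject=subj, runs=runs, events=events))
    ds = Dataset(config=config, truth=truth, events=events, subjects=subjects, seed=seed)
    if out_dir is not None:
        from .io import write_dataset

        write_dataset(ds, out_dir)
    return ds
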