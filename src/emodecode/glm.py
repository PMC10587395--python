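"""Design matrices, trial-wise / condition-wise GLM estimation, smoothing
and the univariate repeated-measures ANOVA maps.

Trial-wise estimation uses a least-squares-all model: every non-catch
trial of a run gets its own HRF-convolved boxcar regressor in a single
per-run model, alongside a combined catch regressor, cosine drift set
(128 s cutoff) and a constant.  With ISIs above 10 s at TR 3 s the
trial regressors are nearly orthogonal, so this is well conditioned.

Condition-wise estimation fits the 12 stimulus-category x emotion
predictors of interest jointly across runs (interest columns shared,
nuisance columns block-diagonal per run), matching a random-effects
GLM whose subject-level estimates enter second-level tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .design import EMOTIONS
from .exceptions import (
    ConfigurationError,
    DesignDegenerateError,
    InsufficientDataError,
)
from .hrf import HRFSpec, event_regressor
from .simulate import BoldRun, SubjectData

#: canonical order of the 12 (stimulus category, emotion) conditions
CONDITIONS_12 = [(st, emo) for st in ("body", "face", "voice") for emo in EMOTIONS]


@dataclass
class DesignMatrix:
    """Volumes x regressors matrix with labels and interest flags."""

    values: np.ndarray
    regressor_labels: list[str]
    interest_flags: np.ndarray  # boolean per regressor
    trial_info: pd.DataFrame | None = None  # one row per interest regressor
    missing_conditions: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        interest = self.values[:, self.interest_flags]
        if interest.shape[1] and not np.all(np.ptp(interest, axis=0) > 0):
            raise DesignDegenerateError("all-zero regressor of interest")

    @property
    def n_interest(self) -> int:
        return int(self.interest_flags.sum())


def cosine_drift(n_volumes: int, tr: float, cutoff: float = 128.0) -> np.ndarray:
    """Discrete-cosine drift basis for periods longer than ``cutoff`` s."""
    total = n_volumes * tr
    n_comp = int(np.floor(2.0 * total / cutoff))
    n = np.arange(n_volumes)
    cols = [
        np.sqrt(2.0 / n_volumes) * np.cos(np.pi * (2 * n + 1) * k / (2 * n_volumes))
        for k in range(1, n_comp + 1)
    ]
    if not cols:
        return np.empty((n_volumes, 0))
    return np.stack(cols, axis=1)


def _nuisance_block(
    events: pd.DataFrame,
    n_volumes: int,
    tr: float,
    hrf: HRFSpec,
    include_drift: bool,
    drift_cutoff: float,
) -> tuple[list[np.ndarray], list[str]]:
    cols: list[np.ndarray] = []
    labels: list[str] = []
    catch = events[events["is_catch"]]
    if len(catch):
        cols.append(
            event_regressor(catch["onset"].to_numpy(), catch["duration"].to_numpy(), n_volumes, tr, hrf)
        )
        labels.append("catch")
    if include_drift:
        drift = cosine_drift(n_volumes, tr, drift_cutoff)
        for k in range(drift.shape[1]):
            cols.append(drift[:, k])
            labels.append(f"drift_{k + 1:02d}")
    cols.append(np.ones(n_volumes))
    labels.append("constant")
    return cols, labels


def build_trialwise_design(
    events: pd.DataFrame,
    n_volumes: int,
    tr: float,
    hrf: HRFSpec = HRFSpec(),
    include_drift: bool = True,
    drift_cutoff: float = 128.0,
) -> DesignMatrix:
    """One interest regressor per non-catch trial, plus nuisance set."""
    trials = events[~events["is_catch"]].reset_index(drop=True)
    if trials["onset"].duplicated().any():
        raise DesignDegenerateError("trials with identical onsets")
    cols = [
        event_regressor(row.onset, row.duration, n_volumes, tr, hrf)
        for row in trials.itertuples()
    ]
    labels = [
        f"trial{idx:03d}_{row.stimulus_type}_{row.emotion}"
        for idx, row in enumerate(trials.itertuples())
    ]
    ncols, nlabels = _nuisance_block(events, n_volumes, tr, hrf, include_drift, drift_cutoff)
    values = np.column_stack(cols + ncols)
    flags = np.array([True] * len(cols) + [False] * len(ncols))
    return DesignMatrix(values, labels + nlabels, flags, trial_info=trials)


def synthetic_motion(n_volumes: int, seed: int = 0, scale: float = 0.05) -> np.ndarray:
    """Six random-walk motion series (stand-in when none are recorded)."""
    rng = np.random.default_rng(seed)
    return np.cumsum(rng.standard_normal((n_volumes, 6)) * scale, axis=0)


def build_condition_design(
    events: pd.DataFrame,
    n_volumes: int,
    tr: float,
    hrf: HRFSpec = HRFSpec(),
    motion: np.ndarray | None = None,
    include_drift: bool = True,
    drift_cutoff: float = 128.0,
    motion_seed: int = 0,
) -> DesignMatrix:
    """Condition GLM design for one run.

    Interest: one regressor per (stimulus category, emotion) condition
    present in the events.  Conditions absent from the run are recorded
    in ``missing_conditions`` rather than zero-filled.  Nuisance: a
    block-start regressor (one event at each run-half onset), a catch
    regressor, six motion series, cosine drift, and a constant.
    """
    trials = events[~events["is_catch"]]
    cols: list[np.ndarray] = []
    labels: list[str] = []
    missing: list[tuple[str, str]] = []
    for st, emo in CONDITIONS_12:
        sub = trials[(trials["stimulus_type"] == st) & (trials["emotion"] == emo)]
        if len(sub) == 0:
            missing.append((st, emo))
            continue
        cols.append(
            event_regressor(sub["onset"].to_numpy(), sub["duration"].to_numpy(), n_volumes, tr, hrf)
        )
        labels.append(f"{st}_{emo}")
    n_interest = len(cols)
    # block starts: first trial onset of each run half
    half_starts = events.groupby("run_half", sort=True)["onset"].min().to_numpy()
    cols.append(event_regressor(half_starts, np.full(half_starts.shape, 1.0), n_volumes, tr, hrf))
    labels.append("block_start")
    ncols, nlabels = _nuisance_block(events, n_volumes, tr, hrf, include_drift, drift_cutoff)
    if motion is None:
        motion = synthetic_motion(n_volumes, motion_seed)
    if motion.shape != (n_volumes, 6):
        raise ConfigurationError("motion must be an (n_volumes, 6) array")
    mcols = [motion[:, j] for j in range(6)]
    mlabels = [f"motion_{j + 1}" for j in range(6)]
    values = np.column_stack(cols + mcols + ncols)
    flags = np.array(
        [True] * n_interest + [False] * (1 + 6 + len(ncols))
    )
    return DesignMatrix(values, labels + mlabels + nlabels, flags, missing_conditions=missing)


@dataclass
class TrialBetaSet:
    """Trial x voxel response amplitudes with label metadata."""

    betas: np.ndarray  # (n_trials, n_mask_voxels)
    labels: pd.DataFrame  # stimulus_type, emotion, session, run, run_half
    mask: np.ndarray  # boolean 3D
    affine: np.ndarray
    subject: int | None = None

    def __post_init__(self) -> None:
        if self.betas.shape[0] != len(self.labels):
            raise ConfigurationError("beta rows and label rows misaligned")
        if self.betas.shape[1] != int(self.mask.sum()):
            raise ConfigurationError("beta columns do not match mask size")


@dataclass
class ConditionBetaSet:
    """12-condition x voxel amplitudes for one subject."""

    betas: np.ndarray  # (12, n_mask_voxels)
    condition_labels: list[tuple[str, str]]
    mask: np.ndarray
    affine: np.ndarray
    subject: int | None = None

    def __post_init__(self) -> None:
        if len(self.condition_labels) != 12 or self.betas.shape[0] != 12:
            raise ConfigurationError("expected exactly 12 conditions (3 categories x 4 emotions)")


def _ols(X: np.ndarray, Y: np.ndarray, labels: list[str]) -> np.ndarray:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [labels[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise DesignDegenerateError(f"rank-deficient design; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return coef


def estimate_betas(run: BoldRun, design: DesignMatrix, mask: np.ndarray | None = None) -> TrialBetaSet:
    """Ordinary least squares per voxel; returns interest betas only."""
    if design.values.shape[0] != run.n_volumes:
        raise ConfigurationError("design rows do not match run volumes")
    if mask is None:
        mask = np.ones(run.data.shape[:3], dtype=bool)
    Y = run.data[mask].T  # (t, voxels)
    coef = _ols(design.values, Y, design.regressor_labels)
    betas = coef[design.interest_flags]
    info = design.trial_info
    if info is None:
        raise ConfigurationError("design has no trial metadata; use build_trialwise_design")
    labels = info[["stimulus_type", "emotion", "session", "run", "run_half", "actor", "onset"]].copy()
    return TrialBetaSet(betas=betas, labels=labels.reset_index(drop=True), mask=mask, affine=run.affine)


def fit_trial_betas(
    subject: SubjectData,
    mask: np.ndarray,
    hrf: HRFSpec = HRFSpec(),
    **design_kwargs,
) -> TrialBetaSet:
    """Trial-wise betas for all runs of one subject, concatenated."""
    parts = []
    frames = []
    for run in subject.runs:
        ev = subject.events[subject.events["run"] == run.run].reset_index(drop=True)
        dm = build_trialwise_design(ev, run.n_volumes, run.tr, hrf, **design_kwargs)
        bs = estimate_betas(run, dm, mask)
        parts.append(bs.betas)
        frames.append(bs.labels)
    labels = pd.concat(frames, ignore_index=True)
    return TrialBetaSet(
        betas=np.vstack(parts),
        labels=labels,
        mask=mask,
        affine=subject.runs[0].affine,
        subject=subject.subject,
    )


def fit_condition_betas(
    subject: SubjectData,
    mask: np.ndarray,
    hrf: HRFSpec = HRFSpec(),
    motion: dict[int, np.ndarray] | None = None,
) -> ConditionBetaSet:
    """Joint 12-condition GLM across all runs of one subject."""
    run_designs = []
    for run in subject.runs:
        ev = subject.events[subject.events["run"] == run.run].reset_index(drop=True)
        m = motion.get(run.run) if motion else None
        run_designs.append(
            build_condition_design(ev, run.n_volumes, run.tr, hrf, motion=m, motion_seed=run.run)
        )
    present = set()
    for dm in run_designs:
        present.update(
            lbl for lbl, f in zip(dm.regressor_labels, dm.interest_flags) if f
        )
    cond_labels = [f"{st}_{emo}" for st, emo in CONDITIONS_12]
    missing = [c for c in cond_labels if c not in present]
    if missing:
        raise InsufficientDataError(f"conditions never presented: {missing}")
    # assemble: shared interest columns, block-diagonal nuisance
    n_total = sum(r.n_volumes for r in subject.runs)
    blocks = []
    interest = np.zeros((n_total, 12))
    row = 0
    labels_all = list(cond_labels)
    for run, dm in zip(subject.runs, run_designs):
        t = run.n_volumes
        for j, (lbl, f) in enumerate(zip(dm.regressor_labels, dm.interest_flags)):
            if f:
                interest[row : row + t, cond_labels.index(lbl)] = dm.values[:, j]
        nuis = dm.values[:, ~dm.interest_flags]
        blocks.append((row, nuis))
        labels_all += [f"run{run.run:02d}_{l}" for l, f in zip(dm.regressor_labels, dm.interest_flags) if not f]
        row += t
    n_nuis = sum(b.shape[1] for _, b in blocks)
    X = np.zeros((n_total, 12 + n_nuis))
    X[:, :12] = interest
    col = 12
    for r0, nuis in blocks:
        X[r0 : r0 + nuis.shape[0], col : col + nuis.shape[1]] = nuis
        col += nuis.shape[1]
    Y = np.vstack([run.data[mask].T for run in subject.runs])
    coef = _ols(X, Y, labels_all)
    return ConditionBetaSet(
        betas=coef[:12],
        condition_labels=list(CONDITIONS_12),
        mask=mask,
        affine=subject.runs[0].affine,
        subject=subject.subject,
    )


def smooth_volume(volume: np.ndarray, fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Gaussian spatial smoothing; ``fwhm_mm = 0`` is the identity."""
    if fwhm_mm < 0:
        raise ConfigurationError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return volume.copy()
    voxel_size = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size
    return ndimage.gaussian_filter(volume.astype(float), sigma=sigma)


@dataclass
class FactorMap:
    """Per-voxel F and p map of a one-way repeated-measures ANOVA."""

    f_values: np.ndarray
    p_values: np.ndarray
    df: tuple[int, int]
    factor: str


_FACTOR_GROUPS = {
    "modality": lambda st, emo: st,
    "emotion": lambda st, emo: emo,
}


def anova_factor_map(condition_betas: list[ConditionBetaSet], factor: str) -> FactorMap:
    """One-way repeated-measures ANOVA across subjects, per voxel.

    Condition betas are averaged into factor levels per subject; the
    error term is the subject x level interaction.
    """
    from scipy.stats import f as f_dist

    if factor not in _FACTOR_GROUPS:
        raise ConfigurationError(f"factor must be one of {sorted(_FACTOR_GROUPS)}")
    if len(condition_betas) < 2:
        raise InsufficientDataError("need at least 2 subjects")
    keyfn = _FACTOR_GROUPS[factor]
    levels = sorted({keyfn(st, emo) for st, emo in CONDITIONS_12})
    if len(levels) < 2:
        raise ConfigurationError("factor has a single level")
    # data: subjects x levels x voxels
    stacks = []
    for cb in condition_betas:
        lv = []
        for level in levels:
            idx = [i for i, (st, emo) in enumerate(cb.condition_labels) if keyfn(st, emo) == level]
            lv.append(cb.betas[idx].mean(axis=0))
        stacks.append(np.stack(lv))
    data = np.stack(stacks)  # (S, L, V)
    S, L, _ = data.shape
    grand = data.mean(axis=(0, 1), keepdims=True)
    subj_mean = data.mean(axis=1, keepdims=True)
    level_mean = data.mean(axis=0, keepdims=True)
    ss_level = S * ((level_mean - grand) ** 2).sum(axis=(0, 1))
    resid = data - subj_mean - level_mean + grand
    ss_err = (resid**2).sum(axis=(0, 1))
    df1, df2 = L - 1, (S - 1) * (L - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_level / df1) / (ss_err / df2)
    p = f_dist.sf(F, df1, df2)
    return FactorMap(f_values=F, p_values=p, df=(df1, df2), factor=factor)
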