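"""Region-of-interest analysis: spherical ROIs at published peak
coordinates, condition-mean extraction, representational dissimilarity
matrices (1 - Pearson r), and the ROI decoding report.

The 16 RDM/condition-mean conditions are ordered in blocks of four —
body, face, voice (session 1), voice (session 2) — and within each
block anger, happy, neutral, fear.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .design import EMOTIONS
from .exceptions import ConfigurationError, InsufficientDataError
from .glm import TrialBetaSet
from .gnb import accuracy, gnb_fit, gnb_predict, leave_one_run_out_folds
from .inference import bh_fdr
from .searchlight import (
    CROSSMODAL_PAIRS,
    CrossmodalTask,
    DecodingTask,
    crossmodal_task,
    emotion_all_task,
    emotion_within_task,
    modality_task,
)

#: the 16 condition cells in mandated block order
CONDITION_BLOCKS = ("body", "face", "voice_session1", "voice_session2")
CONDITIONS_16 = [(blk, emo) for blk in CONDITION_BLOCKS for emo in EMOTIONS]


def load_roi_table() -> pd.DataFrame:
    """Packaged ROI fixture: name, part, reported size, Talairach mm."""
    with resources.files("emodecode.data").joinpath("roi_table1.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def sphere_roi(
    center_mm,
    radius_voxels: float,
    grid_shape,
    affine: np.ndarray,
    brain_mask: np.ndarray | None = None,
    name: str = "ROI",
) -> np.ndarray:
    """Voxels within ``radius_voxels`` (voxel units) of a mm-space center."""
    center_vox = np.linalg.inv(affine) @ np.array([*center_mm, 1.0])
    center_vox = center_vox[:3]
    if np.any(center_vox < -0.5) or np.any(center_vox > np.asarray(grid_shape) - 0.5):
        raise ConfigurationError(f"ROI {name!r} center falls outside the grid")
    grids = np.indices(grid_shape)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center_vox))
    mask = d2 <= radius_voxels**2
    if brain_mask is not None:
        mask &= brain_mask
    if not mask.any():
        if radius_voxels == 0 and brain_mask is None:
            nearest = tuple(np.clip(np.round(center_vox).astype(int), 0, np.asarray(grid_shape) - 1))
            mask[nearest] = True
            return mask
        raise ConfigurationError(f"ROI {name!r} does not intersect the brain mask")
    return mask


def build_rois(
    grid_shape,
    affine: np.ndarray,
    brain_mask: np.ndarray | None = None,
    radius_voxels: float = 5,
    table: pd.DataFrame | None = None,
) -> dict[str, np.ndarray]:
    """Spheres at the fixture coordinates; bilateral parts are unioned."""
    if table is None:
        table = load_roi_table()
    rois: dict[str, np.ndarray] = {}
    for name, grp in table.groupby("name", sort=False):
        mask = np.zeros(grid_shape, dtype=bool)
        for row in grp.itertuples():
            mask |= sphere_roi(
                (row.x, row.y, row.z), radius_voxels, grid_shape, affine, brain_mask, name
            )
        rois[name] = mask
    return rois


def _condition_block(labels: pd.DataFrame) -> pd.Series:
    blk = labels["stimulus_type"].copy()
    voice = blk == "voice"
    blk[voice] = "voice_session" + labels.loc[voice, "session"].astype(str)
    return blk


def _roi_columns(betas: TrialBetaSet, roi_mask: np.ndarray) -> np.ndarray:
    if roi_mask.shape != betas.mask.shape:
        raise ConfigurationError("ROI mask grid does not match beta mask grid")
    if (roi_mask & ~betas.mask).any():
        raise ConfigurationError("ROI extends outside the analysis mask")
    index = np.full(betas.mask.shape, -1, dtype=int)
    index[betas.mask] = np.arange(int(betas.mask.sum()))
    cols = index[roi_mask]
    if cols.size == 0:
        raise ConfigurationError("empty ROI")
    return cols


def condition_patterns(betas: TrialBetaSet, roi_mask: np.ndarray) -> np.ndarray:
    """16 x roi-voxels condition-averaged trial betas (block order)."""
    cols = _roi_columns(betas, roi_mask)
    X = betas.betas[:, cols]
    blocks = _condition_block(betas.labels)
    out = np.empty((16, X.shape[1]))
    for i, (blk, emo) in enumerate(CONDITIONS_16):
        sel = (blocks == blk) & (betas.labels["emotion"] == emo)
        if not sel.any():
            raise InsufficientDataError(f"condition cell ({blk}, {emo}) is empty")
        out[i] = X[sel.to_numpy()].mean(axis=0)
    return out


@dataclass
class ConditionMeans:
    """Per-subject and group condition means over an ROI."""

    per_subject: np.ndarray  # (subjects, 16)
    group_mean: np.ndarray  # (16,)
    group_se: np.ndarray  # (16,)
    condition_labels: list[tuple[str, str]]


def condition_means(betas_per_subject: list[TrialBetaSet], roi_mask: np.ndarray) -> ConditionMeans:
    """Mean over ROI voxels then trials per condition; group mean and SE."""
    per_subject = np.stack(
        [condition_patterns(b, roi_mask).mean(axis=1) for b in betas_per_subject]
    )
    n = per_subject.shape[0]
    se = per_subject.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(16)
    return ConditionMeans(
        per_subject=per_subject,
        group_mean=per_subject.mean(axis=0),
        group_se=se,
        condition_labels=list(CONDITIONS_16),
    )


@dataclass
class RDMatrix:
    """16 x 16 representational dissimilarity matrix (1 - Pearson r)."""

    values: np.ndarray
    condition_labels: list[tuple[str, str]]


def compute_rdm(patterns: np.ndarray) -> RDMatrix:
    """Pairwise 1 - Pearson correlation of condition patterns.

    Zero-variance patterns yield NaN entries (flagged, not silently 0).
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.shape[1] < 2:
        raise InsufficientDataError("RDM needs at least 2 voxels")
    sd = patterns.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(patterns)
    rdm = 1.0 - r
    np.fill_diagonal(rdm, 0.0)
    bad = sd == 0
    rdm[bad, :] = np.nan
    rdm[:, bad] = np.nan
    labels = list(CONDITIONS_16) if patterns.shape[0] == 16 else [
        ("cond", str(i)) for i in range(patterns.shape[0])
    ]
    return RDMatrix(values=rdm, condition_labels=labels)


def plot_rdm(rdm: RDMatrix, path) -> None:
    """Heatmap of an RDM (written to ``path``)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(rdm.values, cmap="viridis", vmin=0, vmax=2)
    ticks = np.arange(len(rdm.condition_labels))
    names = [f"{b}:{e}" for b, e in rdm.condition_labels]
    ax.set_xticks(ticks, names, rotation=90, fontsize=6)
    ax.set_yticks(ticks, names, fontsize=6)
    fig.colorbar(im, ax=ax, label="1 - r")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# ROI decoding report: accuracies and FDR-corrected group p per ROI x task

ROI_TASK_COLUMNS = [
    "modality",
    "emotion",
    "emotion_body",
    "emotion_face",
    "emotion_voice_session1",
    "emotion_voice_session2",
    "emotion_body_to_voice",
    "emotion_voice_to_body",
    "emotion_face_to_voice",
    "emotion_voice_to_face",
]


def default_roi_tasks() -> dict[str, object]:
    """The ten report tasks, keyed by report column."""
    tasks: dict[str, object] = {
        "modality": (modality_task(1), modality_task(2)),
        "emotion": emotion_all_task(),
        "emotion_body": emotion_within_task(["body"], name="emotion_body"),
        "emotion_face": emotion_within_task(["face"], name="emotion_face"),
        "emotion_voice_session1": emotion_within_task(["voice"], session=1, name="emotion_voice_session1"),
        "emotion_voice_session2": emotion_within_task(["voice"], session=2, name="emotion_voice_session2"),
    }
    for train, test in CROSSMODAL_PAIRS:
        tasks[f"emotion_{train}_to_{test}"] = crossmodal_task(train, test)
    return tasks


def _roi_task_accuracy(X: np.ndarray, labels: pd.DataFrame, task) -> float:
    """Subject-level accuracy for one ROI feature set and one task."""
    if isinstance(task, tuple):  # averaged sub-tasks (modality per session)
        return float(np.mean([_roi_task_accuracy(X, labels, t) for t in task]))
    if isinstance(task, CrossmodalTask):
        tr = task.train_select(labels)
        te = task.test_select(labels)
        if np.any(tr & te):
            raise ConfigurationError("train and test trial sets overlap")
        model = gnb_fit(X[tr], labels.loc[tr, task.label_field].to_numpy(), task.class_order)
        pred, _ = gnb_predict(model, X[te])
        return accuracy(pred, labels.loc[te, task.label_field].to_numpy())
    assert isinstance(task, DecodingTask)
    sel = task.select(labels)
    Xs = X[sel]
    y = labels.loc[sel, task.label_field].to_numpy()
    runs = labels.loc[sel, "run"].to_numpy()
    accs = []
    for train, test in leave_one_run_out_folds(runs):
        model = gnb_fit(Xs[train], y[train], task.class_order)
        pred, _ = gnb_predict(model, Xs[test])
        accs.append(accuracy(pred, y[test]))
    return float(np.mean(accs))


def task_chance(task) -> float:
    return task[0].chance_level if isinstance(task, tuple) else task.chance_level


def _one_sided_p(acc: np.ndarray, chance: float) -> np.ndarray:
    """One-sided (greater) one-sample p vs chance over axis 0.

    Degenerate zero-spread samples (e.g. saturated accuracies) get the
    limiting p of 0, 0.5 or 1 instead of NaN.
    """
    from scipy import stats

    n = acc.shape[0]
    mean = acc.mean(axis=0)
    sd = acc.std(axis=0, ddof=1)
    zero_sd = (acc.max(axis=0) - acc.min(axis=0)) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (mean - chance) / (sd / np.sqrt(n))
    p = stats.t.sf(t, n - 1)
    return np.where(
        zero_sd, np.where(mean == chance, 0.5, np.where(mean > chance, 0.0, 1.0)), p
    )


@dataclass
class ROIDecodingReport:
    """Group accuracies and (FDR-corrected) p values per ROI x task."""

    accuracies: pd.DataFrame  # group-mean accuracy
    p_values: pd.DataFrame  # uncorrected one-sided p vs chance
    p_fdr: pd.DataFrame  # BH-adjusted across the full ROI x task grid
    reject: pd.DataFrame
    per_subject: dict[str, pd.DataFrame]  # task column -> subjects x ROIs

    def to_tsv(self, path) -> None:
        self.p_fdr.to_csv(path, sep="\t", float_format="%.4f")


def roi_decode(
    betas_per_subject: list[TrialBetaSet],
    rois: dict[str, np.ndarray],
    tasks: dict[str, object] | None = None,
    q: float = 0.05,
) -> ROIDecodingReport:
    """GNB decoding on whole-ROI feature sets, with group inference.

    Leave-one-run-out CV for within-modality tasks, a single split for
    cross-modal tasks; one-sample t against chance per ROI x task; BH
    FDR applied across the full grid.
    """
    if len(betas_per_subject) < 2:
        raise InsufficientDataError("need at least 2 subjects")
    if tasks is None:
        tasks = default_roi_tasks()
    roi_names = list(rois)
    task_names = list(tasks)
    acc = np.empty((len(betas_per_subject), len(roi_names), len(task_names)))
    for si, b in enumerate(betas_per_subject):
        for ri, rn in enumerate(roi_names):
            cols = _roi_columns(b, rois[rn])
            X = b.betas[:, cols]
            for ti, tn in enumerate(task_names):
                acc[si, ri, ti] = _roi_task_accuracy(X, b.labels, tasks[tn])
    pvals = np.empty((len(roi_names), len(task_names)))
    for ti, tn in enumerate(task_names):
        chance = task_chance(tasks[tn])
        pvals[:, ti] = _one_sided_p(acc[:, :, ti], chance)
    _, p_adj = bh_fdr(pvals, q)
    reject = p_adj <= q
    mk = lambda arr: pd.DataFrame(arr, index=roi_names, columns=task_names)
    per_subject = {
        tn: pd.DataFrame(acc[:, :, ti], columns=roi_names) for ti, tn in enumerate(task_names)
    }
    return ROIDecodingReport(
        accuracies=mk(acc.mean(axis=0)),
        p_values=mk(pvals),
        p_fdr=mk(p_adj),
        reject=mk(reject),
        per_subject=per_subject,
    )
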