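"""Spherical searchlight GNB decoding and the four decoding tasks.

The searchlight repeats leave-one-run-out GNB decoding in a sphere
(default radius 5 voxels, lattice metric ||v||^2 <= r^2) around every
in-mask voxel.  Because GNB sufficient statistics are additive over
trials and independent across voxels, the engine computes per-voxel
per-fold class means/variances once from run-wise sums, turns them into
per-trial per-class per-voxel log-density contributions, and sums those
over sphere members with a sparse adjacency matrix.  This is exactly
equivalent to fitting a separate GNB in every sphere, at a fraction of
the cost.

Tasks
-----
- ``modality_task(session)``: visual vs auditory run halves (2 classes,
  chance 50%), trained per session (body vs voice in session 1, face vs
  voice in session 2);
- ``emotion_all_task()``: 4 emotions pooled over all stimulus types;
- ``emotion_within_task(...)``: 4 emotions within a stimulus-type subset
  (voice; face; body; combined face+body; per-session voice variants);
- ``crossmodal_task(train, test)``: train on one modality's trials, test
  on the voice trials of the same session (single split, no CV) —
  body->voice, voice->body, face->voice, voice->face.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import sparse

from .design import EMOTIONS
from .exceptions import ConfigurationError, InsufficientDataError
from .glm import TrialBetaSet
from .gnb import VAR_FLOOR_ABS, VAR_FLOOR_REL


def sphere_offsets(radius_voxels: int) -> np.ndarray:
    """Integer lattice offsets with squared norm <= radius^2, lexicographic."""
    if radius_voxels < 0:
        raise ConfigurationError("radius must be >= 0")
    r = int(radius_voxels)
    pts = [
        (x, y, z)
        for x in range(-r, r + 1)
        for y in range(-r, r + 1)
        for z in range(-r, r + 1)
        if x * x + y * y + z * z <= radius_voxels**2
    ]
    return np.array(pts, dtype=int)


@dataclass(frozen=True)
class SearchlightSpec:
    radius_voxels: int = 5
    min_voxels: int = 1

    def __post_init__(self) -> None:
        if self.min_voxels < 1:
            raise ConfigurationError("min_voxels must be >= 1")


@dataclass(frozen=True)
class DecodingTask:
    """A within-modality (cross-validated) decoding task."""

    name: str
    label_field: str
    select: Callable[[pd.DataFrame], np.ndarray]
    class_order: tuple[str, ...]

    @property
    def chance_level(self) -> float:
        return 1.0 / len(self.class_order)


@dataclass(frozen=True)
class CrossmodalTask:
    """A single-split cross-modal generalization task."""

    name: str
    train_select: Callable[[pd.DataFrame], np.ndarray]
    test_select: Callable[[pd.DataFrame], np.ndarray]
    class_order: tuple[str, ...] = EMOTIONS
    label_field: str = "emotion"

    @property
    def chance_level(self) -> float:
        return 1.0 / len(self.class_order)


def modality_task(session: int) -> DecodingTask:
    return DecodingTask(
        name=f"modality_session{session}",
        label_field="run_half",
        select=lambda df, s=session: (df["session"] == s).to_numpy(),
        class_order=("auditory", "visual"),
    )


def emotion_all_task() -> DecodingTask:
    return DecodingTask(
        name="emotion_all",
        label_field="emotion",
        select=lambda df: np.ones(len(df), dtype=bool),
        class_order=EMOTIONS,
    )


def emotion_within_task(stimulus_types, session: int | None = None, name: str | None = None) -> DecodingTask:
    types = tuple(stimulus_types)
    if name is None:
        name = "emotion_" + "+".join(types) + (f"_session{session}" if session else "")

    def select(df: pd.DataFrame) -> np.ndarray:
        keep = df["stimulus_type"].isin(types).to_numpy()
        if session is not None:
            keep &= (df["session"] == session).to_numpy()
        return keep

    return DecodingTask(name=name, label_field="emotion", select=select, class_order=EMOTIONS)


_MODALITY_SESSION = {"body": 1, "face": 2}


def crossmodal_task(train: str, test: str) -> CrossmodalTask:
    """Cross-modal emotion task; voice trials come from the session of
    the paired visual category."""
    visual = train if train != "voice" else test
    if visual not in _MODALITY_SESSION:
        raise ConfigurationError("crossmodal pairs must involve body or face plus voice")
    session = _MODALITY_SESSION[visual]

    def selector(stim: str) -> Callable[[pd.DataFrame], np.ndarray]:
        def select(df: pd.DataFrame) -> np.ndarray:
            return ((df["stimulus_type"] == stim) & (df["session"] == session)).to_numpy()

        return select

    return CrossmodalTask(
        name=f"crossmodal_{train}_to_{test}",
        train_select=selector(train),
        test_select=selector(test),
    )


CROSSMODAL_PAIRS = (("body", "voice"), ("voice", "body"), ("face", "voice"), ("voice", "face"))


@dataclass
class AccuracyMap:
    """Per-voxel cross-validated accuracy; NaN where undefined."""

    values: np.ndarray  # 3D, NaN outside mask / invalid centers
    task: str
    chance_level: float
    n_folds: int
    subject: int | None = None
    affine: np.ndarray | None = None

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


def mask_adjacency(mask: np.ndarray, radius_voxels: int) -> sparse.csr_matrix:
    """Sparse centers x voxels matrix: sphere membership within the mask."""
    offsets = sphere_offsets(radius_voxels)
    index_vol = np.full(mask.shape, -1, dtype=np.int64)
    n = int(mask.sum())
    index_vol[mask] = np.arange(n)
    coords = np.argwhere(mask)
    rows_all, cols_all = [], []
    shape = np.array(mask.shape)
    for off in offsets:
        shifted = coords + off
        ok = np.all((shifted >= 0) & (shifted < shape), axis=1)
        nb = index_vol[tuple(shifted[ok].T)]
        valid = nb >= 0
        rows_all.append(np.arange(n)[ok][valid])
        cols_all.append(nb[valid])
    rows = np.concatenate(rows_all)
    cols = np.concatenate(cols_all)
    data = np.ones(len(rows), dtype=np.float64)
    return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))


def _encode_labels(labels: np.ndarray, class_order) -> np.ndarray:
    class_order = list(class_order)
    unknown = set(np.unique(labels)) - set(class_order)
    if unknown:
        raise ConfigurationError(f"labels outside the task's class set: {sorted(unknown)}")
    lut = {c: i for i, c in enumerate(class_order)}
    return np.array([lut[v] for v in labels], dtype=int)


def _suff_stats(X: np.ndarray, y: np.ndarray, runs: np.ndarray, K: int):
    """Per-(run, class) counts, sums and sums of squares per voxel."""
    run_ids = np.unique(runs)
    R = len(run_ids)
    V = X.shape[1]
    n = np.zeros((R, K))
    s = np.zeros((R, K, V))
    ss = np.zeros((R, K, V))
    for ri, r in enumerate(run_ids):
        for k in range(K):
            rows = X[(runs == r) & (y == k)]
            n[ri, k] = rows.shape[0]
            if rows.shape[0]:
                s[ri, k] = rows.sum(axis=0)
                ss[ri, k] = (rows**2).sum(axis=0)
    return run_ids, n, s, ss


def _fold_contributions(X, y, runs, K):
    """Per-trial per-class per-voxel log-density terms under leave-one-run-out.

    Returns (C, P): C[t, k, v] is the voxel-wise log-density of trial t
    under class k of the model trained without trial t's run; P[t, k]
    the corresponding log prior.
    """
    run_ids, n, s, ss = _suff_stats(X, y, runs, K)
    if (n.sum(axis=0) < 2).any():
        raise InsufficientDataError("a class has fewer than 2 trials overall")
    n_tot, s_tot, ss_tot = n.sum(0), s.sum(0), ss.sum(0)
    T, V = X.shape
    C = np.empty((T, K, V))
    P = np.empty((T, K))
    for ri, r in enumerate(run_ids):
        test = runs == r
        n_tr = n_tot - n[ri]  # (K,)
        if (n_tr < 2).any():
            raise InsufficientDataError(
                f"fold holding out run {r} leaves a class with < 2 training trials"
            )
        mu = (s_tot - s[ri]) / n_tr[:, None]
        e2 = (ss_tot - ss[ri]) / n_tr[:, None]
        var = e2 - mu**2
        # per-feature floor from the pooled training variance
        nt = n_tr.sum()
        pooled_mu = (s_tot - s[ri]).sum(0) / nt
        pooled_var = (ss_tot - ss[ri]).sum(0) / nt - pooled_mu**2
        floor = VAR_FLOOR_REL * pooled_var + VAR_FLOOR_ABS
        var = np.maximum(var, floor[None, :])
        Xt = X[test]
        diff = Xt[:, None, :] - mu[None, :, :]
        C[test] = -0.5 * (np.log(2.0 * np.pi * var)[None] + diff**2 / var[None])
        P[test] = np.log(n_tr / nt)[None, :]
    return C, P


def _single_split_contributions(X_train, y_train, X_test, K):
    """Log-density terms for a single train/test split (no CV)."""
    T, V = X_test.shape
    n = np.array([(y_train == k).sum() for k in range(K)], dtype=float)
    if (n < 2).any():
        raise InsufficientDataError("a training class has fewer than 2 trials")
    mu = np.stack([X_train[y_train == k].mean(axis=0) for k in range(K)])
    var = np.stack([X_train[y_train == k].var(axis=0) for k in range(K)])
    pooled = X_train.var(axis=0)
    floor = VAR_FLOOR_REL * pooled + VAR_FLOOR_ABS
    var = np.maximum(var, floor[None, :])
    diff = X_test[:, None, :] - mu[None, :, :]
    C = -0.5 * (np.log(2.0 * np.pi * var)[None] + diff**2 / var[None])
    P = np.tile(np.log(n / n.sum()), (T, 1))
    return C, P


def _sphere_predict(C: np.ndarray, P: np.ndarray, adjacency: sparse.csr_matrix) -> np.ndarray:
    """Argmax class per (trial, center) from summed voxel contributions."""
    T, K, V = C.shape
    M = adjacency @ C.reshape(T * K, V).T  # (centers, T*K)
    M = M.T.reshape(T, K, -1) + P[:, :, None]
    return np.argmax(M, axis=1)  # ties -> earlier class


def _check_runwise_balance(y: np.ndarray, runs: np.ndarray, K: int) -> None:
    for r in np.unique(runs):
        counts = np.bincount(y[runs == r], minlength=K)
        if (counts < 2).any():
            raise InsufficientDataError(
                f"run {r} has fewer than 2 trials for some class"
            )


def searchlight_decode(
    betas: TrialBetaSet,
    task: DecodingTask,
    spec: SearchlightSpec = SearchlightSpec(),
    adjacency: sparse.csr_matrix | None = None,
) -> AccuracyMap:
    """Leave-one-run-out GNB decoding in a sphere around every mask voxel."""
    sel = task.select(betas.labels)
    labels = betas.labels.loc[sel]
    X = betas.betas[sel]
    y = _encode_labels(labels[task.label_field].to_numpy(), task.class_order)
    runs = labels["run"].to_numpy()
    K = len(task.class_order)
    if len(np.unique(runs)) < 2:
        raise InsufficientDataError(
            "leave-one-run-out needs >= 2 runs; use crossmodal_decode for single splits"
        )
    _check_runwise_balance(y, runs, K)
    if adjacency is None:
        adjacency = mask_adjacency(betas.mask, spec.radius_voxels)
    C, P = _fold_contributions(X, y, runs, K)
    preds = _sphere_predict(C, P, adjacency)
    correct = preds == y[:, None]
    run_ids = np.unique(runs)
    fold_acc = np.stack([correct[runs == r].mean(axis=0) for r in run_ids])
    acc = fold_acc.mean(axis=0)
    counts = np.asarray(adjacency.sum(axis=1)).ravel()
    acc = np.where(counts >= spec.min_voxels, acc, np.nan)
    values = np.full(betas.mask.shape, np.nan)
    values[betas.mask] = acc
    return AccuracyMap(
        values=values,
        task=task.name,
        chance_level=task.chance_level,
        n_folds=len(run_ids),
        subject=betas.subject,
        affine=betas.affine,
    )


def crossmodal_decode(
    betas: TrialBetaSet,
    task: CrossmodalTask,
    spec: SearchlightSpec = SearchlightSpec(),
    adjacency: sparse.csr_matrix | None = None,
) -> AccuracyMap:
    """Single-split searchlight decoding: fit on train trials, test on
    the disjoint test trials."""
    tr_sel = task.train_select(betas.labels)
    te_sel = task.test_select(betas.labels)
    if np.any(tr_sel & te_sel):
        raise ConfigurationError("train and test trial sets overlap")
    if not tr_sel.any() or not te_sel.any():
        raise InsufficientDataError("empty train or test set")
    y_train = _encode_labels(
        betas.labels.loc[tr_sel, task.label_field].to_numpy(), task.class_order
    )
    y_test = _encode_labels(
        betas.labels.loc[te_sel, task.label_field].to_numpy(), task.class_order
    )
    K = len(task.class_order)
    if len(np.unique(y_test)) < K:
        raise InsufficientDataError("test set is not class-complete")
    if adjacency is None:
        adjacency = mask_adjacency(betas.mask, spec.radius_voxels)
    C, P = _single_split_contributions(betas.betas[tr_sel], y_train, betas.betas[te_sel], K)
    preds = _sphere_predict(C, P, adjacency)
    acc = (preds == y_test[:, None]).mean(axis=0)
    counts = np.asarray(adjacency.sum(axis=1)).ravel()
    acc = np.where(counts >= spec.min_voxels, acc, np.nan)
    values = np.full(betas.mask.shape, np.nan)
    values[betas.mask] = acc
    return AccuracyMap(
        values=values,
        task=task.name,
        chance_level=task.chance_level,
        n_folds=1,
        subject=betas.subject,
        affine=betas.affine,
    )


def modality_searchlight(
    betas: TrialBetaSet,
    spec: SearchlightSpec = SearchlightSpec(),
    adjacency: sparse.csr_matrix | None = None,
) -> AccuracyMap:
    """Modality decoding averaged over the per-session classifiers
    (body vs voice in session 1, face vs voice in session 2)."""
    if adjacency is None:
        adjacency = mask_adjacency(betas.mask, spec.radius_voxels)
    sessions = sorted(betas.labels["session"].unique())
    maps = [
        searchlight_decode(betas, modality_task(s), spec, adjacency) for s in sessions
    ]
    # per-session maps share the adjacency, hence the same defined set
    values = np.mean(np.stack([m.values for m in maps]), axis=0)
    return AccuracyMap(
        values=values,
        task="modality",
        chance_level=0.5,
        n_folds=sum(m.n_folds for m in maps),
        subject=betas.subject,
        affine=betas.affine,
    )
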