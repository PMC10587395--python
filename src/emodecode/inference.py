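"""Second-level (group) statistics on accuracy maps.

Implements the one-sample t test against chance with one-sided p values,
Bonferroni / max-statistic FWE control, Benjamini-Hochberg FDR, cluster
extent thresholding, and the shared-label permutation procedure: the
same ``n`` emotion-label randomizations are applied to every subject,
the full leave-one-run-out decoding is re-run per permutation, each
permutation yields a paired t map (true minus permuted accuracy across
subjects), and the ``n`` t maps are averaged and thresholded (default
t > 3.9).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError, InsufficientDataError
from .glm import TrialBetaSet
from .searchlight import (
    AccuracyMap,
    DecodingTask,
    SearchlightSpec,
    mask_adjacency,
    searchlight_decode,
)


@dataclass
class GroupStatMap:
    """Per-voxel one-sample t statistics against chance."""

    t_values: np.ndarray  # 3D, NaN where undefined
    p_values: np.ndarray  # one-sided (greater), NaN where undefined
    df: int
    chance_level: float
    affine: np.ndarray | None = None

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.t_values)


def ttest_vs_chance(accuracy_maps: list[AccuracyMap], chance_level: float) -> GroupStatMap:
    """Voxel-wise one-sample t test of accuracy against chance (one-sided).

    Voxels with fewer than 2 subjects defined are left undefined.
    """
    if len(accuracy_maps) < 2:
        raise InsufficientDataError("need at least 2 subjects")
    stack = np.stack([m.values for m in accuracy_maps])  # (S, x, y, z)
    n_def = (~np.isnan(stack)).sum(axis=0)
    # exact zero-spread detection (nanstd of a constant can return ~1e-17)
    zero_sd = (np.nanmax(stack, axis=0) - np.nanmin(stack, axis=0)) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.nansum(stack, axis=0) / np.where(n_def > 0, n_def, 1)
        dev = stack - mean[None]
        sd = np.sqrt(np.nansum(dev**2, axis=0) / np.maximum(n_def - 1, 1))
        se = sd / np.sqrt(np.maximum(n_def, 1))
        t = (mean - chance_level) / se
        t = np.where(
            zero_sd,
            np.where(mean == chance_level, 0.0, np.sign(mean - chance_level) * np.inf),
            t,
        )
    df = len(accuracy_maps) - 1
    p = stats.t.sf(t, df)
    undef = n_def < 2
    t[undef] = np.nan
    p[undef] = np.nan
    return GroupStatMap(
        t_values=t, p_values=p, df=df, chance_level=chance_level,
        affine=accuracy_maps[0].affine,
    )


def fwe_correct(
    stat_map: GroupStatMap,
    alpha: float = 0.05,
    method: str = "bonferroni",
    perm_t_maps: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Family-wise-error-controlled rejection map.

    ``bonferroni`` rejects where p <= alpha / m (m = defined voxels);
    ``max_stat_permutation`` rejects where t exceeds the (1 - alpha)
    quantile of the permutation distribution of the maximum t.
    """
    defined = stat_map.defined
    if method == "bonferroni":
        m = int(defined.sum())
        reject = np.zeros_like(defined)
        if m:
            reject[defined] = stat_map.p_values[defined] <= alpha / m
        return reject
    if method == "max_stat_permutation":
        if not perm_t_maps:
            raise ConfigurationError(
                "max_stat_permutation requires permutation t maps (see permutation_group_test)"
            )
        max_t = np.array([np.nanmax(tm) for tm in perm_t_maps])
        thr = np.quantile(max_t, 1.0 - alpha)
        reject = np.zeros_like(defined)
        reject[defined] = stat_map.t_values[defined] > thr
        return reject
    raise ConfigurationError(f"unknown FWE method {method!r}")


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p)."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject.reshape(np.shape(p_values)), p_adj.reshape(np.shape(p_values))


_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


@dataclass
class ClusterTable:
    """Supra-threshold clusters surviving the extent filter."""

    table: pd.DataFrame  # cluster_size, peak_t, peak_p_unc, x/y/z (vox + mm)
    label_map: np.ndarray  # int 3D, 0 = background

    def __len__(self) -> int:
        return len(self.table)


def cluster_threshold(
    stat_map: GroupStatMap,
    voxel_p_threshold: float = 0.001,
    extent_k: int = 25,
    connectivity: int = 26,
) -> ClusterTable:
    """Uncorrected voxel threshold + minimum cluster extent ``k``."""
    if connectivity not in _CONNECTIVITY:
        raise ConfigurationError("connectivity must be 6, 18 or 26")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    supra = stat_map.defined & (stat_map.p_values < voxel_p_threshold)
    labeled, n = ndimage.label(supra, structure=structure)
    rows = []
    out = np.zeros_like(labeled)
    next_id = 0
    for lab in range(1, n + 1):
        comp = labeled == lab
        size = int(comp.sum())
        if size < extent_k:
            continue
        next_id += 1
        out[comp] = next_id
        tvals = np.where(comp, stat_map.t_values, -np.inf)
        peak = np.unravel_index(np.argmax(tvals), tvals.shape)
        mm = (
            (stat_map.affine @ np.array([*peak, 1.0]))[:3]
            if stat_map.affine is not None
            else (np.nan, np.nan, np.nan)
        )
        rows.append(
            {
                "cluster_size": size,
                "peak_t": float(stat_map.t_values[peak]),
                "peak_p_unc": float(stat_map.p_values[peak]),
                "peak_i": peak[0],
                "peak_j": peak[1],
                "peak_k": peak[2],
                "x_mm": float(mm[0]),
                "y_mm": float(mm[1]),
                "z_mm": float(mm[2]),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "cluster_size", "peak_t", "peak_p_unc",
            "peak_i", "peak_j", "peak_k", "x_mm", "y_mm", "z_mm",
        ],
    ).sort_values("cluster_size", ascending=False, ignore_index=True) if rows else pd.DataFrame(
        columns=[
            "cluster_size", "peak_t", "peak_p_unc",
            "peak_i", "peak_j", "peak_k", "x_mm", "y_mm", "z_mm",
        ]
    )
    return ClusterTable(table=table, label_map=out)


@dataclass
class PermutationScheme:
    """Shared emotion-label randomizations, stratified by run.

    The same permuted label sets are applied to every subject (subjects
    share the trial schedule), and labels are shuffled within run so
    leave-one-run-out folds stay class balanced.
    """

    n_permutations: int = 100
    seed: int = 0
    stratify_by: str = "run"

    def permuted_label_sets(self, labels: pd.DataFrame, field: str = "emotion") -> list[np.ndarray]:
        rng = np.random.default_rng(self.seed)
        base = labels[field].to_numpy()
        strata = labels[self.stratify_by].to_numpy()
        sets = []
        for _ in range(self.n_permutations):
            perm = base.copy()
            for s in np.unique(strata):
                idx = np.where(strata == s)[0]
                perm[idx] = base[idx][rng.permutation(len(idx))]
            sets.append(perm)
        return sets


@dataclass
class PermutationGroupResult:
    averaged_t: np.ndarray  # 3D mean over permutations of paired t maps
    supra_threshold: np.ndarray  # boolean, averaged_t > t_threshold
    t_threshold: float
    true_maps: list[AccuracyMap]
    perm_paired_t: list[np.ndarray] = field(default_factory=list)


def _paired_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Voxel-wise paired t over the subject axis (axis 0)."""
    d = a - b
    n = d.shape[0]
    mean = np.nanmean(d, axis=0)
    sd = np.nanstd(d, axis=0, ddof=1)
    zero_sd = (np.nanmax(d, axis=0) - np.nanmin(d, axis=0)) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where(zero_sd, np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)
    return t


def permutation_group_test(
    betas_per_subject: list[TrialBetaSet],
    task: DecodingTask,
    spec: SearchlightSpec,
    scheme: PermutationScheme,
    t_threshold: float = 3.9,
) -> PermutationGroupResult:
    """Shared-label permutation test on searchlight decoding.

    For every permutation the full leave-one-run-out decoding is redone
    per subject with the permuted labels; a paired t map (true minus
    permuted accuracy, across subjects) is computed per permutation;
    the permutation t maps are averaged and thresholded.
    """
    if len(betas_per_subject) < 2:
        raise InsufficientDataError("need at least 2 subjects")
    adjacency = mask_adjacency(betas_per_subject[0].mask, spec.radius_voxels)
    true_maps = [searchlight_decode(b, task, spec, adjacency) for b in betas_per_subject]
    true_stack = np.stack([m.values for m in true_maps])
    # shared label sets: defined on the first subject's (shared) schedule,
    # shuffled only among the task's selected trials so run-wise class
    # balance (and hence fold balance) is preserved
    ref_labels = betas_per_subject[0].labels
    sel = task.select(ref_labels)
    label_sets = scheme.permuted_label_sets(
        ref_labels.loc[sel].reset_index(drop=True), task.label_field
    )
    paired_maps = []
    for perm_sel in label_sets:
        perm_labels = ref_labels[task.label_field].to_numpy().copy()
        perm_labels[np.where(sel)[0]] = perm_sel
        perm_stack = []
        for b in betas_per_subject:
            labels = b.labels.copy()
            labels[task.label_field] = perm_labels
            b_perm = TrialBetaSet(
                betas=b.betas, labels=labels, mask=b.mask, affine=b.affine, subject=b.subject
            )
            perm_stack.append(searchlight_decode(b_perm, task, spec, adjacency).values)
        paired_maps.append(_paired_t(true_stack, np.stack(perm_stack)))
    averaged = np.mean(np.stack(paired_maps), axis=0)
    supra = np.zeros(averaged.shape, dtype=bool)
    ok = ~np.isnan(averaged)
    supra[ok] = averaged[ok] > t_threshold
    return PermutationGroupResult(
        averaged_t=averaged,
        supra_threshold=supra,
        t_threshold=t_threshold,
        true_maps=true_maps,
        perm_paired_t=paired_maps,
    )
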