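"""Group-level inference: t tests, FWE/FDR, clusters, permutations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emodecode import (
    ConfigurationError,
    PermutationScheme,
    SearchlightSpec,
    bh_fdr,
    cluster_threshold,
    emotion_all_task,
    fwe_correct,
    permutation_group_test,
    ttest_vs_chance,
)
from emodecode.inference import GroupStatMap, _paired_t
from emodecode.searchlight import AccuracyMap


def _maps(values_per_subject, chance=0.25):
    arrs = [np.asarray(v, dtype=float).reshape(1, 1, -1) for v in values_per_subject]
    return [
        AccuracyMap(values=a, task="t", chance_level=chance, n_folds=2, subject=i, affine=np.eye(4))
        for i, a in enumerate(arrs)
    ]


def test_ttest_null_identity():
    maps = _maps([[0.25, 0.25], [0.25, 0.25], [0.25, 0.25]])
    stat = ttest_vs_chance(maps, 0.25)
    assert np.all(stat.t_values == 0.0)
    assert np.all(stat.p_values == 0.5)
    assert stat.df == 2


def test_ttest_matches_textbook_formula():
    accs = np.array([0.30, 0.35, 0.25, 0.30])
    maps = _maps([[a] for a in accs])
    stat = ttest_vs_chance(maps, 0.25)
    expect = (accs.mean() - 0.25) / (accs.std(ddof=1) / np.sqrt(4))
    assert np.isclose(stat.t_values[0, 0, 0], expect)
    from scipy.stats import t as t_dist

    assert np.isclose(stat.p_values[0, 0, 0], t_dist.sf(expect, 3))


def test_ttest_monotone_in_constant_shift():
    base = np.array([0.28, 0.33, 0.26, 0.31])
    ts = []
    for shift in (0.0, 0.02, 0.04):
        stat = ttest_vs_chance(_maps([[a + shift] for a in base]), 0.25)
        ts.append(stat.t_values[0, 0, 0])
    assert ts[0] < ts[1] < ts[2]


def test_ttest_undefined_below_two_subjects():
    maps = _maps([[0.3, np.nan], [0.2, np.nan], [0.4, 0.5]])
    stat = ttest_vs_chance(maps, 0.25)
    assert np.isnan(stat.t_values[0, 0, 1])
    assert not np.isnan(stat.t_values[0, 0, 0])


# --- FWE -------------------------------------------------------------------

def _stat_from_p(p):
    p = np.asarray(p, dtype=float).reshape(1, 1, -1)
    return GroupStatMap(
        t_values=np.zeros_like(p), p_values=p, df=7, chance_level=0.25, affine=np.eye(4)
    )


def test_bonferroni_single_test_reduces_to_alpha():
    assert fwe_correct(_stat_from_p([0.04]), 0.05).any()
    assert not fwe_correct(_stat_from_p([0.06]), 0.05).any()


def test_bonferroni_rejections_nested_in_uncorrected():
    rng = np.random.default_rng(0)
    p = rng.uniform(size=50)
    stat = _stat_from_p(p)
    reject = fwe_correct(stat, 0.05)
    assert np.all(p.reshape(reject.shape)[reject] <= 0.05)


def test_bonferroni_controls_family_wise_error_under_null():
    """Uniform-null p-values: FWER stays at or below alpha."""
    rng = np.random.default_rng(1)
    fw_errors = 0
    for _ in range(500):
        stat = _stat_from_p(rng.uniform(size=100))
        fw_errors += fwe_correct(stat, 0.05).any()
    # binomial(500, 0.05) upper tail: 40 is far beyond any plausible draw
    assert fw_errors <= 40


def test_max_stat_method_requires_permutation_maps():
    with pytest.raises(ConfigurationError):
        fwe_correct(_stat_from_p([0.01]), 0.05, method="max_stat_permutation")


def test_max_stat_threshold_from_permutations():
    rng = np.random.default_rng(2)
    perms = [rng.standard_normal((1, 1, 20)) for _ in range(200)]
    t = np.zeros((1, 1, 20))
    t[0, 0, 0] = 10.0
    stat = GroupStatMap(t_values=t, p_values=np.full_like(t, 0.5), df=7, chance_level=0.25)
    reject = fwe_correct(stat, 0.05, "max_stat_permutation", perm_t_maps=perms)
    assert reject[0, 0, 0] and reject.sum() == 1


# --- FDR -------------------------------------------------------------------

def _bh_oracle(p, q):
    """Exhaustive step-up: largest i with p_(i) <= i q / m."""
    p = np.asarray(p)
    order = np.argsort(p)
    m = len(p)
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


def test_bh_fdr_textbook_example():
    reject, _ = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]), q=0.05)
    assert reject.all()


def test_bh_fdr_rejects_nothing_at_p_one():
    reject, p_adj = bh_fdr(np.ones(10), q=0.05)
    assert not reject.any()
    assert np.all(p_adj == 1.0)


def test_bh_fdr_matches_exhaustive_oracle():
    rng = np.random.default_rng(3)
    for _ in range(100):
        p = rng.uniform(size=rng.integers(1, 40))
        reject, p_adj = bh_fdr(p, q=0.05)
        assert np.array_equal(reject, _bh_oracle(p, 0.05))
        assert np.all(np.diff(p_adj[np.argsort(p)]) >= -1e-12)  # monotone


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.randoms())
def test_bh_fdr_invariant_to_input_order(p, rnd):
    p = np.asarray(p)
    perm = list(range(len(p)))
    rnd.shuffle(perm)
    perm = np.asarray(perm)
    r1, a1 = bh_fdr(p, 0.05)
    r2, a2 = bh_fdr(p[perm], 0.05)
    assert np.array_equal(r1[perm], r2)
    assert np.allclose(a1[perm], a2)


# --- clusters --------------------------------------------------------------

def _stat_from_supra(supra, t=5.0):
    supra = np.asarray(supra, dtype=bool)
    tv = np.where(supra, t, 0.0)
    pv = np.where(supra, 1e-5, 0.6)
    return GroupStatMap(t_values=tv, p_values=pv, df=7, chance_level=0.25, affine=np.eye(4))


def test_single_voxel_removed_by_extent_threshold():
    supra = np.zeros((8, 8, 8), dtype=bool)
    supra[4, 4, 4] = True
    ct = cluster_threshold(_stat_from_supra(supra), extent_k=25)
    assert len(ct) == 0


def test_cube_blob_survives_extent_threshold():
    supra = np.zeros((8, 8, 8), dtype=bool)
    supra[2:5, 2:5, 2:5] = True
    ct = cluster_threshold(_stat_from_supra(supra), extent_k=25)
    assert len(ct) == 1
    assert ct.table.loc[0, "cluster_size"] == 27


def _flood_fill_oracle(supra, connectivity=26):
    """Hand-rolled BFS labeling."""
    from collections import deque

    offs = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
        and {6: abs(dx) + abs(dy) + abs(dz) == 1, 26: True}[connectivity]
    ]
    labels = np.zeros(supra.shape, dtype=int)
    nxt = 0
    for idx in np.argwhere(supra):
        if labels[tuple(idx)]:
            continue
        nxt += 1
        q = deque([tuple(idx)])
        labels[tuple(idx)] = nxt
        while q:
            p = q.popleft()
            for o in offs:
                nb = tuple(np.add(p, o))
                if all(0 <= nb[i] < supra.shape[i] for i in range(3)):
                    if supra[nb] and not labels[nb]:
                        labels[nb] = nxt
                        q.append(nb)
    return labels


def test_cluster_labels_match_flood_fill_oracle():
    rng = np.random.default_rng(4)
    for _ in range(50):
        supra = rng.uniform(size=(6, 6, 6)) < 0.25
        ct = cluster_threshold(_stat_from_supra(supra), extent_k=1)
        oracle = _flood_fill_oracle(supra)
        # same partition: component memberships agree up to label names
        assert (ct.label_map > 0).sum() == (oracle > 0).sum()
        for lab in np.unique(oracle[oracle > 0]):
            comp = oracle == lab
            ours = np.unique(ct.label_map[comp])
            assert len(ours) == 1 and ours[0] > 0


def test_cluster_labels_invariant_under_translation():
    supra = np.zeros((10, 10, 10), dtype=bool)
    supra[1:4, 1:4, 1:4] = True
    supra[6:8, 6:8, 6:8] = True
    a = cluster_threshold(_stat_from_supra(supra), extent_k=1)
    b = cluster_threshold(_stat_from_supra(np.roll(supra, (1, 1, 1), axis=(0, 1, 2))), extent_k=1)
    assert sorted(a.table["cluster_size"]) == sorted(b.table["cluster_size"])


# --- permutation group test ------------------------------------------------

class _IdentityScheme(PermutationScheme):
    def permuted_label_sets(self, labels, field="emotion"):
        return [labels[field].to_numpy().copy() for _ in range(self.n_permutations)]


def test_true_labels_as_permutation_give_zero_paired_t(null_betas):
    res = permutation_group_test(
        null_betas, emotion_all_task(), SearchlightSpec(2, 1), _IdentityScheme(n_permutations=2)
    )
    assert np.all(res.averaged_t == 0.0)
    assert not res.supra_threshold.any()


def test_permutation_scheme_permutes_within_runs(null_betas):
    labels = null_betas[0].labels
    scheme = PermutationScheme(n_permutations=5, seed=3)
    for perm in scheme.permuted_label_sets(labels):
        assert not np.array_equal(perm, labels["emotion"].to_numpy())
        for r in labels["run"].unique():
            idx = (labels["run"] == r).to_numpy()
            assert sorted(perm[idx]) == sorted(labels.loc[idx, "emotion"])


def test_permutation_test_concordant_with_direct_ttest(signal_dataset, signal_betas):
    """Averaged permutation t ranks voxels like the direct t-vs-chance map."""
    from scipy.stats import spearmanr

    from emodecode import emotion_within_task

    task = emotion_within_task(["voice"], name="emotion_voice")
    spec = SearchlightSpec(2, 1)
    res = permutation_group_test(signal_betas, task, spec, PermutationScheme(5, seed=7))
    direct = ttest_vs_chance(res.true_maps, 0.25)
    ok = ~np.isnan(direct.t_values) & np.isfinite(direct.t_values) & np.isfinite(res.averaged_t)
    rho, _ = spearmanr(direct.t_values[ok], res.averaged_t[ok])
    assert rho > 0.3
    region = signal_dataset.truth.region_masks["emotion_voice_region"]
    assert np.nanmean(res.averaged_t[region]) > np.nanmean(res.averaged_t[~region & ok])


def test_paired_t_handles_zero_variance():
    a = np.zeros((3, 2, 1, 1))
    b = np.zeros((3, 2, 1, 1))
    b[:, 1] = -0.1
    t = _paired_t(a, b)
    assert t[0, 0, 0] == 0.0
    assert np.isposinf(t[1, 0, 0])
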