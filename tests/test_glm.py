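"""HRF, design matrices, OLS estimation, smoothing, ANOVA maps."""

import numpy as np
import pytest

from emodecode import (
    DesignDegenerateError,
    ExperimentDesign,
    HRFSpec,
    anova_factor_map,
    build_condition_design,
    build_design,
    build_trialwise_design,
    canonical_hrf,
    estimate_betas,
    smooth_volume,
)
from emodecode.glm import CONDITIONS_12, ConditionBetaSet, _ols, cosine_drift
from emodecode.hrf import hrf_curve
from emodecode.patterns import default_affine
from emodecode.simulate import BoldRun


# --- HRF -------------------------------------------------------------------

def test_hrf_peaks_near_five_seconds():
    """Dense-grid evaluation of the double-gamma difference peaks ~5 s."""
    t = np.arange(0, 32, 0.001)
    k = hrf_curve(t)
    assert abs(t[np.argmax(k)] - 5.0) < 0.1


def test_canonical_hrf_sampling_and_normalization():
    k = canonical_hrf(HRFSpec(kernel_length=32.0), tr=3.0)
    assert len(k) == 11  # ceil(32 / 3)
    assert np.max(k) == 1.0


def test_hrf_invalid_dispersion_rejected():
    from emodecode import ConfigurationError

    with pytest.raises(ConfigurationError):
        HRFSpec(peak_dispersion=0.0)


# --- design matrices -------------------------------------------------------

@pytest.fixture(scope="module")
def full_run_events():
    events = build_design(ExperimentDesign(), seed=5)
    return events[events["run"] == 1].reset_index(drop=True)


def test_trialwise_design_one_regressor_per_regular_trial(full_run_events):
    half = full_run_events[full_run_events["run_half"] == "visual"]
    dm = build_trialwise_design(half, 160, 3.0)
    assert dm.n_interest == 16


def test_trialwise_interest_block_well_conditioned(full_run_events):
    """At ISIs above 10 s the per-trial regressors are nearly orthogonal."""
    dm = build_trialwise_design(full_run_events, 160, 3.0)
    block = dm.values[:, dm.interest_flags]
    assert np.linalg.cond(block) < 10


def test_duplicate_onsets_degenerate(full_run_events):
    doubled = __import__("pandas").concat([full_run_events, full_run_events.head(1)])
    with pytest.raises(DesignDegenerateError):
        build_trialwise_design(doubled, 160, 3.0)


def test_condition_design_has_12_interest_and_stated_nuisance(full_run_events):
    # run 1 alone lacks face conditions; use a face-session run too
    events = build_design(ExperimentDesign(), seed=5)
    dm = build_condition_design(full_run_events, 160, 3.0)
    present = [l for l, f in zip(dm.regressor_labels, dm.interest_flags) if f]
    assert len(present) == 8  # body + voice conditions only in session 1
    assert dm.missing_conditions == [("face", emo) for emo in ("anger", "happy", "neutral", "fear")]
    # nuisance: block_start + catch + 6 motion + 7 drift + constant
    n_drift = cosine_drift(160, 3.0, 128.0).shape[1]
    assert n_drift == 7
    assert (~dm.interest_flags).sum() == 1 + 1 + 6 + n_drift + 1
    # both sessions together cover all 12 conditions
    labels = set()
    for run in (1, 7):
        ev = events[events["run"] == run]
        d = build_condition_design(ev, 160, 3.0)
        labels.update(l for l, f in zip(d.regressor_labels, d.interest_flags) if f)
    assert labels == {f"{st}_{emo}" for st, emo in CONDITIONS_12}


def test_drift_and_constant_absorb_slow_trends():
    n = 160
    drift = cosine_drift(n, 3.0)
    X = np.column_stack([drift, np.ones(n)])
    y = 5.0 + 0.3 * drift[:, 0] - 0.1 * drift[:, 2]
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    assert np.allclose(X @ beta, y, atol=1e-10)


# --- OLS -------------------------------------------------------------------

def test_ols_matches_normal_equations_oracle():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((20, 4))
    Y = rng.standard_normal((20, 5))
    oracle = np.linalg.inv(X.T @ X) @ X.T @ Y
    assert np.allclose(_ols(X, Y, [f"c{i}" for i in range(4)]), oracle, atol=1e-10)


def test_rank_deficient_design_names_columns():
    X = np.ones((10, 2))
    with pytest.raises(DesignDegenerateError, match="collinear"):
        _ols(X, np.ones((10, 1)), ["a", "b"])


def test_voxel_permutation_equivariance(full_run_events):
    rng = np.random.default_rng(1)
    dm = build_trialwise_design(full_run_events, 160, 3.0)
    data = rng.standard_normal((3, 3, 3, 160))
    run = BoldRun(data=data, tr=3.0, affine=default_affine((3, 3, 3)), run=1, session=1)
    betas = estimate_betas(run, dm)
    perm = rng.permutation(27)
    data_perm = data.reshape(27, 160)[perm].reshape(3, 3, 3, 160)
    run2 = BoldRun(data=data_perm, tr=3.0, affine=run.affine, run=1, session=1)
    betas2 = estimate_betas(run2, dm)
    assert np.allclose(betas2.betas, betas.betas[:, perm], atol=1e-12)


def test_orthogonal_nuisance_leaves_interest_betas_unchanged(full_run_events):
    rng = np.random.default_rng(2)
    dm = build_trialwise_design(full_run_events, 160, 3.0)
    y = rng.standard_normal((160, 8))
    base = _ols(dm.values, y, dm.regressor_labels)[dm.interest_flags]
    extra = rng.standard_normal(160)
    # project out the existing design -> exactly orthogonal nuisance
    extra -= dm.values @ np.linalg.lstsq(dm.values, extra, rcond=None)[0]
    X2 = np.column_stack([dm.values, extra])
    aug = _ols(X2, y, dm.regressor_labels + ["extra"])
    assert np.allclose(aug[: dm.values.shape[1]][dm.interest_flags], base, atol=1e-8)


def test_condition_betas_match_trialwise_means_on_noise_free_data(null_dataset):
    """With no noise the condition GLM and per-trial GLM agree."""
    from emodecode import DatasetConfig, fit_condition_betas, fit_trial_betas, generate_dataset
    from emodecode.patterns import NoiseModel, RegionSpec, TruthConfig

    cfg = DatasetConfig(
        design=null_dataset.config.design,
        truth=TruthConfig(
            grid_shape=(5, 5, 5),
            regions=dict(supramodal_emotion_region=RegionSpec((2, 2, 2), 1.5, 2.0)),
        ),
        noise=NoiseModel(sigma=0.0, ar1=0.0, drift_amplitude=0.0),
        n_subjects=2,
    )
    ds = generate_dataset(cfg, seed=1)
    subj = ds.subjects[0]
    tb = fit_trial_betas(subj, ds.truth.brain_mask)
    cb = fit_condition_betas(subj, ds.truth.brain_mask)
    for ci, (st, emo) in enumerate(cb.condition_labels):
        sel = (tb.labels["stimulus_type"] == st) & (tb.labels["emotion"] == emo)
        assert np.allclose(tb.betas[sel.to_numpy()].mean(axis=0), cb.betas[ci], atol=1e-6)


# --- smoothing -------------------------------------------------------------

def test_smoothing_identity_at_zero_fwhm():
    rng = np.random.default_rng(0)
    vol = rng.standard_normal((8, 8, 8))
    assert np.array_equal(smooth_volume(vol, 0.0, 2.0), vol)


def test_smoothed_delta_has_requested_fwhm():
    vol = np.zeros((41, 41, 41))
    vol[20, 20, 20] = 1.0
    sm = smooth_volume(vol, 6.0, 2.0)  # 6 mm at 2 mm voxels = 3 voxels
    profile = sm[:, 20, 20]
    half = profile.max() / 2
    above = np.where(profile >= half)[0]
    width_mm = (above[-1] - above[0] + 1) * 2.0
    assert abs(width_mm - 6.0) <= 2.0  # one-voxel quantization
    assert np.isclose(sm.sum(), 1.0, atol=1e-6)


# --- ANOVA -----------------------------------------------------------------

def _condition_set(betas_12xV, subject):
    mask = np.ones((1, 1, betas_12xV.shape[1]), dtype=bool)
    return ConditionBetaSet(
        betas=betas_12xV,
        condition_labels=list(CONDITIONS_12),
        mask=mask,
        affine=np.eye(4),
        subject=subject,
    )


def test_anova_null_when_level_means_identical():
    rng = np.random.default_rng(3)
    data = rng.standard_normal((4, 12, 6))
    # force every stimulus-type level mean (across subjects) to zero while
    # keeping subject-by-level variability: no level effect, F exactly 0
    types = [st for st, _ in CONDITIONS_12]
    for st in set(types):
        idx = [i for i, t in enumerate(types) if t == st]
        data[:, idx, :] -= data[:, idx, :].mean(axis=(0, 1), keepdims=True)
    sets = [_condition_set(data[s], s) for s in range(4)]
    fm = anova_factor_map(sets, "modality")
    assert np.allclose(fm.f_values, 0.0, atol=1e-24)
    assert np.allclose(fm.p_values, 1.0)


def test_anova_matches_hand_computed_sums_of_squares():
    """3-subject toy against an explicit repeated-measures decomposition."""
    rng = np.random.default_rng(4)
    data = rng.standard_normal((3, 12, 2))
    sets = [_condition_set(data[s], s) for s in range(3)]
    fm = anova_factor_map(sets, "emotion")
    # oracle: average into 4 emotion levels, then textbook RM-ANOVA
    emos = sorted({e for _, e in CONDITIONS_12})
    for v in range(2):
        table = np.stack(
            [
                [
                    data[s, [i for i, (_, e) in enumerate(CONDITIONS_12) if e == emo], v].mean()
                    for emo in emos
                ]
                for s in range(3)
            ]
        )  # subjects x levels
        grand = table.mean()
        ss_level = 3 * ((table.mean(axis=0) - grand) ** 2).sum()
        ss_subj = 4 * ((table.mean(axis=1) - grand) ** 2).sum()
        ss_tot = ((table - grand) ** 2).sum()
        ss_err = ss_tot - ss_level - ss_subj
        F = (ss_level / 3) / (ss_err / 6)
        assert np.isclose(fm.f_values[v], F)
    assert fm.df == (3, 6)


def test_anova_agrees_with_pingouin():
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    rng = np.random.default_rng(5)
    data = rng.standard_normal((5, 12, 1))
    sets = [_condition_set(data[s], s) for s in range(5)]
    fm = anova_factor_map(sets, "modality")
    rows = []
    for s in range(5):
        for i, (st, emo) in enumerate(CONDITIONS_12):
            rows.append({"subject": s, "modality": st, "y": data[s, i, 0]})
    df = pd.DataFrame(rows).groupby(["subject", "modality"], as_index=False)["y"].mean()
    res = pingouin.rm_anova(dv="y", within="modality", subject="subject", data=df)
    assert np.isclose(fm.f_values[0], res["F"].iloc[0])
    assert np.isclose(fm.p_values[0], res["p_unc"].iloc[0])


def test_anova_rejects_unknown_factor(null_dataset):
    from emodecode import ConfigurationError

    with pytest.raises(ConfigurationError):
        anova_factor_map([], "valence")
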