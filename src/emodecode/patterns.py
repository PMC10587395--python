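"""Ground-truth multivoxel patterns for the simulator.

The generator encodes the hypothesis space of the experiment as named
effect regions inside a brain mask:

``modality_region``
    carries one pattern per stimulus category (face / body / voice), so
    stimulus modality is decodable there but emotion is not;
``emotion_face_region`` / ``emotion_body_region`` / ``emotion_voice_region``
    carry one pattern per emotion, for trials of that stimulus category
    only — emotion is decodable within that modality but patterns are
    drawn independently per category, so nothing generalizes across
    modalities;
``supramodal_emotion_region``
    carries one pattern per emotion shared by *all* stimulus categories —
    the configuration under which cross-modal decoding succeeds.

Pattern vectors are zero-mean and unit-norm per region before scaling by
the region's effect amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import EMOTIONS, STIMULUS_TYPES
from .exceptions import ConfigurationError

REGION_NAMES = (
    "modality_region",
    "emotion_face_region",
    "emotion_body_region",
    "emotion_voice_region",
    "supramodal_emotion_region",
)

_EMOTION_REGION_TYPE = {
    "emotion_face_region": "face",
    "emotion_body_region": "body",
    "emotion_voice_region": "voice",
}


@dataclass(frozen=True)
class NoiseModel:
    """AR(1) Gaussian noise plus low-frequency cosine drift.

    ``sigma`` is the marginal (stationary) standard deviation of the
    AR(1) series; ``ar1`` its lag-1 autocorrelation; ``drift_amplitude``
    the standard deviation of the random cosine-drift coefficients.
    """

    sigma: float = 1.0
    ar1: float = 0.3
    drift_amplitude: float = 0.5
    n_drift_components: int = 3
    baseline: float = 100.0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.drift_amplitude < 0:
            raise ConfigurationError("sigma and drift_amplitude must be >= 0")
        if not 0 <= self.ar1 < 1:
            raise ConfigurationError("ar1 must be in [0, 1)")


@dataclass(frozen=True)
class RegionSpec:
    """A spherical effect region: voxel-space center, radius, amplitude."""

    center: tuple[int, int, int]
    radius: float
    amplitude: float


@dataclass
class TruthConfig:
    """Configuration of the simulated ground truth."""

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: float = 2.0
    regions: dict[str, RegionSpec] = field(default_factory=dict)
    catch_amplitude: float = 0.0
    allow_overlap: bool = False
    mask: str = "full"  # "full" cube or inscribed "sphere"


def default_affine(grid_shape, voxel_size: float = 2.0) -> np.ndarray:
    """Grid-centered isotropic affine (mm origin at the grid center)."""
    aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    aff[:3, 3] = -(np.asarray(grid_shape) - 1) / 2.0 * voxel_size
    return aff


def spherical_mask(grid_shape, center, radius: float) -> np.ndarray:
    """Boolean mask of lattice voxels within ``radius`` of ``center``."""
    grids = np.indices(grid_shape)
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


@dataclass
class GroundTruth:
    """Effect regions, condition patterns, and grid geometry."""

    grid_shape: tuple[int, int, int]
    affine: np.ndarray
    brain_mask: np.ndarray  # boolean, grid_shape
    region_masks: dict[str, np.ndarray]  # boolean, grid_shape
    amplitudes: dict[str, float]
    # region -> condition key -> vector over that region's voxels
    patterns: dict[str, dict[tuple, np.ndarray]]
    catch_amplitude: float = 0.0
    seed: int | None = None

    def trial_amplitudes(self, stimulus_type: str, emotion: str, is_catch: bool = False) -> np.ndarray:
        """Amplitude vector over brain-mask voxels for one trial type."""
        n = int(self.brain_mask.sum())
        amp = np.zeros(n)
        if is_catch:
            amp += self.catch_amplitude
            return amp
        mask_flat = self.brain_mask.ravel()
        mask_index = np.full(self.brain_mask.size, -1, dtype=int)
        mask_index[mask_flat] = np.arange(n)
        for name, rmask in self.region_masks.items():
            key = self._condition_key(name, stimulus_type, emotion)
            if key is None:
                continue
            vec = self.patterns[name][key] * self.amplitudes[name]
            idx = mask_index[rmask.ravel()]
            amp[idx] += vec
        return amp

    @staticmethod
    def _condition_key(region: str, stimulus_type: str, emotion: str):
        if region == "modality_region":
            return (stimulus_type,)
        if region == "supramodal_emotion_region":
            return (emotion,)
        rtype = _EMOTION_REGION_TYPE.get(region)
        if rtype is not None:
            return (stimulus_type, emotion) if stimulus_type == rtype else None
        raise ConfigurationError(f"unknown region name {region!r}")

    def to_json_dict(self) -> dict:
        return {
            "grid_shape": list(self.grid_shape),
            "affine": self.affine.tolist(),
            "seed": self.seed,
            "catch_amplitude": self.catch_amplitude,
            "amplitudes": self.amplitudes,
            "regions": {
                name: np.argwhere(mask).tolist()
                for name, mask in self.region_masks.items()
            },
        }


def _unit_pattern(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal(n)
    v -= v.mean()
    norm = np.linalg.norm(v)
    if norm == 0:  # n == 1 after demeaning
        v = np.ones(n)
        norm = 1.0
    return v / norm


def simulate_patterns(config: TruthConfig, seed: int) -> GroundTruth:
    """Draw ground-truth condition patterns for the configured regions.

    Raises :class:`ConfigurationError` when regions overlap without
    ``allow_overlap`` or fall outside the brain mask.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(config.grid_shape)
    if config.mask == "sphere":
        center = tuple((s - 1) / 2.0 for s in shape)
        brain = spherical_mask(shape, center, min(shape) / 2.0)
    else:
        brain = np.ones(shape, dtype=bool)

    region_masks: dict[str, np.ndarray] = {}
    amplitudes: dict[str, float] = {}
    patterns: dict[str, dict[tuple, np.ndarray]] = {}
    occupancy = np.zeros(shape, dtype=int)
    for name, spec in config.regions.items():
        if name not in REGION_NAMES:
            raise ConfigurationError(f"unknown effect region {name!r}")
        rmask = spherical_mask(shape, spec.center, spec.radius)
        if not rmask.any():
            raise ConfigurationError(f"region {name!r} is empty")
        if (rmask & ~brain).any():
            raise ConfigurationError(f"region {name!r} extends outside the brain mask")
        occupancy += rmask
        region_masks[name] = rmask
        amplitudes[name] = float(spec.amplitude)
        n = int(rmask.sum())
        pats: dict[tuple, np.ndarray] = {}
        if name == "modality_region":
            for st in STIMULUS_TYPES:
                pats[(st,)] = _unit_pattern(rng, n)
        elif name == "supramodal_emotion_region":
            for emo in EMOTIONS:
                pats[(emo,)] = _unit_pattern(rng, n)
        else:
            st = _EMOTION_REGION_TYPE[name]
            for emo in EMOTIONS:
                pats[(st, emo)] = _unit_pattern(rng, n)
        patterns[name] = pats
    if not config.allow_overlap and (occupancy > 1).any():
        raise ConfigurationError(
            "effect regions overlap; pass allow_overlap=True to permit this"
        )
    return GroundTruth(
        grid_shape=shape,
        affine=default_affine(shape, config.voxel_size),
        brain_mask=brain,
        region_masks=region_masks,
        amplitudes=amplitudes,
        patterns=patterns,
        catch_amplitude=config.catch_amplitude,
        seed=seed,
    )
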