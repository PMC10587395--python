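"""Canonical double-gamma hemodynamic response function.

The kernel is a difference of two gamma densities — a positive response
peaking near 5 s and a later undershoot — normalized to unit peak
amplitude.  Regressors are built on an oversampled time grid (boxcar of
the stimulus duration convolved with the kernel) and then sampled at
volume-acquisition times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist

from .exceptions import ConfigurationError


@dataclass(frozen=True)
class HRFSpec:
    """Double-gamma HRF parameters (times in seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    kernel_length: float = 32.0

    def __post_init__(self) -> None:
        if self.peak_dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise ConfigurationError("HRF dispersions must be positive")
        if self.peak_undershoot_ratio <= 0:
            raise ConfigurationError("peak/undershoot ratio must be positive")


def hrf_curve(t: np.ndarray, spec: HRFSpec = HRFSpec()) -> np.ndarray:
    """Unnormalized double-gamma HRF evaluated at times ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    peak = gamma_dist.pdf(t, spec.peak_delay / spec.peak_dispersion, scale=spec.peak_dispersion)
    under = gamma_dist.pdf(
        t, spec.undershoot_delay / spec.undershoot_dispersion, scale=spec.undershoot_dispersion
    )
    return peak - under / spec.peak_undershoot_ratio


def canonical_hrf(spec: HRFSpec = HRFSpec(), tr: float = 3.0) -> np.ndarray:
    """HRF kernel sampled every ``tr`` seconds over ``kernel_length``.

    Sampling uses a ceil convention: samples at 0, tr, 2·tr, … strictly
    below ``kernel_length`` (32 s at TR 3 → 11 samples).  The sampled
    kernel is normalized to unit peak.
    """
    if tr <= 0:
        raise ConfigurationError("tr must be positive")
    t = np.arange(0.0, spec.kernel_length, tr)
    k = hrf_curve(t, spec)
    peak = np.max(np.abs(k))
    if peak == 0:
        raise ConfigurationError("degenerate HRF kernel")
    return k / np.max(k)


def event_regressor(
    onsets: np.ndarray,
    durations: np.ndarray,
    n_volumes: int,
    tr: float,
    spec: HRFSpec = HRFSpec(),
    dt: float = 0.1,
) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at volume times.

    Boxcars of the given durations are placed at the onsets on a ``dt``
    grid, convolved with the peak-normalized HRF, and read out at
    t = i·TR for i in [0, n_volumes).
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.atleast_1d(np.asarray(durations, dtype=float))
    if durations.size == 1:
        durations = np.full(onsets.shape, durations[0])
    total = n_volumes * tr
    n_hi = int(np.ceil(total / dt)) + 1
    box = np.zeros(n_hi)
    for onset, dur in zip(onsets, durations):
        i0 = int(round(onset / dt))
        i1 = max(i0 + 1, int(round((onset + dur) / dt)))
        box[i0 : min(i1, n_hi)] = 1.0
    t_hi = np.arange(0.0, spec.kernel_length, dt)
    kernel = hrf_curve(t_hi, spec)
    kernel = kernel / np.max(kernel)
    conv = np.convolve(box, kernel)[:n_hi]
    # volume read-out (no slice-timing offset)
    steps = np.round(np.arange(n_volumes) * tr / dt).astype(int)
    return conv[steps]
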