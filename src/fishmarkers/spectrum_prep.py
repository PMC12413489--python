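"""Profile-spectrum preprocessing: smoothing, baseline correction, peak picking.

An algorithmic stand-in for interactive spectrum processing: moving-average
smoothing, morphological-opening baseline removal and SNR-thresholded local
maxima with a top-N cap, targeting the 80-110 peaks per MALDI spectrum that
the downstream marker miner expects.  The miner itself is agnostic to how
peak lists were produced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .io_meta import PeakList, SampleKey

__all__ = ["ProfileSpectrum", "smooth", "baseline_correct", "pick_peaks", "preprocess"]


@dataclass(frozen=True)
class ProfileSpectrum:
    """Continuous (profile-mode) spectrum on an ascending m/z grid."""

    mz_grid: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz_grid, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "mz_grid", mz)
        object.__setattr__(self, "intensities", inten)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz_grid and intensities must be 1-D and equal length")
        if mz.size > 1 and not np.all(np.diff(mz) > 0):
            raise ValueError("mz_grid must be strictly increasing")


def smooth(s: ProfileSpectrum, window: int = 5) -> ProfileSpectrum:
    """Moving-average smoothing with edge truncation.

    At the edges the average runs over the available points only, so a
    constant signal is a fixed point and total intensity is conserved for
    interior-dominated signals.  ``window`` must be odd; ``window=1`` is the
    identity.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if window == 1 or s.intensities.size == 0:
        return s
    half = window // 2
    csum = np.cumsum(np.concatenate([[0.0], s.intensities]))
    n = s.intensities.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    out = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return ProfileSpectrum(s.mz_grid, out)


def baseline_correct(s: ProfileSpectrum, half_width: int = 50) -> ProfileSpectrum:
    """Subtract a morphological-opening baseline envelope.

    The envelope is a rolling minimum followed by a rolling maximum, both over
    ``2 * half_width + 1`` grid points (a grey opening).  Peaks narrower than
    the window survive; a constant offset is removed exactly.  The result is
    clipped at zero.
    """
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    if s.intensities.size == 0:
        return s
    size = 2 * half_width + 1
    envelope = ndimage.grey_opening(s.intensities, size=size, mode="nearest")
    return ProfileSpectrum(s.mz_grid, np.clip(s.intensities - envelope, 0.0, None))


def pick_peaks(
    s: ProfileSpectrum,
    key: SampleKey,
    snr_min: float = 3.0,
    n_min: int = 80,
    n_max: int = 110,
) -> PeakList:
    """SNR-thresholded local maxima with a most-intense-N cap.

    Noise is estimated robustly as ``1.4826 * MAD`` of the intensities (the
    MAD-to-sigma factor for a normal distribution), so abundant peaks barely
    perturb it.  Local maxima with intensity >= ``snr_min * noise`` are kept;
    if more than ``n_max`` qualify, only the ``n_max`` most intense survive;
    if fewer than ``n_min`` are found a warning is emitted but all are
    returned.  The apex m/z is the grid point of the local maximum.
    """
    if snr_min <= 0:
        raise ValueError("snr_min must be positive")
    if n_min > n_max:
        raise ValueError(f"n_min ({n_min}) must not exceed n_max ({n_max})")
    y = s.intensities
    if y.size == 0 or not np.any(y > 0):
        warnings.warn("no signal above zero; returning empty peak list", stacklevel=2)
        return PeakList(key, np.empty(0), np.empty(0))
    mad = np.median(np.abs(y - np.median(y)))
    noise = 1.4826 * mad
    if noise == 0:  # silent baseline: fall back to a small fraction of the max
        noise = 1e-3 * float(y.max())
    idx, _props = signal.find_peaks(y, height=snr_min * noise)
    if idx.size > n_max:
        keep = np.argsort(y[idx])[::-1][:n_max]
        idx = np.sort(idx[keep])
    if idx.size < n_min:
        warnings.warn(
            f"only {idx.size} peaks found (target at least {n_min})", stacklevel=2
        )
    return PeakList(key, s.mz_grid[idx], y[idx])


def preprocess(
    s: ProfileSpectrum,
    key: SampleKey,
    window: int = 5,
    half_width: int = 50,
    snr_min: float = 3.0,
    n_min: int = 80,
    n_max: int = 110,
) -> PeakList:
    """smooth -> baseline_correct -> pick_peaks with one call."""
    return pick_peaks(
        baseline_correct(smooth(s, window), half_width), key, snr_min, n_min, n_max
    )
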