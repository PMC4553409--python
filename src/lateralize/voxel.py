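"""Voxelwise resting-state metrics: ALFF, fALFF and ReHo.

ALFF is the summed spectral amplitude of a voxel's time course inside the
low-frequency band (default 0.01-0.08 Hz); fALFF is that sum divided by the
amplitude summed over the whole detectable spectrum (DC excluded from both).
ReHo is Kendall's coefficient of concordance (KCC, Kendall's W) between a
voxel and its 26 face/edge/corner neighbours, computed on band-passed,
unsmoothed data; the resulting map is then Gaussian-smoothed. All three maps
are finally divided by their subject-specific in-mask global mean.

Processing order implemented by :func:`voxel_feature_maps`:

    detrend -> smooth -> ALFF / fALFF   (spectra taken before band-pass filtering)
    detrend -> band-pass -> ReHo        (on unsmoothed data) -> smooth ReHo map
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal, stats

from .images import BoldImage

__all__ = [
    "VoxelFeatureMaps",
    "linear_detrend",
    "bandpass",
    "gaussian_smooth",
    "compute_alff",
    "compute_falff",
    "compute_reho",
    "standardize_by_global_mean",
    "voxel_feature_maps",
]

DEFAULT_BAND = (0.01, 0.08)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class VoxelFeatureMaps:
    """Standardized ALFF/fALFF/ReHo maps for one subject (in-mask mean 1)."""

    alff: np.ndarray
    falff: np.ndarray
    reho: np.ndarray
    mask: np.ndarray


def linear_detrend(ts: np.ndarray, axis: int = -1) -> np.ndarray:
    """Remove the ordinary-least-squares line (intercept + slope) from ``ts``.

    The residual is orthogonal to both the constant and the linear ramp.
    A constant series detrends to exactly zero.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.shape[axis] < 3:
        raise ValueError("need at least 3 timepoints to detrend")
    return signal.detrend(ts, axis=axis, type="linear")


def _band_bins(n: int, tr: float, low_hz: float, high_hz: float) -> tuple[np.ndarray, np.ndarray]:
    freqs = np.fft.rfftfreq(n, d=tr)
    inband = (freqs >= low_hz) & (freqs <= high_hz) & (freqs > 0)
    return freqs, inband


def bandpass(ts: np.ndarray, low_hz: float = 0.01, high_hz: float = 0.08,
             tr: float = 2.5, axis: int = -1) -> np.ndarray:
    """Ideal frequency-domain band-pass filter.

    FFT coefficients whose bin frequency lies outside [low_hz, high_hz] are
    zeroed (the DC bin counts as outside whenever ``low_hz > 0``) and the
    inverse transform returned.
    """
    ts = np.asarray(ts, dtype=float)
    nyquist = 1.0 / (2.0 * tr)
    if not (0 <= low_hz < high_hz):
        raise ValueError("require 0 <= low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(f"high_hz={high_hz} must be below the Nyquist frequency {nyquist}")
    n = ts.shape[axis]
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    if low_hz == 0:
        keep |= freqs == 0
    spec = np.fft.rfft(ts, axis=axis)
    shape = [1] * ts.ndim
    shape[axis] = freqs.size
    spec = spec * keep.reshape(shape)
    return np.fft.irfft(spec, n=n, axis=axis)


def gaussian_smooth(vol: np.ndarray, fwhm_mm: float = 4.0,
                    voxel_size_mm=(3.0, 3.0, 3.0)) -> np.ndarray:
    """Separable spatial Gaussian smoothing; ``fwhm_mm=0`` is the identity.

    For 4D input only the three spatial axes are smoothed. Edges use
    nearest-neighbour extension so constant volumes are exactly invariant.
    """
    vol = np.asarray(vol, dtype=float)
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return vol.copy()
    voxel_size_mm = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    sigmas = [fwhm_mm * FWHM_TO_SIGMA / vs for vs in voxel_size_mm]
    if vol.ndim == 4:
        sigmas = sigmas + [0.0]
    elif vol.ndim != 3:
        raise ValueError("expected a 3D or 4D volume")
    return ndimage.gaussian_filter(vol, sigma=sigmas, mode="nearest")


def _amplitude_spectrum(data: np.ndarray, axis: int = -1) -> np.ndarray:
    """Per-bin spectral amplitude: sqrt of periodogram power, REST convention."""
    n = data.shape[axis]
    return np.abs(np.fft.rfft(data, axis=axis)) * 2.0 / n


def compute_alff(bold: BoldImage, band: tuple[float, float] = DEFAULT_BAND) -> np.ndarray:
    """Summed in-band spectral amplitude per voxel (DC bin excluded).

    Input should be detrended (and, per the default pipeline, smoothed) but
    NOT band-pass filtered — the band restriction happens in the spectrum.
    """
    if bold.n_timepoints < 16:
        raise ValueError("ALFF requires at least 16 timepoints")
    _, inband = _band_bins(bold.n_timepoints, bold.tr, *band)
    amp = _amplitude_spectrum(bold.data)
    out = amp[..., inband].sum(axis=-1)
    out[~bold.mask] = 0.0
    return out


def compute_falff(bold: BoldImage, band: tuple[float, float] = DEFAULT_BAND) -> np.ndarray:
    """Fractional ALFF: in-band amplitude over total non-DC amplitude, in [0, 1]."""
    if bold.n_timepoints < 16:
        raise ValueError("fALFF requires at least 16 timepoints")
    freqs, inband = _band_bins(bold.n_timepoints, bold.tr, *band)
    amp = _amplitude_spectrum(bold.data)
    num = amp[..., inband].sum(axis=-1)
    den = amp[..., freqs > 0].sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    out[~bold.mask] = 0.0
    return out


_NEIGHBORHOODS = {
    7: "faces",
    19: "faces+edges",
    27: "faces+edges+corners",
}


def _neighborhood_kernel(size: int) -> np.ndarray:
    if size not in _NEIGHBORHOODS:
        raise ValueError(f"neighborhood must be one of {sorted(_NEIGHBORHOODS)}")
    off = np.abs(np.indices((3, 3, 3)) - 1).sum(axis=0)
    if size == 7:
        k = off <= 1
    elif size == 19:
        k = off <= 2
    else:
        k = np.ones((3, 3, 3), dtype=bool)
    return k.astype(float)


def compute_reho(bold: BoldImage, neighborhood: int = 27,
                 smooth_fwhm_mm: float = 4.0) -> np.ndarray:
    """Regional homogeneity: Kendall's W over each voxel's 3x3x3 neighbourhood.

    Each voxel's time course is ranked over time (average ranks on ties; no
    tie-correction term is applied). For the K <= ``neighborhood`` in-mask
    voxels around a centre,

        W = 12 * sum_t (R_t - K(T+1)/2)^2 / (K^2 (T^3 - T)),

    where R_t is the rank sum across the K voxels at timepoint t.
    Neighbourhoods are truncated at mask and volume borders (K adapts);
    voxels with K < 2 get value 0. The map is Gaussian-smoothed afterwards
    (``smooth_fwhm_mm=0`` returns the raw KCC map).

    Input should be detrended + band-passed and UNSMOOTHED.
    """
    data, mask = bold.data, bold.mask
    T = bold.n_timepoints
    if T < 3:
        raise ValueError("ReHo requires at least 3 timepoints")
    kernel = _neighborhood_kernel(neighborhood)

    ranks = np.zeros_like(data)
    ranks[mask] = stats.rankdata(data[mask], axis=-1)

    k4 = kernel[..., None]
    # Rank sums over the neighbourhood at every timepoint, masked voxels excluded.
    rank_sum = ndimage.correlate(ranks * mask[..., None], k4, mode="constant", cval=0.0)
    K = ndimage.correlate(mask.astype(float), kernel, mode="constant", cval=0.0)

    mean_rank = K[..., None] * (T + 1) / 2.0
    S = ((rank_sum - mean_rank) ** 2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        W = 12.0 * S / (K ** 2 * (T ** 3 - T))
    W[(K < 2) | ~mask] = 0.0
    W[~mask] = 0.0
    if smooth_fwhm_mm > 0:
        W = gaussian_smooth(W, smooth_fwhm_mm, bold.voxel_size_mm)
        W[~mask] = 0.0
    return W


def standardize_by_global_mean(vol: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Divide a map by its in-mask mean so the standardized in-mask mean is 1."""
    vol = np.asarray(vol, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    m = vol[mask].mean()
    if m == 0 or not np.isfinite(m):
        raise ValueError("global mean is zero or non-finite; cannot standardize")
    out = np.zeros_like(vol)
    out[mask] = vol[mask] / m
    return out


def voxel_feature_maps(bold: BoldImage, band: tuple[float, float] = DEFAULT_BAND,
                       fwhm_mm: float = 4.0, neighborhood: int = 27,
                       smooth_before_spectral: bool = True) -> VoxelFeatureMaps:
    """Full univariate feature stage for one subject.

    ``smooth_before_spectral`` controls whether ALFF/fALFF see spatially
    smoothed data (the default) or raw detrended data.
    """
    detrended = linear_detrend(bold.data)
    spectral_input = (
        gaussian_smooth(detrended, fwhm_mm, bold.voxel_size_mm)
        if smooth_before_spectral else detrended
    )
    spec_bold = BoldImage(spectral_input, bold.tr, bold.mask, bold.voxel_size_mm)
    alff = compute_alff(spec_bold, band)
    falff = compute_falff(spec_bold, band)

    filtered = bandpass(detrended, band[0], band[1], bold.tr)
    filt_bold = BoldImage(filtered, bold.tr, bold.mask, bold.voxel_size_mm)
    reho = compute_reho(filt_bold, neighborhood=neighborhood, smooth_fwhm_mm=fwhm_mm)

    return VoxelFeatureMaps(
        alff=standardize_by_global_mean(alff, bold.mask),
        falff=standardize_by_global_mean(falff, bold.mask),
        reho=standardize_by_global_mean(reho, bold.mask),
        mask=bold.mask.copy(),
    )
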