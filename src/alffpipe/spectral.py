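"""Voxelwise spectral fluctuation measures for resting-state BOLD data.

The measures implemented here summarise the one-sided discrete Fourier
magnitude spectrum of each voxel time course:

* **ALFF** — the sum of spectral magnitudes inside a low-frequency band
  (conventionally 0.01–0.1 Hz).
* **fALFF** — ALFF divided by the sum of magnitudes over the whole
  spectrum up to Nyquist (DC excluded), a dimensionless ratio in [0, 1].
* **hfALFF** — ALFF divided by the sum of magnitudes from the *lower band
  edge* up to Nyquist, i.e. fALFF with frequencies below the band excluded
  from the denominator.

Because fALFF and hfALFF are ratios of magnitudes computed from the same
time course, they are invariant under any positive voxelwise gain (receive
coil sensitivity, bias fields), whereas ALFF scales linearly with gain.

Conventions
-----------
Magnitudes are absolute values of the unnormalised forward DFT
coefficients (``numpy.fft.rfft``), one-sided without doubling.  The DC bin
is excluded from every numerator and denominator: it encodes the baseline
intensity, not fluctuation, and its inclusion would break the gain
invariance of fALFF.  No window function or zero padding is applied.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage

__all__ = [
    "Spectrum",
    "Band",
    "FluctuationMap",
    "compute_spectrum",
    "band_bin_indices",
    "alff",
    "falff",
    "hfalff",
    "compute_fluctuation_map",
    "standardise_map",
    "gaussian_smooth",
    "apply_bias_correction",
    "FWHM_TO_SIGMA",
]

#: Conversion factor between a Gaussian full width at half maximum and sigma.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclasses.dataclass(frozen=True)
class Band:
    """A frequency interval in Hz, ``0 < low < high``."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high):
            raise ValueError(
                f"invalid band [{self.low}, {self.high}]: need 0 < low < high"
            )


#: The conventional low-frequency fluctuation band.
DEFAULT_BAND = Band(0.01, 0.1)


@dataclasses.dataclass(frozen=True)
class Spectrum:
    """One-sided DFT magnitude spectrum of a single voxel time course.

    Attributes
    ----------
    magnitudes : ndarray, shape (floor(N/2)+1,)
        ``|rfft(x)|`` per frequency bin, bin 0 being DC.
    frequencies : ndarray
        Frequency of each bin in Hz; the last bin is Nyquist for even N.
    n_timepoints : int
    tr_seconds : float
        Sampling interval.
    """

    magnitudes: np.ndarray
    frequencies: np.ndarray
    n_timepoints: int
    tr_seconds: float

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_seconds)


def compute_spectrum(timecourse: np.ndarray, tr_seconds: float) -> Spectrum:
    """Fourier transform a time course and return its one-sided magnitudes.

    Parameters
    ----------
    timecourse : 1-D array of length >= 4 with finite values.
    tr_seconds : sampling interval in seconds.
    """
    x = np.asarray(timecourse, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"timecourse must be 1-D, got shape {x.shape}")
    if x.size < 4:
        raise ValueError(f"timecourse too short (N={x.size}, need >= 4)")
    if not np.all(np.isfinite(x)):
        bad = np.flatnonzero(~np.isfinite(x))
        raise ValueError(f"non-finite values in timecourse at indices {bad[:5]}")
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    mags = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(x.size, d=tr_seconds)
    return Spectrum(mags, freqs, x.size, tr_seconds)


def band_bin_indices(spectrum: Spectrum, band: Band) -> np.ndarray:
    """Indices of bins with ``band.low <= f <= band.high`` (closed interval).

    The DC bin can never be selected since ``band.low > 0``.
    """
    idx = np.flatnonzero(
        (spectrum.frequencies >= band.low) & (spectrum.frequencies <= band.high)
    )
    if idx.size == 0:
        df = spectrum.frequencies[1] if spectrum.frequencies.size > 1 else np.nan
        raise ValueError(
            f"no DFT bin falls inside band [{band.low}, {band.high}] Hz "
            f"(bin spacing {df:.6g} Hz, N={spectrum.n_timepoints})"
        )
    return idx


def alff(spectrum: Spectrum, band: Band = DEFAULT_BAND) -> float:
    """Sum of spectral magnitudes over the bins inside ``band``."""
    return float(spectrum.magnitudes[band_bin_indices(spectrum, band)].sum())


def falff(spectrum: Spectrum, band: Band = DEFAULT_BAND) -> float:
    """ALFF divided by the magnitude sum over all non-DC bins up to Nyquist.

    Returns NaN (a flagged missing value) when the denominator is zero,
    i.e. for an exactly constant time course.
    """
    num = alff(spectrum, band)
    denom = float(spectrum.magnitudes[1:].sum())
    if denom == 0.0:
        return float("nan")
    return num / denom


def hfalff(spectrum: Spectrum, band: Band = DEFAULT_BAND) -> float:
    """ALFF normalised by the magnitude sum from ``band.low`` up to Nyquist.

    Identical to fALFF except that all frequencies below the lower band
    edge are excluded from the denominator; consequently
    ``hfalff >= falff`` always holds where both are defined.
    """
    num = alff(spectrum, band)
    hf = np.flatnonzero(spectrum.frequencies >= band.low)
    denom = float(spectrum.magnitudes[hf].sum())
    if denom == 0.0:
        return float("nan")
    return num / denom


@dataclasses.dataclass
class FluctuationMap:
    """A voxelwise fluctuation-amplitude volume with its provenance.

    ``values`` is a 3-D array of nonnegative amplitudes (NaN marks voxels
    where the measure is undefined).  ``standardised`` records whether the
    map has been divided by its in-mask mean.
    """

    values: np.ndarray
    measure: str  # one of {"alff", "falff", "hfalff"}
    band: Band
    standardised: bool = False
    smoothing_fwhm_mm: float | None = None

    _MEASURES = ("alff", "falff", "hfalff")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("FluctuationMap values must be a 3-D volume")
        if self.measure not in self._MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and finite.min() < 0:
            raise ValueError("fluctuation amplitudes must be nonnegative")


def compute_fluctuation_map(
    bold: np.ndarray,
    tr_seconds: float,
    measure: str = "alff",
    band: Band = DEFAULT_BAND,
) -> FluctuationMap:
    """Compute a voxelwise ALFF/fALFF/hfALFF map from a 4-D array.

    Parameters
    ----------
    bold : ndarray, shape (x, y, z, N)
        Time along the last axis.
    measure : {"alff", "falff", "hfalff"}

    Notes
    -----
    Vectorised over voxels: one ``rfft`` call for the whole volume.  For
    ratio measures, voxels with a zero denominator (constant time courses)
    are set to NaN.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim != 4:
        raise ValueError("bold must be 4-D (x, y, z, time)")
    if not np.all(np.isfinite(bold)):
        raise ValueError("bold contains non-finite values")
    n = bold.shape[-1]
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    mags = np.abs(np.fft.rfft(bold, axis=-1))
    in_band = (freqs >= band.low) & (freqs <= band.high)
    if not in_band.any():
        raise ValueError(
            f"no DFT bin falls inside band [{band.low}, {band.high}] Hz "
            f"(bin spacing {freqs[1]:.6g} Hz, N={n})"
        )
    num = mags[..., in_band].sum(axis=-1)
    if measure == "alff":
        values = num
    elif measure == "falff":
        denom = mags[..., 1:].sum(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
    elif measure == "hfalff":
        denom = mags[..., freqs >= band.low].sum(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
    else:
        raise ValueError(f"unknown measure {measure!r}")
    return FluctuationMap(values, measure=measure, band=band)


def standardise_map(fmap: FluctuationMap, brain_mask: np.ndarray) -> FluctuationMap:
    """Divide a map by its mean over in-mask voxels; zero outside the mask.

    The resulting in-mask mean is exactly 1, which removes subject-specific
    global amplitude baselines before group comparison.  NaN voxels inside
    the mask are ignored when computing the mean and stay NaN.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if mask.shape != fmap.values.shape:
        raise ValueError("mask shape does not match map shape")
    if not mask.any():
        raise ValueError("brain mask is empty")
    inside = fmap.values[mask]
    mean = float(np.nanmean(inside))
    if not np.isfinite(mean) or mean <= 0:
        raise ValueError(f"in-mask mean must be positive, got {mean}")
    values = np.where(mask, fmap.values / mean, 0.0)
    return FluctuationMap(
        values,
        measure=fmap.measure,
        band=fmap.band,
        standardised=True,
        smoothing_fwhm_mm=fmap.smoothing_fwhm_mm,
    )


def gaussian_smooth(
    fmap: FluctuationMap,
    fwhm_mm: float,
    voxel_size_mm: tuple[float, float, float],
) -> FluctuationMap:
    """Separable Gaussian smoothing with a FWHM given in millimetres.

    ``sigma = fwhm / (2 sqrt(2 ln 2))`` per axis, converted to voxel units
    through the voxel size.  ``fwhm_mm = 0`` is the identity.  Reflecting
    boundaries conserve the total in-volume sum up to edge effects.  NaN
    voxels are treated as zero for the convolution.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return fmap
    voxel = np.asarray(voxel_size_mm, dtype=float)
    if voxel.shape != (3,) or np.any(voxel <= 0):
        raise ValueError("voxel_size_mm must be three positive lengths")
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel
    values = np.nan_to_num(fmap.values, nan=0.0)
    smoothed = ndimage.gaussian_filter(values, sigma=sigma_vox, mode="reflect")
    smoothed = np.clip(smoothed, 0.0, None)  # guard tiny negative round-off
    return FluctuationMap(
        smoothed,
        measure=fmap.measure,
        band=fmap.band,
        standardised=fmap.standardised,
        smoothing_fwhm_mm=fwhm_mm,
    )


def apply_bias_correction(bold: np.ndarray, bias_field: np.ndarray) -> np.ndarray:
    """Divide every time point of a 4-D array voxelwise by a gain field.

    Removing a multiplicative receive-field gain leaves fALFF/hfALFF
    unchanged and rescales ALFF voxelwise.
    """
    bold = np.asarray(bold, dtype=float)
    field = np.asarray(bias_field, dtype=float)
    if bold.ndim != 4 or field.ndim != 3 or bold.shape[:3] != field.shape:
        raise ValueError(
            f"shape mismatch: bold {bold.shape} vs bias field {field.shape}"
        )
    if np.any(field <= 0) or not np.all(np.isfinite(field)):
        raise ValueError("bias field must be strictly positive and finite")
    return bold / field[..., None]
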