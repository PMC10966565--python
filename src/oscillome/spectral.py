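"""Per-region spectra and band-limited envelopes.

Two estimators feed the feature space:

- Welch PSD with a 2-s Hann window and 1-s overlap, z-normalized per
  region across the 2–90 Hz bins; band power is the area under the
  normalized PSD within each canonical band.
- A complex Morlet transform whose temporal resolution scales as
  ``FWHM_tc * fc / f`` (defaults fc = 1 Hz, FWHM_tc = 3 s), giving the
  band-limited analytic coefficients whose magnitude is the power
  envelope used by PEC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft as sfft
from scipy import signal

from oscillome.bands import BandSpec, DEFAULT_BANDS
from oscillome.source import ROITimeSeries

NORM_RANGE = (2.0, 90.0)


@dataclass
class PSDMatrix:
    """Region x frequency-bin power spectral density."""

    values: np.ndarray
    freqs: np.ndarray
    normalized: bool = False
    norm_range: tuple[float, float] = NORM_RANGE
    region_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.values.shape[1] != len(self.freqs):
            raise ValueError("values/freqs bin-count mismatch")


@dataclass(frozen=True)
class MorletParams:
    """Complex Morlet shape: temporal FWHM at frequency f is fwhm_tc*fc/f."""

    fc: float = 1.0
    fwhm_tc: float = 3.0

    def __post_init__(self) -> None:
        if self.fc <= 0 or self.fwhm_tc <= 0:
            raise ValueError("fc and fwhm_tc must be > 0")

    def fwhm_at(self, freq: float) -> float:
        return self.fwhm_tc * self.fc / freq


def welch_psd(
    roi: ROITimeSeries | np.ndarray,
    fs: float | None = None,
    window: float = 2.0,
    overlap: float = 1.0,
) -> PSDMatrix:
    """Averaged windowed periodogram (Hann taper), density scaling.

    Accepts a ROITimeSeries, a 2-D (region x sample) array, or a 3-D
    (epoch x region x sample) array; in the epoch case the window is
    applied within each epoch and the per-epoch spectra are averaged.
    Frequency resolution is 1/window Hz.
    """
    names = None
    if isinstance(roi, ROITimeSeries):
        data, fs, names = roi.data, roi.fs, list(roi.region_names)
    else:
        data = np.asarray(roi, dtype=float)
        if fs is None:
            raise ValueError("fs is required for array input")
    nperseg = int(round(window * fs))
    noverlap = int(round(overlap * fs))
    if data.ndim == 3:
        if data.shape[2] < nperseg:
            raise ValueError("epoch shorter than the Welch window")
        freqs, psd = signal.welch(
            data, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
            detrend="constant", axis=-1,
        )
        psd = psd.mean(axis=0)
    else:
        if data.shape[-1] < nperseg:
            raise ValueError(
                f"signal of {data.shape[-1]} samples shorter than the "
                f"{nperseg}-sample Welch window"
            )
        freqs, psd = signal.welch(
            data, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
            detrend="constant", axis=-1,
        )
    return PSDMatrix(values=psd, freqs=freqs, normalized=False, region_names=names)


def znorm_psd(
    psd: PSDMatrix, norm_range: tuple[float, float] = NORM_RANGE
) -> PSDMatrix:
    """Z-transform each region's PSD across the bins inside norm_range.

    Bins outside the range are dropped.  Standardization uses the
    sample SD (ddof=1).  A region with zero spectral variance cannot be
    normalized and raises.
    """
    lo, hi = norm_range
    keep = (psd.freqs >= lo) & (psd.freqs <= hi)
    if keep.sum() < 2:
        raise ValueError(f"fewer than 2 PSD bins inside {norm_range}")
    vals = psd.values[:, keep]
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    dead = np.flatnonzero(sd.ravel() == 0)
    if dead.size:
        label = (
            psd.region_names[dead[0]] if psd.region_names else f"index {dead[0]}"
        )
        raise ValueError(f"region {label} has a constant PSD (zero SD)")
    return PSDMatrix(
        values=(vals - mean) / sd,
        freqs=psd.freqs[keep],
        normalized=True,
        norm_range=norm_range,
        region_names=psd.region_names,
    )


def band_power(
    psd: PSDMatrix, bands: tuple[BandSpec, ...] = DEFAULT_BANDS
) -> np.ndarray:
    """Area (trapezoid) under the PSD within each band, boundary bins included.

    Returns a (n_regions, n_bands) array.
    """
    out = np.empty((psd.values.shape[0], len(bands)))
    for j, band in enumerate(bands):
        if band.f_lo < psd.freqs.min() or band.f_hi > psd.freqs.max():
            raise ValueError(
                f"band {band.name} [{band.f_lo}, {band.f_hi}] outside the "
                f"available grid [{psd.freqs.min()}, {psd.freqs.max()}]"
            )
        sel = (psd.freqs >= band.f_lo) & (psd.freqs <= band.f_hi)
        out[:, j] = np.trapezoid(psd.values[:, sel], psd.freqs[sel], axis=1)
    return out


def morlet_kernel(freq: float, fs: float, params: MorletParams) -> np.ndarray:
    """Complex Morlet kernel at one center frequency.

    Scaled so the magnitude response to a unit-amplitude tone at
    ``freq`` is 1 (the coefficient magnitude is then directly the
    envelope amplitude).
    """
    sigma_t = params.fwhm_at(freq) / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    half = int(np.ceil(4.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    gauss = np.exp(-(t**2) / (2.0 * sigma_t**2))
    kernel = gauss * np.exp(2j * np.pi * freq * t)
    return 2.0 * kernel / gauss.sum()


def morlet_tf(
    roi: ROITimeSeries | np.ndarray,
    center_freqs,
    fs: float | None = None,
    params: MorletParams = MorletParams(),
) -> np.ndarray:
    """Complex Morlet coefficients, region x frequency x time.

    Linear in the input; |coefficients| is the band-limited envelope.
    """
    if isinstance(roi, ROITimeSeries):
        data, fs = roi.data, roi.fs
    else:
        data = np.atleast_2d(np.asarray(roi, dtype=float))
        if fs is None:
            raise ValueError("fs is required for array input")
    center_freqs = np.atleast_1d(np.asarray(center_freqs, dtype=float))
    if (center_freqs >= fs / 2).any():
        raise ValueError(
            f"center frequency >= Nyquist ({fs / 2} Hz): {center_freqs}"
        )
    # Frequency-domain implementation: the analytic Morlet response is
    # a Gaussian 2*exp(-2 pi^2 sigma_t^2 (f' - f)^2) over positive
    # frequencies (its value at negative frequencies is numerically
    # zero for the supported bands), applied to the zero-padded FFT of
    # the input.  Equivalent to 'same'-mode convolution with the
    # untruncated time kernel.
    n = data.shape[1]
    sigma_max = max(
        params.fwhm_at(f) for f in center_freqs
    ) / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    nfft = sfft.next_fast_len(n + int(np.ceil(8.0 * sigma_max * fs)))
    X = sfft.fft(data, nfft, axis=-1)
    freqs = sfft.fftfreq(nfft, 1.0 / fs)
    out = np.empty((data.shape[0], len(center_freqs), n), dtype=complex)
    for j, f in enumerate(center_freqs):
        sigma_t = params.fwhm_at(f) / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        W = 2.0 * np.exp(-2.0 * np.pi**2 * sigma_t**2 * (freqs - f) ** 2)
        out[:, j, :] = sfft.ifft(X * W, axis=-1)[:, :n]
    return out


def band_envelope_coefficients(
    roi: ROITimeSeries | np.ndarray,
    band: BandSpec,
    fs: float | None = None,
    params: MorletParams = MorletParams(),
) -> np.ndarray:
    """Complex coefficients at the band's geometric-center frequency.

    The default single-carrier convention for connectivity; average
    coefficients over several in-band frequencies by calling
    :func:`morlet_tf` directly if finer coverage is wanted.
    """
    return morlet_tf(roi, [band.center], fs=fs, params=params)[:, 0, :]
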