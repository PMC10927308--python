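"""Welch spectra, relative band power, and aperiodic (1/f) parameterization.

The power spectrum of resting EEG is modeled as an aperiodic background,
linear in log10-power vs. log10-frequency (PSD proportional to f^-chi),
plus a small number of Gaussian oscillatory peaks.  ``fit_aperiodic``
separates the two and reports the aperiodic exponent chi.

Sign convention: chi >= 0 with PSD ~ f^-chi.  The "1/f slope" plotted in
the EEG literature is -chi; a *flatter* spectrum means a *smaller* chi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .preprocess import BANDS, BROADBAND, Recording


@dataclass
class Spectrum:
    """Per-channel Welch power spectral density (units signal^2/Hz)."""

    freqs: np.ndarray
    power: np.ndarray  # channels x freqs
    fs: float
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if self.power.shape[1] != len(self.freqs):
            raise ValueError("power and freqs length mismatch")
        if (self.power < 0).any():
            raise ValueError("PSD must be nonnegative")


@dataclass
class Peak:
    center: float  # Hz
    amplitude: float  # log10 power above the aperiodic line
    width: float  # Hz (Gaussian sigma)


@dataclass
class AperiodicFit:
    """Aperiodic decomposition of one channel's spectrum.

    ``exponent`` is chi in PSD ~ f^-chi (= minus the log-log slope);
    ``offset`` the log10-power intercept at log10 f = 0.
    """

    offset: float
    exponent: float
    peaks: list[Peak] = field(default_factory=list)
    fit_range: tuple[float, float] = (4.0, 40.0)
    r_squared: float = np.nan
    fit_error: float = np.nan

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def welch_psd(
    recording: Recording, window_s: float = 4.0, overlap: float = 0.5
) -> Spectrum:
    """Welch PSD with Hann windows of ``window_s`` seconds and 50% overlap.

    A 4-s window gives a frequency resolution of exactly 0.25 Hz.
    """
    nperseg = int(round(window_s * recording.fs))
    if recording.n_samples < nperseg:
        raise ValueError(
            f"recording of {recording.duration:.1f} s shorter than the "
            f"{window_s} s Welch window"
        )
    freqs, power = signal.welch(
        recording.data,
        fs=recording.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)),
        axis=-1,
    )
    return Spectrum(
        freqs=freqs, power=power, fs=recording.fs,
        channel_labels=list(recording.channel_labels),
    )


def relative_band_power(
    spectrum: Spectrum,
    band: tuple[float, float],
    broadband: tuple[float, float] = BROADBAND,
) -> np.ndarray:
    """Per-channel band power as a fraction of broadband power.

    Both integrals use the trapezoid rule on the discrete PSD grid,
    including both band-edge bins; the ratio is invariant to any global
    rescaling of the signal.
    """
    lo, hi = band
    blo, bhi = broadband
    if not (blo <= lo < hi <= bhi):
        raise ValueError(f"band {band} not inside broadband {broadband}")
    if lo < spectrum.freqs[0] or bhi > spectrum.freqs[-1]:
        raise ValueError(f"spectrum does not cover broadband {broadband}")

    def integrate(low: float, high: float) -> np.ndarray:
        m = (spectrum.freqs >= low) & (spectrum.freqs <= high)
        return np.trapezoid(spectrum.power[:, m], spectrum.freqs[m], axis=-1)

    return integrate(lo, hi) / integrate(blo, bhi)


def band_power_table(
    spectrum: Spectrum, bands: dict[str, tuple[float, float]] = BANDS
) -> pd.DataFrame:
    """Long-format (channel, band, relative_power) table."""
    rows = []
    for band_name, edges in bands.items():
        rel = relative_band_power(spectrum, edges)
        for ch, value in zip(spectrum.channel_labels, rel):
            rows.append({"channel": ch, "band": band_name, "relative_power": value})
    return pd.DataFrame(rows)


# --- aperiodic / periodic decomposition -----------------------------------

def _linfit(logf: np.ndarray, logp: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(logf, logp, 1)
    return float(intercept), float(slope)


def _robust_line(logf: np.ndarray, logp: np.ndarray) -> tuple[float, float]:
    """Line fit down-weighting oscillatory bumps.

    First pass OLS; positive residuals (points above the line — candidate
    peaks) beyond a low-percentile threshold are dropped and the line refit,
    so narrowband power does not drag the aperiodic estimate upward.
    """
    intercept, slope = _linfit(logf, logp)
    resid = logp - (intercept + slope * logf)
    flat = np.clip(resid, 0, None)
    thresh = np.percentile(flat, 2.5)
    keep = flat <= thresh
    if keep.sum() >= 2:
        intercept, slope = _linfit(logf[keep], logp[keep])
    return intercept, slope


def _gaussian(f: np.ndarray, center: float, height: float, sigma: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((f - center) / sigma) ** 2)


def fit_aperiodic(
    spectrum: Spectrum,
    channel: int | str = 0,
    fit_range: tuple[float, float] = (4.0, 40.0),
    max_peaks: int = 6,
    peak_threshold_sd: float = 2.0,
    peak_width_limits: tuple[float, float] = (0.5, 12.0),
) -> AperiodicFit:
    """Decompose one channel's PSD into an aperiodic line plus Gaussian peaks.

    Procedure (knee-free): (1) robust log-log line fit; (2) iteratively fit
    and subtract the largest Gaussian peak in the flattened residual that
    exceeds ``peak_threshold_sd`` residual SDs, up to ``max_peaks``; (3)
    refit the line on the peak-stripped spectrum.  Peaks are Gaussian in
    (linear frequency, log10 power) space with sigma bounded by
    ``peak_width_limits`` (as half-widths).
    """
    if isinstance(channel, str):
        channel = spectrum.channel_labels.index(channel)
    lo, hi = fit_range
    m = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
    if m.sum() < 10:
        raise ValueError(f"fewer than 10 frequency bins inside {fit_range}")
    f = spectrum.freqs[m]
    p = spectrum.power[channel, m]
    if (p <= 0).any():
        raise ValueError("nonpositive power inside the fit range")
    logf, logp = np.log10(f), np.log10(p)

    intercept, slope = _robust_line(logf, logp)
    resid = logp - (intercept + slope * logf)

    sig_lo, sig_hi = peak_width_limits[0] / 2.0, peak_width_limits[1] / 2.0
    peaks: list[Peak] = []
    work = resid.copy()
    for _ in range(max_peaks):
        sd = work.std()
        i = int(np.argmax(work))
        height = work[i]
        if sd == 0 or height < peak_threshold_sd * sd:
            break
        center = f[i]
        # half-height width guess from the local bump
        above = work >= height / 2.0
        j0 = i
        while j0 > 0 and above[j0 - 1]:
            j0 -= 1
        j1 = i
        while j1 < len(f) - 1 and above[j1 + 1]:
            j1 += 1
        fwhm = max(f[j1] - f[j0], f[1] - f[0])
        guess_sigma = np.clip(fwhm / 2.355, sig_lo, sig_hi)
        try:
            popt, _ = optimize.curve_fit(
                _gaussian,
                f,
                work,
                p0=[center, height, guess_sigma],
                bounds=([lo, 0.0, sig_lo], [hi, 1.5 * height + 1e-9, sig_hi]),
                maxfev=2000,
            )
        except RuntimeError:
            break
        peak = Peak(center=float(popt[0]), amplitude=float(popt[1]), width=float(popt[2]))
        peaks.append(peak)
        work = work - _gaussian(f, peak.center, peak.amplitude, peak.width)

    peak_model = np.zeros_like(f)
    for pk in peaks:
        peak_model += _gaussian(f, pk.center, pk.amplitude, pk.width)
    # Final aperiodic refit on the peak-stripped spectrum.  Bins lying under
    # a detected peak are excluded outright: the Gaussian is only an
    # approximation of the true peak shape, and residual skirts would tilt
    # the line.
    clear = peak_model <= 0.05
    if clear.sum() >= 10:
        intercept, slope = _linfit(logf[clear], logp[clear] - peak_model[clear])
    else:
        intercept, slope = _linfit(logf, logp - peak_model)

    model = intercept + slope * logf + peak_model
    err = logp - model
    ss_res = float((err**2).sum())
    ss_tot = float(((logp - logp.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return AperiodicFit(
        offset=intercept,
        exponent=-slope,
        peaks=peaks,
        fit_range=fit_range,
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        fit_error=float(np.abs(err).mean()),
    )


def fit_aperiodic_all(spectrum: Spectrum, **kwargs) -> list[AperiodicFit]:
    """``fit_aperiodic`` for every channel of a spectrum."""
    return [
        fit_aperiodic(spectrum, channel=c, **kwargs)
        for c in range(spectrum.power.shape[0])
    ]
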