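"""Multitaper cross-spectra and weighted phase lag index (wPLI).

The wPLI between channels x and y is

    wPLI(f) = | E{ Im S_xy(f) } | / E{ |Im S_xy(f)| }

with S_xy the cross-spectrum and E the mean over estimates.  Because only
the imaginary part enters, instantaneous (zero-lag) mixing — the signature
of volume conduction at the scalp — contributes nothing, and the index is
bounded in [0, 1] and invariant to per-channel amplitude rescaling.

Estimates are DPSS-multitaper cross-spectra on 12-s epochs.  Two
expectation scopes are provided: pooling all epochs x tapers into a single
wPLI (default, lower variance) or computing wPLI within each epoch and
grand-averaging across epochs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import EpochSet

logger = logging.getLogger(__name__)


@dataclass
class CrossSpectra:
    """Accumulated imaginary cross-spectrum statistics for one band.

    ``imag_sum`` and ``imag_abs_sum`` are channels x channels x band-bins
    sums of Im S_xy and |Im S_xy| over all estimates (tapers x segments);
    they are sufficient statistics for wPLI.
    """

    imag_sum: np.ndarray
    imag_abs_sum: np.ndarray
    freqs: np.ndarray
    band: str
    n_estimates: int


@dataclass
class ConnectivityMatrix:
    """Symmetric weighted channel x channel matrix in [0, 1], zero diagonal."""

    values: np.ndarray
    band: str = ""
    n_epochs_used: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if (v < -1e-12).any() or (v > 1 + 1e-12).any():
            raise ValueError("wPLI values must lie in [0, 1]")
        np.fill_diagonal(v, 0.0)
        self.values = np.clip(v, 0.0, 1.0)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def mean_connectivity(self) -> float:
        """Overall FC: mean of the off-diagonal entries."""
        n = self.n
        return float(self.values.sum() / (n * (n - 1)))


def dpss_tapers(n_samples: int, n_tapers: int = 7, nw: float = 4.0) -> np.ndarray:
    """Slepian tapers (n_tapers x n_samples), unit energy each."""
    if n_tapers < 2:
        raise ValueError("need at least 2 tapers")
    from scipy.signal import windows

    return windows.dpss(n_samples, NW=nw, Kmax=n_tapers)


def multitaper_cross_spectra(
    epochs: EpochSet,
    band: tuple[float, float],
    n_tapers: int = 7,
    nw: float = 4.0,
    band_name: str = "",
) -> CrossSpectra:
    """Accumulate Im S_xy statistics over all epochs and tapers.

    Cross-spectra are formed per taper per epoch and restricted to the
    frequency bins inside ``band`` (half-open [low, high)).
    """
    lo, hi = band
    fs = epochs.fs
    if hi > fs / 2:
        raise ValueError(f"band {band} exceeds Nyquist {fs / 2} Hz")
    n_ep, n_ch, n_t = epochs.epochs.shape
    min_len = 4.0 / max(lo, 1e-9)
    if lo > 0 and n_t / fs < min_len:
        raise ValueError(
            f"epoch of {n_t / fs:.1f} s shorter than 4 cycles at {lo} Hz"
        )
    tapers = dpss_tapers(n_t, n_tapers=n_tapers, nw=nw)
    freqs = np.fft.rfftfreq(n_t, d=1.0 / fs)
    sel = (freqs >= lo) & (freqs < hi)
    if sel.sum() < 1:
        raise ValueError(f"no frequency bins inside band {band}")
    fsel = freqs[sel]

    imag_sum = np.zeros((n_ch, n_ch, sel.sum()))
    imag_abs_sum = np.zeros_like(imag_sum)
    for e in range(n_ep):
        x = epochs.epochs[e]  # ch x time
        # taper x ch x freq
        spec = np.fft.rfft(x[None, :, :] * tapers[:, None, :], axis=-1)[:, :, sel]
        # Im(S_xy) per taper, with S_xy = X_x conj(X_y):
        # Im(a conj(b)) = Im(a)Re(b) - Re(a)Im(b)
        im = np.einsum("kcf,kdf->kcdf", spec.imag, spec.real) - np.einsum(
            "kcf,kdf->kcdf", spec.real, spec.imag
        )
        imag_sum += im.sum(axis=0)
        imag_abs_sum += np.abs(im).sum(axis=0)
    return CrossSpectra(
        imag_sum=imag_sum,
        imag_abs_sum=imag_abs_sum,
        freqs=fsel,
        band=band_name or f"{lo}-{hi}Hz",
        n_estimates=n_ep * n_tapers,
    )


def wpli(estimates: CrossSpectra, n_epochs_used: int | None = None) -> ConnectivityMatrix:
    """wPLI from accumulated cross-spectral statistics.

    Per frequency bin: |sum Im S_xy| / sum |Im S_xy| (the shared 1/N
    cancels); the band value is the unweighted mean over bins.  Pairs whose
    denominator vanishes (identically zero imaginary part, e.g. a channel
    with itself or purely zero-lag coupling) are set to 0 and counted.
    """
    if estimates.n_estimates < 2:
        raise ValueError("need at least 2 cross-spectral estimates")
    num = np.abs(estimates.imag_sum)
    den = estimates.imag_abs_sum
    with np.errstate(invalid="ignore", divide="ignore"):
        per_bin = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    n_ch = per_bin.shape[0]
    degenerate = int(
        (den <= 0).all(axis=-1)[np.triu_indices(n_ch, k=1)].sum()
    )
    if degenerate:
        logger.info("wPLI: %d channel pairs with degenerate denominator -> 0", degenerate)
    values = per_bin.mean(axis=-1)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    return ConnectivityMatrix(
        values=values,
        band=estimates.band,
        n_epochs_used=n_epochs_used or 0,
    )


def band_wpli(
    epochs: EpochSet,
    band: tuple[float, float],
    n_tapers: int = 7,
    nw: float = 4.0,
    band_name: str = "",
    per_epoch: bool = False,
) -> ConnectivityMatrix:
    """wPLI of an epoch set in one band.

    ``per_epoch=False`` (default) pools the expectation over all epochs x
    tapers; ``per_epoch=True`` computes wPLI within each epoch and returns
    the grand average across epochs.
    """
    if not per_epoch:
        cs = multitaper_cross_spectra(epochs, band, n_tapers, nw, band_name)
        return wpli(cs, n_epochs_used=epochs.n_epochs)
    mats = []
    for e in range(epochs.n_epochs):
        sub = EpochSet(
            epochs=epochs.epochs[e : e + 1],
            fs=epochs.fs,
            epoch_length=epochs.epoch_length,
            band=epochs.band,
        )
        cs = multitaper_cross_spectra(sub, band, n_tapers, nw, band_name)
        mats.append(wpli(cs, n_epochs_used=1))
    return grand_average(mats)


def grand_average(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of per-epoch connectivity matrices."""
    if not matrices:
        raise ValueError("no matrices to average")
    shapes = {m.values.shape for m in matrices}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch across matrices: {shapes}")
    mean = np.mean([m.values for m in matrices], axis=0)
    return ConnectivityMatrix(
        values=mean,
        band=matrices[0].band,
        n_epochs_used=sum(m.n_epochs_used for m in matrices),
    )


def nodal_strength(matrix: ConnectivityMatrix) -> np.ndarray:
    """Weighted degree: row sums of the (nonthresholded) weighted matrix."""
    v = matrix.values
    if not np.allclose(v, v.T, atol=1e-8):
        raise ValueError("nodal strength requires a symmetric matrix")
    return v.sum(axis=1)
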