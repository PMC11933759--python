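"""Multitaper power spectral density estimation and relative power.

The PSD estimator follows the classic multitaper recipe: each epoch is
windowed with K orthonormal DPSS (Slepian) tapers of time-bandwidth
product NW, the K eigenspectra are averaged (plain average, matching the
Chronux default), and the per-epoch estimates are averaged over kept
epochs. The one-sided density is scaled so that the trapezoidal integral
of the PSD over frequency recovers the signal variance (Parseval).

Relative power of a band is its integrated power divided by the
integrated power over the total analysis band (0.5–30 Hz by default, the
device's filter passband). Band integrals use the trapezoidal rule on
the closed-interval grid slice, so a band's value reflects its true
bandwidth and contiguous bands are exactly additive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.fft import rfft, rfftfreq
from scipy.signal.windows import dpss as _dpss

from .types import BandDefinition

DEFAULT_NW = 3.0
DEFAULT_K = 5
DEFAULT_TOTAL_BAND = (0.5, 30.0)


@dataclass
class PowerSpectrum:
    """One-sided PSD on a uniform ascending frequency grid (µV²/Hz)."""

    freqs: np.ndarray
    psd: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.freqs.shape != self.psd.shape or self.freqs.ndim != 1:
            raise ValueError("freqs and psd must be 1-D arrays of equal length")
        d = np.diff(self.freqs)
        if len(d) and not np.allclose(d, d[0], rtol=1e-9, atol=1e-12):
            raise ValueError("frequency grid must be uniform")
        if len(d) and d[0] <= 0:
            raise ValueError("frequency grid must be ascending")
        if np.any(self.psd < 0):
            raise ValueError("psd must be non-negative")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def band_slice(self, f_lo: float, f_hi: float) -> slice:
        """Index slice of grid points inside the closed interval [f_lo, f_hi].

        Edges are snapped to the grid within half a grid step, so 8.5 on a
        0.25 Hz grid is included exactly.
        """
        eps = 0.5 * self.df
        idx = np.nonzero((self.freqs >= f_lo - eps) & (self.freqs <= f_hi + eps))[0]
        if len(idx) < 2:
            raise ValueError(
                f"band [{f_lo}, {f_hi}] covers fewer than 2 grid points"
            )
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def band_power(self, f_lo: float, f_hi: float) -> float:
        """Trapezoidal integral of the PSD over [f_lo, f_hi] (µV²)."""
        s = self.band_slice(f_lo, f_hi)
        return float(np.trapezoid(self.psd[s], self.freqs[s]))


def dpss_tapers(
    n_samples: int, nw: float = DEFAULT_NW, k: int = DEFAULT_K
) -> tuple[np.ndarray, np.ndarray]:
    """K unit-norm orthonormal Slepian tapers and their concentration ratios.

    The usable taper count is bounded by k <= 2*nw - 1; beyond that the
    concentration ratios collapse and eigenspectra are dominated by
    out-of-band leakage.
    """
    if k > 2 * nw - 1:
        raise ValueError(f"k={k} exceeds 2*nw-1={2 * nw - 1:g} for nw={nw:g}")
    if n_samples <= k:
        raise ValueError("need more samples than tapers")
    tapers, ratios = _dpss(n_samples, nw, Kmax=k, return_ratios=True)
    return tapers, ratios


def multitaper_psd(
    epochs: np.ndarray,
    fs: float,
    nw: float = DEFAULT_NW,
    k: int = DEFAULT_K,
    meta: dict | None = None,
) -> PowerSpectrum:
    """Multitaper PSD averaged over tapers then over epochs.

    Parameters
    ----------
    epochs : array, shape (n_epochs, n_samples)
        Kept epochs of one channel, in µV. Each epoch is de-meaned before
        tapering.
    fs : float
        Sampling rate in Hz.
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    if epochs.shape[0] < 1:
        raise ValueError("need at least one kept epoch")
    n = epochs.shape[1]
    tapers, _ = dpss_tapers(n, nw, k)
    x = epochs - epochs.mean(axis=1, keepdims=True)
    # (n_epochs, k, n) tapered series; rfft along time
    tapered = x[:, None, :] * tapers[None, :, :]
    spec = rfft(tapered, axis=-1)
    eig = (np.abs(spec) ** 2) / fs  # two-sided density per taper
    psd = eig.mean(axis=(0, 1))
    psd[1:] *= 2.0  # one-sided; DC not doubled
    if n % 2 == 0:
        psd[-1] /= 2.0  # Nyquist bin is not duplicated either
    freqs = rfftfreq(n, 1.0 / fs)
    m = dict(meta or {})
    m.update(n_epochs=epochs.shape[0], nw=nw, k=k, fs=fs)
    return PowerSpectrum(freqs=freqs, psd=psd, meta=m)


def average_channels(ps_a: PowerSpectrum, ps_b: PowerSpectrum) -> PowerSpectrum:
    """Pointwise mean of two spectra on identical grids ("FP-mean")."""
    if ps_a.freqs.shape != ps_b.freqs.shape or not np.array_equal(
        ps_a.freqs, ps_b.freqs
    ):
        raise ValueError("frequency grids differ; cannot average channels")
    meta = dict(ps_a.meta)
    meta["channel"] = "FP-mean"
    return PowerSpectrum(
        freqs=ps_a.freqs.copy(), psd=0.5 * (ps_a.psd + ps_b.psd), meta=meta
    )


def relative_power(
    ps: PowerSpectrum,
    band: BandDefinition | tuple[float, float],
    total_band: tuple[float, float] = DEFAULT_TOTAL_BAND,
) -> float:
    """Band power as a fraction of total power over the analysis band."""
    if isinstance(band, BandDefinition):
        f_lo, f_hi = band.f_lo, band.f_hi
    else:
        f_lo, f_hi = band
    if f_lo < total_band[0] - 1e-9 or f_hi > total_band[1] + 1e-9:
        raise ValueError(f"band [{f_lo}, {f_hi}] not inside total band {total_band}")
    total = ps.band_power(*total_band)
    if total <= 0:
        raise ValueError("total power is zero; relative power undefined")
    return ps.band_power(f_lo, f_hi) / total


def relative_power_spectrum(
    ps: PowerSpectrum,
    bin_range: tuple[float, float] = (5.0, 30.0),
    total_band: tuple[float, float] = DEFAULT_TOTAL_BAND,
    bin_width: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Relative power in contiguous closed bins tiling ``bin_range``.

    Returns (bin_centers, fractions). Because band integrals are
    trapezoidal, adjacent closed bins share only half of each edge point
    and the bins sum exactly to the relative power of the whole range.
    """
    lo, hi = bin_range
    n_bins = int(round((hi - lo) / bin_width))
    if abs(lo + n_bins * bin_width - hi) > 1e-9:
        raise ValueError("bin_width must tile the bin range exactly")
    edges = lo + bin_width * np.arange(n_bins + 1)
    total = ps.band_power(*total_band)
    if total <= 0:
        raise ValueError("total power is zero")
    fractions = np.array(
        [ps.band_power(edges[i], edges[i + 1]) / total for i in range(n_bins)]
    )
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, fractions


def scale(ps: PowerSpectrum, factor: float) -> PowerSpectrum:
    """Return the spectrum scaled by a non-negative factor."""
    if factor < 0:
        raise ValueError("scale factor must be non-negative")
    return replace(ps, psd=ps.psd * factor, freqs=ps.freqs.copy())
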