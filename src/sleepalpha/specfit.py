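"""Aperiodic / periodic decomposition of power spectra.

The broadband background of an EEG spectrum is modeled by the
knee-plus-offset 1/f-like curve

    psd(f) = offset + scale / (knee + f**exponent)

with all four parameters constrained non-negative. The periodic
component is defined as the signed residual raw − aperiodic in linear
power units, so raw = aperiodic + periodic holds identically on the grid
and band powers of the components add up to the raw band power when a
shared raw-total denominator is used.

Fitting is nonlinear least squares on log10 power with iterative
masking of positive-residual outliers (oscillatory peaks), so the
background curve threads under the alpha bump rather than through it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .spectral import PowerSpectrum
from .types import BandDefinition

# The background is fit over 3-24 Hz: both edges of the analyzed 0.5-30 Hz
# range are shaped by the acquisition/offline bandpass roll-off, which the
# knee model cannot follow; fitting inside the flat passband keeps the
# curve unbiased through the alpha region. The curve is still evaluated on
# the full grid for the decomposition.
DEFAULT_FIT_RANGE = (3.0, 24.0)


@dataclass
class AperiodicFit:
    """Fitted background parameters and fit diagnostics."""

    offset: float      # a: constant floor, µV²/Hz
    scale: float       # b: numerator scale, µV²/Hz · Hz^exponent
    knee: float        # c: knee constant, Hz^exponent
    exponent: float    # d: high-frequency log-log slope magnitude
    fit_range: tuple[float, float]
    rmse_log: float
    converged: bool
    n_masked: int = 0

    def curve(self, freqs: np.ndarray) -> np.ndarray:
        return aperiodic_model(np.asarray(freqs, dtype=float),
                               self.offset, self.scale, self.knee, self.exponent)

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.offset, self.scale, self.knee, self.exponent)


@dataclass
class SpectralDecomposition:
    """Raw spectrum split into aperiodic curve and signed periodic residual."""

    freqs: np.ndarray
    raw: np.ndarray
    aperiodic: np.ndarray
    periodic: np.ndarray
    fit: AperiodicFit

    def __post_init__(self) -> None:
        if not (self.freqs.shape == self.raw.shape == self.aperiodic.shape
                == self.periodic.shape):
            raise ValueError("component arrays must share the grid shape")


def aperiodic_model(
    f: np.ndarray, offset: float, scale: float, knee: float, exponent: float
) -> np.ndarray:
    # overflow to inf during optimizer exploration is benign: the residual
    # becomes large and the step is rejected
    with np.errstate(over="ignore"):
        return offset + scale / (knee + np.power(f, exponent))


def _initial_guesses(f: np.ndarray, p: np.ndarray) -> list[np.ndarray]:
    """Three deterministic log-space starts spanning shallow to steep slopes."""
    p_lo = max(float(np.median(p[: max(3, len(p) // 10)])), 1e-12)
    p_hi = max(float(np.median(p[-max(3, len(p) // 10):])), 1e-12)
    f_hi = f[-1]
    guesses = []
    for d0 in (1.0, 2.0, 3.0):
        b0 = p_hi * f_hi**d0
        c0 = max(f[0] ** d0, b0 / p_lo - f[0] ** d0, 1e-6)
        a0 = 0.5 * p_hi
        guesses.append(np.log(np.array([a0, b0, c0, d0])))
    return guesses


def fit_aperiodic(
    ps: PowerSpectrum,
    fit_range: tuple[float, float] = DEFAULT_FIT_RANGE,
    robust_iters: int = 2,
    mad_factor: float = 2.5,
) -> AperiodicFit:
    """Fit the 1/f-like background over ``fit_range``.

    The solve is Levenberg-Marquardt on log10 power with all four
    parameters log-transformed (hence positive by construction). Three
    deterministic initializations are tried and the best RMSE kept;
    after each robust iteration, grid points lying more than
    ``mad_factor`` times the residual MAD *above* the curve are masked
    as oscillatory peaks and the winner is refit on the remainder.
    """
    s = ps.band_slice(*fit_range)
    f = ps.freqs[s]
    p = ps.psd[s]
    if np.any(p <= 0):
        raise ValueError("psd must be strictly positive on the fit range")
    logp = np.log10(p)

    def resid(theta: np.ndarray, mask: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore"):
            params = np.exp(theta)
        model = aperiodic_model(f[mask], *params)
        return np.log10(model) - logp[mask]

    def solve(theta0: np.ndarray, mask: np.ndarray):
        try:
            sol = least_squares(resid, theta0, args=(mask,), method="lm",
                                xtol=1e-6, ftol=1e-6, max_nfev=600)
        except Exception:
            return None
        if not (sol.success and np.all(np.isfinite(sol.x))):
            return None
        return sol

    mask = np.ones(len(f), dtype=bool)
    best = None
    for x0 in _initial_guesses(f, p):
        sol = solve(x0, mask)
        if sol is not None and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        return AperiodicFit(np.nan, np.nan, np.nan, np.nan, fit_range,
                            np.inf, converged=False)
    theta = best.x
    for _ in range(robust_iters):
        r_all = np.log10(aperiodic_model(f, *np.exp(theta))) - logp
        mad = np.median(np.abs(r_all - np.median(r_all)))
        # model − data convention: oscillatory peaks sit below the curve
        new_mask = ~(-r_all > mad_factor * max(mad, 1e-12))
        if new_mask.sum() < 8 or np.array_equal(new_mask, mask):
            break
        mask = new_mask
        sol = solve(theta, mask)
        if sol is None:
            break
        theta = sol.x
    a, b, c, d = np.exp(theta)
    rmse = float(np.sqrt(np.mean(resid(theta, mask) ** 2)))
    return AperiodicFit(
        offset=float(a), scale=float(b), knee=float(c), exponent=float(d),
        fit_range=fit_range, rmse_log=rmse, converged=True,
        n_masked=int((~mask).sum()),
    )


def decompose(ps: PowerSpectrum, fit: AperiodicFit) -> SpectralDecomposition:
    """Split the spectrum into aperiodic curve and signed periodic residual."""
    if not fit.converged:
        raise ValueError("cannot decompose with a non-converged aperiodic fit")
    ap = fit.curve(ps.freqs)
    return SpectralDecomposition(
        freqs=ps.freqs.copy(), raw=ps.psd.copy(), aperiodic=ap,
        periodic=ps.psd - ap, fit=fit,
    )


def component_band_power(
    dec: SpectralDecomposition,
    band: BandDefinition | tuple[float, float],
    total_band: tuple[float, float] = (0.5, 30.0),
) -> dict[str, float]:
    """Relative band power of raw/aperiodic/periodic with a shared denominator.

    All three components are normalized by the RAW total power over
    ``total_band`` so that raw = aperiodic + periodic exactly; the
    periodic value may be negative where the background overshoots.
    """
    if isinstance(band, BandDefinition):
        f_lo, f_hi = band.f_lo, band.f_hi
    else:
        f_lo, f_hi = band
    raw_ps = PowerSpectrum(freqs=dec.freqs, psd=dec.raw)
    total = raw_ps.band_power(*total_band)
    if total <= 0:
        raise ValueError("zero raw total power")
    s = raw_ps.band_slice(f_lo, f_hi)
    out = {}
    for name, arr in (("raw", dec.raw), ("aperiodic", dec.aperiodic),
                      ("periodic", dec.periodic)):
        out[name] = float(np.trapezoid(arr[s], dec.freqs[s])) / total
    return out
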