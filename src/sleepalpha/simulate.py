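"""Synthetic longitudinal cohort generator.

Generates everything the analysis consumes — participation pattern,
latent sleep-quality traits, PSQI questionnaires, and resting-state
prefrontal EEG — with the statistical structure the pipeline is meant
to recover:

* each participant carries a standardized poor-sleep propensity (the
  latent trait); PSQI components are ordinal discretizations of a noisy
  copy of the month-level trait state;
* every recording is colored noise whose one-sided PSD is a 1/f-like
  background (offset + scale/(knee + f^exponent)) plus Gaussian
  oscillatory bumps; the main alpha bump (~10 Hz) is stronger with eyes
  closed (Berger effect) and the low-alpha bump (~7.75 Hz) amplitude is
  a lognormal map of a latent variable correlated rho with the trait;
* the aperiodic background has no systematic open/closed difference —
  its parameters fluctuate recording-to-recording (arousal drift) but
  are drawn from the same distribution in both conditions, so the
  condition contrast lives entirely in the periodic bumps.

Two generation modes: ``timeseries`` (default) synthesizes 3-minute
512 Hz two-channel signals via frequency-domain amplitude shaping of
seeded Gaussian noise; ``spectrum`` draws multitaper-like PSD estimates
directly (target PSD smoothed by the taper bandwidth, times Gamma noise
with the estimator's equivalent averaging count), which is orders of
magnitude faster for calibration and replicate loops.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.fft import irfft, rfftfreq
from scipy.signal import butter, sosfreqz

from .design import MONTHS, CohortDesign, default_design
from .spectral import PowerSpectrum, relative_power
from .types import CONDITIONS, LOW_ALPHA, PSQIRecord, Recording

# ---------------------------------------------------------------------------
# signal specification


@dataclass(frozen=True)
class AperiodicParams:
    """Parameters of the 1/f-like background offset + scale/(knee + f^exponent)."""

    offset: float
    scale: float
    knee: float
    exponent: float

    def curve(self, freqs: np.ndarray) -> np.ndarray:
        f = np.asarray(freqs, dtype=float)
        return self.offset + self.scale / (self.knee + np.power(f, self.exponent))


@dataclass(frozen=True)
class SpectralPeak:
    """Gaussian bump in the PSD: amplitude µV²/Hz at the peak, sd in Hz."""

    center_hz: float
    amplitude: float
    bandwidth_hz: float

    def curve(self, freqs: np.ndarray) -> np.ndarray:
        f = np.asarray(freqs, dtype=float)
        return self.amplitude * np.exp(
            -0.5 * ((f - self.center_hz) / self.bandwidth_hz) ** 2
        )

    @property
    def integrated_power(self) -> float:
        return self.amplitude * self.bandwidth_hz * np.sqrt(2 * np.pi)


@dataclass
class SignalSpec:
    """Target spectral content of one synthetic recording channel."""

    fs: float = 512.0
    duration: float = 180.0
    aperiodic: AperiodicParams = AperiodicParams(0.05, 400.0, 20.0, 2.0)
    oscillations: tuple[SpectralPeak, ...] = ()
    condition: str = "closed"

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        for pk in self.oscillations:
            if pk.amplitude < 0:
                raise ValueError("bump amplitudes must be >= 0")
            if not 0.5 < pk.center_hz < 30.0:
                raise ValueError("bump centers must lie inside (0.5, 30) Hz")

    filter_passes: int = 1

    def target_psd(self, freqs: np.ndarray, filter_passes: int | None = None) -> np.ndarray:
        """Expected one-sided PSD, including the acquisition bandpass.

        ``filter_passes`` counts 4th-order Butterworth passes shaping the
        spectrum: 0 is the bare model (useful for parameter-recovery
        checks), 1 emulates the device's causal 0.5–30 Hz filter, and 3
        additionally folds in the offline zero-phase (forward-backward)
        filter applied by preprocessing. Defaults to the spec's own
        ``filter_passes`` field.
        """
        if filter_passes is None:
            filter_passes = self.filter_passes
        f = np.asarray(freqs, dtype=float)
        p = self.aperiodic.curve(f)
        for pk in self.oscillations:
            p = p + pk.curve(f)
        if np.any(p <= 0):
            raise ValueError("target PSD must be strictly positive")
        if filter_passes == 0:
            return p
        return p * bandpass_gain(f, self.fs, passes=filter_passes)


def bandpass_gain(
    freqs: np.ndarray, fs: float, f_lo: float = 0.5, f_hi: float = 30.0,
    passes: int = 1, order: int = 4,
) -> np.ndarray:
    """PSD gain |H(f)|^(2·passes) of the 0.5–30 Hz Butterworth bandpass."""
    sos = butter(order, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    w = np.asarray(freqs, dtype=float) * 2 * np.pi / fs
    _, h = sosfreqz(sos, worN=w)
    return np.abs(h) ** (2 * passes)


def synthesize_eeg(spec: SignalSpec, seed) -> np.ndarray:
    """One channel of colored noise realizing the spec's target PSD (µV).

    Frequency-domain amplitude shaping: the rFFT coefficients of white
    Gaussian noise are scaled so the expected one-sided PSD equals the
    target, then inverted. Phases are uniformly random, so the signal is
    stationary Gaussian.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(spec.fs * spec.duration))
    freqs = rfftfreq(n, 1.0 / spec.fs)
    p = spec.target_psd(freqs)
    # E|X_k|^2 = P_k * fs * n / 2 for interior bins (one-sided density)
    scale = np.sqrt(p * spec.fs * n / 2.0)
    re = rng.standard_normal(len(freqs))
    im = rng.standard_normal(len(freqs))
    x = scale * (re + 1j * im) / np.sqrt(2.0)
    x[0] = np.sqrt(p[0] * spec.fs * n) * re[0]
    if n % 2 == 0:
        x[-1] = np.sqrt(p[-1] * spec.fs * n) * re[-1]
    return irfft(x, n=n)


# ---------------------------------------------------------------------------
# cohort-level parameters


@dataclass(frozen=True)
class CouplingParams:
    """Latent correlations linking low-alpha amplitude to the sleep trait,
    plus the Berger (eyes-closed alpha enhancement) amplitude ratio.

    The rho values are correlations between the standardized latent
    variable driving the low-alpha bump amplitude and the person-month
    sleep-trait state; the realized pipeline correlation is attenuated
    by PSQI discretization, lognormal amplitude mapping, spectral
    estimation noise and background variability, which is why the
    defaults (frozen from :func:`calibrate_coupling`) exceed the target
    observable correlations (0.45 closed, 0.26 open).
    """

    rho_closed: float = 0.731
    rho_open: float = 0.684
    berger_ratio: float = 5.5

    def __post_init__(self) -> None:
        for rho in (self.rho_closed, self.rho_open):
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"rho {rho} outside [-1, 1]")
        if self.berger_ratio <= 0:
            raise ValueError("berger_ratio must be positive")


@dataclass(frozen=True)
class CohortParams:
    """Generator constants: signal model, individual variability, PSQI model.

    Scales are chosen to resemble resting prefrontal EEG: ~120 µV² total
    power in 0.5–30 Hz, an alpha bump a few µV²/Hz tall with eyes
    closed, lognormal person/recording variability of moderate width,
    and a PSQI marginal centered near 7 with full 0–21 support.
    """

    fs: float = 512.0
    duration: float = 180.0
    epoch_length_s: float = 4.0
    nw: float = 3.0
    k_tapers: int = 5
    # background (aperiodic) base parameters and variability
    aperiodic: AperiodicParams = AperiodicParams(0.05, 400.0, 20.0, 2.0)
    exponent_sd_participant: float = 0.10
    exponent_sd_recording: float = 0.15
    scale_logsd_participant: float = 0.30
    scale_logsd_recording: float = 0.10
    # main alpha bump (Berger-reactive, trait-independent)
    alpha_center_mean: float = 9.8
    alpha_center_sd: float = 0.15
    alpha_bandwidth: float = 0.7
    alpha_amp_open: float = 0.5
    alpha_amp_logsd_participant: float = 0.18
    alpha_amp_logsd_recording: float = 0.30
    # low-alpha bump (trait-coupled)
    la_center_mean: float = 7.75
    la_center_sd: float = 0.15
    la_bandwidth: float = 0.5
    la_amp_closed: float = 1.0
    la_amp_open_ratio: float = 0.45
    la_amp_logsd: float = 0.7
    # latent trait dynamics and PSQI measurement model
    trait_month_jitter: float = 0.30
    psqi_loading: float = 0.75
    psqi_level_probs: tuple[float, ...] = (0.35, 0.40, 0.18, 0.07)


DEFAULT_PARAMS = CohortParams()
DEFAULT_COUPLING = CouplingParams()


@dataclass
class LatentTrait:
    """Standardized poor-sleep propensity and its per-month deviations."""

    participant_id: str
    trait: float
    monthly_jitter: dict[int, float] = field(default_factory=dict)

    def state(self, month: int, jitter_scale: float) -> float:
        """Standardized month-level sleep state."""
        e = self.monthly_jitter.get(month, 0.0)
        return (self.trait + jitter_scale * e) / np.sqrt(1.0 + jitter_scale**2)


@dataclass
class SyntheticCohort:
    """Everything the generator produced for one seed."""

    design: CohortDesign
    params: CohortParams
    coupling: CouplingParams
    seed: int
    mode: str
    psqi_records: list[PSQIRecord]
    recordings: list[Recording] = field(default_factory=list)
    spectra: dict[tuple[str, int, str], PowerSpectrum] = field(default_factory=dict)
    truth: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# seeded substreams


def _rng(master: int, *key: int) -> np.random.Generator:
    """Deterministic substream from a master seed and a stable integer key."""
    return np.random.default_rng(np.random.SeedSequence(int(master), spawn_key=key))


def _psqi_thresholds(level_probs: tuple[float, ...]) -> np.ndarray:
    cum = np.cumsum(level_probs)[:-1]
    return sps.norm.ppf(cum)


# ---------------------------------------------------------------------------
# PSQI generation


def generate_psqi(
    trait: LatentTrait, month: int, seed,
    params: CohortParams = DEFAULT_PARAMS,
) -> PSQIRecord:
    """Draw the 7 ordinal PSQI components from the month-level trait state.

    Each component discretizes loading·state + sqrt(1−loading²)·noise at
    fixed thresholds chosen so the marginal level probabilities match
    ``params.psqi_level_probs``; the expected total is strictly
    increasing in the trait.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not np.isfinite(trait.trait):
        raise ValueError("trait must be finite")
    s = trait.state(month, params.trait_month_jitter)
    lam = params.psqi_loading
    thresholds = _psqi_thresholds(params.psqi_level_probs)
    u = lam * s + np.sqrt(1 - lam**2) * rng.standard_normal(7)
    components = tuple(int(np.searchsorted(thresholds, ui)) for ui in u)
    return PSQIRecord(trait.participant_id, month, components)


# ---------------------------------------------------------------------------
# per-recording spectral content


def _participant_profile(params: CohortParams, master: int, pidx: int) -> dict:
    rng = _rng(master, pidx)
    return dict(
        trait=float(rng.standard_normal()),
        exponent_dev=float(rng.standard_normal() * params.exponent_sd_participant),
        log_scale_dev=float(rng.standard_normal() * params.scale_logsd_participant),
        alpha_center=float(
            params.alpha_center_mean + rng.standard_normal() * params.alpha_center_sd
        ),
        log_alpha_amp_dev=float(
            rng.standard_normal() * params.alpha_amp_logsd_participant
        ),
        la_center=float(
            params.la_center_mean + rng.standard_normal() * params.la_center_sd
        ),
    )


def _recording_spec(
    params: CohortParams, coupling: CouplingParams, profile: dict,
    v: float, condition: str, rng: np.random.Generator,
) -> SignalSpec:
    """SignalSpec for one recording given the latent low-alpha variable v."""
    ap = AperiodicParams(
        offset=params.aperiodic.offset,
        scale=params.aperiodic.scale
        * np.exp(profile["log_scale_dev"]
                 + rng.standard_normal() * params.scale_logsd_recording),
        knee=params.aperiodic.knee,
        exponent=max(
            0.3,
            params.aperiodic.exponent + profile["exponent_dev"]
            + rng.standard_normal() * params.exponent_sd_recording,
        ),
    )
    alpha_amp = (
        params.alpha_amp_open
        * (coupling.berger_ratio if condition == "closed" else 1.0)
        * np.exp(profile["log_alpha_amp_dev"]
                 + rng.standard_normal() * params.alpha_amp_logsd_recording)
    )
    la_base = params.la_amp_closed * (
        1.0 if condition == "closed" else params.la_amp_open_ratio
    )
    la_amp = la_base * np.exp(params.la_amp_logsd * v)
    peaks = (
        SpectralPeak(profile["alpha_center"], alpha_amp, params.alpha_bandwidth),
        SpectralPeak(profile["la_center"], la_amp, params.la_bandwidth),
    )
    return SignalSpec(
        fs=params.fs, duration=params.duration, aperiodic=ap,
        oscillations=peaks, condition=condition,
    )


# ---------------------------------------------------------------------------
# spectrum-level fast mode


def _analysis_grid(params: CohortParams) -> np.ndarray:
    n = int(round(params.epoch_length_s * params.fs))
    freqs = rfftfreq(n, 1.0 / params.fs)
    return freqs[freqs <= 35.0 + 1e-9]


def _taper_smooth(psd: np.ndarray, df: float, nw: float, epoch_length_s: float
                  ) -> np.ndarray:
    """Emulate the multitaper expectation: boxcar smoothing over ±NW/T."""
    half_width = nw / epoch_length_s
    half_bins = int(round(half_width / df))
    if half_bins < 1:
        return psd
    kernel = np.ones(2 * half_bins + 1) / (2 * half_bins + 1)
    padded = np.pad(psd, half_bins, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def simulate_psd_estimate(
    spec: SignalSpec, rng: np.random.Generator,
    params: CohortParams = DEFAULT_PARAMS, n_channels: int = 2,
) -> PowerSpectrum:
    """Draw a multitaper-PSD-like estimate directly from the target spectrum.

    The target (with the full acquisition + offline filter response) is
    smoothed over the taper bandwidth and multiplied by Gamma noise with
    shape equal to the estimator's averaging count: n_channels × k
    tapers × n epochs. The result mimics the FP-mean spectrum the full
    pipeline would produce from time series, minus the slow path.
    """
    freqs = _analysis_grid(params)
    target = spec.target_psd(freqs, filter_passes=3)
    df = float(freqs[1] - freqs[0])
    target = _taper_smooth(target, df, params.nw, params.epoch_length_s)
    n_epochs = int(params.duration // params.epoch_length_s)
    shape = n_channels * params.k_tapers * n_epochs
    noisy = target * rng.gamma(shape, 1.0 / shape, size=len(freqs))
    return PowerSpectrum(
        freqs=freqs, psd=noisy,
        meta=dict(channel="FP-mean", n_epochs=n_epochs, nw=params.nw,
                  k=params.k_tapers, fs=params.fs, mode="spectrum"),
    )


# ---------------------------------------------------------------------------
# full cohort


def generate_cohort(
    design: CohortDesign | None = None,
    coupling: CouplingParams | None = None,
    seed: int = 0,
    params: CohortParams | None = None,
    mode: str = "timeseries",
) -> SyntheticCohort:
    """Generate PSQI records and recordings (or PSD estimates) for the cohort.

    For every participant-month the generator draws one PSQI record and
    one eyes-open plus one eyes-closed recording. The low-alpha bump
    amplitude is exp(sigma·v) with v = rho·state + sqrt(1−rho²)·w, where
    ``state`` is the month-level sleep trait and w is a person-month
    oscillatory disturbance shared by the two conditions.
    """
    design = design or default_design()
    coupling = coupling or DEFAULT_COUPLING
    params = params or DEFAULT_PARAMS
    if mode not in ("timeseries", "spectrum"):
        raise ValueError("mode must be 'timeseries' or 'spectrum'")

    cohort = SyntheticCohort(
        design=design, params=params, coupling=coupling, seed=seed,
        mode=mode, psqi_records=[],
    )
    truth_rows = []
    pids = sorted(design.months_present)
    for pidx, pid in enumerate(pids):
        profile = _participant_profile(params, seed, pidx)
        trait = LatentTrait(pid, profile["trait"])
        for month in MONTHS:
            if month not in design.months_present[pid]:
                continue
            mrng = _rng(seed, pidx, month)
            trait.monthly_jitter[month] = float(mrng.standard_normal())
            state = trait.state(month, params.trait_month_jitter)
            w = float(mrng.standard_normal())
            cohort.psqi_records.append(generate_psqi(trait, month, mrng, params))
            row = dict(participant=pid, month=month, trait=trait.trait, state=state)
            for cidx, condition in enumerate(CONDITIONS):
                rho = coupling.rho_closed if condition == "closed" else coupling.rho_open
                v = rho * state + np.sqrt(1 - rho**2) * w
                rec_rng = _rng(seed, pidx, month, cidx)
                spec = _recording_spec(params, coupling, profile, v,
                                       condition, rec_rng)
                row[f"v_{condition}"] = v
                row[f"la_amp_{condition}"] = spec.oscillations[1].amplitude
                if mode == "timeseries":
                    samples = np.stack([
                        synthesize_eeg(spec, rec_rng) for _ in range(2)
                    ])
                    cohort.recordings.append(Recording(
                        participant_id=pid, month=month, condition=condition,
                        fs=params.fs, samples=samples,
                    ))
                else:
                    cohort.spectra[(pid, month, condition)] = (
                        simulate_psd_estimate(spec, rec_rng, params)
                    )
            truth_rows.append(row)
    cohort.truth = pd.DataFrame(truth_rows)
    return cohort


# ---------------------------------------------------------------------------
# coupling calibration


def realized_la_correlation(
    rho: float, condition: str, seeds: list[int],
    design: CohortDesign | None = None,
    params: CohortParams | None = None,
    coupling: CouplingParams | None = None,
) -> float:
    """Mean pooled Pearson r between low-alpha relative power and PSQI
    total over the given seeds, using spectrum-mode generation."""
    from .stats import pearson

    design = design or default_design()
    params = params or DEFAULT_PARAMS
    base = coupling or DEFAULT_COUPLING
    kw = {"rho_closed": rho} if condition == "closed" else {"rho_open": rho}
    coup = dataclasses.replace(base, **kw)
    rs = []
    for s in seeds:
        cohort = generate_cohort(design, coup, seed=s, params=params,
                                 mode="spectrum")
        psqi = {(r.participant_id, r.month): r.total for r in cohort.psqi_records}
        x, y = [], []
        for (pid, month, cond), ps in cohort.spectra.items():
            if cond != condition:
                continue
            x.append(relative_power(ps, LOW_ALPHA))
            y.append(psqi[(pid, month)])
        rs.append(pearson(x, y).r)
    return float(np.mean(rs))


def calibrate_coupling(
    target_r: float, condition: str, tol: float = 0.02, seed: int = 0,
    n_seeds: int = 20, max_iter: int = 30,
    design: CohortDesign | None = None,
    params: CohortParams | None = None,
) -> float:
    """Find rho such that the pipeline-recovered pooled correlation between
    low-alpha relative power and PSQI matches ``target_r`` within ``tol``.

    Bisection on rho with common-random-number Monte-Carlo evaluation
    (the same generation seeds at every rho, so realized r is a smooth
    monotone function of rho). Raises if the target exceeds what the
    noise model can attain at rho ≈ 1, reporting the attainable bound.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    if not abs(target_r) < 1:
        raise ValueError("|target_r| must be < 1")
    seeds = [int(np.random.SeedSequence(seed, spawn_key=(i,)).generate_state(1)[0]
                 % 2**31) for i in range(n_seeds)]
    eval_r = lambda rho: realized_la_correlation(
        rho, condition, seeds, design=design, params=params)
    hi_sign = 1.0 if target_r >= 0 else -1.0
    bound = eval_r(hi_sign * 0.995)
    if hi_sign * bound < hi_sign * target_r - tol:
        raise ValueError(
            f"target r={target_r} unattainable under the noise model; "
            f"attainable bound at |rho|=0.995 is r={bound:.3f}"
        )
    lo, hi = 0.0, hi_sign * 0.995
    r_lo = eval_r(lo)
    if abs(r_lo - target_r) <= tol:
        return lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r_mid = eval_r(mid)
        if abs(r_mid - target_r) <= tol:
            return float(mid)
        if hi_sign * r_mid < hi_sign * target_r:
            lo = mid
        else:
            hi = mid
    return float(0.5 * (lo + hi))
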