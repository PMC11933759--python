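"""End-to-end orchestration: simulate/load → preprocess → spectra →
decompose → statistics → result bundle.

A run is fully described by a :class:`RunConfig` (validated against a
strict schema: unknown keys are rejected) plus a master seed, and is
deterministic given both. ``analyze`` mode consumes recordings and a
PSQI table from disk; ``simulate`` mode generates them with the
synthetic cohort generator, either as full time series or directly at
the spectrum level (fast mode, used for calibration and replicate
loops).
"""

from __future__ import annotations

import dataclasses
import logging
from itertools import combinations
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__
from .design import MONTHS, default_design
from .eeg_io import (ResultBundle, read_psqi_table, read_recording,
                     recording_filename, write_psqi_table, write_recording)
from .preprocess import bandpass, epoch, reject_artifacts
from .simulate import (CohortParams, CouplingParams, SyntheticCohort,
                       generate_cohort)
from .specfit import component_band_power, decompose, fit_aperiodic
from .spectral import (PowerSpectrum, average_channels, multitaper_psd,
                       relative_power, relative_power_spectrum)
from .stats import band_correlations, bonferroni, correlation_spectrum, paired_t
from .types import DEFAULT_BANDS, Recording

logger = logging.getLogger(__name__)


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FilterConfig(_Strict):
    f_lo: float = 0.5
    f_hi: float = 30.0


class EpochConfig(_Strict):
    length_s: float = 4.0


class ArtifactConfig(_Strict):
    amp_threshold_uv: float = 150.0
    z_threshold: float = 5.0


class TaperConfig(_Strict):
    nw: float = 3.0
    k: int = 5


class FitConfig(_Strict):
    f_lo: float = 3.0
    f_hi: float = 24.0
    robust_iters: int = 2


class CouplingConfig(_Strict):
    rho_closed: float | None = None
    rho_open: float | None = None
    berger_ratio: float | None = None


class CohortConfig(_Strict):
    """Optional overrides of the synthetic-cohort generator constants;
    unset fields keep the calibrated defaults."""

    fs: float | None = None
    duration: float | None = None
    aperiodic_offset: float | None = None
    aperiodic_scale: float | None = None
    aperiodic_knee: float | None = None
    aperiodic_exponent: float | None = None
    alpha_center_mean: float | None = None
    alpha_bandwidth: float | None = None
    alpha_amp_open: float | None = None
    la_center_mean: float | None = None
    la_bandwidth: float | None = None
    la_amp_closed: float | None = None
    la_amp_open_ratio: float | None = None
    la_amp_logsd: float | None = None
    trait_month_jitter: float | None = None
    psqi_loading: float | None = None


class PathsConfig(_Strict):
    recordings: str | None = None
    psqi: str | None = None
    out: str | None = None


class RunConfig(_Strict):
    """Schema-validated configuration of one pipeline run."""

    mode: Literal["simulate", "analyze"] = "simulate"
    generation: Literal["timeseries", "spectrum"] = "timeseries"
    seed: int = 0
    decompose: bool = True
    total_band: tuple[float, float] = (0.5, 30.0)
    corr_bins: tuple[float, float] = (5.0, 30.0)
    filter: FilterConfig = FilterConfig()
    epoch: EpochConfig = EpochConfig()
    artifact: ArtifactConfig = ArtifactConfig()
    taper: TaperConfig = TaperConfig()
    fit: FitConfig = FitConfig()
    coupling: CouplingConfig = CouplingConfig()
    cohort: CohortConfig = CohortConfig()
    paths: PathsConfig = PathsConfig()

    def coupling_params(self) -> CouplingParams:
        base = CouplingParams()
        overrides = {k: v for k, v in self.coupling.model_dump().items()
                     if v is not None}
        return dataclasses.replace(base, **overrides)

    def cohort_params(self) -> CohortParams:
        from .simulate import AperiodicParams
        base = CohortParams()
        overrides = {k: v for k, v in self.cohort.model_dump().items()
                     if v is not None}
        ap_keys = {k: overrides.pop(k) for k in list(overrides)
                   if k.startswith("aperiodic_")}
        if ap_keys:
            ap = dataclasses.replace(
                base.aperiodic,
                **{k.removeprefix("aperiodic_"): v for k, v in ap_keys.items()},
            )
            overrides["aperiodic"] = ap
        return dataclasses.replace(base, **overrides)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON config file into a validated RunConfig."""
    import json

    import yaml

    text = Path(path).read_text()
    data = (json.loads(text) if str(path).endswith(".json")
            else yaml.safe_load(text)) or {}
    return RunConfig(**data)


# ---------------------------------------------------------------------------
# stage helpers


def recording_spectrum(rec: Recording, config: RunConfig) -> PowerSpectrum:
    """Preprocess one recording and return its FP-mean multitaper spectrum."""
    filtered = bandpass(rec, config.filter.f_lo, config.filter.f_hi)
    eps = epoch(filtered, config.epoch.length_s)
    eps = reject_artifacts(eps, config.artifact.amp_threshold_uv,
                           config.artifact.z_threshold)
    per_channel = [
        multitaper_psd(eps.kept_epochs(ci), rec.fs, config.taper.nw,
                       config.taper.k,
                       meta=dict(recording=rec.key, channel=ch))
        for ci, ch in enumerate(rec.channels)
    ]
    ps = per_channel[0]
    for other in per_channel[1:]:
        ps = average_channels(ps, other)
    ps.meta.update(recording=rec.key, n_rejected=int((~eps.kept).sum()))
    return ps


def _band_power_rows(key: tuple[str, int, str], ps: PowerSpectrum,
                     config: RunConfig) -> tuple[list[dict], dict]:
    """Tidy band-power rows (per band × component) and the per-bin row."""
    pid, month, condition = key
    total_band = config.total_band
    rows = []
    if config.decompose:
        fit = fit_aperiodic(ps, (config.fit.f_lo, config.fit.f_hi),
                            config.fit.robust_iters)
        if not fit.converged:
            logger.warning("aperiodic fit failed for %s; skipping decomposition",
                           key)
        dec = decompose(ps, fit) if fit.converged else None
    else:
        dec = None
    for band in DEFAULT_BANDS:
        if dec is not None:
            comp = component_band_power(dec, band, total_band)
        else:
            comp = {"raw": relative_power(ps, band, total_band)}
        for component, value in comp.items():
            rows.append(dict(participant=pid, month=month, condition=condition,
                             band=band.name, component=component,
                             rel_power=value))
    centers, fractions = relative_power_spectrum(
        ps, config.corr_bins, total_band)
    bin_row = dict(participant=pid, month=month, condition=condition)
    bin_row.update({float(c): f for c, f in zip(centers, fractions)})
    return rows, bin_row


def _paired_test_tables(band_power: pd.DataFrame) -> pd.DataFrame:
    """Closed-vs-open paired t per month × band × component."""
    rows = []
    for (month, band, component), sub in band_power.groupby(
        ["month", "band", "component"]
    ):
        wide = sub.pivot(index="participant", columns="condition",
                         values="rel_power").dropna()
        if len(wide) < 2 or "closed" not in wide or "open" not in wide:
            continue
        res = paired_t(wide["closed"].to_numpy(), wide["open"].to_numpy())
        rows.append(dict(month=month, band=band, component=component,
                         n=res.n, t=res.t, df=res.df, p=res.p,
                         mean_diff=res.mean_diff))
    return pd.DataFrame(rows)


def _crossmonth_tables(band_power: pd.DataFrame) -> pd.DataFrame:
    """Month-vs-month paired t on overlapping participants, Bonferroni m=3."""
    rows = []
    raw = band_power[band_power["component"] == "raw"]
    for (condition, band), sub in raw.groupby(["condition", "band"]):
        wide = sub.pivot(index="participant", columns="month",
                         values="rel_power")
        cell = []
        for m1, m2 in combinations(MONTHS, 2):
            if m1 not in wide.columns or m2 not in wide.columns:
                continue
            both = wide[[m1, m2]].dropna()
            if len(both) < 2:
                continue
            res = paired_t(both[m1].to_numpy(), both[m2].to_numpy())
            cell.append(dict(condition=condition, band=band,
                             months=f"{m1}v{m2}", n=res.n, t=res.t, p=res.p))
        if cell:
            p_adj = bonferroni([c["p"] for c in cell], m=3)
            for c, pa in zip(cell, p_adj):
                c["p_adj"] = float(pa)
            rows.extend(cell)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the run


def run(config: RunConfig) -> ResultBundle:
    """Execute all pipeline stages and return the result bundle."""
    if config.mode == "simulate":
        cohort = generate_cohort(
            coupling=config.coupling_params(), seed=config.seed,
            params=config.cohort_params(), mode=config.generation,
        )
        psqi_records = cohort.psqi_records
        if config.generation == "spectrum":
            spectra = dict(cohort.spectra)
        else:
            spectra = {rec.key: recording_spectrum(rec, config)
                       for rec in cohort.recordings}
    else:
        spectra, psqi_records = _load_inputs(config)
    logger.info("stage spectra: %d recordings", len(spectra))

    band_rows: list[dict] = []
    bin_rows: list[dict] = []
    for key in sorted(spectra):
        rows, bin_row = _band_power_rows(key, spectra[key], config)
        band_rows.extend(rows)
        bin_rows.append(bin_row)
    band_power = pd.DataFrame(band_rows)
    bin_powers = pd.DataFrame(bin_rows)
    logger.info("stage band power: %d rows", len(band_power))

    psqi_totals = pd.Series(
        {(r.participant_id, r.month): r.total for r in psqi_records}
    )
    design = default_design()
    complete = design.complete_participants

    corr_spec = correlation_spectrum(bin_powers, psqi_totals)
    band_corr = band_correlations(band_power, psqi_totals,
                                  complete_participants=complete)
    paired = _paired_test_tables(band_power)
    crossmonth = _crossmonth_tables(band_power)

    bundle = ResultBundle(
        band_power=band_power, band_correlations=band_corr,
        correlation_spectrum=corr_spec, paired_tests=paired,
        crossmonth_tests=crossmonth,
        metadata=dict(seed=config.seed, config=config.model_dump(),
                      version=__version__, n_recordings=len(spectra),
                      n_psqi=len(psqi_records)),
    )
    bundle.validate()
    return bundle


def _load_inputs(config: RunConfig):
    rec_dir = config.paths.recordings
    psqi_path = config.paths.psqi
    if not rec_dir or not psqi_path:
        raise ValueError("analyze mode requires paths.recordings and paths.psqi")
    rec_dir = Path(rec_dir)
    files = sorted(rec_dir.glob("*.edf")) + sorted(rec_dir.glob("*.csv"))
    if not files:
        raise FileNotFoundError(f"no recordings found in {rec_dir}")
    spectra = {}
    for f in files:
        rec = read_recording(f)
        spectra[rec.key] = recording_spectrum(rec, config)
    psqi_records = read_psqi_table(psqi_path)
    keys = {(k[0], k[1]) for k in spectra}
    have = {(r.participant_id, r.month) for r in psqi_records}
    missing = keys - have
    if missing:
        raise ValueError(f"recordings without PSQI rows: {sorted(missing)[:5]}")
    return spectra, psqi_records


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path,
                 fmt: str = "edf") -> None:
    """Write a simulated cohort's recordings and PSQI table to disk."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in cohort.recordings:
        write_recording(rec, out_dir / recording_filename(rec, fmt))
    write_psqi_table(cohort.psqi_records, out_dir / "psqi.tsv")


# ---------------------------------------------------------------------------
# replicate summaries


HEADLINE_BANDS = ("LA", "MA", "HA")


def headline_stats(bundle: ResultBundle) -> dict[str, float]:
    """Flatten one run's headline statistics into a name → value dict."""
    out: dict[str, float] = {}
    bc = bundle.band_correlations
    sel = bc[(bc["subset"] == "all") & (bc["grouping"] == "pooled")
             & (bc["component"] == "raw")]
    for _, row in sel.iterrows():
        out[f"r_pooled_{row['condition']}_{row['band']}"] = row["r"]
        out[f"p_pooled_{row['condition']}_{row['band']}"] = row["p"]
    for _, row in bundle.paired_tests.iterrows():
        if row["band"] == "alpha":
            out[f"berger_p_m{row['month']}_{row['component']}"] = row["p"]
            out[f"berger_t_m{row['month']}_{row['component']}"] = row["t"]
    return out


def replicate_summary(config: RunConfig, n_replicates: int,
                      seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Re-run simulate mode with derived seeds; summarize headline stats.

    Returns (summary, per_replicate): the summary holds mean and SD of
    every headline statistic across replicates.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rows = []
    for i in range(n_replicates):
        rep_seed = int(np.random.SeedSequence(seed, spawn_key=(i,))
                       .generate_state(1)[0] % 2**31)
        cfg = config.model_copy(update={"seed": rep_seed})
        stats = headline_stats(run(cfg))
        stats["replicate"] = i
        stats["seed"] = rep_seed
        rows.append(stats)
    per_rep = pd.DataFrame(rows)
    value_cols = [c for c in per_rep.columns if c not in ("replicate", "seed")]
    summary = pd.DataFrame({
        "statistic": value_cols,
        "mean": [per_rep[c].mean() for c in value_cols],
        "sd": [per_rep[c].std(ddof=1) if n_replicates > 1 else 0.0
               for c in value_cols],
        "median": [per_rep[c].median() for c in value_cols],
    })
    return summary, per_rep
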