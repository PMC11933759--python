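"""Synthetic cohort generator: PSQI model, EEG synthesis, coupling."""

import dataclasses

import numpy as np
import pytest

from sleepalpha.design import default_design
from sleepalpha.simulate import (AperiodicParams, CohortParams, CouplingParams,
                                 LatentTrait, SignalSpec, SpectralPeak,
                                 calibrate_coupling, generate_cohort,
                                 generate_psqi, realized_la_correlation,
                                 simulate_psd_estimate, synthesize_eeg)
from sleepalpha.spectral import multitaper_psd, relative_power
from sleepalpha.stats import pearson
from sleepalpha.types import ALPHA, LOW_ALPHA


class TestGeneratePSQI:
    def test_total_is_component_sum_and_in_range(self):
        trait = LatentTrait("P01", 0.3, {1: -0.2})
        rec = generate_psqi(trait, 1, seed=4)
        assert rec.total == sum(rec.components)
        assert 0 <= rec.total <= 21
        assert all(0 <= c <= 3 for c in rec.components)

    def test_deterministic_given_seed(self):
        trait = LatentTrait("P01", 1.1, {2: 0.5})
        assert generate_psqi(trait, 2, 77) == generate_psqi(trait, 2, 77)

    def test_very_poor_sleeper_scores_high(self):
        """trait z=+3 lands in the upper half of 0-21 almost surely."""
        trait = LatentTrait("P01", 3.0, {1: 0.0})
        totals = np.array([generate_psqi(trait, 1, s).total
                           for s in range(10_000)])
        assert (totals > 10.5).mean() > 0.95

    def test_expected_total_increases_with_trait(self):
        means = []
        for z in (-2.0, 0.0, 2.0):
            trait = LatentTrait("P", z, {1: 0.0})
            means.append(np.mean([generate_psqi(trait, 1, s).total
                                  for s in range(400)]))
        assert means[0] < means[1] < means[2]


class TestSynthesizeEEG:
    def test_length_and_determinism(self):
        spec = SignalSpec(duration=10.0)
        x1 = synthesize_eeg(spec, 3)
        x2 = synthesize_eeg(spec, 3)
        assert len(x1) == 5120
        assert np.array_equal(x1, x2)

    def test_psd_matches_target_within_five_percent(self):
        """Band-integrated PSD of the synthesis matches the spec curve."""
        spec = SignalSpec(
            duration=200.0,
            oscillations=(SpectralPeak(10.0, 2.0, 0.8),),
        )
        epochs = []
        for s in range(4):  # 4 x 50 epochs = 200 averaged epochs
            x = synthesize_eeg(spec, s)
            epochs.append(x[: 50 * 2048].reshape(50, 2048))
        ps = multitaper_psd(np.concatenate(epochs), spec.fs)
        target = spec.target_psd(ps.freqs)
        for band in ((1.0, 5.0), (8.0, 13.0), (15.0, 28.0)):
            sel = (ps.freqs >= band[0]) & (ps.freqs <= band[1])
            got = np.trapezoid(ps.psd[sel], ps.freqs[sel])
            want = np.trapezoid(target[sel], ps.freqs[sel])
            assert got == pytest.approx(want, rel=0.05)

    def test_single_bump_peaks_near_its_center(self):
        # flat background so the bump is the only spectral maximum
        spec = SignalSpec(duration=60.0,
                          aperiodic=AperiodicParams(0.5, 0.0, 1.0, 1.0),
                          oscillations=(SpectralPeak(10.0, 5.0, 0.8),))
        x = synthesize_eeg(spec, 0)
        ps = multitaper_psd(x[: 14 * 2048].reshape(14, 2048), spec.fs)
        sel = (ps.freqs >= 5.0) & (ps.freqs <= 30.0)
        f_peak = ps.freqs[sel][np.argmax(ps.psd[sel])]
        assert abs(f_peak - 10.0) <= 0.5

    def test_loglog_slope_matches_exponent(self):
        """With a small knee the 15-30 Hz log-log slope approaches -d."""
        spec = SignalSpec(
            duration=400.0, filter_passes=0,
            aperiodic=AperiodicParams(0.0, 100.0, 0.5, 2.0),
        )
        x = synthesize_eeg(spec, 1)
        ps = multitaper_psd(x.reshape(100, 2048), spec.fs)
        sel = (ps.freqs >= 15.0) & (ps.freqs <= 30.0)
        slope = np.polyfit(np.log10(ps.freqs[sel]),
                           np.log10(ps.psd[sel]), 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.15)

    def test_bump_outside_band_rejected(self):
        with pytest.raises(ValueError, match="centers"):
            SignalSpec(oscillations=(SpectralPeak(40.0, 1.0, 1.0),))

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError, match="amplitude"):
            SignalSpec(oscillations=(SpectralPeak(10.0, -1.0, 1.0),))


class TestSpectrumMode:
    def test_estimate_unbiased_for_flat_target(self):
        spec = SignalSpec(aperiodic=AperiodicParams(1.0, 0.0, 1.0, 1.0))
        rng = np.random.default_rng(0)
        draws = np.stack([
            simulate_psd_estimate(spec, rng).psd for _ in range(200)
        ])
        target = spec.target_psd(
            simulate_psd_estimate(spec, rng).freqs, filter_passes=3)
        sel = slice(30, 100)  # passband interior
        assert np.allclose(draws.mean(axis=0)[sel], target[sel], rtol=0.02)


class TestGenerateCohort:
    def test_same_seed_bit_identical(self):
        c1 = generate_cohort(seed=9, mode="spectrum")
        c2 = generate_cohort(seed=9, mode="spectrum")
        assert [r.components for r in c1.psqi_records] == \
            [r.components for r in c2.psqi_records]
        for key in c1.spectra:
            assert np.array_equal(c1.spectra[key].psd, c2.spectra[key].psd)

    def test_psqi_and_recording_counts_match_design(self):
        c = generate_cohort(seed=0, mode="spectrum")
        assert len(c.psqi_records) == 92  # 27 + 25 + 40 participant-months
        assert len(c.spectra) == 184

    def test_berger_effect_every_month(self):
        """Group-mean closed-eye alpha relative power exceeds open-eye."""
        c = generate_cohort(seed=2, mode="spectrum")
        for month in (1, 2, 3):
            closed = [relative_power(ps, ALPHA)
                      for (p, m, cond), ps in c.spectra.items()
                      if m == month and cond == "closed"]
            opened = [relative_power(ps, ALPHA)
                      for (p, m, cond), ps in c.spectra.items()
                      if m == month and cond == "open"]
            assert np.mean(closed) > np.mean(opened)

    def test_null_coupling_gives_null_correlation(self):
        """rho=0 cohorts show |r| < 0.2 at n=92 in at least 95% of seeds."""
        coup = CouplingParams(rho_closed=0.0, rho_open=0.0)
        hits = 0
        n_seeds = 20
        for s in range(n_seeds):
            c = generate_cohort(coupling=coup, seed=1000 + s, mode="spectrum")
            psqi = {(r.participant_id, r.month): r.total
                    for r in c.psqi_records}
            x = [relative_power(ps, LOW_ALPHA)
                 for (p, m, cond), ps in c.spectra.items() if cond == "closed"]
            y = [psqi[(p, m)] for (p, m, cond) in c.spectra if cond == "closed"]
            if abs(pearson(x, y).r) < 0.2:
                hits += 1
        assert hits >= int(0.9 * n_seeds)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            CouplingParams(rho_closed=1.5)

    def test_timeseries_mode_produces_recordings(self):
        design = dataclasses.replace(default_design())
        small = type(design)({"P01": frozenset({1}), "P02": frozenset({1}),
                              "P03": frozenset({1})})
        params = dataclasses.replace(CohortParams(), duration=12.0)
        c = generate_cohort(design=small, seed=1, params=params)
        assert len(c.recordings) == 6
        rec = c.recordings[0]
        assert rec.samples.shape == (2, int(12.0 * 512))
        assert rec.fs == 512.0


class TestCalibration:
    def test_realized_correlation_monotone_in_rho(self):
        seeds = list(range(6))
        rs = [realized_la_correlation(rho, "closed", seeds)
              for rho in (0.0, 0.45, 0.9)]
        assert rs[0] < rs[1] < rs[2]

    def test_null_target_maps_to_null_rho(self):
        rho = calibrate_coupling(0.0, "closed", tol=0.05, seed=5, n_seeds=4)
        assert abs(rho) < 0.1

    def test_larger_target_needs_larger_rho(self):
        rho_small = calibrate_coupling(0.2, "closed", tol=0.04, seed=5,
                                       n_seeds=4)
        rho_large = calibrate_coupling(0.4, "closed", tol=0.04, seed=5,
                                       n_seeds=4)
        assert rho_large > rho_small

    def test_unattainable_target_reports_bound(self):
        with pytest.raises(ValueError, match="attainable"):
            calibrate_coupling(0.97, "closed", tol=0.01, seed=5, n_seeds=3)
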