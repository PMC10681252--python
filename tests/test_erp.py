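"""ERP averaging, component scoring and reaction-time summaries."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from totonou import (CohortDesign, ErpShapeParams, EventMarker,
                     InsufficientDataError, ParameterError,
                     analyze_oddball_session, average_erp, cohort_erp_table,
                     cohort_rt_table, component_area, component_peak, epoch,
                     erp_result, generate_stimulus_sequence, mixed_anova,
                     rt_summary, simulate_cohort, simulate_oddball_recording,
                     simple_main_effects)
from totonou.preprocess import EpochSet

NOISELESS = dict(background_noise_sd_uv=0.0, blink_rate_per_min=0.0)


def _epochset(arrs, kept=None):
    arrs = np.asarray(arrs, dtype=float)
    n = arrs.shape[0]
    return EpochSet(
        epochs=arrs, times_ms=np.arange(arrs.shape[-1]) * 2.0 - 100.0,
        condition="standard", channel_labels=("Fz",), rate_hz=500.0,
        kept=np.ones(n, dtype=bool) if kept is None else np.asarray(kept),
        rejection_reason=[None] * n)


class TestAverage:
    def test_pointwise_mean(self):
        es = _epochset([np.full((1, 350), 1.0), np.full((1, 350), 3.0)])
        np.testing.assert_allclose(average_erp(es), 2.0)

    def test_only_kept_epochs_enter_average(self):
        es = _epochset([np.full((1, 350), 1.0), np.full((1, 350), 99.0)],
                       kept=[True, False])
        np.testing.assert_allclose(average_erp(es), 1.0)

    def test_zero_kept_epochs_error(self):
        es = _epochset([np.zeros((1, 350))], kept=[False])
        with pytest.raises(InsufficientDataError, match="no usable epochs"):
            average_erp(es)

    def test_noise_average_shrinks_as_sqrt_n(self, rng):
        n = 40
        es = _epochset(rng.normal(size=(n, 1, 350)))
        single_rms = np.sqrt(np.mean(es.epochs[0] ** 2))
        avg_rms = np.sqrt(np.mean(average_erp(es) ** 2))
        assert avg_rms == pytest.approx(single_rms / np.sqrt(n), rel=0.35)


class TestComponentArea:
    times = np.arange(-100.0, 600.0, 2.0)

    def test_zero_waveform_zero_areas(self):
        w = np.zeros_like(self.times)
        assert component_area(self.times, w, (100, 250), "negative") == 0.0
        assert component_area(self.times, w, (240, 400), "positive") == 0.0

    def test_gaussian_area_matches_closed_form(self):
        sigma = 20.0
        w = -5.0 * np.exp(-0.5 * ((self.times - 175.0) / sigma) ** 2)
        area = component_area(self.times, w, (100, 250), "negative")
        assert area == pytest.approx(-5.0 * sigma * np.sqrt(2 * np.pi), rel=0.03)

    def test_positive_waveform_has_zero_mmn_area(self):
        w = np.full_like(self.times, 2.0)
        assert component_area(self.times, w, (100, 250), "negative") == 0.0
        assert component_area(self.times, w, (100, 250), "positive") > 0

    def test_window_outside_span_rejected(self):
        with pytest.raises(ParameterError, match="outside"):
            component_area(self.times, np.zeros_like(self.times),
                           (500, 900), "positive")

    def test_peak_reports_extremum_and_latency(self):
        w = -5.0 * np.exp(-0.5 * ((self.times - 180.0) / 20.0) ** 2)
        amp, lat = component_peak(self.times, w, (100, 250), "negative")
        assert amp == pytest.approx(-5.0, abs=1e-6)
        assert lat == pytest.approx(180.0, abs=2.0)


class TestRecovery:
    def _session(self, shape, n_stim=60, seed=0):
        seq = generate_stimulus_sequence(n_stim, 0.2, 2, seed)
        return simulate_oddball_recording(seq, shape, seed=seed)

    def test_noiseless_latency_within_one_sample(self):
        rec, mk = self._session(ErpShapeParams(mmn_latency_ms=160.0, **NOISELESS))
        res = analyze_oddball_session(rec, mk)
        assert abs(res.mmn_peak_latency_ms["Cz"] - 160.0) <= 2.0

    def test_p300_area_monotone_in_amplitude(self):
        areas = []
        for amp in (2.0, 4.0, 6.0, 8.0):
            rec, mk = self._session(ErpShapeParams(p300_amplitude_uv=amp,
                                                   **NOISELESS))
            areas.append(analyze_oddball_session(rec, mk).p300_area["Cz"])
        assert np.all(np.diff(areas) > 0)

    def test_filtering_changes_noiseless_areas_under_5pct(self):
        rec, mk = self._session(ErpShapeParams(**NOISELESS))
        filtered = analyze_oddball_session(rec, mk)
        sets = epoch(rec, mk)
        raw = erp_result(sets["standard"], sets["target"])
        for ch in ("Fz", "Cz", "Pz"):
            assert filtered.mmn_area[ch] == pytest.approx(raw.mmn_area[ch],
                                                          rel=0.05)
            assert filtered.p300_area[ch] == pytest.approx(raw.p300_area[ch],
                                                           rel=0.05)

    def test_noisy_recovery_matches_clipped_noise_expectation(self):
        """At realistic noise the mean recovered MMN area matches the
        analytic expectation of the polarity-clipped estimator within
        2 SEM over 20 seeds.

        For residual difference-waveform noise ~ N(0, sigma), the
        expected clipped integrand is
        E[min(s + eps, 0)] = s * Phi(-s/sigma) - sigma * phi(s/sigma);
        sigma is estimated from the signal-free tail (>=450 ms) of the
        same difference waveforms.
        """
        shape = ErpShapeParams(mmn_amplitude_uv=-5.0, p300_amplitude_uv=6.0,
                               background_noise_sd_uv=8.0,
                               blink_rate_per_min=0.0)
        areas, tails = [], []
        for seed in range(20):
            seq = generate_stimulus_sequence(200, 0.2, 2, seed)
            rec, mk = simulate_oddball_recording(seq, shape, seed=seed)
            sets = epoch(rec, mk)  # unfiltered: noise marginals known
            res = erp_result(sets["standard"], sets["target"])
            areas.append(res.mmn_area["Cz"])
            t = res.times_ms
            tails.append(res.difference[1][t >= 450.0])
        sigma = np.concatenate(tails).std()
        t = np.arange(-100.0, 600.0, 2.0)
        w = shape.component_width_ms
        s = (shape.mmn_amplitude_uv * np.exp(-0.5 * ((t - 175.0) / w) ** 2)
             + shape.p300_amplitude_uv * np.exp(-0.5 * ((t - 320.0) / w) ** 2))
        expected_integrand = (s * sps.norm.cdf(-s / sigma)
                              - sigma * sps.norm.pdf(s / sigma))
        m = (t >= 100.0) & (t < 250.0)
        expected = np.trapezoid(expected_integrand[m], t[m])
        sem = np.std(areas, ddof=1) / np.sqrt(len(areas))
        assert abs(np.mean(areas) - expected) <= 2 * sem


class TestRtSummary:
    def test_mean_over_correct_responses(self):
        markers = [EventMarker(0, "target", 300.0, True),
                   EventMarker(800, "target", 500.0, True)]
        s = rt_summary(markers)
        assert s.mean_rt_ms == 400.0 and s.n_correct == 2

    def test_incorrect_responses_excluded(self):
        markers = [EventMarker(0, "target", 300.0, True),
                   EventMarker(800, "target", 900.0, False),
                   EventMarker(1200, "standard")]
        s = rt_summary(markers)
        assert s.mean_rt_ms == 300.0 and s.n_correct == 1

    def test_no_correct_responses_error(self):
        with pytest.raises(InsufficientDataError):
            rt_summary([EventMarker(0, "target", 500.0, False)])

    def test_rt_shift_recovered_across_seeds(self):
        """An additive -40 ms stage shift survives the lognormal draw."""
        diffs = []
        for seed in range(20):
            seq = generate_stimulus_sequence(60, 0.2, 2, seed)
            _, mk0 = simulate_oddball_recording(
                seq, ErpShapeParams(**NOISELESS), seed=seed)
            _, mk1 = simulate_oddball_recording(
                seq, ErpShapeParams(rt_shift_ms=-40.0, **NOISELESS), seed=seed)
            diffs.append(rt_summary(mk1).mean_rt_ms - rt_summary(mk0).mean_rt_ms)
        sem = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert np.mean(diffs) == pytest.approx(-40.0, abs=max(2 * sem, 1.0))


class TestCohortDirection:
    def test_sauna_only_stage_effects_detected(self):
        """Cohorts with MMN up / P300 down in the sauna group only show a
        significant stage simple main effect in the sauna group and none
        in control, in >=80% of replicate cohorts (scaled down to 10
        cohorts of 100-stimulus sessions)."""
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            cohort = simulate_cohort(
                CohortDesign(seed=5000 + rep, n_stimuli=100),
                modalities=("oddball",))
            table = cohort_erp_table(cohort.oddball_sessions())
            ok = True
            for col, direction in (("mmn_area", -1), ("p300_area", -1)):
                sub = table.groupby(["participant", "group", "stage"],
                                    as_index=False)[col].mean()
                res = mixed_anova(sub, value=col, within="stage")
                sme = simple_main_effects(res).set_index("group")
                cm = res.cell_means
                shift = cm.loc["sauna", "post3"] - cm.loc["sauna", "pre"]
                ok &= bool(sme.loc["sauna", "significant"])
                ok &= not bool(sme.loc["control", "significant"])
                ok &= direction * shift > 0
            hits += ok
        assert hits >= 0.8 * n_rep

    def test_rt_table_shape(self):
        cohort = simulate_cohort(
            CohortDesign(seed=1, n_per_group=1, n_stimuli=30),
            modalities=("oddball",))
        rt = cohort_rt_table(cohort.oddball_sessions())
        assert len(rt) == 4  # 2 participants x 2 stages
        assert set(rt["stage"]) == {"pre", "post3"}
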