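"""Synthetic-data generator: sequences, sessions, cohorts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from totonou import (BANDS, STAGES, CohortDesign, ErpShapeParams,
                     InsufficientDataError, ParameterError,
                     RestSpectrumParams, analyze_rest_session, band_powers,
                     epoch, estimate_iaf, generate_stimulus_sequence,
                     load_cohort, mixed_anova, pearson_change_correlation,
                     power_spectrum, reject_epochs, reject_segments, segment,
                     simulate_cohort, simulate_inear_rest,
                     simulate_oddball_recording)
from totonou.spectral import band_power_table
from totonou.synth import coupled_score_deltas


def sequence_is_valid(seq, n_total, n_targets, min_gap):
    """Independent brute-force constraint check."""
    if len(seq) != n_total or seq.count("target") != n_targets:
        return False
    positions = [i for i, s in enumerate(seq) if s == "target"]
    return all(b - a - 1 >= min_gap for a, b in zip(positions, positions[1:]))


def identity_design(seed, **kw):
    effects = {s: {b: 1.0 for b in BANDS} for s in STAGES}
    return CohortDesign(stage_effect=effects, seed=seed, **kw)


class TestStimulusSequence:
    def test_zero_fraction_gives_all_standards(self):
        assert generate_stimulus_sequence(10, 0.0, 2, 0) == ["standard"] * 10

    def test_infeasible_gap_rejected(self):
        with pytest.raises(ParameterError, match="infeasible"):
            generate_stimulus_sequence(8, 0.5, 5, 0)

    def test_deterministic_given_seed(self):
        a = generate_stimulus_sequence(100, 0.2, 2, seed=7)
        b = generate_stimulus_sequence(100, 0.2, 2, seed=7)
        assert a == b
        assert a != generate_stimulus_sequence(100, 0.2, 2, seed=8)

    def test_tight_sequence_valid_for_100_seeds(self):
        for seed in range(100):
            seq = generate_stimulus_sequence(8, 0.25, 2, seed)
            assert sequence_is_valid(seq, 8, 2, 2)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(n_total=st.integers(5, 60),
           target_fraction=st.floats(0.0, 0.35),
           min_gap=st.integers(0, 3),
           seed=st.integers(0, 10_000))
    def test_every_emitted_sequence_satisfies_constraint(
            self, n_total, target_fraction, min_gap, seed):
        n_targets = round(n_total * target_fraction)
        try:
            seq = generate_stimulus_sequence(n_total, target_fraction,
                                             min_gap, seed)
        except ParameterError:
            n_standards = n_total - n_targets
            assert n_standards < (n_targets - 1) * min_gap
            return
        assert sequence_is_valid(seq, n_total, n_targets, min_gap)


NOISELESS = dict(background_noise_sd_uv=0.0, blink_rate_per_min=0.0)


class TestOddballSimulation:
    def test_noiseless_difference_min_at_mmn_latency(self):
        shape = ErpShapeParams(mmn_amplitude_uv=-5.0, **NOISELESS)
        seq = generate_stimulus_sequence(60, 0.2, 2, 0)
        rec, markers = simulate_oddball_recording(seq, shape, seed=0)
        sets = epoch(rec, markers)
        diff = (sets["target"].epochs.mean(axis=0)
                - sets["standard"].epochs.mean(axis=0))[0]
        t_ms = sets["target"].times_ms
        assert diff.min() == pytest.approx(-5.0, rel=0.02)
        assert abs(t_ms[np.argmin(diff)] - shape.mmn_latency_ms) <= 2.0

    def test_markers_on_exact_onset_samples(self):
        seq = generate_stimulus_sequence(20, 0.2, 2, 1)
        _, markers = simulate_oddball_recording(
            seq, ErpShapeParams(**NOISELESS), rate_hz=500.0, soa_s=1.5, seed=0)
        assert [m.sample_index for m in markers] == [round(i * 1.5 * 500)
                                                    for i in range(20)]
        for m in markers:
            if m.kind == "target":
                assert m.response_time_ms > 0
                assert m.responded_correctly is not None

    def test_same_seed_bit_identical(self):
        seq = generate_stimulus_sequence(30, 0.2, 2, 0)
        shape = ErpShapeParams()
        a_rec, a_mk = simulate_oddball_recording(seq, shape, seed=3)
        b_rec, b_mk = simulate_oddball_recording(seq, shape, seed=3)
        np.testing.assert_array_equal(a_rec.samples, b_rec.samples)
        assert a_mk == b_mk

    def test_blinks_trip_epoch_rejection(self):
        shape = ErpShapeParams(background_noise_sd_uv=0.0,
                               blink_rate_per_min=30.0,
                               blink_amplitude_uv=120.0)
        seq = generate_stimulus_sequence(40, 0.2, 2, 0)
        rec, markers = simulate_oddball_recording(seq, shape, seed=2)
        sets = epoch(rec, markers)
        rejected = sum(reject_epochs(es).n_rejected for es in sets.values())
        assert rejected >= 1

    def test_component_width_mass_constraint_enforced(self):
        with pytest.raises(ParameterError, match="90"):
            ErpShapeParams(component_width_ms=60.0)


class TestInearSimulation:
    def test_pure_alpha_peak_recovers_iaf(self):
        params = RestSpectrumParams(
            iaf_hz=10.0,
            band_power_targets=dict.fromkeys(BANDS, 0.0) | {"upper_alpha": 5.0},
            background_rms_uv=0.0, alpha_peak_fraction=1.0,
            alpha_peak_am_depth=0.0, seed=0)
        rec = simulate_inear_rest(16.0, params, 600.0)
        spec = power_spectrum(segment(rec, 8.0))
        assert estimate_iaf(spec) == pytest.approx(10.0, abs=0.125)

    def test_doubled_theta_target_doubles_realised_power(self):
        base = {"theta": 40.0, "lower1_alpha": 20.0, "lower2_alpha": 25.0,
                "upper_alpha": 25.0, "beta": 10.0}
        ratios = []
        for seed in range(10):
            a = simulate_inear_rest(64.0, RestSpectrumParams(
                band_power_targets=dict(base), seed=seed), 600.0)
            doubled = dict(base, theta=80.0)
            b = simulate_inear_rest(64.0, RestSpectrumParams(
                band_power_targets=doubled, seed=1000 + seed), 600.0)
            pa = band_powers(analyze_rest_session(a), 10.0)
            pb = band_powers(analyze_rest_session(b), 10.0)
            ratios.append(pb[pb.band == "theta"].power.mean()
                          / pa[pa.band == "theta"].power.mean())
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.2)

    def test_artifacts_trip_segment_rejection(self):
        params = RestSpectrumParams(artifact_rate_per_min=4.0,
                                    artifact_amplitude_uv=150.0, seed=1)
        rec = simulate_inear_rest(32.0, params, 600.0)
        ss = reject_segments(segment(rec, 8.0), 100.0)
        assert 1 <= ss.n_rejected <= 4  # 2 scheduled bursts, each spans <=2 cuts
        clean = simulate_inear_rest(32.0, RestSpectrumParams(seed=1), 600.0)
        assert reject_segments(segment(clean, 8.0), 100.0).n_rejected == 0

    def test_short_duration_rejected(self):
        with pytest.raises(ParameterError, match="segment"):
            simulate_inear_rest(4.0, RestSpectrumParams(), 600.0)

    def test_band_keys_validated(self):
        with pytest.raises(ParameterError, match="band_power_targets"):
            RestSpectrumParams(band_power_targets={"theta": 1.0})


class TestCohort:
    def test_identical_seeds_identical_cohorts(self):
        kw = dict(n_per_group=1, inear_pre_duration_s=16.0,
                  inear_post_duration_s=8.0, n_stimuli=20)
        a = simulate_cohort(CohortDesign(seed=4, **kw))
        b = simulate_cohort(CohortDesign(seed=4, **kw))
        for pa, pb in zip(a.participants, b.participants):
            for stage in pa.inear:
                np.testing.assert_array_equal(pa.inear[stage].samples,
                                              pb.inear[stage].samples)
            for stage in pa.oddball:
                np.testing.assert_array_equal(pa.oddball[stage][0].samples,
                                              pb.oddball[stage][0].samples)
                assert pa.oddball[stage][1] == pb.oddball[stage][1]
        pd.testing.assert_frame_equal(a.scores, b.scores)

    def test_write_load_round_trip(self, tmp_path):
        design = CohortDesign(n_per_group=1, inear_pre_duration_s=16.0,
                              inear_post_duration_s=8.0, n_stimuli=20, seed=2)
        cohort = simulate_cohort(design, out_dir=tmp_path / "tree")
        back = load_cohort(tmp_path / "tree")
        assert back.design == design
        for p0, p1 in zip(cohort.participants, back.participants):
            assert (p0.participant_id, p0.group) == (p1.participant_id, p1.group)
            for stage in p0.inear:
                np.testing.assert_allclose(p1.inear[stage].samples,
                                           p0.inear[stage].samples, atol=1e-9)
            for stage in p0.oddball:
                assert p1.oddball[stage][1] == p0.oddball[stage][1]

    def test_single_participant_tree_valid_but_stats_refuse(self):
        cohort = simulate_cohort(
            identity_design(1, n_per_group=1, inear_pre_duration_s=16.0,
                            inear_post_duration_s=8.0),
            modalities=("inear",))
        table = band_power_table(cohort.inear_sessions())
        assert not table.empty
        sub = table[table.band == "theta"].groupby(
            ["participant", "group", "stage"], as_index=False)["power"].mean()
        with pytest.raises(InsufficientDataError, match="replication"):
            mixed_anova(sub, value="power", within="stage")

    def test_identity_effects_control_interaction_type1(self):
        """Under the null the group-by-set interaction fires at ~alpha."""
        n_sig = n_tests = 0
        for rep in range(12):
            cohort = simulate_cohort(
                identity_design(3000 + rep, inear_pre_duration_s=64.0,
                                inear_post_duration_s=32.0),
                modalities=("inear",))
            table = band_power_table(cohort.inear_sessions())
            for band in BANDS:
                sub = table[table.band == band].groupby(
                    ["participant", "group", "stage"],
                    as_index=False)["power"].mean()
                res = mixed_anova(sub, value="power", within="stage")
                n_tests += 1
                n_sig += res.p("interaction") < 0.05
        assert n_sig / n_tests <= 0.12

    def test_score_coupling_recovered(self):
        """Coupled score deltas correlate with the neural change vector at
        approximately the designed rho (small-sample attenuation included)."""
        rng = np.random.default_rng(0)
        rs = []
        for _ in range(200):
            z = rng.standard_normal(10)
            z = (z - z.mean()) / z.std()
            deltas = coupled_score_deltas(z, 0.8, rng)
            rs.append(np.corrcoef(z, deltas)[0, 1])
        assert 0.72 <= np.mean(rs) <= 0.85

    def test_cohort_theta_change_correlates_with_coupled_item(self):
        cohort = simulate_cohort(CohortDesign(seed=11), modalities=("inear", "scores"))
        table = band_power_table(cohort.inear_sessions())
        theta = table[(table.band == "theta") & (table.group == "sauna")]
        by = theta.groupby(["participant", "stage"])["power"].mean().unstack()
        neural = by["post3"] - by["pre"]
        sc = cohort.scores
        sauna_ids = set(neural.index)
        changes = {}
        for item in ("Q2", "Q4", "Q14"):
            s = sc[(sc.item_id == item)
                   & (sc.participant_id.isin(sauna_ids))]
            wide = s.pivot(index="participant_id", columns="stage",
                           values="score")
            changes[item] = wide["post3"] - wide["pre"]
        res = pearson_change_correlation(neural, pd.DataFrame(changes))
        assert (res["r"] > 0.35).all()
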