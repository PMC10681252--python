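"""Synthetic oddball sessions and in-ear rest recordings.

The generator produces data with the statistical structure the analysis
stages assume, so the whole pipeline is testable without any download:

* **Oddball sessions** — a pseudo-random standard/target sequence (≥2
  standards between targets), 1.5 s onset asynchrony; target epochs
  carry a negative Gaussian MMN deflection and a positive Gaussian P300
  deflection on the scalp channels; background is an equal-power mix of
  pink (1/f) and white noise; blinks are 300 ms half-sine transients on
  the EOG channel bleeding 20 % into the scalp channels; reaction times
  are log-normal (median 400 ms) plus a per-stage additive shift.
* **In-ear rest** — two channels (L, R) whose spectrum is assembled from
  narrow-band filtered-noise oscillators, one per IAF-anchored band,
  each rescaled to a target absolute power (μV²), plus a sharp
  amplitude-modulated alpha peak exactly at the individual alpha
  frequency and a pink-noise background.  Short broadband bursts emulate
  muscle/movement artifacts that trip the ±100 μV rejection.
* **Cohorts** — per participant: one oddball session for pre and post3,
  in-ear rest for all four stages, and a questionnaire score table whose
  designated items are correlated with the participant's theta-power
  change.  The sauna group receives the stage effects; the control group
  receives identity effects plus the same within-subject jitter.

All simulation is deterministic given the seed(s).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal

from .core import (GROUPS, INEAR_CHANNELS, QUESTIONNAIRE_ITEMS,
                   SCALP_CHANNELS, STAGES, ContinuousRecording, EventMarker,
                   SessionLabel)
from .errors import InsufficientDataError, ParameterError
from .io import (read_markers, read_recording, read_table, write_markers,
                 write_recording, write_table)
from .spectral import BANDS, band_edges

# --------------------------------------------------------------------------
# parameter containers


@dataclass
class ErpShapeParams:
    """Shape of the injected oddball ERP components and background.

    Components are Gaussian deflections (``component_width_ms`` is the
    Gaussian sigma); the validator requires ≥90 % of each component's
    mass (±1.645 sigma) to lie inside its scoring window (100-250 ms for
    the MMN, 240-400 ms for the P300).
    """

    mmn_amplitude_uv: float = -4.0
    mmn_latency_ms: float = 175.0
    p300_amplitude_uv: float = 7.0
    p300_latency_ms: float = 320.0
    component_width_ms: float = 20.0
    background_noise_sd_uv: float = 8.0
    blink_rate_per_min: float = 2.0
    blink_amplitude_uv: float = 120.0
    rt_median_ms: float = 400.0
    rt_log_sd: float = 0.2
    rt_shift_ms: float = 0.0
    p_correct: float = 0.95

    def __post_init__(self):
        if self.mmn_amplitude_uv > 0:
            raise ParameterError("mmn_amplitude_uv must be <= 0")
        if self.p300_amplitude_uv < 0:
            raise ParameterError("p300_amplitude_uv must be >= 0")
        if not 100.0 <= self.mmn_latency_ms <= 250.0:
            raise ParameterError("mmn_latency_ms must lie in [100, 250]")
        if not 240.0 <= self.p300_latency_ms <= 400.0:
            raise ParameterError("p300_latency_ms must lie in [240, 400]")
        if not self.component_width_ms > 0:
            raise ParameterError("component_width_ms must be positive")
        half = 1.645 * self.component_width_ms  # 90 % central mass
        for lat, (lo, hi) in ((self.mmn_latency_ms, (100.0, 250.0)),
                              (self.p300_latency_ms, (240.0, 400.0))):
            if lat - half < lo or lat + half > hi:
                raise ParameterError(
                    "component too wide: less than 90 % of its mass lies "
                    "inside its scoring window"
                )
        for name in ("background_noise_sd_uv", "blink_rate_per_min",
                     "blink_amplitude_uv"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")


@dataclass
class RestSpectrumParams:
    """Spectral recipe for one in-ear rest recording.

    ``band_power_targets`` maps each of the five IAF-anchored bands to a
    target absolute power (μV²).  ``alpha_peak_fraction`` of the
    upper-alpha target is realised as a narrow amplitude-modulated peak
    exactly at ``iaf_hz`` (AM depth ``alpha_peak_am_depth``; depth 0
    gives a pure sinusoid), so the spectrum has a local maximum at the
    IAF; the peak's mass straddles the lower2/upper boundary, keeping
    each band's realised power proportional to its own target.
    """

    iaf_hz: float = 10.0
    band_power_targets: dict = field(default_factory=lambda: {
        "theta": 40.0, "lower1_alpha": 20.0, "lower2_alpha": 25.0,
        "upper_alpha": 25.0, "beta": 10.0})
    pink_noise_exponent: float = 1.0
    background_rms_uv: float = 1.5
    alpha_peak_fraction: float = 0.5
    alpha_peak_am_depth: float = 0.3
    artifact_rate_per_min: float = 0.0
    artifact_amplitude_uv: float = 150.0
    seed: int = 0

    def __post_init__(self):
        if set(self.band_power_targets) != set(BANDS):
            raise ParameterError(
                f"band_power_targets keys must be exactly {BANDS}"
            )
        if not 8.0 <= self.iaf_hz <= 13.0:
            raise ParameterError("iaf_hz must lie in [8, 13]")
        if any(v < 0 for v in self.band_power_targets.values()):
            raise ParameterError("band power targets must be non-negative")
        if not 0.0 <= self.alpha_peak_fraction <= 1.0:
            raise ParameterError("alpha_peak_fraction must lie in [0, 1]")


@dataclass
class ErpEffect:
    """Per-stage additive changes applied to the oddball simulation."""

    mmn_delta_uv: float = 0.0
    p300_delta_uv: float = 0.0
    rt_shift_ms: float = 0.0


def _identity_stage_effect():
    return {stage: {b: 1.0 for b in BANDS} for stage in STAGES}


#: Default band-power stage effects for the sauna group: theta and
#: lower-1 alpha rise from the first post set, lower-2 and upper alpha
#: from the second, beta stays flat.
DEFAULT_STAGE_EFFECT = {
    "pre": {b: 1.0 for b in BANDS},
    "post1": {"theta": 1.6, "lower1_alpha": 1.55, "lower2_alpha": 1.0,
              "upper_alpha": 1.0, "beta": 1.0},
    "post2": {"theta": 1.75, "lower1_alpha": 1.7, "lower2_alpha": 1.6,
              "upper_alpha": 1.55, "beta": 1.0},
    "post3": {"theta": 1.85, "lower1_alpha": 1.8, "lower2_alpha": 1.7,
              "upper_alpha": 1.65, "beta": 1.0},
}

#: Default ERP stage effects for the sauna group: after the third set the
#: MMN grows (more negative), the P300 shrinks and responses speed up.
DEFAULT_ERP_STAGE_EFFECT = {
    "pre": ErpEffect(),
    "post3": ErpEffect(mmn_delta_uv=-3.0, p300_delta_uv=-3.5,
                       rt_shift_ms=-40.0),
}

DEFAULT_BASE_BAND_POWER_UV2 = {
    "theta": 40.0, "lower1_alpha": 20.0, "lower2_alpha": 25.0,
    "upper_alpha": 25.0, "beta": 10.0}


@dataclass
class CohortDesign:
    """Full description of a simulated two-group cohort."""

    n_per_group: int = 10
    stage_effect: dict = field(
        default_factory=lambda: {s: dict(v) for s, v in
                                 DEFAULT_STAGE_EFFECT.items()})
    erp_stage_effect: dict = field(
        default_factory=lambda: dict(DEFAULT_ERP_STAGE_EFFECT))
    score_coupling: float = 0.77
    seed: int = 0
    coupled_items: tuple = ("Q2", "Q4", "Q14")
    n_stimuli: int = 200
    target_fraction: float = 0.2
    min_standards_between: int = 2
    soa_s: float = 1.5
    oddball_rate_hz: float = 500.0
    inear_rate_hz: float = 600.0
    inear_pre_duration_s: float = 128.0
    inear_post_duration_s: float = 48.0
    between_subject_sd_log: float = 0.3
    within_subject_sd_log: float = 0.12
    erp_amplitude_sd_uv: float = 0.4
    artifact_rate_per_min: float = 0.5
    erp_shape: ErpShapeParams = field(default_factory=ErpShapeParams)
    base_band_power_uv2: dict = field(
        default_factory=lambda: dict(DEFAULT_BASE_BAND_POWER_UV2))

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ParameterError("n_per_group must be positive")
        if set(self.stage_effect) != set(STAGES):
            raise ParameterError(f"stage_effect must cover stages {STAGES}")
        if any(abs(f - 1.0) > 1e-12 for f in self.stage_effect["pre"].values()):
            raise ParameterError("stage_effect['pre'] must be the identity (1.0)")


# --------------------------------------------------------------------------
# low-level signal builders


def _child_seed(*keys) -> int:
    """Deterministic 31-bit child seed from a key tuple."""
    ss = np.random.SeedSequence([int(k) for k in keys])
    return int(ss.generate_state(1)[0] % (2 ** 31 - 1))


def _pink_noise(n: int, rng, exponent: float = 1.0) -> np.ndarray:
    """Unit-variance 1/f^exponent noise via spectral shaping."""
    f = np.fft.rfftfreq(n)
    amp = np.zeros_like(f)
    amp[1:] = f[1:] ** (-exponent / 2.0)
    spec = amp * (rng.standard_normal(len(f)) + 1j * rng.standard_normal(len(f)))
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _narrowband_noise(n: int, rate: float, lo: float, hi: float, rng) -> np.ndarray:
    """Unit-variance band-limited noise (4th-order zero-phase Butterworth)."""
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _am_peak(n: int, rate: float, f0: float, rng, depth: float) -> np.ndarray:
    """Unit-variance sinusoid at ``f0`` with slow amplitude modulation.

    The modulation envelope is 0.1 Hz low-passed noise, so the spectral
    mass stays within a fraction of a hertz of ``f0``; depth 0 gives a
    pure sinusoid (deterministic apart from the phase).
    """
    t = np.arange(n) / rate
    phase = rng.uniform(0, 2 * np.pi)
    env = np.ones(n)
    if depth > 0:
        sos = signal.butter(2, 0.1, btype="lowpass", fs=rate, output="sos")
        e = signal.sosfiltfilt(sos, rng.standard_normal(n))
        sd = e.std()
        if sd > 0:
            env = 1.0 + depth * e / sd
    x = env * np.sin(2 * np.pi * f0 * t + phase)
    return x / x.std()


# --------------------------------------------------------------------------
# stimulus sequences and oddball sessions


def generate_stimulus_sequence(n_total: int, target_fraction: float,
                               min_standards_between: int = 2,
                               seed: int = 0) -> list:
    """Pseudo-random standard/target sequence under a gap constraint.

    Exactly ``round(n_total * target_fraction)`` targets are placed,
    uniformly at random over all arrangements in which every pair of
    consecutive targets is separated by at least
    ``min_standards_between`` standards.
    """
    if n_total < 1:
        raise ParameterError("n_total must be positive")
    if not 0.0 <= target_fraction < 1.0:
        raise ParameterError("target_fraction must lie in [0, 1)")
    if min_standards_between < 0:
        raise ParameterError("min_standards_between must be non-negative")
    n_targets = int(round(n_total * target_fraction))
    if n_targets == 0:
        return ["standard"] * n_total
    n_standards = n_total - n_targets
    interior = (n_targets - 1) * min_standards_between
    if n_standards < interior:
        raise ParameterError(
            f"infeasible constraint: {n_targets} targets need at least "
            f"{interior} standards between them but only {n_standards} exist"
        )
    free = n_standards - interior
    rng = np.random.default_rng(seed)
    # Stars-and-bars: drop the mandatory gaps, distribute the remaining
    # standards uniformly over the n_targets + 1 slots around the targets.
    slots = free + n_targets
    bars = np.sort(rng.choice(slots, size=n_targets, replace=False))
    parts = np.diff(np.concatenate(([-1], bars, [slots]))) - 1
    seq: list = []
    for i in range(n_targets):
        gap = parts[i] + (min_standards_between if i > 0 else 0)
        seq.extend(["standard"] * int(gap))
        seq.append("target")
    seq.extend(["standard"] * int(parts[-1]))
    assert len(seq) == n_total
    return seq


def simulate_oddball_recording(sequence, shape: ErpShapeParams,
                               rate_hz: float = 500.0, soa_s: float = 1.5,
                               seed: int = 0):
    """Simulate one oddball session.

    Returns ``(ContinuousRecording, markers)`` with channels
    Fz, Cz, Pz, EOG.  Target onsets receive the MMN and P300 Gaussian
    deflections on the scalp channels; markers land on exact onset
    samples; target markers carry simulated reaction times.
    """
    n_stim = len(sequence)
    if n_stim == 0:
        raise ParameterError("empty stimulus sequence")
    duration_s = n_stim * soa_s + 1.0
    n = int(round(duration_s * rate_hz))
    labels = SCALP_CHANNELS + ("EOG",)
    rng = np.random.default_rng(seed)

    data = np.zeros((len(labels), n))
    sd = shape.background_noise_sd_uv
    if sd > 0:
        for c in range(len(labels)):
            pink = _pink_noise(n, rng)
            white = rng.standard_normal(n)
            data[c] = sd * math.sqrt(0.5) * (pink + white)

    # ERP kernel over the post-stimulus span, added at every target onset.
    n_kernel = int(round(0.6 * rate_hz))
    t_ms = np.arange(n_kernel) / rate_hz * 1000.0
    w = shape.component_width_ms
    kernel = (shape.mmn_amplitude_uv
              * np.exp(-0.5 * ((t_ms - shape.mmn_latency_ms) / w) ** 2)
              + shape.p300_amplitude_uv
              * np.exp(-0.5 * ((t_ms - shape.p300_latency_ms) / w) ** 2))
    onsets = [int(round(i * soa_s * rate_hz)) for i in range(n_stim)]
    for i, kind in enumerate(sequence):
        if kind == "target":
            s = onsets[i]
            data[:3, s:s + n_kernel] += kernel[:n - s][None, :]

    # Blinks: 300 ms half-sine on EOG, 20 % bleed into scalp channels.
    n_blinks = int(round(shape.blink_rate_per_min * duration_s / 60.0))
    if n_blinks > 0 and shape.blink_amplitude_uv > 0:
        nb = int(round(0.3 * rate_hz))
        pulse = shape.blink_amplitude_uv * np.sin(np.pi * np.arange(nb) / nb)
        starts = np.sort(rng.uniform(0, duration_s - 0.35, n_blinks))
        for t0 in starts:
            s = int(round(t0 * rate_hz))
            data[3, s:s + nb] += pulse[:n - s]
            data[:3, s:s + nb] += 0.2 * pulse[:n - s][None, :]

    markers = []
    for i, kind in enumerate(sequence):
        if kind == "target":
            rt = float(np.exp(rng.normal(np.log(shape.rt_median_ms),
                                         shape.rt_log_sd)) + shape.rt_shift_ms)
            correct = bool(rng.random() < shape.p_correct)
            markers.append(EventMarker(onsets[i], "target",
                                       response_time_ms=max(rt, 1.0),
                                       responded_correctly=correct))
        else:
            markers.append(EventMarker(onsets[i], "standard"))

    rec = ContinuousRecording(samples=data, rate_hz=rate_hz,
                              channel_labels=labels)
    return rec, markers


# --------------------------------------------------------------------------
# in-ear rest


def simulate_inear_rest(duration_s: float, params: RestSpectrumParams,
                        rate_hz: float = 600.0,
                        min_duration_s: float = 8.0) -> ContinuousRecording:
    """Simulate a two-channel (L, R) in-ear rest recording."""
    if duration_s < min_duration_s:
        raise ParameterError(
            f"duration {duration_s} s is shorter than one analysis segment "
            f"({min_duration_s} s)"
        )
    n = int(round(duration_s * rate_hz))
    rng = np.random.default_rng(params.seed)
    edges = band_edges(params.iaf_hz)
    targets = params.band_power_targets

    # Artifact schedule is shared between channels (eye/muscle events are
    # not channel-specific).
    n_art = int(round(params.artifact_rate_per_min * duration_s / 60.0))
    art_starts = np.sort(rng.uniform(0, duration_s - 0.15, n_art)) if n_art else []

    frac = params.alpha_peak_fraction
    peak_power = frac * targets["upper_alpha"]

    chans = []
    for _ in INEAR_CHANNELS:
        x = np.zeros(n)
        if params.background_rms_uv > 0:
            x += params.background_rms_uv * _pink_noise(
                n, rng, params.pink_noise_exponent)
        for band in BANDS:
            p = targets[band]
            if band == "upper_alpha":
                p *= (1.0 - frac)
            if p > 0:
                lo, hi = edges[band]
                x += math.sqrt(p) * _narrowband_noise(n, rate_hz, lo, hi, rng)
        if peak_power > 0:
            x += math.sqrt(peak_power) * _am_peak(
                n, rate_hz, params.iaf_hz, rng, params.alpha_peak_am_depth)
        chans.append(x)

    if len(art_starts):
        nb = int(round(0.1 * rate_hz))
        pulse = params.artifact_amplitude_uv * np.hanning(nb)
        for t0 in art_starts:
            s = int(round(t0 * rate_hz))
            for x in chans:
                x[s:s + nb] += pulse[:n - s]

    return ContinuousRecording(samples=np.vstack(chans), rate_hz=rate_hz,
                               channel_labels=INEAR_CHANNELS)


# --------------------------------------------------------------------------
# cohorts


@dataclass
class ParticipantData:
    """All simulated sessions of one participant."""

    participant_id: str
    group: str
    iaf_hz: float
    inear: dict = field(default_factory=dict)    # stage -> recording
    oddball: dict = field(default_factory=dict)  # stage -> (recording, markers)


@dataclass
class Cohort:
    """A simulated two-group cohort plus its questionnaire scores."""

    participants: list
    scores: pd.DataFrame
    design: CohortDesign

    def inear_sessions(self):
        """Yield ``(SessionLabel, recording)`` for every rest recording."""
        for p in self.participants:
            for stage, rec in p.inear.items():
                yield SessionLabel(p.participant_id, p.group, stage), rec

    def oddball_sessions(self):
        """Yield ``(SessionLabel, recording, markers)`` per oddball run."""
        for p in self.participants:
            for stage, (rec, markers) in p.oddball.items():
                yield SessionLabel(p.participant_id, p.group, stage), rec, markers


def coupled_score_deltas(z, coupling: float, rng, scale: float = 20.0,
                         shift: float = 25.0) -> np.ndarray:
    """Score changes correlated with a standardised neural change vector.

    ``delta_i = shift + scale * (rho * z_i + sqrt(1 - rho^2) * eps_i)``
    with ``eps ~ N(0, 1)``, giving population correlation ``rho`` with
    ``z``.
    """
    z = np.asarray(z, dtype=float)
    eps = rng.standard_normal(len(z))
    return shift + scale * (coupling * z + np.sqrt(1 - coupling ** 2) * eps)


def _stage_fraction(stage: str) -> float:
    return {"pre": 0.0, "post1": 1 / 3, "post2": 2 / 3, "post3": 1.0}[stage]


def simulate_cohort(design: CohortDesign, out_dir=None,
                    modalities=("inear", "oddball", "scores")) -> Cohort:
    """Simulate a full cohort; optionally write the session tree to disk.

    The sauna group receives ``design.stage_effect`` band-power factors
    and ``design.erp_stage_effect`` ERP deltas; the control group
    receives identity effects.  Both groups share the same within- and
    between-subject variability.  Questionnaire scores for the
    designated items are generated with correlation
    ``design.score_coupling`` to each sauna participant's theta-power
    change (post3 - pre).
    """
    seed = design.seed
    participants = []
    theta_deltas: dict = {}

    for gi, group in enumerate(GROUPS):
        sauna = group == "sauna"
        prefix = "S" if sauna else "C"
        for i in range(design.n_per_group):
            pid = f"{prefix}{i + 1:02d}"
            prng = np.random.default_rng(np.random.SeedSequence([seed, gi, i]))
            iaf = float(prng.uniform(9.0, 11.0))
            base = {b: design.base_band_power_uv2[b]
                    * math.exp(prng.normal(0, design.between_subject_sd_log))
                    for b in BANDS}
            mults = {}
            for stage in STAGES:
                fac = design.stage_effect[stage] if sauna \
                    else {b: 1.0 for b in BANDS}
                mults[stage] = {
                    b: fac[b] * math.exp(
                        prng.normal(0, design.within_subject_sd_log))
                    for b in BANDS}
            theta_deltas[pid] = base["theta"] * (
                mults["post3"]["theta"] - mults["pre"]["theta"])
            mmn_jit = prng.normal(0, design.erp_amplitude_sd_uv)
            p300_jit = prng.normal(0, design.erp_amplitude_sd_uv)

            p = ParticipantData(participant_id=pid, group=group, iaf_hz=iaf)

            if "inear" in modalities:
                for si, stage in enumerate(STAGES):
                    dur = (design.inear_pre_duration_s if stage == "pre"
                           else design.inear_post_duration_s)
                    params = RestSpectrumParams(
                        iaf_hz=iaf,
                        band_power_targets={b: base[b] * mults[stage][b]
                                            for b in BANDS},
                        artifact_rate_per_min=design.artifact_rate_per_min,
                        seed=_child_seed(seed, gi, i, si, 11),
                    )
                    p.inear[stage] = simulate_inear_rest(
                        dur, params, design.inear_rate_hz)

            if "oddball" in modalities:
                for si, stage in enumerate(("pre", "post3")):
                    effect = (design.erp_stage_effect.get(stage, ErpEffect())
                              if sauna else ErpEffect())
                    shape = replace(
                        design.erp_shape,
                        mmn_amplitude_uv=min(
                            design.erp_shape.mmn_amplitude_uv + mmn_jit
                            + effect.mmn_delta_uv, 0.0),
                        p300_amplitude_uv=max(
                            design.erp_shape.p300_amplitude_uv + p300_jit
                            + effect.p300_delta_uv, 0.0),
                        rt_shift_ms=design.erp_shape.rt_shift_ms
                        + effect.rt_shift_ms,
                    )
                    seq = generate_stimulus_sequence(
                        design.n_stimuli, design.target_fraction,
                        design.min_standards_between,
                        seed=_child_seed(seed, gi, i, si, 13))
                    rec, markers = simulate_oddball_recording(
                        seq, shape, design.oddball_rate_hz, design.soa_s,
                        seed=_child_seed(seed, gi, i, si, 17))
                    p.oddball[stage] = (rec, markers)

            participants.append(p)

    scores = _generate_scores(participants, theta_deltas, design) \
        if "scores" in modalities else pd.DataFrame(
            columns=["participant_id", "stage", "item_id", "score"])

    cohort = Cohort(participants=participants, scores=scores, design=design)
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def _generate_scores(participants, theta_deltas, design: CohortDesign) -> pd.DataFrame:
    """VAS questionnaire scores; coupled items track theta change."""
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 999]))
    sauna_ids = [p.participant_id for p in participants if p.group == "sauna"]
    d = np.array([theta_deltas[pid] for pid in sauna_ids])
    sd = d.std()
    z = (d - d.mean()) / sd if sd > 0 else np.zeros_like(d)
    z_by_id = dict(zip(sauna_ids, z))

    # Draw the coupled deltas per item so each coupled item has its own
    # independent noise around the common neural signal.
    coupled_deltas = {
        item: dict(zip(sauna_ids, coupled_score_deltas(
            z, design.score_coupling, rng)))
        for item in design.coupled_items}

    rows = []
    for p in participants:
        for item in QUESTIONNAIRE_ITEMS:
            pre = float(np.clip(rng.normal(30.0, 10.0), 0, 100))
            if p.group == "sauna" and item in design.coupled_items:
                d3 = coupled_deltas[item][p.participant_id]
            elif p.group == "sauna":
                d3 = rng.normal(8.0, 10.0)
            else:
                d3 = rng.normal(0.0, 6.0)
            for stage in STAGES:
                val = pre + _stage_fraction(stage) * d3 + rng.normal(0, 3.0)
                rows.append({"participant_id": p.participant_id,
                             "stage": stage, "item_id": item,
                             "score": float(np.clip(val, 0, 100))})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# on-disk session trees


def design_to_dict(design: CohortDesign) -> dict:
    d = dataclasses.asdict(design)
    d["erp_stage_effect"] = {s: dataclasses.asdict(e)
                             for s, e in design.erp_stage_effect.items()}
    d["coupled_items"] = list(design.coupled_items)
    return d


def design_from_dict(d: dict) -> CohortDesign:
    d = dict(d)
    if "erp_shape" in d and isinstance(d["erp_shape"], dict):
        d["erp_shape"] = ErpShapeParams(**d["erp_shape"])
    if "erp_stage_effect" in d:
        d["erp_stage_effect"] = {s: (ErpEffect(**e) if isinstance(e, dict) else e)
                                 for s, e in d["erp_stage_effect"].items()}
    if "coupled_items" in d:
        d["coupled_items"] = tuple(d["coupled_items"])
    return CohortDesign(**d)


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write recordings, markers, scores and a manifest under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"design": design_to_dict(cohort.design), "participants": []}
    for p in cohort.participants:
        entry = {"id": p.participant_id, "group": p.group,
                 "iaf_hz_true": p.iaf_hz, "inear": {}, "oddball": {}}
        for stage, rec in p.inear.items():
            name = f"{p.participant_id}_inear_{stage}.tsv"
            write_recording(rec, out / name)
            entry["inear"][stage] = name
        for stage, (rec, markers) in p.oddball.items():
            name = f"{p.participant_id}_oddball_{stage}.tsv"
            write_recording(rec, out / name)
            write_markers(markers, out / (name + ".markers.tsv"))
            entry["oddball"][stage] = name
        manifest["participants"].append(entry)
    write_table(cohort.scores, out / "scores.tsv")
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))


def load_cohort(in_dir) -> Cohort:
    """Load a session tree written by :func:`write_cohort`."""
    root = Path(in_dir)
    manifest = yaml.safe_load((root / "manifest.yaml").read_text())
    design = design_from_dict(manifest["design"])
    participants = []
    for entry in manifest["participants"]:
        p = ParticipantData(participant_id=entry["id"], group=entry["group"],
                            iaf_hz=float(entry.get("iaf_hz_true", np.nan)))
        for stage, name in entry.get("inear", {}).items():
            p.inear[stage] = read_recording(root / name)
        for stage, name in entry.get("oddball", {}).items():
            rec = read_recording(root / name)
            markers = read_markers(root / (name + ".markers.tsv"))
            p.oddball[stage] = (rec, markers)
        participants.append(p)
    scores = read_table(root / "scores.tsv")
    return Cohort(participants=participants, scores=scores, design=design)
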