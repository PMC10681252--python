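"""Event-related potential quantification for the auditory oddball task.

The standard and target epochs are averaged per channel; the difference
waveform (target minus standard) carries the two components of interest:

* **MMN** — mismatch negativity, scored in the 100-250 ms window,
* **P300** — scored in the 240-400 ms window.

Both are quantified as *polarity-clipped trapezoidal areas* of the
difference waveform (μV·ms): the MMN area integrates ``min(x, 0)`` over
its window (hence ≤ 0), the P300 area integrates ``max(x, 0)`` (≥ 0).
The extremum amplitude within each window is reported alongside for
users who prefer a peak measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import EOG_CHANNEL, SCALP_CHANNELS
from .errors import InsufficientDataError, ParameterError
from .preprocess import (EPOCH_REJECT_UV, EpochSet, bandpass, epoch,
                         reject_epochs)

#: Scoring windows on the difference waveform, ms from stimulus onset,
#: half-open.
MMN_WINDOW_MS = (100.0, 250.0)
P300_WINDOW_MS = (240.0, 400.0)

#: Scalp-path band-pass cutoffs (Hz).
SCALP_FILTER_HZ = (0.1, 30.0)


@dataclass
class ErpResult:
    """Condition averages, difference waveform and component measures.

    ``difference`` is ``target_avg - standard_avg`` pointwise; all
    component measures are computed from the difference waveform only.
    Areas are μV·ms (MMN ≤ 0, P300 ≥ 0); peaks are the extremum
    amplitude (μV) and its latency (ms) within the scoring window.
    """

    times_ms: np.ndarray
    channel_labels: tuple
    standard_avg: np.ndarray  # (n_channels, n_times)
    target_avg: np.ndarray
    difference: np.ndarray
    n_epochs_used: dict
    mmn_area: dict
    p300_area: dict
    mmn_peak_uv: dict
    mmn_peak_latency_ms: dict
    p300_peak_uv: dict
    p300_peak_latency_ms: dict


@dataclass
class RtSummary:
    """Reaction-time summary over correct target responses only."""

    mean_rt_ms: float
    sd_rt_ms: float
    n_correct: int


def average_erp(epochs: EpochSet) -> np.ndarray:
    """Pointwise mean over *kept* epochs, shape ``(n_channels, n_times)``."""
    if epochs.n_kept == 0:
        raise InsufficientDataError(
            f"no usable epochs for condition {epochs.condition!r}"
        )
    return epochs.epochs[epochs.kept].mean(axis=0)


def component_area(times_ms, waveform, window_ms, polarity: str) -> float:
    """Polarity-clipped trapezoidal area (μV·ms) within a half-open window.

    For ``polarity="negative"`` the integrand is ``min(x, 0)``; for
    ``"positive"`` it is ``max(x, 0)``.
    """
    times_ms = np.asarray(times_ms, dtype=float)
    waveform = np.asarray(waveform, dtype=float)
    lo, hi = window_ms
    if lo < times_ms[0] or hi > times_ms[-1] + (times_ms[1] - times_ms[0]):
        raise ParameterError(
            f"window {window_ms} ms lies outside epoch span "
            f"[{times_ms[0]:.1f}, {times_ms[-1]:.1f}] ms"
        )
    mask = (times_ms >= lo) & (times_ms < hi)
    if polarity == "negative":
        clipped = np.minimum(waveform[mask], 0.0)
    elif polarity == "positive":
        clipped = np.maximum(waveform[mask], 0.0)
    else:
        raise ParameterError("polarity must be 'negative' or 'positive'")
    return float(np.trapezoid(clipped, times_ms[mask]))


def component_peak(times_ms, waveform, window_ms, polarity: str):
    """Extremum amplitude (μV) and its latency (ms) within the window."""
    times_ms = np.asarray(times_ms, dtype=float)
    waveform = np.asarray(waveform, dtype=float)
    lo, hi = window_ms
    mask = (times_ms >= lo) & (times_ms < hi)
    if not mask.any():
        raise ParameterError(f"window {window_ms} ms contains no samples")
    w = waveform[mask]
    t = times_ms[mask]
    i = int(np.argmin(w)) if polarity == "negative" else int(np.argmax(w))
    return float(w[i]), float(t[i])


def erp_result(standard: EpochSet, target: EpochSet) -> ErpResult:
    """Average both conditions and score MMN / P300 on the difference."""
    std_avg = average_erp(standard)
    tgt_avg = average_erp(target)
    diff = tgt_avg - std_avg
    times = target.times_ms
    labels = target.channel_labels
    mmn_area, p300_area = {}, {}
    mmn_pk, mmn_lat, p300_pk, p300_lat = {}, {}, {}, {}
    for i, ch in enumerate(labels):
        mmn_area[ch] = component_area(times, diff[i], MMN_WINDOW_MS, "negative")
        p300_area[ch] = component_area(times, diff[i], P300_WINDOW_MS, "positive")
        mmn_pk[ch], mmn_lat[ch] = component_peak(times, diff[i], MMN_WINDOW_MS, "negative")
        p300_pk[ch], p300_lat[ch] = component_peak(times, diff[i], P300_WINDOW_MS, "positive")
    return ErpResult(
        times_ms=times, channel_labels=labels,
        standard_avg=std_avg, target_avg=tgt_avg, difference=diff,
        n_epochs_used={"standard": standard.n_kept, "target": target.n_kept},
        mmn_area=mmn_area, p300_area=p300_area,
        mmn_peak_uv=mmn_pk, mmn_peak_latency_ms=mmn_lat,
        p300_peak_uv=p300_pk, p300_peak_latency_ms=p300_lat,
    )


def rt_summary(markers) -> RtSummary:
    """Mean/SD reaction time over correct target responses only."""
    rts = [m.response_time_ms for m in markers
           if m.kind == "target" and m.responded_correctly
           and m.response_time_ms is not None]
    if not rts:
        raise InsufficientDataError("no correct target responses")
    rts = np.asarray(rts, dtype=float)
    sd = float(rts.std(ddof=1)) if len(rts) > 1 else 0.0
    return RtSummary(mean_rt_ms=float(rts.mean()), sd_rt_ms=sd, n_correct=len(rts))


def analyze_oddball_session(recording, markers,
                            filter_hz=SCALP_FILTER_HZ,
                            reject_uv: float = EPOCH_REJECT_UV) -> ErpResult:
    """Full scalp pipeline for one session: filter, epoch, reject, score.

    EEG and EOG channels are all monitored for the ±50 μV rejection; all
    targets enter the ERP average (correctness only gates RT summaries).
    """
    filtered = bandpass(recording, *filter_hz)
    sets = epoch(filtered, markers)
    if "standard" not in sets or "target" not in sets:
        raise InsufficientDataError("session lacks standard or target markers")
    std = reject_epochs(sets["standard"], reject_uv)
    tgt = reject_epochs(sets["target"], reject_uv)
    return erp_result(std, tgt)


def cohort_erp_table(sessions) -> pd.DataFrame:
    """ERP measures for every oddball session of a cohort.

    ``sessions`` yields ``(SessionLabel, ContinuousRecording, markers)``.
    One output row per scalp channel with the area and peak measures plus
    epoch bookkeeping.
    """
    rows = []
    for label, rec, markers in sessions:
        res = analyze_oddball_session(rec, markers)
        for ch in res.channel_labels:
            if ch == EOG_CHANNEL or ch not in SCALP_CHANNELS:
                continue
            rows.append({
                "participant": label.participant_id,
                "group": label.group,
                "stage": label.stage,
                "channel": ch,
                "mmn_area": res.mmn_area[ch],
                "p300_area": res.p300_area[ch],
                "mmn_peak_uv": res.mmn_peak_uv[ch],
                "p300_peak_uv": res.p300_peak_uv[ch],
                "n_standard": res.n_epochs_used["standard"],
                "n_target": res.n_epochs_used["target"],
            })
    return pd.DataFrame(rows)


def cohort_rt_table(sessions) -> pd.DataFrame:
    """Reaction-time summary per oddball session of a cohort."""
    rows = []
    for label, _rec, markers in sessions:
        s = rt_summary(markers)
        rows.append({
            "participant": label.participant_id,
            "group": label.group,
            "stage": label.stage,
            "mean_rt_ms": s.mean_rt_ms,
            "sd_rt_ms": s.sd_rt_ms,
            "n_correct": s.n_correct,
        })
    return pd.DataFrame(rows)
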