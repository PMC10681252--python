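"""Filtering, epoching, fixed-length segmentation and artifact rejection.

Two preprocessing paths share this module:

* **scalp / oddball** — 0.1-30 Hz band pass, 700 ms epochs around each
  stimulus (100 ms pre-stimulus baseline), epochs rejected when any
  monitored channel (EEG or EOG) exceeds ±50 μV;
* **in-ear / rest** — 2-30 Hz band pass, non-overlapping fixed-length
  segments (8 s for band-power analysis, 4 s for decoding), segments
  rejected beyond ±100 μV.

Filters are 4th-order Butterworth applied forward-backward, i.e.
zero-phase, so ERP component latencies are not shifted.  Rejection never
mutates sample data: it only flips per-window keep flags and records a
reason, so bookkeeping (kept + rejected = total) always holds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import ContinuousRecording
from .errors import InsufficientDataError, ParameterError

#: Epoch window relative to stimulus onset (seconds, half-open).
EPOCH_WINDOW_S = (-0.100, 0.600)
#: Baseline interval whose mean is subtracted per channel (half-open).
BASELINE_S = (-0.100, 0.0)

EPOCH_REJECT_UV = 50.0
SEGMENT_REJECT_UV = 100.0

#: How the amplitude-threshold test is applied, recorded in output
#: metadata: thresholds are checked on post-filter, baseline-corrected
#: amplitudes.
REJECTION_CONVENTION = "post-filter, baseline-corrected amplitudes"


@dataclass
class EpochSet:
    """Fixed-window epochs of one stimulus condition.

    ``epochs`` has shape ``(n_epochs, n_channels, n_times)``; ``kept`` and
    ``rejection_reason`` run parallel to the first axis.  Markers too
    close to a recording edge never make it into the array; they are
    counted in ``n_edge_dropped``.
    """

    epochs: np.ndarray
    times_ms: np.ndarray
    condition: str
    channel_labels: tuple
    rate_hz: float
    kept: np.ndarray
    rejection_reason: list
    n_edge_dropped: int = 0
    markers: list = dataclasses.field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_kept(self) -> int:
        return int(np.sum(self.kept))

    @property
    def n_rejected(self) -> int:
        return self.n_epochs - self.n_kept


@dataclass
class SegmentSet:
    """Consecutive non-overlapping fixed-length windows of a recording."""

    segments: np.ndarray  # (n_segments, n_channels, n_times)
    segment_length_s: float
    channel_labels: tuple
    rate_hz: float
    kept: np.ndarray
    rejection_reason: list

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]

    @property
    def n_kept(self) -> int:
        return int(np.sum(self.kept))

    @property
    def n_rejected(self) -> int:
        return self.n_segments - self.n_kept


def bandpass(recording: ContinuousRecording, low_hz: float, high_hz: float,
             order: int = 4) -> ContinuousRecording:
    """Zero-phase Butterworth band pass (low pass when ``low_hz <= 0``)."""
    nyq = recording.rate_hz / 2.0
    if not (0 <= low_hz < high_hz < nyq):
        raise ParameterError(
            f"cutoffs must satisfy 0 <= low < high < Nyquist ({nyq} Hz); "
            f"got low={low_hz}, high={high_hz}"
        )
    if low_hz <= 0:
        sos = signal.butter(order, high_hz, btype="lowpass",
                            fs=recording.rate_hz, output="sos")
    else:
        sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                            fs=recording.rate_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, recording.samples, axis=1)
    return ContinuousRecording(
        samples=filtered,
        rate_hz=recording.rate_hz,
        channel_labels=recording.channel_labels,
        start_offset_s=recording.start_offset_s,
    )


def epoch(recording: ContinuousRecording, markers,
          tmin_s: float = EPOCH_WINDOW_S[0], tmax_s: float = EPOCH_WINDOW_S[1],
          baseline_s=BASELINE_S) -> dict:
    """Cut per-stimulus epochs, baseline-correct, and group by condition.

    Each epoch covers the half-open window ``[tmin_s, tmax_s)`` around
    its marker; the per-channel mean over ``baseline_s`` is subtracted.
    Markers whose window crosses a recording edge are dropped with reason
    ``"edge"`` and counted in the returned sets' ``n_edge_dropped``.

    Returns a dict condition -> :class:`EpochSet` (conditions present in
    ``markers`` only).
    """
    rate = recording.rate_hz
    n_t = int(round((tmax_s - tmin_s) * rate))
    off = int(round(tmin_s * rate))
    b0 = int(round((baseline_s[0] - tmin_s) * rate))
    b1 = int(round((baseline_s[1] - tmin_s) * rate))
    times_ms = (tmin_s + np.arange(n_t) / rate) * 1000.0

    by_cond: dict = {}
    edge_drops: dict = {}
    for m in markers:
        start = m.sample_index + off
        bucket = by_cond.setdefault(m.kind, [])
        if start < 0 or start + n_t > recording.n_samples:
            edge_drops[m.kind] = edge_drops.get(m.kind, 0) + 1
            continue
        cut = recording.samples[:, start:start + n_t].copy()
        cut -= cut[:, b0:b1].mean(axis=1, keepdims=True)
        bucket.append((cut, m))

    out = {}
    for cond, items in by_cond.items():
        if items:
            arr = np.stack([c for c, _ in items])
            mk = [m for _, m in items]
        else:
            arr = np.empty((0, recording.n_channels, n_t))
            mk = []
        out[cond] = EpochSet(
            epochs=arr,
            times_ms=times_ms,
            condition=cond,
            channel_labels=recording.channel_labels,
            rate_hz=rate,
            kept=np.ones(len(items), dtype=bool),
            rejection_reason=[None] * len(items),
            n_edge_dropped=edge_drops.get(cond, 0),
            markers=mk,
        )
    return out


def _apply_threshold(data, kept, reasons, threshold_uv, chan_idx):
    """Shared rejection core; returns new flags without touching data."""
    exceed = np.any(np.abs(data[:, chan_idx, :]) > threshold_uv, axis=(1, 2))
    new_kept = kept & ~exceed
    new_reasons = list(reasons)
    for i in np.nonzero(kept & exceed)[0]:
        new_reasons[i] = "amplitude"
    return new_kept, new_reasons


def _channel_indices(labels, channels):
    if channels is None:
        return np.arange(len(labels))
    idx = []
    for c in channels:
        if c not in labels:
            raise ParameterError(f"monitored channel {c!r} not in {labels}")
        idx.append(labels.index(c))
    return np.asarray(idx)


def reject_epochs(epochs: EpochSet, threshold_uv: float = EPOCH_REJECT_UV,
                  channels=None) -> EpochSet:
    """Flag epochs where any monitored channel exceeds ``±threshold_uv``.

    By default all channels (EEG and EOG) are monitored.  The sample data
    are shared with the input set; only ``kept``/``rejection_reason``
    change.
    """
    idx = _channel_indices(epochs.channel_labels, channels)
    kept, reasons = _apply_threshold(epochs.epochs, epochs.kept,
                                     epochs.rejection_reason, threshold_uv, idx)
    return dataclasses.replace(epochs, kept=kept, rejection_reason=reasons)


def segment(recording: ContinuousRecording, length_s: float) -> SegmentSet:
    """Cut the recording into consecutive non-overlapping windows.

    ``floor(duration / length_s)`` segments are produced; any trailing
    remainder is discarded.
    """
    if not length_s > 0:
        raise ParameterError("length_s must be positive")
    n_per = int(round(length_s * recording.rate_hz))
    n_seg = recording.n_samples // n_per
    if n_seg < 1:
        raise InsufficientDataError(
            f"recording of {recording.duration_s:.3f} s is shorter than one "
            f"{length_s} s segment"
        )
    data = recording.samples[:, :n_seg * n_per]
    segs = data.reshape(recording.n_channels, n_seg, n_per).transpose(1, 0, 2)
    return SegmentSet(
        segments=segs,
        segment_length_s=length_s,
        channel_labels=recording.channel_labels,
        rate_hz=recording.rate_hz,
        kept=np.ones(n_seg, dtype=bool),
        rejection_reason=[None] * n_seg,
    )


def reject_segments(segments: SegmentSet,
                    threshold_uv: float = SEGMENT_REJECT_UV,
                    channels=None) -> SegmentSet:
    """Flag segments where any monitored channel exceeds ``±threshold_uv``."""
    idx = _channel_indices(segments.channel_labels, channels)
    kept, reasons = _apply_threshold(segments.segments, segments.kept,
                                     segments.rejection_reason, threshold_uv, idx)
    return dataclasses.replace(segments, kept=kept, rejection_reason=reasons)
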