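"""Per-segment Fourier power, IAF estimation and IAF-anchored band power.

Rest in-ear EEG is cut into 8-s segments; each kept segment is turned
into a Hann-tapered periodogram (power per frequency bin, μV²,
normalised so the bin powers sum to the windowed mean square — i.e. a
Parseval-consistent "absolute power" scale).  The individual alpha
frequency (IAF) is the peak of the segment-and-channel-averaged spectrum
within 8-13 Hz of the *pre-sauna* data; the five analysis bands are
anchored to it:

====================  =======================
theta                 [IAF-6, IAF-4) Hz
lower-1 alpha         [IAF-4, IAF-2) Hz
lower-2 alpha         [IAF-2, IAF)   Hz
upper alpha           [IAF,  IAF+2)  Hz
beta                  [15, 30)       Hz
====================  =======================

Band intervals are half-open and lower-inclusive, so the four
IAF-anchored bands partition [IAF-6, IAF+2) with no gaps or overlaps.
"Gross absolute" band power is the *sum* of bin powers inside the band,
averaged across kept segments, reported per channel (L, R).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .errors import InsufficientDataError, ParameterError
from .preprocess import SegmentSet, bandpass, reject_segments, segment

BANDS = ("theta", "lower1_alpha", "lower2_alpha", "upper_alpha", "beta")

#: IAF search range (Hz, inclusive).
IAF_SEARCH_HZ = (8.0, 13.0)

#: In-ear path band-pass cutoffs (Hz).
INEAR_FILTER_HZ = (2.0, 30.0)

#: Segment length for band-power analysis (s) -> 0.125 Hz resolution.
SPECTRAL_SEGMENT_S = 8.0


def band_edges(iaf_hz: float) -> dict:
    """Half-open band intervals (Hz) anchored at an IAF."""
    if iaf_hz - 6.0 < 0:
        raise ParameterError(f"iaf_hz={iaf_hz} gives a negative theta edge")
    return {
        "theta": (iaf_hz - 6.0, iaf_hz - 4.0),
        "lower1_alpha": (iaf_hz - 4.0, iaf_hz - 2.0),
        "lower2_alpha": (iaf_hz - 2.0, iaf_hz),
        "upper_alpha": (iaf_hz, iaf_hz + 2.0),
        "beta": (15.0, 30.0),
    }


@dataclass
class PowerSpectrum:
    """Per-segment, per-channel power (μV² per frequency bin)."""

    freqs_hz: np.ndarray
    power: np.ndarray  # (n_segments, n_channels, n_freqs)
    resolution_hz: float
    channel_labels: tuple

    def mean_spectrum(self) -> np.ndarray:
        """Average over segments and channels -> (n_freqs,)."""
        return self.power.mean(axis=(0, 1))


def power_spectrum(segments: SegmentSet) -> PowerSpectrum:
    """Hann-tapered periodogram of every kept segment.

    Powers are per-bin μV² scaled so that their sum equals the
    (window-weighted) mean square of the segment, making band sums an
    absolute-power measure.
    """
    if segments.n_kept == 0:
        raise InsufficientDataError("no kept segments to transform")
    data = segments.segments[segments.kept]
    fs = segments.rate_hz
    freqs, pxx = signal.periodogram(data, fs=fs, window="hann",
                                    detrend=False, scaling="density", axis=-1)
    df = freqs[1] - freqs[0]
    return PowerSpectrum(
        freqs_hz=freqs,
        power=pxx * df,
        resolution_hz=float(df),
        channel_labels=segments.channel_labels,
    )


def estimate_iaf(spectra, search_lo: float = IAF_SEARCH_HZ[0],
                 search_hi: float = IAF_SEARCH_HZ[1]) -> float:
    """Individual alpha frequency from pre-stage spectra.

    ``spectra`` is one :class:`PowerSpectrum` or a sequence of them (all
    on the same frequency grid); the argmax of the segment-and-channel
    averaged power over ``[search_lo, search_hi]`` (inclusive) is
    returned on the spectrum's grid.  Ties break toward the lower
    frequency.
    """
    if isinstance(spectra, PowerSpectrum):
        spectra = [spectra]
    spectra = list(spectra)
    if not spectra:
        raise InsufficientDataError("no spectra supplied")
    freqs = spectra[0].freqs_hz
    for s in spectra[1:]:
        if len(s.freqs_hz) != len(freqs) or not np.allclose(s.freqs_hz, freqs):
            raise ParameterError("spectra lie on different frequency grids")
    mean = np.mean([s.mean_spectrum() for s in spectra], axis=0)
    mask = (freqs >= search_lo) & (freqs <= search_hi)
    if not mask.any():
        raise ParameterError(
            f"no frequency bins inside [{search_lo}, {search_hi}] Hz"
        )
    sub = mean[mask]
    return float(freqs[mask][int(np.argmax(sub))])  # argmax -> first/lowest


def band_powers(spectrum: PowerSpectrum, iaf_hz: float) -> pd.DataFrame:
    """Gross absolute power per band and channel.

    Bin powers are summed over each half-open band interval per segment,
    then averaged across segments.  Returns tidy rows
    ``(channel, band, power)``.
    """
    edges = band_edges(iaf_hz)
    freqs = spectrum.freqs_hz
    rows = []
    for band, (lo, hi) in edges.items():
        mask = (freqs >= lo) & (freqs < hi)
        if not mask.any():
            raise ParameterError(
                f"band {band} [{lo}, {hi}) Hz contains no frequency bins "
                f"at {spectrum.resolution_hz} Hz resolution"
            )
        per_seg = spectrum.power[:, :, mask].sum(axis=2)  # (n_seg, n_ch)
        mean_pow = per_seg.mean(axis=0)
        for ch, p in zip(spectrum.channel_labels, mean_pow):
            rows.append({"channel": ch, "band": band, "power": float(p)})
    return pd.DataFrame(rows)


def analyze_rest_session(recording, filter_hz=INEAR_FILTER_HZ,
                         segment_s: float = SPECTRAL_SEGMENT_S,
                         reject_uv: float = 100.0) -> PowerSpectrum:
    """In-ear rest pipeline for one recording: filter, segment, reject, FFT."""
    filtered = bandpass(recording, *filter_hz)
    segs = reject_segments(segment(filtered, segment_s), reject_uv)
    return power_spectrum(segs)


def band_power_table(sessions, filter_hz=INEAR_FILTER_HZ,
                     segment_s: float = SPECTRAL_SEGMENT_S,
                     reject_uv: float = 100.0) -> pd.DataFrame:
    """IAF-anchored band powers for a cohort of in-ear rest sessions.

    ``sessions`` yields ``(SessionLabel, ContinuousRecording)``.  For
    each participant the IAF is estimated from that participant's
    pre-stage spectra only, then applied to every stage.  Output rows:
    ``(participant, group, stage, channel, band, power, iaf_hz)``.
    """
    by_participant: dict = {}
    for label, rec in sessions:
        rec.require_channels(("L", "R"))
        by_participant.setdefault(label.participant_id, []).append((label, rec))

    rows = []
    for pid, items in by_participant.items():
        spectra = {label.stage: (label, analyze_rest_session(
            rec, filter_hz, segment_s, reject_uv)) for label, rec in items}
        if "pre" not in spectra:
            raise InsufficientDataError(
                f"participant {pid} has no pre-stage rest recording to "
                "define the IAF"
            )
        iaf = estimate_iaf(spectra["pre"][1])
        for stage, (label, spec) in spectra.items():
            bp = band_powers(spec, iaf)
            for _, r in bp.iterrows():
                rows.append({
                    "participant": pid,
                    "group": label.group,
                    "stage": stage,
                    "channel": r["channel"],
                    "band": r["band"],
                    "power": r["power"],
                    "iaf_hz": iaf,
                })
    return pd.DataFrame(rows)
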