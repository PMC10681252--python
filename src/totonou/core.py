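"""Shared domain types.

The canonical conventions used by every stage of the pipeline:

* amplitudes are **microvolts** (μV), times are **seconds**,
* sample indices are 0-based,
* windows and band intervals are half-open ``[start, end)``.

A :class:`ContinuousRecording` is a channel-by-time array with a sampling
rate; events on a recording are :class:`EventMarker` rows; a recording's
place in the study design (participant, group, sauna stage) is a
:class:`SessionLabel`.  Questionnaire responses travel as a tidy
:class:`pandas.DataFrame` validated by :func:`validate_score_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataFormatError, ParameterError

#: Sauna-set stages, in study order.  ``pre`` is before the sauna phase;
#: ``post1``..``post3`` are the rest steps after each hot/cold set.
STAGES = ("pre", "post1", "post2", "post3")

GROUPS = ("sauna", "control")

#: Scalp montage used during the auditory oddball task.
SCALP_CHANNELS = ("Fz", "Cz", "Pz")
EOG_CHANNEL = "EOG"

#: In-ear electrode labels (left / right ear canal).
INEAR_CHANNELS = ("L", "R")

#: Visual-analogue-scale questionnaire items (0-100 each).
QUESTIONNAIRE_ITEMS = tuple(f"Q{i}" for i in range(1, 30))

MARKER_KINDS = ("standard", "target")


@dataclass
class ContinuousRecording:
    """Multichannel EEG time series.

    Parameters
    ----------
    samples
        2-D array, shape ``(n_channels, n_samples)``, in microvolts.
    rate_hz
        Sampling rate in samples per second.
    channel_labels
        One label per channel, e.g. ``("Fz", "Cz", "Pz", "EOG")`` for the
        scalp montage or ``("L", "R")`` for in-ear recordings.
    start_offset_s
        Time of the first sample relative to the session clock.
    """

    samples: np.ndarray
    rate_hz: float
    channel_labels: tuple
    start_offset_s: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise DataFormatError(
                f"samples must be 2-D (channel x time), got {self.samples.ndim}-D"
            )
        self.channel_labels = tuple(str(c) for c in self.channel_labels)
        if len(self.channel_labels) != self.samples.shape[0]:
            raise DataFormatError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.samples.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise DataFormatError("duplicate channel labels")
        if not self.rate_hz > 0:
            raise ParameterError(f"rate_hz must be positive, got {self.rate_hz}")
        self.rate_hz = float(self.rate_hz)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def channel(self, label: str) -> np.ndarray:
        """Return one channel as a 1-D view."""
        try:
            i = self.channel_labels.index(label)
        except ValueError:
            raise DataFormatError(
                f"missing channel {label!r}; have {self.channel_labels}"
            ) from None
        return self.samples[i]

    def require_channels(self, labels) -> None:
        """Raise :class:`DataFormatError` unless all ``labels`` are present."""
        missing = [c for c in labels if c not in self.channel_labels]
        if missing:
            raise DataFormatError(
                f"recording lacks required channels {missing}; "
                f"have {list(self.channel_labels)}"
            )


@dataclass
class EventMarker:
    """A stimulus event on a recording.

    ``response_time_ms`` / ``responded_correctly`` are only meaningful for
    target stimuli (the participant presses a button to targets).
    """

    sample_index: int
    kind: str
    response_time_ms: float | None = None
    responded_correctly: bool | None = None

    def __post_init__(self):
        if self.kind not in MARKER_KINDS:
            raise ParameterError(f"marker kind must be one of {MARKER_KINDS}")
        self.sample_index = int(self.sample_index)
        if self.sample_index < 0:
            raise ParameterError("sample_index must be non-negative")
        if self.kind == "standard" and (
            self.response_time_ms is not None or self.responded_correctly is not None
        ):
            raise ParameterError("response fields are only valid on target markers")
        if self.response_time_ms is not None and not self.response_time_ms > 0:
            raise ParameterError("response_time_ms must be positive")


@dataclass(frozen=True)
class SessionLabel:
    """Where a recording sits in the study design."""

    participant_id: str
    group: str
    stage: str

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ParameterError(f"group must be one of {GROUPS}")
        if self.stage not in STAGES:
            raise ParameterError(f"stage must be one of {STAGES}")

    @property
    def decoder_class(self) -> str:
        """Decoder class: pre-sauna rest is ``non_totonou``, all post-set
        rest is ``totonou``."""
        return "non_totonou" if self.stage == "pre" else "totonou"


def validate_score_table(df: pd.DataFrame, items=QUESTIONNAIRE_ITEMS) -> pd.DataFrame:
    """Validate and canonicalise a questionnaire score table.

    Expected tidy columns: ``participant_id``, ``stage``, ``item_id``,
    ``score`` with one row per key and scores on the 0-100 VAS.
    Returns the table sorted by key.
    """
    required = {"participant_id", "stage", "item_id", "score"}
    missing = required - set(df.columns)
    if missing:
        raise DataFormatError(f"score table missing columns {sorted(missing)}")
    bad_stage = set(df["stage"]) - set(STAGES)
    if bad_stage:
        raise DataFormatError(f"unknown stages {sorted(bad_stage)}")
    bad_item = set(df["item_id"]) - set(items)
    if bad_item:
        raise DataFormatError(f"unknown items {sorted(bad_item)}")
    keys = ["participant_id", "stage", "item_id"]
    if df.duplicated(keys).any():
        raise DataFormatError("duplicate (participant, stage, item) keys")
    s = df["score"].to_numpy(dtype=float)
    if np.any(s < 0) or np.any(s > 100):
        raise DataFormatError("scores must lie on the 0-100 VAS")
    return df.sort_values(keys, kind="mergesort").reset_index(drop=True)
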