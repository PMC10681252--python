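"""Readers and writers for recordings, event markers and derived tables.

The delimited recording dialect is a plain TSV (one column per channel,
one row per sample, header row of channel labels) plus a structured-text
sidecar ``<file>.meta.yaml`` holding the sampling rate, amplitude unit
and start offset.  This keeps synthetic fixtures free of any binary
dependency.  EDF files are read through :mod:`mne` when that package is
available.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ContinuousRecording, EventMarker
from .errors import DataFormatError, ParameterError

#: Amplitude-unit scale factors to microvolts.
_UNIT_TO_UV = {"uV": 1.0, "µV": 1.0, "mV": 1e3, "V": 1e6}


def _sidecar(path) -> Path:
    return Path(str(path) + ".meta.yaml")


def write_recording(recording: ContinuousRecording, path) -> None:
    """Write a recording as delimited text plus a metadata sidecar.

    Samples are written with 17 significant digits so a read/write round
    trip is lossless for float64 data.
    """
    path = Path(path)
    header = "\t".join(recording.channel_labels)
    np.savetxt(path, recording.samples.T, fmt="%.17g", delimiter="\t",
               header=header, comments="")
    meta = {
        "rate_hz": recording.rate_hz,
        "channel_labels": list(recording.channel_labels),
        "unit": "uV",
        "start_offset_s": recording.start_offset_s,
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=True))


def read_recording(path, dialect: str = "delimited") -> ContinuousRecording:
    """Read a recording from disk.

    Parameters
    ----------
    path
        Data file.  For the ``delimited`` dialect a sidecar
        ``<path>.meta.yaml`` must declare at least ``rate_hz``.
    dialect
        ``"delimited"`` (TSV + sidecar) or ``"edf"``.
    """
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"unreadable file: {path} does not exist")
    if dialect == "delimited":
        return _read_delimited(path)
    if dialect == "edf":
        return _read_edf(path)
    raise ParameterError(f"unknown dialect {dialect!r}")


def _read_delimited(path: Path) -> ContinuousRecording:
    side = _sidecar(path)
    if not side.exists():
        raise DataFormatError(f"missing sidecar metadata {side}")
    meta = yaml.safe_load(side.read_text()) or {}
    if "rate_hz" not in meta:
        raise DataFormatError(f"missing rate: sidecar {side} declares no rate_hz")
    unit = meta.get("unit", "uV")
    if unit not in _UNIT_TO_UV:
        raise DataFormatError(f"unknown amplitude unit {unit!r}")
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - re-typed for callers
        raise DataFormatError(f"unreadable file {path}: {exc}") from exc
    if df.isna().any().any():
        raise DataFormatError(f"ragged channels in {path}: unequal column lengths")
    labels = tuple(df.columns)
    declared = meta.get("channel_labels")
    if declared is not None and tuple(declared) != labels:
        raise DataFormatError(
            f"channel labels in {path} ({list(labels)}) disagree with "
            f"sidecar ({list(declared)})"
        )
    samples = df.to_numpy(dtype=float).T * _UNIT_TO_UV[unit]
    return ContinuousRecording(
        samples=samples,
        rate_hz=float(meta["rate_hz"]),
        channel_labels=labels,
        start_offset_s=float(meta.get("start_offset_s", 0.0)),
    )


def _read_edf(path: Path) -> ContinuousRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise DataFormatError("EDF support requires the optional 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return ContinuousRecording(
        samples=raw.get_data() * 1e6,  # mne returns volts
        rate_hz=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        start_offset_s=0.0,
    )


def write_markers(markers, path) -> None:
    """Write event markers as a delimited table keyed to a recording file."""
    rows = []
    for m in markers:
        rows.append({
            "sample_index": m.sample_index,
            "kind": m.kind,
            "response_time_ms": "" if m.response_time_ms is None else repr(float(m.response_time_ms)),
            "responded_correctly": "" if m.responded_correctly is None else int(m.responded_correctly),
        })
    pd.DataFrame(rows, columns=["sample_index", "kind", "response_time_ms",
                                "responded_correctly"]).to_csv(path, sep="\t", index=False)


def read_markers(path) -> list:
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"unreadable file: {path} does not exist")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    markers = []
    for _, r in df.iterrows():
        rt = r.get("response_time_ms")
        ok = r.get("responded_correctly")
        markers.append(EventMarker(
            sample_index=int(r["sample_index"]),
            kind=str(r["kind"]),
            response_time_ms=None if pd.isna(rt) else float(rt),
            responded_correctly=None if pd.isna(ok) else bool(int(ok)),
        ))
    return markers


def write_table(df: pd.DataFrame, path) -> None:
    """Write a derived-measure table as delimited text.

    Rows are sorted by all columns so output is deterministic regardless
    of construction order; floats use shortest-exact representation so a
    round trip through :func:`read_table` preserves values exactly.
    """
    out = df.sort_values(list(df.columns), kind="mergesort") if len(df) else df
    out.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"unreadable file: {path} does not exist")
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
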