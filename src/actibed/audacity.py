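"""Bridge between feature series / in-bed events and Audacity.

The seven-channel feature series is written as one multi-channel IEEE-float
32-bit WAV (sample rate 1 Hz) that Audacity imports in a single drag-and-drop,
splitting the channels into stacked tracks.  Raters mark each in-bed period as
a region label and export the label track as tab-separated text
(``start<TAB>end<TAB>text`` in decimal seconds); this module parses those files
back into absolute (to-bed, out-of-bed) events.

Nights are identified by the "noon rule": an event belongs to the calendar
date of its to-bed time if that time is at or after 12:00 local, otherwise to
the previous date — so a 23:30 bedtime and a 00:30 bedtime on either side of
midnight share a night.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date, datetime, timedelta
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .signal_features import CHANNEL_NAMES, FeatureSeries

__all__ = [
    "LabelTrack",
    "InBedEvent",
    "night_of",
    "write_feature_wav",
    "read_feature_wav",
    "read_label_file",
    "write_label_file",
    "labels_to_events",
    "events_to_labels",
    "propose_inbed_labels",
]


@dataclass(frozen=True)
class InBedEvent:
    """One (to-bed, out-of-bed) pair with provenance.

    ``source`` tags where the event came from: ``("rater", id, round)``,
    ``("zm",)`` or ``("diary",)`` — stored as a plain string such as
    ``"rater:2:1"``, ``"zm"`` or ``"diary"``.
    """

    subject_id: str
    night_id: date
    to_bed: datetime
    out_of_bed: datetime
    source: str

    def __post_init__(self) -> None:
        if self.out_of_bed <= self.to_bed:
            raise ValueError(
                f"out_of_bed must come after to_bed "
                f"({self.to_bed} .. {self.out_of_bed})"
            )
        if self.out_of_bed - self.to_bed >= timedelta(hours=24):
            raise ValueError("in-bed period of 24 h or more is implausible")

    @property
    def duration(self) -> timedelta:
        return self.out_of_bed - self.to_bed


class LabelTrack:
    """An ordered Audacity label track: (start_s, end_s, text) regions."""

    def __init__(self, entries=()):
        entries = [(float(s), float(e), str(t)) for s, e, t in entries]
        for s, e, _ in entries:
            if s < 0:
                raise ValueError(f"label start {s} is negative")
            if e < s:
                raise ValueError(f"label end {e} precedes start {s}")
        self.entries = sorted(entries, key=lambda x: (x[0], x[1]))

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, LabelTrack) and self.entries == other.entries

    def __repr__(self) -> str:
        return f"LabelTrack({self.entries!r})"


def night_of(to_bed: datetime) -> date:
    """Calendar night of a to-bed time under the noon rule."""
    d = to_bed.date()
    return d if to_bed.hour >= 12 else d - timedelta(days=1)


def write_feature_wav(
    features: FeatureSeries,
    path,
    subject_id: str = "",
    extra_metadata: dict | None = None,
) -> Path:
    """Write a feature series as a 7-channel float32 WAV plus JSON sidecar.

    Channel order follows :data:`~actibed.signal_features.CHANNEL_NAMES`.
    Values are written verbatim (already in [-1, 1]); missing frames are
    written as 0.0 to keep the tracks visually continuous, with the missing
    mask recorded in the sidecar (``<path>.json``).
    """
    if len(features) == 0:
        raise ValueError("refusing to write an empty feature series")
    path = Path(path)
    data = features.values().astype(np.float32)
    data[~np.isfinite(data)] = 0.0
    wavfile.write(path, int(features.rate), data)
    sidecar = {
        "start_time": features.start_time.isoformat(),
        "subject_id": subject_id,
        "channel_names": list(CHANNEL_NAMES),
        "rate_hz": features.rate,
        "n_frames": len(features),
        "missing_frames": [int(i) for i in np.nonzero(features.missing)[0]],
    }
    if extra_metadata:
        sidecar.update(extra_metadata)
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_feature_wav(path) -> tuple[np.ndarray, dict]:
    """Read back a feature WAV; returns (frames x channels float32, sidecar)."""
    path = Path(path)
    _rate, data = wavfile.read(path)
    sidecar_path = Path(str(path) + ".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    if data.ndim == 1:
        data = data[:, None]
    return data, sidecar


class LabelFileError(ValueError):
    """Malformed Audacity label text file."""


def read_label_file(path) -> LabelTrack:
    """Parse an Audacity label text file (tab-separated start/end/text lines).

    Tolerant of missing text fields and unsorted lines (sorted on read).
    Non-numeric or inverted intervals are rejected with the line number.
    """
    entries = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) < 2:
            raise LabelFileError(f"{path}:{lineno}: expected tab-separated start/end")
        try:
            start_s, end_s = float(parts[0]), float(parts[1])
        except ValueError:
            raise LabelFileError(
                f"{path}:{lineno}: non-numeric label boundary {parts[:2]!r}"
            ) from None
        if end_s < start_s:
            raise LabelFileError(
                f"{path}:{lineno}: label end {end_s} precedes start {start_s}"
            )
        text = parts[2] if len(parts) > 2 else ""
        entries.append((start_s, end_s, text))
    return LabelTrack(entries)


def write_label_file(track: LabelTrack, path) -> Path:
    """Write a label track in Audacity's export dialect (6-decimal seconds)."""
    path = Path(path)
    lines = [f"{s:.6f}\t{e:.6f}\t{t}" for s, e, t in track]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def labels_to_events(
    track: LabelTrack,
    recording_start: datetime,
    subject_id: str,
    source: str = "rater",
) -> list[InBedEvent]:
    """Convert region labels to absolute in-bed events.

    Each label becomes an event with ``to_bed = recording_start + start_s``
    and ``out_of_bed = recording_start + end_s``; the night is assigned by the
    noon rule.  Zero-duration or >= 24 h labels are rejected as implausible
    in-bed periods.
    """
    events = []
    for start_s, end_s, _text in track:
        if end_s - start_s >= 24 * 3600:
            raise ValueError(
                f"label ({start_s}, {end_s}) spans >= 24 h; not an in-bed period"
            )
        to_bed = recording_start + timedelta(seconds=start_s)
        out_of_bed = recording_start + timedelta(seconds=end_s)
        events.append(
            InBedEvent(
                subject_id=subject_id,
                night_id=night_of(to_bed),
                to_bed=to_bed,
                out_of_bed=out_of_bed,
                source=source,
            )
        )
    return events


def events_to_labels(events, recording_start: datetime) -> LabelTrack:
    """Inverse of :func:`labels_to_events` (label text = "inbed")."""
    entries = []
    for ev in events:
        start_s = (ev.to_bed - recording_start).total_seconds()
        end_s = (ev.out_of_bed - recording_start).total_seconds()
        if start_s < 0:
            raise ValueError(f"event {ev} begins before recording start")
        entries.append((start_s, end_s, "inbed"))
    return LabelTrack(entries)


def propose_inbed_labels(
    features: FeatureSeries,
    min_duration_s: float = 1800.0,
    max_gap_s: float = 900.0,
) -> LabelTrack:
    """Threshold-based machine proposal of in-bed regions from the Lying channel.

    Runs of Lying = +1 separated by gaps of at most ``max_gap_s`` (brief sensor
    repositioning, trips to the bathroom) are merged; merged runs shorter than
    ``min_duration_s`` are dropped.  Offsets are relative to the *frame* start
    so they line up with the exported WAV.
    """
    lying = features.channels["Lying"] > 0
    runs = []
    i = 0
    n = len(lying)
    while i < n:
        if lying[i]:
            j = i
            while j + 1 < n and lying[j + 1]:
                j += 1
            runs.append([i, j])
            i = j + 1
        else:
            i += 1
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= max_gap_s:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    entries = [
        (float(i0), float(i1 + 1), "inbed")
        for i0, i1 in merged
        if (i1 + 1 - i0) >= min_duration_s
    ]
    return LabelTrack(entries)
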