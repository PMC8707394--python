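"""Ground-truth in-bed events from EEG-epoch records and sleep diaries.

A Zmachine-style single-channel EEG device scores sleep on 30-s epochs; the
reference in-bed interval for a night runs from the start of the first epoch
without a sensor problem to the end of the last such epoch.  A night whose
recording *begins or ends* with a sensor-problem epoch is discarded outright,
since its true boundary is unknown (poor electrode attachment most commonly).

Sleep diaries report clock times only; overnight rollover (an out-of-bed clock
time earlier than the to-bed clock time) pushes the out-of-bed to the next
day, and a to-bed before noon belongs to the previous calendar night.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date, datetime, time, timedelta

import pandas as pd

from .audacity import InBedEvent, night_of

__all__ = [
    "Stage",
    "ZMEpoch",
    "ZMNight",
    "DiaryEntry",
    "Discarded",
    "EPOCH_SECONDS",
    "parse_zm_csv",
    "derive_inbed_from_zm",
    "parse_diary",
    "diary_to_events",
]

EPOCH_SECONDS = 30


class Stage(enum.Enum):
    WAKE = "WAKE"
    LIGHT = "LIGHT"
    DEEP = "DEEP"
    REM = "REM"
    SENSOR_PROBLEM = "SENSOR_PROBLEM"


_STAGE_ALIASES = {
    "WAKE": Stage.WAKE, "W": Stage.WAKE,
    "LIGHT": Stage.LIGHT, "L": Stage.LIGHT, "N1": Stage.LIGHT, "N2": Stage.LIGHT,
    "DEEP": Stage.DEEP, "D": Stage.DEEP, "N3": Stage.DEEP,
    "REM": Stage.REM, "R": Stage.REM,
    "SENSOR_PROBLEM": Stage.SENSOR_PROBLEM, "SP": Stage.SENSOR_PROBLEM,
}


@dataclass(frozen=True)
class ZMEpoch:
    start: datetime
    stage: Stage

    @property
    def end(self) -> datetime:
        return self.start + timedelta(seconds=EPOCH_SECONDS)


@dataclass
class ZMNight:
    """One night of contiguous 30-s sleep-stage epochs."""

    subject_id: str
    night_id: date
    epochs: list[ZMEpoch]

    def __post_init__(self) -> None:
        if not self.epochs:
            raise ValueError("a night must contain at least one epoch")
        for prev, cur in zip(self.epochs, self.epochs[1:]):
            if cur.start != prev.end:
                raise ValueError(
                    f"epochs not contiguous at {prev.end} -> {cur.start} "
                    f"(subject {self.subject_id}, night {self.night_id})"
                )


@dataclass(frozen=True)
class DiaryEntry:
    """Self-reported bed and rise times for one night (absolute datetimes)."""

    subject_id: str
    night_id: date
    to_bed: datetime | None
    out_of_bed: datetime | None

    @property
    def complete(self) -> bool:
        return self.to_bed is not None and self.out_of_bed is not None


@dataclass(frozen=True)
class Discarded:
    """A night excluded from analysis, with the reason."""

    subject_id: str
    night_id: date
    reason: str


class ZMParseError(ValueError):
    pass


def parse_zm_csv(path) -> list[ZMNight]:
    """Parse an epoch CSV (``subject,night,epoch_start,stage``) into nights.

    Nights are grouped on (subject, night) and validated: epochs must be
    contiguous on the 30-s grid and stage codes known.
    """
    df = pd.read_csv(path, dtype={"subject": str})
    for col in ("subject", "night", "epoch_start", "stage"):
        if col not in df.columns:
            raise ZMParseError(f"{path}: missing required column {col!r}")
    nights = []
    for (subject, night), grp in df.groupby(["subject", "night"], sort=True):
        grp = grp.sort_values("epoch_start")
        epochs = []
        for _, row in grp.iterrows():
            code = str(row["stage"]).strip().upper()
            if code not in _STAGE_ALIASES:
                raise ZMParseError(
                    f"{path}: unknown stage code {row['stage']!r} "
                    f"(subject {subject}, night {night})"
                )
            epochs.append(
                ZMEpoch(
                    start=pd.Timestamp(row["epoch_start"]).to_pydatetime(),
                    stage=_STAGE_ALIASES[code],
                )
            )
        night_id = pd.Timestamp(night).date()
        try:
            nights.append(ZMNight(subject_id=str(subject), night_id=night_id, epochs=epochs))
        except ValueError as exc:
            raise ZMParseError(str(exc)) from None
    return nights


def derive_inbed_from_zm(night: ZMNight) -> InBedEvent | Discarded:
    """Reference in-bed event of a night, or :class:`Discarded`.

    to_bed is the start of the first non-sensor-problem epoch; out_of_bed the
    end of the last.  If the recording begins or ends with a sensor-problem
    epoch (or contains nothing else), the night is discarded.
    """
    ok = [e.stage is not Stage.SENSOR_PROBLEM for e in night.epochs]
    if not any(ok):
        return Discarded(night.subject_id, night.night_id, "all epochs are sensor problems")
    if not ok[0]:
        return Discarded(night.subject_id, night.night_id, "recording begins with sensor problem")
    if not ok[-1]:
        return Discarded(night.subject_id, night.night_id, "recording ends with sensor problem")
    first = ok.index(True)
    last = len(ok) - 1 - ok[::-1].index(True)
    return InBedEvent(
        subject_id=night.subject_id,
        night_id=night.night_id,
        to_bed=night.epochs[first].start,
        out_of_bed=night.epochs[last].end,
        source="zm",
    )


class DiaryParseError(ValueError):
    pass


def _parse_clock(value) -> time | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if not s or s.lower() in ("nan", "na", ""):
        return None
    for fmt in ("%H:%M:%S", "%H:%M"):
        try:
            return datetime.strptime(s, fmt).time()
        except ValueError:
            continue
    raise DiaryParseError(f"unparsable clock time {value!r}")


def parse_diary(path) -> list[DiaryEntry]:
    """Parse a diary CSV (``subject,date,to_bed,out_of_bed`` clock times).

    ``date`` is the night identifier (the evening's calendar date).  A to-bed
    clock before noon falls on the day after ``date``; an out-of-bed clock
    earlier than the to-bed clock rolls over to the next day.  Rows missing
    either time are returned flagged incomplete.
    """
    df = pd.read_csv(path, dtype={"subject": str})
    for col in ("subject", "date", "to_bed", "out_of_bed"):
        if col not in df.columns:
            raise DiaryParseError(f"{path}: missing required column {col!r}")
    entries = []
    for i, row in df.iterrows():
        try:
            bed_clock = _parse_clock(row["to_bed"])
            rise_clock = _parse_clock(row["out_of_bed"])
        except DiaryParseError as exc:
            raise DiaryParseError(f"{path}: row {i + 2}: {exc}") from None
        night = pd.Timestamp(row["date"]).date()
        to_bed = out_of_bed = None
        if bed_clock is not None:
            bed_day = night if bed_clock.hour >= 12 else night + timedelta(days=1)
            to_bed = datetime.combine(bed_day, bed_clock)
            if rise_clock is not None:
                rise_day = bed_day if rise_clock > bed_clock else bed_day + timedelta(days=1)
                out_of_bed = datetime.combine(rise_day, rise_clock)
        entries.append(
            DiaryEntry(
                subject_id=str(row["subject"]),
                night_id=night,
                to_bed=to_bed,
                out_of_bed=out_of_bed,
            )
        )
    return entries


def diary_to_events(entries) -> list[InBedEvent]:
    """Complete diary entries as in-bed events (incomplete rows excluded)."""
    return [
        InBedEvent(
            subject_id=e.subject_id,
            night_id=night_of(e.to_bed),
            to_bed=e.to_bed,
            out_of_bed=e.out_of_bed,
            source="diary",
        )
        for e in entries
        if e.complete
    ]
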