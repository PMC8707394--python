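"""Synthetic free-living study data with known in-bed intervals.

Generates everything the rest of the toolchain consumes, without any real
recordings: per-subject behavior timelines (nightly in-bed segments plus
daytime sit/stand/walk blocks), 30 Hz two-site accelerometry rendered from
gravity projection per posture plus white noise, simulated rater annotations
(truth plus Gaussian per-endpoint error), EEG-epoch nights with optional
boundary sensor problems, and diary entries.

Default condition parameters emulate the source study's free-living setting:
multi-day recordings of about a week per subject, bed/rise schedules with
substantial night-to-night and between-subject spread (tens of minutes), and
annotation errors on the scale of ~14 min SD — the regime in which manual
raters and the EEG reference disagree by roughly half an hour at the limits
of agreement.

All randomness flows from a single seed: each component draws from an
independent child stream of one ``numpy`` SeedSequence, so regenerating any
one artifact is reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .audacity import InBedEvent, night_of
from .ground_truth import EPOCH_SECONDS, Stage, ZMEpoch, ZMNight
from .signal_features import TriaxialRecording

__all__ = [
    "RaterSpec",
    "SimConfig",
    "BehaviorTimeline",
    "Segment",
    "simulate_timeline",
    "render_accel",
    "simulate_raters",
    "simulate_zm",
    "simulate_diary",
    "true_events",
    "write_fixture_dir",
]


@dataclass(frozen=True)
class RaterSpec:
    """Gaussian annotation-error model of one rater: minutes."""

    rater_id: str
    bias_min: float = 0.0
    sd_min: float = 14.0


@dataclass
class SimConfig:
    """Study-condition parameters for the simulator.

    Times are minutes; ``bed_mu_min`` is minutes after the night's reference
    midnight (negative = before midnight), ``rise_mu_min`` minutes after it.
    The night-level spread splits into a between-subject component (habitual
    schedule differences — children vs adults span hours) and a night-to-night
    component.
    """

    n_subjects: int = 10
    n_nights: int = 7
    seed: int = 0
    start_date: date = date(2018, 10, 1)
    bed_mu_min: float = -60.0  # 23:00
    rise_mu_min: float = 7 * 60.0  # 07:00
    between_subject_sd_min: float = 60.0
    night_sd_min: float = 45.0
    raters: tuple[RaterSpec, ...] = (
        RaterSpec("1", 0.0, 14.0),
        RaterSpec("2", 0.0, 14.0),
        RaterSpec("3", 0.0, 14.0),
    )
    n_rounds: int = 2
    zm_jitter_sd_min: float = 0.0
    p_boundary_sensor_problem: float = 0.0
    accel_noise_sd_g: float = 0.01
    accel_hz: float = 30.0

    def __post_init__(self) -> None:
        for name in (
            "between_subject_sd_min",
            "night_sd_min",
            "zm_jitter_sd_min",
            "accel_noise_sd_g",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.p_boundary_sensor_problem <= 1:
            raise ValueError("p_boundary_sensor_problem must be in [0, 1]")

    def seeds(self) -> dict[str, np.random.Generator]:
        """Independent, deterministically derived child streams per component."""
        ss = np.random.SeedSequence(self.seed)
        names = ("timeline", "accel", "raters", "zm", "diary")
        return {n: np.random.default_rng(c) for n, c in zip(names, ss.spawn(len(names)))}


@dataclass(frozen=True)
class Segment:
    start: datetime
    end: datetime
    behavior: str  # in_bed | sit | stand | walk | other


@dataclass
class BehaviorTimeline:
    """Contiguous, non-overlapping behavior segments covering one subject's span."""

    subject_id: str
    segments: list[Segment]

    def __post_init__(self) -> None:
        for prev, cur in zip(self.segments, self.segments[1:]):
            if cur.start != prev.end:
                raise ValueError(f"segments not contiguous at {prev.end}")

    @property
    def span(self) -> tuple[datetime, datetime]:
        return self.segments[0].start, self.segments[-1].end

    def in_bed_events(self) -> list[InBedEvent]:
        return [
            InBedEvent(
                subject_id=self.subject_id,
                night_id=night_of(seg.start),
                to_bed=seg.start,
                out_of_bed=seg.end,
                source="truth",
            )
            for seg in self.segments
            if seg.behavior == "in_bed"
        ]


_DAY_CYCLE = ("sit", "stand", "walk", "sit", "other", "walk")


def simulate_timeline(
    config: SimConfig, rng: np.random.Generator, subject_id: str
) -> BehaviorTimeline:
    """One subject's multi-day timeline with ``n_nights`` in-bed segments.

    Nightly to-bed ~ Normal(mu_bed + subject offset, sd) and rise ~
    Normal(mu_rise + subject offset, sd); infeasible draws (rise not at least
    one hour after bed) are resampled.  Daytime is filled with a fixed cycle
    of sit/stand/walk/other blocks.
    """
    subj_offset = rng.normal(0.0, config.between_subject_sd_min)
    midnights = [
        datetime.combine(config.start_date + timedelta(days=d + 1), datetime.min.time())
        for d in range(config.n_nights)
    ]
    beds, rises = [], []
    for m in midnights:
        for _ in range(1000):
            bed = m + timedelta(minutes=config.bed_mu_min + subj_offset + rng.normal(0.0, config.night_sd_min))
            rise = m + timedelta(minutes=config.rise_mu_min + subj_offset + rng.normal(0.0, config.night_sd_min))
            if rise - bed >= timedelta(hours=1) and rise - bed < timedelta(hours=23):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not draw a feasible night schedule")
        beds.append(bed)
        rises.append(rise)
    for i in range(1, len(beds)):  # keep nights ordered even at extreme draws
        if beds[i] <= rises[i - 1]:
            beds[i] = rises[i - 1] + timedelta(hours=1)

    segments: list[Segment] = []
    span_start = beds[0] - timedelta(hours=4)
    cursor = span_start
    cycle = 0
    for bed, rise in zip(beds, rises):
        t = cursor
        while t < bed:
            block_end = min(t + timedelta(minutes=90), bed)
            segments.append(Segment(t, block_end, _DAY_CYCLE[cycle % len(_DAY_CYCLE)]))
            cycle += 1
            t = block_end
        segments.append(Segment(bed, rise, "in_bed"))
        cursor = rise
    return BehaviorTimeline(subject_id=subject_id, segments=segments)


# Posture geometry: per behavior, (site -> inclination range in degrees) and
# white-noise SD in g, chosen so the decision rules fire on segment interiors:
# in bed, the hip is well past 65 deg and the thigh horizontal and still
# (sitting class); sitting keeps the hip upright; walking shakes the thigh.
_POSTURE = {
    "in_bed": {"hip": (70.0, 110.0), "thigh": (80.0, 100.0), "noise": None},
    "sit": {"hip": (5.0, 25.0), "thigh": (80.0, 100.0), "noise": None},
    "stand": {"hip": (0.0, 10.0), "thigh": (0.0, 10.0), "noise": None},
    "walk": {"hip": (0.0, 10.0), "thigh": (0.0, 10.0), "noise": 0.3},
    "other": {"hip": (35.0, 55.0), "thigh": (55.0, 75.0), "noise": 0.25},
}


def render_accel(
    timeline: BehaviorTimeline,
    site: str,
    config: SimConfig,
    rng: np.random.Generator,
) -> TriaxialRecording:
    """Render a timeline as a 30 Hz tri-axial stream for one site.

    Each segment projects gravity onto a fixed random orientation drawn from
    the posture's inclination range, plus white noise (the quiet-posture SD
    from the config; walking and other activity use a large fixed SD so the
    movement classifier fires).
    """
    start, end = timeline.span
    hz = config.accel_hz
    n_total = int(round((end - start).total_seconds() * hz))
    out = np.empty((n_total, 3))
    for seg in timeline.segments:
        i0 = int(round((seg.start - start).total_seconds() * hz))
        i1 = int(round((seg.end - start).total_seconds() * hz))
        spec = _POSTURE[seg.behavior]
        theta = np.radians(rng.uniform(*spec[site]))
        phi = rng.uniform(0, 2 * np.pi)
        gravity = np.array(
            [np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)]
        )
        noise_sd = spec["noise"] if spec["noise"] is not None else config.accel_noise_sd_g
        out[i0:i1] = gravity + rng.normal(0.0, noise_sd, size=(i1 - i0, 3))
    return TriaxialRecording(
        site=site, start_time=start, sample_rate=hz, samples=out
    )


def true_events(timelines) -> list[InBedEvent]:
    """All true in-bed events across a collection of timelines."""
    evs = []
    for tl in timelines:
        evs.extend(tl.in_bed_events())
    return evs


def simulate_raters(
    events, config: SimConfig, rng: np.random.Generator
) -> dict[tuple[str, int], list[InBedEvent]]:
    """Noisy manual annotations: truth + Normal(bias, sd) per endpoint.

    Returns a map from (rater_id, round) to that rater's event list; each
    endpoint of each night draws independently, per rater and round.
    """
    out: dict[tuple[str, int], list[InBedEvent]] = {}
    for rater in config.raters:
        for rnd in range(1, config.n_rounds + 1):
            annos = []
            for ev in events:
                d_bed = rng.normal(rater.bias_min, rater.sd_min)
                d_rise = rng.normal(rater.bias_min, rater.sd_min)
                annos.append(
                    replace(
                        ev,
                        to_bed=ev.to_bed + timedelta(minutes=d_bed),
                        out_of_bed=ev.out_of_bed + timedelta(minutes=d_rise),
                        source=f"rater:{rater.rater_id}:{rnd}",
                    )
                )
            out[(rater.rater_id, rnd)] = annos
    return out


def _to_epoch_grid(ts: datetime) -> datetime:
    """Round a timestamp to the nearest 30-s epoch boundary."""
    day = datetime.combine(ts.date(), datetime.min.time())
    secs = (ts - day).total_seconds()
    return day + timedelta(seconds=round(secs / EPOCH_SECONDS) * EPOCH_SECONDS)


def simulate_zm(
    events, config: SimConfig, rng: np.random.Generator
) -> list[ZMNight]:
    """EEG-epoch nights tiling each true in-bed interval.

    Endpoints are jittered by Normal(0, zm_jitter_sd_min) minutes and snapped
    to the 30-s epoch grid; with probability ``p_boundary_sensor_problem`` one
    boundary epoch (first or last, coin flip) is flagged as a sensor problem,
    which discards the night downstream.
    """
    stages = [Stage.WAKE, Stage.LIGHT, Stage.DEEP, Stage.REM]
    nights = []
    for ev in events:
        start = _to_epoch_grid(ev.to_bed + timedelta(minutes=rng.normal(0.0, config.zm_jitter_sd_min)))
        end = _to_epoch_grid(ev.out_of_bed + timedelta(minutes=rng.normal(0.0, config.zm_jitter_sd_min)))
        n_epochs = max(int((end - start).total_seconds() // EPOCH_SECONDS), 2)
        stage_idx = rng.integers(0, len(stages), size=n_epochs)
        epochs = [
            ZMEpoch(start + timedelta(seconds=i * EPOCH_SECONDS), stages[j])
            for i, j in enumerate(stage_idx)
        ]
        if rng.random() < config.p_boundary_sensor_problem:
            pos = 0 if rng.random() < 0.5 else -1
            epochs[pos] = ZMEpoch(epochs[pos].start, Stage.SENSOR_PROBLEM)
        nights.append(ZMNight(subject_id=ev.subject_id, night_id=ev.night_id, epochs=epochs))
    return nights


def simulate_diary(
    events,
    config: SimConfig,
    rng: np.random.Generator,
    sd_min: float = 10.0,
    round_to_min: int = 5,
) -> pd.DataFrame:
    """Diary rows (``subject,date,to_bed,out_of_bed``): truth + noise, rounded.

    Self-report is noisier and coarser than the EEG reference: Gaussian error
    plus rounding to the nearest 5 minutes by default.
    """
    rows = []
    for ev in events:
        def clock(ts: datetime, err: float) -> str:
            t = ts + timedelta(minutes=err)
            total = round((t.hour * 60 + t.minute + t.second / 60) / round_to_min) * round_to_min
            return f"{(total // 60) % 24:02d}:{total % 60:02d}"

        rows.append(
            {
                "subject": ev.subject_id,
                "date": ev.night_id.isoformat(),
                "to_bed": clock(ev.to_bed, rng.normal(0.0, sd_min)),
                "out_of_bed": clock(ev.out_of_bed, rng.normal(0.0, sd_min)),
            }
        )
    return pd.DataFrame(rows)


def write_fixture_dir(config: SimConfig, out_dir) -> dict[str, Path]:
    """Write a complete fixture directory in the formats the toolchain reads.

    Emits per-subject truth label files, rater label files, a ZM epoch CSV and
    a diary CSV.  Raw accelerometry CSVs are intentionally not written here
    (they are large); render them on demand with :func:`render_accel`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rngs = config.seeds()
    timelines = [
        simulate_timeline(config, rngs["timeline"], f"S{i + 1:02d}")
        for i in range(config.n_subjects)
    ]
    truth = true_events(timelines)

    from .audacity import events_to_labels, write_label_file

    paths: dict[str, Path] = {}
    truth_rows = []
    for tl in timelines:
        rec_start = tl.span[0]
        track = events_to_labels(tl.in_bed_events(), rec_start)
        p = out / f"{tl.subject_id}_truth.txt"
        write_label_file(track, p)
        paths[f"truth_labels_{tl.subject_id}"] = p
        truth_rows.append({"subject": tl.subject_id, "recording_start": rec_start.isoformat()})
    pd.DataFrame(truth_rows).to_csv(out / "recording_starts.csv", index=False)

    raters = simulate_raters(truth, config, rngs["raters"])
    for (rid, rnd), evs in raters.items():
        rows = [
            {
                "subject": e.subject_id,
                "night": e.night_id.isoformat(),
                "source": e.source,
                "to_bed": e.to_bed.isoformat(),
                "out_of_bed": e.out_of_bed.isoformat(),
            }
            for e in evs
        ]
        p = out / f"rater{rid}_round{rnd}.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        paths[f"rater{rid}_round{rnd}"] = p

    zm_nights = simulate_zm(truth, config, rngs["zm"])
    zm_rows = [
        {
            "subject": night.subject_id,
            "night": night.night_id.isoformat(),
            "epoch_start": ep.start.isoformat(),
            "stage": ep.stage.value,
        }
        for night in zm_nights
        for ep in night.epochs
    ]
    paths["zm"] = out / "zm_epochs.csv"
    pd.DataFrame(zm_rows).to_csv(paths["zm"], index=False)

    paths["diary"] = out / "diary.csv"
    simulate_diary(truth, config, rngs["diary"]).to_csv(paths["diary"], index=False)
    return paths
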