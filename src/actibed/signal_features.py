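"""Signal features for visual in-bed annotation from dual-site accelerometry.

Raw hip- and thigh-worn tri-axial acceleration (units of g, x = longitudinal
body-segment axis, positive toward the head when upright) is converted into
seven encoded channels at 1-second resolution, each scaled into [-1, 1] so
the series can be rendered as audio tracks:

1. Lying            +1 lying / -1 not lying
2. Activity         +1 upright (standing, moving, walking) / 0 sitting / -1 other
3. Time             time of day in six 4-hour bins, -1.0 .. +1.0
4. Thigh-SDacc      longitudinal-axis SD of the thigh, movement proxy
5. Thigh-Inclination angle of the thigh axis to gravity, encoded theta/180
6. Hip-SDacc        longitudinal-axis SD of the hip
7. Hip-Inclination  angle of the hip axis to gravity

Lying is declared when the hip inclination exceeds 65 degrees while the thigh
is concurrently classified as sitting (a Skotte-style inclination/SD decision
rule).  Features are computed over 2-s windows (60 samples at 30 Hz) with 50%
overlap, giving one frame per second.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Activity",
    "TriaxialRecording",
    "Window",
    "FeatureSeries",
    "CHANNEL_NAMES",
    "SENSOR_RANGE_G",
    "read_accel_csv",
    "resample",
    "frame_windows",
    "inclination_deg",
    "sd_longitudinal",
    "classify_activity",
    "classify_lying",
    "time_bin_level",
    "encode",
    "build_features",
]

#: Channel order of the seven features; fixed, also the WAV channel order.
CHANNEL_NAMES = (
    "Lying",
    "Activity",
    "Time",
    "Thigh-SDacc",
    "Thigh-Inclination",
    "Hip-SDacc",
    "Hip-Inclination",
)

#: Accelerometer sensitivity range in g; samples beyond it are clipped.
SENSOR_RANGE_G = 8.0

WINDOW_SAMPLES = 60  # 2 s at 30 Hz
HOP_SAMPLES = 30  # 50% overlap -> 1-s frame spacing
TARGET_HZ = 30.0

#: Default Skotte-style decision thresholds (configurable approximations).
THETA_SIT_DEG = 45.0  # thigh inclination above which the thigh is "horizontal"
S_MOVE_G = 0.1  # longitudinal SD above which the segment is moving
THETA_LYING_DEG = 65.0  # hip inclination must *exceed* this for lying
SD_MAX_G = 0.5  # SDacc encoding saturates here


class Activity(enum.IntEnum):
    """Activity class of the thigh-worn device (encoded level = value)."""

    UPRIGHT = 1  # standing, moving or walking
    SITTING = 0
    OTHER = -1


@dataclass
class TriaxialRecording:
    """A timestamped tri-axial acceleration stream for one body site.

    Parameters
    ----------
    site : {'hip', 'thigh'}
    start_time : datetime
        Absolute (naive local or fixed-offset) time of the first sample.
    sample_rate : float
        Nominal rate in Hz; must be > 0.
    samples : ndarray, shape (n, 3)
        (ax, ay, az) in g.  x is the longitudinal segment axis.  Values are
        clipped to the +/-8 g sensor range on construction; non-finite values
        are rejected.
    time_s : ndarray or None
        Per-sample offsets in seconds from ``start_time``; ``None`` means a
        uniform grid at ``sample_rate``.
    gap_indices : list of int
        Sample indices after which the raw timestamp gap exceeded twice the
        nominal period (flagged by :func:`read_accel_csv`).
    """

    site: str
    start_time: datetime
    sample_rate: float
    samples: np.ndarray
    time_s: np.ndarray | None = None
    gap_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.site not in ("hip", "thigh"):
            raise ValueError(f"site must be 'hip' or 'thigh', got {self.site!r}")
        if not self.sample_rate > 0:
            raise ValueError(f"sample_rate must be > 0, got {self.sample_rate}")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        np.clip(self.samples, -SENSOR_RANGE_G, SENSOR_RANGE_G, out=self.samples)
        if self.time_s is not None:
            self.time_s = np.asarray(self.time_s, dtype=float)
            if self.time_s.shape != (len(self.samples),):
                raise ValueError("time_s length must match samples")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        if len(self) == 0:
            return 0.0
        if self.time_s is not None:
            return float(self.time_s[-1])
        return (len(self) - 1) / self.sample_rate

    @property
    def end_time(self) -> datetime:
        return self.start_time + timedelta(seconds=self.duration_s)

    def sample_times(self) -> np.ndarray:
        """Offsets of every sample in seconds from ``start_time``."""
        if self.time_s is not None:
            return self.time_s
        return np.arange(len(self)) / self.sample_rate


@dataclass(frozen=True)
class Window:
    """One 2-s analysis window of 60 consecutive resampled samples."""

    samples: np.ndarray  # (60, 3)
    center_time: datetime

    def __post_init__(self) -> None:
        if self.samples.shape != (WINDOW_SAMPLES, 3):
            raise ValueError(
                f"window must hold exactly {WINDOW_SAMPLES} tri-axial samples"
            )


@dataclass
class FeatureSeries:
    """The seven encoded channels at 1-s resolution.

    ``channels`` maps each name in :data:`CHANNEL_NAMES` to an equal-length
    float array with values in [-1, 1] (NaN marks missing frames).  ``missing``
    is the boolean frame mask of missing data at either site.
    """

    start_time: datetime
    channels: dict[str, np.ndarray]
    missing: np.ndarray
    rate: float = 1.0

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have the same length")
        if tuple(self.channels) != CHANNEL_NAMES:
            raise ValueError(f"channels must be exactly {CHANNEL_NAMES} in order")
        for name, vals in self.channels.items():
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite.min() < -1 or finite.max() > 1):
                raise ValueError(f"channel {name} has values outside [-1, 1]")
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != (len(self),):
            raise ValueError("missing mask length must match channels")

    def __len__(self) -> int:
        return len(next(iter(self.channels.values()))) if self.channels else 0

    def frame_times(self) -> list[datetime]:
        return [self.start_time + timedelta(seconds=i) for i in range(len(self))]

    def values(self) -> np.ndarray:
        """Frames x channels matrix in channel order (NaN where missing)."""
        return np.column_stack([self.channels[c] for c in CHANNEL_NAMES])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.channels, index=pd.DatetimeIndex(self.frame_times()))
        df.index.name = "time"
        return df


class AccelCSVError(ValueError):
    """Structured parse failure for an accelerometry CSV."""


def read_accel_csv(
    path,
    site: str,
    sample_rate: float | None = None,
) -> TriaxialRecording:
    """Read a ``timestamp,ax,ay,az`` CSV into a :class:`TriaxialRecording`.

    Timestamps are ISO-8601; acceleration is in g.  The sample rate is
    inferred as ``1 / median(dt)`` unless declared.  Gaps longer than twice
    the nominal period are flagged in ``gap_indices``.

    Raises
    ------
    AccelCSVError
        On missing columns or non-monotone timestamps (with the offending
        data line number).
    """
    df = pd.read_csv(path)
    for col in ("timestamp", "ax", "ay", "az"):
        if col not in df.columns:
            raise AccelCSVError(f"{path}: missing required column {col!r}")
    if len(df) == 0:
        raise AccelCSVError(f"{path}: no samples")
    ts = pd.to_datetime(df["timestamp"])
    dt = ts.diff().dt.total_seconds().to_numpy()[1:]
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        # +3: 1 for header, 1 for 0-based, 1 because diff[i] involves row i+1
        raise AccelCSVError(
            f"{path}: non-monotone timestamp at line {int(bad[0]) + 3}"
        )
    if sample_rate is None:
        if len(df) < 2:
            raise AccelCSVError(
                f"{path}: cannot infer sample rate from a single sample; "
                "pass sample_rate explicitly"
            )
        sample_rate = 1.0 / float(np.median(dt))
    period = 1.0 / sample_rate
    gap_indices = [int(i) for i in np.nonzero(dt > 2 * period)[0]]
    start = ts.iloc[0].to_pydatetime()
    time_s = (ts - ts.iloc[0]).dt.total_seconds().to_numpy()
    samples = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(samples)):
        row = int(np.nonzero(~np.isfinite(samples).all(axis=1))[0][0])
        raise AccelCSVError(f"{path}: non-finite acceleration at line {row + 2}")
    return TriaxialRecording(
        site=site,
        start_time=start,
        sample_rate=float(sample_rate),
        samples=samples,
        time_s=time_s,
        gap_indices=gap_indices,
    )


def resample(rec: TriaxialRecording, target_hz: float = TARGET_HZ) -> TriaxialRecording:
    """Linearly interpolate a recording onto a uniform grid at ``target_hz``.

    The start time is preserved; the grid covers the original span.  A
    recording already uniform at the target rate is returned unchanged.
    """
    if not target_hz > 0:
        raise ValueError(f"target_hz must be > 0, got {target_hz}")
    if len(rec) == 0:
        raise ValueError("cannot resample an empty recording")
    if rec.time_s is None and np.isclose(rec.sample_rate, target_hz):
        return rec
    src_t = rec.sample_times()
    n_out = int(np.floor(src_t[-1] * target_hz)) + 1
    new_t = np.arange(n_out) / target_hz
    out = np.column_stack(
        [np.interp(new_t, src_t, rec.samples[:, i]) for i in range(3)]
    )
    return TriaxialRecording(
        site=rec.site,
        start_time=rec.start_time,
        sample_rate=float(target_hz),
        samples=out,
        gap_indices=[],
    )


def frame_windows(rec: TriaxialRecording) -> list[Window]:
    """Slice a uniform 30 Hz recording into 60-sample windows with 30-sample hop.

    The trailing partial window is dropped; fewer than 60 samples yield an
    empty list.  Window ``i`` is centered at ``start_time + (i*30 + 30)/30`` s.
    """
    if rec.time_s is not None or not np.isclose(rec.sample_rate, TARGET_HZ):
        raise ValueError("frame_windows requires a uniform recording at 30 Hz")
    n = len(rec)
    if n < WINDOW_SAMPLES:
        return []
    count = (n - WINDOW_SAMPLES) // HOP_SAMPLES + 1
    return [
        Window(
            samples=rec.samples[i * HOP_SAMPLES : i * HOP_SAMPLES + WINDOW_SAMPLES],
            center_time=rec.start_time
            + timedelta(seconds=(i * HOP_SAMPLES + HOP_SAMPLES) / TARGET_HZ),
        )
        for i in range(count)
    ]


def inclination_deg(window: np.ndarray | Window, axis: int = 0) -> float:
    """Inclination of the longitudinal axis to the mean (gravity) vector, degrees.

    theta = arccos(mean_axis / ||mean vector||), in [0, 180].  A zero-magnitude
    mean vector has no defined inclination and yields NaN (a missing frame).
    """
    samples = window.samples if isinstance(window, Window) else np.asarray(window)
    mean = samples.mean(axis=0)
    norm = float(np.linalg.norm(mean))
    if norm == 0.0:
        return float("nan")
    return float(np.degrees(np.arccos(np.clip(mean[axis] / norm, -1.0, 1.0))))


def sd_longitudinal(window: np.ndarray | Window) -> float:
    """Population SD of the longitudinal (x) axis over the window, in g."""
    samples = window.samples if isinstance(window, Window) else np.asarray(window)
    return float(np.std(samples[:, 0]))


def classify_activity(
    thigh_incl_deg: float,
    thigh_sd_g: float,
    hip_sd_g: float,
    theta_sit_deg: float = THETA_SIT_DEG,
    s_move_g: float = S_MOVE_G,
) -> Activity:
    """Skotte-style activity class from thigh inclination and movement SDs.

    A near-vertical thigh (inclination <= ``theta_sit_deg``) is upright
    regardless of movement (standing, moving and walking share the +1 level);
    a horizontal, still thigh is sitting; a horizontal moving thigh is other
    activity.  ``hip_sd_g`` is accepted for signature completeness — the
    decision here rests on the thigh.
    """
    if not all(np.isfinite([thigh_incl_deg, thigh_sd_g, hip_sd_g])):
        raise ValueError("classify_activity requires finite inputs")
    if thigh_incl_deg <= theta_sit_deg:
        return Activity.UPRIGHT
    if thigh_sd_g <= s_move_g:
        return Activity.SITTING
    return Activity.OTHER


def classify_lying(
    hip_incl_deg: float,
    activity: Activity | int,
    theta_lying_deg: float = THETA_LYING_DEG,
) -> bool:
    """Lying: hip inclination strictly exceeds 65 degrees AND thigh is sitting."""
    if not np.isfinite(hip_incl_deg):
        raise ValueError("classify_lying requires a finite hip inclination")
    return hip_incl_deg > theta_lying_deg and int(activity) == int(Activity.SITTING)


#: Encoded levels of the six 4-hour time-of-day bins, [00:00,04:00) -> -1.0 etc.
TIME_BIN_LEVELS = (-1.0, -0.6, -0.2, 0.2, 0.6, 1.0)


def time_bin_level(timestamp: datetime) -> float:
    """Encoded level of the 4-hour local-clock bin containing ``timestamp``.

    Bins are left-closed right-open: [00:00, 04:00) -> -1.0, [04:00, 08:00)
    -> -0.6, ..., [20:00, 24:00) -> +1.0.
    """
    return TIME_BIN_LEVELS[timestamp.hour // 4]


def encode(value, channel_kind: str, sd_max_g: float = SD_MAX_G) -> float:
    """Map a raw feature value into the [-1, 1] channel scale.

    kinds: 'inclination' (deg in [0,180] -> theta/180, using only the
    non-negative half of the nominal -1..1 range), 'sd' (g, saturating at
    ``sd_max_g``: 0 g -> -1, >= sd_max -> +1), 'lying' (bool -> +/-1),
    'activity' (class level verbatim), 'time' (bin level verbatim).
    NaN propagates (missing frame).
    """
    if isinstance(value, float) and np.isnan(value):
        return float("nan")
    if channel_kind == "inclination":
        if not 0 <= value <= 180:
            raise ValueError(f"inclination must be in [0, 180], got {value}")
        return float(value) / 180.0
    if channel_kind == "sd":
        if value < 0:
            raise ValueError(f"SD must be >= 0, got {value}")
        return -1.0 + 2.0 * min(float(value), sd_max_g) / sd_max_g
    if channel_kind == "lying":
        return 1.0 if value else -1.0
    if channel_kind == "activity":
        level = float(int(value))
        if level not in (-1.0, 0.0, 1.0):
            raise ValueError(f"invalid activity level {value}")
        return level
    if channel_kind == "time":
        if value not in TIME_BIN_LEVELS:
            raise ValueError(f"invalid time bin level {value}")
        return float(value)
    raise ValueError(f"unknown channel kind {channel_kind!r}")


def _windowed_stats(samples: np.ndarray, count: int):
    """Vectorized per-window mean vector and longitudinal population SD."""
    idx = np.arange(count)[:, None] * HOP_SAMPLES + np.arange(WINDOW_SAMPLES)
    wins = samples[idx]  # (count, 60, 3)
    means = wins.mean(axis=1)
    sds = wins[:, :, 0].std(axis=1)
    return means, sds


def _inclinations(means: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(means, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosines = np.where(norms > 0, means[:, 0] / np.where(norms > 0, norms, 1.0), np.nan)
    return np.degrees(np.arccos(np.clip(cosines, -1.0, 1.0)))


def build_features(
    hip: TriaxialRecording,
    thigh: TriaxialRecording,
    target_hz: float = TARGET_HZ,
    theta_sit_deg: float = THETA_SIT_DEG,
    s_move_g: float = S_MOVE_G,
    theta_lying_deg: float = THETA_LYING_DEG,
    sd_max_g: float = SD_MAX_G,
) -> FeatureSeries:
    """Run the full two-site pipeline: resample, trim, window, classify, encode.

    Both recordings are resampled to 30 Hz, trimmed to their common time span
    and windowed in lockstep; the seven channels are computed per 1-s frame.
    Frames with an undefined inclination at either site are marked missing.

    Raises
    ------
    ValueError
        If the recordings do not overlap in time, or sites are swapped.
    """
    if hip.site != "hip" or thigh.site != "thigh":
        raise ValueError("recordings must be passed as (hip, thigh)")
    common_start = max(hip.start_time, thigh.start_time)
    common_end = min(hip.end_time, thigh.end_time)
    if common_end <= common_start:
        raise ValueError("recordings do not overlap in time")

    def trim_resample(rec: TriaxialRecording) -> TriaxialRecording:
        r = resample(rec, target_hz)
        lead = (common_start - r.start_time).total_seconds()
        i0 = int(np.ceil(round(lead * target_hz, 9)))
        span = (common_end - r.start_time).total_seconds()
        i1 = int(np.floor(round(span * target_hz, 9))) + 1
        return TriaxialRecording(
            site=r.site,
            start_time=r.start_time + timedelta(seconds=i0 / target_hz),
            sample_rate=target_hz,
            samples=r.samples[i0:i1],
        )

    hip_r = trim_resample(hip)
    thigh_r = trim_resample(thigh)
    n = min(len(hip_r), len(thigh_r))
    if n < WINDOW_SAMPLES:
        count = 0
    else:
        count = (n - WINDOW_SAMPLES) // HOP_SAMPLES + 1

    hip_means, hip_sds = _windowed_stats(hip_r.samples[:n], count) if count else (
        np.empty((0, 3)),
        np.empty(0),
    )
    thigh_means, thigh_sds = _windowed_stats(thigh_r.samples[:n], count) if count else (
        np.empty((0, 3)),
        np.empty(0),
    )
    hip_incl = _inclinations(hip_means)
    thigh_incl = _inclinations(thigh_means)

    missing = ~np.isfinite(hip_incl) | ~np.isfinite(thigh_incl)

    # Vectorized Skotte rule + lying rule.
    upright = thigh_incl <= theta_sit_deg
    sitting = ~upright & (thigh_sds <= s_move_g)
    activity = np.where(upright, 1.0, np.where(sitting, 0.0, -1.0))
    lying = (hip_incl > theta_lying_deg) & sitting
    activity[missing] = np.nan

    start = hip_r.start_time + timedelta(seconds=WINDOW_SAMPLES / (2 * target_hz))
    frame_times = [start + timedelta(seconds=i) for i in range(count)]
    time_ch = np.array([time_bin_level(t) for t in frame_times])

    def enc_sd(sds: np.ndarray) -> np.ndarray:
        return -1.0 + 2.0 * np.minimum(sds, sd_max_g) / sd_max_g

    channels = {
        "Lying": np.where(missing, np.nan, np.where(lying, 1.0, -1.0)),
        "Activity": activity,
        "Time": time_ch,
        "Thigh-SDacc": np.where(missing, np.nan, enc_sd(thigh_sds)),
        "Thigh-Inclination": thigh_incl / 180.0,
        "Hip-SDacc": np.where(missing, np.nan, enc_sd(hip_sds)),
        "Hip-Inclination": hip_incl / 180.0,
    }
    return FeatureSeries(start_time=start, channels=channels, missing=missing)
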