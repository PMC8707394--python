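"""Agreement statistics for in-bed timestamps: ICC and Bland-Altman.

Night-level to-bed / out-of-bed times from two or more sources (raters,
EEG-epoch reference, diary) are paired by (subject, night) and expressed in
minutes relative to the night's reference midnight (a 23:30 bedtime is -30,
a 00:15 bedtime is +15).  Agreement is then quantified two ways:

* **ICC** — two-way random-effects, absolute-agreement intraclass correlation
  (McGraw & Wong ICC(2,1) for single measures, ICC(2,k) for the average of k
  sources), with 95% confidence intervals from the F-distribution.  Unlike a
  Pearson correlation, the absolute-agreement ICC is penalized by systematic
  offsets between sources, not only by scatter.  Interpretation follows the
  conventional bands applied to the CI *lower bound*: < 0.5 poor, 0.5-0.75
  moderate, 0.75-0.9 good, >= 0.9 excellent.

* **Bland-Altman** — differences are oriented reference - test, so a positive
  bias means the test method places the timestamp *earlier* than the
  reference.  Limits of agreement are bias +/- 1.96 SD by default (a 2.0
  multiplier is available); confidence intervals use the t distribution with
  SE(bias) = SD/sqrt(n) and SE(LOA) = sqrt(3 SD^2 / n).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .audacity import InBedEvent

__all__ = [
    "PairedTimes",
    "ICCResult",
    "BAResult",
    "ICCUndefinedError",
    "minutes_from_midnight",
    "pair_sources",
    "pair_by_night",
    "icc",
    "interpret_icc",
    "bland_altman",
    "density_of_differences",
    "DensityResult",
]


def minutes_from_midnight(ts: datetime, night_id) -> float:
    """Minutes of ``ts`` relative to the midnight ending night ``night_id``.

    The reference midnight is 00:00 on the day *after* the night's calendar
    date, i.e. the midnight the sleeper sleeps through; times before it are
    negative.
    """
    ref = datetime.combine(night_id, datetime.min.time()) + timedelta(days=1)
    return (ts - ref).total_seconds() / 60.0


@dataclass
class PairedTimes:
    """Night-by-source matrix of timestamps in minutes from reference midnight.

    ``data`` is a DataFrame indexed by (subject, night) with one column per
    source; rows with any missing cell are dropped (complete-case analysis).
    """

    data: pd.DataFrame
    endpoint: str

    def __post_init__(self) -> None:
        if self.endpoint not in ("to_bed", "out_of_bed"):
            raise ValueError(f"endpoint must be to_bed or out_of_bed, got {self.endpoint!r}")
        if self.data.shape[1] < 2:
            raise ValueError("paired analysis needs at least 2 sources")
        self.data = self.data.dropna(axis=0, how="any")

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    def matrix(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def column(self, source: str) -> np.ndarray:
        return self.data[source].to_numpy(dtype=float)


def _events_frame(events: Iterable[InBedEvent], endpoint: str, label: str) -> pd.Series:
    idx, vals = [], []
    for ev in events:
        idx.append((ev.subject_id, ev.night_id))
        vals.append(minutes_from_midnight(getattr(ev, endpoint), ev.night_id))
    if len(set(idx)) != len(idx):
        dupes = pd.Index(idx)[pd.Index(idx).duplicated()].tolist()
        raise ValueError(f"duplicate (subject, night) in source {label!r}: {dupes}")
    return pd.Series(
        vals, index=pd.MultiIndex.from_tuples(idx or [("", "")], names=["subject", "night"])[: len(vals)], name=label
    )


def pair_sources(sources: dict[str, Iterable[InBedEvent]], endpoint: str) -> PairedTimes:
    """Join any number of event sources on (subject, night).

    Only nights present (and complete) in *every* source survive.
    """
    cols = {name: _events_frame(evs, endpoint, name) for name, evs in sources.items()}
    df = pd.concat(cols, axis=1, join="inner") if cols else pd.DataFrame()
    return PairedTimes(data=df, endpoint=endpoint)


def pair_by_night(
    events_a: Iterable[InBedEvent],
    events_b: Iterable[InBedEvent],
    endpoint: str,
    names: tuple[str, str] = ("A", "B"),
) -> PairedTimes:
    """Two-source convenience wrapper around :func:`pair_sources`."""
    return pair_sources({names[0]: events_a, names[1]: events_b}, endpoint)


@dataclass(frozen=True)
class ICCResult:
    """ICC estimate with 95% CI.

    For any data with a positive between-night variance component the CI
    brackets the estimate.  On pure-noise data the average-measures
    (Spearman-Brown) transform of the single-measure bounds has a pole at
    -1/(k-1) and the transformed lower bound can escape order; the exact
    formula values are reported rather than clamped.
    """

    estimate: float
    ci_low: float
    ci_high: float
    model: str  # "ICC(2,1)" or "ICC(2,k)"
    n_rows: int
    n_cols: int
    interpretation: str


class ICCUndefinedError(ValueError):
    """Raised when the ICC is undefined (zero total variance)."""


def _two_way_mean_squares(x: np.ndarray):
    """Row, column and residual mean squares of the two-way layout."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    return msr, msc, mse, ss_total


def icc(data: PairedTimes | np.ndarray, form: str = "single", alpha: float = 0.05) -> ICCResult:
    """Two-way random-effects, absolute-agreement intraclass correlation.

    Parameters
    ----------
    data : PairedTimes or (n, k) array
        Complete night-by-source matrix, n >= 5 rows.
    form : {'single', 'average'}
        ICC(2,1) of a single source, or ICC(2,k) of the k-source average.

    Notes
    -----
    Point estimates and F-based confidence intervals follow McGraw & Wong's
    two-way random, absolute agreement definitions; the ICC(2,k) interval is
    the Spearman-Brown transform of the single-measure interval.
    """
    x = data.matrix() if isinstance(data, PairedTimes) else np.asarray(data, dtype=float)
    if x.ndim != 2:
        raise ValueError("data must be a 2-D night-by-source matrix")
    n, k = x.shape
    if n < 5:
        raise ValueError(f"need at least 5 complete rows, got {n}")
    if k < 2:
        raise ValueError("need at least 2 sources")
    if form not in ("single", "average"):
        raise ValueError(f"form must be 'single' or 'average', got {form!r}")
    if np.any(~np.isfinite(x)):
        raise ValueError("data contain missing values; pairing is complete-case")

    msr, msc, mse, ss_total = _two_way_mean_squares(x)
    if ss_total == 0.0:
        raise ICCUndefinedError("zero total variance: ICC undefined")

    est1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    # McGraw-Wong CI for ICC(A,1): Satterthwaite dof for the denominator.
    fj = msc / mse if mse > 0 else np.inf
    df_err = (n - 1) * (k - 1)
    if np.isfinite(fj):
        vn = df_err * (k * est1 * fj + n * (1 + (k - 1) * est1) - k * est1) ** 2
        vd = (n - 1) * k**2 * est1**2 * fj**2 + (n * (1 + (k - 1) * est1) - k * est1) ** 2
        v = vn / vd
    else:
        v = n - 1.0
    f_u = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_l = stats.f.ppf(1 - alpha / 2, v, n - 1)
    low1 = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    high1 = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)

    if form == "single":
        est, low, high = est1, low1, high1
        model = "ICC(2,1)"
    else:
        est = (msr - mse) / (msr + (msc - mse) / n)
        low = low1 * k / (1 + low1 * (k - 1))
        high = high1 * k / (1 + high1 * (k - 1))
        model = "ICC(2,k)"
    return ICCResult(
        estimate=float(est),
        ci_low=float(low),
        ci_high=float(high),
        model=model,
        n_rows=n,
        n_cols=k,
        interpretation=interpret_icc(min(low, 1.0)),
    )


def interpret_icc(ci_low: float) -> str:
    """Agreement band of an ICC value (applied to the 95% CI lower bound).

    The F-based CI lower bound can fall below -1 on pure-noise data; any
    such value is simply "poor".  Values above 1 or non-finite are rejected.
    """
    if not np.isfinite(ci_low) or ci_low > 1:
        raise ValueError(f"ICC interpretation needs a finite value <= 1, got {ci_low}")
    if ci_low < 0.5:
        return "poor"
    if ci_low < 0.75:
        return "moderate"
    if ci_low < 0.9:
        return "good"
    return "excellent"


@dataclass(frozen=True)
class BAResult:
    """Bland-Altman summary in minutes (difference = reference - test)."""

    bias: float
    bias_ci: tuple[float, float]
    loa_lower: float
    loa_lower_ci: tuple[float, float]
    loa_upper: float
    loa_upper_ci: tuple[float, float]
    sd_diff: float
    n: int


def bland_altman(
    test_minutes: Sequence[float],
    ref_minutes: Sequence[float],
    loa_multiplier: float = 1.96,
    alpha: float = 0.05,
) -> BAResult:
    """Bland-Altman bias and limits of agreement with 95% CIs.

    Differences are ``reference - test``, so a test method that places
    timestamps earlier than the reference produces a positive bias.  The SD
    of differences uses the n-1 (sample) denominator.
    """
    test = np.asarray(test_minutes, dtype=float)
    ref = np.asarray(ref_minutes, dtype=float)
    if test.shape != ref.shape or test.ndim != 1:
        raise ValueError("test and reference must be equal-length 1-D vectors")
    n = len(test)
    if n < 3:
        raise ValueError(f"Bland-Altman needs at least 3 pairs, got {n}")
    diff = ref - test
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    t = float(stats.t.ppf(1 - alpha / 2, n - 1))
    se_bias = sd / np.sqrt(n)
    se_loa = np.sqrt(3.0 * sd**2 / n)
    loa_low = bias - loa_multiplier * sd
    loa_high = bias + loa_multiplier * sd
    return BAResult(
        bias=bias,
        bias_ci=(bias - t * se_bias, bias + t * se_bias),
        loa_lower=loa_low,
        loa_lower_ci=(loa_low - t * se_loa, loa_low + t * se_loa),
        loa_upper=loa_high,
        loa_upper_ci=(loa_high - t * se_loa, loa_high + t * se_loa),
        sd_diff=sd,
        n=n,
    )


@dataclass(frozen=True)
class DensityResult:
    grid: np.ndarray
    density: np.ndarray
    point_mass: bool = False


def density_of_differences(
    diffs: Sequence[float],
    grid: np.ndarray | None = None,
    gridsize: int = 512,
) -> DensityResult:
    """Gaussian kernel density of timestamp differences (Silverman bandwidth).

    With a zero-variance input the density is a spike; a degenerate
    point-mass result (single grid point, unit mass) is returned instead of a
    kernel estimate.
    """
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 1 or len(d) < 2:
        raise ValueError("need at least 2 differences")
    if np.allclose(d, d[0]):
        return DensityResult(grid=np.array([d[0]]), density=np.array([1.0]), point_mass=True)
    kde = stats.gaussian_kde(d, bw_method="silverman")
    if grid is None:
        span = d.max() - d.min()
        grid = np.linspace(d.min() - 0.5 * span, d.max() + 0.5 * span, gridsize)
    else:
        grid = np.asarray(grid, dtype=float)
    return DensityResult(grid=grid, density=kde(grid))
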