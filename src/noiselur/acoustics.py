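"""Period noise metrics from raw 1-second A-weighted sound level series.

The measurement protocol modelled here is a fixed five-day analysis window
(Wednesday 06:00 to the following Monday 06:00, 432,000 seconds), a
completeness rule (sites missing more than 10% of the window are excluded),
a single-pass 3-standard-deviation outlier screen on the dB scale, and the
standard day/evening/night equivalent levels with the duration-weighted
day-evening-night level ``L_den`` (+5 dB evening, +10 dB night penalty).

All aggregation is energetic: levels are averaged as ``10^(L/10)`` energies
and converted back to dB, never as arithmetic dB means.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SoundLevelSeries",
    "AnalysisWindow",
    "PeriodDefinition",
    "CleaningReport",
    "NoiseMetrics",
    "DAY",
    "EVENING",
    "NIGHT",
    "FULL",
    "PERIODS",
    "energetic_mean",
    "restrict_to_window",
    "assess_completeness",
    "remove_outliers",
    "period_level",
    "lden_from_components",
    "compute_metrics",
    "read_series_csv",
    "write_metrics_csv",
    "SiteExcludedError",
    "NoSamplesError",
]

#: Physical plausibility bounds for A-weighted levels from a type-II logger.
LEVEL_MIN_DB = 0.0
LEVEL_MAX_DB = 140.0

#: Missingness threshold: strictly more than this fraction missing excludes.
MAX_MISSING_FRACTION = 0.10

#: Outlier screen width in standard deviations (two-sided, single pass).
OUTLIER_SD = 3.0


class NoSamplesError(ValueError):
    """Raised when an operation receives no samples to aggregate."""


class SiteExcludedError(RuntimeError):
    """Raised when a site fails the completeness rule; carries the report."""

    def __init__(self, site_id: str, report: "CleaningReport"):
        self.site_id = site_id
        self.report = report
        super().__init__(
            f"site {site_id!r} excluded: {report.fraction_missing:.1%} of the "
            f"analysis window is missing (limit {MAX_MISSING_FRACTION:.0%})"
        )


@dataclass(frozen=True)
class PeriodDefinition:
    """A clock-time period of the 24-h cycle with its L_den penalty."""

    name: str
    start_hour: int
    end_hour: int
    duration_hours: int
    penalty_db: float

    def contains_hour(self, hours: np.ndarray) -> np.ndarray:
        """Boolean mask of clock hours inside [start, end), wrapping midnight."""
        if self.name == "full":
            return np.ones(len(hours), dtype=bool)
        if self.start_hour < self.end_hour:
            return (hours >= self.start_hour) & (hours < self.end_hour)
        return (hours >= self.start_hour) | (hours < self.end_hour)


DAY = PeriodDefinition("day", 6, 18, 12, 0.0)
EVENING = PeriodDefinition("evening", 18, 22, 4, 5.0)
NIGHT = PeriodDefinition("night", 22, 6, 8, 10.0)
FULL = PeriodDefinition("full", 6, 6, 24, 0.0)
PERIODS = (DAY, EVENING, NIGHT, FULL)


@dataclass(frozen=True)
class AnalysisWindow:
    """Fixed five-day measurement window, Wednesday 06:00 to Monday 06:00."""

    start: pd.Timestamp
    end: pd.Timestamp

    def __post_init__(self) -> None:
        start = pd.Timestamp(self.start)
        end = pd.Timestamp(self.end)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        if end - start != pd.Timedelta(hours=120):
            raise ValueError("analysis window must span exactly 120 hours")
        if start.weekday() != 2 or (start.hour, start.minute, start.second) != (6, 0, 0):
            raise ValueError("analysis window must start on a Wednesday at 06:00")

    @property
    def expected_seconds(self) -> int:
        return int((self.end - self.start) // pd.Timedelta(seconds=1))

    @classmethod
    def five_day(cls, start: str | pd.Timestamp) -> "AnalysisWindow":
        start = pd.Timestamp(start)
        return cls(start=start, end=start + pd.Timedelta(hours=120))


@dataclass
class SoundLevelSeries:
    """One site's 1-s A-weighted equivalent levels with civil timestamps.

    ``samples`` is a float Series indexed by a strictly increasing
    ``DatetimeIndex`` at whole-second resolution; levels must be finite and
    within [0, 140] dB(A). Duplicate or sub-second timestamps are rejected
    rather than merged.
    """

    site_id: str
    samples: pd.Series

    def __post_init__(self) -> None:
        s = self.samples
        if not isinstance(s.index, pd.DatetimeIndex):
            raise TypeError("samples must be indexed by a DatetimeIndex")
        if len(s) and not s.index.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")
        if s.index.has_duplicates:
            raise ValueError("duplicate timestamps")
        if len(s) and ((s.index.microsecond != 0).any() or (s.index.nanosecond != 0).any()):
            raise ValueError("sub-second timestamps are not supported")
        values = s.to_numpy(dtype=float)
        if len(values) and not np.isfinite(values).all():
            raise ValueError("levels must be finite")
        if len(values) and ((values < LEVEL_MIN_DB) | (values > LEVEL_MAX_DB)).any():
            raise ValueError(
                f"levels outside [{LEVEL_MIN_DB}, {LEVEL_MAX_DB}] dB(A)"
            )
        self.samples = s.astype(float)

    def __len__(self) -> int:
        return len(self.samples)

    @classmethod
    def from_arrays(
        cls, site_id: str, timestamps: Iterable, levels: Iterable[float]
    ) -> "SoundLevelSeries":
        idx = pd.DatetimeIndex(timestamps)
        return cls(site_id, pd.Series(np.asarray(list(levels), dtype=float), index=idx))


@dataclass
class CleaningReport:
    """Bookkeeping for the completeness and outlier screens of one site."""

    n_expected: int
    n_present: int
    mean_db: float = float("nan")
    sd_db: float = float("nan")
    n_outliers_removed: int = 0

    @property
    def fraction_missing(self) -> float:
        return 1.0 - self.n_present / self.n_expected

    @property
    def valid(self) -> bool:
        # "more than 10%" excludes: exactly 10% missing is retained.
        return self.fraction_missing <= MAX_MISSING_FRACTION


@dataclass(frozen=True)
class NoiseMetrics:
    """The five aggregated period levels for one site, in dB(A)."""

    site_id: str
    l_day: float
    l_evening: float
    l_night: float
    l_aeq24h: float
    l_den: float

    def as_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "l_day": self.l_day,
            "l_evening": self.l_evening,
            "l_night": self.l_night,
            "l_aeq24h": self.l_aeq24h,
            "l_den": self.l_den,
        }


def energetic_mean(levels: Sequence[float] | np.ndarray) -> float:
    """Equal-energy mean of dB values: ``10*log10(mean(10^(L/10)))``.

    Always at least the arithmetic dB mean (Jensen's inequality); equal to it
    exactly when all levels coincide.
    """
    arr = np.asarray(levels, dtype=float)
    if arr.size == 0:
        raise NoSamplesError("no samples in period")
    if not np.isfinite(arr).all():
        raise ValueError("levels must be finite")
    return float(10.0 * np.log10(np.mean(np.power(10.0, arr / 10.0))))


def restrict_to_window(
    series: SoundLevelSeries, window: AnalysisWindow
) -> SoundLevelSeries:
    """Keep only samples with ``window.start <= t < window.end``."""
    s = series.samples
    mask = (s.index >= window.start) & (s.index < window.end)
    kept = s[mask]
    if kept.empty:
        raise NoSamplesError(
            f"site {series.site_id!r}: no data in analysis window "
            f"[{window.start}, {window.end})"
        )
    return SoundLevelSeries(series.site_id, kept)


def assess_completeness(
    series: SoundLevelSeries, window: AnalysisWindow
) -> CleaningReport:
    """Missingness against the 432,000 expected seconds of the window."""
    return CleaningReport(n_expected=window.expected_seconds, n_present=len(series))


def remove_outliers(
    series: SoundLevelSeries,
) -> tuple[SoundLevelSeries, CleaningReport]:
    """Single-pass screen: drop samples beyond ±3 SD of the five-day dB mean.

    Mean and SD are computed arithmetically on the dB values of the input
    series; flagged samples are removed in one pass with no re-evaluation, so
    removing them never reclassifies the remaining samples.
    """
    if len(series) == 0:
        raise NoSamplesError("cannot screen an empty series")
    values = series.samples.to_numpy()
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    keep = np.abs(values - mean) <= OUTLIER_SD * sd
    report = CleaningReport(
        n_expected=len(series),
        n_present=len(series),
        mean_db=mean,
        sd_db=sd,
        n_outliers_removed=int((~keep).sum()),
    )
    cleaned = SoundLevelSeries(series.site_id, series.samples[keep])
    return cleaned, report


def period_level(series: SoundLevelSeries, period: PeriodDefinition) -> float:
    """Energetic mean of all samples whose clock time falls in the period.

    Samples are pooled across all days of the window (night wraps midnight;
    ``full`` takes every sample), not averaged per day first.
    """
    hours = series.samples.index.hour.to_numpy()
    mask = period.contains_hour(hours)
    if not mask.any():
        raise NoSamplesError(f"no samples in period {period.name!r}")
    return energetic_mean(series.samples.to_numpy()[mask])


def lden_from_components(l_day: float, l_evening: float, l_night: float) -> float:
    """Day-evening-night level from the three period levels.

    Duration-weighted energetic combination with +5 dB on the evening and
    +10 dB on the night term::

        L_den = 10*log10((12*10^(Ld/10) + 4*10^((Le+5)/10) + 8*10^((Ln+10)/10)) / 24)
    """
    terms = (
        DAY.duration_hours * 10.0 ** (l_day / 10.0)
        + EVENING.duration_hours * 10.0 ** ((l_evening + EVENING.penalty_db) / 10.0)
        + NIGHT.duration_hours * 10.0 ** ((l_night + NIGHT.penalty_db) / 10.0)
    )
    return float(10.0 * np.log10(terms / 24.0))


def compute_metrics(
    series: SoundLevelSeries,
    window: AnalysisWindow,
    *,
    return_report: bool = False,
):
    """Full cleaning-and-aggregation chain for one site.

    Window restriction, then the 10% completeness rule (failures raise
    :class:`SiteExcludedError`), then the 3-SD outlier screen, then the four
    period levels and ``L_den``. Outlier-removed seconds do not count toward
    the missingness budget.
    """
    restricted = restrict_to_window(series, window)
    completeness = assess_completeness(restricted, window)
    if not completeness.valid:
        raise SiteExcludedError(series.site_id, completeness)
    cleaned, outlier_report = remove_outliers(restricted)
    report = CleaningReport(
        n_expected=window.expected_seconds,
        n_present=len(restricted),
        mean_db=outlier_report.mean_db,
        sd_db=outlier_report.sd_db,
        n_outliers_removed=outlier_report.n_outliers_removed,
    )
    metrics = NoiseMetrics(
        site_id=series.site_id,
        l_day=period_level(cleaned, DAY),
        l_evening=period_level(cleaned, EVENING),
        l_night=period_level(cleaned, NIGHT),
        l_aeq24h=period_level(cleaned, FULL),
        l_den=lden_from_components(
            period_level(cleaned, DAY),
            period_level(cleaned, EVENING),
            period_level(cleaned, NIGHT),
        ),
    )
    if return_report:
        return metrics, report
    return metrics


# ---------------------------------------------------------------------------
# File interfaces


def read_series_csv(path: str | Path, site_id: str | None = None) -> SoundLevelSeries:
    """Read one site's series from a ``timestamp,laeq_db`` CSV."""
    path = Path(path)
    df = pd.read_csv(path, parse_dates=["timestamp"])
    if site_id is None:
        site_id = path.stem
    return SoundLevelSeries(site_id, pd.Series(df["laeq_db"].to_numpy(), index=pd.DatetimeIndex(df["timestamp"])))


def write_series_csv(series: SoundLevelSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "timestamp": series.samples.index.strftime("%Y-%m-%dT%H:%M:%S"),
            "laeq_db": series.samples.to_numpy(),
        }
    ).to_csv(path, index=False)


def write_metrics_csv(
    rows: Sequence[tuple[NoiseMetrics | None, CleaningReport, str]],
    path: str | Path,
) -> pd.DataFrame:
    """Write the per-site metrics table; excluded sites keep NaN metrics.

    ``rows`` holds ``(metrics_or_None, report, site_id)`` triples.
    """
    records = []
    for metrics, report, site_id in rows:
        rec = {
            "site_id": site_id,
            "l_day": np.nan,
            "l_evening": np.nan,
            "l_night": np.nan,
            "l_aeq24h": np.nan,
            "l_den": np.nan,
            "fraction_missing": report.fraction_missing,
            "n_outliers_removed": report.n_outliers_removed,
            "valid": report.valid,
        }
        if metrics is not None:
            rec.update({k: v for k, v in metrics.as_dict().items() if k != "site_id"})
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    df.to_csv(path, index=False, float_format="%.6f")
    return df
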