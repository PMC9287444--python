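"""Curation of underwater navigation tracks.

Raw position data from ship or vehicle navigation contains outliers
(acoustic positioning dropouts, multipath spikes) and high-frequency
noise.  Before positions can be attached to images the track is curated:
spikes are rejected against a running median using the median absolute
deviation (MAD), the track is smoothed with a centered moving average,
and image timestamps are geolocated by piecewise-linear interpolation.

Horizontal distances use a local equirectangular approximation about the
track's mean latitude: at marine-survey scales (meters between fixes)
the error is negligible, though the approximation degrades near the
poles.  Longitudes are unwrapped before interpolation so antimeridian
crossings behave.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import format_datetime

__all__ = [
    "NavigationTrack",
    "UtcReport",
    "PositionFix",
    "load_track",
    "verify_utc",
    "remove_outliers",
    "smooth",
    "interpolate_to",
]

EARTH_RADIUS_M = 6_371_000.0
MAD_FLOOR_M = 0.01  # 1 cm: avoids zero-division on static (moored) tracks

_UTC_SUFFIX_RE = re.compile(r"(Z|\+00:00|\+0000)$")


@dataclass
class NavigationTrack:
    """A time-ordered sequence of position samples.

    Backed by a DataFrame with columns ``datetime`` (tz-aware UTC),
    ``latitude``, ``longitude``, ``depth`` and ``flags`` (tuple of
    strings per sample).  Timestamps are strictly increasing.
    """

    samples: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"datetime", "latitude", "longitude", "depth", "flags"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValueError(f"track frame lacks columns: {sorted(missing)}")
        times = self.samples["datetime"]
        if len(times) > 1 and not times.is_monotonic_increasing:
            raise ValueError("track timestamps must be increasing")
        lat, lon = self.samples["latitude"], self.samples["longitude"]
        if len(lat) and (lat.abs().max() > 90 or lon.abs().max() > 180):
            raise ValueError("coordinates outside global ranges")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def timestamps(self) -> list[_dt.datetime]:
        return [ts.to_pydatetime() for ts in self.samples["datetime"]]


def _parse_timestamp(text: str, row: int) -> tuple[_dt.datetime, bool]:
    """Parse one CSV timestamp; returns (aware UTC datetime, had_designator)."""
    text = text.strip()
    explicit_utc = bool(_UTC_SUFFIX_RE.search(text))
    try:
        parsed = _dt.datetime.fromisoformat(text.replace("Z", "+00:00"))
    except ValueError as exc:
        raise ValueError(f"row {row}: unparseable datetime {text!r}") from exc
    if parsed.tzinfo is None:
        return parsed.replace(tzinfo=_dt.timezone.utc), False
    if parsed.utcoffset() != _dt.timedelta(0):
        raise ValueError(
            f"row {row}: datetime {text!r} carries a non-UTC offset; "
            "navigation data must be recorded in UTC"
        )
    return parsed.astimezone(_dt.timezone.utc), explicit_utc


def load_track(source: str | Path) -> NavigationTrack:
    """Load a navigation track from a CSV file.

    Required columns: ``datetime, latitude, longitude, depth``.  Rows
    are sorted by time (flagged if reordering was needed); rows sharing
    a timestamp are collapsed to their mean position and flagged.
    Non-UTC offsets are rejected outright; zone-naive timestamps are
    accepted here and flagged by :func:`verify_utc`.
    """
    frame = pd.read_csv(source)
    required = ["datetime", "latitude", "longitude", "depth"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"navigation CSV lacks columns: {missing}")
    times: list[_dt.datetime] = []
    naive_rows: list[int] = []
    for i, raw in enumerate(frame["datetime"].astype(str), start=2):  # row 1 = header
        parsed, explicit = _parse_timestamp(raw, i)
        if not explicit:
            naive_rows.append(i)
        times.append(parsed)
    frame = frame.assign(datetime=pd.Series(times, dtype="object"))
    frame["datetime"] = pd.to_datetime(frame["datetime"], utc=True)
    flags: list[tuple[str, ...]] = [() for _ in range(len(frame))]
    warnings: list[str] = []
    if naive_rows:
        warnings.append(
            f"{len(naive_rows)} timestamps lack an explicit UTC designator"
        )

    if not frame["datetime"].is_monotonic_increasing:
        order = frame["datetime"].argsort(kind="stable")
        frame = frame.iloc[order].reset_index(drop=True)
        flags = [("reordered",) for _ in range(len(frame))]
        warnings.append("input rows were not in time order; sorted")
    frame = frame.assign(flags=flags)

    if frame["datetime"].duplicated().any():
        agg = {
            "latitude": "mean",
            "longitude": "mean",
            "depth": "mean",
            "flags": lambda grp: tuple(
                sorted(set(sum(grp, ())) | ({"duplicate-mean"} if len(grp) > 1 else set()))
            ),
        }
        frame = (
            frame.groupby("datetime", as_index=False, sort=True).agg(agg)
        )
        warnings.append("duplicate timestamps collapsed to mean position")
    return NavigationTrack(samples=frame.reset_index(drop=True), warnings=warnings)


@dataclass
class UtcReport:
    """Findings from timestamp verification."""

    naive: list[int] = field(default_factory=list)       # indices lacking 'Z'
    non_monotone: list[int] = field(default_factory=list)
    gaps: list[tuple[int, float]] = field(default_factory=list)  # (index, seconds)

    @property
    def clean(self) -> bool:
        return not (self.naive or self.non_monotone or self.gaps)


def verify_utc(
    source: NavigationTrack | Sequence[str | _dt.datetime],
    gap_threshold_s: float = 60.0,
) -> UtcReport:
    """Check that a timestamp sequence is explicit UTC, monotone, gap-free.

    Accepts a curated track (whose timestamps are aware by construction)
    or a raw sequence of ISO strings / datetime objects.  A "gap" is an
    inter-sample spacing exceeding ``gap_threshold_s`` seconds.
    """
    report = UtcReport()
    instants: list[_dt.datetime | None] = []
    if isinstance(source, NavigationTrack):
        items: Iterable = source.timestamps
    else:
        items = source
    for i, item in enumerate(items):
        if isinstance(item, str):
            explicit = bool(_UTC_SUFFIX_RE.search(item.strip()))
            try:
                parsed = _dt.datetime.fromisoformat(item.strip().replace("Z", "+00:00"))
            except ValueError:
                report.naive.append(i)
                instants.append(None)
                continue
            if parsed.tzinfo is None:
                parsed = parsed.replace(tzinfo=_dt.timezone.utc)
                explicit = False
            if not explicit or parsed.utcoffset() != _dt.timedelta(0):
                report.naive.append(i)
            instants.append(parsed.astimezone(_dt.timezone.utc))
        else:
            if item.tzinfo is None:
                report.naive.append(i)
                instants.append(item.replace(tzinfo=_dt.timezone.utc))
            else:
                instants.append(item.astimezone(_dt.timezone.utc))
    previous: _dt.datetime | None = None
    for i, instant in enumerate(instants):
        if instant is None:
            continue
        if previous is not None:
            delta = (instant - previous).total_seconds()
            if delta <= 0:
                report.non_monotone.append(i)
            elif delta > gap_threshold_s:
                report.gaps.append((i, delta))
        previous = instant
    return report


# ---------------------------------------------------------------------------
# Local meter frame


def _local_frame(lat: np.ndarray, lon: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project lat/lon (degrees) to local east/north meters."""
    lat0 = float(np.mean(lat))
    lon_u = np.degrees(np.unwrap(np.radians(lon)))  # antimeridian-safe
    east = np.radians(lon_u) * EARTH_RADIUS_M * np.cos(np.radians(lat0))
    north = np.radians(lat) * EARTH_RADIUS_M
    return east, north


def _rolling_median(values: np.ndarray, window: int) -> np.ndarray:
    return (
        pd.Series(values)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


def _rolling_mad(values: np.ndarray, window: int) -> np.ndarray:
    def mad(block: np.ndarray) -> float:
        return float(np.median(np.abs(block - np.median(block))))

    return (
        pd.Series(values)
        .rolling(window, center=True, min_periods=1)
        .apply(lambda s: mad(s.to_numpy()), raw=False)
        .to_numpy()
    )


def remove_outliers(
    track: NavigationTrack, window: int = 11, k: float = 5.0
) -> NavigationTrack:
    """Reject spike samples against a running median, MAD-scaled.

    A sample is a horizontal outlier when its distance to the running
    median position (centered, ``window`` samples) exceeds ``k`` times
    the MAD of those distances within the window; depth outliers are
    judged the same way on the depth residual, independently.  The MAD
    is floored at 1 cm so a perfectly static track divides cleanly.
    Outliers are removed, never replaced.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if k <= 0:
        raise ValueError("k must be positive")
    n = len(track)
    if n < window:
        return replace(
            track,
            warnings=track.warnings + [f"track shorter than window ({n} < {window}); unchanged"],
        )
    frame = track.samples
    lat = frame["latitude"].to_numpy(float)
    lon = frame["longitude"].to_numpy(float)
    depth = frame["depth"].to_numpy(float)
    east, north = _local_frame(lat, lon)

    med_e = _rolling_median(east, window)
    med_n = _rolling_median(north, window)
    dist = np.hypot(east - med_e, north - med_n)
    mad_h = np.maximum(_rolling_mad(dist, window), MAD_FLOOR_M)
    horiz_out = dist > k * mad_h

    med_d = _rolling_median(depth, window)
    ddist = np.abs(depth - med_d)
    mad_d = np.maximum(_rolling_mad(ddist, window), MAD_FLOOR_M)
    depth_out = ddist > k * mad_d

    outliers = horiz_out | depth_out
    if outliers.sum() > 0.5 * n:
        return replace(
            track,
            warnings=track.warnings
            + [
                f"{int(outliers.sum())}/{n} samples flagged as outliers; "
                "refusing to delete more than half the track"
            ],
        )
    kept = frame.loc[~outliers].reset_index(drop=True)
    warnings = list(track.warnings)
    if outliers.any():
        warnings.append(f"removed {int(outliers.sum())} outlier samples")
    return NavigationTrack(samples=kept, warnings=warnings)


def smooth(track: NavigationTrack, window: int = 11) -> NavigationTrack:
    """Centered moving average per coordinate.

    Near the track ends the largest available symmetric window is used,
    so the first and last samples pass through unchanged.  Intended to
    run after :func:`remove_outliers` (a mean is not spike-robust).
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    n = len(track)
    if n < window:
        return replace(
            track,
            warnings=track.warnings + [f"track shorter than window ({n} < {window}); unchanged"],
        )
    frame = track.samples.copy()
    half = window // 2
    for column in ("latitude", "longitude", "depth"):
        values = frame[column].to_numpy(float)
        out = np.empty_like(values)
        for i in range(n):
            h = min(half, i, n - 1 - i)
            out[i] = values[i - h : i + h + 1].mean()
        frame[column] = out
    return NavigationTrack(samples=frame, warnings=list(track.warnings))


@dataclass(frozen=True)
class PositionFix:
    """An interpolated position for one query timestamp."""

    datetime: str
    latitude: float | None
    longitude: float | None
    depth: float | None
    uncertainty_meters: float | None
    error: str | None = None


def interpolate_to(
    track: NavigationTrack,
    timestamps: Sequence[_dt.datetime | str],
    sensor_uncertainty_m: float = 0.0,
    extrapolation_tolerance_s: float = 5.0,
) -> list[PositionFix]:
    """Geolocate timestamps on the track by piecewise-linear interpolation.

    Each coordinate is interpolated independently (longitude unwrapped
    across the antimeridian first).  Queries at sample times reproduce
    the sample exactly.  Queries outside the track's span are clamped to
    the nearest endpoint if within ``extrapolation_tolerance_s`` seconds,
    otherwise reported as a per-timestamp error entry.

    The reported uncertainty is the configured sensor uncertainty plus
    half the horizontal displacement of the bracketing sample pair — the
    position is known no better than the track moves between fixes.
    """
    if len(track) == 0:
        raise ValueError("cannot interpolate on an empty track")
    frame = track.samples
    t = frame["datetime"].astype("int64").to_numpy() / 1e9  # epoch seconds
    lat = frame["latitude"].to_numpy(float)
    lon_unwrapped = np.degrees(np.unwrap(np.radians(frame["longitude"].to_numpy(float))))
    depth = frame["depth"].to_numpy(float)
    east, north = _local_frame(lat, frame["longitude"].to_numpy(float))
    seg_disp = np.hypot(np.diff(east), np.diff(north)) if len(t) > 1 else np.array([])

    fixes: list[PositionFix] = []
    for stamp in timestamps:
        if isinstance(stamp, str):
            instant = _dt.datetime.fromisoformat(stamp.replace("Z", "+00:00"))
        else:
            instant = stamp
        if instant.tzinfo is None:
            instant = instant.replace(tzinfo=_dt.timezone.utc)
        label = format_datetime(instant)
        q = instant.timestamp()
        if q < t[0] - extrapolation_tolerance_s or q > t[-1] + extrapolation_tolerance_s:
            fixes.append(
                PositionFix(label, None, None, None, None,
                            error="timestamp outside track span beyond tolerance")
            )
            continue
        qc = min(max(q, t[0]), t[-1])
        qlat = float(np.interp(qc, t, lat))
        qlon = float(np.interp(qc, t, lon_unwrapped))
        qlon = ((qlon + 180.0) % 360.0) - 180.0
        qdepth = float(np.interp(qc, t, depth))
        if len(t) > 1:
            right = int(np.searchsorted(t, qc, side="right"))
            seg = min(max(right - 1, 0), len(seg_disp) - 1)
            uncertainty = sensor_uncertainty_m + 0.5 * float(seg_disp[seg])
        else:
            uncertainty = sensor_uncertainty_m
        fixes.append(PositionFix(label, qlat, qlon, qdepth, uncertainty))
    return fixes
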