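"""Rule-of-Twelfths tidal interpolation and habitat accessibility.

Tide tables list only the extremes (times and heights of high and low water).
The Rule of Twelfths approximates the roughly sinusoidal height between two
consecutive opposite extremes by splitting the interval into six equal parts
and allocating 1/12, 2/12, 3/12, 3/12, 2/12 and 1/12 of the range to them
(cumulative 1, 3, 6, 9, 11, 12 twelfths), with linear interpolation inside
each part. From interpolated heights and a habitat's benthos level the
fraction of the year each reef zone holds enough water (>= 30 cm by default)
for roving herbivores to graze is computed.

All heights are relative to the tide-table datum of the extremes series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import OutOfBoundsError

_CUM_TWELFTHS = np.array([0.0, 1.0, 3.0, 6.0, 9.0, 11.0, 12.0]) / 12.0
_BREAKS = np.linspace(0.0, 1.0, 7)


def _as_epoch_seconds(t):
    """Convert timestamps (str/datetime/Timestamp/array) to float epoch seconds."""
    arr = pd.to_datetime(t)
    if isinstance(arr, pd.Timestamp):
        return arr.value / 1e9
    return pd.DatetimeIndex(arr).asi8 / 1e9


@dataclass(frozen=True)
class TideExtremes:
    """Alternating high/low water events with strictly increasing times."""

    times: pd.DatetimeIndex
    heights: np.ndarray
    kinds: np.ndarray  # 'high' / 'low'

    def __post_init__(self):
        times = pd.DatetimeIndex(pd.to_datetime(self.times))
        heights = np.asarray(self.heights, dtype=float)
        kinds = np.asarray(self.kinds, dtype=object)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "heights", heights)
        object.__setattr__(self, "kinds", kinds)
        if not (len(times) == len(heights) == len(kinds)):
            raise ValueError("times, heights and kinds must have equal length")
        if len(times) < 2:
            raise ValueError("need at least two extremes")
        if not times.is_monotonic_increasing or times.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")
        if not set(kinds) <= {"high", "low"}:
            raise ValueError("kinds must be 'high' or 'low'")
        if any(kinds[i] == kinds[i + 1] for i in range(len(kinds) - 1)):
            raise ValueError("high/low events must strictly alternate")

    @property
    def span(self) -> tuple:
        return (self.times[0], self.times[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.times,
                "height_m": self.heights,
                "kind": ["H" if k == "high" else "L" for k in self.kinds],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TideExtremes":
        kinds = np.where(df["kind"].astype(str).str.upper().str.startswith("H"), "high", "low")
        return cls(times=pd.DatetimeIndex(pd.to_datetime(df["timestamp"])), heights=df["height_m"].to_numpy(), kinds=kinds)


@dataclass(frozen=True)
class HabitatDepthSpec:
    """A habitat's benthos level relative to the tide datum."""

    habitat: str
    benthos_level: float
    site: str = ""

    def __post_init__(self):
        if not np.isfinite(self.benthos_level):
            raise ValueError("benthos_level must be finite")


def rule_of_twelfths(prev: tuple, nxt: tuple, t) -> float:
    """Interpolated tide height at ``t`` between consecutive opposite extremes.

    ``prev`` and ``nxt`` are ``(time, height)`` pairs. The cumulative height
    change after sub-interval k of six equals (1, 3, 6, 9, 11, 12)/12 of the
    range, linear inside each sub-interval, rising or falling with the sign
    of the range.
    """
    t0, h0 = _as_epoch_seconds(prev[0]), float(prev[1])
    t1, h1 = _as_epoch_seconds(nxt[0]), float(nxt[1])
    if t1 <= t0:
        raise ValueError("extremes must be in increasing time order")
    if h0 == h1:
        raise ValueError("consecutive extremes of equal height look like same-kind events")
    ts = np.atleast_1d(_as_epoch_seconds(t)).astype(float)
    if np.any(ts < t0 - 1e-9) or np.any(ts > t1 + 1e-9):
        raise ValueError("query time outside the extreme pair's interval")
    frac = np.clip((ts - t0) / (t1 - t0), 0.0, 1.0)
    cum = np.interp(frac, _BREAKS, _CUM_TWELFTHS)
    out = h0 + cum * (h1 - h0)
    return float(out[0]) if out.size == 1 else out


def tide_height(extremes: TideExtremes, t):
    """Tide height at time(s) ``t`` via the Rule of Twelfths (vectorised)."""
    ts = np.atleast_1d(_as_epoch_seconds(t)).astype(float)
    et = extremes.times.asi8 / 1e9
    if np.any(ts < et[0] - 1e-9) or np.any(ts > et[-1] + 1e-9):
        raise OutOfBoundsError("query time outside the extremes series span")
    idx = np.clip(np.searchsorted(et, ts, side="right") - 1, 0, len(et) - 2)
    t0, t1 = et[idx], et[idx + 1]
    h0, h1 = extremes.heights[idx], extremes.heights[idx + 1]
    frac = np.clip((ts - t0) / (t1 - t0), 0.0, 1.0)
    cum = np.interp(frac, _BREAKS, _CUM_TWELFTHS)
    out = h0 + cum * (h1 - h0)
    scalar = np.isscalar(t) or isinstance(t, (str, pd.Timestamp)) or getattr(t, "ndim", 1) == 0
    return float(out[0]) if scalar and out.size == 1 else out


def tide_correct_depth(measured_depth: float, t, extremes: TideExtremes, datum: float = 0.0) -> float:
    """Benthos level (m relative to ``datum``) from a depth reading at time ``t``.

    ``benthos = tide_height(t) - measured_depth``; independent of when the
    reading was taken, up to gauge precision.
    """
    return float(tide_height(extremes, t)) - float(measured_depth) - float(datum)


def accessibility(
    spec: HabitatDepthSpec,
    extremes: TideExtremes,
    threshold: float = 0.30,
    step: pd.Timedelta | str = "10min",
) -> float:
    """Percent of the series span with water depth >= ``threshold`` over the habitat.

    Depth exactly at the threshold counts as accessible; the complement is
    the percentage of time the habitat is covered by less water than roving
    herbivores need to graze.
    """
    t0, t1 = extremes.span
    grid = pd.date_range(t0, t1, freq=pd.Timedelta(step))
    depth = tide_height(extremes, grid) - spec.benthos_level
    return float(100.0 * np.mean(depth >= threshold))


def accessibility_report(
    specs: list,
    extremes: TideExtremes,
    threshold: float = 0.30,
    step="10min",
) -> pd.DataFrame:
    """Accessibility table for a list of :class:`HabitatDepthSpec`."""
    rows = []
    for s in specs:
        pct = accessibility(s, extremes, threshold=threshold, step=step)
        rows.append(
            {
                "site": s.site,
                "habitat": s.habitat,
                "benthos_level_m": s.benthos_level,
                "pct_accessible": pct,
                "pct_excluded": 100.0 - pct,
            }
        )
    return pd.DataFrame(rows)
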