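"""Hourly crowding indicators and daily crisis labels.

A subgroup is crowded in a given hour when its occupancy ratio (EDOR)
reaches the mortality-associated threshold (default 0.90, compared with
``>=``).  A calendar day is a crisis day for a subgroup when at least
``min_crowded_hours`` (default 3) of its 24 hours are crowded.  The daily
label covers the whole calendar day and is shared by every forecast origin
of that day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from edcrowd.sim_ed import HourlyOccupancyPanel
from edcrowd.subgroups import SUBGROUPS


@dataclass(frozen=True)
class CrowdingConfig:
    edor_threshold: float = 0.90
    min_crowded_hours: int = 3

    def validate(self) -> None:
        if not self.edor_threshold > 0:
            raise ValueError("edor_threshold must be > 0")
        if self.min_crowded_hours < 1:
            raise ValueError("min_crowded_hours must be >= 1")


@dataclass
class CrowdingLabels:
    """Per-(subgroup, hour) indicators and per-(subgroup, date) crisis labels.

    hourly : DataFrame, hourly DatetimeIndex, one bool column per subgroup.
    daily : DataFrame, date index, one bool column per subgroup.
    crowded_hour_count : DataFrame, date index, one int column per subgroup.
    """

    hourly: pd.DataFrame
    daily: pd.DataFrame
    crowded_hour_count: pd.DataFrame

    def to_csv(self, path) -> None:
        rows = []
        for s in SUBGROUPS:
            rows.append(
                pd.DataFrame(
                    {
                        "subgroup": s,
                        "date": self.daily.index,
                        "crowded_hour_count": self.crowded_hour_count[s].to_numpy(),
                        "label": self.daily[s].astype(int).to_numpy(),
                    }
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, hourly: pd.DataFrame | None = None) -> "CrowdingLabels":
        long = pd.read_csv(path, parse_dates=["date"])
        long["date"] = long["date"].dt.date
        daily = long.pivot(index="date", columns="subgroup", values="label")
        counts = long.pivot(
            index="date", columns="subgroup", values="crowded_hour_count"
        )
        daily = daily[list(SUBGROUPS)].astype(bool)
        counts = counts[list(SUBGROUPS)].astype(int)
        daily.index.name = None
        counts.index.name = None
        daily.columns.name = None
        counts.columns.name = None
        if hourly is None:
            hourly = pd.DataFrame()
        return cls(hourly=hourly, daily=daily, crowded_hour_count=counts)


def _check_complete_days(index: pd.DatetimeIndex) -> None:
    if len(index) == 0:
        raise ValueError("empty hourly series")
    expected = pd.date_range(index[0], periods=len(index), freq="h")
    if not index.equals(expected):
        missing = expected.difference(index)
        raise ValueError(f"hourly grid has gaps or duplicates; first gaps: {missing[:5].tolist()}")
    if index[0].hour != 0 or index[-1].hour != 23:
        raise ValueError(
            "hourly series must cover whole calendar days (00:00 through 23:00); "
            f"got {index[0]} .. {index[-1]}"
        )


def hourly_crowding(
    panel: HourlyOccupancyPanel, config: CrowdingConfig = CrowdingConfig()
) -> pd.DataFrame:
    """Boolean crowding indicator per (hour, subgroup): EDOR >= threshold."""
    config.validate()
    idx = panel.frame.index
    if len(idx) == 0:
        raise ValueError("empty panel")
    expected = pd.date_range(idx[0], periods=len(idx), freq="h")
    if not idx.equals(expected):
        missing = expected.difference(idx)
        raise ValueError(f"hourly grid has gaps; first gaps: {missing[:5].tolist()}")
    out = {}
    for s in SUBGROUPS:
        out[s] = panel.frame[f"edor_{s}"].to_numpy() >= config.edor_threshold
    return pd.DataFrame(out, index=idx)


def daily_labels(
    hourly: pd.DataFrame, config: CrowdingConfig = CrowdingConfig()
) -> CrowdingLabels:
    """Aggregate hourly indicators into per-(subgroup, date) crisis labels.

    Raises if the series does not cover whole calendar days (no silent
    truncation of a partial final day).
    """
    config.validate()
    _check_complete_days(hourly.index)
    dates = pd.Index([ts.date() for ts in hourly.index[::24]])
    counts = {}
    for s in SUBGROUPS:
        v = hourly[s].to_numpy().reshape(-1, 24)
        counts[s] = v.sum(axis=1).astype(int)
    count_frame = pd.DataFrame(counts, index=dates)
    daily = count_frame >= config.min_crowded_hours
    return CrowdingLabels(hourly=hourly, daily=daily, crowded_hour_count=count_frame)


def crowding_labels(
    panel: HourlyOccupancyPanel, config: CrowdingConfig = CrowdingConfig()
) -> CrowdingLabels:
    """Convenience: hourly indicators + daily labels in one call."""
    return daily_labels(hourly_crowding(panel, config), config)


def daily_prevalence(labels: CrowdingLabels) -> dict[str, float]:
    """Fraction of crisis days per subgroup."""
    return {s: float(labels.daily[s].mean()) for s in SUBGROUPS}


def hourly_prevalence_by_hour(labels: CrowdingLabels) -> pd.DataFrame:
    """Crowding prevalence per hour of day (rows 0-23) and subgroup."""
    hours = np.asarray([ts.hour for ts in labels.hourly.index])
    out = {}
    for s in SUBGROUPS:
        v = labels.hourly[s].to_numpy()
        out[s] = [float(v[hours == h].mean()) for h in range(24)]
    return pd.DataFrame(out, index=range(24))
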