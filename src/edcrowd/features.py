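"""Design-matrix assembly: one row per (date, subgroup, forecast origin).

Each row carries 22 base variables — three holiday flags, weekday, month,
regional bed availability, eight daily crowding lags (each subgroup at
t−7 and t−14 days), five weather values, the subgroup code, the day's
crowding label and the origin code — plus a 1,344-column lookback block:
for every subgroup, the hourly crowding indicator and the absolute
occupancy count for the 168 hours [origin−168, origin−1].  With a 790-day
panel, four subgroups and six origins this is the canonical
18,960 × 1,366 matrix.

Lookback cells strictly precede the row's origin hour, so rows differ
across origins and no same-hour information can leak into a forecast.
Missing history (panel start, first 7/14 days for the lags) is carried as
NaN and rows are retained; the learner handles missingness natively.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from edcrowd.crowding import CrowdingLabels
from edcrowd.sim_ed import CovariatePanel, HourlyOccupancyPanel
from edcrowd.subgroups import SUBGROUP_CODES, SUBGROUPS

LOOKBACK_HOURS = 168
LAG_DAYS = (7, 14)
DEFAULT_ORIGINS = (8, 9, 10, 11, 12, 13)

#: short column tags, in subgroup code order
SUBGROUP_ABBREV = {
    "bedoccupying": "bed",
    "critical": "cri",
    "medical": "med",
    "surgical": "sur",
}

LABEL_COLUMN = "crowding"
CATEGORICAL_COLUMNS = ("weekday", "month", "subgroup", "origin")

BASE_COLUMNS = (
    "holiday",
    "after_holiday",
    "before_holiday",
    "weekday",
    "month",
    "beds_all",
    *[f"q90_{SUBGROUP_ABBREV[s]}_7" for s in SUBGROUPS],
    *[f"q90_{SUBGROUP_ABBREV[s]}_14" for s in SUBGROUPS],
    "precipitation_mm",
    "snow_depth_cm",
    "air_temp_mean_C",
    "air_temp_max_C",
    "air_temp_min_C",
    "subgroup",
    "origin",
    LABEL_COLUMN,
)


def lookback_columns() -> list[str]:
    """Canonical lookback column order: per subgroup (code order), 168
    crowding indicators then 168 occupancy counts, lag 1 = origin−1 first."""
    cols: list[str] = []
    for s in SUBGROUPS:
        a = SUBGROUP_ABBREV[s]
        cols += [f"lb_crowd_{a}_{k}" for k in range(1, LOOKBACK_HOURS + 1)]
        cols += [f"lb_occ_{a}_{k}" for k in range(1, LOOKBACK_HOURS + 1)]
    return cols


@dataclass
class DesignMatrix:
    """The assembled matrix plus its column schema.

    ``frame`` holds one bookkeeping column ``date`` plus the 1,366 matrix
    columns in canonical order; ``feature_columns`` excludes the label.
    """

    frame: pd.DataFrame
    origins: tuple[int, ...] = DEFAULT_ORIGINS
    label_column: str = LABEL_COLUMN
    categorical_columns: tuple[str, ...] = CATEGORICAL_COLUMNS

    @property
    def matrix_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c != "date"]

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.matrix_columns if c != self.label_column]

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def schema(self) -> dict:
        cols = []
        for c in self.frame.columns:
            role = (
                "key" if c == "date"
                else "label" if c == self.label_column
                else "feature"
            )
            cols.append(
                {
                    "name": c,
                    "dtype": str(self.frame[c].dtype),
                    "role": role,
                    "categorical": c in self.categorical_columns,
                }
            )
        return {
            "origins": list(self.origins),
            "label_column": self.label_column,
            "subgroup_codes": dict(SUBGROUP_CODES),
            "columns": cols,
        }

    def write(self, out_dir, csv: bool = False) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.frame.to_parquet(out / "matrix.parquet", index=False)
        if csv:
            self.frame.to_csv(out / "matrix.csv", index=False)
        with open(out / "schema.json", "w") as fh:
            json.dump(self.schema(), fh, indent=1)

    @classmethod
    def read(cls, in_dir) -> "DesignMatrix":
        out = Path(in_dir)
        with open(out / "schema.json") as fh:
            schema = json.load(fh)
        pq = out / "matrix.parquet"
        if pq.exists():
            frame = pd.read_parquet(pq)
        else:
            frame = pd.read_csv(out / "matrix.csv", parse_dates=["date"])
            frame["date"] = frame["date"].dt.date
        order = [c["name"] for c in schema["columns"]]
        return cls(
            frame=frame[order],
            origins=tuple(schema["origins"]),
            label_column=schema["label_column"],
        )


def _check_alignment(
    panel: HourlyOccupancyPanel, covariates: CovariatePanel, labels: CrowdingLabels
) -> list:
    panel_dates = [ts.date() for ts in panel.frame.index[::24]]
    if len(panel.frame) != len(panel_dates) * 24:
        raise ValueError("panel does not cover whole calendar days")
    cov_dates = list(covariates.frame.index)
    lab_dates = list(labels.daily.index)
    if panel_dates != cov_dates or panel_dates != lab_dates:
        raise ValueError(
            "date-range mismatch between panel, covariates and labels: "
            f"panel {panel_dates[0]}..{panel_dates[-1]} ({len(panel_dates)} d), "
            f"covariates {len(cov_dates)} d, labels {len(lab_dates)} d"
        )
    return panel_dates


def build_design_matrix(
    panel: HourlyOccupancyPanel,
    covariates: CovariatePanel,
    labels: CrowdingLabels,
    origins: tuple[int, ...] = DEFAULT_ORIGINS,
    subgroups: tuple[str, ...] = SUBGROUPS,
) -> DesignMatrix:
    """Assemble the per-(date, subgroup, origin) design matrix.

    Rows are ordered date-major, then subgroup code, then origin.  Lookback
    and lag cells whose history precedes the panel start are NaN; rows are
    always retained.
    """
    for o in origins:
        if not 0 <= o <= 23:
            raise ValueError(f"origin {o} outside 0..23")
    for s in subgroups:
        if s not in SUBGROUP_CODES:
            raise ValueError(f"unknown subgroup {s!r}")
    dates = _check_alignment(panel, covariates, labels)
    n_days = len(dates)
    n_sub, n_org = len(subgroups), len(origins)
    n_rows = n_days * n_sub * n_org

    # --- row keys: date-major, subgroup, origin --------------------------
    date_rep = np.repeat(np.arange(n_days), n_sub * n_org)
    sub_rep = np.tile(np.repeat(np.arange(n_sub), n_org), n_days)
    org_rep = np.tile(np.asarray(origins), n_days * n_sub)
    sub_codes = np.asarray([SUBGROUP_CODES[s] for s in subgroups])

    cov = covariates.frame
    ts = pd.DatetimeIndex(pd.to_datetime(dates))
    daily_base = pd.DataFrame(
        {
            "holiday": cov["holiday"].to_numpy(int),
            "after_holiday": cov["after_holiday"].to_numpy(int),
            "before_holiday": cov["before_holiday"].to_numpy(int),
            "weekday": ts.weekday.to_numpy(),
            "month": ts.month.to_numpy(),
            "beds_all": cov["beds_available"].to_numpy(int),
            "precipitation_mm": cov["precipitation_mm"].to_numpy(float),
            "snow_depth_cm": cov["snow_depth_cm"].to_numpy(float),
            "air_temp_mean_C": cov["air_temp_mean_C"].to_numpy(float),
            "air_temp_max_C": cov["air_temp_max_C"].to_numpy(float),
            "air_temp_min_C": cov["air_temp_min_C"].to_numpy(float),
        }
    )

    data: dict[str, np.ndarray] = {}
    data["date"] = np.asarray(dates, dtype=object)[date_rep]
    for c in daily_base.columns:
        data[c] = daily_base[c].to_numpy()[date_rep]

    # --- daily crowding lags (all four subgroups on every row) ----------
    for lag in LAG_DAYS:
        for s in SUBGROUPS:
            lab = labels.daily[s].to_numpy(float)
            lagged = np.full(n_days, np.nan)
            lagged[lag:] = lab[:-lag]
            data[f"q90_{SUBGROUP_ABBREV[s]}_{lag}"] = lagged[date_rep]

    data["subgroup"] = sub_codes[sub_rep]
    data["origin"] = org_rep

    # --- label: the row subgroup's daily crisis label -------------------
    label_by_sub = np.stack(
        [labels.daily[s].to_numpy(int) for s in subgroups], axis=1
    )  # (n_days, n_sub)
    data[LABEL_COLUMN] = label_by_sub[date_rep, sub_rep]

    # --- lookback block -------------------------------------------------
    # For a row (day d, origin o), lag k refers to absolute panel hour
    # d*24 + o - k, i.e. window [origin-168, origin-1]; NaN before start.
    start_idx = (date_rep * 24 + org_rep).astype(np.int64)  # per row
    lb: dict[str, np.ndarray] = {}
    for s in SUBGROUPS:
        a = SUBGROUP_ABBREV[s]
        crowd = labels.hourly[s].to_numpy(np.float32)
        occ = panel.frame[f"occ_{s}"].to_numpy(np.float32)
        for tag, series in (("crowd", crowd), ("occ", occ)):
            pad = np.concatenate(
                [np.full(LOOKBACK_HOURS, np.nan, dtype=np.float32), series]
            )
            win = np.lib.stride_tricks.sliding_window_view(pad, LOOKBACK_HOURS)
            # win[i] = hours [i-168, i-1]; reverse so column j is lag j+1
            block = win[start_idx][:, ::-1]
            for k in range(1, LOOKBACK_HOURS + 1):
                lb[f"lb_{tag}_{a}_{k}"] = block[:, k - 1]

    # assemble in canonical order: base columns as declared, then lookback
    frame_cols: dict[str, np.ndarray] = {}
    frame_cols["date"] = data["date"]
    for c in BASE_COLUMNS:
        frame_cols[c] = data[c]
    for c in lookback_columns():
        frame_cols[c] = lb[c]
    frame = pd.DataFrame(frame_cols)
    assert len(frame) == n_rows
    return DesignMatrix(frame=frame, origins=tuple(origins))


# ---------------------------------------------------------------------------
# leakage audit
# ---------------------------------------------------------------------------


@dataclass
class AuditReport:
    n_rows: int
    n_cells_checked: int
    violations: list[tuple] = field(default_factory=list)
    label_dependent_columns: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations and not self.label_dependent_columns


def leakage_audit(
    matrix: DesignMatrix,
    panel: HourlyOccupancyPanel,
    labels: CrowdingLabels,
    max_report: int = 100,
) -> AuditReport:
    """Verify the temporal integrity of a built matrix against its panel.

    Checks that every populated lookback cell equals the panel value at its
    claimed historical hour (latest referenced hour = origin−1), and that
    no feature column reproduces the same-day label verbatim.
    """
    frame = matrix.frame
    dates = list(labels.daily.index)
    date_to_idx = {d: i for i, d in enumerate(dates)}
    day_idx = np.asarray([date_to_idx[d] for d in frame["date"]])
    origin = frame["origin"].to_numpy(int)
    base_hour = day_idx * 24 + origin

    violations: list[tuple] = []
    n_checked = 0
    for s in SUBGROUPS:
        a = SUBGROUP_ABBREV[s]
        crowd = labels.hourly[s].to_numpy(float)
        occ = panel.frame[f"occ_{s}"].to_numpy(float)
        for tag, series in (("crowd", crowd), ("occ", occ)):
            for k in range(1, LOOKBACK_HOURS + 1):
                col = f"lb_{tag}_{a}_{k}"
                got = frame[col].to_numpy(float)
                hour = base_hour - k
                valid = hour >= 0
                expected = np.full(len(got), np.nan)
                expected[valid] = series[hour[valid]]
                n_checked += int(valid.sum())
                # populated cell must match panel; cells before the panel
                # start must be missing
                bad = np.zeros(len(got), dtype=bool)
                bad[valid] = ~np.isclose(got[valid], expected[valid], equal_nan=True)
                bad[~valid] = ~np.isnan(got[~valid])
                if bad.any():
                    for r in np.flatnonzero(bad)[: max(0, max_report - len(violations))]:
                        violations.append(
                            (int(r), col, float(expected[r]) if valid[r] else np.nan,
                             float(got[r]))
                        )
                if len(violations) >= max_report:
                    break

    # same-day-dependence check: a feature column identical to the label
    label = frame[matrix.label_column].to_numpy(float)
    label_cols = []
    for c in matrix.feature_columns:
        v = frame[c].to_numpy(float)
        if np.array_equal(v, label):
            label_cols.append(c)
    return AuditReport(
        n_rows=len(frame),
        n_cells_checked=n_checked,
        violations=violations,
        label_dependent_columns=label_cols,
    )
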