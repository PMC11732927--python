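"""Synthetic ED panel generator.

Generates hourly occupancy for the four ED subgroups together with daily
covariates (weather, regional bed availability, holiday calendar) so that
every downstream stage of the pipeline is testable without access to any
hospital data.

Occupancy is produced by a nonhomogeneous-Poisson arrival / random
length-of-stay queue (an M(t)/G/infinity system): hourly arrival counts are
Poisson with intensity

    lambda_s(t) = base_s * hour_mult_s(hour) * weekday_mult(weekday)
                  * season(t) * dayfactor(day)

and each arrival stays a random whole number of hours drawn from a shifted
negative-binomial length-of-stay law (dispersion 1 = geometric, the
default).  Occupancy at hour t counts the patients present.  The combined
"bedoccupying" series is defined as the sum of the three sections.

``dayfactor`` is a log-normal AR(1) daily demand shock shared by all
subgroups; it creates day-level bursts so that within a day the morning
occupancy level genuinely carries information about afternoon crowding, as
it does in real EDs.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from dateutil import easter

from edcrowd.subgroups import DEFAULT_CAPACITIES, SECTIONS, SUBGROUPS


class ParameterError(ValueError):
    """A configuration field is invalid; the message names the field."""


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArrivalRateModel:
    """Parameters of the nonhomogeneous hourly arrival intensity.

    base
        mean hourly arrivals per section at multiplier 1.
    hour_mult
        per-section 24-vector of hour-of-day multipliers (relative shape).
    weekday_mult
        7-vector, Monday=0 .. Sunday=6; weekend values below weekday values
        make weekend crowding rarer.
    season_amplitude, season_peak_doy
        relative amplitude and day-of-year of the maximum of an annual
        sinusoid.
    daily_noise_sigma, daily_noise_rho, daily_noise_cap
        scale and lag-1 autocorrelation of the log-normal AR(1) daily demand
        factor shared across sections (0 disables it); the factor is capped
        at ``daily_noise_cap`` — demand bursts saturate, which keeps the
        protected morning trough intact even on the heaviest days.
    """

    base: dict[str, float]
    hour_mult: dict[str, tuple[float, ...]]
    weekday_mult: tuple[float, ...]
    season_amplitude: float = 0.0
    season_peak_doy: float = 15.0
    daily_noise_sigma: float = 0.0
    daily_noise_rho: float = 0.0
    daily_noise_cap: float = math.inf


@dataclass(frozen=True)
class LosModel:
    """Length-of-stay law per section: whole hours >= 1.

    ``LOS = 1 + NegativeBinomial(dispersion, p)`` with p chosen so that the
    mean equals ``mean_hours``; dispersion 1 gives the memoryless geometric
    law on {1, 2, ...}.
    """

    mean_hours: dict[str, float]
    dispersion: float = 1.0


@dataclass(frozen=True)
class WeatherModel:
    """Seasonal sinusoid + noise for daily weather covariates.

    Temperatures follow an annual sinusoid with additive Gaussian noise;
    min/max are the mean minus/plus a positive half-range so the ordering
    min <= mean <= max holds by construction.  Precipitation and snow depth
    use the sentinel -1 on days with none.
    """

    temp_mean_c: float = 5.5
    temp_amplitude_c: float = 12.0
    temp_peak_doy: float = 200.0
    temp_noise_sd: float = 3.5
    temp_half_range_c: float = 4.0
    temp_half_range_sd: float = 1.5
    precip_wet_prob: float = 0.55
    precip_gamma_shape: float = 0.8
    precip_gamma_scale: float = 4.0
    snow_amplitude_cm: float = 18.0
    snow_noise_sd: float = 4.0


@dataclass(frozen=True)
class BedsModel:
    """AR(1) daily count of free follow-up-care beds in the region.

    Rounded to integers and deliberately allowed to go negative, matching
    source systems where staff-reported availability can under-run zero.
    """

    mean: float = 29.0
    persistence: float = 0.8
    noise_sd: float = 9.0


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of one synthetic panel."""

    start_date: dt.date
    n_days: int
    capacities: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CAPACITIES)
    )
    arrival_rate_model: ArrivalRateModel | None = None
    los_model: LosModel | None = None
    weather_model: WeatherModel = field(default_factory=WeatherModel)
    beds_model: BedsModel = field(default_factory=BedsModel)
    holidays: tuple[dt.date, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_days < 1:
            raise ParameterError("n_days must be >= 1")
        for name, cap in self.capacities.items():
            if cap <= 0:
                raise ParameterError(f"capacities[{name!r}] must be > 0")
        for name in SUBGROUPS:
            if name not in self.capacities:
                raise ParameterError(f"capacities missing subgroup {name!r}")
        arm = self.arrival_rate_model
        if arm is None:
            raise ParameterError("arrival_rate_model is required")
        for sec in SECTIONS:
            if arm.base.get(sec, -1.0) < 0:
                raise ParameterError(f"arrival_rate_model.base[{sec!r}] must be >= 0")
            hm = arm.hour_mult.get(sec)
            if hm is None or len(hm) != 24 or any(m < 0 for m in hm):
                raise ParameterError(
                    f"arrival_rate_model.hour_mult[{sec!r}] must be 24 nonnegative values"
                )
        if len(arm.weekday_mult) != 7 or any(m < 0 for m in arm.weekday_mult):
            raise ParameterError(
                "arrival_rate_model.weekday_mult must be 7 nonnegative values"
            )
        if arm.season_amplitude < 0 or arm.season_amplitude >= 1:
            raise ParameterError("arrival_rate_model.season_amplitude must be in [0, 1)")
        if arm.daily_noise_sigma < 0:
            raise ParameterError("arrival_rate_model.daily_noise_sigma must be >= 0")
        if not -1 < arm.daily_noise_rho < 1:
            raise ParameterError("arrival_rate_model.daily_noise_rho must be in (-1, 1)")
        if arm.daily_noise_cap <= 0:
            raise ParameterError("arrival_rate_model.daily_noise_cap must be > 0")
        lm = self.los_model
        if lm is None:
            raise ParameterError("los_model is required")
        for sec in SECTIONS:
            if lm.mean_hours.get(sec, 0.0) < 1.0:
                raise ParameterError(f"los_model.mean_hours[{sec!r}] must be >= 1 hour")
        if lm.dispersion <= 0:
            raise ParameterError("los_model.dispersion must be > 0")


# ---------------------------------------------------------------------------
# output containers
# ---------------------------------------------------------------------------


@dataclass
class HourlyOccupancyPanel:
    """Hourly occupancy counts and occupancy ratios (EDOR) per subgroup.

    ``frame`` has a complete hourly DatetimeIndex and columns
    ``occ_<subgroup>`` (nonnegative int) and ``edor_<subgroup>``
    (occupancy / capacity; may exceed 1).
    """

    frame: pd.DataFrame
    capacities: dict[str, int]

    def validate(self) -> None:
        idx = self.frame.index
        if len(idx) == 0:
            raise ValueError("empty panel")
        expected = pd.date_range(idx[0], periods=len(idx), freq="h")
        if not idx.equals(expected):
            raise ValueError("timestamp grid is not a complete hourly range")
        for s in SUBGROUPS:
            occ = self.frame[f"occ_{s}"].to_numpy()
            edor = self.frame[f"edor_{s}"].to_numpy()
            if (occ < 0).any():
                raise ValueError(f"negative occupancy in {s}")
            if not np.allclose(edor * self.capacities[s], occ, atol=1e-6):
                raise ValueError(f"edor inconsistent with occupancy for {s}")

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.insert(0, "timestamp", out.index)
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, capacities: dict[str, int] | None = None
                 ) -> "HourlyOccupancyPanel":
        frame = pd.read_csv(path, parse_dates=["timestamp"])
        frame = frame.set_index("timestamp")
        frame.index.name = None
        if capacities is None:
            # recover capacities from occupancy / edor where edor > 0
            capacities = {}
            for s in SUBGROUPS:
                edor = frame[f"edor_{s}"].to_numpy()
                occ = frame[f"occ_{s}"].to_numpy()
                nz = edor > 0
                capacities[s] = (
                    int(round(float(np.median(occ[nz] / edor[nz])))) if nz.any() else 1
                )
        return cls(frame=frame, capacities=capacities)


@dataclass
class CovariatePanel:
    """Daily covariates: weather, bed availability and holiday flags.

    ``frame`` is indexed by date with columns precipitation_mm,
    snow_depth_cm, air_temp_mean_C, air_temp_max_C, air_temp_min_C (floats;
    -1 is the sentinel for "none" in precipitation/snow), beds_available
    (int, may be negative) and holiday / after_holiday / before_holiday
    (0/1).
    """

    frame: pd.DataFrame

    def validate(self) -> None:
        f = self.frame
        if not (f["air_temp_min_C"] <= f["air_temp_mean_C"]).all():
            raise ValueError("air_temp_min > air_temp_mean on some day")
        if not (f["air_temp_mean_C"] <= f["air_temp_max_C"]).all():
            raise ValueError("air_temp_mean > air_temp_max on some day")

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.insert(0, "date", out.index)
        out.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "CovariatePanel":
        frame = pd.read_csv(path, parse_dates=["date"])
        frame["date"] = frame["date"].dt.date
        frame = frame.set_index("date")
        frame.index.name = None
        return cls(frame=frame)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _section_occupancy(
    arrivals: np.ndarray, los: np.ndarray, n_hours: int
) -> np.ndarray:
    """Occupancy from arrival hours and lengths of stay via a difference array.

    Each arrival at hour t with stay L contributes 1 to occupancy on hours
    [t, t+L-1]; stays are truncated at the panel end.
    """
    diff = np.zeros(n_hours + 1, dtype=np.int64)
    np.add.at(diff, arrivals, 1)
    ends = np.minimum(arrivals + los, n_hours)
    np.add.at(diff, ends, -1)
    return np.cumsum(diff[:-1])


def _holiday_flags(
    dates: pd.DatetimeIndex, holidays: set[dt.date]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    one_day = dt.timedelta(days=1)
    hol = np.array([d.date() in holidays for d in dates])
    after = np.array([(d.date() - one_day) in holidays for d in dates])
    before = np.array([(d.date() + one_day) in holidays for d in dates])
    return hol, after, before


def simulate_panel(config: SimConfig) -> tuple[HourlyOccupancyPanel, CovariatePanel]:
    """Generate one synthetic panel; bit-identical for identical configs."""
    config.validate()
    arm = config.arrival_rate_model
    lm = config.los_model
    n_hours = config.n_days * 24

    root = np.random.SeedSequence(config.seed)
    ss_occ, ss_weather, ss_beds, ss_day = root.spawn(4)
    rng_day = np.random.default_rng(ss_day)

    timestamps = pd.date_range(
        pd.Timestamp(config.start_date), periods=n_hours, freq="h"
    )
    hour = timestamps.hour.to_numpy()
    weekday = timestamps.weekday.to_numpy()
    doy = timestamps.dayofyear.to_numpy()
    day_index = np.arange(n_hours) // 24

    # shared AR(1) log-normal daily demand factor
    if arm.daily_noise_sigma > 0:
        z = np.empty(config.n_days)
        innov = rng_day.standard_normal(config.n_days)
        rho = arm.daily_noise_rho
        z[0] = innov[0]
        for d in range(1, config.n_days):
            z[d] = rho * z[d - 1] + math.sqrt(1 - rho**2) * innov[d]
        dayfactor = np.exp(arm.daily_noise_sigma * z - 0.5 * arm.daily_noise_sigma**2)
        dayfactor = np.minimum(dayfactor, arm.daily_noise_cap)
    else:
        dayfactor = np.ones(config.n_days)

    season = 1.0 + arm.season_amplitude * np.cos(
        2 * np.pi * (doy - arm.season_peak_doy) / 365.25
    )
    wk = np.asarray(arm.weekday_mult)[weekday]

    occ = {}
    rng_sections = np.random.default_rng(ss_occ)
    for sec in SECTIONS:
        hm = np.asarray(arm.hour_mult[sec])[hour]
        lam = arm.base[sec] * hm * wk * season * dayfactor[day_index]
        counts = rng_sections.poisson(lam)
        total = int(counts.sum())
        arrivals = np.repeat(np.arange(n_hours), counts)
        m = lm.mean_hours[sec]
        if total:
            if m <= 1.0:
                los = np.ones(total, dtype=np.int64)
            else:
                r = lm.dispersion
                p = r / (r + m - 1.0)
                los = 1 + rng_sections.negative_binomial(r, p, size=total)
        else:
            los = np.zeros(0, dtype=np.int64)
        occ[sec] = _section_occupancy(arrivals, los, n_hours)
    occ["bedoccupying"] = occ["medical"] + occ["surgical"] + occ["critical"]

    data = {}
    for s in SUBGROUPS:
        data[f"occ_{s}"] = occ[s]
        data[f"edor_{s}"] = occ[s] / config.capacities[s]
    panel = HourlyOccupancyPanel(
        frame=pd.DataFrame(data, index=timestamps), capacities=dict(config.capacities)
    )

    covariates = _simulate_covariates(
        config, ss_weather, ss_beds
    )
    return panel, covariates


def _simulate_covariates(
    config: SimConfig, ss_weather: np.random.SeedSequence, ss_beds: np.random.SeedSequence
) -> CovariatePanel:
    wm = config.weather_model
    bm = config.beds_model
    n = config.n_days
    rng_w = np.random.default_rng(ss_weather)
    rng_b = np.random.default_rng(ss_beds)

    dates = pd.date_range(pd.Timestamp(config.start_date), periods=n, freq="D")
    doy = dates.dayofyear.to_numpy()
    phase = 2 * np.pi * (doy - wm.temp_peak_doy) / 365.25

    mean_t = wm.temp_mean_c + wm.temp_amplitude_c * np.cos(phase) + (
        rng_w.standard_normal(n) * wm.temp_noise_sd
    )
    half_hi = np.abs(wm.temp_half_range_c + rng_w.standard_normal(n) * wm.temp_half_range_sd)
    half_lo = np.abs(wm.temp_half_range_c + rng_w.standard_normal(n) * wm.temp_half_range_sd)
    max_t = mean_t + half_hi
    min_t = mean_t - half_lo

    wet = rng_w.random(n) < wm.precip_wet_prob
    amounts = rng_w.gamma(wm.precip_gamma_shape, wm.precip_gamma_scale, size=n)
    precip = np.where(wet, np.round(amounts, 1), -1.0)

    # snowpack: winter-peaking latent level, clipped; -1 when no snow
    snow_latent = (
        wm.snow_amplitude_cm * np.cos(2 * np.pi * (doy - 30.0) / 365.25)
        + rng_w.standard_normal(n) * wm.snow_noise_sd
    )
    snow = np.where(snow_latent > 0.5, np.round(snow_latent, 1), -1.0)

    beds = np.empty(n)
    innov = rng_b.standard_normal(n)
    beds[0] = bm.mean + innov[0] * bm.noise_sd / math.sqrt(max(1 - bm.persistence**2, 1e-9))
    for d in range(1, n):
        beds[d] = bm.mean + bm.persistence * (beds[d - 1] - bm.mean) + innov[d] * bm.noise_sd
    beds = np.round(beds).astype(int)

    holidays = set(config.holidays)
    hol, after, before = _holiday_flags(dates, holidays)

    frame = pd.DataFrame(
        {
            "precipitation_mm": precip,
            "snow_depth_cm": snow,
            "air_temp_mean_C": np.round(mean_t, 1),
            "air_temp_max_C": np.round(max_t, 1),
            "air_temp_min_C": np.round(min_t, 1),
            "beds_available": beds,
            "holiday": hol.astype(int),
            "after_holiday": after.astype(int),
            "before_holiday": before.astype(int),
        },
        index=[d.date() for d in dates],
    )
    return CovariatePanel(frame=frame)


# ---------------------------------------------------------------------------
# shipped default configuration
# ---------------------------------------------------------------------------


def finnish_holidays(years) -> tuple[dt.date, ...]:
    """Fixed- and Easter-relative public holidays for the given years."""
    out: list[dt.date] = []
    for y in years:
        e = easter.easter(y)
        out += [
            dt.date(y, 1, 1),
            dt.date(y, 1, 6),
            e - dt.timedelta(days=2),   # Good Friday
            e + dt.timedelta(days=1),   # Easter Monday
            dt.date(y, 5, 1),
            e + dt.timedelta(days=39),  # Ascension
            dt.date(y, 6, 24),          # Midsummer (approximate fixed date)
            dt.date(y, 12, 6),
            dt.date(y, 12, 24),
            dt.date(y, 12, 25),
            dt.date(y, 12, 26),
        ]
    return tuple(sorted(out))


# Hour-of-day arrival multipliers (relative shape, trough overnight and
# early morning, peak late morning so that occupancy — which lags arrivals
# by roughly the mean length of stay — peaks mid-afternoon and stays far
# from capacity 8–11 a.m.).  Surgical peaks slightly later than medical;
# critical has a deeper morning trough because its tiny capacity makes its
# crowding probability very sensitive to morning census.
_HOUR_SHAPE_MED = (
    0.28, 0.22, 0.18, 0.16, 0.16, 0.17, 0.20, 0.28,
    0.45, 0.80, 1.35, 1.80, 1.97, 1.97, 1.84, 1.64,
    1.46, 1.33, 1.22, 1.06, 0.90, 0.70, 0.50, 0.36,
)
_HOUR_SHAPE_SUR = (
    0.26, 0.20, 0.16, 0.14, 0.14, 0.15, 0.18, 0.26,
    0.42, 0.75, 1.20, 1.60, 1.85, 1.93, 1.89, 1.76,
    1.60, 1.43, 1.29, 1.10, 0.92, 0.72, 0.52, 0.36,
)
_HOUR_SHAPE_CRI = (
    0.30, 0.24, 0.20, 0.18, 0.16, 0.16, 0.17, 0.20,
    0.30, 0.55, 1.05, 1.70, 2.05, 2.08, 1.95, 1.74,
    1.52, 1.37, 1.24, 1.07, 0.90, 0.70, 0.52, 0.38,
)


def calibrate_default_config(
    start_date: dt.date = dt.date(2018, 1, 1),
    n_days: int = 790,
    seed: int = 0,
) -> SimConfig:
    """The frozen default panel parameterisation shipped with the package.

    Calibrated once so that, over long horizons, daily crowding prevalence
    is close to 28% (bedoccupying), 36% (medical) and 25% (surgical), with
    crowding essentially absent 8–11 a.m., an afternoon peak, and rarer
    weekend crowding.
    """
    years = range(start_date.year, start_date.year + n_days // 365 + 2)
    arm = ArrivalRateModel(
        base={"medical": 3.6554, "surgical": 2.2708, "critical": 0.5743},
        hour_mult={
            "medical": _HOUR_SHAPE_MED,
            "surgical": _HOUR_SHAPE_SUR,
            "critical": _HOUR_SHAPE_CRI,
        },
        weekday_mult=(1.05, 1.05, 1.04, 1.03, 1.00, 0.86, 0.88),
        season_amplitude=0.05,
        season_peak_doy=15.0,
        daily_noise_sigma=0.33,
        daily_noise_rho=0.45,
        daily_noise_cap=1.7,
    )
    lm = LosModel(
        mean_hours={"medical": 6.0, "surgical": 5.0, "critical": 3.0},
        dispersion=1.0,
    )
    return SimConfig(
        start_date=start_date,
        n_days=n_days,
        capacities=dict(DEFAULT_CAPACITIES),
        arrival_rate_model=arm,
        los_model=lm,
        weather_model=WeatherModel(),
        beds_model=BedsModel(),
        holidays=finnish_holidays(years),
        seed=seed,
    )


def replace_config(config: SimConfig, **kwargs) -> SimConfig:
    """Convenience: dataclasses.replace with validation deferred to use."""
    return dataclasses.replace(config, **kwargs)
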