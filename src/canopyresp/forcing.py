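"""Synthetic daily meteorological forcing.

Generates seeded daily series of air temperature and daytime-mean
photosynthetically active radiation (PAR) with the statistical structure of
a lowland tropical climate: warm mean, weak seasonality, AR(1) day-to-day
noise. Stands in for reanalysis or station forcing; the simulator only
needs daily resolution because its carbon accounting is per-day (allocation)
and per-year (demography), with a 10-day acclimation window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClimatologyParams",
    "ForcingSeries",
    "generate_forcing",
    "read_forcing_csv",
    "write_forcing_csv",
    "TROPICAL_PRESET",
]

DAYS_PER_YEAR = 365


@dataclass(frozen=True)
class ClimatologyParams:
    """Parameters of the synthetic daily climate generator.

    Attributes
    ----------
    mean_temp : float
        Annual-mean air temperature, °C.
    seasonal_temp_amplitude : float
        Half-range of the seasonal temperature sinusoid, °C.
    mean_par : float
        Annual-mean daytime-mean PAR at canopy top, μmol photons m⁻² s⁻¹.
    seasonal_par_amplitude : float
        Half-range of the seasonal PAR sinusoid, μmol m⁻² s⁻¹.
    day_length : float
        Hours of daylight per day (constant; tropics default 12 h).
    diurnal_factor : float
        Dimensionless factor converting assimilation computed at the
        daytime-mean PAR into the diurnal-cycle-integrated daily total.
        For sinusoidal daylight a light-limited leaf integrates to 2/π of
        the flat-daytime value, the default here; 1.0 means a flat day.
    noise_sd_temp : float
        Standard deviation of the stationary AR(1) temperature noise, °C.
    noise_sd_par : float
        Standard deviation of multiplicative PAR noise, as a fraction of
        the deterministic PAR value.
    ar1_coefficient : float
        Lag-1 autocorrelation of the daily noise, in [0, 1).
    seed : int
        Seed of the dedicated random stream for one series.
    """

    mean_temp: float = 26.0
    seasonal_temp_amplitude: float = 1.0
    mean_par: float = 1400.0
    seasonal_par_amplitude: float = 100.0
    day_length: float = 12.0
    noise_sd_temp: float = 1.0
    noise_sd_par: float = 0.08
    ar1_coefficient: float = 0.6
    seed: int = 0

    # 2/π: sinusoidal-daylight integral of a light-limited leaf relative
    # to a flat day at the daytime-mean PAR.
    diurnal_factor: float = 2.0 / np.pi

    def __post_init__(self) -> None:
        if self.noise_sd_temp < 0 or self.noise_sd_par < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not (0.0 <= self.ar1_coefficient < 1.0):
            raise ValueError("ar1_coefficient must lie in [0, 1)")
        if not (0.0 < self.day_length <= 24.0):
            raise ValueError("day_length must lie in (0, 24]")


#: Representative lowland-tropical climatology (warm, weakly seasonal).
TROPICAL_PRESET = ClimatologyParams()


@dataclass
class ForcingSeries:
    """Daily meteorological forcing.

    air_temp is °C; par_top is daytime-mean PAR (μmol photons m⁻² s⁻¹);
    day_length is hours. timestep_days is the step duration (always 1 here).
    """

    air_temp: np.ndarray
    par_top: np.ndarray
    day_length: np.ndarray
    timestep_days: float = 1.0
    diurnal_factor: float = 1.0

    def __post_init__(self) -> None:
        self.air_temp = np.asarray(self.air_temp, dtype=float)
        self.par_top = np.asarray(self.par_top, dtype=float)
        self.day_length = np.asarray(self.day_length, dtype=float)
        if not (len(self.air_temp) == len(self.par_top) == len(self.day_length)):
            raise ValueError("forcing arrays must have equal length")
        if not np.all(np.isfinite(self.air_temp)):
            raise ValueError("air_temp must be finite")
        if np.any(self.par_top < 0):
            raise ValueError("par_top must be >= 0")
        if np.any((self.day_length <= 0) | (self.day_length > 24)):
            raise ValueError("day_length must lie in (0, 24]")

    @property
    def n_steps(self) -> int:
        return len(self.air_temp)

    @property
    def n_years(self) -> int:
        return self.n_steps // DAYS_PER_YEAR

    def year(self, i: int) -> "ForcingSeries":
        """Slice out year ``i`` (0-based) as a new series."""
        if not (0 <= i < self.n_years):
            raise IndexError(f"year {i} outside series of {self.n_years} years")
        sl = slice(i * DAYS_PER_YEAR, (i + 1) * DAYS_PER_YEAR)
        return ForcingSeries(
            self.air_temp[sl],
            self.par_top[sl],
            self.day_length[sl],
            self.timestep_days,
            self.diurnal_factor,
        )


def generate_forcing(params: ClimatologyParams, years: int) -> ForcingSeries:
    """Generate ``years`` × 365 daily steps of synthetic forcing.

    Temperature is mean + seasonal sinusoid + stationary AR(1) noise.
    PAR is a seasonal sinusoid modulated by AR(1) multiplicative noise
    and truncated at zero. Deterministic for a given ``params.seed``.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    n = years * DAYS_PER_YEAR
    doy = np.arange(n, dtype=float) % DAYS_PER_YEAR
    phase = np.sin(2.0 * np.pi * doy / DAYS_PER_YEAR)

    rng = np.random.default_rng(params.seed)
    temp_noise = _ar1(rng, n, params.ar1_coefficient, params.noise_sd_temp)
    par_noise = _ar1(rng, n, params.ar1_coefficient, params.noise_sd_par)

    air_temp = params.mean_temp + params.seasonal_temp_amplitude * phase + temp_noise
    par_det = params.mean_par + params.seasonal_par_amplitude * phase
    par_top = np.maximum(0.0, par_det * (1.0 + par_noise))
    day_length = np.full(n, params.day_length)
    return ForcingSeries(
        air_temp, par_top, day_length, diurnal_factor=params.diurnal_factor
    )


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) series with marginal standard deviation ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    eps = rng.normal(0.0, innov_sd, size=n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + eps[t]
    return x


_FORCING_COLUMNS = ["step", "air_temp_C", "par_umol_m2_s", "day_length_h"]


def write_forcing_csv(series: ForcingSeries, path) -> None:
    """Write forcing as delimited text with a mandatory header row."""
    df = pd.DataFrame(
        {
            "step": np.arange(series.n_steps),
            "air_temp_C": series.air_temp,
            "par_umol_m2_s": series.par_top,
            "day_length_h": series.day_length,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_forcing_csv(path, diurnal_factor: float = 1.0) -> ForcingSeries:
    """Read a forcing CSV written by :func:`write_forcing_csv`.

    The diurnal-aggregation factor is not a per-step quantity and is not
    stored in the file; pass it explicitly for user-supplied forcing.
    """
    df = pd.read_csv(path)
    missing = [c for c in _FORCING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"forcing file {path} missing columns: {missing}")
    return ForcingSeries(
        df["air_temp_C"].to_numpy(),
        df["par_umol_m2_s"].to_numpy(),
        df["day_length_h"].to_numpy(),
        diurnal_factor=diurnal_factor,
    )
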