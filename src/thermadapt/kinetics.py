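"""Enzyme temperature profiles and Arrhenius activation energy.

Assay time series (signal vs. time over a 5-minute window) are reduced
to reaction rates by ordinary least squares.  Rates measured across a
temperature series are then fitted to the linearised Arrhenius law

    ln k = ln A − (Ea / R) · (1 / T)

by regressing ln(rate) on reciprocal absolute temperature, so the
activation energy is Ea = −slope·R.  The default fitting window is
2–20 °C: above the activity optimum the law no longer holds, so warmer
assay points are never auto-included.

The model/results split follows the statsmodels idiom:
``ArrheniusModel.from_dataframe(df).fit()`` returns an
:class:`ArrheniusResults` carrying Ea (kJ·mol⁻¹), ln A, r², the number
of distinct temperatures used, and a ``summary()`` table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GAS_CONSTANT = 8.314  # J mol^-1 K^-1
KELVIN_OFFSET = 273.15

logger = logging.getLogger("thermadapt")


@dataclass(frozen=True)
class RateEstimate:
    """OLS slope of signal vs. time; flagged when non-catalytic (slope <= 0)."""

    rate: float
    intercept: float
    n_points: int
    flagged: bool


def rate_from_timeseries(
    times: np.ndarray,
    signals: np.ndarray,
    window: tuple[float, float] = (0.0, 5.0),
    calibration: float = 1.0,
) -> RateEstimate:
    """Reaction rate as the least-squares slope of signal on time.

    *times* are minutes, strictly increasing; only points inside
    *window* (inclusive) are used and at least three are required.
    A non-positive slope is returned flagged rather than raised, so
    callers can exclude non-catalytic assays with a warning.
    """
    times = np.asarray(times, dtype=float)
    signals = np.asarray(signals, dtype=float)
    if times.shape != signals.shape:
        raise ValueError("times and signals must have equal length")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    lo, hi = window
    mask = (times >= lo) & (times <= hi)
    if mask.sum() < 3:
        raise ValueError(
            f"need >=3 time points inside window {window}, got {int(mask.sum())}"
        )
    slope, intercept = np.polyfit(times[mask], signals[mask], 1)
    rate = slope * calibration
    flagged = rate <= 0
    if flagged:
        logger.warning("non-catalytic assay: fitted slope %.4g <= 0", rate)
    return RateEstimate(
        rate=rate, intercept=intercept, n_points=int(mask.sum()), flagged=flagged
    )


class ArrheniusModel:
    """Linearised Arrhenius regression over per-replicate rate points."""

    def __init__(
        self,
        temperatures_c: np.ndarray,
        rates: np.ndarray,
        window: tuple[float, float] = (2.0, 20.0),
    ) -> None:
        self.temperatures_c = np.asarray(temperatures_c, dtype=float)
        self.rates = np.asarray(rates, dtype=float)
        if self.temperatures_c.shape != self.rates.shape:
            raise ValueError("temperatures and rates must have equal length")
        if not window[0] < window[1]:
            raise ValueError("window must satisfy low < high")
        self.window = (float(window[0]), float(window[1]))

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        window: tuple[float, float] = (2.0, 20.0),
        temperature_col: str = "temperature_C",
        rate_col: str = "rate",
    ) -> "ArrheniusModel":
        return cls(df[temperature_col].to_numpy(), df[rate_col].to_numpy(), window)

    def fit(self) -> "ArrheniusResults":
        """Fit ln(rate) ~ 1/T_K inside the temperature window.

        Non-positive rates are excluded with a warning (the log is
        undefined and imputation would bias the slope); at least three
        distinct usable temperatures are required.
        """
        lo, hi = self.window
        in_window = (self.temperatures_c >= lo) & (self.temperatures_c <= hi)
        positive = self.rates > 0
        excluded = int((in_window & ~positive).sum())
        if excluded:
            logger.warning(
                "excluding %d non-positive rate(s) from Arrhenius fit", excluded
            )
        use = in_window & positive
        temps = self.temperatures_c[use]
        if len(np.unique(temps)) < 3:
            raise ValueError(
                "need >=3 distinct temperatures with positive rates inside "
                f"window {self.window}, got {len(np.unique(temps))}"
            )
        inv_t = 1.0 / (temps + KELVIN_OFFSET)
        ln_k = np.log(self.rates[use])
        res = stats.linregress(inv_t, ln_k)
        return ArrheniusResults(
            ea_kj_mol=-res.slope * GAS_CONSTANT / 1000.0,
            ln_a=res.intercept,
            slope=res.slope,
            rsquared=res.rvalue**2,
            n_points=len(np.unique(temps)),
            n_obs=int(use.sum()),
            window=self.window,
        )


@dataclass(frozen=True)
class ArrheniusResults:
    """Fitted activation energy and fit diagnostics.

    ``ea_kj_mol`` is −slope·R/1000 with R = 8.314 J·mol⁻¹·K⁻¹;
    ``n_points`` counts distinct temperatures used, ``n_obs`` the
    replicate observations entering the regression.
    """

    ea_kj_mol: float
    ln_a: float
    slope: float
    rsquared: float
    n_points: int
    n_obs: int
    window: tuple[float, float]

    def predict(self, temperatures_c: np.ndarray) -> np.ndarray:
        """Predicted rates at Celsius temperatures under the fitted law."""
        t_k = np.asarray(temperatures_c, dtype=float) + KELVIN_OFFSET
        return np.exp(self.ln_a + self.slope / t_k)

    def summary(self) -> str:
        lo, hi = self.window
        return "\n".join(
            [
                "Arrhenius fit (ln k ~ 1/T)",
                f"  window           : {lo:g}-{hi:g} C",
                f"  Ea               : {self.ea_kj_mol:.3f} kJ/mol",
                f"  ln A             : {self.ln_a:.3f}",
                f"  r^2              : {self.rsquared:.4f}",
                f"  temperatures used: {self.n_points}",
                f"  observations     : {self.n_obs}",
            ]
        )


GROUP_COLS = ["population", "tissue", "enzyme"]


def fit_arrhenius_per_replicate(
    rates: pd.DataFrame,
    window: tuple[float, float] = (2.0, 20.0),
) -> pd.DataFrame:
    """One Arrhenius fit per population × tissue × enzyme × replicate.

    Each replicate index is taken to identify one individual assayed
    across the temperature series, yielding one Ea per individual —
    the unit of observation for population comparisons.
    """
    rows = []
    for keys, sub in rates.groupby(GROUP_COLS + ["replicate"], sort=True):
        result = ArrheniusModel.from_dataframe(sub, window=window).fit()
        rows.append(
            dict(
                zip(GROUP_COLS + ["replicate"], keys),
                ea_kj_mol=result.ea_kj_mol,
                ln_a=result.ln_a,
                r_squared=result.rsquared,
                n_points=result.n_points,
            )
        )
    return pd.DataFrame(rows)


def temperature_profile(rates: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD, SEM and n per population × tissue × enzyme × temperature."""
    grouped = rates.groupby(GROUP_COLS + ["temperature_C"], sort=True)["rate"]
    out = grouped.agg(mean="mean", sd="std", n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)  # single replicate: SD undefined -> 0
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    return out
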