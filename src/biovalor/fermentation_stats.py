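"""Performance indicators and statistics for mesophilic acidogenic fermentation.

Indicators are computed per sampled day over a pseudo-steady-state window
(by default days >= 3 x HRT) and summarised as mean / SD:

* COD solubilization, Δg-SCOD per g of initial VS;
* VFA yield, Δg-VFA per g of initial VS, on either a COD-equivalent or an
  acid-mass basis (the two differ by the spectrum-weighted COD/mass factor);
* ammonia and phosphate release as a percent of the feed's total N and P;
* VFA/SCOD ratio and a stability summary (SD/mean against a 10% threshold).

A paired two-tailed Student t-test compares day-paired series from two
operating conditions.  Conversions between per-kg feed compositions and
per-litre concentrations assume a density of 1 kg/L (dilute aqueous streams).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic_data import FermenterSeries

logger = logging.getLogger(__name__)

__all__ = [
    "FeedstockCharacterization",
    "DEFAULT_FEEDSTOCK",
    "IndicatorSummary",
    "PerformanceIndicators",
    "VFASpectrum",
    "TTestResult",
    "StabilitySummary",
    "COD_PER_GRAM_ACID",
    "steady_state_window",
    "cod_solubilization",
    "vfa_yield",
    "nutrient_release",
    "vfa_scod_ratio",
    "vfa_spectrum",
    "paired_t_test",
    "stability_summary",
    "performance_indicators",
]


@dataclass(frozen=True)
class FeedstockCharacterization:
    """Pretreated feedstock composition (per-kg solids and per-litre liquid)."""

    ts: float = 45.0  #: g-TS/kg
    vs: float = 32.0  #: g-VS/kg
    scod_in: float = 25_814.0  #: mg/L
    vfa_in: float = 3_500.0  #: mg/L (as COD)
    tkn: float = 12.9  #: g-N/kg-TS
    p: float = 4.0  #: g-P/kg-TS
    cod_ts: float = 565.0  #: g-COD/kg-TS
    nh4_in: float = 325.0  #: mg/L
    po4_in: float = 14.0  #: mg/L

    def __post_init__(self) -> None:
        if self.vs > self.ts:
            raise ValueError("vs cannot exceed ts")
        for name in ("ts", "vs", "scod_in", "vfa_in", "tkn", "p", "cod_ts", "nh4_in", "po4_in"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def tkn_mg_per_l(self) -> float:
        """Feed total Kjeldahl N as mg-N/L (g-N/kg-TS x g-TS/kg, 1 kg ~ 1 L)."""
        return self.tkn * self.ts

    @property
    def p_mg_per_l(self) -> float:
        """Feed total P as mg-P/L."""
        return self.p * self.ts


DEFAULT_FEEDSTOCK = FeedstockCharacterization()


@dataclass(frozen=True)
class IndicatorSummary:
    """Per-day indicator values with their steady-state mean and SD."""

    daily: pd.Series
    mean: float
    sd: float
    basis: str = ""

    @classmethod
    def from_daily(cls, daily: pd.Series, basis: str = "") -> "IndicatorSummary":
        return cls(
            daily=daily,
            mean=float(daily.mean()),
            sd=float(daily.std(ddof=1)) if len(daily) > 1 else 0.0,
            basis=basis,
        )


@dataclass(frozen=True)
class PerformanceIndicators:
    solubilization: IndicatorSummary
    y_vfa: IndicatorSummary
    ammonia_release: IndicatorSummary
    phosphate_release: IndicatorSummary
    vfa_scod_ratio: IndicatorSummary

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("solubilization", "y_vfa", "ammonia_release", "phosphate_release", "vfa_scod_ratio"):
            ind: IndicatorSummary = getattr(self, name)
            rows.append({"indicator": name, "mean": ind.mean, "sd": ind.sd, "basis": ind.basis})
        return pd.DataFrame(rows)


#: acids quantified in the VFA spectrum, in elution order
ACIDS = ("acetic", "propionic", "isobutyric", "butyric", "isovaleric", "valeric", "caproic")

#: g-COD per g of acid; iso-forms share their linear isomer's factor
COD_PER_GRAM_ACID: dict[str, float] = {
    "acetic": 1.066,
    "propionic": 1.512,
    "isobutyric": 1.816,
    "butyric": 1.816,
    "isovaleric": 2.037,
    "valeric": 2.037,
    "caproic": 2.204,
}


@dataclass(frozen=True)
class VFASpectrum:
    """Normalized per-acid weight fractions of the total VFA mass."""

    fractions: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError("fractions must be non-negative")

    def mean_cod_factor(self, factors: Mapping[str, float] = COD_PER_GRAM_ACID) -> float:
        """Spectrum-weighted mean g-COD per g of acid."""
        return sum(frac * factors[acid] for acid, frac in self.fractions.items())


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    df: int
    p_value: float
    ci_level: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")
        if self.df < 1:
            raise ValueError("df must be >= 1")


@dataclass(frozen=True)
class StabilitySummary:
    mean: float
    sd: float
    sd_over_mean: float
    stable: bool


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def steady_state_window(series: FermenterSeries, hrt: float, factor: float = 3.0) -> pd.DataFrame:
    """Rows from day >= factor x HRT (pseudo-steady state)."""
    window = series.data[series.data["day"] >= factor * hrt]
    if window.empty:
        raise ValueError("steady-state window is empty")
    return window


def _window(series: FermenterSeries, steady_from: float | None) -> pd.DataFrame:
    if steady_from is None:
        return series.data
    window = series.data[series.data["day"] >= steady_from]
    if window.empty:
        raise ValueError("steady-state window is empty")
    return window


# ---------------------------------------------------------------------------
# indicators
# ---------------------------------------------------------------------------

def cod_solubilization(
    series: FermenterSeries,
    feed: FeedstockCharacterization = DEFAULT_FEEDSTOCK,
    steady_from: float | None = None,
) -> IndicatorSummary:
    """(SCOD_out - SCOD_in) / VS0, g-SCOD per g of initial VS, per day.

    Both COD terms in g/L and VS0 in g/L under the 1 kg/L density convention.
    Negative values (net loss of soluble COD) are returned as-is but logged.
    """
    if feed.vs <= 0:
        raise ValueError("feed VS must be positive")
    data = _window(series, steady_from)
    daily = (data["scod_g_L"] - feed.scod_in / 1000.0) / feed.vs
    daily.index = data["day"]
    if (daily < 0).any():
        logger.warning("negative COD solubilization on %d day(s)", int((daily < 0).sum()))
    return IndicatorSummary.from_daily(daily, basis="g-SCOD/g-VS0")


def vfa_yield(
    series: FermenterSeries,
    feed: FeedstockCharacterization = DEFAULT_FEEDSTOCK,
    basis: str = "cod",
    spectrum: VFASpectrum | None = None,
    cod_to_mass: Mapping[str, float] = COD_PER_GRAM_ACID,
    steady_from: float | None = None,
) -> IndicatorSummary:
    """(VFA_out - VFA_in) / VS0 per day.

    ``basis="cod"`` keeps the COD-equivalent measurement unit; ``basis="mass"``
    divides by the spectrum-weighted g-COD/g-acid factor to express the yield
    on an acid-mass basis (a spectrum is then required).
    """
    if feed.vs <= 0:
        raise ValueError("feed VS must be positive")
    if basis not in ("cod", "mass"):
        raise ValueError(f"unknown basis {basis!r}")
    data = _window(series, steady_from)
    daily = (data["vfa_gscod_L"] - feed.vfa_in / 1000.0) / feed.vs
    daily.index = data["day"]
    if basis == "mass":
        if spectrum is None:
            raise ValueError("mass basis requires a VFASpectrum")
        daily = daily / spectrum.mean_cod_factor(cod_to_mass)
    unit = "g-VFA(COD)/g-VS0" if basis == "cod" else "g-VFA/g-VS0"
    return IndicatorSummary.from_daily(daily, basis=unit)


def nutrient_release(
    series: FermenterSeries,
    feed: FeedstockCharacterization = DEFAULT_FEEDSTOCK,
    steady_from: float | None = None,
) -> tuple[IndicatorSummary, IndicatorSummary]:
    """Ammonia and phosphate release as percent of feed total N and P.

    Ammonia % = 100 x (NH4_out - NH4_in) / (TKN per litre of feed);
    phosphate analogous with total P.  Releases above 100% violate the mass
    balance and raise.
    """
    if feed.tkn <= 0 or feed.p <= 0:
        raise ValueError("feed TKN and P must be positive")
    data = _window(series, steady_from)
    ammonia = 100.0 * (data["nh4_mg_L"] - feed.nh4_in) / feed.tkn_mg_per_l
    phosphate = 100.0 * (data["po4_mg_L"] - feed.po4_in) / feed.p_mg_per_l
    for name, rel in (("ammonia", ammonia), ("phosphate", phosphate)):
        if (rel > 100.0 + 1e-9).any():
            raise ValueError(f"{name} release exceeds 100% — inconsistent inputs")
    ammonia.index = phosphate.index = data["day"]
    return (
        IndicatorSummary.from_daily(ammonia, basis="%"),
        IndicatorSummary.from_daily(phosphate, basis="%"),
    )


def vfa_scod_ratio(series: FermenterSeries, steady_from: float | None = None) -> IndicatorSummary:
    """Daily VFA/SCOD mass ratio (kg/kg) with mean and SD."""
    data = _window(series, steady_from)
    if (data["scod_g_L"] <= 0).any():
        raise ValueError("SCOD must be positive on every day")
    daily = data["vfa_gscod_L"] / data["scod_g_L"]
    daily.index = data["day"]
    return IndicatorSummary.from_daily(daily, basis="kg/kg")


def vfa_spectrum(per_acid_concentrations: Mapping[str, float]) -> VFASpectrum:
    """Normalize per-acid concentrations into weight fractions summing to 1."""
    values = {acid: float(v) for acid, v in per_acid_concentrations.items()}
    if any(v < 0 for v in values.values()):
        raise ValueError("acid concentrations must be non-negative")
    total = sum(values.values())
    if total <= 0:
        raise ValueError("at least one acid concentration must be positive")
    return VFASpectrum({acid: v / total for acid, v in values.items()})


def paired_t_test(x: Sequence[float], y: Sequence[float], ci_level: float = 0.95) -> TTestResult:
    """Two-tailed paired Student t-test on day-paired series.

    Differences are taken as ``d = y - x``; ``t = mean(d) / (sd(d)/sqrt(n))``
    with ``df = n - 1``.  The confidence interval is for the mean difference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = y - x
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        raise ValueError("zero variance of paired differences")
    se = sd / math.sqrt(n)
    t_stat = float(d.mean()) / se
    df = n - 1
    p = 2.0 * float(sps.t.sf(abs(t_stat), df))
    tcrit = float(sps.t.ppf(0.5 + ci_level / 2.0, df))
    return TTestResult(
        t_stat=t_stat,
        df=df,
        p_value=p,
        ci_level=ci_level,
        ci_low=float(d.mean()) - tcrit * se,
        ci_high=float(d.mean()) + tcrit * se,
    )


def stability_summary(values: Sequence[float], threshold: float = 0.10) -> StabilitySummary:
    """Mean, SD, SD/mean, and a stability flag (SD/mean < threshold)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty window")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    if mean == 0.0:
        raise ValueError("zero mean — SD/mean undefined")
    ratio = sd / mean
    return StabilitySummary(mean=mean, sd=sd, sd_over_mean=ratio, stable=ratio < threshold)


def performance_indicators(
    series: FermenterSeries,
    feed: FeedstockCharacterization = DEFAULT_FEEDSTOCK,
    hrt: float | None = None,
    spectrum: VFASpectrum | None = None,
    yield_basis: str = "cod",
    steady_factor: float = 3.0,
) -> PerformanceIndicators:
    """Convenience wrapper computing the full indicator table for one run."""
    steady_from = steady_factor * hrt if hrt is not None else None
    ammonia, phosphate = nutrient_release(series, feed, steady_from)
    return PerformanceIndicators(
        solubilization=cod_solubilization(series, feed, steady_from),
        y_vfa=vfa_yield(series, feed, yield_basis, spectrum, steady_from=steady_from),
        ammonia_release=ammonia,
        phosphate_release=phosphate,
        vfa_scod_ratio=vfa_scod_ratio(series, steady_from),
    )
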