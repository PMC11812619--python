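"""Biochemical methane potential (BMP) data processing and kinetic model fitting.

The processing chain mirrors a standard batch BMP workflow:

1. gas-composition series measured only on a sparse day grid are completed
   with inverse-distance-weighted k-nearest-neighbour imputation
   (:func:`knn_impute_composition`);
2. per-bottle cumulative volumes are corrected for the endogenous production
   of the inoculum using blank (inoculum-only) bottles and averaged over
   replicates (:func:`blank_correct`);
3. the net specific cumulative methane curve is fitted with a first-order
   hydrolysis model or a modified Gompertz model (:func:`fit_model`);
4. headline indicators (SMP, SGP, biogas yield, maximum CH4 content) are
   summarised (:func:`bmp_summary`).

Units: specific yields are Nm3 CH4 (or biogas) per kg volatile solids, i.e.
numerically identical to L/g-VS; the maximum Gompertz rate ``rm`` is kept in
mL/(g-VS.day) as conventionally reported and converted internally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "BMPDataset",
    "KineticFit",
    "BMPSummary",
    "first_order_curve",
    "gompertz_curve",
    "knn_impute_composition",
    "blank_correct",
    "fit_model",
    "bmp_summary",
]

#: conversion factor between mL/(g-VS.d) and Nm3/(kg-VS.d)
_ML_PER_GVS_TO_NM3_PER_KGVS = 1e-3

READINGS_COLUMNS = ["day", "bottle_id", "condition", "cum_biogas_mL", "cum_ch4_mL", "ch4_frac"]
BOTTLE_COLUMNS = ["bottle_id", "condition", "vs_feedstock", "vs_inoculum", "is_blank"]


@dataclass
class BMPDataset:
    """Per-bottle cumulative gas readings plus bottle metadata.

    Parameters
    ----------
    readings
        Tidy frame with columns ``day, bottle_id, condition, cum_biogas_mL,
        cum_ch4_mL, ch4_frac``.  ``ch4_frac`` is NaN on days without a
        gas-chromatography measurement.
    bottles
        One row per bottle: ``bottle_id, condition, vs_feedstock,
        vs_inoculum, is_blank`` (VS masses in grams).
    """

    readings: pd.DataFrame
    bottles: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(READINGS_COLUMNS) - set(self.readings.columns)
        if missing:
            raise ValueError(f"readings missing columns: {sorted(missing)}")
        missing = set(BOTTLE_COLUMNS) - set(self.bottles.columns)
        if missing:
            raise ValueError(f"bottles missing columns: {sorted(missing)}")
        frac = self.readings["ch4_frac"].dropna()
        if ((frac < 0) | (frac > 1)).any():
            raise ValueError("ch4_frac outside [0, 1]")
        for col in ("cum_biogas_mL", "cum_ch4_mL"):
            dec = (
                self.readings.sort_values("day")
                .groupby("bottle_id")[col]
                .apply(lambda s: (s.diff().dropna() < -1e-9).any())
            )
            if dec.any():
                raise ValueError(f"{col} decreases within a bottle")

    @property
    def conditions(self) -> list[str]:
        mask = ~self.bottles["is_blank"]
        return sorted(self.bottles.loc[mask, "condition"].unique())

    def blank_ids(self) -> list:
        return list(self.bottles.loc[self.bottles["is_blank"], "bottle_id"])

    def concat(self, other: "BMPDataset") -> "BMPDataset":
        return BMPDataset(
            readings=pd.concat([self.readings, other.readings], ignore_index=True),
            bottles=pd.concat([self.bottles, other.bottles], ignore_index=True),
        )

    def to_csv(self, readings_path, bottles_path) -> None:
        self.readings.to_csv(readings_path, index=False)
        self.bottles.to_csv(bottles_path, index=False)

    @classmethod
    def from_csv(cls, readings_path, bottles_path) -> "BMPDataset":
        return cls(pd.read_csv(readings_path), pd.read_csv(bottles_path))


@dataclass(frozen=True)
class KineticFit:
    """Least-squares calibration result for one model on one condition."""

    model_id: str
    b0: float
    k: float | None = None
    rm: float | None = None
    lam: float | None = None
    rmse: float = math.nan
    n_points: int = 0
    converged: bool = False

    def predict(self, t) -> np.ndarray:
        if self.model_id == "first_order":
            return first_order_curve(t, self.b0, self.k)
        return gompertz_curve(t, self.b0, self.rm, self.lam)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "b0": self.b0,
            "k": self.k,
            "rm": self.rm,
            "lam": self.lam,
            "rmse": self.rmse,
            "n_points": self.n_points,
            "converged": self.converged,
        }


@dataclass(frozen=True)
class BMPSummary:
    """Headline batch-test indicators for one condition."""

    smp: float  #: Nm3 CH4 / kg-VS fed
    sgp: float  #: Nm3 biogas / kg-VS fed
    biogas_yield: float  #: g biogas / g-VS fed
    max_ch4_content: float  #: % v/v

    def __post_init__(self) -> None:
        if self.smp > self.sgp + 1e-12:
            raise ValueError("smp cannot exceed sgp")
        if not 0.0 <= self.max_ch4_content <= 100.0:
            raise ValueError("max_ch4_content outside [0, 100]")


# ---------------------------------------------------------------------------
# model curves
# ---------------------------------------------------------------------------

def first_order_curve(t, b0: float, k: float):
    """Cumulative yield ``B(t) = b0 * (1 - exp(-k t))``.

    Parameters
    ----------
    t : array-like
        Time in days, non-negative.
    b0 : float
        Ultimate specific yield (Nm3/kg-VS).
    k : float
        First-order hydrolysis rate constant (1/day).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    return b0 * (1.0 - np.exp(-k * t))


def gompertz_curve(t, b0: float, rm: float, lam: float):
    """Modified Gompertz cumulative yield.

    ``B(t) = b0 * exp(-exp(rm' * e / b0 * (lam - t) + 1))`` with
    ``rm' = rm / 1000`` converting mL/(g-VS.d) to Nm3/(kg-VS.d).

    Parameters
    ----------
    t : array-like
        Time in days, non-negative.
    b0 : float
        Asymptotic specific yield (Nm3/kg-VS); must be positive.
    rm : float
        Maximum production rate in mL/(g-VS.day).
    lam : float
        Lag phase in days.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if b0 <= 0:
        raise ValueError("b0 must be positive")
    rm_nm3 = rm * _ML_PER_GVS_TO_NM3_PER_KGVS
    inner = rm_nm3 * math.e / b0 * (lam - t) + 1.0
    # cap to avoid overflow in exp for very early times / long lags
    return b0 * np.exp(-np.exp(np.minimum(inner, 700.0)))


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def knn_impute_composition(series: pd.Series, k: int = 4, weighting: str = "distance") -> pd.Series:
    """Fill gaps in a day-indexed series by k-nearest-neighbour imputation.

    Distance is the absolute day difference; each missing day receives the
    weighted mean of its ``k`` nearest observed days.  With
    ``weighting="distance"`` weights are ``1/|delta day|``; ``"uniform"``
    averages the neighbours equally.  Observed values are never modified.

    Raises
    ------
    ValueError
        If fewer than ``k`` days are observed, the series is all-missing,
        or ``k < 1``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if weighting not in ("distance", "uniform"):
        raise ValueError(f"unknown weighting {weighting!r}")
    s = series.astype(float).copy()
    observed = s.dropna()
    if observed.empty:
        raise ValueError("cannot impute an all-missing series")
    if len(observed) < k:
        raise ValueError(f"need at least k={k} observed points, got {len(observed)}")
    obs_days = observed.index.to_numpy(dtype=float)
    obs_vals = observed.to_numpy(dtype=float)
    for day in s.index[s.isna()]:
        dist = np.abs(obs_days - float(day))
        nearest = np.argsort(dist, kind="stable")[:k]
        d = dist[nearest]
        v = obs_vals[nearest]
        if weighting == "distance":
            w = 1.0 / d  # observed days have d > 0 by construction
        else:
            w = np.ones_like(d)
        s.loc[day] = float(np.sum(w * v) / np.sum(w))
    return s


# ---------------------------------------------------------------------------
# blank correction
# ---------------------------------------------------------------------------

def blank_correct(dataset: BMPDataset) -> dict[str, pd.DataFrame]:
    """Subtract the endogenous (inoculum-only) production and average replicates.

    For every non-blank condition, each bottle's cumulative curves are reduced
    by the mean blank curve — scaled by the bottle-to-blank inoculum-VS ratio
    when the masses differ — then replicates are averaged and negative net
    values are clipped to zero (the clip count is logged).

    Returns
    -------
    dict
        ``condition -> DataFrame`` indexed by day with columns
        ``net_ch4_mL`` and ``net_biogas_mL``.
    """
    blank_ids = dataset.blank_ids()
    if not blank_ids:
        raise ValueError("blank correction requires at least one blank bottle")
    readings = dataset.readings
    meta = dataset.bottles.set_index("bottle_id")

    blanks = readings[readings["bottle_id"].isin(blank_ids)]
    blank_mean = blanks.groupby("day")[["cum_ch4_mL", "cum_biogas_mL"]].mean()
    blank_vs_in = float(meta.loc[blank_ids, "vs_inoculum"].mean())

    out: dict[str, pd.DataFrame] = {}
    for condition in dataset.conditions:
        ids = meta.index[(meta["condition"] == condition) & (~meta["is_blank"])]
        nets = []
        for bid in ids:
            bottle = (
                readings[readings["bottle_id"] == bid]
                .set_index("day")[["cum_ch4_mL", "cum_biogas_mL"]]
                .sort_index()
            )
            scale = 1.0
            if blank_vs_in > 0:
                scale = float(meta.loc[bid, "vs_inoculum"]) / blank_vs_in
            common = bottle.index.intersection(blank_mean.index)
            if len(common) < len(bottle):
                logger.info(
                    "condition %s bottle %s: day grids differ, inner join keeps %d/%d days",
                    condition, bid, len(common), len(bottle),
                )
            nets.append(bottle.loc[common] - scale * blank_mean.loc[common])
        net = sum(nets) / len(nets)
        n_clipped = int((net < 0).to_numpy().sum())
        if n_clipped:
            logger.warning(
                "condition %s: clipped %d negative net readings to zero", condition, n_clipped
            )
        net = net.clip(lower=0.0)
        net.columns = ["net_ch4_mL", "net_biogas_mL"]
        out[condition] = net
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _first_order_starts(t: np.ndarray, b: np.ndarray) -> list[tuple[float, float]]:
    bmax = max(b.max(), 1e-9)
    half = bmax / 2.0
    above = t[b >= half]
    t_half = float(above[0]) if above.size and above[0] > 0 else max(t[-1] / 4.0, 0.5)
    k0 = math.log(2.0) / t_half
    return [
        (bmax, k0),
        (bmax * 1.05, k0),
        (bmax * 1.2, k0 * 0.5),
        (bmax * 1.5, k0 * 2.0),
        (bmax, 0.1),
        (bmax * 2.0, 0.05),
    ]


def _gompertz_starts(t: np.ndarray, b: np.ndarray) -> list[tuple[float, float, float]]:
    bmax = max(b.max(), 1e-9)
    db = np.diff(b)
    dt = np.diff(t)
    slopes = db / np.where(dt > 0, dt, 1.0)
    rm0 = max(float(slopes.max()) / _ML_PER_GVS_TO_NM3_PER_KGVS, 1e-3)
    above = t[b > 0.05 * bmax]
    lam0 = float(above[0]) if above.size else 0.0
    return [
        (bmax, rm0, lam0),
        (bmax * 1.05, rm0, 0.0),
        (bmax * 1.2, rm0 * 0.5, lam0),
        (bmax * 1.5, rm0 * 2.0, lam0 + 1.0),
        (bmax, rm0 * 0.25, 0.0),
        (bmax * 2.0, rm0, max(lam0 - 1.0, 0.0)),
    ]


def fit_model(
    t: Sequence[float],
    b: Sequence[float],
    model_id: str,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    starts: Sequence[tuple] | None = None,
) -> KineticFit:
    """Fit a kinetic model to a cumulative specific-yield curve.

    Unweighted nonlinear least squares with deterministic multi-start
    initialisation; the best (lowest-SSE) converged start wins.

    Parameters
    ----------
    t, b
        Days and cumulative specific yield (Nm3/kg-VS); at least 4 points,
        ``t`` non-negative and strictly increasing.
    model_id
        ``"first_order"`` or ``"gompertz"``.
    bounds
        Optional per-parameter ``(lo, hi)`` overrides keyed by parameter name.
    starts
        Optional explicit start tuples replacing the built-in heuristics.
    """
    t = np.asarray(t, dtype=float)
    b = np.asarray(b, dtype=float)
    if t.shape != b.shape:
        raise ValueError("t and b must have equal length")
    if t.size < 4:
        raise ValueError("need at least 4 points to fit")
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("t must be non-negative and strictly increasing")
    if np.allclose(b, b[0]):
        raise ValueError("degenerate (constant) response")

    bmax = float(b.max())
    if model_id == "first_order":
        names = ("b0", "k")
        default_bounds = {"b0": (1e-9, 10.0 * bmax + 1.0), "k": (1e-6, 20.0)}
        model = first_order_curve
        start_list = list(starts) if starts is not None else _first_order_starts(t, b)
    elif model_id == "gompertz":
        names = ("b0", "rm", "lam")
        default_bounds = {
            "b0": (1e-9, 10.0 * bmax + 1.0),
            "rm": (1e-9, 1e5),
            "lam": (0.0, float(t[-1])),
        }
        model = gompertz_curve
        start_list = list(starts) if starts is not None else _gompertz_starts(t, b)
    else:
        raise ValueError(f"unknown model_id {model_id!r}")

    if bounds:
        default_bounds.update(bounds)
    lo = [default_bounds[n][0] for n in names]
    hi = [default_bounds[n][1] for n in names]

    best_params = None
    best_sse = math.inf
    for p0 in start_list:
        p0 = tuple(min(max(v, l), h) for v, l, h in zip(p0, lo, hi))
        try:
            popt, _ = curve_fit(model, t, b, p0=p0, bounds=(lo, hi), maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        resid = b - model(t, *popt)
        sse = float(resid @ resid)
        if sse < best_sse:
            best_sse = sse
            best_params = popt
    if best_params is None:
        raise RuntimeError(f"{model_id} fit failed to converge from all starts")

    rmse = math.sqrt(best_sse / t.size)
    fitted = dict(zip(names, (float(v) for v in best_params)))
    return KineticFit(
        model_id=model_id,
        b0=fitted["b0"],
        k=fitted.get("k"),
        rm=fitted.get("rm"),
        lam=fitted.get("lam"),
        rmse=rmse,
        n_points=int(t.size),
        converged=True,
    )


# ---------------------------------------------------------------------------
# summary indicators
# ---------------------------------------------------------------------------

def bmp_summary(
    net_curves: pd.DataFrame,
    composition: pd.Series,
    vs_feedstock: float,
    biogas_density_g_l: float = 1.2,
) -> BMPSummary:
    """Compute SMP, SGP, biogas yield, and maximum CH4 content.

    Parameters
    ----------
    net_curves
        Blank-corrected condition frame (``net_ch4_mL``, ``net_biogas_mL``
        indexed by day) from :func:`blank_correct`.
    composition
        CH4 volume fraction series on the full day grid (already imputed).
    vs_feedstock
        Grams of feedstock VS in the bottle.
    biogas_density_g_l
        Biogas density used to express the yield on a mass basis.
    """
    if vs_feedstock <= 0:
        raise ValueError("vs_feedstock must be positive")
    final = net_curves.sort_index().iloc[-1]
    # mL/g-VS is numerically Nm3/kg-VS after the 1e-3 L/mL conversion
    smp = float(final["net_ch4_mL"]) / 1000.0 / vs_feedstock
    sgp = float(final["net_biogas_mL"]) / 1000.0 / vs_feedstock
    biogas_yield = sgp * biogas_density_g_l
    max_ch4 = float(composition.dropna().max()) * 100.0
    return BMPSummary(smp=smp, sgp=sgp, biogas_yield=biogas_yield, max_ch4_content=max_ch4)
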