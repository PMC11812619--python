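"""Seeded generators for BMP bottle datasets and fermenter monitoring series.

Every downstream stage (imputation, blank correction, model fitting,
performance indicators, t-tests) is exercised against data produced here, so
the generators reproduce the structural features of a batch BMP campaign:
duplicate bottles per condition, an inoculum-only blank, cumulative volumes
that follow a chosen kinetic model plus Gaussian noise (clipped to stay
non-decreasing), and gas-composition readings only on the sparse
chromatography day grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .bmp_kinetics import BMPDataset, first_order_curve, gompertz_curve

__all__ = [
    "KineticParams",
    "BottleSpec",
    "MeasurementSchedule",
    "FermenterSeries",
    "DEFAULT_COMPOSITION_DAYS",
    "DEFAULT_SCHEDULE",
    "DEFAULT_BLANK",
    "gen_bmp_dataset",
    "gen_bmp_experiment",
    "gen_fermenter_series",
]

#: chromatography measurement days within the 25-day test
DEFAULT_COMPOSITION_DAYS = (1, 4, 6, 10, 14, 16, 18, 21, 25)


@dataclass(frozen=True)
class KineticParams:
    """Parameters of a cumulative-yield kinetic model.

    ``b0`` is the ultimate specific methane yield in Nm3/kg-VS; ``k`` the
    first-order rate (1/day); ``rm`` (mL/g-VS.d) and ``lam`` (days) the
    modified-Gompertz maximum rate and lag.
    """

    model_id: str
    b0: float
    k: float | None = None
    rm: float | None = None
    lam: float | None = None

    def __post_init__(self) -> None:
        if self.model_id not in ("first_order", "gompertz"):
            raise ValueError(f"unknown model_id {self.model_id!r}")
        if self.b0 <= 0:
            raise ValueError("b0 must be positive")
        if self.model_id == "first_order":
            if self.k is None or self.k <= 0:
                raise ValueError("first_order requires k > 0")
        else:
            if self.rm is None or self.rm <= 0:
                raise ValueError("gompertz requires rm > 0")
            if self.lam is None or self.lam < 0:
                raise ValueError("gompertz requires lam >= 0")

    def curve(self, t) -> np.ndarray:
        """Evaluate the cumulative specific yield (Nm3/kg-VS) at days ``t``."""
        if self.model_id == "first_order":
            return first_order_curve(t, self.b0, self.k)
        return gompertz_curve(t, self.b0, self.rm, self.lam)


@dataclass(frozen=True)
class BottleSpec:
    """Replicate layout and masses for one BMP condition."""

    condition: str
    n_replicates: int = 2
    vs_feedstock: float = 1.0  #: g-VS of feedstock per bottle (0 for blanks)
    vs_inoculum: float = 3.33  #: g-VS of inoculum per bottle
    noise_sd: float = 0.0  #: cumulative-volume noise SD, mL
    seed: int = 0
    is_blank: bool | None = None  #: None -> inferred from vs_feedstock == 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.vs_feedstock < 0:
            raise ValueError("vs_feedstock must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class MeasurementSchedule:
    """Day grids for volume readings and gas-composition measurements."""

    gas_volume_days: tuple = tuple(range(0, 26))
    composition_days: tuple = DEFAULT_COMPOSITION_DAYS
    horizon: int = 25

    def __post_init__(self) -> None:
        if len(self.gas_volume_days) == 0:
            raise ValueError("empty gas_volume_days schedule")
        for days in (self.gas_volume_days, self.composition_days):
            if any(b <= a for a, b in zip(days, days[1:])):
                raise ValueError("schedule days must be strictly increasing")
        if any(d < 0 or d > self.horizon for d in self.composition_days):
            raise ValueError("composition_days must lie within [0, horizon]")


DEFAULT_SCHEDULE = MeasurementSchedule()

#: endogenous inoculum-only production, per g of inoculum VS (configurable;
#: small first-order curve so blank correction stays exercisable)
DEFAULT_BLANK = KineticParams("first_order", b0=0.02, k=0.10)


def gen_bmp_dataset(
    params: KineticParams,
    spec: BottleSpec,
    schedule: MeasurementSchedule = DEFAULT_SCHEDULE,
    blank_params: KineticParams | None = DEFAULT_BLANK,
    ch4_fraction: float | Callable[[np.ndarray], np.ndarray] = 0.6,
) -> BMPDataset:
    """Generate cumulative gas curves for the replicate bottles of one condition.

    Each bottle's cumulative CH4 volume (mL) on the volume day grid is
    ``params.curve(day) * vs_feedstock * 1000`` plus the endogenous blank
    contribution ``blank_params.curve(day) * vs_inoculum * 1000`` plus
    ``N(0, noise_sd^2)`` noise; a running-maximum clip restores monotonicity.
    Biogas is CH4 divided by the CH4 fraction; the ``ch4_frac`` column is
    populated only on ``schedule.composition_days``.  Identical specs and
    seeds yield identical datasets.
    """
    days = np.asarray(schedule.gas_volume_days, dtype=float)
    rng = np.random.default_rng(spec.seed)

    if callable(ch4_fraction):
        frac = np.asarray(ch4_fraction(days), dtype=float)
    else:
        frac = np.full_like(days, float(ch4_fraction))
    if np.any((frac <= 0) | (frac > 1)):
        raise ValueError("ch4_fraction must lie in (0, 1]")

    feed_ml = params.curve(days) * spec.vs_feedstock * 1000.0
    blank_ml = np.zeros_like(days)
    if blank_params is not None and spec.vs_inoculum > 0:
        blank_ml = blank_params.curve(days) * spec.vs_inoculum * 1000.0
    clean_ch4 = feed_ml + blank_ml

    comp_mask = np.isin(days, np.asarray(schedule.composition_days, dtype=float))
    is_blank = spec.is_blank if spec.is_blank is not None else spec.vs_feedstock == 0.0

    rows = []
    bottles = []
    for rep in range(spec.n_replicates):
        ch4 = clean_ch4 + rng.normal(0.0, spec.noise_sd, size=days.size) if spec.noise_sd else clean_ch4.copy()
        biogas = clean_ch4 / frac + (rng.normal(0.0, spec.noise_sd, size=days.size) if spec.noise_sd else 0.0)
        ch4 = np.maximum.accumulate(np.clip(ch4, 0.0, None))
        biogas = np.maximum.accumulate(np.clip(biogas, 0.0, None))
        biogas = np.maximum(biogas, ch4)  # biogas contains CH4
        bottle_id = f"{spec.condition}_{rep + 1}"
        rows.append(
            pd.DataFrame(
                {
                    "day": days,
                    "bottle_id": bottle_id,
                    "condition": spec.condition,
                    "cum_biogas_mL": biogas,
                    "cum_ch4_mL": ch4,
                    "ch4_frac": np.where(comp_mask, frac, np.nan),
                }
            )
        )
        bottles.append(
            {
                "bottle_id": bottle_id,
                "condition": spec.condition,
                "vs_feedstock": spec.vs_feedstock,
                "vs_inoculum": spec.vs_inoculum,
                "is_blank": is_blank,
            }
        )
    return BMPDataset(pd.concat(rows, ignore_index=True), pd.DataFrame(bottles))


def gen_bmp_experiment(
    conditions: dict[str, tuple[KineticParams, BottleSpec]],
    blank_spec: BottleSpec,
    schedule: MeasurementSchedule = DEFAULT_SCHEDULE,
    blank_params: KineticParams = DEFAULT_BLANK,
    ch4_fraction: float | Callable = 0.6,
) -> BMPDataset:
    """Assemble a full multi-condition campaign including blank bottles."""
    if blank_spec.vs_feedstock != 0:
        raise ValueError("blank_spec must have vs_feedstock == 0")
    dataset = gen_bmp_dataset(
        # the feedstock curve is irrelevant for a zero-VS blank; reuse blank kinetics
        blank_params, blank_spec, schedule, blank_params, ch4_fraction
    )
    for params, spec in conditions.values():
        dataset = dataset.concat(
            gen_bmp_dataset(params, spec, schedule, blank_params, ch4_fraction)
        )
    return dataset


# ---------------------------------------------------------------------------
# fermenter monitoring series
# ---------------------------------------------------------------------------

FERMENTER_COLUMNS = ["day", "vfa_gscod_L", "scod_g_L", "ph", "nh4_mg_L", "po4_mg_L"]


@dataclass
class FermenterSeries:
    """Daily fermenter effluent measurements (tidy frame wrapper)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(FERMENTER_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"fermenter series missing columns: {sorted(missing)}")
        if (self.data["vfa_gscod_L"] > self.data["scod_g_L"] + 1e-9).any():
            raise ValueError("VFA (as COD) cannot exceed SCOD")
        numeric = self.data[["vfa_gscod_L", "scod_g_L", "nh4_mg_L", "po4_mg_L"]]
        if (numeric < 0).any().any():
            raise ValueError("concentrations must be non-negative")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FermenterSeries":
        return cls(pd.read_csv(path))


def gen_fermenter_series(
    mean_vfa: float,
    sd_vfa: float,
    n_days: int,
    vfa_scod_ratio: float = 0.892,
    seed: int | None = None,
    ph_mean: float = 6.56,
    ph_sd: float = 0.25,
    nh4_mean_mg_l: float = 528.0,
    nh4_sd_mg_l: float = 40.0,
    po4_mean_mg_l: float = 38.0,
    po4_sd_mg_l: float = 8.0,
) -> FermenterSeries:
    """Draw a daily effluent series with VFA ~ Normal(mean, sd) truncated at 0.

    SCOD is derived as ``vfa / vfa_scod_ratio`` so the per-day VFA/SCOD ratio
    is exactly the supplied value; pH and nutrient columns get independent
    Gaussian noise (clipped at zero where physically required).
    """
    if n_days <= 0:
        raise ValueError("n_days must be positive")
    if mean_vfa <= 0:
        raise ValueError("mean_vfa must be positive")
    if sd_vfa < 0:
        raise ValueError("sd_vfa must be >= 0")
    if not 0 < vfa_scod_ratio <= 1:
        raise ValueError("vfa_scod_ratio must be in (0, 1]")
    rng = np.random.default_rng(seed)
    vfa = np.clip(rng.normal(mean_vfa, sd_vfa, size=n_days), 0.0, None)
    data = pd.DataFrame(
        {
            "day": np.arange(1, n_days + 1),
            "vfa_gscod_L": vfa,
            "scod_g_L": vfa / vfa_scod_ratio,
            "ph": rng.normal(ph_mean, ph_sd, size=n_days),
            "nh4_mg_L": np.clip(rng.normal(nh4_mean_mg_l, nh4_sd_mg_l, size=n_days), 0.0, None),
            "po4_mg_L": np.clip(rng.normal(po4_mean_mg_l, po4_sd_mg_l, size=n_days), 0.0, None),
        }
    )
    return FermenterSeries(data)
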