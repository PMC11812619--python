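"""Energy balance and economics for a scenario run.

The energy layer sums stream-heating duties recorded by the flowsheet, wall
losses of the reactors (above-ground wall to air, buried wall and floor to
ground), and the combined-heat-and-power (CHP) output from the biogas.  The
economics layer turns the VFA product and electricity into an annual income,
subtracts configured costs, and reports an undiscounted payback period.

The reference wall-loss geometry is a vertical cylinder with height equal to
diameter and a 20% buried fraction; all geometry and boundary-condition
parameters are configurable, so the absolute surplus figures depend on those
choices (only directional comparisons between scenarios are contract-level).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .flowsheet import ReactorSpec, ScenarioResult

logger = logging.getLogger(__name__)

__all__ = [
    "EnergyParams",
    "EnergyBalance",
    "Prices",
    "Costs",
    "EconomicSummary",
    "stream_heating",
    "wall_loss",
    "chp",
    "energy_balance",
    "economics",
    "payback_years",
    "calibrate_vfa_price",
    "evaluate_scenario",
]

SECONDS_PER_DAY = 86_400.0
MJ_PER_MWH = 3_600.0


@dataclass(frozen=True)
class EnergyParams:
    """Boundary conditions for the energy flow analysis."""

    lhv_biogas: float = 23.012  #: MJ/Nm3
    eta_el: float = 0.4
    eta_th: float = 0.5
    t_operative: float = 37.0
    t_water: float = 15.0
    t_air: float = 20.0
    t_ground: float = 25.0
    cp_water: float = 4.186  #: kJ/(kg.degC)

    def __post_init__(self) -> None:
        if not (0.0 < self.eta_el < 1.0 and 0.0 < self.eta_th < 1.0):
            raise ValueError("efficiencies must lie in (0, 1)")
        if self.lhv_biogas <= 0:
            raise ValueError("lhv_biogas must be positive")


@dataclass(frozen=True)
class EnergyBalance:
    heating_demand: float  #: MJ/day
    wall_loss: float  #: MJ/day
    thermal_recovered: float  #: MJ/day
    electricity: float  #: MJ/day
    surplus: float  #: MJ/day (may be negative)

    def __post_init__(self) -> None:
        expected = self.thermal_recovered + self.electricity - self.heating_demand - self.wall_loss
        if not math.isclose(self.surplus, expected, rel_tol=1e-9, abs_tol=1e-6):
            raise ValueError("surplus inconsistent with components")


@dataclass(frozen=True)
class Prices:
    electricity_eur_per_mwh: float = 130.0
    vfa_eur_per_kg: float = 0.1708  #: back-solved against the reference annual income


@dataclass(frozen=True)
class Costs:
    """Annual operating costs; zero by default (the reference accounting is
    not published, so income defaults to gross)."""

    opex_eur_yr: float = 0.0
    water_eur_per_m3: float = 0.0
    disposal_eur_per_ton: float = 0.0  #: typical secondary-waste range 75-125


@dataclass(frozen=True)
class EconomicSummary:
    capex: float
    annual_income: float
    annual_cost: float
    payback: float  #: years; inf when net income <= 0
    payback_defined: bool


# ---------------------------------------------------------------------------
# energy
# ---------------------------------------------------------------------------

def stream_heating(mass_flow: float, t_in: float, t_out: float, cp: float = 4.186) -> float:
    """Sensible heating duty in MJ/day: m x cp x dT / 1000.

    Negative temperature lifts clamp to zero (cooling is not credited).
    """
    if cp <= 0:
        raise ValueError("cp must be positive")
    if t_out <= t_in:
        if t_out < t_in:
            logger.info("stream_heating: t_out < t_in, duty clamped to 0")
        return 0.0
    return mass_flow * cp * (t_out - t_in) / 1000.0


def wall_loss(spec: ReactorSpec, params: EnergyParams = EnergyParams()) -> float:
    """Reactor heat loss in MJ/day from U x A x dT over the three surfaces."""
    spec = spec.with_geometry()
    if spec.diameter is None or spec.height is None:
        raise ValueError("reactor geometry required for wall losses")
    lateral = math.pi * spec.diameter * spec.height
    a_above = lateral * (1.0 - spec.buried_fraction)
    a_buried = lateral * spec.buried_fraction
    a_floor = math.pi / 4.0 * spec.diameter**2
    t_op = spec.temperature
    watts = (
        spec.u_wall_outer * a_above * max(t_op - params.t_air, 0.0)
        + spec.u_wall_inner * a_buried * max(t_op - params.t_ground, 0.0)
        + spec.u_floor * a_floor * max(t_op - params.t_ground, 0.0)
    )
    return watts * SECONDS_PER_DAY / 1e6


def chp(biogas_nm3_day: float, params: EnergyParams = EnergyParams()) -> tuple[float, float]:
    """Electricity and recoverable heat (MJ/day) from the biogas LHV."""
    if biogas_nm3_day < 0:
        raise ValueError("biogas volume must be >= 0")
    energy = biogas_nm3_day * params.lhv_biogas
    return params.eta_el * energy, params.eta_th * energy


def energy_balance(result: ScenarioResult, params: EnergyParams = EnergyParams()) -> EnergyBalance:
    """Daily energy balance of one scenario run."""
    heating = sum(
        stream_heating(ev.mass_flow, ev.t_in, ev.t_out, params.cp_water)
        for ev in result.heating_events
    )
    losses = sum(wall_loss(info["spec"], params) for info in result.reactors.values())
    electricity, heat = chp(result.biogas_nm3_day, params)
    return EnergyBalance(
        heating_demand=heating,
        wall_loss=losses,
        thermal_recovered=heat,
        electricity=electricity,
        surplus=heat + electricity - heating - losses,
    )


# ---------------------------------------------------------------------------
# economics
# ---------------------------------------------------------------------------

def payback_years(capex: float, annual_net_income: float) -> tuple[float, bool]:
    """Undiscounted payback; (inf, False) when the net income is non-positive."""
    if annual_net_income <= 0:
        return math.inf, False
    return capex / annual_net_income, True


def economics(
    capex: float,
    vfa_kg_day: float,
    electricity_mj_day: float,
    prices: Prices = Prices(),
    costs: Costs = Costs(),
    water_m3_day: float = 0.0,
    residual_solids_kg_day: float = 0.0,
) -> EconomicSummary:
    """Annual income, cost, and payback for one scenario.

    Income = 365 x (VFA mass x VFA price + electricity sold at the
    electricity price); only non-negative electricity is credited.
    """
    elec_mwh_day = max(electricity_mj_day, 0.0) / MJ_PER_MWH
    annual_income = 365.0 * (
        vfa_kg_day * prices.vfa_eur_per_kg + elec_mwh_day * prices.electricity_eur_per_mwh
    )
    annual_cost = (
        costs.opex_eur_yr
        + 365.0 * water_m3_day * costs.water_eur_per_m3
        + 365.0 * residual_solids_kg_day / 1000.0 * costs.disposal_eur_per_ton
    )
    payback, defined = payback_years(capex, annual_income - annual_cost)
    if not defined:
        logger.warning("non-positive net annual income — payback undefined (inf)")
    return EconomicSummary(
        capex=capex,
        annual_income=annual_income,
        annual_cost=annual_cost,
        payback=payback,
        payback_defined=defined,
    )


def calibrate_vfa_price(
    vfa_kg_day: float,
    electricity_mj_day: float,
    target_annual_net_income: float,
    prices: Prices = Prices(),
    costs: Costs = Costs(),
    water_m3_day: float = 0.0,
    residual_solids_kg_day: float = 0.0,
) -> float:
    """Back-solve the VFA price reproducing a target annual net income.

    Documentation utility: the returned price is a fitted quantity, not an
    observed market value.
    """
    if vfa_kg_day <= 0:
        raise ValueError("vfa_kg_day must be positive to calibrate its price")
    elec_income = 365.0 * max(electricity_mj_day, 0.0) / MJ_PER_MWH * prices.electricity_eur_per_mwh
    annual_cost = (
        costs.opex_eur_yr
        + 365.0 * water_m3_day * costs.water_eur_per_m3
        + 365.0 * residual_solids_kg_day / 1000.0 * costs.disposal_eur_per_ton
    )
    return (target_annual_net_income + annual_cost - elec_income) / (365.0 * vfa_kg_day)


DEFAULT_CAPEX = {1: 809_000.0, 2: 1_618_000.0}


def evaluate_scenario(
    result: ScenarioResult,
    params: EnergyParams = EnergyParams(),
    prices: Prices = Prices(),
    costs: Costs = Costs(),
    capex: float | None = None,
    use_gross_electricity: bool = True,
) -> tuple[EnergyBalance, EconomicSummary]:
    """Run the energy balance and economics for a flowsheet result."""
    balance = energy_balance(result, params)
    if capex is None:
        capex = DEFAULT_CAPEX[result.scenario]
    electricity = balance.electricity if use_gross_electricity else balance.surplus
    summary = economics(
        capex=capex,
        vfa_kg_day=result.vfa_product_kg_day,
        electricity_mj_day=electricity,
        prices=prices,
        costs=costs,
        water_m3_day=result.additions["water_kg_day"] / 1000.0,
        residual_solids_kg_day=result.residual_solids_kg_day,
    )
    return balance, summary
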