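"""Coupled body-clothing-environment simulation and experiment runners.

Assembles the passive tissue balances, the active controller and the
clothing microclimate into one ODE system (65 body nodes plus two clothing
nodes per clothed segment), integrates it, finds steady states, decomposes
the skin-to-clothing flux, sweeps the air-gap thickness for the natural-
convection onset, and reproduces the five-garment reference experiment.

Default integrator: fixed-step classical RK4 with dt = 0.1 s.  The inner-
air clothing node has a time constant of order 0.1 s (a few J/K of film
capacity against ~50 W/K of conductance), which makes the system mildly
stiff; the step is chosen well inside the explicit stability limit, and an
adaptive stiff solver (LSODA) is available behind ``solver="lsoda"`` and is
used internally for steady-state searches.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
import tomllib

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .body import (BodyRegistry, BodyState, N_SEGMENTS, ValidationError,
                   initial_state, load_default_body)
from .clothing import (AirProperties, Environment, Fabric, Garment,
                       SurfaceCoefficients, clothing_derivatives,
                       evaporative_coefficient, max_evaporation,
                       operative_temperature, rayleigh_number,
                       sensible_exchange_bare, skin_evaporation,
                       total_heat_transfer_coefficient)
from .control import error_signals, shivering, sweat_rate, vasomotor
from .passive import (CHEST, TissueFluxes, blood_derivative, respiration_loss,
                      tissue_derivatives)

MET_W_M2 = 58.15  # 1 Met in W/m2

__all__ = [
    "Scenario", "SimulationResult", "FluxBreakdown", "OnsetSweepResult",
    "IntegrationError", "ConvergenceError",
    "load_reference_scenario", "reference_garment", "thermal_neutrality_scenario",
    "evaluate_state", "integrate", "steady_state", "flux_partition",
    "convection_onset_sweep", "run_paper_experiment", "write_results",
    "energy_closure", "MET_W_M2",
]


class IntegrationError(RuntimeError):
    """Raised when the integration produces a non-finite state."""


class ConvergenceError(RuntimeError):
    """Raised when the steady-state search does not converge."""


# ---------------------------------------------------------------------------
# scenario definition
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """One simulation setup: body, garment, environment and solver settings."""

    registry: BodyRegistry
    garment: Garment
    environment: Environment
    metabolic_rate: float = 100.4        # W/m2 whole body
    duration: float = 1800.0             # s
    time_step: float = 0.1               # s (fixed-step RK4)
    output_interval: float = 60.0        # s
    solver: str = "rk4"
    air: AirProperties = field(default_factory=AirProperties.standard)
    surface: SurfaceCoefficients | None = None
    seed: int | None = None              # reserved; the model is deterministic

    def __post_init__(self) -> None:
        if self.duration <= 0.0:
            raise ValidationError("duration must be positive")
        if not (0.0 < self.time_step <= self.duration):
            raise ValidationError("time step must be positive and <= duration")
        if self.solver not in ("rk4", "lsoda"):
            raise ValidationError(f"unknown solver '{self.solver}'")
        if self.surface is None:
            self.surface = _default_surface()

    def describe(self) -> dict:
        """JSON-serialisable description used for run-metadata hashing."""
        return {
            "registry": self.registry.to_dict(),
            "garment": {"name": self.garment.name,
                        "gap_m": [None if not np.isfinite(g) else g
                                  for g in self.garment.gap],
                        "fabric": vars(self.garment.fabric).copy()},
            "environment": vars(self.environment).copy(),
            "metabolic_rate_w_m2": self.metabolic_rate,
            "duration_s": self.duration, "time_step_s": self.time_step,
            "output_interval_s": self.output_interval, "solver": self.solver,
            "surface": {"h_c": self.surface.h_c.tolist(),
                        "h_r": self.surface.h_r.tolist(),
                        "skin_emissivity": self.surface.skin_emissivity},
        }

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.describe(), sort_keys=True).encode()).hexdigest()[:16]


def _reference_config() -> dict:
    with resources.files("thermoclo.data").joinpath("reference.toml").open("rb") as fh:
        return tomllib.load(fh)


def _default_surface() -> SurfaceCoefficients:
    cfg = _reference_config()["surface"]
    return SurfaceCoefficients(h_c=np.array(cfg["h_c"]), h_r=np.array(cfg["h_r"]),
                               skin_emissivity=cfg["skin_emissivity"])


def reference_fabric() -> Fabric:
    cfg = _reference_config()["fabric"]
    return Fabric(fiber=cfg["fiber"],
                  areal_density=cfg["areal_density_g_m2"] / 1000.0,
                  thickness=cfg["thickness_mm"] / 1000.0,
                  insulation_clo=cfg["insulation_clo"],
                  i_cl=cfg["vapor_permeation_efficiency"],
                  specific_heat=cfg["specific_heat_J_kgK"],
                  emissivity=cfg["emissivity"])


def reference_garment(code: str, registry: BodyRegistry | None = None) -> Garment:
    """One of the five packaged garments (A-E) with its average air gap
    applied uniformly to every clothed segment."""
    registry = registry or load_default_body()
    gaps = _reference_config()["garments"]
    if code not in gaps:
        raise KeyError(f"unknown garment '{code}' (expected one of {sorted(gaps)})")
    return Garment.uniform(gaps[code], registry, reference_fabric(), name=code)


def load_reference_scenario(garment: str = "A",
                            registry: BodyRegistry | None = None,
                            **overrides) -> Scenario:
    """The packaged reference scenario (standing subject, 1.7 Met, 25/20 degC,
    0.25 m/s) wearing one of garments A-E; keyword overrides patch any
    :class:`Scenario` field."""
    registry = registry or load_default_body()
    cfg = _reference_config()
    env = Environment(T_a=cfg["environment"]["air_temperature_c"],
                      T_r=cfg["environment"]["radiant_temperature_c"],
                      v=cfg["environment"]["air_speed_m_s"],
                      RH=cfg["environment"]["relative_humidity"])
    scen = Scenario(registry=registry,
                    garment=reference_garment(garment, registry),
                    environment=env,
                    metabolic_rate=cfg["scenario"]["metabolic_rate_w_m2"],
                    duration=cfg["scenario"]["duration_s"],
                    time_step=cfg["scenario"]["time_step_s"],
                    output_interval=cfg["scenario"]["output_interval_s"])
    return replace(scen, **overrides) if overrides else scen


def thermal_neutrality_scenario(registry: BodyRegistry | None = None,
                                **overrides) -> Scenario:
    """The reference environment with a sedentary (1 Met) subject — the
    thermal-neutrality condition under which evaporation is a diffusion-
    dominated 10-25% of total heat loss."""
    return load_reference_scenario(garment="A", registry=registry,
                                   metabolic_rate=MET_W_M2, **overrides)


# ---------------------------------------------------------------------------
# state-vector packing
# ---------------------------------------------------------------------------

def _pack(state: BodyState, clothed: np.ndarray) -> np.ndarray:
    return np.concatenate([state.T[:, :4].ravel(), [state.T_blood],
                           state.T[clothed, 4], state.T[clothed, 5]])


def _unpack(y: np.ndarray, clothed: np.ndarray, t: float = 0.0) -> BodyState:
    n_cl = int(clothed.sum())
    T = np.empty((N_SEGMENTS, 6))
    T[:, :4] = y[:64].reshape(N_SEGMENTS, 4)
    T[:, 4] = T[:, 3]          # bare segments mirror the skin
    T[:, 5] = T[:, 3]
    T[clothed, 4] = y[65:65 + n_cl]
    T[clothed, 5] = y[65 + n_cl:65 + 2 * n_cl]
    return BodyState(T=T, T_blood=float(y[64]), t=t)


# ---------------------------------------------------------------------------
# full right-hand side
# ---------------------------------------------------------------------------

def evaluate_state(scenario: Scenario, state: BodyState):
    """Assemble all fluxes and derivatives for one state.

    Returns ``(dstate, diag)`` where ``dstate`` is a dict with ``tissue``
    (16, 4), ``blood`` (float), ``inner``/``outer`` (16,), all in K/s, and
    ``diag`` carries every intermediate flux for analysis and testing.
    """
    reg = scenario.registry
    env = scenario.environment
    surf = scenario.surface
    air = scenario.air
    ctl = reg.control
    clothed = reg.clothed
    T4 = state.T[:, 3]

    signals = error_signals(state, reg)

    # metabolic heat: basal + work split to muscles + shivering
    M_total = scenario.metabolic_rate * reg.total_area
    work_total = max(M_total - reg.total_basal, 0.0)
    work = ctl.work_distribution * work_total
    shiv = shivering(signals, ctl)
    Q = reg.Q_basal.copy()
    Q[:, 1] += work + shiv

    # blood-flow conductances: exercise hyperaemia + vasomotor skin control
    BF = reg.BF_basal.copy()
    BF[:, 1] += ctl.work_bf_coupling * (work + shiv)
    BF[:, 3] = vasomotor(signals, ctl, reg.BF_basal[:, 3])
    B = BF * (state.T[:, :4] - state.T_blood)

    D = reg.D_cond * (state.T[:, :3] - state.T[:, 1:4])
    RES = respiration_loss(M_total, env.T_a, env.p_a)

    # evaporation: Lewis relation; clothed segments through fabric + air layer
    h_e_bare = air.LR * surf.h_c
    h_e_clothed = evaporative_coefficient(
        scenario.garment.fabric.insulation_clo, scenario.garment.fabric.i_cl,
        surf.h_c, scenario.garment.f_cl, air.LR)
    h_e = np.where(clothed, h_e_clothed, h_e_bare)
    E_max = max_evaporation(h_e, T4, env.p_a, reg.A_n)
    E_sw = sweat_rate(signals, ctl, E_max)
    E = skin_evaporation(E_sw, E_max)

    # sensible skin loss: gap path (clothed) or operative-temperature path
    dT5, dT6, cdiag = clothing_derivatives(state, scenario.garment, env, reg,
                                           air, surf)
    t_o = operative_temperature(env.T_a, env.T_r, surf.h_c, surf.h_r)
    h_t = total_heat_transfer_coefficient(0.0, surf.h_c, surf.h_r, 1.0)
    Q_t = sensible_exchange_bare(T4, t_o, h_t, reg.A_n)
    Q_skin_out = np.where(clothed, cdiag["Q_nc"], Q_t)

    fluxes = TissueFluxes(Q=Q, B=B, D=D, RES=RES, E_skin=E, Q_skin_out=Q_skin_out)
    dT_tissue = tissue_derivatives(state, fluxes, reg)
    dT_blood = blood_derivative(state, fluxes, reg)

    dstate = {"tissue": dT_tissue, "blood": dT_blood, "inner": dT5, "outer": dT6}
    diag = {"fluxes": fluxes, "signals": signals, "E_sw": E_sw, "E_max": E_max,
            "h_e": h_e, "t_o": t_o, "h_t": h_t, "Q_t": Q_t, "M_total": M_total,
            "work": work, "shiver": shiv, "BF": BF, **cdiag}
    return dstate, diag


def _rhs(scenario: Scenario):
    clothed = scenario.registry.clothed
    def fun(t, y):
        state = _unpack(y, clothed, t)
        d, _ = evaluate_state(scenario, state)
        return np.concatenate([d["tissue"].ravel(), [d["blood"]],
                               d["inner"][clothed], d["outer"][clothed]])
    return fun


def _max_rate(scenario: Scenario, state: BodyState) -> float:
    fun = _rhs(scenario)
    return float(np.max(np.abs(fun(0.0, _pack(state, scenario.registry.clothed)))))


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class FluxBreakdown:
    """Decomposition of one segment's skin heat loss, W/m2 of skin area.

    The sensible gap flux splits exactly into its conductive/convective and
    radiant terms; evaporation is reported alongside.  ``shares`` are the
    two sensible fractions (they sum to 1 when both terms share a sign).
    """

    segment: int
    conductive_convective: float
    radiant: float
    evaporative: float
    total_sensible: float
    shares: dict

    def __post_init__(self) -> None:
        if abs(self.conductive_convective + self.radiant - self.total_sensible) \
                > 1e-9 * max(abs(self.total_sensible), 1.0):
            raise ValidationError("sensible components must sum to the total")


@dataclass
class SimulationResult:
    """Trajectories at the output cadence plus final-state diagnostics."""

    scenario: Scenario
    times: np.ndarray                # (nt,)
    T: np.ndarray                    # (nt, 16, 6) degC
    T_blood: np.ndarray              # (nt,)
    breakdown: np.ndarray            # (nt, 16, 3): conv, rad, evap W/m2 skin
    max_rate_end: float              # max |dT/dt| at the final state, K/s

    @property
    def final_state(self) -> BodyState:
        return BodyState(T=self.T[-1].copy(), T_blood=float(self.T_blood[-1]),
                         t=float(self.times[-1]))

    def state_at(self, k: int) -> BodyState:
        return BodyState(T=self.T[k].copy(), T_blood=float(self.T_blood[k]),
                         t=float(self.times[k]))


def _snapshot_breakdown(scenario: Scenario, state: BodyState) -> np.ndarray:
    _, diag = evaluate_state(scenario, state)
    A = scenario.registry.A_n
    return np.stack([diag["Q_nc_conv"] / A, diag["Q_nc_rad"] / A,
                     diag["fluxes"].E_skin / A], axis=-1)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def integrate(scenario: Scenario) -> SimulationResult:
    """Advance the coupled system over the scenario duration.

    Fixed-step RK4 at ``time_step`` (default) or adaptive LSODA
    (``solver="lsoda"``); trajectories are stored at the output cadence.
    Raises :class:`IntegrationError`, naming the offending node, if the
    state leaves the sanity range.
    """
    reg = scenario.registry
    clothed = reg.clothed
    fun = _rhs(scenario)
    y0 = _pack(initial_state(reg), clothed)
    n_out = int(np.floor(scenario.duration / scenario.output_interval + 1e-9))
    t_out = np.linspace(0.0, n_out * scenario.output_interval, n_out + 1)
    if abs(t_out[-1] - scenario.duration) > 1e-9:
        t_out = np.append(t_out, scenario.duration)

    ys = [y0]
    if scenario.solver == "lsoda":
        sol = solve_ivp(fun, (0.0, scenario.duration), y0, method="LSODA",
                        t_eval=t_out, rtol=1e-8, atol=1e-8)
        if not sol.success:
            raise IntegrationError(f"LSODA failed: {sol.message}")
        ys = list(sol.y.T)
    else:
        dt = scenario.time_step
        y = y0.copy()
        t = 0.0
        next_out = 1
        n_steps = int(np.ceil(scenario.duration / dt - 1e-12))
        for k in range(n_steps):
            h = min(dt, scenario.duration - t)
            k1 = fun(t, y)
            k2 = fun(t + h / 2, y + h / 2 * k1)
            k3 = fun(t + h / 2, y + h / 2 * k2)
            k4 = fun(t + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
            if not np.all(np.isfinite(y)):
                bad = int(np.argmax(~np.isfinite(y)))
                raise IntegrationError(
                    f"non-finite state at t={t:.1f}s, state index {bad}")
            while next_out < len(t_out) and t >= t_out[next_out] - 1e-9:
                ys.append(y.copy())
                next_out += 1

    states = [_unpack(y, clothed, t) for y, t in zip(ys, t_out)]
    T = np.stack([s.T for s in states])
    Tb = np.array([s.T_blood for s in states])
    br = np.stack([_snapshot_breakdown(scenario, s) for s in states])
    return SimulationResult(scenario=scenario, times=t_out, T=T, T_blood=Tb,
                            breakdown=br, max_rate_end=_max_rate(scenario, states[-1]))


def steady_state(scenario: Scenario, pre_integrate: float = 14400.0,
                 tol: float = 1e-9) -> BodyState:
    """Steady state of the coupled system, independent of integration time.

    Integrates with LSODA to damp the transient, then polishes with a
    root-find on the full right-hand side; the result satisfies
    max |dT/dt| < ``tol`` K/s or :class:`ConvergenceError` is raised.
    """
    reg = scenario.registry
    clothed = reg.clothed
    fun = _rhs(scenario)
    y0 = _pack(initial_state(reg), clothed)
    sol = solve_ivp(fun, (0.0, pre_integrate), y0, method="LSODA",
                    rtol=1e-8, atol=1e-8)
    if not sol.success:
        raise ConvergenceError(f"pre-integration failed: {sol.message}")
    y = sol.y[:, -1]
    res = root(lambda v: fun(0.0, v), y, method="hybr", tol=1e-13)
    if res.success:
        y = res.x
    rate = float(np.max(np.abs(fun(0.0, y))))
    if rate >= tol:
        raise ConvergenceError(
            f"steady-state residual {rate:.2e} K/s exceeds {tol:.0e}")
    return _unpack(y, clothed, 0.0)


# ---------------------------------------------------------------------------
# analyses
# ---------------------------------------------------------------------------

def flux_partition(result: SimulationResult | BodyState, segment: int,
                   scenario: Scenario | None = None) -> FluxBreakdown:
    """Flux decomposition at a clothed segment at the final time.

    ``segment`` is 1-based.  Accepts a :class:`SimulationResult` or a bare
    state plus its scenario.
    """
    if isinstance(result, SimulationResult):
        scenario = result.scenario
        state = result.final_state
    else:
        if scenario is None:
            raise ValueError("flux_partition of a bare state needs its scenario")
        state = result
    k = segment - 1
    if not scenario.registry.clothed[k]:
        raise ValidationError(f"segment {segment} is bare; no gap partition")
    _, diag = evaluate_state(scenario, state)
    A = scenario.registry.A_n[k]
    conv = float(diag["Q_nc_conv"][k] / A)
    rad = float(diag["Q_nc_rad"][k] / A)
    evap = float(diag["fluxes"].E_skin[k] / A)
    total = conv + rad
    shares = ({"conductive_convective": conv / total, "radiant": rad / total}
              if total != 0.0 else
              {"conductive_convective": 0.0, "radiant": 0.0})
    return FluxBreakdown(segment=segment, conductive_convective=conv,
                         radiant=rad, evaporative=evap, total_sensible=total,
                         shares=shares)


@dataclass
class OnsetSweepResult:
    """Gap-thickness sweep: per-thickness chest Rayleigh numbers and the
    interpolated thickness (m) where Ra first crosses 10^3 (None if no
    crossing in range)."""

    thicknesses: np.ndarray
    rayleigh: np.ndarray
    onset: float | None


def convection_onset_sweep(scenario: Scenario,
                           thickness_grid) -> OnsetSweepResult:
    """Find the natural-convection onset by sweeping the air-gap thickness.

    For each thickness the full coupled steady state is computed with that
    gap applied uniformly to all clothed segments and the chest-gap
    Rayleigh number evaluated from the steady skin/inner-layer temperature
    difference; the Ra = 10^3 crossing is linearly interpolated.
    """
    grid = np.asarray(thickness_grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0.0):
        raise ValueError("thickness grid must be strictly increasing")
    ras = []
    for L in grid:
        scen = replace(scenario, garment=Garment.uniform(
            float(L), scenario.registry, scenario.garment.fabric,
            name=f"gap={L * 1000:.2f}mm"))
        st = steady_state(scen)
        dT = st.T[CHEST, 3] - st.T[CHEST, 4]
        ras.append(rayleigh_number(dT, float(L), scenario.air))
    ras = np.array(ras)
    onset = None
    above = ras > 1.0e3
    if above[0]:
        onset = float(grid[0])
    elif above.any():
        i = int(np.argmax(above))
        r0, r1 = ras[i - 1], ras[i]
        onset = float(grid[i - 1] + (1.0e3 - r0) / (r1 - r0) * (grid[i] - grid[i - 1]))
    return OnsetSweepResult(thicknesses=grid, rayleigh=ras, onset=onset)


def run_paper_experiment(registry: BodyRegistry | None = None,
                         out_dir: str | Path | None = None,
                         solver: str = "lsoda") -> dict:
    """Run all five garments (A-E) for 30 min at reference conditions.

    Returns a dict with a per-garment summary table (chest/back clothing
    temperatures, flux partitions, chest-gap Rayleigh number) and the
    qualitative pattern flags; optionally writes per-garment result tables.
    """
    registry = registry or load_default_body()
    rows = []
    results = {}
    for code in "ABCDE":
        scen = load_reference_scenario(garment=code, registry=registry,
                                       solver=solver)
        res = integrate(scen)
        results[code] = res
        st = res.final_state
        part = flux_partition(res, CHEST + 1)
        _, diag = evaluate_state(scen, st)
        rows.append({
            "garment": code,
            "gap_mm": float(scen.garment.gap[CHEST]) * 1000.0,
            "chest_skin_c": st.T[CHEST, 3],
            "chest_inner_c": st.T[CHEST, 4],
            "chest_outer_c": st.T[CHEST, 5],
            "back_inner_c": st.T[2, 4],
            "back_outer_c": st.T[2, 5],
            "chest_ra": float(diag["Ra"][CHEST]),
            "conductive_share_pct": part.shares["conductive_convective"] * 100.0,
            "radiant_share_pct": part.shares["radiant"] * 100.0,
            "total_sensible_w_m2": part.total_sensible,
        })
        if out_dir is not None:
            write_results(res, Path(out_dir) / f"garment_{code}")
    table = pd.DataFrame(rows).set_index("garment")
    inner = table["chest_inner_c"].to_numpy()
    outer = table["chest_outer_c"].to_numpy()
    pattern = {
        "inner_decreases_A_to_D": bool(np.all(np.diff(inner[:4]) < 0.0)),
        "outer_decreases_A_to_D": bool(np.all(np.diff(outer[:4]) < 0.0)),
        "rises_at_E": bool(inner[4] > inner[3] and outer[4] > outer[3]),
        "back_not_warmer_than_chest": bool(
            np.all(table["back_inner_c"] <= table["chest_inner_c"] + 1e-9)
            and np.all(table["back_outer_c"] <= table["chest_outer_c"] + 1e-9)),
    }
    if out_dir is not None:
        path = Path(out_dir)
        path.mkdir(parents=True, exist_ok=True)
        table.to_csv(path / "summary.csv", float_format="%.17g")
    return {"table": table, "pattern": pattern, "results": results}


def energy_closure(scenario: Scenario, state: BodyState) -> dict:
    """Whole-system energy bookkeeping at one state, W.

    storage (sum C dT/dt over all nodes including clothing and blood) must
    equal production - losses to round-off at any state, and vanish at
    steady state.
    """
    d, diag = evaluate_state(scenario, state)
    reg = scenario.registry
    clothed = reg.clothed
    storage = float(np.sum(reg.C * d["tissue"])
                    + reg.blood_capacity * d["blood"]
                    + np.sum(diag["C_inner"][clothed] * d["inner"][clothed])
                    + np.sum(diag["C_outer"][clothed] * d["outer"][clothed]))
    production = float(diag["fluxes"].Q.sum())
    losses = float(diag["fluxes"].RES + diag["fluxes"].E_skin.sum()
                   + diag["Q_t"][~clothed].sum() + diag["Q_a"][clothed].sum())
    return {"storage": storage, "production": production, "losses": losses,
            "residual": storage - (production - losses)}


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def write_results(result: SimulationResult, path: str | Path) -> dict:
    """Write tidy result tables with a commented metadata header.

    ``temperatures.csv``: one row per time x segment x layer;
    ``fluxes.csv``: one row per time x segment with the breakdown terms.
    Values are written at full precision so re-reading (with a round-trip
    float parser, e.g. ``pd.read_csv(..., float_precision="round_trip")``)
    reproduces them bit-exactly; identical scenarios produce identical bytes.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scen = result.scenario
    header = (f"# garment: {scen.garment.name}\n"
              f"# solver: {scen.solver} dt={scen.time_step}s\n"
              f"# config_hash: {scen.config_hash()}\n")

    nt = len(result.times)
    layers = np.arange(1, 7)
    rec = {
        "time_s": np.repeat(result.times, N_SEGMENTS * 6),
        "segment": np.tile(np.repeat(np.arange(1, N_SEGMENTS + 1), 6), nt),
        "layer": np.tile(layers, nt * N_SEGMENTS),
        "temperature_c": result.T.reshape(nt, -1).ravel(),
    }
    temps = pd.DataFrame(rec)
    flux = pd.DataFrame({
        "time_s": np.repeat(result.times, N_SEGMENTS),
        "segment": np.tile(np.arange(1, N_SEGMENTS + 1), nt),
        "conductive_convective_w_m2": result.breakdown[:, :, 0].ravel(),
        "radiant_w_m2": result.breakdown[:, :, 1].ravel(),
        "evaporative_w_m2": result.breakdown[:, :, 2].ravel(),
    })
    out = {}
    for name, df in (("temperatures.csv", temps), ("fluxes.csv", flux)):
        target = path / name
        with open(target, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False, float_format="%.17g", lineterminator="\n")
        out[name] = target
    return out
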